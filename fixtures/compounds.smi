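# Chalcone and diarylpentanoid structures transcribed from the systematic
# names in the synthesis section of the source study (one SMILES<TAB>id per
# line).  Compounds 3, 5, 6, 8, 9, 11, 13 and 15 are only characterized in
# the study's appendix; their A-ring substitution pattern follows the series
# logic (unsubstituted / 4,5- or 6,7-dimethoxy / 5,6-dimethoxy) and is an
# assumption documented in the repository notes.
CCCc1c(OC)ccc(C(=O)/C=C/c2cc(OC)c(OC)c(OC)c2)c1O	1
O=C1C(=Cc2ccc(Cl)cc2)COCC1=Cc1ccc(Cl)cc1	2
O=C1c2ccccc2CC1=Cc1cc(OC)c(OC)c(OC)c1	3
O=C1c2ccc(OC)c(OC)c2CC1=Cc1cc(OC)c(OC)c(OC)c1	4
O=C1c2cc(OC)c(OC)cc2CC1=Cc1cc(OC)c(OC)c(OC)c1	5
O=C1c2ccccc2CC1=Cc1ccc(Cl)cc1	6
O=C1c2ccc(OC)c(OC)c2CC1=Cc1ccc(Cl)cc1	7
O=C1c2cc(OC)c(OC)cc2CC1=Cc1ccc(Cl)cc1	8
O=C1c2ccccc2CCC1=Cc1cc(OC)c(OC)c(OC)c1	9
O=C1c2cc(OC)c(OC)cc2CCC1=Cc1cc(OC)c(OC)c(OC)c1	10
O=C1c2ccc(OC)c(OC)c2CCC1=Cc1cc(OC)c(OC)c(OC)c1	11
O=C1c2ccccc2SCC1=Cc1cc(OC)c(OC)c(OC)c1	12
O=C1c2ccccc2CCC1=Cc1ccc(Cl)cc1	13
O=C1c2cc(OC)c(OC)cc2CCC1=Cc1ccc(Cl)cc1	14
O=C1c2ccc(OC)c(OC)c2CCC1=Cc1ccc(Cl)cc1	15
O=C1c2ccccc2SCC1=Cc1ccc(Cl)cc1	16
O=C(/C=C/c1ccc(Cl)cc1)/C=C/c1ccc(Cl)cc1	17
O=C1C(=Cc2ccc(Cl)cc2)CCC1=Cc1ccc(Cl)cc1	18
O=C1C(=Cc2ccc(Cl)cc2)CCCC1=Cc1ccc(Cl)cc1	19
O=C1C(=Cc2ccc(Cl)cc2)CSCC1=Cc1ccc(Cl)cc1	20
O=C(/C=C/c1cc(OC)c(OC)c(OC)c1)/C=C/c1cc(OC)c(OC)c(OC)c1	21
O=C1C(=Cc2cc(OC)c(OC)c(OC)c2)CCC1=Cc1cc(OC)c(OC)c(OC)c1	22
O=C1C(=Cc2cc(OC)c(OC)c(OC)c2)CCCC1=Cc1cc(OC)c(OC)c(OC)c1	23
O=C1C(=Cc2cc(OC)c(OC)c(OC)c2)CSCC1=Cc1cc(OC)c(OC)c(OC)c1	24
CCCc1c(OC)ccc(C(C)=O)c1O	25
CCCc1c(OC)ccc(C(=O)/C=C/c2cc(OC)c(OC)c(OC)c2)c1OCC=C(C)C	26
O=C1C=C(c2cc(OC)c(OC)c(OC)c2)Oc2c(CCC)c(OC)ccc21	27
OC(/C=C/c1cc(OC)c(OC)c(OC)c1)c1ccc(OC)c(CCC)c1O	28
CCCc1c(OC)ccc(C(=O)CCc2cc(OC)c(OC)c(OC)c2)c1O	29
OC1C(=Cc2ccc(Cl)cc2)COCC1=Cc1ccc(Cl)cc1	30
O=C1C(Cc2ccc(Cl)cc2)COCC1Cc1ccc(Cl)cc1	31
CCCc1c(OC)ccc(C(=O)/C=C/c2ccc(Cl)cc2)c1O	32
CCCc1c(OC)ccc(C(=O)/C=C/c2ccc(F)cc2)c1O	33
CCCc1c(OC)ccc(C(=O)/C=C/c2ccc(Br)cc2)c1O	34
CCCc1c(OC)ccc(C(=O)/C=C/c2ccc(N(C)C)cc2)c1O	35
CCCc1c(OC)ccc(C(=O)/C=C/c2ccc(N3CCOCC3)cc2)c1O	36
O=C1C(=Cc2ccccc2OCC=C(C)C)COCC1=Cc1ccccc1OCC=C(C)C	38
O=C1C(=Cc2ccc(OCC=C(C)C)cc2)COCC1=Cc1ccc(OCC=C(C)C)cc1	40
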
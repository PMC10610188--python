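# GI50 values (uM) transcribed from the activity table and results text of
# the source study.  Only individually printed values are included; values
# given there only as ranges are omitted.  The HFF-1 entry for compound 17
# is back-derived from its printed selectivity index SI2 = 12.43 times the
# printed HCT116 p53+/+ GI50 (2.18 uM), i.e. 27.10 uM, which the same text
# corroborates as "12-fold higher".  ">30" marks censoring at the assay
# ceiling.
compound_id,cell_line,gi50_um
1,HCT116_p53_wt,2.6
12,HCT116_p53_wt,5.7
16,HCT116_p53_wt,0.69
17,HCT116_p53_wt,2.18
17,HFF1,27.10
18,HCT116_p53_wt,>30
20,HCT116_p53_wt,1.13
21,HCT116_p53_wt,>30
22,HCT116_p53_wt,0.09
23,HCT116_p53_wt,2.3
24,HCT116_p53_wt,0.31
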
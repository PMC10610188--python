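"""End-to-end orchestration: structures -> descriptors -> model -> validation.

Every artifact is written with sorted JSON keys and no timestamps, so a rerun
with the same configuration produces byte-identical reports.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .activity import load_activity_table
from .chem import add_hydrogens, read_molfile, read_smiles_file
from .descriptors import DescriptorConfig, compute_descriptor_vector
from .qsar import (
    DescriptorMatrix,
    HeuristicConfig,
    assemble_matrix,
    external_validate,
    fit_ols,
    heuristic_search,
    loo_q2,
    prefilter,
)
from .tables import read_descriptor_csv, write_descriptor_csv

log = logging.getLogger("chalqsar.pipeline")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    structures: str = ""  # .sdf/.mol or .smi; or a ready descriptor CSV
    descriptors_csv: str = ""
    activity: str = ""
    cell_line: str = "HCT116_p53_wt"
    out_dir: str = "out"
    heuristic: HeuristicConfig = field(default_factory=HeuristicConfig)
    descriptor_config: DescriptorConfig = field(default_factory=DescriptorConfig)
    test_size: int = 0  # 0 = no external split
    log_level: str = "INFO"

    @staticmethod
    def from_dict(raw: dict) -> "PipelineConfig":
        cfg = PipelineConfig()
        for key in ("structures", "descriptors_csv", "activity", "cell_line", "out_dir", "log_level"):
            if key in raw:
                setattr(cfg, key, raw[key])
        cfg.test_size = int(raw.get("test_size", 0))
        if "heuristic" in raw:
            cfg.heuristic = HeuristicConfig(**raw["heuristic"])
        if "descriptors" in raw:
            cfg.descriptor_config = DescriptorConfig(**raw["descriptors"])
        return cfg

    def echo(self) -> dict:
        return {
            "structures": self.structures,
            "descriptors_csv": self.descriptors_csv,
            "activity": self.activity,
            "cell_line": self.cell_line,
            "test_size": self.test_size,
            "heuristic": asdict(self.heuristic),
            "descriptors": asdict(self.descriptor_config),
        }


def load_structures(path: str | Path):
    """Read .sdf/.mol or .smi into hydrogen-explicit molecules."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in (".sdf", ".mol"):
        mols = read_molfile(text)
    else:
        mols = read_smiles_file(text.splitlines())
    out = []
    for i, mol in enumerate(mols):
        if not mol.name:
            mol.name = f"mol{i + 1}"
        out.append(add_hydrogens(mol))
    return out


def compute_descriptor_matrix(mols, cfg: DescriptorConfig) -> DescriptorMatrix:
    vectors = [compute_descriptor_vector(m, cfg) for m in mols]
    return assemble_matrix(vectors, [m.name for m in mols])


def split_train_test(ids: list[str], test_size: int, seed: int):
    """Seeded uniform draw of test compounds (recorded in the report)."""
    if test_size <= 0:
        return list(ids), []
    rng = np.random.default_rng(seed)
    test_idx = sorted(rng.choice(len(ids), size=test_size, replace=False).tolist())
    test = [ids[i] for i in test_idx]
    train = [c for c in ids if c not in test]
    return train, test


def _dump_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run the full pipeline; returns the model report dict.

    Writes descriptors.csv, model.json, validation.json and run.log under
    the configured output directory.  Deterministic given the config
    (including the heuristic seed).
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("chalqsar")
    root.addHandler(handler)
    root.setLevel(cfg.log_level)
    try:
        stage = "descriptors"
        try:
            if cfg.descriptors_csv:
                matrix = read_descriptor_csv(Path(cfg.descriptors_csv).read_text())
            else:
                mols = load_structures(cfg.structures)
                matrix = compute_descriptor_matrix(mols, cfg.descriptor_config)
            (out / "descriptors.csv").write_text(write_descriptor_csv(matrix))
        except Exception as exc:
            raise PipelineError(stage, exc) from exc

        stage = "activity"
        try:
            table = load_activity_table(
                Path(cfg.activity).read_text().splitlines()
            )
            pgi = table.pgi50_map()
            usable = [
                c
                for c in matrix.compound_ids
                if (c, cfg.cell_line) in pgi
            ]
            if not usable:
                raise ValueError(
                    f"no compounds with uncensored {cfg.cell_line} activity"
                )
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(stage, exc) from exc

        stage = "fit"
        try:
            train_ids, test_ids = split_train_test(
                usable, cfg.test_size, cfg.heuristic.seed
            )
            sub = DescriptorMatrix(
                data=matrix.data.loc[train_ids], classes=dict(matrix.classes)
            )
            y_train = np.array([pgi[(c, cfg.cell_line)] for c in sub.compound_ids])
            filtered, elim_log = prefilter(sub, y_train, cfg.heuristic)
            ranked = heuristic_search(filtered, y_train, cfg.heuristic)
            best = ranked[0]
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(stage, exc) from exc

        stage = "validate"
        try:
            X_train = filtered.subset(best.term_names)
            report_val = loo_q2(X_train, y_train, best)
            best.q2_loo = report_val.q2
            best.press = report_val.press
            external_mad = None
            if test_ids:
                test_matrix = DescriptorMatrix(
                    data=matrix.data.loc[test_ids], classes=dict(matrix.classes)
                )
                y_test = np.array(
                    [pgi[(c, cfg.cell_line)] for c in test_matrix.compound_ids]
                )
                external_mad = external_validate(best, test_matrix, y_test)
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(stage, exc) from exc

        model_report = best.to_dict()
        model_report.update(
            {
                "external_mad": external_mad,
                "config": cfg.echo(),
                "elimination_log": elim_log,
                "train_ids": train_ids,
                "test_ids": test_ids,
            }
        )
        _dump_json(model_report, out / "model.json")
        _dump_json(
            {
                "press": report_val.press,
                "q2": report_val.q2,
                "r2": report_val.r2,
                "external_mad": external_mad,
                "overfit_ok": report_val.overfit_ok,
            },
            out / "validation.json",
        )
        log.info("pipeline complete: %d train, %d test", len(train_ids), len(test_ids))
        return model_report
    finally:
        root.removeHandler(handler)
        handler.close()
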
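"""Heuristic multilinear-regression model building and validation.

The workflow mirrors the classic heuristic method: prefilter the descriptor
pool (drop missing, near-constant, pairwise-collinear, and insignificant
columns), then grow multilinear models by a deterministic forward beam
search capped at one descriptor per five training molecules, and validate
with leave-one-out PRESS/Q2 plus an external test-set deviation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import t as student_t

from .descriptors.vector import DescriptorVector

__all__ = [
    "DescriptorMatrix",
    "QsarModel",
    "HeuristicConfig",
    "ValidationReport",
    "assemble_matrix",
    "prefilter",
    "fit_ols",
    "f_statistic",
    "loo_q2",
    "heuristic_search",
    "external_validate",
    "predict_eq1",
    "PUBLISHED_MODEL",
    "QsarError",
]


class QsarError(ValueError):
    pass


@dataclass
class DescriptorMatrix:
    """Compounds x descriptors table; NaN marks MISSING values."""

    data: pd.DataFrame
    classes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.data.columns.duplicated().any():
            raise QsarError("duplicate descriptor names")
        if self.data.index.duplicated().any():
            raise QsarError("duplicate compound ids")
        # canonical column order keeps the search invariant to column input
        # order; row order is preserved because y vectors align with it
        self.data = self.data.sort_index(axis=1)

    @property
    def compound_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def descriptor_names(self) -> list[str]:
        return list(self.data.columns)

    def subset(self, names: Sequence[str]) -> np.ndarray:
        return self.data.loc[:, list(names)].to_numpy(dtype=float)


def assemble_matrix(
    vectors: Sequence[DescriptorVector], ids: Sequence[str]
) -> DescriptorMatrix:
    """Union of descriptor names over all vectors, MISSING preserved as NaN."""
    if len(vectors) == 0:
        raise QsarError("no descriptor vectors given")
    if len(vectors) != len(ids):
        raise QsarError("ids and vectors have different lengths")
    if len(set(ids)) != len(ids):
        raise QsarError("duplicate compound ids")
    rows = []
    classes: dict[str, str] = {}
    for vec in vectors:
        rows.append({k: (np.nan if v is None else v) for k, v in vec.values.items()})
        classes.update(vec.classes)
    frame = pd.DataFrame(rows, index=list(ids), dtype=float)
    return DescriptorMatrix(data=frame, classes=classes)


@dataclass
class HeuristicConfig:
    variance_min: float = 1e-8
    alpha_single: float = 0.10
    r_max_pair: float = 0.80
    beam_width: int = 10
    max_terms: Optional[int] = None  # None -> floor(n/5) rule
    seed: int = 0  # used only for train/test splitting

    def __post_init__(self) -> None:
        if not 0 < self.alpha_single < 1:
            raise QsarError("alpha_single must be in (0, 1)")
        if not 0 < self.r_max_pair < 1:
            raise QsarError("r_max_pair must be in (0, 1)")
        if self.beam_width < 1:
            raise QsarError("beam_width must be >= 1")

    def term_cap(self, n: int) -> int:
        return self.max_terms if self.max_terms is not None else max(n // 5, 1)


@dataclass
class QsarModel:
    intercept: float
    intercept_se: float
    terms: list[tuple[str, float, float]]  # (descriptor, coefficient, std error)
    n: int
    m: int
    r2: float
    f_stat: float
    s2: float
    q2_loo: Optional[float] = None
    press: Optional[float] = None

    @property
    def term_names(self) -> tuple[str, ...]:
        return tuple(name for name, _, _ in self.terms)

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        coefs = np.array([c for _, c, _ in self.terms])
        return self.intercept + X @ coefs

    def predict_frame(self, matrix: DescriptorMatrix) -> np.ndarray:
        for name in self.term_names:
            if name not in matrix.data.columns:
                raise QsarError(f"descriptor {name!r} absent from matrix")
        return self.predict(matrix.subset(self.term_names))

    def to_dict(self) -> dict:
        return {
            "intercept": self.intercept,
            "intercept_se": self.intercept_se,
            "terms": [
                {"name": name, "coef": coef, "se": se} for name, coef, se in self.terms
            ],
            "n": self.n,
            "m": self.m,
            "r2": self.r2,
            "f": self.f_stat,
            "s2": self.s2,
            "q2": self.q2_loo,
            "press": self.press,
        }


@dataclass
class ValidationReport:
    press: float
    q2: float
    r2: float
    external_mad: Optional[float] = None

    @property
    def overfit_ok(self) -> bool:
        return self.q2 > 0.5 and (self.r2 - self.q2) < 0.3


# ---------------------------------------------------------------------------
# Prefiltering
# ---------------------------------------------------------------------------


def _t_test_p_single(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided p-value of the slope t-test in the one-descriptor model."""
    n = len(y)
    model = _ols(x[:, None], y)
    if model.r2 >= 1.0 - 1e-14:
        return 0.0
    _, coef, se = model.terms[0]
    if se == 0:
        return 1.0
    return 2.0 * float(student_t.sf(abs(coef / se), n - 2))


def prefilter(
    X: DescriptorMatrix, y: Sequence[float], cfg: HeuristicConfig
) -> tuple[DescriptorMatrix, list[dict]]:
    """Heuristic descriptor preselection.

    Drops, in order: columns with any MISSING value; columns with variance
    below ``variance_min``; of each pair correlated above |r| = 0.99 the one
    less correlated with y (lexicographic tie-break); columns whose
    one-descriptor regression fails the slope t-test at ``alpha_single``.
    Returns the reduced matrix and an elimination log.
    """
    y = np.asarray(y, dtype=float)
    if len(y) != len(X.compound_ids):
        raise QsarError("y length does not match matrix rows")
    frame = X.data
    log: list[dict] = []
    keep = list(frame.columns)

    dropped = [c for c in keep if frame[c].isna().any()]
    for c in dropped:
        log.append({"descriptor": c, "reason": "missing_values"})
    keep = [c for c in keep if c not in dropped]

    dropped = [c for c in keep if float(frame[c].var(ddof=1)) < cfg.variance_min]
    for c in dropped:
        log.append({"descriptor": c, "reason": "low_variance"})
    keep = [c for c in keep if c not in dropped]

    # pairwise near-duplicates: keep the member more correlated with y
    def corr_y(c: str) -> float:
        v = frame[c].to_numpy(dtype=float)
        sd = v.std()
        if sd == 0 or y.std() == 0:
            return 0.0
        return abs(float(np.corrcoef(v, y)[0, 1]))

    removed: set[str] = set()
    for i, ci in enumerate(keep):
        if ci in removed:
            continue
        for cj in keep[i + 1 :]:
            if cj in removed:
                continue
            r = float(np.corrcoef(frame[ci], frame[cj])[0, 1])
            if abs(r) > 0.99:
                ri, rj = corr_y(ci), corr_y(cj)
                # tie -> lexicographically first survives
                loser = cj if (rj < ri or (rj == ri and cj > ci)) else ci
                removed.add(loser)
                log.append(
                    {"descriptor": loser, "reason": "pairwise_collinear", "with": cj if loser == ci else ci}
                )
                if loser == ci:
                    break
    keep = [c for c in keep if c not in removed]

    dropped = []
    for c in keep:
        p = _t_test_p_single(frame[c].to_numpy(dtype=float), y)
        if p > cfg.alpha_single:
            dropped.append(c)
            log.append({"descriptor": c, "reason": "insignificant", "p": p})
    keep = [c for c in keep if c not in dropped]

    if not keep:
        raise QsarError("all descriptors eliminated by prefiltering")
    return DescriptorMatrix(data=frame.loc[:, keep], classes=dict(X.classes)), log


# ---------------------------------------------------------------------------
# OLS fitting and validation statistics
# ---------------------------------------------------------------------------


def _ols(X: np.ndarray, y: np.ndarray, names: Optional[Sequence[str]] = None) -> QsarModel:
    n, m = X.shape
    if n <= m + 1:
        raise QsarError(f"need n > m + 1 (n={n}, m={m})")
    design = np.column_stack([np.ones(n), X])
    gram = design.T @ design
    if np.linalg.matrix_rank(gram) < m + 1:
        raise QsarError("singular design matrix (rank-deficient descriptors)")
    beta = np.linalg.solve(gram, design.T @ y)
    resid = y - design @ beta
    sse = float(resid @ resid)
    sst = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - sse / sst if sst > 0 else 1.0
    dof = n - m - 1
    s2 = sse / dof
    cov = s2 * np.linalg.inv(gram)
    se = np.sqrt(np.diag(cov))
    names = list(names) if names is not None else [f"x{i}" for i in range(m)]
    return QsarModel(
        intercept=float(beta[0]),
        intercept_se=float(se[0]),
        terms=[(names[i], float(beta[i + 1]), float(se[i + 1])) for i in range(m)],
        n=n,
        m=m,
        r2=r2,
        f_stat=f_statistic(r2, n, m),
        s2=s2,
    )


def fit_ols(
    X_sub: np.ndarray | DescriptorMatrix,
    y: Sequence[float],
    names: Optional[Sequence[str]] = None,
) -> QsarModel:
    """Least-squares multilinear fit with per-coefficient standard errors."""
    if isinstance(X_sub, DescriptorMatrix):
        names = X_sub.descriptor_names
        X_sub = X_sub.subset(names)
    X = np.asarray(X_sub, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    return _ols(X, np.asarray(y, dtype=float), names=names)


def f_statistic(r2: float, n: int, m: int) -> float:
    """F = [R2/(1-R2)] * [(n-m-1)/m]."""
    if not 0 <= r2 <= 1:
        raise QsarError(f"R2 out of range: {r2}")
    if n <= m + 1:
        raise QsarError("need n > m + 1")
    if r2 >= 1.0:
        return math.inf
    return (r2 / (1.0 - r2)) * ((n - m - 1) / m)


def loo_q2(
    X_sub: np.ndarray, y: Sequence[float], model: Optional[QsarModel] = None
) -> ValidationReport:
    """Leave-one-out PRESS and Q2 via the hat-matrix shortcut.

    PRESS = sum_i (e_i / (1 - h_ii))^2 where h_ii are the leverages of the
    design including the intercept; Q2 = 1 - PRESS/SST.
    """
    X = np.asarray(X_sub, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y, dtype=float)
    if model is None:
        model = fit_ols(X, y)
    design = np.column_stack([np.ones(len(y)), X])
    hat = design @ np.linalg.solve(design.T @ design, design.T)
    h = np.diag(hat)
    bad = np.where(h > 1.0 - 1e-10)[0]
    if bad.size:
        raise QsarError(f"leverage 1 at rows {bad.tolist()}: LOO prediction undefined")
    resid = y - model.predict(X)
    press = float(((resid / (1.0 - h)) ** 2).sum())
    sst = float(((y - y.mean()) ** 2).sum())
    q2 = 1.0 - press / sst
    return ValidationReport(press=press, q2=q2, r2=model.r2)


def external_validate(
    model: QsarModel, X_test: np.ndarray | DescriptorMatrix, y_test: Sequence[float]
) -> float:
    """Mean absolute deviation of the model's predictions on a test set."""
    if isinstance(X_test, DescriptorMatrix):
        pred = model.predict_frame(X_test)
    else:
        pred = model.predict(np.asarray(X_test, dtype=float))
    y_test = np.asarray(y_test, dtype=float)
    return float(np.mean(np.abs(pred - y_test)))


# ---------------------------------------------------------------------------
# Forward beam search
# ---------------------------------------------------------------------------


def _rank_key(model: QsarModel) -> tuple:
    # rounding keeps the ordering stable under row-permutation float noise
    return (-round(model.r2, 12), -round(model.f_stat, 9), model.term_names)


def heuristic_search(
    X: DescriptorMatrix, y: Sequence[float], cfg: HeuristicConfig
) -> list[QsarModel]:
    """Deterministic forward beam search over descriptor subsets.

    Seeds the beam with the best single-descriptor models, extends each beam
    member with every descriptor whose pairwise |r| with all included
    descriptors is <= ``r_max_pair``, keeps the ``beam_width`` best per
    size, and grows to the floor(n/5) term cap.  Returns every explored
    beam model ranked by R2, then F, then lexicographic term names.
    """
    y = np.asarray(y, dtype=float)
    names = X.descriptor_names
    if not names:
        raise QsarError("empty descriptor pool")
    if len(y) != len(X.compound_ids):
        raise QsarError("y length does not match matrix rows")
    cols = {c: X.data[c].to_numpy(dtype=float) for c in names}
    max_terms = cfg.term_cap(len(y))

    corr_cache: dict[tuple[str, str], float] = {}

    def pair_ok(a: str, b: str) -> bool:
        key = (a, b) if a < b else (b, a)
        if key not in corr_cache:
            corr_cache[key] = abs(float(np.corrcoef(cols[key[0]], cols[key[1]])[0, 1]))
        return corr_cache[key] <= cfg.r_max_pair

    def fit(subset: tuple[str, ...]) -> Optional[QsarModel]:
        mat = np.column_stack([cols[c] for c in subset])
        try:
            return _ols(mat, y, names=subset)
        except QsarError:
            return None

    all_models: dict[tuple[str, ...], QsarModel] = {}
    beam: list[QsarModel] = []
    for c in names:
        model = fit((c,))
        if model is not None:
            all_models[(c,)] = model
    beam = sorted(all_models.values(), key=_rank_key)[: cfg.beam_width]

    for _size in range(2, max_terms + 1):
        candidates: dict[tuple[str, ...], QsarModel] = {}
        for model in beam:
            included = model.term_names
            for c in names:
                if c in included:
                    continue
                if not all(pair_ok(c, inc) for inc in included):
                    continue
                subset = tuple(sorted(included + (c,)))
                if subset in all_models or subset in candidates:
                    continue
                fitted = fit(subset)
                if fitted is not None:
                    candidates[subset] = fitted
        if not candidates:
            break
        all_models.update(candidates)
        beam = sorted(candidates.values(), key=_rank_key)[: cfg.beam_width]

    ranked = sorted(all_models.values(), key=_rank_key)
    return ranked


# ---------------------------------------------------------------------------
# The published five-descriptor model
# ---------------------------------------------------------------------------

#: Published multilinear model: intercept and (coefficient, std error) per
#: descriptor, on raw descriptor scales; fit statistics n=25, R2=0.7217,
#: F=9.85, S2=0.1029, Q2=0.6650.
PUBLISHED_MODEL = {
    "intercept": (-0.9136, 1.7354),
    "ABIC2": (-3.0874, 1.2789),
    "RNSA": (13.643, 8.1444),
    "XYS/XYR": (4.6709, 1.7685),
    "WPSA-2-W-PPSA": (1.0132e-3, 4.5879e-4),
    "MPCO": (5.6120, 4.6556),
}

PUBLISHED_MODEL_STATS = {"n": 25, "r2": 0.7217, "f": 9.85, "s2": 0.1029, "q2": 0.6650}


def predict_eq1(d: DescriptorVector | dict) -> float:
    """Evaluate the published five-descriptor model on one descriptor vector.

    All five descriptors must be present (not MISSING); otherwise raises
    listing the absent ones.
    """
    values = d.values if isinstance(d, DescriptorVector) else d
    needed = [k for k in PUBLISHED_MODEL if k != "intercept"]
    absent = [k for k in needed if values.get(k) is None]
    if absent:
        raise QsarError(f"missing descriptors for published model: {absent}")
    out = PUBLISHED_MODEL["intercept"][0]
    for k in needed:
        out += PUBLISHED_MODEL[k][0] * float(values[k])
    return out
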
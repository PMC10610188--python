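"""GI50 activity tables, pGI50 conversion, and selectivity indices.

GI50 values are in micromolar; pGI50 = 6 - log10(GI50/uM), i.e. the negative
decadic log of the molar concentration.  A value reported only as a bound
("">30"") is stored with a censoring flag and excluded from model training by
default.  Selectivity indices are GI50 fold-ratios of a reference line over
the p53 wild-type cancer line:

* SI1 = GI50(HCT116 p53-/-) / GI50(HCT116 p53+/+)
* SI2 = GI50(HFF-1) / GI50(HCT116 p53+/+)
"""

from __future__ import annotations

import csv
import io
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional

log = logging.getLogger(__name__)

CELL_LINES = ("HCT116_p53_wt", "HCT116_p53_null", "HFF1")


class ActivityError(ValueError):
    pass


@dataclass(frozen=True)
class ActivityRecord:
    compound_id: str
    cell_line: str
    gi50: float  # uM; the bound when censored
    censored: bool = False

    def __post_init__(self) -> None:
        if self.gi50 <= 0:
            raise ActivityError(f"GI50 must be positive, got {self.gi50}")


def pgi50(gi50_um: float) -> float:
    """pGI50 = 6 - log10(GI50 in uM) = -log10(GI50 in mol/L)."""
    if gi50_um <= 0:
        raise ActivityError(f"GI50 must be positive, got {gi50_um}")
    return 6.0 - math.log10(gi50_um)


def selectivity_index(gi50_reference: float, gi50_cancer: float) -> float:
    """Fold selectivity: reference-line GI50 over cancer-line GI50."""
    if gi50_reference <= 0 or gi50_cancer <= 0:
        raise ActivityError("GI50 values must be positive")
    return gi50_reference / gi50_cancer


@dataclass
class PotencyTable:
    records: list[ActivityRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen = set()
        for r in self.records:
            key = (r.compound_id, r.cell_line)
            if key in seen:
                raise ActivityError(f"duplicate record for {key}")
            seen.add(key)

    def get(self, compound_id: str, cell_line: str) -> Optional[ActivityRecord]:
        for r in self.records:
            if r.compound_id == compound_id and r.cell_line == cell_line:
                return r
        return None

    def pgi50_map(self, include_censored: bool = False) -> dict[tuple[str, str], float]:
        return {
            (r.compound_id, r.cell_line): pgi50(r.gi50)
            for r in self.records
            if include_censored or not r.censored
        }

    def selectivity(self, compound_id: str, reference_line: str) -> Optional[dict]:
        """SI of *compound_id* with the given reference line over
        HCT116_p53_wt; flagged as a lower bound if the reference is
        censored.  None when either record is absent."""
        ref = self.get(compound_id, reference_line)
        cancer = self.get(compound_id, "HCT116_p53_wt")
        if ref is None or cancer is None:
            return None
        si = selectivity_index(ref.gi50, cancer.gi50)
        return {"si": si, "lower_bound": ref.censored, "cancer_censored": cancer.censored}

    def training_ids(self, cell_line: str = "HCT116_p53_wt") -> list[str]:
        """Compound ids with an uncensored measurement on *cell_line*."""
        return sorted(
            r.compound_id
            for r in self.records
            if r.cell_line == cell_line and not r.censored
        )


def _parse_gi50(raw: str) -> tuple[float, bool]:
    raw = raw.strip()
    if raw.startswith(">"):
        return float(raw[1:]), True
    return float(raw), False


def load_activity_table(stream: Iterable[str]) -> PotencyTable:
    """Read a CSV with header ``compound_id,cell_line,gi50_um``.

    GI50 cells are numeric or ``>x`` (censored at the bound x).  Lines
    starting with ``#`` are comments.  Duplicate (compound, line) keys and
    unparseable values are rejected with the offending line number.
    """
    lines = [l for l in stream]
    rows = [
        (n, l) for n, l in enumerate(lines, start=1) if l.strip() and not l.lstrip().startswith("#")
    ]
    if not rows:
        log.warning("empty activity table")
        return PotencyTable()
    header = next(csv.reader([rows[0][1]]))
    expected = ["compound_id", "cell_line", "gi50_um"]
    if [h.strip() for h in header] != expected:
        raise ActivityError(f"expected header {expected}, got {header}")
    records = []
    for lineno, line in rows[1:]:
        fields = next(csv.reader([line]))
        if len(fields) != 3:
            raise ActivityError(f"line {lineno}: expected 3 fields, got {len(fields)}")
        cid, cell_line, raw = (f.strip() for f in fields)
        try:
            gi50, censored = _parse_gi50(raw)
        except ValueError as exc:
            raise ActivityError(f"line {lineno}: cannot parse GI50 {raw!r}") from exc
        try:
            records.append(ActivityRecord(cid, cell_line, gi50, censored))
        except ActivityError as exc:
            raise ActivityError(f"line {lineno}: {exc}") from exc
    return PotencyTable(records=records)


def dump_activity_table(table: PotencyTable) -> str:
    """CSV round-trip partner of :func:`load_activity_table`."""
    buf = io.StringIO()
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow(["compound_id", "cell_line", "gi50_um"])
    for r in table.records:
        raw = f">{r.gi50:g}" if r.censored else f"{r.gi50:g}"
        writer.writerow([r.compound_id, r.cell_line, raw])
    return buf.getvalue()
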
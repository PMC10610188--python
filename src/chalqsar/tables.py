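"""CSV serialization of descriptor matrices (empty cell = MISSING)."""

from __future__ import annotations

import io
from typing import Iterable

import pandas as pd

from .descriptors.vector import descriptor_catalogue
from .qsar import DescriptorMatrix


def write_descriptor_csv(matrix: DescriptorMatrix) -> str:
    frame = matrix.data.copy()
    frame.insert(0, "compound_id", frame.index)
    buf = io.StringIO()
    frame.to_csv(buf, index=False, lineterminator="\n", float_format="%.10g")
    return buf.getvalue()


def read_descriptor_csv(stream: Iterable[str] | str) -> DescriptorMatrix:
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    frame = pd.read_csv(stream, comment="#")
    if "compound_id" not in frame.columns:
        raise ValueError("descriptor CSV must have a compound_id column")
    frame["compound_id"] = frame["compound_id"].astype(str)
    frame = frame.set_index("compound_id")
    frame.index.name = None
    catalogue = descriptor_catalogue()
    classes = {c: catalogue.get(c, "unknown") for c in frame.columns}
    return DescriptorMatrix(data=frame.astype(float), classes=classes)
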
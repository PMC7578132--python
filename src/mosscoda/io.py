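"""Reading and writing concentration tables.

The on-disk dialect is a plain CSV with one header row: ``sample_id``,
``park``, ``site_class`` (``lowland`` | ``mountain``), then one column per
element in mg/kg dry weight.  Censored (below-detection-limit) cells are
encoded as the literal token ``<DL``; a companion two-column CSV
(``element,detection_limit``) supplies the limits used by multiplicative
replacement.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["ConcentrationTable", "read_concentration_table", "read_detection_limits"]

META_COLUMNS = ("park", "site_class")
NONDETECT_TOKEN = "<DL"


@dataclass
class ConcentrationTable:
    """A samples x elements concentration matrix with sample metadata.

    ``values`` holds floats with NaN at censored cells; ``nondetect`` is the
    censoring mask; ``meta`` carries ``park`` and ``site_class`` indexed by
    sample id, aligned with ``values.index``.
    """

    values: pd.DataFrame
    meta: pd.DataFrame
    nondetect: pd.DataFrame = field(default=None)

    def __post_init__(self):
        if self.nondetect is None:
            self.nondetect = self.values.isna()
        if not self.values.index.equals(self.meta.index):
            raise ValueError("values and meta must share the sample index")

    @property
    def elements(self) -> list:
        return list(self.values.columns)

    @property
    def site_class(self) -> pd.Series | None:
        if "site_class" in self.meta.columns and self.meta["site_class"].notna().any():
            return self.meta["site_class"]
        return None

    def to_csv(self, path) -> None:
        out = self.meta.reindex(columns=list(META_COLUMNS)).copy()
        vals = self.values.copy().astype(object)
        vals[self.nondetect] = NONDETECT_TOKEN
        out = pd.concat([out, vals], axis=1)
        out.index.name = "sample_id"
        out.to_csv(path)


def read_concentration_table(path) -> ConcentrationTable:
    """Read the CSV dialect described in the module docstring."""
    raw = pd.read_csv(path, index_col="sample_id", dtype=str)
    missing_meta = [c for c in META_COLUMNS if c not in raw.columns]
    meta = raw.reindex(columns=list(META_COLUMNS))
    element_cols = [c for c in raw.columns if c not in META_COLUMNS]
    if not element_cols:
        raise ValueError(f"no element columns found in {path}")
    block = raw[element_cols]
    nondetect = block.apply(lambda c: c.str.strip() == NONDETECT_TOKEN)
    # Python's float() is correctly rounded, so written tables round-trip
    # bit-exactly (pd.to_numeric can be off by one ulp).
    values = block.mask(nondetect).apply(
        lambda c: c.map(lambda v: float(v) if isinstance(v, str) else np.nan)
    )
    if missing_meta:
        for c in missing_meta:
            meta[c] = pd.NA
    return ConcentrationTable(values=values, meta=meta, nondetect=nondetect)


def read_detection_limits(path) -> pd.Series:
    """Read a two-column ``element,detection_limit`` CSV into a Series."""
    df = pd.read_csv(path)
    if not {"element", "detection_limit"}.issubset(df.columns):
        raise ValueError("detection-limit CSV needs element and detection_limit columns")
    s = df.set_index("element")["detection_limit"].astype(float)
    if (s <= 0).any() or not np.isfinite(s).all():
        raise ValueError("detection limits must be positive and finite")
    return s


def checksum(path) -> str:
    """SHA-256 of a file, for run manifests."""
    import hashlib

    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
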
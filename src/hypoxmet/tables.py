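"""Samples x metabolites concentration table with missing-value support.

Missing (below-detection) entries are stored as NaN in ``data``; the optional
``sub_detection`` frame carries the tiny residual trace levels used when
rendering spectra, so that "undetectable" means "below the limit", not
"absent from the sample".
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

META_COLUMNS = ("condition", "time_point", "replicate")


class ConcentrationTable:
    def __init__(
        self,
        data: pd.DataFrame,
        meta: pd.DataFrame,
        sub_detection: pd.DataFrame | None = None,
    ):
        if not data.index.equals(meta.index):
            raise ValueError("data and meta must share a sample index")
        for col in META_COLUMNS:
            if col not in meta.columns:
                raise ValueError(f"meta missing column {col!r}")
        self.data = data
        self.meta = meta
        self.sub_detection = sub_detection

    # ---------------------------------------------------------------- views

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.index

    @property
    def metabolites(self) -> list[str]:
        return list(self.data.columns)

    def subset(self, condition: str | None = None, time_point: int | None = None) -> "ConcentrationTable":
        mask = pd.Series(True, index=self.meta.index)
        if condition is not None:
            mask &= self.meta["condition"] == condition
        if time_point is not None:
            mask &= self.meta["time_point"] == time_point
        sub = None
        if self.sub_detection is not None:
            sub = self.sub_detection.loc[mask]
        return ConcentrationTable(self.data.loc[mask], self.meta.loc[mask], sub)

    def render_values(self) -> pd.DataFrame:
        """Concentrations for spectrum rendering: NaN replaced by trace levels."""
        if self.sub_detection is None:
            return self.data.fillna(0.0)
        return self.data.where(~self.data.isna(), self.sub_detection).fillna(0.0)

    def copy(self) -> "ConcentrationTable":
        return ConcentrationTable(
            self.data.copy(),
            self.meta.copy(),
            None if self.sub_detection is None else self.sub_detection.copy(),
        )

    def __eq__(self, other) -> bool:
        if not isinstance(other, ConcentrationTable):
            return NotImplemented
        same = self.data.equals(other.data) and self.meta.equals(other.meta)
        if self.sub_detection is None or other.sub_detection is None:
            return same and (self.sub_detection is None) == (other.sub_detection is None)
        return same and self.sub_detection.equals(other.sub_detection)

    # ------------------------------------------------------------------ I/O

    def to_csv(self, path: str | Path) -> None:
        out = pd.concat([self.meta[list(META_COLUMNS)], self.data], axis=1)
        out.index.name = "sample_id"
        out.to_csv(path)

    @classmethod
    def read_csv(cls, path: str | Path) -> "ConcentrationTable":
        frame = pd.read_csv(path, index_col="sample_id")
        meta = frame[list(META_COLUMNS)].copy()
        meta["time_point"] = meta["time_point"].astype(int)
        meta["replicate"] = meta["replicate"].astype(int)
        data = frame.drop(columns=list(META_COLUMNS)).astype(float)
        return cls(data, meta)
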
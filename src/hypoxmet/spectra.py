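"""Frequency-domain 1H-NMR spectrum container and plain-text I/O.

A :class:`Spectrum` holds one sample's chemical-shift axis (ppm, stored in
descending order as spectrometers plot it) together with the intensity trace
and the sample metadata used throughout the pipeline (condition, time point,
replicate).  Spectra are serialized as two-column text with a ``# key: value``
header so that fixtures stay human-readable and diff-able.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np

HYPOXIA = "hypoxia"
NORMOXIA = "normoxia"
CONDITIONS = (HYPOXIA, NORMOXIA)
TIME_POINTS = (4, 24, 48)  # hours


@dataclasses.dataclass
class Spectrum:
    """One sample's frequency-domain trace.

    Parameters
    ----------
    ppm
        Chemical-shift axis in ppm, strictly monotone decreasing.
    intensity
        Intensities, same length as ``ppm``.
    sample_id
        Unique sample identifier.
    condition
        ``"hypoxia"`` or ``"normoxia"`` (may be ``None`` for anonymous spectra).
    time_point
        Treatment duration in hours (4, 24 or 48; may be ``None``).
    replicate
        1-based replicate index within (condition, time_point).
    """

    ppm: np.ndarray
    intensity: np.ndarray
    sample_id: str = ""
    condition: str | None = None
    time_point: int | None = None
    replicate: int | None = None

    def __post_init__(self):
        self.ppm = np.asarray(self.ppm, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.ppm.shape != self.intensity.shape or self.ppm.ndim != 1:
            raise ValueError("ppm and intensity must be 1-D arrays of equal length")
        d = np.diff(self.ppm)
        if d.size and not (np.all(d < 0) or np.all(d > 0)):
            raise ValueError("ppm axis must be strictly monotone")
        if d.size and np.all(d > 0):
            # store descending, the plotting convention
            self.ppm = self.ppm[::-1].copy()
            self.intensity = self.intensity[::-1].copy()

    def copy(self, **updates) -> "Spectrum":
        fields = dataclasses.asdict(self)
        fields["ppm"] = self.ppm.copy()
        fields["intensity"] = self.intensity.copy()
        fields.update(updates)
        return Spectrum(**fields)

    @property
    def n_points(self) -> int:
        return self.ppm.size

    def window(self, lo: float, hi: float) -> np.ndarray:
        """Boolean mask of points with ``lo <= ppm <= hi``."""
        return (self.ppm >= lo) & (self.ppm <= hi)

    # ------------------------------------------------------------------ I/O

    def write(self, path: str | Path) -> None:
        path = Path(path)
        with open(path, "w") as fh:
            fh.write(f"# sample_id: {self.sample_id}\n")
            if self.condition is not None:
                fh.write(f"# condition: {self.condition}\n")
            if self.time_point is not None:
                fh.write(f"# time_point: {self.time_point}\n")
            if self.replicate is not None:
                fh.write(f"# replicate: {self.replicate}\n")
            fh.write("# columns: ppm intensity\n")
            for p, y in zip(self.ppm, self.intensity):
                fh.write(f"{p:.6f}\t{y:.8e}\n")

    @classmethod
    def read(cls, path: str | Path) -> "Spectrum":
        meta: dict[str, str] = {}
        ppm, inten = [], []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                if line.startswith("#"):
                    body = line.lstrip("#").strip()
                    if ":" in body:
                        key, _, val = body.partition(":")
                        meta[key.strip()] = val.strip()
                    continue
                a, b = line.split()
                ppm.append(float(a))
                inten.append(float(b))
        tp = meta.get("time_point")
        rep = meta.get("replicate")
        return cls(
            ppm=np.array(ppm),
            intensity=np.array(inten),
            sample_id=meta.get("sample_id", ""),
            condition=meta.get("condition") or None,
            time_point=int(tp) if tp else None,
            replicate=int(rep) if rep else None,
        )
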
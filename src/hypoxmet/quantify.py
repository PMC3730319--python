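"""Targeted quantification and median fold-change profiling.

Concentrations are estimated by non-negative least squares against the
metabolite peak-template library on the un-binned preprocessed spectrum
(multiplet shape is information the 0.01-ppm bins would blur).  Fitted
components whose peak height falls below a detection limit (default three
fitted-noise SDs) are reported MISSING rather than zero.

Fold changes follow the signed-ratio convention: the group-median ratio
hypoxia/normoxia r is reported as +r when r >= 1 and as -1/r otherwise,
with the log2 of the raw ratio carried alongside.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .errors import DegenerateSampleError, IllConditionedError, ZeroMedianError
from .spectra import HYPOXIA, NORMOXIA, Spectrum
from .spectra_prep import BIN_HI, BIN_LO, PrepParams, preprocess
from .tables import ConcentrationTable
from .synthdata.templates import MetaboliteTemplate, default_library, template_profile


def quantify_targeted(
    s: Spectrum,
    library: tuple[MetaboliteTemplate, ...] | None = None,
    detection_sigma: float = 3.0,
    fit_lo: float = BIN_LO,
    fit_hi: float = BIN_HI,
    background_degree: int = 5,
) -> dict[str, float]:
    """Fit template profiles to one preprocessed spectrum.

    The smooth instrumental background is estimated jointly with the
    concentrations through signed Chebyshev nuisance columns (degree
    ``background_degree``); separating the two steps would let a baseline
    estimator swallow part of the Lorentzian tails, biasing samples with
    more total signal.  Returns metabolite -> concentration (NaN for
    below-detection).  Raises IllConditionedError, naming the offending
    pair, when two templates are near-collinear on the fit window.
    """
    library = library or default_library()
    mask = s.window(fit_lo, fit_hi)
    ppm = s.ppm[mask]
    y = s.intensity[mask]
    A = np.column_stack([template_profile(ppm, t) for t in library])

    norms = np.linalg.norm(A, axis=0)
    ok = norms > 0
    G = (A[:, ok] / norms[ok]).T @ (A[:, ok] / norms[ok])
    np.fill_diagonal(G, 0.0)
    i, j = np.unravel_index(np.argmax(np.abs(G)), G.shape)
    if abs(G[i, j]) > 0.9999:
        names = [t.name for t, keep in zip(library, ok) if keep]
        raise IllConditionedError((names[i], names[j]))

    # signed Chebyshev nuisance columns absorb the smooth background
    x = np.linspace(-1.0, 1.0, ppm.size)
    cheb = np.polynomial.chebyshev.chebvander(x, background_degree)
    A_fit = np.column_stack([A, cheb, -cheb])
    all_coeffs, _ = nnls(A_fit, y)
    coeffs = all_coeffs[: len(library)]
    resid = y - A_fit @ all_coeffs
    noise_sd = float(np.median(np.abs(resid - np.median(resid))) * 1.4826)

    out: dict[str, float] = {}
    for t, c in zip(library, coeffs):
        height = c * float(template_profile(ppm, t).max())
        out[t.name] = float(c) if height >= detection_sigma * noise_sd else np.nan
    return out


def quantify_study(
    spectra,
    library: tuple[MetaboliteTemplate, ...] | None = None,
    prep: PrepParams | None = None,
    detection_sigma: float = 3.0,
    preprocessed: bool = False,
) -> ConcentrationTable:
    """Preprocess and quantify a set of spectra into a concentration table."""
    library = library or default_library()
    rows, meta_rows, ids = [], [], []
    for s in spectra:
        sp = s if preprocessed else preprocess(s, prep, normalize=False, baseline=False)
        rows.append(quantify_targeted(sp, library, detection_sigma))
        meta_rows.append(
            {"condition": s.condition, "time_point": s.time_point, "replicate": s.replicate}
        )
        ids.append(s.sample_id)
    data = pd.DataFrame(rows, index=ids, columns=[t.name for t in library], dtype=float)
    meta = pd.DataFrame(meta_rows, index=ids)
    return ConcentrationTable(data, meta)


def normalize_total(t: ConcentrationTable) -> ConcentrationTable:
    """Divide each sample's non-missing values by their sum (sum becomes 1)."""
    out = t.copy()
    sums = out.data.sum(axis=1, skipna=True)
    if (sums <= 0).any() or sums.isna().any():
        bad = sums.index[(sums <= 0) | sums.isna()][0]
        raise DegenerateSampleError(f"sample {bad} has no positive concentrations")
    out.data = out.data.div(sums, axis=0)
    return out


@dataclasses.dataclass(frozen=True)
class FoldChangeRecord:
    metabolite: str
    time_point: int
    signed_ratio: float  # +r (higher in hypoxia) or -r (higher in normoxia)
    log2_value: float
    missing: bool

    @classmethod
    def from_ratio(cls, metabolite: str, time_point: int, ratio: float) -> "FoldChangeRecord":
        signed = ratio if ratio >= 1 else -1.0 / ratio
        return cls(metabolite, time_point, float(signed), float(np.log2(ratio)), False)

    @classmethod
    def missing_record(cls, metabolite: str, time_point: int) -> "FoldChangeRecord":
        return cls(metabolite, time_point, np.nan, np.nan, True)


def fold_changes(
    t: ConcentrationTable, max_missing_fraction: float = 0.5
) -> list[FoldChangeRecord]:
    """Median-based signed fold changes per metabolite and time point.

    A group median counts as missing when more than ``max_missing_fraction``
    of its samples are below detection; either group missing masks the cell.
    """
    records: list[FoldChangeRecord] = []
    for tp in sorted(t.meta["time_point"].unique()):
        hyp = t.subset(condition=HYPOXIA, time_point=int(tp)).data
        nor = t.subset(condition=NORMOXIA, time_point=int(tp)).data
        if hyp.empty or nor.empty:
            raise ValueError(f"both groups required at time point {tp}")
        for met in t.metabolites:
            h, n = hyp[met], nor[met]
            if (
                h.isna().mean() > max_missing_fraction
                or n.isna().mean() > max_missing_fraction
            ):
                records.append(FoldChangeRecord.missing_record(met, int(tp)))
                continue
            mh, mn = float(h.median(skipna=True)), float(n.median(skipna=True))
            if mh == 0 or mn == 0:
                raise ZeroMedianError(f"{met} at {tp} h has a zero group median")
            records.append(FoldChangeRecord.from_ratio(met, int(tp), mh / mn))
    return records


def heatmap_matrix(
    records: list[FoldChangeRecord], metabolite_order: tuple[str, ...] | None = None
) -> pd.DataFrame:
    """Metabolite x time matrix of log2 fold changes (NaN = masked)."""
    if metabolite_order is None:
        metabolite_order = tuple(dict.fromkeys(r.metabolite for r in records))
    times = sorted({r.time_point for r in records})
    mat = pd.DataFrame(np.nan, index=list(metabolite_order), columns=times)
    for r in records:
        if r.metabolite in mat.index and not r.missing:
            mat.loc[r.metabolite, r.time_point] = r.log2_value
    mat.columns = [f"{tp}h" for tp in times]
    return mat


def fold_change_report(records: list[FoldChangeRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "metabolite": r.metabolite,
                "time_point": r.time_point,
                "signed_ratio": r.signed_ratio,
                "log2": r.log2_value,
                "missing": r.missing,
            }
            for r in records
        ]
    )
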
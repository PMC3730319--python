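"""Mean-centered PCA on binned spectra and loading-distance region selection.

The discriminating-region procedure: rank bins by the Euclidean norm of
their PC1/PC2 loadings, keep bins above a distance quantile, merge adjacent
survivors into contiguous regions, integrate each region per sample, and
confirm each region with a paired t-test across matched hypoxia/normoxia
replicates.  Surviving regions are annotated with every library metabolite
that has a resonance inside the (slightly padded) region - the usual
one-dimensional-NMR ambiguity, under which a crowded region is attributed
to all co-resonant candidates.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats

from .errors import RankError, UnpairedError
from .spectra import HYPOXIA, NORMOXIA
from .spectra_prep import BinnedMatrix
from .synthdata.templates import MetaboliteTemplate, default_library


@dataclasses.dataclass
class PCAModel:
    """Scores (samples x k), orthonormal loadings (bins x k), variance fractions."""

    scores: pd.DataFrame
    loadings: pd.DataFrame
    explained_variance_fraction: np.ndarray
    mean_: np.ndarray

    @property
    def k(self) -> int:
        return self.loadings.shape[1]


def fit_pca(m: BinnedMatrix, k: int = 2) -> PCAModel:
    """Mean-centered PCA by singular value decomposition.

    Component sign is fixed so each component's largest-magnitude loading is
    positive, making results invariant to sample order up to permutation.
    """
    X = m.values.to_numpy(dtype=float)
    n, p = X.shape
    if n < 2:
        raise ValueError("need at least two samples")
    if k > min(n - 1, p):
        raise RankError(f"k={k} exceeds min(n-1, p)={min(n - 1, p)}")
    mu = X.mean(axis=0)
    Xc = X - mu
    if k > np.linalg.matrix_rank(Xc):
        raise RankError(f"k={k} exceeds data rank {np.linalg.matrix_rank(Xc)}")
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    total = float((S**2).sum())
    loadings = Vt[:k].T.copy()  # p x k, orthonormal columns
    scores = (U[:, :k] * S[:k]).copy()
    for j in range(k):
        if loadings[np.argmax(np.abs(loadings[:, j])), j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    comp_names = [f"PC{j + 1}" for j in range(k)]
    return PCAModel(
        scores=pd.DataFrame(scores, index=m.values.index, columns=comp_names),
        loadings=pd.DataFrame(loadings, index=m.values.columns, columns=comp_names),
        explained_variance_fraction=(S[:k] ** 2) / total,
        mean_=mu,
    )


def loading_distance(model: PCAModel) -> np.ndarray:
    """Per-bin Euclidean distance of the PC1 and PC2 loadings."""
    if model.k < 2:
        raise ValueError("loading distance needs at least two components")
    L = model.loadings.to_numpy()
    return np.sqrt(L[:, 0] ** 2 + L[:, 1] ** 2)


@dataclasses.dataclass
class Region:
    start_bin: int
    end_bin: int  # inclusive
    ppm_lo: float
    ppm_hi: float
    distance: float  # maximum loading distance within the region
    t_stat: float
    p_value: float
    metabolites: tuple[str, ...]


@dataclasses.dataclass
class SelectionResult:
    regions: list[Region]
    selected_metabolites: tuple[str, ...]
    alpha: float
    threshold: float

    def report(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "ppm_lo": r.ppm_lo,
                    "ppm_hi": r.ppm_hi,
                    "distance": r.distance,
                    "t": r.t_stat,
                    "p": r.p_value,
                    "metabolites": ";".join(r.metabolites),
                }
                for r in self.regions
            ]
        )


def _paired_rows(m: BinnedMatrix):
    """Yield (hypoxia index, normoxia index) pairs matched by (time, replicate)."""
    meta = m.meta
    hyp = meta[meta["condition"] == HYPOXIA]
    nor = meta[meta["condition"] == NORMOXIA]
    key = lambda df: list(zip(df["time_point"], df["replicate"]))
    hyp_keys = dict(zip(key(hyp), hyp.index))
    nor_keys = dict(zip(key(nor), nor.index))
    if set(hyp_keys) != set(nor_keys) or not hyp_keys:
        raise UnpairedError("hypoxia/normoxia replicates do not pair one-to-one")
    pairs = [(hyp_keys[k], nor_keys[k]) for k in sorted(hyp_keys)]
    return pairs


def _contiguous_runs(mask: np.ndarray):
    runs, start = [], None
    for i, flag in enumerate(mask):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            runs.append((start, i - 1))
            start = None
    if start is not None:
        runs.append((start, mask.size - 1))
    return runs


def select_regions(
    m: BinnedMatrix,
    model: PCAModel,
    threshold: float = 0.90,
    alpha: float = 0.05,
    library: tuple[MetaboliteTemplate, ...] | None = None,
    map_pad: float | None = None,
    paired: bool = True,
) -> SelectionResult:
    """Loading-distance thresholding plus paired-t confirmation.

    ``threshold`` is a quantile of the per-bin loading-distance distribution
    (default the 90th percentile).  ``map_pad`` widens each region (default
    one bin width) before metabolite annotation, absorbing residual
    alignment error.  With ``paired=False`` a Welch t-test across the two
    groups replaces the paired test.
    """
    library = library or default_library()
    dist = loading_distance(model)
    cut = float(np.quantile(dist, threshold))
    mask = dist > cut
    edges = m.edges
    pad = (edges[1] - edges[0]) if map_pad is None else map_pad
    X = m.values.to_numpy(dtype=float)

    if paired:
        pairs = _paired_rows(m)
        hyp_idx = [m.values.index.get_loc(h) for h, _ in pairs]
        nor_idx = [m.values.index.get_loc(n) for _, n in pairs]
    else:
        hyp_idx = [i for i, c in enumerate(m.meta["condition"]) if c == HYPOXIA]
        nor_idx = [i for i, c in enumerate(m.meta["condition"]) if c == NORMOXIA]

    regions: list[Region] = []
    selected: list[str] = []
    for start, end in _contiguous_runs(mask):
        integ = X[:, start : end + 1].sum(axis=1)
        a, b = integ[hyp_idx], integ[nor_idx]
        if paired:
            t, p = stats.ttest_rel(a, b)
        else:
            t, p = stats.ttest_ind(a, b, equal_var=False)
        if not np.isfinite(p) or p > alpha:
            continue
        lo, hi = edges[start], edges[end + 1]
        mets = tuple(
            t_.name
            for t_ in library
            if any(lo - pad <= pk.center <= hi + pad for pk in t_.peaks)
        )
        regions.append(
            Region(start, end, lo, hi, float(dist[start : end + 1].max()), float(t), float(p), mets)
        )
        for name in mets:
            if name not in selected:
                selected.append(name)
    return SelectionResult(regions, tuple(selected), alpha, cut)
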
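"""Forward simulation: concentrations with planted effects, rendered spectra.

The concentration model is multiplicative: for metabolite m with baseline
level b_m, a normoxia sample draws b_m * eps and a hypoxia sample draws
b_m * a_m(t) * eps, where a_m(t) is the applied fold ratio at time t and eps
is lognormal noise with a configurable coefficient of variation (mean 1).
MISSING cells yield sub-detection trace levels in both groups.

Spectra are rendered as sums of Lorentzian peak templates scaled by
concentration, plus a TMSP reference singlet at 0 ppm, a broad water artifact
around 4.75 ppm, smooth polynomial baseline drift, and additive Gaussian
noise; an optional calibration shift displaces every feature along the axis.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping

import numpy as np
import pandas as pd

from ..errors import CoverageError
from ..spectra import CONDITIONS, HYPOXIA, NORMOXIA, TIME_POINTS, Spectrum
from ..tables import ConcentrationTable
from .effects import EffectSizeConfig, default_effect_table, is_missing
from .templates import MetaboliteTemplate, default_library, lorentzian, template_profile

#: Representative relative intracellular abundances (arbitrary units) used as
#: normoxia baselines.  Chosen once to give a realistic dynamic range: sugars,
#: lactate and osmolytes high; branched-chain amino acids and pyruvate low.
BASELINE_LEVELS: dict[str, float] = {
    "lactate": 3.0,
    "pyruvate": 0.5,
    "glucose": 2.0,
    "glutamine": 1.5,
    "glutamate": 2.0,
    "alanine": 1.2,
    "glycine": 1.0,
    "valine": 0.5,
    "leucine": 0.5,
    "methionine": 0.4,
    "proline": 0.8,
    "creatine": 1.0,
    "creatine_phosphate": 1.0,
    "taurine": 2.5,
    "myo_inositol": 2.0,
    "acetate": 0.8,
    "ethanol": 0.8,
}

#: Concentration below which a metabolite counts as undetectable.
DETECTION_LIMIT = 0.05


@dataclasses.dataclass(frozen=True)
class StudyDesign:
    """Balanced two-condition, three-time-point design (default 2x3x9 = 54)."""

    n_per_group: int = 9
    time_points: tuple[int, ...] = TIME_POINTS
    conditions: tuple[str, ...] = CONDITIONS
    seed: int = 0

    @property
    def n_samples(self) -> int:
        return self.n_per_group * len(self.time_points) * len(self.conditions)


@dataclasses.dataclass(frozen=True)
class RenderParams:
    """Settings of the spectrum forward model."""

    ppm_max: float = 10.0
    ppm_min: float = -0.5
    spacing: float = 0.001  # ppm per point
    tmsp_area: float = 1.0
    tmsp_fwhm: float = 0.004
    water_center: float = 4.75
    water_sd: float = 0.10  # Gaussian width of the residual-water hump
    water_area: float = 5.0
    drift_amplitude: float = 20.0  # scale of the polynomial baseline (raw units)
    drift_degree: int = 3
    # Additive noise chosen so that a metabolite at the concentration
    # detection limit sits right at ~3 sigma of peak height: trace levels are
    # genuinely undetectable while panel signals stay at high SNR.
    noise_sd: float = 2.5  # Gaussian noise per point (raw units)
    gain: float = 1.0  # global receiver gain
    ppm_shift: float = 0.0  # calibration error applied to every feature

    def axis(self) -> np.ndarray:
        n = int(round((self.ppm_max - self.ppm_min) / self.spacing)) + 1
        return np.linspace(self.ppm_max, self.ppm_min, n)


def _sample_id(condition: str, time_point: int, replicate: int) -> str:
    return f"{condition[0].upper()}{time_point:02d}R{replicate}"


def simulate_concentrations(
    design: StudyDesign,
    effects: EffectSizeConfig | None = None,
    cv: float = 0.10,
    seed: int | None = None,
    baselines: Mapping[str, float] | None = None,
) -> ConcentrationTable:
    """Simulate a concentration table with planted fold changes.

    With cv = 0 the hypoxia/normoxia ratio equals the configured effect
    exactly; identical seeds give identical tables.
    """
    if cv < 0:
        raise ValueError("cv must be non-negative")
    effects = effects or default_effect_table()
    baselines = dict(baselines or BASELINE_LEVELS)
    for met, b in baselines.items():
        if b <= 0:
            raise ValueError(f"non-positive baseline level for {met}: {b}")
    metabolites = [m for m in effects.metabolites]
    rng = np.random.default_rng(design.seed if seed is None else seed)

    sigma = np.sqrt(np.log1p(cv**2))
    rows, meta_rows, ids = [], [], []
    trace_rows = []
    for tp in design.time_points:
        for cond in design.conditions:
            for rep in range(1, design.n_per_group + 1):
                vals, traces = {}, {}
                for met in metabolites:
                    b = baselines.get(met, 1.0)
                    eps = (
                        1.0
                        if cv == 0
                        else float(np.exp(rng.normal(-(sigma**2) / 2.0, sigma)))
                    )
                    a = effects.applied_ratio(met, tp)
                    if is_missing(a):
                        # below-detection trace level in *both* groups
                        vals[met] = np.nan
                        traces[met] = DETECTION_LIMIT * rng.uniform(0.2, 0.6)
                        continue
                    level = b * eps
                    if cond == HYPOXIA:
                        level *= a
                    vals[met] = level
                    traces[met] = np.nan
                rows.append(vals)
                trace_rows.append(traces)
                meta_rows.append({"condition": cond, "time_point": tp, "replicate": rep})
                ids.append(_sample_id(cond, tp, rep))

    data = pd.DataFrame(rows, index=ids, columns=metabolites, dtype=float)
    meta = pd.DataFrame(meta_rows, index=ids)
    sub = pd.DataFrame(trace_rows, index=ids, columns=metabolites, dtype=float)
    return ConcentrationTable(data, meta, sub_detection=sub)


def render_spectrum(
    concentrations: Mapping[str, float],
    library: tuple[MetaboliteTemplate, ...] | None = None,
    params: RenderParams | None = None,
    seed: int | None = None,
) -> Spectrum:
    """Render one sample's frequency-domain spectrum from concentrations.

    The area contributed by each metabolite is proportional to its
    concentration; unknown metabolite names raise KeyError.
    """
    library = library or default_library()
    params = params or RenderParams()
    ppm = params.axis()
    if ppm[0] < 4.4 or ppm[-1] > 0.2:
        raise CoverageError("rendered axis must cover the 0.2-4.4 ppm window")
    by_name = {t.name: t for t in library}

    signal = np.zeros_like(ppm)
    for name, conc in concentrations.items():
        if conc == 0 or (isinstance(conc, float) and np.isnan(conc)):
            continue
        signal += conc * template_profile(ppm, by_name[name], shift=params.ppm_shift)

    # TMSP reference singlet at 0.00 ppm (fixed area) and residual water hump
    signal += lorentzian(ppm, 0.0 + params.ppm_shift, params.tmsp_area, params.tmsp_fwhm)
    center = params.water_center + params.ppm_shift
    signal += (
        params.water_area
        / (params.water_sd * np.sqrt(2 * np.pi))
        * np.exp(-0.5 * ((ppm - center) / params.water_sd) ** 2)
    )

    rng = np.random.default_rng(seed)
    if params.drift_amplitude > 0:
        x = np.linspace(-1.0, 1.0, ppm.size)
        coeffs = rng.normal(0.0, params.drift_amplitude, params.drift_degree + 1)
        signal += np.polynomial.chebyshev.chebval(x, coeffs)
    if params.noise_sd > 0:
        signal += rng.normal(0.0, params.noise_sd, ppm.size)

    return Spectrum(ppm=ppm, intensity=params.gain * signal)


def make_study(
    seed: int = 0,
    design: StudyDesign | None = None,
    effects: EffectSizeConfig | None = None,
    cv: float = 0.10,
    params: RenderParams | None = None,
    gain_sd: float = 0.2,
    shift_range: float = 0.004,
) -> tuple[list[Spectrum], ConcentrationTable]:
    """Generate the full synthetic study: 54 spectra plus ground truth.

    Per-sample nuisance factors (receiver gain, calibration shift, drift,
    noise) are drawn from the same seed, so the whole study is a pure
    function of (config, seed).
    """
    design = design or StudyDesign(seed=seed)
    params = params or RenderParams()
    table = simulate_concentrations(design, effects, cv=cv, seed=seed)
    render = table.render_values()

    root = np.random.SeedSequence(seed)
    sample_seeds = root.spawn(len(table.sample_ids))
    nuisance = np.random.default_rng(root.spawn(1)[0])

    spectra = []
    for sid, sseq in zip(table.sample_ids, sample_seeds):
        gain = float(np.exp(nuisance.normal(0.0, gain_sd)))
        shift = float(nuisance.uniform(-shift_range, shift_range))
        p = dataclasses.replace(params, gain=gain, ppm_shift=shift)
        spec = render_spectrum(
            render.loc[sid].to_dict(),
            params=p,
            seed=int(sseq.generate_state(1)[0] % (2**31)),
        )
        m = table.meta.loc[sid]
        spectra.append(
            spec.copy(
                sample_id=sid,
                condition=m["condition"],
                time_point=int(m["time_point"]),
                replicate=int(m["replicate"]),
            )
        )
    return spectra, table
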
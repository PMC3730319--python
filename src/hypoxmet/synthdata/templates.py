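"""Peak-template library for the 17-metabolite hypoxia panel.

Each metabolite is described by a small set of Lorentzian components whose
centers follow literature 1H chemical shifts (D2O, near-neutral pH) and whose
relative areas follow proton counts.  Multiplets are collapsed to one
component per resonance cluster; the values are fixture constants of this
package, adequate for rendering realistic-looking overlap (the crowded
3.2-3.9 ppm sugar region in particular) but not a curated shift database.
"""

from __future__ import annotations

import dataclasses

import numpy as np

#: Default full width at half maximum in ppm (~2.4 Hz at 600 MHz).
DEFAULT_FWHM = 0.004


@dataclasses.dataclass(frozen=True)
class Peak:
    center: float  # ppm
    relative_area: float  # fraction of the metabolite's total area
    fwhm: float = DEFAULT_FWHM  # ppm


@dataclasses.dataclass(frozen=True)
class MetaboliteTemplate:
    name: str
    kegg_compound_id: str
    peaks: tuple[Peak, ...]

    def __post_init__(self):
        total = sum(p.relative_area for p in self.peaks)
        if not np.isclose(total, 1.0, atol=1e-6):
            raise ValueError(f"{self.name}: peak areas sum to {total}, expected 1")
        for p in self.peaks:
            if not (0.0 <= p.center <= 10.0):
                raise ValueError(f"{self.name}: peak at {p.center} ppm outside 0-10")
            if p.relative_area <= 0:
                raise ValueError(f"{self.name}: non-positive peak area")


def _t(name, cid, *peaks):
    return MetaboliteTemplate(name, cid, tuple(Peak(c, a) for c, a in peaks))


#: The 17 metabolites quantified in the hypoxia panel, in heatmap row order.
PANEL = (
    "lactate",
    "pyruvate",
    "glucose",
    "glutamine",
    "glutamate",
    "alanine",
    "glycine",
    "valine",
    "leucine",
    "methionine",
    "proline",
    "creatine",
    "creatine_phosphate",
    "taurine",
    "myo_inositol",
    "acetate",
    "ethanol",
)

_LIBRARY = (
    _t("lactate", "C00186", (1.325, 0.75), (4.115, 0.25)),
    _t("pyruvate", "C00022", (2.375, 1.0)),
    _t(
        "glucose",
        "C00031",
        (3.245, 0.12),
        (3.417, 0.12),
        (3.465, 0.12),
        (3.534, 0.12),
        (3.725, 0.12),
        (3.835, 0.12),
        (3.885, 0.12),
        (4.645, 0.06),  # beta anomeric
        (5.223, 0.10),  # alpha anomeric doublet, the alignment reference
    ),
    _t("glutamine", "C00064", (2.137, 0.4), (2.455, 0.4), (3.775, 0.2)),
    _t("glutamate", "C00025", (2.085, 0.4), (2.346, 0.4), (3.755, 0.2)),
    _t("alanine", "C00041", (1.475, 0.75), (3.785, 0.25)),
    _t("glycine", "C00037", (3.565, 1.0)),
    _t("valine", "C00183", (0.985, 0.375), (1.045, 0.375), (2.275, 0.125), (3.605, 0.125)),
    _t("leucine", "C00123", (0.955, 0.6), (1.705, 0.3), (3.735, 0.1)),
    _t("methionine", "C00073", (2.132, 0.5), (2.645, 0.333), (3.865, 0.167)),
    _t(
        "proline",
        "C00148",
        (2.005, 0.43),
        (2.342, 0.14),
        (3.335, 0.145),
        (3.415, 0.14),
        (4.125, 0.145),
    ),
    _t("creatine", "C00300", (3.035, 0.6), (3.935, 0.4)),
    _t("creatine_phosphate", "C02305", (3.055, 0.6), (3.955, 0.4)),
    _t("taurine", "C00245", (3.253, 0.5), (3.425, 0.5)),
    _t(
        "myo_inositol",
        "C00137",
        (3.275, 1 / 6),
        (3.525, 1 / 3),
        (3.615, 1 / 3),
        (4.065, 1 / 6),
    ),
    _t("acetate", "C00033", (1.925, 1.0)),
    _t("ethanol", "C00469", (1.185, 0.75), (3.665, 0.25)),
)


def default_library() -> tuple[MetaboliteTemplate, ...]:
    """The packaged 17-metabolite template library (names unique, areas sum to 1)."""
    names = [t.name for t in _LIBRARY]
    assert len(set(names)) == len(names)
    return _LIBRARY


def template_profile(ppm: np.ndarray, template: MetaboliteTemplate, shift: float = 0.0) -> np.ndarray:
    """Unit-concentration spectral profile of one metabolite on a ppm grid.

    Each peak is a Lorentzian of area ``relative_area`` so the profile
    integrates (over ppm) to 1 per unit concentration.
    """
    ppm = np.asarray(ppm, dtype=float)
    out = np.zeros_like(ppm)
    for p in template.peaks:
        out += lorentzian(ppm, p.center + shift, p.relative_area, p.fwhm)
    return out


def lorentzian(x: np.ndarray, center: float, area: float, fwhm: float) -> np.ndarray:
    """Lorentzian line with the given integrated area (over x-units)."""
    gamma = fwhm / 2.0  # half width at half maximum
    return area * (gamma / np.pi) / ((x - center) ** 2 + gamma**2)
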
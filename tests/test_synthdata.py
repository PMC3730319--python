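"""Effect table, concentration simulation, spectrum rendering, fixtures."""

import dataclasses

import numpy as np
import pytest

from hypoxmet.errors import NotInPanelError
from hypoxmet.spectra import CONDITIONS, HYPOXIA, NORMOXIA, TIME_POINTS
from hypoxmet.synthdata import (
    BASELINE_LEVELS,
    MISSING,
    PANEL,
    RenderParams,
    StudyDesign,
    default_effect_table,
    default_library,
    is_missing,
    make_pathway_fixture,
    make_study,
    render_spectrum,
    simulate_concentrations,
    template_profile,
)
from hypoxmet.synthdata.pathway_fixture import GENE_MAP_ROWS, PATHWAY_MEMBERSHIP
from hypoxmet.synthdata.simulate import DETECTION_LIMIT
from hypoxmet.synthdata.templates import lorentzian


class TestEffectTable:
    def test_printed_48h_values(self):
        eff = default_effect_table()
        assert eff.lookup("lactate", 48) == pytest.approx(1.99)
        assert eff.lookup("pyruvate", 48) == pytest.approx(1.80)
        assert eff.lookup("myo_inositol", 48) == pytest.approx(-4.29)

    def test_missing_cells(self):
        eff = default_effect_table()
        assert is_missing(eff.lookup("pyruvate", 4))
        assert is_missing(eff.lookup("glucose", 48))
        assert not is_missing(eff.lookup("glucose", 4))

    def test_every_panel_metabolite_covered(self):
        eff = default_effect_table()
        assert set(eff.metabolites) == set(PANEL)
        for met in PANEL:
            for tp in TIME_POINTS:
                eff.lookup(met, tp)  # must not raise

    def test_off_panel_raises(self):
        with pytest.raises(NotInPanelError):
            default_effect_table().lookup("citrate", 48)

    def test_attenuation_monotone_in_time(self):
        eff = default_effect_table()
        for met in ("lactate", "glutamate", "taurine"):
            mags = [abs(np.log2(abs(eff.lookup(met, tp)))) for tp in TIME_POINTS]
            assert mags[0] < mags[1] < mags[2]

    def test_applied_ratio_inverts_negatives(self):
        eff = default_effect_table()
        r = eff.lookup("myo_inositol", 48)  # -4.29
        assert eff.applied_ratio("myo_inositol", 48) == pytest.approx(1 / abs(r))
        assert eff.applied_ratio("lactate", 48) == pytest.approx(1.99)

    def test_invariant_ratio_magnitude(self):
        from hypoxmet.synthdata import EffectSizeConfig

        entries = {("lactate", tp): 0.5 for tp in TIME_POINTS}
        with pytest.raises(ValueError):
            EffectSizeConfig(entries)


class TestSimulateConcentrations:
    def test_cv_zero_ratio_exact(self):
        table = simulate_concentrations(StudyDesign(seed=0), cv=0.0)
        eff = default_effect_table()
        for tp in TIME_POINTS:
            hyp = table.subset(HYPOXIA, tp).data
            nor = table.subset(NORMOXIA, tp).data
            for met in PANEL:
                a = eff.applied_ratio(met, tp)
                if is_missing(a):
                    assert hyp[met].isna().all() and nor[met].isna().all()
                else:
                    np.testing.assert_allclose(
                        hyp[met].to_numpy() / nor[met].to_numpy(), a
                    )

    def test_design_counts(self):
        table = simulate_concentrations(StudyDesign(seed=3))
        assert len(table.sample_ids) == 54
        counts = table.meta.groupby(["condition", "time_point"]).size()
        assert (counts == 9).all() and len(counts) == 6

    def test_deterministic_in_seed(self):
        a = simulate_concentrations(StudyDesign(seed=7))
        b = simulate_concentrations(StudyDesign(seed=7))
        c = simulate_concentrations(StudyDesign(seed=8))
        assert a == b
        assert not a.data.equals(c.data)

    def test_monte_carlo_median_ratio(self):
        # mean-1 lognormal noise: the median hypoxia/normoxia ratio across
        # many replicates concentrates on the configured effect within 5%
        ratios = []
        for seed in range(200):
            t = simulate_concentrations(StudyDesign(seed=seed), cv=0.10)
            h = t.subset(HYPOXIA, 48).data["lactate"].median()
            n = t.subset(NORMOXIA, 48).data["lactate"].median()
            ratios.append(h / n)
        assert np.mean(ratios) == pytest.approx(1.99, rel=0.05)

    def test_trace_levels_below_limit(self):
        t = simulate_concentrations(StudyDesign(seed=0))
        traces = t.sub_detection["glucose"][t.meta["time_point"] == 48]
        assert (traces < DETECTION_LIMIT).all() and (traces > 0).all()

    def test_negative_cv_rejected(self):
        with pytest.raises(ValueError):
            simulate_concentrations(StudyDesign(seed=0), cv=-0.1)


class TestRender:
    def test_lorentzian_integral_matches_area(self):
        x = np.linspace(-5, 5, 200001)
        y = lorentzian(x, 0.0, 2.5, 0.004)
        # analytic: integral over (-inf, inf) is the area parameter; over
        # +/-5 ppm the truncation error is ~ fwhm/(pi*5)
        assert np.trapezoid(y, x) == pytest.approx(2.5, rel=1e-3)

    def test_template_profile_unit_area(self):
        x = np.linspace(10, -5, 600001)
        for t in default_library():
            area = np.trapezoid(template_profile(x, t), x)
            assert abs(area) == pytest.approx(1.0, rel=2e-3)

    def test_render_linearity(self):
        # doubling all concentrations doubles the signal above the fixed
        # TMSP + water + baseline background (no noise, no drift)
        p = RenderParams(noise_sd=0.0, drift_amplitude=0.0)
        base = render_spectrum({}, params=p)
        one = render_spectrum({"lactate": 1.0}, params=p)
        two = render_spectrum({"lactate": 2.0}, params=p)
        np.testing.assert_allclose(
            two.intensity - base.intensity, 2 * (one.intensity - base.intensity)
        )

    def test_render_additivity(self):
        p = RenderParams(noise_sd=0.0, drift_amplitude=0.0)
        base = render_spectrum({}, params=p).intensity
        lac = render_spectrum({"lactate": 1.5}, params=p).intensity - base
        ala = render_spectrum({"alanine": 0.7}, params=p).intensity - base
        both = render_spectrum({"lactate": 1.5, "alanine": 0.7}, params=p).intensity - base
        np.testing.assert_allclose(both, lac + ala, atol=1e-10)

    def test_gain_scales_everything(self):
        p = RenderParams(noise_sd=0.0, drift_amplitude=0.0)
        a = render_spectrum({"lactate": 1.0}, params=p)
        b = render_spectrum({"lactate": 1.0}, params=dataclasses.replace(p, gain=3.0))
        np.testing.assert_allclose(b.intensity, 3.0 * a.intensity)

    def test_nan_and_zero_concentrations_skipped(self):
        p = RenderParams(noise_sd=0.0, drift_amplitude=0.0)
        a = render_spectrum({}, params=p)
        b = render_spectrum({"lactate": 0.0, "alanine": float("nan")}, params=p)
        np.testing.assert_allclose(a.intensity, b.intensity)

    def test_unknown_metabolite_raises(self):
        with pytest.raises(KeyError):
            render_spectrum({"citrate": 1.0})


class TestMakeStudy:
    def test_counts_and_metadata(self, study):
        spectra, truth = study
        assert len(spectra) == 54
        seen = {(s.condition, s.time_point) for s in spectra}
        assert seen == {(c, t) for c in CONDITIONS for t in TIME_POINTS}
        for s in spectra:
            assert s.sample_id in truth.sample_ids

    def test_deterministic(self):
        small = StudyDesign(n_per_group=2, seed=5)
        p = RenderParams(spacing=0.002)
        s1, t1 = make_study(seed=5, design=small, params=p)
        s2, t2 = make_study(seed=5, design=small, params=p)
        assert t1 == t2
        for a, b in zip(s1, s2):
            np.testing.assert_array_equal(a.intensity, b.intensity)

    def test_seeds_differ(self):
        small = StudyDesign(n_per_group=2, seed=5)
        p = RenderParams(spacing=0.002)
        s1, _ = make_study(seed=5, design=small, params=p)
        s2, _ = make_study(seed=6, design=small, params=p)
        assert not np.array_equal(s1[0].intensity, s2[0].intensity)

    def test_baselines_positive(self):
        assert set(BASELINE_LEVELS) == set(PANEL)
        assert all(v > 0 for v in BASELINE_LEVELS.values())


class TestPathwayFixture:
    def test_membership_counts(self):
        met = sum(1 for _, _, m, _ in PATHWAY_MEMBERSHIP if m)
        trans = sum(1 for _, _, _, t in PATHWAY_MEMBERSHIP if t)
        common = sum(1 for _, _, m, t in PATHWAY_MEMBERSHIP if m and t)
        assert (met, trans, common) == (14, 11, 4)

    def test_files_written(self, tmp_path):
        fix = make_pathway_fixture(tmp_path)
        assert len(list(fix["kgml_dir"].glob("*.xml"))) == 21
        genes = fix["genes"].read_text().split()
        assert len(genes) == 66 and len(set(genes)) == 66
        panel_lines = fix["panel"].read_text().splitlines()
        assert len(panel_lines) == 18  # header + 17 metabolites

    def test_gene_map_closure(self, tmp_path):
        # every enzyme in the gene map appears in at least one fixture pathway
        from hypoxmet.pathway_net import parse_kgml

        fix = make_pathway_fixture(tmp_path)
        records = parse_kgml(sorted(fix["kgml_dir"].glob("*.xml")))
        all_enzymes = set().union(*(r.enzymes for r in records))
        for _, _, ec in GENE_MAP_ROWS:
            assert ec in all_enzymes
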
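"""Tests of the ACE twin-cohort generator against closed-form oracles."""

import numpy as np
import pytest

from sleeptopo import (ACEParams, CohortSpec, SignalSpec,
                       expected_pair_correlation, expected_self_correlation,
                       generate_hypnogram, generate_signal_cohort,
                       generate_twin_maps, epoch_psd, normalize_bins)
from sleeptopo.topography import TopographyMap
from sleeptopo.util import smooth_field, substream

from conftest import pair_correlations


class TestExpectedPairCorrelation:
    @pytest.mark.parametrize("rel,expected", [
        ("MZ", 0.8), ("DZ", 0.55), ("NR", 0.0),
    ])
    def test_closed_form(self, small_ace, rel, expected):
        assert expected_pair_correlation(small_ace, rel) == pytest.approx(expected)

    def test_template_dominates(self):
        ace = ACEParams(0.5, 0.3, 0.2, template_var=1e9)
        for rel in ("MZ", "DZ", "NR"):
            assert expected_pair_correlation(ace, rel) == pytest.approx(1.0, abs=1e-6)

    def test_unknown_relationship(self, small_ace):
        with pytest.raises(ValueError):
            expected_pair_correlation(small_ace, "cousin")

    def test_self_correlation(self, small_ace):
        # A and C persist; E re-drawn with correlation 0.85
        assert expected_self_correlation(small_ace, 0.85) == pytest.approx(
            0.5 + 0.3 + 0.2 * 0.85)


class TestGenerateTwinMaps:
    def test_pure_unique_no_shared_signal(self):
        ace = ACEParams(a2=0, c2=0, e2=1, template_var=0, n_channels=58)
        spec = CohortSpec(n_mz_pairs=300, n_dz_pairs=0, n_timepoints=1,
                          bands=("delta",), seed=11)
        maps, truth = generate_twin_maps(ace, spec, mode="linear")
        rs = pair_correlations(maps, truth)
        assert abs(np.mean(rs["MZ"])) < 3 / np.sqrt(55 * 300)

    def test_pure_genetic_mz_identical(self):
        ace = ACEParams(a2=1, c2=0, e2=0, template_var=0, n_channels=20)
        spec = CohortSpec(n_mz_pairs=1, n_dz_pairs=0, n_timepoints=1,
                          bands=("delta",), seed=1)
        maps, truth = generate_twin_maps(ace, spec, mode="linear")
        _, s1, s2, _ = truth.pairs[0]
        by_id = {m.subject_id: m for m in maps}
        np.testing.assert_allclose(by_id[s1].values, by_id[s2].values)

    def test_monte_carlo_matches_closed_form(self, small_ace):
        """Mean pair correlation within 3 SE of the oracle at 2000 pairs."""
        spec = CohortSpec(n_mz_pairs=2000, n_dz_pairs=2000, n_timepoints=1,
                          bands=("delta",), seed=7)
        maps, truth = generate_twin_maps(small_ace, spec, mode="linear")
        rs = pair_correlations(maps, truth)
        for rel in ("MZ", "DZ"):
            vals = np.asarray(rs[rel])
            se = vals.std(ddof=1) / np.sqrt(len(vals))
            expected = expected_pair_correlation(small_ace, rel)
            # finite-channel Pearson bias ~ -rho(1-rho^2)/(2*57)
            bias = -expected * (1 - expected ** 2) / (2 * 57)
            assert abs(vals.mean() - (expected + bias)) < 3 * se

    def test_compositional_maps_positive_sum_one(self, small_ace):
        spec = CohortSpec(n_mz_pairs=5, n_dz_pairs=5, bands=("delta", "sigma"),
                          seed=2)
        maps, _ = generate_twin_maps(small_ace, spec, mode="compositional")
        assert len(maps) == 40  # 20 subjects x 2 time points
        for m in maps:
            assert np.all(m.values > 0)
            np.testing.assert_allclose(m.values.sum(axis=0), 1.0, atol=1e-12)

    def test_group_ordering_mz_dz_nr(self):
        """MZ >= DZ >= NR mean correlation whenever a2 > 0 (500 pairs)."""
        ace = ACEParams(a2=0.4, c2=0.3, e2=0.3, template_var=0.0,
                        n_channels=58, smoothness=3)
        spec = CohortSpec(n_mz_pairs=500, n_dz_pairs=500, n_timepoints=1,
                          bands=("delta",), seed=5)
        maps, truth = generate_twin_maps(ace, spec, mode="linear")
        rs = pair_correlations(maps, truth)
        idx = {(m.subject_id, m.time_point): m for m in maps}
        rng = np.random.default_rng(0)
        subjects = truth.subjects()
        fam = {sid: f for f, s1, s2, _ in truth.pairs for sid in (s1, s2)}
        nr = []
        for _ in range(500):
            a, b = rng.choice(subjects, 2, replace=False)
            if fam[a] != fam[b]:
                nr.append(np.corrcoef(idx[(a, 1)].band("delta"),
                                      idx[(b, 1)].band("delta"))[0, 1])
        assert np.mean(rs["MZ"]) >= np.mean(rs["DZ"]) >= np.mean(nr)

    def test_same_seed_reproducible(self, small_ace):
        spec = CohortSpec(n_mz_pairs=3, n_dz_pairs=2, bands=("delta",), seed=9)
        maps1, _ = generate_twin_maps(small_ace, spec)
        maps2, _ = generate_twin_maps(small_ace, spec)
        for m1, m2 in zip(maps1, maps2):
            assert m1.subject_id == m2.subject_id
            np.testing.assert_array_equal(m1.values, m2.values)

    def test_band_mismatch_rejected(self, small_ace):
        spec = CohortSpec(n_mz_pairs=1, n_dz_pairs=0, bands=("delta", "theta"))
        with pytest.raises(ValueError):
            generate_twin_maps({"delta": small_ace}, spec)

    def test_invalid_fractions_rejected(self):
        with pytest.raises(ValueError):
            ACEParams(a2=0.5, c2=0.6, e2=-0.1)
        with pytest.raises(ValueError):
            ACEParams(a2=0.5, c2=0.3, e2=0.3)


class TestSmoothField:
    def test_unit_variance_and_correlation(self, rng):
        x = smooth_field(rng, 60, smoothness=5, size=20000)
        assert x.var() == pytest.approx(1.0, rel=0.05)
        # neighbouring channels share 4 of 5 smoothing cells
        r = np.corrcoef(x[:, 0], x[:, 1])[0, 1]
        assert r == pytest.approx(0.8, abs=0.05)


class TestGenerateHypnogram:
    def test_absorbing_rem(self):
        trans = {s: {"REM": 1.0} for s in
                 ("Wake", "S1", "S2", "SWS", "REM", "Movement")}
        spec = SignalSpec(n_epochs=50, stage_transition=trans)
        hyp = generate_hypnogram(spec, seed=0)
        assert all(s == "REM" for s in hyp.stages[1:])

    def test_determinism(self, fast_transitions):
        spec = SignalSpec(n_epochs=200, stage_transition=fast_transitions)
        h1 = generate_hypnogram(spec, seed=4)
        h2 = generate_hypnogram(spec, seed=4)
        np.testing.assert_array_equal(h1.stages, h2.stages)

    def test_stationary_rem_fraction(self):
        """i.i.d. rows make the stationary law explicit: REM prob 0.25."""
        row = {"Wake": 0.10, "S2": 0.45, "SWS": 0.20, "REM": 0.25}
        trans = {s: dict(row) for s in
                 ("Wake", "S1", "S2", "SWS", "REM", "Movement")}
        spec = SignalSpec(n_epochs=10000, stage_transition=trans)
        hyp = generate_hypnogram(spec, seed=21)
        frac = np.mean([s == "REM" for s in hyp.stages])
        assert abs(frac - 0.25) < 0.03

    def test_malformed_transition_rejected(self):
        with pytest.raises(ValueError):
            SignalSpec(stage_transition={"Wake": {"Wake": 0.7}})


class TestGenerateSignalCohort:
    @staticmethod
    def _uniform_cohort(n_ch, bands=("delta",)):
        values = np.full((n_ch, len(bands)), 1.0 / n_ch)
        m = TopographyMap(values=values, bands=list(bands), state="NREM",
                          subject_id="fam0000a", time_point=1)
        from sleeptopo.synthetic import CohortTruth, ACEParams
        truth = CohortTruth(maps={("fam0000a", 1): values},
                            pairs=[("fam0000", "fam0000a", "fam0000b", "MZ")],
                            ace={b: ACEParams(0, 0, 1) for b in bands},
                            mode="compositional")
        return [m], truth

    def test_no_artifacts_empty_log(self, fast_transitions):
        maps, truth = self._uniform_cohort(8)
        spec = SignalSpec(sampling_rate=100.0, n_epochs=4, artifact_rate=0.0,
                          stage_transition=fast_transitions,
                          initial_stage="S2")
        list(generate_signal_cohort({"NREM": maps}, truth, spec, seed=0,
                                    subjects=["fam0000a"]))
        assert truth.artifacts == []

    def test_uniform_map_yields_uniform_topography(self, fast_transitions):
        """Equal channel gains -> downstream normalized map ~ 1/n_channels."""
        n_ch = 8
        maps, truth = self._uniform_cohort(n_ch)
        spec = SignalSpec(sampling_rate=100.0, n_epochs=120,
                          stage_transition=fast_transitions,
                          background_amplitude=0.0, initial_stage="S2")
        rec, hyp = next(generate_signal_cohort({"NREM": maps}, truth, spec,
                                               seed=3, subjects=["fam0000a"]))
        sp = epoch_psd(rec, hyp)
        nrem = np.fromiter((s in ("S2", "SWS") for s in sp.stage), dtype=bool)
        mean = sp.power[nrem].mean(axis=0)
        sel = (sp.bin_centers >= 1.0) & (sp.bin_centers <= 4.6)
        frac = normalize_bins(mean[:, sel]).mean(axis=1)
        np.testing.assert_allclose(frac, 1.0 / n_ch, rtol=0.08)

    def test_delta_gain_ratio_recovered(self, fast_transitions):
        """A 3:1 normalized delta power ratio survives the pipeline +-10%."""
        n_ch = 8
        values = np.array([3.0] * 4 + [1.0] * 4)
        values = (values / values.sum())[:, None]
        m = TopographyMap(values=values, bands=["delta"], state="NREM",
                          subject_id="fam0000a", time_point=1)
        from sleeptopo.synthetic import CohortTruth
        truth = CohortTruth(maps={("fam0000a", 1): values},
                            pairs=[("fam0000", "fam0000a", "fam0000b", "MZ")],
                            ace={"delta": ACEParams(0, 0, 1)},
                            mode="compositional")
        spec = SignalSpec(sampling_rate=100.0, n_epochs=60,
                          stage_transition=fast_transitions,
                          background_amplitude=0.0, initial_stage="S2")
        rec, hyp = next(generate_signal_cohort({"NREM": [m]}, truth, spec,
                                               seed=6, subjects=["fam0000a"]))
        sp = epoch_psd(rec, hyp)
        nrem = np.fromiter((s in ("S2", "SWS") for s in sp.stage), dtype=bool)
        mean = sp.power[nrem].mean(axis=0)
        sel = (sp.bin_centers >= 1.0) & (sp.bin_centers <= 4.6)
        frac = normalize_bins(mean[:, sel]).mean(axis=1)
        ratio = frac[:4].mean() / frac[4:].mean()
        assert ratio == pytest.approx(3.0, rel=0.10)

    def test_artifact_log_and_determinism(self, fast_transitions):
        maps, truth = self._uniform_cohort(8)
        spec = SignalSpec(sampling_rate=100.0, n_epochs=20, artifact_rate=0.2,
                          artifact_gain=10.0,
                          stage_transition=fast_transitions,
                          initial_stage="S2")
        rec1, _ = next(generate_signal_cohort({"NREM": maps}, truth, spec,
                                              seed=8, subjects=["fam0000a"]))
        assert len(truth.artifacts) >= 4
        maps2, truth2 = self._uniform_cohort(8)
        rec2, _ = next(generate_signal_cohort({"NREM": maps2}, truth2, spec,
                                              seed=8, subjects=["fam0000a"]))
        np.testing.assert_array_equal(rec1.samples, rec2.samples)
        assert truth.artifacts == truth2.artifacts
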
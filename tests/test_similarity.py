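"""Pair-group construction, topographic correlations, Fisher-z averaging."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as hst

from sleeptopo import (ACEParams, CohortSpec, TopographyMap,
                       build_pair_groups, expected_pair_correlation, fisher_z,
                       fisher_z_inv, generate_twin_maps,
                       group_mean_similarity, topo_correlation)


def tmap(values, subject="s", tp=1, state="NREM", bands=None):
    values = np.atleast_2d(np.asarray(values, dtype=float)).T
    return TopographyMap(values=values, bands=bands or ["delta"], state=state,
                         subject_id=subject, time_point=tp, normalized=False)


def manifest_for(n_mz, n_dz):
    rows = []
    for i in range(n_mz + n_dz):
        zyg = "MZ" if i < n_mz else "DZ"
        for suffix in "ab":
            rows.append({"subject_id": f"fam{i:04d}{suffix}",
                         "family_id": f"fam{i:04d}", "zygosity": zyg})
    return pd.DataFrame(rows)


class TestTopoCorrelation:
    def test_self_correlation_is_one(self, rng):
        m = tmap(rng.uniform(0, 1, 10))
        assert topo_correlation(m, m, "delta") == pytest.approx(1.0)

    def test_exact_anticorrelation(self, rng):
        v = rng.uniform(0, 1, 12)
        m1 = tmap(v)
        m2 = tmap(2 * v.mean() - v)
        assert topo_correlation(m1, m2, "delta") == pytest.approx(-1.0)

    def test_reversed_equal_spacing(self):
        m1 = tmap([0.1, 0.2, 0.3, 0.4])
        m2 = tmap([0.4, 0.3, 0.2, 0.1])
        assert topo_correlation(m1, m2, "delta") == pytest.approx(-1.0)

    def test_zero_variance_is_nan(self, caplog):
        m1 = tmap([0.25, 0.25, 0.25, 0.25])
        m2 = tmap([0.1, 0.2, 0.3, 0.4])
        with caplog.at_level("WARNING"):
            assert np.isnan(topo_correlation(m1, m2, "delta"))
        assert "zero-variance" in caplog.text

    def test_symmetry_and_affine_invariance(self, rng):
        a, b = rng.uniform(0, 1, 20), rng.uniform(0, 1, 20)
        r1 = topo_correlation(tmap(a), tmap(b), "delta")
        r2 = topo_correlation(tmap(b), tmap(a), "delta")
        r3 = topo_correlation(tmap(3 * a + 1), tmap(3 * b + 1), "delta")
        assert r1 == pytest.approx(r2) == pytest.approx(r3)

    def test_mismatched_channels_rejected(self, rng):
        with pytest.raises(ValueError):
            topo_correlation(tmap(rng.uniform(0, 1, 5)),
                             tmap(rng.uniform(0, 1, 6)), "delta")


class TestFisherZ:
    def test_values(self):
        assert fisher_z(0.0) == 0.0
        assert fisher_z(0.5) == pytest.approx(0.5493061443)

    def test_round_trip(self):
        assert fisher_z_inv(fisher_z(0.8)) == pytest.approx(0.8, abs=1e-12)

    def test_domain(self):
        with pytest.raises(ValueError):
            fisher_z(1.0)

    @given(hst.lists(hst.floats(min_value=0.05, max_value=0.95), min_size=3,
                     max_size=12))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_jensen_direction(self, rs):
        """Back-transformed z-mean >= arithmetic mean for non-negative r."""
        rs = np.asarray(rs)
        z_mean = fisher_z_inv(fisher_z(rs).mean())
        assert z_mean >= rs.mean() - 1e-12


class TestBuildPairGroups:
    def test_study_cohort_counts(self):
        groups = build_pair_groups(manifest_for(14, 11), time_point=1)
        assert len(groups["MZ"]) == 14
        assert len(groups["DZ"]) == 11
        # all cross-family unordered pairs: C(50,2) - 25 co-twin pairs
        assert len(groups["NR"]) == 50 * 49 // 2 - 25 == 1200
        assert len(groups["Self"]) == 50

    def test_two_families_four_nr_pairs(self):
        groups = build_pair_groups(manifest_for(1, 1), time_point=2)
        assert len(groups["NR"]) == 4
        assert all(tp == 2 for pair in groups["NR"] for _, tp in pair)

    def test_exclusions_remove_subject_and_cotwin_pair(self):
        groups = build_pair_groups(manifest_for(2, 0), time_point=1,
                                   exclude_subjects=["fam0000a"])
        assert len(groups["MZ"]) == 1
        # remaining subjects: fam0000b + fam0001a/b -> cross-family pairs only
        assert len(groups["NR"]) == 2
        assert len(groups["Self"]) == 3

    def test_malformed_family_rejected(self):
        m = manifest_for(1, 0).iloc[:1]
        with pytest.raises(ValueError):
            build_pair_groups(m, time_point=1)


class TestGroupMeanSimilarity:
    @staticmethod
    def _maps_from(maps):
        return {(m.subject_id, m.time_point, m.state): m for m in maps}

    def test_single_pair_mean_is_pair_r(self, rng):
        maps = self._maps_from([tmap(rng.uniform(0, 1, 8), subject=s)
                                for s in ("a", "b")])
        pair_lists = {"MZ": [(("a", 1), ("b", 1))]}
        table = group_mean_similarity(pair_lists, maps, ["delta"], ["NREM"])
        expected = topo_correlation(maps[("a", 1, "NREM")],
                                    maps[("b", 1, "NREM")], "delta")
        assert table.cell("MZ", "delta", "NREM", 1)["mean_r"] == \
            pytest.approx(expected)

    def test_equal_rs_average_to_same(self, rng):
        v = rng.uniform(0, 1, 8)
        w = v + rng.uniform(0, 0.1, 8)
        maps = {}
        for fam in ("f0", "f1"):
            for sid, vals in ((fam + "a", v), (fam + "b", w)):
                maps[(sid, 1, "NREM")] = tmap(vals, subject=sid)
        pair_lists = {"DZ": [(("f0a", 1), ("f0b", 1)),
                             (("f1a", 1), ("f1b", 1))]}
        table = group_mean_similarity(pair_lists, maps, ["delta"], ["NREM"])
        cell = table.cell("DZ", "delta", "NREM", 1)
        assert cell["n_pairs"] == 2
        assert cell["mean_r"] == pytest.approx(
            topo_correlation(tmap(v), tmap(w), "delta"))

    def test_missing_map_rejected(self, rng):
        maps = self._maps_from([tmap(rng.uniform(0, 1, 8), subject="a")])
        with pytest.raises(KeyError):
            group_mean_similarity({"MZ": [(("a", 1), ("b", 1))]}, maps,
                                  ["delta"], ["NREM"])

    def test_linear_cohort_group_means_match_oracle(self, small_ace):
        """500 MZ/DZ pairs: group means within 0.03 of the closed form."""
        spec = CohortSpec(n_mz_pairs=500, n_dz_pairs=500, n_timepoints=1,
                          bands=("delta",), seed=17)
        maps, truth = generate_twin_maps(small_ace, spec, mode="linear")
        maps_d = self._maps_from(maps)
        pair_lists = {"MZ": [], "DZ": []}
        for fam, s1, s2, zyg in truth.pairs:
            pair_lists[zyg].append(((s1, 1), (s2, 1)))
        table = group_mean_similarity(pair_lists, maps_d, ["delta"], ["NREM"])
        for rel in ("MZ", "DZ"):
            mean_r = table.cell(rel, "delta", "NREM", 1)["mean_r"]
            assert mean_r == pytest.approx(
                expected_pair_correlation(small_ace, rel), abs=0.03)

    def test_self_exceeds_twin_groups(self):
        """r_Self >= r_MZ >= r_DZ >= r_NR in an a2 > 0 simulation."""
        ace = ACEParams(a2=0.5, c2=0.2, e2=0.3, template_var=0.0,
                        n_channels=58, smoothness=1)
        spec = CohortSpec(n_mz_pairs=40, n_dz_pairs=40, n_timepoints=2,
                          retest_stability=0.85, bands=("delta",), seed=23)
        maps, truth = generate_twin_maps(ace, spec, mode="linear")
        maps_d = self._maps_from(maps)
        manifest = truth.manifest()
        pair_lists = build_pair_groups(manifest, time_point=1)
        table = group_mean_similarity(pair_lists, maps_d, ["delta"], ["NREM"])
        r = {g: table.cell(g, "delta", "NREM", 1 if g != "Self" else 0)["mean_r"]
             for g in ("MZ", "DZ", "NR")}
        r["Self"] = table.cell("Self", "delta", "NREM", 0)["mean_r"]
        assert r["Self"] >= r["MZ"] >= r["DZ"] >= r["NR"]
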
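"""ToxPi scaling, aggregation, ranking, and class summaries."""

import numpy as np
import pandas as pd
import pytest

from namscreen import toxpi
from conftest import make_pod_frame


def pod_frame_from_dict(pods_by_chemical, cell_type="ct", phenotype="ph"):
    rows = [
        (chem, cell_type, phenotype, "functional", pod, False)
        for chem, pod in pods_by_chemical.items()
    ]
    return make_pod_frame(rows)


class TestScaling:
    def test_symmetric_decades_log_mode(self):
        pods = pod_frame_from_dict({"a": 0.01, "b": 1.0, "c": 100.0})
        m = toxpi.scale_pod_matrix(pods, "log10")
        col = m.scores["ct:ph"]
        assert col["a"] == pytest.approx(1.0)
        assert col["b"] == pytest.approx(0.5)
        assert col["c"] == pytest.approx(0.0)

    def test_linear_mode_interpolates_raw_values(self):
        pods = pod_frame_from_dict({"a": 0.0, "b": 25.0, "c": 100.0})
        m = toxpi.scale_pod_matrix(pods, "linear")
        col = m.scores["ct:ph"]
        assert col["b"] == pytest.approx(0.75)

    def test_all_equal_pods_scored_zero_and_flagged(self):
        pods = pod_frame_from_dict({"a": 1.0, "b": 1.0, "c": 1.0})
        m = toxpi.scale_pod_matrix(pods)
        assert (m.scores["ct:ph"] == 0.0).all()
        assert m.degenerate_phenotypes == ["ct:ph"]

    def test_censored_scores_exactly_zero(self):
        pods = make_pod_frame(
            [
                ("a", "ct", "ph", "functional", 0.1, False),
                ("b", "ct", "ph", "functional", 10.0, False),
                ("c", "ct", "ph", "functional", 100.0, True),
            ]
        )
        m = toxpi.scale_pod_matrix(pods)
        assert m.scores.loc["c", "ct:ph"] == 0.0

    def test_scale_invariance_in_log_mode(self):
        pods = pod_frame_from_dict({"a": 0.03, "b": 0.7, "c": 55.0})
        scaled = pods.assign(pod_uM=pods["pod_uM"] * 137.0)
        a = toxpi.scale_pod_matrix(pods).scores
        b = toxpi.scale_pod_matrix(scaled).scores
        pd.testing.assert_frame_equal(a, b)

    def test_unknown_mode_rejected(self):
        with pytest.raises(toxpi.ToxPiConfigurationError):
            toxpi.scale_pod_matrix(pod_frame_from_dict({"a": 1.0}), "sqrt")


class TestProfiles:
    def _matrix(self, scores_by_slice):
        """scores_by_slice: {slice: {chemical: score}} with one phenotype each."""
        scores = pd.DataFrame(
            {f"{s}:ph": pd.Series(v) for s, v in scores_by_slice.items()}
        )
        scores.index.name = "chemical"
        slices = {f"{s}:ph": s for s in scores_by_slice}
        return toxpi.ToxPiInputMatrix(scores=scores.fillna(0.0), slices=slices)

    def test_overall_is_mean_of_slices(self):
        m = self._matrix(
            {s: {"chem": v} for s, v in zip("abcde", [0.2, 0.4, 0.6, 0.8, 1.0])}
        )
        profile = toxpi.toxpi_profile(m)
        assert profile.loc[0, "overall"] == pytest.approx(0.6)

    def test_all_zero_chemical_ranks_last(self):
        m = self._matrix({"s1": {"a": 0.5, "b": 0.0}, "s2": {"a": 0.3, "b": 0.0}})
        profile = toxpi.toxpi_profile(m).set_index("chemical")
        assert profile.loc["b", "overall"] == 0.0
        assert profile.loc["b", "rank"] == 2

    def test_ranks_are_permutation_with_deterministic_ties(self):
        m = self._matrix({"s1": {"a": 0.5, "b": 0.5, "c": 0.1}})
        profile = toxpi.toxpi_profile(m).set_index("chemical")
        assert sorted(profile["rank"]) == [1, 2, 3]
        assert profile.loc["a", "rank"] < profile.loc["b", "rank"]  # tie -> id order

    def test_lowering_a_pod_never_lowers_overall_score(self):
        """Monotonicity under POD improvement, randomized perturbation."""
        rng = np.random.default_rng(41)
        for _ in range(30):
            chems = [f"c{i}" for i in range(6)]
            rows = []
            for ct in ("ct1", "ct2"):
                for ph in ("p1", "p2"):
                    for c in chems:
                        rows.append((c, ct, ph, "functional", 10 ** rng.uniform(-2, 2), False))
            pods = make_pod_frame(rows)
            target = rng.choice(chems)
            i = pods[pods["chemical"] == target].sample(1, random_state=int(rng.integers(2**31))).index[0]
            improved = pods.copy()
            improved.loc[i, "pod_uM"] *= 10 ** -rng.uniform(0.1, 2)
            before = toxpi.toxpi_profile(toxpi.scale_pod_matrix(pods)).set_index("chemical")
            after = toxpi.toxpi_profile(toxpi.scale_pod_matrix(improved)).set_index("chemical")
            assert after.loc[target, "overall"] >= before.loc[target, "overall"] - 1e-12

    def test_scores_bounded_and_match_independent_recomputation(self, pods):
        m = toxpi.scale_pod_matrix(pods)
        profile = toxpi.toxpi_profile(m).set_index("chemical")
        assert ((profile["overall"] >= 0) & (profile["overall"] <= 1)).all()
        # brute-force recomputation from the scaled matrix, independent path
        for chem in profile.index[:7]:
            slice_means = {}
            for key, s in m.slices.items():
                slice_means.setdefault(s, []).append(m.scores.loc[chem, key])
            expected = np.mean([np.mean(v) for s, v in sorted(slice_means.items())])
            assert profile.loc[chem, "overall"] == pytest.approx(expected, abs=1e-12)


class TestClassRanges:
    def _profiles(self, overall_by_chem):
        df = pd.DataFrame(
            {"chemical": list(overall_by_chem), "slice_ct": list(overall_by_chem.values())}
        )
        df["overall"] = df["slice_ct"]
        df["rank"] = df["overall"].rank(ascending=False).astype(int)
        return df

    def test_min_max_of_two_member_class(self):
        profiles = self._profiles({"a": 0.1, "b": 0.3, "c": 0.9})
        classing = pd.DataFrame(
            {"chemical": ["a", "b", "c"], "chem_class": ["x", "x", "y"]}
        )
        out = toxpi.class_score_ranges(profiles, classing)
        row = out[(out["chem_class"] == "x") & (out["component"] == "overall")].iloc[0]
        assert (row["min"], row["max"]) == (0.1, 0.3)

    def test_single_chemical_class_degenerate_range(self):
        profiles = self._profiles({"a": 0.4, "b": 0.8})
        classing = pd.DataFrame({"chemical": ["a", "b"], "chem_class": ["x", "y"]})
        out = toxpi.class_score_ranges(profiles, classing)
        row = out[(out["chem_class"] == "x") & (out["component"] == "overall")].iloc[0]
        assert row["min"] == row["max"] == 0.4

    def test_unlabelled_chemical_rejected(self):
        profiles = self._profiles({"a": 0.4})
        classing = pd.DataFrame({"chemical": ["zzz"], "chem_class": ["x"]})
        with pytest.raises(ValueError):
            toxpi.class_score_ranges(profiles, classing)

    def test_broadly_potent_class_tops_median_ranking(self, pods, reference_classing):
        """The class planted as broadly potent across cell types ranks first
        by median overall ToxPi score."""
        m = toxpi.scale_pod_matrix(pods)
        profiles = toxpi.toxpi_profile(m)
        out = toxpi.class_score_ranges(profiles, reference_classing)
        top = out[out["class_rank_by_median_overall"] == 1]["chem_class"].unique()
        assert list(top) == ["inorganic"]
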
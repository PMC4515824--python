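"""Normalisation, titration fit, cross-tabs, rank test, diagnosis scoring."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import mannwhitneyu

import leukopan as lp
from leukopan.quantify import (
    crosstab,
    call_immunophenotype,
    fc_concordance,
    fit_saturation,
    flag_profile,
    mann_whitney,
    normalize,
    reference_ranges,
    suggest_diagnosis,
)


class TestNormalize:
    def test_fitted_asymptote_ratios(self):
        prof = normalize(pd.Series({"CD45": 6400.0, "CD3": 3580.0, "CD19": 330.0}))
        assert prof.normalized["CD3"] == pytest.approx(55.9, abs=0.05)
        assert prof.normalized["CD19"] == pytest.approx(5.2, abs=0.05)
        assert prof.normalized["CD45"] == 100.0

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError, match="undefined"):
            normalize(pd.Series({"CD45": 0.0, "CD3": 10.0}))

    def test_values_above_100_flagged_not_clipped(self):
        prof = normalize(pd.Series({"CD45": 100.0, "CD64": 120.0}))
        assert prof.normalized["CD64"] == pytest.approx(120.0)
        assert prof.over_100 == ["CD64"]


class TestFitSaturation:
    xs = np.array([0.5, 1, 2, 3, 5, 7, 10])

    def _series(self, noise=0.0, rng=None):
        rows = []
        for spot, a in (("CD45", 6400), ("CD3", 3580), ("CD19", 330)):
            y = a * (1 - np.exp(-self.xs / 2.4))
            if noise:
                y = y * (1 + noise * rng.standard_normal(len(y)))
            for xi, yi in zip(self.xs, y):
                rows.append({"x": xi, "spot": spot, "density": yi})
        return pd.DataFrame(rows)

    def test_noiseless_exact_recovery(self):
        params, se = fit_saturation(self._series())
        assert params.x0 == pytest.approx(2.4, abs=1e-6)
        for spot, a in (("CD45", 6400), ("CD3", 3580), ("CD19", 330)):
            assert params.a[spot] == pytest.approx(a, abs=1e-3)

    def test_single_concentration_rejected(self):
        df = pd.DataFrame({"x": [5, 5, 5], "spot": "CD45", "density": [1, 2, 3]})
        with pytest.raises(ValueError):
            fit_saturation(df)

    def test_flat_series_unidentifiable(self):
        df = pd.DataFrame(
            {"x": [1, 2, 4, 8], "spot": ["CD45"] * 4, "density": [5000.0] * 4}
        )
        with pytest.raises(ValueError, match="unidentifiable"):
            fit_saturation(df)

    def test_noisy_replicates_recover_parameters(self):
        rng = np.random.default_rng(1)
        x0s, a45s = [], []
        for _ in range(20):
            params, _ = fit_saturation(self._series(noise=0.05, rng=rng))
            x0s.append(params.x0)
            a45s.append(params.a["CD45"])
        assert np.mean(x0s) == pytest.approx(2.4, abs=0.2)
        assert np.mean(a45s) == pytest.approx(6400, abs=100)


class TestCrosstab:
    def test_single_donor_pure_population(self):
        df = pd.DataFrame(
            {"antibody": ["CD45"] * 300, "morphotype": ["small_lymphocyte"] * 300}
        )
        xt = crosstab([df])
        assert xt.mean_percent.loc["CD45", "small_lymphocyte"] == pytest.approx(100.0)

    def test_rows_are_compositions(self, healthy_capture):
        per_donor = []
        frames = []
        for ab in ("CD45", "CD3", "CD8", "CD14", "CD19"):
            cells = healthy_capture.spots[ab].cells
            frames.append(pd.DataFrame({"antibody": ab, "morphotype": cells["morphotype"]}))
        per_donor.append(pd.concat(frames, ignore_index=True))
        xt = crosstab(per_donor)
        sums = xt.mean_percent.sum(axis=1)
        assert ((sums - 100.0).abs() < 0.5).all()

    def test_low_count_warns(self):
        df = pd.DataFrame({"antibody": ["CD3"] * 10, "morphotype": ["small_lymphocyte"] * 10})
        with pytest.warns(UserWarning, match="only 10"):
            crosstab([df])


class TestImmunophenotypeCalls:
    def _xtab(self):
        mean = pd.DataFrame(
            {"granular_lymphocyte": [6.0, 23.0, 0.1, 0.0, 54.0, 2.0]},
            index=["CD3", "CD8", "CD4", "CD19", "CD16", "CD45x"],
        )
        sem = mean * 0 + 0.5
        from leukopan.quantify import MorphotypeByAntibody

        return MorphotypeByAntibody(mean, sem, 40)

    def test_positive_negative_split(self):
        call = call_immunophenotype(self._xtab(), "granular_lymphocyte")
        assert call.calls["CD3"] == "positive"
        assert call.calls["CD8"] == "positive"
        assert call.calls["CD16"] == "positive"
        assert call.calls["CD4"] == "negative"
        assert call.calls["CD19"] == "negative"

    def test_uniform_2pct_never_positive(self):
        from leukopan.quantify import MorphotypeByAntibody

        mean = pd.DataFrame({"m": [2.0, 2.0]}, index=["CD3", "CD19"])
        xt = MorphotypeByAntibody(mean, mean * 0 + 0.2, 10)
        call = call_immunophenotype(xt, "m")
        assert all(v != "positive" for v in call.calls.values())

    def test_absent_morphotype_rejected(self):
        with pytest.raises(ValueError):
            call_immunophenotype(self._xtab(), "plasma_cell")


def _oracle_p(a, b):
    """Independent exhaustive permutation oracle for the two-sided MW test."""
    pooled = np.concatenate([a, b])
    n1 = len(a)

    def u_of(idx):
        x = pooled[list(idx)]
        y = np.delete(pooled, list(idx))
        gt = sum((xi > yj) + 0.5 * (xi == yj) for xi in x for yj in y)
        return gt

    mu = n1 * len(b) / 2.0
    obs = abs(u_of(range(n1)) - mu)
    hits = total = 0
    for pick in combinations(range(len(pooled)), n1):
        total += 1
        if abs(u_of(pick) - mu) >= obs - 1e-12:
            hits += 1
    return hits / total


class TestMannWhitney:
    def test_separated_samples_exact_p(self):
        res = mann_whitney([1, 2, 3], [4, 5, 6])
        assert res.U == 0.0
        assert res.p == pytest.approx(0.1, abs=1e-12)

    def test_identical_samples(self):
        res = mann_whitney([1, 2, 2, 3], [1, 2, 2, 3])
        assert res.p == 1.0

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])

    @settings(max_examples=30, deadline=None)
    @given(
        st.lists(st.integers(0, 5), min_size=1, max_size=6),
        st.lists(st.integers(0, 5), min_size=1, max_size=6),
    )
    def test_matches_permutation_oracle_with_ties(self, a, b):
        res = mann_whitney(a, b)
        assert res.p == pytest.approx(_oracle_p(np.array(a, float), np.array(b, float)),
                                      abs=1e-12)
        assert 0 <= res.U <= len(a) * len(b)

    def test_large_sample_tracks_scipy_asymptotic(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 1, 30)
        b = rng.normal(0.7, 1, 25)
        res = mann_whitney(a, b)
        ref = mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        assert res.p == pytest.approx(ref.pvalue, rel=1e-6)


class TestReferenceRangesAndDiagnosis:
    def _profiles(self, n, seed=0, jitter=0.0):
        rng = np.random.default_rng(seed)
        base = pd.Series({"CD45": 6000.0, "CD3": 4200.0, "CD19": 700.0, "CD23": 80.0})
        out = []
        for _ in range(n):
            noisy = base * (1 + jitter * rng.standard_normal(len(base)))
            out.append(normalize(noisy))
        return out

    def test_constant_cohort_zero_width(self):
        with pytest.warns(UserWarning):
            r = reference_ranges(self._profiles(5))
        assert (r["hi"] - r["lo"]).abs().max() < 1e-9

    def test_two_donors_rejected(self):
        with pytest.raises(ValueError):
            reference_ranges(self._profiles(2))

    def test_interval_covers_generative_center(self):
        with pytest.warns(UserWarning):
            r = reference_ranges(self._profiles(19, jitter=0.05))
        assert r.loc["CD3", "lo"] <= 70.0 <= r.loc["CD3", "hi"]

    def test_healthy_profile_reports_normal(self):
        with pytest.warns(UserWarning):
            ranges = reference_ranges(self._profiles(10, jitter=0.03))
        prof = self._profiles(1, seed=99, jitter=0.0)[0]
        sugg = suggest_diagnosis(prof, ranges)
        assert sugg[0].disease == "normal"

    def test_panel_mismatch_rejected(self):
        with pytest.warns(UserWarning):
            ranges = reference_ranges(self._profiles(5, jitter=0.02))
        bad = normalize(pd.Series({"CD45": 6000.0, "CD3": 4000.0}))
        with pytest.raises(ValueError, match="panel mismatch"):
            flag_profile(bad, ranges)


class TestConcordance:
    def test_perfect_pairs(self):
        df = pd.DataFrame(
            {
                "cd": ["CD3"] * 4 + ["CD8"] * 4,
                "microarray_pct": [50, 60, 70, 80, 10, 20, 30, 40],
                "flow_pct": [50, 60, 70, 80, 10, 20, 30, 40],
            }
        )
        res = fc_concordance(df)
        assert all(r == pytest.approx(1.0) for r in res.pearson_r.values())
        assert res.slope == pytest.approx(1.0)

    def test_zero_variance_flagged(self):
        df = pd.DataFrame(
            {"cd": ["CD3"] * 4, "microarray_pct": [50] * 4, "flow_pct": [48, 50, 52, 51]}
        )
        res = fc_concordance(df)
        assert "CD3" in res.undefined

    def test_too_few_donors_rejected(self):
        df = pd.DataFrame({"cd": ["CD3"] * 2, "microarray_pct": [1, 2], "flow_pct": [1, 2]})
        with pytest.raises(ValueError):
            fc_concordance(df)
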
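import numpy as np
import pandas as pd
import pytest
from scipy import stats

from catchcurve import (
    AgeFrequency,
    SubsampleSpec,
    ancova_slopes,
    frequency_matched_subsample,
    nested_ancova,
    posthoc_pairs,
    species_ttest,
    temporal_trend,
)


def limb(slope, intercept=8.0, n=16, start=1.1, width=0.2, noise_sd=0.0, rng=None):
    """AgeFrequency whose log-counts follow intercept - slope * age (+ noise)."""
    ages = start + width * np.arange(n)
    ln_c = intercept - slope * ages
    if noise_sd:
        ln_c = ln_c + noise_sd * rng.standard_normal(n)
    return AgeFrequency(width, ages, np.exp(ln_c))


def glm_interaction_oracle(groups):
    """Brute-force extra-sum-of-squares F for slope homogeneity.

    Explicit design matrices, normal equations; full model = separate line
    per group, reduced model = separate intercepts, common slope.
    """
    rows = []
    for gi, af in enumerate(groups.values()):
        a, c = af.nonzero()
        for age, count in zip(a, c):
            rows.append((gi, age, np.log(count)))
    g = np.array([r[0] for r in rows])
    x = np.array([r[1] for r in rows])
    y = np.array([r[2] for r in rows])
    k = len(groups)
    n = len(rows)
    dummies = np.eye(k)[g]
    X_full = np.column_stack([dummies, dummies * x[:, None]])
    X_red = np.column_stack([dummies, x])

    def rss(X):
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ beta
        return r @ r

    rss_full, rss_red = rss(X_full), rss(X_red)
    df_num = k - 1
    df_den = n - 2 * k
    f = (rss_red - rss_full) / df_num / (rss_full / df_den)
    p = stats.f.sf(f, df_num, df_den)
    return f, df_num, df_den, p


class TestAncovaSlopes:
    def test_identical_groups_no_interaction(self):
        groups = {"a": limb(1.0), "b": limb(1.0)}
        comp = ancova_slopes(groups)
        assert comp.f_stat == pytest.approx(0.0, abs=1e-6)
        assert comp.group_fits["a"].z == pytest.approx(1.0, abs=1e-9)
        assert comp.group_fits["b"].z == pytest.approx(1.0, abs=1e-9)

    def test_distinct_noiseless_slopes_separate(self):
        comp = ancova_slopes({"a": limb(1.0), "b": limb(2.0)})
        assert comp.group_fits["a"].z == pytest.approx(1.0, abs=1e-9)
        assert comp.group_fits["b"].z == pytest.approx(2.0, abs=1e-9)
        assert comp.p < 1e-12

    def test_matches_design_matrix_oracle(self, rng):
        groups = {
            "a": limb(1.0, noise_sd=0.1, rng=rng),
            "b": limb(1.4, n=12, noise_sd=0.1, rng=rng),
            "c": limb(1.2, n=20, noise_sd=0.1, rng=rng),
        }
        comp = ancova_slopes(groups)
        f, df_num, df_den, p = glm_interaction_oracle(groups)
        assert comp.f_stat == pytest.approx(f, rel=1e-9)
        assert (comp.df_num, comp.df_den) == (df_num, df_den)
        assert comp.p == pytest.approx(p, rel=1e-9)

    def test_per_level_slopes_equal_separate_ols(self, rng):
        """ANCOVA per-level slopes coincide with independent per-group fits."""
        for _ in range(20):
            k = rng.integers(2, 5)
            groups = {
                f"g{i}": limb(rng.uniform(0.5, 2.5), n=int(rng.integers(5, 21)),
                              noise_sd=0.15, rng=rng)
                for i in range(k)
            }
            comp = ancova_slopes(groups)
            params = np.asarray(comp._model.params)
            names = comp._model.model.exog_names
            base = params[names.index("age")]
            for lvl, fit in comp.group_fits.items():
                term = f"C(level)[T.{lvl}]:age"
                slope = base + (params[names.index(term)] if term in names else 0.0)
                assert fit.z == pytest.approx(-slope, abs=1e-9)

    def test_short_level_rejected_by_name(self):
        groups = {"ok": limb(1.0), "tiny": limb(1.0, n=2)}
        with pytest.raises(ValueError, match="tiny"):
            ancova_slopes(groups)

    def test_single_level_rejected(self):
        with pytest.raises(ValueError, match="2 levels"):
            ancova_slopes({"a": limb(1.0)})


class TestNestedAncova:
    def test_homogeneous_cells_no_interaction(self):
        cells = {(s, r): limb(1.1) for s in ("S1", "S2") for r in ("MA", "OAA")}
        comp = nested_ancova(cells)
        assert comp.f_stat == pytest.approx(0.0, abs=1e-6)
        assert comp.df_num == 3  # 4 cells - 1

    def test_one_cell_slope_doubled(self):
        cells = {("S1", "MA"): limb(1.0), ("S1", "OAA"): limb(1.0),
                 ("S2", "MA"): limb(2.0), ("S2", "OAA"): limb(1.0)}
        comp = nested_ancova(cells)
        assert comp.group_fits["S2|MA"].z == pytest.approx(2.0, abs=1e-9)
        assert comp.p < 1e-12

    def test_matches_oracle_on_noisy_cells(self, rng):
        cells = {
            ("S1", "MA"): limb(1.0, noise_sd=0.1, rng=rng),
            ("S1", "OAA"): limb(1.5, noise_sd=0.1, rng=rng),
            ("S2", "MA"): limb(0.9, n=11, noise_sd=0.1, rng=rng),
            ("S2", "OAA"): limb(1.6, n=13, noise_sd=0.1, rng=rng),
        }
        comp = nested_ancova(cells)
        flat = {"|".join(k): v for k, v in cells.items()}
        f, df_num, df_den, p = glm_interaction_oracle(flat)
        assert comp.f_stat == pytest.approx(f, rel=1e-9)
        assert (comp.df_num, comp.df_den) == (df_num, df_den)


class TestPosthocPairs:
    def test_identical_pair_p_near_one(self):
        comp = ancova_slopes({"a": limb(1.0), "b": limb(1.0), "c": limb(2.0)})
        res = posthoc_pairs(comp, [("a", "b")])
        assert res[("a", "b")]["p"] > 0.99

    def test_distinct_noiseless_pair_p_tiny(self):
        comp = ancova_slopes({"a": limb(1.0), "b": limb(2.0), "c": limb(1.5)})
        res = posthoc_pairs(comp, [("a", "b")])
        assert res[("a", "b")]["p"] < 1e-10

    def test_contrast_equals_slope_difference_t_squared(self, rng):
        """Pair F equals squared t of the slope difference from the oracle
        covariance matrix of the full design-matrix solve."""
        groups = {
            "a": limb(1.0, noise_sd=0.1, rng=rng),
            "b": limb(1.3, noise_sd=0.1, rng=rng),
            "c": limb(1.6, n=10, noise_sd=0.1, rng=rng),
        }
        comp = ancova_slopes(groups)
        res = posthoc_pairs(comp, [("b", "c")])
        # oracle: cell-means coding, slope per group, full covariance
        rows = []
        for gi, af in enumerate(groups.values()):
            a, c = af.nonzero()
            rows.extend((gi, age, np.log(ct)) for age, ct in zip(a, c))
        g = np.array([r[0] for r in rows]); x = np.array([r[1] for r in rows])
        y = np.array([r[2] for r in rows])
        D = np.eye(3)[g]
        X = np.column_stack([D, D * x[:, None]])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        resid = y - X @ beta
        s2 = resid @ resid / (len(y) - 6)
        cov = s2 * np.linalg.inv(X.T @ X)
        cvec = np.zeros(6); cvec[4] = 1.0; cvec[5] = -1.0  # slope(b) - slope(c)
        t = (cvec @ beta) / np.sqrt(cvec @ cov @ cvec)
        assert res[("b", "c")]["f"] == pytest.approx(t * t, rel=1e-9)

    def test_unknown_level_rejected(self):
        comp = ancova_slopes({"a": limb(1.0), "b": limb(2.0)})
        with pytest.raises(ValueError, match="unknown level"):
            posthoc_pairs(comp, [("a", "zzz")])

    def test_holm_adjustment_monotone(self, rng):
        groups = {l: limb(s, noise_sd=0.1, rng=rng)
                  for l, s in zip("abc", (1.0, 1.3, 1.6))}
        comp = ancova_slopes(groups)
        pairs = [("a", "b"), ("a", "c"), ("b", "c")]
        raw = posthoc_pairs(comp, pairs)
        adj = posthoc_pairs(comp, pairs, adjust="holm")
        for pr in pairs:
            assert adj[pr]["p"] >= raw[pr]["p"] - 1e-15


class TestTemporalTrend:
    def test_constant_series_f_zero(self):
        pts = [("A", 1999 + i, 1.5) for i in range(10)]
        res = temporal_trend(pts)
        assert res["f"] == pytest.approx(0.0, abs=1e-20)
        assert res["p"] == pytest.approx(1.0)

    def test_perfect_linear_r2_one(self):
        pts = [("A", 2000 + i, 1.0 + 0.05 * i) for i in range(8)]
        res = temporal_trend(pts)
        assert res["r2"] == pytest.approx(1.0)

    def test_noisy_54_points_matches_ols_oracle(self, rng):
        years = np.tile(np.arange(1999, 2013), 4)[:54]
        z = 1.5 + 0.01 * (years - 2005) + 0.2 * rng.standard_normal(54)
        pts = [(f"ma{i % 5}", int(y), zz) for i, (y, zz) in enumerate(zip(years, z))]
        res = temporal_trend(pts)
        assert (res["df_num"], res["df_den"]) == (1, 52)
        lr = stats.linregress(years.astype(float), z)
        t = lr.slope / lr.stderr
        assert res["f"] == pytest.approx(t * t, rel=1e-9)
        assert res["p"] == pytest.approx(lr.pvalue, rel=1e-9)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            temporal_trend([("A", 2000, 1.0), ("A", 2001, 1.1)])


class TestSpeciesTTest:
    def test_identical_samples_t_zero(self):
        res = species_ttest([1.0, 1.2, 1.4], [1.0, 1.2, 1.4])
        assert res["t"] == pytest.approx(0.0, abs=1e-12)

    def test_df_from_study_cell_counts(self, rng):
        z1 = rng.normal(2.0, 0.3, size=54)
        z2 = rng.normal(0.6, 0.2, size=53)
        assert species_ttest(z1, z2)["df"] == 105

    def test_matches_pooled_variance_formula(self):
        a = [1.9, 2.1, 2.4, 1.7, 2.2]
        b = [0.5, 0.7, 0.6]
        res = species_ttest(a, b)
        a, b = np.array(a), np.array(b)
        sp2 = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / (a.size + b.size - 2)
        t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / a.size + 1 / b.size))
        assert res["t"] == pytest.approx(t, rel=1e-12)
        assert res["df"] == 6

    def test_antisymmetric_in_arguments(self, rng):
        z1 = rng.normal(1.0, 0.2, 10)
        z2 = rng.normal(1.5, 0.2, 12)
        r12, r21 = species_ttest(z1, z2), species_ttest(z2, z1)
        assert r12["t"] == pytest.approx(-r21["t"])
        assert r12["p"] == pytest.approx(r21["p"])

    def test_degenerate_variance_rejected(self):
        with pytest.raises(ValueError):
            species_ttest([1.0, 1.0], [2.0, 2.0])


def records_df(lengths):
    return pd.DataFrame({"length_mm": np.asarray(lengths, dtype=float)})


class TestFrequencyMatchedSubsample:
    def test_full_size_is_permutation(self, rng):
        df = records_df(rng.uniform(20, 120, size=80))
        out = frequency_matched_subsample(df, SubsampleSpec(n_target=80, seed=0))
        assert sorted(out["length_mm"]) == pytest.approx(sorted(df["length_mm"]))

    def test_two_class_proportional_split(self):
        # 100 records in one 1-mm class, 300 in another; quota 100 -> 25/75
        df = records_df([10.5] * 100 + [20.5] * 300)
        out = frequency_matched_subsample(df, SubsampleSpec(n_target=100, seed=1))
        counts = np.floor(out["length_mm"]).value_counts()
        assert counts[10] == 25 and counts[20] == 75

    def test_output_size_exact(self, rng):
        # a large pool downsampled to the study's open-access quota
        df = records_df(rng.normal(100, 15, size=1352).clip(30, 160))
        out = frequency_matched_subsample(df, SubsampleSpec(n_target=422, seed=2))
        assert len(out) == 422

    def test_proportions_within_largest_remainder_bound(self, rng):
        df = records_df(rng.uniform(30, 90, size=600))
        n_t = 150
        out = frequency_matched_subsample(df, SubsampleSpec(n_target=n_t, seed=3))
        src = np.floor(df["length_mm"]).value_counts(normalize=True)
        got = np.floor(out["length_mm"]).value_counts(normalize=True)
        for cls, p_src in src.items():
            p_got = got.get(cls, 0.0)
            assert abs(p_got - p_src) <= 1.0 / n_t + 1e-12

    def test_oversized_target_rejected(self, rng):
        df = records_df(rng.uniform(30, 90, size=10))
        with pytest.raises(ValueError):
            frequency_matched_subsample(df, SubsampleSpec(n_target=11))

    def test_seed_reproducible(self, rng):
        df = records_df(rng.uniform(30, 90, size=200))
        a = frequency_matched_subsample(df, SubsampleSpec(77, seed=9))
        b = frequency_matched_subsample(df, SubsampleSpec(77, seed=9))
        pd.testing.assert_frame_equal(a, b)
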
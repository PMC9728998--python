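import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from vnseeg.clinical import reference_cohort
from vnseeg.stats import (
    build_fdr_families,
    classify_responder,
    cohens_d,
    compare_groups,
    correlate_with_outcome,
    fdr_bh,
    labar_index,
    mann_whitney_u,
    relative_variation,
    spearman_rho,
)

from tests_support import bh_stepup_bruteforce, mwu_enumeration_p


# ---------------------------------------------------------------- MWU


class TestMannWhitney:
    def test_disjoint_samples_exact(self):
        u, p = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert u == 0
        assert p == pytest.approx(0.1)

    def test_identical_multisets_p_near_one(self):
        vals = list(range(10))
        _, p = mann_whitney_u(vals, vals)
        assert p > 0.9

    def test_invariant_to_monotone_transform(self, rng):
        x = rng.normal(0, 1, 12)
        y = rng.normal(0.5, 1, 15)
        u1, p1 = mann_whitney_u(x, y)
        u2, p2 = mann_whitney_u(np.exp(x), np.exp(y))
        assert u1 == u2 and p1 == pytest.approx(p2)

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])

    @pytest.mark.parametrize("n1,n2,seed", [(3, 4, 0), (5, 5, 1), (6, 4, 2), (2, 6, 3)])
    def test_exact_branch_matches_full_enumeration(self, n1, n2, seed):
        gen = np.random.default_rng(seed)
        x = gen.normal(0, 1, n1)
        y = gen.normal(0.8, 1, n2)
        _, p = mann_whitney_u(x, y)
        assert p == pytest.approx(mwu_enumeration_p(x, y), abs=1e-12)


# ---------------------------------------------------------------- FDR


class TestFdrBH:
    def test_single_p_unchanged(self):
        adj, mask = fdr_bh([0.03])
        assert adj[0] == pytest.approx(0.03)
        assert mask[0]

    def test_all_equal_stay_equal(self):
        adj, _ = fdr_bh([0.2, 0.2, 0.2, 0.2])
        np.testing.assert_allclose(adj, 0.2)

    def test_hand_example(self):
        adj, mask = fdr_bh([0.01, 0.02, 0.04, 0.60])
        np.testing.assert_allclose(adj, [0.04, 0.04, 4 * 0.04 / 3, 0.60])
        assert mask.tolist() == [True, True, False, False]

    def test_out_of_range_errors(self):
        with pytest.raises(ValueError):
            fdr_bh([0.0, 0.5])
        with pytest.raises(ValueError):
            fdr_bh([0.5, 1.5])

    def test_adjusted_at_least_raw_and_monotone_mask(self, rng):
        p = rng.uniform(0.001, 1.0, 30)
        adj, _ = fdr_bh(p)
        assert (adj >= p - 1e-12).all()
        masks = [fdr_bh(p, alpha=a)[1].sum() for a in (0.01, 0.05, 0.2, 0.5)]
        assert masks == sorted(masks)

    def test_matches_bruteforce_on_1000_random_vectors(self):
        gen = np.random.default_rng(17)
        for _ in range(1000):
            m = gen.integers(1, 12)
            p = gen.uniform(1e-6, 1.0, m)
            adj, _ = fdr_bh(p)
            np.testing.assert_allclose(adj, bh_stepup_bruteforce(p), atol=1e-12)

    @given(st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=20))
    def test_property_matches_stepup_definition(self, p):
        adj, _ = fdr_bh(p)
        np.testing.assert_allclose(adj, bh_stepup_bruteforce(p), atol=1e-12)


# ---------------------------------------------------------------- effect sizes


class TestCohensD:
    def test_unit_difference_unit_sd(self, rng):
        x = rng.normal(1, 1, 20000)
        y = rng.normal(0, 1, 20000)
        assert cohens_d(x, y) == pytest.approx(1.0, abs=0.05)

    def test_identical_samples_zero(self):
        assert cohens_d([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 0.0

    def test_arithmetic_example(self):
        # equal-n, means 0.18/0.17, sd 0.04/0.03 -> 0.01/sqrt(0.00125)
        gen = np.random.default_rng(0)

        def sample(mean, sd, n=400):
            z = gen.normal(0, 1, n)
            z = (z - z.mean()) / z.std(ddof=1)
            return mean + sd * z

        d = cohens_d(sample(0.18, 0.04), sample(0.17, 0.03))
        assert d == pytest.approx(0.01 / math.sqrt((0.04**2 + 0.03**2) / 2), abs=1e-9)

    def test_zero_pooled_sd_flagged(self):
        with pytest.warns(UserWarning):
            assert math.isnan(cohens_d([1.0, 1.0], [1.0, 1.0]))


class TestRelativeVariation:
    def test_examples(self):
        assert relative_variation([2.0, 2.0], [1.0, 1.0]) == pytest.approx(-0.5)
        assert relative_variation([1, 2, 3], [1, 2, 3]) == 0.0
        assert relative_variation([1, 2, 3], [2, 4, 6]) == pytest.approx(1.0)

    def test_zero_pre_median_flagged(self):
        with pytest.warns(UserWarning):
            assert math.isnan(relative_variation([-1, 0, 1], [1, 2, 3]))


# ---------------------------------------------------------------- Labar


class TestLabar:
    @pytest.mark.parametrize(
        "pre,post,expected",
        [(11.80, 11.25, 4.66), (43.70, 47.40, -8.47), (0.13, 0.00, 100.00)],
    )
    def test_worked_examples(self, pre, post, expected):
        assert round(labar_index(pre, post), 2) == expected

    def test_both_zero_defined_as_zero(self):
        assert labar_index(0.0, 0.0) == 0.0

    def test_zero_pre_with_seizures_after_flagged(self):
        with pytest.warns(UserWarning):
            assert math.isnan(labar_index(0.0, 2.0))

    def test_reference_cohort_reproduced(self):
        df = reference_cohort()
        consistent = df[df["id"] <= 9]
        for _, row in consistent.iterrows():
            got = round(labar_index(row.pre_rate, row.post_rate), 2)
            assert got == row.labar_printed, row.id

    def test_responder_split_is_five_five(self):
        df = reference_cohort()
        groups = [
            classify_responder(labar_index(r.pre_rate, r.post_rate))[0]
            for r in df.itertuples()
        ]
        assert groups.count("R") == 5
        assert groups.count("NR") == 5


class TestClassifyResponder:
    @pytest.mark.parametrize(
        "labar,group,bucket",
        [
            (85.67, "R", "I"),
            (99.50, "R", "I"),
            (72.0, "R", "II"),
            (50.0, "R", "II"),
            (49.99, "NR", "other"),
            (4.66, "NR", "other"),
            (-8.47, "NR", "other"),
        ],
    )
    def test_rule(self, labar, group, bucket):
        assert classify_responder(labar) == (group, bucket)


# ---------------------------------------------------------------- Spearman


class TestSpearman:
    def test_monotone_extremes(self):
        x = [1.0, 2.0, 5.0, 9.0]
        rho_up, _ = spearman_rho(x, [2.0, 4.0, 6.0, 8.0])
        rho_dn, _ = spearman_rho(x, [8.0, 6.0, 4.0, 2.0])
        assert rho_up == pytest.approx(1.0)
        assert rho_dn == pytest.approx(-1.0)

    def test_hand_example(self):
        rho, _ = spearman_rho([1, 2, 3, 4], [2, 1, 4, 3])
        assert rho == pytest.approx(0.6)

    def test_exact_permutation_p(self):
        # n=4 perfectly concordant: 1/24 permutations reach |rho|=1 on each
        # side -> two-sided p = 2/24
        _, p = spearman_rho([1, 2, 3, 4], [10, 20, 30, 40])
        assert p == pytest.approx(2 / 24)

    def test_constant_input_flagged(self):
        with pytest.warns(UserWarning):
            rho, p = spearman_rho([1, 1, 1], [1, 2, 3])
        assert math.isnan(rho)

    def test_large_n_t_approximation_close_to_scipy(self, rng):
        from scipy import stats as sps

        x = rng.normal(0, 1, 30)
        y = x + rng.normal(0, 1, 30)
        rho, p = spearman_rho(x, y)
        ref = sps.spearmanr(x, y)
        assert rho == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue, rel=1e-6)


# ---------------------------------------------------------------- families & tables


def _feature_frame(rows):
    return pd.DataFrame(
        rows,
        columns=["measure", "group", "scale", "unit", "variable", "p_raw"],
    )


class TestFdrFamilies:
    def test_regional_pli_family_spans_bands(self):
        rows = [
            ("pli", "R", "regional", region, band, 0.05)
            for region in ("frontal", "occipital")
            for band in ("delta", "theta", "alpha", "beta", "gamma")
        ]
        fam = build_fdr_families(_feature_frame(rows))
        assert fam.nunique() == 2
        assert fam.value_counts().tolist() == [5, 5]

    def test_channel_scale_single_family_by_default(self):
        rows = [
            ("pli", "R", "channel", ch, band, 0.5)
            for ch in ("Cz", "Pz", "Fz")
            for band in ("delta", "alpha")
        ]
        fam = build_fdr_families(_feature_frame(rows))
        assert fam.nunique() == 1

    def test_aperiodic_global_family(self):
        rows = [
            ("aperiodic", "NR", "global", "global", param, 0.2)
            for param in ("offset", "exponent")
        ]
        fam = build_fdr_families(_feature_frame(rows))
        assert fam.nunique() == 1

    def test_unlabeled_errors(self):
        with pytest.raises(ValueError):
            build_fdr_families(pd.DataFrame({"p_raw": [0.1]}))


def _long_table(rng, shift_nr_offset=0.0, n_subj=5, n_epochs=20):
    """Epoch-level global feature table with a controllable NR offset shift."""
    rows = []
    for group in ("R", "NR"):
        for s in range(n_subj):
            subj = f"{group}{s}"
            base = rng.normal(1.5, 0.2)
            for session in ("pre", "post"):
                for measure, variable, sd in (
                    ("aperiodic", "offset", 0.05),
                    ("aperiodic", "exponent", 0.05),
                    ("pli", "alpha", 0.02),
                ):
                    shift = (
                        shift_nr_offset
                        if (group == "NR" and variable == "offset"
                            and session == "post")
                        else 0.0
                    )
                    for e in range(n_epochs):
                        rows.append(
                            {
                                "subject": subj,
                                "group": group,
                                "session": session,
                                "measure": measure,
                                "scale": "global",
                                "unit": "global",
                                "variable": variable,
                                "epoch": e,
                                "value": base + shift + rng.normal(0, sd),
                            }
                        )
    return pd.DataFrame(rows)


class TestCompareGroups:
    def test_injected_nr_offset_shift_detected_with_up_trend(self, rng):
        table = _long_table(rng, shift_nr_offset=0.3)
        out = compare_groups(table)
        nr_offset = out[(out.group == "NR") & (out.variable == "offset")].iloc[0]
        r_offset = out[(out.group == "R") & (out.variable == "offset")].iloc[0]
        assert nr_offset.significant and nr_offset.trend == "up"
        assert not r_offset.significant

    def test_identical_pre_post_family_error_controlled(self):
        # null replicates: family-level false discoveries bounded near alpha
        gen = np.random.default_rng(99)
        n_sig = 0
        n_families = 0
        for _ in range(200):
            table = _long_table(gen, shift_nr_offset=0.0, n_subj=2, n_epochs=5)
            out = compare_groups(table)
            for _, fam in out.groupby("family"):
                n_families += 1
                n_sig += int(fam.significant.any())
        assert n_sig / n_families <= 0.05 + 3 * math.sqrt(0.05 * 0.95 / n_families)

    def test_missing_group_errors(self, rng):
        table = _long_table(rng)
        with pytest.raises(ValueError):
            compare_groups(table[table.group == "R"])

    def test_subject_mode_uses_medians(self, rng):
        table = _long_table(rng, shift_nr_offset=0.3)
        out = compare_groups(table, unit_mode="subject")
        nr_offset = out[(out.group == "NR") & (out.variable == "offset")].iloc[0]
        assert nr_offset.n_pre == 5  # subjects, not epochs


class TestCorrelateWithOutcome:
    def _subjects(self, labar):
        return pd.DataFrame(
            {"subject": [f"s{i}" for i in range(len(labar))], "labar": labar}
        )

    def _features(self, labar, slope, noise_sd, rng, n_epochs=10):
        rows = []
        for i, lab in enumerate(labar):
            base = 2.0
            variation = slope * lab / 100 + rng.normal(0, noise_sd)
            for session, level in (("pre", base), ("post", base * (1 + variation))):
                for e in range(n_epochs):
                    rows.append(
                        {
                            "subject": f"s{i}",
                            "group": "R",
                            "session": session,
                            "measure": "aperiodic",
                            "scale": "global",
                            "unit": "global",
                            "variable": "exponent",
                            "epoch": e,
                            "value": level + rng.normal(0, 0.01),
                        }
                    )
        return pd.DataFrame(rows)

    def test_linear_anticorrelation_recovered(self, rng):
        labar = np.linspace(-20, 100, 8)
        feats = self._features(labar, slope=-0.3, noise_sd=0.005, rng=rng)
        out = correlate_with_outcome(self._subjects(labar), feats)
        assert out.iloc[0].rho < -0.9

    def test_independent_variation_rarely_significant(self):
        gen = np.random.default_rng(5)
        sig = 0
        for _ in range(200):
            labar = gen.uniform(-20, 100, 8)
            feats = self._features(labar, slope=0.0, noise_sd=0.2, rng=gen)
            out = correlate_with_outcome(self._subjects(labar), feats)
            sig += int(out.iloc[0].p < 0.05)
        assert sig / 200 <= 0.10

    def test_minimal_three_subjects_defined(self, rng):
        labar = np.array([10.0, 50.0, 90.0])
        feats = self._features(labar, slope=-0.3, noise_sd=0.01, rng=rng)
        out = correlate_with_outcome(self._subjects(labar), feats)
        assert np.isfinite(out.iloc[0].rho)
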
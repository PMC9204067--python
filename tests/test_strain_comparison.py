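"""Sample correlations, the rank-sum screen and cohort-level trends."""

import itertools

import numpy as np
import pandas as pd
import pytest

import muriclock as mc
from muriclock.errors import (
    UndefinedCorrelationError,
    UnderpoweredDesignError,
    ValidationError,
)
from conftest import strain_samples


def exact_ranksum_p(a, b):
    """Two-sided exact rank-sum p by full enumeration over group assignments.

    Enumerates every C(n1+n2, n1) split of the pooled values, computes the
    Mann-Whitney U of the first group, and doubles the smaller tail
    (capped at 1) — independent of any library routine.
    """
    pooled = np.concatenate([a, b])
    n1 = len(a)
    ranks = pd.Series(pooled).rank().to_numpy()
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    us = []
    for idx in itertools.combinations(range(len(pooled)), n1):
        us.append(ranks[list(idx)].sum() - n1 * (n1 + 1) / 2)
    us = np.asarray(us)
    p = 2 * min((us <= u_obs).mean(), (us >= u_obs).mean())
    return min(p, 1.0)


class TestSampleCorrelationMatrix:
    def test_duplicate_samples_correlate_perfectly(self):
        rng = np.random.default_rng(0)
        col = rng.uniform(0, 1, 50)
        v = pd.DataFrame({"s1": col, "s2": col, "s3": rng.uniform(0, 1, 50)})
        r = mc.sample_correlation_matrix(mc.BetaMatrix(v))
        assert r.at["s1", "s2"] == pytest.approx(1.0)
        assert (np.diag(r) == 1.0).all()

    def test_anticorrelated_pair(self):
        x = np.linspace(0.1, 0.9, 20)
        v = pd.DataFrame({"up": x, "down": x[::-1]})
        r = mc.sample_correlation_matrix(mc.BetaMatrix(v))
        assert r.at["up", "down"] == pytest.approx(-1.0)

    def test_within_strain_exceeds_between_strain(self, small_cohort):
        matrix, sheet, _, _ = small_cohort
        r = mc.sample_correlation_matrix(matrix)
        b6 = strain_samples(sheet, "B6")
        dba = strain_samples(sheet, "DBA")
        within = np.concatenate(
            [r.loc[b6, b6].to_numpy()[np.triu_indices(len(b6), 1)],
             r.loc[dba, dba].to_numpy()[np.triu_indices(len(dba), 1)]]
        )
        between = r.loc[b6, dba].to_numpy().ravel()
        assert within.mean() > between.mean()

    def test_symmetric_and_psd(self, small_cohort):
        matrix = small_cohort[0]
        sub = matrix.subset(probes=matrix.probe_ids[:500])
        r = mc.sample_correlation_matrix(sub)
        np.testing.assert_allclose(r.to_numpy(), r.to_numpy().T, atol=1e-12)
        eigs = np.linalg.eigvalsh(r.to_numpy())
        assert eigs.min() >= -1e-10

    def test_too_few_shared_probes_names_pair(self):
        v = pd.DataFrame(
            {
                "s1": [0.1, 0.2, np.nan, np.nan],
                "s2": [np.nan, np.nan, 0.3, 0.4],
                "s3": [0.1, 0.2, 0.3, 0.4],
            }
        )
        with pytest.raises(ValidationError, match="s1.*s2"):
            mc.sample_correlation_matrix(mc.BetaMatrix(v))


class TestDifferentialMethylation:
    def _cohort(self, A, B):
        """Build a matrix/sheet with per-probe group values A|B."""
        A, B = np.atleast_2d(A), np.atleast_2d(B)
        na, nb = A.shape[1], B.shape[1]
        ids = [f"g1_{i}" for i in range(na)] + [f"g2_{i}" for i in range(nb)]
        v = pd.DataFrame(
            np.hstack([A, B]),
            index=[f"p{i}" for i in range(A.shape[0])],
            columns=ids,
        )
        sheet = pd.DataFrame(
            {
                "sample_id": ids,
                "strain": ["B6"] * na + ["DBA"] * nb,
                "sex": "F",
                "age_weeks": 10.0,
            }
        )
        return mc.BetaMatrix(v), sheet

    def test_identical_groups_not_significant(self):
        a = np.array([0.1, 0.2, 0.3, 0.4])
        matrix, sheet = self._cohort(a, a)
        res = mc.differential_methylation(matrix, sheet)
        assert res["p_raw"].iloc[0] == pytest.approx(1.0)
        assert not res["significant"].iloc[0]

    def test_exact_p_matches_enumeration_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            a = rng.uniform(0, 1, 4)
            b = rng.uniform(0, 1, 4)
            matrix, sheet = self._cohort(a, b)
            res = mc.differential_methylation(matrix, sheet)
            assert res["p_raw"].iloc[0] == pytest.approx(
                exact_ranksum_p(a, b), abs=1e-12
            )

    def test_separated_groups_hit_enumeration_minimum(self):
        a = np.array([0.1, 0.11, 0.12, 0.13])
        b = np.array([0.9, 0.91, 0.92, 0.93])
        matrix, sheet = self._cohort(a, b)
        res = mc.differential_methylation(matrix, sheet)
        # complete separation of 4v4: p = 2/C(8,4) = 2/70
        assert res["p_raw"].iloc[0] == pytest.approx(2 / 70)
        assert res["p_raw"].iloc[0] == pytest.approx(exact_ranksum_p(a, b))

    def test_small_group_is_underpowered(self):
        matrix, sheet = self._cohort([0.1, 0.2, 0.3], [0.4, 0.5, 0.6, 0.7])
        with pytest.raises(UnderpoweredDesignError):
            mc.differential_methylation(matrix, sheet)

    def test_label_swap_invariance(self):
        rng = np.random.default_rng(8)
        A = rng.uniform(0, 1, size=(20, 6))
        B = rng.uniform(0, 1, size=(20, 6))
        m1, s1 = self._cohort(A, B)
        m2, s2 = self._cohort(B, A)
        r1 = mc.differential_methylation(m1, s1)
        r2 = mc.differential_methylation(m2, s2)
        np.testing.assert_allclose(r1["p_raw"], r2["p_raw"], atol=1e-12)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(9)
        A = rng.uniform(0.01, 0.99, size=(10, 5))
        B = rng.uniform(0.01, 0.99, size=(10, 5))
        r1 = mc.differential_methylation(*self._cohort(A, B))
        r2 = mc.differential_methylation(*self._cohort(A**3, B**3))
        np.testing.assert_allclose(r1["p_raw"], r2["p_raw"], atol=1e-12)

    def test_bonferroni_monotone_and_capped(self):
        rng = np.random.default_rng(10)
        A = rng.uniform(0.0, 0.85, size=(50, 8))
        B = rng.uniform(0.1, 0.95, size=(50, 8))
        res = mc.differential_methylation(*self._cohort(A, B))
        assert (res["p_adj"] <= 1.0).all()
        # uncapped entries are scaled by one common divisor (m = 50)
        uncapped = res[res["p_adj"] < 1.0]
        np.testing.assert_allclose(uncapped["p_adj"], uncapped["p_raw"] * 50)
        # adjustment never inverts the raw ordering
        ordered = res.sort_values("p_raw")["p_adj"].to_numpy()
        assert (np.diff(ordered) >= -1e-15).all()

    def test_strain_offset_probes_detected(self):
        """>=95% of planted offset >= 0.3 probes flagged at 12 v 12."""
        spec = mc.CohortSpec(seed=31, n_probes=5000, n_strain_offset=500)
        matrix, sheet, ann, truth = mc.generate_mouse_cohort(spec)
        keep = ~(
            ann["is_snp"] | ann["is_cross_reactive"]
            | mc.methylome_io.is_xy(ann["chrom"])
        )
        sub = matrix.subset(probes=ann.loc[keep, "probe_id"])
        res = mc.differential_methylation(sub, sheet)
        off = truth.loc[
            (truth["class"] == "strain_offset")
            & (truth["strain_offset"].abs() >= 0.3),
            "probe_id",
        ]
        off = [p for p in off if p in res.index]
        flagged = res.loc[off, "significant"].mean()
        assert flagged >= 0.95


class TestSexEffect:
    def test_identical_distributions_not_significant(self):
        delta = np.concatenate([np.arange(6), np.arange(6) + 0.5])
        sexes = np.array(["M"] * 6 + ["F"] * 6)
        assert mc.sex_effect_test(delta, sexes) >= 0.05

    def test_planted_shift_detected(self):
        rng = np.random.default_rng(4)
        delta = np.concatenate(
            [rng.normal(0, 1, 10), rng.normal(30, 1, 10)]
        )
        sexes = np.array(["M"] * 10 + ["F"] * 10)
        assert mc.sex_effect_test(delta, sexes) < 0.01

    def test_single_sex_cohort_errors(self):
        with pytest.raises(UnderpoweredDesignError):
            mc.sex_effect_test([1.0, 2.0, 3.0, 4.0], np.array(["M"] * 4))

    def test_agrees_with_rank_sum_screen(self):
        rng = np.random.default_rng(5)
        m_vals, f_vals = rng.uniform(0, 1, 6), rng.uniform(0, 1, 6)
        p_sex = mc.sex_effect_test(
            np.concatenate([m_vals, f_vals]), np.array(["M"] * 6 + ["F"] * 6)
        )
        ids = [f"s{i}" for i in range(12)]
        matrix = mc.BetaMatrix(
            pd.DataFrame([np.concatenate([m_vals, f_vals])], index=["p0"],
                         columns=ids)
        )
        sheet = pd.DataFrame(
            {"sample_id": ids, "strain": ["B6"] * 6 + ["DBA"] * 6,
             "sex": "F", "age_weeks": 10.0}
        )
        p_dm = mc.differential_methylation(matrix, sheet)["p_raw"].iloc[0]
        assert p_sex == pytest.approx(p_dm, abs=1e-12)


class TestGlobalTrend:
    def _sheet(self, ids, ages):
        return pd.DataFrame(
            {"sample_id": ids, "strain": "B6", "sex": "F", "age_weeks": ages}
        )

    def test_constant_fraction_has_undefined_correlation(self):
        ids = ["s1", "s2", "s3"]
        v = pd.DataFrame(0.9, index=["p1", "p2"], columns=ids)
        with pytest.raises(UndefinedCorrelationError):
            mc.global_methylation_trend(
                mc.BetaMatrix(v), self._sheet(ids, [10.0, 50.0, 90.0])
            )

    def test_threshold_one_gives_zero_fractions(self):
        ids = ["s1", "s2", "s3"]
        v = pd.DataFrame(
            np.random.default_rng(0).uniform(0, 1, (5, 3)), columns=ids
        )
        with pytest.raises(UndefinedCorrelationError):
            mc.global_methylation_trend(
                mc.BetaMatrix(v), self._sheet(ids, [10.0, 50.0, 90.0]),
                call_threshold=1.0,
            )

    def test_planted_demethylation_gives_negative_trend(self):
        rng = np.random.default_rng(6)
        ids = [f"s{i}" for i in range(10)]
        ages = np.linspace(10, 100, 10)
        # fraction of probes above 0.5 decreases with age
        v = np.empty((200, 10))
        for j, age in enumerate(ages):
            p_meth = 0.7 - 0.4 * (age - 10) / 90
            v[:, j] = np.where(rng.random(200) < p_meth, 0.8, 0.2)
        table, r = mc.global_methylation_trend(
            mc.BetaMatrix(pd.DataFrame(v, columns=ids)), self._sheet(ids, ages)
        )
        assert r < 0
        assert table["fraction_methylated"].between(0, 1).all()
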
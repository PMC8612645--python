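"""Statistical layer: oracles for the omnibus tests, correlation and
the OLS regression ledger."""

import math

import numpy as np
import pandas as pd
import pytest

from tonicephys.group_stats import (
    DEFAULT_MODEL_SPECS,
    correlate,
    fit_regression_ledger,
    omnibus_and_posthoc,
)


def _kruskal_h_oracle(groups):
    """Brute-force Kruskal-Wallis H from first principles (rank sums,
    tie-corrected)."""
    all_vals = np.concatenate(groups)
    order = np.argsort(all_vals, kind="mergesort")
    ranks = np.empty(len(all_vals))
    sorted_vals = all_vals[order]
    i = 0
    while i < len(sorted_vals):
        j = i
        while j < len(sorted_vals) and sorted_vals[j] == sorted_vals[i]:
            j += 1
        ranks[order[i:j]] = 0.5 * (i + 1 + j)
        i = j
    n = len(all_vals)
    pos = 0
    h = 0.0
    for g in groups:
        r = ranks[pos:pos + len(g)]
        h += r.sum() ** 2 / len(g)
        pos += len(g)
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    _, counts = np.unique(all_vals, return_counts=True)
    tie = 1.0 - ((counts ** 3 - counts).sum() / (n ** 3 - n))
    return h / tie


class TestOmnibus:
    def test_identical_groups_give_null_result(self):
        v = [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]
        g = ["a"] * 3 + ["b"] * 3
        r = omnibus_and_posthoc(v, g, "student_t")
        assert r.statistic == pytest.approx(0.0, abs=1e-12)
        assert r.p == pytest.approx(1.0)

    def test_kruskal_matches_rank_oracle(self):
        groups = [np.array([1.0, 2.0, 3.0]), np.array([4.0, 5.0, 6.0])]
        v = np.concatenate(groups)
        g = ["a"] * 3 + ["b"] * 3
        r = omnibus_and_posthoc(v, g, "kruskal+dunn")
        assert r.statistic == pytest.approx(_kruskal_h_oracle(groups), abs=1e-12)

    def test_kruskal_oracle_with_ties(self, rng):
        groups = [rng.integers(0, 4, size=8).astype(float) for _ in range(3)]
        v = np.concatenate(groups)
        g = np.repeat(["a", "b", "c"], 8)
        r = omnibus_and_posthoc(v, g, "kruskal+dunn")
        assert r.statistic == pytest.approx(_kruskal_h_oracle(groups), abs=1e-10)
        assert len(r.post_hoc) == 3

    def test_zero_within_variance_distinct_means_guarded(self):
        v = [1.0, 1.0, 2.0, 2.0, 5.0, 5.0]
        g = ["a", "a", "b", "b", "c", "c"]
        r = omnibus_and_posthoc(v, g, "anova+tukey")
        assert r.p < 1e-15
        assert math.isinf(r.statistic) or r.statistic > 1e10

    def test_constant_everything_returns_p_one(self):
        r = omnibus_and_posthoc([3.0] * 8, ["a"] * 4 + ["b"] * 4, "anova+tukey")
        assert r.statistic == 0.0 and r.p == 1.0

    def test_two_way_anova_type_ii(self, rng):
        """Main effect recovered in an unbalanced design."""
        rows = []
        for a in ("x", "y"):
            for b in ("u", "v"):
                n = 8 if (a, b) != ("y", "v") else 4  # unbalanced
                mu = 3.0 if a == "y" else 0.0
                for val in rng.normal(mu, 1.0, n):
                    rows.append((val, (a, b)))
        v = [r[0] for r in rows]
        g = [r[1] for r in rows]
        r = omnibus_and_posthoc(v, g, "two_way_anova")
        assert r.effect["factor_a"][1] < 0.001
        assert r.effect["factor_b"][1] > 0.01

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            omnibus_and_posthoc([1.0, 2.0, 3.0], ["a", "a", "b"], "anova+tukey")

    def test_tukey_flags_only_separated_pairs(self, rng):
        v = np.concatenate([rng.normal(0, 1, 15), rng.normal(0, 1, 15),
                            rng.normal(6, 1, 15)])
        g = np.repeat(["a", "b", "c"], 15)
        r = omnibus_and_posthoc(v, g, "anova+tukey")
        ph = dict(r.post_hoc)
        assert ph[("a", "b")] > 0.05
        assert ph[("a", "c")] < 0.001 and ph[("b", "c")] < 0.001


class TestCorrelate:
    def test_perfect_line(self):
        x = np.arange(10.0)
        r = correlate(x, 2.0 * x + 1.0)
        assert r.statistic == pytest.approx(1.0)
        assert r.effect["slope"] == pytest.approx(2.0)
        assert r.effect["intercept"] == pytest.approx(1.0)

    def test_anticorrelation(self):
        x = np.arange(10.0)
        assert correlate(x, -x).statistic == pytest.approx(-1.0)

    def test_zero_variance_x_rejected(self):
        with pytest.raises(ValueError):
            correlate(np.ones(10), np.arange(10.0))

    def test_permutation_null_p_roughly_uniform(self, rng):
        """Under independence, p-values should not concentrate low."""
        ps = []
        x = rng.normal(size=30)
        y = rng.normal(size=30)
        for _ in range(200):
            ps.append(correlate(x, rng.permutation(y)).p)
        ps = np.array(ps)
        assert 0.01 < np.mean(ps < 0.5) < 0.75
        assert np.mean(ps < 0.05) < 0.15


def _ols_oracle(X, y):
    """Normal equations (X'X)^-1 X'y with an explicit intercept column."""
    Xd = np.column_stack([np.ones(len(X)), X])
    return np.linalg.solve(Xd.T @ Xd, Xd.T @ y)


class TestRegressionLedger:
    def _table(self, rng, n=60):
        ages = rng.uniform(35, 75, n)
        sexes = rng.choice(["M", "F"], n)
        return pd.DataFrame({
            "I_tonic": rng.normal(10, 4, n) + 0.2 * (ages - 55),
            "age": ages,
            "sex": sexes,
            "firing_cluster": rng.integers(1, 6, n),
            "axonal_class": rng.choice(
                ["rosehip", "neurogliaform", "L2-3", "stalked", "other"], n),
            "pathology": rng.choice(["glioblastoma", "meningioma"], n),
            "seizure_history": rng.choice(
                ["none", "within_1y", "more_than_1y_ago"], n),
            "dexamethasone": rng.choice(["none", "at_surgery", "presurgery"], n),
            "levetiracetam": rng.choice([True, False], n),
            "hemisphere": rng.choice(["left", "right"], n),
            "lobe": rng.choice(["temporal", "frontal", "parietal"], n),
        })

    def test_ols_matches_normal_equations(self, rng):
        table = self._table(rng)
        led = fit_regression_ledger(table, {"m": ["age", "sex_male"]})[0]
        X = np.column_stack([table["age"], (table["sex"] == "M").astype(float)])
        beta = _ols_oracle(X, table["I_tonic"].to_numpy())
        assert led.coefficients["intercept"][0] == pytest.approx(beta[0], abs=1e-8)
        assert led.coefficients["age"][0] == pytest.approx(beta[1], abs=1e-8)
        assert led.coefficients["sex_male"][0] == pytest.approx(beta[2], abs=1e-8)

    def test_ledger_self_consistency(self, rng):
        """R^2 from residual/total SS and F from (R^2, df) identities."""
        table = self._table(rng)
        for led in fit_regression_ledger(table):
            y = table["I_tonic"].to_numpy()
            tss = np.sum((y - y.mean()) ** 2)
            assert led.r2 == pytest.approx(1.0 - led.residual_ss / tss, abs=1e-10)
            k = led.n - led.df - 1  # number of slopes
            if k > 0 and led.r2 < 1.0:
                f_expected = (led.r2 / k) / ((1 - led.r2) / led.df)
                assert led.f_stat == pytest.approx(f_expected, rel=1e-8)
            assert led.adj_r2 <= led.r2 + 1e-12
            assert led.df == led.n - (k + 1)

    def test_intercept_only_r2_zero(self, rng):
        table = self._table(rng)
        led = fit_regression_ledger(table, {"m0": []})[0]
        assert led.r2 == pytest.approx(0.0, abs=1e-12)
        assert led.coefficients["intercept"][0] == pytest.approx(
            table["I_tonic"].mean(), abs=1e-9)

    def test_collinear_term_dropped_with_report(self, rng):
        table = self._table(rng)
        table["axonal_class"] = "rosehip"  # all six dummies would alias
        led = fit_regression_ledger(
            table, {"m": ["axon_rosehip", "axon_neurogliaform", "axon_l23",
                          "axon_stalked", "axon_other", "axon_not_recovered"]})[0]
        assert len(led.dropped_terms) >= 1
        assert "axon_rosehip" in led.coefficients or "axon_rosehip" in led.dropped_terms

    def test_default_specs_cover_thirteen_models(self):
        assert len(DEFAULT_MODEL_SPECS) == 13

    def test_reference_categories_recorded(self, rng):
        table = self._table(rng)
        led = fit_regression_ledger(
            table, {"m": ["age", "cluster:1,2,3,4"]})[0]
        assert led.reference_categories["firing_cluster"] == "5"

    def test_injected_archetype_effect_recovered(self):
        """The ledger recovers a +10 pA cluster-1 effect from a
        generator cohort at n = 200."""
        from tonicephys.synthetic_data import CohortConfig, simulate_cohort

        cfg = CohortConfig(archetype_tonic_effects={"archetype1": 10.0},
                           simulate_iv=False)
        recs, pats = simulate_cohort(cfg, n_cells=200, seed=17)
        arch2cluster = {f"archetype{i}": i for i in range(1, 6)}
        table = pd.DataFrame({
            "cell_id": [r.cell_id for r in recs],
            "I_tonic": [r.ground_truth.true_tonic_shift for r in recs],
            "firing_cluster": [arch2cluster[r.ground_truth.archetype] for r in recs],
            "axonal_class": [r.axonal_class for r in recs],
            "patient_id": [r.patient_id for r in recs],
        }).merge(pd.DataFrame([vars(p) for p in pats]), on="patient_id")
        led = fit_regression_ledger(table, {"m2": ["age", "sex_male",
                                                   "cluster:1,2,3,4"]})[0]
        est, se, p = led.coefficients["cluster_1"]
        # Monte-Carlo tolerance: ~3 standard errors of the group contrast
        tol = 3.0 * cfg.tonic_sd * math.sqrt(1 / 40 + 1 / 160)
        assert est == pytest.approx(10.0, abs=tol)
        assert p < 0.001
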
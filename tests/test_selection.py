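"""Selection statistics against independent oracles, plus the three-step
probe selection on simulated cohorts."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import special, stats

from episig import (SelectionParams, bh_adjust, compute_auroc,
                    compute_probe_stats, correlation_prune, discover_signature,
                    fit_moderated_model, hypo_hyper_split, select_dmps)
from episig.selection import auroc_per_probe


# ---------------------------------------------------------------------------
# independent oracles


def moderated_t_oracle(m: np.ndarray, n_case: int):
    """Scalar-loop implementation of empirical-Bayes variance moderation,
    written directly from the moment-matching formulas."""
    n = m.shape[1]
    n_ctrl = n - n_case
    d = n - 2
    coefs, s2s = [], []
    for row in m:
        case, ctrl = row[:n_case], row[n_case:]
        coefs.append(case.mean() - ctrl.mean())
        ss = ((case - case.mean()) ** 2).sum() + ((ctrl - ctrl.mean()) ** 2).sum()
        s2s.append(ss / d)
    s2s = np.array(s2s)
    z = np.log(s2s)
    e = z - special.digamma(d / 2) + np.log(d / 2)
    mean_e, var_e = e.mean(), e.var(ddof=1)
    target = var_e - special.polygamma(1, d / 2)
    if target > 0:
        # invert trigamma by bisection (independent of the package's Newton)
        lo, hi = 1e-8, 1e8
        for _ in range(200):
            mid = np.sqrt(lo * hi)
            if special.polygamma(1, mid) > target:
                lo = mid
            else:
                hi = mid
        half_d0 = lo
        d0 = 2 * half_d0
        s0_2 = np.exp(mean_e + special.digamma(half_d0) - np.log(half_d0))
    else:
        d0, s0_2 = np.inf, np.exp(mean_e)
    out_t, out_p = [], []
    for coef, s2 in zip(coefs, s2s):
        if np.isinf(d0):
            s2_post = s0_2
        else:
            s2_post = (d0 * s0_2 + d * s2) / (d0 + d)
        t = coef / np.sqrt(s2_post * (1 / n_case + 1 / n_ctrl))
        if np.isinf(d0):
            p = 2 * stats.norm.sf(abs(t))
        else:
            p = 2 * stats.t.sf(abs(t), d + d0)
        out_t.append(t)
        out_p.append(p)
    return np.array(out_t), np.array(out_p)


def bh_oracle(p):
    """Literal step-up enumeration: adj_(i) = min_{j>=i} p_(j) * m / j."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    for rank_i, idx in enumerate(order, start=1):
        candidates = [p[order[j - 1]] * m / j for j in range(rank_i, m + 1)]
        adj[idx] = min(1.0, min(candidates))
    return adj


def auroc_oracle(case, ctrl):
    """Brute-force pair counting with half credit for ties."""
    total = 0.0
    for a in case:
        for b in ctrl:
            if a > b:
                total += 1.0
            elif a == b:
                total += 0.5
    return total / (len(case) * len(ctrl))


# ---------------------------------------------------------------------------


class TestModeratedFit:
    def test_matches_direct_formula_oracle(self, rng):
        m = rng.normal(0, 1, size=(40, 6))
        m[:5] += rng.normal(0, 2, size=(40, 1))[:5]  # heterogeneous variances
        df = pd.DataFrame(m, columns=[f"s{i}" for i in range(6)])
        labels = pd.Series(["case"] * 3 + ["control"] * 3, index=df.columns)
        fit, table = fit_moderated_model(df, labels)
        t_or, p_or = moderated_t_oracle(m, 3)
        assert np.allclose(table["t_mod"], t_or, rtol=1e-6)
        assert np.allclose(table["p"], p_or, rtol=1e-6)

    def test_prior_df_zero_is_ordinary_t(self, rng):
        m = rng.normal(size=(30, 10))
        df = pd.DataFrame(m, columns=[f"s{i}" for i in range(10)])
        labels = pd.Series(["case"] * 5 + ["control"] * 5, index=df.columns)
        _, table = fit_moderated_model(df, labels, prior_df=0)
        t, p = stats.ttest_ind(m[:, :5], m[:, 5:], axis=1)
        assert np.allclose(table["t_mod"], t, rtol=1e-12)
        assert np.allclose(table["p"], p, rtol=1e-12)

    def test_constant_probe_stays_finite(self, rng):
        m = rng.normal(size=(20, 8))
        m[0] = [1, 1, 1, 1, 0, 0, 0, 0]  # zero within-group variance
        df = pd.DataFrame(m, columns=[f"s{i}" for i in range(8)])
        labels = pd.Series(["case"] * 4 + ["control"] * 4, index=df.columns)
        fit, table = fit_moderated_model(df, labels)
        assert fit.s2[0] == 0 and fit.s2_post[0] > 0
        assert np.isfinite(table.loc[0, "t_mod"])

    def test_small_group_rejected(self, rng):
        df = pd.DataFrame(rng.normal(size=(5, 3)), columns=list("abc"))
        labels = pd.Series(["case", "control", "control"], index=df.columns)
        with pytest.raises(ValueError):
            fit_moderated_model(df, labels)


class TestBHAdjust:
    @pytest.mark.parametrize(
        "p,expected",
        [((0.01, 0.02, 0.03), (0.03, 0.03, 0.03)),
         ((0.04,), (0.04,)),
         ((1.0, 1.0, 1.0), (1.0, 1.0, 1.0))],
    )
    def test_examples(self, p, expected):
        assert np.allclose(bh_adjust(p), expected)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                    max_size=40))
    @settings(deadline=None)
    def test_matches_step_up_oracle(self, p):
        adj = bh_adjust(p)
        assert np.allclose(adj, bh_oracle(p), atol=1e-12)
        assert (adj >= np.asarray(p) - 1e-12).all()


class TestAUROC:
    def test_perfect_separation(self):
        assert compute_auroc([0.9, 0.8], [0.1, 0.2]) == 1.0

    def test_mixed_pairs(self):
        assert compute_auroc([0.9, 0.7], [0.8, 0.1]) == 0.75

    def test_identical_groups_half(self):
        assert compute_auroc([0.3, 0.5], [0.3, 0.5]) == 0.5

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            compute_auroc([], [0.5])

    @given(
        st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=50),
        st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=50),
    )
    @settings(deadline=None)
    def test_matches_pair_counting_oracle(self, case, ctrl):
        assert compute_auroc(case, ctrl) == pytest.approx(auroc_oracle(case, ctrl))

    def test_vectorized_matches_scalar(self, rng):
        x = rng.random((20, 12))
        is_case = np.array([True] * 5 + [False] * 7)
        df = pd.DataFrame(x, columns=[f"s{i}" for i in range(12)])
        vec = auroc_per_probe(df, is_case)
        for i in range(20):
            a = compute_auroc(x[i, :5], x[i, 5:])
            assert vec[i] == pytest.approx(max(a, 1 - a))


def correlated_triplet(corr: np.ndarray, n: int, rng) -> np.ndarray:
    """Rows with *empirical* correlation exactly ``corr`` (via whitening)."""
    k = corr.shape[0]
    raw = rng.normal(size=(k, n))
    raw -= raw.mean(axis=1, keepdims=True)
    cov = raw @ raw.T / n
    white = np.linalg.cholesky(np.linalg.inv(cov))
    iid = white @ raw
    return np.linalg.cholesky(corr) @ iid


class TestCorrelationPrune:
    def _beta(self, data, rng):
        n = data.shape[1]
        cols = [f"s{i}" for i in range(2 * n)]
        # same empirical correlation structure in both groups
        full = np.hstack([data, data[:, ::-1]])
        labels = pd.Series(["case"] * n + ["control"] * n, index=cols)
        return pd.DataFrame(full, index=[f"p{i}" for i in range(len(data))],
                            columns=cols), labels

    def test_high_correlation_drops_lower_rank(self, rng):
        corr = np.array([[1.0, 0.99], [0.99, 1.0]])
        beta, labels = self._beta(correlated_triplet(corr, 20, rng), rng)
        assert correlation_prune(["p0", "p1"], beta, labels) == ["p0"]

    def test_threshold_is_strict(self, rng):
        corr = np.array([[1.0, 0.849], [0.849, 1.0]])
        beta, labels = self._beta(correlated_triplet(corr, 20, rng), rng)
        retained = correlation_prune(["p0", "p1"], beta, labels, r_max=0.85)
        assert retained == ["p0", "p1"]

    def test_chain_keeps_first_and_third(self, rng):
        # r(0,1) and r(1,2) exceed the threshold, r(0,2) does not, so the
        # greedy scan drops only the middle probe (r(0,2) is bounded below
        # by 2*0.9^2-1 = 0.62 for a valid correlation matrix)
        corr = np.array([[1.0, 0.9, 0.65], [0.9, 1.0, 0.9], [0.65, 0.9, 1.0]])
        beta, labels = self._beta(correlated_triplet(corr, 30, rng), rng)
        assert correlation_prune(["p0", "p1", "p2"], beta, labels) == ["p0", "p2"]

    def test_either_group_can_trigger(self, rng):
        # correlated within cases only; uncorrelated within controls
        n = 20
        case = correlated_triplet(np.array([[1.0, 0.95], [0.95, 1.0]]), n, rng)
        ctrl = correlated_triplet(np.array([[1.0, 0.0], [0.0, 1.0]]), n, rng)
        cols = [f"s{i}" for i in range(2 * n)]
        beta = pd.DataFrame(np.hstack([case, ctrl]), index=["p0", "p1"],
                            columns=cols)
        labels = pd.Series(["case"] * n + ["control"] * n, index=cols)
        assert correlation_prune(["p0", "p1"], beta, labels) == ["p0"]


class TestSelectDMPs:
    def test_step_counts_and_pruned_correlations(self, cc_setup):
        sig, stats_table = discover_signature(cc_setup["beta"], cc_setup["labels"])
        assert sig.n_step1 == 500
        assert sig.n_step2 == 250
        assert len(sig) <= 250
        # exhaustive pairwise check of the retained set in both groups
        lab = cc_setup["labels"]
        for grp in ("case", "control"):
            sub = cc_setup["beta"].loc[sig.probe_ids, lab[lab == grp].index]
            r = np.corrcoef(sub.to_numpy())
            np.fill_diagonal(r, 0.0)
            assert np.nanmax(r) <= 0.85 + 1e-12

    def test_too_few_probes_rejected(self, cc_setup):
        stats_table = compute_probe_stats(cc_setup["beta"].iloc[:100],
                                          cc_setup["labels"])
        with pytest.raises(ValueError, match="testable"):
            select_dmps(stats_table, cc_setup["beta"].iloc[:100],
                        cc_setup["labels"])

    def test_signature_dominated_by_truth_probes(self, cc_setup):
        sig, _ = discover_signature(cc_setup["beta"], cc_setup["labels"])
        truth = set(cc_setup["cohort"].truth_dmps["probe_id"])
        precision = np.mean([p in truth for p in sig.probe_ids])
        assert precision >= 0.95

    def test_product_score_rank_invariant_to_log_base(self, rng):
        delta = rng.random(100)
        p_bh = rng.random(100) * 0.99 + 0.005
        base10 = delta * -np.log10(p_bh)
        natural = delta * -np.log(p_bh)
        assert (np.argsort(base10) == np.argsort(natural)).all()

    def test_signature_serialization_roundtrip(self, cc_setup, tmp_path):
        from episig import Episignature

        sig, _ = discover_signature(cc_setup["beta"], cc_setup["labels"])
        path = tmp_path / "sig.json"
        sig.to_json(path)
        back = Episignature.from_json(path)
        assert back.probe_ids == sig.probe_ids
        assert np.allclose(back.stats["delta_beta"], sig.stats["delta_beta"])


class TestHypoHyperSplit:
    def test_single_hypo_probe(self):
        from episig import Episignature

        sig = Episignature(
            stats=pd.DataFrame({"delta_beta": [-0.2]}, index=["p0"]),
            params=SelectionParams(), n_step1=1, n_step2=1,
        )
        assert hypo_hyper_split(sig) == (1.0, 0.0)

    def test_empty_rejected(self):
        from episig import Episignature

        sig = Episignature(stats=pd.DataFrame({"delta_beta": []}),
                           params=SelectionParams(), n_step1=0, n_step2=0)
        with pytest.raises(ValueError):
            hypo_hyper_split(sig)

    def test_recovers_simulated_direction_mix(self, cc_setup):
        sig, _ = discover_signature(cc_setup["beta"], cc_setup["labels"])
        hypo, hyper = hypo_hyper_split(sig)
        assert abs(hypo - 0.87) < 0.05
        assert hypo + hyper == pytest.approx(1.0)
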
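"""Per-probe moderated differential methylation and episignature selection.

The discovery statistic follows the standard empirical-Bayes moderated-t
framework for array data: an ordinary least-squares fit of M values on a
case/control indicator per probe, followed by shrinkage of the per-probe
residual variances s_g^2 toward a pooled prior. The prior is a scaled
inverse chi-square with df d0 and scale s0^2, whose hyperparameters are
estimated by method of moments on the log residual variances; the posterior
variance

    s~_g^2 = (d0 * s0^2 + d * s_g^2) / (d0 + d)

replaces s_g^2 in the t statistic, which then has d + d0 degrees of
freedom. With d0 = 0 the moderated t collapses to the ordinary pooled
two-sample t.

The episignature itself is chosen in three steps:

1. keep the ``n_top_product`` probes (default 500) with the highest
   |delta-beta| x (-log10 BH-adjusted p) product score;
2. of those, keep the ``n_top_auroc`` probes (default 250) with the highest
   case-vs-control AUROC;
3. greedily drop probes whose Pearson correlation with an already-retained
   probe exceeds ``r_max`` (default 0.85) within the case samples or within
   the control samples.

Effect sizes (delta-beta) are computed on the beta scale, where a 0.10
difference means a 10% methylation change; p-values come from the M-scale
model where variances are comparable across the methylation range.
"""

from __future__ import annotations

import hashlib
import json
import pathlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .preprocess import beta_to_m

_TINY_P = np.finfo(float).tiny


@dataclass(frozen=True)
class SelectionParams:
    """Thresholds of the three-step probe selection."""

    n_top_product: int = 500
    n_top_auroc: int = 250
    r_max: float = 0.85

    def __post_init__(self):
        if self.n_top_auroc > self.n_top_product:
            raise ValueError("n_top_auroc must be <= n_top_product")
        if not (0.0 < self.r_max <= 1.0):
            raise ValueError("r_max must be in (0, 1]")


@dataclass
class ModeratedFit:
    """Empirical-Bayes hyperparameters and per-probe variances."""

    s2: np.ndarray          # per-probe residual variance
    df_residual: float      # d = n - 2
    prior_df: float         # d0 (may be inf when variances are homogeneous)
    prior_s2: float         # s0^2
    s2_post: np.ndarray     # posterior (moderated) variance


@dataclass
class Episignature:
    """Selected probe set with per-probe statistics and reference means.

    ``stats`` is ordered by final rank and carries delta_beta, t_mod, p,
    p_bh, product_score, auroc, case_mean and control_mean per probe.
    """

    stats: pd.DataFrame
    params: SelectionParams
    n_step1: int
    n_step2: int
    provenance: dict = field(default_factory=dict)

    @property
    def probe_ids(self) -> list[str]:
        return list(self.stats.index)

    def __len__(self) -> int:
        return len(self.stats)

    def to_json(self, path=None) -> str:
        payload = {
            "params": {
                "n_top_product": self.params.n_top_product,
                "n_top_auroc": self.params.n_top_auroc,
                "r_max": self.params.r_max,
            },
            "n_step1": self.n_step1,
            "n_step2": self.n_step2,
            "provenance": self.provenance,
            "probes": [
                {"probe_id": pid, **{k: (None if pd.isna(v) else float(v))
                                     for k, v in row.items()}}
                for pid, row in self.stats.iterrows()
            ],
        }
        text = json.dumps(payload, indent=1, sort_keys=True)
        if path is not None:
            pathlib.Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source) -> "Episignature":
        p = pathlib.Path(source)
        payload = json.loads(p.read_text() if p.exists() else source)
        stats_df = pd.DataFrame(payload["probes"]).set_index("probe_id")
        return cls(
            stats=stats_df,
            params=SelectionParams(**payload["params"]),
            n_step1=payload["n_step1"],
            n_step2=payload["n_step2"],
            provenance=payload.get("provenance", {}),
        )


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 (Newton iteration)."""
    if x <= 0:
        return np.inf
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y = y + dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def estimate_prior(s2: np.ndarray, df_residual: float) -> tuple[float, float]:
    """Method-of-moments fit of the variance prior (d0, s0^2).

    Works on z = log(s^2): under the scaled-F sampling model,
    E[z] = log(s0^2) + psi(d/2) - log(d/2) - psi(d0/2) + log(d0/2) and
    Var[z] = psi'(d/2) + psi'(d0/2). Probes with zero residual variance are
    excluded from the moment fit (their posterior variance is still defined).
    An empirical variance at or below the theoretical sampling variance
    means the prior is degenerate: d0 = inf, s0^2 = geometric-mean variance.
    """
    d = df_residual
    z = np.log(s2[s2 > 0])
    if len(z) == 0:
        return np.inf, 1.0
    e = z - special.digamma(d / 2.0) + np.log(d / 2.0)
    e_mean = float(np.mean(e))
    e_var = float(np.var(e, ddof=1)) if len(e) > 1 else 0.0
    excess = e_var - float(special.polygamma(1, d / 2.0))
    if excess <= 0:
        return np.inf, float(np.exp(e_mean))
    d0 = 2.0 * _trigamma_inverse(excess)
    s0_2 = float(np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0_2


def fit_moderated_model(
    m: pd.DataFrame,
    labels: pd.Series | dict | np.ndarray,
    prior_df: float | None = None,
) -> tuple[ModeratedFit, pd.DataFrame]:
    """Per-probe group contrast on M values with variance moderation.

    ``labels`` maps each sample (column of ``m``) to ``"case"`` or
    ``"control"``. Returns the fit object and a partial statistics table
    (index probe_id) with columns ``delta_m``, ``t_mod``, ``p``.

    ``prior_df`` overrides the estimated d0; ``prior_df=0`` disables
    moderation and reproduces the ordinary pooled two-sample t exactly.
    """
    lab = pd.Series(labels)
    lab = lab.reindex(m.columns)
    if lab.isna().any():
        raise ValueError("labels missing for some samples")
    is_case = (lab == "case").to_numpy()
    is_ctrl = (lab == "control").to_numpy()
    n1, n0 = int(is_case.sum()), int(is_ctrl.sum())
    if n1 < 2 or n0 < 2:
        raise ValueError(f"need >= 2 samples per group, got case={n1}, control={n0}")

    x = m.to_numpy(dtype=float)
    case = x[:, is_case]
    ctrl = x[:, is_ctrl]
    mean1 = case.mean(axis=1)
    mean0 = ctrl.mean(axis=1)
    coef = mean1 - mean0

    # pooled residual variance of the two-group OLS fit
    ss = ((case - mean1[:, None]) ** 2).sum(axis=1) + ((ctrl - mean0[:, None]) ** 2).sum(axis=1)
    d = float(n1 + n0 - 2)
    s2 = ss / d

    if prior_df is None:
        d0, s0_2 = estimate_prior(s2, d)
    elif prior_df == 0:
        d0, s0_2 = 0.0, float(np.mean(s2[s2 > 0])) if np.any(s2 > 0) else 1.0
    else:
        d0 = float(prior_df)
        _, s0_2 = estimate_prior(s2, d)

    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_2)
        df_total = np.inf
    else:
        s2_post = (d0 * s0_2 + d * s2) / (d0 + d)
        df_total = d + d0

    stderr = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t_mod = np.where(stderr > 0, coef / np.where(stderr > 0, stderr, 1.0), 0.0)
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t_mod))
    else:
        p = 2.0 * stats.t.sf(np.abs(t_mod), df=df_total)

    fit = ModeratedFit(s2=s2, df_residual=d, prior_df=d0, prior_s2=s0_2, s2_post=s2_post)
    table = pd.DataFrame({"delta_m": coef, "t_mod": t_mod, "p": p}, index=m.index)
    return fit, table


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def compute_auroc(case_values, control_values) -> float:
    """Area under the ROC for one probe, case-high orientation.

    Equals the pairwise concordance (concordant + half-credit ties) over
    all case x control pairs; computed via the rank-sum identity.
    """
    case = np.asarray(case_values, dtype=float)
    ctrl = np.asarray(control_values, dtype=float)
    if case.size == 0 or ctrl.size == 0:
        raise ValueError("both groups must be non-empty")
    ranks = stats.rankdata(np.concatenate([case, ctrl]))
    u = ranks[: case.size].sum() - case.size * (case.size + 1) / 2.0
    return float(u / (case.size * ctrl.size))


def auroc_per_probe(beta: pd.DataFrame, is_case: np.ndarray) -> np.ndarray:
    """Vectorized direction-free AUROC for every probe (row) of ``beta``.

    Direction-free: values below 0.5 are reflected to ``1 - auroc`` so hypo-
    and hypermethylated probes compete on equal footing.
    """
    x = beta.to_numpy(dtype=float)
    ranks = stats.rankdata(x, axis=1)
    n1 = int(is_case.sum())
    n0 = x.shape[1] - n1
    u = ranks[:, is_case].sum(axis=1) - n1 * (n1 + 1) / 2.0
    auc = u / (n1 * n0)
    return np.maximum(auc, 1.0 - auc)


def correlation_prune(
    ranked_probes,
    beta: pd.DataFrame,
    labels,
    r_max: float = 0.85,
) -> list[str]:
    """Greedy correlation filter over a ranked probe list.

    Scans probes in the given rank order and drops any probe whose Pearson
    correlation with an already-retained probe strictly exceeds ``r_max``
    within the case samples *or* within the control samples; the earlier-
    ranked member of a correlated pair survives.
    """
    ranked = list(ranked_probes)
    if not ranked:
        return []
    lab = pd.Series(labels).reindex(beta.columns)
    is_case = (lab == "case").to_numpy()
    is_ctrl = (lab == "control").to_numpy()
    sub = beta.loc[ranked]
    with np.errstate(invalid="ignore", divide="ignore"):
        r_case = np.corrcoef(sub.to_numpy()[:, is_case])
        r_ctrl = np.corrcoef(sub.to_numpy()[:, is_ctrl])
    # constant probes yield NaN correlations: treat as not exceeding
    exceeds = (np.nan_to_num(r_case, nan=0.0) > r_max) | (
        np.nan_to_num(r_ctrl, nan=0.0) > r_max
    )
    retained_idx: list[int] = []
    for i in range(len(ranked)):
        if any(exceeds[i, j] for j in retained_idx):
            continue
        retained_idx.append(i)
    return [ranked[i] for i in retained_idx]


def _ranked_head(values: pd.Series, n: int) -> pd.Index:
    """Top-n index by value, descending, ties broken by probe id."""
    df = values.to_frame("v")
    df["pid"] = df.index
    df = df.sort_values(["v", "pid"], ascending=[False, True])
    return df.index[:n]


def compute_probe_stats(
    beta: pd.DataFrame,
    labels,
    prior_df: float | None = None,
) -> pd.DataFrame:
    """Full per-probe statistics table for case-vs-control discovery.

    Columns: delta_beta (case mean minus control mean, beta scale), t_mod,
    p, p_bh, product_score (= |delta_beta| * -log10 p_bh), auroc.
    """
    lab = pd.Series(labels).reindex(beta.columns)
    is_case = (lab == "case").to_numpy()
    is_ctrl = (lab == "control").to_numpy()
    m = beta_to_m(beta)
    _, table = fit_moderated_model(m, lab, prior_df=prior_df)
    x = beta.to_numpy(dtype=float)
    case_mean = x[:, is_case].mean(axis=1)
    ctrl_mean = x[:, is_ctrl].mean(axis=1)
    table = table.copy()
    table["delta_beta"] = case_mean - ctrl_mean
    table["case_mean"] = case_mean
    table["control_mean"] = ctrl_mean
    table["p_bh"] = bh_adjust(table["p"].to_numpy())
    table["product_score"] = np.abs(table["delta_beta"]) * (
        -np.log10(np.maximum(table["p_bh"].to_numpy(), _TINY_P))
    )
    table["auroc"] = auroc_per_probe(beta, is_case)
    return table


def select_dmps(
    stats: pd.DataFrame,
    beta: pd.DataFrame,
    labels,
    params: SelectionParams = SelectionParams(),
) -> Episignature:
    """Three-step DMP selection producing the episignature.

    Step 1 keeps the top ``n_top_product`` probes by product score, step 2
    the top ``n_top_auroc`` of those by AUROC, step 3 correlation-prunes in
    AUROC rank order. Ties at each cutoff break by probe id. The returned
    signature is ordered by step-2 rank and carries case/control reference
    means per probe.
    """
    if len(stats) < params.n_top_product:
        raise ValueError(
            f"need >= {params.n_top_product} testable probes, got {len(stats)}"
        )
    step1 = _ranked_head(stats["product_score"], params.n_top_product)
    step2 = _ranked_head(stats.loc[step1, "auroc"], params.n_top_auroc)
    retained = correlation_prune(step2, beta, labels, r_max=params.r_max)

    sig_stats = stats.loc[retained, ["delta_beta", "t_mod", "p", "p_bh",
                                     "product_score", "auroc", "case_mean",
                                     "control_mean"]].copy()
    prov = {
        "input_hash": hashlib.sha256(
            np.ascontiguousarray(beta.to_numpy()).tobytes()
        ).hexdigest()[:16],
        "n_samples": int(beta.shape[1]),
        "n_testable_probes": int(len(stats)),
    }
    return Episignature(
        stats=sig_stats,
        params=params,
        n_step1=len(step1),
        n_step2=len(step2),
        provenance=prov,
    )


def discover_signature(
    beta: pd.DataFrame,
    labels,
    params: SelectionParams = SelectionParams(),
) -> tuple[Episignature, pd.DataFrame]:
    """Convenience wrapper: stats table + three-step selection in one call."""
    stats_table = compute_probe_stats(beta, labels)
    sig = select_dmps(stats_table, beta, labels, params)
    return sig, stats_table


def hypo_hyper_split(sig: Episignature) -> tuple[float, float]:
    """Fraction of signature probes hypo- vs hypermethylated in cases.

    Probes with delta_beta < 0 count as hypo; zero-delta probes (a
    measure-zero event) count as hyper so the fractions always sum to 1.
    """
    if len(sig) == 0:
        raise ValueError("empty signature")
    hypo = float((sig.stats["delta_beta"] < 0).mean())
    return hypo, 1.0 - hypo
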
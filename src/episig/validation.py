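"""Unsupervised robustness checks for a discovered episignature.

Three complementary checks, all operating on the beta matrix restricted to
signature probes:

* Ward-linkage hierarchical clustering on Euclidean distances, cut into two
  clusters and scored against the known case/control labels;
* classical (Torgerson) metric multidimensional scaling of the pairwise
  Euclidean distances, for a 2-D view of sample structure;
* leave-one-out cross-validation in which the signature is *re-derived*
  from scratch in every round — holding out one case, selecting probes on
  the remaining cases vs the controls, then assigning the held-out sample
  to the nearer group centroid in that round's signature space. Re-deriving
  per round is what makes the check honest: reusing the full-data probe set
  would leak the held-out sample into probe selection.

Cohort projection places new samples (a testing set, or a different
disorder entirely) into the reference clustering/MDS without refitting,
which is how specificity against clinically overlapping syndromes is
examined.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform

from .selection import Episignature, SelectionParams, discover_signature

log = logging.getLogger(__name__)


@dataclass
class ClusterResult:
    linkage_matrix: np.ndarray
    labels2: pd.Series            # 2-cut cluster labels per sample
    truth: pd.Series | None
    agreement: float | None       # majority-mapped accuracy vs truth

    @property
    def merge_heights(self) -> np.ndarray:
        return self.linkage_matrix[:, 2]


@dataclass
class MDSResult:
    coords: pd.DataFrame          # sample x dim, centered at the origin
    eigenvalues: np.ndarray
    stress: float                 # relative residual of reproduced distances


@dataclass
class LOOReport:
    rounds: list[dict] = field(default_factory=list)

    @property
    def n_rounds(self) -> int:
        return len(self.rounds)

    @property
    def n_correct(self) -> int:
        return sum(1 for r in self.rounds if r["correct"])

    def to_dict(self) -> dict:
        return {"n_rounds": self.n_rounds, "n_correct": self.n_correct,
                "rounds": self.rounds}


def ward_cluster(beta_at_signature: pd.DataFrame, truth=None) -> ClusterResult:
    """Ward clustering of samples on Euclidean distance over signature probes.

    ``truth`` (optional) maps sample id to group; the 2-cluster cut is then
    scored by majority mapping (each cluster takes the label of its majority
    group; agreement is the fraction of samples whose mapped label matches).
    """
    if beta_at_signature.shape[1] < 2:
        raise ValueError("need >= 2 samples")
    x = beta_at_signature.to_numpy(dtype=float).T  # samples x probes
    z = linkage(x, method="ward", metric="euclidean")
    labels = pd.Series(fcluster(z, t=2, criterion="maxclust"),
                       index=beta_at_signature.columns)
    agreement = None
    truth_series = None
    if truth is not None:
        truth_series = pd.Series(truth).reindex(labels.index)
        correct = 0
        for c in labels.unique():
            members = truth_series[labels == c]
            correct += int(members.value_counts().iloc[0]) if len(members) else 0
        agreement = correct / len(labels)
    return ClusterResult(linkage_matrix=z, labels2=labels, truth=truth_series,
                         agreement=agreement)


def mds_embed(beta_at_signature: pd.DataFrame, n_dims: int = 2) -> MDSResult:
    """Classical (Torgerson) metric MDS of pairwise Euclidean distances.

    Double-centers the squared-distance matrix and takes the top
    eigenvectors scaled by the square roots of their eigenvalues. Axis sign
    convention: the largest-magnitude coordinate on each axis is positive.
    Degenerate input (all pairwise distances zero) yields all-zero
    coordinates with a warning.
    """
    n = beta_at_signature.shape[1]
    if n < 3:
        raise ValueError("need >= 3 samples")
    x = beta_at_signature.to_numpy(dtype=float).T
    d = squareform(pdist(x, metric="euclidean"))
    if np.allclose(d, 0.0):
        log.warning("all pairwise distances are zero: returning zero coordinates")
        coords = pd.DataFrame(np.zeros((n, n_dims)), index=beta_at_signature.columns,
                              columns=[f"dim{j + 1}" for j in range(n_dims)])
        return MDSResult(coords=coords, eigenvalues=np.zeros(n), stress=0.0)
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d ** 2) @ j
    evals, evecs = np.linalg.eigh(b)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    pos = np.maximum(evals[:n_dims], 0.0)
    coords = evecs[:, :n_dims] * np.sqrt(pos)[None, :]
    for jdim in range(n_dims):
        k = int(np.argmax(np.abs(coords[:, jdim])))
        if coords[k, jdim] < 0:
            coords[:, jdim] *= -1.0
    coords_df = pd.DataFrame(coords, index=beta_at_signature.columns,
                             columns=[f"dim{j_ + 1}" for j_ in range(n_dims)])
    d_hat = squareform(pdist(coords, metric="euclidean"))
    stress = float(np.sqrt(np.sum((d - d_hat) ** 2) / np.sum(d ** 2)))
    return MDSResult(coords=coords_df, eigenvalues=evals, stress=stress)


def _nearest_centroid(sample: np.ndarray, case_mat: np.ndarray, ctrl_mat: np.ndarray) -> str:
    d_case = np.linalg.norm(sample - case_mat.mean(axis=1))
    d_ctrl = np.linalg.norm(sample - ctrl_mat.mean(axis=1))
    return "case" if d_case < d_ctrl else "control"


def loo_validate(
    case_ids,
    control_ids,
    beta: pd.DataFrame,
    params: SelectionParams = SelectionParams(),
) -> LOOReport:
    """Leave-one-out validation with per-round signature re-selection.

    For each case: re-run the three-step selection on the remaining cases
    vs the (fixed) matched controls, then assign the held-out case to the
    nearer group centroid in that round's signature-probe beta space. A
    selection failure in a round is recorded as incorrect with its reason.
    """
    case_ids = sorted(case_ids)
    control_ids = list(control_ids)
    if len(case_ids) < 3:
        raise ValueError("need >= 3 cases for leave-one-out")
    report = LOOReport()
    for held in case_ids:
        train_cases = [c for c in case_ids if c != held]
        cols = train_cases + control_ids
        labels = pd.Series(
            ["case"] * len(train_cases) + ["control"] * len(control_ids), index=cols
        )
        try:
            sig, _ = discover_signature(beta[cols], labels, params)
            sub = beta.loc[sig.probe_ids]
            assigned = _nearest_centroid(
                sub[held].to_numpy(dtype=float),
                sub[train_cases].to_numpy(dtype=float),
                sub[control_ids].to_numpy(dtype=float),
            )
            report.rounds.append(
                {"held_out": held, "assigned": assigned,
                 "correct": assigned == "case", "n_signature": len(sig)}
            )
        except ValueError as exc:
            report.rounds.append(
                {"held_out": held, "assigned": "error", "correct": False,
                 "reason": str(exc)}
            )
    return report


def project_cohort(
    signature: Episignature,
    new_beta: pd.DataFrame,
    reference_beta: pd.DataFrame,
    reference_labels,
    max_missing: float = 0.05,
) -> dict:
    """Place new samples into the reference clustering and MDS.

    ``new_beta`` may lack up to ``max_missing`` of the signature probes;
    missing probes are imputed with the reference control-group mean (the
    neutral baseline). Returns a dict with the combined ClusterResult and
    MDSResult plus a per-new-sample nearest-centroid group call.
    """
    probes = signature.probe_ids
    missing = [p for p in probes if p not in new_beta.index]
    if len(missing) > len(probes) * max_missing:
        raise ValueError(
            f"{len(missing)}/{len(probes)} signature probes missing from new samples "
            f"(> {max_missing:.0%} allowed)"
        )
    if missing:
        log.info("imputing %d missing signature probes with reference means", len(missing))
        fill = signature.stats.loc[missing, "control_mean"]
        add = pd.DataFrame(
            np.tile(fill.to_numpy()[:, None], (1, new_beta.shape[1])),
            index=missing, columns=new_beta.columns,
        )
        new_beta = pd.concat([new_beta, add])
    new_sub = new_beta.loc[probes]
    ref_sub = reference_beta.loc[probes]
    lab = pd.Series(reference_labels).reindex(ref_sub.columns)
    case_mat = ref_sub.loc[:, (lab == "case").to_numpy()].to_numpy(dtype=float)
    ctrl_mat = ref_sub.loc[:, (lab == "control").to_numpy()].to_numpy(dtype=float)
    calls = {
        sid: _nearest_centroid(new_sub[sid].to_numpy(dtype=float), case_mat, ctrl_mat)
        for sid in new_sub.columns
    }
    combined = pd.concat([ref_sub, new_sub], axis=1)
    truth = {**{s: lab[s] for s in ref_sub.columns},
             **{s: "test" for s in new_sub.columns}}
    cluster = ward_cluster(combined, truth=None)
    mds = mds_embed(combined)
    return {"cluster": cluster, "mds": mds, "calls": calls, "groups": truth}
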
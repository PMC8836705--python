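"""Matched-control selection with iterative PCA-based outlier removal.

Each case is paired with ``ratio`` (default 2) controls drawn without
replacement from a reference pool, requiring exact agreement on sex and
array type and minimizing age distance (z-scored). After each matching
round a PCA of the combined case + selected-control M-value matrix is
inspected: samples whose first- or second-component score deviates from the
component median by more than ``k`` robust standard deviations (MAD-based)
are flagged. Flagged controls are dropped from the pool and matching
repeats until the embedding is clean; a flagged *case* is never removed
automatically — it is surfaced as an error for the operator to resolve.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .preprocess import beta_to_m

log = logging.getLogger(__name__)

MAD_SCALE = 1.4826  # consistency factor: MAD -> SD under normality


class MatchingError(RuntimeError):
    pass


@dataclass
class MatchResult:
    selected_control_ids: list[str]
    assignments: dict[str, list[str]]      # case_id -> matched control ids
    iterations: int = 1
    removed_outlier_ids: list[list[str]] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "selected_control_ids": self.selected_control_ids,
            "assignments": self.assignments,
            "iterations": self.iterations,
            "removed_outlier_ids": self.removed_outlier_ids,
        }


def match_controls(cases: pd.DataFrame, pool: pd.DataFrame, ratio: int = 2) -> MatchResult:
    """Greedy nearest-neighbour 1:ratio matching without replacement.

    ``cases`` and ``pool`` are sample-sheet slices (index sample_id, columns
    including age, sex, array_type). Cases are processed in lexicographic id
    order; for each, the ``ratio`` unused pool samples with identical sex
    and array type and smallest |age difference| (ages z-scored over all
    samples) are taken, ties broken by control id. A case with missing age
    matches on sex/array only.
    """
    if ratio == 0:
        return MatchResult(selected_control_ids=[], assignments={}, iterations=1)
    ages = pd.concat([cases["age"], pool["age"]]).astype(float)
    mu, sd = ages.mean(), ages.std(ddof=0)
    sd = sd if sd > 0 else 1.0

    available = pool.copy()
    assignments: dict[str, list[str]] = {}
    selected: list[str] = []
    for case_id in sorted(cases.index):
        row = cases.loc[case_id]
        compat = available[
            (available["sex"] == row["sex"]) & (available["array_type"] == row["array_type"])
        ]
        if len(compat) < ratio:
            raise MatchingError(
                f"case {case_id!r}: only {len(compat)} sex/array-compatible "
                f"controls remain (need {ratio})"
            )
        if pd.isna(row["age"]):
            log.warning("case %s has missing age: matching on sex/array only", case_id)
            dist = pd.Series(0.0, index=compat.index)
        else:
            dist = ((compat["age"].astype(float) - float(row["age"])) / sd).abs()
            dist = dist.fillna(np.inf)  # ageless controls matched last
        order = pd.DataFrame({"d": dist, "cid": compat.index}).sort_values(["d", "cid"])
        chosen = list(order.index[:ratio])
        assignments[case_id] = chosen
        selected.extend(chosen)
        available = available.drop(index=chosen)
    return MatchResult(selected_control_ids=selected, assignments=assignments)


def pca_embed(m: pd.DataFrame, n_components: int = 2) -> pd.DataFrame:
    """Sample scores on the top principal components of the M matrix.

    ``m`` is probe x sample; probes are centered. Sign convention: each
    component is flipped so its largest-magnitude probe loading is positive,
    making the embedding deterministic. Returns a sample x component frame
    with columns PC1, PC2, ...
    """
    x = m.to_numpy(dtype=float).T  # samples x probes
    if x.shape[0] < 2:
        raise ValueError("need >= 2 samples")
    if np.allclose(x.var(axis=0), 0.0):
        raise ValueError("zero-variance matrix: PCA undefined")
    n_components = min(n_components, x.shape[0] - 1, x.shape[1])
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(x)
    for j in range(n_components):
        k = int(np.argmax(np.abs(pca.components_[j])))
        if pca.components_[j, k] < 0:
            scores[:, j] *= -1.0
    return pd.DataFrame(
        scores, index=m.columns, columns=[f"PC{j + 1}" for j in range(n_components)]
    )


def detect_outliers(coords: pd.DataFrame, k: float = 3.0,
                    groups: pd.Series | None = None) -> list[str]:
    """Flag samples deviating > k robust SDs on PC1 or PC2.

    Robust SD is MAD * 1.4826 about the component median; a component with
    zero MAD (no spread) flags nothing.

    When ``groups`` is given (sample id -> group label), each sample's
    deviation is taken from its own group's median while the MAD is pooled
    over all within-group deviations. This keeps the scale estimate stable
    when one group is small, and stops a genuine group difference (cases
    versus controls separated along a component) from being mistaken for
    outlyingness.

    The scale is the larger of the MAD-based robust SD and the plain SD of
    the (within-group) residuals: the MAD is immune to gross outliers but
    underestimates a mildly heavy-tailed spread, while the plain SD covers
    that case and still leaves a >10-SD sample far past ``k``.
    """
    if len(coords) < 3:
        raise ValueError("need >= 3 samples to call outliers")
    flagged: set[str] = set()
    for col in coords.columns[:2]:
        v = coords[col].to_numpy(dtype=float)
        if groups is None:
            resid = v - np.median(v)
        else:
            g = pd.Series(groups).reindex(coords.index)
            resid = np.empty(len(v))
            for label in g.unique():
                mask = (g == label).to_numpy()
                resid[mask] = v[mask] - np.median(v[mask])
        dev = np.abs(resid)
        mad = np.median(dev)
        if mad == 0:
            continue
        scale = max(MAD_SCALE * mad, float(np.std(resid)))
        flagged.update(coords.index[dev / scale > k])
    return sorted(flagged)


def iterate_matching(
    cases: pd.DataFrame,
    pool: pd.DataFrame,
    beta: pd.DataFrame,
    ratio: int = 2,
    k_sd: float = 3.0,
    max_iterations: int | None = None,
) -> MatchResult:
    """Match, embed, flag, drop flagged controls — repeat until clean.

    Terminates because the pool strictly shrinks whenever an outlier is
    found. A flagged case aborts with :class:`MatchingError` (cases are a
    curated clinical set; their removal is an operator decision).

    Outliers are judged within their own group in the shared embedding:
    a strong episignature makes cases and controls occupy different regions
    of the top components, so a pooled deviation rule would mistake the
    minority group itself for outliers. Each sample is compared against the
    robust spread of its peers instead.
    """
    if ratio == 0:
        return MatchResult(selected_control_ids=[], assignments={}, iterations=1)
    removed_per_iter: list[list[str]] = []
    current_pool = pool.copy()
    limit = max_iterations if max_iterations is not None else len(pool) + 1
    for iteration in range(1, limit + 1):
        result = match_controls(cases, current_pool, ratio=ratio)
        case_ids = sorted(cases.index)
        control_ids = result.selected_control_ids
        m = beta_to_m(beta[case_ids + control_ids])
        coords = pca_embed(m, n_components=2)
        groups = pd.Series(
            ["case"] * len(case_ids) + ["control"] * len(control_ids),
            index=case_ids + control_ids,
        )
        flagged = detect_outliers(coords, k=k_sd, groups=groups)
        flagged_cases = [s for s in flagged if s in cases.index]
        flagged_controls = [s for s in flagged if s not in cases.index]
        if not flagged:
            result.iterations = iteration
            result.removed_outlier_ids = removed_per_iter
            return result
        if flagged_cases and not flagged_controls:
            # a gross control outlier can drag mild samples past the
            # threshold on its axis, so cases are only surfaced once the
            # embedding contains no removable control
            raise MatchingError(
                f"case sample(s) flagged as PCA outliers: {flagged_cases}; "
                "cases are not removed automatically"
            )
        removed_per_iter.append(flagged_controls)
        log.info("matching iteration %d: removing outlier controls %s",
                 iteration, flagged_controls)
        current_pool = current_pool.drop(index=flagged_controls)
    raise MatchingError(
        f"no outlier-free matching within {limit} iterations; "
        f"removed so far: {removed_per_iter}"
    )
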
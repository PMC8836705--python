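"""Differentially methylated region (DMR) calling.

Regions are grown by genomic proximity: per chromosome, probes are sorted
by position and split wherever the gap between consecutive probes exceeds
``max_gap_bp`` (default 1 kb). A cluster is reported as a DMR when it
simultaneously satisfies

* at least ``min_cpgs`` member CpGs (default 3),
* absolute mean case-control beta difference >= ``min_mean_delta_beta``
  (default 0.10, i.e. a 10% methylation difference), and
* Fisher-combined member p-value, BH-adjusted across all candidate
  clusters, below ``alpha`` (default 0.01).

The region effect is the unweighted mean of member-probe delta-beta with
its sign kept, so hypo- and hypermethylated regions remain distinguishable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .selection import bh_adjust

log = logging.getLogger(__name__)

_TINY_P = np.finfo(float).tiny


@dataclass(frozen=True)
class DMRParams:
    min_cpgs: int = 3
    max_gap_bp: int = 1000
    min_mean_delta_beta: float = 0.10
    alpha: float = 0.01
    #: "gap" splits on consecutive-probe distance; "span" additionally caps
    #: the total cluster span at max_gap_bp
    gap_mode: str = "gap"

    def __post_init__(self):
        if self.min_cpgs < 1:
            raise ValueError("min_cpgs must be >= 1")
        if self.max_gap_bp <= 0:
            raise ValueError("max_gap_bp must be > 0")
        if not (0 < self.min_mean_delta_beta < 1):
            raise ValueError("min_mean_delta_beta must be in (0, 1)")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")


@dataclass
class DMRRecord:
    chrom: str
    start: int
    end: int
    n_cpgs: int
    mean_delta_beta: float
    combined_p: float
    probe_ids: tuple[str, ...]


def cluster_probes(manifest: pd.DataFrame, candidate_probes, max_gap_bp: int = 1000,
                   gap_mode: str = "gap") -> list[list[str]]:
    """Group candidate probes into proximity clusters, ordered genomically.

    Probes on different chromosomes never co-cluster. In the default
    ``gap`` mode a new cluster starts when the distance to the previous
    probe exceeds ``max_gap_bp``; ``span`` mode also starts a new cluster
    when the running cluster span would exceed ``max_gap_bp``.
    """
    candidates = list(candidate_probes)
    missing = [p for p in candidates if p not in manifest.index]
    if missing:
        raise KeyError(f"candidate probes missing manifest coordinates: {missing[:5]}")
    sub = manifest.loc[candidates, ["chrom", "start"]].copy()
    sub = sub.sort_values(["chrom", "start"])
    clusters: list[list[str]] = []
    for chrom, grp in sub.groupby("chrom", sort=True):
        current: list[str] = []
        prev_pos = None
        first_pos = None
        for pid, pos in zip(grp.index, grp["start"]):
            split = prev_pos is not None and (pos - prev_pos) > max_gap_bp
            if gap_mode == "span" and first_pos is not None and (pos - first_pos) > max_gap_bp:
                split = True
            if split:
                clusters.append(current)
                current = []
                first_pos = None
            if first_pos is None:
                first_pos = pos
            current.append(pid)
            prev_pos = pos
        if current:
            clusters.append(current)
    return clusters


def combine_pvalues(p) -> float:
    """Fisher's combined probability: chi-square tail of -2 sum(ln p)."""
    p = np.asarray(p, dtype=float)
    if np.any(p <= 0):
        log.warning("flooring %d nonpositive p-values", int((p <= 0).sum()))
        p = np.maximum(p, _TINY_P)
    stat, combined = stats.combine_pvalues(p, method="fisher")
    return float(combined)


def find_dmrs(
    stats_table: pd.DataFrame,
    manifest: pd.DataFrame,
    params: DMRParams = DMRParams(),
) -> list[DMRRecord]:
    """Call DMRs from a per-probe statistics table.

    ``stats_table`` is the per-probe discovery output (index probe_id,
    columns at least ``delta_beta`` and ``p``). All testable probes are
    clustered; every cluster with >= ``min_cpgs`` members is a candidate
    whose combined p-value enters the BH correction; candidates passing the
    effect-size floor and adjusted-p threshold are returned sorted by
    combined p (ties by position).
    """
    if len(stats_table) == 0:
        return []
    clusters = cluster_probes(manifest, stats_table.index, params.max_gap_bp,
                              params.gap_mode)
    candidates = [c for c in clusters if len(c) >= params.min_cpgs]
    if not candidates:
        return []
    combined = np.array([
        combine_pvalues(stats_table.loc[c, "p"].to_numpy()) for c in candidates
    ])
    adjusted = bh_adjust(combined)
    records: list[DMRRecord] = []
    for cluster, p_adj in zip(candidates, adjusted):
        mean_delta = float(stats_table.loc[cluster, "delta_beta"].mean())
        if abs(mean_delta) < params.min_mean_delta_beta or p_adj >= params.alpha:
            continue
        coords = manifest.loc[cluster]
        records.append(DMRRecord(
            chrom=str(coords["chrom"].iloc[0]),
            start=int(coords["start"].min()),
            end=int(coords["end"].max()),
            n_cpgs=len(cluster),
            mean_delta_beta=mean_delta,
            combined_p=float(p_adj),
            probe_ids=tuple(cluster),
        ))
    records.sort(key=lambda r: (r.combined_p, r.chrom, r.start))
    return records


def dmrs_to_frame(records: list[DMRRecord]) -> pd.DataFrame:
    """Tabular view of DMR calls (one row per region)."""
    return pd.DataFrame(
        [
            {
                "chrom": r.chrom, "start": r.start, "end": r.end,
                "n_cpgs": r.n_cpgs, "mean_delta_beta": r.mean_delta_beta,
                "combined_p": r.combined_p, "probe_ids": ",".join(r.probe_ids),
            }
            for r in records
        ],
        columns=["chrom", "start", "end", "n_cpgs", "mean_delta_beta",
                 "combined_p", "probe_ids"],
    )


def dmrs_to_bed(records: list[DMRRecord]) -> str:
    """BED text: chrom, start, end, name, score = -log10 combined p."""
    lines = []
    for i, r in enumerate(records, 1):
        score = -np.log10(max(r.combined_p, _TINY_P))
        lines.append(f"{r.chrom}\t{r.start}\t{r.end}\tDMR{i}\t{score:.4g}")
    return "\n".join(lines) + ("\n" if lines else "")
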
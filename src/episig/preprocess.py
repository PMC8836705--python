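"""Probe-level quality filtering and the beta/M transforms.

Methylation arrays report, per CpG probe and sample, a methylated and an
unmethylated signal intensity. The methylation fraction

    beta = meth / (meth + unmeth)            (in [0, 1])

is the universal currency of the pipeline; for linear modeling it is mapped
to the homoscedastic M scale

    M = log2(beta / (1 - beta))

Probes are removed before any statistics when they sit on a sex chromosome,
fail detection in any sample, overlap a SNP, or cross-react with other
genomic regions; those four criteria cover the standard array blocklists.

Matrices are pandas DataFrames with probe ids on the index and sample ids on
the columns; a probe manifest is a DataFrame indexed by probe id with columns
``chrom``, ``start``, ``end``, ``snp_flag``, ``crossreactive_flag``
(coordinates 0-based half-open).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

SEX_CHROMS = frozenset({"chrX", "chrY"})

#: Default clip bound for the logit transform; keeps M finite without
#: materially moving interior beta values.
DEFAULT_EPSILON = 1e-6

#: Default per-sample detection p-value threshold.
DEFAULT_DETP_THRESHOLD = 0.01


@dataclass
class FilterReport:
    """Tally of probes removed per criterion, attributed to the first
    criterion a probe fails (sex-chromosome, then detection-p, then SNP,
    then cross-reactive)."""

    n_input: int = 0
    n_sex_chrom: int = 0
    n_detection_p: int = 0
    n_snp: int = 0
    n_crossreactive: int = 0
    n_retained: int = 0

    @property
    def n_removed(self) -> int:
        return self.n_sex_chrom + self.n_detection_p + self.n_snp + self.n_crossreactive

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_sex_chrom": self.n_sex_chrom,
            "n_detection_p": self.n_detection_p,
            "n_snp": self.n_snp,
            "n_crossreactive": self.n_crossreactive,
            "n_retained": self.n_retained,
        }


def beta_from_intensities(methylated_signal, unmethylated_signal):
    """Methylation fraction from raw signal intensities.

    ``meth / (meth + unmeth)``; NaN where both signals are zero (the probe
    measured nothing). Accepts scalars or arrays.
    """
    meth = np.asarray(methylated_signal, dtype=float)
    unmeth = np.asarray(unmethylated_signal, dtype=float)
    if np.any(meth < 0) or np.any(unmeth < 0):
        raise ValueError("signal intensities must be non-negative")
    total = meth + unmeth
    with np.errstate(invalid="ignore", divide="ignore"):
        beta = np.where(total > 0, meth / np.where(total > 0, total, 1.0), np.nan)
    if beta.ndim == 0:
        return float(beta)
    return beta


def beta_to_m(beta: pd.DataFrame, epsilon: float = DEFAULT_EPSILON) -> pd.DataFrame:
    """Logit transform to M values, ``log2(beta / (1 - beta))``.

    Beta is clipped to ``[epsilon, 1 - epsilon]`` so boundary values stay
    finite; missing values propagate as missing.
    """
    if not (0 < epsilon < 0.5):
        raise ValueError(f"epsilon must be in (0, 0.5), got {epsilon}")
    clipped = np.clip(beta.to_numpy(dtype=float), epsilon, 1.0 - epsilon)
    clipped[np.isnan(beta.to_numpy(dtype=float))] = np.nan
    m = np.log2(clipped / (1.0 - clipped))
    return pd.DataFrame(m, index=beta.index, columns=beta.columns)


def m_to_beta(m: pd.DataFrame) -> pd.DataFrame:
    """Inverse of :func:`beta_to_m`: ``beta = 2^M / (1 + 2^M)``."""
    arr = np.asarray(m, dtype=float)
    beta = 1.0 / (1.0 + np.power(2.0, -arr))
    if isinstance(m, pd.DataFrame):
        return pd.DataFrame(beta, index=m.index, columns=m.columns)
    return beta


def filter_probes(
    beta: pd.DataFrame,
    detp: pd.DataFrame,
    manifest: pd.DataFrame,
    detp_threshold: float = DEFAULT_DETP_THRESHOLD,
) -> tuple[pd.DataFrame, FilterReport]:
    """Remove unreliable probes before differential analysis.

    A probe is dropped if it (1) lies on chrX or chrY, (2) has detection
    p-value above ``detp_threshold`` in *any* sample, (3) carries a SNP flag,
    or (4) carries a cross-reactivity flag. The report attributes each
    removed probe to the first criterion it fails, in that order, so the
    counts sum exactly to the input probe count.

    Returns the filtered beta matrix (row order preserved) and a
    :class:`FilterReport`.
    """
    missing = beta.index.difference(manifest.index)
    if len(missing) > 0:
        raise KeyError(f"probes absent from manifest: {list(missing[:5])!r}")
    missing_detp = beta.index.difference(detp.index)
    if len(missing_detp) > 0:
        raise KeyError(f"probes absent from detection-p matrix: {list(missing_detp[:5])!r}")

    man = manifest.loc[beta.index]
    dp = detp.loc[beta.index, beta.columns]

    on_sex = man["chrom"].isin(SEX_CHROMS).to_numpy()
    fails_detp = (dp.to_numpy(dtype=float) > detp_threshold).any(axis=1)
    snp = man["snp_flag"].astype(bool).to_numpy()
    xreact = man["crossreactive_flag"].astype(bool).to_numpy()

    report = FilterReport(n_input=len(beta.index))
    # first-failing-criterion attribution
    report.n_sex_chrom = int(on_sex.sum())
    report.n_detection_p = int((~on_sex & fails_detp).sum())
    report.n_snp = int((~on_sex & ~fails_detp & snp).sum())
    report.n_crossreactive = int((~on_sex & ~fails_detp & ~snp & xreact).sum())

    keep = ~(on_sex | fails_detp | snp | xreact)
    report.n_retained = int(keep.sum())
    return beta.loc[keep], report
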
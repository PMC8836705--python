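"""Synthetic methylation-cohort simulator with known ground truth.

Generates probe-by-sample beta matrices that emulate the marginal structure
of Infinium-style methylation arrays: a bimodal baseline (most CpGs are
either lowly or highly methylated), logit-scale per-sample noise, a small
array-type batch shift, and per-probe detection p-values with occasional
failures. On top of the baseline it spikes

* single differentially methylated probes (DMPs) in the case group, with a
  deterministic hypomethylated/hypermethylated direction split (default
  87% / 13%, the direction mix of the disorder the pipeline targets), and
* region-clustered groups of CpGs (DMRs) packed within a configurable span,

and records both as ground truth so every downstream stage — probe
filtering, matching, probe selection, classification, region calling — can
be scored against a known answer.

The simulator is the package's study-condition generator, not a model of
array chemistry: probe-type bias, cell-composition heterogeneity and raw
intensity channels are deliberately out of scope.
"""

from __future__ import annotations

import pathlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocess import beta_to_m, m_to_beta

_AUTOSOMES = [f"chr{i}" for i in range(1, 23)]

# beta-mixture hyperparameters for the baseline probe means: low mode near
# 0.1, high mode near 0.85, equal weights — the canonical array marginal.
_LOW_A, _LOW_B = 5.0, 45.0
_HIGH_A, _HIGH_B = 34.0, 6.0
_MIX_LOW_WEIGHT = 0.5

# clip for spiked group means so logits stay well-behaved
_MEAN_CLIP = 0.01


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated cohort.

    Defaults encode the discovery design emulated throughout the package:
    41 cases against a control pool large enough for 1:2 matched selection,
    a hypomethylation-dominant effect direction mix (87%/13%), and spiked
    effect sizes comfortably above the 10% methylation-difference floor the
    region caller uses.
    """

    n_probes: int = 20_000
    n_cases: int = 41
    n_control_pool: int = 200
    n_other_cohorts: int = 0
    n_samples_per_other_cohort: int = 20
    n_spiked_dmps: int = 300
    hypo_fraction: float = 0.87
    delta_beta_mean: float = 0.18
    delta_beta_sd: float = 0.03
    n_spiked_dmrs: int = 0
    dmr_n_cpgs: int = 4
    dmr_span_bp: int = 800
    #: optional explicit region plan [(n_cpgs, delta_beta), ...]; overrides
    #: n_spiked_dmrs/dmr_n_cpgs/delta_beta for regions when given
    dmr_regions: tuple[tuple[int, float], ...] | None = None
    noise_sd: float = 0.25
    batch_sd: float = 0.05
    #: projected sample-score SDs (M units) of global-structure latent
    #: factors; these dominate the top principal components the way batch
    #: and cell-composition variation do on real arrays
    latent_factor_sds: tuple[float, ...] = (40.0, 28.0)
    n_outliers: int = 0
    outlier_magnitude: float = 0.0
    age_range: tuple[float, float] = (2.0, 40.0)
    #: fraction of each other-disorder cohort's spiked probes drawn from the
    #: case truth set (0 = disjoint signatures)
    other_overlap: float = 0.0
    frac_chrx: float = 0.02
    frac_chry: float = 0.005
    frac_snp: float = 0.01
    frac_crossreactive: float = 0.01
    frac_detp_fail: float = 0.002
    seed: int = 0

    def validate(self) -> None:
        if not (0.0 <= self.hypo_fraction <= 1.0):
            raise ValueError("hypo_fraction must be in [0, 1]")
        for name in ("n_probes", "n_cases", "n_control_pool", "n_other_cohorts",
                     "n_samples_per_other_cohort", "n_spiked_dmps", "n_spiked_dmrs",
                     "n_outliers"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_spiked_dmps > self.n_probes:
            raise ValueError("n_spiked_dmps exceeds n_probes")
        if self.dmr_n_cpgs < 3 and self.n_spiked_dmrs > 0 and self.dmr_regions is None:
            raise ValueError("dmr_n_cpgs must be >= 3")


@dataclass
class SimulatedCohort:
    """A cohort plus its ground truth.

    ``beta``/``detection_p`` are probe-by-sample DataFrames, ``manifest`` a
    probe-indexed coordinate/flag table, ``samples`` the sample sheet
    (sample_id index; group, age, sex, array_type, cohort columns).
    ``truth_dmps`` records (probe_id, direction, true delta-beta) for spiked
    single probes; ``truth_dmrs`` records (chrom, start, end, probe_ids) for
    planted regions.
    """

    config: SimConfig
    beta: pd.DataFrame
    detection_p: pd.DataFrame
    manifest: pd.DataFrame
    samples: pd.DataFrame
    truth_dmps: pd.DataFrame
    truth_dmrs: pd.DataFrame
    outlier_ids: list[str] = field(default_factory=list)

    def equals(self, other: "SimulatedCohort") -> bool:
        return (
            self.beta.equals(other.beta)
            and self.detection_p.equals(other.detection_p)
            and self.manifest.equals(other.manifest)
            and self.samples.equals(other.samples)
            and self.truth_dmps.equals(other.truth_dmps)
            and self.truth_dmrs.equals(other.truth_dmrs)
            and self.outlier_ids == other.outlier_ids
        )


def _probe_ids(n: int) -> list[str]:
    return [f"cg{i:08d}" for i in range(n)]


def _make_manifest(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Assign coordinates and blocklist flags.

    Probes are laid down in contiguous blocks per chromosome, 5 kb apart, so
    no background pair ever falls within the region caller's 1 kb gap; only
    planted regions create dense clusters. Sex-chromosome and flagged probes
    are taken from the tail of the probe list so spike-in targets (drawn from
    the head) are always clean autosomal probes.
    """
    ids = _probe_ids(cfg.n_probes)
    n = cfg.n_probes
    n_x = int(round(cfg.frac_chrx * n))
    n_y = int(round(cfg.frac_chry * n))
    n_auto = n - n_x - n_y

    chroms = np.empty(n, dtype=object)
    starts = np.empty(n, dtype=np.int64)
    per_chrom = int(np.ceil(n_auto / len(_AUTOSOMES))) if n_auto else 0
    for i in range(n_auto):
        chroms[i] = _AUTOSOMES[i // per_chrom]
        starts[i] = 10_000 + (i % per_chrom) * 5_000
    for i in range(n_auto, n_auto + n_x):
        chroms[i] = "chrX"
        starts[i] = 10_000 + (i - n_auto) * 5_000
    for i in range(n_auto + n_x, n):
        chroms[i] = "chrY"
        starts[i] = 10_000 + (i - n_auto - n_x) * 5_000

    snp = np.zeros(n, dtype=bool)
    xreact = np.zeros(n, dtype=bool)
    n_snp = int(round(cfg.frac_snp * n))
    n_xr = int(round(cfg.frac_crossreactive * n))
    # flags live just before the sex-chromosome block
    flag_hi = n_auto
    snp[flag_hi - n_snp: flag_hi] = True
    xreact[flag_hi - n_snp - n_xr: flag_hi - n_snp] = True

    return pd.DataFrame(
        {
            "chrom": chroms,
            "start": starts,
            "end": starts + 2,
            "snp_flag": snp,
            "crossreactive_flag": xreact,
        },
        index=pd.Index(ids, name="probe_id"),
    )


def _make_samples(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []

    def draw(group: str, cohort: str, n: int):
        ages = rng.uniform(cfg.age_range[0], cfg.age_range[1], size=n).round(1)
        sexes = rng.choice(["m", "f"], size=n)
        arrays = rng.choice(["EPIC", "450k"], size=n, p=[0.8, 0.2])
        for i in range(n):
            rows.append((f"{cohort}_{i:03d}", group, ages[i], sexes[i], arrays[i], cohort))

    draw("case", "case", cfg.n_cases)
    draw("control_pool", "control", cfg.n_control_pool)
    for c in range(cfg.n_other_cohorts):
        name = f"other{c}"
        draw(f"other_cohort:{name}", name, cfg.n_samples_per_other_cohort)

    df = pd.DataFrame(rows, columns=["sample_id", "group", "age", "sex", "array_type", "cohort"])
    return df.set_index("sample_id")


def _region_plan(cfg: SimConfig) -> list[tuple[int, float]]:
    if cfg.dmr_regions is not None:
        return [(int(k), float(d)) for k, d in cfg.dmr_regions]
    return [(cfg.dmr_n_cpgs, cfg.delta_beta_mean)] * cfg.n_spiked_dmrs


def simulate_cohort(config: SimConfig) -> SimulatedCohort:
    """Generate a full cohort with spiked DMPs and DMRs.

    The baseline mean beta of each probe is drawn from a two-component Beta
    mixture (modes near 0.1 and 0.85); each sample's value is the probe's
    baseline logit plus Gaussian noise (sd ``noise_sd``) mapped back through
    the inverse logit, so values land in (0, 1) by construction. Samples run
    on the 450k array type receive an additional global logit shift of
    ``batch_sd``. Spiked probes move the *case-group mean* on the beta scale
    by the probe's drawn effect size (clipped into [0.01, 0.99]); exactly
    ``round(hypo_fraction * n_spiked_dmps)`` of the spiked DMPs are
    hypomethylated in cases. Planted regions pack their CpGs within
    ``dmr_span_bp`` on one chromosome, replacing the coordinates of the
    probes they consume.

    Identical config (including seed) gives bit-identical output.
    """
    config.validate()
    cfg = config
    ss = np.random.SeedSequence(cfg.seed)
    rng_manifest, rng_samples, rng_base, rng_spike, rng_noise, rng_detp, rng_other, rng_out = (
        np.random.default_rng(s) for s in ss.spawn(8)
    )

    manifest = _make_manifest(cfg, rng_manifest)
    samples = _make_samples(cfg, rng_samples)
    probe_ids = manifest.index
    sample_ids = samples.index
    n_probes, n_samples = len(probe_ids), len(sample_ids)

    # baseline probe means from the bimodal mixture
    low = rng_base.random(n_probes) < _MIX_LOW_WEIGHT
    mean_beta = np.where(
        low,
        rng_base.beta(_LOW_A, _LOW_B, size=n_probes),
        rng_base.beta(_HIGH_A, _HIGH_B, size=n_probes),
    )
    mean_beta = np.clip(mean_beta, _MEAN_CLIP, 1 - _MEAN_CLIP)

    # choose spike targets among clean autosomal probes (head of the list)
    clean = (
        ~manifest["chrom"].isin(["chrX", "chrY"])
        & ~manifest["snp_flag"]
        & ~manifest["crossreactive_flag"]
    ).to_numpy()
    clean_idx = np.flatnonzero(clean)
    plan = _region_plan(cfg)
    n_region_probes = sum(k for k, _ in plan)
    if cfg.n_spiked_dmps + n_region_probes > len(clean_idx):
        raise ValueError("not enough clean probes for requested spikes")
    chosen = rng_spike.choice(clean_idx, size=cfg.n_spiked_dmps + n_region_probes, replace=False)
    dmp_idx = np.sort(chosen[: cfg.n_spiked_dmps])
    region_pool = np.sort(chosen[cfg.n_spiked_dmps:])

    # deterministic direction split: first round(f*n) of the (shuffled)
    # spiked probes are hypomethylated
    n_hypo = int(round(cfg.hypo_fraction * cfg.n_spiked_dmps))
    order = rng_spike.permutation(cfg.n_spiked_dmps)
    signs = np.empty(cfg.n_spiked_dmps)
    signs[order[:n_hypo]] = -1.0
    signs[order[n_hypo:]] = +1.0
    deltas = np.abs(rng_spike.normal(cfg.delta_beta_mean, cfg.delta_beta_sd, cfg.n_spiked_dmps))

    case_mean = mean_beta.copy()
    truth_rows = []
    for idx, sign, d in zip(dmp_idx, signs, deltas):
        # re-anchor the baseline so the nominal effect is fully realizable
        # on the beta scale (a 0.18 hypo shift needs headroom below)
        if sign < 0:
            base = float(np.clip(mean_beta[idx], d + 0.05, 1 - _MEAN_CLIP))
        else:
            base = float(np.clip(mean_beta[idx], _MEAN_CLIP, 0.95 - d))
        mean_beta[idx] = base
        target = base + sign * d
        case_mean[idx] = target
        truth_rows.append(
            (probe_ids[idx], "hypo" if sign < 0 else "hyper", target - base)
        )
    truth_dmps = pd.DataFrame(truth_rows, columns=["probe_id", "direction", "delta_beta"])

    # planted regions: consume probes from region_pool, rewrite coordinates
    # to dense clusters, shift case means (hypomethylated regions)
    truth_dmr_rows = []
    pool_pos = 0
    for r, (k, d) in enumerate(plan):
        members = region_pool[pool_pos: pool_pos + k]
        pool_pos += k
        anchor = members[0]
        chrom = manifest.iloc[anchor]["chrom"]
        start0 = int(manifest.iloc[anchor]["start"])
        span = max(cfg.dmr_span_bp, k - 1)
        offsets = np.linspace(0, span, k).astype(np.int64)
        for m_i, off in zip(members, offsets):
            manifest.iloc[m_i, manifest.columns.get_loc("chrom")] = chrom
            manifest.iloc[m_i, manifest.columns.get_loc("start")] = start0 + off
            manifest.iloc[m_i, manifest.columns.get_loc("end")] = start0 + off + 2
        for m_i in members:
            # anchor region means in mid-methylation so the full delta is
            # realizable on the beta scale
            base = float(np.clip(mean_beta[m_i], 0.35, 0.75))
            mean_beta[m_i] = base
            case_mean[m_i] = np.clip(base - d, _MEAN_CLIP, 1 - _MEAN_CLIP)
        truth_dmr_rows.append(
            (chrom, start0, start0 + int(offsets[-1]) + 2,
             ",".join(probe_ids[m] for m in members))
        )
    truth_dmrs = pd.DataFrame(truth_dmr_rows, columns=["chrom", "start", "end", "probe_ids"])

    # other-disorder cohorts get their own spiked probe sets
    group = samples["group"].to_numpy()
    is_case = group == "case"
    other_means = {}
    for c in range(cfg.n_other_cohorts):
        n_shared = int(round(cfg.other_overlap * cfg.n_spiked_dmps))
        shared = rng_other.choice(dmp_idx, size=n_shared, replace=False) if n_shared else np.array([], dtype=int)
        avail = np.setdiff1d(clean_idx, chosen)
        own = rng_other.choice(avail, size=cfg.n_spiked_dmps - n_shared, replace=False)
        cm = mean_beta.copy()
        for idx in np.concatenate([shared, own]).astype(int):
            d = abs(rng_other.normal(cfg.delta_beta_mean, cfg.delta_beta_sd))
            sign = -1.0 if rng_other.random() < cfg.hypo_fraction else 1.0
            if idx in dmp_idx:  # shared probes move the same direction as in cases
                row = truth_dmps.loc[truth_dmps["probe_id"] == probe_ids[idx]]
                sign = -1.0 if row["direction"].iloc[0] == "hypo" else 1.0
            cm[idx] = np.clip(mean_beta[idx] + sign * d, _MEAN_CLIP, 1 - _MEAN_CLIP)
        other_means[f"other{c}"] = cm

    # assemble per-sample logit means, add noise, map back to beta
    logit = lambda p: np.log2(p / (1 - p))
    base_logit = logit(mean_beta)
    case_logit = logit(case_mean)
    cohort = samples["cohort"].to_numpy()
    arr450 = (samples["array_type"] == "450k").to_numpy()

    mu = np.tile(base_logit[:, None], (1, n_samples))
    mu[:, is_case] = case_logit[:, None]
    for name, cm in other_means.items():
        cols = cohort == name
        mu[:, cols] = logit(cm)[:, None]
    mu[:, arr450] += cfg.batch_sd

    noise = rng_noise.normal(0.0, cfg.noise_sd, size=(n_probes, n_samples))
    # global-structure latent factors: per-probe loadings scaled so the
    # projected sample-score SD equals the configured value regardless of
    # probe count; scores truncated at 2 SD so a clean cohort produces no
    # spurious outliers at the default 3-robust-SD flagging threshold
    for s in cfg.latent_factor_sds:
        loadings = rng_noise.normal(0.0, s / max(np.sqrt(n_probes), 1.0), size=n_probes)
        scores = np.clip(rng_noise.normal(0.0, 1.0, size=n_samples), -2.0, 2.0)
        noise += loadings[:, None] * scores[None, :]
    beta_vals = m_to_beta(mu + noise)
    beta = pd.DataFrame(beta_vals, index=probe_ids, columns=sample_ids)

    # detection p-values: near zero, with rare injected failures
    detp_vals = rng_detp.uniform(0.0, 0.005, size=(n_probes, n_samples))
    n_fail = int(round(cfg.frac_detp_fail * n_probes))
    if n_fail:
        # failures hit non-spiked probes only, one random sample each
        avail = np.setdiff1d(clean_idx, chosen)
        fail_probes = rng_detp.choice(avail, size=n_fail, replace=False)
        fail_samples = rng_detp.integers(0, n_samples, size=n_fail)
        detp_vals[fail_probes, fail_samples] = rng_detp.uniform(0.02, 0.5, size=n_fail)
    detp = pd.DataFrame(detp_vals, index=probe_ids, columns=sample_ids)

    cohort_obj = SimulatedCohort(
        config=cfg,
        beta=beta,
        detection_p=detp,
        manifest=manifest,
        samples=samples,
        truth_dmps=truth_dmps,
        truth_dmrs=truth_dmrs,
    )
    if cfg.n_outliers:
        cohort_obj = inject_outliers(cohort_obj, cfg.n_outliers, cfg.outlier_magnitude,
                                     rng=rng_out)
    return cohort_obj


def inject_outliers(
    cohort: SimulatedCohort,
    n: int,
    magnitude: float,
    rng: np.random.Generator | None = None,
) -> SimulatedCohort:
    """Globally shift ``n`` control-pool samples on the logit scale.

    Each designated sample's M values are shifted by ``magnitude`` times the
    per-probe population SD of M, emulating a sample with grossly aberrant
    global structure (failed bisulfite conversion, sample swap). Shifted
    sample ids are recorded in ``outlier_ids``. ``n=0`` or ``magnitude=0``
    leaves beta untouched.
    """
    pool = cohort.samples.index[cohort.samples["group"] == "control_pool"]
    if n > len(pool):
        raise ValueError(f"cannot inject {n} outliers into pool of {len(pool)}")
    if n == 0:
        return cohort
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(cohort.config.seed).spawn(8)[-1].entropy % (2**31))
    chosen = sorted(rng.choice(np.asarray(pool), size=n, replace=False).tolist())
    beta = cohort.beta.copy()
    if magnitude != 0.0:
        m = beta_to_m(beta)
        sd = m.to_numpy().std(axis=1, ddof=1)
        for sid in chosen:
            m[sid] = m[sid].to_numpy() + magnitude * sd
        beta = m_to_beta(m)
    return SimulatedCohort(
        config=cohort.config,
        beta=beta,
        detection_p=cohort.detection_p,
        manifest=cohort.manifest,
        samples=cohort.samples,
        truth_dmps=cohort.truth_dmps,
        truth_dmrs=cohort.truth_dmrs,
        outlier_ids=list(cohort.outlier_ids) + chosen,
    )


# float format that survives a text round-trip bit-exactly
_FLOAT_FMT = "%.17g"


def write_fixtures(cohort: SimulatedCohort, directory) -> dict[str, pathlib.Path]:
    """Write the cohort as plain-text fixture files.

    Emits ``beta.tsv``, ``detp.tsv`` (probe rows x sample columns),
    ``manifest.tsv`` (BED-like, 0-based half-open), ``samples.csv``,
    ``truth_dmps.tsv`` and ``truth_dmrs.tsv``. Floats are written with
    enough digits that reading the files back reproduces the cohort exactly.
    """
    directory = pathlib.Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "beta": directory / "beta.tsv",
        "detp": directory / "detp.tsv",
        "manifest": directory / "manifest.tsv",
        "samples": directory / "samples.csv",
        "truth_dmps": directory / "truth_dmps.tsv",
        "truth_dmrs": directory / "truth_dmrs.tsv",
    }
    cohort.beta.to_csv(paths["beta"], sep="\t", float_format=_FLOAT_FMT, index_label="probe_id")
    cohort.detection_p.to_csv(paths["detp"], sep="\t", float_format=_FLOAT_FMT, index_label="probe_id")
    cohort.manifest.to_csv(paths["manifest"], sep="\t", index_label="probe_id")
    cohort.samples.to_csv(paths["samples"], float_format=_FLOAT_FMT, index_label="sample_id")
    cohort.truth_dmps.to_csv(paths["truth_dmps"], sep="\t", index=False, float_format=_FLOAT_FMT)
    cohort.truth_dmrs.to_csv(paths["truth_dmrs"], sep="\t", index=False)
    return paths


def read_fixtures(directory) -> dict[str, pd.DataFrame]:
    """Read back the tables written by :func:`write_fixtures`."""
    directory = pathlib.Path(directory)
    out = {
        "beta": pd.read_csv(directory / "beta.tsv", sep="\t", index_col="probe_id",
                            float_precision="round_trip"),
        "detp": pd.read_csv(directory / "detp.tsv", sep="\t", index_col="probe_id",
                            float_precision="round_trip"),
        "manifest": pd.read_csv(directory / "manifest.tsv", sep="\t", index_col="probe_id"),
        "samples": pd.read_csv(directory / "samples.csv", index_col="sample_id"),
        "truth_dmps": pd.read_csv(directory / "truth_dmps.tsv", sep="\t"),
        "truth_dmrs": pd.read_csv(directory / "truth_dmrs.tsv", sep="\t"),
    }
    return out
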
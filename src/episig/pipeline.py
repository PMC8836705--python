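"""End-to-end orchestration: filter -> match -> discover -> validate ->
train -> score -> DMR call, with a consolidated run report.

Every stage consumes only the files (or frames) the previous stage
produced, so deleting intermediates and re-running from the same config
reproduces them; with a fixed seed the signature, model and DMR artifacts
are byte-identical between runs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import pathlib
from dataclasses import dataclass, field

import pandas as pd

from . import io as eio
from .dmr import DMRParams, dmrs_to_bed, dmrs_to_frame, find_dmrs
from .matching import iterate_matching
from .mvp import TrainConfig, score_samples, train_mvp
from .preprocess import DEFAULT_DETP_THRESHOLD, filter_probes
from .selection import SelectionParams, compute_probe_stats, hypo_hyper_split, select_dmps
from .validation import loo_validate, mds_embed, ward_cluster

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    beta_path: str
    detp_path: str
    manifest_path: str
    samples_path: str
    out_dir: str
    detp_threshold: float = DEFAULT_DETP_THRESHOLD
    match_ratio: int = 2
    k_sd: float = 3.0
    selection: SelectionParams = field(default_factory=SelectionParams)
    train: TrainConfig = field(default_factory=TrainConfig)
    dmr: DMRParams = field(default_factory=DMRParams)
    run_loo: bool = True
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        raw = yaml.safe_load(pathlib.Path(path).read_text())
        sel = SelectionParams(**raw.pop("selection", {}))
        train = TrainConfig(**raw.pop("train", {}))
        dmr = DMRParams(**raw.pop("dmr", {}))
        return cls(selection=sel, train=train, dmr=dmr, **raw)

    def config_hash(self) -> str:
        # out_dir is where results land, not what they are: exclude it so
        # identical analyses hash identically wherever they are written
        items = {k: str(v) for k, v in sorted(self.__dict__.items())
                 if k != "out_dir"}
        blob = json.dumps(items, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages and return the run report (also written to disk).

    Artifacts written to ``out_dir``: filtered beta TSV, match.json,
    signature.json, probe_stats.tsv, model.json, scores.tsv, dmrs.tsv,
    dmrs.bed, loo.json (when enabled), mds.tsv, clusters.tsv, report.json.
    """
    out = pathlib.Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name in ("beta_path", "detp_path", "manifest_path", "samples_path"):
        p = pathlib.Path(getattr(config, name))
        if not p.exists():
            raise FileNotFoundError(f"{name} does not exist: {p}")

    beta = eio.read_beta_matrix(config.beta_path)
    detp = eio.read_detp_matrix(config.detp_path)
    manifest = eio.read_manifest(config.manifest_path)
    samples = eio.read_sample_sheet(config.samples_path)

    # 1. probe filtering
    beta_f, filter_report = filter_probes(beta, detp, manifest, config.detp_threshold)
    eio.write_matrix(beta_f, out / "beta_filtered.tsv")
    log.info("probe filter: %s", filter_report.to_dict())

    # 2. matched-control selection with iterative outlier removal
    cases = samples[samples["group"] == "case"]
    pool = samples[samples["group"] == "control_pool"]
    match = iterate_matching(cases, pool, beta_f, ratio=config.match_ratio,
                             k_sd=config.k_sd)
    (out / "match.json").write_text(json.dumps(match.to_dict(), indent=1, sort_keys=True))

    case_ids = sorted(cases.index)
    control_ids = match.selected_control_ids
    cols = case_ids + control_ids
    labels = pd.Series(["case"] * len(case_ids) + ["control"] * len(control_ids),
                       index=cols)
    beta_cc = beta_f[cols]

    # 3. probe statistics + three-step selection
    stats_table = compute_probe_stats(beta_cc, labels)
    stats_table.to_csv(out / "probe_stats.tsv", sep="\t", float_format="%.8g",
                       index_label="probe_id")
    signature = select_dmps(stats_table, beta_cc, labels, config.selection)
    signature.provenance["config_hash"] = config.config_hash()
    signature.provenance["seed"] = config.seed
    signature.to_json(out / "signature.json")
    hypo, hyper = hypo_hyper_split(signature)

    # 4. unsupervised validation
    beta_sig = beta_cc.loc[signature.probe_ids]
    cluster = ward_cluster(beta_sig, truth=labels)
    mds = mds_embed(beta_sig)
    mds.coords.assign(group=labels).to_csv(out / "mds.tsv", sep="\t",
                                           index_label="sample_id")
    pd.DataFrame({"cluster": cluster.labels2, "group": labels}).to_csv(
        out / "clusters.tsv", sep="\t", index_label="sample_id")
    loo_summary = None
    if config.run_loo:
        loo = loo_validate(case_ids, control_ids, beta_f, config.selection)
        (out / "loo.json").write_text(json.dumps(loo.to_dict(), indent=1, sort_keys=True))
        loo_summary = {"n_rounds": loo.n_rounds, "n_correct": loo.n_correct}

    # 5. classifier
    model = train_mvp(beta_sig, labels, config.train)
    model.save(out / "model.json")
    scores = score_samples(model, beta_f)
    scores.assign(group=samples["group"].reindex(scores.index)).to_csv(
        out / "scores.tsv", sep="\t", float_format="%.8g", index_label="sample_id")

    # 6. DMR calling over all testable probes
    dmrs = find_dmrs(stats_table, manifest, config.dmr)
    dmrs_to_frame(dmrs).to_csv(out / "dmrs.tsv", sep="\t", index=False,
                               float_format="%.8g")
    (out / "dmrs.bed").write_text(dmrs_to_bed(dmrs))

    report = {
        "filter": filter_report.to_dict(),
        "match": {
            "n_cases": len(case_ids),
            "n_controls": len(control_ids),
            "iterations": match.iterations,
            "removed_outliers": match.removed_outlier_ids,
        },
        "selection": {
            "n_step1": signature.n_step1,
            "n_step2": signature.n_step2,
            "n_signature": len(signature),
            "hypo_fraction": hypo,
            "hyper_fraction": hyper,
        },
        "validation": {
            "ward_agreement": cluster.agreement,
            "mds_stress": mds.stress,
            "loo": loo_summary,
        },
        "classifier": {
            "cost": model.cost,
            "cv_accuracy": model.cv_accuracy,
        },
        "dmr": {"n_dmrs": len(dmrs)},
        "provenance": {"config_hash": config.config_hash(), "seed": config.seed},
    }
    (out / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    return report
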
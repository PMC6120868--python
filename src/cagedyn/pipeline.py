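"""End-to-end orchestration of the promoter-dynamics analysis.

One configuration drives the whole flow: (optionally) simulate inputs, then
normalize -> pairwise differential expression per agonist -> response
dynamics -> k-means clustering of TF-promoter profiles -> motif activity
fitting for the promoter and enhancer compartments -> motif-activity
clustering -> promoter-vs-enhancer motif categorization.  Every stage writes
a TSV, one structured log line reports rows in/out, and a JSON manifest
records parameters, seed and SHA-256 checksums of all outputs so a rerun can
be audited byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .clustering import kmeans_profiles, mean_cluster_profiles, select_tf_promoters
from .diffexpr import pairwise_de
from .dynamics import (
    ShapeParams,
    classify_all_shapes,
    count_significant_per_timepoint,
    partition_responders,
    responder_set,
)
from .io import (
    CountMatrix,
    ValidationError,
    read_count_table,
    read_promoter_bed,
    read_sample_metadata,
    write_count_table,
    write_sample_metadata,
)
from .mara import categorize_motif_dynamics, fit_motif_activities, motif_dynamism_z
from .normalize import log2fc_vs_t0, tags_to_tpm, timepoint_mean
from .simulate import SynthConfig, make_promoter_annotations, simulate_motif_system, simulate_timecourse

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineError", "run_full_pipeline"]


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and a machine-readable code."""

    def __init__(self, stage: str, code: str, message: str):
        super().__init__(f"[{stage}/{code}] {message}")
        self.stage = stage
        self.code = code


@dataclass
class PipelineConfig:
    """Parameters of a full run; file paths may be omitted to simulate inputs."""

    counts_path: str | None = None
    meta_path: str | None = None
    annotations_path: str | None = None
    synth: SynthConfig = field(default_factory=SynthConfig)
    alpha: float = 0.05
    min_tags: int = 5
    min_tpm: float = 10.0
    k_tf: int = 10
    k_motif: int = 5
    ridge_lambda: float = 1.0
    z_threshold: float = 2.0
    shape_params: ShapeParams = field(default_factory=ShapeParams)
    seed: int = 0

    def validate(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValidationError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.min_tags < 0 or self.min_tpm < 0:
            raise ValidationError("thresholds must be non-negative")
        if self.k_tf < 1 or self.k_motif < 1:
            raise ValidationError("cluster counts must be positive")
        if self.ridge_lambda < 0:
            raise ValidationError("ridge_lambda must be >= 0")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write(df: pd.DataFrame, path: Path, **kw) -> None:
    df.to_csv(path, sep="\t", float_format="%.10g", **kw)


def run_full_pipeline(cfg: PipelineConfig, outdir: str | Path) -> dict:
    """Run every stage and return the manifest (also written as manifest.json)."""
    cfg.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, str] = {}

    def emit(stage: str, name: str, df: pd.DataFrame, **kw) -> None:
        path = outdir / name
        _write(df, path, **kw)
        outputs[name] = _sha256(path)
        logger.info("stage=%s wrote=%s rows=%d", stage, name, len(df))

    # -- inputs -------------------------------------------------------------
    stage = "inputs"
    try:
        if cfg.counts_path and cfg.meta_path:
            counts = read_count_table(cfg.counts_path)
            meta = read_sample_metadata(cfg.meta_path)
            if cfg.annotations_path is None:
                raise ValidationError("annotations_path is required with user-supplied counts")
            annotations = read_promoter_bed(cfg.annotations_path)
            truth = None
        else:
            synth = SynthConfig(**{**asdict(cfg.synth), "seed": cfg.seed})
            counts, meta, truth = simulate_timecourse(synth)
            annotations = make_promoter_annotations(synth)
            write_count_table(counts, outdir / "counts.tsv")
            write_sample_metadata(meta, outdir / "samples.tsv")
            outputs["counts.tsv"] = _sha256(outdir / "counts.tsv")
            outputs["samples.tsv"] = _sha256(outdir / "samples.tsv")
    except ValidationError as exc:
        raise PipelineError(stage, "invalid_input", str(exc)) from exc

    agonists = sorted({m.agonist.value for m in meta} - {"NONE"})
    logger.info("stage=inputs promoters=%d samples=%d agonists=%s",
                counts.shape[0], counts.shape[1], agonists)

    # -- normalize ----------------------------------------------------------
    stage = "normalize"
    tpm = tags_to_tpm(counts)
    emit(stage, "tpm.tsv", tpm.data, index_label="promoter_id")
    lfc_by_agonist = {}
    for ag in agonists:
        means = timepoint_mean(tpm, meta, ag)
        lfc = log2fc_vs_t0(means)
        lfc_by_agonist[ag] = lfc
        emit(stage, f"log2fc_{ag}.tsv", lfc, index_label="promoter_id")

    # -- differential expression --------------------------------------------
    stage = "diffexpr"
    de_by_agonist = {}
    for ag in agonists:
        try:
            de = pairwise_de(counts, meta, ag, alpha=cfg.alpha, min_tags=cfg.min_tags)
        except ValidationError as exc:
            raise PipelineError(stage, "de_failed", str(exc)) from exc
        de_by_agonist[ag] = de
        emit(stage, f"de_{ag}.tsv", de, index=False)

    # -- dynamics -----------------------------------------------------------
    stage = "dynamics"
    tally_rows = []
    shape_tables = {}
    for ag in agonists:
        de = de_by_agonist[ag]
        tally = count_significant_per_timepoint(de)
        tally_rows.extend({"agonist": ag, "time_min": t, "n_significant": n}
                          for t, n in tally.items())
        anchored = de[de["time_a"] == 0]
        sig = anchored.pivot(index="region_id", columns="time_b", values="significant")
        lfc = lfc_by_agonist[ag].reindex(sig.index)
        shapes = classify_all_shapes(lfc, sig.fillna(False).astype(bool), cfg.shape_params)
        shape_tables[ag] = shapes
        emit(stage, f"shapes_{ag}.tsv", shapes)
    emit(stage, "significant_per_timepoint.tsv", pd.DataFrame(tally_rows), index=False)

    partition_df = pd.DataFrame()
    if len(agonists) == 2:
        sets = {ag: responder_set(de_by_agonist[ag]) for ag in agonists}
        try:
            part = partition_responders(sets.get("FGF2", set()), sets.get("IL1B", set()))
            partition_df = pd.DataFrame(
                [
                    {"set": "fgf2_only", "n": len(part.fgf2_only), "pct": part.pct_fgf2_only},
                    {"set": "il1b_only", "n": len(part.il1b_only), "pct": part.pct_il1b_only},
                    {"set": "both", "n": len(part.both), "pct": part.pct_both},
                    {"set": "total", "n": part.total, "pct": 100.0},
                ]
            )
        except ValidationError:
            logger.warning("stage=dynamics no responders; partition skipped")
    emit(stage, "responder_partition.tsv", partition_df, index=False)

    # -- clustering of TF promoter profiles ----------------------------------
    stage = "clustering"
    tf_ids = select_tf_promoters(annotations)
    for ag in agonists:
        lfc = lfc_by_agonist[ag]
        rows = [p for p in lfc.index if p in tf_ids]
        if len(rows) < cfg.k_tf:
            raise PipelineError(stage, "too_few_tf", f"{len(rows)} TF promoters < k={cfg.k_tf}")
        res = kmeans_profiles(lfc.loc[rows], k=cfg.k_tf, seed=cfg.seed)
        means, sizes = mean_cluster_profiles(res, lfc.loc[rows])
        emit(stage, f"tf_clusters_{ag}.tsv", res.assignments.to_frame(), index_label="promoter_id")
        emit(stage, f"tf_cluster_profiles_{ag}.tsv",
             means.join(sizes), index_label="cluster")

    # -- MARA (promoter + enhancer compartments, synthetic site matrices) ----
    stage = "mara"
    motif_synth = SynthConfig(**{**asdict(cfg.synth), "seed": cfg.seed + 101})
    expr_prom, sites_prom, _ = simulate_motif_system(motif_synth)
    enh_synth = SynthConfig(**{**asdict(cfg.synth), "seed": cfg.seed + 202})
    expr_enh, sites_enh, _ = simulate_motif_system(enh_synth)
    fit_prom = fit_motif_activities(expr_prom, sites_prom, ridge_lambda=cfg.ridge_lambda)
    fit_enh = fit_motif_activities(expr_enh, sites_enh, ridge_lambda=cfg.ridge_lambda)
    emit(stage, "mara_activities_promoter.tsv", fit_prom.activities, index_label="motif_id")
    emit(stage, "mara_activities_enhancer.tsv", fit_enh.activities, index_label="motif_id")

    times = [int(s[1:]) for s in fit_prom.activities.columns]
    res_motif = kmeans_profiles(fit_prom.activities, k=cfg.k_motif, seed=cfg.seed)
    emit(stage, "motif_clusters.tsv", res_motif.assignments.to_frame(), index_label="motif_id")

    cats = categorize_motif_dynamics(fit_prom, fit_enh, z_threshold=cfg.z_threshold, times=times)
    cat_df = pd.DataFrame([vars(c) for c in cats])
    emit(stage, "motif_categories.tsv", cat_df, index=False)

    manifest = {
        "tool": "cagedyn",
        "version": __version__,
        "seed": cfg.seed,
        "parameters": {
            "alpha": cfg.alpha,
            "min_tags": cfg.min_tags,
            "min_tpm": cfg.min_tpm,
            "k_tf": cfg.k_tf,
            "k_motif": cfg.k_motif,
            "ridge_lambda": cfg.ridge_lambda,
            "z_threshold": cfg.z_threshold,
        },
        "agonists": agonists,
        "outputs": outputs,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
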
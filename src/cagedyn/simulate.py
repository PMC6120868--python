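"""Synthetic two-agonist CAGE time courses with planted ground truth.

The generator emulates the study conditions: a shared unstimulated baseline
(t = 0) plus stimulated libraries at 15/30/45/60/120/180/240/300/360 min for
an inflammatory-cytokine-like course and the same grid minus the 240-min
point for a growth-factor-like course (that library failed quality control
in the emulated study).  Tag counts are negative-binomial around TPM-scale
means (variance = mu + phi * mu^2), matching the differential-expression
model; the motif system adds Gaussian noise in log space, matching the
motif-activity model.  Every planted quantity -- responder shapes, log2FC
trajectories, activities, constants -- is recorded so recovery can be scored
without re-simulation.

Responders are planted only among promoters with a baseline of at least
``min_responder_baseline_tpm`` (responsive promoters in this setting are
well-expressed genes); baseline expression itself is log-normal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import (
    Agonist,
    CountMatrix,
    MotifSiteMatrix,
    PromoterAnnotation,
    SampleMeta,
    ValidationError,
)
from .normalize import ExpressionMatrix

__all__ = [
    "SynthConfig",
    "SynthTruth",
    "MotifSystemTruth",
    "SHAPE_TEMPLATES",
    "shape_trajectory",
    "simulate_timecourse",
    "simulate_motif_system",
    "render_tpm",
    "simulate_profile_archetypes",
    "make_promoter_annotations",
]

TIMES_FGF2 = (0, 15, 30, 45, 60, 120, 180, 300, 360)
TIMES_IL1B = (0, 15, 30, 45, 60, 120, 180, 240, 300, 360)

# Response-shape templates: time (min) -> fraction of the planted effect size.
# Times absent from a template are at baseline.  Shapes echo the canonical
# time-course vocabulary: immediate-early pulses, sustained inductions, late
# waves, and a biphasic dip-then-peak.
SHAPE_TEMPLATES: dict[str, dict[int, float]] = {
    "rapid_short": {15: 0.8, 30: 1.0, 45: 1.0, 60: 0.8, 120: 0.25},
    "rapid_long": {15: 0.6, 30: 0.9, 45: 1.0, 60: 1.0, 120: 1.0, 180: 1.0,
                   240: 1.0, 300: 1.0, 360: 1.0},
    "early_standard": {120: 1.0, 180: 0.6, 240: 0.15, 300: 0.1, 360: 0.1},
    "long": {120: 0.7, 180: 1.0, 240: 1.0, 300: 1.0, 360: 1.0},
    "late": {240: 0.7, 300: 1.0, 360: 1.0},
    "late_flat": {180: 1.0, 240: 0.6, 300: 0.15, 360: 0.1},
    "biphasic": {15: -0.7, 30: -0.7, 45: -0.3, 120: 0.5, 180: 0.8, 240: 1.0,
                 300: 0.8, 360: 0.6},
    "pulse_60": {45: 0.25, 60: 1.0, 120: 0.25},
    "pulse_240": {180: 0.25, 240: 1.0, 300: 0.25},
}

# Motif-activity archetypes over a time grid (minutes -> activity multiplier).
ACTIVITY_ARCHETYPES: dict[str, dict[int, float]] = {
    "pulse_60": {30: 0.4, 45: 0.8, 60: 1.0, 120: 0.4, 180: 0.1},
    "ramp_240": {60: 0.2, 120: 0.5, 180: 0.8, 240: 1.0, 300: 0.9, 360: 0.8},
    "biphasic_dip_peak": {15: -0.6, 30: -0.4, 120: 0.4, 180: 0.8, 240: 1.0, 300: 0.7},
    "static": {},
}


def shape_trajectory(shape: str, times, effect_log2fc: float) -> np.ndarray:
    """Planted log2FC at each time point for a named response shape."""
    if shape not in SHAPE_TEMPLATES:
        raise ValidationError(f"unknown response shape {shape!r}")
    tpl = SHAPE_TEMPLATES[shape]
    return np.array([tpl.get(int(t), 0.0) * effect_log2fc for t in times])


@dataclass(frozen=True)
class SynthConfig:
    """Study-condition parameters of the generator (defaults ARE the conditions)."""

    n_promoters: int = 2000
    n_tf_promoters: int = 200
    n_motifs: int = 50
    time_points_fgf2: tuple[int, ...] = TIMES_FGF2
    time_points_il1b: tuple[int, ...] = TIMES_IL1B
    replicates_per_point: int = 3
    library_size: float = 1e6
    dispersion_phi: float = 0.1
    noise_sd: float = 0.1
    responder_fractions: dict = field(
        default_factory=lambda: {
            "FGF2": {
                "rapid_short": 0.020,
                "rapid_long": 0.010,
                "early_standard": 0.008,
                "long": 0.005,
                "late": 0.005,
                "biphasic": 0.004,
            },
            "IL1B": {
                "rapid_short": 0.004,
                "late": 0.006,
                "long": 0.004,
                "biphasic": 0.006,
            },
        }
    )
    effect_log2fc: float = 2.0
    motif_site_density: float = 0.5
    activity_archetypes: tuple[str, ...] = ("pulse_60", "ramp_240", "biphasic_dip_peak", "static")
    activity_amplitude: float = 1.0
    baseline_log2_tpm_mean: float = 6.0
    baseline_log2_tpm_sd: float = 1.5
    min_responder_baseline_tpm: float = 20.0
    max_responder_baseline_tpm: float = 60.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_promoters < 1 or self.n_motifs < 1:
            raise ValidationError("n_promoters and n_motifs must be positive")
        if self.library_size <= 0 or self.noise_sd < 0 or self.dispersion_phi < 0:
            raise ValidationError("scales must be positive (noise/dispersion non-negative)")
        if self.replicates_per_point < 1:
            raise ValidationError("replicates_per_point must be >= 1")
        for ag, fr in self.responder_fractions.items():
            if ag not in ("FGF2", "IL1B"):
                raise ValidationError(f"unknown agonist {ag!r} in responder_fractions")
            if sum(fr.values()) > 1.0:
                raise ValidationError(f"responder fractions for {ag} exceed 1")
            for shape in fr:
                if shape not in SHAPE_TEMPLATES:
                    raise ValidationError(f"unknown shape {shape!r} in responder_fractions")


@dataclass(frozen=True)
class SynthTruth:
    """Planted ground truth of a simulated count time course."""

    responder_shapes: dict  # agonist -> {promoter_id: shape name}
    lfc_trajectories: dict  # agonist -> DataFrame promoters x nonzero times
    baseline_tpm: pd.Series
    phi: float
    seed: int

    def responders(self, agonist: str) -> set[str]:
        return set(self.responder_shapes[str(agonist)])


@dataclass(frozen=True)
class MotifSystemTruth:
    """Planted ground truth of a simulated motif-activity system."""

    activities: pd.DataFrame  # motifs x samples, row-centered
    archetype: pd.Series  # motif -> archetype name
    sites: pd.DataFrame
    promoter_const: pd.Series
    sample_const: pd.Series
    noise_sd: float
    seed: int


def _promoter_ids(n: int) -> list[str]:
    return [f"p1@GENE{i:04d}" for i in range(n)]


def make_promoter_annotations(cfg: SynthConfig) -> list[PromoterAnnotation]:
    """Single-bp promoter annotations; the first n_tf_promoters are TF genes."""
    ids = _promoter_ids(cfg.n_promoters)
    return [
        PromoterAnnotation(
            promoter_id=pid,
            chrom="chr1",
            start=1000 * (i + 1),
            end=1000 * (i + 1) + 1,
            strand="+",
            gene_symbol=pid.split("@", 1)[1],
            rank=1,
            is_tf=i < cfg.n_tf_promoters,
        )
        for i, pid in enumerate(ids)
    ]


def _nb_counts(rng: np.random.Generator, mean: np.ndarray, phi: float) -> np.ndarray:
    """NB(mu, phi) via gamma-Poisson mixing; phi = 0 is Poisson."""
    mean = np.clip(mean, 1e-12, None)
    if phi == 0:
        return rng.poisson(mean)
    lam = rng.gamma(shape=1.0 / phi, scale=mean * phi)
    return rng.poisson(lam)


def simulate_timecourse(cfg: SynthConfig) -> tuple[CountMatrix, list[SampleMeta], SynthTruth]:
    """Simulate the two-agonist count time course with planted responders."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    ids = _promoter_ids(cfg.n_promoters)
    baseline = 2.0 ** rng.normal(cfg.baseline_log2_tpm_mean, cfg.baseline_log2_tpm_sd,
                                 cfg.n_promoters)
    # recorded on the renormalized (observed-TPM) scale
    baseline_tpm = pd.Series(baseline * 1e6 / baseline.sum(), index=ids, name="baseline_tpm")

    # responders sit in a modest expression band so planted inductions stay a
    # small share of library mass (the realistic regime: responsive promoters
    # are well-expressed but do not dominate the transcriptome)
    eligible = np.flatnonzero(
        (baseline >= cfg.min_responder_baseline_tpm)
        & (baseline <= cfg.max_responder_baseline_tpm)
    )
    responder_shapes: dict[str, dict[str, str]] = {}
    lfc_traj: dict[str, pd.DataFrame] = {}
    grids = {"FGF2": cfg.time_points_fgf2, "IL1B": cfg.time_points_il1b}

    for agonist, grid in grids.items():
        fractions = cfg.responder_fractions.get(agonist, {})
        nonzero = [t for t in grid if t != 0]
        lfc = pd.DataFrame(0.0, index=ids, columns=nonzero)
        shapes: dict[str, str] = {}
        pool = eligible.copy()
        rng.shuffle(pool)
        cursor = 0
        for shape, frac in fractions.items():
            n = int(round(frac * cfg.n_promoters))
            chosen = pool[cursor:cursor + n]
            if len(chosen) < n:
                raise ValidationError("not enough well-expressed promoters for the responder plan")
            cursor += n
            traj = shape_trajectory(shape, nonzero, cfg.effect_log2fc)
            for i in chosen:
                shapes[ids[i]] = shape
                lfc.iloc[i] = traj
        responder_shapes[agonist] = shapes
        lfc_traj[agonist] = lfc

    # a library sequences a fixed number of tags, so per-sample mean TPM is
    # renormalized to 1e6: induced promoters take reads from the rest
    def _sample_mean(tpm_vec: np.ndarray) -> np.ndarray:
        comp = tpm_vec * (1e6 / tpm_vec.sum())
        return comp / 1e6 * cfg.library_size

    meta: list[SampleMeta] = []
    columns: dict[str, np.ndarray] = {}
    for r in range(1, cfg.replicates_per_point + 1):
        sid = f"t000_r{r}"
        meta.append(SampleMeta(sid, Agonist.NONE, 0, r))
        columns[sid] = _nb_counts(rng, _sample_mean(baseline), cfg.dispersion_phi)
    for agonist, grid in grids.items():
        lfc = lfc_traj[agonist]
        for t in grid:
            if t == 0:
                continue
            mean = _sample_mean(baseline * 2.0 ** lfc[t].to_numpy())
            for r in range(1, cfg.replicates_per_point + 1):
                sid = f"{agonist}_t{t:03d}_r{r}"
                meta.append(SampleMeta(sid, Agonist(agonist), t, r))
                columns[sid] = _nb_counts(rng, mean, cfg.dispersion_phi)

    counts = CountMatrix(pd.DataFrame(columns, index=ids).astype(np.int64))
    truth = SynthTruth(
        responder_shapes=responder_shapes,
        lfc_trajectories=lfc_traj,
        baseline_tpm=baseline_tpm,
        phi=cfg.dispersion_phi,
        seed=cfg.seed,
    )
    return counts, meta, truth


def simulate_motif_system(
    cfg: SynthConfig,
    constant_site_motifs: int = 0,
) -> tuple[ExpressionMatrix, MotifSiteMatrix, MotifSystemTruth]:
    """Simulate log expression driven by sparse site counts and planted activities.

    e[p, s] = c_p + c_s + sum_m N[p, m] A[m, s] + Normal(0, noise_sd)

    Site counts are sparse Poisson(motif_site_density).  Each motif gets an
    activity archetype (cycled over cfg.activity_archetypes) scaled by a
    motif-specific amplitude; planted activities are centered per motif.
    `constant_site_motifs` extra motifs get a constant (nonzero, zero-variance)
    site column -- the GC-rich-like case a site-count model cannot see.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed + 1)
    times = [t for t in cfg.time_points_il1b]
    S = len(times)
    P, M = cfg.n_promoters, cfg.n_motifs
    ids = _promoter_ids(P)
    motif_ids = [f"MOTIF{j:03d}" for j in range(M)]

    N = rng.poisson(cfg.motif_site_density, size=(P, M)).astype(float)
    arche = [cfg.activity_archetypes[j % len(cfg.activity_archetypes)] for j in range(M)]
    if constant_site_motifs:
        for j in range(constant_site_motifs):
            motif_ids.append(f"CONSTMOTIF{j:03d}")
            N = np.hstack([N, np.full((P, 1), 2.0)])
            arche.append("pulse_60")
    amps = rng.uniform(0.5, 1.5, size=len(motif_ids)) * cfg.activity_amplitude

    A = np.zeros((len(motif_ids), S))
    for j, name in enumerate(arche):
        if name not in ACTIVITY_ARCHETYPES:
            raise ValidationError(f"unknown activity archetype {name!r}")
        tpl = ACTIVITY_ARCHETYPES[name]
        A[j] = amps[j] * np.array([tpl.get(int(t), 0.0) for t in times])
    A -= A.mean(axis=1, keepdims=True)

    c_p = rng.normal(3.0, 1.0, size=P)
    c_s = rng.normal(0.0, 0.1, size=S)
    E = c_p[:, None] + c_s[None, :] + N @ A
    if cfg.noise_sd > 0:
        E = E + rng.normal(0.0, cfg.noise_sd, size=E.shape)

    sample_ids = [f"t{t:03d}" for t in times]
    expr = ExpressionMatrix(pd.DataFrame(E, index=ids, columns=sample_ids), scale="log")
    sites = MotifSiteMatrix(pd.DataFrame(N, index=ids, columns=motif_ids))
    truth = MotifSystemTruth(
        activities=pd.DataFrame(A, index=motif_ids, columns=sample_ids),
        archetype=pd.Series(arche, index=motif_ids, name="archetype"),
        sites=sites.data,
        promoter_const=pd.Series(c_p, index=ids, name="c_p"),
        sample_const=pd.Series(c_s, index=sample_ids, name="c_s"),
        noise_sd=cfg.noise_sd,
        seed=cfg.seed,
    )
    return expr, sites, truth


def render_tpm(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Exponentiate log expression and renormalize each column to 1e6 (TPM)."""
    if expr.scale != "log":
        raise ValidationError("render_tpm expects log-scale expression")
    lin = np.exp2(expr.data) - 1.0
    lin = lin.clip(lower=0.0)
    tpm = lin.div(lin.sum(axis=0), axis=1) * 1e6
    return ExpressionMatrix(tpm, scale="tpm")


def simulate_profile_archetypes(
    n_per_cluster: int,
    k: int,
    n_timepoints: int,
    separation: float,
    noise_sd: float,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Planted profile clusters: k one-hot archetype centroids plus Gaussian noise.

    Centroid i puts `separation` at time slot i (mod T), giving pairwise
    centroid distances of separation * sqrt(2) -- well separated when
    separation >> noise_sd.  Returns the items x time matrix and true labels.
    """
    if k > n_timepoints:
        raise ValidationError("k archetypes need at least k distinct time slots")
    rng = np.random.default_rng(seed)
    centroids = np.zeros((k, n_timepoints))
    for i in range(k):
        centroids[i, i % n_timepoints] = separation
    labels = np.repeat(np.arange(k), n_per_cluster)
    X = centroids[labels] + rng.normal(0.0, noise_sd, size=(len(labels), n_timepoints))
    ids = [f"item{i:04d}" for i in range(len(labels))]
    cols = list(range(n_timepoints))
    return (
        pd.DataFrame(X, index=ids, columns=cols),
        pd.Series(labels, index=ids, name="true_cluster"),
    )
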
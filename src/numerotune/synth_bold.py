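"""Synthetic multi-subject BOLD simulation with known ground truth.

Voxels come in four kinds:

``numerosity_tuned``
    respond to a stimulus of numerosity *n* with
    ``amplitude * exp(-(ln n - ln mu)^2 / (2 sigma^2))`` — a log-Gaussian
    tuning curve with preferred numerosity ``mu`` (stimulus units) and
    tuning width ``sigma`` (natural-log units).  Real cortical voxels mix
    neural populations, so a tuned voxel may additionally carry a
    nonspecific ``visual_amplitude`` response to every stimulus event;
    the default is 0, in which case the response is the pure tuning curve.
``scenery_responsive``
    respond with ``amplitude`` to every natural-image event and not at all
    to dot stimuli (the parahippocampal pattern).
``visual_untuned``
    respond with ``amplitude`` to every stimulus event.
``null``
    pure noise.

Responses are built on the shared linear forward model (50 ms boxcars,
double-gamma HRF, TR integration), scaled to percent signal change around a
baseline intensity, and corrupted with AR(1) noise (marginal SD equal to
the configured white SD) plus a per-run linear drift.  The first 8 acquired
frames of every run are discarded, mirroring standard preprocessing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from ._forward import HrfParams, hrf_kernel, log_gaussian, regressor_basis
from .stimgen import (
    BlockParams,
    LocalizerParams,
    NATURAL_CATEGORIES,
    Timeline,
    build_block_timeline,
    build_localizer_timeline,
    default_category_pools,
)

__all__ = [
    "HrfParams",
    "hrf_kernel",
    "TuningParams",
    "NoiseParams",
    "VoxelSpec",
    "BoldRun",
    "CohortConfig",
    "Subject",
    "Cohort",
    "neural_timecourse",
    "simulate_run",
    "simulate_cohort",
    "write_cohort",
    "NUMEROSITY_MAPS",
    "CONTROL_ROIS",
]

NUMEROSITY_MAPS = ("NPC1", "NPC2", "NPC3", "NTO", "NPO", "NF")
CONTROL_ROIS = ("V1", "LO", "PPA")
VOXEL_KINDS = ("numerosity_tuned", "scenery_responsive", "visual_untuned", "null")

#: labels whose events legitimately carry no numerosity annotation
NUMEROSITY_FREE_LABELS = frozenset({"nat_scenery"})


@dataclass(frozen=True)
class TuningParams:
    """Log-Gaussian numerosity tuning: preferred numerosity (count units,
    the mean of the Gaussian on the log axis) and tuning width (SD in
    natural-log numerosity units)."""

    preferred_numerosity: float
    tuning_width: float

    def __post_init__(self) -> None:
        if self.preferred_numerosity <= 0 or self.tuning_width <= 0:
            raise ValueError("tuning parameters must be positive")


@dataclass(frozen=True)
class NoiseParams:
    """white_sd: marginal noise SD in % signal; ar1: lag-1 autocorrelation;
    drift_max: largest absolute linear drift excursion per run (% signal)."""

    white_sd: float = 1.0
    ar1: float = 0.3
    drift_max: float = 0.5

    def __post_init__(self) -> None:
        if self.white_sd < 0 or not (-1 < self.ar1 < 1) or self.drift_max < 0:
            raise ValueError("invalid noise parameters")


@dataclass(frozen=True)
class VoxelSpec:
    roi_label: str
    kind: str
    tuning: TuningParams | None = None
    amplitude: float = 1.0  # percent-signal response scale
    visual_amplitude: float = 0.0  # nonspecific response to any stimulus
    noise: NoiseParams = field(default_factory=NoiseParams)

    def __post_init__(self) -> None:
        if self.kind not in VOXEL_KINDS:
            raise ValueError(f"unknown voxel kind {self.kind!r}")
        if (self.kind == "numerosity_tuned") != (self.tuning is not None):
            raise ValueError("tuning must be present iff kind is numerosity_tuned")
        if self.amplitude < 0 or self.visual_amplitude < 0:
            raise ValueError("amplitudes must be non-negative")


def neural_timecourse(timeline: Timeline, spec: VoxelSpec) -> np.ndarray:
    """Per-event neural response amplitudes (stimulus resolution).

    Tuned voxels follow the log-Gaussian at each event's numerosity (events
    of numerosity-free categories such as scenery contribute only through
    ``visual_amplitude``); scenery-responsive voxels respond to natural-
    image categories only; untuned voxels to every event; null voxels never.
    """
    ev = timeline.events
    num = ev["numerosity"].to_numpy(dtype=float)
    labels = ev["label"].astype(str).to_numpy()
    resp = np.full(len(ev), float(spec.visual_amplitude)) if len(ev) else np.zeros(0)

    if spec.kind == "numerosity_tuned":
        have = np.isfinite(num)
        unlabeled_bad = ~have & ~np.isin(labels, list(NUMEROSITY_FREE_LABELS))
        if unlabeled_bad.any():
            raise ValueError(
                "numerosity-tuned voxel given events without numerosity labels"
            )
        if not have.any():
            raise ValueError("timeline carries no numerosity-labelled events")
        t = spec.tuning
        resp[have] += spec.amplitude * log_gaussian(
            num[have], t.preferred_numerosity, t.tuning_width
        )
    elif spec.kind == "scenery_responsive":
        resp += spec.amplitude * np.isin(labels, list(NATURAL_CATEGORIES))
    elif spec.kind == "visual_untuned":
        resp += spec.amplitude
    else:  # null
        resp = np.zeros(len(ev))
    return resp


@dataclass
class BoldRun:
    """One simulated functional run: a voxels x retained-timepoints matrix."""

    signal: np.ndarray
    tr_ms: int
    n_discarded: int
    timeline: Timeline
    subject_id: str = ""
    seed: int | None = None
    baseline: float = 1000.0

    @property
    def n_voxels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.signal.shape[1]

    def percent_signal(self) -> np.ndarray:
        """Signal expressed as % change around each voxel's temporal mean."""
        mean = self.signal.mean(axis=1, keepdims=True)
        out = np.zeros_like(self.signal)
        ok = mean[:, 0] != 0
        out[ok] = 100.0 * (self.signal[ok] / mean[ok] - 1.0)
        return out


def _noiseless_psc(
    specs: list[VoxelSpec],
    timeline: Timeline,
    n_volumes: int,
    hrf: HrfParams | None,
    dt_ms: int,
) -> np.ndarray:
    """Percent-signal prediction matrix (voxels x volumes) on the shared
    forward model; grouped by voxel kind so each regressor basis is built
    once per timeline."""
    ev = timeline.events
    out = np.zeros((len(specs), n_volumes))
    kinds = np.array([s.kind for s in specs])
    common = dict(tr_ms=timeline.tr_ms, n_volumes=n_volumes, hrf=hrf, dt_ms=dt_ms)

    needs_all = [
        i
        for i, s in enumerate(specs)
        if (s.kind == "visual_untuned" and s.amplitude > 0)
        or (s.kind != "null" and s.visual_amplitude > 0)
    ]
    W_all = None
    if needs_all:
        _, W_all = regressor_basis(ev, group="all", **common)
        w_all = W_all[:, 0]
        for i in needs_all:
            s = specs[i]
            amp = s.visual_amplitude + (s.amplitude if s.kind == "visual_untuned" else 0.0)
            out[i] += amp * w_all
    idx_tuned = np.flatnonzero(kinds == "numerosity_tuned")
    if idx_tuned.size:
        num = ev["numerosity"].to_numpy(dtype=float)
        labels = ev["label"].astype(str).to_numpy()
        bad = ~np.isfinite(num) & ~np.isin(labels, list(NUMEROSITY_FREE_LABELS))
        if bad.any():
            raise ValueError(
                "numerosity-tuned voxel given events without numerosity labels"
            )
        if not np.isfinite(num).any():
            raise ValueError("timeline carries no numerosity-labelled events")
        values, Wn = regressor_basis(ev, group="numerosity", **common)
        values = np.asarray(values, dtype=float)
        G = np.stack(
            [
                specs[i].amplitude
                * log_gaussian(
                    values,
                    specs[i].tuning.preferred_numerosity,
                    specs[i].tuning.tuning_width,
                )
                for i in idx_tuned
            ],
            axis=1,
        )
        out[idx_tuned] += (Wn @ G).T

    idx_scen = np.flatnonzero(kinds == "scenery_responsive")
    if idx_scen.size:
        names, Wc = regressor_basis(ev, group="label", **common)
        nat = [j for j, nm in enumerate(names) if nm in NATURAL_CATEGORIES]
        w_nat = Wc[:, nat].sum(axis=1)
        amps = np.array([specs[i].amplitude for i in idx_scen])
        out[idx_scen] += np.outer(amps, w_nat)
    return out


def simulate_run(
    specs: list[VoxelSpec],
    timeline: Timeline,
    seed: int = 0,
    *,
    n_volumes: int | None = None,
    n_discard: int = 8,
    baseline: float = 1000.0,
    hrf: HrfParams | None = None,
    dt_ms: int = 50,
    subject_id: str = "",
) -> BoldRun:
    """Simulate one functional run for a set of voxel specs.

    ``n_volumes`` defaults to the number of full TRs covering the timeline;
    the first ``n_discard`` acquired frames are dropped from the returned
    matrix (they absorb the timeline's lead-in rest).
    """
    if n_volumes is None:
        n_volumes = int(np.ceil(timeline.total_duration_ms / timeline.tr_ms))
    if n_volumes <= n_discard:
        raise ValueError("run shorter than the number of discarded frames")
    if n_volumes < 9:
        raise ValueError("timeline must cover at least 9 TRs")

    psc = _noiseless_psc(specs, timeline, n_volumes, hrf, dt_ms)

    rng = np.random.default_rng(seed)
    V, T = psc.shape
    t_frac = np.arange(T) / max(T - 1, 1) - 0.5
    # draws are consumed per voxel in order, so the realization of voxel i
    # does not depend on the noise parameters of other voxels
    white = rng.standard_normal((V, T))
    slopes = rng.uniform(-1.0, 1.0, size=V)
    for params in {s.noise for s in specs}:
        rows = np.array([s.noise == params for s in specs])
        if params.white_sd > 0:
            # AR(1) with stationary start; innovations scaled so the
            # marginal SD equals the configured white SD
            innov = white[rows] * params.white_sd * np.sqrt(1 - params.ar1**2)
            innov[:, 0] = white[rows][:, 0] * params.white_sd
            psc[rows] += lfilter([1.0], [1.0, -params.ar1], innov, axis=1)
        if params.drift_max > 0:
            psc[rows] += np.outer(slopes[rows] * params.drift_max, t_frac)

    signal = baseline * (1.0 + 0.01 * psc)
    return BoldRun(
        signal=signal[:, n_discard:],
        tr_ms=timeline.tr_ms,
        n_discarded=n_discard,
        timeline=timeline,
        subject_id=subject_id,
        seed=seed,
        baseline=baseline,
    )


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CohortConfig:
    """Ground-truth composition of the simulated cohort.

    The six numerosity maps mix tuned, scenery-responsive, untuned and null
    voxels; V1/LO are dominated by untuned visually responsive voxels and
    PPA by scenery-responsive ones.  Preferred numerosities are drawn
    log-uniformly over ``mu_range`` with a linear width-versus-log-preferred
    trend.  Tuned voxels carry a heterogeneous nonspecific visual component
    (mixed neural populations within a voxel).
    """

    n_subjects: int = 7
    voxels_per_roi: int = 200
    n_localizer_runs: int = 4
    n_block_runs: int = 7
    nf_subjects: int = 4
    map_mix: dict = field(
        default_factory=lambda: {
            "numerosity_tuned": 0.5,
            "scenery_responsive": 0.2,
            "visual_untuned": 0.2,
            "null": 0.1,
        }
    )
    v1_lo_mix: dict = field(
        default_factory=lambda: {"visual_untuned": 0.9, "null": 0.1}
    )
    ppa_mix: dict = field(
        default_factory=lambda: {"scenery_responsive": 0.9, "null": 0.1}
    )
    mu_range: tuple[float, float] = (1.0, 7.0)
    width_intercept: float = 0.3
    width_slope: float = 0.25
    width_jitter: float = 0.05
    tuned_amplitude: float = 4.5
    visual_amplitude_range: tuple[float, float] = (0.0, 1.0)
    scenery_amplitude: float = 1.0
    untuned_amplitude: float = 1.0
    noise: NoiseParams = field(default_factory=NoiseParams)
    baseline: float = 1000.0
    tr_ms: int = 1500
    n_discard: int = 8
    untuned_only: bool = False  # control cohort: replace tuned/scenery by untuned

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.voxels_per_roi < 1:
            raise ValueError("cohort must have at least one subject and voxel")
        if self.nf_subjects < 0:
            raise ValueError("nf_subjects must be non-negative")
        # smaller test cohorts keep NF in as many subjects as they have
        object.__setattr__(
            self, "nf_subjects", min(self.nf_subjects, self.n_subjects)
        )
        if self.n_block_runs < 0 or self.n_localizer_runs < 0:
            raise ValueError("run counts must be non-negative")


@dataclass
class Subject:
    subject_id: str
    voxels: pd.DataFrame  # roi, kind, mu, sigma, amplitude, visual_amplitude
    specs: list[VoxelSpec]
    localizer_timelines: list[Timeline]
    localizer_runs: list[BoldRun]
    block_timelines: list[Timeline]
    block_runs: list[BoldRun]

    @property
    def rois(self) -> list[str]:
        return list(dict.fromkeys(self.voxels["roi"]))

    def roi_indices(self, roi: str) -> np.ndarray:
        return np.flatnonzero(self.voxels["roi"].to_numpy() == roi)


@dataclass
class Cohort:
    subjects: list[Subject]
    config: CohortConfig
    master_seed: int

    def ground_truth(self) -> pd.DataFrame:
        frames = []
        for s in self.subjects:
            df = s.voxels.copy()
            df.insert(0, "subject", s.subject_id)
            df.insert(1, "voxel", np.arange(len(df)))
            frames.append(df)
        return pd.concat(frames, ignore_index=True)


def _mix_kinds(mix: dict, n: int, rng: np.random.Generator) -> list[str]:
    kinds: list[str] = []
    items = list(mix.items())
    for k, (kind, frac) in enumerate(items):
        count = int(round(frac * n)) if k < len(items) - 1 else n - len(kinds)
        kinds.extend([kind] * max(count, 0))
    kinds = kinds[:n]
    rng.shuffle(kinds)
    return kinds


def _make_subject_voxels(
    config: CohortConfig, rois: list[str], rng: np.random.Generator
) -> tuple[pd.DataFrame, list[VoxelSpec]]:
    rows = []
    specs: list[VoxelSpec] = []
    for roi in rois:
        if roi in NUMEROSITY_MAPS:
            mix = config.map_mix
        elif roi == "PPA":
            mix = config.ppa_mix
        else:
            mix = config.v1_lo_mix
        kinds = _mix_kinds(mix, config.voxels_per_roi, rng)
        if config.untuned_only:
            kinds = [
                "visual_untuned" if k in ("numerosity_tuned", "scenery_responsive") else k
                for k in kinds
            ]
        for kind in kinds:
            mu = np.nan
            sigma = np.nan
            vis = 0.0
            if kind == "numerosity_tuned":
                lo, hi = config.mu_range
                mu = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
                sigma = config.width_intercept + config.width_slope * np.log(mu)
                sigma = float(
                    max(sigma + rng.normal(0.0, config.width_jitter), 0.05)
                )
                amp = config.tuned_amplitude
                vis = float(rng.uniform(*config.visual_amplitude_range))
                tuning = TuningParams(mu, sigma)
            elif kind == "scenery_responsive":
                amp = config.scenery_amplitude
                tuning = None
            elif kind == "visual_untuned":
                amp = config.untuned_amplitude
                tuning = None
            else:
                amp = 0.0
                tuning = None
            specs.append(
                VoxelSpec(
                    roi_label=roi,
                    kind=kind,
                    tuning=tuning,
                    amplitude=amp,
                    visual_amplitude=vis,
                    noise=config.noise,
                )
            )
            rows.append(
                {
                    "roi": roi,
                    "kind": kind,
                    "mu": mu,
                    "sigma": sigma,
                    "amplitude": amp,
                    "visual_amplitude": vis,
                }
            )
    return pd.DataFrame(rows), specs


def simulate_cohort(
    config: CohortConfig | None = None, master_seed: int = 0
) -> Cohort:
    """Simulate the full cohort: per subject, ground-truth voxel specs,
    localizer runs and block-design runs, all derived from one master seed.

    The frontal map (NF) is present for ``nf_subjects`` of the subjects
    (the first ones by index); every other ROI is present for everyone.
    """
    config = config if config is not None else CohortConfig()
    ss = np.random.SeedSequence(master_seed)
    subject_seeds = ss.spawn(config.n_subjects)

    subjects = []
    for s_idx in range(config.n_subjects):
        rng = np.random.default_rng(subject_seeds[s_idx])
        sid = f"sub-{s_idx + 1:02d}"
        rois = [r for r in NUMEROSITY_MAPS if r != "NF"]
        if s_idx < config.nf_subjects:
            rois.append("NF")
        rois.extend(CONTROL_ROIS)
        voxels, specs = _make_subject_voxels(config, rois, rng)

        loc_timelines, loc_runs = [], []
        loc_params = LocalizerParams(tr_ms=config.tr_ms)
        for _ in range(config.n_localizer_runs):
            tl = build_localizer_timeline(loc_params, seed=int(rng.integers(2**31)))
            run = simulate_run(
                specs,
                tl,
                seed=int(rng.integers(2**31)),
                n_discard=config.n_discard,
                baseline=config.baseline,
                subject_id=sid,
            )
            loc_timelines.append(tl)
            loc_runs.append(run)

        blk_timelines, blk_runs = [], []
        blk_params = BlockParams(tr_ms=config.tr_ms)
        pools = default_category_pools(seed=int(rng.integers(2**31)))
        for _ in range(config.n_block_runs):
            tl = build_block_timeline(
                blk_params, seed=int(rng.integers(2**31)), pools=pools
            )
            run = simulate_run(
                specs,
                tl,
                seed=int(rng.integers(2**31)),
                n_discard=config.n_discard,
                baseline=config.baseline,
                subject_id=sid,
            )
            blk_timelines.append(tl)
            blk_runs.append(run)

        subjects.append(
            Subject(
                subject_id=sid,
                voxels=voxels,
                specs=specs,
                localizer_timelines=loc_timelines,
                localizer_runs=loc_runs,
                block_timelines=blk_timelines,
                block_runs=blk_runs,
            )
        )
    return Cohort(subjects=subjects, config=config, master_seed=master_seed)


def write_cohort(cohort: Cohort, out_dir: str | Path, lite: bool = True) -> None:
    """Write the cohort to disk: per subject, ground truth and ROI labels as
    TSV, timelines as BIDS-style events TSV, and each run either as a flat
    binary (.npy + JSON sidecar, lite mode) or as a 4D NIfTI volume with
    voxels along the first axis."""
    out_dir = Path(out_dir)
    for subject in cohort.subjects:
        sdir = out_dir / subject.subject_id
        sdir.mkdir(parents=True, exist_ok=True)
        gt = subject.voxels.copy()
        gt.insert(0, "voxel", np.arange(len(gt)))
        gt.to_csv(sdir / "ground_truth.tsv", sep="\t", index=False)
        for kind, timelines, runs in (
            ("localizer", subject.localizer_timelines, subject.localizer_runs),
            ("block", subject.block_timelines, subject.block_runs),
        ):
            for i, (tl, run) in enumerate(zip(timelines, runs)):
                stem = sdir / f"{kind}_run-{i + 1:02d}"
                tl.to_tsv(stem.with_suffix(".events.tsv"))
                meta = {
                    "tr_ms": run.tr_ms,
                    "n_discarded": run.n_discarded,
                    "subject_id": run.subject_id,
                    "seed": run.seed,
                    "baseline": run.baseline,
                }
                if lite:
                    np.save(stem.with_suffix(".npy"), run.signal)
                    stem.with_suffix(".bold.json").write_text(json.dumps(meta))
                else:
                    import nibabel as nib

                    img = nib.Nifti1Image(
                        run.signal[:, None, None, :].astype(np.float32), np.eye(4)
                    )
                    img.header.set_zooms((1.0, 1.0, 1.0, run.tr_ms / 1000.0))
                    nib.save(img, stem.with_suffix(".nii.gz"))
                    stem.with_suffix(".bold.json").write_text(json.dumps(meta))
    gt_all = cohort.ground_truth()
    gt_all.to_csv(out_dir / "ground_truth.tsv", sep="\t", index=False)
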
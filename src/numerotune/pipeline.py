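"""End-to-end orchestration: simulate -> pRF fit -> GLM -> ROI inference.

``run_all`` drives the whole chain from one validated config and a single
master seed (fanned out deterministically to per-stage, per-subject child
seeds), optionally writing each stage's tables under
``out/{stimuli,bold,prf,glm,stats}``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .glm import SCENERY_T_THRESHOLD, BlockGlm
from .prf_fit import GridSpec, NumerosityPrf
from .roistats import (
    SubjectStats,
    low_vs_high,
    positivity_tests,
    roi_table,
)
from .synth_bold import CONTROL_ROIS, CohortConfig, simulate_cohort, write_cohort
from .synth_bold import NUMEROSITY_MAPS

__all__ = ["RunConfig", "PipelineReport", "validate_config", "run_all"]

log = logging.getLogger("numerotune")


@dataclass(frozen=True)
class RunConfig:
    """Everything one pipeline run needs, fully serializable."""

    seed: int = 0
    cohort: CohortConfig = field(default_factory=CohortConfig)
    grid: GridSpec = field(default_factory=GridSpec)
    ve_min: float = 0.3
    t_threshold: float = SCENERY_T_THRESHOLD
    alpha: float = 0.05
    num_range: tuple[float, float] = (1.0, 3.0)
    apply_selection: bool = True
    lite: bool = True

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw)
        if "cohort" in raw and isinstance(raw["cohort"], dict):
            cohort = dict(raw["cohort"])
            if "noise" in cohort and isinstance(cohort["noise"], dict):
                from .synth_bold import NoiseParams

                cohort["noise"] = NoiseParams(**cohort["noise"])
            for key in ("mu_range", "visual_amplitude_range"):
                if key in cohort:
                    cohort[key] = tuple(cohort[key])
            raw["cohort"] = CohortConfig(**cohort)
        if "grid" in raw and isinstance(raw["grid"], dict):
            raw["grid"] = GridSpec(**raw["grid"])
        if "num_range" in raw:
            raw["num_range"] = tuple(raw["num_range"])
        return cls(**raw)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            import yaml

            raw = yaml.safe_load(text) or {}
        else:
            raw = json.loads(text) if text.strip() else {}
        return cls.from_dict(raw)


def validate_config(config: RunConfig | dict | None) -> RunConfig:
    """Fill defaults and check cross-field constraints; raise with every
    problem listed on failure."""
    if config is None:
        config = RunConfig()
    if isinstance(config, dict):
        config = RunConfig.from_dict(config)
    errors = []
    if not (0 < config.alpha < 1):
        errors.append(f"alpha must be in (0, 1), got {config.alpha}")
    if not (0 <= config.ve_min <= 1):
        errors.append(f"ve_min must be in [0, 1], got {config.ve_min}")
    if config.cohort.tr_ms <= 0:
        errors.append("tr_ms must be positive")
    lo, hi = config.num_range
    if not (0 < lo <= hi):
        errors.append(f"num_range must be positive and ordered, got {config.num_range}")
    if config.t_threshold < 0:
        errors.append("t_threshold must be non-negative")
    if errors:
        raise ValueError("invalid config:\n  " + "\n  ".join(errors))
    return config


@dataclass
class PipelineReport:
    """Key statistics of one pipeline run."""

    seed: int
    config_hash: str
    stages: dict
    subject_counts: pd.DataFrame  # per subject: voxels, selected, mask-excluded
    table_masked: pd.DataFrame
    table_unmasked: pd.DataFrame
    positivity_maps: pd.DataFrame
    positivity_controls: pd.DataFrame
    low_vs_high_natural: pd.DataFrame
    low_vs_high_dots: pd.DataFrame

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        stats = out / "stats"
        stats.mkdir(parents=True, exist_ok=True)
        self.subject_counts.to_csv(stats / "subject_counts.tsv", sep="\t", index=False)
        self.table_masked.to_csv(stats / "roi_table_masked.tsv", sep="\t", index=False)
        self.table_unmasked.to_csv(
            stats / "roi_table_unmasked.tsv", sep="\t", index=False
        )
        self.positivity_maps.to_csv(stats / "positivity_maps.tsv", sep="\t", index=False)
        self.positivity_controls.to_csv(
            stats / "positivity_controls.tsv", sep="\t", index=False
        )
        self.low_vs_high_natural.to_csv(
            stats / "low_vs_high_natural.tsv", sep="\t", index=False
        )
        self.low_vs_high_dots.to_csv(
            stats / "low_vs_high_dots.tsv", sep="\t", index=False
        )
        summary = {
            "seed": self.seed,
            "config_hash": self.config_hash,
            "stages": self.stages,
        }
        (stats / "report.json").write_text(json.dumps(summary, indent=1))


def run_all(
    config: RunConfig | dict | None = None, out_dir: str | Path | None = None
) -> PipelineReport:
    """Run every stage in order on a freshly simulated cohort.

    Deterministic given ``config.seed``; with ``out_dir`` set, stage
    outputs (ground truth, fit tables, ROI tables, test tables) are written
    beneath it.
    """
    config = validate_config(config)
    chash = config.config_hash()
    stages: dict = {"config_hash": chash}

    log.info("stage=simulate seed=%d", config.seed)
    cohort = simulate_cohort(config.cohort, master_seed=config.seed)
    stages["simulate"] = {
        "n_subjects": len(cohort.subjects),
        "runs_per_subject": [
            len(s.localizer_runs) + len(s.block_runs) for s in cohort.subjects
        ],
    }
    if out_dir is not None and config.lite:
        write_cohort(cohort, Path(out_dir) / "bold", lite=True)

    subject_stats: list[SubjectStats] = []
    counts = []
    fit_tables = []
    for subject in cohort.subjects:
        if config.apply_selection:
            if not subject.localizer_runs:
                raise RuntimeError(
                    f"{subject.subject_id}: tuned selection requested but no "
                    "localizer runs simulated"
                )
            model = NumerosityPrf.from_runs(subject.localizer_runs)
            fit = model.fit(config.grid)
            selection = fit.select_tuned(
                num_range=config.num_range, ve_min=config.ve_min
            )
            tuned_idx = selection.indices
            fit_df = fit.params.copy()
            fit_df.insert(0, "subject", subject.subject_id)
            fit_df.insert(1, "voxel", np.arange(len(fit_df)))
            fit_tables.append(fit_df)
        else:
            tuned_idx = np.arange(len(subject.specs))

        glm_model = BlockGlm(subject.block_runs, subject.block_timelines)
        glm_res = glm_model.fit()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mask = glm_res.scenery_mask(threshold=config.t_threshold)
        psc = glm_res.psc()
        rois = subject.voxels["roi"].to_numpy()

        subject_stats.append(
            SubjectStats(
                subject_id=subject.subject_id,
                psc=psc,
                rois=rois,
                tuned_indices=tuned_idx,
                scenery_mask=mask,
            )
        )
        map_vox = np.isin(rois, NUMEROSITY_MAPS)
        counts.append(
            {
                "subject": subject.subject_id,
                "n_voxels": len(rois),
                "n_selected": int(len(tuned_idx)),
                "n_mask_excluded_maps": int((map_vox & ~mask).sum()),
            }
        )
        log.info(
            "stage=subject id=%s selected=%d mask_excluded=%d",
            subject.subject_id,
            len(tuned_idx),
            int((map_vox & ~mask).sum()),
        )

    subject_counts = pd.DataFrame(counts)
    stages["prf"] = {"selected": subject_counts["n_selected"].tolist()}
    stages["glm"] = {
        "mask_excluded_maps": subject_counts["n_mask_excluded_maps"].tolist()
    }

    table_masked = roi_table(
        subject_stats,
        apply_scenery_mask=True,
        apply_selection=config.apply_selection,
    )
    table_unmasked = roi_table(
        subject_stats,
        apply_scenery_mask=False,
        apply_selection=config.apply_selection,
    )

    maps_present = tuple(r for r in NUMEROSITY_MAPS if r in set(table_masked["roi"]))
    pos_maps = positivity_tests(table_masked, rois=maps_present, alpha=config.alpha)
    pos_controls = positivity_tests(
        table_masked, rois=CONTROL_ROIS, alpha=config.alpha
    )
    lvh_nat = low_vs_high(table_masked, alpha=config.alpha)
    lvh_dots = low_vs_high(
        table_masked, low="dots_low", high="dots_high", alpha=config.alpha
    )
    stages["stats"] = {
        "low_vs_high_max_adj_p": (
            float(lvh_nat["p_adjusted"].max()) if len(lvh_nat) else None
        ),
        "n_positivity_cells_maps": int(len(pos_maps)),
    }

    report = PipelineReport(
        seed=config.seed,
        config_hash=chash,
        stages=stages,
        subject_counts=subject_counts,
        table_masked=table_masked,
        table_unmasked=table_unmasked,
        positivity_maps=pos_maps,
        positivity_controls=pos_controls,
        low_vs_high_natural=lvh_nat,
        low_vs_high_dots=lvh_dots,
    )
    if out_dir is not None:
        out = Path(out_dir)
        (out / "prf").mkdir(parents=True, exist_ok=True)
        if fit_tables:
            pd.concat(fit_tables, ignore_index=True).to_csv(
                out / "prf" / "fits.tsv", sep="\t", index=False
            )
        report.write(out)
    return report
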
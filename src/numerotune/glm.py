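"""Block-design GLM: per-category responses, contrasts, scenery exclusion.

One regressor per stimulus category — the HRF-convolved train of that
category's 300 ms presentations (which is nonzero only around its 15 s
blocks), peak-normalized to 1 — plus a constant and a linear drift per run.
Multiple runs are combined by concatenating their design matrices with
shared category columns and per-run nuisance columns, which keeps the
degrees-of-freedom bookkeeping exact.

Betas are reported in percent signal change, defined as 100 x beta divided
by the voxel's fitted constant (averaged over runs).  The scenery exclusion
reproduces the rule of dropping cortical points whose scenery-versus-rest
contrast is negative or non-significant: a voxel is retained iff its
one-directional t is at least 1.96 (exactly 1.96 is retained; the rule
excludes strictly smaller values).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._forward import HrfParams, regressor_basis
from .stimgen import CATEGORIES, Timeline
from .synth_bold import BoldRun

__all__ = [
    "DesignMatrix",
    "ContrastSpec",
    "BlockGlm",
    "BlockGlmResults",
    "build_design",
    "scenery_contrast",
    "SCENERY_T_THRESHOLD",
]

SCENERY_T_THRESHOLD = 1.96


@dataclass
class DesignMatrix:
    """timepoints x regressors matrix with named columns."""

    matrix: np.ndarray
    names: list[str]
    tr_ms: int

    def __post_init__(self) -> None:
        if self.matrix.shape[1] != len(self.names):
            raise ValueError("name count does not match column count")
        rank = np.linalg.matrix_rank(self.matrix)
        if rank < self.matrix.shape[1]:
            # identify near-collinear columns via the smallest singular vector
            _, s, vt = np.linalg.svd(self.matrix, full_matrices=False)
            bad = np.flatnonzero(np.abs(vt[-1]) > 0.3)
            offenders = [self.names[j] for j in bad]
            raise ValueError(f"design matrix is rank deficient; check {offenders}")


@dataclass(frozen=True)
class ContrastSpec:
    name: str
    weights: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if not np.any(w != 0):
            raise ValueError("contrast weights must not be all zero")
        object.__setattr__(self, "weights", w)


def build_design(
    timeline: Timeline,
    hrf: HrfParams | None = None,
    tr_ms: int | None = None,
    *,
    n_volumes: int | None = None,
    n_discard: int = 8,
    dt_ms: int = 50,
    run_tag: str = "",
) -> DesignMatrix:
    """Design for one block run: 6 category regressors + constant + drift.

    Category regressors are the convolved event trains, peak-normalized to
    1; the drift is a linear term over the retained frames, mean-centered
    and scaled to [-0.5, 0.5].
    """
    if timeline.design != "category_block":
        raise ValueError("build_design expects a category_block timeline")
    if len(timeline.events) == 0:
        raise ValueError("timeline has no events")
    tr = tr_ms if tr_ms is not None else timeline.tr_ms
    if n_volumes is None:
        n_volumes = int(np.ceil(timeline.total_duration_ms / tr))
    names, W = regressor_basis(
        timeline.events,
        tr_ms=tr,
        n_volumes=n_volumes,
        hrf=hrf,
        dt_ms=dt_ms,
        group="label",
    )
    W = W[n_discard:]
    peaks = W.max(axis=0)
    if np.any(peaks <= 0):
        flat = [names[j] for j in np.flatnonzero(peaks <= 0)]
        raise ValueError(f"categories with empty regressors: {flat}")
    W = W / peaks

    T = W.shape[0]
    drift = np.arange(T) / max(T - 1, 1) - 0.5
    cols = [W, np.ones((T, 1)), drift[:, None]]
    sfx = f"_{run_tag}" if run_tag else ""
    colnames = [str(n) for n in names] + [f"constant{sfx}", f"drift{sfx}"]
    return DesignMatrix(matrix=np.hstack(cols), names=colnames, tr_ms=tr)


def scenery_contrast(names: list[str], category: str = "nat_scenery") -> ContrastSpec:
    """Contrast of one category's regressor against rest (implicit baseline)."""
    w = np.zeros(len(names))
    if category not in names:
        raise ValueError(f"{category!r} not among regressors")
    w[names.index(category)] = 1.0
    return ContrastSpec(name=f"{category}_vs_rest", weights=w)


class BlockGlm:
    """OLS general linear model for one subject's block-design runs.

    Accepts one or several runs (with their timelines); several runs are
    concatenated in time with shared category regressors and per-run
    constant/drift columns.
    """

    def __init__(
        self,
        runs: list[BoldRun],
        timelines: list[Timeline] | None = None,
        *,
        hrf: HrfParams | None = None,
        categories: tuple[str, ...] = CATEGORIES,
        dt_ms: int = 50,
    ) -> None:
        if not runs:
            raise ValueError("need at least one run")
        if timelines is None:
            timelines = [r.timeline for r in runs]
        if len(timelines) != len(runs):
            raise ValueError("one timeline per run required")
        self.categories = list(categories)

        blocks = []
        n_runs = len(runs)
        nuisance_per_run = 2
        total_cols = len(self.categories) + nuisance_per_run * n_runs
        names = list(self.categories)
        for k, (run, tl) in enumerate(zip(runs, timelines)):
            d = build_design(
                tl,
                hrf=hrf,
                n_volumes=run.n_timepoints + run.n_discarded,
                n_discard=run.n_discarded,
                dt_ms=dt_ms,
                run_tag=f"run{k + 1}",
            )
            cat_cols = [d.names.index(c) for c in self.categories]
            nuis_cols = [j for j in range(d.matrix.shape[1]) if j not in cat_cols]
            T = d.matrix.shape[0]
            X = np.zeros((T, total_cols))
            X[:, : len(self.categories)] = d.matrix[:, cat_cols]
            off = len(self.categories) + k * nuisance_per_run
            X[:, off : off + nuisance_per_run] = d.matrix[:, nuis_cols]
            blocks.append(X)
        for k in range(n_runs):
            names += [f"constant_run{k + 1}", f"drift_run{k + 1}"]

        self.design = DesignMatrix(
            matrix=np.vstack(blocks), names=names, tr_ms=runs[0].tr_ms
        )
        Y = np.hstack([r.signal for r in runs])
        if Y.shape[1] != self.design.matrix.shape[0]:
            raise ValueError("run timepoints do not match design rows")
        self.data = Y
        self.n_runs = n_runs

    def fit(self) -> "BlockGlmResults":
        """Ordinary least squares per voxel."""
        X = self.design.matrix
        Y = self.data.T  # timepoints x voxels
        XtX = X.T @ X
        XtX_inv = np.linalg.inv(XtX)
        beta = XtX_inv @ (X.T @ Y)
        resid = Y - X @ beta
        dof = X.shape[0] - np.linalg.matrix_rank(X)
        sigma2 = (resid**2).sum(axis=0) / dof
        flagged = Y.std(axis=0) == 0
        return BlockGlmResults(
            model=self,
            beta=beta.T,
            sigma2=sigma2,
            dof=dof,
            xtx_inv=XtX_inv,
            flagged=flagged,
        )


@dataclass
class BlockGlmResults:
    """Per-voxel betas, residual variance and contrast machinery."""

    model: BlockGlm
    beta: np.ndarray  # voxels x regressors (signal units)
    sigma2: np.ndarray
    dof: int
    xtx_inv: np.ndarray
    flagged: np.ndarray

    @property
    def names(self) -> list[str]:
        return self.model.design.names

    def _constant(self) -> np.ndarray:
        cols = [
            j for j, n in enumerate(self.names) if n.startswith("constant")
        ]
        return self.beta[:, cols].mean(axis=1)

    def psc(self) -> pd.DataFrame:
        """Category betas in percent signal change (100 x beta / constant)."""
        const = self._constant()
        out = {}
        for cat in self.model.categories:
            j = self.names.index(cat)
            with np.errstate(divide="ignore", invalid="ignore"):
                vals = np.where(const != 0, 100.0 * self.beta[:, j] / const, np.nan)
            out[cat] = vals
        df = pd.DataFrame(out)
        df.loc[self.flagged] = np.nan
        return df

    def t_contrast(self, contrast: ContrastSpec | str) -> np.ndarray:
        """t = c'beta / sqrt(sigma2 * c'(X'X)^-1 c); NaN for flagged voxels."""
        if isinstance(contrast, str):
            contrast = scenery_contrast(self.names, contrast)
        c = np.asarray(contrast.weights, dtype=float)
        if c.shape[0] != len(self.names):
            raise ValueError("contrast length does not match regressor count")
        num = self.beta @ c
        var = self.sigma2 * float(c @ self.xtx_inv @ c)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(var > 0, num / np.sqrt(var), np.nan)
        t = np.asarray(t, dtype=float)
        t[self.flagged] = np.nan
        return t

    def scenery_mask(
        self, threshold: float = SCENERY_T_THRESHOLD, category: str = "nat_scenery"
    ) -> np.ndarray:
        """Inclusion mask: keep voxels with scenery-vs-rest t >= threshold.

        Voxels with negative or non-significant scenery responses
        (t < threshold) are excluded; t exactly at the threshold is kept.
        NaN t (flagged voxels) are excluded.
        """
        t = self.t_contrast(scenery_contrast(self.names, category))
        with np.errstate(invalid="ignore"):
            mask = t >= threshold
        mask = np.asarray(mask, dtype=bool)
        if not mask.any():
            warnings.warn("scenery mask is empty", stacklevel=2)
        return mask

    def summary(self) -> str:
        mask = self.scenery_mask()
        lines = [
            "Block-design GLM",
            f"  voxels:          {self.beta.shape[0]}"
            f" ({int(self.flagged.sum())} flagged zero-variance)",
            f"  runs:            {self.model.n_runs}",
            f"  dof:             {self.dof}",
            f"  scenery mask:    {int(mask.sum())} retained,"
            f" {int((~mask).sum())} excluded at t < {SCENERY_T_THRESHOLD}",
        ]
        return "\n".join(lines)
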
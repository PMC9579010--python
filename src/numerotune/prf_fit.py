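"""Numerosity population receptive field (pRF) estimation.

The model: each voxel's aggregate neural response to a display of *n* items
is a log-Gaussian tuning curve

    r(n) = A * exp(-(ln n - ln mu)^2 / (2 sigma^2)) + b

with preferred numerosity ``mu`` (the stimulus count at which the response
peaks) and tuning width ``sigma`` (SD in natural-log units).  Predictions
run through the same forward model as the simulator (event boxcars, HRF,
TR integration), so a noiseless simulated voxel is fitted exactly.

Fitting follows the standard two-stage pRF recipe: an exhaustive grid
search over log-spaced (mu, sigma) candidates — amplitude and baseline
solved per candidate by ordinary least squares, variance explained used as
the objective — followed by bounded continuous refinement from the grid
optimum.  Negative-amplitude fits are rejected (tuned responses are
excitatory), so VE is the squared *positive-part* correlation between
prediction and data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from ._forward import HrfParams, log_gaussian, regressor_basis
from .stimgen import Timeline
from .synth_bold import BoldRun

__all__ = [
    "GridSpec",
    "NumerosityPrf",
    "PrfResults",
    "TunedSelection",
    "predict_timecourse",
    "select_tuned",
]


@dataclass(frozen=True)
class GridSpec:
    """Log-spaced candidate grid for the (mu, sigma) search."""

    mu_min: float = 1.0
    mu_max: float = 10.0
    n_mu: int = 25
    sigma_min: float = 0.05
    sigma_max: float = 3.0
    n_sigma: int = 20

    def __post_init__(self) -> None:
        if self.mu_min <= 0 or self.sigma_min <= 0:
            raise ValueError("grid bounds must be positive")
        if self.mu_max <= self.mu_min or self.sigma_max <= self.sigma_min:
            raise ValueError("grid bounds must be increasing")
        if self.n_mu < 2 or self.n_sigma < 2:
            raise ValueError("grid needs at least 2 points per axis")

    @property
    def mus(self) -> np.ndarray:
        return np.geomspace(self.mu_min, self.mu_max, self.n_mu)

    @property
    def sigmas(self) -> np.ndarray:
        return np.geomspace(self.sigma_min, self.sigma_max, self.n_sigma)


def predict_timecourse(
    timeline: Timeline,
    mu: float,
    sigma: float,
    hrf: HrfParams | None = None,
    *,
    n_volumes: int | None = None,
    n_discard: int = 8,
    dt_ms: int = 50,
) -> np.ndarray:
    """Unit-amplitude BOLD prediction for log-Gaussian tuning (mu, sigma).

    Identical computation to the simulator's noiseless forward model (same
    code path), with the first ``n_discard`` frames dropped.
    """
    if sigma <= 0 or mu <= 0:
        raise ValueError("mu and sigma must be positive")
    if n_volumes is None:
        n_volumes = int(np.ceil(timeline.total_duration_ms / timeline.tr_ms))
    values, Wn = regressor_basis(
        timeline.events,
        tr_ms=timeline.tr_ms,
        n_volumes=n_volumes,
        hrf=hrf,
        dt_ms=dt_ms,
        group="numerosity",
    )
    if not values:
        raise ValueError("timeline carries no numerosity-labelled events")
    g = log_gaussian(np.asarray(values, dtype=float), mu, sigma)
    return (Wn @ g)[n_discard:]


@dataclass
class TunedSelection:
    """Voxel indices passing the tuned-population selection rule."""

    indices: np.ndarray
    rule: dict

    def __len__(self) -> int:
        return len(self.indices)


class NumerosityPrf:
    """Grid-plus-refinement log-Gaussian numerosity pRF model.

    Parameters
    ----------
    data
        Voxels x timepoints matrix in percent-signal (or any affine) units;
        the model fits a free amplitude and baseline per voxel.
    timeline
        Localizer timeline whose events carry numerosities.
    n_discard
        Acquired frames dropped from the head of each run (must match the
        data's preprocessing).
    """

    def __init__(
        self,
        data: np.ndarray,
        timeline: Timeline,
        *,
        hrf: HrfParams | None = None,
        n_discard: int = 8,
        dt_ms: int = 50,
    ) -> None:
        data = np.atleast_2d(np.asarray(data, dtype=float))
        self.timeline = timeline
        self.hrf = hrf
        self.n_discard = n_discard
        self.dt_ms = dt_ms
        n_volumes = int(np.ceil(timeline.total_duration_ms / timeline.tr_ms))
        self.n_volumes = n_volumes
        if data.shape[1] != n_volumes - n_discard:
            raise ValueError(
                f"data has {data.shape[1]} timepoints; timeline implies "
                f"{n_volumes - n_discard} retained volumes"
            )
        self.data = data
        values, Wn = regressor_basis(
            timeline.events,
            tr_ms=timeline.tr_ms,
            n_volumes=n_volumes,
            hrf=hrf,
            dt_ms=dt_ms,
            group="numerosity",
        )
        if not values:
            raise ValueError("timeline carries no numerosity-labelled events")
        self._num_values = np.asarray(values, dtype=float)
        self._Wn = Wn[n_discard:]

    @classmethod
    def from_runs(
        cls,
        runs: list[BoldRun],
        timeline: Timeline | None = None,
        **kwargs,
    ) -> "NumerosityPrf":
        """Build the model from one or more runs of the same protocol,
        averaging their percent-signal time courses."""
        if not runs:
            raise ValueError("need at least one run")
        data = np.mean([r.percent_signal() for r in runs], axis=0)
        tl = timeline if timeline is not None else runs[0].timeline
        kwargs.setdefault("n_discard", runs[0].n_discarded)
        return cls(data, tl, **kwargs)

    # -- internals ---------------------------------------------------------

    def _prediction(self, mu: float, sigma: float) -> np.ndarray:
        return self._Wn @ log_gaussian(self._num_values, mu, sigma)

    def _ve_for_predictions(self, P: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Positive-part squared correlation between each voxel and each
        prediction column; returns (VE matrix, correlation matrix)."""
        Y = self.data
        Yc = Y - Y.mean(axis=1, keepdims=True)
        Pc = P - P.mean(axis=0, keepdims=True)
        sy = np.sqrt((Yc**2).sum(axis=1))
        sp = np.sqrt((Pc**2).sum(axis=0))
        denom = np.outer(sy, sp)
        with np.errstate(divide="ignore", invalid="ignore"):
            r = np.where(denom > 0, (Yc @ Pc) / denom, 0.0)
        ve = np.clip(np.maximum(r, 0.0) ** 2, 0.0, 1.0)
        return ve, r

    # -- fitting -----------------------------------------------------------

    def fit(
        self,
        grid: GridSpec | None = None,
        refine: bool = True,
        refine_ve_floor: float = 0.05,
    ) -> "PrfResults":
        """Grid search over (mu, sigma), then optional bounded refinement.

        Refinement maximizes VE in (ln mu, ln sigma) space within the grid
        bounds, starting from the grid optimum; it never decreases VE
        (the grid solution is kept when the optimizer fails to improve).
        Voxels below ``refine_ve_floor`` after the grid stage are left at
        their grid estimates.
        """
        grid = grid if grid is not None else GridSpec()
        mus, sigmas = grid.mus, grid.sigmas
        MU, SIG = np.meshgrid(mus, sigmas, indexing="ij")
        pairs = np.column_stack([MU.ravel(), SIG.ravel()])

        G = np.stack(
            [log_gaussian(self._num_values, m, s) for m, s in pairs], axis=1
        )
        P = self._Wn @ G  # timepoints x n_grid
        ve, _ = self._ve_for_predictions(P)
        best = np.argmax(ve, axis=1)
        V = self.data.shape[0]

        mu_hat = pairs[best, 0].copy()
        sig_hat = pairs[best, 1].copy()
        ve_hat = ve[np.arange(V), best].copy()
        valid = self.data.std(axis=1) > 0
        ve_hat[~valid] = 0.0
        refine_failed = np.zeros(V, dtype=bool)

        if refine:
            bounds = [
                (np.log(grid.mu_min), np.log(grid.mu_max)),
                (np.log(grid.sigma_min), np.log(grid.sigma_max)),
            ]
            Yc = self.data - self.data.mean(axis=1, keepdims=True)
            sy = np.sqrt((Yc**2).sum(axis=1))
            for i in range(V):
                if not valid[i] or ve_hat[i] < refine_ve_floor:
                    continue
                yc = Yc[i]
                syi = sy[i]

                def neg_ve(theta):
                    p = self._prediction(np.exp(theta[0]), np.exp(theta[1]))
                    pc = p - p.mean()
                    sp = np.sqrt((pc**2).sum())
                    if sp == 0 or syi == 0:
                        return 0.0
                    r = float(yc @ pc) / (syi * sp)
                    return -max(r, 0.0) ** 2

                x0 = np.log([mu_hat[i], sig_hat[i]])
                try:
                    # Nelder-Mead: the VE surface has curved (mu, sigma)
                    # ridges where quasi-Newton steps stall prematurely
                    res = minimize(
                        neg_ve,
                        x0,
                        method="Nelder-Mead",
                        bounds=bounds,
                        options={"xatol": 1e-6, "fatol": 1e-12, "maxiter": 400},
                    )
                    cand_ve = -res.fun
                    if np.isfinite(cand_ve) and cand_ve >= ve_hat[i]:
                        mu_hat[i], sig_hat[i] = np.exp(res.x)
                        ve_hat[i] = min(cand_ve, 1.0)
                    else:
                        refine_failed[i] = True
                except Exception:  # optimizer failure: keep the grid optimum
                    refine_failed[i] = True

        # final amplitude/baseline by OLS at the selected (mu, sigma)
        amp = np.zeros(V)
        base = np.zeros(V)
        for i in range(V):
            p = self._prediction(mu_hat[i], sig_hat[i])
            pc = p - p.mean()
            var_p = float(pc @ pc)
            if var_p > 0 and valid[i]:
                a = float((self.data[i] - self.data[i].mean()) @ pc) / var_p
                amp[i] = max(a, 0.0)
                if a < 0:
                    ve_hat[i] = 0.0
            base[i] = self.data[i].mean() - amp[i] * p.mean()

        sigma_bound_tol = 1e-6
        at_bound = (
            sig_hat >= grid.sigma_max * (1 - sigma_bound_tol)
        ) | (sig_hat <= grid.sigma_min * (1 + sigma_bound_tol))

        params = pd.DataFrame(
            {
                "preferred_numerosity": mu_hat,
                "tuning_width": sig_hat,
                "amplitude": amp,
                "baseline": base,
                "variance_explained": ve_hat,
                "at_sigma_bound": at_bound,
                "refine_failed": refine_failed,
                "valid": valid,
            }
        )
        return PrfResults(model=self, params=params, grid=grid)


@dataclass
class PrfResults:
    """Per-voxel log-Gaussian tuning estimates."""

    model: NumerosityPrf
    params: pd.DataFrame
    grid: GridSpec

    @property
    def preferred_numerosity(self) -> np.ndarray:
        return self.params["preferred_numerosity"].to_numpy()

    @property
    def tuning_width(self) -> np.ndarray:
        return self.params["tuning_width"].to_numpy()

    @property
    def variance_explained(self) -> np.ndarray:
        return self.params["variance_explained"].to_numpy()

    def predict(self, voxel: int) -> np.ndarray:
        """Fitted time course (amplitude * prediction + baseline)."""
        row = self.params.iloc[voxel]
        p = self.model._prediction(
            row["preferred_numerosity"], row["tuning_width"]
        )
        return row["amplitude"] * p + row["baseline"]

    def select_tuned(
        self,
        num_range: tuple[float, float] = (1.0, 3.0),
        ve_min: float = 0.3,
        exclude_sigma_bound: bool = True,
    ) -> TunedSelection:
        """Select populations tuned to the low numerosities.

        Keeps voxels with preferred numerosity inside ``num_range``
        (closed interval) and VE at or above ``ve_min``; by default fits
        whose tuning width sits on the search bound are excluded, since a
        width at the upper bound is the signature of an untuned visually
        responsive voxel rather than genuine tuning.
        """
        lo, hi = num_range
        p = self.params
        keep = (
            p["valid"]
            & (p["preferred_numerosity"] >= lo)
            & (p["preferred_numerosity"] <= hi)
            & (p["variance_explained"] >= ve_min)
        )
        if exclude_sigma_bound:
            keep &= ~p["at_sigma_bound"]
        idx = np.flatnonzero(keep.to_numpy())
        if idx.size == 0:
            warnings.warn("tuned selection is empty", stacklevel=2)
        return TunedSelection(
            indices=idx,
            rule={
                "num_range": [float(lo), float(hi)],
                "ve_min": float(ve_min),
                "exclude_sigma_bound": bool(exclude_sigma_bound),
            },
        )

    def summary(self) -> str:
        p = self.params
        ok = p["valid"]
        lines = [
            "Numerosity pRF fit",
            f"  voxels:              {len(p)} ({int(ok.sum())} valid)",
            f"  grid:                mu [{self.grid.mu_min}, {self.grid.mu_max}] x"
            f" sigma [{self.grid.sigma_min}, {self.grid.sigma_max}]",
            f"  median VE:           {p.loc[ok, 'variance_explained'].median():.3f}",
            f"  median preferred n:  {p.loc[ok, 'preferred_numerosity'].median():.3f}",
            f"  median width:        {p.loc[ok, 'tuning_width'].median():.3f}",
            f"  at sigma bound:      {int(p['at_sigma_bound'].sum())}",
        ]
        return "\n".join(lines)


def select_tuned(
    fit: PrfResults,
    num_range: tuple[float, float] = (1.0, 3.0),
    ve_min: float = 0.3,
    **kwargs,
) -> TunedSelection:
    """Functional alias for :meth:`PrfResults.select_tuned`."""
    return fit.select_tuned(num_range=num_range, ve_min=ve_min, **kwargs)
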
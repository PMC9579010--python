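"""Shared neural-to-BOLD forward model.

Every stage that needs a predicted BOLD time course — the simulator, the
numerosity-pRF fit and the block-design GLM — goes through the functions
here, so that a model prediction and a noiseless simulation are the *same*
computation, not merely similar ones.

The forward model is linear: stimulus events are boxcars at a fine temporal
resolution (default 50 ms), convolved with a canonical double-gamma HRF and
integrated (averaged) within each TR window.  Because convolution is linear,
any voxel's response is a weighted sum of a small set of per-group
regressors (one per unique numerosity, per category, or one for all events),
which makes grid searches and optimizers over tuning parameters cheap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import fftconvolve
from scipy.stats import gamma as _gamma_dist

__all__ = ["HrfParams", "hrf_kernel", "regressor_basis"]


@dataclass(frozen=True)
class HrfParams:
    """Canonical double-gamma hemodynamic response parameters (seconds)."""

    peak_delay: float = 6.0
    undershoot_delay: float = 16.0
    peak_dispersion: float = 1.0
    undershoot_dispersion: float = 1.0
    undershoot_ratio: float = 1.0 / 6.0
    length_s: float = 32.0

    def __post_init__(self) -> None:
        if self.length_s < 24.0:
            raise ValueError("HRF kernel length must be at least 24 s")
        if self.peak_dispersion <= 0 or self.undershoot_dispersion <= 0:
            raise ValueError("HRF dispersions must be positive")


def hrf_kernel(params: HrfParams | None = None, dt: float = 0.05) -> np.ndarray:
    """Sample the double-gamma HRF on ``t = 0, dt, ..., length_s`` (inclusive).

    The kernel is peak-normalized so its maximum equals 1; the undershoot is
    the second gamma scaled by ``undershoot_ratio`` and subtracted.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    p = params if params is not None else HrfParams()
    t = np.arange(0.0, p.length_s + dt / 2, dt)
    peak = _gamma_dist.pdf(t, p.peak_delay / p.peak_dispersion, scale=p.peak_dispersion)
    under = _gamma_dist.pdf(
        t, p.undershoot_delay / p.undershoot_dispersion, scale=p.undershoot_dispersion
    )
    h = peak - p.undershoot_ratio * under
    return h / h.max()


def _group_columns(events: pd.DataFrame, group: str) -> tuple[list, list[np.ndarray]]:
    """Return (group names, list of event-row index arrays) for a grouping."""
    if group == "all":
        return ["all"], [np.arange(len(events))]
    if group == "numerosity":
        num = events["numerosity"].to_numpy(dtype=float)
        present = np.isfinite(num)
        values = np.unique(num[present])
        return (
            [float(v) for v in values],
            [np.flatnonzero(present & (num == v)) for v in values],
        )
    if group == "label":
        labels = events["label"].astype(str).to_numpy()
        values = sorted(set(labels))
        return values, [np.flatnonzero(labels == v) for v in values]
    raise ValueError(f"unknown grouping {group!r}")


def regressor_basis(
    events: pd.DataFrame,
    *,
    tr_ms: int,
    n_volumes: int,
    hrf: HrfParams | None = None,
    dt_ms: int = 50,
    group: str = "numerosity",
) -> tuple[list, np.ndarray]:
    """HRF-convolved, TR-integrated regressor per event group.

    Parameters
    ----------
    events
        Event table with integer ``onset_ms``/``duration_ms`` columns and,
        depending on ``group``, ``numerosity`` or ``label`` columns.
    tr_ms, n_volumes
        Acquisition grid; the basis covers ``n_volumes`` full TRs (events
        beyond that window are clipped).
    group
        ``"numerosity"`` (one column per unique finite numerosity),
        ``"label"`` (one per event label) or ``"all"`` (single column).

    Returns
    -------
    names, W
        ``names`` identifies the columns; ``W`` has shape
        ``(n_volumes, len(names))``.
    """
    if tr_ms % dt_ms != 0:
        raise ValueError("tr_ms must be a multiple of dt_ms")
    if n_volumes < 1:
        raise ValueError("need at least one volume")
    per_tr = tr_ms // dt_ms
    n_samples = n_volumes * per_tr

    names, groups = _group_columns(events, group)
    onset = events["onset_ms"].to_numpy(dtype=np.int64)
    dur = events["duration_ms"].to_numpy(dtype=np.int64)
    box = np.zeros((n_samples, len(groups)))
    for j, rows in enumerate(groups):
        for i in rows:
            a = int(onset[i]) // dt_ms
            b = int(onset[i] + dur[i]) // dt_ms
            if a >= n_samples:
                continue
            box[a : min(b, n_samples), j] = 1.0

    # unit-area kernel: a sustained unit neural drive converges to a unit
    # plateau, so voxel amplitudes are in percent-signal units
    h = hrf_kernel(hrf, dt=dt_ms / 1000.0)
    h = h / h.sum()
    conv = fftconvolve(box, h[:, None], axes=0)[:n_samples]
    W = conv.reshape(n_volumes, per_tr, len(groups)).mean(axis=1)
    return names, W


def log_gaussian(numerosity, mu: float, sigma: float):
    """Log-Gaussian tuning weight exp(-(ln n - ln mu)^2 / (2 sigma^2))."""
    if mu <= 0 or sigma <= 0:
        raise ValueError("mu and sigma must be positive")
    n = np.asarray(numerosity, dtype=float)
    return np.exp(-((np.log(n) - np.log(mu)) ** 2) / (2.0 * sigma**2))
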
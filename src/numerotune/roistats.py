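"""ROI-level aggregation and nonparametric inference.

Per subject and region, the percent-signal responses of the relevant
voxels are averaged into one value per stimulus category: numerosity-map
regions use the intersection of the tuned selection (populations preferring
numerosities 1-3) with the scenery inclusion mask, while control regions
(V1, LO, PPA) use every voxel in the region.  The subject is the
experimental unit for all tests.

Inference is the one-sided Wilcoxon signed-rank test — exact for small
samples via full enumeration of the sign assignments of the observed
(mid)ranks, computed with a dynamic program equivalent to the 2^n sum —
followed by Benjamini-Hochberg step-up FDR correction within each analysis
family.  Two analyses mirror the experiment's questions: positivity of the
category responses (response > 0) per ROI x category, and the paired
low-versus-high numerosity comparison per map (frontal maps excluded).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synth_bold import NUMEROSITY_MAPS

__all__ = [
    "SubjectStats",
    "roi_table",
    "WilcoxonResult",
    "wilcoxon_one_sided",
    "signed_rank_sf",
    "bh_fdr",
    "positivity_tests",
    "low_vs_high",
    "plot_category_responses",
]

LOW_CATEGORY = "nat_low"
HIGH_CATEGORY = "nat_high"


# ---------------------------------------------------------------------------
# ROI response table
# ---------------------------------------------------------------------------


@dataclass
class SubjectStats:
    """One subject's inputs to the ROI table."""

    subject_id: str
    psc: pd.DataFrame  # voxels x categories, percent signal change
    rois: np.ndarray  # per-voxel ROI label
    tuned_indices: np.ndarray  # voxel indices of the tuned-to-1..3 selection
    scenery_mask: np.ndarray  # per-voxel inclusion mask (scenery t >= 1.96)


def roi_table(
    subjects: list[SubjectStats],
    apply_scenery_mask: bool = True,
    apply_selection: bool = True,
) -> pd.DataFrame:
    """Subject x ROI x category mean responses.

    Numerosity-map rows average over tuned-selection voxels intersected
    with the scenery mask (either filter can be disabled, e.g. for the
    unmasked supplementary variant or an untuned control cohort); control
    ROIs always average over all their voxels.  Empty voxel sets yield a
    row with ``n_voxels = 0`` and a missing mean.
    """
    rows = []
    for s in subjects:
        rois_here = list(dict.fromkeys(s.rois))
        tuned = np.zeros(len(s.rois), dtype=bool)
        tuned[np.asarray(s.tuned_indices, dtype=int)] = True
        for roi in rois_here:
            in_roi = s.rois == roi
            if roi in NUMEROSITY_MAPS:
                keep = in_roi.copy()
                if apply_selection:
                    keep &= tuned
                if apply_scenery_mask:
                    keep &= s.scenery_mask
            else:
                keep = in_roi
            for cat in s.psc.columns:
                vals = s.psc.loc[keep, cat].to_numpy()
                vals = vals[np.isfinite(vals)]
                rows.append(
                    {
                        "subject": s.subject_id,
                        "roi": roi,
                        "category": cat,
                        "mean_psc": float(vals.mean()) if vals.size else np.nan,
                        "n_voxels": int(vals.size),
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank (one-sided, exact for small n)
# ---------------------------------------------------------------------------


def _midranks(values: np.ndarray) -> np.ndarray:
    """Midranks of |values| (ties share the average rank)."""
    order = np.argsort(values, kind="mergesort")
    ranks = np.empty(len(values))
    sorted_vals = values[order]
    i = 0
    while i < len(values):
        j = i
        while j + 1 < len(values) and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def signed_rank_sf(ranks: np.ndarray, w_obs: float) -> float:
    """P(W+ >= w_obs) under the signed-rank null for the given (mid)ranks.

    Equivalent to enumerating all 2^n sign assignments: a dynamic program
    counts, over the 2^n equally likely subsets, how many achieve each
    possible rank-sum.  Midranks are doubled so sums stay integral.
    """
    d = np.round(2.0 * np.asarray(ranks, dtype=float)).astype(np.int64)
    if np.any(np.abs(2.0 * np.asarray(ranks) - d) > 1e-9):
        raise ValueError("ranks must be integers or half-integers")
    total = int(d.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in d:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    w2 = 2.0 * w_obs
    # half-integer-safe threshold: include every achievable sum >= w2
    k = int(np.ceil(w2 - 1e-9))
    tail = counts[k:].sum()
    return float(tail / counts.sum())


@dataclass(frozen=True)
class WilcoxonResult:
    statistic: float  # W+ = sum of ranks of positive values
    p_value: float
    n_used: int
    n_zero: int
    method: str


def wilcoxon_one_sided(
    values, exact_max_n: int = 25
) -> WilcoxonResult:
    """One-sided Wilcoxon signed-rank test of median > 0.

    Zeros are dropped before ranking (their count is reported); ties share
    midranks.  For ``n <= exact_max_n`` the p-value is exact (enumeration
    over sign patterns of the observed ranks); above that a normal
    approximation with continuity and tie correction is used.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("no observations")
    if np.any(~np.isfinite(x)):
        raise ValueError("values must be finite")
    nz = x != 0
    n_zero = int((~nz).sum())
    x = x[nz]
    n = x.size
    if n == 0:
        raise ValueError("all values are zero: signed-rank test undefined")

    ranks = _midranks(np.abs(x))
    w_pos = float(ranks[x > 0].sum())

    if n <= exact_max_n:
        p = signed_rank_sf(ranks, w_pos)
        method = "exact"
    else:
        mean = n * (n + 1) / 4.0
        var = (ranks**2).sum() / 4.0  # tie-corrected: sum r_i^2 / 4
        from scipy.stats import norm

        z = (w_pos - mean - 0.5) / np.sqrt(var)
        p = float(norm.sf(z))
        method = "normal"
    p = min(max(p, np.finfo(float).tiny), 1.0)
    return WilcoxonResult(
        statistic=w_pos, p_value=p, n_used=n, n_zero=n_zero, method=method
    )


def bh_fdr(p_values, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up adjusted p-values and rejections.

    adjusted_i = min over j with p_(j) >= p_(i) of m * p_(j) / j, capped at
    1; a hypothesis is rejected iff its adjusted value is below ``alpha``.
    Order-equivariant; empty input yields empty output.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p <= 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / (np.arange(m) + 1)
    adj_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.empty(m)
    adj[order] = np.minimum(adj_sorted, 1.0)
    return adj, adj < alpha


# ---------------------------------------------------------------------------
# The two analysis families
# ---------------------------------------------------------------------------


def positivity_tests(
    table: pd.DataFrame,
    rois: tuple[str, ...] | None = None,
    alpha: float = 0.05,
    low_power_n: int = 4,
) -> pd.DataFrame:
    """One-sided Wilcoxon (response > 0) per ROI x category across subjects,
    BH-corrected over all tested cells of the family.

    ``rois`` restricts the family (e.g. the control ROIs, or the numerosity
    maps); cells with fewer than ``low_power_n`` subjects are flagged
    ``low_power`` but still tested.
    """
    sub = table if rois is None else table[table["roi"].isin(rois)]
    rows = []
    for (roi, cat), grp in sub.groupby(["roi", "category"], sort=False):
        vals = grp["mean_psc"].to_numpy()
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            continue
        res = wilcoxon_one_sided(vals)
        rows.append(
            {
                "roi": roi,
                "category": cat,
                "comparison": "response > 0",
                "n_subjects": res.n_used + res.n_zero,
                "statistic": res.statistic,
                "p_value": res.p_value,
                "low_power": res.n_used + res.n_zero < low_power_n,
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        adj, rej = bh_fdr(out["p_value"].to_numpy(), alpha=alpha)
        out["p_adjusted"] = adj
        out["significant"] = rej
    return out


def low_vs_high(
    table: pd.DataFrame,
    low: str = LOW_CATEGORY,
    high: str = HIGH_CATEGORY,
    maps: tuple[str, ...] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Paired one-sided Wilcoxon of (low - high) numerosity responses per
    numerosity map, BH-corrected across maps.

    Defaults test the natural-image categories over all numerosity maps
    except the frontal maps (excluded for lack of power).  All-zero
    difference vectors are untestable and raise.
    """
    if maps is None:
        maps = tuple(r for r in NUMEROSITY_MAPS if r != "NF")
    for cat in (low, high):
        if cat not in set(table["category"]):
            raise ValueError(f"category {cat!r} missing from the table")
    wide = table.pivot_table(
        index=["subject", "roi"], columns="category", values="mean_psc"
    )
    rows = []
    for roi in maps:
        if roi not in {r for _, r in wide.index}:
            continue
        sub = wide.xs(roi, level="roi")[[low, high]].dropna()
        diffs = (sub[low] - sub[high]).to_numpy()
        if diffs.size == 0:
            continue
        res = wilcoxon_one_sided(diffs)
        rows.append(
            {
                "roi": roi,
                "comparison": f"{low} > {high}",
                "n_subjects": res.n_used + res.n_zero,
                "statistic": res.statistic,
                "p_value": res.p_value,
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        adj, rej = bh_fdr(out["p_value"].to_numpy(), alpha=alpha)
        out["p_adjusted"] = adj
        out["significant"] = rej
    return out


def plot_category_responses(
    table: pd.DataFrame, rois: tuple[str, ...], path=None
):
    """Per-ROI bar panel: subject dots, median marker, SD error bars."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    cats = list(dict.fromkeys(table["category"]))
    fig, axes = plt.subplots(
        1, len(rois), figsize=(3.2 * len(rois), 3.2), squeeze=False, sharey=True
    )
    for ax, roi in zip(axes[0], rois):
        sub = table[table["roi"] == roi]
        for i, cat in enumerate(cats):
            vals = sub.loc[sub["category"] == cat, "mean_psc"].dropna().to_numpy()
            if vals.size == 0:
                continue
            ax.scatter(np.full(vals.size, i), vals, s=12, alpha=0.7, zorder=3)
            ax.errorbar(
                i, np.median(vals), yerr=vals.std(ddof=1) if vals.size > 1 else 0,
                fmt="o", color="black", mfc="none", capsize=3, zorder=4,
            )
        ax.axhline(0, color="0.6", lw=0.8)
        ax.set_title(roi)
        ax.set_xticks(range(len(cats)))
        ax.set_xticklabels(cats, rotation=60, ha="right", fontsize=7)
    axes[0][0].set_ylabel("response (% signal change)")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
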
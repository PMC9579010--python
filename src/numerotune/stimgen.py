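"""Stimulus generation: dot arrays, run timelines, fixture images, spectra.

This module builds the two experimental protocols used throughout the
package:

* a **numerosity localizer sweep** — 1..7 dots presented in ascending then
  descending order with long 20-dot baseline stretches, repeated four times
  per run; the substrate of the numerosity-pRF fit, and
* a **six-category block design** — natural images with 1-3 main objects,
  natural images with many (10-42) objects, natural scenery, and three dot
  analogues (1-3 dots, 20 dots, 10-42 dots), shown as 15 s stimulus blocks
  alternating with 15 s of rest.

It also generates the synthetic "natural image" fixtures (1/f-amplitude
random-phase textures with countable high-contrast blobs as objects) that
stand in for photographs, and the radially averaged amplitude-spectrum QC
used to confirm their 1/f statistics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.stats import linregress, norm

__all__ = [
    "DotDisplay",
    "PlacementError",
    "generate_dot_display",
    "render_display",
    "Timeline",
    "LocalizerParams",
    "build_localizer_timeline",
    "BlockParams",
    "build_block_timeline",
    "default_category_pools",
    "PoolSpec",
    "PoolManifest",
    "generate_fixture_pool",
    "synthesize_fixture_image",
    "synthesize_power_law_image",
    "sample_high_numerosity_count",
    "high_numerosity_pmf",
    "SpectrumProfile",
    "amplitude_spectrum",
]

NATURAL_CATEGORIES = ("nat_low", "nat_high", "nat_scenery")
DOT_CATEGORIES = ("dots_low", "dots_20", "dots_high")
CATEGORIES = NATURAL_CATEGORIES + DOT_CATEGORIES

#: Pool sizes of the five underlying image sets: 1 / 2 / 3 main objects,
#: high numerosity (10-42 objects) and scenery.
DEFAULT_POOL_SIZES = {"one": 93, "two": 95, "three": 70, "high": 70, "scenery": 61}

HIGH_COUNT_RANGE = (10, 42)
HIGH_COUNT_MEAN = 19.42
HIGH_COUNT_SD = 8.8


# ---------------------------------------------------------------------------
# Dot displays
# ---------------------------------------------------------------------------


class PlacementError(RuntimeError):
    """Raised when non-overlapping dot placement fails within the retry budget."""


@dataclass(frozen=True)
class DotDisplay:
    """A dot-array stimulus.

    centers/radii are in degrees of visual angle relative to the field
    center; ``mode`` records which magnitude was held constant across
    numerosities (total dot surface area, or individual dot size).
    """

    centers: np.ndarray
    radii: np.ndarray
    numerosity: int
    field_diameter: float
    mode: str
    polarity: str = "black"

    @property
    def total_area(self) -> float:
        return float(np.sum(np.pi * self.radii**2))


def _default_total_area(field_diameter: float, baseline_factor: float = 20.0) -> float:
    # area of a single dot of 0.4 deg diameter (scaled to the field) times a
    # baseline factor, so the 20-dot baseline display has 0.4-deg-scale dots
    r0 = 0.05 * field_diameter
    return np.pi * r0**2 * baseline_factor


def generate_dot_display(
    n: int,
    mode: str = "constant_total_area",
    field_diameter: float = 4.0,
    seed: int = 0,
    *,
    total_area: float | None = None,
    dot_radius: float | None = None,
    gap_factor: float = 0.1,
    max_tries: int = 10000,
    polarity: str = "black",
) -> DotDisplay:
    """Place ``n`` non-overlapping dots uniformly at random in a circular field.

    Rejection sampling: candidate centers are drawn uniformly over the disc
    that keeps the dot fully inside the field; a candidate is rejected if it
    comes within ``(1 + gap_factor)`` times the sum of radii of any placed
    dot.  ``max_tries`` rejected candidates raise :class:`PlacementError`.
    """
    if n < 1:
        raise ValueError("numerosity must be a positive integer")
    if field_diameter <= 0:
        raise ValueError("field_diameter must be positive")
    if mode not in ("constant_total_area", "constant_dot_size"):
        raise ValueError(f"unknown mode {mode!r}")
    if polarity not in ("black", "white"):
        raise ValueError(f"unknown polarity {polarity!r}")

    if mode == "constant_total_area":
        area = _default_total_area(field_diameter) if total_area is None else total_area
        if area <= 0:
            raise ValueError("total_area must be positive")
        r = float(np.sqrt(area / (n * np.pi)))
    else:
        r = 0.05 * field_diameter if dot_radius is None else float(dot_radius)
        if r <= 0:
            raise ValueError("dot_radius must be positive")

    R = field_diameter / 2.0
    if r >= R:
        raise PlacementError(f"dot radius {r:.3g} does not fit in field radius {R:.3g}")

    rng = np.random.default_rng(seed)
    centers = np.empty((n, 2))
    placed = 0
    tries = 0
    min_dist = 2.0 * r * (1.0 + gap_factor)
    while placed < n:
        if tries >= max_tries:
            raise PlacementError(
                f"could not place {n} dots of radius {r:.3g} in a "
                f"{field_diameter:.3g} deg field after {max_tries} tries"
            )
        tries += 1
        # uniform over the disc of radius R - r (dot fully inside the field)
        rho = (R - r) * np.sqrt(rng.uniform())
        theta = rng.uniform(0.0, 2.0 * np.pi)
        cand = np.array([rho * np.cos(theta), rho * np.sin(theta)])
        if placed and np.any(
            np.linalg.norm(centers[:placed] - cand, axis=1) <= min_dist
        ):
            continue
        centers[placed] = cand
        placed += 1

    radii = np.full(n, r)
    return DotDisplay(
        centers=centers,
        radii=radii,
        numerosity=n,
        field_diameter=field_diameter,
        mode=mode,
        polarity=polarity,
    )


def render_display(display: DotDisplay, n_pixels: int = 256) -> np.ndarray:
    """Rasterize a display to an ``n_pixels`` square binary image (1 = dot)."""
    half = display.field_diameter / 2.0
    coords = (np.arange(n_pixels) + 0.5) / n_pixels * display.field_diameter - half
    xx, yy = np.meshgrid(coords, coords)
    img = np.zeros((n_pixels, n_pixels))
    for (cx, cy), r in zip(display.centers, display.radii):
        img[(xx - cx) ** 2 + (yy - cy) ** 2 < r**2] = 1.0
    return img


# ---------------------------------------------------------------------------
# Timelines
# ---------------------------------------------------------------------------

_EVENT_COLUMNS = [
    "onset_ms",
    "duration_ms",
    "label",
    "numerosity",
    "display_ref",
    "attention_flag",
]


@dataclass
class Timeline:
    """Ordered stimulus events of one functional run.

    ``events`` columns: onset_ms, duration_ms (ints), label (category or
    numerosity tag), numerosity (float, NaN where undefined), display_ref,
    attention_flag (bool).  Onsets are run-relative; serializes to a
    BIDS-style events TSV (onset/duration in seconds) with a JSON sidecar
    for run-level metadata.
    """

    events: pd.DataFrame
    design: str
    total_duration_ms: int
    tr_ms: int = 1500
    seed: int | None = None

    def __post_init__(self) -> None:
        ev = self.events
        missing = [c for c in _EVENT_COLUMNS if c not in ev.columns]
        if missing:
            raise ValueError(f"events table missing columns {missing}")
        onset = ev["onset_ms"].to_numpy()
        dur = ev["duration_ms"].to_numpy()
        if len(ev):
            if np.any(np.diff(onset) <= 0):
                raise ValueError("event onsets must be strictly increasing")
            if np.any(onset[:-1] + dur[:-1] > onset[1:]):
                raise ValueError("events overlap in time")
            if np.any(onset < 0) or np.any(dur <= 0):
                raise ValueError("onsets must be >= 0 and durations > 0")
            if onset[-1] + dur[-1] > self.total_duration_ms:
                raise ValueError("total_duration_ms shorter than the last event")

    @property
    def n_events(self) -> int:
        return len(self.events)

    def to_tsv(self, path: str | Path) -> None:
        path = Path(path)
        out = pd.DataFrame(
            {
                "onset": self.events["onset_ms"] / 1000.0,
                "duration": self.events["duration_ms"] / 1000.0,
                "label": self.events["label"],
                "numerosity": self.events["numerosity"],
                "display_ref": self.events["display_ref"],
                "attention_flag": self.events["attention_flag"].astype(int),
            }
        )
        out.to_csv(path, sep="\t", index=False, float_format="%.3f")
        sidecar = {
            "design": self.design,
            "total_duration_ms": int(self.total_duration_ms),
            "tr_ms": int(self.tr_ms),
            "seed": self.seed,
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def from_tsv(cls, path: str | Path) -> "Timeline":
        path = Path(path)
        raw = pd.read_csv(path, sep="\t")
        meta = json.loads(path.with_suffix(".json").read_text())
        events = pd.DataFrame(
            {
                "onset_ms": np.round(raw["onset"] * 1000).astype(np.int64),
                "duration_ms": np.round(raw["duration"] * 1000).astype(np.int64),
                "label": raw["label"].astype(str),
                "numerosity": raw["numerosity"].astype(float),
                "display_ref": raw["display_ref"].astype(str),
                "attention_flag": raw["attention_flag"].astype(bool),
            }
        )
        return cls(
            events=events,
            design=meta["design"],
            total_duration_ms=meta["total_duration_ms"],
            tr_ms=meta["tr_ms"],
            seed=meta["seed"],
        )


@dataclass(frozen=True)
class LocalizerParams:
    """Numerosity-sweep protocol parameters (all durations in ms)."""

    present_ms: int = 300
    cycle_ms: int = 650
    repeats_per_numerosity: int = 6
    sweep: tuple[int, ...] = (1, 2, 3, 4, 5, 6, 7)
    baseline_numerosity: int = 20
    baseline_epochs: int = 6
    sweep_repetitions: int = 4
    oddball_rate: float = 0.10
    initial_rest_ms: int = 12000
    tr_ms: int = 1500

    @property
    def epoch_ms(self) -> int:
        return self.repeats_per_numerosity * self.cycle_ms


def build_localizer_timeline(
    params: LocalizerParams | None = None, seed: int = 0
) -> Timeline:
    """Build one localizer run: (ascending sweep, baseline, descending sweep,
    baseline) repeated ``sweep_repetitions`` times.

    Each numerosity occupies one epoch of ``repeats_per_numerosity`` dot
    presentations at the ``cycle_ms`` stimulus-onset asynchrony (defaults:
    6 x 650 ms = 3900 ms per numerosity).  A random ~``oddball_rate``
    fraction of presentations shows white instead of black dots and carries
    the attention flag.
    """
    p = params if params is not None else LocalizerParams()
    if p.present_ms > p.cycle_ms:
        raise ValueError("presentation duration exceeds the stimulus cycle")
    if not (0.0 <= p.oddball_rate <= 1.0):
        raise ValueError("oddball_rate must be in [0, 1]")
    rng = np.random.default_rng(seed)

    epoch_numerosities: list[int] = []
    baseline = [p.baseline_numerosity] * p.baseline_epochs
    for _ in range(p.sweep_repetitions):
        epoch_numerosities.extend(list(p.sweep))
        epoch_numerosities.extend(baseline)
        epoch_numerosities.extend(list(p.sweep)[::-1])
        epoch_numerosities.extend(baseline)

    rows = []
    t = p.initial_rest_ms
    idx = 0
    for n in epoch_numerosities:
        for _ in range(p.repeats_per_numerosity):
            flag = bool(rng.uniform() < p.oddball_rate)
            rows.append(
                {
                    "onset_ms": t,
                    "duration_ms": p.present_ms,
                    "label": f"num{n}",
                    "numerosity": float(n),
                    "display_ref": f"dots_n{n}_ev{idx:04d}",
                    "attention_flag": flag,
                }
            )
            t += p.cycle_ms
            idx += 1
    events = pd.DataFrame(rows, columns=_EVENT_COLUMNS)
    return Timeline(
        events=events,
        design="localizer_sweep",
        total_duration_ms=t,
        tr_ms=p.tr_ms,
        seed=seed,
    )


@dataclass(frozen=True)
class BlockParams:
    """Six-category block protocol parameters (durations in ms)."""

    categories: tuple[str, ...] = CATEGORIES
    repeats_per_category: int = 2
    events_per_block: int = 30
    on_ms: int = 300
    off_ms: int = 200
    rest_ms: int = 15000
    initial_rest_ms: int = 12000
    final_rest_ms: int = 12000
    tr_ms: int = 1500

    @property
    def block_ms(self) -> int:
        return self.events_per_block * (self.on_ms + self.off_ms)


def default_category_pools(seed: int = 0) -> dict[str, pd.DataFrame]:
    """Default stimulus pools, one table (display_id, numerosity) per category.

    The three natural-image categories follow the five fixture pools
    (93 one-object, 95 two-object, 70 three-object images; 70 high-
    numerosity; 61 scenery, numerosity undefined).  The dot categories
    mirror them: 1-3 dots in the low pool, a constant 20, and 10-42 dots
    with counts drawn from the calibrated high-numerosity distribution.
    """
    rng = np.random.default_rng(seed)
    sizes = DEFAULT_POOL_SIZES
    pools: dict[str, pd.DataFrame] = {}

    low_counts = [1] * sizes["one"] + [2] * sizes["two"] + [3] * sizes["three"]
    pools["nat_low"] = pd.DataFrame(
        {
            "display_id": [f"nat_low_{i:04d}" for i in range(len(low_counts))],
            "numerosity": np.asarray(low_counts, dtype=float),
        }
    )
    high_counts = sample_high_numerosity_count(rng, size=sizes["high"])
    pools["nat_high"] = pd.DataFrame(
        {
            "display_id": [f"nat_high_{i:04d}" for i in range(sizes["high"])],
            "numerosity": high_counts.astype(float),
        }
    )
    pools["nat_scenery"] = pd.DataFrame(
        {
            "display_id": [f"nat_scenery_{i:04d}" for i in range(sizes["scenery"])],
            "numerosity": np.full(sizes["scenery"], np.nan),
        }
    )
    pools["dots_low"] = pd.DataFrame(
        {
            "display_id": [f"dots_low_{i:04d}" for i in range(len(low_counts))],
            "numerosity": np.asarray(low_counts, dtype=float),
        }
    )
    pools["dots_20"] = pd.DataFrame(
        {
            "display_id": [f"dots_20_{i:04d}" for i in range(sizes["high"])],
            "numerosity": np.full(sizes["high"], 20.0),
        }
    )
    dot_high = sample_high_numerosity_count(rng, size=sizes["high"])
    pools["dots_high"] = pd.DataFrame(
        {
            "display_id": [f"dots_high_{i:04d}" for i in range(sizes["high"])],
            "numerosity": dot_high.astype(float),
        }
    )
    return pools


def build_block_timeline(
    params: BlockParams | None = None,
    seed: int = 0,
    pools: dict[str, pd.DataFrame] | None = None,
) -> Timeline:
    """Build one block-design run.

    Twelve 15 s stimulus blocks (each category twice, seeded-random order),
    each a train of 30 stimuli (300 ms on, 200 ms off) drawn without
    replacement from the category pool, each block followed by 15 s of rest.
    """
    p = params if params is not None else BlockParams()
    rng = np.random.default_rng(seed)
    if pools is None:
        pools = default_category_pools(seed=int(rng.integers(2**31)))
    for cat in p.categories:
        if cat not in pools:
            raise ValueError(f"no stimulus pool for category {cat!r}")
        if len(pools[cat]) < p.events_per_block:
            raise ValueError(
                f"pool for {cat!r} has {len(pools[cat])} entries; "
                f"{p.events_per_block} needed per block"
            )

    order = list(p.categories) * p.repeats_per_category
    rng.shuffle(order)

    rows = []
    t = p.initial_rest_ms
    for cat in order:
        pool = pools[cat]
        pick = rng.choice(len(pool), size=p.events_per_block, replace=False)
        for i, j in enumerate(pick):
            rows.append(
                {
                    "onset_ms": t + i * (p.on_ms + p.off_ms),
                    "duration_ms": p.on_ms,
                    "label": cat,
                    "numerosity": float(pool["numerosity"].iloc[j]),
                    "display_ref": str(pool["display_id"].iloc[j]),
                    "attention_flag": False,
                }
            )
        t += p.block_ms + p.rest_ms
    total = p.initial_rest_ms + len(order) * (p.block_ms + p.rest_ms) + p.final_rest_ms
    events = pd.DataFrame(rows, columns=_EVENT_COLUMNS)
    return Timeline(
        events=events,
        design="category_block",
        total_duration_ms=total,
        tr_ms=p.tr_ms,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# High-numerosity count sampler
# ---------------------------------------------------------------------------

_PMF_CACHE: dict[tuple, tuple[np.ndarray, np.ndarray]] = {}


def high_numerosity_pmf(
    mean: float = HIGH_COUNT_MEAN,
    sd: float = HIGH_COUNT_SD,
    lo: int = HIGH_COUNT_RANGE[0],
    hi: int = HIGH_COUNT_RANGE[1],
) -> tuple[np.ndarray, np.ndarray]:
    """Discrete count distribution on ``lo..hi`` moment-matched to (mean, sd).

    The maximum-entropy distribution on the integer support subject to the
    first two moments, ``p_k proportional to exp(a k + b k^2)``; (a, b) are
    solved numerically so the distribution reproduces the requested mean
    and SD exactly.  (A log-normal truncated to [10, 42] cannot reach an
    SD of 8.8 at mean 19.42 — truncation caps its SD near 8.5 — so the
    moment constraints themselves pick the family.)  Returns
    (support, probabilities).
    """
    key = (round(mean, 6), round(sd, 6), lo, hi)
    if key in _PMF_CACHE:
        return _PMF_CACHE[key]
    support = np.arange(lo, hi + 1)
    k = support.astype(float)
    k0 = k - k.mean()  # centered for numerical conditioning

    def pmf_for(a: float, b: float) -> np.ndarray:
        w = np.exp(a * k0 + b * k0**2)
        return w / w.sum()

    def residuals(theta):
        p = pmf_for(*theta)
        mu = float(p @ support)
        var = float(p @ (support - mu) ** 2)
        return [mu - mean, np.sqrt(var) - sd]

    sol = least_squares(residuals, x0=[0.0, 0.0], xtol=1e-14, ftol=1e-14)
    p = pmf_for(*sol.x)
    got_mean = float(p @ support)
    got_sd = float(np.sqrt(p @ (support - got_mean) ** 2))
    if abs(got_mean - mean) > 0.05 or abs(got_sd - sd) > 0.05:
        raise RuntimeError(
            f"count-sampler calibration failed: mean {got_mean:.3f}, sd {got_sd:.3f}"
        )
    _PMF_CACHE[key] = (support, p)
    return support, p


def sample_high_numerosity_count(
    seed_or_rng: int | np.random.Generator, size: int | None = None
) -> np.ndarray | int:
    """Draw object counts for the high-numerosity category (10-42 items).

    Long-run mean 19.42 and SD 8.8, matching the annotation statistics of
    the high-numerosity image pool.
    """
    rng = (
        seed_or_rng
        if isinstance(seed_or_rng, np.random.Generator)
        else np.random.default_rng(seed_or_rng)
    )
    support, p = high_numerosity_pmf()
    draw = rng.choice(support, size=size, p=p)
    return draw if size is not None else int(draw)


# ---------------------------------------------------------------------------
# Fixture images and amplitude spectra
# ---------------------------------------------------------------------------


def synthesize_power_law_image(
    size: int = 128, exponent: float = -1.0, seed: int = 0
) -> np.ndarray:
    """Random-phase image whose Fourier amplitude follows |f|^exponent.

    exponent = -1 gives the 1/f amplitude statistics characteristic of
    natural images; 0 gives white noise.  Output is normalized to zero mean
    and unit variance.
    """
    rng = np.random.default_rng(seed)
    fx = np.fft.fftfreq(size) * size  # cycles per image
    fy = np.fft.fftfreq(size) * size
    f = np.sqrt(fx[None, :] ** 2 + fy[:, None] ** 2)
    amp = np.zeros_like(f)
    nz = f > 0
    amp[nz] = f[nz] ** exponent
    phase = rng.uniform(0, 2 * np.pi, size=(size, size))
    spectrum = amp * np.exp(1j * phase)
    img = np.real(np.fft.ifft2(spectrum))
    img -= img.mean()
    sd = img.std()
    if sd > 0:
        img /= sd
    return img


def synthesize_fixture_image(
    n_objects: int,
    size: int = 128,
    seed: int = 0,
    *,
    blob_sigma_frac: float = 0.03,
    blob_contrast: float = 0.3,
) -> np.ndarray:
    """Synthetic "natural image": 1/f background plus ``n_objects`` blobs.

    Objects are Gaussian-profile high-contrast blobs at random positions
    (scenery fixtures use ``n_objects = 0`` and are background texture
    only).  Blob contrast is kept modest so the composite image preserves
    the 1/f amplitude-spectrum statistics of the background.
    """
    if n_objects < 0:
        raise ValueError("n_objects must be >= 0")
    rng = np.random.default_rng(seed)
    img = synthesize_power_law_image(size=size, exponent=-1.0, seed=int(rng.integers(2**31)))
    if n_objects:
        sig = blob_sigma_frac * size
        margin = int(np.ceil(2 * sig))
        coords = np.arange(size)
        xx, yy = np.meshgrid(coords, coords)
        for _ in range(n_objects):
            cx = rng.uniform(margin, size - margin)
            cy = rng.uniform(margin, size - margin)
            sign = 1.0 if rng.uniform() < 0.5 else -1.0
            img = img + sign * blob_contrast * np.exp(
                -((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * sig**2)
            )
    return img


@dataclass(frozen=True)
class PoolSpec:
    """Sizes and geometry of the fixture-image pools."""

    sizes: dict = field(
        default_factory=lambda: dict(DEFAULT_POOL_SIZES)
    )
    image_px: int = 128


@dataclass
class PoolManifest:
    """Per-image records of the generated fixture pools."""

    records: pd.DataFrame  # image_id, pool, category, n_objects, path
    spec: PoolSpec
    seed: int

    def pool_sizes(self) -> dict[str, int]:
        return self.records.groupby("pool").size().to_dict()

    def to_json(self, path: str | Path) -> None:
        payload = {
            "seed": self.seed,
            "image_px": self.spec.image_px,
            "records": self.records.to_dict(orient="records"),
        }
        Path(path).write_text(json.dumps(payload, indent=1))


_POOL_TO_CATEGORY = {
    "one": "nat_low",
    "two": "nat_low",
    "three": "nat_low",
    "high": "nat_high",
    "scenery": "nat_scenery",
}
_POOL_COUNTS = {"one": 1, "two": 2, "three": 3}


def generate_fixture_pool(
    spec: PoolSpec | None = None,
    seed: int = 0,
    out_dir: str | Path | None = None,
    overwrite: bool = False,
) -> PoolManifest:
    """Generate the five fixture pools and their object-count manifest.

    With ``out_dir`` set, each image is written as an 8-bit grayscale PNG
    and the manifest as ``manifest.json``; otherwise only the manifest is
    materialized (images can be re-synthesized from their recorded seeds via
    :func:`synthesize_fixture_image`).
    """
    spec = spec if spec is not None else PoolSpec()
    rng = np.random.default_rng(seed)
    rows = []
    for pool, n_images in spec.sizes.items():
        category = _POOL_TO_CATEGORY.get(pool, pool)
        for i in range(int(n_images)):
            if pool in _POOL_COUNTS:
                count = _POOL_COUNTS[pool]
            elif pool == "high":
                count = int(sample_high_numerosity_count(rng))
            else:
                count = 0
            rows.append(
                {
                    "image_id": f"{pool}_{i:04d}",
                    "pool": pool,
                    "category": category,
                    "n_objects": count,
                    "image_seed": int(rng.integers(2**31)),
                    "path": "",
                }
            )
    records = pd.DataFrame(
        rows, columns=["image_id", "pool", "category", "n_objects", "image_seed", "path"]
    )

    if out_dir is not None:
        from PIL import Image

        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        manifest_path = out_dir / "manifest.json"
        if manifest_path.exists() and not overwrite:
            raise FileExistsError(f"{manifest_path} exists (pass overwrite=True)")
        for idx, rec in records.iterrows():
            img = synthesize_fixture_image(
                rec["n_objects"], size=spec.image_px, seed=rec["image_seed"]
            )
            lo, hi = img.min(), img.max()
            byte = np.zeros_like(img) if hi == lo else (img - lo) / (hi - lo)
            path = out_dir / f"{rec['image_id']}.png"
            if path.exists() and not overwrite:
                raise FileExistsError(f"{path} exists (pass overwrite=True)")
            Image.fromarray((byte * 255).astype(np.uint8), mode="L").save(path)
            records.at[idx, "path"] = str(path)

    manifest = PoolManifest(records=records, spec=spec, seed=seed)
    high = records.loc[records["pool"] == "high", "n_objects"]
    if len(high) and not high.between(*HIGH_COUNT_RANGE).all():
        raise RuntimeError("high-numerosity annotation outside 10-42")
    if out_dir is not None:
        manifest.to_json(Path(out_dir) / "manifest.json")
    return manifest


@dataclass(frozen=True)
class SpectrumProfile:
    """Radially averaged amplitude spectrum with a log-log power-law fit."""

    frequencies: np.ndarray  # cycles/image, bin centers (geometric)
    amplitudes: np.ndarray
    slope: float
    slope_se: float


def amplitude_spectrum(
    image: np.ndarray, n_bins: int = 16, f_min: float = 2.0
) -> SpectrumProfile:
    """Radially averaged Fourier amplitude and its log-log slope.

    A slope near -1 is the 1/f amplitude distribution of natural images;
    white noise gives a slope near 0.  Frequencies are in cycles per image;
    the DC component is excluded and amplitudes are averaged within
    log-spaced radial bins before the least-squares line fit.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2 or img.shape[0] != img.shape[1]:
        raise ValueError("image must be square")
    size = img.shape[0]
    if size < 64:
        raise ValueError("image side must be at least 64 px")
    if np.ptp(img) == 0:
        raise ValueError("constant image has no amplitude spectrum")

    F = np.fft.fft2(img - img.mean())
    amp = np.abs(F)
    fx = np.fft.fftfreq(size) * size
    f = np.sqrt(fx[None, :] ** 2 + fx[:, None] ** 2)

    nyquist = size / 2.0
    edges = np.geomspace(f_min, nyquist, n_bins + 1)
    freqs, amps = [], []
    for a, b in zip(edges[:-1], edges[1:]):
        m = (f >= a) & (f < b)
        if m.any():
            freqs.append(np.sqrt(a * b))
            amps.append(amp[m].mean())
    freqs = np.asarray(freqs)
    amps = np.asarray(amps)
    if len(freqs) < 8:
        raise ValueError("need at least 8 populated frequency bins for the fit")
    fit = linregress(np.log10(freqs), np.log10(amps))
    return SpectrumProfile(
        frequencies=freqs,
        amplitudes=amps,
        slope=float(fit.slope),
        slope_se=float(fit.stderr),
    )
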
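"""Synthetic single-worm fluorescence microscopy with aging-dependent spots.

The generator emulates the statistical structure the staging method relies
on, without attempting photorealism:

* bright, roughly circular fluorescent protein spots (isotropic Gaussian
  profiles, "radius" = 2 sigma) on a dim, smooth worm-tissue background;
* a spot count whose expectation grows linearly with relative age
  (``base_spot_count + spot_count_slope * relative_age``), reflecting the
  progressive accumulation of aggregated metastable protein with age;
* spot centers drawn around a fixed set of aggregation nuclei whose spread
  shrinks linearly with relative age (aggregation modes are shared across
  individuals; only the rate differs);
* Gaussian read noise plus Poisson shot noise whose photon budget scales
  with the exposure time (1/20, 1/40 or 1/80 s), so shorter exposures give
  lower SNR.

Everything is driven by a single seed: identical config + seed reproduces
bit-identical images and manifests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage

from wormstage import staging

REFERENCE_EXPOSURE = 1.0 / 20.0  # s; photon budget is defined at this exposure
VALID_EXPOSURES = (1.0 / 20.0, 1.0 / 40.0, 1.0 / 80.0)

MANIFEST_COLUMNS = [
    "individual_id",
    "day",
    "lifespan",
    "stage_fine",
    "stage_group",
    "exposure",
    "path",
]


@dataclass(frozen=True)
class NoiseModel:
    """Read + shot noise. ``poisson_scale`` is the photon count per unit
    intensity at the reference exposure of 1/20 s; 0 disables shot noise."""

    gaussian_sd: float = 0.01
    poisson_scale: float = 400.0


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic microscope.

    Spot geometry is specified at the native ``image_height x image_width``
    scale; use :meth:`scaled` to move every length-scale coherently to a
    different resolution. The spot-count law and its parameters are a
    synthetic stand-in — the real count-versus-age relationship of the
    luciferase reporter is not quantified anywhere; only its monotone
    trend is emulated.
    """

    image_height: int = 512
    image_width: int = 512
    background_level: float = 0.08
    tissue_amplitude: float = 0.10
    spot_intensity_range: tuple[float, float] = (0.45, 0.85)
    spot_radius_range: tuple[float, float] = (3.0, 7.0)
    base_spot_count: int = 5
    spot_count_slope: float = 20.0
    n_cluster_nuclei: int = 4
    cluster_base_spread: float = 0.25  # fraction of min(H, W)
    cluster_tightness: float = 0.7  # fractional spread shrink at age 1
    noise_model: NoiseModel = field(default_factory=NoiseModel)
    exposure_label: float = 1.0 / 40.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_height < 64 or self.image_width < 64:
            raise ValueError("image dimensions must be >= 64")
        lo, hi = self.spot_intensity_range
        if not (self.background_level < lo <= hi <= 1.0):
            raise ValueError(
                "spot intensities must lie in (background_level, 1], got "
                f"{self.spot_intensity_range}"
            )
        r_lo, r_hi = self.spot_radius_range
        if not 1.0 <= r_lo <= r_hi:
            raise ValueError(f"spot radii must satisfy 1 <= r_min <= r_max, got {self.spot_radius_range}")
        if self.base_spot_count < 0 or self.spot_count_slope < 0:
            raise ValueError("spot count law parameters must be non-negative")
        if not 0.0 <= self.cluster_tightness <= 1.0:
            raise ValueError("cluster_tightness must be in [0, 1]")
        if not any(math.isclose(self.exposure_label, e) for e in VALID_EXPOSURES):
            raise ValueError(
                f"exposure_label {self.exposure_label} not one of 1/20, 1/40, 1/80 s"
            )

    def scaled(self, factor: float) -> "SimulationConfig":
        """Return a config with all pixel length-scales multiplied by
        ``factor`` (areas implicitly by ``factor**2``)."""
        r_lo, r_hi = self.spot_radius_range
        return replace(
            self,
            image_height=int(round(self.image_height * factor)),
            image_width=int(round(self.image_width * factor)),
            spot_radius_range=(max(1.0, r_lo * factor), max(1.0, r_hi * factor)),
        )


@dataclass(frozen=True)
class WormImage:
    """A single-channel micrograph with its acquisition metadata."""

    pixels: np.ndarray  # H x W float in [0, 1]
    individual_id: str
    day: int
    lifespan: int
    exposure_label: float

    def __post_init__(self) -> None:
        if self.day > self.lifespan:
            raise ValueError("day exceeds lifespan")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("non-finite pixel intensities")
        if self.pixels.min() < 0 or self.pixels.max() > 1:
            raise ValueError("pixel intensities outside [0, 1]")


@dataclass(frozen=True)
class GroundTruth:
    """True spot parameters and stage labels recorded before noise."""

    spots: list[tuple[float, float, float]]  # (x=col, y=row, r) in pixels
    stage_fine: int
    stage_group: int


@dataclass(frozen=True)
class LifespanLaw:
    """Lifespan sampling law for a cohort; the default matches 20 degC
    culture, where isogenic lifespans range from 10 to 30 days."""

    min_days: int = 10
    max_days: int = 30
    distribution: str = "uniform"

    def sample(self, rng: np.random.Generator) -> int:
        if self.min_days < 1 or self.max_days < self.min_days:
            raise ValueError("invalid lifespan law bounds")
        if self.distribution != "uniform":
            raise ValueError(f"unknown lifespan distribution {self.distribution!r}")
        return int(rng.integers(self.min_days, self.max_days + 1))


def _tissue_background(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Smooth low-frequency worm-body signal: heavily blurred white noise,
    rescaled to [0, tissue_amplitude]."""
    h, w = config.image_height, config.image_width
    field_ = rng.standard_normal((h, w))
    sigma = min(h, w) / 8.0
    field_ = ndimage.gaussian_filter(field_, sigma, mode="reflect")
    span = field_.max() - field_.min()
    if span <= 0:
        return np.zeros((h, w))
    return (field_ - field_.min()) / span * config.tissue_amplitude


def _render_spot(
    image: np.ndarray, x: float, y: float, r: float, amplitude: float
) -> None:
    """Add an isotropic Gaussian spot (radius = 2 sigma) in place."""
    sigma = r / 2.0
    half = int(math.ceil(4 * sigma))
    h, w = image.shape
    r0, r1 = max(0, int(y) - half), min(h, int(y) + half + 1)
    c0, c1 = max(0, int(x) - half), min(w, int(x) + half + 1)
    if r0 >= r1 or c0 >= c1:
        return
    yy, xx = np.mgrid[r0:r1, c0:c1]
    image[r0:r1, c0:c1] += amplitude * np.exp(
        -((xx - x) ** 2 + (yy - y) ** 2) / (2 * sigma**2)
    )


def _apply_noise(
    clean: np.ndarray, config: SimulationConfig, rng: np.random.Generator
) -> np.ndarray:
    noisy = clean
    nm = config.noise_model
    if nm.poisson_scale > 0:
        photons_per_unit = nm.poisson_scale * config.exposure_label / REFERENCE_EXPOSURE
        noisy = rng.poisson(np.clip(noisy, 0, None) * photons_per_unit) / photons_per_unit
    if nm.gaussian_sd > 0:
        noisy = noisy + rng.normal(0.0, nm.gaussian_sd, size=noisy.shape)
    return np.clip(noisy, 0.0, 1.0)


def generate_worm_image(
    config: SimulationConfig,
    relative_age: float,
    rng: np.random.Generator | None = None,
    individual_id: str = "synthetic",
    day: int | None = None,
    lifespan: int | None = None,
) -> tuple[WormImage, GroundTruth]:
    """Generate one labeled synthetic micrograph at a given relative age.

    The number of spots is Poisson with mean
    ``base_spot_count + spot_count_slope * relative_age``; centers are drawn
    around ``n_cluster_nuclei`` fixed nuclei with Gaussian spread
    ``cluster_base_spread * min(H, W) * (1 - cluster_tightness * relative_age)``.
    Ground truth (spot list + stage labels) is recorded before noise.

    When ``day``/``lifespan`` are omitted they are synthesized from
    ``relative_age`` against a nominal 100-day lifespan so stage labels stay
    consistent with the staging rules.
    """
    if not 0.0 <= relative_age <= 1.0:
        raise ValueError(f"relative_age {relative_age} outside [0, 1]")
    if rng is None:
        rng = np.random.default_rng(config.seed)

    h, w = config.image_height, config.image_width
    clean = np.full((h, w), config.background_level, dtype=float)
    clean += _tissue_background(config, rng)

    mean_count = config.base_spot_count + config.spot_count_slope * relative_age
    n_spots = int(rng.poisson(mean_count)) if mean_count > 0 else 0

    margin = config.spot_radius_range[1]
    nuclei = np.column_stack(
        [
            rng.uniform(margin, w - margin, size=config.n_cluster_nuclei),
            rng.uniform(margin, h - margin, size=config.n_cluster_nuclei),
        ]
    )
    spread = (
        config.cluster_base_spread
        * min(h, w)
        * (1.0 - config.cluster_tightness * relative_age)
    )
    spread = max(spread, 1.0)

    spots: list[tuple[float, float, float]] = []
    for _ in range(n_spots):
        k = int(rng.integers(config.n_cluster_nuclei))
        x = float(np.clip(nuclei[k, 0] + rng.normal(0, spread), margin, w - 1 - margin))
        y = float(np.clip(nuclei[k, 1] + rng.normal(0, spread), margin, h - 1 - margin))
        r = float(rng.uniform(*config.spot_radius_range))
        amplitude = float(rng.uniform(*config.spot_intensity_range)) - config.background_level
        _render_spot(clean, x, y, r, amplitude)
        spots.append((x, y, r))

    pixels = _apply_noise(np.clip(clean, 0.0, 1.0), config, rng)

    if lifespan is None:
        lifespan = 100
    if day is None:
        day = int(round(relative_age * lifespan))
    label = staging.stage_label(day, lifespan)

    image = WormImage(
        pixels=pixels,
        individual_id=individual_id,
        day=day,
        lifespan=lifespan,
        exposure_label=config.exposure_label,
    )
    truth = GroundTruth(spots=spots, stage_fine=label.fine, stage_group=label.group)
    return image, truth


@dataclass
class Cohort:
    """A generated cohort: manifest plus (optionally in-memory) images."""

    manifest: pd.DataFrame
    images: list[WormImage]
    truths: list[GroundTruth]


def generate_cohort(
    config: SimulationConfig,
    n_individuals: int,
    lifespan_law: LifespanLaw | None = None,
    out_dir: str | Path | None = None,
    keep_in_memory: bool = True,
) -> Cohort:
    """Generate a full cohort: one image per day from day 1 to lifespan.

    Each individual draws a lifespan from ``lifespan_law`` (uniform 10–30
    days by default). If ``out_dir`` is given, images are written as 16-bit
    single-channel TIFFs and a ``manifest.csv`` is written alongside; the
    manifest rows carry individual id, day, lifespan, stage labels, exposure
    and file path.
    """
    if n_individuals < 1:
        raise ValueError(f"n_individuals must be >= 1, got {n_individuals}")
    law = lifespan_law or LifespanLaw()
    root = np.random.SeedSequence(config.seed)
    lifespans_rng = np.random.default_rng(root.spawn(1)[0])

    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)
        (out_path / "images").mkdir(exist_ok=True)

    rows: list[dict] = []
    images: list[WormImage] = []
    truths: list[GroundTruth] = []
    for idx in range(n_individuals):
        individual_id = f"worm{idx:03d}"
        lifespan = law.sample(lifespans_rng)
        for day in range(1, lifespan + 1):
            child = np.random.SeedSequence(
                entropy=config.seed, spawn_key=(idx, day)
            )
            rng = np.random.default_rng(child)
            image, truth = generate_worm_image(
                config,
                relative_age=day / lifespan,
                rng=rng,
                individual_id=individual_id,
                day=day,
                lifespan=lifespan,
            )
            rel_path = f"images/{individual_id}_d{day:02d}.tif"
            if out_path is not None:
                tifffile.imwrite(
                    out_path / rel_path,
                    np.round(image.pixels * 65535).astype(np.uint16),
                )
            rows.append(
                {
                    "individual_id": individual_id,
                    "day": day,
                    "lifespan": lifespan,
                    "stage_fine": truth.stage_fine,
                    "stage_group": truth.stage_group,
                    "exposure": config.exposure_label,
                    "path": rel_path if out_path is not None else "",
                }
            )
            if keep_in_memory:
                images.append(image)
                truths.append(truth)

    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    if out_path is not None:
        manifest.to_csv(out_path / "manifest.csv", index=False)
    return Cohort(manifest=manifest, images=images, truths=truths)


def resolvable_spots(
    spots: Sequence[tuple[float, float, float]]
) -> list[tuple[float, float, float]]:
    """Merge rendered spots that are optically one aggregate.

    Two Gaussian spots whose centers are closer than the sum of their
    profile sigmas (``(r_i + r_j) / 2`` with radius = 2 sigma) render as a
    single bright blob with one intensity maximum; no local-extrema
    detector can count them separately. Validating detection against this
    merged list measures detector quality rather than an identifiability
    limit of overlapping profiles. Merged entries take the
    intensity-weighted (area-proportional) mean center and the larger
    radius.
    """
    merged = [list(s) for s in spots]
    changed = True
    while changed:
        changed = False
        for i in range(len(merged)):
            for j in range(i + 1, len(merged)):
                x1, y1, r1 = merged[i]
                x2, y2, r2 = merged[j]
                if math.hypot(x1 - x2, y1 - y2) < (r1 + r2) / 2.0:
                    w1, w2 = r1**2, r2**2
                    merged[i] = [
                        (x1 * w1 + x2 * w2) / (w1 + w2),
                        (y1 * w1 + y2 * w2) / (w1 + w2),
                        max(r1, r2),
                    ]
                    del merged[j]
                    changed = True
                    break
            if changed:
                break
    return [tuple(s) for s in merged]


def match_spots(
    true_spots: Sequence[tuple[float, float, float]],
    detected: Sequence[tuple[float, float, float]],
    max_dist: float = 6.0,
) -> tuple[int, int, int]:
    """Greedy one-to-one matching of detected spots to ground truth.

    A detection matches an unused true spot if their centers are within
    ``max_dist`` pixels. Returns ``(tp, fp, fn)``.
    """
    from scipy.optimize import linear_sum_assignment

    if not true_spots or not detected:
        return 0, len(detected), len(true_spots)
    t = np.asarray([(s[0], s[1]) for s in true_spots], dtype=float)
    d = np.asarray([(s[0], s[1]) for s in detected], dtype=float)
    cost = np.linalg.norm(t[:, None, :] - d[None, :, :], axis=2)
    rows, cols = linear_sum_assignment(cost)
    tp = int(np.sum(cost[rows, cols] <= max_dist))
    return tp, len(detected) - tp, len(true_spots) - tp
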
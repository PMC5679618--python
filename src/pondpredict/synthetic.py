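"""Synthetic scenes and pond series with known truth.

The scene generator lays archetype spectra (green, nir, mir triplets per
cover class) on a truth-label grid and adds Gaussian reflectance noise; the
series generator samples a smooth seasonal curve at a fixed revisit cadence
with multiplicative year effects, additive noise, dry truncation and random
cloud loss.  Everything is bit-reproducible under a fixed seed.

Defaults emulate a Landsat-5/7-like record: 16-day revisit, 30 m pixels,
27-year span, ~50% of observations lost to cloud.
"""

from __future__ import annotations

import datetime as _dt
import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .errors import ConfigurationError, InputError
from .raster_io import CLOUD, SALT, SOIL, WATER, Scene
from .timeseries import PondSeries
from .water_detection import ClassifiedScene, PondObservation, classify_pixel

#: Archetype reflectance (green, nir, mir) per cover class; each sits well
#: clear of both classification thresholds.
DEFAULT_ARCHETYPES = {
    WATER: (0.30, 0.10, 0.10),
    SALT: (0.35, 0.60, 0.15),
    SOIL: (0.15, 0.30, 0.35),
}


@dataclass
class SceneTruth:
    """Ground truth for one synthetic scene."""

    truth_labels: np.ndarray
    archetypes: dict[int, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_ARCHETYPES)
    )
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.truth_labels = np.asarray(self.truth_labels)
        present = set(np.unique(self.truth_labels).tolist())
        if not present <= {SOIL, SALT, WATER, CLOUD}:
            raise InputError("truth labels must lie in {0,1,2,3}")
        for label, (g, n, m) in self.archetypes.items():
            if label == CLOUD:
                continue
            got = classify_pixel(g, n, m, cloud=False)
            if got != label:
                raise ConfigurationError(
                    f"archetype for label {label} classifies as {got}, not itself"
                )


def generate_scene(truth: SceneTruth, scene_id: str = "synthetic",
                   date: _dt.date = _dt.date(2000, 6, 15),
                   pixel_area: float = 900.0) -> tuple[Scene, ClassifiedScene]:
    """Render a Scene from truth labels; returns (scene, truth classification)."""
    rng = np.random.default_rng(truth.seed)
    shape = truth.truth_labels.shape
    green = np.zeros(shape)
    nir = np.zeros(shape)
    mir = np.zeros(shape)
    for label, (g, n, m) in truth.archetypes.items():
        where = truth.truth_labels == label
        green[where], nir[where], mir[where] = g, n, m
    if truth.noise_sd > 0:
        green = green + rng.normal(0.0, truth.noise_sd, shape)
        nir = nir + rng.normal(0.0, truth.noise_sd, shape)
        mir = mir + rng.normal(0.0, truth.noise_sd, shape)
    green, nir, mir = (np.clip(a, 0.0, 1.0) for a in (green, nir, mir))
    cloud = truth.truth_labels == CLOUD
    scene = Scene(scene_id=scene_id, date=date, green=green, nir=nir, mir=mir,
                  cloud=cloud, pixel_area=pixel_area)
    truth_classified = ClassifiedScene(
        scene_id=scene_id, date=date,
        labels=truth.truth_labels.astype(np.uint8), pixel_area=pixel_area,
    )
    return scene, truth_classified


def cosine_seasonal(amplitude: float = 0.8, peak_doy: float = 15.0) -> Callable[[float], float]:
    """Smooth non-negative seasonal curve of expected normalized area."""
    def curve(doy: float) -> float:
        return max(0.0, 1.0 + amplitude * math.cos(2 * math.pi * (doy - peak_doy) / 365.25))
    return curve


@dataclass
class SeriesTruth:
    """Generating process for one pond's area time series.

    Observed normalized area: A' = max(0, seasonal(doy) * year_effect + eps),
    zeroed below ``dry_threshold``; area = A' * mean_area.  Cloud loss is
    all-or-nothing by default (cloud_fraction 1 with probability
    ``cloud_prob``); ``partial_clouds`` draws cloud_fraction ~ U(0, 1)
    instead, to exercise the state-interval exclusion rule.

    ``availability`` thins the nominal revisit cadence: each 16-day slot
    yields a scene with that probability, so the defaults (27 years, 0.7
    availability, 0.5 cloud) produce roughly 430 scenes and ~215 cloud-free
    observations per pond, matching a two-satellite archive with gaps.
    """

    pond_id: int = 1
    mean_area: float = 10_000.0
    seasonal: Callable[[float], float] | None = None
    noise_sd: float = 0.2
    dry_threshold: float = 0.0
    inter_annual_sd: float = 0.0
    revisit_days: int = 16
    availability: float = 0.7
    cloud_prob: float = 0.5
    years: int = 27
    start_year: int = 1984
    partial_clouds: bool = False
    capacity_factor: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.cloud_prob < 1.0:
            raise InputError("cloud_prob must lie in [0, 1)")
        if not 0.0 < self.availability <= 1.0:
            raise InputError("availability must lie in (0, 1]")
        if self.mean_area <= 0 or self.revisit_days < 1 or self.years < 1:
            raise InputError("mean_area, revisit_days and years must be positive")

    def seasonal_value(self, doy: float) -> float:
        curve = self.seasonal or cosine_seasonal()
        value = curve(doy)
        if value < 0:
            raise ConfigurationError("seasonal curve must be non-negative")
        return value


def generate_pond_series(truth: SeriesTruth) -> PondSeries:
    """Sample one pond series from its generating process."""
    rng = np.random.default_rng(truth.seed)
    start = _dt.date(truth.start_year, 1, 1)
    end = _dt.date(truth.start_year + truth.years, 1, 1)
    capacity = truth.capacity_factor * truth.mean_area
    year_effects: dict[int, float] = {}
    observations = []
    date = start
    while date < end:
        if truth.availability < 1.0 and rng.random() >= truth.availability:
            date += _dt.timedelta(days=truth.revisit_days)
            continue
        year = date.year
        if year not in year_effects:
            year_effects[year] = (
                math.exp(rng.normal(0.0, truth.inter_annual_sd))
                if truth.inter_annual_sd > 0 else 1.0
            )
        doy = date.timetuple().tm_yday
        eps = rng.normal(0.0, truth.noise_sd) if truth.noise_sd > 0 else 0.0
        aprime = max(0.0, truth.seasonal_value(doy) * year_effects[year] + eps)
        if aprime < truth.dry_threshold:
            aprime = 0.0
        true_area = aprime * truth.mean_area

        if truth.partial_clouds:
            clouded = rng.random() < truth.cloud_prob
            cf = float(rng.random()) if clouded else 0.0
        else:
            cf = 1.0 if rng.random() < truth.cloud_prob else 0.0
        if cf == 0.0:
            area = area_max = true_area
        else:
            area = (1.0 - cf) * true_area
            area_max = area + cf * max(capacity, true_area)
        observations.append(
            PondObservation(truth.pond_id, date, area, area_max, cf)
        )
        date += _dt.timedelta(days=truth.revisit_days)
    return PondSeries(truth.pond_id, observations)
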
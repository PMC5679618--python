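"""Two-condition water/salt pixel classification and pond-area extraction.

A pixel is a water candidate when its MNDWI, (green - mir)/(green + mir), is
strictly positive; candidates with NIR reflectance >= ``nir_salt_cut``
(default 0.4) are reclassified as salt crust.  Cloud pixels stay cloud.

Per-pond areas carry an interval [area, area_max]: clouds inside the pond are
counted as non-water in ``area`` and as potentially water in ``area_max``, so
downstream state assignment can tell whether cloud cover could change the
outcome.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass

import numpy as np

from .errors import InputError
from .raster_io import CLOUD, SALT, SOIL, WATER, PondMask, Scene

#: Sentinel MNDWI for zero total reflectance: treated as non-water.
MNDWI_UNDEFINED = -2.0

#: Default NIR reflectance at and above which a water candidate is salt crust.
NIR_SALT_CUT = 0.4


@dataclass
class ClassifiedScene:
    """Per-pixel nominal labels {0 soil, 1 salt, 2 water, 3 cloud} for one date."""

    scene_id: str
    date: _dt.date
    labels: np.ndarray
    pixel_area: float = 900.0

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.size and not np.isin(self.labels, (SOIL, SALT, WATER, CLOUD)).all():
            raise InputError("classified labels must lie in {0,1,2,3}")


@dataclass(frozen=True)
class PondObservation:
    """One pond x one date area record with cloud-uncertainty bounds (m^2)."""

    pond_id: int
    date: _dt.date
    area: float
    area_max: float
    cloud_fraction: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.area <= self.area_max + 1e-9:
            raise InputError(
                f"pond {self.pond_id} {self.date}: need 0 <= area <= area_max, "
                f"got {self.area} / {self.area_max}"
            )
        if not 0.0 <= self.cloud_fraction <= 1.0:
            raise InputError("cloud_fraction must lie in [0, 1]")
        if self.cloud_fraction == 0.0 and self.area != self.area_max:
            raise InputError("cloud-free observation must have area == area_max")


def mndwi(green, mir):
    """Modified Normalized Difference Water Index, (green - mir)/(green + mir).

    Accepts scalars or arrays.  Zero total reflectance maps to the
    :data:`MNDWI_UNDEFINED` sentinel (classified non-water downstream).
    """
    green = np.asarray(green, dtype=np.float64)
    mir = np.asarray(mir, dtype=np.float64)
    if np.any(green < 0) or np.any(mir < 0):
        raise InputError("reflectance must be non-negative")
    total = green + mir
    with np.errstate(divide="ignore", invalid="ignore"):
        index = np.where(total > 0, (green - mir) / np.where(total > 0, total, 1.0), MNDWI_UNDEFINED)
    if index.ndim == 0:
        return float(index)
    return index


def classify_pixel(green: float, nir: float, mir: float, cloud: bool = False,
                   nir_salt_cut: float = NIR_SALT_CUT) -> int:
    """Classify one pixel: cloud > soil (MNDWI <= 0) > salt (NIR >= cut) > water.

    The salt filter only applies to pixels that already pass the MNDWI
    condition; a dark-NIR pixel with MNDWI <= 0 is soil, never salt.
    """
    if cloud:
        return CLOUD
    if nir < 0:
        raise InputError("reflectance must be non-negative")
    if mndwi(green, mir) <= 0:
        return SOIL
    if nir >= nir_salt_cut:
        return SALT
    return WATER


def classify_scene(scene: Scene, nir_salt_cut: float = NIR_SALT_CUT) -> ClassifiedScene:
    """Vectorized elementwise classification of a whole scene."""
    index = mndwi(scene.green, scene.mir)
    if np.any(scene.nir < 0):
        raise InputError("reflectance must be non-negative")
    labels = np.full(scene.shape, SOIL, dtype=np.uint8)
    candidate = np.asarray(index) > 0
    labels[candidate & (scene.nir >= nir_salt_cut)] = SALT
    labels[candidate & (scene.nir < nir_salt_cut)] = WATER
    labels[scene.cloud] = CLOUD
    return ClassifiedScene(
        scene_id=scene.scene_id, date=scene.date, labels=labels, pixel_area=scene.pixel_area
    )


def pond_area(classified: ClassifiedScene, mask: PondMask, pond_id: int,
              pixel_area: float | None = None) -> PondObservation:
    """Water-surface area of one pond in one classified scene.

    ``area`` counts water pixels only; ``area_max`` additionally counts cloud
    pixels (they could hide water).
    """
    if pond_id not in mask.pond_ids:
        raise InputError(f"unknown pond id {pond_id}")
    mask.check_aligned(classified.labels.shape)
    if pixel_area is None:
        pixel_area = classified.pixel_area
    inside = mask.labels == pond_id
    n_pixels = int(inside.sum())
    n_water = int(np.count_nonzero(classified.labels[inside] == WATER))
    n_cloud = int(np.count_nonzero(classified.labels[inside] == CLOUD))
    return PondObservation(
        pond_id=pond_id,
        date=classified.date,
        area=n_water * pixel_area,
        area_max=(n_water + n_cloud) * pixel_area,
        cloud_fraction=n_cloud / n_pixels,
    )


def pond_areas(classified: ClassifiedScene, mask: PondMask,
               pixel_area: float | None = None) -> list[PondObservation]:
    """`pond_area` for every pond in the mask."""
    if not mask.pond_ids:
        raise InputError("pond mask holds no ponds; nothing to extract")
    return [pond_area(classified, mask, pid, pixel_area) for pid in mask.pond_ids]


def water_frequency_map(stack: list[ClassifiedScene], mask: PondMask | None = None) -> np.ndarray:
    """Per-pixel fraction of non-cloud scenes in which the pixel is water.

    Pixels that are cloud in every scene (or outside ``mask`` when given) are
    NaN.  Order of scenes is irrelevant.
    """
    if not stack:
        raise InputError("empty scene stack")
    shape = stack[0].labels.shape
    water = np.zeros(shape, dtype=np.int64)
    usable = np.zeros(shape, dtype=np.int64)
    for scene in stack:
        if scene.labels.shape != shape:
            raise InputError("scene stack shapes differ")
        water += scene.labels == WATER
        usable += scene.labels != CLOUD
    with np.errstate(invalid="ignore"):
        freq = np.where(usable > 0, water / np.maximum(usable, 1), np.nan)
    if mask is not None:
        mask.check_aligned(shape)
        freq = np.where(mask.labels > 0, freq, np.nan)
    return freq
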
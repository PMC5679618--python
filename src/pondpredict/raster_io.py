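"""Reading and writing dated multiband reflectance rasters and label grids.

Rasters are stored as GeoTIFF (via :mod:`tifffile`) with the standard
``ModelPixelScale``/``ModelTiepoint`` geo-tags so products open in common GIS
readers.  Reflectance is kept as float in [0, 1]; integer-scaled archives
(e.g. reflectance x 10,000) are converted on read through ``scale``.

Label palette for classified scenes: 0 soil, 1 salt, 2 water, 3 cloud.
"""

from __future__ import annotations

import csv
import datetime as _dt
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

from .errors import AlignmentError, ConfigurationError, InputError

# Classified-scene palette (single-band uint8 GeoTIFF).
SOIL = 0
SALT = 1
WATER = 2
CLOUD = 3

LABEL_NAMES = {SOIL: "soil", SALT: "salt", WATER: "water", CLOUD: "cloud"}

# GeoTIFF tag ids.
_MODEL_PIXEL_SCALE = 33550
_MODEL_TIEPOINT = 33922

#: Default pixel footprint: 30 m x 30 m.
DEFAULT_PIXEL_AREA = 900.0

_REQUIRED_BANDS = ("green", "nir", "mir")


@dataclass
class Scene:
    """One dated multiband surface-reflectance raster with a cloud mask.

    ``cloud`` is the single "unusable" channel: genuine cloud, nodata and
    out-of-range pixels are all flagged here and never un-flagged downstream.
    """

    scene_id: str
    date: _dt.date
    green: np.ndarray
    nir: np.ndarray
    mir: np.ndarray
    cloud: np.ndarray
    pixel_area: float = DEFAULT_PIXEL_AREA
    geotransform: tuple[float, float, float, float, float, float] | None = None

    def __post_init__(self) -> None:
        shapes = {np.shape(self.green), np.shape(self.nir), np.shape(self.mir), np.shape(self.cloud)}
        if len(shapes) != 1:
            raise InputError(f"scene {self.scene_id}: band/cloud shapes differ: {shapes}")
        if self.pixel_area <= 0:
            raise InputError(f"scene {self.scene_id}: pixel_area must be > 0")
        if not isinstance(self.date, _dt.date):
            raise InputError(f"scene {self.scene_id}: date must be a datetime.date")
        self.cloud = np.asarray(self.cloud, dtype=bool)

    @property
    def shape(self) -> tuple[int, int]:
        return self.green.shape

    @property
    def day_of_year(self) -> int:
        return self.date.timetuple().tm_yday


@dataclass
class PondMask:
    """Integer label grid: 0 background, k > 0 identifies pond k."""

    labels: np.ndarray
    pond_ids: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise InputError("pond mask must hold integer labels")
        present = sorted(int(v) for v in np.unique(self.labels) if v > 0)
        if not self.pond_ids:
            self.pond_ids = present
        else:
            missing = set(self.pond_ids) - set(present)
            if missing:
                raise InputError(f"pond ids {sorted(missing)} absent from label grid")

    def check_aligned(self, shape: tuple[int, int]) -> None:
        if self.labels.shape != tuple(shape):
            raise AlignmentError(
                f"pond mask shape {self.labels.shape} does not match scene shape {tuple(shape)}"
            )


def parse_date(value) -> _dt.date:
    """Coerce an ISO-8601 string (or date) to :class:`datetime.date`."""
    if isinstance(value, _dt.datetime):
        return value.date()
    if isinstance(value, _dt.date):
        return value
    try:
        return _dt.date.fromisoformat(str(value).strip())
    except ValueError as exc:
        raise InputError(f"cannot parse date {value!r} (expected ISO-8601)") from exc


def _geotags(geotransform):
    """Build tifffile extratags carrying a GDAL-style geotransform."""
    x0, px, _, y0, _, py = geotransform
    scale = (abs(px), abs(py), 0.0)
    tiepoint = (0.0, 0.0, 0.0, x0, y0, 0.0)
    return [
        (_MODEL_PIXEL_SCALE, "d", 3, scale, True),
        (_MODEL_TIEPOINT, "d", 6, tiepoint, True),
    ]


def _read_geotransform(page) -> tuple | None:
    scale = page.tags.get(_MODEL_PIXEL_SCALE)
    tie = page.tags.get(_MODEL_TIEPOINT)
    if scale is None or tie is None:
        return None
    sx, sy = scale.value[0], scale.value[1]
    _, _, _, x0, y0, _ = tie.value[:6]
    return (float(x0), float(sx), 0.0, float(y0), 0.0, -float(sy))


def read_scene(
    path,
    band_map: dict[str, int],
    date,
    *,
    scene_id: str | None = None,
    scale: float = 1.0,
    nodata: float | None = None,
    cloud_path=None,
) -> Scene:
    """Read a multiband GeoTIFF into a :class:`Scene`.

    Parameters
    ----------
    band_map
        Maps the semantic names ``green``, ``nir``, ``mir`` (and optionally
        ``cloud``) to 1-based band indices in the file.
    scale
        Multiplicative factor applied on read (e.g. 1e-4 for x10,000 archives).
    nodata
        Sentinel value; matching pixels are flagged unusable (cloud).
    cloud_path
        Optional sidecar single-band raster; nonzero means cloud.
    """
    for name in _REQUIRED_BANDS:
        if name not in band_map:
            raise ConfigurationError(f"band_map lacks required band {name!r}")
    path = Path(path)
    try:
        with tifffile.TiffFile(path) as tif:
            arr = tif.asarray()
            geotransform = _read_geotransform(tif.pages[0])
    except (OSError, tifffile.TiffFileError) as exc:
        raise InputError(f"cannot read raster {path}: {exc}") from exc
    arr = _as_band_stack(arr)
    n_bands = arr.shape[0]
    bands = {}
    for name, idx in band_map.items():
        if not 1 <= idx <= n_bands:
            raise ConfigurationError(
                f"band_map[{name!r}] = {idx} outside file's 1..{n_bands} bands"
            )
        bands[name] = arr[idx - 1].astype(np.float64)

    cloud = np.zeros(bands["green"].shape, dtype=bool)
    if "cloud" in bands:
        cloud |= bands["cloud"] != 0
    if cloud_path is not None:
        sidecar = _as_band_stack(tifffile.imread(cloud_path))[0]
        if sidecar.shape != cloud.shape:
            raise AlignmentError("cloud mask shape does not match scene")
        cloud |= sidecar != 0

    grids = {}
    for name in _REQUIRED_BANDS:
        grid = bands[name]
        if nodata is not None:
            cloud |= grid == nodata
        cloud |= ~np.isfinite(grid)
        grid = grid * scale
        # Out-of-range reflectance is unusable, like nodata.
        cloud |= (grid < 0) | (grid > 1)
        grids[name] = grid

    pixel_area = DEFAULT_PIXEL_AREA
    if geotransform is not None:
        pixel_area = abs(geotransform[1] * geotransform[5])
    return Scene(
        scene_id=scene_id or path.stem,
        date=parse_date(date),
        green=grids["green"],
        nir=grids["nir"],
        mir=grids["mir"],
        cloud=cloud,
        pixel_area=pixel_area,
        geotransform=geotransform,
    )


def _as_band_stack(arr: np.ndarray) -> np.ndarray:
    """Normalize a tifffile array to (band, row, col)."""
    if arr.ndim == 2:
        return arr[None]
    if arr.ndim != 3:
        raise InputError(f"unsupported raster dimensionality {arr.ndim}")
    # Pages-first is our writer's layout; samples-last comes from other tools.
    if arr.shape[0] <= 16 < arr.shape[-1]:
        return arr
    if arr.shape[-1] <= 16 < arr.shape[0]:
        return np.moveaxis(arr, -1, 0)
    return arr


def write_scene(scene: Scene, path) -> None:
    """Write a Scene as a 4-band float32 GeoTIFF (green, nir, mir, cloud)."""
    stack = np.stack(
        [scene.green, scene.nir, scene.mir, scene.cloud.astype(np.float32)]
    ).astype(np.float32)
    extratags = _geotags(scene.geotransform) if scene.geotransform else []
    tifffile.imwrite(path, stack, photometric="minisblack", extratags=extratags)


def read_pond_mask(path) -> PondMask:
    """Read an integer pond-label raster."""
    try:
        arr = _as_band_stack(tifffile.imread(path))[0]
    except (OSError, tifffile.TiffFileError) as exc:
        raise InputError(f"cannot read pond mask {path}: {exc}") from exc
    if not np.issubdtype(arr.dtype, np.integer):
        if not np.all(arr == np.round(arr)):
            raise InputError("pond mask raster holds non-integer values")
        arr = arr.astype(np.int32)
    return PondMask(labels=arr)


def write_pond_mask(mask: PondMask, path) -> None:
    tifffile.imwrite(path, mask.labels.astype(np.int32))


def write_labels(labels, path, geotransform=None) -> None:
    """Write a classified-label grid as single-band uint8 GeoTIFF.

    Palette: 0 soil, 1 salt, 2 water, 3 cloud.  Accepts either a bare array
    or any object with a ``labels`` attribute (a ClassifiedScene).
    """
    grid = np.asarray(getattr(labels, "labels", labels))
    if grid.size and (grid.min() < SOIL or grid.max() > CLOUD):
        raise InputError("label values must lie in 0..3 (soil/salt/water/cloud)")
    extratags = _geotags(geotransform) if geotransform else []
    tifffile.imwrite(path, grid.astype(np.uint8), extratags=extratags)


def read_labels(path) -> np.ndarray:
    grid = _as_band_stack(tifffile.imread(path))[0]
    if grid.size and (grid.min() < SOIL or grid.max() > CLOUD):
        raise InputError("label raster holds values outside 0..3")
    return grid.astype(np.uint8)


def read_manifest(path) -> list[dict]:
    """Read a scene manifest CSV with columns scene_id, path, date.

    Relative raster paths are resolved against the manifest's directory.
    """
    path = Path(path)
    rows = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"scene_id", "path", "date"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise InputError(f"manifest {path} must have columns {sorted(required)}")
        for rec in reader:
            raster = Path(rec["path"])
            if not raster.is_absolute():
                raster = path.parent / raster
            rows.append(
                {
                    "scene_id": rec["scene_id"],
                    "path": raster,
                    "date": parse_date(rec["date"]),
                }
            )
    return rows
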
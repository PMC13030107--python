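"""Snapshot multispectral-filter-array (MSFA) image handling.

A snapshot multispectral camera overlays a repeating 5 x 5 tile of narrowband
filters on the sensor, so one exposure interleaves 25 spectral bands in a
single mosaiced frame.  Demosaicing here is pure per-tile subsampling (no
interpolation): each of the 25 tile positions is read out into one band plane,
producing a ``rows x cols x 25`` hypercube.  A dark-reference hypercube
(acquired with the shutter closed / illumination off) is subtracted band-wise
to remove the sensor offset, and mean spectra are extracted from polygonal
regions of interest on leaves.

Coordinate convention: arrays are indexed ``(row, col)`` = ``(y, x)``,
0-based.  The camera's stated offsets of 0 along x and 3 along y map to
column-offset 0 and row-offset 3; a 2048 x 1088 frame (2048 wide, 1088 tall)
then demosaics to a 217 x 409 x 25 cube, i.e. 409 x 217 spatial pixels in
(x, y) order.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import tifffile

__all__ = [
    "MosaicFrame",
    "Hypercube",
    "RoiPolygon",
    "default_layout",
    "demosaic",
    "dark_correct",
    "extract_roi_spectrum",
    "pot_spectrum",
    "points_in_polygon",
    "read_mosaic_tiff",
    "write_mosaic_tiff",
    "read_envi",
    "write_envi",
]

PATTERN = 5
N_BANDS = PATTERN * PATTERN


def default_layout(pattern: int = PATTERN) -> np.ndarray:
    """Row-major band-to-tile-position map.

    Returns an ``(n_bands, 2)`` integer array where row ``b`` holds the
    ``(tile_row, tile_col)`` of band ``b``.  The vendor's true layout is not
    public; any fixed bijection yields an equivalent pipeline because the
    mosaic and demosaic operations share the map.
    """
    n = pattern * pattern
    return np.stack([np.arange(n) // pattern, np.arange(n) % pattern], axis=1)


def _check_layout(layout: np.ndarray, pattern: int) -> np.ndarray:
    layout = np.asarray(layout, dtype=int)
    n = pattern * pattern
    if layout.shape != (n, 2):
        raise ValueError(f"layout must be ({n}, 2), got {layout.shape}")
    flat = layout[:, 0] * pattern + layout[:, 1]
    if (layout < 0).any() or (layout >= pattern).any() or len(set(flat.tolist())) != n:
        raise ValueError("layout is not a bijection over the tile positions")
    return layout


@dataclass
class MosaicFrame:
    """Single-channel mosaiced sensor frame.

    ``values`` is an ``H x W`` nonnegative intensity array; ``bit_depth``
    gives the sensor maximum ``2**bit_depth - 1``.
    """

    values: np.ndarray
    bit_depth: int = 16

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("mosaic frame must be 2-D")
        if (self.values < 0).any():
            raise ValueError("mosaic frame intensities must be nonnegative")
        if self.values.max(initial=0) > 2**self.bit_depth - 1:
            raise ValueError("frame exceeds sensor maximum")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class Hypercube:
    """``rows x cols x bands`` spectral image with band-center wavelengths.

    ``kind`` tracks provenance: ``raw`` (demosaiced), ``dark`` (dark
    reference) or ``corrected`` (dark-subtracted).
    """

    values: np.ndarray
    wavelengths: np.ndarray
    kind: str = "raw"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("hypercube must be 3-D (rows, cols, bands)")
        if self.values.shape[2] != self.wavelengths.size:
            raise ValueError("band count does not match wavelength vector")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if self.kind not in ("raw", "dark", "corrected"):
            raise ValueError(f"unknown cube kind {self.kind!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def n_bands(self) -> int:
        return self.values.shape[2]


@dataclass
class RoiPolygon:
    """Closed polygon in pixel coordinates (implicitly closed last-to-first)."""

    vertices: np.ndarray  # (n, 2) as (row, col)
    label: int | None = None

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2:
            raise ValueError("vertices must be an (n, 2) array of (row, col)")
        if len(self.vertices) < 3:
            raise ValueError("a polygon needs at least 3 vertices")


def demosaic(
    frame: MosaicFrame,
    pattern: int = PATTERN,
    offset_x: int = 0,
    offset_y: int = 3,
    layout: np.ndarray | None = None,
    wavelengths: np.ndarray | None = None,
    kind: str = "raw",
) -> Hypercube:
    """Subsample a mosaiced frame into a hypercube.

    Band ``b`` at spatial cell ``(i, j)`` is read from frame position
    ``(offset_y + pattern*i + r_b, offset_x + pattern*j + c_b)`` where
    ``(r_b, c_b) = layout[b]``.  Output spatial dims are
    ``floor((H - offset_y)/pattern) x floor((W - offset_x)/pattern)``;
    incomplete edge tiles are discarded.
    """
    if not (0 <= offset_x < pattern and 0 <= offset_y < pattern):
        raise ValueError("offsets must lie in [0, pattern)")
    layout = default_layout(pattern) if layout is None else _check_layout(layout, pattern)
    H, W = frame.shape
    rows = (H - offset_y) // pattern
    cols = (W - offset_x) // pattern
    if rows < 1 or cols < 1:
        raise ValueError("frame smaller than one full tile after offsets")
    n = pattern * pattern
    cube = np.empty((rows, cols, n), dtype=float)
    for b, (r, c) in enumerate(layout):
        cube[:, :, b] = frame.values[
            offset_y + r : offset_y + r + rows * pattern : pattern,
            offset_x + c : offset_x + c + cols * pattern : pattern,
        ]
    if wavelengths is None:
        from .synthetic_data import default_wavelengths

        wavelengths = default_wavelengths(n)
    return Hypercube(cube, wavelengths, kind=kind)


def dark_correct(raw: Hypercube, dark: Hypercube, floor: float = 0.0) -> Hypercube:
    """Subtract the dark reference band-wise: corrected = raw - dark.

    Values below ``floor`` (default 0; fluorescence intensity is physically
    nonnegative) are clipped up to ``floor``.
    """
    if raw.kind != "raw" or dark.kind != "dark":
        raise ValueError("expected a raw cube and a dark cube")
    if raw.shape != dark.shape:
        raise ValueError(f"dimension mismatch: {raw.shape} vs {dark.shape}")
    if not np.array_equal(raw.wavelengths, dark.wavelengths):
        raise ValueError("wavelength vectors differ between raw and dark cubes")
    corrected = np.maximum(raw.values - dark.values, floor)
    return Hypercube(corrected, raw.wavelengths, kind="corrected")


def points_in_polygon(points: np.ndarray, vertices: np.ndarray) -> np.ndarray:
    """Even-odd rule point-in-polygon test, vectorized over points.

    ``points`` is ``(m, 2)`` and ``vertices`` ``(n, 2)``, both ``(row, col)``.
    A point is inside if a ray cast in +col direction crosses the boundary an
    odd number of times.  The even-odd rule is order-invariant (clockwise vs
    counterclockwise) and well defined for self-intersecting polygons.
    """
    pts = np.asarray(points, dtype=float)
    v = np.asarray(vertices, dtype=float)
    y, x = pts[:, 0][:, None], pts[:, 1][:, None]
    y1, x1 = v[:, 0][None, :], v[:, 1][None, :]
    y2, x2 = np.roll(v[:, 0], -1)[None, :], np.roll(v[:, 1], -1)[None, :]
    crosses = (y1 > y) != (y2 > y)
    with np.errstate(divide="ignore", invalid="ignore"):
        x_at_y = x1 + (y - y1) / (y2 - y1) * (x2 - x1)
    hits = crosses & (x < x_at_y)
    return hits.sum(axis=1) % 2 == 1


def polygon_mask(shape: tuple[int, int], vertices: np.ndarray) -> np.ndarray:
    """Boolean mask of pixels whose centers fall inside the polygon."""
    rr, cc = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")
    pts = np.stack([rr.ravel(), cc.ravel()], axis=1)
    return points_in_polygon(pts, vertices).reshape(shape)


def extract_roi_spectrum(cube: Hypercube, roi: RoiPolygon) -> np.ndarray:
    """Mean spectrum over pixels whose centers fall inside the ROI polygon."""
    if cube.kind != "corrected":
        raise ValueError("ROI extraction expects a dark-corrected cube")
    mask = polygon_mask(cube.shape[:2], roi.vertices)
    if not mask.any():
        raise ValueError("polygon encloses no pixel centers")
    return cube.values[mask].mean(axis=0)


def pot_spectrum(roi_spectra: list[np.ndarray] | np.ndarray) -> np.ndarray:
    """Average several leaf-ROI spectra into one pot-level representative."""
    spectra = np.asarray(roi_spectra, dtype=float)
    if spectra.size == 0:
        raise ValueError("need at least one ROI spectrum")
    return np.atleast_2d(spectra).mean(axis=0)


# ---------------------------------------------------------------------------
# I/O: 16-bit TIFF mosaic frames; ENVI band-sequential hypercubes.


def write_mosaic_tiff(path: str | os.PathLike, frame: MosaicFrame) -> None:
    tifffile.imwrite(path, frame.values.astype(np.uint16))


def read_mosaic_tiff(path: str | os.PathLike, bit_depth: int = 16) -> MosaicFrame:
    return MosaicFrame(tifffile.imread(path).astype(float), bit_depth=bit_depth)


def write_envi(path_base: str | os.PathLike, cube: Hypercube) -> None:
    """Write a hypercube as ENVI band-sequential (.bsq) with a text header."""
    base = os.fspath(path_base)
    rows, cols, bands = cube.shape
    # BSQ stores complete band planes one after another
    np.ascontiguousarray(np.moveaxis(cube.values, 2, 0), dtype=np.float32).tofile(
        base + ".bsq"
    )
    wl = ", ".join(f"{w:.3f}" for w in cube.wavelengths)
    header = (
        "ENVI\n"
        f"description = {{fluorocold {cube.kind} hypercube}}\n"
        f"samples = {cols}\n"
        f"lines = {rows}\n"
        f"bands = {bands}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        "data type = 4\n"
        "interleave = bsq\n"
        "byte order = 0\n"
        f"wavelength units = nm\n"
        f"wavelength = {{{wl}}}\n"
    )
    with open(base + ".hdr", "w") as fh:
        fh.write(header)


def read_envi(path_base: str | os.PathLike, kind: str = "raw") -> Hypercube:
    base = os.fspath(path_base)
    fields: dict[str, str] = {}
    with open(base + ".hdr") as fh:
        text = fh.read()
    for line in text.replace("{", " ").replace("}", " ").splitlines():
        if "=" in line:
            key, _, val = line.partition("=")
            fields[key.strip()] = val.strip()
    rows, cols, bands = int(fields["lines"]), int(fields["samples"]), int(fields["bands"])
    wavelengths = np.array([float(w) for w in fields["wavelength"].split(",") if w.strip()])
    data = np.fromfile(base + ".bsq", dtype=np.float32).reshape(bands, rows, cols)
    return Hypercube(np.moveaxis(data, 0, 2).astype(float), wavelengths, kind=kind)
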
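"""Raster and ROI-annotation I/O plus polygon rasterization.

Coordinate convention used throughout the package: 0-based pixel indices,
x rightward and y downward, and polygon containment decided at pixel
*centers* ``(col + 0.5, row + 0.5)``.  With this convention an axis-aligned
rectangle with integer corners ``(x0, y0)-(x1, y1)`` covers exactly
``(x1 - x0) * (y1 - y0)`` pixels (half-open behaviour falls out of the
center test, no special casing needed).

Annotations travel as GeoJSON (RFC 7946) FeatureCollections; each feature
is a ``Polygon`` with a required ``role`` property naming how the region is
used downstream:

``cortex``
    inclusion region (the manually outlined cortical section),
``exclusion``
    regions deleted from the evaluation (glomeruli, medium arteries),
``ref_positive`` / ``ref_negative``
    operator reference patches of Sirius-Red-positive collagen and
    negative (counterstained) tissue used for per-slide calibration.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import shapely
from PIL import Image
from shapely.geometry import Polygon as ShapelyPolygon

from .errors import (
    EmptySelectionError,
    InputError,
    PreconditionError,
    SchemaError,
    UnsupportedFormatError,
)

VALID_ROLES = frozenset({"cortex", "exclusion", "ref_positive", "ref_negative"})

# TIFF 6.0 ResolutionUnit tag values
_RES_UNIT_INCH = 2
_RES_UNIT_CM = 3
_MICRONS_PER_INCH = 25400.0
_MICRONS_PER_CM = 10000.0


@dataclass
class RasterImage:
    """8-bit RGB section raster with optional physical resolution.

    Attributes
    ----------
    pixels:
        ``(H, W, 3)`` uint8 array.
    microns_per_pixel:
        Physical pixel pitch if known (from TIFF resolution tags), else None.
    slide_id:
        Free-text identifier carried through results.
    """

    pixels: np.ndarray
    microns_per_pixel: float | None = None
    slide_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise PreconditionError(
                f"RasterImage requires an (H, W, 3) array, got {self.pixels.shape}"
            )
        if self.pixels.dtype != np.uint8:
            raise PreconditionError("RasterImage pixels must be 8-bit (uint8)")
        if self.pixels.shape[0] < 1 or self.pixels.shape[1] < 1:
            raise PreconditionError("image must contain at least one pixel")
        if self.microns_per_pixel is not None and not self.microns_per_pixel > 0:
            raise PreconditionError("microns_per_pixel must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        """(H, W) of the raster."""
        return self.pixels.shape[0], self.pixels.shape[1]


@dataclass
class RoiPolygon:
    """A single region-of-interest ring in pixel coordinates.

    Vertices are ``(x, y)`` pairs; the ring is implicitly closed (the first
    vertex follows the last).  At least three vertices and a non-zero
    enclosed area are required.
    """

    vertices: Sequence[tuple[float, float]]
    role: str
    label: str | None = None

    def __post_init__(self) -> None:
        self.vertices = [(float(x), float(y)) for x, y in self.vertices]
        if len(self.vertices) < 3:
            raise SchemaError(
                f"polygon needs at least 3 vertices, got {len(self.vertices)}"
            )
        if self.role not in VALID_ROLES:
            raise SchemaError(
                f"unknown role {self.role!r}; expected one of {sorted(VALID_ROLES)}"
            )
        if self.shapely().area <= 0:
            raise SchemaError("polygon encloses zero area")

    def shapely(self) -> ShapelyPolygon:
        """Shapely geometry of the (closed) ring, repaired if self-touching."""
        poly = ShapelyPolygon(self.vertices)
        if not poly.is_valid:
            poly = shapely.make_valid(poly)
        return poly


@dataclass
class AnnotationSet:
    """All ROI polygons for one slide."""

    slide_id: str = ""
    polygons: list[RoiPolygon] = field(default_factory=list)

    def by_role(self, role: str) -> list[RoiPolygon]:
        return [p for p in self.polygons if p.role == role]


@dataclass
class LabelMask:
    """Boolean evaluation-region raster (union of cortex minus exclusions)."""

    grid: np.ndarray
    provenance: str = ""

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=bool)

    @property
    def n_set(self) -> int:
        return int(self.grid.sum())


def read_image(path: str | Path) -> RasterImage:
    """Read a PNG or TIFF file as an 8-bit RGB :class:`RasterImage`.

    An alpha channel is dropped.  Non-RGB content (16-bit, grayscale,
    palette) raises :class:`UnsupportedFormatError`.  TIFF resolution tags,
    when present, populate ``microns_per_pixel``.
    """
    path = Path(path)
    try:
        with Image.open(path) as im:
            mode = im.mode
            if mode == "RGBA":
                pixels = np.asarray(im)[:, :, :3]
            elif mode == "RGB":
                pixels = np.asarray(im)
            else:
                raise UnsupportedFormatError(
                    f"{path}: mode {mode!r} is not 8-bit RGB"
                )
            mpp = _microns_per_pixel_from_tags(im)
    except UnsupportedFormatError:
        raise
    except FileNotFoundError as exc:
        raise InputError(f"image file not found: {path}") from exc
    except Exception as exc:  # undecodable / truncated
        raise InputError(f"could not read image {path}: {exc}") from exc
    return RasterImage(
        pixels=np.ascontiguousarray(pixels, dtype=np.uint8),
        microns_per_pixel=mpp,
        slide_id=path.stem,
    )


def _microns_per_pixel_from_tags(im: Image.Image) -> float | None:
    tags = getattr(im, "tag_v2", None)
    if tags is None:
        return None
    xres = tags.get(282)  # XResolution
    unit = tags.get(296, _RES_UNIT_INCH)  # ResolutionUnit, default inch
    if not xres:
        return None
    xres = float(xres)
    if xres <= 0:
        return None
    if unit == _RES_UNIT_CM:
        return _MICRONS_PER_CM / xres
    if unit == _RES_UNIT_INCH:
        return _MICRONS_PER_INCH / xres
    return None


def write_image(image: RasterImage, path: str | Path) -> None:
    """Write the raster as PNG or TIFF (chosen by extension)."""
    Image.fromarray(image.pixels, mode="RGB").save(Path(path))


def read_annotations(path: str | Path) -> AnnotationSet:
    """Load an :class:`AnnotationSet` from a GeoJSON FeatureCollection."""
    path = Path(path)
    try:
        with open(path) as fh:
            doc = json.load(fh)
    except FileNotFoundError as exc:
        raise InputError(f"annotation file not found: {path}") from exc
    except json.JSONDecodeError as exc:
        raise SchemaError(f"{path} is not valid JSON: {exc}") from exc

    if doc.get("type") != "FeatureCollection":
        raise SchemaError(f"{path}: expected a GeoJSON FeatureCollection")
    polygons: list[RoiPolygon] = []
    for i, feat in enumerate(doc.get("features", [])):
        geom = feat.get("geometry") or {}
        if geom.get("type") != "Polygon":
            raise SchemaError(f"feature {i}: geometry type must be Polygon")
        props = feat.get("properties") or {}
        role = props.get("role")
        if role not in VALID_ROLES:
            raise SchemaError(
                f"feature {i}: missing or invalid 'role' property ({role!r})"
            )
        rings = geom.get("coordinates") or []
        if not rings:
            raise SchemaError(f"feature {i}: polygon has no rings")
        ring = [(float(x), float(y)) for x, y in rings[0]]
        # GeoJSON rings repeat the first vertex at the end; our model closes
        # implicitly.
        if len(ring) >= 2 and ring[0] == ring[-1]:
            ring = ring[:-1]
        try:
            polygons.append(
                RoiPolygon(vertices=ring, role=role, label=props.get("label"))
            )
        except SchemaError as exc:
            raise SchemaError(f"feature {i}: {exc}") from exc
    return AnnotationSet(slide_id=str(doc.get("name", "")), polygons=polygons)


def write_annotations(annotations: AnnotationSet, path: str | Path) -> None:
    """Write an :class:`AnnotationSet` as a GeoJSON FeatureCollection.

    Round trips through :func:`read_annotations` preserve roles, labels and
    vertex order.
    """
    features = []
    for poly in annotations.polygons:
        ring = list(poly.vertices) + [poly.vertices[0]]
        props: dict = {"role": poly.role}
        if poly.label is not None:
            props["label"] = poly.label
        features.append(
            {
                "type": "Feature",
                "geometry": {
                    "type": "Polygon",
                    "coordinates": [[list(v) for v in ring]],
                },
                "properties": props,
            }
        )
    doc = {
        "type": "FeatureCollection",
        "name": annotations.slide_id,
        "features": features,
    }
    try:
        with open(path, "w") as fh:
            json.dump(doc, fh)
    except OSError as exc:
        raise InputError(f"cannot write annotations to {path}: {exc}") from exc


def _polygon_union_mask(
    polygons: Iterable[RoiPolygon], height: int, width: int
) -> np.ndarray:
    """Boolean mask of pixels whose centers lie inside the polygon union."""
    geoms = [p.shapely() for p in polygons]
    mask = np.zeros((height, width), dtype=bool)
    if not geoms:
        return mask
    union = shapely.union_all(geoms)
    minx, miny, maxx, maxy = union.bounds
    c0 = max(int(np.floor(minx - 0.5)), 0)
    c1 = min(int(np.ceil(maxx + 0.5)), width)
    r0 = max(int(np.floor(miny - 0.5)), 0)
    r1 = min(int(np.ceil(maxy + 0.5)), height)
    if c0 >= c1 or r0 >= r1:
        return mask
    cols = np.arange(c0, c1) + 0.5
    rows = np.arange(r0, r1) + 0.5
    xs, ys = np.meshgrid(cols, rows)
    inside = shapely.contains_xy(union, xs.ravel(), ys.ravel())
    mask[r0:r1, c0:c1] = inside.reshape(r1 - r0, c1 - c0)
    return mask


def rasterize(annotations: AnnotationSet, height: int, width: int) -> LabelMask:
    """Rasterize cortex-minus-exclusion polygons into the evaluation mask.

    The mask is 1 exactly on ``(union of cortex) minus (union of exclusion)``
    tested at pixel centers; reference patches never affect it.  Overlapping
    polygons of the same role are unioned; exclusion wins over cortex,
    mirroring the operator workflow of selecting the cortical section and
    then deleting glomeruli and arteries from it.
    """
    cortex = annotations.by_role("cortex")
    if not cortex:
        raise PreconditionError(
            "rasterize requires at least one cortex polygon"
        )
    mask = _polygon_union_mask(cortex, height, width)
    exclusions = annotations.by_role("exclusion")
    if exclusions:
        mask &= ~_polygon_union_mask(exclusions, height, width)
    return LabelMask(grid=mask, provenance=f"slide={annotations.slide_id}")


def extract_pixels(
    image: RasterImage, polygons: Sequence[RoiPolygon]
) -> np.ndarray:
    """RGB values of all pixels whose centers fall in the polygon union.

    Returns an ``(N, 3)`` uint8 array in row-major scan order.  Raises
    :class:`EmptySelectionError` when the union misses every pixel center
    (e.g. a degenerate sliver drawn between centers).
    """
    if not polygons:
        raise PreconditionError("extract_pixels requires at least one polygon")
    h, w = image.shape
    mask = _polygon_union_mask(polygons, h, w)
    if not mask.any():
        raise EmptySelectionError(
            "polygon selection covers no pixel centers"
        )
    return image.pixels[mask]
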
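"""Geometric primitives for bone-segment phantoms.

Each skeletal segment is approximated by one of six shapes: box, (elliptic)
cylinder, deformed cylinder (two parallel elliptic bases of different axes
joined by a ruled surface; a truncated cone is a special case), isosceles
triangular prism, ellipsoid, and tube (the wall between two coaxial circular
cylinders).  The module provides closed-form volumes, center-sampled
voxelization onto an isotropic grid, and face-selective cortical shells grown
inward so that the printed dimensions are outer dimensions.

Coordinate convention: grid axis x spans the ``a`` dimension, y spans ``b``,
z spans ``h``.  Labels: 0 background, 1 marrow, 2 trabecular bone,
3 cortical bone.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

BACKGROUND, MARROW, TRABECULAR, CORTICAL = 0, 1, 2, 3

SHAPE_KINDS = ("box", "cylinder", "deformed_cylinder", "prism", "ellipsoid", "tube")

#: valid cortical face identifiers per shape kind (suffixes 1/2 pick one face
#: of a parallel pair; the bare id covers both).  Curved shapes use "lateral";
#: the whole ellipsoid surface is "total".
FACE_SETS: dict[str, tuple[str, ...]] = {
    "box": ("ha", "ha1", "ha2", "hb", "hb1", "hb2", "ab", "ab1", "ab2"),
    "cylinder": ("lateral", "ab", "ab1", "ab2"),
    "deformed_cylinder": ("lateral",),
    "prism": ("ah", "ah1", "bh", "bh1", "ch", "ch1", "abb", "abb1", "abb2"),
    "ellipsoid": ("total",),
    "tube": ("lateral", "ab", "ab1", "ab2"),
}


class ShapeError(ValueError):
    """Invalid shape specification (non-positive or inconsistent dimensions)."""


class CorticalError(ValueError):
    """Cortical specification invalid or consuming the whole interior."""


@dataclass(frozen=True)
class ShapeSpec:
    """One geometric primitive with outer dimensions in mm.

    Dimension meaning by kind:

    - box: h x a x b (height x length x width)
    - cylinder: h, a, b = height, major axis, minor axis of the elliptic base
    - deformed_cylinder: h, lower base axes (a, b), upper base axes (c, d)
    - prism: h, a = triangular base length, b = equal side length
    - ellipsoid: h, a, b = the three axes
    - tube: h, a = outer diameter, b = inner diameter
    """

    kind: str
    h: float
    a: float
    b: float
    c: float | None = None
    d: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in SHAPE_KINDS:
            raise ShapeError(f"unknown shape kind {self.kind!r}")
        for name in ("h", "a", "b"):
            v = getattr(self, name)
            if not (v is not None and np.isfinite(v) and v > 0):
                raise ShapeError(f"{self.kind}: dimension {name}={v!r} must be > 0")
        if self.kind == "deformed_cylinder":
            if self.c is None or self.d is None or self.c <= 0 or self.d <= 0:
                raise ShapeError("deformed_cylinder requires positive c and d (upper base axes)")
        elif self.c is not None or self.d is not None:
            raise ShapeError(f"{self.kind} does not take c/d dimensions")
        if self.kind == "tube" and self.a <= self.b:
            raise ShapeError(f"tube requires outer diameter a > inner diameter b (a={self.a}, b={self.b})")
        if self.kind == "prism" and self.b <= self.a / 2:
            raise ShapeError(f"prism triangle does not exist: b={self.b} <= a/2={self.a / 2}")

    # -- analytic geometry -------------------------------------------------

    @property
    def extents(self) -> tuple[float, float, float]:
        """Axis-aligned bounding extents (x, y, z) in mm."""
        if self.kind == "deformed_cylinder":
            return (max(self.a, self.c), max(self.b, self.d), self.h)
        if self.kind == "prism":
            return (self.a, _prism_apex(self.a, self.b), self.h)
        if self.kind == "tube":
            return (self.a, self.a, self.h)
        return (self.a, self.b, self.h)

    def volume(self) -> float:
        """Closed-form volume in mm^3."""
        h, a, b = self.h, self.a, self.b
        if self.kind == "box":
            return h * a * b
        if self.kind == "cylinder":
            return math.pi * h * a * b / 4.0
        if self.kind == "deformed_cylinder":
            c, d = self.c, self.d
            return math.pi * h / 24.0 * (2 * a * b + 2 * c * d + a * d + c * b)
        if self.kind == "prism":
            return h * (a / 2.0) * _prism_apex(a, b)
        if self.kind == "ellipsoid":
            return math.pi / 6.0 * h * a * b
        if self.kind == "tube":
            return math.pi * h / 4.0 * (a * a - b * b)
        raise AssertionError(self.kind)

    def face_area(self, face: str) -> float:
        """Outer area (mm^2) of one cortical face (a bare pair id gives one face)."""
        base = face.rstrip("12")
        h, a, b = self.h, self.a, self.b
        if self.kind == "box":
            return {"ha": h * a, "hb": h * b, "ab": a * b}[base]
        if self.kind == "cylinder":
            if base == "lateral":
                return _ellipse_perimeter(a / 2, b / 2) * h
            return math.pi * a * b / 4.0
        if self.kind == "deformed_cylinder":
            # ruled surface; integrate the slice perimeter numerically
            t = np.linspace(0.0, 1.0, 65)
            per = np.array(
                [_ellipse_perimeter((a + (self.c - a) * ti) / 2, (b + (self.d - b) * ti) / 2) for ti in t]
            )
            return float(np.trapezoid(per, t) * h)
        if self.kind == "prism":
            s = _prism_apex(a, b)
            return {"ah": a * h, "bh": b * h, "ch": b * h, "abb": a * s / 2.0}[base]
        if self.kind == "ellipsoid":
            # Thomsen approximation for the full surface
            p = 1.6075
            x, y, z = a / 2, b / 2, h / 2
            return 4 * math.pi * ((x**p * y**p + x**p * z**p + y**p * z**p) / 3) ** (1 / p)
        if self.kind == "tube":
            if base == "lateral":
                return math.pi * a * h
            return math.pi * (a * a - b * b) / 4.0
        raise AssertionError(self.kind)

    def valid_faces(self) -> tuple[str, ...]:
        return FACE_SETS[self.kind]


def _prism_apex(a: float, b: float) -> float:
    return math.sqrt(b * b - a * a / 4.0)


def _ellipse_perimeter(rx: float, ry: float) -> float:
    # Ramanujan's second approximation
    lam = (rx - ry) / (rx + ry)
    return math.pi * (rx + ry) * (1 + 3 * lam**2 / (10 + math.sqrt(4 - 3 * lam**2)))


@dataclass
class VoxelPhantom:
    """Labelled voxel raster of one segment on an isotropic grid.

    ``labels`` is indexed [ix, iy, iz] with x spanning the ``a`` dimension,
    y spanning ``b`` and z spanning ``h``; ``voxel_size`` is in mm.
    """

    labels: np.ndarray
    voxel_size: float
    meta: dict = field(default_factory=dict)

    def counts(self) -> dict[int, int]:
        vals, cnts = np.unique(self.labels, return_counts=True)
        out = {int(k): 0 for k in (BACKGROUND, MARROW, TRABECULAR, CORTICAL)}
        out.update({int(v): int(c) for v, c in zip(vals, cnts)})
        return out

    def media_volumes_mm3(self) -> dict[str, float]:
        c = self.counts()
        v = self.voxel_size**3
        return {
            "marrow": c[MARROW] * v,
            "trabecular": c[TRABECULAR] * v,
            "cortical": c[CORTICAL] * v,
            "total": (c[MARROW] + c[TRABECULAR] + c[CORTICAL]) * v,
        }


def default_voxel_size(tb_th: float, clamp: tuple[float, float] = (0.04, 0.25)) -> float:
    """Default voxel resolution: 0.7 x Tb.Th, clamped to ``clamp`` (mm)."""
    if not tb_th > 0:
        raise ShapeError(f"tb_th must be > 0, got {tb_th}")
    return float(min(max(0.7 * tb_th, clamp[0]), clamp[1]))


def _grid_coords(extent: float, voxel: float) -> np.ndarray:
    """Voxel-center coordinates covering [-extent/2, extent/2]."""
    n = max(1, int(math.ceil(extent / voxel)))
    return (np.arange(n) - (n - 1) / 2.0) * voxel


def _inside(spec: ShapeSpec, x: np.ndarray, y: np.ndarray, z: np.ndarray) -> np.ndarray:
    """Boolean interior test for broadcastable center coordinates (origin at shape center)."""
    h, a, b = spec.h, spec.a, spec.b
    if spec.kind == "box":
        return (np.abs(x) <= a / 2) & (np.abs(y) <= b / 2) & (np.abs(z) <= h / 2)
    if spec.kind == "cylinder":
        return ((2 * x / a) ** 2 + (2 * y / b) ** 2 <= 1.0) & (np.abs(z) <= h / 2)
    if spec.kind == "deformed_cylinder":
        t = np.clip(z / h + 0.5, 0.0, 1.0)
        at = a + (spec.c - a) * t
        bt = b + (spec.d - b) * t
        return ((2 * x / at) ** 2 + (2 * y / bt) ** 2 <= 1.0) & (np.abs(z) <= h / 2)
    if spec.kind == "prism":
        s = _prism_apex(a, b)
        # triangle with base on y = -s/2 (vertices (+-a/2, -s/2) and (0, +s/2))
        yy = y + s / 2
        # side edges: from (-a/2, 0) to (0, s) in the shifted frame
        return (yy >= 0) & (np.abs(z) <= h / 2) & (yy <= s * (1 - 2 * np.abs(x) / a))
    if spec.kind == "ellipsoid":
        return (2 * x / a) ** 2 + (2 * y / b) ** 2 + (2 * z / h) ** 2 <= 1.0
    if spec.kind == "tube":
        r2 = x**2 + y**2
        return (r2 <= (a / 2) ** 2) & (r2 >= (b / 2) ** 2) & (np.abs(z) <= h / 2)
    raise AssertionError(spec.kind)


def voxelize_shape(
    spec: ShapeSpec,
    voxel_size: float,
    max_voxels: int = 150_000_000,
    meta: dict | None = None,
) -> VoxelPhantom:
    """Rasterize a shape: voxels whose centers fall inside become marrow (1).

    Center-point sampling makes axis-aligned boxes exact and gives first-order
    convergence of the voxel volume to the closed form for curved shapes.
    """
    if not voxel_size > 0:
        raise ShapeError(f"voxel_size must be > 0, got {voxel_size}")
    ex, ey, ez = spec.extents
    nx, ny, nz = (max(1, int(math.ceil(e / voxel_size))) for e in (ex, ey, ez))
    if nx * ny * nz > max_voxels:
        raise MemoryError(
            f"grid {nx}x{ny}x{nz} = {nx * ny * nz} voxels exceeds the budget of {max_voxels}; "
            f"increase voxel_size (currently {voxel_size} mm)"
        )
    x = _grid_coords(ex, voxel_size)[:, None, None]
    y = _grid_coords(ey, voxel_size)[None, :, None]
    z = _grid_coords(ez, voxel_size)[None, None, :]
    labels = np.where(_inside(spec, x, y, z), MARROW, BACKGROUND).astype(np.uint8)
    m = dict(meta or {})
    m.setdefault("shape", spec.kind)
    return VoxelPhantom(labels=labels, voxel_size=float(voxel_size), meta=m)


# -- cortical shells -------------------------------------------------------


def _face_thicknesses(cortical: Mapping[str, float], spec: ShapeSpec) -> dict[str, float]:
    for face, t in cortical.items():
        if face not in spec.valid_faces():
            raise CorticalError(f"face {face!r} is not valid for shape {spec.kind!r}")
        if not t > 0:
            raise CorticalError(f"cortical thickness on {face!r} must be > 0, got {t}")
    return dict(cortical)


def _pair_sides(cortical: Mapping[str, float], base: str) -> tuple[float, float]:
    """Thickness on (low side, high side) for a planar face pair, 0 if uncovered."""
    lo = hi = 0.0
    if base in cortical:
        lo = hi = cortical[base]
    if base + "1" in cortical:
        lo = cortical[base + "1"]
    if base + "2" in cortical:
        hi = cortical[base + "2"]
    return lo, hi


def inner_dimensions(spec: ShapeSpec, cortical: Mapping[str, float]) -> ShapeSpec | None:
    """The spongiosa envelope left after growing every cortical face inward.

    Returns a new ShapeSpec for shapes whose eroded interior is again a shape
    of the same family (all six kinds here, by construction of the face
    grammar), or raises CorticalError if a shell consumes the interior.
    Prism interiors with side-face cover are not a centered isosceles prism in
    general; they are handled separately by :func:`spongiosa_volume`.
    """
    cortical = _face_thicknesses(cortical, spec)
    if not cortical:
        return spec
    h, a, b = spec.h, spec.a, spec.b
    if spec.kind == "box":
        tha = _pair_sides(cortical, "ha")  # normal to b (y)
        thb = _pair_sides(cortical, "hb")  # normal to a (x)
        tab = _pair_sides(cortical, "ab")  # normal to h (z)
        hi, ai, bi = h - sum(tab), a - sum(thb), b - sum(tha)
        _check_positive(hi, ai, bi)
        return ShapeSpec("box", hi, ai, bi)
    if spec.kind == "cylinder":
        t = cortical.get("lateral", 0.0)
        tab = _pair_sides(cortical, "ab")
        hi, ai, bi = h - sum(tab), a - 2 * t, b - 2 * t
        _check_positive(hi, ai, bi)
        return ShapeSpec("cylinder", hi, ai, bi)
    if spec.kind == "deformed_cylinder":
        t = cortical.get("lateral", 0.0)
        dims = (h, a - 2 * t, b - 2 * t, spec.c - 2 * t, spec.d - 2 * t)
        _check_positive(*dims)
        return ShapeSpec("deformed_cylinder", *dims)
    if spec.kind == "ellipsoid":
        t = cortical.get("total", 0.0)
        hi, ai, bi = h - 2 * t, a - 2 * t, b - 2 * t
        _check_positive(hi, ai, bi)
        return ShapeSpec("ellipsoid", hi, ai, bi)
    if spec.kind == "tube":
        t = cortical.get("lateral", 0.0)
        tab = _pair_sides(cortical, "ab")
        hi, ai = h - sum(tab), a - 2 * t
        _check_positive(hi, ai - b)
        return ShapeSpec("tube", hi, ai, b)
    return None  # prism: see spongiosa_volume


def _check_positive(*vals: float) -> None:
    if any(v <= 0 for v in vals):
        raise CorticalError("cortical shell consumes the whole interior (no spongiosa left)")


def _prism_inner_area(spec: ShapeSpec, cortical: Mapping[str, float]) -> float:
    """Area of the triangle cross-section after offsetting covered edges inward."""
    a, b = spec.a, spec.b
    s = _prism_apex(a, b)
    # edges in the centered frame: base y = -s/2; sides y - s/2 = +- (2s/a) x
    t_ah = cortical.get("ah", 0.0) or cortical.get("ah1", 0.0)
    t_bh = cortical.get("bh", 0.0) or cortical.get("bh1", 0.0)
    t_ch = cortical.get("ch", 0.0) or cortical.get("ch1", 0.0)
    # side constraints as y <= s/2 +- m x - t*sec, where the vertical shift
    # t*sec makes the perpendicular offset equal to t
    m = 2 * s / a
    sec = math.sqrt(1 + m * m)
    y0 = -s / 2 + t_ah
    # intersect the two side lines: y = s/2 - m|x|' shifted inward
    #   left side passes through (-a/2, -s/2): y = s/2 + m x - t_bh*sec
    #   right side:                            y = s/2 - m x - t_ch*sec
    # apex: x = (t_bh - t_ch)*sec/(2m), y = s/2 - (t_bh + t_ch)*sec/2
    xa = (t_bh - t_ch) * sec / (2 * m)
    ya = s / 2 - (t_bh + t_ch) * sec / 2
    # base intersections
    xl = (y0 - s / 2 + t_bh * sec) / m
    xr = -(y0 - s / 2 + t_ch * sec) / m
    if ya <= y0 or xr <= xl:
        raise CorticalError("cortical shell consumes the whole interior (no spongiosa left)")
    # triangle (xl, y0), (xr, y0), (xa, ya)
    return 0.5 * abs((xr - xl) * (ya - y0))


def spongiosa_volume(spec: ShapeSpec, cortical: Mapping[str, float]) -> float:
    """Closed-form volume (mm^3) of the interior left inside the cortical shell."""
    cortical = _face_thicknesses(cortical, spec)
    if spec.kind == "prism":
        tabb = _pair_sides(cortical, "abb")
        hi = spec.h - sum(tabb)
        if hi <= 0:
            raise CorticalError("cortical shell consumes the whole interior (no spongiosa left)")
        return _prism_inner_area(spec, cortical) * hi
    inner = inner_dimensions(spec, cortical)
    return inner.volume()


def apply_cortical_shell(phantom: VoxelPhantom, spec: ShapeSpec, cortical: Mapping[str, float]) -> VoxelPhantom:
    """Relabel voxels within each covered face's thickness as cortical bone.

    The shell grows inward from the outer surface; uncovered faces keep
    marrow/trabecular voxels at the surface.  The spongiosa region is exactly
    the voxelization of the eroded interior, so analytic and voxel cortical
    volumes converge together.
    """
    cortical = _face_thicknesses(cortical, spec)
    if not cortical:
        return phantom
    labels = phantom.labels
    vox = phantom.voxel_size
    nx, ny, nz = labels.shape
    ex, ey, ez = spec.extents
    x = _grid_coords(ex, vox)[:, None, None]
    y = _grid_coords(ey, vox)[None, :, None]
    z = _grid_coords(ez, vox)[None, None, :]

    if spec.kind == "prism":
        tabb = _pair_sides(cortical, "abb")
        hi = spec.h - sum(tabb)
        if hi <= 0:
            raise CorticalError("cortical shell consumes the whole interior (no spongiosa left)")
        a, b = spec.a, spec.b
        s = _prism_apex(a, b)
        m = 2 * s / a
        sec = math.sqrt(1 + m * m)
        t_ah = cortical.get("ah", 0.0) or cortical.get("ah1", 0.0)
        t_bh = cortical.get("bh", 0.0) or cortical.get("bh1", 0.0)
        t_ch = cortical.get("ch", 0.0) or cortical.get("ch1", 0.0)
        inner = (
            (y >= -s / 2 + t_ah)
            & (y <= s / 2 + m * x - t_bh * sec)
            & (y <= s / 2 - m * x - t_ch * sec)
        )
        if not np.any(inner & (labels != BACKGROUND)):
            raise CorticalError("cortical shell consumes the whole interior (no spongiosa left)")
        zlo = -spec.h / 2 + (cortical.get("abb", 0.0) or cortical.get("abb1", 0.0))
        zhi = spec.h / 2 - (cortical.get("abb", 0.0) or cortical.get("abb2", 0.0))
        inner = inner & (z >= zlo) & (z <= zhi)
    else:
        inner_spec = inner_dimensions(spec, cortical)
        # base slabs shift the inner region's center along z
        if spec.kind in ("cylinder", "tube"):
            lo, hiside = _pair_sides(cortical, "ab")
        elif spec.kind == "box":
            lo, hiside = _pair_sides(cortical, "ab")
        else:
            lo = hiside = 0.0
        zc = (lo - hiside) / 2.0
        if spec.kind == "box":
            tha = _pair_sides(cortical, "ha")
            thb = _pair_sides(cortical, "hb")
            xc = (thb[0] - thb[1]) / 2.0
            yc = (tha[0] - tha[1]) / 2.0
        else:
            xc = yc = 0.0
        if spec.kind == "tube":
            # inner surface stays open: erode only the outer radius and bases
            r2 = x**2 + y**2
            inner = (
                (r2 <= (inner_spec.a / 2) ** 2)
                & (r2 >= (spec.b / 2) ** 2)
                & (np.abs(z - zc) <= inner_spec.h / 2)
            )
        else:
            inner = _inside(inner_spec, x - xc, y - yc, z - zc)

    interior = labels != BACKGROUND
    shell = interior & ~inner
    if not np.any(interior & inner):
        raise CorticalError("cortical shell consumes the whole interior (no spongiosa left)")
    out = labels.copy()
    out[shell] = CORTICAL
    meta = dict(phantom.meta)
    meta["cortical"] = dict(cortical)
    return VoxelPhantom(labels=out, voxel_size=vox, meta=meta)
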
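"""Parametric 2D primitives and boolean region algebra for head phantoms.

All coordinates are in millimetres with the origin at the centre of the
electrode belt, x to the right and y up.  Images export row 0 at the top
(largest y).  Regions are built from tilted ellipses and half-planes and
combined with union / intersection / difference into an expression tree
that can be evaluated as a vectorised point-membership predicate or
rasterised onto a regular grid by pixel-centre sampling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property

import numpy as np
from scipy.special import ellipe


__all__ = [
    "EllipseSpec",
    "HalfPlaneSpec",
    "RegionExpr",
    "Grid",
    "ellipse_perimeter",
    "point_in_region",
    "rasterize",
]


def ellipse_perimeter(semi_a: float, semi_b: float) -> float:
    """Exact perimeter of an ellipse with semiaxes ``semi_a``, ``semi_b`` (mm).

    Uses the complete elliptic integral of the second kind,
    ``P = 4 a E(m)`` with ``m = 1 - (b/a)^2`` for ``a >= b``.
    """
    if semi_a <= 0 or semi_b <= 0:
        raise ValueError(f"semiaxes must be positive, got ({semi_a}, {semi_b})")
    a, b = max(semi_a, semi_b), min(semi_a, semi_b)
    return float(4.0 * a * ellipe(1.0 - (b / a) ** 2))


@dataclass(frozen=True)
class EllipseSpec:
    """Tilted ellipse: centre (mm), semiaxes (mm), tilt (deg CCW about centre)."""

    center_x: float
    center_y: float
    semi_a: float  # along local x
    semi_b: float  # along local y
    tilt: float = 0.0

    def __post_init__(self):
        if self.semi_a <= 0 or self.semi_b <= 0:
            raise ValueError(f"semiaxes must be positive, got ({self.semi_a}, {self.semi_b})")
        # normalise tilt into (-180, 180]
        t = (self.tilt + 180.0) % 360.0 - 180.0
        if t == -180.0:
            t = 180.0
        object.__setattr__(self, "tilt", t)

    @cached_property
    def perimeter(self) -> float:
        return ellipse_perimeter(self.semi_a, self.semi_b)

    def contains(self, x, y):
        """Vectorised membership (boundary counts as inside)."""
        t = np.deg2rad(self.tilt)
        dx = np.asarray(x, float) - self.center_x
        dy = np.asarray(y, float) - self.center_y
        u = dx * np.cos(t) + dy * np.sin(t)
        v = -dx * np.sin(t) + dy * np.cos(t)
        return (u / self.semi_a) ** 2 + (v / self.semi_b) ** 2 <= 1.0

    def boundary_point(self, theta):
        """Point(s) on the ellipse at parameter angle ``theta`` (rad)."""
        t = np.deg2rad(self.tilt)
        bx = self.semi_a * np.cos(theta)
        by = self.semi_b * np.sin(theta)
        return (
            self.center_x + bx * np.cos(t) - by * np.sin(t),
            self.center_y + bx * np.sin(t) + by * np.cos(t),
        )

    def outward_normal(self, theta):
        """Unit outward normal at parameter angle ``theta`` (rad)."""
        t = np.deg2rad(self.tilt)
        nx = self.semi_b * np.cos(theta)
        ny = self.semi_a * np.sin(theta)
        wx = nx * np.cos(t) - ny * np.sin(t)
        wy = nx * np.sin(t) + ny * np.cos(t)
        n = np.hypot(wx, wy)
        return wx / n, wy / n

    def scaled(self, s: float) -> "EllipseSpec":
        return EllipseSpec(self.center_x, self.center_y, s * self.semi_a, s * self.semi_b, self.tilt)

    def region(self) -> "RegionExpr":
        return RegionExpr("prim", primitive=self)


@dataclass(frozen=True)
class HalfPlaneSpec:
    """Half-plane bounded by a line through (anchor_x, anchor_y).

    ``tilt`` is the line's angle in degrees relative to the vertical axis
    (positive tilts the top of the line toward +x).  ``side`` selects which
    half-plane membership returns true for.
    """

    anchor_x: float
    anchor_y: float
    tilt: float = 0.0
    side: str = "left"

    def __post_init__(self):
        if self.side not in ("left", "right"):
            raise ValueError(f"side must be 'left' or 'right', got {self.side!r}")

    def signed_distance(self, x, y):
        t = np.deg2rad(self.tilt)
        return (np.asarray(x, float) - self.anchor_x) * np.cos(t) - (
            np.asarray(y, float) - self.anchor_y
        ) * np.sin(t)

    def contains(self, x, y):
        s = self.signed_distance(x, y)
        return s <= 0.0 if self.side == "left" else s > 0.0

    def region(self) -> "RegionExpr":
        return RegionExpr("prim", primitive=self)


@dataclass(frozen=True)
class RegionExpr:
    """Boolean region expression tree over ellipse / half-plane primitives."""

    op: str  # 'prim' | 'union' | 'intersection' | 'difference'
    primitive: object = None
    children: tuple = field(default_factory=tuple)

    _OPS = ("prim", "union", "intersection", "difference")

    def __post_init__(self):
        if self.op not in self._OPS:
            raise ValueError(f"unknown op {self.op!r}")
        if self.op == "prim" and self.primitive is None:
            raise ValueError("'prim' node needs a primitive")
        if self.op != "prim" and len(self.children) < 1:
            raise ValueError(f"{self.op!r} node needs children")

    def evaluate(self, x, y):
        if self.op == "prim":
            return self.primitive.contains(x, y)
        masks = [c.evaluate(x, y) for c in self.children]
        if self.op == "union":
            out = masks[0]
            for m in masks[1:]:
                out = out | m
            return out
        if self.op == "intersection":
            out = masks[0]
            for m in masks[1:]:
                out = out & m
            return out
        out = masks[0]
        for m in masks[1:]:
            out = out & ~m
        return out

    def __or__(self, other):
        return RegionExpr("union", children=(self, other))

    def __and__(self, other):
        return RegionExpr("intersection", children=(self, other))

    def __sub__(self, other):
        return RegionExpr("difference", children=(self, other))


def point_in_region(expr: RegionExpr, x, y):
    """Boolean membership of point(s) (x, y) in a region expression."""
    return expr.evaluate(x, y)


@dataclass(frozen=True)
class Grid:
    """Square raster grid: ``extent_mm`` per side, ``n`` x ``n`` pixels,
    centred on (0, 0), row 0 at the top (largest y)."""

    extent_mm: float
    n: int

    def __post_init__(self):
        if self.n < 8:
            raise ValueError("grid resolution must be at least 8x8")

    @property
    def pixel_mm(self) -> float:
        return self.extent_mm / self.n

    @cached_property
    def xy(self):
        h = self.extent_mm / 2.0
        xs = (np.arange(self.n) + 0.5) * self.pixel_mm - h
        ys = h - (np.arange(self.n) + 0.5) * self.pixel_mm  # row 0 = top
        return np.meshgrid(xs, ys)

    @property
    def pixel_area(self) -> float:
        return self.pixel_mm**2


def rasterize(expr: RegionExpr, grid: Grid) -> np.ndarray:
    """Binary mask of ``expr`` on ``grid`` by pixel-centre sampling."""
    X, Y = grid.xy
    return expr.evaluate(X, Y)
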
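"""Constrained random sampling of head-phantom geometry.

The head outline is a fixed 77 x 105 mm ellipse (575 mm circumference).
Inside it, a skin + skull shell of sampled thickness encloses the cranial
cavity; the brain is the intersection of the sampled ``Inner`` ellipse with
the union of two ellipses per hemisphere, split by a near-vertical dividing
line; cerebrospinal fluid (CSF) fills the rest of the cavity plus five
explicit ellipses (a central one and four lobes placed on its boundary).

Two generation modes are provided: constraint-based sampling from the
shipped tables (truncated-normal within mean +- half-range, with rejection
against circumference / axes-ratio / area-fraction / hemisphere-balance
windows) and perturbation of an existing geometry with small Gaussian noise.
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional

import numpy as np

from .geometry import EllipseSpec, Grid, HalfPlaneSpec, RegionExpr, ellipse_perimeter

__all__ = [
    "ConstraintEntry",
    "ConstraintTables",
    "HeadGeometry",
    "SamplingError",
    "load_tables",
    "sample_geometry",
    "perturb_geometry",
    "build_geometry",
]


class SamplingError(RuntimeError):
    """Raised when the rejection budget is exhausted; names the violated constraint."""


@dataclass(frozen=True)
class ConstraintEntry:
    """One table element: parameter name -> (mean, half_range)."""

    element: str
    params: dict

    def __post_init__(self):
        for k, (m, hr) in self.params.items():
            if hr < 0:
                raise ValueError(f"{self.element}.{k}: half-range must be >= 0, got {hr}")


_ELEMENTS = ("inner", "l_down", "l_up", "r_down", "r_up", "divider",
             "csf_center", "lobe1", "lobe2", "lobe3", "lobe4", "shell")


@dataclass(frozen=True)
class ConstraintTables:
    """Parsed geometric constraint tables plus rejection windows."""

    head_a: float
    head_b: float
    skin_thickness: float
    entries: dict            # element -> ConstraintEntry
    limits: dict             # name -> (center, half_range)
    image_extent: float
    raster_n: int

    def zeroed(self) -> "ConstraintTables":
        """Copy with every half-range set to 0 (degenerate mean sampler)."""
        ent = {
            k: ConstraintEntry(k, {p: (m, 0.0) for p, (m, hr) in e.params.items()})
            for k, e in self.entries.items()
        }
        return ConstraintTables(self.head_a, self.head_b, self.skin_thickness,
                                ent, self.limits, self.image_extent, self.raster_n)

    @property
    def raster_grid(self) -> Grid:
        return Grid(self.image_extent, self.raster_n)


def _pair(v):
    if isinstance(v, (int, float)):
        return (float(v), 0.0)
    m, hr = v
    return (float(m), float(hr))


def load_tables(path: Optional[str] = None) -> ConstraintTables:
    """Load constraint tables from a TOML config (default: shipped tables)."""
    if path is None:
        text = resources.files("cceit.data").joinpath("head_model.toml").read_text()
        cfg = tomllib.loads(text)
    else:
        with open(path, "rb") as fh:
            cfg = tomllib.load(fh)

    entries = {}
    entries["shell"] = ConstraintEntry("shell", {"skull_thickness": _pair(cfg["shell"]["skull_thickness"])})
    entries["inner"] = ConstraintEntry("inner", {k: _pair(v) for k, v in cfg["inner"].items()})
    for name in ("l_down", "l_up", "r_down", "r_up"):
        entries[name] = ConstraintEntry(name, {k: _pair(v) for k, v in cfg["hemi"][name].items()})
    entries["divider"] = ConstraintEntry("divider", {k: _pair(v) for k, v in cfg["divider"].items()})
    entries["csf_center"] = ConstraintEntry("csf_center", {k: _pair(v) for k, v in cfg["csf"]["center"].items()})
    for i in (1, 2, 3, 4):
        entries[f"lobe{i}"] = ConstraintEntry(f"lobe{i}", {k: _pair(v) for k, v in cfg["csf"][f"lobe{i}"].items()})

    limits = {k: _pair(v) for k, v in cfg["limits"].items()}
    return ConstraintTables(
        head_a=float(cfg["head"]["semi_a"]),
        head_b=float(cfg["head"]["semi_b"]),
        skin_thickness=float(cfg["shell"]["skin_thickness"]),
        entries=entries,
        limits=limits,
        image_extent=float(cfg["image"]["extent_mm"]),
        raster_n=int(cfg["image"]["raster_n"]),
    )


@dataclass
class HeadGeometry:
    """One sampled head geometry: ellipse specs, divider, and area statistics.

    ``params`` is the flat dictionary of sampled table parameters from which
    the geometry was built (used by the perturbation generator and recorded
    in dataset manifests for bit-reproducibility).
    """

    head: EllipseSpec
    skin_inner: EllipseSpec
    cavity: EllipseSpec
    inner: EllipseSpec
    hemis: dict              # 'l_down' | 'l_up' | 'r_down' | 'r_up' -> EllipseSpec
    divider: HalfPlaneSpec
    csf_center: EllipseSpec
    csf_lobes: list
    params: dict
    fractions: dict = field(default_factory=dict)  # brain/csf/rest %, hemisphere ratio %

    # -- region expressions -------------------------------------------------

    def inner_region(self) -> RegionExpr:
        return self.inner.region() & self.cavity.region()

    def hemisphere_region(self, side: str) -> RegionExpr:
        """Hemisphere = Inner  (up U down)  one side of the divider."""
        up, down = (("l_up", "l_down") if side == "left" else ("r_up", "r_down"))
        div = HalfPlaneSpec(self.divider.anchor_x, self.divider.anchor_y,
                            self.divider.tilt, side)
        return self.inner_region() & (self.hemis[up].region() | self.hemis[down].region()) & div.region()

    def csf_ellipse_region(self) -> RegionExpr:
        expr = self.csf_center.region()
        for e in self.csf_lobes:
            expr = expr | e.region()
        return expr & self.inner_region()

    def brain_region(self, side: str) -> RegionExpr:
        return self.hemisphere_region(side) - self.csf_ellipse_region()

    def csf_region(self) -> RegionExpr:
        """All cavity area that is not brain (includes the explicit CSF ellipses)."""
        return self.cavity.region() - (self.brain_region("left") | self.brain_region("right"))

    def shell_region(self) -> RegionExpr:
        return self.head.region() - self.cavity.region()

    # -- statistics ---------------------------------------------------------

    def masks(self, grid: Grid) -> dict:
        """Region masks on ``grid``, evaluating each shared primitive once."""
        X, Y = grid.xy
        head = self.head.contains(X, Y)
        cavity = self.cavity.contains(X, Y)
        inner = self.inner.contains(X, Y) & cavity
        left_side = self.divider.signed_distance(X, Y) <= 0.0
        csf5 = self.csf_center.contains(X, Y)
        for e in self.csf_lobes:
            csf5 |= e.contains(X, Y)
        csf5 &= inner
        bl = inner & (self.hemis["l_up"].contains(X, Y) | self.hemis["l_down"].contains(X, Y)) & left_side & ~csf5
        br = inner & (self.hemis["r_up"].contains(X, Y) | self.hemis["r_down"].contains(X, Y)) & ~left_side & ~csf5
        return {
            "head": head,
            "skin": head & ~self.skin_inner.contains(X, Y),
            "shell": head & ~cavity,
            "cavity": cavity,
            "brain_left": bl,
            "brain_right": br,
            "csf": cavity & ~(bl | br),
        }

    def area_fractions(self, grid: Grid) -> dict:
        """Region areas as percent of total image area, plus hemisphere ratio."""
        m = self.masks(grid)
        tot = grid.n**2
        nl, nr = int(m["brain_left"].sum()), int(m["brain_right"].sum())
        return {
            "brain_area_pct": 100.0 * (nl + nr) / tot,
            "csf_area_pct": 100.0 * float(m["csf"].sum()) / tot,
            "rest_area_pct": 100.0 * float(m["shell"].sum()) / tot,
            "hemisphere_ratio_pct": 100.0 * nl / nr if nr else np.inf,
        }


# ---------------------------------------------------------------------------
# building a geometry from a flat parameter dictionary

def _rot(dx, dy, tilt_deg):
    t = np.deg2rad(tilt_deg)
    return dx * np.cos(t) - dy * np.sin(t), dx * np.sin(t) + dy * np.cos(t)


def _fit_scale(inner: EllipseSpec, cavity: EllipseSpec, n: int = 256) -> float:
    """Largest s <= 1 such that ``inner`` scaled by s about its centre lies in
    ``cavity`` (cavity is axis-aligned and centred at the origin)."""
    th = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    bx, by = inner.boundary_point(th)
    rx, ry = bx - inner.center_x, by - inner.center_y
    a, b = cavity.semi_a, cavity.semi_b
    A = (rx / a) ** 2 + (ry / b) ** 2
    B = 2.0 * (inner.center_x * rx / a**2 + inner.center_y * ry / b**2)
    C = (inner.center_x / a) ** 2 + (inner.center_y / b) ** 2 - 1.0
    if C >= 0:  # centre outside the cavity: degenerate, caller rejects
        return 0.0
    s = (-B + np.sqrt(B**2 - 4.0 * A * C)) / (2.0 * A)
    return float(min(1.0, s.min()))


def build_geometry(tables: ConstraintTables, params: dict) -> HeadGeometry:
    """Deterministically assemble a :class:`HeadGeometry` from sampled parameters."""
    p = params
    head = EllipseSpec(0.0, 0.0, tables.head_a, tables.head_b, 0.0)
    skin_inner = EllipseSpec(0.0, 0.0, tables.head_a - tables.skin_thickness,
                             tables.head_b - tables.skin_thickness, 0.0)
    t_total = tables.skin_thickness + p[("shell", "skull_thickness")]
    cavity = EllipseSpec(0.0, 0.0, tables.head_a - t_total, tables.head_b - t_total, 0.0)

    inner_sampled_a = tables.head_a + p[("inner", "dsize_x")]
    inner_sampled_b = tables.head_b + p[("inner", "dsize_y")]
    inner = EllipseSpec(
        p[("inner", "center_x")], p[("inner", "center_y")],
        inner_sampled_a, inner_sampled_b, p[("inner", "tilt")],
    )
    s = _fit_scale(inner, cavity)
    if s <= 0:
        raise SamplingError("inner_center_outside_cavity")
    if s < 1.0:
        inner = inner.scaled(s)

    # Relative sizes below are offsets to the *sampled* Inner semiaxes (the
    # table semantics); degenerate candidates are floored to a small positive
    # size and left for the rejection windows to weed out, so that the
    # unconstrained sampling law stays unbiased.
    def _semi(value):
        return max(value, 2.0)

    hemis = {}
    for name in ("l_down", "l_up", "r_down", "r_up"):
        # centre offsets are applied in the Inner ellipse's tilted frame,
        # sizes are additive offsets to Inner's semiaxes, tilts compose.
        ox, oy = _rot(p[(name, "center_x")], p[(name, "center_y")], inner.tilt)
        hemis[name] = EllipseSpec(inner.center_x + ox, inner.center_y + oy,
                                  _semi(inner_sampled_a + p[(name, "dsize_x")]),
                                  _semi(inner_sampled_b + p[(name, "dsize_y")]),
                                  inner.tilt + p[(name, "tilt")])

    divider = HalfPlaneSpec(p[("divider", "shift_x")], p[("divider", "shift_y")],
                            p[("divider", "tilt")], "left")

    ox, oy = _rot(p[("csf_center", "center_x")], p[("csf_center", "center_y")], inner.tilt)
    csf_center = EllipseSpec(inner.center_x + ox, inner.center_y + oy,
                             _semi(inner_sampled_a + p[("csf_center", "dsize_x")]),
                             _semi(inner_sampled_b + p[("csf_center", "dsize_y")]),
                             inner.tilt + p[("csf_center", "tilt")])

    lobes = []
    for i in (1, 2, 3, 4):
        nm = f"lobe{i}"
        # axis angle measured CCW from the vertical axis of the central CSF ellipse
        th = np.deg2rad(90.0 + p[(nm, "angle")])
        bx, by = csf_center.boundary_point(th)
        nx, ny = csf_center.outward_normal(th)
        sh = p[(nm, "shift")]
        lobes.append(EllipseSpec(bx + sh * nx, by + sh * ny,
                                 p[(nm, "semi_a")], p[(nm, "semi_b")], p[(nm, "tilt")]))

    return HeadGeometry(head, skin_inner, cavity, inner, hemis, divider,
                        csf_center, lobes, dict(params))


# ---------------------------------------------------------------------------
# constraint checks

def check_constraints(geom: HeadGeometry, tables: ConstraintTables,
                      grid: Optional[Grid] = None) -> Optional[str]:
    """Return the name of the first violated rejection window, or None."""
    lim = tables.limits

    def within(name, value):
        c, hr = lim[name]
        return abs(value - c) <= hr

    p_inner = ellipse_perimeter(geom.inner.semi_a, geom.inner.semi_b)
    if not within("inner_circumference", p_inner):
        return "inner_circumference"
    if not within("inner_axes_ratio", geom.inner.semi_b / geom.inner.semi_a):
        return "inner_axes_ratio"
    p_csf = ellipse_perimeter(geom.csf_center.semi_a, geom.csf_center.semi_b)
    if not within("center_csf_circumference_ratio", p_csf / p_inner):
        return "center_csf_circumference_ratio"
    if not within("center_csf_axes_ratio", geom.csf_center.semi_b / geom.csf_center.semi_a):
        return "center_csf_axes_ratio"
    for i, lobe in enumerate(geom.csf_lobes, start=1):
        if not within(f"lobe{i}_circumference", ellipse_perimeter(lobe.semi_a, lobe.semi_b)):
            return f"lobe{i}_circumference"

    grid = grid or tables.raster_grid
    fr = geom.area_fractions(grid)
    geom.fractions = fr
    for name in ("brain_area_pct", "csf_area_pct", "rest_area_pct", "hemisphere_ratio_pct"):
        if not np.isfinite(fr[name]) or not within(name, fr[name]):
            return name
    return None


# ---------------------------------------------------------------------------
# samplers

def _draw_params(tables: ConstraintTables, rng: np.random.Generator, law: str) -> dict:
    params = {}
    for element, entry in tables.entries.items():
        for name, (mean, hr) in entry.params.items():
            if hr == 0.0:
                params[(element, name)] = mean
            elif law == "uniform":
                params[(element, name)] = rng.uniform(mean - hr, mean + hr)
            else:  # truncated normal, sd = hr/2, truncated at +-hr
                while True:
                    v = rng.normal(mean, hr / 2.0)
                    if abs(v - mean) <= hr:
                        params[(element, name)] = v
                        break
    return params


def sample_geometry(tables: Optional[ConstraintTables] = None,
                    rng_seed=0, law: str = "truncnorm",
                    validate: bool = True,
                    max_attempts: int = 10000) -> HeadGeometry:
    """Draw one valid head geometry from the constraint tables.

    Parameters are drawn within their table windows (truncated normal by
    default, ``law='uniform'`` for uniform) and the candidate is rejected
    until every enforced circumference / ratio / area window is met.
    Deterministic for a fixed ``rng_seed`` (an int seed or a Generator).
    """
    tables = tables or load_tables()
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) else np.random.default_rng(rng_seed)
    degenerate = all(hr == 0.0 for e in tables.entries.values() for _, hr in e.params.values())
    counts: dict = {}
    for _ in range(max_attempts):
        try:
            geom = build_geometry(tables, _draw_params(tables, rng, law))
        except SamplingError as err:
            counts[str(err)] = counts.get(str(err), 0) + 1
            continue
        if not validate:
            geom.fractions = geom.area_fractions(tables.raster_grid)
            return geom
        bad = check_constraints(geom, tables)
        if bad is None:
            return geom
        counts[bad] = counts.get(bad, 0) + 1
        if degenerate:
            raise SamplingError(
                f"degenerate (all half-ranges zero) geometry violates constraint {bad!r}")
    worst = max(counts, key=counts.get)
    raise SamplingError(
        f"rejection budget ({max_attempts}) exhausted; most-violated constraint: "
        f"{worst!r} ({counts[worst]} times)")


def perturb_geometry(base: HeadGeometry, relative_sd: float = 0.05,
                     rng_seed=0, tables: Optional[ConstraintTables] = None,
                     validate: bool = True,
                     max_attempts: int = 10000) -> HeadGeometry:
    """Perturb every free parameter of ``base`` with independent Gaussian noise.

    The noise sd of a parameter is ``relative_sd`` times its characteristic
    scale, taken as the full table range (2 x half-range); parameters with a
    zero half-range are fixed.  The result is re-validated against the same
    rejection windows as :func:`sample_geometry` and re-perturbed on
    violation.
    """
    if relative_sd <= 0:
        raise ValueError("relative_sd must be > 0")
    tables = tables or load_tables()
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) else np.random.default_rng(rng_seed)
    scales = {}
    for element, entry in tables.entries.items():
        for name, (_, hr) in entry.params.items():
            scales[(element, name)] = 2.0 * hr
    counts: dict = {}
    for _ in range(max_attempts):
        params = {k: v + relative_sd * scales.get(k, 0.0) * rng.standard_normal()
                  for k, v in base.params.items()}
        try:
            geom = build_geometry(tables, params)
        except SamplingError as err:
            counts[str(err)] = counts.get(str(err), 0) + 1
            continue
        if not validate:
            geom.fractions = geom.area_fractions(tables.raster_grid)
            return geom
        bad = check_constraints(geom, tables)
        if bad is None:
            return geom
        counts[bad] = counts.get(bad, 0) + 1
    worst = max(counts, key=counts.get)
    raise SamplingError(
        f"rejection budget ({max_attempts}) exhausted; most-violated constraint: "
        f"{worst!r} ({counts[worst]} times)")
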
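"""Labelled head phantoms: region maps, dielectric properties, stroke lesions.

A phantom is a rasterised label map (outside / skin / skull / left brain /
right brain / CSF / lesion) with per-pixel conductivity (mS/m) and relative
permittivity maps at 64 MHz.  Region values are drawn from Gaussian priors
derived from segmented MRI cross-sections, re-drawn until the physical
ordering CSF > brain > skull+skin holds for both properties.

Stroke lesions are circular regions placed on one of six rays that model
the main cerebral artery territories.  A hemorrhagic lesion (blood) raises
conductivity to 1230 mS/m with permittivity 76; an ischemic lesion scales
the host hemisphere's conductivity to a uniform 60-70 % (65 +- 5 %) with
unchanged permittivity.  Lesions never overlap CSF and are confined to one
hemisphere.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from .geometry import Grid
from .sampler import HeadGeometry

__all__ = [
    "REGION",
    "TissueTable",
    "RegionPropertyPriors",
    "RegionProperties",
    "StrokeDescriptor",
    "HeadPhantom",
    "DegeneratePhantomError",
    "StrokeInsertionError",
    "assign_region_properties",
    "build_healthy_phantom",
    "artery_lines",
    "sample_stroke",
    "apply_stroke",
    "insert_stroke",
]


class DegeneratePhantomError(RuntimeError):
    pass


class StrokeInsertionError(RuntimeError):
    pass


#: Region label codes used in HeadPhantom.region_map.
REGION = {
    "outside": 0,
    "skin": 1,
    "skull": 2,
    "brain_left": 3,
    "brain_right": 4,
    "csf": 5,
    "lesion": 6,
}

ARTERY_ANGLES_DEG = (12.0, 80.0, 135.0, -12.0, -80.0, -135.0)

#: Dielectric properties of individual brain tissues at 64 MHz
#: (relative permittivity, conductivity in mS/m).
@dataclass(frozen=True)
class TissueTable:
    frequency_hz: float = 64e6
    white_matter: tuple = (67.8, 292.0)
    grey_matter: tuple = (97.4, 511.0)
    bones: tuple = (16.7, 59.5)
    csf: tuple = (97.3, 2070.0)
    fat: tuple = (13.6, 66.2)
    skin: tuple = (92.2, 436.0)

    def __post_init__(self):
        for name in ("white_matter", "grey_matter", "bones", "csf", "fat", "skin"):
            eps, sig = getattr(self, name)
            if eps < 1 or sig <= 0:
                raise ValueError(f"{name}: need eps_r >= 1 and sigma > 0")


#: Gaussian priors for the averaged model regions at 64 MHz
#: (eps mean, eps sd, sigma mean mS/m, sigma sd mS/m).
@dataclass(frozen=True)
class RegionPropertyPriors:
    skull_skin: tuple = (14.79, 1.77, 102.0, 29.0)
    brain: tuple = (46.46, 3.44, 378.0, 59.0)
    csf: tuple = (61.26, 4.40, 788.0, 207.0)

    def __post_init__(self):
        for name in ("skull_skin", "brain", "csf"):
            em, es, sm, ss = getattr(self, name)
            if em <= 0 or sm <= 0 or es < 0 or ss < 0:
                raise ValueError(f"{name}: means must be positive and sds >= 0")


@dataclass(frozen=True)
class RegionProperties:
    """One sampled set of per-region (eps_r, sigma mS/m) values."""

    skull_skin: tuple
    brain_left: tuple
    brain_right: tuple
    csf: tuple


def assign_region_properties(priors: RegionPropertyPriors = RegionPropertyPriors(),
                             rng_seed=0, max_attempts: int = 10000) -> RegionProperties:
    """Draw per-region Gaussian property values with the ordering constraint
    CSF > brain > skull+skin enforced (both permittivity and conductivity).

    The two hemispheres are drawn independently from the brain prior.
    """
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) else np.random.default_rng(rng_seed)
    for _ in range(max_attempts):
        ek, sk = rng.normal(priors.skull_skin[0], priors.skull_skin[1]), rng.normal(priors.skull_skin[2], priors.skull_skin[3])
        el, sl = rng.normal(priors.brain[0], priors.brain[1]), rng.normal(priors.brain[2], priors.brain[3])
        er, sr = rng.normal(priors.brain[0], priors.brain[1]), rng.normal(priors.brain[2], priors.brain[3])
        ec, sc = rng.normal(priors.csf[0], priors.csf[1]), rng.normal(priors.csf[2], priors.csf[3])
        if (ec > max(el, er) and sc > max(sl, sr)
                and min(el, er) > ek and min(sl, sr) > sk
                and ek > 1.0 and sk > 0.0):
            return RegionProperties((ek, sk), (el, sl), (er, sr), (ec, sc))
    raise RuntimeError("could not satisfy CSF > brain > skull ordering "
                       f"in {max_attempts} draws")


@dataclass(frozen=True)
class StrokeDescriptor:
    kind: str                 # 'hemorrhagic' | 'ischemic'
    artery_index: int         # 1..6
    center_x: float           # mm
    center_y: float           # mm
    radius: float             # mm (precursor circle radius, >= 15)
    sigma_lesion: float       # mS/m
    eps_lesion: float
    hemisphere: str           # 'left' | 'right'

    def __post_init__(self):
        if self.kind not in ("hemorrhagic", "ischemic"):
            raise ValueError(f"unknown stroke kind {self.kind!r}")
        if self.radius < 15.0:
            raise ValueError("precursor lesion radius must be >= 15 mm")


@dataclass
class HeadPhantom:
    geometry: HeadGeometry
    properties: RegionProperties
    grid: Grid
    region_map: np.ndarray    # uint8 labels, REGION codes
    sigma_map: np.ndarray     # mS/m
    eps_map: np.ndarray       # relative permittivity
    condition: str = "healthy"
    stroke: Optional[StrokeDescriptor] = None


HEMORRHAGE_SIGMA_MS_M = 1230.0
HEMORRHAGE_EPS = 76.0
ISCHEMIA_FRACTION = (0.60, 0.70)


def build_healthy_phantom(geometry: HeadGeometry, properties: RegionProperties,
                          grid: Grid) -> HeadPhantom:
    """Rasterise a healthy phantom: label map plus sigma / eps maps.

    Background (air outside the head) gets eps_r = 1, sigma = 0.
    """
    m = geometry.masks(grid)
    if not m["brain_left"].any() or not m["brain_right"].any():
        raise DegeneratePhantomError("a hemisphere rasterises to zero pixels")
    if not m["csf"].any():
        raise DegeneratePhantomError("CSF region rasterises to zero pixels")

    region = np.zeros((grid.n, grid.n), dtype=np.uint8)
    region[m["shell"]] = REGION["skull"]
    region[m["skin"]] = REGION["skin"]
    region[m["csf"]] = REGION["csf"]
    region[m["brain_left"]] = REGION["brain_left"]
    region[m["brain_right"]] = REGION["brain_right"]

    sigma = np.zeros((grid.n, grid.n))
    eps = np.ones((grid.n, grid.n))
    p = properties
    for label, (e, s) in (("skin", p.skull_skin), ("skull", p.skull_skin),
                          ("brain_left", p.brain_left), ("brain_right", p.brain_right),
                          ("csf", p.csf)):
        sel = region == REGION[label]
        sigma[sel] = s
        eps[sel] = e
    return HeadPhantom(geometry, properties, grid, region, sigma, eps)


def artery_lines(geometry: HeadGeometry):
    """Six artery rays: common anchor point and unit directions.

    The anchor is the midpoint between the Inner-ellipse centre and the
    topmost point of the Inner ellipse on its vertical (local y) axis.
    Ray angles are measured from the (downward) vertical axis, positive
    toward +x; the fan descends from the anchor through the brain mass so
    every ray crosses brain tissue.  Returns
    ``(anchor, [(angle_deg, direction), ...])``.
    """
    inner = geometry.inner
    t = np.deg2rad(inner.tilt)
    ax = inner.center_x - np.sin(t) * inner.semi_b / 2.0
    ay = inner.center_y + np.cos(t) * inner.semi_b / 2.0
    rays = []
    for ang in ARTERY_ANGLES_DEG:
        a = np.deg2rad(ang)
        rays.append((ang, (np.sin(a), -np.cos(a))))
    return (ax, ay), rays


def _ray_profile(geometry: HeadGeometry, anchor, direction, step=0.5, t_max=220.0):
    """Membership of brain / CSF along a ray, sampled every ``step`` mm."""
    ts = np.arange(0.0, t_max, step)
    xs = anchor[0] + ts * direction[0]
    ys = anchor[1] + ts * direction[1]
    bl = geometry.brain_region("left").evaluate(xs, ys)
    br = geometry.brain_region("right").evaluate(xs, ys)
    csf = geometry.csf_region().evaluate(xs, ys)
    return ts, bl | br, csf


def sample_stroke(geometry: HeadGeometry, properties: RegionProperties,
                  kind: str, rng_seed=0) -> StrokeDescriptor:
    """Draw a stroke descriptor on a randomly chosen artery ray.

    The lesion radius is uniform in [15 mm, gap], where the gap is the
    distance along the ray from its last CSF crossing to the brain edge.
    Hemorrhagic centres lie on the ray inside the brain; ischemic centres
    lie on the ray beyond the brain edge so only the circle-hemisphere
    intersection becomes lesion.  Arteries whose gap is below 15 mm are
    skipped; after all six fail an error is raised.
    """
    if kind not in ("hemorrhagic", "ischemic"):
        raise ValueError(f"unknown stroke kind {kind!r}")
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) else np.random.default_rng(rng_seed)
    anchor, rays = artery_lines(geometry)
    for idx in rng.permutation(len(rays)):
        ang, direction = rays[idx]
        ts, in_brain, in_csf = _ray_profile(geometry, anchor, direction)
        if not in_brain.any():
            continue
        i_out = int(np.nonzero(in_brain)[0][-1])          # last point inside brain
        run = np.nonzero(in_brain[: i_out + 1])[0]
        csf_before = np.nonzero(in_csf[: i_out + 1])[0]
        i_start = int(csf_before[-1]) + 1 if csf_before.size else int(run[0])
        gap = ts[i_out] - ts[i_start]
        if gap < 15.0:
            continue
        radius = rng.uniform(15.0, gap)
        if kind == "hemorrhagic":
            t_c = rng.uniform(ts[i_start], ts[i_out])
        else:
            t_c = ts[i_out] + rng.uniform(0.1, 0.9) * radius
        cx = anchor[0] + t_c * direction[0]
        cy = anchor[1] + t_c * direction[1]
        side = "left" if geometry.divider.signed_distance(cx, cy) <= 0 else "right"
        if kind == "hemorrhagic":
            sig, eps = HEMORRHAGE_SIGMA_MS_M, HEMORRHAGE_EPS
        else:
            host = properties.brain_left if side == "left" else properties.brain_right
            sig = rng.uniform(*ISCHEMIA_FRACTION) * host[1]
            eps = host[0]
        return StrokeDescriptor(kind, int(idx) + 1, float(cx), float(cy),
                                float(radius), float(sig), float(eps), side)
    raise StrokeInsertionError(
        "no artery ray admits a lesion radius of at least 15 mm for this geometry")


def apply_stroke(phantom: HeadPhantom, stroke: StrokeDescriptor) -> HeadPhantom:
    """Rasterise ``stroke`` onto a healthy phantom (returns a new phantom).

    The lesion is the circle intersected with the host hemisphere's brain
    mask, so CSF is excluded and the lesion cannot cross the midline.
    """
    if phantom.condition != "healthy":
        raise ValueError("strokes can only be inserted into healthy phantoms")
    X, Y = phantom.grid.xy
    circle = (X - stroke.center_x) ** 2 + (Y - stroke.center_y) ** 2 <= stroke.radius**2
    host = REGION["brain_left" if stroke.hemisphere == "left" else "brain_right"]
    lesion = circle & (phantom.region_map == host)
    if not lesion.any():
        raise StrokeInsertionError("lesion rasterises to zero pixels")
    region = phantom.region_map.copy()
    sigma = phantom.sigma_map.copy()
    eps = phantom.eps_map.copy()
    region[lesion] = REGION["lesion"]
    sigma[lesion] = stroke.sigma_lesion
    eps[lesion] = stroke.eps_lesion
    return replace(phantom, region_map=region, sigma_map=sigma, eps_map=eps,
                   condition=stroke.kind, stroke=stroke)


def insert_stroke(phantom: HeadPhantom, kind: str, rng_seed=0,
                  max_attempts: int = 6) -> HeadPhantom:
    """Sample a stroke descriptor and apply it to a healthy phantom."""
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) else np.random.default_rng(rng_seed)
    last = None
    for _ in range(max_attempts):
        try:
            stroke = sample_stroke(phantom.geometry, phantom.properties, kind, rng)
            return apply_stroke(phantom, stroke)
        except StrokeInsertionError as err:
            last = err
    raise StrokeInsertionError(f"stroke insertion failed after {max_attempts} attempts: {last}")


def export_region_png(phantom: HeadPhantom, path) -> None:
    """Write the region label map as a paletted PNG for visual inspection."""
    from PIL import Image

    palette = [0, 0, 0, 255, 224, 196, 200, 200, 200, 230, 120, 120,
               120, 120, 230, 120, 210, 230, 255, 40, 40]
    img = Image.fromarray(phantom.region_map, mode="P")
    img.putpalette(palette + [0] * (768 - len(palette)))
    img.save(path)
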
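"""Finite-volume forward solver for capacitively coupled impedance tomography.

The sensor is a 16-electrode belt around the fixed head outline.  Electrodes
are insulated from the scalp by a dielectric layer (the coupling capacitance
of the equivalent circuit) and surrounded by a grounded elliptical screen.
Measurements are single-frequency (64 MHz) phasor quantities: the complex
relative permittivity is

    eps = eps' - j * sigma / (omega * eps0),

and each measurement is the complex capacitance between an excited electrode
(held at V volts) and a measuring electrode (held at 0 V), obtained by
integrating Gauss's law over a contour one cell off the measuring electrode.

The quasi-static potential solves div(eps grad V) = 0 on a regular Cartesian
grid with harmonic-mean face permittivities and Dirichlet conditions on the
electrode and screen cells.  Because the excitation only changes Dirichlet
*values* (not the matrix), one sparse LU factorisation per permittivity field
serves all 16 excitations.

The insulation layer is treated through the equivalent circuit: the field is
solved with electrodes in contact with the scalp, and the coupling
capacitance C_c = eps0 * eps_ins * arc_length / thickness of each electrode's
dielectric cover is combined in series with the field capacitance.  A thin
layer handled this way is exact in the layered-medium limit and keeps the
discrete solution grid-convergent, which a sub-cell rasterised film is not.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from functools import lru_cache
from typing import Optional

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from .geometry import Grid
from .phantom import HeadPhantom

__all__ = [
    "EPS0",
    "SensorModel",
    "PermittivityField",
    "FieldSolution",
    "MeasurementFrame",
    "SolverError",
    "complex_permittivity",
    "field_from_phantom",
    "homogeneous_head_field",
    "solve_dirichlet",
    "solve_field",
    "gauss_capacitance",
    "measure_frame",
    "measurement_pairs",
    "add_measurement_noise",
]

EPS0 = 8.8541878128e-12  # F/m


class SolverError(RuntimeError):
    pass


def complex_permittivity(eps_r, sigma_mS_per_m, frequency_hz: float):
    """Complex relative permittivity ``eps_r - j sigma / (2 pi f eps0)``.

    ``sigma`` is in mS/m (the unit used throughout the tissue tables).
    Accepts scalars or arrays.
    """
    if frequency_hz <= 0:
        raise ValueError("frequency must be positive")
    sigma = np.asarray(sigma_mS_per_m, dtype=float)
    if np.any(sigma < 0):
        raise ValueError("conductivity must be non-negative")
    omega = 2.0 * np.pi * frequency_hz
    out = np.asarray(eps_r, dtype=complex) - 1j * (sigma * 1e-3) / (omega * EPS0)
    return out if out.ndim else complex(out)


@dataclass(frozen=True)
class SensorModel:
    """16-electrode insulated belt with a grounded elliptical screen."""

    n_electrodes: int = 16
    head_semi_a: float = 77.0
    head_semi_b: float = 105.0
    insulation_thickness: float = 0.5   # mm, dielectric cover -> coupling C_c
    insulation_eps: float = 4.0
    electrode_fraction: float = 0.8     # fraction of each angular sector covered
    electrode_depth: float = 3.0        # radial extent of electrode cells, mm
    screen_offset: float = 20.0         # gap between electrodes and screen, mm
    excitation_v: float = 1.0
    frequency_hz: float = 64e6

    def __post_init__(self):
        if not (0 < self.electrode_fraction < 1):
            raise ValueError("electrode_fraction must be in (0, 1)")
        if self.insulation_thickness <= 0:
            raise ValueError("insulation thickness must be positive")

    @property
    def omega(self) -> float:
        return 2.0 * np.pi * self.frequency_hz

    def default_grid(self, n: int = 256) -> Grid:
        extent = 2.0 * (self.head_semi_b + self.electrode_depth
                        + self.screen_offset) + 8.0
        return Grid(extent, n)

    def electrode_arc_length(self, k: int) -> float:
        """Arc length (mm) of electrode ``k``'s span on the belt ellipse."""
        from scipy.integrate import quad

        sector = 2.0 * np.pi / self.n_electrodes
        centre = np.pi / 2.0 - k * sector
        half = 0.5 * sector * self.electrode_fraction
        a, b = self.head_semi_a, self.head_semi_b
        val, _ = quad(lambda t: np.hypot(a * np.sin(t), b * np.cos(t)),
                      centre - half, centre + half)
        return float(val)

    def coupling_capacitance(self, k: int) -> float:
        """Series coupling capacitance C_c of electrode ``k`` (F/m, per unit depth)."""
        arc_m = self.electrode_arc_length(k) * 1e-3
        return EPS0 * self.insulation_eps * arc_m / (self.insulation_thickness * 1e-3)


@dataclass(frozen=True)
class _Layout:
    """Grid classification for one (sensor, grid) pairing."""

    dirichlet: np.ndarray        # bool (n, n): electrodes + screen
    electrode_id: np.ndarray     # int (n, n): -1 or electrode index
    screen: np.ndarray           # bool (n, n)


@lru_cache(maxsize=8)
def _layout(sensor: SensorModel, grid: Grid) -> _Layout:
    X, Y = grid.xy

    def rho(a, b):
        return (X / a) ** 2 + (Y / b) ** 2

    a0, b0 = sensor.head_semi_a, sensor.head_semi_b
    a2, b2 = a0 + sensor.electrode_depth, b0 + sensor.electrode_depth
    a3, b3 = a2 + sensor.screen_offset, b2 + sensor.screen_offset

    ring = (rho(a0, b0) > 1.0) & (rho(a2, b2) <= 1.0)
    screen = rho(a3, b3) > 1.0

    # electrode angular spans in the elliptic parameter angle, electrode 0
    # centred at the top, numbering clockwise
    phi = np.degrees(np.arctan2(Y / b0, X / a0))
    sector = 360.0 / sensor.n_electrodes
    k = np.round((90.0 - phi) / sector).astype(int) % sensor.n_electrodes
    centre = 90.0 - k * sector
    dphi = (phi - centre + 180.0) % 360.0 - 180.0
    on_electrode = ring & (np.abs(dphi) <= 0.5 * sector * sensor.electrode_fraction)

    electrode_id = np.where(on_electrode, k, -1)
    dirichlet = on_electrode | screen
    return _Layout(dirichlet, electrode_id, screen)


@dataclass
class PermittivityField:
    """Complex relative permittivity on a solver grid (sensor overlays applied)."""

    grid: Grid
    eps: np.ndarray              # complex (n, n)
    omega: float

    def __post_init__(self):
        if self.eps.shape != (self.grid.n, self.grid.n):
            raise ValueError("eps shape does not match grid")


def field_from_phantom(phantom: HeadPhantom, sensor: SensorModel) -> PermittivityField:
    """Complex permittivity field of a phantom on its (solver) grid."""
    eps = complex_permittivity(phantom.eps_map, phantom.sigma_map, sensor.frequency_hz)
    return PermittivityField(phantom.grid, np.asarray(eps, complex), sensor.omega)


def homogeneous_head_field(sensor: SensorModel, grid: Grid,
                           eps_r: float = 46.46, sigma_mS_per_m: float = 378.0) -> PermittivityField:
    """Reference field: homogeneous brain-averaged tissue filling the head outline."""
    X, Y = grid.xy
    inside = (X / sensor.head_semi_a) ** 2 + (Y / sensor.head_semi_b) ** 2 <= 1.0
    eps = np.where(inside, complex_permittivity(eps_r, sigma_mS_per_m, sensor.frequency_hz), 1.0 + 0j)
    return PermittivityField(grid, eps, sensor.omega)


@dataclass
class FieldSolution:
    potential: np.ndarray        # complex (n, n)
    excited: int
    excitation_v: float
    residual: float


# ---------------------------------------------------------------------------
# assembly and solving

def _faces(eps: np.ndarray, dirichlet: np.ndarray):
    """Face permittivities and flat index pairs for all grid faces.

    Interior faces take the harmonic mean of the two cell values; faces
    touching a Dirichlet (conductor) cell take the free side's value, so the
    conductor surface carries no spurious dielectric film of its own.
    """
    n = eps.shape[0]
    idx = np.arange(n * n).reshape(n, n)
    a = np.concatenate([idx[:, :-1].ravel(), idx[:-1, :].ravel()])
    b = np.concatenate([idx[:, 1:].ravel(), idx[1:, :].ravel()])
    epsf = eps.ravel()
    dirf = dirichlet.ravel()
    ea, eb = epsf[a], epsf[b]
    ef = 2.0 * ea * eb / (ea + eb)
    da, db = dirf[a], dirf[b]
    ef = np.where(da & ~db, eb, ef)
    ef = np.where(db & ~da, ea, ef)
    return a, b, ef


class _FactorizedSystem:
    """One LU factorisation of the finite-volume operator, reusable across
    excitations (only Dirichlet values change)."""

    def __init__(self, eps: np.ndarray, dirichlet: np.ndarray):
        n2 = eps.size
        self.shape = eps.shape
        self.dirichlet = dirichlet.ravel()
        a, b, ef = _faces(eps, dirichlet)
        free = ~self.dirichlet
        fa, fb = free[a], free[b]
        rows = np.concatenate([a[fa], a[fa], b[fb], b[fb],
                               np.nonzero(self.dirichlet)[0]])
        cols = np.concatenate([a[fa], b[fa], b[fb], a[fb],
                               np.nonzero(self.dirichlet)[0]])
        vals = np.concatenate([ef[fa], -ef[fa], ef[fb], -ef[fb],
                               np.ones(int(self.dirichlet.sum()), complex)])
        A = sp.coo_matrix((vals, (rows, cols)), shape=(n2, n2)).tocsc()
        self._A = A
        try:
            self._lu = splu(A)
        except RuntimeError as err:  # pragma: no cover - singular systems
            raise SolverError(f"factorisation failed: {err}") from err

    def solve(self, dirichlet_values: np.ndarray):
        rhs = np.zeros(self._A.shape[0], complex)
        rhs[self.dirichlet] = dirichlet_values.ravel()[self.dirichlet]
        v = self._lu.solve(rhs)
        denom = max(np.linalg.norm(rhs), 1e-300)
        residual = float(np.linalg.norm(self._A @ v - rhs) / denom)
        if not np.isfinite(residual) or residual > 1e-8:
            raise SolverError(f"ill-conditioned system, relative residual {residual:.2e}")
        return v.reshape(self.shape), residual


def solve_dirichlet(field: PermittivityField, dirichlet_mask: np.ndarray,
                    dirichlet_values: np.ndarray):
    """Solve div(eps grad V) = 0 with arbitrary Dirichlet data (generic core)."""
    sys_ = _FactorizedSystem(field.eps, dirichlet_mask)
    return sys_.solve(dirichlet_values)


def solve_field(field: PermittivityField, sensor: SensorModel, excited: int) -> FieldSolution:
    """Potential for one excitation: electrode ``excited`` at V, others and
    the screen grounded.  ``excited`` is a 0-based electrode index."""
    if field.grid.n < 64:
        raise ValueError("solver grid must be at least 64x64")
    if not (0 <= excited < sensor.n_electrodes):
        raise ValueError(f"excited electrode out of range: {excited}")
    lay = _layout(sensor, field.grid)
    values = np.where(lay.electrode_id == excited, sensor.excitation_v, 0.0).astype(complex)
    v, res = solve_dirichlet(field, lay.dirichlet, values)
    return FieldSolution(v, excited, sensor.excitation_v, res)


def _electrode_flux_faces(lay: _Layout, j: int):
    """Faces crossing from electrode ``j`` cells to non-Dirichlet cells.

    Returns flat indices (electrode cell, outside cell) for the four shift
    directions; this is the Gauss contour one cell off the electrode.
    """
    on_j = lay.electrode_id == j
    free = ~lay.dirichlet
    pairs = []
    for axis, shift in ((0, 1), (0, -1), (1, 1), (1, -1)):
        nb_free = np.roll(free, -shift, axis=axis)
        sel = on_j & nb_free
        # guard the wrap-around row/column (screen encloses, so it is empty anyway)
        if shift == 1:
            if axis == 0:
                sel[-1, :] = False
            else:
                sel[:, -1] = False
        else:
            if axis == 0:
                sel[0, :] = False
            else:
                sel[:, 0] = False
        e_idx = np.nonzero(sel.ravel())[0]
        n = sel.shape[0]
        nb_idx = e_idx + (shift * n if axis == 0 else shift)
        pairs.append((e_idx, nb_idx))
    e_all = np.concatenate([p[0] for p in pairs])
    nb_all = np.concatenate([p[1] for p in pairs])
    return e_all, nb_all


def _flux_into_electrode(solution_v: np.ndarray, eps: np.ndarray,
                         lay: _Layout, j: int) -> complex:
    e_idx, nb_idx = _electrode_flux_faces(lay, j)
    if e_idx.size == 0:
        raise SolverError(f"electrode {j} has no free neighbours (geometry error)")
    ef = eps.ravel()[nb_idx]  # conductor-boundary faces use the free side's eps
    v = solution_v.ravel()
    return complex(np.sum(ef * (v[nb_idx] - v[e_idx])))


def gauss_capacitance(solution: FieldSolution, field: PermittivityField,
                      sensor: SensorModel, measuring: int) -> complex:
    """Complex capacitance (F/m, per unit depth) on the measuring electrode.

    Integrates eps * E over the contour one cell off the electrode surface
    and divides by the excitation potential difference.
    """
    if measuring == solution.excited:
        raise ValueError("measuring electrode must differ from the excited one")
    lay = _layout(sensor, field.grid)
    flux = _flux_into_electrode(solution.potential, field.eps, lay, measuring)
    return EPS0 * flux / (solution.excitation_v - 0.0)


def measurement_pairs(n_electrodes: int):
    """All ordered electrode pairs (excite, measure), length N(N-1)."""
    return [(i, j) for i in range(n_electrodes) for j in range(n_electrodes) if j != i]


@dataclass
class MeasurementFrame:
    """Ordered-pair complex capacitance vector with acquisition metadata."""

    values: np.ndarray           # complex (N(N-1),)
    n_electrodes: int
    excitation_v: float = 1.0
    snr_db: float = np.inf

    def __post_init__(self):
        m = self.n_electrodes * (self.n_electrodes - 1)
        if self.values.shape != (m,):
            raise ValueError(f"expected {m} ordered-pair values, got {self.values.shape}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite capacitance values")

    @property
    def pairs(self):
        return measurement_pairs(self.n_electrodes)

    def as_real_input(self) -> np.ndarray:
        """Stack (Re, Im) rows: the 2 x M network input."""
        return np.stack([self.values.real, self.values.imag])

    def to_csv(self, path) -> None:
        import csv

        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["excite", "measure", "re_c", "im_c"])
            for (i, j), c in zip(self.pairs, self.values):
                w.writerow([i + 1, j + 1, repr(c.real), repr(c.imag)])


def measure_frame(field: PermittivityField, sensor: SensorModel,
                  include_coupling: bool = True) -> MeasurementFrame:
    """Full measurement protocol: excite each electrode, measure on all others.

    With ``include_coupling`` (default) each pair's field capacitance C_x is
    combined in series with the two electrodes' insulation coupling
    capacitances: C_m = (1/C_c_i + 1/C_x + 1/C_c_j)^-1, following the
    two-wire equivalent circuit of the measurement system.
    """
    lay = _layout(sensor, field.grid)
    present = np.unique(lay.electrode_id[lay.electrode_id >= 0])
    if present.size != sensor.n_electrodes:
        raise SolverError("not every electrode maps to at least one grid cell; "
                          "increase the grid resolution")
    sys_ = _FactorizedSystem(field.eps, lay.dirichlet)
    flux_faces = {j: _electrode_flux_faces(lay, j) for j in range(sensor.n_electrodes)}
    epsf = field.eps.ravel()
    out = np.empty(sensor.n_electrodes * (sensor.n_electrodes - 1), complex)
    m = 0
    for i in range(sensor.n_electrodes):
        values = np.where(lay.electrode_id == i, sensor.excitation_v, 0.0).astype(complex)
        v, _ = sys_.solve(values)
        vf = v.ravel()
        for j in range(sensor.n_electrodes):
            if j == i:
                continue
            e_idx, nb_idx = flux_faces[j]
            ef = epsf[nb_idx]
            out[m] = EPS0 * np.sum(ef * (vf[nb_idx] - vf[e_idx])) / sensor.excitation_v
            m += 1
    if include_coupling:
        cc = np.array([sensor.coupling_capacitance(k) for k in range(sensor.n_electrodes)])
        for m, (i, j) in enumerate(measurement_pairs(sensor.n_electrodes)):
            out[m] = 1.0 / (1.0 / cc[i] + 1.0 / out[m] + 1.0 / cc[j])
    return MeasurementFrame(out, sensor.n_electrodes, sensor.excitation_v)


def add_measurement_noise(frame: MeasurementFrame, snr_db: float, rng_seed=0) -> MeasurementFrame:
    """Add complex Gaussian noise at a peak SNR of ``snr_db`` decibels.

    The per-component noise sd is referenced to the maximum-magnitude frame
    entry: sd = max|C| / 10^(snr/20).  Infinite SNR returns the frame as is.
    """
    if np.isinf(snr_db):
        return frame
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) else np.random.default_rng(rng_seed)
    sd = np.max(np.abs(frame.values)) / 10.0 ** (snr_db / 20.0)
    noise = rng.normal(0.0, sd, frame.values.shape) + 1j * rng.normal(0.0, sd, frame.values.shape)
    return MeasurementFrame(frame.values + noise, frame.n_electrodes,
                            frame.excitation_v, snr_db)
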
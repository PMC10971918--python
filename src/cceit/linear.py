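"""Linearised forward operator and classical reconstruction baselines.

The sensitivity matrix S is the Jacobian of the ordered-pair capacitance
vector with respect to per-pixel complex permittivity, evaluated at a
reference field.  It is assembled from the per-electrode field solutions via
the adjoint (energy) identity of the finite-volume discretisation,

    dC_ij / d eps_f = -eps0 * (d_f v_i) (d_f v_j),

where d_f v is the potential difference across face f, and the chain rule
through the harmonic-mean face coefficients maps face derivatives onto cell
(pixel) derivatives.  This is exact for the discrete system, so it matches
finite-difference perturbation to first order.

Two baselines operate on the linearised model: linear back projection
(normalised S^T) and a truncated-SVD Moore-Penrose pseudoinverse.
Conductivity images use the imaginary part of the capacitance change, since
conductivity enters the complex permittivity through the imaginary part.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .geometry import Grid
from .solver import (EPS0, PermittivityField, SensorModel, _FactorizedSystem,
                     _layout, measurement_pairs)

__all__ = [
    "SensitivityMatrix",
    "sensitivity_matrix",
    "conductivity_operator",
    "lbp_reconstruct",
    "pinv_reconstruct",
]


@dataclass
class SensitivityMatrix:
    """Jacobian dC/d eps: rows = ordered electrode pairs, columns = pixels."""

    matrix: np.ndarray           # complex (M, Npix)
    pairs: list                  # ordered (excite, measure) tuples
    image_grid: Grid
    solver_grid: Grid
    omega: float

    def __post_init__(self):
        if self.matrix.shape[0] != len(self.pairs):
            raise ValueError("row count must equal number of pairs")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("non-finite sensitivity entries")

    def save(self, path) -> None:
        np.savez_compressed(
            path, matrix=self.matrix,
            pairs=np.asarray(self.pairs),
            image_extent=self.image_grid.extent_mm, image_n=self.image_grid.n,
            solver_extent=self.solver_grid.extent_mm, solver_n=self.solver_grid.n,
            omega=self.omega)

    @classmethod
    def load(cls, path) -> "SensitivityMatrix":
        z = np.load(path)
        return cls(z["matrix"], [tuple(p) for p in z["pairs"]],
                   Grid(float(z["image_extent"]), int(z["image_n"])),
                   Grid(float(z["solver_extent"]), int(z["solver_n"])),
                   float(z["omega"]))


def _cell_jacobian(field: PermittivityField, sensor: SensorModel) -> np.ndarray:
    """dC/d eps_cell on the solver grid, shape (M, n*n), via the adjoint identity."""
    lay = _layout(sensor, field.grid)
    sys_ = _FactorizedSystem(field.eps, lay.dirichlet)
    n = field.grid.n
    sols = []
    for i in range(sensor.n_electrodes):
        values = np.where(lay.electrode_id == i, sensor.excitation_v, 0.0).astype(complex)
        v, _ = sys_.solve(values)
        sols.append(v.ravel())

    idx = np.arange(n * n).reshape(n, n)
    a = np.concatenate([idx[:, :-1].ravel(), idx[:-1, :].ravel()])
    b = np.concatenate([idx[:, 1:].ravel(), idx[1:, :].ravel()])
    epsf = field.eps.ravel()
    dirf = lay.dirichlet.ravel()
    ea, eb = epsf[a], epsf[b]
    h = 2.0 * ea * eb / (ea + eb)
    da, db = dirf[a], dirf[b]
    # d(face eps)/d(cell eps): harmonic-mean chain rule on interior faces;
    # conductor-boundary faces carry the free cell's eps directly.
    wa = np.where(~da & ~db, 0.5 * (h / ea) ** 2, np.where(db & ~da, 1.0, 0.0))
    wb = np.where(~da & ~db, 0.5 * (h / eb) ** 2, np.where(da & ~db, 1.0, 0.0))

    pairs = measurement_pairs(sensor.n_electrodes)
    S = np.zeros((len(pairs), n * n), complex)
    row_of = {p: m for m, p in enumerate(pairs)}
    for i in range(sensor.n_electrodes):
        dv_i = sols[i][a] - sols[i][b]
        for j in range(i + 1, sensor.n_electrodes):
            prod = -EPS0 * dv_i * (sols[j][a] - sols[j][b]) / sensor.excitation_v**2
            row = (np.bincount(a, weights=(prod * wa).real, minlength=n * n)
                   + 1j * np.bincount(a, weights=(prod * wa).imag, minlength=n * n)
                   + np.bincount(b, weights=(prod * wb).real, minlength=n * n)
                   + 1j * np.bincount(b, weights=(prod * wb).imag, minlength=n * n))
            S[row_of[(i, j)]] = row
            S[row_of[(j, i)]] = row  # reciprocity
    return S


def sensitivity_matrix(sensor: SensorModel, reference_field: PermittivityField,
                       image_grid: Grid,
                       include_coupling: bool = True) -> SensitivityMatrix:
    """Sensitivity matrix on ``image_grid`` pixels at the reference field.

    Solver-cell derivatives are aggregated into image pixels by summing the
    cells whose centres fall in each pixel (a permittivity change on an image
    pixel perturbs all solver cells it covers).  With ``include_coupling``
    the Jacobian is taken through the series coupling capacitances to match
    :func:`cceit.solver.measure_frame`'s output: dC_m/dC_x = (C_m/C_x)^2.
    """
    from .solver import measure_frame

    S_cell = _cell_jacobian(reference_field, sensor)
    if include_coupling:
        c_x = measure_frame(reference_field, sensor, include_coupling=False).values
        c_m = measure_frame(reference_field, sensor, include_coupling=True).values
        S_cell *= ((c_m / c_x) ** 2)[:, None]
    sg, ig = reference_field.grid, image_grid
    X, Y = sg.xy
    col = np.floor((X.ravel() + ig.extent_mm / 2.0) / ig.pixel_mm).astype(int)
    row = np.floor((ig.extent_mm / 2.0 - Y.ravel()) / ig.pixel_mm).astype(int)
    ok = (col >= 0) & (col < ig.n) & (row >= 0) & (row < ig.n)
    pix = row * ig.n + col
    M = S_cell.shape[0]
    S_img = np.zeros((M, ig.n * ig.n), complex)
    idx = pix[ok]
    for m in range(M):
        S_img[m] = (np.bincount(idx, weights=S_cell[m, ok].real, minlength=ig.n * ig.n)
                    + 1j * np.bincount(idx, weights=S_cell[m, ok].imag, minlength=ig.n * ig.n))
    return SensitivityMatrix(S_img, measurement_pairs(sensor.n_electrodes),
                             ig, sg, reference_field.omega)


def conductivity_operator(S: SensitivityMatrix) -> np.ndarray:
    """Real operator mapping per-pixel conductivity change (mS/m) to Im(dC).

    With eps = eps' - j sigma/(omega eps0), a conductivity change d sigma
    produces d eps = -j d sigma * 1e-3 / (omega eps0), so
    Im(dC) = -Re(dC/d eps) * 1e-3 / (omega eps0) * d sigma.
    """
    return -S.matrix.real * 1e-3 / (S.omega * EPS0)


def lbp_reconstruct(delta_c: np.ndarray, S: np.ndarray,
                    image_shape: Optional[tuple] = None) -> np.ndarray:
    """Linear back projection: normalised S^T applied to the measurement change.

    Each pixel is the sensitivity-weighted average of the measurement changes:
    x_p = sum_m S_mp dc_m / sum_m |S_mp|.  Pixels with zero total sensitivity
    are set to 0 with a warning.
    """
    S = np.asarray(S)
    delta_c = np.asarray(delta_c)
    if S.shape[0] != delta_c.shape[0]:
        raise ValueError(f"dimension mismatch: S has {S.shape[0]} rows, "
                         f"delta_c has {delta_c.shape[0]} entries")
    num = S.T @ delta_c
    norm = np.abs(S).sum(axis=0)
    zero = norm == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} pixels have zero sensitivity; set to 0")
        norm = np.where(zero, 1.0, norm)
    img = np.where(zero, 0.0, num / norm)
    if image_shape is not None:
        img = img.reshape(image_shape)
    return img


def pinv_reconstruct(delta_c: np.ndarray, S: np.ndarray,
                     truncation: Optional[int] = None,
                     image_shape: Optional[tuple] = None) -> np.ndarray:
    """Truncated-SVD Moore-Penrose pseudoinverse solution of S x = delta_c.

    With ``truncation=None`` the rank is chosen at the Picard-plot elbow:
    the largest rank whose singular value still exceeds 1e-2 of the largest
    (a simple, documented elbow heuristic; pass an integer to override).
    """
    S = np.asarray(S)
    delta_c = np.asarray(delta_c)
    if S.shape[0] != delta_c.shape[0]:
        raise ValueError("dimension mismatch between S and delta_c")
    U, sv, Vt = np.linalg.svd(S, full_matrices=False)
    if truncation is None:
        truncation = max(1, int(np.sum(sv > 1e-2 * sv[0])))
    if not (1 <= truncation <= sv.size):
        raise ValueError(f"truncation rank must be in [1, {sv.size}], got {truncation}")
    x = Vt[:truncation].T @ ((U[:, :truncation].T @ delta_c) / sv[:truncation])
    if image_shape is not None:
        x = x.reshape(image_shape)
    return x
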
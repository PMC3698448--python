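"""EEG forward modelling: registration, source space, and two lead-field engines.

Two engines compute the gain matrix (uV of scalp potential per nAm of dipole
moment, free orientation, average-referenced):

* ``sphere`` — the analytic series solution for a current dipole inside a
  multi-layer concentric sphere with piecewise-constant conductivity and an
  insulating outer boundary.  On the spherical phantom this is exact (up to
  series truncation) and serves as the oracle for the numerical engine.
* ``fdm`` — a finite-difference (finite-volume, 7-point stencil) solution of
  the quasi-static Poisson problem  div(sigma grad V) = div J  on the labeled
  conductivity voxel grid.  Lead fields are assembled by reciprocity: one
  linear solve per electrode against a fixed reference, with the dipole
  realized as two opposing monopoles one voxel apart per orientation axis.

Conductivities default to literature-standard values (S/m): scalp 0.33,
skull 0.0042, CSF 1.79, gray 0.33, white 0.14, eye 0.50, air cavity 1e-8.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.ndimage as ndi
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.spatial import cKDTree

from .errors import (
    ConvergenceError,
    EmptySourceSpaceError,
    GeometryError,
    RegistrationError,
    TopologyError,
)
from .montage import Montage
from .volumes import TISSUE_IDS, LabelVolume

log = logging.getLogger(__name__)

DEFAULT_CONDUCTIVITY: dict[str, float] = {
    "background": 0.0,
    "scalp": 0.33,
    "skull": 0.0042,
    "csf": 1.79,
    "gray": 0.33,
    "white": 0.14,
    "eye": 0.50,
    "air": 1e-8,
}

#: uV per nAm given potentials in V per (A m).
_UV_PER_NAM = 1e-3


@dataclass
class SourceSpace:
    """Ordered dipole nodes at gray/eye voxel centers (free orientation)."""

    positions_mm: np.ndarray  # (M, 3) head coordinates
    voxels: np.ndarray  # (M, 3) parent voxel indices
    labels: np.ndarray  # (M,) tissue label of the parent voxel
    spacing_mm: float
    orientation: str = "free"

    @property
    def n_nodes(self) -> int:
        return self.positions_mm.shape[0]


@dataclass
class LeadField:
    """Gain matrix, channels x nodes x 3 orientations, uV per nAm."""

    gain: np.ndarray
    channels: list[str]
    node_positions: np.ndarray
    node_voxels: np.ndarray | None
    engine: str
    units: str = "uV/nAm"
    meta: dict = field(default_factory=dict)

    @property
    def matrix(self) -> np.ndarray:
        """2-D view, channels x (nodes * 3)."""
        c, m, _ = self.gain.shape
        return self.gain.reshape(c, m * 3)


# ---------------------------------------------------------------------------
# Electrode registration
# ---------------------------------------------------------------------------

def register_electrodes(
    montage: Montage, head_fiducials: dict[str, np.ndarray]
) -> tuple[Montage, dict]:
    """Rigid + isotropic-scale registration of the montage to head space.

    A similarity transform (rotation R, scale s, translation t) is fitted by
    least squares to the fiducial pairs shared between the montage and
    ``head_fiducials`` and applied to every electrode.  Returns the
    transformed montage and a report with the residual RMS (mm).
    """
    names = [n for n in montage.fiducials if n in head_fiducials]
    if len(names) < 3:
        raise RegistrationError("need at least three shared fiducials")
    A = np.array([montage.fiducials[n] for n in names], dtype=float)
    B = np.array([np.asarray(head_fiducials[n], dtype=float) for n in names])
    Ac, Bc = A - A.mean(0), B - B.mean(0)
    if np.linalg.matrix_rank(Ac, tol=1e-8) < 2:
        raise RegistrationError("fiducials are collinear; registration is degenerate")

    # Umeyama similarity fit
    cov = Bc.T @ Ac / len(names)
    U, D, Vt = np.linalg.svd(cov)
    S = np.eye(3)
    if np.linalg.det(U) * np.linalg.det(Vt) < 0:
        S[2, 2] = -1.0
    R = U @ S @ Vt
    var_a = (Ac**2).sum() / len(names)
    s = float(np.trace(np.diag(D) @ S) / var_a)
    t = B.mean(0) - s * R @ A.mean(0)

    def apply(x: np.ndarray) -> np.ndarray:
        return (s * (R @ np.atleast_2d(x).T)).T + t

    resid = apply(A) - B
    rms = float(np.sqrt((resid**2).sum(axis=1).mean()))
    out = montage.copy()
    out.positions = apply(out.positions)
    out.fiducials = {n: apply(p)[0] for n, p in out.fiducials.items()}
    report = {"rotation": R, "scale": s, "translation": t, "residual_rms_mm": rms}
    log.info("register_electrodes: residual RMS %.4f mm, scale %.4f", rms, s)
    return out, report


# ---------------------------------------------------------------------------
# Source space
# ---------------------------------------------------------------------------

def build_source_space(
    tissue: LabelVolume, spacing_mm: float, include_eyes: bool = True
) -> SourceSpace:
    """Nodes at gray (and optionally eye) voxel centers on a regular subgrid.

    The subsample keeps voxels whose indices are multiples of
    ``round(spacing / voxel_size)`` on every axis; node order is the
    lexicographic voxel-index order, which is stable across runs.
    """
    h = tissue.voxel_size_mm
    if spacing_mm < h - 1e-9:
        raise ValueError("spacing must be at least the voxel size")
    step = max(1, int(round(spacing_mm / h)))
    mask = tissue.grid == TISSUE_IDS["gray"]
    if include_eyes:
        mask |= tissue.grid == TISSUE_IDS["eye"]
    ijk = np.argwhere(mask)
    keep = np.all(ijk % step == 0, axis=1)
    ijk = ijk[keep]
    if ijk.shape[0] == 0:
        raise EmptySourceSpaceError("no gray/eye voxels on the source grid")
    return SourceSpace(
        positions_mm=tissue.voxel_to_head(ijk),
        voxels=ijk,
        labels=tissue.grid[tuple(ijk.T)].astype(int),
        spacing_mm=float(step * h),
    )


# ---------------------------------------------------------------------------
# Analytic multi-layer sphere
# ---------------------------------------------------------------------------

def _sphere_radial_coeffs(
    n_orders: int, radii_m: np.ndarray, sigmas: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Outer-layer radial coefficients (A_n, B_n) for the layered sphere.

    For each spherical-harmonic order n, solves the 1-D radial boundary-value
    problem (continuity of potential and radial current at each interface,
    zero radial current at the outer boundary) for a unit source coefficient
    in the innermost layer.  The potential evaluated at scaled radius
    x = r/R inside the outermost layer is

        V(x, gamma) = 1/(4 pi sigma_1 R^2) * sum_n (A_n x^n + B_n x^-(n+1))
                      (b/R)^(n-1) [ n p_r P_n(cos g) + p_t P_n'(cos g) ]

    At the surface (x = 1) the factor A_n + B_n reduces to (2n+1)/n for a
    homogeneous sphere.
    """
    R = radii_m[-1]
    x = radii_m / R  # interface radii, scaled; x[-1] == 1
    N = len(radii_m)
    GA = np.zeros(n_orders + 1)
    GB = np.zeros(n_orders + 1)
    if N == 1:
        # insulating homogeneous sphere: a_n = (n+1)/n, source term b_n = 1
        ns = np.arange(1, n_orders + 1, dtype=float)
        GA[1:] = (ns + 1) / ns
        GB[1:] = 1.0
        return GA, GB
    for n in range(1, n_orders + 1):
        # unknowns: a_1, (a_k, b_k) for k=2..N  -> 2N-1
        dim = 2 * N - 1
        A = np.zeros((dim, dim))
        rhs = np.zeros(dim)

        def a_col(k: int) -> int:  # layer index 1-based
            return 0 if k == 1 else 2 * k - 3

        def b_col(k: int) -> int:
            return 2 * k - 2

        row = 0
        for k in range(1, N):  # interface between layer k and k+1 at x[k-1]
            xk = x[k - 1]
            u, w = xk**n, xk ** -(n + 1)
            du, dw = n * xk ** (n - 1), -(n + 1) * xk ** -(n + 2)
            # potential continuity
            A[row, a_col(k)] += u
            if k > 1:
                A[row, b_col(k)] += w
            A[row, a_col(k + 1)] -= u
            A[row, b_col(k + 1)] -= w
            rhs[row] = -w if k == 1 else 0.0  # source term lives in layer 1
            row += 1
            # radial current continuity
            A[row, a_col(k)] += sigmas[k - 1] * du
            if k > 1:
                A[row, b_col(k)] += sigmas[k - 1] * dw
            A[row, a_col(k + 1)] -= sigmas[k] * du
            A[row, b_col(k + 1)] -= sigmas[k] * dw
            rhs[row] = -sigmas[k - 1] * dw if k == 1 else 0.0
            row += 1
        # insulating outer boundary at x = 1
        A[row, a_col(N)] = n
        A[row, b_col(N)] = -(n + 1)
        coef = np.linalg.solve(A, rhs)
        GA[n] = coef[a_col(N)]
        GB[n] = coef[b_col(N)]
    return GA, GB


def leadfield_sphere(
    montage: Montage,
    source_space: SourceSpace,
    shell_radii_mm: tuple[float, ...],
    shell_conductivities: tuple[float, ...],
    rtol: float = 1e-12,
    n_max: int = 400,
) -> LeadField:
    """Analytic lead field for sources inside a multi-layer sphere.

    ``shell_radii_mm`` / ``shell_conductivities`` are matched outer radii and
    conductivities of each layer (any order; sorted ascending internally;
    sources must lie inside the innermost interface).  Electrodes are
    evaluated at their true radius within the outermost layer (clipped to
    that layer), so electrode sets snapped to scalp voxels are handled
    consistently.  The series is truncated once the remaining terms fall
    below ``rtol`` relative.
    """
    order = np.argsort(shell_radii_mm)
    radii_m = np.asarray(shell_radii_mm, dtype=float)[order] / 1000.0
    sigmas = np.asarray(shell_conductivities, dtype=float)[order]
    if np.any(sigmas <= 0):
        raise GeometryError("shell conductivities must be positive")
    R = radii_m[-1]

    pos = source_space.positions_mm / 1000.0
    b = np.linalg.norm(pos, axis=1)
    if np.any(b > radii_m[0] + 1e-9):
        raise GeometryError(
            "all sources must lie inside the innermost shell boundary"
        )
    bhat = b / R
    rb = np.divide(pos, b[:, None], out=np.zeros_like(pos), where=b[:, None] > 1e-12)
    rb[b <= 1e-12] = (0.0, 0.0, 1.0)  # arbitrary; only the n=1 term survives

    e_norm = np.linalg.norm(montage.positions, axis=1)
    e = montage.positions / e_norm[:, None]
    M, C = pos.shape[0], e.shape[0]
    cosg = np.clip(rb @ e.T, -1.0, 1.0)  # (M, C)

    # electrodes are evaluated at their true radius within the outer layer
    # (electrode sets snapped to scalp voxels sit below the surface)
    x_lo = radii_m[-2] / R if len(radii_m) > 1 else 0.5
    x_e = np.clip(e_norm / 1000.0 / R, x_lo, 1.0)  # (C,)

    GA, GB = _sphere_radial_coeffs(n_max, radii_m, sigmas)
    # Legendre recurrences, accumulated term by term
    P_prev = np.ones_like(cosg)  # P_0
    P = cosg.copy()  # P_1
    dP_prev = np.zeros_like(cosg)  # P_0'
    dP = np.ones_like(cosg)  # P_1'
    R_sum = np.zeros_like(cosg)
    T_sum = np.zeros_like(cosg)
    bpow = np.ones(M)  # bhat^(n-1)
    xe_a = x_e.copy()  # x_e^n
    xe_b = x_e**-2.0  # x_e^-(n+1)
    scale_ref = 0.0
    for n in range(1, n_max + 1):
        Fe = GA[n] * xe_a + GB[n] * xe_b  # (C,) outer-layer radial factor
        An = bpow[:, None] * Fe[None, :]
        R_sum += An * (n * P)
        T_sum += An * dP
        bound = np.abs(Fe).max() * bpow.max() * n * (n + 1)
        scale_ref = max(scale_ref, bound)
        if n > 5 and bound < rtol * scale_ref:
            break
        bpow = bpow * bhat
        xe_a = xe_a * x_e
        xe_b = xe_b / x_e
        P_next = ((2 * n + 1) * cosg * P - n * P_prev) / (n + 1)
        dP_next = dP_prev + (2 * n + 1) * P
        P_prev, P = P, P_next
        dP_prev, dP = dP, dP_next
    else:
        log.warning("leadfield_sphere: series not converged at n_max=%d", n_max)

    S = 1.0 / (4.0 * np.pi * sigmas[0] * R**2)
    gain = np.empty((C, M, 3))
    for a in range(3):
        ea = np.zeros(3)
        ea[a] = 1.0
        p_r = rb @ ea  # (M,)
        # p_t * sin(gamma) = e_axis . (e_hat - cos(g) r_hat)
        t_comp = e[None, :, a] - cosg * rb[:, None, a]  # (M, C)
        V = S * (p_r[:, None] * R_sum + t_comp * T_sum)  # volts per A m
        gain[:, :, a] = V.T * _UV_PER_NAM
    gain -= gain.mean(axis=0, keepdims=True)
    return LeadField(
        gain=gain,
        channels=list(montage.channels),
        node_positions=source_space.positions_mm.copy(),
        node_voxels=source_space.voxels.copy(),
        engine="sphere",
        meta={"radii_mm": list(np.sort(shell_radii_mm)), "conductivities": list(sigmas)},
    )


# ---------------------------------------------------------------------------
# Finite-difference engine
# ---------------------------------------------------------------------------

def conductivity_volume(
    tissue: LabelVolume, table: dict[str, float] | None = None
) -> np.ndarray:
    """Per-voxel conductivity (S/m) from the tissue label volume."""
    table = dict(DEFAULT_CONDUCTIVITY, **(table or {}))
    sigma = np.zeros(tissue.grid.shape)
    for lab, name in tissue.label_table.items():
        if name in table:
            sigma[tissue.grid == lab] = table[name]
    return sigma


def _assemble_fdm(sigma: np.ndarray, h_m: float):
    """7-point finite-volume operator on conductive voxels.

    Face conductances use the harmonic mean of the two adjacent voxel
    conductivities.  Returns (laplacian, flat ids of conductive voxels,
    id-lookup grid).
    """
    cond = sigma > 0
    _, n_lab = ndi.label(cond)
    if n_lab != 1:
        raise TopologyError(f"conductive domain has {n_lab} connected components")
    ids = -np.ones(sigma.shape, dtype=np.int64)
    flat = np.argwhere(cond)
    ids[tuple(flat.T)] = np.arange(flat.shape[0])
    n = flat.shape[0]

    rows, cols, vals = [], [], []
    diag = np.zeros(n)
    for axis in range(3):
        sl_a = [slice(None)] * 3
        sl_b = [slice(None)] * 3
        sl_a[axis] = slice(None, -1)
        sl_b[axis] = slice(1, None)
        sa, sb = sigma[tuple(sl_a)], sigma[tuple(sl_b)]
        ia, ib = ids[tuple(sl_a)], ids[tuple(sl_b)]
        ok = (sa > 0) & (sb > 0)
        g = np.zeros_like(sa)
        g[ok] = 2.0 * sa[ok] * sb[ok] / (sa[ok] + sb[ok]) * h_m
        ga = g[ok]
        a_idx, b_idx = ia[ok], ib[ok]
        rows.extend([a_idx, b_idx])
        cols.extend([b_idx, a_idx])
        vals.extend([-ga, -ga])
        np.add.at(diag, a_idx, ga)
        np.add.at(diag, b_idx, ga)
    rows.append(np.arange(n))
    cols.append(np.arange(n))
    vals.append(diag)
    A = sp.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    )
    return A, flat, ids


def _snap_electrodes(tissue: LabelVolume, montage: Montage) -> np.ndarray:
    """Nearest scalp-voxel index for each electrode."""
    scalp = np.argwhere(tissue.grid == TISSUE_IDS["scalp"])
    if scalp.shape[0] == 0:
        raise GeometryError("tissue volume has no scalp voxels")
    tree = cKDTree(tissue.voxel_to_head(scalp))
    _, idx = tree.query(montage.positions)
    return scalp[idx]


def leadfield_fdm(
    tissue: LabelVolume,
    conductivity_table: dict[str, float] | None,
    montage: Montage,
    source_space: SourceSpace,
    reference_channel: int = 0,
    solver: str = "direct",
    tol: float = 1e-8,
    maxiter: int = 20000,
) -> LeadField:
    """Finite-difference lead field via reciprocity.

    One linear solve per electrode injects unit current at that electrode's
    scalp voxel with the reference electrode's voxel grounded; the gain for a
    dipole at a source node is the central difference of the reciprocal
    potential across the node's neighbor voxels (two opposing monopoles one
    voxel apart).  ``solver`` is ``direct`` (one sparse LU factorization
    shared across electrodes) or ``iterative`` (ILU-preconditioned
    BiCGStab to relative residual ``tol``).
    """
    h_m = tissue.voxel_size_mm / 1000.0
    sigma = conductivity_volume(tissue, conductivity_table)
    A, flat, ids = _assemble_fdm(sigma, h_m)
    n = A.shape[0]

    elec_vox = _snap_electrodes(tissue, montage)
    elec_ids = ids[tuple(elec_vox.T)]
    if np.any(elec_ids < 0):
        raise TopologyError("an electrode voxel is outside the conductive domain")
    ref_id = int(elec_ids[reference_channel])

    keep = np.ones(n, dtype=bool)
    keep[ref_id] = False  # ground the reference voxel
    Ar = A[keep][:, keep].tocsc()
    remap = -np.ones(n, dtype=np.int64)
    remap[keep] = np.arange(n - 1)

    if solver == "direct":
        lu = spla.splu(Ar)
        solve = lu.solve
    elif solver == "iterative":
        ilu = spla.spilu(Ar, drop_tol=1e-4, fill_factor=30)
        M = spla.LinearOperator(Ar.shape, ilu.solve)

        def solve(rhs: np.ndarray) -> np.ndarray:
            x, info = spla.bicgstab(Ar, rhs, rtol=tol, atol=0.0, maxiter=maxiter, M=M)
            if info != 0:  # breakdown: fall back to restarted GMRES
                x, info = spla.gmres(
                    Ar, rhs, rtol=tol, atol=0.0, maxiter=maxiter, restart=50, M=M
                )
            if info != 0:
                raise ConvergenceError(f"iterative solve failed (info={info})")
            return x

    else:
        raise ValueError(f"unknown solver {solver!r}")

    # neighbor ids for the two-monopole dipole stencil at each node
    node_vox = source_space.voxels
    nb_plus = np.empty((source_space.n_nodes, 3), dtype=np.int64)
    nb_minus = np.empty_like(nb_plus)
    for a in range(3):
        step = np.zeros(3, dtype=int)
        step[a] = 1
        nb_plus[:, a] = ids[tuple((node_vox + step).T)]
        nb_minus[:, a] = ids[tuple((node_vox - step).T)]
    if np.any(nb_plus < 0) or np.any(nb_minus < 0):
        raise GeometryError("a source node touches the non-conductive boundary")

    C = len(montage.channels)
    gain = np.zeros((C, source_space.n_nodes, 3))
    V_full = np.zeros(n)
    for c in range(C):
        if c == reference_channel:
            continue  # reference row stays zero; fixed by average reference
        rhs = np.zeros(n - 1)
        eid = int(elec_ids[c])
        if eid == ref_id:
            continue
        rhs[remap[eid]] = 1.0  # 1 A in, returned through the grounded reference
        V = solve(rhs)
        V_full[:] = 0.0
        V_full[keep] = V
        # reciprocity: lead = grad of reciprocal field at the node (V per A m)
        dV = (V_full[nb_plus] - V_full[nb_minus]) / (2.0 * h_m)
        gain[c] = dV * _UV_PER_NAM

    gain -= gain.mean(axis=0, keepdims=True)
    return LeadField(
        gain=gain,
        channels=list(montage.channels),
        node_positions=source_space.positions_mm.copy(),
        node_voxels=node_vox.copy(),
        engine="fdm",
        meta={"reference_channel": reference_channel, "solver": solver},
    )


def rdm(col_a: np.ndarray, col_b: np.ndarray) -> float:
    """Relative difference measure between two lead-field columns."""
    a = col_a / np.linalg.norm(col_a)
    b = col_b / np.linalg.norm(col_b)
    return float(np.linalg.norm(a - b))
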
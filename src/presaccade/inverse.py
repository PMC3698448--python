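"""sLORETA current-density reconstruction.

The minimum-norm estimate for average-referenced data is

    j_hat = T d,    T = K' (K K' + alpha H)^+

with K the (centered) lead field, H = I - 11'/n the average-reference
centering operator, and ^+ the Moore-Penrose pseudo-inverse (eigendecomposition
with a relative cutoff).  sLORETA standardizes the per-node 3-vector estimate
by the node's 3x3 block of the resolution form S = T K:

    cdr_l = sqrt( j_l' S_ll^+ j_l )

For noiseless data generated by a single dipole this standardized map attains
its maximum exactly at the generating node (the zero-localization-error
property), for alpha = 0 and for the default data-driven alpha alike.

Reported values are non-negative standardized magnitudes in nAm-equivalent
units; signed time courses are unavailable by construction (free orientation,
magnitude readout).  Raw unstandardized minimum-norm magnitudes are available
via ``standardized=False``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError
from .forward import LeadField

log = logging.getLogger(__name__)

_EIG_CUTOFF_REL = 1e-10


@dataclass
class InverseKernel:
    """Precomputed sLORETA transfer and standardization blocks."""

    transfer: np.ndarray  # (3M, C)
    std_blocks: np.ndarray  # (M, 3, 3) resolution blocks S_ll
    std_whitener: np.ndarray  # (M, 3, 3) symmetric S_ll^(-1/2)
    alpha: float
    channels: list[str]
    node_positions: np.ndarray
    node_voxels: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return self.std_blocks.shape[0]


@dataclass
class CDRSeries:
    """Per-node non-negative current-density magnitude per 4-ms slice."""

    values: np.ndarray  # (M, n_times) >= 0
    times: np.ndarray
    node_positions: np.ndarray
    node_voxels: np.ndarray | None = None
    standardized: bool = True


def default_alpha(leadfield: LeadField, snr: float = 10.0) -> float:
    """Data-independent regularization: trace(KK') / (n_channels * snr^2)."""
    K = leadfield.matrix
    return float(np.sum(K * K) / (K.shape[0] * snr**2))


def sloreta_kernel(
    leadfield: LeadField, alpha: float | None = None, snr: float = 10.0
) -> InverseKernel:
    """Build the sLORETA inverse kernel for an average-referenced lead field.

    ``alpha=None`` selects ``trace(KK')/(n_channels * snr^2)``; ``alpha=0``
    gives the unregularized pseudo-inverse solution.  All resolved values are
    logged.  A conditioning warning is emitted when the regularized Gram
    matrix is rank-deficient beyond the average-reference null space.
    """
    if alpha is not None and alpha < 0:
        raise ParameterError("alpha must be non-negative")
    K = leadfield.matrix.copy()
    C = K.shape[0]
    K -= K.mean(axis=0, keepdims=True)  # enforce centering
    if alpha is None:
        alpha = default_alpha(leadfield, snr)
    log.info("sloreta_kernel: alpha=%.6g (snr=%.3g)", alpha, snr)

    H = np.eye(C) - 1.0 / C
    gram = K @ K.T + alpha * H
    w, U = np.linalg.eigh(gram)
    cutoff = _EIG_CUTOFF_REL * w.max()
    inv_w = np.where(w > cutoff, 1.0 / np.where(w > cutoff, w, 1.0), 0.0)
    rank = int((w > cutoff).sum())
    if rank < C - 1:
        warnings.warn(
            f"sloreta_kernel: Gram matrix rank {rank} < {C - 1}; "
            "solution restricted to the resolvable subspace",
            stacklevel=2,
        )
    gram_pinv = (U * inv_w) @ U.T
    T = K.T @ gram_pinv  # (3M, C)

    M = K.shape[1] // 3
    T3 = T.reshape(M, 3, C)
    K3 = K.reshape(C, M, 3)
    S = np.einsum("mic,cmj->mij", T3, K3)
    S = 0.5 * (S + np.swapaxes(S, 1, 2))  # symmetrize

    ws, Us = np.linalg.eigh(S)
    wmax = ws.max(axis=1, keepdims=True)
    ok = ws > np.maximum(wmax, 1e-300) * _EIG_CUTOFF_REL
    inv_sqrt = np.where(ok, 1.0 / np.sqrt(np.where(ok, ws, 1.0)), 0.0)
    whiten = np.einsum("mij,mj,mkj->mik", Us, inv_sqrt, Us)

    return InverseKernel(
        transfer=T,
        std_blocks=S,
        std_whitener=whiten,
        alpha=float(alpha),
        channels=list(leadfield.channels),
        node_positions=leadfield.node_positions.copy(),
        node_voxels=None if leadfield.node_voxels is None else leadfield.node_voxels.copy(),
        meta={"engine": leadfield.engine, "snr": snr},
    )


def apply_inverse(kernel: InverseKernel, data: np.ndarray) -> np.ndarray:
    """Minimum-norm 3-vector estimates, (M, 3, n_times)."""
    data = np.atleast_2d(np.asarray(data, dtype=float))
    if data.shape[0] != len(kernel.channels):
        raise ValueError(
            f"data has {data.shape[0]} channels, kernel expects {len(kernel.channels)}"
        )
    # the kernel lives in average-reference space; centering here is exact
    # where relying on T 1 = 0 would leave O(eps) reference leakage
    data = data - data.mean(axis=0, keepdims=True)
    J = kernel.transfer @ data  # (3M, T)
    return J.reshape(kernel.n_nodes, 3, -1)


def cdr_series(erp, kernel: InverseKernel, standardized: bool = True) -> CDRSeries:
    """Standardized current-density magnitude for every 4-ms ERP slice."""
    J = apply_inverse(kernel, erp.data)
    if standardized:
        Jw = np.einsum("mij,mjt->mit", kernel.std_whitener, J)
    else:
        Jw = J
    values = np.sqrt(np.einsum("mit,mit->mt", Jw, Jw))
    return CDRSeries(
        values=values,
        times=np.asarray(erp.times, dtype=float).copy(),
        node_positions=kernel.node_positions,
        node_voxels=kernel.node_voxels,
        standardized=standardized,
    )


def peak_localization(cdr_slice: np.ndarray) -> int:
    """Index of the maximal magnitude; ties break to the lowest node index."""
    x = np.asarray(cdr_slice, dtype=float)
    if x.size == 0 or np.all(np.isnan(x)):
        raise ValueError("cannot localize an empty or all-NaN slice")
    return int(np.nanargmax(x))
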
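"""Standardized low-resolution electromagnetic tomography (sLORETA).

Minimum-norm inverse on the average-reference subspace, standardized by the
3×3 diagonal blocks of the resolution matrix.  For an average-referenced
gain K (sensors × 3M), centering operator H = I − 11ᵀ/N and regularization
α ≥ 0::

    T = Kᵀ (K Kᵀ + α H)⁺            (transfer matrix, pseudo-inverse)
    ĵ = T φ                          (minimum-norm current estimate)
    σ_l = ĵ_lᵀ [ (T K)_ll ]⁺ ĵ_l     (standardized power of source l)

The reported amplitude √σ_l is a pseudo-statistic: on noiseless single-
dipole data its maximum falls exactly on the true source (zero localization
error).  A single calibration constant maps it onto the μA reporting
convention; absolute physical scale is not claimed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .forward import LeadField

__all__ = [
    "InverseOperator",
    "SourceEstimate",
    "build_inverse",
    "apply_sloreta",
    "select_alpha",
]

_EIG_CUTOFF = 1e-12  # relative eigenvalue cutoff for all pseudo-inverses


class InverseError(ValueError):
    pass


def _pinv_sym(mat: np.ndarray, cutoff: float = _EIG_CUTOFF) -> np.ndarray:
    """Pseudo-inverse of a symmetric PSD matrix via eigendecomposition."""
    vals, vecs = np.linalg.eigh(mat)
    tol = cutoff * vals.max() if vals.size and vals.max() > 0 else np.inf
    inv = np.where(vals > tol, 1.0 / np.where(vals > tol, vals, 1.0), 0.0)
    return (vecs * inv) @ vecs.T


@dataclass(frozen=True)
class InverseOperator:
    transfer: np.ndarray  # (n_comp*M, N)
    resolution_inv: np.ndarray  # (M, n_comp, n_comp) pseudo-inverted blocks
    alpha: float
    n_sources: int
    n_comp: int  # 3 (free) or 1 (fixed)
    calibration: float = 1.0

    @property
    def n_channels(self) -> int:
        return self.transfer.shape[1]


@dataclass(frozen=True)
class SourceEstimate:
    amplitude: np.ndarray  # (M, n_samples), standardized, μA convention
    times_s: np.ndarray
    band: str = "full"

    def __post_init__(self) -> None:
        if np.any(self.amplitude < 0):
            raise InverseError("standardized amplitudes must be >= 0")


def build_inverse(lead_field: LeadField, alpha: float,
                  calibration: float = 1.0) -> InverseOperator:
    """Assemble the sLORETA transfer matrix and standardization blocks."""
    if alpha < 0:
        raise InverseError("alpha must be >= 0")
    if not lead_field.average_referenced:
        raise InverseError("lead field must be average-referenced")
    K = lead_field.gain
    N = K.shape[0]
    n_comp = 3 if lead_field.orientation_mode == "free" else 1
    M = lead_field.n_sources
    H = np.eye(N) - np.full((N, N), 1.0 / N)
    C = K @ K.T + alpha * H
    vals = np.linalg.eigvalsh(C)
    # average reference leaves one null direction (the constant vector);
    # fewer than min(3M, N-1) nonzero eigenvalues means degenerate geometry
    expected_rank = min(n_comp * M, N - 1)
    if alpha == 0 and np.sum(vals > _EIG_CUTOFF * vals.max()) < expected_rank:
        raise InverseError("rank-deficient geometry: regularization required")
    T = K.T @ _pinv_sym(C)
    res_inv = np.empty((M, n_comp, n_comp))
    for l in range(M):
        sl = slice(n_comp * l, n_comp * (l + 1))
        block = T[sl] @ K[:, sl]
        block = 0.5 * (block + block.T)
        res_inv[l] = _pinv_sym(block)
    return InverseOperator(transfer=T, resolution_inv=res_inv, alpha=alpha,
                           n_sources=M, n_comp=n_comp,
                           calibration=calibration)


def apply_sloreta(inv_op: InverseOperator, data: np.ndarray,
                  times_s: np.ndarray | None = None,
                  band: str = "full") -> SourceEstimate:
    """Standardized per-source amplitude time series for scalp data (μV).

    The data are re-centered across channels (reference invariance) before
    applying the transfer matrix.
    """
    data = np.atleast_2d(np.asarray(data, dtype=float))
    if data.shape[0] != inv_op.n_channels:
        raise InverseError(
            f"channel mismatch: {data.shape[0]} != {inv_op.n_channels}")
    phi = data - data.mean(axis=0, keepdims=True)
    J = inv_op.transfer @ phi  # (n_comp*M, T)
    Jb = J.reshape(inv_op.n_sources, inv_op.n_comp, -1)
    power = np.einsum("mit,mij,mjt->mt", Jb, inv_op.resolution_inv, Jb)
    amp = inv_op.calibration * np.sqrt(np.maximum(power, 0.0))
    if times_s is None:
        times_s = np.arange(data.shape[1], dtype=float)
    return SourceEstimate(amplitude=amp, times_s=np.asarray(times_s),
                          band=band)


def select_alpha(lead_field: LeadField, lam: float = 1e-2) -> float:
    """Regularization from the gain scale: α = λ · trace(K Kᵀ)/N."""
    if lam < 0:
        raise InverseError("lambda must be >= 0")
    K = lead_field.gain
    return lam * float(np.einsum("ij,ij->", K, K)) / K.shape[0]
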
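"""Elastic network models and per-mode derived quantities.

Two coarse-grained harmonic models are supported, both built on the Cα
trace of a structure:

* **GNM** — the Gaussian network model.  Nodes i, j are connected by a
  uniform spring of constant ``gamma`` whenever their distance is at most
  a cutoff (10 Å by default).  The model is the N×N Kirchhoff (graph
  Laplacian) matrix Γ; fluctuations are isotropic and the inverse
  eigenvalues 1/λ_k set the amplitude of each mode.

* **ANM** — the anisotropic network model.  The 3N×3N Hessian H is built
  from 3×3 super-elements ``-(γ/d²)·Δr Δrᵀ`` for each contact (cutoff
  15 Å by default), giving directional mode shapes.

A connected GNM has exactly one zero mode; a non-degenerate ANM has six
(rigid-body translations/rotations).  These are removed on
decomposition and the remaining modes are indexed k = 1..K from the
softest (lowest frequency, most collective) upward.

Units: distances in Å; spring constant γ arbitrary with k_BT/γ = 1, so
mean-square fluctuations carry no absolute scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "ModelKind",
    "EnmModel",
    "ModeSet",
    "build_kirchhoff",
    "build_hessian",
    "decompose",
    "msf",
    "cross_correlation",
    "collectivity",
    "mode_weights",
    "write_modes",
]

DEFAULT_GNM_CUTOFF = 10.0
DEFAULT_ANM_CUTOFF = 15.0
DEFAULT_ZERO_TOL = 1e-8


class ModelKind(str, Enum):
    GNM = "GNM"
    ANM = "ANM"


@dataclass(frozen=True)
class EnmModel:
    """A built elastic network: the Kirchhoff (GNM) or Hessian (ANM) matrix."""

    kind: ModelKind
    cutoff: float
    gamma: float
    matrix: np.ndarray  # N x N (GNM) or 3N x 3N (ANM), symmetric, rows sum to 0
    n_sites: int

    @property
    def dim(self) -> int:
        return self.matrix.shape[0]


@dataclass(frozen=True)
class ModeSet:
    """Nonzero normal modes of one member's elastic network.

    ``eigenvalues`` are ascending and strictly positive; ``eigenvectors``
    is (dim, K) with orthonormal columns, dim = N for GNM or 3N for ANM.
    ``weights`` are the fractional contributions w_k = λ_k⁻¹ / Σ λ⁻¹
    normalized over the *full* nonzero spectrum (so they sum to 1 only
    when the full spectrum was kept).
    """

    member_id: str
    kind: ModelKind
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    n_zero_removed: int
    collectivity: np.ndarray
    weights: np.ndarray
    n_sites: int

    @property
    def n_modes(self) -> int:
        return len(self.eigenvalues)

    def site_vectors(self, k: int) -> np.ndarray:
        """Mode k (1-based) reshaped to per-site rows: (N,) GNM or (N, 3) ANM."""
        u = self.eigenvectors[:, k - 1]
        if self.kind is ModelKind.ANM:
            return u.reshape(self.n_sites, 3)
        return u


def _check_coords(coords: np.ndarray) -> np.ndarray:
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 3:
        raise ValueError(f"coordinates must be (N, 3), got {coords.shape}")
    if not np.all(np.isfinite(coords)):
        raise ValueError("coordinates contain non-finite values")
    return coords


def build_kirchhoff(coords: np.ndarray, cutoff: float = DEFAULT_GNM_CUTOFF,
                    gamma: float = 1.0) -> EnmModel:
    """Build the GNM Kirchhoff matrix from Cα coordinates.

    Γ_ij = -γ for 0 < d_ij ≤ cutoff, 0 otherwise; Γ_ii = -Σ_{j≠i} Γ_ij.
    """
    coords = _check_coords(coords)
    n = len(coords)
    if n < 2:
        raise ValueError("GNM requires at least 2 sites")
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    d = squareform(pdist(coords))
    off = ~np.eye(n, dtype=bool)
    if np.any(d[off] == 0.0):
        raise ValueError("duplicate coordinates: zero inter-site distance")
    contact = (d <= cutoff) & off
    k = np.where(contact, -gamma, 0.0)
    np.fill_diagonal(k, -k.sum(axis=1))
    return EnmModel(ModelKind.GNM, cutoff, gamma, k, n)


def build_hessian(coords: np.ndarray, cutoff: float = DEFAULT_ANM_CUTOFF,
                  gamma: float = 1.0) -> EnmModel:
    """Build the ANM Hessian from Cα coordinates.

    For each contact the off-diagonal super-element is the rank-1 block
    H_ij = -(γ/d_ij²)·(r_j - r_i)(r_j - r_i)ᵀ; diagonal blocks balance
    their row so rigid-body motions cost no energy.
    """
    coords = _check_coords(coords)
    n = len(coords)
    if n < 3:
        raise ValueError("ANM requires at least 3 sites")
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    d = squareform(pdist(coords))
    off = ~np.eye(n, dtype=bool)
    if np.any(d[off] == 0.0):
        raise ValueError("duplicate coordinates: zero inter-site distance")
    h = np.zeros((3 * n, 3 * n))
    ii, jj = np.where(np.triu((d <= cutoff) & off))
    for i, j in zip(ii, jj):
        dv = coords[j] - coords[i]
        block = -(gamma / (d[i, j] ** 2)) * np.outer(dv, dv)
        h[3 * i:3 * i + 3, 3 * j:3 * j + 3] = block
        h[3 * j:3 * j + 3, 3 * i:3 * i + 3] = block
        h[3 * i:3 * i + 3, 3 * i:3 * i + 3] -= block
        h[3 * j:3 * j + 3, 3 * j:3 * j + 3] -= block
    return EnmModel(ModelKind.ANM, cutoff, gamma, h, n)


def _fix_signs(vecs: np.ndarray) -> np.ndarray:
    """Deterministic sign convention: largest-magnitude component positive."""
    idx = np.argmax(np.abs(vecs), axis=0)
    signs = np.sign(vecs[idx, np.arange(vecs.shape[1])])
    signs[signs == 0] = 1.0
    return vecs * signs


def decompose(model: EnmModel, n_modes: int | None = None,
              zero_tol: float = DEFAULT_ZERO_TOL,
              member_id: str = "") -> ModeSet:
    """Eigendecompose an elastic network and strip its zero modes.

    Eigenvalues below ``zero_tol * λ_max`` are treated as zero modes;
    their count must be 1 (GNM, connected network) or 6 (ANM,
    non-degenerate geometry), otherwise the network is disconnected or
    geometrically degenerate and an error names the member.
    """
    evals, evecs = np.linalg.eigh(model.matrix)
    lam_max = evals[-1]
    if lam_max <= 0:
        raise ValueError("elastic network has no positive eigenvalues")
    nonzero = evals > zero_tol * lam_max
    n_zero = int(np.sum(~nonzero))
    expected = 1 if model.kind is ModelKind.GNM else 6
    if n_zero != expected:
        who = f" for member '{member_id}'" if member_id else ""
        raise ValueError(
            f"disconnected network / degenerate geometry{who}: "
            f"{n_zero} zero modes found, expected {expected} "
            f"({model.kind.value}, cutoff {model.cutoff} Å may be too small)")
    evals = evals[nonzero]
    evecs = _fix_signs(evecs[:, nonzero])
    w = mode_weights(evals)
    if n_modes is not None:
        evals = evals[:n_modes]
        evecs = evecs[:, :n_modes]
        w = w[:n_modes]
    kappa = np.array([collectivity(evecs[:, k], kind=model.kind)
                      for k in range(evecs.shape[1])])
    return ModeSet(member_id, model.kind, evals, evecs, n_zero, kappa, w,
                   model.n_sites)


def _window_slice(modes: ModeSet, window: tuple[int, int] | None) -> slice:
    if window is None:
        return slice(0, modes.n_modes)
    i, j = window
    if not (1 <= i <= j <= modes.n_modes):
        raise ValueError(
            f"invalid mode window [{i}..{j}] for {modes.n_modes} modes")
    return slice(i - 1, j)


def _per_site_square(vecs: np.ndarray, kind: ModelKind,
                     n_sites: int) -> np.ndarray:
    """Squared components per site: (N, K). ANM sums x/y/z per site."""
    sq = vecs ** 2
    if kind is ModelKind.ANM:
        sq = sq.reshape(n_sites, 3, -1).sum(axis=1)
    return sq


def msf(modes: ModeSet, window: tuple[int, int] | None = None) -> np.ndarray:
    """Per-site mean-square fluctuations from a window of modes.

    MSF_n = Σ_{k in window} λ_k⁻¹ u_{k,n}² (ANM: the three Cartesian
    components of site n are summed).  Units k_BT/γ = 1.
    """
    sl = _window_slice(modes, window)
    inv = 1.0 / modes.eigenvalues[sl]
    sq = _per_site_square(modes.eigenvectors[:, sl], modes.kind, modes.n_sites)
    return sq @ inv


def cross_correlation(modes: ModeSet, window: tuple[int, int] | None = None,
                      normalized: bool = False) -> np.ndarray:
    """N×N covariance (cross-correlation) map from a window of modes.

    C_mn = Σ_k λ_k⁻¹ u_{k,m} u_{k,n}; for ANM the 3-vectors of sites m
    and n are dotted.  The normalized variant C_mn/√(C_mm C_nn) lies in
    [-1, 1] with unit diagonal.
    """
    sl = _window_slice(modes, window)
    inv = 1.0 / modes.eigenvalues[sl]
    vecs = modes.eigenvectors[:, sl]
    if modes.kind is ModelKind.ANM:
        v = vecs.reshape(modes.n_sites, 3, -1)
        cov = np.einsum("k,mak,nak->mn", inv, v, v)
    else:
        cov = (vecs * inv) @ vecs.T
    if normalized:
        diag = np.diag(cov)
        if np.any(diag <= 0):
            raise ValueError("cannot normalize: zero diagonal covariance")
        cov = cov / np.sqrt(np.outer(diag, diag))
    return cov


def collectivity(u: np.ndarray, kind: ModelKind = ModelKind.GNM) -> float:
    """Degree of collectivity κ of a unit-norm mode (entropy form).

    With per-site participations p_n = u_n² (ANM: summed over x/y/z),
    κ = exp(-Σ p_n ln p_n)/N ∈ [1/N, 1]: 1 for a uniform mode, 1/N for
    one localized on a single site.  0·ln 0 is taken as 0.
    """
    u = np.asarray(u, dtype=float)
    norm = np.linalg.norm(u)
    if not np.isclose(norm, 1.0, atol=1e-6):
        raise ValueError(f"eigenvector must be unit-norm (got ‖u‖={norm:.6g})")
    p = u ** 2
    if kind is ModelKind.ANM:
        if len(p) % 3:
            raise ValueError("ANM mode length must be a multiple of 3")
        p = p.reshape(-1, 3).sum(axis=1)
    p = p / p.sum()
    nz = p > 0
    entropy = -np.sum(p[nz] * np.log(p[nz]))
    return float(np.exp(entropy) / len(p))


def mode_weights(eigenvalues: Sequence[float]) -> np.ndarray:
    """Fractional mode weights w_k = λ_k⁻¹ / Σ_l λ_l⁻¹ (non-increasing)."""
    lam = np.asarray(eigenvalues, dtype=float)
    if np.any(lam <= 0):
        raise ValueError("eigenvalues must be strictly positive")
    inv = 1.0 / lam
    return inv / inv.sum()


def write_modes(path, modes: ModeSet) -> None:
    """Plain-text mode dump: one line per mode, ``k λ_k u_k1 u_k2 ...``."""
    with open(path, "w") as fh:
        for k in range(1, modes.n_modes + 1):
            comps = " ".join(f"{c:.6g}" for c in modes.eigenvectors[:, k - 1])
            fh.write(f"{k} {modes.eigenvalues[k - 1]:.6g} {comps}\n")
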
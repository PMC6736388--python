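"""Match mode spectra across family members and measure their (dis)similarity.

Each member's elastic network is decomposed on its core Cα positions.
Because eigenvalue order is not stable across homologs, every member's
modes are re-ordered against a reference member by maximizing mode–mode
correlation cosines ("equivalent modes"), with signs flipped so matched
dot products are non-negative.  On the matched ensemble we compute:

* the per-mode conservation profile cc_k — the correlation cosine of
  equivalent mode k averaged over all M(M-1)/2 member pairs;
* the spectral overlap SO_ij between two members over a mode window
  i..j — a covariance-overlap with mode variances σ_k = 1/λ_k — and the
  spectral distance d = arccos(SO), a metric used for classification;
* signature profiles: family mean ± SD of per-residue mean-square
  fluctuations and of residue–residue cross-correlation maps.

Mode windows follow the frequency regimes used throughout: global
(k ≤ 3), LF (4–20), LTIF (21–60), HF (k > 60), and a very-high-frequency
tail (VHF).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

from .enm import (ModeSet, ModelKind, build_hessian, build_kirchhoff,
                  decompose, DEFAULT_ANM_CUTOFF, DEFAULT_GNM_CUTOFF)
from .ensemble import FamilyEnsemble

__all__ = [
    "ModeEnsemble",
    "default_regimes",
    "correlation_cosine",
    "match_modes",
    "build_mode_ensemble",
    "conservation_profile",
    "spectral_overlap",
    "spectral_distance",
    "pairwise_spectral_distances",
    "cumulative_overlap_curve",
    "signature_msf",
    "signature_covariance",
    "extreme_sites",
    "write_nmd",
]

MAX_MATCH_MODES = 100  # matching beyond this adds noise, not signal


def default_regimes(n_modes: int, vhf_size: int | None = None
                    ) -> dict[str, tuple[int, int]]:
    """Named frequency windows clipped to the available K modes.

    global [1..3], LF [4..20], LTIF [21..60], HF [61..K], and VHF —
    the last max(3, ceil(0.02 K)) modes.  Windows that vanish after
    clipping are omitted.
    """
    if vhf_size is None:
        vhf_size = max(3, math.ceil(0.02 * n_modes))
    raw = {
        "global": (1, 3),
        "lf": (4, 20),
        "ltif": (21, 60),
        "hf": (61, n_modes),
        "vhf": (max(1, n_modes - vhf_size + 1), n_modes),
    }
    return {name: (i, min(j, n_modes)) for name, (i, j) in raw.items()
            if i <= min(j, n_modes)}


def correlation_cosine(u: np.ndarray, v: np.ndarray) -> float:
    """|cos| of the angle between two mode vectors; sign-invariant, in [0,1]."""
    u, v = np.asarray(u, float), np.asarray(v, float)
    if u.shape != v.shape:
        raise ValueError("vectors must have equal dimension")
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("zero vector has no direction")
    return float(min(abs(u @ v) / (nu * nv), 1.0))


def match_modes(reference: ModeSet | np.ndarray, member: ModeSet | np.ndarray,
                method: str = "greedy", n_match: int | None = None):
    """One-to-one assignment of member modes to reference modes.

    ``greedy`` repeatedly takes the largest remaining |cosine| in the
    cross-cosine matrix; ``optimal`` solves the assignment problem
    maximizing the summed cosines.  Returns ``(permutation, sign_flips)``
    where ``permutation[k]`` is the member mode matched to reference
    mode k (0-based) and flips make each matched dot product ≥ 0.
    Deterministic: ties go to the lowest (reference, member) index pair.
    """
    uref = reference.eigenvectors if isinstance(reference, ModeSet) else reference
    umem = member.eigenvectors if isinstance(member, ModeSet) else member
    if uref.shape[0] != umem.shape[0]:
        raise ValueError("mode vectors must share dimension")
    kmax = min(uref.shape[1], umem.shape[1], MAX_MATCH_MODES)
    n = kmax if n_match is None else n_match
    if n > min(uref.shape[1], umem.shape[1]):
        raise ValueError("n_match exceeds available modes")
    dots = uref[:, :n].T @ umem[:, :n]
    cos = np.abs(dots)
    if method == "optimal":
        rows, cols = linear_sum_assignment(-cos)
        perm = np.empty(n, dtype=int)
        perm[rows] = cols
    elif method == "greedy":
        perm = np.full(n, -1, dtype=int)
        c = cos.copy()
        for _ in range(n):
            k, j = np.unravel_index(np.argmax(c), c.shape)  # row-major ties
            perm[k] = j
            c[k, :] = -1.0
            c[:, j] = -1.0
    else:
        raise ValueError(f"unknown matching method '{method}'")
    flips = np.where(dots[np.arange(n), perm] < 0, -1.0, 1.0)
    return perm, flips


@dataclass
class ModeEnsemble:
    """Per-member mode sets matched ("equivalent modes") to a reference.

    ``vectors`` is (M, dim, K): member eigenvectors embedded on the full
    core (zeros at positions a member lacks, then re-normalized),
    reordered to the reference mode order and sign-aligned.
    ``eigenvalues`` is (M, K) in the same matched order.
    """

    member_ids: list[str]
    kind: ModelKind
    n_sites: int
    mode_sets: list[ModeSet]
    vectors: np.ndarray
    eigenvalues: np.ndarray
    permutations: np.ndarray  # (M, K)
    sign_flips: np.ndarray  # (M, K)
    reference_index: int
    mask: np.ndarray  # (M, N) core presence per member
    matched: bool = True

    @property
    def n_members(self) -> int:
        return len(self.member_ids)

    @property
    def n_modes(self) -> int:
        return self.vectors.shape[2]

    def regimes(self) -> dict[str, tuple[int, int]]:
        return default_regimes(self.n_modes)

    def natural_order(self, i: int) -> tuple[np.ndarray, np.ndarray]:
        """Member i's (eigenvalues, vectors) back in its own ascending order.

        Windowed quantities (MSF, spectral overlap over modes i..j) select
        each member's *own* softest-to-fastest modes; the matched order is
        for per-mode comparisons (conservation, signature mode shapes).
        """
        inv = np.argsort(self.permutations[i])
        return self.eigenvalues[i][inv], self.vectors[i][:, inv]

    def pair_vectors(self, a: int, b: int):
        """Natural-order spectra of members a and b on their shared core.

        Positions absent in *either* member are zeroed in both members'
        mode vectors, which are then re-normalized, so a truncated
        terminus does not inflate the apparent spectral distance of an
        otherwise similar pair.  Pairs with complete cores are returned
        unchanged; self-comparison still yields unit overlap.
        """
        ea, va = self.natural_order(a)
        eb, vb = self.natural_order(b)
        shared = self.mask[a] & self.mask[b]
        if shared.all():
            return ea, va, eb, vb
        per_site = 3 if self.kind is ModelKind.ANM else 1
        keep = np.repeat(shared, per_site)
        out = []
        for vec in (va, vb):
            v = np.where(keep[:, None], vec, 0.0)
            norms = np.linalg.norm(v, axis=0)
            out.append(v / np.where(norms == 0, 1.0, norms))
        return ea, out[0], eb, out[1]


def _embed(vecs: np.ndarray, mask: np.ndarray, kind: ModelKind,
           n_sites: int) -> np.ndarray:
    """Zero-fill member eigenvectors onto the full core; re-normalize."""
    per_site = 3 if kind is ModelKind.ANM else 1
    full = np.zeros((n_sites * per_site, vecs.shape[1]))
    idx = np.repeat(np.where(mask)[0] * per_site,
                    per_site) + np.tile(np.arange(per_site), mask.sum())
    full[idx] = vecs
    norms = np.linalg.norm(full, axis=0)
    return full / np.where(norms == 0, 1.0, norms)


def build_mode_ensemble(ensemble: FamilyEnsemble,
                        kind: ModelKind = ModelKind.GNM,
                        cutoff: float | None = None,
                        n_modes: int | None = None,
                        match_method: str = "greedy") -> ModeEnsemble:
    """ENM + decomposition per member, then match all members to the reference.

    Each member's network is built on its present core coordinates; its
    eigenvectors are embedded on the full core dimension (zeros at absent
    positions, re-normalized) so all comparison vectors share dimension.
    """
    kind = ModelKind(kind)
    if cutoff is None:
        cutoff = DEFAULT_GNM_CUTOFF if kind is ModelKind.GNM \
            else DEFAULT_ANM_CUTOFF
    builder = build_kirchhoff if kind is ModelKind.GNM else build_hessian
    mode_sets, embedded = [], []
    for i, mid in enumerate(ensemble.member_ids):
        pts = ensemble.coords[i][ensemble.mask[i]]
        model = builder(pts, cutoff=cutoff)
        ms = decompose(model, n_modes=n_modes, member_id=mid)
        mode_sets.append(ms)
        embedded.append(_embed(ms.eigenvectors, ensemble.mask[i], kind,
                               ensemble.n_core))
    k = min(ms.n_modes for ms in mode_sets)
    if n_modes is not None:
        k = min(k, n_modes)
    ref = ensemble.reference_index
    m = ensemble.n_members
    dim = embedded[0].shape[0]
    vectors = np.zeros((m, dim, k))
    eigenvalues = np.zeros((m, k))
    perms = np.zeros((m, k), dtype=int)
    flips = np.ones((m, k))
    n_match = min(k, MAX_MATCH_MODES)
    for i in range(m):
        if i == ref:
            perm = np.arange(n_match)
            flip = np.ones(n_match)
        else:
            perm, flip = match_modes(embedded[ref][:, :k], embedded[i][:, :k],
                                     method=match_method, n_match=n_match)
        full_perm = np.arange(k)
        full_perm[:n_match] = perm
        full_flip = np.ones(k)
        full_flip[:n_match] = flip
        perms[i], flips[i] = full_perm, full_flip
        vectors[i] = embedded[i][:, full_perm] * full_flip
        eigenvalues[i] = mode_sets[i].eigenvalues[full_perm]
    return ModeEnsemble(list(ensemble.member_ids), kind, ensemble.n_core,
                        mode_sets, vectors, eigenvalues, perms, flips, ref,
                        ensemble.mask.copy())


# ------------------------------------------------------------ conservation

@dataclass(frozen=True)
class ConservationProfile:
    cc_mean: np.ndarray  # per mode k
    cc_sd: np.ndarray
    n_pairs: int


def conservation_profile(me: ModeEnsemble) -> ConservationProfile:
    """Mean ± SD over member pairs of |u_k^A · u_k^B| for each matched mode."""
    if not me.matched:
        raise ValueError("mode ensemble is not matched")
    m, k = me.n_members, me.n_modes
    pairs = []
    for a in range(m):
        for b in range(a + 1, m):
            dots = np.einsum("dk,dk->k", me.vectors[a], me.vectors[b])
            pairs.append(np.abs(dots))
    arr = np.array(pairs)
    return ConservationProfile(arr.mean(axis=0), arr.std(axis=0), len(pairs))


# -------------------------------------------------------- spectral overlap

def _window(window, k):
    if window is None:
        return 0, k
    i, j = window
    j = min(j, k)
    if not (1 <= i <= j):
        raise ValueError(f"empty or invalid mode window [{window[0]}..{window[1]}]")
    return i - 1, j


def spectral_overlap(eig_a, vec_a=None, eig_b=None, vec_b=None,
                     window: tuple[int, int] | None = None) -> float:
    """Covariance overlap of two matched mode subsets, in [0, 1].

    With per-mode variances σ_k = 1/λ_k,
    SO = 1 − √[(Σ(σ_k^A + σ_k^B) − 2ΣΣ √(σ_k^A σ_l^B)(u_k^A·u_l^B)²)
               / Σ(σ_k^A + σ_k^B)];
    identical mode sets give 1, mutually orthogonal subspaces give 0.
    Accepts ModeSet objects or (eigenvalues, eigenvectors) arrays whose
    mode order has already been matched.
    """
    if isinstance(eig_a, ModeSet):
        if isinstance(vec_a, ModeSet) and eig_b is None:
            eig_b, vec_b = vec_a.eigenvalues, vec_a.eigenvectors
        eig_a, vec_a = eig_a.eigenvalues, eig_a.eigenvectors
    if isinstance(eig_b, ModeSet):
        eig_b, vec_b = eig_b.eigenvalues, eig_b.eigenvectors
    if vec_a is None or eig_b is None or vec_b is None:
        raise TypeError("provide two ModeSets or two (eigenvalues, "
                        "eigenvectors) pairs")
    if vec_a.shape[0] != vec_b.shape[0]:
        raise ValueError("mode vectors must share dimension")
    k = min(vec_a.shape[1], vec_b.shape[1])
    lo, hi = _window(window, k)
    sa, sb = 1.0 / eig_a[lo:hi], 1.0 / eig_b[lo:hi]
    ua, ub = vec_a[:, lo:hi], vec_b[:, lo:hi]
    cross = np.sqrt(np.outer(sa, sb)) * (ua.T @ ub) ** 2
    denom = sa.sum() + sb.sum()
    rad = (denom - 2.0 * cross.sum()) / denom
    return float(1.0 - math.sqrt(max(rad, 0.0)))


def spectral_distance(eig_a, vec_a=None, eig_b=None, vec_b=None,
                      window=None) -> float:
    """d = arccos(SO) in radians, in [0, π/2]; 0 iff the spectra coincide."""
    so = spectral_overlap(eig_a, vec_a, eig_b, vec_b, window)
    return float(math.acos(min(max(so, 0.0), 1.0)))


def pairwise_spectral_distances(me: ModeEnsemble,
                                window=None) -> np.ndarray:
    """Member × member spectral distance matrix over a mode window."""
    m = me.n_members
    d = np.zeros((m, m))
    for a in range(m):
        for b in range(a + 1, m):
            d[a, b] = d[b, a] = spectral_distance(*me.pair_vectors(a, b),
                                                  window=window)
    return d


@dataclass(frozen=True)
class OverlapCurve:
    n: np.ndarray  # mode counts 1..K
    so_mean: np.ndarray  # mean over pairs of SO over [1..n]
    so_sd: np.ndarray
    argmin: int  # n at which the mean cumulative overlap is minimal
    cum_weight: np.ndarray  # member-averaged cumulative mode weight


def cumulative_overlap_curve(me: ModeEnsemble) -> OverlapCurve:
    """Cumulative spectral overlap SO(1..n) vs n, averaged over member pairs.

    The curve typically peaks at the soft end (conserved global modes),
    dips where members differentiate, and climbs back toward 1 as the
    mode set approaches a complete basis.  Uses 2-D prefix sums of the
    weighted cross-cosine matrix, so the whole curve costs one K×K
    product per pair.
    """
    m, k = me.n_members, me.n_modes
    curves = []
    for a in range(m):
        for b in range(a + 1, m):
            ea, va, eb, vb = me.pair_vectors(a, b)
            sa, sb = 1.0 / ea, 1.0 / eb
            ov = (va.T @ vb) ** 2
            w = np.sqrt(np.outer(sa, sb)) * ov
            cross = w.cumsum(axis=0).cumsum(axis=1).diagonal()
            denom = np.cumsum(sa + sb)
            rad = np.maximum((denom - 2.0 * cross) / denom, 0.0)
            curves.append(1.0 - np.sqrt(rad))
    arr = np.array(curves)
    mean = arr.mean(axis=0)
    weights = np.array([np.cumsum(ms.weights[:k])
                        for ms in me.mode_sets])
    return OverlapCurve(np.arange(1, k + 1), mean, arr.std(axis=0),
                        int(np.argmin(mean)) + 1, weights.mean(axis=0))


# ------------------------------------------------------ signature profiles

@dataclass(frozen=True)
class SignatureProfile:
    window: tuple[int, int]
    mean: np.ndarray
    sd: np.ndarray
    min: np.ndarray
    max: np.ndarray
    per_member: np.ndarray  # (M, N), NaN where a member lacks the position


def _member_site_msf(me: ModeEnsemble, i: int, lo: int, hi: int) -> np.ndarray:
    eig, vec = me.natural_order(i)
    inv = 1.0 / eig[lo:hi]
    sq = vec[:, lo:hi] ** 2
    if me.kind is ModelKind.ANM:
        sq = sq.reshape(me.n_sites, 3, -1).sum(axis=1)
    out = sq @ inv
    out[~me.mask[i]] = np.nan
    return out


def signature_msf(me: ModeEnsemble, window: tuple[int, int] | None = None,
                  as_rmsf: bool = False) -> SignatureProfile:
    """Family mean/SD/min/max of per-residue MSF (or RMSF) over a window.

    Positions absent in a member are excluded from that member's
    contribution to the statistics.
    """
    k = me.n_modes
    lo, hi = _window(window, k)
    per = np.array([_member_site_msf(me, i, lo, hi)
                    for i in range(me.n_members)])
    if as_rmsf:
        per = np.sqrt(per)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return SignatureProfile(
            (1, hi) if window is None else (window[0], hi),
            np.nanmean(per, axis=0), np.nanstd(per, axis=0),
            np.nanmin(per, axis=0), np.nanmax(per, axis=0), per)


@dataclass(frozen=True)
class SignatureCovariance:
    window: tuple[int, int]
    mean: np.ndarray  # N×N
    sd: np.ndarray  # N×N
    sd_row_average: np.ndarray  # length N


def signature_covariance(me: ModeEnsemble,
                         window: tuple[int, int] | None = None,
                         normalized: bool = True) -> SignatureCovariance:
    """Elementwise mean and SD over members of the residue covariance maps."""
    k = me.n_modes
    lo, hi = _window(window, k)
    maps = []
    for i in range(me.n_members):
        eig, vec = me.natural_order(i)
        inv = 1.0 / eig[lo:hi]
        v = vec[:, lo:hi]
        if me.kind is ModelKind.ANM:
            vv = v.reshape(me.n_sites, 3, -1)
            cov = np.einsum("k,mak,nak->mn", inv, vv, vv)
        else:
            cov = (v * inv) @ v.T
        absent = ~me.mask[i]
        if normalized:
            diag = np.diag(cov).copy()
            diag[absent] = 1.0  # masked below
            if np.any(diag <= 0):
                raise ValueError("cannot normalize: zero diagonal covariance")
            cov = cov / np.sqrt(np.outer(diag, diag))
        cov[absent, :] = np.nan
        cov[:, absent] = np.nan
        maps.append(cov)
    arr = np.array(maps)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(arr, axis=0)
        sd = np.nanstd(arr, axis=0)
        row_avg = np.nanmean(sd, axis=1)
    win = (1, hi) if window is None else (window[0], hi)
    return SignatureCovariance(win, mean, sd, row_avg)


def extreme_sites(profile: np.ndarray, kind: str = "minima",
                  frac_threshold: float = 0.05) -> np.ndarray:
    """Near-zero sites or local peaks of a per-residue profile (1-based).

    Minima — e.g. the pivotal hinge sites of a global-mode shape or of a
    covariance row-average — are sites where |value| falls at or below
    ``frac_threshold`` of the profile's largest magnitude.  Maxima are
    local peaks above (1 − frac_threshold) of the maximum.  A flat
    profile has no extreme sites.
    """
    v = np.asarray(profile, dtype=float)
    if v.size == 0:
        raise ValueError("empty profile")
    if np.ptp(v) < 1e-12:
        return np.array([], dtype=int)
    mag = np.abs(v)
    if kind == "minima":
        return np.where(mag <= frac_threshold * mag.max())[0] + 1
    if kind == "maxima":
        lvl = (1.0 - frac_threshold) * v.max()
        left = np.r_[-np.inf, v[:-1]]
        right = np.r_[v[1:], -np.inf]
        return np.where((v >= left) & (v >= right) & (v >= lvl))[0] + 1
    raise ValueError(f"unknown kind '{kind}'")


def write_nmd(path, name: str, coords: np.ndarray, modes: np.ndarray,
              scales=None) -> None:
    """Write modes in NMD format for normal-mode viewers.

    ``coords`` is (N, 3); ``modes`` is (3N, K) with one column per mode;
    ``scales`` defaults to 1 per mode.
    """
    modes = np.atleast_2d(modes)
    if modes.shape[0] != 3 * len(coords):
        raise ValueError("modes must have 3N rows")
    if scales is None:
        scales = np.ones(modes.shape[1])
    with open(path, "w") as fh:
        fh.write(f"name {name}\n")
        fh.write("coordinates " +
                 " ".join(f"{c:.3f}" for c in np.ravel(coords)) + "\n")
        for k in range(modes.shape[1]):
            comps = " ".join(f"{c:.6f}" for c in modes[:, k])
            fh.write(f"mode {k + 1} {scales[k]:.6f} {comps}\n")
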
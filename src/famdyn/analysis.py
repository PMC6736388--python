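"""Sequence–dynamics coupling and classification of family members.

Three complementary distances classify the members of a fold family:

* sequence — Hamming distance d_H = 1 − (fraction of identical residues
  over mutually aligned core positions);
* structure — pairwise Cα RMSD after superposition, or the TM-score
  based distance 1 − TM;
* dynamics — the spectral distance arccos(SO) between mode spectra,
  evaluated per frequency regime.

Member–member distances are averaged over subfamilies to expose which
frequency regime discriminates subfamilies (typically the
low-to-intermediate one), and UPGMA dendrograms re-order the matrices
for display.  Sequence variability per core column (Shannon entropy, in
nats) is related to the divergence of residue fluctuations ΔRMSF — the
across-member standard deviation of RMSF — via a binned curve and a
lognormal fit of the entropy histogram.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .ensemble import FamilyEnsemble, pairwise_matrices
from .modes import ModeEnsemble, ModelKind, pairwise_spectral_distances, \
    signature_msf

__all__ = [
    "DistanceMatrix",
    "SubfamilyDistanceMatrix",
    "shannon_entropy",
    "delta_rmsf",
    "entropy_binned_divergence",
    "subfamily_distances",
    "sequence_distance_matrix",
    "rmsd_distance_matrix",
    "tm_score",
    "tm_distance_matrix",
    "dendrogram",
    "structure_pca",
    "project_on_signature_modes",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class DistanceMatrix:
    labels: list[str]
    matrix: np.ndarray
    metric: str  # hamming | rmsd | tm_distance | spectral

    def __post_init__(self):
        m = self.matrix
        if m.shape[0] != m.shape[1] or len(self.labels) != m.shape[0]:
            raise ValueError("distance matrix shape/label mismatch")
        if not np.allclose(m, m.T):
            raise ValueError("distance matrix must be symmetric")


@dataclass(frozen=True)
class SubfamilyDistanceMatrix:
    labels: list[str]  # qualifying subfamily names
    sizes: list[int]
    window: tuple[int, int] | None
    matrix: np.ndarray  # m×m; diagonal = within-subfamily averages
    excluded: list[str]  # subfamilies below the size floor


# -------------------------------------------------------- entropy / ΔRMSF

def shannon_entropy(ensemble: FamilyEnsemble) -> np.ndarray:
    """Per-core-column Shannon entropy H (nats) of amino-acid frequencies.

    Gaps are excluded from the frequencies; an all-gap column yields
    NaN.  Range [0, ln 20].
    """
    n = ensemble.n_core
    h = np.full(n, np.nan)
    for j in range(n):
        col = [s[j] for s in ensemble.aligned_seqs if s[j] in AMINO_ACIDS]
        if not col:
            continue
        _, counts = np.unique(col, return_counts=True)
        f = counts / counts.sum()
        h[j] = float(-(f * np.log(f)).sum())
    return h


def delta_rmsf(me: ModeEnsemble, window: tuple[int, int] | None = None,
               kind: str = "sd") -> np.ndarray:
    """Divergence of residue flexibility across members, per core column.

    ΔRMSF_j is the across-member standard deviation (ddof=1) of RMSF_j
    computed from the mode window; ``kind="range"`` returns max − min
    instead.  Windows beyond the available K are clipped with a warning.
    """
    if window is not None and window[1] > me.n_modes:
        warnings.warn(f"mode window {window} clipped to K={me.n_modes}")
    prof = signature_msf(me, window, as_rmsf=True)
    per = prof.per_member
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        if kind == "range":
            return np.nanmax(per, axis=0) - np.nanmin(per, axis=0)
        if kind != "sd":
            raise ValueError(f"unknown kind '{kind}'")
        counts = np.sum(np.isfinite(per), axis=0)
        sd = np.nanstd(per, axis=0, ddof=1)
        sd[counts < 2] = np.nan
        return sd


@dataclass(frozen=True)
class EntropyDivergenceCurve:
    bin_centers: np.ndarray
    mean_divergence: np.ndarray
    bin_counts: np.ndarray
    hist_centers: np.ndarray
    hist_density: np.ndarray
    lognorm_mu: float
    lognorm_sigma: float
    pearson_r: float


def entropy_binned_divergence(entropy: np.ndarray, divergence: np.ndarray,
                              bin_width: float = 0.15,
                              min_count: int = 3) -> EntropyDivergenceCurve:
    """Bin ΔRMSF by sequence entropy; fit a lognormal to the entropy histogram.

    Columns are binned by H with the given width; bins holding fewer
    than ``min_count`` columns are dropped from the curve.  The
    lognormal (μ, σ) is the maximum-likelihood fit to H > 0 values, and
    ``pearson_r`` correlates the empirical bin densities with the fitted
    density at bin centers.
    """
    h = np.asarray(entropy, float)
    d = np.asarray(divergence, float)
    if h.shape != d.shape:
        raise ValueError("entropy and divergence profiles differ in length")
    ok = np.isfinite(h) & np.isfinite(d)
    h, d = h[ok], d[ok]
    pos = h[h > 0]
    if pos.size < 3 or np.ptp(pos) < 1e-12:
        raise ValueError("entropy profile too degenerate for a lognormal fit")
    edges = np.arange(0.0, h.max() + bin_width, bin_width)
    if edges[-1] <= h.max():
        edges = np.append(edges, edges[-1] + bin_width)
    idx = np.digitize(h, edges) - 1
    centers, means, counts = [], [], []
    for b in range(len(edges) - 1):
        sel = idx == b
        if sel.sum() >= min_count:
            centers.append(0.5 * (edges[b] + edges[b + 1]))
            means.append(d[sel].mean())
            counts.append(int(sel.sum()))
    dens, hedges = np.histogram(pos, bins=edges, density=True)
    hcenters = 0.5 * (hedges[:-1] + hedges[1:])
    shape, _, scale = stats.lognorm.fit(pos, floc=0)
    mu, sigma = float(np.log(scale)), float(shape)
    fitted = stats.lognorm.pdf(hcenters, shape, 0, scale)
    nz = dens > 0
    r = float(stats.pearsonr(dens[nz], fitted[nz])[0]) if nz.sum() > 2 \
        else float("nan")
    return EntropyDivergenceCurve(np.array(centers), np.array(means),
                                  np.array(counts), hcenters, dens,
                                  mu, sigma, r)


# ------------------------------------------------------ distance matrices

def sequence_distance_matrix(ensemble: FamilyEnsemble) -> DistanceMatrix:
    """Hamming distances d_H = 1 − sequence identity over shared core sites."""
    mats = pairwise_matrices(ensemble)
    d = 1.0 - mats["seq_identity"]
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(list(ensemble.member_ids), d, "hamming")


def rmsd_distance_matrix(ensemble: FamilyEnsemble) -> DistanceMatrix:
    return DistanceMatrix(list(ensemble.member_ids),
                          pairwise_matrices(ensemble)["rmsd"], "rmsd")


def tm_score(coords_a: np.ndarray, coords_b: np.ndarray,
             l_norm: int | None = None) -> float:
    """TM-score over a fixed (core) alignment of superposed coordinates.

    TM = (1/L_norm) Σ_i 1/(1 + (d_i/d_0)²) with
    d_0 = max(0.5, 1.24·(L_norm − 15)^⅓ − 1.8).  No rotational search is
    performed: the coordinates are taken as already superposed on the
    shared core.  NaN rows (absent positions) are skipped.
    """
    a, b = np.asarray(coords_a, float), np.asarray(coords_b, float)
    ok = np.all(np.isfinite(a), axis=1) & np.all(np.isfinite(b), axis=1)
    if l_norm is None:
        l_norm = len(a)
    if l_norm < 1:
        raise ValueError("l_norm must be at least 1")
    d0 = max(0.5, 1.24 * (l_norm - 15) ** (1.0 / 3.0) - 1.8) \
        if l_norm > 15 else 0.5
    dist = np.linalg.norm(a[ok] - b[ok], axis=1)
    return float(np.sum(1.0 / (1.0 + (dist / d0) ** 2)) / l_norm)


def tm_distance_matrix(ensemble: FamilyEnsemble) -> DistanceMatrix:
    """1 − TM-score on the core alignment, per member pair."""
    m = ensemble.n_members
    d = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            tm = tm_score(ensemble.coords[i], ensemble.coords[j],
                          l_norm=ensemble.n_core)
            d[i, j] = d[j, i] = 1.0 - tm
    return DistanceMatrix(list(ensemble.member_ids), d, "tm_distance")


def spectral_distance_matrix(me: ModeEnsemble,
                             window=None) -> DistanceMatrix:
    return DistanceMatrix(list(me.member_ids),
                          pairwise_spectral_distances(me, window), "spectral")


def subfamily_distances(me: ModeEnsemble, labels, window=None,
                        min_size: int = 4) -> SubfamilyDistanceMatrix:
    """Subfamily × subfamily mean spectral distances over a mode window.

    Entry (p, s) averages the member-pair spectral distances across the
    two subfamilies; diagonal entries average within-subfamily pairs.
    Subfamilies with fewer than ``min_size`` members are excluded (and
    reported).
    """
    if isinstance(labels, dict):
        labels = [labels[mid] for mid in me.member_ids]
    labels = list(labels)
    if len(labels) != me.n_members:
        raise ValueError("one subfamily label per member required")
    names = sorted(set(labels))
    groups = {g: [i for i, l in enumerate(labels) if l == g] for g in names}
    qual = [g for g in names if len(groups[g]) >= min_size]
    excluded = [g for g in names if g not in qual]
    if len(qual) < 2:
        raise ValueError(
            f"need at least 2 subfamilies with >= {min_size} members "
            f"(got {len(qual)})")
    dmat = pairwise_spectral_distances(me, window)
    m = len(qual)
    out = np.zeros((m, m))
    for p in range(m):
        gp = groups[qual[p]]
        within = [dmat[a, b] for ai, a in enumerate(gp) for b in gp[ai + 1:]]
        out[p, p] = float(np.mean(within))
        for s in range(p + 1, m):
            gs = groups[qual[s]]
            cross = dmat[np.ix_(gp, gs)]
            out[p, s] = out[s, p] = float(cross.mean())
    return SubfamilyDistanceMatrix(qual, [len(groups[g]) for g in qual],
                                   window, out, excluded)


# ---------------------------------------------------------- classification

def _min_leaf(node, labels):
    if node.is_leaf():
        return labels[node.id]
    return min(_min_leaf(node.get_left(), labels),
               _min_leaf(node.get_right(), labels))


def _newick(node, labels) -> str:
    if node.is_leaf():
        return labels[node.id]
    children = sorted((node.get_left(), node.get_right()),
                      key=lambda c: _min_leaf(c, labels))
    parts = [f"{_newick(c, labels)}:{node.dist / 2.0 - c.dist / 2.0:g}"
             for c in children]
    return "(" + ",".join(parts) + ")"


def dendrogram(dm: DistanceMatrix, linkage: str = "upgma"):
    """UPGMA (or complete/single) tree from a distance matrix.

    Returns ``(newick, leaf_order, linkage_matrix)``; leaf order re-sorts
    the distance matrix for display.  Branch lengths place each merge at
    half its cophenetic distance, so ultrametric input is reconstructed
    exactly.
    """
    method = {"upgma": "average", "complete": "complete",
              "single": "single"}.get(linkage)
    if method is None:
        raise ValueError(f"unknown linkage '{linkage}'")
    if dm.matrix.shape[0] < 2:
        raise ValueError("need at least 2 members for a dendrogram")
    z = hierarchy.linkage(squareform(dm.matrix, checks=False), method=method)
    tree = hierarchy.to_tree(z)
    order = [dm.labels[i] for i in hierarchy.leaves_list(z)]
    return _newick(tree, dm.labels) + ";", order, z


def cluster_members(dm: DistanceMatrix, n_clusters: int,
                    linkage: str = "upgma") -> np.ndarray:
    """Cut the dendrogram into ``n_clusters`` flat clusters (1-based ids)."""
    _, _, z = dendrogram(dm, linkage)
    return hierarchy.fcluster(z, t=n_clusters, criterion="maxclust")


@dataclass(frozen=True)
class StructurePca:
    components: np.ndarray  # (n_pc, 3N)
    projections: np.ndarray  # (M, n_pc)
    variance_fractions: np.ndarray
    member_ids: list[str]
    degenerate: bool = False


def structure_pca(ensemble: FamilyEnsemble, n_pc: int = 2) -> StructurePca:
    """Principal components of structural variation across members.

    Members with incomplete cores are excluded; each remaining member's
    flattened deviation from the mean structure is a sample, and the top
    components of the 3N×3N covariance give the projection axes.
    Identical members give zero covariance; the result is then flagged
    degenerate with all-zero projections.
    """
    full = np.where(ensemble.mask.all(axis=1))[0]
    if len(full) < 3:
        raise ValueError("structure PCA needs >= 3 complete-core members")
    x = ensemble.coords[full].reshape(len(full), -1)
    x = x - x.mean(axis=0)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    total = float(np.sum(s ** 2))
    if total < 1e-12:
        warnings.warn("zero structural variance: PCA is degenerate")
        return StructurePca(np.zeros((n_pc, x.shape[1])),
                            np.zeros((len(full), n_pc)), np.zeros(n_pc),
                            [ensemble.member_ids[i] for i in full], True)
    comp = vt[:n_pc]
    # deterministic orientation: largest-|.| loading positive
    signs = np.sign(comp[np.arange(len(comp)),
                         np.argmax(np.abs(comp), axis=1)])
    comp = comp * signs[:, None]
    proj = x @ comp.T
    var = (s ** 2 / total)[:n_pc]
    return StructurePca(comp, proj, var,
                        [ensemble.member_ids[i] for i in full])


def project_on_signature_modes(me: ModeEnsemble, ensemble: FamilyEnsemble,
                               modes: tuple[int, int] = (1, 2)) -> np.ndarray:
    """Project members onto the plane of the first two signature ANM modes.

    The signature mode s_k is the unit-normalized member average of the
    sign-aligned equivalent eigenvectors for reference mode k; member A
    maps to (Δr_A·s_1, Δr_A·s_2) with Δr_A its flattened 3N deviation
    from the mean structure.
    """
    if me.kind is not ModelKind.ANM:
        raise ValueError("signature-mode projection requires an ANM ensemble")
    sigs = []
    for k in modes:
        s = me.vectors[:, :, k - 1].mean(axis=0)
        norm = np.linalg.norm(s)
        if norm < 1e-6:
            raise ValueError(f"signature mode {k} is degenerate (norm {norm:g})")
        sigs.append(s / norm)
    mean = ensemble.mean_coords().ravel()
    out = np.zeros((ensemble.n_members, len(modes)))
    for i in range(ensemble.n_members):
        dr = np.nan_to_num(ensemble.coords[i].ravel() - mean)
        out[i] = [dr @ s for s in sigs]
    return out
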
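"""Build a core-aligned, superposed ensemble of homologous structures.

Input is a set of Cα structures plus a multiple sequence alignment of the
same members.  Columns of the MSA whose occupancy (fraction of non-gap
members) reaches a threshold — 0.7 by default — define the *core*: the
shared fold positions over which all downstream dynamics comparisons are
made.  Members are iteratively superposed onto their running mean
structure (Kabsch least-squares), and the ensemble can be refined by
dropping structural outliers (RMSD to the reference above a ceiling,
7 Å by default) and collapsing near-duplicate sequences.

Members may lack residues at some core columns (e.g. truncated termini);
those positions are carried as NaN coordinates with a boolean presence
mask.  A member missing more than 5% of the core is dropped outright so
that mode vectors of all retained members share the core dimension.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from Bio import AlignIO
from Bio.PDB import PDBParser
from Bio.PDB.Polypeptide import protein_letters_3to1
from scipy.spatial.transform import Rotation

__all__ = [
    "Structure",
    "FamilyEnsemble",
    "load_structures",
    "read_msa",
    "read_labels",
    "build_core",
    "build_ensemble",
    "superpose",
    "pairwise_matrices",
    "refine",
    "write_ensemble_pdb",
]

DEFAULT_OCCUPANCY = 0.7
DEFAULT_RMSD_MAX = 7.0
DEFAULT_SEQID_MAX = 0.98
MIN_CORE_FRACTION = 0.95  # member dropped if it covers less of the core
SEQ_MISMATCH_TOL = 0.05  # MSA row vs structure sequence
MIN_CORE_SIZE = 10


@dataclass(frozen=True)
class Structure:
    """One member's Cα trace: labels, coordinates and one-letter sequence."""

    member_id: str
    residue_labels: tuple  # (chain, resseq, icode) per residue
    ca_coords: np.ndarray  # (N_full, 3) Å
    sequence: str

    def __post_init__(self):
        if len(self.sequence) != len(self.ca_coords):
            raise ValueError(
                f"{self.member_id}: sequence length {len(self.sequence)} != "
                f"coordinate count {len(self.ca_coords)}")
        if not np.all(np.isfinite(self.ca_coords)):
            raise ValueError(f"{self.member_id}: non-finite coordinates")


@dataclass
class FamilyEnsemble:
    """M members superposed on N core MSA columns.

    ``coords`` is (M, N, 3) with NaN at positions a member lacks;
    ``mask`` is the matching (M, N) presence indicator.  The full
    structures and MSA rows are retained so refinement can rebuild the
    core over the surviving member subset.
    """

    member_ids: list[str]
    structures: list[Structure]
    msa_rows: list[str]
    core_columns: np.ndarray  # 0-based MSA column indices, length N
    occupancy: np.ndarray  # per core column, in [0, 1]
    coords: np.ndarray  # (M, N, 3), superposed, NaN where absent
    mask: np.ndarray  # (M, N) bool
    aligned_seqs: list[str]  # core-restricted rows over {aa, '-'}
    reference_index: int
    subfamily_labels: list[str] | None = None

    @property
    def n_members(self) -> int:
        return len(self.member_ids)

    @property
    def n_core(self) -> int:
        return len(self.core_columns)

    @property
    def reference_id(self) -> str:
        return self.member_ids[self.reference_index]

    def mean_coords(self) -> np.ndarray:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmean(self.coords, axis=0)


# ---------------------------------------------------------------- loading

def load_structures(pdb_paths, chain_spec=None) -> list[Structure]:
    """Read Cα traces from PDB files.

    Only Cα atoms of standard residues are kept; for alternate locations
    the first altloc is used; residues without a Cα are dropped.  The
    member id is the file stem unless ``chain_spec`` maps ids to
    (path, chain).  ``chain_spec`` may also be a single chain id applied
    to every file.
    """
    parser = PDBParser(QUIET=True)
    out = []
    for p in map(Path, pdb_paths):
        member_id = p.stem
        chain_id = chain_spec.get(member_id) if isinstance(chain_spec, dict) \
            else chain_spec
        try:
            model = next(parser.get_structure(member_id, str(p)).get_models())
        except (StopIteration, Exception) as exc:  # noqa: BLE001
            raise ValueError(f"unreadable PDB file {p}: {exc}") from exc
        labels, coords, seq = [], [], []
        for chain in model:
            if chain_id is not None and chain.id != chain_id:
                continue
            for res in chain:
                if res.id[0] != " " or "CA" not in res:
                    continue
                atom = res["CA"]
                if atom.is_disordered():
                    atom = atom.disordered_get_list()[0]
                labels.append((chain.id, res.id[1], res.id[2]))
                coords.append(atom.coord.astype(float))
                seq.append(protein_letters_3to1.get(res.resname, "X"))
        if not coords:
            raise ValueError(f"no Cα atoms found in {p}")
        out.append(Structure(member_id, tuple(labels), np.array(coords),
                             "".join(seq)))
    return out


def read_msa(path) -> dict[str, str]:
    """Aligned FASTA → {member_id: aligned row}."""
    aln = AlignIO.read(str(path), "fasta")
    return {rec.id: str(rec.seq).upper() for rec in aln}


def read_labels(path) -> dict[str, str]:
    """TSV ``member_id<TAB>subfamily`` → dict."""
    out = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        mid, lab = line.split("\t")[:2]
        out[mid] = lab
    return out


# ------------------------------------------------------------- core + build

def build_core(structures, msa, occupancy_threshold=DEFAULT_OCCUPANCY):
    """Identify high-occupancy MSA columns and map them to residue indices.

    Returns ``(core_columns, occupancy, maps)`` where ``maps[m][c]`` is
    the residue index of member m at core column c, or -1 if absent.
    Each member's ungapped MSA row must match its structure sequence
    (mismatches above 5% of positions raise, naming the member).
    """
    m = len(structures)
    rows = []
    for s in structures:
        if s.member_id not in msa:
            raise ValueError(f"member '{s.member_id}' missing from MSA")
        row = msa[s.member_id]
        ungapped = row.replace("-", "")
        if len(ungapped) != len(s.sequence):
            raise ValueError(
                f"MSA/structure length mismatch for '{s.member_id}': "
                f"{len(ungapped)} aligned residues vs {len(s.sequence)} in "
                "structure")
        mism = sum(a != b for a, b in zip(ungapped, s.sequence))
        if mism > SEQ_MISMATCH_TOL * len(s.sequence):
            raise ValueError(
                f"MSA row disagrees with structure sequence for "
                f"'{s.member_id}' at {mism}/{len(s.sequence)} positions")
        rows.append(row)
    ncol = len(rows[0])
    if any(len(r) != ncol for r in rows):
        raise ValueError("MSA rows have unequal lengths")
    gap = np.array([[c == "-" for c in r] for r in rows])
    occupancy = 1.0 - gap.mean(axis=0)
    core = np.where(occupancy >= occupancy_threshold)[0]
    if len(core) < MIN_CORE_SIZE:
        raise ValueError(
            f"only {len(core)} core columns at occupancy "
            f">= {occupancy_threshold}; need at least {MIN_CORE_SIZE}")
    maps = np.full((m, len(core)), -1, dtype=int)
    for i, row in enumerate(rows):
        residx = np.cumsum([c != "-" for c in row]) - 1
        for j, col in enumerate(core):
            if row[col] != "-":
                maps[i, j] = residx[col]
    return core, occupancy[core], maps


def build_ensemble(structures, msa, occupancy_threshold=DEFAULT_OCCUPANCY,
                   labels=None, reference=None,
                   min_core_fraction=MIN_CORE_FRACTION) -> FamilyEnsemble:
    """Assemble, superpose, and pick a reference for a family ensemble.

    Members covering less than ``min_core_fraction`` of the core are
    dropped (with a warning) so all mode vectors share dimension N.  The
    reference defaults to the member with minimal mean RMSD to all
    others after superposition.
    """
    core, occ, maps = build_core(structures, msa, occupancy_threshold)
    keep = [i for i in range(len(structures))
            if (maps[i] >= 0).mean() >= min_core_fraction]
    dropped = [structures[i].member_id for i in range(len(structures))
               if i not in keep]
    if dropped:
        warnings.warn(f"dropping members covering <{min_core_fraction:.0%} "
                      f"of core: {dropped}")
    if len(keep) < 2:
        raise ValueError("fewer than 2 members survive core coverage filter")
    structures = [structures[i] for i in keep]
    # recompute the core over survivors (occupancy can only rise)
    core, occ, maps = build_core(structures, msa, occupancy_threshold)
    m, n = maps.shape
    coords = np.full((m, n, 3), np.nan)
    mask = maps >= 0
    for i, s in enumerate(structures):
        coords[i, mask[i]] = s.ca_coords[maps[i, mask[i]]]
    aligned = ["".join(msa[s.member_id][c] for c in core) for s in structures]
    ids = [s.member_id for s in structures]
    lab = [labels[i] for i in ids] if labels else None
    ens = FamilyEnsemble(ids, structures, [msa[i] for i in ids], core, occ,
                         coords, mask, aligned, 0, lab)
    ens = superpose(ens)
    if reference is not None:
        if reference not in ids:
            raise ValueError(f"reference '{reference}' not in ensemble")
        ens.reference_index = ids.index(reference)
    else:
        rmsd = pairwise_matrices(ens)["rmsd"]
        ens.reference_index = int(np.argmin(rmsd.mean(axis=1)))
    return ens


# ------------------------------------------------------------ superposition

def _kabsch_transform(target: np.ndarray, mobile: np.ndarray):
    """Rotation + translation mapping ``mobile`` onto ``target`` (least squares)."""
    tc, mc = target.mean(axis=0), mobile.mean(axis=0)
    rot, _ = Rotation.align_vectors(target - tc, mobile - mc)
    return rot, tc, mc


def _apply(rot, tc, mc, pts):
    return rot.apply(pts - mc) + tc


def superpose(ensemble: FamilyEnsemble, tol=1e-6, max_iter=100) -> FamilyEnsemble:
    """Iteratively superpose all members onto their mean structure.

    Each round fits every member (over its present core positions) onto
    the running nan-mean, then recomputes the mean; stops when the mean
    RMSD to the mean changes by less than ``tol`` Å.
    """
    coords = ensemble.coords.copy()
    mask = ensemble.mask
    mean = np.where(mask[0, :, None], coords[0], np.nan)
    prev = np.inf
    for _ in range(max_iter):
        for i in range(len(coords)):
            shared = mask[i] & np.all(np.isfinite(mean), axis=1)
            if shared.sum() < 3:
                raise ValueError(
                    f"member '{ensemble.member_ids[i]}' shares fewer than 3 "
                    "core positions with the mean structure")
            rot, tc, mc = _kabsch_transform(mean[shared], coords[i][shared])
            coords[i, mask[i]] = _apply(rot, tc, mc, coords[i][mask[i]])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            mean = np.nanmean(coords, axis=0)
        resid = np.nanmean(np.sum((coords - mean) ** 2, axis=2), axis=1)
        cur = float(np.mean(np.sqrt(resid)))
        if abs(prev - cur) < tol:
            break
        prev = cur
    out = replace(ensemble)
    out.coords = coords
    return out


# ------------------------------------------------------- pairwise + refine

def _pair_rmsd(a, b, mask_a, mask_b):
    shared = mask_a & mask_b
    if shared.sum() < 3:
        raise ValueError("fewer than 3 mutually present core positions")
    p, q = a[shared], b[shared]
    rot, tc, mc = _kabsch_transform(p, q)
    q = _apply(rot, tc, mc, q)
    return float(np.sqrt(np.mean(np.sum((p - q) ** 2, axis=1))))


def pairwise_matrices(ensemble: FamilyEnsemble) -> dict[str, np.ndarray]:
    """Pairwise sequence identity and Kabsch RMSD over the core.

    Identity is counted over mutually non-gap core positions; RMSD comes
    from a fresh per-pair superposition on mutually present positions.
    """
    m = ensemble.n_members
    seqid = np.eye(m)
    rmsd = np.zeros((m, m))
    seqs = ensemble.aligned_seqs
    for i in range(m):
        for j in range(i + 1, m):
            both = [(a, b) for a, b in zip(seqs[i], seqs[j])
                    if a != "-" and b != "-"]
            if not both:
                raise ValueError(
                    f"no shared core positions between "
                    f"'{ensemble.member_ids[i]}' and '{ensemble.member_ids[j]}'")
            seqid[i, j] = seqid[j, i] = \
                sum(a == b for a, b in both) / len(both)
            rmsd[i, j] = rmsd[j, i] = _pair_rmsd(
                ensemble.coords[i], ensemble.coords[j],
                ensemble.mask[i], ensemble.mask[j])
    return {"seq_identity": seqid, "rmsd": rmsd}


def refine(ensemble: FamilyEnsemble, seqid_max=DEFAULT_SEQID_MAX,
           rmsd_max=DEFAULT_RMSD_MAX,
           occupancy_threshold=DEFAULT_OCCUPANCY) -> FamilyEnsemble:
    """Filter outliers and redundancy, then rebuild the ensemble.

    (1) members with RMSD to the reference above ``rmsd_max`` are
    dropped; (2) while any pair exceeds ``seqid_max`` sequence identity,
    the more redundant member of the worst pair (lower mean RMSD to the
    rest; the reference is always kept) is removed; (3) the core and
    superposition are recomputed over survivors.  Iterates to a fixed
    point so refinement is idempotent.
    """
    current = ensemble
    for _ in range(10):
        mats = pairwise_matrices(current)
        ref = current.reference_index
        keep = [i for i in range(current.n_members)
                if i == ref or mats["rmsd"][i, ref] <= rmsd_max]
        seqid, rmsd = mats["seq_identity"][np.ix_(keep, keep)], \
            mats["rmsd"][np.ix_(keep, keep)]
        keep = list(keep)
        ref_pos = keep.index(ref)
        while True:
            iu = np.triu_indices(len(keep), 1)
            over = seqid[iu] > seqid_max
            if not over.any():
                break
            worst = np.argmax(np.where(over, seqid[iu], -1))
            a, b = iu[0][worst], iu[1][worst]
            if a == ref_pos:
                drop = b
            elif b == ref_pos:
                drop = a
            else:  # remove the one closer (more redundant) to the rest
                drop = a if rmsd[a].mean() <= rmsd[b].mean() else b
            keep.pop(drop)
            seqid = np.delete(np.delete(seqid, drop, 0), drop, 1)
            rmsd = np.delete(np.delete(rmsd, drop, 0), drop, 1)
            ref_pos = keep.index(ref) if ref in keep else 0
        if len(keep) < 2:
            raise ValueError("fewer than 2 members survive refinement")
        if len(keep) == current.n_members:
            return current
        ids = [current.member_ids[i] for i in keep]
        labels = None
        if current.subfamily_labels is not None:
            labels = dict(zip(current.member_ids, current.subfamily_labels))
        msa = dict(zip(current.member_ids, current.msa_rows))
        current = build_ensemble(
            [current.structures[i] for i in keep], msa,
            occupancy_threshold, labels,
            reference=current.reference_id)
    return current


# -------------------------------------------------------------------- I/O

def write_ensemble_pdb(ensemble: FamilyEnsemble, pdb_path, sidecar_path=None):
    """Write the superposed core as a multi-model PDB plus a JSON sidecar."""
    lines = []
    for i, mid in enumerate(ensemble.member_ids):
        lines.append(f"MODEL     {i + 1:>4}")
        serial = 1
        for j in range(ensemble.n_core):
            if not ensemble.mask[i, j]:
                continue
            x, y, z = ensemble.coords[i, j]
            aa = ensemble.aligned_seqs[i][j]
            res3 = _ONE_TO_THREE.get(aa, "UNK")
            lines.append(
                f"ATOM  {serial:>5}  CA  {res3} A{j + 1:>4}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C")
            serial += 1
        lines.append("ENDMDL")
    lines.append("END")
    Path(pdb_path).write_text("\n".join(lines) + "\n")
    if sidecar_path is not None:
        meta = {
            "member_ids": ensemble.member_ids,
            "core_columns": [int(c) for c in ensemble.core_columns],
            "occupancy": [round(float(o), 6) for o in ensemble.occupancy],
            "reference_id": ensemble.reference_id,
        }
        Path(sidecar_path).write_text(json.dumps(meta, indent=1) + "\n")


_ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}
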
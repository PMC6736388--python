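"""Seeded generator of toy fold families for end-to-end testing.

A *family* is a set of member structures derived from one base fold — a
self-avoiding helix-like curve whose Cα spacing and contact density make
the default-cutoff elastic networks connected — plus a gapless multiple
sequence alignment and per-member subfamily labels.  Each member is the
base fold perturbed by

* isotropic Gaussian coordinate noise (``noise_sigma``),
* its subfamily's localized deformation: a smooth bump over a fixed
  residue segment, displaced along a subfamily-specific direction,
* an optional global displacement along a soft ANM mode of the base
  (member-specific amplitude), emulating conformational spread,
* optional terminal deletions, which create MSA columns with occupancy
  below 1.

Sequences are evolved from a random ancestor with per-site substitution
probability proportional to the base fold's GNM mean-square fluctuation,
so that sequence entropy and flexibility divergence are positively
coupled, with an extra subfamily-lineage divergence step.  Everything is
driven by one integer seed; file output uses fixed float formatting so
repeated runs are byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .enm import build_hessian, build_kirchhoff, decompose, msf
from .ensemble import Structure, _ONE_TO_THREE

__all__ = ["FamilySpec", "FamilyData", "generate_base_fold",
           "generate_family", "write_family"]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

# base-fold geometry: α-helical rise/radius with a gentle superhelical
# drift; consecutive Cα ≈ 3.8 Å, min pair distance >= 2.5 Å, GNM at
# 10 Å connected by construction
HELIX_RISE = 1.5
HELIX_RADIUS = 2.3
HELIX_TWIST = np.deg2rad(99.0)
SUPERHELIX_RADIUS = 200.0


@dataclass(frozen=True)
class FamilySpec:
    """Generation parameters; fixed spec + seed gives byte-identical output."""

    n_residues: int = 100
    n_members: int = 12
    n_subfamilies: int = 3
    noise_sigma: float = 0.3  # Å, isotropic per coordinate
    deform_segment_length: int = 20  # residues per subfamily bump
    deform_amplitude: float = 8.0  # Å, peak of the subfamily bump
    deform_modulation: float = 0.5  # fine-scale amplitude dip (crumple depth)
    global_mode_amplitude: float = 0.5  # Å RMS along a soft ANM mode
    substitution_rate_scale: float = 1.0
    terminal_deletion_prob: float = 0.0  # per member; off: truncation
    # genuinely shifts the mid-spectrum standing waves, so the default
    # family keeps complete cores and ragged termini are opt-in
    max_terminal_deletion: int = 5  # residues; keeps core coverage >= 95%
    seed: int = 0


@dataclass
class FamilyData:
    structures: list[Structure]
    msa: dict[str, str]
    labels: dict[str, str]
    truth: dict


def _gnm_connected(coords: np.ndarray, cutoff: float = 10.0) -> bool:
    d2 = np.sum((coords[:, None] - coords[None]) ** 2, axis=2)
    adj = csr_matrix((d2 <= cutoff ** 2) & (d2 > 0))
    return connected_components(adj, directed=False)[0] == 1


def generate_base_fold(n_residues: int = 100, seed: int = 0) -> Structure:
    """Helix-like self-avoiding base fold with a slow superhelical drift."""
    if n_residues < 20:
        raise ValueError("base fold needs at least 20 residues")
    i = np.arange(n_residues)
    theta = i * HELIX_TWIST
    x = HELIX_RADIUS * np.cos(theta)
    y = HELIX_RADIUS * np.sin(theta)
    z = i * HELIX_RISE
    # bend the helix axis along a large-radius arc (drift in the x-z plane)
    phi = z / SUPERHELIX_RADIUS
    xb = (SUPERHELIX_RADIUS + x) * np.cos(phi) - SUPERHELIX_RADIUS
    zb = (SUPERHELIX_RADIUS + x) * np.sin(phi)
    coords = np.column_stack([xb, y, zb])
    steps = np.linalg.norm(np.diff(coords, axis=0), axis=1)
    if not np.all((steps > 3.7) & (steps < 3.9)):
        raise ValueError("base fold geometry violates the Cα spacing contract")
    d = np.linalg.norm(coords[:, None] - coords[None], axis=2)
    if np.min(d[~np.eye(n_residues, dtype=bool)]) < 2.5:
        raise ValueError("base fold has steric clashes (< 2.5 Å)")
    rng = np.random.default_rng(seed)
    seq = "".join(rng.choice(list(AMINO_ACIDS), size=n_residues))
    labels = tuple(("A", k + 1, " ") for k in range(n_residues))
    return Structure("base", labels, coords, seq)


def _bump(n: int, start: int, length: int) -> np.ndarray:
    """Smooth cosine window over [start, start+length), zero elsewhere."""
    w = np.zeros(n)
    t = np.arange(length)
    w[start:start + length] = 0.5 * (1 - np.cos(2 * np.pi * (t + 0.5) / length))
    return w


def _mutate(seq: str, probs: np.ndarray, rng) -> str:
    out = list(seq)
    hits = rng.random(len(seq)) < probs
    for j in np.where(hits)[0]:
        choices = AMINO_ACIDS.replace(out[j], "")
        out[j] = choices[rng.integers(len(choices))]
    return "".join(out)


def generate_family(spec: FamilySpec = FamilySpec()) -> FamilyData:
    """Generate structures + gapless MSA + labels + a truth record."""
    rng = np.random.default_rng(spec.seed)
    base = generate_base_fold(spec.n_residues, seed=spec.seed)
    n, m = spec.n_residues, spec.n_members

    # mobility-proportional per-site substitution probability (per branch)
    gnm = decompose(build_kirchhoff(base.ca_coords), member_id="base")
    mob = msf(gnm)
    sub_prob = np.clip(
        spec.substitution_rate_scale * 0.35 * mob / mob.mean(), 0.0, 0.9)

    # soft ANM displacement field of the base fold (first nonzero mode)
    anm = decompose(build_hessian(base.ca_coords), n_modes=1,
                    member_id="base")
    soft = anm.eigenvectors[:, 0].reshape(n, 3)
    soft = soft / np.sqrt(np.mean(np.sum(soft ** 2, axis=1)))  # unit RMS

    # subfamily-specific deformation segments spread over the interior,
    # displaced perpendicular to the local chain tangent so the bump
    # reliably alters packing rather than sliding along the chain
    margin = 15
    span = n - 2 * margin
    seg_len = spec.deform_segment_length
    segments, directions = [], []
    for p in range(spec.n_subfamilies):
        start = margin + int(round(p * span / spec.n_subfamilies))
        start = min(start, n - margin - seg_len)
        segments.append((start, start + seg_len))
        v = rng.normal(size=3)
        mid = start + seg_len // 2
        tangent = base.ca_coords[mid + 2] - base.ca_coords[mid - 2]
        tangent = tangent / np.linalg.norm(tangent)
        v = v - (v @ tangent) * tangent
        directions.append(v / np.linalg.norm(v))

    ancestor = base.sequence
    sub_seqs = [_mutate(ancestor, sub_prob, rng)
                for _ in range(spec.n_subfamilies)]

    structures, msa, labels = [], {}, {}
    deleted = {}
    for i in range(m):
        p = i % spec.n_subfamilies
        mid = f"m{i:02d}"
        start, stop = segments[p]
        # periodic amplitude dip "crumples" the segment with a
        # subfamily-specific period, so each subfamily's deformation
        # changes local packing (contact topology), not just position
        period = p + 3
        modulation = 1.0 - spec.deform_modulation * (np.arange(n) % period == 0)
        profile = spec.deform_amplitude * _bump(n, start, stop - start) \
            * modulation
        disp = profile[:, None] * directions[p]
        coef = rng.normal(0.0, spec.global_mode_amplitude)
        coords = (base.ca_coords + disp + coef * soft
                  + rng.normal(0.0, spec.noise_sigma, size=(n, 3)))
        seq = _mutate(sub_seqs[p], sub_prob, rng)
        # optional terminal deletion -> gap columns in the MSA
        keep = np.ones(n, dtype=bool)
        if rng.random() < spec.terminal_deletion_prob:
            ndel = int(rng.integers(1, spec.max_terminal_deletion + 1))
            if rng.random() < 0.5:
                keep[:ndel] = False
            else:
                keep[n - ndel:] = False
        deleted[mid] = int(n - keep.sum())
        if not _gnm_connected(coords[keep]):
            raise ValueError(
                f"member {mid}: deformation amplitudes break GNM connectivity")
        kept_idx = np.where(keep)[0]
        res_labels = tuple(("A", int(k) + 1, " ") for k in kept_idx)
        structures.append(Structure(
            mid, res_labels, coords[keep],
            "".join(seq[k] for k in kept_idx)))
        msa[mid] = "".join(seq[k] if keep[k] else "-" for k in range(n))
        labels[mid] = f"sf{p}"
    truth = {
        "spec": asdict(spec),
        "segments": [[int(a), int(b)] for a, b in segments],
        "directions": [list(map(float, v)) for v in directions],
        "subfamily_of": labels,
        "substitution_prob": [float(q) for q in sub_prob],
        "terminal_deletions": deleted,
    }
    return FamilyData(structures, msa, labels, truth)


# ------------------------------------------------------------------- I/O

def _pdb_lines(s: Structure):
    for serial, ((chain, resseq, icode), aa, (x, y, z)) in enumerate(
            zip(s.residue_labels, s.sequence, s.ca_coords), start=1):
        res3 = _ONE_TO_THREE.get(aa, "UNK")
        yield (f"ATOM  {serial:>5}  CA  {res3} {chain}{resseq:>4}{icode:1}"
               f"   {x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C")


def write_family(family: FamilyData, outdir) -> dict[str, object]:
    """Write one PDB per member, the aligned FASTA, labels TSV, truth JSON.

    Fixed float formatting keeps outputs byte-identical for a fixed spec.
    Returns the paths written.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pdb_dir = outdir / "pdb"
    pdb_dir.mkdir(exist_ok=True)
    pdb_paths = []
    for s in family.structures:
        p = pdb_dir / f"{s.member_id}.pdb"
        p.write_text("\n".join(_pdb_lines(s)) + "\nEND\n")
        pdb_paths.append(p)
    msa_path = outdir / "family.fasta"
    with open(msa_path, "w") as fh:
        for mid, row in family.msa.items():
            fh.write(f">{mid}\n{row}\n")
    labels_path = outdir / "labels.tsv"
    with open(labels_path, "w") as fh:
        for mid, lab in family.labels.items():
            fh.write(f"{mid}\t{lab}\n")
    truth_path = outdir / "truth.json"
    truth_path.write_text(
        json.dumps(family.truth, indent=1, sort_keys=True) + "\n")
    return {"pdb": pdb_paths, "msa": msa_path, "labels": labels_path,
            "truth": truth_path}
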
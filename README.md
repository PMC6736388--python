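# famdyn

Signature dynamics of protein fold families from elastic-network normal
modes.

Members of a fold family share a topology, and that topology encodes a
spectrum of intrinsic motions. `famdyn` quantifies which parts of the
spectrum are *shared* across homologs (the family's signature dynamics)
and which parts *diverge*, and uses the divergent part to classify
members and subfamilies — alongside the classical sequence- and
structure-based classifications.

## What it computes

For a set of homologous Cα structures plus a multiple sequence
alignment:

1. **Core ensemble** — MSA columns with occupancy ≥ 0.7 define the
   shared core of N residues; members are iteratively superposed
   (Kabsch) and refined (pairwise RMSD ≤ 7 Å to the reference,
   sequence identity ≤ 0.98).
2. **Mode spectra** — each member's GNM Kirchhoff matrix Γ (contact
   cutoff 10 Å) or ANM Hessian H (15 Å) is decomposed into modes
   (λ_k, u_k), k = 1..K from soft/collective to fast/local, with
   collectivity κ_k and weight w_k = λ_k⁻¹/Σλ⁻¹ per mode.
3. **Equivalent modes** — member modes are matched to a reference
   member's mode order by maximizing |cos(u_k, u_l)| (greedy or optimal
   assignment).
4. **Conservation / divergence** — the per-mode conservation profile
   cc_k = ⟨|u_k^A·u_k^B|⟩ over all M(M−1)/2 member pairs; the spectral
   overlap SO_ij(A,B) of mode windows i..j (a covariance overlap with
   mode variances 1/λ_k); and the spectral distance d = arccos(SO), a
   metric on mode spectra. Windows follow the standard frequency
   regimes: global (k ≤ 3), LF (4–20), LTIF (21–60), HF (> 60), VHF
   (fastest ~2%).
5. **Signature profiles** — family mean ± SD of residue mean-square
   fluctuations MSF_n = Σ_k λ_k⁻¹u_{k,n}² and of N×N cross-correlation
   maps; near-zero sites of a global-mode shape mark hinge (pivotal)
   residues.
6. **Sequence–dynamics coupling** — per-column Shannon entropy H (nats,
   gaps excluded) against ΔRMSF, the across-member SD of residue RMSF,
   with the entropy histogram fitted by a lognormal (MLE).
7. **Classification** — UPGMA dendrograms from Hamming
   (1 − sequence identity), RMSD, TM-score, and spectral distances;
   subfamily × subfamily mean spectral distances per regime; member
   projections onto the top signature ANM modes and structural PCs.

A seeded synthetic-family generator (helix-like base fold, subfamily
specific localized deformations, mobility-proportional sequence
divergence) makes the whole pipeline testable without any downloads.

## Worked example

```python
import famdyn as fd

family = fd.generate_family(fd.FamilySpec(seed=0))
ens = fd.refine(fd.build_ensemble(family.structures, family.msa,
                                  labels=family.labels))
gnm = fd.build_mode_ensemble(ens)

prof = fd.conservation_profile(gnm)
curve = fd.cumulative_overlap_curve(gnm)
print(f"M = {ens.n_members} members, core N = {ens.n_core}")
print(f"cc (global, k<=3)    = {prof.cc_mean[:3].mean():.3f}")
print(f"cc (LTIF, 21<=k<=60) = {prof.cc_mean[20:60].mean():.3f}")
print(f"cumulative overlap: SO(1..3) = {curve.so_mean[2]:.3f}, "
      f"minimum {curve.so_mean[curve.argmin-1]:.3f} at n = {curve.argmin}, "
      f"SO(all) = {curve.so_mean[-1]:.3f}")

dm = fd.spectral_distance_matrix(gnm, (21, 60))
newick, order, _ = fd.dendrogram(dm)
print("LTIF dendrogram leaf order:",
      " ".join(family.labels[m] for m in order))
```

prints

```
M = 12 members, core N = 100
cc (global, k<=3)    = 0.990
cc (LTIF, 21<=k<=60) = 0.220
cumulative overlap: SO(1..3) = 0.920, minimum 0.761 at n = 54, SO(all) = 0.933
LTIF dendrogram leaf order: sf2 sf2 sf2 sf2 sf0 sf0 sf0 sf0 sf1 sf1 sf1 sf1
```

The global modes are almost perfectly conserved across the family
(cc ≈ 0.99) while the low-to-intermediate-frequency modes have
diverged (cc ≈ 0.22); the cumulative spectral overlap dips to an
interior minimum in the LTIF regime before climbing back as the mode
set approaches a complete basis. Clustering the members by their LTIF
spectral distances recovers the three generating subfamilies exactly —
the mid-spectrum is where subfamily-specific dynamics live.

## Command line

```
famdyn synth --outdir fam --seed 7            # make a synthetic family
famdyn run --pdb-dir fam/pdb --msa fam/family.fasta \
           --labels fam/labels.tsv --outdir out
```

`run` executes the full workflow and writes TSV profiles and matrices,
Newick trees, an NMD file with the signature ANM modes, a multi-model
PDB of the superposed core, and a resolved `config.json` + `run.log`.
Individual stages are available as `build`, `modes`, `signature`,
`compare`, `subfam`, and `tree`.

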
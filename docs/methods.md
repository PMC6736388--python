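# Methods

## Elastic network models

Each family member is reduced to its core Cα trace and modeled as a
network of identical springs (constant γ = 1, k_BT/γ = 1, so
fluctuation amplitudes carry no absolute units). Two models are
provided:

* **GNM** — the N×N Kirchhoff matrix Γ with Γ_ij = −γ for
  0 < d_ij ≤ r_c (default r_c = 10 Å) and row sums zero. A connected
  network has exactly one zero mode.
* **ANM** — the 3N×3N Hessian assembled from rank-1 super-elements
  −(γ/d²)·ΔrΔrᵀ per contact (default r_c = 15 Å); six zero modes for a
  non-degenerate geometry.

Decomposition uses dense symmetric eigensolvers; eigenvalues below
1e-8 × λ_max are treated as zero modes and their count is validated
(a mismatch raises a "disconnected network / degenerate geometry"
error naming the member — the usual cause is a cutoff too small for
the geometry). Eigenvector signs are fixed deterministically (largest
magnitude component positive) before any cross-member matching.

Per mode we report the collectivity κ_k = exp(−Σ p_n ln p_n)/N with
p_n = u_{k,n}² (ANM: summed over x/y/z; 0·ln 0 := 0), an entropy-based
measure ranging from 1/N (single-site) to 1 (uniform), and the
fractional weight w_k = λ_k⁻¹/Σλ⁻¹, normalized over the full nonzero
spectrum.

GNM is the default for all cross-member comparisons; ANM supplies the
3-D signature mode shapes used for member projections and NMD export.

## Core, superposition, refinement

The MSA is the alignment source; no structural aligner is run. Core
columns are those with occupancy ≥ 0.7 (inclusive). Members missing a
core position carry NaN coordinates there and a presence mask; a member
covering < 95% of the core is dropped so that all mode vectors share
the core dimension N.

Superposition iterates Kabsch fits of every member onto the running
nan-mean until the mean RMSD to the mean changes by < 1e-6 Å (≤ 100
iterations). Refinement (1) drops members with RMSD to the reference
above 7 Å, (2) greedily collapses pairs above 0.98 sequence identity —
keeping the reference, and of an offending pair removing the member
with the smaller mean RMSD to the rest (the more redundant one) — and
(3) rebuilds core and superposition over the survivors, iterating to a
fixed point so refinement is idempotent. The reference member is
user-specified or the member with minimal mean RMSD to all others.

## Mode matching and window semantics

Equivalent modes are found per member against the reference by
maximizing |cos| between eigenvectors: greedy selection of the globally
largest remaining cosine (default) or an optimal linear-sum assignment,
over at most the first 100 modes; signs are flipped so matched dot
products are non-negative. Ties break deterministically toward lower
indices.

Two order conventions coexist, chosen by what a quantity means:

* **Matched (equivalent-mode) order** is used for per-mode quantities:
  the conservation profile cc_k (mean ± SD over all member pairs of
  |u_k^A·u_k^B|) and the signature mode shapes (member-averaged,
  sign-aligned eigenvectors).
* **Natural (own ascending) order** is used for windowed quantities:
  per-member MSF over modes i..j, windowed covariance maps, and the
  spectral overlap of windows. Within a window the covariance-overlap
  double sum is invariant to mode order, so the only effect of the
  convention is *which* modes enter the window; in the mid-spectrum,
  where near-degenerate modes mix strongly, greedy matching is close to
  arbitrary and would scramble window membership, whereas each member's
  own modes i..j define the intended frequency band.

The spectral overlap of members A and B over window i..j uses mode
variances σ_k = 1/λ_k:

SO = 1 − √[(Σ(σ_k^A + σ_k^B) − 2ΣΣ √(σ_k^Aσ_l^B)(u_k^A·u_l^B)²) /
Σ(σ_k^A + σ_k^B)],

clamping tiny negative radicands at zero. SO = 1 for identical
spectra, 0 for orthogonal subspaces; d = arccos(SO) ∈ [0, π/2] is the
spectral distance (symmetric, zero iff SO = 1; the triangle inequality
is not asserted). For pairs where one member lacks core positions, both
members' window vectors are restricted to mutually present positions
and re-normalized — the analogue of computing pairwise RMSD on shared
positions — so a truncated terminus does not masquerade as dynamical
divergence. Self-overlap remains exactly 1 and complete-core pairs are
unaffected.

Frequency regimes: global k ≤ 3, LF 4–20, LTIF 21–60, HF > 60, plus a
VHF tail of max(3, ⌈0.02K⌉) fastest modes; windows are clipped to the
available K and dropped if empty.

## Sequence–dynamics coupling and classification

Column entropy is Shannon entropy in nats over the 20 amino acids,
gaps excluded (all-gap columns are NaN), bounded by ln 20 ≈ 3.0.
ΔRMSF is the across-member standard deviation (ddof = 1) of windowed
RMSF; a max−min variant is available. The entropy histogram (bin width
0.15) is fitted by a lognormal via maximum likelihood (location fixed
at 0), and the fit quality is the Pearson correlation between the
empirical bin densities and the fitted density at bin centers; binned
ΔRMSF means drop bins with fewer than 3 columns.

TM-score is computed on the fixed core alignment after ensemble
superposition with d_0 = max(0.5, 1.24(L−15)^⅓ − 1.8) — no rotational
re-search is performed, which is adequate here because RMSD- and
TM-based classifications are interchangeable in practice for
superposable cores.

Dendrograms use UPGMA (average linkage; complete/single by flag) on a
chosen distance matrix, serialized as Newick with each merge placed at
half its cophenetic height (ultrametric inputs are reconstructed
exactly); children are ordered by their smallest leaf label for
deterministic output. Subfamily matrices average member-pair spectral
distances within/between subfamilies with at least 4 members.
Structural PCA decomposes the member deviations from the mean
structure (complete-core members only); projections onto the first two
signature ANM modes use Δr_A·s_k with s_k the unit-normalized member
average of sign-aligned equivalent eigenvectors.

## Synthetic families

The generator emulates the statistical structure of a real fold family
at toy scale — it is a study-condition fixture, not a protein model:

* **Base fold**: an α-helix-like curve (rise 1.5 Å, radius 2.3 Å,
  ~99°/residue) bent along a 200 Å superhelical arc; consecutive Cα
  3.8 ± 0.1 Å, minimum pair distance ≥ 2.5 Å, 10 Å GNM connected by
  construction.
* **Members** (defaults: N = 100 residues, M = 12, 3 subfamilies):
  base fold + isotropic Gaussian coordinate noise (σ = 0.3 Å) + the
  subfamily's localized deformation + a member-specific displacement
  along the softest ANM mode (0.5 Å RMS amplitude).
* **Subfamily deformation**: a cosine bump over a 20-residue segment
  (segments spread over the chain interior, 15-residue margins),
  displaced up to 8 Å along a per-subfamily random direction taken
  perpendicular to the local chain tangent, with a periodic amplitude
  dip (depth 0.5, period 3/4/5 by subfamily) that "crumples" the
  segment. The crumple matters: a rigid-ish displacement moves a
  segment without changing its internal packing, and contact-topology
  models only feel packing changes. The deformation amplitude is large
  relative to the noise because the mid-spectrum modes of a quasi-1D
  fold are extremely sensitive to random contact flips; the resulting
  between-subfamily RMSD (~2 Å) stays well within the refinement
  ceiling.
* **Sequences**: evolved from a random ancestor with per-site
  substitution probability proportional to the base fold's GNM MSF
  (mean per-branch rate 0.35, two branches: root → subfamily →
  member), producing mean pairwise identities around 0.2–0.35 and a
  positive entropy–flexibility coupling. Substitutions are independent
  with uniform targets; no indels except optional terminal deletions.
* **Terminal deletions** (default probability 0, up to 5 residues when
  enabled): create occupancy < 1 columns and exercise the presence
  mask. They are off by default because truncating a quasi-1D chain
  genuinely shifts the wavelengths of its mid-spectrum standing waves,
  which makes LTIF spectra incomparable — a real physical effect, and
  the reason the method works on high-occupancy cores.

Output is deterministic per seed and byte-identical across runs (fixed
float formatting in PDB/FASTA/TSV/JSON writers). A truth record stores
segments, directions, substitution rates, and labels for
parameter-recovery tests.

What passing tests on these fixtures does and does not show: they
verify the mathematics (matching, overlap, distances, clustering) and
the qualitative regime structure — conserved global modes, divergent
mid-spectrum, interior overlap minimum — under controlled conditions.
They do not validate biological conclusions on real families, where
alignment quality, conformational heterogeneity within subfamilies,
and non-local contact topology all differ from the fixture.

## Numerical choices and limitations

* zero-mode tolerance 1e-8 relative to λ_max; SO radicands clamped at
  0; arccos near SO = 1 amplifies float noise, so spectral distances
  below ~1e-3 rad should be read as zero.
* Degenerate cases: structural PCA of identical members returns
  all-zero projections with a warning; flat profiles have no extreme
  sites; all-zero entropy profiles refuse the lognormal fit.
* Problem sizes: analyses in tests and examples run at N = 100,
  M = 12 with full GNM spectra (K = 99) and 30-mode ANM ensembles —
  sizes at which every stage is exact dense linear algebra and the
  full pipeline completes in seconds.
* The greedy redundancy-collapse rule and the MSA-as-aligner choice
  are pragmatic stand-ins for heavier external tooling; both are
  isolated behind single functions.
* Hinge detection and HF-peak detection operate on any per-residue
  profile; thresholds are fractions of the profile's largest
  magnitude, so they are scale-free but not noise-adaptive.
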
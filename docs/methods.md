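# Methods

## Model and assumptions

A DNA duplex of N base pairs is a two-legged tight-binding ladder: one
lattice site per base, two chains (reference/L strand and complement/H
strand) aligned position-by-position, rungs across each Watson-Crick pair.
A single hole moves on this lattice with Hamiltonian entries

* diagonal: the base's gas-phase ionization potential, used as the on-site
  hole energy — ε_G = 7.75, ε_C = 8.87, ε_A = 8.24, ε_T = 9.14 eV.
  Guanine is the deepest well, so holes localize preferentially on G and
  especially on G runs, where the run acts as a wider (hence deeper-bound)
  potential well;
* off-diagonal: t_∥ = 1.0 eV between stacked neighbours on the same
  strand, t_⊥ = 0.5 eV across each rung. Only magnitudes matter for the
  probability spectra computed here: the ladder graph is bipartite for the
  even-length periodic segments used in practice, so negating the hoppings
  is a gauge transformation that leaves every |Ψ|² unchanged (verified by
  test on small duplexes).

Assumptions worth stating: a single hole (no hole-hole interaction), no
environment/solvation correction to the ionization potentials, no backbone
sites, no next-nearest-neighbour hopping, and no time dependence — the
model scores where an equilibrated hole would sit, not how it gets there.

Boundary conditions are periodic by default (first and last site of each
chain coupled), reflecting the circular mitochondrial genome from which
the packaged segment is drawn; a linear (open) variant is available. The
minimum segment length is 3, because a 2-site periodic ring would place a
doubled bond between the same pair of sites. Ambiguous bases (`N`) are
rejected by default; an explicit `impute-mean` policy assigns the average
of the four on-site energies instead, so silent imputation can never bias
a spectrum.

## Spectrum

Dense symmetric diagonalization (`scipy.linalg.eigh`) yields all 2N
eigenpairs; for the packaged 956-bp ND1 segment that is a 1912 × 1912
problem solved in about a second. The hole spectrum is the canonical
average

    P(m,c) = Σ_i w_i |Ψ_i(m,c)|²,  w_i = exp(−(E_i − E_0)/k_BT) / Z,

where E_0 is the ground-state energy and Z normalizes Σ w_i = 1, so
Σ P = 1 exactly (asserted to 1e−10 after every computation). Degenerate
eigenvalues need no tie-breaking: the weights depend only on E_i, and the
summed density over a degenerate subspace is basis-invariant. Round-off
can leave components at −1e−16; values in (−1e−14, 0) are clamped to zero.

k_BT is an *effective* (pseudo-thermal) energy, default 0.047 eV — large
enough that the spectrum blends the several dozen lowest, strongly
localized eigenstates into a full profile rather than reproducing only the
ground state. It is exposed as a plain parameter with no claim to a
physical temperature. Limits used as self-checks: k_BT ≥ 1e6 eV gives the
uniform spectrum 1/(2N) by eigenbasis completeness; k_BT ≤ 1e−6 eV gives
|Ψ_0|² when the ground state is unique.

Normalized tracks divide P by a baseline: the mean over all 2N sites
(mode `both_strands`, baseline analytically 1/(2N) — computed from the
data and asserted against the analytic value as a self-check), or the
mean over one strand's sites (`L_only`, `H_only`). The mean of N over the
baseline-defining positions is 1 by construction.

## Peaks

A peak is a strict local maximum of a normalized track on one strand,
with neighbours taken circularly when the spectrum is periodic. Plateaus
(runs of exactly equal values above both flanks) collapse to their
leftmost position; on linear segments the two ends are eligible only
under an explicit `include_ends` flag (default off). These policies exist
because "peak" has no canonical definition for discrete tracks; both are
exposed so a census can be reproduced either way. Top-k selection breaks
height ties toward the smaller coordinate for determinism. Peak-feature
matching reports, for each tolerance d ∈ {0, 1, 4} bp, how many peaks
have their nearest feature within d — monotone in d by construction.

## Variant correlation and constraint

Variant-frequency tracks g (per-site counts of observed variants, alleles
summed per site) are compared with hole tracks three ways:

* **Pearson's r**, computed directly; zero variance in either input is an
  error rather than a NaN.
* **Capping and smoothing before r.** Frequencies are clipped at 350 by
  default — reproduction and selection amplify a handful of common
  variants by orders of magnitude, and without a cap those few sites
  dominate the covariance. Both tracks are then smoothed with an
  exponential moving average, weights ∝ decay^|j| over j ∈ [−8, 8]
  (decay 0.5 by default, renormalized at segment ends), so maxima offset
  by one or two base pairs — as expected if holes migrate a short distance
  before reacting — still overlap. The weight profile is the one free
  choice in the EMA family; it is declared in the configuration rather
  than hidden.
* **Variant constraint** N′ = N/(Ag + 1) for a sweep of scale factors A
  (default 0, 1, 10, 100, 1000). The identity at A = 0, pointwise
  monotonicity in A, and the A → ∞ limit N·[g = 0] are property-tested.
  Peaks surviving at large A sit where germline variation is rare or
  absent — the candidate critical base pairs; the same scaling applied to
  a disease-mutation indicator track m (display magnitude configurable;
  1 by default) highlights candidate driver mutations.

Absolute r-values against real variant databases depend on the database
snapshot and are not asserted anywhere; the test suite instead checks the
qualitative behaviour on synthetic data (spikes planted at hole peaks give
positive smoothed r; independent tracks stay within |r| < 0.1).

## Conservation

For protein-coding regions, each alignment column (one per codon) gets the
Shannon entropy S = −Σ p_i ln p_i over residue fractions and the
conservation score C = 2·exp(−S): C = 2 means complete conservation, and
the factor 2 keeps the track on the same visual scale as the hole tracks.
Natural log is the default; the alternative convention C = 2^(−S) sits
behind a flag. Gaps are excluded from the counts by default (policy flag
to count them as a 21st symbol). Codon k of a gene starting at position
s covers nucleotides s + 3(k−1) … s + 3k − 1; the mapping reproduces the
ND1 anchors 3745 → codon 147 and 4216 → codon 304 and is round-trip
tested.

## Packaged data

`data/nd1_rcrs.fasta` is the human mitochondrial ND1 gene region, rCRS
(NC_012920.1) positions 3307–4262, L-strand, transcribed from the
reference and cross-checked against a battery of independent anchors:
MITOMAP reference alleles and their amino-acid consequences at fourteen
positions across the gene, the C6 tract at 3566–3571 (the m.3571insC
hotspot), the m.3902_3908inv motif, and full translation to the 318-residue
ND1 protein in the vertebrate mitochondrial code.

## Synthetic data

The fixture generators emulate the pipeline's three inputs: sequences with
planted base runs in a uniform or random-GC background (the analogue of
the guanine triplets/quadruplets that trap holes in natural sequence),
variant tracks as zero or Poisson background plus spikes at chosen
positions, and alignment columns drawn from per-column residue
distributions. All stochastic modes require an explicit seed and use
NumPy's PCG64 generator, so fixtures are bit-reproducible. What they do
*not* emulate: realistic mutational signatures (transition/transversion
bias, strand asymmetry), linkage between nearby variants, or alignment
columns with phylogenetic correlation — so passing synthetic tests shows
the machinery is correct, not that real variant spectra will correlate
with hole spectra at any particular strength.

## Numerical choices

Dense `eigh` rather than banded or sparse solvers: the periodic and
interchain couplings give the matrix bandwidth N, so banded storage buys
nothing, and full spectra are needed anyway. Probabilities are clamped at
−1e−14 as above; probability conservation, eigenvector norms and baseline
identities are asserted at 1e−10; oracle comparisons (independent
edge-list construction + numpy diagonalization) at 1e−8 on duplexes up to
64 bp. bedGraph/BED exports convert the internal 1-based inclusive
coordinates to 0-based half-open at the boundary, with round-trip tests
at 1e−9.

## Known limitations

* The ensemble heights are sensitive to k_BT and t_⊥ in a way the peak
  *positions* are not. Under the default parameter set, every documented
  hole-maximum position on the ND1 segment is reproduced exactly as a
  strict local maximum (all fourteen anchor maxima, the small peaks at
  3756 and 3768, the H-strand maxima at 3415 and 3895, and the G-run
  peaks at 3437, 3665, 3915), and all ten of the largest H-strand peaks
  fall inside H-strand G≥3 runs. The *ranking* differs from published
  reference analyses of this segment: the canonical ensemble at
  k_BT = 0.047 eV concentrates weight in states bound to the longest
  H-strand guanine runs, so the L-strand track is topped by
  partner-cytosine peaks (e.g. 3569, opposite the H-strand G6 run) rather
  than by the native L-strand G-triplet peaks at 3437 and 3665, and the
  N > 1 maxima censuses come out 50 (L) / 44 (H) rather than the reference
  42 / 34. Parameter scans show no k_BT or t_⊥ reproducing both the
  reference ranking and the reference censuses simultaneously, so the
  defaults are kept at their stated physical values rather than fitted.
* Ionization potentials are gas-phase values; solvation and base-stacking
  corrections would shift the wells by tenths of an eV.
* The model is static; hole migration kinetics, decoherence and polaron
  effects are out of scope, and the EMA smoothing is the only (purely
  phenomenological) nod to migration.
* Whole-genome circles are supported only as "periodic on the supplied
  segment"; no windowed stitching is provided.
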
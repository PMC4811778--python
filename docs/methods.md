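# Methods

## Scope and model

`xlquant` covers the computational stages of a quantitative CXMS
experiment with a cleavable, biotin-tagged, isotope-coded lysine
cross-linker: mass bookkeeping for linked species, light/heavy ratio
estimation from MS1 data, identification filtering and deduplication,
structural validation against Cα coordinates, and PPI network module
extraction.  Database search (identification of cross-linked spectra) is
deliberately out of scope — search-engine reports are consumed, not
recomputed — as are FDR/E-value estimation, fragment-ion prediction, and
any modeling of the linker's cleavage chemistry.

## Mass arithmetic

All masses are monoisotopic.  Residue and element masses come from the
NIST tables shipped with pyteomics; water is 18.010565 Da and the proton
1.007276 Da, used for all charge arithmetic with electron mass ignored —
the convention under which the worked-example inter-link reproduces its
published MH⁺ to four decimals.

The bAL2 inter-link residual (the mass one cleaved cross-link adds to the
sum of two peptide masses) is 318.1505 Da.  The linker's exact
post-cleavage elemental composition is not public, so this constant is
back-computed from the published worked example by subtracting both
peptide masses (with two carbamidomethyl groups) and one proton; the test
suite repeats that derivation against an independent residue-mass oracle.
The mono-link residual defaults to the inter residual + 18.010565 Da, i.e.
a hydrolyzed second arm.  Quenching with ammonium bicarbonate could in
principle leave an amidated arm instead (residual + 17.0265); the default
is hydrolysis, and the constant is configurable on `LinkerSpec`.  The d6
label delta is computed as 6·(m(2H) − m(1H)) = 6.037660 Da.  bAL1 is
modeled with the same cleaved residual as bAL2 — the two designs differ
only in linker backbone details that the cleavage removes, and they behave
identically in practice.  The BS3 built-in (138.06808 Da suberate
residual, 11.4 Å spacer, no reporter, 24 Å strict cutoff) is provided as a
conventional non-enrichable reference; its residual is a standard value,
not derived here.

The reporter ion is treated as the fixed m/z 122.0606, the protonated
composition C7H7NO computed without electron-mass correction (equivalently
C7H8NO⁺ at neutral-composition mass).  No fragment-structure reasoning is
done; `verify_reporter` is a ppm-window peak lookup.

## Ratio estimation

Per identified spectrum, an EIC is built for each predicted isotopic peak
of the light and heavy precursor at the identified charge state.  Defaults:
10 ppm extraction tolerance, ±90 s retention-time window around the
identifying scan, integration bounds from the contiguous above-baseline
region (baseline = 1% of the window apex) around the apex nearest the
identification time.  Isotopic peaks are spaced by the 13C−12C delta
(1.0033548 Da); envelopes are predicted with the averagine model (average
peptide composition C4.9384 H7.7583 N1.3577 O1.4773 S0.0417 per 111.1254 Da),
convolving per-element isotope patterns, truncating below 5% of the base
peak and at 8 peaks.  Averagine is an approximation: it ignores the
linker's own atoms and any unusual amino-acid composition, which shifts
envelope *shapes* slightly but not the regression ratio, since light and
heavy share the envelope.

The estimator is least squares through the origin, â = ΣXY/ΣX², with
standard error σ̂ = sqrt(Σ(Y−âX)²/((K−1)·ΣX²)).  The printed rendering of
this expression is typographically ambiguous; the parenthesization used
here is the standard-error form that vanishes exactly on perfect fits,
matching the stated endpoint semantics.  The normalization of σ̂ to the
[0, 1] confidence score is likewise only specified by its endpoints
(0 = interference-free, 1 = inundated); we use the relative error
min(1, σ̂/â), which satisfies both.  Ratios with σ ≥ 0.5 are discarded
(inclusive at the boundary); the per-link value is the median of surviving
per-spectrum ratios, with per-spectrum estimates kept separate until the
median.  Peak-selection strategies: monoisotopic peak, most intense peak
(largest summed light+heavy area), or least interfered peak (minimal σ).

A deliberate asymmetry: regressing Y on X is not the inverse of regressing
X on Y when noise is present, so swapping channels inverts â exactly only
for interference-free signals.  The label-swap test is therefore run on
noise-free simulations; on noisy data the forward/reverse reciprocal
design, not algebraic inversion, provides the symmetry control.

All-or-none detection flags species present in only one channel: a channel
is absent when its integrated window area stays below 3× the median
nonzero intensity of the trace window (configurable); both channels empty
is unquantifiable, not all-or-none.  Spike-in normalization divides every
ratio by the median ratio across the spike-in protein's quantified links
and refuses to run silently when no spike-in was quantified.

Reciprocal analysis re-orients measured heavy/light ratios to
state1/state2 using the per-experiment channel assignment and calls a
consistent change only when both oriented ratios pass the fold threshold
on the same side.  Links quantified in one direction only are reported
unpaired.

## Identification handling

Spectrum-level thresholds (FDR < 0.05, E-value < 0.01 by default) apply to
report rows; the spectral-count floor (≥3 by default) applies after
deduplication, at the pair level, matching how non-redundant pair counts
are conventionally reported.  Pair identity is the canonical
(lexicographically ordered) unordered pair of (accession, residue number),
with the first-listed accession representing multi-mapped peptides; loop-
and mono-links keep their own record kinds and never merge into inter-link
identity.  Classification is intra/inter only when both peptides map
uniquely; any multi-mapped peptide makes the pair ambiguous (the grey
edges of conventional network figures), and ambiguous pairs are tallied
separately rather than forced into either class.  Dataset merging unions
canonical pairs, sums spectral counts while keeping per-source counts, and
reports pairwise overlaps, so inclusion–exclusion is checkable.

## Structural validation

Distances are Cα–Cα only; side chains are not modeled.  Structures are
read with gemmi (PDB or mmCIF), taking the highest-occupancy alternate
location and preserving insertion codes.  Protein sequences are globally
aligned to each chain (Biopython PairwiseAligner, free end gaps); identity
is matches over the shorter sequence, so truncated constructs and tags do
not penalize, with a 0.9 default threshold chosen to tolerate point
differences without cross-protein mismapping.  Residue numbering is never
assumed to be a fixed offset — the per-residue map comes from the
alignment.  For multi-copy structures the minimum distance over all
consistent chain assignments is reported along with the winning chain
pair; intra-protein pairs are restricted to same-chain assignments unless
cross-copy search is enabled (useful when apparently incompatible long
links may reflect contacts between complex copies), and the search can be
restricted to one assembly instance.  Cutoffs are inclusive (≤22 Å strict,
≤30 Å relaxed).  Summaries always print their denominators: unmapped pairs
are excluded from every fraction.

## Network modules

The PPI graph has one edge per protein pair, weighted by summed spectral
counts, flagged ambiguous if any supporting site pair is.  Module
extraction is classic MCODE: vertex weight = core number of the highest
k-core of the closed neighborhood × that core's density; greedy expansion
from the top-weighted seed admits neighbors within the node-weight
percentage (default 0.2) of the seed weight; haircut trims
singly-connected members; fluff is off.  The module score is density ×
size, and the highest-scoring module over all seeds is returned.  Spectral
counts deliberately do not enter the clustering — they are rendering
attributes — mirroring the separation between line width and clustering in
conventional figures.  On small graphs (cliques with pendants, disjoint
and node-sharing cliques, barbells) the greedy result matches exhaustive
densest-connected-subgraph enumeration; that is not a general guarantee of
MCODE-style greedy search on adversarial graphs.

## Synthetic data

The simulators exist so every stage closes the loop against ground truth
offline.  MS1 runs: Gaussian elution (default σ = 6 s) of light/heavy
averagine envelope pairs at theoretical m/z, heavy apex = light apex ×
true ratio, multiplicative log-normal noise (mean-one parameterization) at
a configurable CV, additive baseline, per-peak m/z jitter in ppm, and
explicit co-eluting interferents; 1 s scan interval.  The default test
conditions — ratios spanning 0.2–5, five species per ratio, 5%
multiplicative noise, no interference — represent a clean, well-behaved
experiment; recovery within 10% under these conditions does not bound
errors on real data with chimeric envelopes, ragged elution, or detector
saturation, which the noise model does not emulate.  Report simulation
plants a known true pair set with sub-threshold E-values/FDR and decoys
that violate at least one threshold, so standard filtering recovers
exactly the truth; toy structures are Cα-only PDB text with arbitrary
per-chain sequences and translated copies.  All generators are pure
functions of (config, seed).

## Problem sizes in the test suite

Simulated runs span 200–320 s at 1 s per scan with up to 20 species; the
regression oracle comparison uses 1000 random short series; module
enumeration oracles run on graphs of ≤10 nodes.  These sizes exercise
every code path while keeping the full suite in a few seconds.

## Known limitations

- No chromatographic alignment between runs; forward and reverse
  experiments are quantified independently.
- No deconvolution of overlapping isotope envelopes; interference is
  handled only through the confidence score.
- EICs are not summed across charge states; quantification uses the
  identified charge only.
- Chain mapping is sequence-based; it cannot resolve residues missing from
  the model (those pairs are reported unmapped, never guessed).
- Buried-surface-area analysis and database overlap of PPI networks are
  out of scope.
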
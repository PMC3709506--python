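# Methods

This note records the models behind each stage, the parameters that
matter, what the simulations do and do not emulate, and the numerical
choices made where the design was open.

## Native-MS forward model and inversion

**Forward model.** A species of neutral average mass *M* produces one peak
per charge *z* at *m/z* = (*M* + *z*·p)/*z* with p = 1.00728 Da (average
proton; ammonium-acetate electrospray, no salt adducts). Peaks are
Gaussian with σ = m/(2.3548·R), the standard FWHM convention at resolving
power R, sampled on a grid of σ_min/5; intensity is equal across charge
states of one species. Noise is additive Gaussian on intensity (sd
relative to the base peak), clipped at zero — the simplest model that
exercises peak-picking thresholds. Resolving powers are free parameters
because instrument peak widths for the 0.4–0.55 MDa species are not
tabulated anywhere authoritative; the analysis uses R = 1000 for intact
complexes and R = 5000 for the bare F1 head, where experimental spectra
visibly sharpen enough to resolve ~507 Da nucleotide splitting at
~10 000 m/z.

**Peak picking** takes strict local maxima above snr·noise, with noise a
MAD estimate of the trace, and refines apexes with a three-point parabola
on log intensity (exact for a Gaussian). Optional Gaussian pre-smoothing
(in grid points) is used on noisy traces.

**Deconvolution** is a greedy charge-hypothesis search: for the strongest
unassigned peak, every z in the allowed range implies a mass and hence a
full predicted series; the hypothesis matching the most unassigned peaks
(within `match_tol_ppm`, default 50 ppm; 150 ppm in the noisy drivers)
wins. Ties favour hypotheses whose matched charges are consecutive — a
z-harmonic (2z, 3z…) reproduces the same peak positions but only at every
second or third charge, so this tie-break rejects harmonics — then lower
mass. A series needs ≥3 peaks; each peak joins at most one series, so
assigned intensity never exceeds picked intensity. The neutral mass is the
intensity-weighted mean of z·(m/z − p). Two robustness steps follow:
series whose masses agree within 5×10⁻⁴ (relative) are merged, because
under noise a species can split when a few apexes drift outside the match
tolerance, and series below 1% of the base series' intensity are dropped
as noise artefacts. Seeds that support no series (e.g. a merged peak where
two species' charge states coincide) are skipped, not fatal.

**Composition assignment** enumerates copy-number vectors depth-first over
subunits sorted by descending mass, pruning a branch when the running mass
exceeds target+tol or cannot reach target−tol even at maximal remaining
copies; this is exhaustive within bounds (property-tested against naive
enumeration). Default tolerance is 0.2% of the observed mass — complexes
of 0.1–0.55 MDa are matched to roughly the nearest kDa. Ranking is by
|mass error|, then fewer total components, then fewer distinct component
types, then lexicographic composition, which makes the order fully
deterministic. Plausibility rules are user-supplied predicates on the
composition (the analysis uses: intact α3β3 head; III ring all-or-nothing
at 14 copies; one lipid per ring subunit; stators and IV only with the
ring). At the default tolerance an unconstrained search over nine subunit
types admits many isobaric impostors — this ambiguity is intrinsic to
subset-sum assignment and is why the rules exist. The shipped subunit
table is an explicitly approximate stand-in (rounded masses consistent
with a ~399 kDa F1 and a ~112.3 kDa ring), not measured values.

**PTM mass shifts** are explained by a small bounded subset-sum over
Met loss (−131.040), N-acetylation (+42.011), oxidation (+15.995, ≤4) and
phosphorylation (+79.966, ≤3), ranked by |residual| at a 0.05 Da default
tolerance.

**Occupancy calling** anchors the apo mass at the lightest detected
species and assigns each species the integer k minimising
|M − base − k·m_nuc| (ATP 507.2, γS-ATP 523.3, ADP 427.2 Da average),
rejecting to an explicit `unassigned` list beyond a 100 Da tolerance.
Conditions with no remaining apo population (e.g. tenfold ATP excess) use
the `apo_mass` override, taken in the analysis from deconvolving the apo
F1 spectrum of the same experiment rather than from a constant. Abundance
ratios are reported normalised to the smallest population.

## Cross-link identification

Peptides are tryptic (cleave after K/R except before P) with ≤2 missed
cleavages; masses are monoisotopic residue sums (cross-checked against
pyteomics). Variable modifications are carbamidomethyl-C (+57.0215) and
oxidation-M (+15.9949), capped at 3 per peptide. A linkable lysine must be
an internal missed-cleavage site, since trypsin does not cleave after a
derivatised K. Candidates are all unordered peptide pairs with one link
site choice per peptide and one isotope form each; BS3 bridge masses are
fixed by elemental composition (d0 +138.0681, d4 +142.0932, shift
4.02511 Da = 4×(²H−¹H)); hydrolysed mono-links are out of scope.

Matching uses a 10 ppm precursor and 0.8 Da fragment tolerance by default.
The MS2 score is (matched fraction of theoretical b/y ions) × (matched
fraction of spectrum intensity), in [0,1]; fragments containing the linked
residue carry the partner peptide plus bridge as a fixed addition. This
simple score replaces proprietary engine scores; its default acceptance
threshold is 0.3. Validation applies exactly two criteria — score ≥
threshold and presence of the isotope doublet partner at m/z ± shift/z in
a co-eluting MS1 feature — then deduplicates hits to unique residue pairs
and classifies intra/inter-protein. FDR (%) is
100·(N_hits − N_validated)/N_hits, reported to two decimals. In the
analysis driver, "hits" are candidate–spectrum matches with score ≥ 0.1,
mirroring the fact that engines only report matches with some fragment
evidence; the FDR definition itself is unchanged.

The simulated identification run shows a realistic failure mode: peptides
that overlap a true peptide (sharing a tryptic segment, made isobaric by
residue-composition coincidences) can score just above threshold against
the true spectrum and inherit its doublet, producing an occasional false
unique link. This is reported, not suppressed.

## Comparative quantification

XICs sum MS1 feature intensities within m/z ± 10 ppm per retention time,
windowed ±30 s (±18 s in the dense drivers) around the link's elution;
areas are trapezoidal; no background subtraction and no inter-run RT
alignment by default (the compared samples are pooled into a single
injection; an optional constant rt shift exists for the heavy channel,
default 0, as is the generator's optional d4 co-elution shift). The ratio
is oriented untreated/dephosphorylated so a reduction upon
dephosphorylation gives ratio > 1. Fold-change classes use half-open bins
on the symmetric fold max(r, 1/r): [1,2) unchanged, [2,5), [5,10),
[10,∞); a boundary value falls in the higher bin, so a noiseless 5.0 is
"5–10", while a true fivefold link under noise legitimately lands on
either side of that boundary. A zero heavy area reports an infinite
ratio, class >10, flagged. Ratios are scale-invariant and invert exactly
under label swap (property-tested).

## Structure mapping

Distances are measured between Cα atoms by default — the published cutoff
pair (24.4 Å strict = 11.4 Å spacer + 2×6.5 Å side chains; 35 Å dynamic)
is defined per cross-link without naming atoms, and Cα is robust to
unresolved side chains. An Nζ rule is available and falls back to Cα with
a note. Residues are addressed by chain + author numbering via a
configurable protein→chain map; absent residues yield "unresolved", never
an exception. The lipid-pose screen keeps poses with donor–acceptor
distance strictly below the cutoff (default 5 Å) sorted ascending; the
atom selectors are user-specified since no canonical atom pair defines
the lipid–arginine gap. Phosphosite context flags a link when either
linked residue is within a radius (default 15 Å) of a site, falling back
to sequence separation × 3.8 Å (extended-chain upper bound) when
coordinates are missing.

## What the simulations do and do not show

The generators reproduce the statistical structure the analysis assumes:
exact charge-state geometry, Gaussian peaks and chromatograms, exact
doublet spacing, complete b/y ladders for true links, decoys built by
residue shuffling (mass-preserving, fragment-scrambling, no doublet
partner), and deterministic byte-identical output per seed. They omit
detergent-micelle adducts, isotopic fine structure, charge-state intensity
envelopes, peak tailing, co-elution interference and missing fragments.
Passing round-trip tests therefore demonstrates correctness of the
inversions under their own model assumptions, not performance on real
instrument data, where peak-shape and interference effects dominate.

## Problem sizes

Tests and drivers run at desk scale by design: 3–8 proteins of 80–510
residues, 1–32 links per run, 21 charge states per envelope, ~10⁴ m/z grid
points per spectrum, ≤6 subunit types in assignment property tests. The
headline round trips (123 kDa mass difference; maximum occupancy 3;
fivefold quant recovery at 5% noise; 9.29% FDR arithmetic) complete in
seconds.
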
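# Methods

This note documents the models implemented in `mirtarget`, the
assumptions behind them, the defaults that matter, and what the
synthetic-data generators do and do not emulate.

## Seed matching

A target site is the exact Watson–Crick reverse complement of the
miRNA seed (1-based start 2, length 7 by default; 6 and 8 supported)
occurring in a 3′-UTR.  Scanning is canonical-only by default; G:U
wobble matching is an opt-in flag that affects only the scanner.
Seed-type taxonomy (7mer-A1 vs 7mer-m8, 8mer) is deliberately not
distinguished: a site is defined purely by the reverse complement of
the configured seed region.  Positions containing N never match.
Coordinates are 0-based half-open internally and 1-based inclusive in
reports.  Multiple transcripts per gene are scanned independently;
collapsing is left to the caller.

## Thermodynamic features

The reduced nearest-neighbour model scores a non-crossing secondary
structure by loop decomposition:

- stacked pairs: tabulated free energies (`data/stack_energies.tsv`,
  kcal/mol at 37 °C) over Watson–Crick and G:U pairs, with the
  rotational symmetry stack(XY/WZ) = stack(ZW/YX) enforced on load;
- hairpin loops (minimum 3 unpaired): 5.6 + 0.3·size;
- internal/bulge loops: 4.0 + 0.5·size, capped at 30 unpaired nt;
- multiloops: 4.6 + 0.4·(branches + 1) + 0.1·unpaired;
- exterior loops free; duplexes pay one initiation term (4.09) when
  any intermolecular pair exists, and loops containing the cut
  between the two molecules are scored like exterior loops.

There are no dangling ends and no coaxial stacking.  Minimum free
energy (with traceback) and partition functions are computed by
dynamic programming; for two-molecule folds the cut-aware recursions
follow the cofold decomposition (cut loop, cut-spanning interior
loop, cut-spanning multiloop branch).  The same energy function,
applied to exhaustively enumerated structures, serves as an
independent oracle; DP and enumeration agree to 1e-6 kcal/mol on
random instances up to the enumeration cap (14 nt total).  Because
the parameter set is reduced, absolute energies differ from
full-Turner implementations; the intended product is the ranking of
sites, and the backend is pluggable through `BackendContract`.

Feature definitions: `dg_duplex` is the MFE of the joint structure of
the miRNA and the site region (the seed match extended 5′ on the UTR
so the region length equals the miRNA length — the extension is
configurable since the amount of upstream context is a free choice);
`dg_binding` = G(pair ensemble) − G(miRNA) − G(site); `dg_open` =
G(window, site constrained single-stranded) − G(window) with the
constraint on a 70-nt segment centred on the site and the folded
window extending it by 70 nt per side (both truncated at UTR ends).
`dg_open` is reported with the positive-cost sign convention (≥ 0,
clamped at numerical zero below 1e-6), and the unconstrained term is
computed on the same window rather than the whole UTR, keeping the
O(n³) fold local.  `dg_total` = `dg_duplex` + `dg_open` exactly.

## Probabilistic features

The UTR is modelled as an order-1 Markov chain — UTRs are too short
to estimate higher orders — fitted to the same UTR that is scored,
with pseudocount 1 (a never-observed context falls back to a uniform
row with a warning when the pseudocount is 0).  `p_over_binomial`
treats the L − m + 1 start positions as independent trials with the
chain's start probability.  `p_over_exact` embeds the motif's KMP
failure-function automaton in the chain, propagating a joint
(state, count) distribution; occurrences are counted with overlaps
(the automaton restarts from the longest border after each match),
matching the scanner.  The observed count n is the per-UTR number of
seed matches for the miRNA.  Reports carry −log10 of the tails so
that larger values mean more over-represented.

## Conservation features

Alignments are per-UTR MAF blocks (species = text before the first
dot of the source name); gaps and Ns are missing data in all
likelihoods.  The species topology is user-supplied Newick; only
branch lengths are fitted, by maximising the Felsenstein pruning
likelihood with bounded L-BFGS-B (bounds 1e-8..10 substitutions/site,
start 0.1, topology derooted so every edge is identifiable).  HKY85
(κ = 2, uniform frequencies) is the default model; JC69 is available
and used in closed-form checks.  Alignments need ≥ 2 shared species
and ≥ 20 non-gap columns.

**BLS** prunes the fitted tree to the species that retain the site
(mode `anywhere` by default: the motif occurs somewhere in the
species' row; `same_columns` requires the exact reference columns)
and sums the remaining branch lengths.  Stem edges above the pruned
subtree's MRCA are excluded; pruning was validated against an
edge-cut oracle over every subset of an 8-leaf tree.

**Negative-selection test** (`phylop` feature): the site columns are
scored on the UTR-fitted tree (null) and on the same tree with all
branch lengths scaled by ρ ∈ (0, 1] (alternative, ρ̂ by bounded
scalar optimisation; ρ is floored at 1e-4).  The statistic
2(lnL_alt − lnL_null) is referred to the boundary mixture
½χ²₀ + ½χ²₁; the feature is −log10 P.  This is a deliberate
approximation of substitution-count-posterior tests of the same
hypothesis (locally shortened branches): it shares the null and the
direction but not the exact machinery.  Calibration on a 12-leaf
tree with 7-column sites gives an empirical size of about 5–8% at
the nominal 5% level, and median ρ̂ within 0.02 of the truth for
simulated ρ ∈ {0.2, 0.5}.  Sites need ≥ 6 alignment columns; with
fewer than 2 informative species the test degenerates to P = 1.

**PhastCons averaging**: the mean of available per-base scores over
the seed, with the covered fraction reported alongside; no covered
base yields an absent value, never a silent zero.

A utility reports, per site, the fraction of motif-bearing species
whose match sits at the reference alignment columns (species without
any match are discarded) — the position-conservation check that
motivates testing the site at fixed columns.

## Sequence features

`au_content`: A/U fraction over 30-nt flanks on both sides, weighted
1/d by distance from the site boundary; N excluded from numerator
and denominator; no usable flank base gives an absent value.
`pairing3`: best contiguous run of Watson–Crick pairs between miRNA
positions ≥ 9 and the UTR upstream of the seed, 1.0 per pair in the
13–16 core and 0.5 elsewhere, minus 0.5·max(0, |offset| − 2),
maximised over offsets up to 8 and floored at 0.  `utr_position`:
distance to the nearest UTR end, capped at 1500 nt so long UTRs do
not dominate linear fits.  The 1/d weights, the 13–16 core and the
offset penalty are fixed here as the reference behaviour.

## Model combination

`fit_linear` z-scores features internally (scalers stored with the
model), solves OLS, and refuses rank-deficient designs naming the
collinear columns.  `car_importance` computes ω = (R^{−1/2} r)² via
the symmetric eigendecomposition of the feature correlation matrix;
a singular R is ridge-regularised with λ = 1e-8·trace/p under a
warning.  Σω equals the OLS R² algebraically, and the importances
are invariant to affine rescaling of any feature.  `dg_total` should
be excluded from joint fits (it is the sum of two other features and
makes the design singular).  No trained coefficients are shipped:
the fitted model depends on the expression dataset at hand; the
repo provides the machinery plus simulation-trained demo fits.
Multi-site aggregation offers best (min or max by the feature's
correlation sign), sum, and a numerically stable log-sum-exp;
`quantile_report` bins predictions into q near-equal rank bins
(stable ties) and reports mean response per bin.

## Synthetic data

All tests run on generated data under a single integer seed,
deterministically split per generator.  `sim_utr` samples the
order-1 chain (uniform by default) and overwrites the motif at
non-overlapping positions; `sim_alignment` evolves a root sequence
column-independently down the tree with per-region branch scaling ρ
and no indels (gaps enter tests only through hand-written MAF
fixtures, keeping the likelihood oracle exact); `sim_feature_table`
draws features from a given covariance and adds a linear Gaussian
response.  The CLI `simulate` bundle re-plants the reference row
with the UTR sequence after evolution so the reference-row invariant
holds exactly.  The acceptance script's planted regression table
uses ten standardised features with decaying coefficients and a
noise level chosen for a weak linear signal (R² ≈ 0.12), the typical
magnitude for repression-strength regressions on expression data.

What the generators do **not** emulate: indels and alignment error,
context-dependent substitution (stacking-aware evolution),
UTR-annotation noise, isoform structure, and expression-measurement
artefacts.  Passing tests therefore establish internal correctness
(oracle equivalence, calibration, recovery) — not performance on
real transcriptome data, which additionally depends on those
factors.

## Numerical choices and limitations

- Folding: temperature fixed at 37 °C (RT ≈ 0.6163 kcal/mol);
  partition functions in linear space (float64 suffices at the
  window sizes used); traceback resolves ties by first candidate at
  1e-7 tolerance; `dg_open` windows default to 70/70 nt.
- Tree fitting is deterministic given the fixed start and optimiser
  tolerances; degenerate (substitution-free) alignments drive all
  branches to the lower bound with a warning.
- The selection LRT relies on the asymptotic boundary mixture at
  7-column sites; its finite-sample size (≈ 5–8%) is reported by the
  calibration test rather than assumed.
- Out of scope: pseudoknots, temperature scans, non-canonical or
  centred sites, ORF/5′-UTR sites, genome-annotation handling, and
  higher-order backgrounds.
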
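# Methods

## Scope and data model

`f2linkage` implements the computational chain for building and comparing
genetic linkage maps from codominant SNP genotypes of F2 intercross
populations.  All stages operate on a single container, the ABH genotype
matrix (individuals × markers, codes A/H/B/missing, internally the dose of
parent-2 alleles with −1 for missing).  Phase is fixed coupling: A and B are
defined by parent of origin, so no phase search is needed.  Dominant marker
classes are not implemented.

## Two-point estimation

For loci in coupling with recombination fraction r (q = 1 − r) the F2
joint-genotype probabilities are q²/4 (AA, BB), r²/4 (AB, BA), qr/2 (the
four single-heterozygote classes) and (q² + r²)/2 (HH).  The MLE is computed
by EM on the hidden recombinant-gamete count: corners contribute 0, edges 1,
anti-corners 2, and each HH individual an expected 2r²/(q² + r²); the M-step
is r ← E[recombinant gametes]/2N.  Initialization r₀ = 0.25, tolerance 1e-6
on |Δr|, at most 500 iterations, clamped to [0, 0.5].  The estimate is
checked in the test suite against an independent grid-search oracle over the
multinomial log-likelihood (step 1e-4, agreement to 1e-3 on random tables).
LOD compares the likelihood at r̂ with independence (r = 0.5); tiny negative
round-off is clamped to 0.  All-pairs estimation runs the same EM
simultaneously on the 3×3 count tables obtained from one-hot indicator
products, so a 120-marker group needs nine matrix multiplications rather
than 7,140 scalar passes.  The batch and scalar solvers are both fixed-point
approximations at the same tolerance and may differ by ~1e-7 in r̂.

Distances use the Kosambi map function d = 25 ln((1+2r)/(1−2r)) (inverse
r = tanh(d/50)/2); Haldane d = −50 ln(1−2r) is available for cross-checks.

## Grouping, ordering, positions

Linkage groups are the transitive closure of the pairwise graph with an edge
when LOD ≥ lod_min and r̂ ≤ r_max.  Defaults lod_min = 6.0 and r_max = 0.45
are deliberately conservative for dense panels (hundreds of markers per
chromosome at n ≈ 80–200 give adjacent LODs far above 6); both are exposed
as configuration.  Singleton groups are retained and reported.

Ordering minimizes the lexicographic objective (total obligate crossovers,
then summed adjacent Kosambi length), a formalization of manual map curation
that first minimizes crossovers and then map length.  Obligate crossovers
are Σ |dose(g) − dose(g′)| over consecutive observed genotypes per
individual, skipping missing calls.  The search chains markers greedily by
nearest r̂ from the tightest pair, then alternates 2-opt segment reversals
and window ripple (windows of 2–4, reinsertion at every position in both
orientations) until no move improves, at most 40 rounds.  Moves are scored
with a pairwise crossover-cost matrix (1 per A–H/H–B pair, 2 per A–B pair,
over individuals observed at both markers), whose adjacent sum equals the
exact obligate-crossover count whenever there are no missing calls; with
missing data it is an upper-bound surrogate and the exact objective is
available for reporting (`ordering_objective`).  On 6-marker instances the
heuristic reaches the exhaustive-permutation optimum; on 30-marker
error-free simulations (n = 200) it recovers the true order exactly.
Orientation of a group is arbitrary; it is normalized against a reference
order when one is supplied, otherwise lexicographically by terminal marker
ids.

Positions are cumulative Kosambi distances over adjacent two-point
estimates (no multipoint likelihood).  Markers with r̂ < 1e-6 to their
predecessor join its genetic bin and share its position; an adjacent
r̂ ≥ 0.5 raises an explicit infinite-gap error.  Map summaries report, per
group and in total: marker count, bin count, coverage (last bin position),
maximum adjacent-bin gap, and the average bin interval defined as
coverage / number of bins, rounded to one decimal — the convention of the
published tomato map tables this package mirrors.

## Synthetic F2 populations

Each individual is the union of two independent gametes.  Crossovers are
placed on the true cM axis either as a Poisson process at 1 per 100 cM (no
interference; consistent with Haldane distances) or as a gamma-renewal
process (default shape 2.6, mean spacing 100 cM, burned in from upstream of
the chromosome for approximate stationarity), whose positive interference
matches the Kosambi function closely.  Genotype = dose of parent-2 alleles
read from the two gamete phases.  On top of the meiotic model:

- **Genotyping error** ε: each observed call is replaced by one of the other
  two codes uniformly with probability ε, then masked to missing with the
  missing rate.  The default ε in examples (0.005–0.01) is a placeholder for
  array-scale error, not an inferred value.
- **Viability selection**: optional per-locus fitness triples (wAA, wAH,
  wBB); zygotes are rejection-sampled by the product of relative fitnesses,
  producing segregation distortion that the χ² scan must flag.
- **Inversions**: declared cM intervals suppress crossovers completely (no
  recombinant gametes emitted for the interval).  A cross whose parents
  differ by an inversion is emulated by `reverse_segment`, which reverses
  the marker order inside the interval for the second population so the two
  maps disagree locally with negative slope.
- **Physical coordinates**: either proportional to cM or with a
  pericentromeric plateau — a central fraction of the bp axis carrying
  `compression`-fold less cM per Mbp, giving a sigmoidal Marey curve.
  `bp_uniform_chromosome` places markers uniformly on the physical axis
  (mimicking gene-based array design) so the plateau appears as a flat
  Marey segment rather than a marker desert.

A single integer seed drives one generator; fixed seed ⇒ byte-identical
output.  What the generator does **not** emulate: locus-specific error
(cluster-calling artifacts that miscall a roughly fixed number of samples
per SNP), linkage disequilibrium in the parents, segregation of structural
variants other than simple inversions, and real marker ascertainment bias.
Passing tests therefore demonstrate correctness of the estimators under the
stated generative model, not calibration to any particular array.

## Map comparison

- **Distortion scan**: per-marker χ² goodness-of-fit against 1:2:1 on
  observed counts, df = 2, α = 0.05 per marker with no multiple-testing
  correction (the published scans report raw distorted-marker counts);
  markers with < 10 observed calls are untestable and excluded from
  per-group fractions.  The type-I error of the scan is verified to sit in
  [0.03, 0.07] on 1,000 undistorted simulated markers.
- **Distortion–expansion regression**: OLS of per-group length ratio on
  distorted fraction; a flat response returns slope 0, R² = 0; a constant
  predictor is an error.
- **Spaced resampling**: per group, a random anchor bin within the first
  min_spacing (default 5 cM) and greedy sweeps in both directions retain
  bins ≥ min_spacing apart (the bidirectional sweep preserves the group's
  span; a one-directional sweep would truncate ~min_spacing/2 per group on
  average), with one random marker per retained bin.  Each iteration
  re-estimates pairwise linkage on the subset, re-orders every group from
  genotypes alone, and records per-group and total lengths; failed
  iterations are recorded and skipped.  Populations are compared by one-way
  fixed-effects ANOVA; zero within-group variance with unequal means is
  flagged as infinite F.
- **Colinearity**: common markers (by id) are ranked within each map's
  group (ties — co-binned markers — get average ranks) and rank_B is
  regressed on rank_A; R² is the reported coefficient.  A fully reversed
  group gives R² = 1 with negative slope: orientation, not disorder.
- **Inverted blocks**: after flipping map B if the global rank correlation
  is negative, maximal runs of ≥ min_block (default 4) consecutive markers
  in map-A order with within-run Spearman ≤ −slope_threshold (default 0.8)
  are reported with their index span and local correlation.  The defaults
  trade sensitivity (a 6-marker simulated inversion is localized exactly)
  against false positives (zero calls across 100 independently mapped
  colinear population pairs).

## Physical placement and Marey profiles

A SNP assayed from a flanking sequence `LEFT[X/Y]RIGHT` sits f = len(LEFT)
bases into its query.  From the best 12-column alignment hit (highest
bitscore, ties by lowest e-value, residual ties ambiguous → no placement),
the 1-based position is sstart + offset on the forward strand (sstart ≤
send) and sstart − offset on the reverse, with offset = f − (qstart − 1);
the qstart correction covers partial query alignments.  Sites outside the
aligned query interval are errors.  Coordinates are 1-based inclusive
throughout; conversion to 0-based half-open happens only in the optional
BED-style serialization.  The placement arithmetic round-trips exactly on
both strands by construction and by test.

Synteny classification compares each linkage group's assigned chromosome
(majority vote of its placed markers unless supplied) with each marker's
physical chromosome.  Physical summaries report per-chromosome count,
coverage (max − min)/1e6 Mbp, maximum gap, and an average interval
recomputed as coverage/count (published per-chromosome "average" columns
that follow a different, unstated convention are not reproduced).

Marey profiles slide a window (default 2 Mbp, step 0.5 Mbp) along each
chromosome and take the OLS slope of cM on Mbp over the ≥ 2 markers inside;
negative slopes are clamped to 0 and counted.  Suppression regions are
maximal runs of windows with rate < 0.2 cM/Mbp spanning ≥ 2 Mbp.  Window
scheme and thresholds are configuration; the defaults resolve a simulated
pericentromeric plateau (compression 20 over the central 50 %) with ≥ 80 %
overlap.

## Numerical and design choices

- Missing genotype tokens "-" (canonical), "U", "NA", "" are accepted on
  input; "-" is always written.  Default missingness filter 0.2.
- Matrices are stored markers-in-columns; both file orientations are read.
- Bin membership uses r̂ < 1e-6 (EM converges quadratically to 0 for pairs
  with no observed recombination, so the threshold is far from data-driven
  r̂ values at realistic n).
- Ordering tie-breaks use 1e-9 tolerances on the surrogate objective;
  determinism is guaranteed for a fixed seed.
- ANOVA is one-way fixed-effects; rank ties get average ranks.
- Map tables serialize positions with `repr` so read/write round-trips
  exactly while always printing a decimal point.

## Problem sizes used in the test suite

Simulation tests run at desk scale chosen to keep the full suite in a few
minutes while preserving the regimes of interest: order recovery at 30
markers / 50 cM / n = 200; exhaustive-oracle ordering at 6 markers;
map-inflation experiments at 120 markers / 60 cM (sub-cM spacing, the dense
regime of real array maps) with ε = 0.01 and 20 paired replicates
(subsampling 79 individuals from each 160-individual population gives
common random numbers); resampling at 60 iterations; inversion detection at
2 × 30 markers / n = 150 and 100 colinear pairs.

## Known limitations

- Distances come from adjacent two-point estimates only; there is no
  multipoint likelihood and no hidden-Markov genotype-error correction, so
  genotyping error inflates maps (by roughly 100·ε·(number of markers) cM
  in the dense regime, since each isolated miscall forces about two
  spurious crossovers whose map-length cost is ~100/n cM each across the
  ~ε·n·m expected errors).  A consequence worth stating plainly: under this
  per-call error model the *expected* inflation is independent of
  population size — the paired experiments in the acceptance suite show the
  n = 79 and n = 160 means within noise of each other — so a small
  population is not, by itself, sufficient to reproduce a strong small-n
  map expansion with this estimator.  Spaced-subset resampling does shrink
  inflated dense maps toward truth, because the inflation scales with the
  number of retained markers.
- The ordering heuristic is local search, not exact, beyond ~8 markers;
  quality is asserted statistically on synthetic truth.
- F2 only; no backcross or RIL designs, no dominant markers.
- The generator's inversion model is complete crossover suppression;
  partial suppression and double heterozygote inversion loops are out of
  scope.
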
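# Methods

This note records the statistical model, the default parameters, what the
synthetic data can and cannot demonstrate, and the numerical choices made in
`linkanchor`.

## Population and genetic model

The package targets doubled-haploid (DH) populations. Every line is fully
homozygous, each biallelic locus takes one of two parental states (`A`/`B`),
and a single meiosis separates the parents from each line, so the expected
frequency of recombinant lines between two loci equals the recombination
fraction r directly.

For a marker pair, let N be the number of lines non-missing at both loci and R
the number of recombinant lines among them. The maximum-likelihood estimate is
r̂ = R/N, and the LOD score against the null of free recombination (r = 1/2)
is

    LOD = R·log₁₀(r̂) + (N−R)·log₁₀(1−r̂) + N·log₁₀(2).

r̂ is capped at 0.4999 before evaluating the LOD, so R/N ≥ 1/2 yields LOD ≤ 0
rather than a spurious positive score; the cap also avoids log(0). Pairs with
N = 0 carry NaN sentinels and never form linkage edges. Heterozygous calls are
rejected at input validation: only `A`, `B`, and `-` (missing) are legal DH
symbols.

Map distances use Haldane's function d = −50·ln(1−2r) cM with inverse
r = (1−e^(−d/50))/2. This is the exact inverse of the simulator's crossover
model (below), so simulated and estimated distances are directly comparable.

## Simulator

`simulate_dataset(seed, **overrides)` produces a genome, scaffolds, markers,
and a DH genotype matrix. Defaults (all overridable):

| parameter | default | rationale |
|---|---|---|
| chromosomes | 10 × 28.38 Mbp | a mid-size diploid plant genome, 283.8 Mbp total |
| recombination rate | 4.349 cM/Mbp, uniform | gives ≈1234 cM of total genetic length |
| scaffolds | ~150 (mean 1.9 Mbp, min 100 kbp) | Poisson fragmentation; fragments below the minimum merge leftward |
| markers | 507 = 415 InDel + 92 SSR | typical intraspecific map density (~2.4 cM/marker) |
| DH lines | 119 | typical mapping-population size |
| missing data | 2% | masked uniformly at random |
| genotyping error | 0.5% | independent allele flips |

Crossovers per chromosome per line are Poisson with mean G/100 (G = genetic
length in cM), positions uniform in genetic coordinates, starting phase
random — i.e. no crossover interference, which is exactly the process under
which Haldane's map function is correct. Scaffolds receive random strands;
minus-strand scaffold sequence is the reverse complement of the chromosomal
segment, and marker primers are cut verbatim from scaffold sequence so that
in-silico PCR must handle both orientations. Marker genetic positions follow
from physical position times the uniform rate, so markers are collinear by
construction and ground truth (chromosome, bp, cM, strand) is recorded for
every scaffold and marker.

What the synthetic data **does** demonstrate: correctness of the two-point
statistics, grouping, ordering, anchoring, orientation, AGP construction, and
the reporting arithmetic, all scored against a known truth at the full
problem scale (283.8 Mbp of sequence, 128k marker pairs).

What it does **not** demonstrate: segregation distortion, non-uniform
recombination (centromeric suppression), crossover interference, paralogy or
repeat-induced false primer hits beyond what random sequence produces,
scaffold misassembly, or dominant/codominant marker mixtures. Claims about
real genomes should not be inferred from the defaults; they are a scale
choice, not an empirical calibration.

## Linkage engine

`LinkageMapper` is a scikit-learn-style estimator (`fit`, `get_params`,
`set_params`, trailing-underscore fitted attributes) because the computation
is genuinely fit-shaped: it consumes a call matrix and estimates grouping
labels and positions.

- **Pairwise table.** r̂, LOD, and N for all pairs are computed with
  vectorised float matrix products over match/informative masks, identical (to
  float round-off) to the scalar definition; tests assert agreement with an
  independent binomial log-likelihood oracle built on
  `scipy.stats.binom.logpmf`.
- **Grouping.** Union-find over edges with LOD ≥ 7 (default) and r̂ < 0.5.
- **Binning.** Markers with R = 0 and N > 0 between them co-segregate and are
  merged into a single bin (no recombination information separates them at
  this population size).
- **Ordering.** Bins are ordered to minimise SARF (sum of adjacent
  recombination fractions), with inter-bin r pooled N-weighted across member
  pairs. Groups with ≤8 bins are solved exactly by exhaustive permutation
  (reversals filtered). Larger groups use greedy seriation seeded from the
  most distant pair followed by 2-opt refinement; tests verify the heuristic
  attains the exhaustive optimum on instances small enough to check.
- **Canonical form.** Each group is written with its lexicographically smaller
  terminal bin first, making the map invariant to input column order. If
  anchor markers with known chromosomes/positions are supplied, groups are
  named by majority anchor vote and flipped so anchor positions ascend
  (Kendall tau sign).
- **Positions.** Cumulative Haldane transform of the ordered inter-bin r̂.

Two-point estimation with adjacent-interval summation has a well-known bias:
every genotyping error at an interior marker creates two false recombination
events. With the default 0.5% error rate and 507 markers the summed map is
≈1689 cM against a simulated 1234 cM (+37%). This **map inflation** is a
property of the estimator class, not a code defect; the test suite verifies
map-length recovery within sampling tolerance on clean genotypes, where the
median absolute length error at n = 119 is ≈5% and shrinks with population
size as expected for a binomial-sampling-dominated error.

## In-silico PCR and anchoring

Marker placement requires an exact occurrence of the forward primer and the
reverse complement of the reverse primer (or the swapped configuration on
minus-strand templates) with an amplicon span of 80–200 bp. Exact matching
over the full 283.8 Mbp is implemented with a vectorised 2-bit rolling k-mer
prefix hash (k = shortest primer length) with full-string verification of
candidate positions — an implementation speed-up only; a naive scan is the
test oracle. Markers with more than one amplicon anywhere in the assembly are
non-unique and excluded from anchoring.

Scaffolds are assigned to the linkage group holding ≥2/3 of their mapped
markers (ties and weak majorities are flagged as conflicts), positioned at the
median cM of supporting markers (robust to a single misplaced marker), and
oriented by the sign of Kendall's tau between marker cM and amplicon midpoint
bp; scaffolds with fewer than two distinct positions remain unoriented.
Pseudochromosomes are emitted as AGP 2.1 (1-based, W components and 100-bp U
gaps) plus BED marker tracks; FASTA output is optional.

## Marker design

InDels of 4–10 bp are selected as assay candidates. Primer design is a
deterministic scan (amplicon length, then window start, then primer length
18–24 bp) for the first pair satisfying: amplicon 80–200 bp spanning the
variant, GC fraction > 0.35, Tm ∈ [55, 63] °C, |ΔTm| < 3 °C. Tm uses the
GC-count approximation Tm = 64.9 + 41·(#GC − 16.4)/length — adequate for
ranking candidate primers on synthetic sequence, not a thermodynamic
nearest-neighbour model.

## Map integration

Anchor sets from multiple maps are merged under an explicit precedence order:
for each scaffold the highest-precedence assignment wins, disagreements are
logged as conflicts with full evidence lists, and common loci between two maps
are scaffold pairs assigned within 100 kbp, matched greedily one-to-one by
distance. Integration is idempotent and monotone in coverage (tests verify
both).

## Numerical and reporting conventions

- Percentages and per-marker densities in tables are rounded half-up to two
  decimals via `decimal.Decimal` (banker's rounding would disagree with
  conventional table arithmetic at exact .005 boundaries); the total row's
  average interval is the Decimal mean of the per-group two-decimal averages.
- Marker proximity reports Σ min(Lᵢ, 2·radius)/Σ Lᵢ over inter-bin intervals —
  the fraction of covered map length within the radius of a marker.
- Collinearity uses the Marey construction: markers projected onto
  pseudochromosome coordinates via the AGP, with the collinear fraction being
  the longest non-decreasing subsequence of cM per chromosome
  (O(n log n) bisect); per-scaffold slopes are judged in pseudomolecule
  coordinates so that an inverted scaffold is flagged by its negative slope.
- All randomness flows from a single integer seed through
  `numpy.random.default_rng`; stage sub-seeds are fixed offsets, and pipeline
  output is byte-identical across runs at the same seed.

## Limitations

- Two-point ordering only; no multipoint likelihood (e.g. hidden Markov
  regression) and therefore no per-interval error correction, hence the map
  inflation described above.
- Uniform recombination and uniform marker placement make the synthetic
  ordering problem easier than centromere-bearing real chromosomes.
- Exact-match in-silico PCR has no mismatch tolerance; real primer assays
  tolerate some mismatches, so real-data uniqueness screens should be more
  conservative.
- Orientation by rank correlation is undefined for scaffolds whose markers
  co-segregate; at 119 lines this leaves a substantial minority of short
  scaffolds unoriented (correctly reported as `undetermined`).
- The greedy + 2-opt seriation is not guaranteed optimal above 8 bins,
  although it attains the optimum on all tested instances.
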
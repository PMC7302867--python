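# Methods

## The repeat model

A *polytract* is a maximal perfect run of a repeated 1-, 2- or 3-nt motif
in a reference sequence, with any incomplete terminal unit included. The
three clades are mono-, di- and tri-nucleotide repeats (MNR/DNR/TNR) with
minimum sizes of six units for MNRs and three units for DNRs/TNRs, i.e.
6 / 6 / 9 nt. Only perfect matches qualify: a single substitution ends a
run, and non-ACGT characters (assembly Ns, gaps) can never lie inside one.
Scanning is case-insensitive, so soft-masked sequence is treated like
unmasked sequence.

The clade of a run is decided by the *smallest period* of the enclosed
sequence: `AAAAAA` is an MNR only, `ATATAT` a DNR only. Scans per clade
are otherwise independent, so a nucleotide may belong to runs of different
clades (the union territory is used for combined analyses). Within one
clade, maximal runs of a fixed period are provably disjoint.

Because a repeat is the same double-stranded object under cyclic rotation
of its unit and under reverse complement, units collapse into 16 canonical
*species*: A/T and C/G (MNR); TA, CT/GA, CA/GT and GC (DNR); and ten TNR
groups named AAC, AAG, AAT, ACC, GAC, ACT, CAG, AGG, ATC, CGG, each
covering the six words of its rotation/reverse-complement orbit. Note
that a word such as CTC is a valid trimer unit although the word itself
has period 2 — the run `CTCCTC…` still has smallest period 3; only the
homopolymer words (AA…TT, AAA…TTT) are degenerate and unmapped, which is
why exactly 4 + 12 + 60 words carry labels.

A *hinge* is a single nucleotide separating two tandem polytracts: some
tract ends exactly at the hinge, another starts immediately after it, and
the hinge itself lies inside no tract of any clade. When several tracts
share a boundary, the longest abutting tract labels that side, with clade
priority MNR > DNR > TNR on equal length — an arbitrary but fixed rule;
duplex labels are reported as unordered species pairs.

## Enrichment statistics

The *territory* of a polytract subset is the merged set of genome
positions it occupies. By default each tract is first widened by one
nucleotide per side ("adjacency extension", suppressible), because
features caused by repeat-boundary artifacts concentrate immediately
outside the exact repeat. Hinge territories are the hinge positions
themselves and are not extended by default.

For a genome of N nucleotides, a territory of n, and a feature with M
instances of which k overlap the territory, over-representation is tested
with the exact binomial tail

    p = P(X ≥ k),   X ~ Binomial(M, n/N)

and under-representation with P(X ≤ k); no normal approximation is used.
In *singleton* mode k and M count instances (an instance overlapping the
territory anywhere, even across two disjoint intervals, counts once); in
*multiplex* mode they count nucleotides. A historical variant of the same
test swaps the roles of the feature and the territory, drawing n trials
with success probability M/N; it is numerically different and available
behind `swap_roles=True`, but the instance-based form is the default.

The effect size is the relative risk RR = (k/M)/(n/N), with a 95%
confidence interval by the Katz log method:
exp(ln RR ± 1.96·SE), SE = √(1/k − 1/M + 1/n − 1/N). For k = 0 the RR is
0 and the interval is reported unavailable. Multiple testing across a
feature landscape is controlled by Bonferroni (default single-test alpha
0.01; an explicit rounded threshold such as 1e-4 for a ~100-feature
landscape can be supplied). For heatmap-style reporting, cells that are
non-elevated (RR < 1) or insignificant (p > alpha) can be imputed to 1,
with the symmetric rule for the under-representation view.

Embedding of polytracts in a set of E regions (e.g. enhancers) is tested
hypergeometrically from four numbers: population N (genome nucleotides),
successes n (territory nucleotides), draws E (regions), observed k_e
(regions embedding ≥ 1 polytract). This parameterization mixes units —
regions are drawn from a population of nucleotides — and is kept because
it is the established form for this analysis; a dimensionally clean
per-region binomial alternative with success probability
q = 1 − (1 − n/N)^L (L the region length) is provided as
`embed_binomial_p`.

Species length distributions are compared by the two-sample
Kolmogorov–Smirnov statistic D (sup ECDF difference) for every pair, and
the rows of the D matrix are clustered hierarchically with
one-minus-Pearson-correlation distance and average linkage. Constant rows
make the correlation distance undefined; the implementation defines the
distance of such a pair as 0 when the rows are equal and 1 otherwise.
Chromosome-level association between mean tract length and tract density
(tracts per Mb) uses the Pearson correlation with the two-sided test for
r ≠ 0; zero-variance inputs are flagged as undefined.

## Region annotation

From an Ensembl-dialect GTF, each tract is assigned one of seven
categories under the fixed precedence

    exonic_splicing > UTR5 > UTR3 > ncRNA > intronic > up_down_stream > intergenic.

`exonic_splicing` means overlap with a protein-coding CDS or with a
±2 nt window (configurable) around an internal intron/exon boundary of a
protein-coding transcript; UTRs come from the explicit GTF UTR features;
`ncRNA` is overlap with an exon of a non-protein-coding gene;
`up_down_stream` covers 1 kb (configurable) beyond either end of a gene
span. Junction windows are restricted to protein-coding transcripts so
that the ncRNA category is not absorbed by its own splice sites — a
deliberate convention, since the annotation style this follows does not
print its tie-breaking rules. Exon intervals are deduplicated across
transcripts. With the up/down window set to 0, all up_down_stream tracts
become intergenic.

## Synthetic data

The simulator makes every statistic testable without downloads:

- **Backgrounds** are i.i.d. uniform ACGT sequences post-processed so a
  full scan returns nothing: every qualifying run is broken by
  substituting its center base, with candidate bases screened on a local
  window rescan, iterating to convergence. Deterministic per seed.
- **Planted genomes** write requested tracts (position, unit, number of
  units, partial terminal) into a clean background, separated by ≥ 2 nt —
  or exactly 1 nt to request a hinge — and repair flanking background
  bases (never planted bases) until a genome-wide scan returns exactly
  the truth records.
- **Feature sets** place each of M instances fully inside the territory
  with probability π = c·n/N (uniform within), else uniformly outside, so
  c = 1 realizes the null of the binomial test and c > 1 gives an
  expected singleton RR of c.

What the simulator does *not* emulate: real base composition (GC
gradients, isochores), imperfect/interrupted repeats, alignability or
mapping error structure, and correlated feature placement. Passing tests
therefore demonstrate algorithmic correctness and statistical
calibration under the stated model, not biological conclusions about any
particular genome.

## Test and simulation sizes

The suite verifies the scanner against a per-base brute-force oracle on
1,000 random 500-nt sequences over several alphabets, recovers planted
truth exactly on fifty 1 Mb genomes (40 tracts, 2–8 hinge pairs each),
checks the binomial tails against exact rational arithmetic, and checks
calibration with 10,000 null feature sets of M = 1,000 on a toy
territory occupying 30% of a 100 kb genome. That occupancy was chosen
analytically: the binomial test is discrete, and at M = 1,000 the exact
attained level of "p < 0.01" is 0.0091 at 30% occupancy (it drops to
0.0075 at 2%), keeping the Monte-Carlo fraction well inside its expected
band. Effect recovery uses a 2%-occupancy territory of a 1 Mb genome so
that the largest multiplier (c = 8) keeps π ≤ 1; empirical RR is required
within 3 binomial SE of c and the Katz interval must cover c in ≥ 93% of
1,000 replicates. `scripts/acceptance.py` reruns a scaled version of the
same pipeline (2,000 null replicates, 500 coverage replicates) from a
single command-line seed.

## Numerical and interface conventions

Coordinates are 0-based half-open internally and in all BED output;
points TSV input is 1-based and converted on read. Genome size N counts
all bases of the analyzed sequences, including Ns. Binomial and
hypergeometric tails come from scipy's exact implementations
(`binom.sf/cdf`, `hypergeom.sf`). Reports are deterministic TSV with a
reproducibility header (package version, configuration, seeds); identical
configurations produce byte-identical files. All simulator randomness
flows through one seeded NumPy generator.

## Known limitations

- Units of length 4–6 and imperfect (TRF-style) repeats are out of scope.
- The seven-category precedence and the junction convention are fixed
  choices; annotation fractions are sensitive to the GTF version used.
- The hypergeometric embedding test inherits the dimensional caveat
  described above.
- Full-genome census numbers for a real reference require only a FASTA
  and the `scan`/`summarize` commands, but no reference data ships with
  the package and such results are annotation- and contig-set-dependent.
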
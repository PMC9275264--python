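# Methods

This note documents the models, conventions and numerical choices behind
rohscape, and what the simulation-based validation does and does not show
about real array data.

## Genotype representation and QC

Genotypes are stored as small integer codes (0 hom-reference, 1 het, 2
hom-alternate, −1 missing) against a locus map sorted by (chromosome,
position). The PLINK text dialect carries no allele designation, so the
reference allele at a locus is simply the first allele observed when a
file is read; every downstream statistic in the package depends only on
het/hom/missing status and is invariant to this labelling (asserted by
test). Tables produced by the simulator are canonicalized with the same
first-seen rule so that write → read is the identity.

QC filters run in a fixed order: autosome restriction (chromosomes 1–31,
the horse autosome count, configurable) → per-sample call rate ≥ 0.90 →
per-locus call rate ≥ 0.90 → minor allele frequency ≥ 0.001, with MAF
computed from non-missing genotypes on the post-call-rate data. The order
mirrors conventional array-QC practice: sample-level failures are removed
before locus statistics are trusted, and MAF last so frequencies are not
distorted by low-quality samples. Every stage's survivor counts are
recorded in a report whose counts are non-increasing by construction.
When several array datasets are merged, only loci present in all of them
with agreeing coordinates are kept (conflicts are an error, not a silent
drop), and per-dataset allele labellings are reconciled to the first
dataset's reference.

## ROH calling

Parameters (defaults): minimum 30 consecutive SNPs, maximum 1 Mb between
adjacent SNPs in a run, at most 2 missing and 1 heterozygous call, no
minimum length in bp. The heterozygote allowance absorbs array genotyping
errors; 1 is the stringent end of the usual 1–3 range and is the default
because relaxing it mostly merges runs across isolated miscalls without
changing population-level conclusions. The bp minimum defaults to 0 —
with 30 SNPs required at array density a run is already ≳ 1 Mb — but is
configurable for users who want parity with tools whose defaults differ.

Runs are trimmed so both endpoints are homozygous and non-missing;
otherwise a tolerated het or missing call at the edge would inflate run
length with sequence that carries no evidence of homozygosity.
`length_bp` is end − start, the coordinate span between the first and
last SNP; the off-by-one against an inclusive convention is negligible at
Mb scale.

A het/missing budget admits *overlapping* maximal windows (two windows
can share a homozygous core while each spends the budget on a different
flank), so "report all maximal windows" and "runs are disjoint" cannot
both hold. rohscape resolves this the way consecutive-run callers behave
in practice: qualifying windows are selected greedily left to right
(smallest start, ties to the largest end), discarding windows that
overlap an emitted run. `detect_runs` implements the selection with a
linear two-pointer scan (extension is monotone because every constraint
is inherited by subwindows); `brute_force_runs` re-derives it from full
O(L²) window enumeration. The two routes are compared for exact segment
equality on randomized instances in the tests. One consequence of
disjoint greedy calling is that relaxing the het/missing budget by one
can occasionally *reduce* total called bases (a longer first run may
swallow the head of a following run, leaving a remainder below the SNP
minimum); the quantity that is provably monotone under relaxation is the
union of all qualifying windows, and that is what the monotonicity test
checks.

## Inbreeding coefficients

F_ROH is the summed run length divided by total genome length, with
per-chromosome analogues and thresholded variants (runs strictly longer
than 0/2/4/8/16 Mb). The genome-length denominator defaults to the span
between the first and last retained SNP per chromosome — ROH are only
observable where SNPs exist — and assembly lengths can be supplied
instead; the choice shifts all F_ROH values by a common factor and does
not affect comparisons made with a fixed panel. The genome-wide value
equals the chromosome-length-weighted mean of per-chromosome values by
construction, and thresholded values are non-increasing in the threshold;
both are asserted for every simulated individual.

Run-length classes are 0–2, 2–4, 4–8, 8–16 and >16 Mb, half-open and
lower-inclusive (a 2.0 Mb run is in 2–4).

F_IS follows the method-of-moments observed/expected homozygosity
estimator used by standard SNP QC tooling: E_hom sums, over the sample's
non-missing loci, 1 − 2p̂q̂·n/(n−1) with p̂ estimated from the n
non-missing alleles of the grouping unit. Frequencies are computed within
population by default (each breed is its own reference), with a pooled
"global" mode available; which convention a given published analysis used
is often unstated, and the two differ in structured samples. Loci with
fewer than two non-missing alleles in the group are excluded; samples
whose denominator N − E_hom is non-positive get NaN with an explicit
flag rather than a silent zero.

## ROH islands

Incidence is computed per population as the percentage of individuals
whose ROH cover each SNP position. With binning enabled the genome is
partitioned into 1-Mb bins ([0, 1 Mb), [1, 2 Mb), …) and only the
highest-incidence SNP per bin (ties to the smallest position, for
determinism) enters the threshold distribution; this damps the uneven SNP
density of commercial arrays. The threshold is mean + Φ⁻¹(0.999)·sd with
the sample (n−1) standard deviation, clamped into [30 %, 80 %]: the lower
clamp prevents islands from being missed in populations where no SNP
reaches the z cutoff, the upper prevents calling most of the genome in
populations with uniformly high incidence. Both raw and clamped values
are reported. A zero-sd incidence distribution is flagged degenerate and
calls no islands.

Islands are maximal stretches of consecutive SNPs whose incidence
*strictly* exceeds the clamped threshold. When binning is used the
threshold comes from the binned distribution but membership and
boundaries are evaluated on the full SNP track — island boundaries are
defined as the positions of the first and last qualifying SNP, which
could not be sub-Mb precise if evaluated on bin representatives only.
This is an interpretive choice; the incidence track is emitted in full so
the alternative (bin-level membership) is recoverable. Single-SNP
islands are reported with a flag and can be filtered with
`min_island_snps`.

## Gene overlap and enrichment

Genes are kept if they overlap an island by at least one base pair
(no fraction-of-gene threshold), deduplicated and position-sorted.
Enrichment is the upper-tail hypergeometric probability P(X ≥ k) for k
query genes in a K-gene term, an n-gene query and an N-gene universe.
The universe is a required explicit input: results are only as meaningful
as the declared background (all annotated genes vs the array footprint
give different answers). Benjamini–Hochberg adjusted values are attached
via statsmodels. Web enrichment services embed versioned databases and
background choices that cannot be reproduced offline; this local test is
deliberately minimal and transparent instead. Coordinates are 1-based
inclusive internally; BED I/O converts to 0-based half-open.

## The simulator

Gene dropping with exact bookkeeping: founder chromosome copies get unique
integer labels; each meiosis draws crossovers per chromosome as
Poisson(rate × length in Morgans) with uniform positions (Haldane, no
interference) and a random starting phase, so descendants' chromosomes
are piecewise founder-label tracks with base-pair-precise breakpoints.
An individual is autozygous where its two labels coincide; truth
intervals and fractions follow exactly, with no SNP discretization.

Defaults emulate a medium-density array study: uniform founder MAF on
[0.05, 0.5] (arrays are ascertained for common variants), 1 cM/Mb
(close to the horse genome-wide average of ~1.24 cM/Mb; per-chromosome
multipliers allow e.g. an elevated-recombination chromosome), 3
chromosomes of 50 Mb with ~1000 SNPs each for validation runs — large
enough for Mb-scale ROH structure, small enough that the whole suite
runs in seconds. Chromosome count scales to 31 and SNP densities may be
uneven per chromosome. Pedigree schemes: explicit mating lists, random
mating, selfing lineages, full-sib families, and bottlenecks (constant
effective size for g generations, then an expansion generation);
expected autozygosity is analytic for the first four (0, 1 − 2⁻ᵍ, 1/4,
elevated) and all are recovered within Monte-Carlo error in the tests.
A sweep overwrites a chosen fraction of founder haplotypes with one
fixed haplotype over an interval — homozygosity by state that island
detection should find, while label-based truth is untouched. Genotyping
noise is injected last: optional uniform het errors (to exercise the het
budget), then uniform missingness.

What the simulator does not emulate: linkage-disequilibrium structure and
ascertainment of real array panels, genotyping error that correlates with
probe quality, crossover interference and recombination hotspots, mutation,
and selection acting through the pedigree (sweeps are planted, not
evolved). Passing tests therefore demonstrate that the *algorithms* are
correct and well calibrated under a known generative model, not that any
particular biological dataset meets that model's assumptions.

## Scoring detection against truth

Precision and recall are computed at base level on the SNP-covered genome
(the span between first and last SNP per chromosome), because no caller
can see outside it; truth intervals are clipped accordingly. Under dense
SNP settings (≥ 1 SNP / 50 kb) F_ROH from detected runs correlates with
true autozygous fraction at r > 0.99 in bottleneck simulations.

## Numerical conventions and degenerate inputs

* Strict inequalities where thresholds are exceeded (p > 0.999, incidence
  > clamped threshold, F_ROH length classes use length > t).
* Sample standard deviation (n−1) throughout.
* Ties broken by genomic position wherever a unique choice is needed.
* Empty results are errors only where silence would be misleading
  (filters that remove everything, populations with no members); empty
  segment lists, queries and tracks otherwise propagate as empty outputs
  with flags or warnings.
* All simulation randomness flows from a single mandatory seed; identical
  parameters and seed give bit-identical PED/MAP and truth files.

## Known limitations

* Binary PLINK (.bed) is not read; the text dialect is the contract.
* The consecutive caller is not an HMM/likelihood IBD inference; very
  short or SNP-sparse autozygous segments below the SNP minimum are
  invisible by design.
* Enrichment does not propagate ontology structure (no parent-term
  inheritance); terms are treated as flat sets.
* The simulator's founders are unrelated by construction; background
  relatedness must be produced through the pedigree.
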
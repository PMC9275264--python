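# rohscape

Runs of homozygosity (ROH) analysis for SNP-array genotypes: consecutive-run
ROH calling, ROH-based and excess-homozygosity inbreeding coefficients,
ROH-island detection, gene-overlap enrichment — and a gene-dropping
simulator that provides exact autozygosity ground truth, so every stage of
the pipeline can be validated without access to real (often undeposited)
genotype data.

The package is aimed at population and conservation geneticists working
with medium-density array data (tens of thousands of SNPs, tens to hundreds
of individuals per population), the regime typical of livestock panels and
of feral or wild populations genotyped on commercial arrays.

## What it computes

**ROH calling.** A run of homozygosity is a maximal stretch of consecutive
SNPs in one individual with every inter-SNP gap ≤ 1 Mb, at most 1
heterozygous and 2 missing calls, at least 30 SNPs, and homozygous
non-missing endpoints (all configurable). `detect_runs` implements this
with a linear scan; `brute_force_runs` re-derives the same definition by
exhaustive window enumeration and is used as an independent oracle in the
tests.

**Inbreeding.** For individual *i*,

    F_ROH(i) = Σ length(ROH of i) / L_genome,

with per-chromosome analogues and length-thresholded variants (runs > 0,
2, 4, 8, 16 Mb) that index the age of inbreeding — long runs coalesce
recently, short runs many generations ago. The excess-homozygosity
coefficient

    F_IS(i) = (O_hom − E_hom) / (N_nonmissing − E_hom),
    E_hom = Σ_j [1 − 2 p_j q_j · n_j/(n_j − 1)],

uses method-of-moments allele frequencies with the small-sample
correction; F_IS ≈ 0 under random mating, > 0 under consanguinity.

**ROH islands.** Per SNP, the incidence x_i is the percentage of a
population's individuals whose ROH cover it. Incidences (optionally reduced
to the best SNP per 1-Mb bin to even out array density) are z-scored, and
SNPs with upper-tail normal probability p > 0.999 exceed the
population-specific threshold mean + Φ⁻¹(0.999)·sd, clamped into
[30 %, 80 %]. Islands are maximal consecutive stretches of qualifying SNPs.

**Enrichment.** Genes overlapping islands (any-bp overlap against a local
annotation) are tested for term over-representation with the upper-tail
hypergeometric probability against an explicit gene universe, with an
optional Benjamini–Hochberg column.

**Simulation.** Founders carry uniquely labelled haplotypes; meioses follow
the Haldane model (Poisson crossovers, ~1 cM/Mb by default). Autozygosity
is tracked exactly by label identity, so true inbred fractions (full-sib
offspring → 1/4, g selfing generations → 1 − 2⁻ᵍ, bottlenecks → elevated
F) and planted locally-fixed haplotypes (ROH islands) are all recoverable
ground truth.

## Worked example

Simulate a severely bottlenecked population (effective size 10 for 20
generations — a feral-island-like history), call ROH, and compute
inbreeding metrics:

```python
from rohscape import (SimParams, PedigreeSpec, simulate_population,
                      detect_runs, ROHParams, GenomeLengths,
                      inbreeding_table, true_vs_detected)

params = SimParams(seed=42, n_chromosomes=3,
                   chromosome_length_bp=50_000_000, n_snps=1000,
                   n_founders=60)
table, lmap, truth = simulate_population(
    params, PedigreeSpec.bottleneck(10, 20, 40))

segs = detect_runs(table, lmap, ROHParams())
records = inbreeding_table(segs, table, GenomeLengths.from_map(lmap))
print(records[["sample", "froh", "froh_gt8mb", "fis"]]
      .head(3).to_string(index=False))
print(round(true_vs_detected(truth, segs, lmap)["correlation"], 3))
```

Output:

```
sample     froh  froh_gt8mb       fis
 G20_0 0.746662    0.681010  0.157188
 G20_1 0.570945    0.417071 -0.362784
 G20_2 0.766829    0.706965  0.291466
0.997
```

341 runs are called across the 40 sampled individuals; mean F_ROH is 0.66
— the bottleneck has driven most of the genome into ROH — and F_ROH per
individual correlates with the simulator's exact autozygous fraction at
r = 0.997. The first individual carries two-thirds of its genome in runs
longer than 8 Mb (recent coalescence, as expected from a short, severe
bottleneck), while mean F_IS ≈ −0.09 shows the *current* generation mates
close to randomly: inbreeding here is demographic history, not recent
consanguinity.

The same pipeline is available from the shell:

```
rohscape simulate --scheme bottleneck --ne 10 --generations 20 --seed 42 --out-prefix sim
rohscape filter   --ped sim.ped --map sim.map --out-prefix qc
rohscape detect   --ped qc.ped --map qc.map --out roh.tsv
rohscape inbreeding --ped qc.ped --map qc.map --segments roh.tsv --out inb.tsv
rohscape islands  --ped qc.ped --map qc.map --segments roh.tsv --out-prefix isl
```

## Layout

| module | contents |
| --- | --- |
| `rohscape.genotype_io` | PLINK PED/MAP text I/O, dataset intersection, QC filters |
| `rohscape.roh_detection` | consecutive-run caller + enumeration oracle |
| `rohscape.inbreeding` | F_ROH variants, F_IS, length classes, per-chromosome summaries |
| `rohscape.roh_islands` | incidence, binning, z-score thresholds, island calling, Manhattan plot |
| `rohscape.annotation_enrichment` | gene-interval overlap, hypergeometric enrichment |
| `rohscape.synthetic_data` | gene-dropping simulator, truth scoring |
| `rohscape.cli` | `rohscape` command-line entry point |

See `docs/methods.md` for the modelling and numerical choices.
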
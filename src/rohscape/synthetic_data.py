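"""Gene-dropping simulator with exact autozygosity ground truth.

Founders receive two uniquely labelled haplotypes per chromosome with
alleles drawn independently per locus from a founder allele-frequency
distribution (uniform MAF on [0.05, 0.5] by default, emulating an
ascertained SNP array).  Each meiosis draws a Poisson number of crossovers
per chromosome (Haldane model, mean = cM/Mb rate x length, no
interference) at uniform positions, so offspring haplotypes are mosaics of
founder haplotypes whose labels are tracked exactly.  An individual is
autozygous wherever its two haplotype labels coincide — identity by
descent, not merely by state — which yields base-pair-exact truth
intervals (:class:`TruthSegments`) against which detected ROH can be
scored.

Pedigree schemes cover the regimes relevant to a feral-vs-domestic ROH
contrast: random mating (outbred control), bottlenecks (founder effects
producing abundant 2-8 Mb ROH), full-sib matings and selfing
(consanguinity producing long ROH with known expected autozygosity), and
a plantable locally-fixed haplotype (an ROH island / sweep stand-in).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genotype_io import (GenotypeTable, HET, LocusMap, MISSING,
                          canonicalize_alleles)
from .inbreeding import GenomeLengths, froh


def _per_chrom(value, n: int) -> list:
    if np.isscalar(value):
        return [value] * n
    value = list(value)
    if len(value) != n:
        raise ValueError(f"expected {n} per-chromosome values, got {len(value)}")
    return value


@dataclass
class SimParams:
    """Simulation parameters.  ``seed`` is mandatory: every random draw
    flows from one generator so identical params give bit-identical output.

    ``chromosome_length_bp``, ``n_snps`` and ``recomb_rate_cm_per_mb`` may
    be scalars or per-chromosome sequences (uneven SNP densities and e.g.
    an elevated-recombination chromosome are expressed that way)."""

    seed: int
    n_chromosomes: int = 3
    chromosome_length_bp: object = 50_000_000
    n_snps: object = 1000
    n_founders: int = 50
    founder_maf_range: tuple = (0.05, 0.5)
    recomb_rate_cm_per_mb: object = 1.0
    missing_rate: float = 0.0
    het_error_rate: float = 0.0
    population: str = "sim"

    def __post_init__(self) -> None:
        if not (1 <= self.n_chromosomes <= 31):
            raise ValueError("n_chromosomes must be in 1..31")
        if self.n_founders < 1:
            raise ValueError("need at least one founder")
        lo, hi = self.founder_maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("founder MAF range must lie in (0, 0.5]")
        for r in (self.missing_rate, self.het_error_rate):
            if not (0.0 <= r < 1.0):
                raise ValueError("rates must be in [0, 1)")
        self.lengths = [int(x) for x in
                        _per_chrom(self.chromosome_length_bp, self.n_chromosomes)]
        self.snps_per_chrom = [int(x) for x in
                               _per_chrom(self.n_snps, self.n_chromosomes)]
        self.rates = [float(x) for x in
                      _per_chrom(self.recomb_rate_cm_per_mb, self.n_chromosomes)]
        if any(L <= 0 for L in self.lengths) or any(n < 1 for n in self.snps_per_chrom):
            raise ValueError("lengths and SNP counts must be positive")


@dataclass
class SweepSpec:
    """Overwrite ``carrier_freq`` of founder haplotypes with one fixed
    haplotype on [start_bp, end_bp] of ``chrom`` — a locally fixed
    haplotype that detection should recover as an ROH island."""

    chrom: int
    start_bp: int
    end_bp: int
    carrier_freq: float = 0.95

    def __post_init__(self) -> None:
        if not (0.0 < self.carrier_freq <= 1.0):
            raise ValueError("carrier_freq must be in (0, 1]")
        if self.start_bp >= self.end_bp:
            raise ValueError("sweep interval is empty")


@dataclass
class PedigreeSpec:
    """Matings per generation: list of generations, each a list of
    (sire_id, dam_id, n_offspring).  Founders are ``F0..F{n-1}``; children
    are named ``G{gen}_{k}``.  Named schemes expand deterministically from
    the simulation seed."""

    scheme: str
    options: dict = field(default_factory=dict)

    @classmethod
    def explicit(cls, matings) -> "PedigreeSpec":
        return cls("explicit", {"matings": matings})

    @classmethod
    def random_mating(cls, n_per_generation: int, generations: int) -> "PedigreeSpec":
        return cls("random_mating", {"n": n_per_generation,
                                     "generations": generations})

    @classmethod
    def selfing(cls, n_lineages: int, generations: int) -> "PedigreeSpec":
        return cls("selfing", {"n_lineages": n_lineages,
                               "generations": generations})

    @classmethod
    def full_sib(cls, n_families: int, n_offspring: int = 1) -> "PedigreeSpec":
        return cls("full_sib", {"n_families": n_families,
                                "n_offspring": n_offspring})

    @classmethod
    def bottleneck(cls, ne: int, generations: int, n_out: int) -> "PedigreeSpec":
        return cls("bottleneck", {"ne": ne, "generations": generations,
                                  "n_out": n_out})

    def expand(self, n_founders: int, rng: np.random.Generator):
        founders = [f"F{i}" for i in range(n_founders)]
        gens = []

        def pair(pool):
            i, j = rng.choice(len(pool), size=2, replace=False)
            return pool[i], pool[j]

        if self.scheme == "explicit":
            gens = [list(g) for g in self.options["matings"]]
        elif self.scheme == "random_mating":
            prev = founders
            for g in range(self.options["generations"]):
                matings = []
                for k in range(self.options["n"]):
                    s, d = pair(prev)
                    matings.append((s, d, 1))
                gens.append(matings)
                prev = [f"G{g}_{k}" for k in range(self.options["n"])]
        elif self.scheme == "selfing":
            n = self.options["n_lineages"]
            if n > n_founders:
                raise ValueError("more selfing lineages than founders")
            prev = founders[:n]
            for g in range(self.options["generations"]):
                gens.append([(p, p, 1) for p in prev])
                prev = [f"G{g}_{k}" for k in range(n)]
        elif self.scheme == "full_sib":
            nf = self.options["n_families"]
            if 2 * nf > n_founders:
                raise ValueError("full_sib needs 2 founders per family")
            sibs = []
            for k in range(nf):
                sibs.append((founders[2 * k], founders[2 * k + 1], 2))
            gens.append(sibs)
            matings = []
            child = 0
            for k in range(nf):
                a, b = f"G0_{child}", f"G0_{child + 1}"
                child += 2
                matings.append((a, b, self.options["n_offspring"]))
            gens.append(matings)
        elif self.scheme == "bottleneck":
            ne = self.options["ne"]
            prev = founders
            for g in range(self.options["generations"]):
                matings = []
                for k in range(ne):
                    s, d = pair(prev)
                    matings.append((s, d, 1))
                gens.append(matings)
                prev = [f"G{g}_{k}" for k in range(ne)]
            matings = []
            for k in range(self.options["n_out"]):
                s, d = pair(prev)
                matings.append((s, d, 1))
            gens.append(matings)
        else:
            raise ValueError(f"unknown scheme {self.scheme!r}")

        known = set(founders)
        resolved = []
        for g, matings in enumerate(gens):
            children, out = [], []
            for (s, d, n_off) in matings:
                if s not in known or d not in known:
                    raise ValueError(f"mating references unknown parent: "
                                     f"{s if s not in known else d}")
                for _ in range(int(n_off)):
                    cid = f"G{g}_{len(children)}"
                    children.append(cid)
                    out.append((s, d, cid))
            resolved.append(out)
            known |= set(children)
        return founders, resolved


@dataclass
class TruthSegments:
    """Exact autozygous (founder-IBD) intervals per individual, plus the
    genome length used as the fraction denominator."""

    intervals: dict          # sample -> list of (chrom, start_bp, end_bp)
    genome_length_bp: int

    def fraction(self, sample: str) -> float:
        return sum(e - s for _, s, e in self.intervals[sample]) \
            / self.genome_length_bp

    @property
    def samples(self) -> list:
        return list(self.intervals)

    def to_frame(self) -> pd.DataFrame:
        rows = [(smp, c, s, e) for smp, ivs in self.intervals.items()
                for c, s, e in ivs]
        return pd.DataFrame(rows, columns=["sample", "chrom", "start_bp",
                                           "end_bp"])

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


# A haplotype on one chromosome is a piecewise-constant founder-label
# track: (breaks, labels) with segment k covering [breaks[k-1], breaks[k])
# and breaks[-1] == chromosome length.


def _recombine(hap_a, hap_b, length: int, morgans: float,
               rng: np.random.Generator):
    n_x = rng.poisson(morgans)
    source = int(rng.integers(2))
    if n_x == 0:
        return hap_a if source == 0 else hap_b
    xpos = np.sort(rng.uniform(0.0, float(length), size=n_x))
    haps = (hap_a, hap_b)
    breaks_out, labels_out = [], []
    prev = 0.0
    cuts = list(xpos) + [float(length)]
    for cut in cuts:
        br, lb = haps[source]
        i0 = int(np.searchsorted(br, prev, side="right"))
        i1 = int(np.searchsorted(br, cut, side="left"))
        for i in range(i0, i1 + 1):
            end = min(float(br[i]), cut)
            if end > prev:
                if labels_out and labels_out[-1] == lb[i]:
                    breaks_out[-1] = end
                else:
                    breaks_out.append(end)
                    labels_out.append(lb[i])
                prev = end
        source = 1 - source
        prev = cut if cut > prev else prev
    breaks_out[-1] = float(length)
    return np.array(breaks_out), np.array(labels_out)


def _labels_at(hap, positions: np.ndarray) -> np.ndarray:
    br, lb = hap
    return lb[np.searchsorted(br, positions, side="right").clip(max=len(lb) - 1)]


def _autozygous_intervals(hap_a, hap_b, length: int):
    """Intervals where the two label tracks agree, merged and disjoint."""
    cuts = np.union1d(hap_a[0], hap_b[0])
    out = []
    prev = 0.0
    for cut in cuts:
        mid = 0.5 * (prev + cut)
        la = _labels_at(hap_a, np.array([mid]))[0]
        lb = _labels_at(hap_b, np.array([mid]))[0]
        if la == lb and cut > prev:
            if out and out[-1][1] == prev:
                out[-1] = (out[-1][0], cut)
            else:
                out.append((prev, cut))
        prev = cut
    return [(int(round(s)), int(round(e))) for s, e in out if e > s]


def simulate_population(params: SimParams, pedigree: PedigreeSpec,
                        sweep: SweepSpec | None = None):
    """Run the gene-dropping simulation.

    Returns ``(GenotypeTable, LocusMap, TruthSegments)`` for the final
    pedigree generation (the founders themselves when the pedigree has no
    matings).  Genotypes are coded against the simulated reference allele
    and canonicalized so PED round-trips are exact.
    """
    rng = np.random.default_rng(params.seed)
    n_chrom = params.n_chromosomes

    positions, chrom_col = [], []
    for c in range(n_chrom):
        L, n = params.lengths[c], params.snps_per_chrom[c]
        draw = rng.integers(1, L + 1, size=4 * n + 16)
        uniq = np.unique(draw)
        if len(uniq) < n:
            raise ValueError(f"cannot place {n} distinct SNPs on a "
                             f"{L} bp chromosome")
        pos = np.sort(rng.choice(uniq, size=n, replace=False))
        positions.append(pos)
        chrom_col.append(np.full(n, c + 1))
    all_pos = np.concatenate(positions)
    all_chrom = np.concatenate(chrom_col)
    total_snps = len(all_pos)
    locus_ids = np.array(
        [f"chr{c}_snp{i}" for c, i in
         zip(all_chrom, np.concatenate([np.arange(len(p)) for p in positions]))],
        dtype=object)

    lo, hi = params.founder_maf_range
    p_alt = rng.uniform(lo, hi, size=total_snps)
    n_haps = 2 * params.n_founders
    founder_alleles = (rng.random((n_haps, total_snps)) < p_alt).astype(np.int8)

    if sweep is not None:
        if not (1 <= sweep.chrom <= n_chrom):
            raise ValueError("sweep chromosome outside simulated genome")
        in_iv = (all_chrom == sweep.chrom) & (all_pos >= sweep.start_bp) \
            & (all_pos <= sweep.end_bp)
        carriers = rng.random(n_haps) < sweep.carrier_freq
        carriers[0] = True  # haplotype 0 defines the fixed sweep haplotype
        founder_alleles[np.ix_(carriers, np.nonzero(in_iv)[0])] = \
            founder_alleles[0, in_iv]

    founders, generations = pedigree.expand(params.n_founders, rng)
    genomes = {}
    for k, fid in enumerate(founders):
        genomes[fid] = [
            ((np.array([float(params.lengths[c])]), np.array([2 * k])),
             (np.array([float(params.lengths[c])]), np.array([2 * k + 1])))
            for c in range(n_chrom)
        ]
    final = list(founders)
    for matings in generations:
        children = []
        for (sire, dam, child) in matings:
            chroms = []
            for c in range(n_chrom):
                morgans = params.rates[c] * params.lengths[c] / 1e6 / 100.0
                g1 = _recombine(*genomes[sire][c], params.lengths[c],
                                morgans, rng)
                g2 = _recombine(*genomes[dam][c], params.lengths[c],
                                morgans, rng)
                chroms.append((g1, g2))
            genomes[child] = chroms
            children.append(child)
        if children:
            final = children

    codes = np.empty((len(final), total_snps), dtype=np.int8)
    intervals = {}
    offsets = np.concatenate([[0], np.cumsum(params.snps_per_chrom)])
    for i, ind in enumerate(final):
        ivs = []
        for c in range(n_chrom):
            hap_a, hap_b = genomes[ind][c]
            pos = positions[c]
            la = _labels_at(hap_a, pos.astype(float))
            lb = _labels_at(hap_b, pos.astype(float))
            j0, j1 = offsets[c], offsets[c + 1]
            codes[i, j0:j1] = (founder_alleles[la, np.arange(j0, j1)] +
                               founder_alleles[lb, np.arange(j0, j1)])
            ivs.extend((c + 1, s, e) for s, e in
                       _autozygous_intervals(hap_a, hap_b, params.lengths[c]))
        intervals[ind] = ivs

    if params.het_error_rate > 0.0:
        flip = rng.random(codes.shape) < params.het_error_rate
        codes[flip] = HET
    if params.missing_rate > 0.0:
        miss = rng.random(codes.shape) < params.missing_rate
        codes[miss] = MISSING

    table = GenotypeTable(
        np.array(final, dtype=object),
        np.array([params.population] * len(final), dtype=object),
        codes,
    )
    locus_map = LocusMap(all_chrom, locus_ids, all_pos,
                         np.array(["A"] * total_snps, dtype=object),
                         np.array(["C"] * total_snps, dtype=object))
    table, locus_map = canonicalize_alleles(table, locus_map)
    truth = TruthSegments(intervals, sum(params.lengths))
    return table, locus_map, truth


# ---------------------------------------------------------------------------
# Scoring detected runs against simulator truth


def _intersect_length(a, b) -> int:
    """Total overlap between two sorted disjoint interval lists."""
    total = i = j = 0
    a, b = sorted(a), sorted(b)
    while i < len(a) and j < len(b):
        s = max(a[i][0], b[j][0])
        e = min(a[i][1], b[j][1])
        if e > s:
            total += e - s
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return total


def true_vs_detected(truth: TruthSegments, segments,
                     locus_map: LocusMap) -> dict:
    """Score detected ROH against exact autozygosity truth.

    Base-level precision/recall are computed on the SNP-covered genome
    (the span between the first and last SNP per chromosome) because
    detection cannot see outside it.  Returns a per-individual table and
    the Pearson correlation between true autozygous fraction and F_ROH.
    """
    spans = {}
    for c in np.unique(locus_map.chrom):
        p = locus_map.pos[locus_map.chrom == c]
        spans[int(c)] = (int(p.min()), int(p.max()))
    lengths = GenomeLengths.from_map(locus_map)

    det_by_sample: dict[str, dict] = {s: {} for s in truth.samples}
    seg_lists: dict[str, list] = {s: [] for s in truth.samples}
    for seg in segments:
        if seg.sample not in det_by_sample:
            raise ValueError(f"detected sample {seg.sample!r} absent from truth")
        det_by_sample[seg.sample].setdefault(seg.chrom, []).append(
            (seg.start_bp, seg.end_bp))
        seg_lists[seg.sample].append(seg)

    rows = []
    for s in truth.samples:
        truth_by_chrom: dict[int, list] = {}
        for c, a, b in truth.intervals[s]:
            lo, hi = spans.get(c, (0, 0))
            a2, b2 = max(a, lo), min(b, hi)
            if b2 > a2:
                truth_by_chrom.setdefault(c, []).append((a2, b2))
        det = det_by_sample[s]
        inter = sum(_intersect_length(det.get(c, []), truth_by_chrom.get(c, []))
                    for c in spans)
        det_len = sum(e - a for ivs in det.values() for a, e in ivs)
        tru_len = sum(e - a for ivs in truth_by_chrom.values() for a, e in ivs)
        rows.append({
            "sample": s,
            "true_fraction": truth.fraction(s),
            "froh": froh(seg_lists[s], lengths)["overall"],
            "precision": inter / det_len if det_len else np.nan,
            "recall": inter / tru_len if tru_len else np.nan,
            "flag": "no_detected_runs" if det_len == 0 and tru_len > 0 else "",
        })
    df = pd.DataFrame(rows)
    if len(df) >= 3 and df.true_fraction.std() > 0 and df.froh.std() > 0:
        corr = float(stats.pearsonr(df.true_fraction, df.froh).statistic)
    else:
        corr = np.nan
    return {"table": df, "correlation": corr}
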
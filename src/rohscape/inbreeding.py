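"""Inbreeding coefficients and ROH summary statistics.

F_ROH is the fraction of the autosomal genome covered by runs of
homozygosity: sum of run lengths divided by total genome length, with
length-thresholded variants (runs longer than 0/2/4/8/16 Mb) indexing the
"age" of inbreeding — long runs coalesce recently, short runs long ago.

F_IS is the method-of-moments excess-homozygosity coefficient used by SNP
QC tools: for sample i,

    F_IS = (O_hom - E_hom) / (N_nm - E_hom)

where O_hom counts observed homozygous genotypes, N_nm non-missing
genotypes, and E_hom = sum over the sample's non-missing loci of
1 - 2 p q * n/(n-1), with p the group allele frequency estimated from n
non-missing alleles (the n/(n-1) factor is the small-sample correction).
F_IS = 0 under random mating, > 0 under consanguinity, < 0 under
inbreeding avoidance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genotype_io import GenotypeTable, HET, LocusMap, MISSING

MB = 1_000_000

#: Run-length thresholds (Mb) for F_ROH variants: F_ROH(>t) uses only runs
#: strictly longer than t Mb.
DEFAULT_FROH_THRESHOLDS_MB = (0, 2, 4, 8, 16)

#: Run-length class edges (Mb): 0-2, 2-4, 4-8, 8-16, >16, half-open
#: lower-inclusive.
DEFAULT_LENGTH_CLASS_EDGES_MB = (0, 2, 4, 8, 16, np.inf)


@dataclass
class GenomeLengths:
    """Per-chromosome denominator lengths (bp) for F_ROH."""

    lengths: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for c, L in self.lengths.items():
            if L <= 0:
                raise ValueError(f"chromosome {c} has non-positive length")

    @property
    def total(self) -> int:
        return sum(self.lengths.values())

    @classmethod
    def from_map(cls, locus_map: LocusMap) -> "GenomeLengths":
        """Span between first and last retained SNP per chromosome.

        ROH are only detectable where SNPs exist, so the SNP span is the
        default denominator; assembly lengths can be supplied instead."""
        out = {}
        for c in np.unique(locus_map.chrom):
            p = locus_map.pos[locus_map.chrom == c]
            out[int(c)] = int(p.max() - p.min()) if len(p) > 1 else int(p.max())
        return cls(out)


def froh(segments, lengths: GenomeLengths,
         thresholds_mb=DEFAULT_FROH_THRESHOLDS_MB) -> dict:
    """F_ROH for one individual's segments.

    Returns ``{"overall": ..., "by_threshold": {t: ...},
    "by_chromosome": {c: ...}}`` where by_threshold[t] uses only runs with
    length_bp > t Mb and overall == by_threshold[min(thresholds)].
    """
    for seg in segments:
        if seg.chrom not in lengths.lengths:
            raise ValueError(f"segment on chromosome {seg.chrom} absent from "
                             "genome lengths")
    total = lengths.total
    by_thr = {}
    for t in thresholds_mb:
        covered = sum(s.length_bp for s in segments if s.length_bp > t * MB)
        by_thr[t] = covered / total
    by_chrom = {}
    for c, L in lengths.lengths.items():
        covered = sum(s.length_bp for s in segments if s.chrom == c)
        by_chrom[c] = covered / L
    return {"overall": by_thr[min(thresholds_mb)], "by_threshold": by_thr,
            "by_chromosome": by_chrom}


def inbreeding_table(segments, table: GenotypeTable, lengths: GenomeLengths,
                     thresholds_mb=DEFAULT_FROH_THRESHOLDS_MB,
                     fis_grouping: str = "population") -> pd.DataFrame:
    """One row per sample: population, F_ROH variants, F_IS and its parts."""
    by_sample: dict[str, list] = {str(s): [] for s in table.samples}
    for seg in segments:
        by_sample[seg.sample].append(seg)
    rows = []
    for i, s in enumerate(table.samples):
        f = froh(by_sample[str(s)], lengths, thresholds_mb)
        row = {"sample": str(s), "population": table.populations[i],
               "froh": f["overall"]}
        for t in thresholds_mb:
            row[f"froh_gt{t}mb"] = f["by_threshold"][t]
        rows.append(row)
    df = pd.DataFrame(rows)
    fis_df = fis(table, grouping=fis_grouping)
    return df.merge(fis_df.drop(columns=["population"]), on="sample")


def length_class_distribution(segments, populations: dict,
                              edges_mb=DEFAULT_LENGTH_CLASS_EDGES_MB) -> pd.DataFrame:
    """Per-population proportion of runs in each length class.

    Classes are half-open lower-inclusive ``[lo, hi)`` in Mb; a run of
    exactly 2 Mb falls in the 2-4 Mb class.
    """
    edges = np.asarray(edges_mb, dtype=float)
    if np.any(np.diff(edges) <= 0):
        raise ValueError("class edges must be strictly increasing")
    labels = [
        f"{edges[k]:g}-{edges[k + 1]:g}Mb" if np.isfinite(edges[k + 1])
        else f">{edges[k]:g}Mb"
        for k in range(len(edges) - 1)
    ]
    rows = []
    for seg in segments:
        k = int(np.searchsorted(edges, seg.length_bp / MB, side="right")) - 1
        k = min(max(k, 0), len(labels) - 1)
        rows.append((populations[seg.sample], labels[k]))
    df = pd.DataFrame(rows, columns=["population", "length_class"])
    counts = (df.value_counts().unstack(fill_value=0)
              .reindex(columns=labels, fill_value=0))
    return counts.div(counts.sum(axis=1), axis=0)


def fis(table: GenotypeTable, locus_map: LocusMap | None = None,
        grouping: str = "population") -> pd.DataFrame:
    """Method-of-moments F_IS per sample (``--het``-style O/E homozygosity).

    ``grouping="population"`` estimates allele frequencies within each
    population; ``"global"`` pools every sample.  Loci with fewer than two
    non-missing alleles in a group are excluded from that group's sums.
    Samples with a non-positive denominator get NaN and ``flag="undefined"``.
    """
    codes = table.codes
    rows = []
    groups = table.populations if grouping == "population" else \
        np.array(["__all__"] * table.n_samples, dtype=object)
    for g in pd.unique(groups):
        idx = np.nonzero(groups == g)[0]
        sub = codes[idx]
        nm = sub != MISSING
        n_alleles = 2.0 * nm.sum(axis=0)
        alt = np.where(nm, sub, 0).sum(axis=0)
        usable = n_alleles >= 2
        with np.errstate(invalid="ignore", divide="ignore"):
            p = alt / n_alleles
            e_term = 1.0 - 2.0 * p * (1.0 - p) * n_alleles / (n_alleles - 1.0)
        for k, i in enumerate(idx):
            use = nm[k] & usable
            o_hom = int(np.sum(use & (sub[k] != HET)))
            e_hom = float(np.sum(e_term[use]))
            n_nm = int(np.sum(use))
            denom = n_nm - e_hom
            if denom <= 0:
                f, flag = np.nan, "undefined"
            else:
                f, flag = (o_hom - e_hom) / denom, ""
            rows.append({"sample": str(table.samples[i]),
                         "population": table.populations[i],
                         "o_hom": o_hom, "e_hom": e_hom, "n_nm": n_nm,
                         "fis": f, "flag": flag})
    out = pd.DataFrame(rows)
    order = {str(s): i for i, s in enumerate(table.samples)}
    return out.sort_values("sample", key=lambda s: s.map(order),
                           ignore_index=True)


def froh_vs_fis(records: pd.DataFrame) -> pd.DataFrame:
    """Per-population least-squares regression of F_ROH on F_IS.

    Populations with < 3 complete points are skipped (flag ``too_few``);
    constant F_IS yields an undefined r^2 (flag ``degenerate``).
    """
    rows = []
    for pop, grp in records.groupby("population", sort=False):
        ok = grp[["froh", "fis"]].dropna()
        if len(ok) < 3:
            rows.append({"population": pop, "n": len(ok), "slope": np.nan,
                         "intercept": np.nan, "r2": np.nan, "flag": "too_few"})
            continue
        if np.ptp(ok.fis.to_numpy()) == 0.0:
            rows.append({"population": pop, "n": len(ok), "slope": np.nan,
                         "intercept": np.nan, "r2": np.nan, "flag": "degenerate"})
            continue
        res = stats.linregress(ok.fis, ok.froh)
        rows.append({"population": pop, "n": len(ok), "slope": res.slope,
                     "intercept": res.intercept, "r2": res.rvalue ** 2,
                     "flag": ""})
    return pd.DataFrame(rows)


def chromosome_summary(segments, table: GenotypeTable, lengths: GenomeLengths,
                       exclude_chroms=()) -> dict:
    """Per-(population, chromosome) mean run count/length, plus the R^2 of
    overall mean run count regressed on chromosome length.

    ``exclude_chroms`` drops chromosomes from the regression only (e.g. the
    low-SNP-density outliers), not from the per-population table.
    """
    chroms = sorted(lengths.lengths)
    pop_of = {str(s): p for s, p in zip(table.samples, table.populations)}
    pop_sizes = pd.Series(table.populations).value_counts().to_dict()

    df = pd.DataFrame(
        [(seg.sample, pop_of[seg.sample], seg.chrom, seg.length_bp)
         for seg in segments],
        columns=["sample", "population", "chrom", "length_bp"],
    )
    rows = []
    for pop, n_pop in pop_sizes.items():
        sub = df[df.population == pop]
        for c in chroms:
            runs = sub[sub.chrom == c]
            rows.append({
                "population": pop, "chrom": c,
                "mean_n_roh": len(runs) / n_pop,
                "mean_length_bp": runs.length_bp.mean() if len(runs) else np.nan,
            })
    per_pop = pd.DataFrame(rows)

    n_total = table.n_samples
    mean_counts = np.array(
        [np.sum(df.chrom == c) / n_total for c in chroms], dtype=float)
    chrom_len = np.array([lengths.lengths[c] for c in chroms], dtype=float)
    keep = np.array([c not in set(exclude_chroms) for c in chroms])
    if keep.sum() < 2 or np.ptp(chrom_len[keep]) == 0:
        r2, flag = np.nan, "degenerate"
    else:
        res = stats.linregress(chrom_len[keep], mean_counts[keep])
        r2, flag = res.rvalue ** 2, ""
    return {"per_population": per_pop, "r2": r2, "flag": flag,
            "excluded": tuple(exclude_chroms)}
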
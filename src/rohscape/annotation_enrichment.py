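"""Gene overlap for ROH islands and hypergeometric term enrichment.

Island intervals are intersected with a local gene annotation (BED or
4-column TSV); any base-pair overlap includes a gene.  Term
over-representation is tested with the upper-tail hypergeometric
probability P(X >= k) for X ~ Hypergeom(N, K, n): N genes in the universe,
K annotated with the term, n in the query list, k in both.  The universe
is an explicit input — enrichment is meaningless without stating the
background.  Coordinates are 1-based inclusive internally; BED I/O
converts to/from 0-based half-open.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass(frozen=True)
class GeneInterval:
    chrom: int
    start_bp: int
    end_bp: int
    name: str

    def __post_init__(self) -> None:
        if self.start_bp > self.end_bp:
            raise ValueError(f"gene {self.name}: start > end")


@dataclass
class TermAnnotation:
    """term -> set of gene names, plus the gene universe."""

    term_to_genes: dict
    universe: set

    def __post_init__(self) -> None:
        self.universe = set(self.universe)
        for term, genes in self.term_to_genes.items():
            extra = set(genes) - self.universe
            if extra:
                raise ValueError(
                    f"term {term!r} annotates genes outside the universe: "
                    f"{sorted(extra)[:5]}"
                )
            self.term_to_genes[term] = set(genes)


def read_gene_intervals(path, fmt: str = "tsv") -> list[GeneInterval]:
    """Load gene intervals.

    ``fmt="tsv"``: 4 columns chrom/start/end/name, 1-based inclusive.
    ``fmt="bed"``: BED 0-based half-open, converted on read.
    """
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "name"],
                     dtype={"chrom": np.int64, "start": np.int64,
                            "end": np.int64, "name": str})
    if fmt == "bed":
        df["start"] = df["start"] + 1
    elif fmt != "tsv":
        raise ValueError(f"unknown format {fmt!r}")
    genes = [GeneInterval(int(r.chrom), int(r.start), int(r.end), r.name)
             for r in df.itertuples()]
    names = [g.name for g in genes]
    if len(set(names)) != len(names):
        raise ValueError("gene names are not unique in annotation")
    return genes


def write_gene_bed(genes, path) -> None:
    """Write intervals as BED (0-based half-open)."""
    pd.DataFrame(
        [(g.chrom, g.start_bp - 1, g.end_bp, g.name) for g in genes]
    ).to_csv(path, sep="\t", header=False, index=False)


def read_term_map(path, universe) -> TermAnnotation:
    """2-column TSV (gene<TAB>term) -> TermAnnotation over ``universe``."""
    df = pd.read_csv(path, sep="\t", header=None, names=["gene", "term"],
                     dtype=str)
    mapping: dict[str, set] = {}
    for gene, term in zip(df.gene, df.term):
        mapping.setdefault(term, set()).add(gene)
    return TermAnnotation(mapping, universe)


def genes_overlapping(islands, annotation) -> list[str]:
    """Genes with any bp overlap with any island, deduplicated, sorted by
    genomic position.  Raises if island chromosomes are absent from the
    annotation's chromosome set."""
    ann_chroms = {g.chrom for g in annotation}
    unmatched = sorted({i.chrom for i in islands} - ann_chroms)
    if unmatched:
        raise ValueError(
            f"island chromosomes absent from annotation: {unmatched}"
        )
    hits = []
    for g in annotation:
        for isl in islands:
            if g.chrom == isl.chrom and g.start_bp <= isl.end_bp \
                    and isl.start_bp <= g.end_bp:
                hits.append(g)
                break
    hits.sort(key=lambda g: (g.chrom, g.start_bp, g.end_bp, g.name))
    return [g.name for g in hits]


def enrich(query, terms: TermAnnotation, p_cut: float = 0.05,
           top_k: int = 50) -> pd.DataFrame:
    """Ranked hypergeometric enrichment of ``query`` against ``terms``.

    Rows with upper-tail p <= p_cut, ascending by p, truncated to
    ``top_k``; a Benjamini-Hochberg column is attached.  Query genes
    outside the universe are dropped with a warning.
    """
    query = list(dict.fromkeys(query))
    inside = [g for g in query if g in terms.universe]
    if len(inside) < len(query):
        dropped = sorted(set(query) - set(inside))
        warnings.warn(f"dropping {len(dropped)} query genes outside the "
                      f"universe: {dropped[:5]}...")
    if not inside:
        warnings.warn("empty query after universe filtering; no enrichment")
        return pd.DataFrame(columns=["term", "k", "K", "n", "N", "p",
                                     "p_bh", "rank"])
    N = len(terms.universe)
    n = len(inside)
    qset = set(inside)
    rows = []
    for term, genes in terms.term_to_genes.items():
        K = len(genes)
        k = len(qset & genes)
        # P(X >= k); sf(k-1) is the exact upper tail
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append({"term": term, "k": k, "K": K, "n": n, "N": N, "p": p})
    df = pd.DataFrame(rows)
    df["p_bh"] = multipletests(df.p, method="fdr_bh")[1]
    df = df[df.p <= p_cut].sort_values(["p", "term"], ignore_index=True)
    df = df.head(top_k)
    df["rank"] = np.arange(1, len(df) + 1)
    return df
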
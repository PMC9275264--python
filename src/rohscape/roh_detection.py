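"""Consecutive-run ROH calling.

A run of homozygosity is a maximal stretch of consecutive SNPs in one
individual satisfying, simultaneously:

* every gap between adjacent SNPs in the run <= ``max_gap_bp``;
* at most ``max_het`` heterozygous and ``max_missing`` missing genotypes;
* at least ``min_snps`` SNPs and at least ``min_length_bp`` of span;
* both endpoints homozygous and non-missing (runs are trimmed inward so
  het/missing calls never pad a boundary).

Because a het/missing budget admits overlapping maximal windows, runs are
selected greedily left to right: among all qualifying windows, the one with
the smallest start (ties: largest end) is emitted, every window overlapping
it is discarded, and the selection repeats.  This yields disjoint runs per
(individual, chromosome) and matches the behaviour of consecutive-run
callers used with SNP-array data.  :func:`detect_runs` implements the
selection with a linear two-pointer scan; :func:`brute_force_runs`
re-derives it from full window enumeration and serves as the test oracle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_io import GenotypeTable, HET, LocusMap, MISSING


@dataclass
class ROHParams:
    min_snps: int = 30
    max_gap_bp: int = 1_000_000
    max_missing: int = 2
    max_het: int = 1
    min_length_bp: int = 0

    def __post_init__(self) -> None:
        if self.min_snps < 1:
            raise ValueError("min_snps must be >= 1")
        for name in ("max_gap_bp", "max_missing", "max_het", "min_length_bp"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass(frozen=True)
class ROHSegment:
    """One homozygous run. ``length_bp`` is end_bp - start_bp, the span
    between the first and last SNP of the run."""

    sample: str
    chrom: int
    start_bp: int
    end_bp: int
    n_snps: int
    n_het: int
    n_missing: int

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp


def segments_to_frame(segments, populations: dict | None = None) -> pd.DataFrame:
    """Tabulate segments; optionally attach a sample -> population mapping."""
    df = pd.DataFrame(
        [(s.sample, s.chrom, s.start_bp, s.end_bp, s.n_snps, s.n_het,
          s.n_missing, s.length_bp) for s in segments],
        columns=["sample", "chrom", "start_bp", "end_bp", "n_snps",
                 "n_het", "n_missing", "length_bp"],
    )
    if populations is not None:
        df.insert(1, "population", df["sample"].map(populations))
    return df


def write_segments_tsv(segments, path, populations: dict | None = None) -> None:
    segments_to_frame(segments, populations).to_csv(path, sep="\t", index=False)


def _window_counts(col: np.ndarray):
    """Prefix counts of het and missing codes for one sample/chromosome."""
    het = np.concatenate([[0], np.cumsum(col == HET)])
    mis = np.concatenate([[0], np.cumsum(col == MISSING)])
    return het, mis


def detect_runs(table: GenotypeTable, locus_map: LocusMap,
                params: ROHParams | None = None) -> list[ROHSegment]:
    """Call ROH for every sample; output sorted by (sample order, chrom, start)."""
    params = params or ROHParams()
    if table.n_loci != locus_map.n_loci:
        raise ValueError("table and map disagree on locus count")
    if not locus_map.is_sorted():
        raise ValueError("locus map must be sorted by (chromosome, position)")
    segments: list[ROHSegment] = []
    for i in range(table.n_samples):
        for c in np.unique(locus_map.chrom):
            sel = locus_map.chrom == c
            segments.extend(
                _scan_chromosome(
                    str(table.samples[i]), int(c),
                    table.codes[i, sel], locus_map.pos[sel], params,
                )
            )
    return segments


def _scan_chromosome(sample, chrom, col, pos, params) -> list[ROHSegment]:
    L = len(col)
    if L == 0:
        return []
    hom = (col != HET) & (col != MISSING)
    het_pref, mis_pref = _window_counts(col)
    gap_ok = np.diff(pos) <= params.max_gap_bp  # gap_ok[k]: k -> k+1 allowed

    out = []
    s = 0
    e_max = -1  # furthest end reached by the two-pointer extension
    while s < L:
        if not hom[s]:
            s += 1
            continue
        if e_max < s:
            e_max = s
        # extend e_max while the next SNP keeps gaps and budgets legal
        while e_max + 1 < L and gap_ok[e_max] \
                and het_pref[e_max + 2] - het_pref[s] <= params.max_het \
                and mis_pref[e_max + 2] - mis_pref[s] <= params.max_missing:
            e_max += 1
        # trim the right endpoint back to a homozygous SNP
        e = e_max
        while e > s and not hom[e]:
            e -= 1
        n = e - s + 1
        if n >= params.min_snps and pos[e] - pos[s] >= params.min_length_bp:
            out.append(ROHSegment(
                sample, chrom, int(pos[s]), int(pos[e]), n,
                int(het_pref[e + 1] - het_pref[s]),
                int(mis_pref[e + 1] - mis_pref[s]),
            ))
            s = e + 1
            e_max = e  # restart extension beyond the emitted run
        else:
            s += 1
    return out


def brute_force_runs(table: GenotypeTable, locus_map: LocusMap,
                     params: ROHParams | None = None) -> list[ROHSegment]:
    """O(L^2) oracle: enumerate every SNP window, keep qualifying ones, then
    select greedily by (smallest start, largest end), discarding overlaps.

    Intended for small inputs (<= ~500 SNPs per chromosome)."""
    params = params or ROHParams()
    if not locus_map.is_sorted():
        raise ValueError("locus map must be sorted by (chromosome, position)")
    segments = []
    for i in range(table.n_samples):
        for c in np.unique(locus_map.chrom):
            sel = locus_map.chrom == c
            col = table.codes[i, sel]
            pos = locus_map.pos[sel]
            wins = _qualifying_windows(col, pos, params)
            for (s, e) in _greedy_select(wins):
                het = int(np.sum(col[s:e + 1] == HET))
                mis = int(np.sum(col[s:e + 1] == MISSING))
                segments.append(ROHSegment(
                    str(table.samples[i]), int(c), int(pos[s]), int(pos[e]),
                    e - s + 1, het, mis,
                ))
    return segments


def _qualifying_windows(col, pos, params):
    L = len(col)
    hom = (col != HET) & (col != MISSING)
    wins = []
    for s in range(L):
        if not hom[s]:
            continue
        het = mis = 0
        for e in range(s, L):
            if e > s and pos[e] - pos[e - 1] > params.max_gap_bp:
                break
            het += col[e] == HET
            mis += col[e] == MISSING
            if het > params.max_het or mis > params.max_missing:
                break
            if hom[e] and e - s + 1 >= params.min_snps \
                    and pos[e] - pos[s] >= params.min_length_bp:
                wins.append((s, e))
    return wins


def _greedy_select(windows):
    chosen = []
    remaining = sorted(windows, key=lambda w: (w[0], -w[1]))
    while remaining:
        best = remaining[0]
        chosen.append(best)
        remaining = [w for w in remaining if w[0] > best[1]]
    return chosen


def qualifying_window_union_bp(table: GenotypeTable, locus_map: LocusMap,
                               params: ROHParams | None = None) -> dict:
    """Total bp covered by the union of all qualifying windows, per sample.

    The union over *all* qualifying windows (not just the emitted disjoint
    runs) is monotone under relaxation of the het/missing budgets, which
    makes it the right quantity for monotonicity checks."""
    params = params or ROHParams()
    totals: dict[str, int] = {str(s): 0 for s in table.samples}
    for i in range(table.n_samples):
        for c in np.unique(locus_map.chrom):
            sel = locus_map.chrom == c
            col = table.codes[i, sel]
            pos = locus_map.pos[sel]
            ivals = [(pos[s], pos[e]) for s, e in _qualifying_windows(col, pos, params)]
            totals[str(table.samples[i])] += _union_length(ivals)
    return totals


def _union_length(intervals) -> int:
    total, cur_s, cur_e = 0, None, None
    for s, e in sorted(intervals):
        if cur_e is None or s > cur_e:
            if cur_e is not None:
                total += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    if cur_e is not None:
        total += cur_e - cur_s
    return total
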
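"""Read, filter, intersect and write PLINK text-format genotype data.

The in-memory representation is a :class:`GenotypeTable` (samples x loci
matrix of small integer codes) paired with a :class:`LocusMap` (ordered
per-locus metadata).  Genotypes are coded

====================  ====
homozygous reference     0
heterozygous             1
homozygous alternate     2
missing                 -1
====================  ====

where "reference" is simply the first allele observed at a locus when the
file is read (the PLINK text dialect carries no allele designation).  All
downstream ROH statistics depend only on het/hom/missing status and are
invariant to this labelling.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

HOM_REF = 0
HET = 1
HOM_ALT = 2
MISSING = -1

MISSING_ALLELE = "0"

#: Horse autosomes are numbered 1..31; chromosome codes outside this range
#: (sex chromosomes, unplaced scaffolds) are dropped by the autosome filter.
DEFAULT_MAX_AUTOSOME = 31


class PlinkParseError(ValueError):
    """Malformed PED/MAP content (ragged rows, allele-count mismatch...)."""


class LocusConflictError(ValueError):
    """Same locus id mapped to different coordinates across datasets."""


class EmptyResultError(ValueError):
    """A filter stage removed every sample or every locus."""


@dataclass
class LocusMap:
    """Ordered per-locus metadata: chromosome, id, bp position, alleles.

    Positions must be strictly increasing within a chromosome and locus ids
    unique; :meth:`validate` enforces both.  ``allele1`` is the reference
    (first-seen) allele; ``allele2`` is "0" while a second allele has not
    been observed (monomorphic locus).
    """

    chrom: np.ndarray
    locus_id: np.ndarray
    pos: np.ndarray
    allele1: np.ndarray
    allele2: np.ndarray

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=np.int64)
        self.locus_id = np.asarray(self.locus_id, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.allele1 = np.asarray(self.allele1, dtype=object)
        self.allele2 = np.asarray(self.allele2, dtype=object)

    @property
    def n_loci(self) -> int:
        return len(self.locus_id)

    def validate(self) -> None:
        if len(set(self.locus_id)) != self.n_loci:
            raise ValueError("locus ids are not unique")
        for c in np.unique(self.chrom):
            p = self.pos[self.chrom == c]
            if np.any(np.diff(p) <= 0):
                raise ValueError(
                    f"positions not strictly increasing on chromosome {c}"
                )
        if np.any(self.pos < 1):
            raise ValueError("positions must be >= 1")

    def is_sorted(self) -> bool:
        order = np.lexsort((self.pos, self.chrom))
        return bool(np.all(order == np.arange(self.n_loci)))

    def subset(self, idx: np.ndarray) -> "LocusMap":
        return LocusMap(
            self.chrom[idx], self.locus_id[idx], self.pos[idx],
            self.allele1[idx], self.allele2[idx],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "chrom": self.chrom, "locus_id": self.locus_id, "pos": self.pos,
            "allele1": self.allele1, "allele2": self.allele2,
        })


@dataclass
class GenotypeTable:
    """Samples x loci genotype codes plus sample metadata.

    ``codes`` is an int8 matrix aligned to a :class:`LocusMap`'s column
    order; ``populations`` carries one label per sample.
    """

    samples: np.ndarray
    populations: np.ndarray
    codes: np.ndarray

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=object)
        self.populations = np.asarray(self.populations, dtype=object)
        self.codes = np.asarray(self.codes, dtype=np.int8)
        if self.codes.ndim != 2:
            raise ValueError("codes must be 2-D (samples x loci)")
        if self.codes.shape[0] != len(self.samples):
            raise ValueError("codes row count != number of samples")
        if len(self.populations) != len(self.samples):
            raise ValueError("one population label per sample required")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_loci(self) -> int:
        return self.codes.shape[1]

    def subset(self, sample_idx=None, locus_idx=None) -> "GenotypeTable":
        s = np.arange(self.n_samples) if sample_idx is None else np.asarray(sample_idx)
        l = np.arange(self.n_loci) if locus_idx is None else np.asarray(locus_idx)
        return GenotypeTable(
            self.samples[s], self.populations[s], self.codes[np.ix_(s, l)]
        )


@dataclass
class FilterParams:
    min_sample_call_rate: float = 0.90
    min_locus_call_rate: float = 0.90
    min_maf: float = 0.001
    autosomes_only: bool = True
    max_autosome: int = DEFAULT_MAX_AUTOSOME

    def __post_init__(self) -> None:
        if not (0.0 <= self.min_sample_call_rate <= 1.0):
            raise ValueError("min_sample_call_rate must be in [0, 1]")
        if not (0.0 <= self.min_locus_call_rate <= 1.0):
            raise ValueError("min_locus_call_rate must be in [0, 1]")
        if not (0.0 <= self.min_maf <= 0.5):
            raise ValueError("min_maf must be in [0, 0.5]")


@dataclass
class FilterReport:
    """Per-stage sample/locus survivor counts, in application order."""

    stages: list = field(default_factory=list)  # (name, n_samples, n_loci)

    def record(self, name: str, n_samples: int, n_loci: int) -> None:
        if self.stages:
            _, ps, pl = self.stages[-1]
            if n_samples > ps or n_loci > pl:
                raise ValueError("filter stage counts must be non-increasing")
        self.stages.append((name, n_samples, n_loci))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.stages, columns=["stage", "n_samples", "n_loci"])

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# PED/MAP reading and writing


def read_plink_text(ped_path, map_path, pop_source: str | dict = "fid"):
    """Read a PLINK PED/MAP text pair into (GenotypeTable, LocusMap).

    Parameters
    ----------
    pop_source
        ``"fid"`` takes the population label from the PED family-id column;
        a dict (or a path to a two-column TSV ``sample_id<TAB>population``)
        overrides labels per sample id.

    The first allele observed at each locus (scanning samples in file
    order) becomes the reference allele; ``"0 0"`` is the missing genotype.
    """
    mp = pd.read_csv(
        map_path, sep=r"\s+", header=None,
        names=["chrom", "locus_id", "cm", "pos"],
        dtype={"chrom": np.int64, "locus_id": str, "pos": np.int64},
    )
    if mp.shape[1] != 4:
        raise PlinkParseError(f"{map_path}: expected 4 columns in MAP file")
    n_loci = len(mp)

    samples, fids, rows = [], [], []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 6 + 2 * n_loci:
                raise PlinkParseError(
                    f"{ped_path}:{lineno}: expected {6 + 2 * n_loci} fields "
                    f"(6 + 2 x {n_loci} alleles), found {len(fields)}"
                )
            fids.append(fields[0])
            samples.append(fields[1])
            rows.append(fields[6:])

    alleles = np.array(rows, dtype=object).reshape(len(samples), n_loci, 2) \
        if samples else np.empty((0, n_loci, 2), dtype=object)

    codes = np.full((len(samples), n_loci), MISSING, dtype=np.int8)
    a1 = np.full(n_loci, MISSING_ALLELE, dtype=object)
    a2 = np.full(n_loci, MISSING_ALLELE, dtype=object)
    for j in range(n_loci):
        ref = alt = None
        col = alleles[:, j, :]
        for i in range(len(samples)):
            x, y = col[i]
            if x == MISSING_ALLELE or y == MISSING_ALLELE:
                if x != y:
                    raise PlinkParseError(
                        f"{ped_path}: half-missing genotype for sample "
                        f"{samples[i]} at locus {mp.locus_id[j]}"
                    )
                continue
            for a in (x, y):
                if ref is None:
                    ref = a
                elif a != ref and alt is None:
                    alt = a
                elif a != ref and a != alt:
                    raise PlinkParseError(
                        f"{ped_path}: >2 alleles at locus {mp.locus_id[j]}"
                    )
            codes[i, j] = (x != ref) + (y != ref)
        if ref is not None:
            a1[j] = ref
        if alt is not None:
            a2[j] = alt

    locus_map = LocusMap(mp.chrom.to_numpy(), mp.locus_id.to_numpy(dtype=object),
                         mp.pos.to_numpy(), a1, a2)
    locus_map.validate()

    pops = _resolve_populations(pop_source, samples, fids)
    table = GenotypeTable(np.array(samples, dtype=object), pops, codes)
    return table, locus_map


def _resolve_populations(pop_source, samples, fids) -> np.ndarray:
    if isinstance(pop_source, str) and pop_source != "fid":
        tsv = pd.read_csv(pop_source, sep="\t", header=None,
                          names=["sample_id", "population"], dtype=str)
        pop_source = dict(zip(tsv.sample_id, tsv.population))
    if pop_source == "fid":
        return np.array(fids, dtype=object)
    missing = [s for s in samples if s not in pop_source]
    if missing:
        raise ValueError(f"no population label for samples: {missing}")
    return np.array([pop_source[s] for s in samples], dtype=object)


def write_plink_text(table: GenotypeTable, locus_map: LocusMap, out_prefix) -> tuple:
    """Write PED/MAP files such that :func:`read_plink_text` inverts them.

    Inversion is exact provided the table's allele labelling is canonical
    (reference = first allele seen in sample order), which holds for any
    table produced by :func:`read_plink_text` and for simulator output.
    """
    if table.n_samples == 0 or locus_map.n_loci == 0:
        raise EmptyResultError("refusing to write an empty dataset")
    ped_path = f"{out_prefix}.ped"
    map_path = f"{out_prefix}.map"
    pd.DataFrame({
        "chrom": locus_map.chrom, "locus_id": locus_map.locus_id,
        "cm": 0, "pos": locus_map.pos,
    }).to_csv(map_path, sep="\t", header=False, index=False)

    pair = {
        HOM_REF: lambda j: f"{locus_map.allele1[j]} {locus_map.allele1[j]}",
        HET: lambda j: f"{locus_map.allele1[j]} {locus_map.allele2[j]}",
        HOM_ALT: lambda j: f"{locus_map.allele2[j]} {locus_map.allele2[j]}",
        MISSING: lambda j: "0 0",
    }
    with open(ped_path, "w") as fh:
        for i in range(table.n_samples):
            cols = [table.populations[i], table.samples[i], "0", "0", "0", "-9"]
            cols.extend(pair[int(c)](j) for j, c in enumerate(table.codes[i]))
            fh.write(" ".join(cols) + "\n")
    return ped_path, map_path


def canonicalize_alleles(table: GenotypeTable, locus_map: LocusMap):
    """Relabel ref/alt per locus so the first non-missing sample carries the
    reference allele, making write -> read the identity on codes."""
    codes = table.codes.copy()
    a1 = locus_map.allele1.copy()
    a2 = locus_map.allele2.copy()
    for j in range(locus_map.n_loci):
        col = codes[:, j]
        nm = np.nonzero(col != MISSING)[0]
        if nm.size and col[nm[0]] == HOM_ALT:
            hom_ref, hom_alt = col == HOM_REF, col == HOM_ALT
            col[hom_ref], col[hom_alt] = HOM_ALT, HOM_REF
            a1[j], a2[j] = a2[j], a1[j]
    return (
        GenotypeTable(table.samples, table.populations, codes),
        LocusMap(locus_map.chrom, locus_map.locus_id, locus_map.pos, a1, a2),
    )


# ---------------------------------------------------------------------------
# Merging and filtering


def intersect_on_loci(datasets):
    """Merge >=2 datasets on their common loci.

    Retains loci whose id appears in every dataset with agreeing
    (chromosome, position); samples are concatenated and the output is
    sorted by (chromosome, position).  Genotype codes are reconciled so
    every dataset uses the first dataset's reference allele.
    """
    if len(datasets) < 2:
        raise ValueError("need at least 2 datasets to intersect")

    common = None
    coord = {}
    conflicts = set()
    for table, lmap in datasets:
        ids = set(lmap.locus_id)
        common = ids if common is None else (common & ids)
        for c, lid, p in zip(lmap.chrom, lmap.locus_id, lmap.pos):
            if lid in coord and coord[lid] != (c, p):
                conflicts.add(lid)
            coord[lid] = (c, p)
    conflicts &= common
    if conflicts:
        raise LocusConflictError(
            "conflicting coordinates for loci: " + ", ".join(sorted(conflicts))
        )

    ref_table, ref_map = datasets[0]
    keep = np.array([lid in common for lid in ref_map.locus_id])
    idx = np.nonzero(keep)[0]
    order = np.lexsort((ref_map.pos[idx], ref_map.chrom[idx]))
    idx = idx[order]
    out_map = ref_map.subset(idx)

    blocks, samples, pops = [], [], []
    for table, lmap in datasets:
        lookup = {lid: k for k, lid in enumerate(lmap.locus_id)}
        cols = np.array([lookup[lid] for lid in out_map.locus_id])
        codes = table.codes[:, cols].copy()
        # flip codes where this dataset's ref allele is the output's alt
        for jo in range(out_map.n_loci):
            ja = cols[jo]
            if lmap.allele1[ja] == out_map.allele1[jo] or \
               lmap.allele1[ja] == MISSING_ALLELE:
                continue
            if lmap.allele1[ja] == out_map.allele2[jo] or \
               out_map.allele2[jo] == MISSING_ALLELE:
                col = codes[:, jo]
                hr, ha = col == HOM_REF, col == HOM_ALT
                col[hr], col[ha] = HOM_ALT, HOM_REF
            else:
                raise LocusConflictError(
                    f"allele mismatch at locus {out_map.locus_id[jo]}"
                )
        blocks.append(codes)
        samples.append(table.samples)
        pops.append(table.populations)

    out_table = GenotypeTable(
        np.concatenate(samples), np.concatenate(pops), np.vstack(blocks)
    )
    return out_table, out_map


def minor_allele_frequencies(codes: np.ndarray) -> np.ndarray:
    """Per-locus MAF from non-missing genotypes (NaN where all missing)."""
    nm = codes != MISSING
    n_alleles = 2.0 * nm.sum(axis=0)
    alt = np.where(nm, codes, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = alt / n_alleles
    return np.minimum(p, 1.0 - p)


def apply_filters(table: GenotypeTable, locus_map: LocusMap,
                  params: FilterParams | None = None):
    """Apply QC filters in fixed order: autosomes -> sample call rate ->
    locus call rate -> MAF (computed on post-call-rate data).

    Returns (table, locus_map, FilterReport).  Raises
    :class:`EmptyResultError` if any stage removes everything.
    """
    params = params or FilterParams()
    if table.n_loci != locus_map.n_loci:
        raise ValueError("table and map disagree on locus count")

    report = FilterReport()
    report.record("input", table.n_samples, table.n_loci)

    if params.autosomes_only:
        keep = (locus_map.chrom >= 1) & (locus_map.chrom <= params.max_autosome)
        table = table.subset(locus_idx=np.nonzero(keep)[0])
        locus_map = locus_map.subset(np.nonzero(keep)[0])
    report.record("autosomes", table.n_samples, table.n_loci)
    _check_nonempty(table, "autosome filter")

    call = (table.codes != MISSING).mean(axis=1) if table.n_loci else np.ones(table.n_samples)
    keep_s = np.nonzero(call >= params.min_sample_call_rate)[0]
    table = table.subset(sample_idx=keep_s)
    report.record("sample_call_rate", table.n_samples, table.n_loci)
    _check_nonempty(table, "sample call-rate filter")

    call = (table.codes != MISSING).mean(axis=0) if table.n_samples else np.ones(table.n_loci)
    keep_l = np.nonzero(call >= params.min_locus_call_rate)[0]
    table = table.subset(locus_idx=keep_l)
    locus_map = locus_map.subset(keep_l)
    report.record("locus_call_rate", table.n_samples, table.n_loci)
    _check_nonempty(table, "locus call-rate filter")

    maf = minor_allele_frequencies(table.codes)
    keep_l = np.nonzero(np.nan_to_num(maf, nan=-1.0) >= params.min_maf)[0]
    table = table.subset(locus_idx=keep_l)
    locus_map = locus_map.subset(keep_l)
    report.record("maf", table.n_samples, table.n_loci)
    _check_nonempty(table, "MAF filter")

    return table, locus_map, report


def _check_nonempty(table: GenotypeTable, stage: str) -> None:
    if table.n_samples == 0:
        raise EmptyResultError(f"{stage} removed every sample")
    if table.n_loci == 0:
        raise EmptyResultError(f"{stage} removed every locus")
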
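"""ROH islands: per-SNP in-ROH incidence, binning, z-score thresholds.

For each population the incidence x_i of SNP i is the percentage of
individuals whose ROH cover its position.  Incidences are (optionally)
reduced to the best SNP per 1-Mb bin to even out array density, z-scored
(sample sd), and SNPs with upper-tail normal probability p > p_cut
(default 0.999) exceed the population-specific threshold

    threshold = mean + Phi^-1(p_cut) * sd,

clamped into [30, 80] percent so that populations with uniformly high
incidence do not call the whole genome and populations where no SNP
reaches the cutoff still can call extreme regions.  Islands are maximal
stretches of consecutive SNPs above the clamped threshold; when binning is
used the threshold comes from the binned distribution but island
membership and boundaries are evaluated on the full SNP track, so
boundaries are the positions of the first and last qualifying SNP.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genotype_io import GenotypeTable, LocusMap


@dataclass
class IslandParams:
    bin_size_bp: int = 1_000_000
    p_cut: float = 0.999
    clamp_min_pct: float = 30.0
    clamp_max_pct: float = 80.0
    use_binning: bool = True
    min_island_snps: int = 1

    def __post_init__(self) -> None:
        if not (0.0 < self.p_cut < 1.0):
            raise ValueError("p_cut must be in (0, 1)")
        if not (0.0 <= self.clamp_min_pct < self.clamp_max_pct <= 100.0):
            raise ValueError("need 0 <= clamp_min < clamp_max <= 100")
        if self.bin_size_bp <= 0:
            raise ValueError("bin_size_bp must be positive")


@dataclass
class IslandThreshold:
    population: str
    mean: float
    sd: float
    raw: float
    clamped: float
    used_binning: bool
    degenerate: bool = False


@dataclass(frozen=True)
class ROHIsland:
    population: str
    chrom: int
    start_bp: int
    end_bp: int
    n_snps: int
    peak_incidence: float
    single_snp: bool


def incidence(segments, table: GenotypeTable, locus_map: LocusMap,
              population: str | None = None) -> pd.DataFrame:
    """Per-SNP percentage of a population's individuals covered by an ROH.

    Returns a tidy frame (population, chrom, pos, locus_id, pct) covering
    every retained SNP; ``population=None`` computes every population.
    """
    pops = [population] if population is not None else \
        list(pd.unique(table.populations))
    seg_by_sample: dict[str, list] = {str(s): [] for s in table.samples}
    for seg in segments:
        seg_by_sample[seg.sample].append(seg)

    frames = []
    for pop in pops:
        members = [str(s) for s, p in zip(table.samples, table.populations)
                   if p == pop]
        if not members:
            raise ValueError(f"population {pop!r} has no samples")
        counts = np.zeros(locus_map.n_loci, dtype=np.int64)
        for s in members:
            covered = np.zeros(locus_map.n_loci, dtype=bool)
            for seg in seg_by_sample[s]:
                idx = np.nonzero(locus_map.chrom == seg.chrom)[0]
                chrom_pos = locus_map.pos[idx]
                lo = np.searchsorted(chrom_pos, seg.start_bp, "left")
                hi = np.searchsorted(chrom_pos, seg.end_bp, "right")
                covered[idx[lo:hi]] = True
            counts += covered
        frames.append(pd.DataFrame({
            "population": pop, "chrom": locus_map.chrom,
            "pos": locus_map.pos, "locus_id": locus_map.locus_id,
            "pct": 100.0 * counts / len(members),
        }))
    return pd.concat(frames, ignore_index=True)


def bin_select(track: pd.DataFrame, bin_size_bp: int = 1_000_000) -> pd.DataFrame:
    """Keep the highest-incidence SNP per (population, chromosome, 1-Mb bin).

    Bins partition each chromosome as [0, bin), [bin, 2 bin), ...; ties on
    incidence break to the smallest position so output is deterministic.
    """
    if bin_size_bp <= 0:
        raise ValueError("bin_size_bp must be positive")
    t = track.copy()
    t["bin"] = t["pos"] // bin_size_bp
    t = t.sort_values(["population", "chrom", "bin", "pct", "pos"],
                      ascending=[True, True, True, False, True],
                      kind="mergesort")
    out = t.groupby(["population", "chrom", "bin"], sort=True).head(1)
    return (out.drop(columns="bin")
               .sort_values(["population", "chrom", "pos"])
               .reset_index(drop=True))


def compute_threshold(values, params: IslandParams | None = None,
                      population: str = "") -> IslandThreshold:
    """Population-specific island threshold from an incidence distribution.

    raw = mean + Phi^-1(p_cut) * sd (sample sd, n-1); the working threshold
    is raw clamped into [clamp_min_pct, clamp_max_pct].  sd == 0 flags a
    degenerate distribution: no islands should be called from it.
    """
    params = params or IslandParams()
    x = np.asarray(values, dtype=float)
    if len(x) < 2:
        raise ValueError("need >= 2 incidence values")
    mean = float(np.mean(x))
    sd = float(np.std(x, ddof=1))
    if sd == 0.0:
        warnings.warn(f"degenerate incidence distribution for population "
                      f"{population!r} (sd = 0); no islands will be called")
        return IslandThreshold(population, mean, sd, np.nan,
                               np.nan, params.use_binning, degenerate=True)
    raw = mean + stats.norm.ppf(params.p_cut) * sd
    clamped = float(np.clip(raw, params.clamp_min_pct, params.clamp_max_pct))
    return IslandThreshold(population, mean, sd, float(raw), clamped,
                           params.use_binning)


def call_islands(full_track: pd.DataFrame, threshold: IslandThreshold,
                 params: IslandParams | None = None) -> list[ROHIsland]:
    """Maximal consecutive stretches of SNPs with incidence strictly above
    the clamped threshold, evaluated on the full (unbinned) track."""
    params = params or IslandParams()
    if threshold.degenerate:
        return []
    t = full_track[full_track.population == threshold.population]
    t = t.sort_values(["chrom", "pos"])
    islands = []
    for c, grp in t.groupby("chrom", sort=True):
        above = (grp.pct > threshold.clamped).to_numpy()
        pos = grp.pos.to_numpy()
        pct = grp.pct.to_numpy()
        j = 0
        while j < len(above):
            if not above[j]:
                j += 1
                continue
            k = j
            while k + 1 < len(above) and above[k + 1]:
                k += 1
            n = k - j + 1
            if n >= params.min_island_snps:
                islands.append(ROHIsland(
                    threshold.population, int(c), int(pos[j]), int(pos[k]),
                    n, float(pct[j:k + 1].max()), single_snp=(n == 1),
                ))
            j = k + 1
    return islands


def find_islands(segments, table: GenotypeTable, locus_map: LocusMap,
                 params: IslandParams | None = None):
    """Full per-population island scan.

    Returns (thresholds, islands, full_track): the incidence track is
    computed per population, optionally reduced to 1-Mb bin maxima for the
    threshold, and islands are delimited on the full track.
    """
    params = params or IslandParams()
    full = incidence(segments, table, locus_map)
    thresholds, islands = [], []
    for pop in pd.unique(full.population):
        track = full[full.population == pop]
        values = bin_select(track, params.bin_size_bp).pct if params.use_binning \
            else track.pct
        thr = compute_threshold(values.to_numpy(), params, population=pop)
        thresholds.append(thr)
        islands.extend(call_islands(full, thr, params))
    return thresholds, islands, full


def islands_to_frame(islands) -> pd.DataFrame:
    """Islands as a BED-like table with 1-based inclusive coordinates."""
    return pd.DataFrame(
        [(i.chrom, i.start_bp, i.end_bp, i.population, i.n_snps,
          i.peak_incidence, i.single_snp) for i in islands],
        columns=["chrom", "start_bp", "end_bp", "population", "n_snps",
                 "peak_incidence", "single_snp"],
    )


def plot_incidence(full_track: pd.DataFrame, thresholds, path) -> None:
    """Manhattan-style incidence plot per population with threshold lines."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pops = list(pd.unique(full_track.population))
    fig, axes = plt.subplots(len(pops), 1, figsize=(10, 3 * len(pops)),
                             squeeze=False)
    thr_by_pop = {t.population: t for t in thresholds}
    for ax, pop in zip(axes.ravel(), pops):
        t = full_track[full_track.population == pop]
        offset, ticks = 0, []
        for c, grp in t.groupby("chrom", sort=True):
            ax.scatter(grp.pos + offset, grp.pct, s=2,
                       color="C0" if c % 2 else "C1")
            ticks.append((offset + grp.pos.mean(), str(c)))
            offset += grp.pos.max()
        thr = thr_by_pop.get(pop)
        if thr is not None and not thr.degenerate:
            ax.axhline(thr.clamped, color="red", lw=0.8)
        ax.set_xticks([x for x, _ in ticks])
        ax.set_xticklabels([l for _, l in ticks])
        ax.set_ylabel("% in ROH")
        ax.set_title(pop)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
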
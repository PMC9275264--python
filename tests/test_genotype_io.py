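import numpy as np
import pytest
from hypothesis import given, strategies as st

from rohscape import genotype_io as gio
from rohscape.genotype_io import (EmptyResultError, FilterParams,
                                  GenotypeTable, LocusConflictError, LocusMap,
                                  PlinkParseError, apply_filters,
                                  canonicalize_alleles, intersect_on_loci,
                                  minor_allele_frequencies, read_plink_text,
                                  write_plink_text)

from conftest import make_dataset


def _write_pair(tmp_path, ped_lines, map_lines):
    ped = tmp_path / "t.ped"
    mp = tmp_path / "t.map"
    ped.write_text("\n".join(ped_lines) + "\n")
    mp.write_text("\n".join(map_lines) + "\n")
    return str(ped), str(mp)


class TestReadPlinkText:
    def test_allele_pairs_map_to_codes(self, tmp_path):
        ped, mp = _write_pair(
            tmp_path,
            ["fam1 s1 0 0 0 -9 A A A G"],
            ["1 snp1 0 100", "1 snp2 0 200"],
        )
        table, lmap = read_plink_text(ped, mp)
        assert table.codes.tolist() == [[gio.HOM_REF, gio.HET]]
        assert list(lmap.allele1) == ["A", "A"]
        assert list(lmap.allele2) == ["0", "G"]

    def test_zero_zero_is_missing(self, tmp_path):
        ped, mp = _write_pair(
            tmp_path,
            ["fam1 s1 0 0 0 -9 0 0 C C"],
            ["1 snp1 0 100", "1 snp2 0 200"],
        )
        table, _ = read_plink_text(ped, mp)
        assert table.codes.tolist() == [[gio.MISSING, gio.HOM_REF]]

    def test_population_from_fid_and_tsv(self, tmp_path):
        ped, mp = _write_pair(
            tmp_path,
            ["breedA s1 0 0 0 -9 A A", "breedB s2 0 0 0 -9 A G"],
            ["1 snp1 0 100"],
        )
        table, _ = read_plink_text(ped, mp)
        assert list(table.populations) == ["breedA", "breedB"]
        tsv = tmp_path / "pops.tsv"
        tsv.write_text("s1\tferal\ns2\tferal\n")
        table, _ = read_plink_text(ped, mp, pop_source=str(tsv))
        assert list(table.populations) == ["feral", "feral"]

    def test_ragged_row_names_line(self, tmp_path):
        ped, mp = _write_pair(
            tmp_path,
            ["fam1 s1 0 0 0 -9 A A", "fam1 s2 0 0 0 -9 A"],
            ["1 snp1 0 100"],
        )
        with pytest.raises(PlinkParseError, match=":2:"):
            read_plink_text(ped, mp)


class TestRoundTrip:
    @given(st.integers(0, 2 ** 31 - 1))
    def test_write_read_identity(self, tmp_path_factory, seed):
        """Writing a canonical table and rereading it reproduces codes,
        coordinates, ids and population labels exactly."""
        rng = np.random.default_rng(seed)
        codes = rng.choice([-1, 0, 1, 2], size=(5, 10), p=[0.05, 0.4, 0.3, 0.25])
        table, lmap = make_dataset(codes)
        table, lmap = canonicalize_alleles(table, lmap)
        prefix = tmp_path_factory.mktemp("rt") / "d"
        write_plink_text(table, lmap, prefix)
        table2, lmap2 = read_plink_text(f"{prefix}.ped", f"{prefix}.map")
        assert np.array_equal(table.codes, table2.codes)
        assert np.array_equal(lmap.pos, lmap2.pos)
        assert list(lmap.locus_id) == list(lmap2.locus_id)
        assert list(table.samples) == list(table2.samples)
        assert list(table.populations) == list(table2.populations)

    def test_missing_serialized_as_zero_zero(self, tmp_path):
        table, lmap = make_dataset([[0, -1]])
        write_plink_text(table, lmap, tmp_path / "m")
        fields = (tmp_path / "m.ped").read_text().split()
        assert fields[6:] == ["A", "A", "0", "0"]

    def test_empty_table_refused(self, tmp_path):
        table, lmap = make_dataset([[0, 0]])
        empty = table.subset(sample_idx=np.array([], dtype=int))
        with pytest.raises(EmptyResultError):
            write_plink_text(empty, lmap, tmp_path / "e")


class TestIntersect:
    def _dataset(self, ids, positions, codes):
        n = len(ids)
        lmap = LocusMap(np.ones(n, dtype=int),
                        np.array(ids, dtype=object),
                        np.array(positions),
                        np.array(["A"] * n, dtype=object),
                        np.array(["C"] * n, dtype=object))
        table = GenotypeTable(np.array([f"s{id(ids)}"], dtype=object),
                              np.array(["p"], dtype=object),
                              np.array([codes], dtype=np.int8))
        return table, lmap

    def test_locus_set_intersection(self):
        d1 = self._dataset(["a", "b", "c"], [100, 200, 300], [0, 1, 2])
        d2 = self._dataset(["b", "c", "d"], [200, 300, 400], [2, 0, 1])
        table, lmap = intersect_on_loci([d1, d2])
        assert list(lmap.locus_id) == ["b", "c"]
        assert table.n_samples == 2
        assert table.codes.tolist() == [[1, 2], [2, 0]]

    def test_identity_on_identical_datasets(self):
        d1 = self._dataset(["a", "b"], [100, 200], [0, 1])
        d2 = self._dataset(["a", "b"], [100, 200], [2, 1])
        table, lmap = intersect_on_loci([d1, d2])
        assert list(lmap.locus_id) == ["a", "b"]

    def test_conflicting_position_raises(self):
        d1 = self._dataset(["a", "b"], [100, 200], [0, 1])
        d2 = self._dataset(["a", "b"], [100, 999], [0, 1])
        with pytest.raises(LocusConflictError, match="b"):
            intersect_on_loci([d1, d2])


class TestFilters:
    def test_low_call_rate_sample_removed(self):
        codes = (np.add.outer(np.arange(4), np.arange(6)) % 3).astype(np.int8)
        codes[2, :4] = -1  # sample ind2: call rate 2/6
        table, lmap = make_dataset(codes)
        out, _, report = apply_filters(table, lmap, FilterParams())
        assert "ind2" not in list(out.samples)
        stages = dict((s, (ns, nl)) for s, ns, nl in report.stages)
        assert stages["sample_call_rate"] == (3, 6)

    def test_monomorphic_locus_removed_at_maf_stage(self):
        codes = np.zeros((4, 3), dtype=np.int8)
        codes[:, 1] = [0, 1, 2, 1]  # polymorphic
        codes[:, 2] = [2, 2, 2, 2]  # monomorphic (all hom-alt)
        table, lmap = make_dataset(codes)
        out, lmap2, report = apply_filters(table, lmap, FilterParams())
        assert lmap2.n_loci == 1
        assert list(lmap2.locus_id) == ["c1_s1"]

    def test_planted_violation_fixture_matches_independent_recount(self, rng):
        """10x20 fixture with planted violations of each filter; stage
        survivor counts must match an independent pure-Python recount."""
        codes = rng.choice([0, 1, 2], size=(10, 20)).astype(np.int8)
        chrom = np.ones(20, dtype=int)
        chrom[17:] = 32            # 3 loci on a sex chromosome
        codes[3, :15] = -1         # sample call rate 5/17 after autosomes
        codes[:9, 5] = -1          # locus 5: low call rate
        codes[:, 7] = 0            # locus 7: monomorphic
        pos = 1_000_000 + 100_000 * np.arange(20)
        lmap = LocusMap(chrom, np.array([f"s{i}" for i in range(20)], object),
                        pos, np.array(["A"] * 20, object),
                        np.array(["C"] * 20, object))
        table = GenotypeTable(np.array([f"i{k}" for k in range(10)], object),
                              np.array(["p"] * 10, object), codes)

        # independent recount, plain loops
        loci = [j for j in range(20) if 1 <= chrom[j] <= 31]
        samples = list(range(10))
        samples = [i for i in samples
                   if np.mean([codes[i, j] != -1 for j in loci]) >= 0.9]
        loci2 = [j for j in loci
                 if np.mean([codes[i, j] != -1 for i in samples]) >= 0.9]
        keep_loci = []
        for j in loci2:
            obs = [codes[i, j] for i in samples if codes[i, j] != -1]
            p = sum(obs) / (2.0 * len(obs))
            if min(p, 1 - p) >= 0.001:
                keep_loci.append(j)

        _, _, report = apply_filters(table, lmap, FilterParams())
        expected = [("input", 10, 20), ("autosomes", 10, len(loci)),
                    ("sample_call_rate", len(samples), len(loci)),
                    ("locus_call_rate", len(samples), len(loci2)),
                    ("maf", len(samples), len(keep_loci))]
        assert report.stages == expected

    def test_filtering_is_idempotent(self, rng):
        codes = rng.choice([-1, 0, 1, 2], size=(12, 30),
                           p=[0.05, 0.35, 0.3, 0.3]).astype(np.int8)
        table, lmap = make_dataset(codes)
        t1, m1, _ = apply_filters(table, lmap, FilterParams())
        t2, m2, r2 = apply_filters(t1, m1, FilterParams())
        assert np.array_equal(t1.codes, t2.codes)
        assert list(m1.locus_id) == list(m2.locus_id)
        # second pass removes nothing at any stage
        counts = {(ns, nl) for _, ns, nl in r2.stages}
        assert counts == {(t1.n_samples, t1.n_loci)}

    def test_report_counts_non_increasing_and_match_output(self, rng):
        codes = rng.choice([-1, 0, 1, 2], size=(8, 25),
                           p=[0.1, 0.3, 0.3, 0.3]).astype(np.int8)
        table, lmap = make_dataset(codes)
        out, outmap, report = apply_filters(table, lmap, FilterParams())
        ns = [s for _, s, _ in report.stages]
        nl = [l for _, _, l in report.stages]
        assert ns == sorted(ns, reverse=True)
        assert nl == sorted(nl, reverse=True)
        assert report.stages[-1][1:] == (out.n_samples, outmap.n_loci)

    def test_all_removed_raises(self):
        codes = np.full((3, 4), -1, dtype=np.int8)
        table, lmap = make_dataset(codes)
        with pytest.raises(EmptyResultError):
            apply_filters(table, lmap, FilterParams())


def test_maf_ignores_missing_genotypes():
    codes = np.array([[0], [2], [-1], [1]], dtype=np.int8)
    # non-missing alleles: 0,0 / 2 alt,alt / het -> p_alt = 3/6
    assert minor_allele_frequencies(codes)[0] == pytest.approx(0.5)
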
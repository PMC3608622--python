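"""Generator contracts: determinism, planted statistics, read-model round trips."""

import numpy as np
import pytest

from rescan import digestion, simdata
from rescan._util import revcomp
from rescan.errors import ConfigurationError, IncompatibleReferenceError, InvalidParameterError


class TestGenReference:
    def test_deterministic_and_named(self):
        g1 = simdata.gen_reference(2, [1000, 2000], seed=7)
        g2 = simdata.gen_reference(2, [1000, 2000], seed=7)
        assert g1.chromosomes == g2.chromosomes
        assert list(g1.chromosomes) == ["chr1", "chr2"]
        assert g1.lengths == {"chr1": 1000, "chr2": 2000}
        g3 = simdata.gen_reference(2, [1000, 2000], seed=8)
        assert g3.chromosomes != g1.chromosomes

    @pytest.mark.parametrize("lengths", [[0], [-5], [100, 0]])
    def test_nonpositive_length_rejected(self, lengths):
        with pytest.raises(InvalidParameterError):
            simdata.gen_reference(len(lengths), lengths, seed=1)

    def test_site_frequency_matches_iid_expectation(self):
        # P(CATG at a position) = 4^-4 for i.i.d. uniform bases
        L = 2_000_000
        genome = simdata.gen_reference(1, [L], seed=11)
        from rescan._util import find_sites

        observed = len(find_sites(genome.chromosomes["chr1"], "CATG"))
        expected = L / 256
        assert abs(observed - expected) / expected < 0.05


class TestPlantFounders:
    def test_zero_rate_identical_to_reference(self):
        ref = simdata.gen_reference(1, [10_000], seed=3)
        founders, truth = simdata.plant_founders(ref, 2, 0.0, seed=4)
        assert all(not f.variants for f in founders)
        assert founders[0].sequence("chr1") == ref.chromosomes["chr1"]

    def test_rate_bounds_enforced(self):
        ref = simdata.gen_reference(1, [1000], seed=3)
        for bad in (-1e-4, 0.01, 0.5):
            with pytest.raises(InvalidParameterError):
                simdata.plant_founders(ref, 1, bad, seed=1)

    def test_planted_count_binomial(self):
        ref = simdata.gen_reference(1, [1_000_000], seed=5)
        founders, _ = simdata.plant_founders(ref, 3, 1e-4, seed=6)
        mean, sd = 100.0, np.sqrt(1_000_000 * 1e-4 * (1 - 1e-4))
        for f in founders:
            assert abs(len(f.variants) - mean) < 3 * sd

    def test_alt_base_never_reference(self):
        ref = simdata.gen_reference(1, [50_000], seed=5)
        founders, _ = simdata.plant_founders(ref, 1, 1e-3, seed=6)
        for (chrom, pos), alt in founders[0].variants.items():
            assert alt != ref.chromosomes[chrom][pos]

    def test_seed_determinism(self):
        ref = simdata.gen_reference(1, [100_000], seed=5)
        a, _ = simdata.plant_founders(ref, 2, 1e-4, seed=9)
        b, _ = simdata.plant_founders(ref, 2, 1e-4, seed=9)
        c, _ = simdata.plant_founders(ref, 2, 1e-4, seed=10)
        assert [f.variants for f in a] == [f.variants for f in b]
        assert [f.variants for f in a] != [f.variants for f in c]


@pytest.fixture(scope="module")
def parents():
    ref = simdata.gen_reference(1, [200_000], seed=21)
    founders, _ = simdata.plant_founders(ref, 2, 5e-4, seed=22)
    return founders


class TestSimulateCross:

    def test_zero_rate_single_parent_genome(self, parents):
        child = simdata.simulate_cross(parents[0], parents[1], 0.0, seed=1)
        (segs,) = child.origin_track.values()
        assert len(segs) == 1
        parent = {p.cultivar_id: p for p in parents}[segs[0][2]]
        assert child.variants == parent.variants

    def test_child_allele_matches_origin_parent(self, parents):
        child = simdata.simulate_cross(parents[0], parents[1], 5.0, seed=2)
        by_id = {p.cultivar_id: p for p in parents}
        for chrom, segs in child.origin_track.items():
            for start, end, pid in segs:
                origin, other = by_id[pid], by_id[[p.cultivar_id for p in parents if p.cultivar_id != pid][0]]
                for (c, pos), alt in origin.variants.items():
                    if c == chrom and start <= pos < end:
                        assert child.variants.get((c, pos)) == alt
                # positions variant only in the non-origin parent stay reference
                for (c, pos), alt in other.variants.items():
                    if c == chrom and start <= pos < end and (c, pos) not in origin.variants:
                        assert (c, pos) not in child.variants

    def test_origin_track_partitions_chromosome(self, parents):
        child = simdata.simulate_cross(parents[0], parents[1], 3.0, seed=3)
        for chrom, segs in child.origin_track.items():
            assert segs[0][0] == 0
            assert segs[-1][1] == parents[0].reference.lengths[chrom]
            for (s0, e0, _), (s1, _e1, _) in zip(segs, segs[1:]):
                assert e0 == s1 and s0 < e0

    def test_breakpoint_count_poisson(self):
        ref = simdata.Genome({"chr1": "ACGT" * 1_250_000})  # 5 Mb
        a = simdata.CultivarGenome("a", ref)
        b = simdata.CultivarGenome("b", ref)
        counts = []
        for s in range(300):
            child = simdata.simulate_cross(a, b, 2.0, seed=s)
            counts.append(len(child.origin_track["chr1"]) - 1)
        lam = 10.0
        assert abs(np.mean(counts) - lam) < 3 * np.sqrt(lam / len(counts))

    def test_incompatible_references_rejected(self, parents):
        other_ref = simdata.gen_reference(1, [200_000], seed=99)
        alien = simdata.CultivarGenome("alien", other_ref)
        with pytest.raises(IncompatibleReferenceError):
            simdata.simulate_cross(parents[0], alien, 1.0, seed=1)


class TestLibraryDesign:
    def test_duplicate_or_ragged_barcodes_rejected(self):
        with pytest.raises(ConfigurationError):
            simdata.LibraryDesign(barcode_map={"a": "AAAAA", "b": "AAAAA"})
        with pytest.raises(ConfigurationError):
            simdata.LibraryDesign(barcode_map={"a": "AAAAA", "b": "CCCC"})

    def test_read_length_must_cover_barcode_and_site(self):
        with pytest.raises(ConfigurationError):
            simdata.LibraryDesign(barcode_map={"a": "AAAAA"}, read_length=9)


@pytest.fixture(scope="module")
def setup():
    ref = simdata.gen_reference(1, [600_000], seed=31)
    founders, truth = simdata.plant_founders(ref, 1, 1e-4, seed=32)
    cv = founders[0]
    design = simdata.LibraryDesign(barcode_map={cv.cultivar_id: "ACGTA"})
    return ref, cv, design


class TestRescanReads:

    def test_error_free_reads_round_trip_to_genome(self, setup):
        _ref, cv, design = setup
        reads = simdata.simulate_rescan_reads(cv, design, 2.0, 0.0, seed=33)
        seqs = {c: cv.sequence(c) for c in cv.reference.chromosomes}
        assert reads
        for rid, seq, qual in reads[:2000]:
            cid, chrom, pos, strand = rid.split(":")[:4]
            body = seq[design.barcode_length :]
            assert body.startswith(design.site)
            assert len(seq) == len(qual)
            p = int(pos)
            if strand == "F":
                assert seqs[chrom][p : p + len(body)] == body
            else:
                assert revcomp(seqs[chrom][p + 4 - len(body) : p + 4]) == body

    def test_read_count_matches_retained_end_expectation(self, setup):
        _ref, cv, design = setup
        mean_depth = 30.0
        reads = simdata.simulate_rescan_reads(cv, design, mean_depth, 0.0, seed=34)
        inv = digestion.digest(cv.genome(), design.site)
        profile = digestion.retention_profile("sharp", *design.insert_window)
        recs = inv.records
        lengths = inv.lengths
        retained = profile.probability(lengths) == 1.0
        n_ends = 0
        chrom_len = {c: len(s) for c, s in cv.reference.chromosomes.items()}
        for keep, chrom, s, e in zip(retained, recs["chrom"], recs["start"], recs["end"]):
            if keep:
                n_ends += (1 if s > 0 else 0) + (1 if e < chrom_len[chrom] else 0)
        expected = n_ends * mean_depth
        assert abs(len(reads) - expected) / expected < 0.05

    def test_gel_retains_more_in_window_reads_than_spri(self, setup):
        _ref, cv, design = setup
        inv = digestion.digest(cv.genome(), design.site)
        fracs = {}
        for prof in ("gel", "spri"):
            d = simdata.LibraryDesign(
                barcode_map=design.barcode_map, retention_profile=prof
            )
            reads = simdata.simulate_rescan_reads(cv, d, 3.0, 0.0, seed=35)
            lens = digestion.attribute_reads_to_fragments([r[0] for r in reads], inv)
            fracs[prof] = ((lens >= 200) & (lens <= 300)).mean()
        assert fracs["gel"] > fracs["spri"]

    def test_fastq_output_byte_identical_across_runs(self, setup, tmp_path):
        _ref, cv, design = setup
        p1, p2 = tmp_path / "a.fastq", tmp_path / "b.fastq"
        for p in (p1, p2):
            simdata.write_fastq(
                simdata.simulate_rescan_reads(cv, design, 2.0, 0.003, seed=36), p
            )
        assert p1.read_bytes() == p2.read_bytes()

    def test_error_rate_bound_enforced(self, setup):
        _ref, cv, design = setup
        with pytest.raises(InvalidParameterError):
            simdata.simulate_rescan_reads(cv, design, 2.0, 0.2, seed=1)


def test_truth_table_json_round_trip(tmp_path):
    ref = simdata.gen_reference(1, [50_000], seed=41)
    _, panel, truth, _ = simdata.simulate_panel(
        41, n_chromosomes=1, chromosome_length=50_000, n_founders=2, n_crosses=1
    )
    path = tmp_path / "truth.json"
    truth.to_json(path)
    loaded = simdata.TruthTable.from_json(path)
    assert loaded.variants == truth.variants
    assert loaded.pedigree == truth.pedigree
    assert loaded.origins == truth.origins
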
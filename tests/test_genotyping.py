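"""Anchored alignment and the SNP-calling filter chain."""

import numpy as np
import pandas as pd
import pytest

from rescan import genotyping, readproc, simdata
from rescan._util import BASE_INDEX, revcomp
from rescan.errors import UndefinedStatisticError
from rescan.genotyping import ALT, MISSING, REF


def _design(ids=("s1",), read_length=50):
    return simdata.LibraryDesign(
        barcode_map={cid: bc for cid, bc in zip(ids, simdata.make_barcodes(len(ids)))},
        read_length=read_length,
    )


def make_gm(calls, cultivars=None, breadth_bp=1_000_000):
    """GenotypeMatrix straight from a call array (loci x cultivars)."""
    calls = np.asarray(calls, dtype=np.int8)
    n_loci, n_cult = calls.shape
    cultivars = cultivars or [f"c{i}" for i in range(n_cult)]
    return genotyping.GenotypeMatrix(
        loci=pd.DataFrame(
            {
                "chrom": ["chr1"] * n_loci,
                "pos": np.arange(n_loci) * 1000,
                "ref": ["A"] * n_loci,
                "alt": ["C"] * n_loci,
            }
        ),
        calls=pd.DataFrame(calls, columns=cultivars),
        depth=pd.DataFrame(np.full_like(calls, 10, dtype=np.int32), columns=cultivars),
        gq=pd.DataFrame(np.full_like(calls, 99, dtype=float), columns=cultivars),
        breadth_bp=pd.Series({c: breadth_bp for c in cultivars}),
    )


class TestAnchorIndex:
    def test_truncated_terminal_anchors(self):
        genome = simdata.Genome({"chr1": "AAACATGCCC"})
        idx = genotyping.build_anchor_index(genome, _design(read_length=14))  # span 9
        by = {(a.strand): a for a in idx.anchors}
        assert by["F"].seq == "CATGCCC" and by["F"].truncated
        assert by["R"].seq == "CATGTTT" and by["R"].truncated
        assert all(a.seq.startswith("CATG") for a in idx.anchors)

    def test_two_anchors_per_occurrence(self):
        genome = simdata.gen_reference(1, [50_000], seed=3)
        from rescan._util import find_sites

        n_sites = len(find_sites(genome.chromosomes["chr1"], "CATG"))
        idx = genotyping.build_anchor_index(genome, _design())
        assert len(idx.anchors) == 2 * n_sites

    def test_deterministic(self):
        genome = simdata.gen_reference(1, [20_000], seed=5)
        a = genotyping.build_anchor_index(genome, _design())
        b = genotyping.build_anchor_index(genome, _design())
        assert a.anchors == b.anchors


@pytest.fixture(scope="module")
def indexed():
    genome = simdata.gen_reference(1, [100_000], seed=7)
    design = _design()
    return genome, design, genotyping.build_anchor_index(genome, design)


class TestAlignReads:

    def _forward_anchor(self, idx):
        return next(a for a in idx.anchors if a.strand == "F" and not a.truncated)

    def test_error_free_read_maps_exactly(self, indexed):
        _genome, _design_, idx = indexed
        anchor = self._forward_anchor(idx)
        sr = readproc.SampleReads("s1", [("r1", anchor.seq, "I" * len(anchor.seq))])
        cov = genotyping.align_reads(sr, idx)
        assert cov.counters == {"aligned": 1, "unaligned": 0, "ambiguous": 0}
        ref_base = anchor.seq[10]
        assert cov.counts["chr1"][BASE_INDEX[ref_base], anchor.site_pos + 10] == 1

    def test_substitution_lands_at_correct_reference_coordinate(self, indexed):
        _genome, _design_, idx = indexed
        anchor = self._forward_anchor(idx)
        offset = 20
        original = anchor.seq[offset]
        sub = "ACGT"[(BASE_INDEX[original] + 1) % 4]
        read = anchor.seq[:offset] + sub + anchor.seq[offset + 1 :]
        sr = readproc.SampleReads("s1", [("r1", read, "I" * len(read))])
        cov = genotyping.align_reads(sr, idx)
        assert cov.counters["aligned"] == 1
        assert cov.counts["chr1"][BASE_INDEX[sub], anchor.site_pos + offset] == 1
        assert cov.counts["chr1"][BASE_INDEX[original], anchor.site_pos + offset] == 0

    def test_reverse_read_contributes_complemented_bases(self, indexed):
        genome, design, idx = indexed
        anchor = next(a for a in idx.anchors if a.strand == "R" and not a.truncated)
        sr = readproc.SampleReads("s1", [("r1", anchor.seq, "I" * len(anchor.seq))])
        cov = genotyping.align_reads(sr, idx)
        assert cov.counters["aligned"] == 1
        seq = genome.chromosomes["chr1"]
        end = anchor.site_pos + 4
        for ref_pos in (end - 1, end - 10, end - len(anchor.seq)):
            assert cov.counts["chr1"][BASE_INDEX[seq[ref_pos]], ref_pos] == 1

    def test_too_many_mismatches_unaligned(self, indexed):
        _genome, _design_, idx = indexed
        anchor = self._forward_anchor(idx)
        read = anchor.seq[:4] + "".join(
            "ACGT"[(BASE_INDEX[b] + 1) % 4] for b in anchor.seq[4:12]
        ) + anchor.seq[12:]
        sr = readproc.SampleReads("s1", [("r1", read, "I" * len(read))])
        cov = genotyping.align_reads(sr, idx, max_mismatch=3)
        assert cov.counters["unaligned"] == 1

    def test_duplicated_locus_is_ambiguous(self):
        unit = "TTAGGCCTTA" * 2 + "CATG" + "GATTACAGGT" * 5
        genome = simdata.Genome({"chr1": unit + unit})
        design = _design()
        idx = genotyping.build_anchor_index(genome, design)
        fwd = next(a for a in idx.anchors if a.strand == "F" and not a.truncated)
        sr = readproc.SampleReads("s1", [("r1", fwd.seq, "I" * len(fwd.seq))])
        cov = genotyping.align_reads(sr, idx)
        assert cov.counters["ambiguous"] == 1
        assert cov.counts["chr1"].sum() == 0


@pytest.fixture(scope="module")
def ref():
    return simdata.Genome({"chr1": "A" * 100})


class TestCallVariants:
    def _coverage(self, ref, spec):
        """spec: {cultivar: [(chrom, pos, base, count, q)]}."""
        covs = {}
        for cid, entries in spec.items():
            cov = genotyping.SiteCoverage.empty(ref.lengths)
            for chrom, pos, base, count, q in entries:
                b = BASE_INDEX[base]
                cov.counts[chrom][b, pos] += count
                cov.qualsum[chrom][b, pos] += count * q
            covs[cid] = cov
        return covs

    def test_clean_alt_vs_ref_matches_hand_likelihood(self, ref):
        covs = self._coverage(
            ref,
            {
                "alt10": [("chr1", 10, "C", 10, 30)],
                "ref10": [("chr1", 10, "A", 10, 30)],
            },
        )
        gm = genotyping.call_variants(covs, ref)
        assert gm.n_loci == 1
        assert gm.loci.iloc[0]["ref"] == "A" and gm.loci.iloc[0]["alt"] == "C"
        assert gm.calls.iloc[0]["alt10"] == ALT
        assert gm.calls.iloc[0]["ref10"] == REF
        # hand oracle: GQ = 10 * n * log10((1 - e) / (e / 3)), e = 1e-3 (floor)
        e = 1e-3
        expected_gq = 10 * 10 * np.log10((1 - e) / (e / 3))
        assert gm.gq.iloc[0]["alt10"] == pytest.approx(expected_gq, rel=1e-9)

    def test_depth_three_call_is_missing(self, ref):
        covs = self._coverage(
            ref,
            {
                "thin": [("chr1", 10, "C", 3, 30)],
                "alt": [("chr1", 10, "C", 10, 30)],
                "refc": [("chr1", 10, "A", 10, 30)],
            },
        )
        gm = genotyping.call_variants(covs, ref)
        assert gm.n_loci == 1
        assert gm.calls.iloc[0]["thin"] == MISSING
        assert gm.calls.iloc[0]["alt"] == ALT

    def test_mixed_bases_ambiguous_in_inbred(self, ref):
        covs = self._coverage(
            ref,
            {
                "mixed": [("chr1", 10, "C", 6, 30), ("chr1", 10, "A", 4, 30)],
                "alt": [("chr1", 10, "C", 10, 30)],
                "refc": [("chr1", 10, "A", 10, 30)],
            },
        )
        gm = genotyping.call_variants(covs, ref)
        assert gm.calls.iloc[0]["mixed"] == MISSING

    def test_all_reference_position_not_emitted(self, ref):
        covs = self._coverage(
            ref, {"a": [("chr1", 10, "A", 10, 30)], "b": [("chr1", 10, "A", 8, 30)]}
        )
        gm = genotyping.call_variants(covs, ref)
        assert gm.n_loci == 0

    def test_single_class_locus_not_emitted(self, ref):
        # both cultivars ALT, nobody REF -> fails the two-genotype-class rule
        covs = self._coverage(
            ref, {"a": [("chr1", 10, "C", 10, 30)], "b": [("chr1", 10, "C", 10, 30)]}
        )
        gm = genotyping.call_variants(covs, ref)
        assert gm.n_loci == 0
        assert gm.filter_counts["too_few_classes"] == 1

    def test_conflicting_alt_bases_dropped_as_multiallelic(self, ref):
        covs = self._coverage(
            ref,
            {
                "a": [("chr1", 10, "C", 10, 30)],
                "b": [("chr1", 10, "G", 10, 30)],
                "c": [("chr1", 10, "A", 10, 30)],
            },
        )
        gm = genotyping.call_variants(covs, ref)
        assert gm.n_loci == 0
        assert gm.filter_counts["multiallelic"] == 1

    def test_raising_min_depth_never_adds_calls(self, clean_run):
        scored = []
        for min_depth in (2, 4, 8, 16):
            cfg = genotyping.FilterConfig(min_depth=min_depth)
            gm = genotyping.call_variants(clean_run.coverages, clean_run.ref, cfg)
            scored.append(int((gm.calls.to_numpy() != MISSING).sum()))
        assert scored == sorted(scored, reverse=True)


class TestMatrixStats:
    def test_printed_density_arithmetic(self):
        assert genotyping.snp_density(861, 16.7) == 5.2
        assert genotyping.snp_density(1910, 11.5) == 16.6
        assert genotyping.snp_density(0, 5.0) == 0.0
        with pytest.raises(UndefinedStatisticError):
            genotyping.snp_density(10, 0.0)

    def test_density_stats_consistent_with_breadth(self, clean_run):
        per_cultivar, per_chrom = genotyping.density_stats(clean_run.gm, clean_run.ref.lengths)
        for row in per_cultivar.itertuples(index=False):
            n = int((clean_run.gm.calls[row.cultivar] == ALT).sum())
            assert row.snps == n
            breadth_mb = clean_run.gm.breadth_bp[row.cultivar] / 1e6
            assert row.snps_per_100kb == genotyping.snp_density(n, breadth_mb)
        assert per_chrom["snps"].sum() == clean_run.gm.n_loci

    def test_missingness_hand_counts(self):
        calls = np.zeros((2, 45), dtype=np.int8)
        calls[0, :9] = MISSING  # locus 0 missing in 9 of 45
        miss = genotyping.missingness(make_gm(calls))
        assert miss["per_locus"].iloc[0] == pytest.approx(0.2)
        assert miss["per_locus"].iloc[1] == 0.0
        total = (calls == MISSING).sum() / calls.size
        assert miss["per_locus"].mean() == pytest.approx(total)

    def test_complete_matrix_has_zero_missingness(self):
        miss = genotyping.missingness(make_gm(np.ones((3, 4), dtype=np.int8)))
        assert miss["locus_summary"]["max"] == 0.0


class TestSerialization:
    def test_tsv_round_trip(self, clean_run, tmp_path):
        path = tmp_path / "gm.tsv"
        clean_run.gm.to_tsv(path)
        loaded = genotyping.GenotypeMatrix.from_tsv(path)
        assert loaded.loci.equals(clean_run.gm.loci)
        assert (loaded.calls.to_numpy() == clean_run.gm.calls.to_numpy()).all()
        assert (loaded.depth.to_numpy() == clean_run.gm.depth.to_numpy()).all()
        assert loaded.breadth_bp.to_dict() == {
            k: int(v) for k, v in clean_run.gm.breadth_bp.items()
        }

    def test_vcf_positions_one_based_and_parseable(self, clean_run, tmp_path):
        path = tmp_path / "calls.vcf"
        clean_run.gm.to_vcf(path)
        lines = [l for l in path.read_text().splitlines() if not l.startswith("#")]
        assert len(lines) == clean_run.gm.n_loci
        first = lines[0].split("\t")
        assert int(first[1]) == int(clean_run.gm.loci.iloc[0]["pos"]) + 1
        assert first[3] != first[4]
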
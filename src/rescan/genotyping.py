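"""Site-anchored alignment, pileup, and SNP calling for inbred panels.

Because every RESCAN read starts at a restriction site, full alignment is
unnecessary: the reference is indexed at its site occurrences (two anchors
per occurrence, one per strand) and each read is compared against the
candidate anchors retrieved through offset-matched seed k-mers. Calls use a
homozygous substitution model (the panel is inbred): per sample and position
the likelihoods of "all reads drawn from base b" are compared between the
reference base and the modal non-reference base, giving a phred-scaled
genotype quality; the filter chain applies a minimum per-sample depth, a
minimum genotype quality, an in-sample ambiguity rule, a minimum site
quality, and a minimum number of genotype classes across the panel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._util import ASCII_TO_INDEX, BASES, revcomp, seq_to_indices
from .errors import DataIntegrityError, InvalidParameterError, UndefinedStatisticError
from .readproc import SampleReads
from .simdata import Genome, LibraryDesign

__all__ = [
    "REF",
    "ALT",
    "MISSING",
    "Anchor",
    "AnchorIndex",
    "SiteCoverage",
    "FilterConfig",
    "GenotypeMatrix",
    "build_anchor_index",
    "align_reads",
    "call_variants",
    "density_stats",
    "snp_density",
    "missingness",
]

REF = 0
ALT = 1
MISSING = -1

_SEED_K = 16
_SEED_OFFSETS = (0, 16, 32)
_COMP = {0: 3, 1: 2, 2: 1, 3: 0}


@dataclass(frozen=True)
class Anchor:
    """One mappable read start: (chromosome, site position, orientation).

    Forward anchors read site + following bases; reverse anchors are the
    reverse complement of the preceding bases + site, which again begins
    with the site (CATG is its own reverse complement). Anchors that would
    run past a chromosome terminus are truncated and flagged.
    """

    chrom: str
    site_pos: int
    strand: str  # "F" or "R"
    seq: str
    truncated: bool


@dataclass
class AnchorIndex:
    anchors: list[Anchor]
    seed_map: dict[tuple[int, str], list[int]]
    site: str
    anchor_length: int
    chrom_lengths: dict[str, int]


def build_anchor_index(ref: Genome, design: LibraryDesign) -> AnchorIndex:
    """Index every site occurrence of the reference as <=2 anchors."""
    from ._util import find_sites

    site = design.site
    slen = len(site)
    alen = design.anchor_length
    anchors: list[Anchor] = []
    seed_map: dict[tuple[int, str], list[int]] = {}

    def _add(anchor: Anchor) -> None:
        idx = len(anchors)
        anchors.append(anchor)
        for off in _SEED_OFFSETS:
            if off >= len(anchor.seq):
                continue
            key = (off, anchor.seq[off : off + _SEED_K])
            seed_map.setdefault(key, []).append(idx)

    for chrom, seq in ref.chromosomes.items():
        L = len(seq)
        for p in find_sites(seq, site):
            fwd = seq[p : p + alen]
            _add(Anchor(chrom, p, "F", fwd, len(fwd) < alen))
            rev = revcomp(seq[max(0, p + slen - alen) : p + slen])
            _add(Anchor(chrom, p, "R", rev, len(rev) < alen))
    return AnchorIndex(
        anchors=anchors,
        seed_map=seed_map,
        site=site,
        anchor_length=alen,
        chrom_lengths=ref.lengths,
    )


@dataclass
class SiteCoverage:
    """Dense per-position base counts and summed base qualities for one sample."""

    counts: dict[str, np.ndarray]  # (4, L) uint16 per chromosome
    qualsum: dict[str, np.ndarray]  # (4, L) uint32 per chromosome
    counters: dict[str, int] = field(
        default_factory=lambda: {"aligned": 0, "unaligned": 0, "ambiguous": 0}
    )

    @classmethod
    def empty(cls, chrom_lengths: dict[str, int]) -> "SiteCoverage":
        return cls(
            counts={c: np.zeros((4, L), dtype=np.uint16) for c, L in chrom_lengths.items()},
            qualsum={c: np.zeros((4, L), dtype=np.uint32) for c, L in chrom_lengths.items()},
        )

    def depth(self, chrom: str) -> np.ndarray:
        return self.counts[chrom].sum(axis=0, dtype=np.int64)

    def breadth(self) -> int:
        """Sequenced-base breadth: reference positions with depth >= 1."""
        return int(sum((self.depth(c) > 0).sum() for c in self.counts))


def align_reads(sr: SampleReads, idx: AnchorIndex, max_mismatch: int = 3) -> SiteCoverage:
    """Align one sample's reads to the anchor index and pile up coverage.

    Candidates are the union of offset-matched seed hits; the alignment is
    the candidate with the fewest mismatches over the full overlap, accepted
    only if unique and within `max_mismatch`. Reverse-orientation alignments
    contribute complemented bases at reverse-mapped coordinates.
    """
    cov = SiteCoverage.empty(idx.chrom_lengths)
    anchors = idx.anchors
    seed_map = idx.seed_map
    min_overlap = len(idx.site) + 4

    per_anchor: dict[int, list[tuple[str, str]]] = {}
    for _rid, seq, qual in sr.reads:
        cand: set[int] = set()
        for off in _SEED_OFFSETS:
            if off >= len(seq):
                break
            hits = seed_map.get((off, seq[off : off + _SEED_K]))
            if hits:
                cand.update(hits)
        best_mm = max_mismatch + 1
        best_ids: list[int] = []
        for aid in cand:
            aseq = anchors[aid].seq
            overlap = min(len(seq), len(aseq))
            if overlap < min_overlap:
                continue
            if seq[:overlap] == aseq[:overlap]:
                mm = 0
            else:
                mm = sum(a != b for a, b in zip(seq[:overlap], aseq[:overlap]))
            if mm < best_mm:
                best_mm = mm
                best_ids = [aid]
            elif mm == best_mm:
                best_ids.append(aid)
        if best_mm > max_mismatch or not best_ids:
            cov.counters["unaligned"] += 1
        elif len(best_ids) > 1:
            cov.counters["ambiguous"] += 1
        else:
            cov.counters["aligned"] += 1
            aid = best_ids[0]
            overlap = min(len(seq), len(anchors[aid].seq))
            per_anchor.setdefault(aid, []).append((seq[:overlap], qual[:overlap]))

    for aid, pairs in per_anchor.items():
        _accumulate(cov, anchors[aid], pairs, len(idx.site))
    return cov


def _accumulate(
    cov: SiteCoverage, anchor: Anchor, pairs: list[tuple[str, str]], slen: int
) -> None:
    by_len: dict[int, list[tuple[str, str]]] = {}
    for seq, qual in pairs:
        by_len.setdefault(len(seq), []).append((seq, qual))
    counts = cov.counts[anchor.chrom]
    qualsum = cov.qualsum[anchor.chrom]
    for w, group in by_len.items():
        seqs = "".join(s for s, _ in group)
        quals = "".join(q for _, q in group)
        arr = ASCII_TO_INDEX[np.frombuffer(seqs.encode("ascii"), dtype=np.uint8)].reshape(
            len(group), w
        )
        qarr = (np.frombuffer(quals.encode("ascii"), dtype=np.uint8) - 33).reshape(
            len(group), w
        )
        for b in range(4):
            mask = arr == b
            col = mask.sum(axis=0)
            if not col.any():
                continue
            qcol = (mask * qarr).sum(axis=0)
            if anchor.strand == "F":
                start = anchor.site_pos
                counts[b, start : start + w] += col.astype(np.uint16)
                qualsum[b, start : start + w] += qcol.astype(np.uint32)
            else:
                end = anchor.site_pos + slen
                counts[_COMP[b], end - w : end] += col[::-1].astype(np.uint16)
                qualsum[_COMP[b], end - w : end] += qcol[::-1].astype(np.uint32)


@dataclass(frozen=True)
class FilterConfig:
    """The SNP filter chain: minimum overall (site) quality 20, minimum
    per-sample depth 4, minimum conditional genotype quality 20, and at
    least two genotype classes across the panel."""

    min_site_quality: float = 20.0
    min_depth: int = 4
    min_genotype_quality: float = 20.0
    min_genotype_classes: int = 2
    base_error_floor: float = 1e-3
    max_minor_fraction: float = 0.2

    def __post_init__(self) -> None:
        if min(self.min_site_quality, self.min_depth, self.min_genotype_quality) < 0:
            raise InvalidParameterError("thresholds must be >= 0")
        if not 0 < self.base_error_floor < 0.5:
            raise InvalidParameterError("base_error_floor out of range")


@dataclass
class GenotypeMatrix:
    """Sites x cultivars calls in {REF, ALT, MISSING} plus depth/GQ and
    per-cultivar sequenced-base breadth."""

    loci: pd.DataFrame  # chrom, pos (0-based), ref, alt
    calls: pd.DataFrame  # int8, columns = cultivars
    depth: pd.DataFrame
    gq: pd.DataFrame
    breadth_bp: pd.Series
    filter_counts: dict[str, int] = field(default_factory=dict)

    @property
    def cultivars(self) -> list[str]:
        return list(self.calls.columns)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def subset(self, mask) -> "GenotypeMatrix":
        mask = np.asarray(mask)
        return GenotypeMatrix(
            loci=self.loci.loc[mask].reset_index(drop=True),
            calls=self.calls.loc[mask].reset_index(drop=True),
            depth=self.depth.loc[mask].reset_index(drop=True),
            gq=self.gq.loc[mask].reset_index(drop=True),
            breadth_bp=self.breadth_bp,
            filter_counts=dict(self.filter_counts),
        )

    def to_vcf(self, path) -> None:
        """Minimal VCF 4.2: haploid GT with DP and GQ per sample."""
        cultivars = self.cultivars
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
            fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">\n')
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
            fh.write("\t".join(cultivars) + "\n")
            calls = self.calls.to_numpy()
            depth = self.depth.to_numpy()
            gq = self.gq.to_numpy()
            for i, row in enumerate(self.loci.itertuples(index=False)):
                alt_gqs = gq[i][calls[i] == ALT]
                qual = int(round(alt_gqs.max())) if alt_gqs.size else 0
                fields = [
                    row.chrom, str(row.pos + 1), ".", row.ref, row.alt,
                    str(qual), "PASS", ".", "GT:DP:GQ",
                ]
                for j in range(len(cultivars)):
                    if calls[i, j] == MISSING:
                        fields.append(f".:{depth[i, j]}:.")
                    else:
                        fields.append(f"{calls[i, j]}:{depth[i, j]}:{int(round(gq[i, j]))}")
                fh.write("\t".join(fields) + "\n")

    def to_tsv(self, path) -> None:
        cultivars = self.cultivars
        with open(path, "w") as fh:
            fh.write("#breadth_bp\t" + "\t".join(f"{c}={int(self.breadth_bp[c])}" for c in cultivars) + "\n")
            fh.write("chrom\tpos\tref\talt\t" + "\t".join(cultivars) + "\n")
            calls = self.calls.to_numpy()
            depth = self.depth.to_numpy()
            gq = self.gq.to_numpy()
            for i, row in enumerate(self.loci.itertuples(index=False)):
                cells = [
                    ("." if calls[i, j] == MISSING else str(calls[i, j]))
                    + f"|{depth[i, j]}|{gq[i, j]:.0f}"
                    for j in range(len(cultivars))
                ]
                fh.write(f"{row.chrom}\t{row.pos}\t{row.ref}\t{row.alt}\t" + "\t".join(cells) + "\n")

    @classmethod
    def from_tsv(cls, path) -> "GenotypeMatrix":
        with open(path) as fh:
            header = fh.readline().rstrip("\n")
            if not header.startswith("#breadth_bp"):
                raise DataIntegrityError("genotype matrix TSV missing breadth header")
            breadth = {}
            for item in header.split("\t")[1:]:
                cid, val = item.split("=")
                breadth[cid] = int(val)
            cols = fh.readline().rstrip("\n").split("\t")
            cultivars = cols[4:]
            loci_rows, call_rows, depth_rows, gq_rows = [], [], [], []
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                loci_rows.append((parts[0], int(parts[1]), parts[2], parts[3]))
                crow, drow, qrow = [], [], []
                for cell in parts[4:]:
                    call, dp, gq = cell.split("|")
                    crow.append(MISSING if call == "." else int(call))
                    drow.append(int(dp))
                    qrow.append(float(gq))
                call_rows.append(crow)
                depth_rows.append(drow)
                gq_rows.append(qrow)
        return cls(
            loci=pd.DataFrame(loci_rows, columns=["chrom", "pos", "ref", "alt"]),
            calls=pd.DataFrame(call_rows, columns=cultivars, dtype=np.int8),
            depth=pd.DataFrame(depth_rows, columns=cultivars, dtype=np.int32),
            gq=pd.DataFrame(gq_rows, columns=cultivars),
            breadth_bp=pd.Series(breadth),
        )


def call_variants(
    coverages: dict[str, SiteCoverage], ref: Genome, cfg: FilterConfig | None = None
) -> GenotypeMatrix:
    """Call SNPs against the reference from all cultivars' pileups.

    Per cultivar and covered position the homozygous-model likelihoods
    L(b) = prod over reads of (1 - e_i if base_i == b else e_i / 3) are
    evaluated for b in {reference base, modal non-reference base}, with e_i
    from the base quality floored at `base_error_floor`. The call is the
    argmax; GQ is the phred-scaled likelihood ratio. A call is MISSING when
    depth < min_depth, GQ < min_genotype_quality, or the two most frequent
    bases both exceed `max_minor_fraction` of reads (ambiguous in an inbred).
    A locus is emitted when at least one cultivar is called ALT with a single
    alternate base across the panel, the site quality (max GQ among ALT
    calls) reaches min_site_quality, and at least `min_genotype_classes`
    call classes occur across cultivars.
    """
    if cfg is None:
        cfg = FilterConfig()
    if not coverages:
        raise InvalidParameterError("need coverage from at least one cultivar")
    cultivars = list(coverages)
    for cov in coverages.values():
        if set(cov.counts) != set(ref.chromosomes):
            raise DataIntegrityError("coverage chromosomes disagree with the reference")

    chrom_records = []
    filter_counts = {
        "candidates": 0,
        "no_alt_call": 0,
        "multiallelic": 0,
        "low_site_quality": 0,
        "too_few_classes": 0,
        "emitted": 0,
    }

    for chrom, seq in ref.chromosomes.items():
        L = len(seq)
        ref_idx = seq_to_indices(seq)
        total = np.zeros((4, L), dtype=np.int64)
        for cov in coverages.values():
            total += cov.counts[chrom]
        ar = np.arange(L)
        nonref = total.sum(axis=0) - total[ref_idx, ar]
        cand = np.nonzero(nonref > 0)[0]
        if cand.size == 0:
            continue
        filter_counts["candidates"] += int(cand.size)
        m = cand.size
        arm = np.arange(m)
        rix = ref_idx[cand]

        calls = np.full((len(cultivars), m), MISSING, dtype=np.int8)
        gqs = np.zeros((len(cultivars), m))
        depths = np.zeros((len(cultivars), m), dtype=np.int32)
        alt_ix = np.zeros((len(cultivars), m), dtype=np.int8)

        for ci, cid in enumerate(cultivars):
            cnt = coverages[cid].counts[chrom][:, cand].astype(np.float64)
            qs = coverages[cid].qualsum[chrom][:, cand].astype(np.float64)
            depth = cnt.sum(axis=0)
            with np.errstate(divide="ignore", invalid="ignore"):
                qmean = np.where(cnt > 0, qs / np.maximum(cnt, 1), 0.0)
            e = np.clip(10.0 ** (-qmean / 10.0), cfg.base_error_floor, 0.75)
            log_match = np.log10(1.0 - e)
            log_mis = np.log10(e / 3.0)
            # unobserved bases contribute nothing
            log_match = np.where(cnt > 0, log_match, 0.0)
            log_mis_obs = np.where(cnt > 0, log_mis, 0.0)

            refc = cnt[rix, arm]
            tmp = cnt.copy()
            tmp[rix, arm] = -1.0
            aix = tmp.argmax(axis=0)
            altc = cnt[aix, arm]

            # start from "every read mismatches", then swap in the match term
            # for the hypothesis base
            base_ll = (cnt * log_mis_obs).sum(axis=0)
            ll_ref = base_ll + refc * (log_match[rix, arm] - log_mis_obs[rix, arm])
            ll_alt = base_ll + altc * (log_match[aix, arm] - log_mis_obs[aix, arm])

            gq = 10.0 * np.abs(ll_alt - ll_ref)
            call = np.where(ll_alt > ll_ref, ALT, REF).astype(np.int8)

            snt = np.sort(cnt, axis=0)
            second = snt[-2]
            ambiguous = (second > cfg.max_minor_fraction * depth) & (second > 0)
            missing = (depth < cfg.min_depth) | (gq < cfg.min_genotype_quality) | ambiguous
            call[missing] = MISSING

            calls[ci] = call
            gqs[ci] = gq
            depths[ci] = depth.astype(np.int32)
            alt_ix[ci] = aix.astype(np.int8)

        alt_mask = calls == ALT
        has_alt = alt_mask.any(axis=0)
        filter_counts["no_alt_call"] += int((~has_alt).sum())

        # single alternate base across the panel
        alt_of_callers = np.where(alt_mask, alt_ix, -1)
        n_alt_bases = np.array(
            [len(set(alt_of_callers[:, j][alt_of_callers[:, j] >= 0])) for j in range(m)]
        )
        multi = has_alt & (n_alt_bases > 1)
        filter_counts["multiallelic"] += int(multi.sum())

        site_q = np.where(alt_mask, gqs, -np.inf).max(axis=0)
        low_q = has_alt & ~multi & (site_q < cfg.min_site_quality)
        filter_counts["low_site_quality"] += int(low_q.sum())

        n_classes = (calls == REF).any(axis=0).astype(int) + has_alt.astype(int)
        few = has_alt & ~multi & ~low_q & (n_classes < cfg.min_genotype_classes)
        filter_counts["too_few_classes"] += int(few.sum())

        emit = has_alt & ~multi & ~low_q & ~few
        idx_emit = np.nonzero(emit)[0]
        for j in idx_emit:
            alt_b = int(alt_of_callers[:, j].max())
            chrom_records.append(
                (
                    chrom,
                    int(cand[j]),
                    seq[cand[j]],
                    BASES[alt_b],
                    calls[:, j].copy(),
                    depths[:, j].copy(),
                    gqs[:, j].copy(),
                )
            )
    filter_counts["emitted"] = len(chrom_records)

    breadth = pd.Series({cid: cov.breadth() for cid, cov in coverages.items()})
    if chrom_records:
        loci = pd.DataFrame(
            [(r[0], r[1], r[2], r[3]) for r in chrom_records],
            columns=["chrom", "pos", "ref", "alt"],
        )
        calls_df = pd.DataFrame(
            np.stack([r[4] for r in chrom_records]), columns=cultivars
        ).astype(np.int8)
        depth_df = pd.DataFrame(np.stack([r[5] for r in chrom_records]), columns=cultivars)
        gq_df = pd.DataFrame(np.stack([r[6] for r in chrom_records]), columns=cultivars)
    else:
        loci = pd.DataFrame(columns=["chrom", "pos", "ref", "alt"])
        calls_df = pd.DataFrame(columns=cultivars, dtype=np.int8)
        depth_df = pd.DataFrame(columns=cultivars, dtype=np.int32)
        gq_df = pd.DataFrame(columns=cultivars)
    return GenotypeMatrix(
        loci=loci,
        calls=calls_df,
        depth=depth_df,
        gq=gq_df,
        breadth_bp=breadth,
        filter_counts=filter_counts,
    )


def snp_density(count: int, breadth_mb: float) -> float:
    """SNPs per sequenced 100 kb, reported to one decimal."""
    if breadth_mb <= 0:
        raise UndefinedStatisticError("zero sequenced breadth")
    return round(count / (breadth_mb * 10.0), 1)


def density_stats(
    gm: GenotypeMatrix, chrom_lengths: dict[str, int] | None = None
) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Per-cultivar (SNP count, breadth Mb, SNPs per sequenced 100 kb) and,
    when chromosome lengths are given, per-chromosome SNPs per Mb."""
    rows = []
    for cid in gm.cultivars:
        count = int((gm.calls[cid] == ALT).sum())
        breadth_mb = gm.breadth_bp[cid] / 1e6
        rows.append((cid, count, round(breadth_mb, 1), snp_density(count, breadth_mb)))
    per_cultivar = pd.DataFrame(
        rows, columns=["cultivar", "snps", "sequenced_mb", "snps_per_100kb"]
    )
    per_chrom = None
    if chrom_lengths is not None:
        counts = gm.loci["chrom"].value_counts()
        per_chrom = pd.DataFrame(
            [
                (c, int(counts.get(c, 0)), round(counts.get(c, 0) / (L / 1e6), 1))
                for c, L in chrom_lengths.items()
            ],
            columns=["chrom", "snps", "snps_per_mb"],
        )
    return per_cultivar, per_chrom


def missingness(gm: GenotypeMatrix) -> dict:
    """Per-locus and per-cultivar missing-data fractions with summaries."""
    if gm.n_loci == 0:
        raise UndefinedStatisticError("empty genotype matrix")
    miss = (gm.calls.to_numpy() == MISSING)
    per_locus = pd.Series(miss.mean(axis=1))
    per_cultivar = pd.Series(miss.mean(axis=0), index=gm.cultivars)

    def _summary(s: pd.Series) -> dict:
        return {
            "min": float(s.min()),
            "max": float(s.max()),
            "mean": float(s.mean()),
            "sd": float(s.std(ddof=1)) if len(s) > 1 else 0.0,
        }

    return {
        "per_locus": per_locus,
        "per_cultivar": per_cultivar,
        "locus_summary": _summary(per_locus),
        "cultivar_summary": _summary(per_cultivar),
    }
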
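"""Synthetic data generation for the RESCAN pipeline.

Emulates the study system end to end: a multi-chromosome reference genome, a
panel of fully inbred cultivars diverged from the reference at controlled SNP
rates, bi-parental inbred offspring carrying recombination mosaics (modeling
single-seed descent to fixation), and restriction-enzyme-phased, inline
barcoded, size-selected short reads (RESCAN libraries).

Every generator is deterministic given its seed, and the planted truth
(variants, parental-origin segments) is recorded so downstream calls can be
scored against it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from . import digestion
from ._util import BASES, error_rate_to_q, find_sites, phred_char, revcomp
from .errors import ConfigurationError, IncompatibleReferenceError, InvalidParameterError

__all__ = [
    "Genome",
    "CultivarGenome",
    "LibraryDesign",
    "TruthTable",
    "Read",
    "gen_reference",
    "plant_founders",
    "simulate_cross",
    "simulate_rescan_reads",
    "gen_annotation",
    "make_barcodes",
    "simulate_panel",
    "pooled_reads",
    "write_fastq",
    "read_fastq",
    "write_barcode_manifest",
    "write_pedigree_manifest",
]

_BASE_ARR = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class Genome:
    """A haploid reference: ordered map of chromosome name -> ACGT string."""

    chromosomes: dict[str, str]

    def __post_init__(self) -> None:
        if not self.chromosomes:
            raise InvalidParameterError("genome needs at least one chromosome")
        for name, seq in self.chromosomes.items():
            if not seq:
                raise InvalidParameterError(f"chromosome {name!r} is empty")
            if set(seq) - set(BASES):
                raise InvalidParameterError(f"chromosome {name!r} has non-ACGT characters")

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.chromosomes.items()}

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.chromosomes.values())

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for name, seq in self.chromosomes.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), 80):
                    fh.write(seq[i : i + 80] + "\n")

    @classmethod
    def from_fasta(cls, path) -> "Genome":
        chroms = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
        return cls(chroms)


@dataclass
class CultivarGenome:
    """A fully homozygous cultivar: reference plus a substitution set.

    `origin_track` (present for cross-derived cultivars) partitions each
    chromosome into half-open intervals labeled with the parent each segment
    was inherited from.
    """

    cultivar_id: str
    reference: Genome
    variants: dict[tuple[str, int], str] = field(default_factory=dict)
    parents: tuple[str, str] | None = None
    origin_track: dict[str, list[tuple[int, int, str]]] | None = None

    def __post_init__(self) -> None:
        lengths = self.reference.lengths
        for (chrom, pos), alt in self.variants.items():
            if chrom not in lengths or not (0 <= pos < lengths[chrom]):
                raise InvalidParameterError(f"variant {chrom}:{pos} outside reference bounds")
            if alt == self.reference.chromosomes[chrom][pos]:
                raise InvalidParameterError(f"variant {chrom}:{pos} equals the reference base")
        if self.origin_track is not None:
            for chrom, segs in self.origin_track.items():
                L = lengths[chrom]
                expect = 0
                for start, end, _parent in segs:
                    if start != expect:
                        raise InvalidParameterError(f"origin track gap/overlap at {chrom}:{start}")
                    expect = end
                if expect != L:
                    raise InvalidParameterError(f"origin track does not cover {chrom}")

    def sequence(self, chrom: str) -> str:
        seq = bytearray(self.reference.chromosomes[chrom], "ascii")
        for (c, pos), alt in self.variants.items():
            if c == chrom:
                seq[pos] = ord(alt)
        return seq.decode("ascii")

    def genome(self) -> Genome:
        return Genome({c: self.sequence(c) for c in self.reference.chromosomes})


@dataclass(frozen=True)
class LibraryDesign:
    """RESCAN library parameters.

    The read layout mirrors the adapter chemistry: a 5-bp inline barcode is
    sequenced first, the restriction site (reconstituted at ligation) follows,
    then genomic sequence, for `read_length` bases in total. `insert_window`
    is the targeted fragment size range *before* adapter ligation.
    """

    barcode_map: dict[str, str]
    site: str = "CATG"
    read_length: int = 50
    insert_window: tuple[int, int] = (200, 300)
    retention_profile: str = "sharp"

    def __post_init__(self) -> None:
        barcodes = list(self.barcode_map.values())
        if len(set(barcodes)) != len(barcodes):
            raise ConfigurationError("barcodes are not unique")
        if not barcodes:
            raise ConfigurationError("barcode map is empty")
        blens = {len(b) for b in barcodes}
        if len(blens) != 1:
            raise ConfigurationError("barcodes differ in length")
        if any(set(b) - set(BASES) for b in barcodes):
            raise ConfigurationError("barcodes must be ACGT-only")
        if not self.site or set(self.site) - set(BASES):
            raise ConfigurationError("enzyme site must be non-empty ACGT")
        if self.read_length <= self.barcode_length + len(self.site):
            raise ConfigurationError("read_length must exceed barcode + site length")
        low, high = self.insert_window
        if not low < high:
            raise ConfigurationError("insert window low must be < high")

    @property
    def barcode_length(self) -> int:
        return len(next(iter(self.barcode_map.values())))

    @property
    def anchor_length(self) -> int:
        """Genomic bases per read (site included): read_length - barcode_length."""
        return self.read_length - self.barcode_length


@dataclass
class TruthTable:
    """Planted ground truth for a simulated panel."""

    variants: dict[str, dict[tuple[str, int], str]] = field(default_factory=dict)
    origins: dict[str, dict[str, list[tuple[int, int, str]]]] = field(default_factory=dict)
    pedigree: dict[str, tuple[str, str]] = field(default_factory=dict)
    seed: int | None = None

    def record(self, cultivar: CultivarGenome) -> None:
        self.variants[cultivar.cultivar_id] = dict(cultivar.variants)
        if cultivar.origin_track is not None:
            self.origins[cultivar.cultivar_id] = {
                c: list(segs) for c, segs in cultivar.origin_track.items()
            }
        if cultivar.parents is not None:
            self.pedigree[cultivar.cultivar_id] = cultivar.parents

    def to_json(self, path) -> None:
        payload = {
            "seed": self.seed,
            "variants": {
                cid: {f"{c}:{p}": a for (c, p), a in vs.items()}
                for cid, vs in self.variants.items()
            },
            "origins": self.origins,
            "pedigree": {k: list(v) for k, v in self.pedigree.items()},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "TruthTable":
        with open(path) as fh:
            payload = json.load(fh)

        def _key(s: str) -> tuple[str, int]:
            chrom, pos = s.rsplit(":", 1)
            return chrom, int(pos)

        return cls(
            variants={
                cid: {_key(k): a for k, a in vs.items()}
                for cid, vs in payload["variants"].items()
            },
            origins={
                cid: {c: [tuple(s) for s in segs] for c, segs in tracks.items()}
                for cid, tracks in payload["origins"].items()
            },
            pedigree={k: tuple(v) for k, v in payload["pedigree"].items()},
            seed=payload.get("seed"),
        )


Read = tuple[str, str, str]  # (id, sequence, phred+33 quality string)


def gen_reference(n_chromosomes: int, lengths: list[int], seed: int) -> Genome:
    """I.i.d.-uniform ACGT reference with chromosomes named chr1..chrN."""
    if n_chromosomes != len(lengths):
        raise InvalidParameterError("n_chromosomes must match len(lengths)")
    if any(L <= 0 for L in lengths):
        raise InvalidParameterError("chromosome lengths must be positive")
    rng = np.random.default_rng(seed)
    chroms = {}
    for i, L in enumerate(lengths, start=1):
        idx = rng.integers(0, 4, size=L, dtype=np.uint8)
        chroms[f"chr{i}"] = _BASE_ARR[idx].tobytes().decode("ascii")
    return Genome(chroms)


def plant_founders(
    ref: Genome,
    n: int,
    snp_rate: float,
    seed: int,
    ids: list[str] | None = None,
) -> tuple[list[CultivarGenome], TruthTable]:
    """Independent inbred founders diverged from the reference.

    Each founder carries Binomial(L, snp_rate) substitutions per chromosome,
    alternate bases drawn uniformly from the three non-reference bases.
    """
    if not 0 <= snp_rate < 0.01:
        raise InvalidParameterError("snp_rate must be in [0, 0.01)")
    if n < 1:
        raise InvalidParameterError("need at least one founder")
    if ids is None:
        ids = [f"founder{i + 1}" for i in range(n)]
    if len(ids) != n:
        raise InvalidParameterError("ids must match n")
    rng = np.random.default_rng(seed)
    truth = TruthTable(seed=seed)
    founders = []
    for cid in ids:
        variants: dict[tuple[str, int], str] = {}
        for chrom, seq in ref.chromosomes.items():
            L = len(seq)
            k = rng.binomial(L, snp_rate)
            if k == 0:
                continue
            positions = np.sort(rng.choice(L, size=k, replace=False))
            shifts = rng.integers(1, 4, size=k)
            for pos, shift in zip(positions.tolist(), shifts.tolist()):
                ref_base = seq[pos]
                variants[(chrom, pos)] = BASES[(BASES.index(ref_base) + shift) % 4]
        founder = CultivarGenome(cultivar_id=cid, reference=ref, variants=variants)
        founders.append(founder)
        truth.record(founder)
    return founders, truth


def simulate_cross(
    parent_a: CultivarGenome,
    parent_b: CultivarGenome,
    breakpoint_rate: float,
    seed: int,
    child_id: str | None = None,
) -> CultivarGenome:
    """Inbred bi-parental offspring as an alternating parental mosaic.

    Breakpoints per chromosome are Poisson(rate_per_Mb x length); the mosaic
    starts from a fair-coin parent and the child carries the origin parent's
    allele at every position (homozygous, modeling fixation by single-seed
    descent).
    """
    if parent_a.reference is not parent_b.reference and (
        parent_a.reference.chromosomes != parent_b.reference.chromosomes
    ):
        raise IncompatibleReferenceError("parents are defined on different references")
    if breakpoint_rate < 0:
        raise InvalidParameterError("breakpoint_rate must be non-negative")
    rng = np.random.default_rng(seed)
    ref = parent_a.reference
    if child_id is None:
        child_id = f"{parent_a.cultivar_id}x{parent_b.cultivar_id}"
    variants: dict[tuple[str, int], str] = {}
    origin_track: dict[str, list[tuple[int, int, str]]] = {}
    by_parent = {parent_a.cultivar_id: parent_a, parent_b.cultivar_id: parent_b}
    order = [parent_a.cultivar_id, parent_b.cultivar_id]
    for chrom, seq in ref.chromosomes.items():
        L = len(seq)
        n_bp = rng.poisson(breakpoint_rate * L / 1e6)
        bps = sorted(set(rng.integers(1, L, size=n_bp).tolist())) if n_bp else []
        first = int(rng.integers(0, 2))
        bounds = [0, *bps, L]
        segs = []
        for i in range(len(bounds) - 1):
            parent = order[(first + i) % 2]
            segs.append((bounds[i], bounds[i + 1], parent))
        origin_track[chrom] = segs
        for start, end, parent in segs:
            for (c, pos), alt in by_parent[parent].variants.items():
                if c == chrom and start <= pos < end:
                    variants[(c, pos)] = alt
    return CultivarGenome(
        cultivar_id=child_id,
        reference=ref,
        variants=variants,
        parents=(parent_a.cultivar_id, parent_b.cultivar_id),
        origin_track=origin_track,
    )


def simulate_rescan_reads(
    cultivar: CultivarGenome,
    design: LibraryDesign,
    mean_depth: float,
    error_rate: float,
    seed: int,
) -> list[Read]:
    """Simulate single-end RESCAN reads from one cultivar's library.

    The cultivar genome (not the reference) is digested at enzyme-site
    occurrences, cutting immediately after the site on the top strand.
    Fragments are retained stochastically under the design's size-selection
    profile evaluated on the pre-ligation fragment length. Each retained
    fragment yields reads from its site-bearing ends (terminal fragments:
    internal end only) at Poisson(mean_depth) coverage per end, with equal
    end probability by construction. A read is barcode + site + adjacent
    genomic bases; right-hand (reverse) ends are reverse-complemented, which
    again starts with the site because the site is its own reverse complement.
    Substitution errors are i.i.d. at `error_rate` over the whole read, and
    the uniform phred+33 qualities encode that rate.

    Read ids carry the truth: cultivar:chrom:site_position:strand:serial
    (suffix ":trunc" when the read was truncated at a fragment end).
    """
    if not 0 <= error_rate < 0.1:
        raise InvalidParameterError("error_rate must be in [0, 0.1)")
    if cultivar.cultivar_id not in design.barcode_map:
        raise ConfigurationError(f"no barcode for cultivar {cultivar.cultivar_id!r}")
    rng = np.random.default_rng(seed)
    barcode = design.barcode_map[cultivar.cultivar_id]
    site = design.site
    slen = len(site)
    alen = design.anchor_length
    profile = digestion.retention_profile(design.retention_profile, *design.insert_window)
    q = error_rate_to_q(error_rate)
    qchar = phred_char(q)

    reads: list[Read] = []
    serial = 0
    for chrom in cultivar.reference.chromosomes:
        seq = cultivar.sequence(chrom)
        L = len(seq)
        cuts = [p + slen for p in find_sites(seq, site) if 0 < p + slen < L]
        bounds = [0, *cuts, L]
        starts = np.asarray(bounds[:-1])
        ends = np.asarray(bounds[1:])
        lengths = ends - starts
        keep = rng.random(len(lengths)) < profile.probability(lengths)
        for s, e, retained in zip(starts.tolist(), ends.tolist(), keep.tolist()):
            if not retained:
                continue
            ends_here = []
            if s > 0:  # left end bears the site at [s-slen, s)
                ends_here.append("F")
            if e < L:  # right end bears the site at [e-slen, e)
                ends_here.append("R")
            if not ends_here:
                continue
            n_reads = rng.poisson(mean_depth * len(ends_here))
            which = rng.integers(0, len(ends_here), size=n_reads)
            for w in which.tolist():
                strand = ends_here[w]
                if strand == "F":
                    a = s - slen
                    gseq = seq[a : min(a + alen, e)]
                    site_pos = a
                else:
                    left_limit = s - slen if s > 0 else 0
                    a = max(e - alen, left_limit)
                    gseq = revcomp(seq[a:e])
                    site_pos = e - slen
                trunc = len(gseq) < alen
                rid = f"{cultivar.cultivar_id}:{chrom}:{site_pos}:{strand}:{serial}"
                if trunc:
                    rid += ":trunc"
                reads.append((rid, barcode + gseq, qchar * (len(barcode) + len(gseq))))
                serial += 1

    if error_rate > 0 and reads:
        reads = _apply_errors(reads, error_rate, rng)
    return reads


def _apply_errors(reads: list[Read], error_rate: float, rng: np.random.Generator) -> list[Read]:
    n_err = rng.binomial([len(s) for _, s, _ in reads], error_rate)
    out: list[Read] = []
    for (rid, seq, qual), k in zip(reads, n_err.tolist()):
        if k:
            positions = rng.choice(len(seq), size=k, replace=False)
            shifts = rng.integers(1, 4, size=k)
            b = bytearray(seq, "ascii")
            for pos, shift in zip(positions.tolist(), shifts.tolist()):
                b[pos] = ord(BASES[(BASES.index(chr(b[pos])) + shift) % 4])
            seq = b.decode("ascii")
        out.append((rid, seq, qual))
    return out


def gen_annotation(
    genome: Genome,
    path,
    seed: int,
    mean_gene_length: int = 3000,
    genic_fraction: float = 0.45,
    utr5_length: int = 150,
    utr3_length: int = 250,
) -> int:
    """Write a synthetic GFF3 gene annotation for `genome`; returns gene count.

    Non-overlapping gene models (gene/mRNA/five_prime_UTR/exon/three_prime_UTR)
    are placed along each chromosome until roughly `genic_fraction` of the
    sequence is genic; each gene has 1-5 exons with the UTRs inside the
    terminal exons. Purely synthetic plumbing for annotation-overlap analyses.
    """
    rng = np.random.default_rng(seed)
    n_genes = 0
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom, seq in genome.chromosomes.items():
            L = len(seq)
            fh.write(f"##sequence-region {chrom} 1 {L}\n")
            cursor = int(rng.integers(200, 2000))
            while cursor < L - mean_gene_length:
                glen = int(rng.integers(mean_gene_length // 2, mean_gene_length * 2))
                if cursor + glen >= L:
                    break
                gstart, gend = cursor + 1, cursor + glen  # GFF3 1-based inclusive
                n_genes += 1
                gid = f"gene{n_genes}"
                fh.write(f"{chrom}\trescan_sim\tgene\t{gstart}\t{gend}\t.\t+\t.\tID={gid}\n")
                fh.write(
                    f"{chrom}\trescan_sim\tmRNA\t{gstart}\t{gend}\t.\t+\t.\t"
                    f"ID={gid}.1;Parent={gid}\n"
                )
                n_exons = int(rng.integers(1, 6))
                edges = np.sort(rng.choice(np.arange(1, glen), size=2 * n_exons - 2, replace=False)) if n_exons > 1 else np.array([], dtype=int)
                bounds = [0, *edges.tolist(), glen]
                exons = [(bounds[2 * i], bounds[2 * i + 1]) for i in range(n_exons)]
                if exons[0][1] - exons[0][0] < utr5_length + 10:
                    exons[0] = (exons[0][0], exons[0][0] + utr5_length + 10)
                if exons[-1][1] - exons[-1][0] < utr3_length + 10:
                    exons[-1] = (max(exons[-1][1] - utr3_length - 10, exons[-2][1] if n_exons > 1 else 0), exons[-1][1])
                fh.write(
                    f"{chrom}\trescan_sim\tfive_prime_UTR\t{gstart + exons[0][0]}\t"
                    f"{gstart + exons[0][0] + utr5_length - 1}\t.\t+\t.\tParent={gid}.1\n"
                )
                for estart, eend in exons:
                    fh.write(
                        f"{chrom}\trescan_sim\texon\t{gstart + estart}\t"
                        f"{gstart + eend - 1}\t.\t+\t.\tParent={gid}.1\n"
                    )
                fh.write(
                    f"{chrom}\trescan_sim\tthree_prime_UTR\t{gstart + exons[-1][1] - utr3_length}\t"
                    f"{gstart + exons[-1][1] - 1}\t.\t+\t.\tParent={gid}.1\n"
                )
                gap = int(glen * (1 - genic_fraction) / max(genic_fraction, 1e-6))
                cursor += glen + max(200, int(rng.integers(gap // 2 + 1, gap + 2)))
    return n_genes


def make_barcodes(n: int, length: int = 5) -> list[str]:
    """`n` distinct ACGT barcodes, spread evenly over the barcode space so
    pairwise Hamming distances are generally > 1."""
    from itertools import product

    space = 4**length
    if n > space:
        raise InvalidParameterError("barcode space too small")
    all_codes = ["".join(p) for p in product(BASES, repeat=length)]
    step = space // n
    return [all_codes[i * step] for i in range(n)]


def simulate_panel(
    seed: int,
    n_chromosomes: int = 2,
    chromosome_length: int = 1_000_000,
    n_founders: int = 3,
    n_crosses: int = 3,
    snp_rate: float = 1e-4,
    breakpoint_rate: float = 2.0,
    site: str = "CATG",
    read_length: int = 50,
    barcode_length: int = 5,
    insert_window: tuple[int, int] = (200, 300),
    retention_profile: str = "sharp",
) -> tuple[Genome, list[CultivarGenome], TruthTable, LibraryDesign]:
    """One call that sets up a whole study panel: reference, founders,
    bi-parental crosses (cross k = founder k x founder k+1, cyclic), truth
    table, and a barcoded library design."""
    ref = gen_reference(n_chromosomes, [chromosome_length] * n_chromosomes, seed)
    founders, truth = plant_founders(ref, n_founders, snp_rate, seed + 1)
    truth.seed = seed
    panel = list(founders)
    if n_crosses:
        cross_seeds = _spawn_seeds(seed + 2, n_crosses)
        for k in range(n_crosses):
            child = simulate_cross(
                founders[k % n_founders],
                founders[(k + 1) % n_founders],
                breakpoint_rate,
                cross_seeds[k],
                child_id=f"cross{k + 1}",
            )
            panel.append(child)
            truth.record(child)
    design = LibraryDesign(
        barcode_map=dict(
            zip([c.cultivar_id for c in panel], make_barcodes(len(panel), barcode_length))
        ),
        site=site,
        read_length=read_length,
        insert_window=insert_window,
        retention_profile=retention_profile,
    )
    return ref, panel, truth, design


def pooled_reads(
    panel: list[CultivarGenome],
    design: LibraryDesign,
    mean_depth: float,
    error_rate: float,
    seed: int,
) -> list[Read]:
    """Pool one RESCAN library per cultivar, each with its own derived seed."""
    seeds = _spawn_seeds(seed, len(panel))
    pooled: list[Read] = []
    for cultivar, s in zip(panel, seeds):
        pooled.extend(simulate_rescan_reads(cultivar, design, mean_depth, error_rate, s))
    return pooled


def _spawn_seeds(seed: int, n: int) -> list[int]:
    return [int(s) & 0x7FFFFFFF for s in np.random.SeedSequence(seed).generate_state(n)]


def write_fastq(reads: list[Read], path) -> None:
    with open(path, "w") as fh:
        for rid, seq, qual in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")


def read_fastq(path) -> list[Read]:
    with open(path) as fh:
        return [(rid, seq, qual) for rid, seq, qual in FastqGeneralIterator(fh)]


def write_barcode_manifest(design: LibraryDesign, path) -> None:
    with open(path, "w") as fh:
        fh.write("cultivar\tbarcode\n")
        for cid, bc in design.barcode_map.items():
            fh.write(f"{cid}\t{bc}\n")


def write_pedigree_manifest(truth: TruthTable, path) -> None:
    with open(path, "w") as fh:
        fh.write("child\tparent_a\tparent_b\n")
        for child, (pa, pb) in truth.pedigree.items():
            fh.write(f"{child}\t{pa}\t{pb}\n")
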
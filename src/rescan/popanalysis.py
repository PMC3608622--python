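"""Panel-level SNP analyses: frequency binning, haplotype maps and blocks,
pedigree parental-origin assignment, annotation overlap, and genotype
concordance.

All operations consume the GenotypeMatrix produced by the genotyping module.
The panel is inbred, so calls are treated as haplotypes throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InvalidParameterError, UndefinedStatisticError
from .genotyping import ALT, MISSING, REF, GenotypeMatrix

__all__ = [
    "BinThresholds",
    "OriginClassification",
    "bin_snp_frequency",
    "haplotype_map",
    "detect_blocks",
    "assign_pedigree_origin",
    "annotate_snps",
    "concordance",
    "render_haplotype_map",
]

#: per-SNP origin labels at child-ALT loci
SHARED, FROM_A, FROM_B, UNEXPLAINED, PARENT_MISSING = (
    "SHARED",
    "FROM_A",
    "FROM_B",
    "UNEXPLAINED",
    "PARENT_MISSING",
)


@dataclass(frozen=True)
class BinThresholds:
    """Carrier-count bin edges: <= rare_max rare, <= medium_max medium, else
    common (counts of exactly rare_max/medium_max use the closed-left
    convention; the field's wording leaves the edges open)."""

    rare_max: int = 15
    medium_max: int = 30

    def __post_init__(self) -> None:
        if not 0 < self.rare_max < self.medium_max:
            raise InvalidParameterError("need 0 < rare_max < medium_max")


def bin_snp_frequency(
    gm: GenotypeMatrix, thresholds: BinThresholds | None = None
) -> tuple[pd.Series, pd.DataFrame]:
    """Categorize each locus by how many cultivars carry the alternate
    allele, and give each cultivar's composition over the categories of its
    own ALT loci."""
    if gm.n_loci == 0:
        raise UndefinedStatisticError("empty genotype matrix")
    if thresholds is None:
        thresholds = BinThresholds()
    alt_counts = (gm.calls.to_numpy() == ALT).sum(axis=1)
    category = pd.Series(
        np.select(
            [alt_counts <= thresholds.rare_max, alt_counts <= thresholds.medium_max],
            ["rare", "medium"],
            default="common",
        )
    )
    rows = []
    for cid in gm.cultivars:
        is_alt = (gm.calls[cid] == ALT).to_numpy()
        n = int(is_alt.sum())
        if n == 0:
            rows.append((cid, 0, 0.0, 0.0, 0.0))
            continue
        frac = category[is_alt].value_counts(normalize=True)
        rows.append(
            (cid, n, float(frac.get("rare", 0)), float(frac.get("medium", 0)), float(frac.get("common", 0)))
        )
    composition = pd.DataFrame(
        rows, columns=["cultivar", "n_alt_loci", "rare", "medium", "common"]
    )
    return category, composition


def haplotype_map(gm: GenotypeMatrix) -> pd.DataFrame:
    """Per-cultivar haplotype states along the genome.

    Long-format frame (chrom, pos, cultivar, state) with state MONOMORPHIC
    for reference calls, VARIANT for alternate calls, MISSING otherwise —
    the direct analogue of a blue/red/white haplotype map.
    """
    order = np.lexsort((gm.loci["pos"].to_numpy(), gm.loci["chrom"].to_numpy()))
    state_names = {REF: "MONOMORPHIC", ALT: "VARIANT", MISSING: "MISSING"}
    frames = []
    for cid in gm.cultivars:
        frames.append(
            pd.DataFrame(
                {
                    "chrom": gm.loci["chrom"].to_numpy()[order],
                    "pos": gm.loci["pos"].to_numpy()[order],
                    "cultivar": cid,
                    "state": [state_names[c] for c in gm.calls[cid].to_numpy()[order]],
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def detect_blocks(
    track: pd.DataFrame, min_snps: int = 3, max_gap: int = 500_000
) -> pd.DataFrame:
    """Haplotype blocks: maximal runs of VARIANT states per cultivar and
    chromosome with at least `min_snps` loci and consecutive loci at most
    `max_gap` bp apart. MISSING states are transparent: they neither break a
    run nor count toward `min_snps`.
    """
    if min_snps < 2:
        raise InvalidParameterError("min_snps must be >= 2")
    blocks = []
    for (cid, chrom), grp in track.groupby(["cultivar", "chrom"], sort=False):
        grp = grp.sort_values("pos")
        run_positions: list[int] = []
        for pos, state in zip(grp["pos"], grp["state"]):
            if state == "MISSING":
                continue
            if state == "VARIANT":
                if run_positions and pos - run_positions[-1] > max_gap:
                    if len(run_positions) >= min_snps:
                        blocks.append((cid, chrom, run_positions[0], run_positions[-1] + 1, len(run_positions)))
                    run_positions = []
                run_positions.append(pos)
            else:  # MONOMORPHIC breaks the run
                if len(run_positions) >= min_snps:
                    blocks.append((cid, chrom, run_positions[0], run_positions[-1] + 1, len(run_positions)))
                run_positions = []
        if len(run_positions) >= min_snps:
            blocks.append((cid, chrom, run_positions[0], run_positions[-1] + 1, len(run_positions)))
    return pd.DataFrame(blocks, columns=["cultivar", "chrom", "start", "end", "n_snps"])


@dataclass
class OriginClassification:
    """Parental origin of one bi-parental cultivar's alternate alleles."""

    child: str
    parent_a: str
    parent_b: str
    labels: pd.DataFrame  # chrom, pos, label (one row per child-ALT locus)
    fractions: dict[str, float]  # over {SHARED, FROM_A, FROM_B, UNEXPLAINED}
    n_labeled: int
    n_parent_missing: int


def assign_pedigree_origin(
    gm: GenotypeMatrix, child: str, parent_a: str, parent_b: str
) -> OriginClassification:
    """Label each child-ALT locus by which parent(s) share the allele.

    Both parents ALT -> SHARED; one parent ALT -> FROM_A / FROM_B; neither
    -> UNEXPLAINED; any parent MISSING -> PARENT_MISSING (excluded from the
    summary denominator, reported separately — matching a fully-scored
    percentage breakdown).
    """
    for cid in (child, parent_a, parent_b):
        if cid not in gm.calls.columns:
            raise KeyError(f"cultivar {cid!r} not in the genotype matrix")
    c = gm.calls[child].to_numpy()
    a = gm.calls[parent_a].to_numpy()
    b = gm.calls[parent_b].to_numpy()
    child_alt = c == ALT
    label = np.full(len(c), "", dtype=object)
    label[child_alt & (a == MISSING)] = PARENT_MISSING
    label[child_alt & (b == MISSING)] = PARENT_MISSING
    scored = child_alt & (a != MISSING) & (b != MISSING)
    label[scored & (a == ALT) & (b == ALT)] = SHARED
    label[scored & (a == ALT) & (b == REF)] = FROM_A
    label[scored & (a == REF) & (b == ALT)] = FROM_B
    label[scored & (a == REF) & (b == REF)] = UNEXPLAINED

    labels = pd.DataFrame(
        {
            "chrom": gm.loci["chrom"][child_alt].to_numpy(),
            "pos": gm.loci["pos"][child_alt].to_numpy(),
            "label": label[child_alt],
        }
    )
    n_labeled = int(scored.sum())
    fractions = {}
    for name in (SHARED, FROM_A, FROM_B, UNEXPLAINED):
        fractions[name] = (
            float((label == name).sum() / n_labeled) if n_labeled else float("nan")
        )
    return OriginClassification(
        child=child,
        parent_a=parent_a,
        parent_b=parent_b,
        labels=labels,
        fractions=fractions,
        n_labeled=n_labeled,
        n_parent_missing=int((label == PARENT_MISSING).sum()),
    )


def annotate_snps(gm: GenotypeMatrix, gff3_path) -> dict[str, float]:
    """SNP composition over {five_prime_utr, three_prime_utr, exon, intron,
    intergenic} from a GFF3 annotation on the same reference.

    Each locus gets the most specific overlapping feature (UTR > exon >
    intron > intergenic); introns are gene/mRNA spans not covered by an exon.
    """
    import gffutils
    from intervaltree import IntervalTree

    with open(gff3_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise InvalidParameterError(
                    f"malformed GFF3 {gff3_path} line {lineno}: "
                    f"expected 9 tab-separated fields, got {len(fields)}"
                )
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError as exc:
                raise InvalidParameterError(
                    f"malformed GFF3 {gff3_path} line {lineno}: non-integer coordinates"
                ) from exc
            if start < 1 or end < start:
                raise InvalidParameterError(
                    f"malformed GFF3 {gff3_path} line {lineno}: bad interval {start}-{end}"
                )

    try:
        db = gffutils.create_db(
            str(gff3_path), ":memory:", merge_strategy="create_unique", keep_order=True
        )
    except Exception as exc:  # gffutils reports the offending line
        raise InvalidParameterError(f"malformed GFF3 {gff3_path}: {exc}") from exc

    trees: dict[str, dict[str, IntervalTree]] = {}

    def _tree(kind: str, chrom: str) -> IntervalTree:
        return trees.setdefault(kind, {}).setdefault(chrom, IntervalTree())

    kind_map = {
        "five_prime_UTR": "five_prime_utr",
        "three_prime_UTR": "three_prime_utr",
        "exon": "exon",
        "CDS": "exon",
        "gene": "gene",
        "mRNA": "gene",
    }
    for feat in db.all_features():
        kind = kind_map.get(feat.featuretype)
        if kind is None:
            continue
        # GFF3 is 1-based inclusive -> 0-based half-open
        _tree(kind, feat.seqid).addi(feat.start - 1, feat.end)

    priority = ["five_prime_utr", "three_prime_utr", "exon"]
    counts = {k: 0 for k in ("five_prime_utr", "three_prime_utr", "exon", "intron", "intergenic")}
    assignments = []
    for chrom, pos in zip(gm.loci["chrom"], gm.loci["pos"]):
        hit = None
        for kind in priority:
            if trees.get(kind, {}).get(chrom) and trees[kind][chrom][pos]:
                hit = kind
                break
        if hit is None:
            if trees.get("gene", {}).get(chrom) and trees["gene"][chrom][pos]:
                hit = "intron"
            else:
                hit = "intergenic"
        counts[hit] += 1
        assignments.append(hit)
    n = max(gm.n_loci, 1)
    fractions = {k: v / n for k, v in counts.items()}
    fractions["genic"] = 1.0 - fractions["intergenic"]
    fractions["_counts"] = counts  # type: ignore[assignment]
    return fractions


def concordance(calls_a, calls_b) -> tuple[int, int, float]:
    """(co-scored n, discordant n, error rate) between two genotype vectors
    over {REF, ALT, MISSING}; pairs with any MISSING are ignored."""
    a = np.asarray(calls_a)
    b = np.asarray(calls_b)
    if a.shape != b.shape:
        raise InvalidParameterError("genotype vectors differ in length")
    scored = (a != MISSING) & (b != MISSING)
    n = int(scored.sum())
    if n == 0:
        raise UndefinedStatisticError("no co-scored genotype pairs")
    discordant = int((a[scored] != b[scored]).sum())
    return n, discordant, discordant / n


def render_haplotype_map(track: pd.DataFrame, path, chrom: str | None = None) -> None:
    """Render a haplotype map figure (blue monomorphic, red variant, white
    missing), one row per cultivar."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import ListedColormap

    sub = track if chrom is None else track[track["chrom"] == chrom]
    cultivars = sub["cultivar"].unique()
    positions = np.sort(sub["pos"].unique())
    pos_ix = {p: i for i, p in enumerate(positions)}
    code = {"MISSING": 0, "MONOMORPHIC": 1, "VARIANT": 2}
    img = np.zeros((len(cultivars), len(positions)))
    for r, cid in enumerate(cultivars):
        rows = sub[sub["cultivar"] == cid]
        for p, s in zip(rows["pos"], rows["state"]):
            img[r, pos_ix[p]] = code[s]
    fig, ax = plt.subplots(figsize=(10, 0.3 * len(cultivars) + 1))
    ax.imshow(img, aspect="auto", cmap=ListedColormap(["white", "#3b6fb6", "#c0392b"]), interpolation="nearest")
    ax.set_yticks(range(len(cultivars)), cultivars, fontsize=6)
    ax.set_xlabel("SNP index" + (f" ({chrom})" if chrom else ""))
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
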
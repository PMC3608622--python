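"""Pipeline orchestration: stage runner over a single configuration.

Each stage reads its upstream artifacts from the output directory (raising a
DependencyError naming any missing file), runs the corresponding library
code, writes its outputs, and appends a machine-readable JSON run log with
the parameters and the counts at every filter. Stages are idempotent given
identical inputs and seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import yaml

from . import digestion, genotyping, phylogeny, popanalysis, readproc, simdata
from .errors import DependencyError, InvalidParameterError

__all__ = ["PipelineConfig", "run_stage", "run_all", "STAGES", "make_barcodes"]

STAGES = (
    "simulate",
    "digest",
    "demux",
    "call",
    "stats",
    "haplo",
    "pedigree",
    "phylo",
    "annotate",
    "report",
)


@dataclass
class PipelineConfig:
    out_dir: str = "rescan_run"
    seed: int = 1

    # simulation
    n_chromosomes: int = 2
    chromosome_length: int = 1_000_000
    n_founders: int = 3
    n_crosses: int = 3
    snp_rate: float = 1e-4
    breakpoint_rate: float = 2.0  # per Mb
    mean_depth: float = 20.0
    error_rate: float = 0.0

    # library design
    site: str = "CATG"
    read_length: int = 50
    barcode_length: int = 5
    insert_window: tuple[int, int] = (200, 300)
    retention_profile: str = "sharp"

    # alignment / calling
    max_mismatch: int = 3
    min_site_quality: float = 20.0
    min_depth: int = 4
    min_genotype_quality: float = 20.0
    min_genotype_classes: int = 2

    # downstream analyses
    rare_max: int = 15
    medium_max: int = 30
    block_min_snps: int = 3
    block_max_gap: int = 500_000
    min_scored: int | None = None  # default: half the panel, min 2
    annotation: str | None = None
    render_figures: bool = False

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise InvalidParameterError(f"unknown config keys: {sorted(unknown)}")
        if "insert_window" in raw:
            raw["insert_window"] = tuple(raw["insert_window"])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        payload = asdict(self)
        payload["insert_window"] = list(self.insert_window)
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh)

    # --- derived objects -------------------------------------------------
    @property
    def out(self) -> Path:
        return Path(self.out_dir)

    def design(self, cultivar_ids: list[str]) -> simdata.LibraryDesign:
        return simdata.LibraryDesign(
            barcode_map=dict(zip(cultivar_ids, make_barcodes(len(cultivar_ids), self.barcode_length))),
            site=self.site,
            read_length=self.read_length,
            insert_window=self.insert_window,
            retention_profile=self.retention_profile,
        )

    def filter_config(self) -> genotyping.FilterConfig:
        return genotyping.FilterConfig(
            min_site_quality=self.min_site_quality,
            min_depth=self.min_depth,
            min_genotype_quality=self.min_genotype_quality,
            min_genotype_classes=self.min_genotype_classes,
        )


make_barcodes = simdata.make_barcodes


def _require(path: Path) -> Path:
    if not path.exists():
        raise DependencyError(str(path))
    return path


def _log(cfg: PipelineConfig, stage: str, payload: dict) -> None:
    log_dir = cfg.out / "logs"
    log_dir.mkdir(parents=True, exist_ok=True)
    payload = {"stage": stage, "seed": cfg.seed, **payload}
    with open(log_dir / f"{stage}.json", "w") as fh:
        json.dump(payload, fh, indent=2, default=str)


def _load_design(cfg: PipelineConfig) -> simdata.LibraryDesign:
    import pandas as pd

    manifest = _require(cfg.out / "barcodes.tsv")
    bc = pd.read_csv(manifest, sep="\t")
    return simdata.LibraryDesign(
        barcode_map=dict(zip(bc["cultivar"], bc["barcode"])),
        site=cfg.site,
        read_length=cfg.read_length,
        insert_window=cfg.insert_window,
        retention_profile=cfg.retention_profile,
    )


# --- stages ---------------------------------------------------------------


def _stage_simulate(cfg: PipelineConfig) -> dict:
    out = cfg.out
    out.mkdir(parents=True, exist_ok=True)
    ref, panel, truth, design = simdata.simulate_panel(
        cfg.seed,
        n_chromosomes=cfg.n_chromosomes,
        chromosome_length=cfg.chromosome_length,
        n_founders=cfg.n_founders,
        n_crosses=cfg.n_crosses,
        snp_rate=cfg.snp_rate,
        breakpoint_rate=cfg.breakpoint_rate,
        site=cfg.site,
        read_length=cfg.read_length,
        barcode_length=cfg.barcode_length,
        insert_window=cfg.insert_window,
        retention_profile=cfg.retention_profile,
    )
    pooled = simdata.pooled_reads(panel, design, cfg.mean_depth, cfg.error_rate, cfg.seed + 3)
    per_cultivar: dict[str, int] = {}
    for rid, _seq, _qual in pooled:
        cid = rid.split(":", 1)[0]
        per_cultivar[cid] = per_cultivar.get(cid, 0) + 1
    ref.to_fasta(out / "ref.fasta")
    simdata.write_fastq(pooled, out / "reads.fastq")
    simdata.write_barcode_manifest(design, out / "barcodes.tsv")
    simdata.write_pedigree_manifest(truth, out / "pedigree.tsv")
    truth.to_json(out / "truth.json")
    return {
        "cultivars": [c.cultivar_id for c in panel],
        "n_reads": len(pooled),
        "reads_per_cultivar": per_cultivar,
        "planted_snps": {cid: len(v) for cid, v in truth.variants.items()},
    }


def _stage_digest(cfg: PipelineConfig) -> dict:
    ref = simdata.Genome.from_fasta(_require(cfg.out / "ref.fasta"))
    inv = digestion.digest(ref, cfg.site)
    inv.to_bed(cfg.out / "fragments.bed")
    inv.length_histogram().to_csv(cfg.out / "fragment_hist.tsv", sep="\t", index=False)
    low, high = cfg.insert_window
    frag_frac, len_frac, n_in = digestion.window_stats(inv, low, high)
    report = {
        "n_fragments": len(inv),
        "mean_length": float(inv.lengths.mean()),
        "window": [low, high],
        "in_window_fragment_fraction": frag_frac,
        "in_window_genome_fraction": len_frac,
        "in_window_count": n_in,
    }
    with open(cfg.out / "digest_report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    return report


def _stage_demux(cfg: PipelineConfig) -> dict:
    design = _load_design(cfg)
    reads = simdata.read_fastq(_require(cfg.out / "reads.fastq"))
    result = readproc.demultiplex(reads, design)
    demux_dir = cfg.out / "demux"
    demux_dir.mkdir(exist_ok=True)
    rows = []
    for cid, sr in result.samples.items():
        sr = readproc.quality_filter(sr)
        simdata.write_fastq(sr.reads, demux_dir / f"{cid}.fastq")
        rows.append({"cultivar": cid, **sr.counts})
    import pandas as pd

    pd.DataFrame(rows).to_csv(cfg.out / "demux_report.tsv", sep="\t", index=False)
    counts = result.counts
    counts["conserved"] = (
        counts["assigned"] + counts["rejected_no_site"] + counts["unassigned"]
        == counts["input"]
    )
    return counts


def _stage_call(cfg: PipelineConfig) -> dict:
    ref = simdata.Genome.from_fasta(_require(cfg.out / "ref.fasta"))
    design = _load_design(cfg)
    demux_dir = _require(cfg.out / "demux")
    idx = genotyping.build_anchor_index(ref, design)
    coverages = {}
    align_counts = {}
    for cid in design.barcode_map:
        fq = _require(demux_dir / f"{cid}.fastq")
        sr = readproc.SampleReads(cultivar_id=cid, reads=simdata.read_fastq(fq))
        cov = genotyping.align_reads(sr, idx, cfg.max_mismatch)
        coverages[cid] = cov
        align_counts[cid] = dict(cov.counters)
    gm = genotyping.call_variants(coverages, ref, cfg.filter_config())
    gm.to_vcf(cfg.out / "calls.vcf")
    gm.to_tsv(cfg.out / "genotype_matrix.tsv")
    return {
        "n_anchors": len(idx.anchors),
        "alignment": align_counts,
        "filter_counts": gm.filter_counts,
        "n_loci": gm.n_loci,
    }


def _stage_stats(cfg: PipelineConfig) -> dict:
    gm = genotyping.GenotypeMatrix.from_tsv(_require(cfg.out / "genotype_matrix.tsv"))
    ref = simdata.Genome.from_fasta(_require(cfg.out / "ref.fasta"))
    per_cultivar, per_chrom = genotyping.density_stats(gm, ref.lengths)
    per_cultivar.to_csv(cfg.out / "density.tsv", sep="\t", index=False)
    per_chrom.to_csv(cfg.out / "per_chrom_density.tsv", sep="\t", index=False)
    miss = genotyping.missingness(gm)
    with open(cfg.out / "missingness.json", "w") as fh:
        json.dump(
            {"per_cultivar": miss["per_cultivar"].to_dict(),
             "locus_summary": miss["locus_summary"],
             "cultivar_summary": miss["cultivar_summary"]},
            fh, indent=2,
        )
    thresholds = popanalysis.BinThresholds(cfg.rare_max, cfg.medium_max)
    category, composition = popanalysis.bin_snp_frequency(gm, thresholds)
    composition.to_csv(cfg.out / "bins.tsv", sep="\t", index=False)
    return {
        "n_loci": gm.n_loci,
        "missingness_mean": miss["locus_summary"]["mean"],
        "bin_counts": category.value_counts().to_dict(),
    }


def _stage_haplo(cfg: PipelineConfig) -> dict:
    gm = genotyping.GenotypeMatrix.from_tsv(_require(cfg.out / "genotype_matrix.tsv"))
    track = popanalysis.haplotype_map(gm)
    track.to_csv(cfg.out / "haplotype_track.tsv", sep="\t", index=False)
    blocks = popanalysis.detect_blocks(track, cfg.block_min_snps, cfg.block_max_gap)
    blocks.to_csv(cfg.out / "blocks.tsv", sep="\t", index=False)
    if cfg.render_figures:
        popanalysis.render_haplotype_map(track, cfg.out / "haplotype_map.png")
    return {"n_states": len(track), "n_blocks": len(blocks)}


def _stage_pedigree(cfg: PipelineConfig) -> dict:
    import pandas as pd

    gm = genotyping.GenotypeMatrix.from_tsv(_require(cfg.out / "genotype_matrix.tsv"))
    pedigree = pd.read_csv(_require(cfg.out / "pedigree.tsv"), sep="\t")
    rows = []
    for row in pedigree.itertuples(index=False):
        oc = popanalysis.assign_pedigree_origin(gm, row.child, row.parent_a, row.parent_b)
        rows.append(
            {
                "child": row.child,
                "parent_a": row.parent_a,
                "parent_b": row.parent_b,
                "n_labeled": oc.n_labeled,
                "n_parent_missing": oc.n_parent_missing,
                **{k.lower(): v for k, v in oc.fractions.items()},
            }
        )
    pd.DataFrame(rows).to_csv(cfg.out / "origin_summary.tsv", sep="\t", index=False)
    return {"n_triples": len(rows)}


def _stage_phylo(cfg: PipelineConfig) -> dict:
    gm = genotyping.GenotypeMatrix.from_tsv(_require(cfg.out / "genotype_matrix.tsv"))
    min_scored = cfg.min_scored
    if min_scored is None:
        min_scored = max(2, len(gm.cultivars) // 2)
    informative = phylogeny.select_informative(gm, min_scored)
    dm = phylogeny.chord_distance(informative)
    dm.to_frame().to_csv(cfg.out / "distances.tsv", sep="\t")
    tree = phylogeny.neighbor_joining(dm)
    tree.write(str(cfg.out / "tree.nwk"))
    return {
        "min_scored": min_scored,
        "n_informative_loci": informative.n_loci,
        "n_taxa": len(dm.ids),
    }


def _stage_annotate(cfg: PipelineConfig) -> dict:
    gm = genotyping.GenotypeMatrix.from_tsv(_require(cfg.out / "genotype_matrix.tsv"))
    if cfg.annotation is not None:
        gff = _require(Path(cfg.annotation))
        n_genes = None
    else:
        ref = simdata.Genome.from_fasta(_require(cfg.out / "ref.fasta"))
        gff = cfg.out / "annotation.gff3"
        n_genes = simdata.gen_annotation(ref, gff, cfg.seed + 7)
    fractions = popanalysis.annotate_snps(gm, gff)
    counts = fractions.pop("_counts")
    with open(cfg.out / "annotation_composition.json", "w") as fh:
        json.dump({"fractions": fractions, "counts": counts}, fh, indent=2)
    return {"n_genes": n_genes, **{k: round(v, 4) for k, v in fractions.items()}}


def _stage_report(cfg: PipelineConfig) -> dict:
    log_dir = _require(cfg.out / "logs")
    combined = {}
    for stage in STAGES[:-1]:
        path = log_dir / f"{stage}.json"
        if path.exists():
            with open(path) as fh:
                combined[stage] = json.load(fh)
    with open(cfg.out / "report.json", "w") as fh:
        json.dump(combined, fh, indent=2)
    return {"stages_logged": sorted(combined)}


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "digest": _stage_digest,
    "demux": _stage_demux,
    "call": _stage_call,
    "stats": _stage_stats,
    "haplo": _stage_haplo,
    "pedigree": _stage_pedigree,
    "phylo": _stage_phylo,
    "annotate": _stage_annotate,
    "report": _stage_report,
}


def run_stage(name: str, cfg: PipelineConfig) -> dict:
    """Run one named stage; returns (and logs) its summary dictionary."""
    if name not in _STAGE_FUNCS:
        raise InvalidParameterError(f"unknown stage {name!r}; one of {STAGES}")
    summary = _STAGE_FUNCS[name](cfg)
    _log(cfg, name, summary)
    return summary


def run_all(cfg: PipelineConfig, stages=STAGES) -> dict[str, dict]:
    return {name: run_stage(name, cfg) for name in stages}
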
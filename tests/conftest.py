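"""Shared fixtures: a small simulated panel carried through the pipeline."""

from __future__ import annotations

from dataclasses import dataclass

import pytest

from rescan import evaluation, genotyping, readproc, simdata


@dataclass
class PanelRun:
    """A simulated panel carried through demux, alignment, and calling."""

    ref: simdata.Genome
    panel: list[simdata.CultivarGenome]
    truth: simdata.TruthTable
    design: simdata.LibraryDesign
    reads: list[simdata.Read]
    demux: readproc.DemuxResult
    index: genotyping.AnchorIndex
    coverages: dict[str, genotyping.SiteCoverage]
    gm: genotyping.GenotypeMatrix


def run_panel(
    seed: int = 42,
    chromosome_length: int = 400_000,
    n_chromosomes: int = 2,
    n_founders: int = 3,
    n_crosses: int = 3,
    mean_depth: float = 20.0,
    error_rate: float = 0.0,
    snp_rate: float = 1e-4,
    breakpoint_rate: float = 2.0,
    retention_profile: str = "sharp",
) -> PanelRun:
    ref, panel, truth, design = simdata.simulate_panel(
        seed,
        n_chromosomes=n_chromosomes,
        chromosome_length=chromosome_length,
        n_founders=n_founders,
        n_crosses=n_crosses,
        snp_rate=snp_rate,
        breakpoint_rate=breakpoint_rate,
        retention_profile=retention_profile,
    )
    reads = simdata.pooled_reads(panel, design, mean_depth, error_rate, seed + 3)
    demux = readproc.demultiplex(reads, design)
    index = genotyping.build_anchor_index(ref, design)
    coverages = {
        cid: genotyping.align_reads(sr, index) for cid, sr in demux.samples.items()
    }
    gm = genotyping.call_variants(coverages, ref)
    return PanelRun(ref, panel, truth, design, reads, demux, index, coverages, gm)


@pytest.fixture(scope="session")
def clean_run() -> PanelRun:
    """Error-free panel: 2x400 kb, 3 founders + 3 crosses, depth 20."""
    return run_panel(error_rate=0.0)


@pytest.fixture(scope="session")
def noisy_run() -> PanelRun:
    """Same panel conditions with a 0.5% per-base substitution rate."""
    return run_panel(error_rate=0.005)
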
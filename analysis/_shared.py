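"""Shared configuration for the numbered analysis drivers.

All drivers operate on one pipeline run under results/pipeline_run: a 2 x 1 Mb
reference, 3 founder cultivars plus 3 bi-parental crosses, 50 bp RESCAN reads
at per-end depth 20 with a 0.2% substitution rate, sharp 200-300 bp size
selection. Rerunning any driver is idempotent for a fixed seed.
"""

from pathlib import Path

from rescan.pipeline import PipelineConfig

RESULTS = Path(__file__).resolve().parent.parent / "results"
SEED = 2013


def pipeline_config() -> PipelineConfig:
    return PipelineConfig(
        out_dir=str(RESULTS / "pipeline_run"),
        seed=SEED,
        n_chromosomes=2,
        chromosome_length=1_000_000,
        n_founders=3,
        n_crosses=3,
        snp_rate=1e-4,
        breakpoint_rate=2.0,
        mean_depth=20.0,
        error_rate=0.002,
        retention_profile="sharp",
    )
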
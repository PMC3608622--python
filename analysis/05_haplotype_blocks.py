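#!/usr/bin/env python
"""Haplotype tracks and block detection.

Finding: each cultivar's calls form a blue/red/white-style track
(monomorphic / variant / missing) along the genome; runs of >= 3 variant
loci within 500 kb form haplotype blocks, which in crosses trace the
founder segments they inherited.
"""

import pandas as pd

from _shared import pipeline_config

from rescan.pipeline import run_stage


def main() -> None:
    cfg = pipeline_config()
    summary = run_stage("haplo", cfg)
    blocks = pd.read_csv(cfg.out / "blocks.tsv", sep="\t")
    print(f"haplotype states: {summary['n_states']:,}; blocks: {summary['n_blocks']}")
    if len(blocks):
        print(blocks.to_string(index=False))
    print(f"track and blocks written under {cfg.out_dir}")


if __name__ == "__main__":
    main()
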
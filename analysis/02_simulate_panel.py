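#!/usr/bin/env python
"""Simulate the study panel and its pooled RESCAN library.

Finding: 3 founder cultivars diverged from the reference at 1 SNP / 10 kb
plus 3 bi-parental crosses yield a pooled single-lane-style FASTQ of
barcoded 50 bp reads; the truth table (planted variants, recombination
mosaics, pedigree) is stored alongside for downstream scoring.
"""

from _shared import pipeline_config

from rescan.pipeline import run_stage


def main() -> None:
    cfg = pipeline_config()
    summary = run_stage("simulate", cfg)
    print(f"panel: {', '.join(summary['cultivars'])}")
    print(f"pooled reads: {summary['n_reads']:,}")
    for cid, n in summary["planted_snps"].items():
        print(f"  {cid}: {n} planted SNPs, {summary['reads_per_cultivar'][cid]:,} reads")
    print(f"inputs written under {cfg.out_dir}")


if __name__ == "__main__":
    main()
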
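#!/usr/bin/env python
"""Per-cultivar SNP density, missing-data summary, and frequency binning.

Finding: SNPs per sequenced 100 kb normalizes cultivar SNP counts by each
cultivar's own sequenced breadth, making founders and crosses comparable
despite coverage differences; binning loci by carrier count separates
founder-private (rare) from cross-shared variants.
"""

import json

from _shared import pipeline_config

from rescan.pipeline import run_stage


def main() -> None:
    cfg = pipeline_config()
    summary = run_stage("stats", cfg)
    import pandas as pd

    density = pd.read_csv(cfg.out / "density.tsv", sep="\t")
    print(density.to_string(index=False))
    miss = json.loads((cfg.out / "missingness.json").read_text())
    ls = miss["locus_summary"]
    print(f"per-locus missingness: mean {100 * ls['mean']:.1f}% "
          f"(range {100 * ls['min']:.0f}-{100 * ls['max']:.0f}%)")
    print(f"bin counts (carriers <= {cfg.rare_max} rare, <= {cfg.medium_max} medium): "
          f"{summary['bin_counts']}")


if __name__ == "__main__":
    main()
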
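#!/usr/bin/env python
"""Chord-distance neighbor-joining tree of the panel.

Finding: after informative-locus selection, Cavalli-Sforza chord distances
with pairwise deletion place each cross-derived cultivar nearest its
parents; the unrooted NJ tree is written as Newick.
"""

from _shared import pipeline_config

from rescan.pipeline import run_stage


def main() -> None:
    cfg = pipeline_config()
    summary = run_stage("phylo", cfg)
    print(f"informative loci (scored in >= {summary['min_scored']} cultivars): "
          f"{summary['n_informative_loci']}")
    print((cfg.out / "tree.nwk").read_text().strip())


if __name__ == "__main__":
    main()
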
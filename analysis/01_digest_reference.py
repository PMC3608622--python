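#!/usr/bin/env python
"""In silico NlaIII digestion of a simulated reference and the two
size-selection chemistries.

Finding: a 4-bp cutter fragments an i.i.d.-uniform genome into ~L/256
fragments (mean length ~256 bp); roughly 13-15% of fragments fall in the
200-300 bp target window, and at the read level gel fractionation enriches
the window far more strongly than SPRI beads (both well above the unselected
baseline), mirroring the contrast between LabChip and AMPure libraries.
"""

import json

from _shared import RESULTS, SEED

from rescan import digestion, simdata


def main() -> None:
    out = RESULTS / "digestion"
    out.mkdir(parents=True, exist_ok=True)

    ref = simdata.gen_reference(1, [5_000_000], SEED)
    inv = digestion.digest(ref, "CATG")
    frag_frac, genome_frac, n_in = digestion.window_stats(inv, 200, 300)
    print(f"fragments: {len(inv):,}  mean length {inv.lengths.mean():.1f} bp")
    print(f"in 200-300 bp window: {n_in:,} fragments "
          f"({100 * frag_frac:.1f}% of fragments, {100 * genome_frac:.2f}% of the genome)")
    inv.length_histogram(bin_width=20).to_csv(out / "fragment_hist.tsv", sep="\t", index=False)

    lib = simdata.CultivarGenome("lib", ref)
    report = {"baseline_fragment_fraction": frag_frac}
    for profile in ("gel", "spri"):
        design = simdata.LibraryDesign(barcode_map={"lib": "ACGTA"}, retention_profile=profile)
        reads = simdata.simulate_rescan_reads(lib, design, 3.0, 0.0, SEED + 1)
        lengths = digestion.attribute_reads_to_fragments([r[0] for r in reads], inv)
        rep = digestion.enrichment_report(lengths, inv, 200, 300)
        report[profile] = rep
        print(f"{profile}: {100 * rep['selected_fraction']:.1f}% of reads in window "
              f"({rep['enrichment_ratio']:.1f}-fold enrichment, {rep['n_selected']:,} reads)")
    with open(out / "enrichment.json", "w") as fh:
        json.dump(report, fh, indent=2)
    print(f"wrote {out}/fragment_hist.tsv and enrichment.json")


if __name__ == "__main__":
    main()
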
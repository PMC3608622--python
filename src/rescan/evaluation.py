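"""Scoring called genotypes against simulated ground truth.

These helpers define the evaluation universes precisely: reduced
representation covers only restriction-anchored footprints, so recovery is
scored over planted variants that the library design could have seen (the
carrier and at least one other cultivar sequenced the position deeply enough
for the caller's panel-level filters to apply).
"""

from __future__ import annotations

import numpy as np

from .genotyping import ALT, MISSING, SiteCoverage, GenotypeMatrix
from .popanalysis import FROM_A, FROM_B, OriginClassification
from .simdata import TruthTable

__all__ = [
    "snp_recovery",
    "genotype_discordance",
    "breakpoint_recovery",
]


def snp_recovery(
    truth: TruthTable,
    gm: GenotypeMatrix,
    coverages: dict[str, SiteCoverage],
    min_depth: int = 4,
) -> dict:
    """Precision/recall of ALT calls against planted variants.

    Recall is measured over the *callable universe*: planted (cultivar,
    position) pairs where the carrier has depth >= `min_depth` and at least
    one non-carrier cultivar does too (the caller requires a second genotype
    class across the panel before emitting a locus, and carriers of the same
    variant cannot provide it). Precision is measured over all ALT calls.
    """
    called: set[tuple[str, str, int]] = set()
    for cid in gm.cultivars:
        is_alt = (gm.calls[cid] == ALT).to_numpy()
        for chrom, pos in zip(
            gm.loci["chrom"].to_numpy()[is_alt], gm.loci["pos"].to_numpy()[is_alt]
        ):
            called.add((cid, chrom, int(pos)))

    depth_cache = {
        cid: {chrom: cov.depth(chrom) for chrom in cov.counts}
        for cid, cov in coverages.items()
    }
    carriers: dict[tuple[str, int], set[str]] = {}
    for cid, variants in truth.variants.items():
        if cid in coverages:
            for site in variants:
                carriers.setdefault(site, set()).add(cid)

    planted: set[tuple[str, str, int]] = set()
    universe: set[tuple[str, str, int]] = set()
    for cid, variants in truth.variants.items():
        if cid not in coverages:
            continue
        for (chrom, pos), _alt in variants.items():
            planted.add((cid, chrom, pos))
            if depth_cache[cid][chrom][pos] < min_depth:
                continue
            if any(
                depth_cache[other][chrom][pos] >= min_depth
                for other in coverages
                if other not in carriers[(chrom, pos)]
            ):
                universe.add((cid, chrom, pos))

    tp_universe = len(called & universe)
    tp_planted = len(called & planted)
    n_called = len(called)
    return {
        "n_planted": len(planted),
        "n_universe": len(universe),
        "n_called": n_called,
        "recall": tp_universe / len(universe) if universe else float("nan"),
        "precision": tp_planted / n_called if n_called else float("nan"),
        "false_calls": n_called - tp_planted,
        "missed": len(universe) - tp_universe,
    }


def genotype_discordance(truth: TruthTable, gm: GenotypeMatrix) -> dict:
    """Discordance of non-missing calls against the planted truth.

    The truth call for a cultivar at an emitted locus is ALT if that exact
    variant was planted there, REF otherwise.
    """
    loci = list(zip(gm.loci["chrom"], gm.loci["pos"], gm.loci["alt"]))
    co_scored = 0
    discordant = 0
    for cid in gm.cultivars:
        calls = gm.calls[cid].to_numpy()
        variants = truth.variants.get(cid, {})
        for i, (chrom, pos, alt) in enumerate(loci):
            if calls[i] == MISSING:
                continue
            expected = ALT if variants.get((chrom, int(pos))) == alt else 0
            co_scored += 1
            if calls[i] != expected:
                discordant += 1
    return {
        "co_scored": co_scored,
        "discordant": discordant,
        "discordance": discordant / co_scored if co_scored else float("nan"),
    }


def breakpoint_recovery(
    oc: OriginClassification, origin_track: dict[str, list[tuple[int, int, str]]]
) -> dict:
    """Score parental-origin labels and breakpoint localization against the
    planted recombination mosaic.

    Informative loci are those labeled FROM_A/FROM_B. A planted breakpoint is
    detectable when the nearest informative loci on its two sides expect
    different labels; it is recovered when the observed labels switch within
    that bracketing inter-SNP interval (which they do exactly when every
    informative label matches its truth segment).
    """

    def _expected_label(chrom: str, pos: int) -> str:
        for start, end, parent in origin_track[chrom]:
            if start <= pos < end:
                return FROM_A if parent == oc.parent_a else FROM_B
        raise ValueError(f"position {chrom}:{pos} outside the origin track")

    informative = oc.labels[oc.labels["label"].isin([FROM_A, FROM_B])]
    n_informative = len(informative)
    label_errors = 0
    detectable = 0
    recovered = 0
    spurious = 0
    interval_widths = []
    for chrom, grp in informative.groupby("chrom"):
        grp = grp.sort_values("pos")
        positions = grp["pos"].to_numpy()
        observed = grp["label"].to_numpy()
        expected = np.array([_expected_label(chrom, int(p)) for p in positions])
        label_errors += int((observed != expected).sum())
        for k in range(len(positions) - 1):
            exp_switch = expected[k] != expected[k + 1]
            obs_switch = observed[k] != observed[k + 1]
            if exp_switch:
                detectable += 1
                if obs_switch:
                    recovered += 1
                    interval_widths.append(int(positions[k + 1] - positions[k]))
            elif obs_switch:
                spurious += 1
    return {
        "n_informative": n_informative,
        "label_errors": label_errors,
        "detectable_breakpoints": detectable,
        "recovered_breakpoints": recovered,
        "spurious_switches": spurious,
        "recovered_fraction": recovered / detectable if detectable else float("nan"),
        "mean_interval_bp": float(np.mean(interval_widths)) if interval_widths else float("nan"),
    }
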
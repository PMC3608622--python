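"""In silico restriction digestion and size-selection modeling.

A 4-bp cutter (NlaIII, CATG) cuts immediately after each top-strand
occurrence of its site, so the fragments between consecutive cuts tile each
chromosome exactly. Size selection is modeled as an independent per-fragment
retention probability as a function of pre-ligation fragment length: a sharp
indicator of the target window, or two-sided logistic profiles with different
edge softness for gel-electrophoresis (steep) and SPRI-bead (shallow)
fractionation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd

from ._util import find_sites
from .errors import InvalidParameterError, UndefinedStatisticError

if TYPE_CHECKING:  # pragma: no cover
    from .simdata import Genome

__all__ = [
    "FragmentInventory",
    "RetentionProfile",
    "retention_profile",
    "digest",
    "window_stats",
    "apply_size_selection",
    "enrichment_report",
    "attribute_reads_to_fragments",
]

#: calibrated edge softness (bp) per fractionation method; gel cuts a much
#: steeper size band than SPRI beads
PROFILE_SOFTNESS = {"gel": 5.0, "spri": 40.0}


@dataclass(frozen=True)
class FragmentInventory:
    """Restriction fragments as 0-based half-open top-strand intervals."""

    records: pd.DataFrame  # columns: chrom, start, end

    def __post_init__(self) -> None:
        missing = {"chrom", "start", "end"} - set(self.records.columns)
        if missing:
            raise InvalidParameterError(f"inventory missing columns {sorted(missing)}")

    @property
    def lengths(self) -> np.ndarray:
        return (self.records["end"] - self.records["start"]).to_numpy()

    def __len__(self) -> int:
        return len(self.records)

    @property
    def total_length(self) -> int:
        return int(self.lengths.sum())

    def to_bed(self, path) -> None:
        self.records[["chrom", "start", "end"]].to_csv(
            path, sep="\t", header=False, index=False
        )

    def length_histogram(self, bin_width: int = 10) -> pd.DataFrame:
        lengths = self.lengths
        bins = (lengths // bin_width) * bin_width
        counts = pd.Series(bins).value_counts().sort_index()
        return pd.DataFrame({"bin_start": counts.index, "count": counts.to_numpy()})


@dataclass(frozen=True)
class RetentionProfile:
    """Fragment-length -> retention-probability contract for size selection.

    ``sharp`` is the indicator of [low, high]; ``gel`` and ``spri`` are
    two-sided logistic curves whose softness parameters are a calibration of
    the two fractionation chemistries, not ground truth.
    """

    profile_id: str
    low: float
    high: float
    softness_low: float = 0.0
    softness_high: float = 0.0

    def probability(self, length) -> np.ndarray:
        length = np.asarray(length, dtype=float)
        if self.softness_low <= 0 and self.softness_high <= 0:
            return ((length >= self.low) & (length <= self.high)).astype(float)
        with np.errstate(over="ignore"):
            rise = 1.0 / (1.0 + np.exp(-(length - self.low) / max(self.softness_low, 1e-9)))
            fall = 1.0 / (1.0 + np.exp((length - self.high) / max(self.softness_high, 1e-9)))
        return rise * fall


def retention_profile(profile_id: str, low: float, high: float) -> RetentionProfile:
    """Factory for the named profiles: sharp, gel, spri, none."""
    if low > high:
        raise InvalidParameterError("window low must be <= high")
    if profile_id == "sharp":
        return RetentionProfile("sharp", low, high)
    if profile_id == "none":
        return RetentionProfile("none", -np.inf, np.inf, 0.0, 0.0)
    if profile_id in PROFILE_SOFTNESS:
        s = PROFILE_SOFTNESS[profile_id]
        return RetentionProfile(profile_id, low, high, s, s)
    raise InvalidParameterError(f"unknown retention profile {profile_id!r}")


def digest(genome: "Genome", site: str) -> FragmentInventory:
    """Digest every chromosome at `site`, cutting right after each occurrence.

    Overlapping occurrences (impossible for CATG) are each cut. A chromosome
    with no occurrence yields a single full-length fragment.
    """
    if not site or set(site) - set("ACGT"):
        raise InvalidParameterError("site must be non-empty ACGT")
    slen = len(site)
    chroms, starts, ends = [], [], []
    for chrom, seq in genome.chromosomes.items():
        L = len(seq)
        cuts = sorted({p + slen for p in find_sites(seq, site) if 0 < p + slen < L})
        bounds = [0, *cuts, L]
        for s, e in zip(bounds[:-1], bounds[1:]):
            chroms.append(chrom)
            starts.append(s)
            ends.append(e)
    records = pd.DataFrame({"chrom": chroms, "start": starts, "end": ends})
    return FragmentInventory(records)


def window_stats(inv: FragmentInventory, low: float, high: float):
    """(fragment-count fraction, genome-length fraction, in-window count)."""
    if low > high:
        raise InvalidParameterError("window low must be <= high")
    if len(inv) == 0:
        raise UndefinedStatisticError("empty fragment inventory")
    lengths = inv.lengths
    in_window = (lengths >= low) & (lengths <= high)
    return (
        float(in_window.mean()),
        float(lengths[in_window].sum() / lengths.sum()),
        int(in_window.sum()),
    )


def apply_size_selection(
    inv: FragmentInventory, profile: RetentionProfile, seed: int
) -> FragmentInventory:
    """Retain each fragment independently with probability profile(length)."""
    rng = np.random.default_rng(seed)
    p = profile.probability(inv.lengths)
    keep = rng.random(len(inv)) < p
    return FragmentInventory(inv.records.loc[keep].reset_index(drop=True))


def enrichment_report(selected_lengths, inv: FragmentInventory, low: float, high: float) -> dict:
    """Compare the in-window fraction of selected items against the unselected
    fragment inventory baseline.

    `selected_lengths` are the fragment lengths of retained fragments or of
    the fragments reads were sampled from (one entry per read).
    """
    baseline_fraction, _, _ = window_stats(inv, low, high)
    selected_lengths = np.asarray(selected_lengths)
    if len(selected_lengths) == 0:
        raise UndefinedStatisticError("no selected items")
    selected_fraction = float(
        ((selected_lengths >= low) & (selected_lengths <= high)).mean()
    )
    return {
        "window": [float(low), float(high)],
        "n_selected": int(len(selected_lengths)),
        "baseline_fraction": baseline_fraction,
        "selected_fraction": selected_fraction,
        "enrichment_ratio": selected_fraction / baseline_fraction,
    }


def attribute_reads_to_fragments(read_ids: list[str], inv: FragmentInventory) -> np.ndarray:
    """Fragment length for each simulated read, resolved from its truth id.

    A forward read at site position p comes from the fragment starting at
    p + site length; a reverse read at p comes from the fragment ending at
    p + site length (site length 4 assumed, matching the simulator).
    """
    by_start: dict[tuple[str, int], int] = {}
    by_end: dict[tuple[str, int], int] = {}
    recs = inv.records
    for chrom, s, e in zip(recs["chrom"], recs["start"], recs["end"]):
        by_start[(chrom, int(s))] = int(e - s)
        by_end[(chrom, int(e))] = int(e - s)
    out = np.empty(len(read_ids), dtype=float)
    for i, rid in enumerate(read_ids):
        parts = rid.split(":")
        chrom, pos, strand = parts[1], int(parts[2]), parts[3]
        cut = pos + 4
        out[i] = by_start[(chrom, cut)] if strand == "F" else by_end[(chrom, cut)]
    return out
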
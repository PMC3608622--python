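"""Published sequencing summary for the 45-cultivar California rice RESCAN
panel, and the arithmetic that validates its density statistics.

The bundled table carries, per cultivar: total and aligned read counts,
sequenced breadth (Mb), SNPs detected against the Nipponbare reference, and
SNPs per sequenced 100 kb, plus a grain-type classification (short / medium /
long) reconstructed from California cultivar naming and pedigree conventions
(S-/Calmochi-/Calhikari-/Calamylow- prefixes and the ancestral short grains
are short; M-/Calrose lines are medium; L-/A-/Calmati- lines are long).

Note the summary row of the published table: the total-reads figure
(208,330,188) is the arithmetic column sum, while the SNP total (20,987) is
the number of *distinct* SNPs across the panel — the per-cultivar SNP column
sums to more (70,714) because most SNPs are carried by several cultivars.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .genotyping import snp_density

__all__ = [
    "PUBLISHED_TOTAL_READS",
    "PUBLISHED_DISTINCT_SNPS",
    "load_panel_table",
    "recompute_densities",
    "grain_group_density_means",
    "table_summary",
]

PUBLISHED_TOTAL_READS = 208_330_188
PUBLISHED_DISTINCT_SNPS = 20_987


def load_panel_table() -> pd.DataFrame:
    with resources.files("rescan.data").joinpath("california_table1.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def recompute_densities(table: pd.DataFrame) -> pd.Series:
    """SNPs per sequenced 100 kb recomputed from the SNP and Mb columns."""
    return pd.Series(
        [snp_density(int(s), float(mb)) for s, mb in zip(table["snps"], table["sequenced_mb"])],
        index=table["cultivar"],
    )


def grain_group_density_means(table: pd.DataFrame) -> dict[str, float]:
    """Mean of the printed density column per grain-type group."""
    return {
        grain: float(grp["snps_per_100kb"].mean())
        for grain, grp in table.groupby("grain")
    }


def table_summary(table: pd.DataFrame | None = None) -> dict:
    """All the panel-table arithmetic in one place."""
    if table is None:
        table = load_panel_table()
    recomputed = recompute_densities(table)
    printed = pd.Series(table["snps_per_100kb"].to_numpy(), index=table["cultivar"])
    groups = grain_group_density_means(table)
    return {
        "n_cultivars": int(len(table)),
        "total_reads_sum": int(table["total_reads"].sum()),
        "total_reads_mean_millions": round(float(table["total_reads"].mean()) / 1e6, 2),
        "total_reads_sd_millions": round(float(table["total_reads"].std(ddof=1)) / 1e6, 2),
        "snp_column_sum": int(table["snps"].sum()),
        "density_recomputed": recomputed,
        "density_matches": int((recomputed == printed).sum()),
        "group_density_means": {k: round(v, 2) for k, v in groups.items()},
        "aligned_fraction": round(
            float(table["aligned_reads"].sum() / table["total_reads"].sum()), 3
        ),
    }
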
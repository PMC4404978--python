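"""Published summary table for the sweetpotato wild-relative genepool.

The 14 wild taxa of *Ipomoea* series *Batatas* — the closest wild relatives
of sweetpotato — with their genepool class, counts of germplasm accessions
conserved ex situ (total and georeferenced), the gap-analysis collecting
priority, the mean expert priority, and ecogeographic cluster membership.
The compiled occurrence dataset behind these figures held 5,614 records:
749 germplasm records from four genebanks and 4,865 herbarium/reference
records from 42 providers, of which 3,650 carried unique cross-checked
coordinates; per-species record counts ranged from 8 to 1,409.

These numbers serve as consistency fixtures for the scoring and
categorization code and as inputs to summary recomputations; they are not
produced by this package.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

#: compiled-dataset record counts
TOTAL_RECORDS = 5614
GERMPLASM_RECORDS = 749
REFERENCE_RECORDS = 4865
UNIQUE_COORDINATE_RECORDS = 3650
MIN_RECORDS_PER_SPECIES = 8
MAX_RECORDS_PER_SPECIES = 1409


def load_summary_table() -> pd.DataFrame:
    """The per-taxon genepool summary table (14 rows)."""
    with resources.files("cwrgap.data").joinpath("cwr_summary.csv").open() as fh:
        return pd.read_csv(fh)


def summary_statistics(table: pd.DataFrame | None = None) -> dict:
    """Recompute headline arithmetic from the per-taxon table.

    Returns the total accession count, counts per priority category, the HPS
    share, the expert-HPS count, the number of sparsely conserved taxa
    (<= 10 accessions), and the overall sampling-representativeness score of
    the genepool implied by the compiled record counts.
    """
    from .gap_analysis import srs

    t = load_summary_table() if table is None else table
    cat_counts = t["gap_category"].value_counts().to_dict()
    n = len(t)
    return {
        "n_taxa": n,
        "accessions_total": int(t["accessions"].sum()),
        "hps_count": int(cat_counts.get("HPS", 0)),
        "mps_count": int(cat_counts.get("MPS", 0)),
        "lps_count": int(cat_counts.get("LPS", 0)),
        "nfcr_count": int(cat_counts.get("NFCR", 0)),
        "hps_percent": 100.0 * cat_counts.get("HPS", 0) / n,
        "expert_hps_count": int((t["expert_category"] == "HPS").sum()),
        "taxa_with_leq10_accessions": int((t["accessions"] <= 10).sum()),
        "overall_srs": srs(GERMPLASM_RECORDS,
                           TOTAL_RECORDS - GERMPLASM_RECORDS),
    }
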
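"""Worked-example evaluation data for a multi-family apple breeding study.

Per-family prediction accuracies for 10 culling traits in five application
full-sib families, as reported for a commercial European apple breeding
evaluation.  The grid is the canonical input for the report-aggregation
machinery: family means over all traits and over the four symmetric traits,
trait means, and the confidence-interval summaries all recompute from these
cells.  Two families were not scored for pre-harvest dropping, so their
grids have 9 cells.
"""

import numpy as np
import pandas as pd

APPLICATION_FAMILY_SIZES = {
    "AF1_Da66": 662,
    "AF2_Pi63": 172,
    "AF3_31Fu": 269,
    "AF4_31Ga": 109,
    "AF5_33Br": 178,
}

# robust high-density SNPs plus the low-density panel SNPs that fell outside
# the robust set; together they form the marker matrix
N_ROBUST_SNPS = 7651
N_EXTRA_PANEL_SNPS = 178
N_LOW_DENSITY_USABLE = 364

#: per-family accuracy of genomic prediction (Pearson r of GBV vs score)
ACCURACY_GRID = pd.DataFrame(
    {
        "AF1_Da66": [0.21, 0.08, 0.26, 0.18, -0.09, np.nan, 0.31, 0.34, -0.03, -0.06],
        "AF2_Pi63": [0.18, 0.09, 0.19, 0.21, -0.05, np.nan, 0.22, 0.17, 0.12, 0.00],
        "AF3_31Fu": [0.35, 0.02, 0.08, 0.38, 0.13, 0.02, 0.50, 0.44, 0.09, -0.25],
        "AF4_31Ga": [0.19, 0.19, 0.33, 0.30, -0.02, -0.06, 0.46, 0.49, -0.05, -0.23],
        "AF5_33Br": [0.14, 0.03, 0.25, -0.06, 0.07, -0.02, 0.36, 0.32, 0.17, -0.14],
    },
    index=[
        "attractiveness",
        "fruit_cropping",
        "fruit_size",
        "percent_russet",
        "fruit_cracking",
        "preharvest_dropping",
        "percent_over_colour",
        "over_colour",
        "ground_colour",
        "type_of_colour",
    ],
)

#: estimated SNP-inclusion proportions (pi) reported for three contrasting
#: traits, with the QTL counts they imply on the combined marker set
EXAMPLE_PI = {"over_colour": 0.007, "attractiveness": 0.062,
              "fruit_cropping": 0.319}


def accuracy_long() -> pd.DataFrame:
    """The grid in long (family, trait, r) form for aggregate_report."""
    long = ACCURACY_GRID.reset_index(names="trait").melt(
        id_vars="trait", var_name="family", value_name="r")
    return long.dropna(subset=["r"]).reset_index(drop=True)
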
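"""Published per-cohort parameter estimates for the NSDUH analysis.

Reference point estimates fitted under random interaction for nine cohorts
of US adolescents followed from age 12 to 17 (cohorts starting 2001-2009,
annual cigarette-use prevalence from the National Survey on Drug Use and
Health).  They serve as default sensitivity-sweep centers, as the defaults
of the synthetic-data generator, and for internal-consistency checks of the
published table (e.g. that the printed cross-cohort means match the printed
per-cohort values).

Printed precision: alpha and beta to one decimal, initial opinion to 2-3
decimals, pseudo R^2 to two decimals.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "COHORT_ALPHA",
    "COHORT_BETA",
    "COHORT_P0",
    "COHORT_PSEUDO_R2",
    "INTERACTION_PROPORTION",
    "MEAN_ALPHA",
    "MEAN_BETA",
    "MEAN_P0",
    "MEAN_LIKELIHOOD_SUM",
    "MEAN_PSEUDO_R2",
    "reference_table",
]

# Per-cohort fitted values, cohorts 1..9 (start years 2001..2009).
COHORT_ALPHA = (0.5, 0.5, 0.8, 0.8, 0.7, 0.7, 0.6, 0.9, 0.7)
COHORT_BETA = (0.9, 0.9, 0.8, 0.8, 0.8, 0.9, 0.8, 0.5, 0.9)
COHORT_P0 = (0.02, 0.02, 0.02, 0.02, 0.02, 0.015, 0.02, 0.019, 0.01)
COHORT_PSEUDO_R2 = (0.97, 0.98, 0.99, 0.99, 0.98, 0.98, 0.98, 0.96, 0.99)

#: Monthly interaction proportion, identical across cohorts.
INTERACTION_PROPORTION = 0.1

# Printed cross-cohort means.
MEAN_ALPHA = 0.7
MEAN_BETA = 0.8
MEAN_P0 = 0.02
MEAN_LIKELIHOOD_SUM = 1.5
MEAN_PSEUDO_R2 = 0.99


def reference_table() -> pd.DataFrame:
    """The reference estimates as a cohort-by-quantity DataFrame."""
    return pd.DataFrame(
        {
            "cohort": np.arange(1, 10),
            "start_year": np.arange(2001, 2010),
            "alpha": COHORT_ALPHA,
            "beta": COHORT_BETA,
            "p0": COHORT_P0,
            "proportion": INTERACTION_PROPORTION,
            "alpha_plus_beta": np.add(COHORT_ALPHA, COHORT_BETA),
            "pseudo_r2": COHORT_PSEUDO_R2,
        }
    )
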
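"""Small built-in reference datasets."""

from __future__ import annotations

import pandas as pd

__all__ = ["reference_cfu_means"]


def reference_cfu_means() -> pd.DataFrame:
    """Published plate-count summary for the Tolypothrix–Pseudomonas system.

    Mean ± SD CFU/L of the eGFP-tagged Pseudomonas partner after one month of
    capillary-reactor co-cultivation: resident cells recovered from the
    biofilm vs detached cells counted in the flow-through, under N2-fixing
    (nitrate-free) and nitrate-fed media. These are the inputs for the
    resident:detached retention-ratio comparison between conditions.
    """
    return pd.DataFrame(
        [
            {"condition": "N2-fixing", "source": "detached", "mean_cfu_per_l": 2.92e8, "sd_cfu_per_l": 3.20e7},
            {"condition": "N2-fixing", "source": "resident", "mean_cfu_per_l": 1.42e11, "sd_cfu_per_l": 1.36e10},
            {"condition": "nitrate-fed", "source": "detached", "mean_cfu_per_l": 2.03e9, "sd_cfu_per_l": 2.09e8},
            {"condition": "nitrate-fed", "source": "resident", "mean_cfu_per_l": 3.48e11, "sd_cfu_per_l": 1.48e10},
        ]
    )
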
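"""Bundled reference data.

``load_food_web_summary`` returns published summary statistics for 46
empirical food webs (marine, freshwater and terrestrial): species count
N, basal count B, link count L, the measured trophic incoherence q, and
the GPPM temperature reported to reproduce that q.  The full species-
level topologies are not bundled; these summaries suffice to drive the
model-calibration and regression analyses.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_food_web_summary"]


def load_food_web_summary() -> pd.DataFrame:
    """Summary table of 46 empirical food webs, indexed by numeric ID.

    Columns: ``name``, ``habitat``, ``n_species`` (N), ``n_basal`` (B),
    ``n_links`` (L), ``q`` (trophic incoherence), ``temperature``
    (GPPM T calibrated to q).  IDs are assigned in order of increasing q.
    """
    with resources.files(__package__).joinpath("data/food_web_summary.csv").open() as fh:
        df = pd.read_csv(fh)
    return df.set_index("id")
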
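"""Bundled worked-example tables.

These small fixtures let the documentation and tests exercise reporting
code (correspondence tables, exclusion bookkeeping, proportion summaries)
without fitting a model first.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

# Correspondence between a published cross-sectional atrophy-subtype
# clustering of a 72-patient dementia cohort and its longitudinal
# re-clustering (rows: cross-sectional subtypes; columns: longitudinal
# clusters under HPD-interval classification, with the two outlier
# clusters and the HPD-uncertain group broken out).
_CORRESPONDENCE_ROWS = {
    "Diffuse 1 (Typical AD)":   [6, 12, 15, 2, 1, 0, 0, 1, 2],
    "Diffuse 2 (Typical AD)":   [0, 0, 0, 2, 0, 0, 0, 1, 0],
    "Hippocampal sparing":      [0, 0, 0, 0, 3, 4, 0, 0, 0],
    "Limbic predominant":       [0, 1, 0, 0, 0, 0, 1, 0, 1],
    "Minimal atrophy":          [17, 2, 0, 0, 0, 1, 0, 0, 0],
}

_CORRESPONDENCE_COLUMNS = [
    "Minimal Atrophy",
    "Diffuse 1 (Typical AD)",
    "Diffuse 2 (Typical AD)",
    "Diffuse 3 (Typical AD)",
    "Hippocampal sparing early onset",
    "Hippocampal sparing late onset",
    "Cluster 7",
    "Cluster 8",
    "HPD uncertain",
]


def correspondence_table(with_margins: bool = False) -> pd.DataFrame:
    """Example cross-sectional × longitudinal cluster correspondence matrix.

    Row sums are the cross-sectional cluster sizes; the grand total is the
    72-patient cohort.  With ``with_margins`` a ``Sum`` row and column are
    appended.
    """
    df = pd.DataFrame.from_dict(
        _CORRESPONDENCE_ROWS, orient="index", columns=_CORRESPONDENCE_COLUMNS
    )
    if with_margins:
        df = df.copy()
        df["Sum"] = df.sum(axis=1)
        df.loc["Sum"] = df.sum(axis=0)
    return df


def cluster_proportions(sizes, total: int | None = None) -> np.ndarray:
    """Cluster sizes as percentages of the cohort, e.g. 34/72 -> 47.2."""
    sizes = np.asarray(sizes, dtype=float)
    total = float(total) if total is not None else sizes.sum()
    return 100.0 * sizes / total
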
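"""Node-label table for the Harvard–Oxford parcellation used by the pipeline.

The parcellation covers 48 cortical and 7 subcortical structural areas
bilaterally (110 regions).  Labels are the standard abbreviations suffixed
with ``_L`` / ``_R``; the six bilateral body-representation regions
(postcentral gyrus, superior parietal lobule, insular cortex) are the default
nodes of interest (NOIs).
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources

import pandas as pd

#: Abbreviations of the default nodes of interest (without hemisphere suffix).
NOI_BASE = ("PostC", "SPL", "IC")


@lru_cache(maxsize=1)
def load_label_table() -> pd.DataFrame:
    """Return the atlas label table (abbreviation, region name, tier)."""
    path = resources.files("hubnet.data") / "harvard_oxford_labels.tsv"
    with resources.as_file(path) as p:
        return pd.read_csv(p, sep="\t")


def region_labels(n_regions: int = 110) -> list[str]:
    """Bilateral region labels in canonical order.

    For the full 110-region parcellation this interleaves hemispheres
    (``Fpole_L, Fpole_R, IC_L, IC_R, ...``).  For reduced simulations
    (``n_regions != 110``) generic labels ``R000, R001, ...`` are returned,
    since a truncated atlas would be anatomically meaningless.
    """
    if n_regions == 110:
        table = load_label_table()
        out: list[str] = []
        for abbr in table["abbreviation"]:
            out.extend([f"{abbr}_L", f"{abbr}_R"])
        return out
    return [f"R{i:03d}" for i in range(n_regions)]


def noi_labels() -> list[str]:
    """Default nodes of interest: bilateral PostC, SPL and IC."""
    return [f"{abbr}_{h}" for abbr in NOI_BASE for h in ("L", "R")]


def noi_indices(labels: list[str] | None = None) -> list[int]:
    """Indices of the default NOIs within a label list (110-region default)."""
    if labels is None:
        labels = region_labels()
    index = {lab: i for i, lab in enumerate(labels)}
    missing = [lab for lab in noi_labels() if lab not in index]
    if missing:
        raise KeyError(f"labels do not contain the default NOIs: {missing}")
    return [index[lab] for lab in noi_labels()]
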
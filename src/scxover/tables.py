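"""Published per-mouse summary tables shipped as package data.

These printed tables (per-mouse MLH1 count summaries and chromosome-1 SC
summaries for wild and laboratory-raised Peromyscus males) serve as inputs
for the desk-scale arithmetic: pooled group rows, map-length estimates and
focus-class percentages are recomputed from them rather than hard-coded.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd


def _load(name: str) -> pd.DataFrame:
    with resources.files("scxover").joinpath(f"data/{name}").open() as fh:
        return pd.read_csv(fh, comment="#")


def load_count_summary() -> pd.DataFrame:
    """Per-mouse MLH1 focus-count summaries (n_cells, mean, sd, se, cv)."""
    return _load("mlh1_counts_summary.csv")


def load_chr1_summary() -> pd.DataFrame:
    """Per-mouse chromosome-1 SC summaries (lengths, focus classes, r-bar)."""
    return _load("chr1_sc_summary.csv")
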
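"""Shared fixtures: synthetic datasets measured once per session."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from scxover.pipeline import measure_image
from scxover.synth import BivalentSpec, CellSpec, generate_cell, manifest_frame


def render_cells(seeds, **cell_kwargs):
    """Generate and measure a set of synthetic cells.

    Returns (measurements DataFrame, manifest DataFrame); cell ids are
    keyed by seed so datasets with different seeds never collide.
    """
    defaults = dict(n_bivalents=9, include_xy=False, canvas_size=(620, 620))
    defaults.update(cell_kwargs)
    frames, manifests = [], []
    for seed in seeds:
        spec = CellSpec(seed=seed, **defaults)
        img, truths = generate_cell(spec)
        cell_id = f"cell_s{seed}"
        for t in truths:
            t.cell_id = cell_id
        result = measure_image(img, cell_id)
        frames.append(result.frame())
        manifests.append(manifest_frame(truths))
    return (pd.concat(frames, ignore_index=True),
            pd.concat(manifests, ignore_index=True))


@pytest.fixture(scope="session")
def clean_dataset():
    """54 non-overlapping bivalents across 6 cells, no injected errors."""
    return render_cells(range(100, 106))


@pytest.fixture(scope="session")
def error_dataset():
    """Cells with injected end-to-end merges and stray off-centre foci."""
    return render_cells(range(300, 306), overlap_fraction=0.25, n_stray_foci=3)


@pytest.fixture()
def straight_bar_spec():
    """A perfectly straight 100-px bivalent with two foci and a centromere."""
    cp = np.array([[60.0, 40.0], [60.0, 90.0], [60.0, 140.0]])
    return BivalentSpec(control_points=cp, centromere_arc_pos=25.0,
                        foci_arc_pos=(30.0, 90.0))


def render_single(spec: BivalentSpec, shape=(120, 200)):
    canvas = np.zeros((3, *shape), dtype=float)
    from scxover.synth import render_bivalent
    truth = render_bivalent(spec, canvas)
    img = (np.clip(canvas, 0, 1) * 65535).astype(np.uint16)
    return img, truth
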
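"""Shared fixtures: small deterministic stimulus sets and populations.

Everything is generated programmatically; session scope amortises the
geometry and simulation cost across test modules.
"""

from __future__ import annotations

import numpy as np
import pytest

from fgpop import fg_labeling as fl
from fgpop import stimulus_geometry as sg
from fgpop import synthetic_population as sp


@pytest.fixture(scope="session")
def bases12():
    return sg.default_bases(12, seed=0)


@pytest.fixture(scope="session")
def bases105():
    return sg.default_bases(105, seed=0)


@pytest.fixture(scope="session")
def filled_set(bases12):
    return sg.enumerate_set(bases12, ["filled"], seed=0)


@pytest.fixture(scope="session")
def filled_set_full(bases105):
    return sg.enumerate_set(bases105, ["filled"], seed=0)


@pytest.fixture(scope="session")
def population():
    return sp.sample_population(40, sp.PopulationConfig(), seed=1)


@pytest.fixture(scope="session")
def counts(population, filled_set):
    return sp.simulate_counts(population, filled_set, seed=2)


@pytest.fixture(scope="session")
def labels(population, filled_set):
    return fl.label_by_center(population, filled_set)


@pytest.fixture(scope="session")
def mp_pairs(labels, filled_set):
    return fl.build_pairs(labels, filled_set, "MP")


def make_table(counts_arr: np.ndarray, pre_arr: np.ndarray | None = None):
    """Hand-built SpikeCountTable from an (N, S, T) array."""
    counts_arr = np.asarray(counts_arr)
    if pre_arr is None:
        pre_arr = np.zeros_like(counts_arr)
    N, S, _ = counts_arr.shape
    return sp.SpikeCountTable(
        [f"n{i:05d}" for i in range(N)],
        [f"stim{j}" for j in range(S)],
        counts_arr.astype(np.int64), np.asarray(pre_arr).astype(np.int64),
    )


def make_labels(fg: np.ndarray, contrast: np.ndarray | None = None,
                method: str = "center"):
    fg = np.asarray(fg, dtype=bool)
    if contrast is None:
        contrast = np.zeros_like(fg, dtype=np.int8)
    return fl.LabelTable(
        [f"n{i:05d}" for i in range(fg.shape[0])],
        [f"stim{j}" for j in range(fg.shape[1])],
        fg, np.asarray(contrast, dtype=np.int8), method,
        np.ones(fg.shape[0], dtype=bool),
    )
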
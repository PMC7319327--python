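"""Pseudo-population decoding: dataset balancing, neuron sampling,
pseudo-sample assembly, and SVM behaviour on controlled inputs."""

import numpy as np
import pytest
from scipy import stats

from conftest import make_labels, make_table
from fgpop import population_decoding as pdec


def _dataset(values, labels, nid="n0"):
    return pdec.NeuronDataset(nid, np.asarray(values, dtype=float),
                              np.asarray(labels, dtype=bool), balanced=True)


# ---------------------------------------------------------------------------
# build_dataset
# ---------------------------------------------------------------------------


def test_build_dataset_balances_majority_class():
    rng = np.random.default_rng(0)
    fg = np.zeros((1, 210), dtype=bool)
    fg[0, :120] = True  # 120 figure / 90 ground records
    tab = make_table(rng.poisson(2.0, size=(1, 210, 10)))
    ds = pdec.build_dataset(tab, make_labels(fg), 0, rng=rng)
    assert ds.class_counts() == (90, 90)
    assert ds.balanced


def test_build_dataset_empty_class_raises():
    fg = np.ones((1, 50), dtype=bool)
    tab = make_table(np.ones((1, 50, 10)))
    with pytest.raises(pdec.EmptyClassError):
        pdec.build_dataset(tab, make_labels(fg), 0)


def test_build_dataset_paired_record_bound(counts, labels, mp_pairs):
    rng = np.random.default_rng(1)
    for i in range(5):
        if not mp_pairs.usable[i].any():
            continue
        n_usable = int(mp_pairs.usable[i].sum())
        try:
            ds = pdec.build_dataset(counts, labels, i, mode="paired",
                                    pairs=mp_pairs, rng=rng)
        except pdec.EmptyClassError:
            continue
        assert len(ds.values) <= n_usable


def test_build_dataset_max_per_class_cap(counts, labels):
    rng = np.random.default_rng(2)
    ds = pdec.build_dataset(counts, labels, 0, rng=rng, max_per_class=7)
    assert ds.class_counts() == (7, 7)


# ---------------------------------------------------------------------------
# neuron sampling
# ---------------------------------------------------------------------------


def test_sample_whole_pool():
    rng = np.random.default_rng(0)
    pool = np.arange(12)
    got = pdec.sample_neuron_subset(pool, 12, rng)
    assert sorted(got) == list(range(12))


def test_sample_too_many_raises():
    with pytest.raises(ValueError):
        pdec.sample_neuron_subset(np.arange(5), 6, np.random.default_rng(0))


def test_sampling_is_uniform():
    rng = np.random.default_rng(3)
    pool = np.arange(8)
    draws = np.array([pdec.sample_neuron_subset(pool, 1, rng)[0]
                      for _ in range(4000)])
    obs = np.bincount(draws, minlength=8)
    chi2, p = stats.chisquare(obs)
    assert p > 1e-4


def test_within_session_scope():
    rng = np.random.default_rng(4)
    pool = np.arange(30)
    sessions = np.repeat([0, 1, 2], 10)
    got = pdec.sample_neuron_subset(pool, 10, rng, scope="within-session",
                                    sessions=sessions)
    assert len({sessions[g] for g in got}) == 1
    with pytest.raises(ValueError):
        pdec.sample_neuron_subset(pool, 11, rng, scope="within-session",
                                  sessions=sessions)


# ---------------------------------------------------------------------------
# pseudo-sample assembly
# ---------------------------------------------------------------------------


def test_assemble_min_class_count():
    rng = np.random.default_rng(5)
    d1 = _dataset([1, 2, 3, 10, 11, 12], [1, 1, 1, 0, 0, 0], "a")
    d2 = _dataset([4, 5, 6, 13, 14, 15], [1, 1, 1, 0, 0, 0], "b")
    X, y = pdec.assemble_pseudo_samples([d1, d2], rng)
    assert X.shape == (6, 2)
    assert y.sum() == 3
    # every feature value really comes from the matching neuron and class
    for row, lab in zip(X, y):
        assert row[0] in (d1.values[d1.labels == lab])
        assert row[1] in (d2.values[d2.labels == lab])


def test_assemble_no_within_neuron_repetition():
    rng = np.random.default_rng(6)
    d1 = _dataset([1, 2, 3, 4, 5, 6], [1, 1, 1, 0, 0, 0], "a")
    X, y = pdec.assemble_pseudo_samples([d1], rng)
    assert sorted(X[y == 1, 0]) == [1, 2, 3]
    assert sorted(X[y == 0, 0]) == [4, 5, 6]


def test_assemble_null_class_means_match():
    rng = np.random.default_rng(7)
    datasets = []
    for k in range(6):
        vals = rng.poisson(20, 80).astype(float)
        labs = np.zeros(80, dtype=bool)
        labs[:40] = True  # labels carry no signal
        datasets.append(_dataset(vals, labs, f"n{k}"))
    X, y = pdec.assemble_pseudo_samples(datasets, rng)
    gap = np.abs(X[y == 1].mean(axis=0) - X[y == 0].mean(axis=0))
    se = X.std(axis=0) * np.sqrt(2 / 40)
    assert np.all(gap < 4 * se)


def test_permuting_neurons_permutes_feature_columns():
    rng1 = np.random.default_rng(8)
    rng2 = np.random.default_rng(8)
    d1 = _dataset([1, 2, 10, 20], [1, 1, 0, 0], "a")
    d2 = _dataset([3, 4, 30, 40], [1, 1, 0, 0], "b")
    X12, _ = pdec.assemble_pseudo_samples([d1, d2], rng1)
    X21, _ = pdec.assemble_pseudo_samples([d2, d1], rng2)
    assert np.array_equal(X12[:, 0], X21[:, 1])
    assert np.array_equal(X12[:, 1], X21[:, 0])


# ---------------------------------------------------------------------------
# decoding
# ---------------------------------------------------------------------------


def test_decode_separable_classes():
    rng = np.random.default_rng(9)
    X = np.vstack([rng.normal(-3, 0.1, (50, 2)), rng.normal(3, 0.1, (50, 2))])
    y = np.repeat([0, 1], 50)
    rate = pdec.decode(X, y, pdec.DecoderConfig(), rng)
    assert rate >= 0.98


def test_decode_shuffled_labels_at_chance():
    rng = np.random.default_rng(10)
    X = rng.normal(0, 1, (120, 4))
    rates = [pdec.decode(X, rng.permutation(np.repeat([0, 1], 60)),
                         pdec.DecoderConfig(), rng) for _ in range(6)]
    assert abs(np.mean(rates) - 0.5) < 0.08


def test_decode_degenerate_features_chance(caplog):
    X = np.ones((40, 3))
    y = np.repeat([0, 1], 20)
    with caplog.at_level("WARNING"):
        assert pdec.decode(X, y, pdec.DecoderConfig()) == 0.5


def test_decode_needs_enough_samples():
    X = np.random.default_rng(0).normal(size=(6, 2))
    y = np.array([0, 0, 0, 1, 1, 1])
    with pytest.raises(ValueError):
        pdec.decode(X, y, pdec.DecoderConfig(folds=5))


def test_integration_curve_shapes_and_balance(counts, labels):
    cfg = pdec.DecoderConfig(repeats=2, neuron_counts=(2, 4), max_per_class=20)
    curve = pdec.integration_curve(counts, labels, np.arange(10), cfg, seed=1,
                                   condition="filled")
    assert curve.rates.shape == (2, 2)
    assert np.all((curve.rates >= 0) & (curve.rates <= 1))
    assert curve.mean.shape == (2,) and np.all(curve.sd >= 0)
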
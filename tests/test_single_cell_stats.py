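"""Per-neuron statistics: responsiveness power, ANOVA calibration,
favorites, paired differentials, exclusion rules, and correct rates."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import make_labels, make_table
from fgpop import single_cell_stats as scs
from fgpop import synthetic_population as sp
from fgpop import fg_labeling as fl
from fgpop import stimulus_geometry as sg


# ---------------------------------------------------------------------------
# responsiveness
# ---------------------------------------------------------------------------


def test_responsiveness_identical_windows_not_significant():
    rng = np.random.default_rng(0)
    c = rng.poisson(3.0, size=(1, 50, 10))
    tab = make_table(c, c.copy())
    p, flag = scs.responsiveness_test(tab, 0)
    assert not flag and p > 0.9


def test_responsiveness_zero_variance_convention():
    tab = make_table(np.zeros((1, 20, 10)), np.zeros((1, 20, 10)))
    p, flag = scs.responsiveness_test(tab, 0)
    assert p == 1.0 and not flag


def test_responsiveness_power_at_strong_drive():
    """Baseline 5 Hz vs evoked 30 Hz over 10 trials x 100 stimuli is
    detected in essentially every seed."""
    for seed in range(10):
        rng = np.random.default_rng(seed)
        stim = rng.poisson(0.2 * 35.0, size=(1, 100, 10))
        pre = rng.poisson(0.1 * 5.0, size=(1, 100, 10))
        _, flag = scs.responsiveness_test(make_table(stim, pre), 0)
        assert flag


# ---------------------------------------------------------------------------
# ANOVA
# ---------------------------------------------------------------------------


def _null_population(n, seed, n_stim=160):
    rng = np.random.default_rng(seed)
    counts = rng.poisson(1.5, size=(n, n_stim, 10))
    fg = rng.random((n, n_stim)) < 0.5
    contrast = np.where(rng.random((n, n_stim)) < 0.5, 1, -1).astype(np.int8)
    return make_table(counts), make_labels(fg, contrast)


def test_anova_type_one_error_calibrated():
    tab, lab = _null_population(400, seed=5)
    sig = [scs.fg_contrast_anova(tab, lab, i).fg_p < 0.05 for i in range(400)]
    rate = np.mean(sig)
    se = np.sqrt(0.05 * 0.95 / 400)
    assert abs(rate - 0.05) < 4 * se


def test_anova_detects_strong_modulation():
    rng = np.random.default_rng(1)
    fg = rng.random((1, 160)) < 0.5
    lam = np.where(fg[0], 4.0, 1.0)
    counts = rng.poisson(lam[None, :, None], size=(1, 160, 10))
    contrast = np.where(rng.random((1, 160)) < 0.5, 1, -1).astype(np.int8)
    res = scs.fg_contrast_anova(make_table(counts), make_labels(fg, contrast), 0)
    assert res.fg_p < 1e-6 and res.design == "two-way"


def test_anova_one_way_for_unlabelled_contrast():
    tab, lab = _null_population(1, seed=2)
    lab.contrast[:] = 0  # natural stimuli: no polarity labels
    res = scs.fg_contrast_anova(tab, lab, 0, design="one-way")
    assert res.contrast_p is None and res.design == "one-way"


def test_anscombe_changes_few_calls():
    """The Anscombe transform changes the FG-significant set for at most a
    sliver of neurons."""
    tab, lab = _null_population(200, seed=9)
    raw = np.array([scs.fg_contrast_anova(tab, lab, i).fg_p < 0.05
                    for i in range(200)])
    tr = np.array([scs.fg_contrast_anova(tab, lab, i, transform="anscombe").fg_p < 0.05
                   for i in range(200)])
    assert np.mean(raw != tr) <= 0.02


# ---------------------------------------------------------------------------
# preference / modulation ratio / favorites
# ---------------------------------------------------------------------------


def test_fg_preference_and_tie():
    fg = np.array([[True, True, False, False]])
    tab = make_table(np.array([[[3]*10, [3]*10, [1]*10, [1]*10]]))
    assert scs.fg_preference(tab, make_labels(fg), 0) == "figure"
    tab2 = make_table(np.array([[[1]*10, [1]*10, [3]*10, [3]*10]]))
    assert scs.fg_preference(tab2, make_labels(fg), 0) == "ground"
    tab3 = make_table(np.array([[[2]*10, [2]*10, [2]*10, [2]*10]]))
    assert scs.fg_preference(tab3, make_labels(fg), 0) == "figure"  # tie rule


def test_modulation_ratio_definition():
    fg = np.array([[True, True, False, False]])
    tab = make_table(np.array([[[4]*10, [4]*10, [2]*10, [2]*10]]))
    # (4 - 2) / 3 with overall mean 3
    assert scs.modulation_ratio(tab, make_labels(fg), 0) == pytest.approx(2/3)


def test_favorite_stimuli_rule():
    """Peak single-trial count 10 -> threshold 5 (exclusive); stimulus
    means {6,5,4,3,2} leave only the 6 as favorite."""
    c = np.tile(np.array([6, 5, 4, 3, 2])[None, :, None], (1, 1, 10))
    c = c.astype(np.int64)
    c[0, 0, 0] = 10  # single peak trial; keeps the first mean above 6? no:
    # rebuild so the means stay exactly {6,5,4,3,2}
    c = np.tile(np.array([6, 5, 4, 3, 2])[None, :, None], (1, 1, 10)).astype(np.int64)
    c[0, 0, 0] = 10
    c[0, 0, 1] = 2  # mean of stim0 stays 6
    tab = make_table(c)
    assert scs.favorite_stimuli(tab, 0) == ["stim0"]


def test_favorite_stimuli_all_zero():
    tab = make_table(np.zeros((1, 5, 10)))
    assert scs.favorite_stimuli(tab, 0) == []


# ---------------------------------------------------------------------------
# paired differentials
# ---------------------------------------------------------------------------


def test_paired_difference_zero_for_identical_responses(counts, labels,
                                                        mp_pairs):
    i = 0
    tab = make_table(np.full_like(counts.counts[:1], 3))
    d = scs.paired_difference(
        sp.SpikeCountTable(counts.neuron_ids[:1], counts.stimulus_ids,
                           np.full_like(counts.counts[:1], 3),
                           np.zeros_like(counts.counts[:1])),
        mp_pairs, i, "figure")
    assert np.allclose(d, 0.0)


def test_paired_anova_type_one_rate():
    rng = np.random.default_rng(4)
    ps = [scs.paired_anova(rng.normal(0, 1, 60)) for _ in range(400)]
    rate = np.mean(np.array(ps) < 0.05)
    assert abs(rate - 0.05) < 4 * np.sqrt(0.05 * 0.95 / 400)


def test_paired_rank_curve_crossing():
    """63 positive differences out of 93 put the zero crossing right of
    centre and give the worked 68 % correct rate."""
    rng = np.random.default_rng(0)
    d = np.concatenate([rng.uniform(0.5, 5.0, 63), rng.uniform(-5.0, -0.5, 30)])
    res = scs.paired_correct_rate(rng.permutation(d))
    assert (res.n_correct, res.n_total) == (63, 93)
    assert round(100 * res.correct_rate) == 68
    assert res.zero_crossing_index == 63
    assert np.all(np.diff(res.rank_curve) <= 0)


# ---------------------------------------------------------------------------
# exclusion rules
# ---------------------------------------------------------------------------


def test_exclusion_silent_class():
    fg = np.zeros((1, 200), dtype=bool)
    fg[0, :100] = True
    c = np.zeros((1, 200, 10), dtype=np.int64)
    c[0, :100] = 2          # responds to figures only
    tab = make_table(c)
    lab = make_labels(fg)
    exc, reasons = scs.exclusion_filter(tab, lab, rule="single_cell")
    assert exc[0] and "ground" in reasons[0]


def test_exclusion_boundary_strict_vs_inclusive():
    """The single-cell rule excludes at < 80 active trials, the population
    rule at <= 80 active stimuli; both boundaries behave as printed."""
    fg = np.zeros((1, 200), dtype=bool)
    fg[0, :100] = True
    c = np.zeros((1, 200, 10), dtype=np.int64)
    c[0, :100] = 5
    # ground class: exactly 80 trials with spikes (8 stimuli x 10 trials)
    c[0, 100:108] = 1
    tab = make_table(c)
    lab = make_labels(fg)
    exc_sc, _ = scs.exclusion_filter(tab, lab, rule="single_cell")
    assert not exc_sc[0]        # 80 trials is not < 80
    exc_pop, _ = scs.exclusion_filter(tab, lab, rule="population")
    assert exc_pop[0]           # 8 active stimuli <= 80


# ---------------------------------------------------------------------------
# correct rates
# ---------------------------------------------------------------------------


def test_correct_rate_schematic_neuron():
    """Five stimuli, preference figure, threshold 3: counts {4,6,2,1,3}
    with labels {F,F,G,G,F} give 4 of 5 correct = 80 %."""
    values = np.array([4, 6, 2, 1, 3], dtype=float)
    preferred = np.array([True, True, False, False, True])
    n_c, n_t = scs.correct_rate_at_threshold(values, preferred, 3.0)
    assert (n_c, n_t) == (4, 5)
    assert 100.0 * n_c / n_t == 80.0


@settings(max_examples=40, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000))
def test_search_threshold_beats_any_integer_threshold(seed):
    rng = np.random.default_rng(seed)
    values = rng.poisson(3.0, 30).astype(float)
    preferred = rng.random(30) < 0.5
    if preferred.all() or (~preferred).all() or np.ptp(values) == 0:
        return
    thr, n_best = scs._search_threshold(values, preferred)
    for t in range(int(values.min()) - 1, int(values.max()) + 2):
        n_c, _ = scs.correct_rate_at_threshold(values, preferred, float(t))
        assert n_c <= n_best


def test_search_vs_svm_threshold_close(population, filled_set_full):
    """At the full stimulus count the exhaustive-search and 1-D SVM
    thresholds give mean correct rates within one percentage point."""
    tab = sp.simulate_counts(population[:20], filled_set_full, seed=61)
    lab = fl.label_by_center(population[:20], filled_set_full)
    diffs = []
    for i in range(20):
        a = scs.correct_rate(tab, lab, i, threshold_method="search")
        b = scs.correct_rate(tab, lab, i, threshold_method="svm-1d")
        diffs.append(a.correct_rate - b.correct_rate)
    assert abs(np.mean(diffs)) <= 0.01
    # search is optimal, so it can never lose to the SVM threshold
    assert min(diffs) >= 0.0


def test_correct_rate_degenerate_counts():
    fg = np.array([[True, True, False]])
    tab = make_table(np.full((1, 3, 10), 2, dtype=np.int64))
    res = scs.correct_rate(tab, make_labels(fg), 0, preference="figure")
    assert res.correct_rate == pytest.approx(2 / 3)


def test_correct_rate_monotone_in_modulation(filled_set):
    """Mean correct rate rises with the generative modulation ratio."""
    means = []
    for m in (0.0, 0.3, 0.6):
        pop = []
        for i in range(12):
            pop.append(sp.NeuronModel(
                id=f"n{i}", session_id="s0",
                crf_center=(0.4 * (i % 5) - 0.8, 0.3), crf_sigma=(0.8, 0.8),
                baseline_rate=5.0, drive_gain=30.0, fg_mod=m,
                contrast_mod=0.0, responsive_fraction=1.0, drive_jitter_sd=0.0,
                onset_latency=0.0, mod_latency=0.0,
                fg_significant_truth=m > 0))
        tab = sp.simulate_counts(pop, filled_set, seed=31)
        lab = fl.label_by_center(pop, filled_set)
        means.append(np.mean([
            scs.correct_rate(tab, lab, i).correct_rate for i in range(12)
        ]))
    assert means[0] < means[1] < means[2]
    assert means[0] < 0.62  # near-chance at the null


def test_paired_beats_single_under_stimulus_nuisance(filled_set):
    """With strong per-base drive nuisance the paired rates dominate the
    single-stimulus rates (pairing cancels the shared nuisance)."""
    from dataclasses import replace

    cfg = replace(sp.PopulationConfig(), responsive_fraction=1.0,
                  drive_jitter_sd=0.8, fg_significant_fraction=1.0)
    pop = sp.sample_population(15, cfg, seed=41)
    tab = sp.simulate_counts(pop, filled_set, seed=42)
    lab = fl.label_by_center(pop, filled_set)
    pairs = fl.build_pairs(lab, filled_set, "MP")
    single, paired = [], []
    for i in range(15):
        single.append(scs.correct_rate(tab, lab, i).correct_rate)
        pref = scs.fg_preference(tab, lab, i)
        d = scs.paired_difference(tab, pairs, i, pref)
        if d.size:
            paired.append(scs.paired_correct_rate(d).correct_rate)
    assert np.mean(paired) > np.mean(single)
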
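"""Per-neuron response statistics: responsiveness, FG/contrast ANOVA,
modulation ratio, favorite stimuli, paired differentials, exclusion rules,
and single-cell FG-classification consistency (correct rates).

Observation convention for the ANOVA: the unit of observation is the
stimulus (its mean count over trials), with FG and contrast as
between-stimulus factors — the simplest design consistent with
``response = FG + contrast + FG*contrast + noise``.  A trial-level variant
is available behind a flag.  Effects are tested with Type-II nested-model
F tests on statsmodels OLS fits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .fg_labeling import LabelTable, PairIndex
from .synthetic_population import SpikeCountTable

log = logging.getLogger(__name__)

ALPHA = 0.05


# ---------------------------------------------------------------------------
# responsiveness
# ---------------------------------------------------------------------------


def responsiveness_test(counts: SpikeCountTable, neuron: int | str) -> tuple[float, bool]:
    """Paired t test of stimulus-window vs pre-stimulus-window counts over
    all (stimulus, trial) observations.  Returns (p, significant_at_.05);
    zero variance in both windows gives p = 1 by convention."""
    i = counts.neuron_index(neuron) if isinstance(neuron, str) else neuron
    stim = counts.counts[i].ravel().astype(float)
    pre = counts.pre_counts[i].ravel().astype(float)
    diff = stim - pre
    if np.allclose(diff.std(), 0.0):
        if not np.allclose(diff.mean(), 0.0):  # constant nonzero shift
            return 0.0, True
        log.info("responsiveness_test: neuron %s has zero-variance windows", neuron)
        return 1.0, False
    t, p = stats.ttest_rel(stim, pre)
    return float(p), bool(p < ALPHA)


# ---------------------------------------------------------------------------
# FG / contrast ANOVA
# ---------------------------------------------------------------------------


def anscombe(x: np.ndarray) -> np.ndarray:
    """Variance-stabilising transform for Poisson counts: 2*sqrt(x + 3/8)."""
    return 2.0 * np.sqrt(np.asarray(x, dtype=float) + 0.375)


def _nested_f(y: np.ndarray, x_full: np.ndarray, x_restr: np.ndarray) -> float:
    full = sm.OLS(y, x_full).fit()
    restr = sm.OLS(y, x_restr).fit()
    if full.df_resid <= 0 or restr.ssr <= full.ssr:
        return 1.0
    f, p, _ = full.compare_f_test(restr)
    return float(p)


@dataclass
class AnovaResult:
    fg_p: float
    contrast_p: float | None
    interaction_p: float | None
    design: str  # 'two-way' | 'one-way'

    @property
    def fg_significant(self) -> bool:
        return self.fg_p < ALPHA


def fg_contrast_anova(
    counts: SpikeCountTable,
    labels: LabelTable,
    neuron: int | str,
    *,
    design: str = "two-way",
    transform: str = "none",
    observations: str = "stimulus",
    stimulus_mask: np.ndarray | None = None,
) -> AnovaResult:
    """FG x contrast ANOVA for one neuron.

    ``design='two-way'`` tests FG, contrast and their interaction (filled /
    square stimuli); ``'one-way'`` tests FG only (natural stimuli, which
    carry no contrast label).  ``transform='anscombe'`` stabilises the
    Poisson variance before averaging.  An empty design cell demotes the
    two-way design to one-way with a warning.
    """
    if design not in ("two-way", "one-way"):
        raise ValueError(f"unknown design {design!r}")
    if transform not in ("none", "anscombe"):
        raise ValueError(f"unknown transform {transform!r}")
    i = counts.neuron_index(neuron) if isinstance(neuron, str) else neuron
    c = counts.counts[i].astype(float)
    if transform == "anscombe":
        c = anscombe(c)
    fg = labels.fg[i]
    con = labels.contrast[i]
    sel = np.ones(len(fg), dtype=bool) if stimulus_mask is None else stimulus_mask
    if design == "two-way":
        sel = sel & (con != 0)
    fg, con, c = fg[sel], con[sel], c[sel]
    if observations == "stimulus":
        y = c.mean(axis=1)
        f_fac, c_fac = fg.astype(float), (con > 0).astype(float)
    elif observations == "trial":
        y = c.ravel()
        t = c.shape[1]
        f_fac = np.repeat(fg.astype(float), t)
        c_fac = np.repeat((con > 0).astype(float), t)
    else:
        raise ValueError(f"unknown observations {observations!r}")
    if fg.size < 4 or len(np.unique(fg)) < 2:
        return AnovaResult(1.0, None, None, design)
    one = np.ones_like(y)
    if design == "two-way":
        cells = {(a, b) for a, b in zip(f_fac, c_fac)}
        if len(cells) < 4:
            log.warning("fg_contrast_anova: empty design cell for neuron %s; "
                        "falling back to one-way", neuron)
            design = "one-way"
    if design == "one-way":
        p_fg = _nested_f(y, np.column_stack([one, f_fac]),
                         one[:, None])
        return AnovaResult(p_fg, None, None, "one-way")
    inter = f_fac * c_fac
    x_add = np.column_stack([one, f_fac, c_fac])
    p_fg = _nested_f(y, x_add, np.column_stack([one, c_fac]))
    p_con = _nested_f(y, x_add, np.column_stack([one, f_fac]))
    p_int = _nested_f(y, np.column_stack([one, f_fac, c_fac, inter]), x_add)
    return AnovaResult(p_fg, p_con, p_int, "two-way")


# ---------------------------------------------------------------------------
# modulation ratio, preference, favorites
# ---------------------------------------------------------------------------


def fg_preference(counts: SpikeCountTable, labels: LabelTable,
                  neuron: int | str) -> str:
    """Preferred side = the FG label with the higher mean rate; exact ties
    resolve to 'figure' (logged)."""
    i = counts.neuron_index(neuron) if isinstance(neuron, str) else neuron
    mean_per_stim = counts.counts[i].mean(axis=1)
    fg = labels.fg[i]
    if fg.all() or (~fg).all():
        raise ValueError(f"neuron {neuron}: only one FG label present")
    mf, mg = mean_per_stim[fg].mean(), mean_per_stim[~fg].mean()
    if mf == mg:
        log.info("fg_preference: exact tie for neuron %s; defaulting to figure",
                 neuron)
        return "figure"
    return "figure" if mf > mg else "ground"


def modulation_ratio(counts: SpikeCountTable, labels: LabelTable,
                     neuron: int | str) -> float:
    """(preferred mean - non-preferred mean) / overall mean, >= 0."""
    i = counts.neuron_index(neuron) if isinstance(neuron, str) else neuron
    mean_per_stim = counts.counts[i].mean(axis=1)
    fg = labels.fg[i]
    mf, mg = mean_per_stim[fg].mean(), mean_per_stim[~fg].mean()
    overall = mean_per_stim.mean()
    if overall <= 0:
        return 0.0
    return float(abs(mf - mg) / overall)


def favorite_stimuli(counts: SpikeCountTable, neuron: int | str,
                     *, criterion: str = "mean") -> list[str]:
    """Stimuli whose response exceeds half the neuron's peak response
    across all trials.

    Default: mean response per stimulus compared against half of the
    maximum single-trial count; ``criterion='trial'`` compares the
    per-stimulus maximum trial instead.
    """
    i = counts.neuron_index(neuron) if isinstance(neuron, str) else neuron
    c = counts.counts[i]
    peak = c.max()
    if peak <= 0:
        return []
    resp = c.mean(axis=1) if criterion == "mean" else c.max(axis=1)
    sel = resp > 0.5 * peak
    return [counts.stimulus_ids[j] for j in np.flatnonzero(sel)]


# ---------------------------------------------------------------------------
# paired differentials
# ---------------------------------------------------------------------------


def paired_difference(
    counts: SpikeCountTable, pairs: PairIndex, neuron: int | str,
    preference: str = "figure",
) -> np.ndarray:
    """Preferred-minus-non-preferred mean responses over the usable pairs.

    Each usable pair contributes (response to the member whose region label
    matches the neuron's preferred side) - (response to the other member).
    """
    i = counts.neuron_index(neuron) if isinstance(neuron, str) else neuron
    mean_per_stim = counts.counts[i].mean(axis=1)
    use = pairs.usable[i]
    fm = pairs.figure_member[i][use]
    a = pairs.pairs[use, 0]
    b = pairs.pairs[use, 1]
    fig_resp = np.where(fm == 0, mean_per_stim[a], mean_per_stim[b])
    gnd_resp = np.where(fm == 0, mean_per_stim[b], mean_per_stim[a])
    d = fig_resp - gnd_resp
    return d if preference == "figure" else -d


def paired_anova(diffs: np.ndarray) -> float:
    """F test (= squared one-sample t) of zero mean paired difference."""
    diffs = np.asarray(diffs, dtype=float)
    if diffs.size < 2 or np.allclose(diffs.std(ddof=1), 0):
        return 1.0 if np.allclose(diffs.mean(), 0) else 0.0
    t, p = stats.ttest_1samp(diffs, 0.0)
    return float(p)


# ---------------------------------------------------------------------------
# exclusion rules
# ---------------------------------------------------------------------------


def exclusion_filter(
    counts: SpikeCountTable, labels: LabelTable,
    *, rule: str = "single_cell", min_count: int = 80,
) -> tuple[np.ndarray, list[str]]:
    """Low-response exclusion flags (True = excluded), with reasons.

    ``rule='single_cell'``: a neuron is excluded when spikes were observed
    in strictly fewer than ``min_count`` trials for either FG class.
    ``rule='population'``: excluded when spikes were observed in at most
    ``min_count`` stimuli (10-trial sums) for either class.  Both printed
    criteria are kept as separately named rules.
    """
    if rule not in ("single_cell", "population"):
        raise ValueError(f"unknown exclusion rule {rule!r}")
    N = counts.counts.shape[0]
    excluded = np.zeros(N, dtype=bool)
    reasons = [""] * N
    for i in range(N):
        fg = labels.fg[i]
        for cls, sel in (("figure", fg), ("ground", ~fg)):
            if rule == "single_cell":
                n_active = int((counts.counts[i][sel] > 0).sum())
                bad = n_active < min_count
            else:
                sums = counts.counts[i][sel].sum(axis=1)
                n_active = int((sums > 0).sum())
                bad = n_active <= min_count
            if bad:
                excluded[i] = True
                reasons[i] = (f"{rule}: spikes in {n_active} {cls} "
                              f"responses (limit {min_count})")
                break
    return excluded, reasons


# ---------------------------------------------------------------------------
# correct rates
# ---------------------------------------------------------------------------


@dataclass
class ConsistencyResult:
    threshold: float
    correct_rate: float
    n_correct: int
    n_total: int
    mode: str                      # 'single' | 'paired-MP' | 'paired-TP'
    rank_curve: np.ndarray | None = None  # sorted F-G values, descending
    method: str = "search"

    @property
    def zero_crossing_index(self) -> int | None:
        if self.rank_curve is None:
            return None
        return int(np.sum(self.rank_curve > 0))


def correct_rate_at_threshold(
    values: np.ndarray, preferred: np.ndarray, threshold: float
) -> tuple[int, int]:
    """Apply the correct-rate rule at a fixed threshold.

    A response is correct when it is strictly greater than the threshold
    for a preferred-side stimulus, or strictly smaller for a non-preferred
    one; a response exactly at the threshold counts incorrect.
    """
    values = np.asarray(values, dtype=float)
    preferred = np.asarray(preferred, dtype=bool)
    correct = np.where(preferred, values > threshold, values < threshold)
    return int(correct.sum()), int(values.size)


def _search_threshold(values: np.ndarray, preferred: np.ndarray) -> tuple[float, int]:
    """Exhaustive threshold search over midpoints of adjacent observed
    values (plus flanking candidates); ties resolve to the lower threshold."""
    uniq = np.unique(values)
    cands = [uniq[0] - 1.0]
    cands += list((uniq[:-1] + uniq[1:]) / 2.0)
    cands.append(uniq[-1] + 1.0)
    best_thr, best_n = cands[0], -1
    for thr in cands:
        n_c, _ = correct_rate_at_threshold(values, preferred, thr)
        if n_c > best_n:
            best_thr, best_n = thr, n_c
    return float(best_thr), int(best_n)


def _svm1d_threshold(values: np.ndarray, preferred: np.ndarray) -> float:
    """One-dimensional soft-margin linear SVM separator on the counts.

    C is picked from a small grid by the in-sample correct rate of the
    resulting threshold (ties to the smallest C), mirroring the grid-search
    practice of the population decoder.
    """
    from sklearn.svm import SVC

    values = np.asarray(values, dtype=float)
    mu, sd = values.mean(), values.std()
    if sd <= 0:
        return float(mu)
    x = ((values - mu) / sd).reshape(-1, 1)
    y = np.asarray(preferred, dtype=int)
    best = None
    for c in (0.01, 0.1, 1.0, 10.0, 100.0, 1000.0):
        clf = SVC(kernel="linear", C=c)
        clf.fit(x, y)
        w = float(clf.coef_[0, 0])
        if abs(w) < 1e-9:
            continue
        thr = float(-clf.intercept_[0] / w) * sd + mu
        n_c, _ = correct_rate_at_threshold(values, preferred, thr)
        if best is None or n_c > best[0]:
            best = (n_c, thr)
    if best is None:
        return float(np.median(values))
    return best[1]


def correct_rate(
    counts: SpikeCountTable,
    labels: LabelTable,
    neuron: int | str,
    *,
    preference: str | None = None,
    threshold_method: str = "search",
    stimulus_mask: np.ndarray | None = None,
) -> ConsistencyResult:
    """Single-stimulus FG-classification consistency for one neuron.

    Per-stimulus responses (trial means) are classified against a
    per-neuron threshold determined either by exhaustive search or by a 1-D
    linear SVM; the correct rate is n_correct / n_total under the strict
    threshold rule.
    """
    i = counts.neuron_index(neuron) if isinstance(neuron, str) else neuron
    values = counts.counts[i].mean(axis=1)
    fg = labels.fg[i]
    if stimulus_mask is not None:
        values, fg = values[stimulus_mask], fg[stimulus_mask]
    if preference is None:
        preference = fg_preference(counts, labels, i)
    preferred = fg if preference == "figure" else ~fg
    if np.ptp(values) == 0:
        n_maj = int(max(preferred.sum(), (~preferred).sum()))
        log.info("correct_rate: neuron %s has single-valued counts", neuron)
        return ConsistencyResult(float(values[0]), n_maj / values.size,
                                 n_maj, values.size, "single",
                                 method=threshold_method)
    if threshold_method == "search":
        thr, n_c = _search_threshold(values, preferred)
    elif threshold_method == "svm-1d":
        thr = _svm1d_threshold(values, preferred)
        n_c, _ = correct_rate_at_threshold(values, preferred, thr)
    else:
        raise ValueError(f"unknown threshold_method {threshold_method!r}")
    return ConsistencyResult(thr, n_c / values.size, n_c, values.size,
                             "single", method=threshold_method)


def paired_correct_rate(
    diffs: np.ndarray, *, threshold: float = 0.0, mode: str = "paired-MP"
) -> ConsistencyResult:
    """Consistency over usable pairs: a pair is correct when its
    preferred-minus-non-preferred difference exceeds the threshold.

    The rank curve (differences sorted descending) crosses zero at the
    number of correct pairs.
    """
    d = np.sort(np.asarray(diffs, dtype=float))[::-1]
    n_c = int(np.sum(d > threshold))
    return ConsistencyResult(threshold, n_c / d.size if d.size else 0.0,
                             n_c, int(d.size), mode, rank_curve=d)


# ---------------------------------------------------------------------------
# per-neuron summary
# ---------------------------------------------------------------------------


@dataclass
class NeuronStats:
    neuron_id: str
    responsive: bool
    responsive_p: float
    fg_p: float
    contrast_p: float | None
    interaction_p: float | None
    fg_significant: bool
    preference: str
    modulation_ratio: float
    favorite_ids: list[str] = field(default_factory=list)
    excluded: bool = False
    exclusion_reason: str = ""

    @property
    def n_favorite(self) -> int:
        return len(self.favorite_ids)


def neuron_stats(
    counts: SpikeCountTable,
    labels: LabelTable,
    *,
    design: str = "two-way",
    transform: str = "none",
    exclusion_rule: str = "single_cell",
    stimulus_mask: np.ndarray | None = None,
) -> list[NeuronStats]:
    """Full per-neuron statistics table (responsiveness gate included:
    a neuron is FG-significant only if also responsive)."""
    excluded, reasons = exclusion_filter(counts, labels, rule=exclusion_rule)
    out = []
    for i, nid in enumerate(counts.neuron_ids):
        p_resp, resp = responsiveness_test(counts, i)
        res = fg_contrast_anova(counts, labels, i, design=design,
                                transform=transform,
                                stimulus_mask=stimulus_mask)
        out.append(NeuronStats(
            neuron_id=nid,
            responsive=resp, responsive_p=p_resp,
            fg_p=res.fg_p, contrast_p=res.contrast_p,
            interaction_p=res.interaction_p,
            fg_significant=bool(resp and res.fg_p < ALPHA),
            preference=fg_preference(counts, labels, i),
            modulation_ratio=modulation_ratio(counts, labels, i),
            favorite_ids=favorite_stimuli(counts, i),
            excluded=bool(excluded[i]),
            exclusion_reason=reasons[i],
        ))
    return out
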
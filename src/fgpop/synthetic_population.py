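"""Generative V4-like neuron populations and their spike-count responses.

Each simulated neuron is summarised by a classical receptive field (CRF)
centre and Gaussian extent, a baseline rate, a stimulus drive, a signed
figure-ground modulation ratio, a contrast modulation, a per-stimulus
responsiveness gate, and onset / FG-modulation latencies.  Responses are
inhomogeneous-Poisson spike counts:

    rate(t) = baseline                                   t < onset
            = baseline + g * drive * (1 + c*s_c)         onset <= t < mod
            = baseline + g * drive * (1 + m*s_fg) * (1 + c*s_c)   t >= mod

with s_fg = +1 when the stimulus' figure region covers the CRF centre
(-1 otherwise), s_c = +1 for a dark region at the centre (-1 light,
0 when polarity is undefined), and g a per-(neuron, stimulus) Bernoulli
responsiveness gate that is fixed across trials.  m is the neuron's signed
modulation ratio (negative for ground-preferring cells).

Counts and time-binned histograms are generated from shared per-segment
Poisson totals (bins are multinomial splits of the segment totals), so bin
sums over an analysis window reproduce the window counts exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from ._rng import substream
from .stimulus_geometry import GratingStimulus, StimulusSet, StimulusVariant

DEFAULT_WINDOW = (50.0, 250.0)      # ms relative to stimulus onset
DEFAULT_PRE_WINDOW = (-50.0, 50.0)  # baseline window
TRIALS_PER_STIMULUS = 10


@dataclass(frozen=True)
class PopulationConfig:
    """Generative defaults for the simulated population.

    The default values encode the regime the analysis targets: 24.3 % of
    cells carry genuine FG modulation, with mean modulation-ratio magnitude
    0.326 among them and 0.054 residual among the rest; 24 % of modulated
    cells prefer ground; the CRF extent averages 1.8 degrees in half-height
    diameter; onset and FG-modulation latencies default to 52.5 / 79.4 ms.
    """

    fg_significant_fraction: float = 0.243
    fg_mod_mean_significant: float = 0.326
    fg_mod_mean_null: float = 0.054
    ground_preferring_fraction: float = 0.24
    baseline_rate_mean: float = 5.0      # Hz
    drive_gain_mean: float = 30.0        # Hz above baseline when responsive
    responsive_fraction: float = 0.11    # P(a base patch drives the neuron)
    drive_jitter_sd: float = 0.5         # lognormal sigma of per-(neuron, base)
                                         # drive gain (stimulus-identity nuisance)
    contrast_mod_mean: float = 0.15
    crf_diameter_mean: float = 1.8       # degrees (half-height diameter)
    crf_diameter_sd: float = 0.45
    center_box_fraction: float = 0.22    # CRF centres uniform in +-frac*scale;
                                         # keeps CRFs inside the grating grid
                                         # with margin, as stimulus placement
                                         # over recorded fields would
    onset_latency_ms: float = 52.5
    mod_latency_ms: float = 79.4
    latency_jitter_ms: float = 0.0
    session_size: int = 40
    scale: float = 8.0                   # patch side, degrees

    def validate(self) -> None:
        for name in ("fg_significant_fraction", "ground_preferring_fraction",
                     "responsive_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        for name in ("baseline_rate_mean", "drive_gain_mean"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.fg_mod_mean_significant >= 0.9 or self.fg_mod_mean_null >= 0.9:
            raise ValueError(
                "modulation-ratio means must stay below 0.9 to keep "
                "(1 + m)(1 + c) rates non-negative"
            )
        if self.mod_latency_ms < self.onset_latency_ms:
            raise ValueError("mod_latency_ms must be >= onset_latency_ms")


def null_config(**overrides) -> PopulationConfig:
    """Configuration with zero FG modulation everywhere (the decoding null)."""
    return replace(
        PopulationConfig(fg_significant_fraction=0.0, fg_mod_mean_null=0.0),
        **overrides,
    )


@dataclass(frozen=True)
class NeuronModel:
    id: str
    session_id: str
    crf_center: tuple[float, float]   # degrees, patch frame
    crf_sigma: tuple[float, float]    # Gaussian sigma, degrees
    baseline_rate: float              # Hz
    drive_gain: float                 # Hz
    fg_mod: float                     # signed modulation ratio
    contrast_mod: float               # signed
    responsive_fraction: float
    drive_jitter_sd: float            # lognormal sigma of per-base drive gain
    onset_latency: float              # ms
    mod_latency: float                # ms
    fg_significant_truth: bool

    def __post_init__(self):
        if self.mod_latency < self.onset_latency:
            raise ValueError("mod_latency must be >= onset_latency")


_SIGMA_PER_DIAMETER = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def sample_population(
    n_neurons: int,
    config: PopulationConfig = PopulationConfig(),
    seed: int = 0,
) -> list[NeuronModel]:
    """Draw ground-truth neuron models (deterministic given seed).

    Each neuron uses its own counter-derived substream, so any subset of the
    population is reproducible independent of iteration order.
    """
    if n_neurons < 1:
        raise ValueError("n_neurons must be >= 1")
    config.validate()
    box = config.center_box_fraction * config.scale
    out: list[NeuronModel] = []
    for i in range(n_neurons):
        rng = substream(seed, "population", i)
        significant = bool(rng.random() < config.fg_significant_fraction)
        mean = (config.fg_mod_mean_significant if significant
                else config.fg_mod_mean_null)
        mag = float(min(rng.gamma(4.0, mean / 4.0), 0.9)) if mean > 0 else 0.0
        sign = -1.0 if rng.random() < config.ground_preferring_fraction else 1.0
        cmag = (float(min(rng.gamma(4.0, config.contrast_mod_mean / 4.0), 0.9))
                if config.contrast_mod_mean > 0 else 0.0)
        csign = -1.0 if rng.random() < 0.5 else 1.0
        diam = float(np.clip(
            rng.normal(config.crf_diameter_mean, config.crf_diameter_sd),
            0.4, 4.0,
        ))
        sig = diam * _SIGMA_PER_DIAMETER
        onset = config.onset_latency_ms
        mod = config.mod_latency_ms
        if config.latency_jitter_ms > 0:
            onset = max(0.0, onset + rng.normal(0, config.latency_jitter_ms))
            mod = max(onset, mod + rng.normal(0, config.latency_jitter_ms))
        out.append(NeuronModel(
            id=f"n{i:05d}",
            session_id=f"s{i // config.session_size:03d}",
            crf_center=(float(rng.uniform(-box, box)),
                        float(rng.uniform(-box, box))),
            crf_sigma=(sig, sig),
            baseline_rate=float(rng.gamma(4.0, config.baseline_rate_mean / 4.0)),
            drive_gain=float(rng.gamma(4.0, config.drive_gain_mean / 4.0)),
            fg_mod=sign * mag,
            contrast_mod=csign * cmag,
            responsive_fraction=config.responsive_fraction,
            drive_jitter_sd=config.drive_jitter_sd,
            onset_latency=onset,
            mod_latency=mod,
            fg_significant_truth=significant,
        ))
    return out


def population_frame(neurons: Sequence[NeuronModel]) -> pd.DataFrame:
    """Per-neuron ground truth as a DataFrame (CSV-exportable)."""
    return pd.DataFrame([
        {
            "neuron_id": n.id, "session_id": n.session_id,
            "crf_x": n.crf_center[0], "crf_y": n.crf_center[1],
            "crf_sigma_x": n.crf_sigma[0], "crf_sigma_y": n.crf_sigma[1],
            "baseline_rate": n.baseline_rate, "drive_gain": n.drive_gain,
            "fg_mod": n.fg_mod, "contrast_mod": n.contrast_mod,
            "responsive_fraction": n.responsive_fraction,
            "onset_latency": n.onset_latency, "mod_latency": n.mod_latency,
            "fg_significant_truth": n.fg_significant_truth,
        }
        for n in neurons
    ])


# ---------------------------------------------------------------------------
# stimulus sign structure
# ---------------------------------------------------------------------------


def stimulus_signs(
    neurons: Sequence[NeuronModel], variants: Sequence[StimulusVariant]
) -> tuple[np.ndarray, np.ndarray]:
    """(s_fg, s_c) sign matrices of shape (n_neurons, n_stimuli).

    s_fg is +1 where the variant's figure region covers the neuron's CRF
    centre; s_c is +1 for a dark region there, -1 light, 0 undefined.
    Uses the same geometric path as the veridical labelling.
    """
    centers = np.array([n.crf_center for n in neurons], dtype=float)
    s_fg = np.empty((len(neurons), len(variants)), dtype=np.int8)
    s_c = np.zeros((len(neurons), len(variants)), dtype=np.int8)
    for j, v in enumerate(variants):
        fig = v.figure_at(centers)
        s_fg[:, j] = np.where(fig, 1, -1)
        pol = v.polarity_at(centers)
        if pol is not None:
            s_c[:, j] = np.where(pol == "dark", 1, -1)
    return s_fg, s_c


def responsiveness_gates(
    neurons: Sequence[NeuronModel],
    variants: Sequence[StimulusVariant],
    seed: int,
) -> np.ndarray:
    """Per-(neuron, stimulus) effective drive multipliers, trial-fixed.

    The Bernoulli responsiveness gate and a lognormal drive jitter are
    drawn per (neuron, *base patch*), so every variant of the same base
    shares them.  The jitter is the stimulus-identity nuisance that makes
    responses to a base idiosyncratic; mirror/translation pairing cancels
    it, as it cancels shape-selectivity in recorded neurons.
    """
    base_ids = sorted({v.base_id for v in variants})
    base_index = {b: k for k, b in enumerate(base_ids)}
    col = np.array([base_index[v.base_id] for v in variants])
    mods = np.empty((len(neurons), len(variants)))
    for i, n in enumerate(neurons):
        rng = substream(seed, "gate", i)
        gate = rng.random(len(base_ids)) < n.responsive_fraction
        jitter = (rng.lognormal(-0.5 * n.drive_jitter_sd**2, n.drive_jitter_sd,
                                len(base_ids))
                  if n.drive_jitter_sd > 0 else np.ones(len(base_ids)))
        mods[i] = (gate * jitter)[col]
    return mods


def _segments(
    neuron: NeuronModel, t0: float, t1: float,
    extra_edges: tuple[float, ...] = (),
) -> np.ndarray:
    """Breakpoints of the piecewise-constant rate profile within [t0, t1].

    ``extra_edges`` (analysis-window boundaries) are inserted so that every
    window of interest is an exact union of segments; counts and binned
    draws must use the same edge set to share their Poisson totals.
    """
    edges = {t0, t1, 0.0, neuron.onset_latency, neuron.mod_latency,
             *extra_edges}
    return np.array(sorted(t for t in edges if t0 <= t <= t1))


def _segment_rates(
    neuron: NeuronModel, gate: np.ndarray, s_fg: np.ndarray, s_c: np.ndarray,
    edges: np.ndarray,
) -> np.ndarray:
    """Rates (Hz) per (segment, stimulus) for one neuron; ``gate`` is the
    effective per-stimulus drive multiplier (0 when unresponsive)."""
    drive = gate * neuron.drive_gain
    contrast_term = 1.0 + neuron.contrast_mod * s_c
    fg_term = 1.0 + neuron.fg_mod * s_fg
    rates = np.empty((len(edges) - 1, len(gate)))
    for k in range(len(edges) - 1):
        t = edges[k]
        if t < neuron.onset_latency or t < 0.0:
            rates[k] = neuron.baseline_rate
        elif t < neuron.mod_latency:
            rates[k] = neuron.baseline_rate + drive * contrast_term
        else:
            rates[k] = neuron.baseline_rate + drive * contrast_term * fg_term
    return np.maximum(rates, 0.0)


# ---------------------------------------------------------------------------
# count tables
# ---------------------------------------------------------------------------


@dataclass
class SpikeCountTable:
    """Spike counts per (neuron, stimulus, trial) for two analysis windows."""

    neuron_ids: list[str]
    stimulus_ids: list[str]
    counts: np.ndarray       # (N, S, T) stimulus-window counts
    pre_counts: np.ndarray   # (N, S, T) pre-stimulus-window counts
    window: tuple[float, float] = DEFAULT_WINDOW
    pre_window: tuple[float, float] = DEFAULT_PRE_WINDOW
    gates: np.ndarray | None = None   # (N, S) effective drive multipliers
    s_fg: np.ndarray | None = None    # (N, S) generative FG signs

    @property
    def trials_per_stimulus(self) -> int:
        return self.counts.shape[2]

    def neuron_index(self, neuron_id: str) -> int:
        return self.neuron_ids.index(neuron_id)


@dataclass
class BinnedResponse:
    """Time-binned counts (N, S, T, B); summing bins over a window
    reproduces the matching SpikeCountTable entries exactly."""

    neuron_ids: list[str]
    stimulus_ids: list[str]
    bins: np.ndarray          # (N, S, T, B) uint16
    bin_ms: float
    time_range: tuple[float, float]

    @property
    def bin_edges(self) -> np.ndarray:
        t0, t1 = self.time_range
        return np.arange(t0, t1 + 0.5 * self.bin_ms, self.bin_ms)

    @property
    def bin_centers(self) -> np.ndarray:
        e = self.bin_edges
        return 0.5 * (e[:-1] + e[1:])

    def window_sum(self, window: tuple[float, float]) -> np.ndarray:
        e = self.bin_edges
        sel = (e[:-1] >= window[0] - 1e-9) & (e[1:] <= window[1] + 1e-9)
        return self.bins[..., sel].sum(axis=-1)


def _draw_segment_counts(
    neurons: Sequence[NeuronModel],
    gates: np.ndarray, s_fg: np.ndarray, s_c: np.ndarray,
    t_range: tuple[float, float], trials: int, seed: int,
    extra_edges: tuple[float, ...] = (),
):
    """Yield (i, edges, counts[(n_seg, S, T)]) per neuron, from the shared
    'counts' substreams (the seed protocol shared by counts and bins)."""
    for i, n in enumerate(neurons):
        rng = substream(seed, "counts", i)
        edges = _segments(n, *t_range, extra_edges)
        rates = _segment_rates(n, gates[i], s_fg[i], s_c[i], edges)
        durs = np.diff(edges) / 1000.0  # s
        lam = rates * durs[:, None]     # (n_seg, S)
        counts = rng.poisson(np.repeat(lam[:, :, None], trials, axis=2))
        yield i, edges, counts


def simulate_counts(
    neurons: Sequence[NeuronModel],
    stimulus_set: StimulusSet,
    seed: int = 0,
    *,
    window: tuple[float, float] = DEFAULT_WINDOW,
    pre_window: tuple[float, float] = DEFAULT_PRE_WINDOW,
    trials: int = TRIALS_PER_STIMULUS,
) -> SpikeCountTable:
    """Poisson spike-count table over the stimulus and pre-stimulus windows."""
    variants = stimulus_set.variants
    scale = stimulus_set.scale
    for n in neurons:
        if max(abs(n.crf_center[0]), abs(n.crf_center[1])) > scale / 2:
            raise ValueError(f"neuron {n.id} CRF centre outside the patch frame")
    s_fg, s_c = stimulus_signs(neurons, variants)
    gates = responsiveness_gates(neurons, variants, seed)
    t_range = (min(pre_window[0], window[0]), max(pre_window[1], window[1]))
    N, S = len(neurons), len(variants)
    counts = np.zeros((N, S, trials), dtype=np.int64)
    pre = np.zeros((N, S, trials), dtype=np.int64)
    win_edges = (*window, *pre_window)
    for i, edges, seg_counts in _draw_segment_counts(
        neurons, gates, s_fg, s_c, t_range, trials, seed, win_edges
    ):
        in_win = (edges[:-1] >= window[0] - 1e-9) & (edges[1:] <= window[1] + 1e-9)
        in_pre = (edges[:-1] >= pre_window[0] - 1e-9) & (edges[1:] <= pre_window[1] + 1e-9)
        counts[i] = seg_counts[in_win].sum(axis=0)
        pre[i] = seg_counts[in_pre].sum(axis=0)
    return SpikeCountTable(
        [n.id for n in neurons], [v.id for v in variants],
        counts, pre, window, pre_window, gates, s_fg,
    )


def simulate_binned(
    neurons: Sequence[NeuronModel],
    stimulus_set: StimulusSet,
    bin_ms: float = 1.0,
    seed: int = 0,
    *,
    time_range: tuple[float, float] = (-50.0, 250.0),
    trials: int = TRIALS_PER_STIMULUS,
    align_windows: tuple[tuple[float, float], tuple[float, float]] = (
        DEFAULT_WINDOW, DEFAULT_PRE_WINDOW),
) -> BinnedResponse:
    """Time-binned responses sharing segment totals with simulate_counts.

    Each piecewise-constant rate segment's total (the same Poisson draw used
    for the window counts) is spread over the covered bins multinomially
    with probabilities proportional to bin/segment overlap, making bin sums
    exactly consistent with the count table under the same seed.
    """
    span = time_range[1] - time_range[0]
    nb = span / bin_ms
    if abs(nb - round(nb)) > 1e-9:
        raise ValueError("bin width must divide the time range")
    nb = int(round(nb))
    variants = stimulus_set.variants
    s_fg, s_c = stimulus_signs(neurons, variants)
    gates = responsiveness_gates(neurons, variants, seed)
    N, S = len(neurons), len(variants)
    bins = np.zeros((N, S, trials, nb), dtype=np.uint16)
    bin_lo = time_range[0] + bin_ms * np.arange(nb)
    bin_hi = bin_lo + bin_ms
    win_edges = tuple(t for w in align_windows for t in w)
    for i, edges, seg_counts in _draw_segment_counts(
        neurons, gates, s_fg, s_c, time_range, trials, seed, win_edges
    ):
        rng = substream(seed, "bins", i)
        for k in range(len(edges) - 1):
            a, b = edges[k], edges[k + 1]
            overlap = np.clip(np.minimum(bin_hi, b) - np.maximum(bin_lo, a), 0, None)
            if overlap.sum() <= 0:
                continue
            p = overlap / overlap.sum()
            bins[i] += rng.multinomial(
                seg_counts[k], p
            ).astype(np.uint16)
    return BinnedResponse(
        [n.id for n in neurons], [v.id for v in variants],
        bins, bin_ms, time_range,
    )


# ---------------------------------------------------------------------------
# grating maps
# ---------------------------------------------------------------------------


@dataclass
class GratingMaps:
    """Mean spike-count maps on the CRF-mapping position grid."""

    neuron_ids: list[str]
    positions: np.ndarray   # (P, 2) degrees
    maps: np.ndarray        # (N, P) mean counts over repeats


def grating_positions(gratings: Sequence[GratingStimulus]) -> np.ndarray:
    pos = sorted({g.position for g in gratings})
    return np.array(pos, dtype=float)


def simulate_grating_maps(
    neurons: Sequence[NeuronModel],
    positions: np.ndarray,
    seed: int = 0,
    *,
    repeats: int = 10,
    window_s: float = 0.2,
) -> GratingMaps:
    """Mean spike counts at each grating position (Poisson over repeats).

    The expected count is (baseline + drive * G(pos)) * window with G the
    neuron's CRF Gaussian; the grid must cover every CRF centre.
    """
    positions = np.asarray(positions, dtype=float)
    lo, hi = positions.min(axis=0), positions.max(axis=0)
    for n in neurons:
        c = np.asarray(n.crf_center)
        if np.any(c < lo - 1e-9) or np.any(c > hi + 1e-9):
            raise ValueError(f"grid does not cover CRF centre of neuron {n.id}")
    maps = np.empty((len(neurons), len(positions)))
    for i, n in enumerate(neurons):
        rng = substream(seed, "grating", i)
        d = positions - np.asarray(n.crf_center)
        g = np.exp(-(d[:, 0] ** 2 / (2 * n.crf_sigma[0] ** 2)
                     + d[:, 1] ** 2 / (2 * n.crf_sigma[1] ** 2)))
        lam = (n.baseline_rate + n.drive_gain * g) * window_s
        if repeats <= 0:  # noiseless limit
            maps[i] = lam
        else:
            maps[i] = rng.poisson(np.repeat(lam[None, :], repeats, axis=0)).mean(axis=0)
    return GratingMaps([n.id for n in neurons], positions, maps)
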
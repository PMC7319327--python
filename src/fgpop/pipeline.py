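"""End-to-end orchestration: stimuli -> simulate -> CRF -> label ->
single-cell statistics -> latency -> population decoding.

A run is fully described by a :class:`RunConfig`; re-running with the same
config (and hence the same master seed) reproduces the summary JSON byte
for byte.  Every stage consumes only the outputs of earlier stages.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .crf_mapping import CRFEstimate, fit_population
from .fg_labeling import LabelTable, PairIndex, build_pairs, label_by_center, \
    label_by_overlap
from .latency import estimate_latencies
from .population_decoding import DecoderConfig, integration_curve
from .single_cell_stats import correct_rate, fg_preference, neuron_stats, \
    paired_correct_rate, paired_difference
from .stimulus_geometry import StimulusSet, default_bases, enumerate_set, \
    grating_set, manifest
from .synthetic_population import GratingMaps, PopulationConfig, \
    grating_positions, population_frame, sample_population, simulate_binned, \
    simulate_counts, simulate_grating_maps

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """A complete, serialisable description of one analysis run."""

    seed: int = 0
    n_bases: int = 105
    families: tuple[str, ...] = ("natural", "filled")
    n_neurons: int = 200
    population: PopulationConfig = field(default_factory=PopulationConfig)
    label_method: str = "center"          # 'center' | 'overlap'
    use_fitted_crf: bool = True           # False: generative-truth labels
    anova_transform: str = "none"         # 'none' | 'anscombe'
    exclusion_rule: str = "single_cell"
    threshold_method: str = "search"      # 'search' | 'svm-1d'
    latency_n_bases: int = 30             # filled bases used for PSTHs
    latency_max_neurons: int = 60
    decoder: DecoderConfig = field(default_factory=lambda: DecoderConfig(
        repeats=20, neuron_counts=(1, 10, 30), max_per_class=50))
    conditions: tuple[str, ...] = ("filled", "mp", "control")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["decoder"]["c_grid"] = [float(x) for x in d["decoder"]["c_grid"]]
        d["decoder"]["gamma_grid"] = [float(x) for x in d["decoder"]["gamma_grid"]]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "population" in d and isinstance(d["population"], dict):
            d["population"] = PopulationConfig(**d["population"])
        if "decoder" in d and isinstance(d["decoder"], dict):
            dec = dict(d["decoder"])
            for k in ("c_grid", "gamma_grid"):
                if k in dec:
                    dec[k] = np.asarray(dec[k], dtype=float)
            if "neuron_counts" in dec:
                dec["neuron_counts"] = tuple(dec["neuron_counts"])
            d["decoder"] = DecoderConfig(**dec)
        for k in ("families", "conditions"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage


def _round(x, nd=6):
    if isinstance(x, dict):
        return {k: _round(v, nd) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_round(v, nd) for v in x]
    if isinstance(x, (float, np.floating)):
        return round(float(x), nd)
    if isinstance(x, (int, np.integer, bool, str)) or x is None:
        return x
    return x


def run_pipeline(config: RunConfig, out_dir: str | Path | None = None) -> dict:
    """Execute the full analysis and return (and optionally write) the
    summary.  Any stage failure aborts with the stage name; outputs of the
    completed stages are already on disk when ``out_dir`` is given."""
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    def save_df(df: pd.DataFrame, name: str):
        if out is not None:
            df.to_csv(out / name, index=False)

    stage = "stimuli"
    try:
        bases = default_bases(config.n_bases, seed=config.seed,
                              scale=config.population.scale)
        stimset = enumerate_set(bases, config.families, seed=config.seed)
        if out is not None:
            (out / "stimuli.json").write_text(manifest(stimset))

        stage = "simulate"
        neurons = sample_population(config.n_neurons, config.population,
                                    seed=config.seed)
        counts = simulate_counts(neurons, stimset, seed=config.seed + 1)
        positions = grating_positions(grating_set(scale=config.population.scale))
        maps = simulate_grating_maps(neurons, positions, seed=config.seed + 2)
        save_df(population_frame(neurons), "population.csv")

        stage = "crf"
        if config.use_fitted_crf:
            estimates = fit_population(maps)
            sources = estimates
            save_df(pd.DataFrame([
                {"neuron_id": n.id, "x": e.center[0], "y": e.center[1],
                 "sigma_x": e.sigma[0], "sigma_y": e.sigma[1],
                 "extent_diameter": e.extent_diameter, "r2": e.fit_quality,
                 "valid": e.valid}
                for n, e in zip(neurons, estimates)
            ]), "crf.csv")
        else:
            sources = neurons

        stage = "label"
        if config.label_method == "center":
            labels = label_by_center(sources, stimset)
        else:
            if not config.use_fitted_crf:
                raise ValueError("overlap labelling requires fitted CRFs")
            labels = label_by_overlap(sources, stimset)
        labels.neuron_ids = [n.id for n in neurons]

        stage = "cellstats"
        fam = np.array([v.family for v in stimset.variants])
        two_way_mask = np.isin(fam, ("filled", "square"))
        stats = neuron_stats(counts, labels, transform=config.anova_transform,
                             exclusion_rule=config.exclusion_rule,
                             stimulus_mask=two_way_mask if two_way_mask.any() else None)
        save_df(pd.DataFrame([{
            "neuron_id": s.neuron_id, "responsive": s.responsive,
            "fg_p": s.fg_p, "fg_significant": s.fg_significant,
            "preference": s.preference,
            "modulation_ratio": s.modulation_ratio,
            "n_favorite": s.n_favorite, "excluded": s.excluded,
        } for s in stats]), "cellstats.csv")

        sig = np.array([s.fg_significant for s in stats])
        kept = sig & ~np.array([s.excluded for s in stats]) & labels.valid
        filled_mask = fam == "filled"
        single_rates = [
            correct_rate(counts, labels, i,
                         threshold_method=config.threshold_method,
                         stimulus_mask=filled_mask if filled_mask.any() else None
                         ).correct_rate
            for i in np.flatnonzero(kept)
        ]
        mp_pairs = build_pairs(labels, stimset, "MP")
        tp_pairs = (build_pairs(labels, stimset, "TP")
                    if "filled" in config.families else None)
        mp_rates = []
        for i in np.flatnonzero(kept):
            pref = fg_preference(counts, labels, i)
            d = paired_difference(counts, mp_pairs, int(i), pref)
            if d.size:
                mp_rates.append(paired_correct_rate(d).correct_rate)

        stage = "latency"
        lat_pool = np.flatnonzero(sig)[: config.latency_max_neurons]
        latencies: dict = {}
        if lat_pool.size >= 3:
            lat_bases = bases[: config.latency_n_bases]
            lat_set = enumerate_set(lat_bases, ["filled"], seed=config.seed)
            lat_neurons = [neurons[i] for i in lat_pool]
            # independent seed: the preferred side must not be estimated on
            # the same draws that enter the PSTH, or the argmax selection
            # noise masquerades as FG modulation starting at response onset
            binned = simulate_binned(lat_neurons, lat_set, 1.0,
                                     seed=config.seed + 7)
            lat_labels = label_by_center(
                [sources[i] for i in lat_pool] if config.use_fitted_crf
                else lat_neurons, lat_set)
            pref_class = np.empty_like(lat_labels.fg)
            for k, i in enumerate(lat_pool):
                pref = fg_preference(counts, labels, int(i))
                pref_class[k] = lat_labels.fg[k] if pref == "figure" \
                    else ~lat_labels.fg[k]
            ests = estimate_latencies(binned, pref_class)
            latencies = {
                "onset_ms": ests["onset"].latency_ms,
                "onset_r2": ests["onset"].fit_r2,
                "modulation_ms": ests["modulation"].latency_ms,
                "modulation_r2": ests["modulation"].fit_r2,
            }
            if out is not None:
                (out / "latency.json").write_text(
                    json.dumps(_round(latencies), indent=1, sort_keys=True))

        stage = "decode"
        curves = {}
        pool_map = {
            "filled": (np.flatnonzero(kept), "raw", None, filled_mask),
            "natural": (np.flatnonzero(kept), "raw", None, fam == "natural"),
            "mp": (np.flatnonzero(kept), "paired", mp_pairs, None),
            "tp": (np.flatnonzero(kept), "paired", tp_pairs, None),
            "control": (np.flatnonzero(~sig & labels.valid), "raw", None,
                        filled_mask),
        }
        rows = []
        for cond in config.conditions:
            pool, mode, prs, smask = pool_map[cond]
            max_n = max(config.decoder.neuron_counts)
            if pool.size < max_n:
                log.warning("decode: pool for %s holds %d < %d neurons; skipped",
                            cond, pool.size, max_n)
                continue
            if smask is not None and not smask.any():
                continue
            curve = integration_curve(
                counts, labels, pool, config.decoder, seed=config.seed + 3,
                mode=mode, pairs=prs, stimulus_mask=smask, condition=cond)
            curves[cond] = {
                "n": list(curve.neuron_counts),
                "mean": [float(m) for m in curve.mean],
                "sd": [float(s) for s in curve.sd],
            }
            for k, n in enumerate(curve.neuron_counts):
                rows.append({"condition": cond, "n_neurons": n,
                             "mean": curve.mean[k], "sd": curve.sd[k],
                             "repeats": config.decoder.repeats})
        if rows:
            save_df(pd.DataFrame(rows), "decoding.csv")
    except Exception as e:  # noqa: BLE001 - annotate the failing stage
        raise StageError(stage, e) from e

    summary = _round({
        "config_digest": config.digest(),
        "seed": config.seed,
        "version": __version__,
        "n_neurons": config.n_neurons,
        "n_stimuli": len(stimset.variants),
        "family_counts": stimset.family_counts,
        "fraction_responsive": float(np.mean([s.responsive for s in stats])),
        "fraction_fg_significant": float(sig.mean()),
        "fraction_excluded": float(np.mean([s.excluded for s in stats])),
        "mean_n_favorite": float(np.mean([s.n_favorite for s in stats])),
        "mean_modulation_ratio_significant": float(np.mean(
            [s.modulation_ratio for s in stats if s.fg_significant])) if sig.any() else None,
        "mean_modulation_ratio_other": float(np.mean(
            [s.modulation_ratio for s in stats if not s.fg_significant])) if (~sig).any() else None,
        "mean_correct_rate_single": float(np.mean(single_rates)) if single_rates else None,
        "mean_correct_rate_paired_mp": float(np.mean(mp_rates)) if mp_rates else None,
        "latencies": latencies,
        "decoding": curves,
    })
    if out is not None:
        (out / "summary.json").write_text(
            json.dumps(summary, indent=1, sort_keys=True))
        (out / "config.json").write_text(
            json.dumps(config.to_dict(), indent=1, sort_keys=True))
    return summary
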
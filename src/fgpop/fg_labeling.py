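"""Veridical figure-ground labelling per (neuron, stimulus) and pair indices.

Two labelling rules are provided, mirroring the two ways a receptive field
can be related to a stimulus region:

* centre rule — the label of the region containing the CRF centre;
* overlap rule — 'figure' when the half-height CRF ellipse overlaps the
  figural region more than the ground region (area computed on the 69x69
  mask lattice; exact ties fall back to the centre rule).

Mirror pairs (MPs) and translation pairs (TPs) are indexed per neuron; a
pair is *usable* when exactly one member is labelled figure, so that the
pair yields one figure and one ground response.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .crf_mapping import CRFEstimate, crf_ellipse
from .stimulus_geometry import StimulusSet, lattice_points

log = logging.getLogger(__name__)


@dataclass
class LabelTable:
    """Per-(neuron, stimulus) FG and contrast labels.

    ``fg`` is True for 'figure'; ``contrast`` is +1 dark / -1 light / 0 n.a.
    ``valid`` flags neurons whose labels could be computed (CRF inside the
    frame / ellipse overlapping it).
    """

    neuron_ids: list[str]
    stimulus_ids: list[str]
    fg: np.ndarray        # (N, S) bool
    contrast: np.ndarray  # (N, S) int8
    method: str           # 'center' | 'overlap'
    valid: np.ndarray     # (N,) bool

    def frame(self) -> pd.DataFrame:
        n_idx, s_idx = np.meshgrid(
            np.arange(len(self.neuron_ids)), np.arange(len(self.stimulus_ids)),
            indexing="ij",
        )
        return pd.DataFrame({
            "neuron_id": np.asarray(self.neuron_ids)[n_idx.ravel()],
            "stimulus_id": np.asarray(self.stimulus_ids)[s_idx.ravel()],
            "fg": np.where(self.fg.ravel(), "figure", "ground"),
            "contrast": np.choose(self.contrast.ravel() + 1,
                                  ["light", "na", "dark"]),
            "method": self.method,
        })


def _centers_from(sources) -> np.ndarray:
    pts = []
    for s in sources:
        if isinstance(s, CRFEstimate):
            pts.append(s.center)
        elif hasattr(s, "crf_center"):
            pts.append(s.crf_center)
        else:
            pts.append(tuple(s))
    return np.asarray(pts, dtype=float)


def label_by_center(sources, stimulus_set: StimulusSet) -> LabelTable:
    """Centre-rule labels.

    ``sources`` may be CRF estimates, neuron models (generative-truth mode)
    or raw (x, y) centres.  Neurons whose centre falls outside the patch
    frame are flagged invalid and logged.
    """
    centers = _centers_from(sources)
    half = stimulus_set.scale / 2.0
    valid = np.all(np.isfinite(centers), axis=1) & \
        np.all(np.abs(centers) <= half, axis=1)
    for i in np.flatnonzero(~valid):
        log.info("label_by_center: neuron %d excluded (centre %s outside frame)",
                 i, centers[i])
    variants = stimulus_set.variants
    N, S = len(centers), len(variants)
    fg = np.zeros((N, S), dtype=bool)
    contrast = np.zeros((N, S), dtype=np.int8)
    safe = np.where(valid[:, None], centers, 0.0)
    for j, v in enumerate(variants):
        fg[:, j] = v.figure_at(safe)
        pol = v.polarity_at(safe)
        if pol is not None:
            contrast[:, j] = np.where(pol == "dark", 1, -1)
    ids = [getattr(s, "id", f"n{i:05d}") for i, s in enumerate(sources)]
    return LabelTable(ids, [v.id for v in variants], fg, contrast, "center", valid)


def label_by_overlap(
    estimates: Sequence[CRFEstimate], stimulus_set: StimulusSet
) -> LabelTable:
    """Overlap-rule labels from half-height CRF ellipses.

    The figure/ground overlap areas are integrated on the 69x69 mask
    lattice (cell-centre sampling).  Exact area ties fall back to the
    centre rule (logged); an ellipse with no lattice cell inside the frame
    invalidates the neuron.  Contrast labels use the centre rule (polarity
    is a point property).
    """
    variants = stimulus_set.variants
    pts = lattice_points(stimulus_set.scale).reshape(-1, 2)
    masks = np.stack([v.mask().ravel() for v in variants])  # (S, P)
    center_tab = label_by_center(estimates, stimulus_set)
    N, S = len(estimates), len(variants)
    fg = np.zeros((N, S), dtype=bool)
    valid = center_tab.valid.copy()
    n_ties = 0
    for i, est in enumerate(estimates):
        if not valid[i]:
            continue
        inside = crf_ellipse(est, 0.5)(pts)  # (P,)
        if not inside.any():
            valid[i] = False
            log.info("label_by_overlap: neuron %d excluded (ellipse outside frame)", i)
            continue
        fig_area = masks[:, inside].sum(axis=1)
        gnd_area = inside.sum() - fig_area
        tie = fig_area == gnd_area
        n_ties += int(tie.sum())
        fg[i] = np.where(tie, center_tab.fg[i], fig_area > gnd_area)
    if n_ties:
        log.info("label_by_overlap: %d exact ties resolved by the centre rule", n_ties)
    return LabelTable(center_tab.neuron_ids, center_tab.stimulus_ids,
                      fg, center_tab.contrast, "overlap", valid)


@dataclass
class PairIndex:
    """Mirror/translation pair structure over a stimulus set.

    ``pairs`` holds (index_a, index_b) into the stimulus list, member a
    being the unmirrored/untranslated one.  ``usable[i, p]`` is True when
    exactly one member is labelled figure for neuron i; ``figure_member``
    records which member (0=a, 1=b, -1 unusable).
    """

    neuron_ids: list[str]
    stimulus_ids: list[str]
    base_ids: list[str]
    pairs: np.ndarray          # (P, 2) int
    pair_type: str             # 'MP' | 'TP'
    usable: np.ndarray         # (N, P) bool
    figure_member: np.ndarray  # (N, P) int8

    def usable_counts(self) -> np.ndarray:
        return self.usable.sum(axis=1)

    def frame(self) -> pd.DataFrame:
        rows = []
        sid = np.asarray(self.stimulus_ids)
        for i, nid in enumerate(self.neuron_ids):
            for p, (a, b) in enumerate(self.pairs):
                rows.append({
                    "neuron_id": nid, "base_id": self.base_ids[p],
                    "stim_a": sid[a], "stim_b": sid[b],
                    "pair_type": self.pair_type,
                    "usable": bool(self.usable[i, p]),
                })
        return pd.DataFrame(rows)


def build_pairs(
    labels: LabelTable, stimulus_set: StimulusSet, pair_type: str
) -> PairIndex:
    """Index MPs or TPs and mark the usable ones per neuron.

    Pair members agree on every variant flag except the paired one
    (mirrored for MPs, translated for TPs).  Pairs with a missing member
    are skipped with a log entry.
    """
    if pair_type not in ("MP", "TP"):
        raise ValueError("pair_type must be 'MP' or 'TP'")
    flag = "mirrored" if pair_type == "MP" else "translated"
    groups: dict[tuple, dict[bool, int]] = {}
    for j, v in enumerate(stimulus_set.variants):
        key = (v.base_id, v.family, v.contrast, v.rotation, v.single_or_pair,
               v.translated if pair_type == "MP" else v.mirrored)
        groups.setdefault(key, {})[getattr(v, flag)] = j
    pairs, base_ids = [], []
    for key, members in sorted(groups.items(), key=lambda kv: str(kv[0])):
        if len(members) != 2:
            log.info("build_pairs: %s pair for %s missing a member; skipped",
                     pair_type, key[0])
            continue
        pairs.append((members[False], members[True]))
        base_ids.append(key[0])
    pairs_arr = np.array(pairs, dtype=int).reshape(-1, 2)
    fg_a = labels.fg[:, pairs_arr[:, 0]]
    fg_b = labels.fg[:, pairs_arr[:, 1]]
    usable = fg_a != fg_b
    figure_member = np.where(usable, np.where(fg_a, 0, 1), -1).astype(np.int8)
    usable = usable & labels.valid[:, None]
    return PairIndex(labels.neuron_ids, labels.stimulus_ids, base_ids,
                     pairs_arr, pair_type, usable, figure_member)
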
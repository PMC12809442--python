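"""Ensemble plausibility checks: letter support and Cα distance intervals.

Given a reference model and an ensemble of conformations of the same protein
(e.g. frames exported from a molecular-dynamics trajectory), two questions
are asked. First, how often does each position of the ensemble adopt the same
structural letter as the reference model? Positions supported by fewer than
20% of frames carry *rare* reference conformations, those above 80% *strong*
ones. Second, for every unordered pair of Cα atoms (inter-chain pairs
included), the central interval containing 99% of the ensemble's distances
(IC_MD, empirical 0.5%–99.5% quantiles with linear interpolation) is
computed; a reference-model distance falling outside its interval is an
outlier, and maximal runs of residues involved in at least one outlier pair
delineate the questionable regions.
"""

from __future__ import annotations

import dataclasses
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist

from .alphabet import UNASSIGNED, LetterSequence
from .io_structures import ResKey, StructureModel, extract_ca_trace

RARE_CUTOFF = 0.20
STRONG_CUTOFF = 0.80
DEFAULT_LEVEL = 0.99

PairLabel = Tuple[str, ResKey]   # (chain_id, res_key)


class EnsembleConsistencyError(ValueError):
    """Frames do not share a common residue set."""


@dataclasses.dataclass
class LetterSupport:
    chain_id: str
    res_key: ResKey
    ref_letter: str
    support: Optional[float]     # None when the reference letter is unassigned
    n_frames_assigned: int
    label: Optional[str]         # rare | supported | strong | None


def support_label(support: float) -> str:
    if support < RARE_CUTOFF:
        return "rare"
    if support > STRONG_CUTOFF:
        return "strong"
    return "supported"


def letter_support(
    ref_seq: LetterSequence, ensemble_seqs: Sequence[LetterSequence]
) -> List[LetterSupport]:
    """Fraction of frames sharing the reference letter at each position.

    The denominator is the number of frames with an assigned letter at that
    position; positions whose reference letter is unassigned get
    ``support=None`` and no label.
    """
    if not ensemble_seqs:
        raise ValueError("need at least one ensemble frame")
    frame_letters = [seq.letters() for seq in ensemble_seqs]
    out = []
    for res_key, _aa, ref_letter in ref_seq.entries:
        if ref_letter == UNASSIGNED:
            out.append(LetterSupport(ref_seq.chain_id, res_key, ref_letter, None, 0, None))
            continue
        assigned = [
            fl[res_key] for fl in frame_letters
            if fl.get(res_key, UNASSIGNED) != UNASSIGNED
        ]
        if not assigned:
            out.append(LetterSupport(ref_seq.chain_id, res_key, ref_letter, None, 0, None))
            continue
        support = sum(1 for l in assigned if l == ref_letter) / len(assigned)
        out.append(
            LetterSupport(
                ref_seq.chain_id, res_key, ref_letter,
                support, len(assigned), support_label(support),
            )
        )
    return out


def _ca_labels_coords(model: StructureModel) -> Tuple[List[PairLabel], np.ndarray]:
    labels: List[PairLabel] = []
    coords = []
    for chain in model.chains:
        trace = extract_ca_trace(model, chain.chain_id)
        for pos in trace.positions:
            labels.append((chain.chain_id, pos.res_key))
            coords.append(pos.ca_xyz)
    return labels, np.array(coords, dtype=float)


@dataclasses.dataclass
class DistanceIntervals:
    """IC_MD quantile intervals for every unordered Cα pair."""

    labels: List[PairLabel]           # n Cα positions, fixed order
    lo: np.ndarray                    # (n_pairs,) condensed order as scipy pdist
    hi: np.ndarray
    level: float

    @property
    def n_positions(self) -> int:
        return len(self.labels)

    @property
    def n_pairs(self) -> int:
        return len(self.lo)

    def pair_labels(self) -> List[Tuple[PairLabel, PairLabel]]:
        n = self.n_positions
        out = []
        for i in range(n):
            for j in range(i + 1, n):
                out.append((self.labels[i], self.labels[j]))
        return out


def distance_intervals(
    ensemble: Sequence[StructureModel], level: float = DEFAULT_LEVEL
) -> DistanceIntervals:
    """Central quantile interval of every Cα–Cα distance over the ensemble.

    For n Cα positions there are n(n−1)/2 unordered pairs; with ``level`` q,
    the interval is the [(1−q)/2, 1−(1−q)/2] empirical quantile range, with
    linear interpolation between order statistics at the Weibull plotting
    position (n+1)p — the choice whose exceedance probability for a new draw
    matches the nominal tail mass, so a held-out frame falls outside its
    interval with probability ≈ 1−q. Level 1.0 gives [min, max].
    """
    if len(ensemble) < 2:
        raise ValueError("need at least 2 frames to estimate distance intervals")
    if not 0 < level <= 1:
        raise ValueError("level must be in (0, 1]")
    labels, coords0 = _ca_labels_coords(ensemble[0])
    mats = np.empty((len(ensemble), len(coords0) * (len(coords0) - 1) // 2))
    mats[0] = pdist(coords0)
    for k, frame in enumerate(ensemble[1:], start=1):
        frame_labels, coords = _ca_labels_coords(frame)
        if frame_labels != labels:
            raise EnsembleConsistencyError(
                f"frame {frame.frame_index} residue set differs from frame 0"
            )
        mats[k] = pdist(coords)
    alpha = (1.0 - level) / 2.0
    lo = np.quantile(mats, alpha, axis=0, method="weibull")
    hi = np.quantile(mats, 1.0 - alpha, axis=0, method="weibull")
    return DistanceIntervals(labels, lo, hi, level)


@dataclasses.dataclass
class OutlierSummary:
    n_pairs: int
    n_outliers: int
    fraction: float
    per_residue: Dict[PairLabel, int]          # outlier pairs each residue joins
    regions: List[Tuple[str, ResKey, ResKey]]  # maximal runs with >=1 outlier pair


def outlier_distances(
    ref_model: StructureModel, intervals: DistanceIntervals
) -> Tuple[pd.DataFrame, OutlierSummary]:
    """Flag reference-model Cα distances outside their ensemble intervals.

    Returns a per-pair table (lo, hi, ref distance, outlier flag) and a
    summary with per-residue outlier involvement and the maximal
    consecutive-residue regions touched by at least one outlier pair.
    """
    labels, coords = _ca_labels_coords(ref_model)
    if labels != intervals.labels:
        raise KeyError("reference model residue set does not match the intervals")
    ref_d = pdist(coords)
    outlier = (ref_d < intervals.lo) | (ref_d > intervals.hi)

    pairs = intervals.pair_labels()
    table = pd.DataFrame(
        {
            "chain_i": [p[0][0] for p in pairs],
            "resnum_i": [p[0][1][0] for p in pairs],
            "chain_j": [p[1][0] for p in pairs],
            "resnum_j": [p[1][1][0] for p in pairs],
            "lo": intervals.lo,
            "hi": intervals.hi,
            "ref_distance": ref_d,
            "outlier": outlier,
        }
    )

    per_residue: Dict[PairLabel, int] = {label: 0 for label in labels}
    for flag, (a, b) in zip(outlier, pairs):
        if flag:
            per_residue[a] += 1
            per_residue[b] += 1

    regions: List[Tuple[str, ResKey, ResKey]] = []
    current_start: Optional[ResKey] = None
    prev_label: Optional[PairLabel] = None
    for label in labels:
        involved = per_residue[label] > 0
        same_chain = prev_label is not None and prev_label[0] == label[0]
        if involved:
            if current_start is None or not same_chain:
                if current_start is not None and prev_label is not None:
                    regions.append((prev_label[0], current_start, prev_label[1]))
                current_start = label[1]
        else:
            if current_start is not None and prev_label is not None:
                regions.append((prev_label[0], current_start, prev_label[1]))
                current_start = None
        prev_label = label
    if current_start is not None and prev_label is not None:
        regions.append((prev_label[0], current_start, prev_label[1]))

    n_out = int(outlier.sum())
    summary = OutlierSummary(
        n_pairs=len(ref_d),
        n_outliers=n_out,
        fraction=n_out / len(ref_d) if len(ref_d) else 0.0,
        per_residue=per_residue,
        regions=regions,
    )
    return table, summary
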
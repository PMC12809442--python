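"""Core detection protocol: paired-model comparison and R_DC classification.

Two models of the same protein (e.g. an X-ray model and its energy-minimized
or re-refined counterpart) are encoded into structural-letter sequences and
compared residue by residue. A residue whose letters differ is a candidate
conformational change; because some letters are geometric near-neighbours, a
letter change is only retained when the Cα RMSD of the two corresponding
four-residue fragments — after proper-rotation Kabsch superposition — reaches
the threshold (0.1 Å by default, inclusive). Retained residues are classified
R_DC (questionable/deviating conformation), everything else R_CC (consistent
conformation). The per-model proportion of R_DC residues is P_DC, and maximal
consecutive runs of R_DC residues form the pattern set.
"""

from __future__ import annotations

import dataclasses
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .alphabet import UNASSIGNED, AlphabetParameters, LetterSequence, encode
from .io_structures import CaTrace, ResKey, StructureModel, extract_ca_trace

DEFAULT_RMSD_THRESHOLD = 0.1

R_DC = "R_DC"
R_CC = "R_CC"
CALL_UNASSIGNED = "UNASSIGNED"


class ModelMismatchError(ValueError):
    """Paired models do not describe the same protein."""


@dataclasses.dataclass
class ResidueComparison:
    chain_id: str
    res_key: ResKey
    aa: str
    sl_ref: str
    sl_alt: str
    rmsd_frag: Optional[float]
    call: str


@dataclasses.dataclass
class PatternSet:
    """Maximal consecutive R_DC runs; length-1 runs are the isolated residues."""

    isolated: List[Tuple[str, ResKey]]
    runs: List[Tuple[str, ResKey, int]]      # (chain_id, start res_key, length >= 2)

    @property
    def n_isolated(self) -> int:
        return len(self.isolated)

    @property
    def n_in_runs(self) -> int:
        return sum(length for _, _, length in self.runs)

    def run_lengths(self) -> List[int]:
        return [length for _, _, length in self.runs]


@dataclasses.dataclass
class ComparisonResult:
    residues: List[ResidueComparison]
    n_rdc: int
    n_assigned: int
    n_residues_ref: int
    n_dropped: int
    p_dc: float
    threshold: float
    patterns: PatternSet
    sl_pair_counts: pd.DataFrame
    mode: str


def fragment_rmsd(frag_ref: np.ndarray, frag_alt: np.ndarray) -> float:
    """Cα RMSD of two 4-point fragments after least-squares superposition.

    Kabsch superposition restricted to proper rotations (determinant +1);
    reflections are physically inadmissible.
    """
    a = np.asarray(frag_ref, dtype=float)
    b = np.asarray(frag_alt, dtype=float)
    if a.shape != (4, 3) or b.shape != (4, 3):
        raise ValueError("fragments must be 4x3 coordinate arrays")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("non-finite coordinates in fragment")
    a_c = a - a.mean(axis=0)
    b_c = b - b.mean(axis=0)
    if np.allclose(a_c, 0) or np.allclose(b_c, 0):
        raise ValueError("degenerate fragment: all points identical")
    # align_vectors performs proper-rotation Kabsch; rssd is the residual
    _, rssd = Rotation.align_vectors(a_c, b_c)
    return float(rssd / np.sqrt(a.shape[0]))


def classify_call(
    sl_ref: str, sl_alt: str, rmsd_frag: Optional[float], threshold: float
) -> str:
    """Classification rule for one residue.

    Letters equal → R_CC. Letters differ → R_DC when the fragment RMSD
    reaches the threshold (inclusive), else reclassified R_CC (the letter
    change is within the noise of near-neighbour letters). Either letter
    unassigned → UNASSIGNED.
    """
    if UNASSIGNED in (sl_ref, sl_alt):
        return CALL_UNASSIGNED
    if sl_ref == sl_alt:
        return R_CC
    if rmsd_frag is None:
        raise ValueError("rmsd_frag required when letters differ")
    return R_DC if rmsd_frag >= threshold else R_CC


def compare_models(
    model_ref: StructureModel,
    model_alt: StructureModel,
    params: AlphabetParameters,
    threshold: float = DEFAULT_RMSD_THRESHOLD,
    mode: str = "auto",
    rmsd_all: bool = False,
) -> ComparisonResult:
    """Compare two models of the same protein and classify residues.

    Residue matching is by (chain id, residue number, insertion code) over
    the intersection of the two models' residue sets; amino acids must agree
    at every matched key. Letters equal → R_CC; letters differ → R_DC when
    ``rmsd_frag >= threshold``, else reclassified R_CC; windows unassigned on
    either side → UNASSIGNED. ``p_dc`` is normalized by the total residue
    count of the reference model (including unassigned positions).

    ``rmsd_all`` additionally computes rmsd_frag for letter-equal positions
    (diagnostic only; the protocol itself needs it only where letters differ).
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    ref_chains = {c.chain_id for c in model_ref.chains}
    alt_chains = {c.chain_id for c in model_alt.chains}
    shared_chains = [c.chain_id for c in model_ref.chains if c.chain_id in alt_chains]
    if not shared_chains:
        raise ModelMismatchError("models share no chain identifiers")

    records: List[ResidueComparison] = []
    n_rdc = 0
    n_assigned = 0
    n_matched = 0
    for chain_id in shared_chains:
        trace_ref = extract_ca_trace(model_ref, chain_id)
        trace_alt = extract_ca_trace(model_alt, chain_id)
        idx_ref = {p.res_key: i for i, p in enumerate(trace_ref.positions)}
        idx_alt = {p.res_key: i for i, p in enumerate(trace_alt.positions)}
        shared_keys = [p.res_key for p in trace_ref.positions if p.res_key in idx_alt]
        for key in shared_keys:
            aa_ref = trace_ref.positions[idx_ref[key]].aa
            aa_alt = trace_alt.positions[idx_alt[key]].aa
            if aa_ref != aa_alt:
                raise ModelMismatchError(
                    f"amino-acid mismatch at chain {chain_id} residue {key}: "
                    f"{aa_ref} vs {aa_alt}"
                )
        n_matched += len(shared_keys)

        seq_ref = encode(trace_ref, params, mode=mode)
        seq_alt = encode(trace_alt, params, mode=mode)
        letters_ref = seq_ref.letters()
        letters_alt = seq_alt.letters()
        coords_ref = trace_ref.coords()
        coords_alt = trace_alt.coords()

        for key in shared_keys:
            aa = trace_ref.positions[idx_ref[key]].aa
            sl_ref = letters_ref[key]
            sl_alt = letters_alt[key]
            rmsd: Optional[float] = None
            if sl_ref != UNASSIGNED and sl_alt != UNASSIGNED and (
                sl_ref != sl_alt or rmsd_all
            ):
                i, j = idx_ref[key], idx_alt[key]
                rmsd = fragment_rmsd(
                    coords_ref[i - 2:i + 2], coords_alt[j - 2:j + 2]
                )
            call = classify_call(sl_ref, sl_alt, rmsd, threshold)
            if call != CALL_UNASSIGNED:
                n_assigned += 1
            if call == R_DC:
                n_rdc += 1
            records.append(
                ResidueComparison(chain_id, key, aa, sl_ref, sl_alt, rmsd, call)
            )

    n_ref_total = model_ref.n_residues
    n_dropped = n_ref_total - n_matched
    if n_ref_total and n_dropped > 0.5 * n_ref_total:
        raise ModelMismatchError(
            f"only {n_matched}/{n_ref_total} reference residues matched the "
            "alternate model"
        )
    p_dc = n_rdc / n_ref_total if n_ref_total else 0.0

    result = ComparisonResult(
        residues=records,
        n_rdc=n_rdc,
        n_assigned=n_assigned,
        n_residues_ref=n_ref_total,
        n_dropped=n_dropped,
        p_dc=p_dc,
        threshold=threshold,
        patterns=PatternSet([], []),
        sl_pair_counts=pd.DataFrame(),
        mode=mode,
    )
    result.patterns = extract_patterns(result)
    result.sl_pair_counts = _pair_counts(result, params)
    return result


def extract_patterns(result: ComparisonResult) -> PatternSet:
    """Maximal consecutive R_DC runs per chain.

    UNASSIGNED positions and chain boundaries break runs; a run of length 1
    (flanked by non-R_DC context) is reported as an isolated residue.
    """
    isolated: List[Tuple[str, ResKey]] = []
    runs: List[Tuple[str, ResKey, int]] = []
    current: List[ResidueComparison] = []

    def flush() -> None:
        nonlocal current
        if len(current) == 1:
            isolated.append((current[0].chain_id, current[0].res_key))
        elif len(current) >= 2:
            runs.append((current[0].chain_id, current[0].res_key, len(current)))
        current = []

    prev_chain = None
    for rec in result.residues:
        if rec.chain_id != prev_chain:
            flush()
            prev_chain = rec.chain_id
        if rec.call == R_DC:
            current.append(rec)
        else:
            flush()
    flush()
    return PatternSet(isolated, runs)


def _pair_counts(result: ComparisonResult, params: AlphabetParameters) -> pd.DataFrame:
    counts = pd.DataFrame(
        0, index=params.letters, columns=params.letters, dtype=int
    )
    for rec in result.residues:
        if rec.call == R_DC:
            counts.loc[rec.sl_ref, rec.sl_alt] += 1
    return counts


def sl_pair_table(result: ComparisonResult) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """(counts, row-normalized proportions) of SL_ref–SL_alt pairs over R_DC.

    Rows are the reference-model letters, columns the alternate-model
    letters; each nonempty row of the proportion table sums to 1.
    """
    counts = result.sl_pair_counts
    if counts.values.sum() == 0:
        import warnings

        warnings.warn("no R_DC residues: SL pair table is empty")
        return counts, counts.astype(float)
    row_sums = counts.sum(axis=1)
    props = counts.div(row_sums.replace(0, np.nan), axis=0).fillna(0.0)
    return counts, props


def residues_frame(result: ComparisonResult) -> pd.DataFrame:
    """Per-residue comparison records as a tidy DataFrame."""
    return pd.DataFrame(
        {
            "chain": [r.chain_id for r in result.residues],
            "resnum": [r.res_key[0] for r in result.residues],
            "icode": [r.res_key[1] for r in result.residues],
            "aa": [r.aa for r in result.residues],
            "sl_ref": [r.sl_ref for r in result.residues],
            "sl_alt": [r.sl_alt for r in result.residues],
            "rmsd_frag": [r.rmsd_frag for r in result.residues],
            "call": [r.call for r in result.residues],
        }
    )
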
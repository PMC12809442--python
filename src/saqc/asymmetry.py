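"""Structural asymmetry between same-sequence chains of a homo-oligomer.

Two chains with the same amino-acid sequence within one model are compared
position by position on their structural letters: same letter → symmetric,
different letters → structurally asymmetric. Unlike the R_DC protocol, no
RMSD filter is applied by default (within the error margin of a
crystallographic model a letter change is not necessarily significant, so
the counts are an estimate); pass ``rmsd_threshold`` together with the two
traces to apply the same fragment-RMSD filter as the paired-model
comparison.
"""

from __future__ import annotations

import dataclasses
import itertools
from typing import Dict, List, Optional, Tuple

from .alphabet import UNASSIGNED, AlphabetParameters, LetterSequence, encode
from .comparison import fragment_rmsd
from .io_structures import CaTrace, ResKey, StructureModel, extract_ca_trace


class ChainMismatchError(ValueError):
    """Chains do not share the same amino-acid sequence."""


@dataclasses.dataclass
class AsymmetryResult:
    chain_pair: Tuple[str, str]
    asymmetric_positions: List[ResKey]
    symmetric_positions: List[ResKey]
    n_unassigned: int

    @property
    def n_compared(self) -> int:
        return len(self.asymmetric_positions) + len(self.symmetric_positions)


def compare_chains(
    seq_a: LetterSequence,
    seq_b: LetterSequence,
    traces: Optional[Tuple[CaTrace, CaTrace]] = None,
    rmsd_threshold: Optional[float] = None,
) -> AsymmetryResult:
    """Position-wise letter comparison of two same-sequence chains.

    Residues are matched by residue number + insertion code (no alignment);
    an amino-acid mismatch at a matched key raises
    :class:`ChainMismatchError`. Positions unassigned on either side are
    excluded and counted in ``n_unassigned``.
    """
    a_entries = {key: (aa, letter) for key, aa, letter in seq_a.entries}
    b_entries = {key: (aa, letter) for key, aa, letter in seq_b.entries}
    shared = [key for key, _, _ in seq_a.entries if key in b_entries]
    for key in shared:
        if a_entries[key][0] != b_entries[key][0]:
            raise ChainMismatchError(
                f"amino-acid mismatch at residue {key}: "
                f"{a_entries[key][0]} vs {b_entries[key][0]} "
                "(not a homo-oligomer chain pair)"
            )
    if rmsd_threshold is not None and traces is None:
        raise ValueError("rmsd_threshold requires the two Cα traces")

    asymmetric: List[ResKey] = []
    symmetric: List[ResKey] = []
    n_unassigned = 0
    if traces is not None:
        idx_a = {p.res_key: i for i, p in enumerate(traces[0].positions)}
        idx_b = {p.res_key: i for i, p in enumerate(traces[1].positions)}
        coords_a = traces[0].coords()
        coords_b = traces[1].coords()
    for key in shared:
        la = a_entries[key][1]
        lb = b_entries[key][1]
        if la == UNASSIGNED or lb == UNASSIGNED:
            n_unassigned += 1
        elif la == lb:
            symmetric.append(key)
        else:
            if rmsd_threshold is not None:
                i, j = idx_a[key], idx_b[key]
                rmsd = fragment_rmsd(coords_a[i - 2:i + 2], coords_b[j - 2:j + 2])
                if rmsd < rmsd_threshold:
                    symmetric.append(key)
                    continue
            asymmetric.append(key)
    return AsymmetryResult(
        (seq_a.chain_id, seq_b.chain_id), asymmetric, symmetric, n_unassigned
    )


def compare_all_chain_pairs(
    model: StructureModel,
    params: AlphabetParameters,
    mode: str = "auto",
    rmsd_threshold: Optional[float] = None,
) -> List[AsymmetryResult]:
    """Enumerate all same-sequence chain pairs of a model and compare each.

    For an oligomer of n identical chains this yields n·(n−1)/2 results;
    chain pairs whose sequences differ are skipped (they are not
    homo-oligomer pairs).
    """
    traces: Dict[str, CaTrace] = {}
    seqs: Dict[str, LetterSequence] = {}
    for chain in model.chains:
        trace = extract_ca_trace(model, chain.chain_id)
        traces[chain.chain_id] = trace
        seqs[chain.chain_id] = encode(trace, params, mode=mode)
    results = []
    for id_a, id_b in itertools.combinations(sorted(traces), 2):
        aa_a = {p.res_key: p.aa for p in traces[id_a].positions}
        aa_b = {p.res_key: p.aa for p in traces[id_b].positions}
        shared = set(aa_a) & set(aa_b)
        if not shared or any(aa_a[k] != aa_b[k] for k in shared):
            continue
        results.append(
            compare_chains(
                seqs[id_a], seqs[id_b],
                traces=(traces[id_a], traces[id_b]),
                rmsd_threshold=rmsd_threshold,
            )
        )
    return results
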
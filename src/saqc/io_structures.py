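"""Reading and writing of structure models and extraction of Cα traces.

PDB and mmCIF parsing is delegated to :mod:`gemmi`; this module reduces a
coordinate file to the light-weight containers the rest of the package works
with: a :class:`StructureModel` holding protein chains, and per-chain
:class:`CaTrace` objects (ordered Cα coordinates with residue metadata and
chain-break flags) that feed the structural-alphabet encoder.

Conventions
-----------
* Waters, ions and other hetero groups are excluded; only amino-acid residues
  are kept.
* Alternate locations are resolved per atom by keeping the altloc with the
  highest occupancy (ties broken by the lexicographically first altloc id).
* Residues are ordered by author residue number + insertion code, and a chain
  break (``gap_after``) is flagged whenever consecutive Cα atoms are more than
  ``CA_BREAK_CUTOFF`` apart or an intervening residue is missing.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, List, Optional, Sequence, Tuple

import gemmi
import numpy as np

#: Consecutive Cα–Cα distance (Å) above which a chain break is flagged.
CA_BREAK_CUTOFF = 4.5

ResKey = Tuple[int, str]

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    "MSE": "M", "SEC": "U", "PYL": "O",
}
_ONE_TO_THREE = {v: k for k, v in reversed(list(_THREE_TO_ONE.items()))}


class StructureParseError(ValueError):
    """Raised when a coordinate file cannot be parsed or is inconsistent."""


@dataclasses.dataclass
class Atom:
    name: str
    element: str
    xyz: np.ndarray
    occupancy: float
    b_iso: float


@dataclasses.dataclass
class Residue:
    res_key: ResKey
    aa: str
    ca_xyz: Optional[np.ndarray]
    b_iso_mean: float
    occupancy: float
    all_atoms: List[Atom]

    @property
    def ca_missing(self) -> bool:
        return self.ca_xyz is None


@dataclasses.dataclass
class Chain:
    chain_id: str
    residues: List[Residue]

    def __post_init__(self) -> None:
        keys = [r.res_key for r in self.residues]
        if len(keys) != len(set(keys)):
            raise StructureParseError(
                f"duplicate residue keys in chain {self.chain_id!r}"
            )


@dataclasses.dataclass
class StructureModel:
    model_id: str
    chains: List[Chain]
    source_format: str = "pdb"
    frame_index: int = 0

    def __post_init__(self) -> None:
        ids = [c.chain_id for c in self.chains]
        if len(ids) != len(set(ids)):
            raise StructureParseError("duplicate chain identifiers in model")

    def chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        raise KeyError(f"chain {chain_id!r} not found in model {self.model_id!r}")

    @property
    def n_residues(self) -> int:
        return sum(len(c.residues) for c in self.chains)


@dataclasses.dataclass
class TracePosition:
    res_key: ResKey
    aa: str
    ca_xyz: np.ndarray
    b_iso_mean: float
    occupancy: float


@dataclasses.dataclass
class CaTrace:
    """Ordered Cα positions of one chain, with chain-break bookkeeping."""

    chain_id: str
    positions: List[TracePosition]
    gap_after: List[bool]

    def __len__(self) -> int:
        return len(self.positions)

    def coords(self) -> np.ndarray:
        return np.array([p.ca_xyz for p in self.positions], dtype=float)

    def segments(self) -> List[List[int]]:
        """Indices of maximal gap-free runs of consecutive positions."""
        segs: List[List[int]] = []
        cur: List[int] = []
        for i in range(len(self.positions)):
            cur.append(i)
            if self.gap_after[i]:
                segs.append(cur)
                cur = []
        if cur:
            segs.append(cur)
        return segs


def _resolve_altlocs(res: gemmi.Residue) -> List[gemmi.Atom]:
    """Keep one atom per name: highest occupancy, ties to first altloc id."""
    by_name: dict = {}
    for atom in res:
        prev = by_name.get(atom.name)
        if (
            prev is None
            or atom.occ > prev.occ
            or (atom.occ == prev.occ and (atom.altloc or "") < (prev.altloc or ""))
        ):
            by_name[atom.name] = atom
    return list(by_name.values())


def _convert_residue(res: gemmi.Residue) -> Optional[Residue]:
    info = gemmi.find_tabulated_residue(res.name)
    if info is None or not info.is_amino_acid():
        return None
    atoms = []
    ca = None
    b_values = []
    occ_values = []
    for atom in _resolve_altlocs(res):
        el = atom.element.name
        xyz = np.array([atom.pos.x, atom.pos.y, atom.pos.z], dtype=float)
        atoms.append(Atom(atom.name, el, xyz, atom.occ, atom.b_iso))
        if el == "H":
            continue
        b_values.append(atom.b_iso)
        occ_values.append(atom.occ)
        if atom.name == "CA":
            ca = xyz
    if not atoms:
        return None
    icode = res.seqid.icode.strip()
    return Residue(
        res_key=(res.seqid.num, icode),
        aa=_THREE_TO_ONE.get(res.name, "X"),
        ca_xyz=ca,
        b_iso_mean=float(np.mean(b_values)) if b_values else float("nan"),
        occupancy=float(min(occ_values)) if occ_values else 1.0,
        all_atoms=atoms,
    )


def _convert_model(
    st: gemmi.Structure, gmodel: gemmi.Model, source_format: str, frame_index: int
) -> StructureModel:
    chains = []
    for gchain in gmodel:
        residues = []
        for res in gchain:
            conv = _convert_residue(res)
            if conv is not None:
                residues.append(conv)
        if residues:
            residues.sort(key=lambda r: (r.res_key[0], r.res_key[1]))
            chains.append(Chain(gchain.name, residues))
    return StructureModel(
        model_id=st.name or "model",
        chains=chains,
        source_format=source_format,
        frame_index=frame_index,
    )


def _read_gemmi(path: str | Path, format: str) -> Tuple[gemmi.Structure, str]:
    path = str(path)
    try:
        if format == "pdb":
            st = gemmi.read_pdb(path)
            fmt = "pdb"
        elif format == "mmcif":
            st = gemmi.read_structure(path, format=gemmi.CoorFormat.Mmcif)
            fmt = "mmcif"
        elif format == "auto":
            st = gemmi.read_structure(path, format=gemmi.CoorFormat.Detect)
            fmt = "mmcif" if path.endswith((".cif", ".cif.gz", ".mmcif")) else "pdb"
        else:
            raise ValueError(f"unknown format {format!r}")
    except (RuntimeError, ValueError) as exc:
        raise StructureParseError(f"cannot parse {path}: {exc}") from exc
    if len(st) == 0:
        raise StructureParseError(f"no models found in {path}")
    return st, fmt


def read_structure(
    path: str | Path, format: str = "auto", model_index: int = 0
) -> StructureModel:
    """Read one model from a PDB/mmCIF file.

    Parameters
    ----------
    path
        Coordinate file.
    format
        ``auto`` (detect), ``pdb`` or ``mmcif``.
    model_index
        0-based index into the file's MODEL blocks.
    """
    st, fmt = _read_gemmi(path, format)
    if not 0 <= model_index < len(st):
        raise IndexError(
            f"model_index {model_index} out of range (file has {len(st)} models)"
        )
    return _convert_model(st, st[model_index], fmt, model_index)


def read_ensemble(path: str | Path, format: str = "auto") -> List[StructureModel]:
    """Read every model of a multi-model file as one ensemble frame each.

    All frames must share identical residue keys per chain; a mismatch raises
    :class:`StructureParseError` naming the offending frame.
    """
    st, fmt = _read_gemmi(path, format)
    frames = [
        _convert_model(st, st[i], fmt, i) for i in range(len(st))
    ]
    ref_keys = {
        c.chain_id: [r.res_key for r in c.residues] for c in frames[0].chains
    }
    for frame in frames[1:]:
        keys = {c.chain_id: [r.res_key for r in c.residues] for c in frame.chains}
        if keys != ref_keys:
            raise StructureParseError(
                f"frame {frame.frame_index} has a residue set differing from frame 0"
            )
    return frames


def extract_ca_trace(model: StructureModel, chain_id: str) -> CaTrace:
    """Extract the ordered Cα trace of one chain.

    Residues lacking a Cα atom are excluded and the preceding position is
    flagged as a break; breaks are also flagged on numbering jumps and on
    consecutive Cα distances above :data:`CA_BREAK_CUTOFF`.
    """
    chain = model.chain(chain_id)
    positions: List[TracePosition] = []
    dropped_before: List[bool] = []  # a CA-less residue preceded this position
    pending_drop = False
    for res in chain.residues:
        if res.ca_missing:
            pending_drop = True
            continue
        positions.append(
            TracePosition(res.res_key, res.aa, res.ca_xyz, res.b_iso_mean, res.occupancy)
        )
        dropped_before.append(pending_drop)
        pending_drop = False

    gap_after = [False] * len(positions)
    for i in range(len(positions) - 1):
        a, b = positions[i], positions[i + 1]
        dist = float(np.linalg.norm(a.ca_xyz - b.ca_xyz))
        number_jump = b.res_key[0] > a.res_key[0] + 1
        if dist > CA_BREAK_CUTOFF or number_jump or dropped_before[i + 1]:
            gap_after[i] = True
    return CaTrace(chain_id, positions, gap_after)


# ---------------------------------------------------------------------------
# writing


def _to_gemmi(models: Sequence[StructureModel]) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = models[0].model_id if models else "model"
    for k, model in enumerate(models):
        gmodel = gemmi.Model(k + 1)
        for chain in model.chains:
            gchain = gemmi.Chain(chain.chain_id)
            for res in chain.residues:
                gres = gemmi.Residue()
                gres.name = _ONE_TO_THREE.get(res.aa, "UNK")
                gres.seqid = gemmi.SeqId(res.res_key[0], res.res_key[1] or " ")
                for atom in res.all_atoms:
                    ga = gemmi.Atom()
                    ga.name = atom.name
                    ga.element = gemmi.Element(atom.element)
                    ga.pos = gemmi.Position(*atom.xyz)
                    ga.occ = atom.occupancy
                    ga.b_iso = atom.b_iso
                    gres.add_atom(ga)
                gchain.add_residue(gres)
            gmodel.add_chain(gchain)
        st.add_model(gmodel)
    st.setup_entities()
    return st


def write_structure(model: StructureModel, path: str | Path) -> None:
    """Write a single model as PDB."""
    _to_gemmi([model]).write_pdb(str(path))


def write_ensemble(models: Sequence[StructureModel], path: str | Path) -> None:
    """Write frames as a multi-model PDB (MODEL/ENDMDL blocks)."""
    _to_gemmi(list(models)).write_pdb(str(path))
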
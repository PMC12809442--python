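"""Synthetic backbone fixtures: paired conformers with known perturbations.

Chains are built from ideal internal coordinates (bond lengths and angles of
the peptide backbone, trans peptide bonds) given a per-residue (φ, ψ) plan, so
every test has exact ground truth: a perturbation rotates one named dihedral
by a known angle and leaves everything upstream of that bond bit-identical,
and a pseudo-ensemble jitters all dihedrals with seeded Gaussian noise. This
emulates the kind of paired X-ray/minimized conformers and MD frame sets the
detection protocol consumes, without any physics: there are no energies, no
side chains and no clash resolution beyond the broad coil φ/ψ region used for
sampling.
"""

from __future__ import annotations

import dataclasses
from typing import List, Literal, Optional, Sequence, Tuple

import numpy as np
from scipy.spatial.transform import Rotation

from .io_structures import Atom, CaTrace, Chain, Residue, StructureModel, extract_ca_trace

# ideal backbone internal coordinates (Å, degrees)
B_N_CA = 1.458
B_CA_C = 1.525
B_C_N = 1.329
B_C_O = 1.231
ANG_N_CA_C = 111.2
ANG_CA_C_N = 116.2
ANG_C_N_CA = 121.7
ANG_CA_C_O = 120.8
OMEGA = 180.0

#: default (φ, ψ) in degrees per secondary-structure type
DIHEDRAL_TABLE = {"helix": (-57.0, -47.0), "strand": (-135.0, 135.0)}
#: broad allowed region that coil dihedrals are sampled from
COIL_PHI_RANGE = (-180.0, -30.0)
COIL_PSI_RANGE = (-60.0, 180.0)

SegmentKind = Literal["helix", "strand", "coil"]


@dataclasses.dataclass
class BuildSpec:
    """Plan for one synthetic chain.

    ``segments`` is a list of (kind, length) pairs whose lengths must sum to
    ``n_residues``; coil φ/ψ are sampled per residue from the broad allowed
    region using ``seed``, so a fixed seed gives bit-identical coordinates.
    """

    n_residues: int
    segments: Optional[List[Tuple[SegmentKind, int]]] = None
    dihedral_table: Optional[dict] = None
    seed: int = 0
    chain_id: str = "A"
    sequence: Optional[str] = None
    b_factors: Optional[Sequence[float]] = None
    occupancies: Optional[Sequence[float]] = None

    def __post_init__(self) -> None:
        if self.n_residues < 4:
            raise ValueError("n_residues must be >= 4")
        if self.segments is None:
            self.segments = [("helix", self.n_residues)]
        if sum(length for _, length in self.segments) != self.n_residues:
            raise ValueError("segment lengths must sum to n_residues")
        if self.sequence is not None and len(self.sequence) != self.n_residues:
            raise ValueError("sequence length must equal n_residues")


@dataclasses.dataclass
class PerturbSpec:
    """Targets are (0-based residue index, 'phi'|'psi', delta in degrees)."""

    targets: List[Tuple[int, str, float]]
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for _, dihedral, _ in self.targets:
            if dihedral not in ("phi", "psi"):
                raise ValueError(f"unknown dihedral {dihedral!r}")


def _place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
                bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """NeRF placement of atom D bonded to C, given A-B-C and internal coords."""
    theta = np.deg2rad(angle_deg)
    chi = np.deg2rad(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * np.cos(theta),
        bond * np.sin(theta) * np.cos(chi),
        bond * np.sin(theta) * np.sin(chi),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def _build_backbone(phis: np.ndarray, psis: np.ndarray) -> np.ndarray:
    """Coordinates of N, CA, C, O for each residue; shape (n, 4, 3)."""
    n_res = len(phis)
    coords = np.zeros((n_res, 4, 3))
    # first residue in a canonical frame
    coords[0, 0] = np.array([0.0, 0.0, 0.0])                       # N
    coords[0, 1] = np.array([B_N_CA, 0.0, 0.0])                    # CA
    theta = np.deg2rad(ANG_N_CA_C)
    coords[0, 2] = coords[0, 1] + B_CA_C * np.array(               # C
        [-np.cos(theta), np.sin(theta), 0.0]
    )
    for i in range(n_res - 1):
        n_i, ca_i, c_i = coords[i, 0], coords[i, 1], coords[i, 2]
        n_next = _place_atom(n_i, ca_i, c_i, B_C_N, ANG_CA_C_N, psis[i])
        ca_next = _place_atom(ca_i, c_i, n_next, B_N_CA, ANG_C_N_CA, OMEGA)
        c_next = _place_atom(c_i, n_next, ca_next, B_CA_C, ANG_N_CA_C, phis[i + 1])
        coords[i + 1, 0] = n_next
        coords[i + 1, 1] = ca_next
        coords[i + 1, 2] = c_next
        coords[i, 3] = _place_atom(n_i, ca_i, c_i, B_C_O, ANG_CA_C_O, psis[i] + 180.0)
    i = n_res - 1
    coords[i, 3] = _place_atom(
        coords[i, 0], coords[i, 1], coords[i, 2], B_C_O, ANG_CA_C_O, psis[i] + 180.0
    )
    return coords


def dihedral_plan(spec: BuildSpec) -> Tuple[np.ndarray, np.ndarray]:
    """Per-residue (φ, ψ) arrays implied by the segment plan."""
    table = dict(DIHEDRAL_TABLE)
    if spec.dihedral_table:
        table.update(spec.dihedral_table)
    rng = np.random.default_rng(spec.seed)
    phis, psis = [], []
    for kind, length in spec.segments:  # type: ignore[union-attr]
        for _ in range(length):
            if kind == "coil":
                phis.append(rng.uniform(*COIL_PHI_RANGE))
                psis.append(rng.uniform(*COIL_PSI_RANGE))
            else:
                phi, psi = table[kind]
                phis.append(phi)
                psis.append(psi)
    return np.array(phis), np.array(psis)


def _model_from_backbone(
    coords: np.ndarray, spec_like: dict
) -> StructureModel:
    n_res = coords.shape[0]
    sequence = spec_like.get("sequence") or "A" * n_res
    b_factors = spec_like.get("b_factors")
    occupancies = spec_like.get("occupancies")
    atom_names = ["N", "CA", "C", "O"]
    elements = ["N", "C", "C", "O"]
    residues = []
    for i in range(n_res):
        b = float(b_factors[i]) if b_factors is not None else 15.0
        occ = float(occupancies[i]) if occupancies is not None else 1.0
        atoms = [
            Atom(atom_names[j], elements[j], coords[i, j].copy(), occ, b)
            for j in range(4)
        ]
        residues.append(
            Residue(
                res_key=(i + 1, ""),
                aa=sequence[i],
                ca_xyz=coords[i, 1].copy(),
                b_iso_mean=b,
                occupancy=occ,
                all_atoms=atoms,
            )
        )
    return StructureModel(
        model_id=spec_like.get("model_id", "synthetic"),
        chains=[Chain(spec_like.get("chain_id", "A"), residues)],
        source_format="pdb",
    )


def _default_b_profile(n_res: int, seed: int) -> np.ndarray:
    """Crystallographic-looking B-factors: elevated termini, seeded noise."""
    rng = np.random.default_rng(seed + 77)
    x = np.linspace(-1.0, 1.0, n_res)
    return 15.0 + 12.0 * x ** 2 + rng.normal(0.0, 2.0, n_res)


def build_chain(spec: BuildSpec) -> StructureModel:
    """Build a single-chain model from a :class:`BuildSpec`."""
    phis, psis = dihedral_plan(spec)
    coords = _build_backbone(phis, psis)
    b_factors = spec.b_factors
    if b_factors is None:
        b_factors = _default_b_profile(spec.n_residues, spec.seed)
    return _model_from_backbone(
        coords,
        dict(
            sequence=spec.sequence,
            b_factors=b_factors,
            occupancies=spec.occupancies,
            chain_id=spec.chain_id,
            model_id=f"synthetic_seed{spec.seed}",
        ),
    )


def _chain_backbone(chain: Chain) -> np.ndarray:
    coords = np.zeros((len(chain.residues), 4, 3))
    for i, res in enumerate(chain.residues):
        by_name = {a.name: a.xyz for a in res.all_atoms}
        for j, name in enumerate(["N", "CA", "C", "O"]):
            coords[i, j] = by_name[name]
    return coords


def _rebuild_model(model: StructureModel, new_coords_per_chain: List[np.ndarray]) -> StructureModel:
    chains = []
    for chain, coords in zip(model.chains, new_coords_per_chain):
        residues = []
        for i, res in enumerate(chain.residues):
            atoms = [
                Atom(a.name, a.element, coords[i, j].copy(), a.occupancy, a.b_iso)
                for j, a in enumerate(res.all_atoms)
            ]
            residues.append(
                Residue(res.res_key, res.aa, coords[i, 1].copy(),
                        res.b_iso_mean, res.occupancy, atoms)
            )
        chains.append(Chain(chain.chain_id, residues))
    return StructureModel(model.model_id, chains, model.source_format, model.frame_index)


def perturb(model: StructureModel, spec: PerturbSpec, chain_id: Optional[str] = None) -> StructureModel:
    """Rotate listed backbone dihedrals by their deltas.

    The rotation is applied to the downstream atoms only, so everything
    upstream of the first perturbed bond stays bit-identical; a delta of 0 is
    skipped entirely and leaves the model unchanged.
    """
    new_coords = []
    for chain in model.chains:
        coords = _chain_backbone(chain)
        if chain_id is None or chain.chain_id == chain_id:
            n_res = coords.shape[0]
            for idx, dihedral, delta in spec.targets:
                if not 0 <= idx < n_res:
                    raise ValueError(f"target residue index {idx} out of range")
                if delta == 0.0:
                    continue
                if dihedral == "phi":
                    origin, tip = coords[idx, 0], coords[idx, 1]  # N -> CA
                else:
                    origin, tip = coords[idx, 1], coords[idx, 2]  # CA -> C
                axis = tip - origin
                axis /= np.linalg.norm(axis)
                rot = Rotation.from_rotvec(np.deg2rad(delta) * axis)
                moving = _downstream_mask(n_res, idx, dihedral)
                flat = coords.reshape(-1, 3)
                flat[moving] = rot.apply(flat[moving] - origin) + origin
                coords = flat.reshape(n_res, 4, 3)
        new_coords.append(coords)
    return _rebuild_model(model, new_coords)


def _downstream_mask(n_res: int, idx: int, dihedral: str) -> np.ndarray:
    """Flat (n_res*4) mask of atoms downstream of the rotated bond."""
    mask = np.zeros((n_res, 4), dtype=bool)
    mask[idx + 1:, :] = True
    if dihedral == "phi":
        mask[idx, 2] = True  # C
        mask[idx, 3] = True  # O
    else:  # psi: O follows the carbonyl plane defined relative to next N
        mask[idx, 3] = True
    return mask.reshape(-1)


def measure_dihedrals(chain: Chain) -> Tuple[np.ndarray, np.ndarray]:
    """(φ, ψ) in degrees measured from backbone coordinates.

    φ of the first residue is undefined and set to the ideal helix value so
    that rebuilding from the returned arrays reproduces the backbone.
    """
    coords = _chain_backbone(chain)
    n = coords.shape[0]
    phis = np.full(n, np.nan)
    psis = np.full(n, np.nan)
    for i in range(n):
        if i > 0:
            phis[i] = _torsion(coords[i - 1, 2], coords[i, 0], coords[i, 1], coords[i, 2])
        if i < n - 1:
            psis[i] = _torsion(coords[i, 0], coords[i, 1], coords[i, 2], coords[i + 1, 0])
        else:
            # recover the ψ used to place the terminal O
            psis[i] = _torsion(coords[i, 0], coords[i, 1], coords[i, 2], coords[i, 3]) - 180.0
    phis[0] = -57.0  # arbitrary: φ of the first residue is not defined
    return phis, psis


def _torsion(p1, p2, p3, p4) -> float:
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    x = np.dot(n1, n2)
    y = np.dot(m1, n2)
    return float(np.rad2deg(np.arctan2(y, x)))


def _superpose_onto(coords: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Least-squares fit of a rebuilt backbone onto the reference backbone."""
    flat = coords.reshape(-1, 3)
    ref_flat = ref.reshape(-1, 3)
    mu, mu_ref = flat.mean(axis=0), ref_flat.mean(axis=0)
    rot, _ = Rotation.align_vectors(ref_flat - mu_ref, flat - mu)
    return (rot.apply(flat - mu) + mu_ref).reshape(coords.shape)


def build_ensemble(
    model: StructureModel, n_frames: int, noise_sd: float, seed: int = 0
) -> List[StructureModel]:
    """Pseudo-trajectory: frames with Gaussian dihedral jitter around a model.

    Each chain is rebuilt from its measured (φ, ψ) plus independent
    N(0, noise_sd²) jitter and least-squares fitted back onto the original
    chain, so multi-chain models keep their approximate relative geometry.
    ``noise_sd`` is in degrees; 0 reproduces the input in every frame.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    frames = []
    ref_backbones = [_chain_backbone(c) for c in model.chains]
    ref_dihedrals = [measure_dihedrals(c) for c in model.chains]
    for k in range(n_frames):
        new_coords = []
        for (phis, psis), ref in zip(ref_dihedrals, ref_backbones):
            if noise_sd == 0:
                new_coords.append(ref.copy())
                continue
            jittered_phi = phis + rng.normal(0, noise_sd, len(phis))
            jittered_psi = psis + rng.normal(0, noise_sd, len(psis))
            coords = _build_backbone(jittered_phi, jittered_psi)
            new_coords.append(_superpose_onto(coords, ref))
        frame = _rebuild_model(model, new_coords)
        frame.frame_index = k
        frames.append(frame)
    return frames


def build_oligomer(
    spec: BuildSpec, n_chains: int = 2, chain_ids: Optional[Sequence[str]] = None,
    separation: float = 30.0,
) -> StructureModel:
    """Identical-sequence oligomer: translated copies of one built chain."""
    base = build_chain(spec)
    if chain_ids is None:
        chain_ids = [chr(ord("A") + i) for i in range(n_chains)]
    chains = []
    for i, cid in enumerate(chain_ids):
        shift = np.array([0.0, 0.0, separation * i])
        residues = []
        for res in base.chains[0].residues:
            atoms = [
                Atom(a.name, a.element, a.xyz + shift, a.occupancy, a.b_iso)
                for a in res.all_atoms
            ]
            residues.append(
                Residue(res.res_key, res.aa, res.ca_xyz + shift,
                        res.b_iso_mean, res.occupancy, atoms)
            )
        chains.append(Chain(cid, residues))
    return StructureModel(base.model_id, chains, "pdb")


def helix_trace(n_residues: int = 30, seed: int = 0) -> CaTrace:
    """Convenience: Cα trace of an ideal α-helix (used widely in tests)."""
    model = build_chain(BuildSpec(n_residues=n_residues, seed=seed))
    return extract_ca_trace(model, "A")
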
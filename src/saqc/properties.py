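"""Per-residue property annotation: flexibility, occupancy class, accessibility.

Flexibility follows the normalized-B-factor convention: the mean isotropic B
over all (non-hydrogen) atoms of a residue is z-scored against all residues
of the model, and a residue is *flexible* when its z-score is strictly
positive, *rigid* otherwise. Occupancy classes split residues into those
modeled with zero occupancy, partial occupancy (at least two alternative
conformations) and full single-conformation occupancy. Solvent accessibility
is computed atom-wise with the Shrake–Rupley sphere-sampling method (probe
radius 1.4 Å, ≥960 sample points per atom), summed per residue and expressed
relative to a per-amino-acid reference area; residues with rASA strictly
above 20% are *accessible*.
"""

from __future__ import annotations

import dataclasses
from importlib import resources
from pathlib import Path
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .io_structures import ResKey, StructureModel

DEFAULT_PROBE_RADIUS = 1.4
DEFAULT_N_POINTS = 960
RASA_ACCESSIBLE_CUTOFF = 20.0


class DegenerateModelError(ValueError):
    """Model has no B-factor spread to normalize against."""


@dataclasses.dataclass
class ResidueAnnotation:
    chain_id: str
    res_key: ResKey
    aa: str
    b_norm: float
    flexibility: str          # flexible | rigid
    occ_category: str         # zero | alternative | single
    asa: float
    rasa: float               # percent of reference; NaN for unknown residues
    accessibility: str        # accessible | buried


def _load_table(name: str) -> Dict[str, float]:
    text = resources.files("saqc.data").joinpath(name).read_text()
    table = {}
    for raw in text.splitlines():
        line = raw.split("#", 1)[0].strip()
        if line:
            key, value = line.split()
            table[key.upper()] = float(value)
    return table


def load_radii(path: Optional[str | Path] = None) -> Dict[str, float]:
    if path is None:
        return _load_table("atomic_radii.txt")
    table = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if line:
            key, value = line.split()
            table[key.upper()] = float(value)
    return table


def load_reference_asa(path: Optional[str | Path] = None) -> Dict[str, float]:
    if path is None:
        return _load_table("reference_asa.txt")
    return load_radii(path)  # same two-column format


def normalize_b_factors(model: StructureModel) -> Dict[Tuple[str, ResKey], float]:
    """Z-score of each residue's mean B against all residues of the model.

    Uses the population standard deviation, so the output has mean 0 and
    standard deviation 1 exactly; a model whose residues all share one B
    value raises :class:`DegenerateModelError`.
    """
    keys = []
    values = []
    for chain in model.chains:
        for res in chain.residues:
            keys.append((chain.chain_id, res.res_key))
            values.append(res.b_iso_mean)
    if len(values) < 2:
        raise DegenerateModelError("need at least 2 residues to normalize B-factors")
    arr = np.array(values, dtype=float)
    sd = arr.std()  # population sd
    if sd == 0:
        raise DegenerateModelError(
            f"all residues of model {model.model_id!r} share the same mean B-factor"
        )
    z = (arr - arr.mean()) / sd
    return dict(zip(keys, z.tolist()))


def flexibility_label(b_norm: float) -> str:
    """Flexible iff the normalized B-factor is strictly greater than 0."""
    return "flexible" if b_norm > 0 else "rigid"


def accessibility_label(rasa: float) -> str:
    """Accessible iff rASA is strictly greater than 20%; NaN counts buried."""
    return "accessible" if rasa > RASA_ACCESSIBLE_CUTOFF else "buried"


def occupancy_category(occupancy) -> str:
    """zero / alternative / single, from a residue or an occupancy fraction."""
    occ = occupancy.occupancy if hasattr(occupancy, "occupancy") else float(occupancy)
    if not 0.0 <= occ <= 1.0:
        raise ValueError(f"occupancy {occ} outside [0, 1]")
    if occ == 0.0:
        return "zero"
    if occ == 1.0:
        return "single"
    return "alternative"


def _sphere_points(n: int) -> np.ndarray:
    """Nearly uniform points on the unit sphere (golden-spiral lattice)."""
    k = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * k / n)
    theta = np.pi * (1 + 5 ** 0.5) * k
    return np.column_stack(
        [np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi)]
    )


def shrake_rupley(
    coords: np.ndarray,
    radii: np.ndarray,
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    n_points: int = DEFAULT_N_POINTS,
) -> np.ndarray:
    """Per-atom solvent-accessible surface area (Å²).

    Each atom's solvent-extended sphere is sampled at ``n_points`` lattice
    points; a point is accessible when outside every neighbour's extended
    sphere, and the atom's area is the accessible fraction of its sphere.
    """
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float) + probe_radius
    n_atoms = len(coords)
    points = _sphere_points(n_points)
    areas = np.zeros(n_atoms)
    if n_atoms == 0:
        return areas
    for i in range(n_atoms):
        # neighbours whose extended spheres can occlude atom i's surface
        d = np.linalg.norm(coords - coords[i], axis=1)
        mask = d < radii[i] + radii
        mask[i] = False
        neighbours = np.where(mask)[0]
        surface = coords[i] + radii[i] * points
        if len(neighbours):
            diff = surface[:, None, :] - coords[neighbours][None, :, :]
            dist2 = np.einsum("ijk,ijk->ij", diff, diff)
            buried = (dist2 < radii[neighbours][None, :] ** 2).any(axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        areas[i] = frac * 4.0 * np.pi * radii[i] ** 2
    return areas


def relative_asa(
    model: StructureModel,
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    n_points: int = DEFAULT_N_POINTS,
    radii_table: Optional[Dict[str, float]] = None,
    reference_table: Optional[Dict[str, float]] = None,
    include_hydrogens: bool = False,
) -> pd.DataFrame:
    """Per-residue (asa, rasa, accessibility) for a whole model.

    rASA is ``100 * asa / reference_asa(aa)``; residues without a reference
    value (unknown amino acid) get ``rasa = NaN`` and are labelled buried.
    An element missing from the radii table raises ``KeyError``.
    """
    radii_table = radii_table or load_radii()
    reference_table = reference_table or load_reference_asa()
    coords = []
    radii = []
    owner = []        # index into the residue list
    residues = []
    for chain in model.chains:
        for res in chain.residues:
            residues.append((chain.chain_id, res))
            for atom in res.all_atoms:
                el = atom.element.upper()
                if el == "H" and not include_hydrogens:
                    continue
                if el not in radii_table:
                    raise KeyError(
                        f"no van der Waals radius configured for element {el!r}"
                    )
                coords.append(atom.xyz)
                radii.append(radii_table[el])
                owner.append(len(residues) - 1)
    areas = shrake_rupley(np.array(coords), np.array(radii), probe_radius, n_points)
    per_res = np.zeros(len(residues))
    np.add.at(per_res, np.array(owner, dtype=int), areas)

    rows = []
    for i, (chain_id, res) in enumerate(residues):
        ref = reference_table.get(res.aa.upper())
        rasa = 100.0 * per_res[i] / ref if ref else float("nan")
        rows.append(
            {
                "chain": chain_id,
                "resnum": res.res_key[0],
                "icode": res.res_key[1],
                "aa": res.aa,
                "asa": per_res[i],
                "rasa": rasa,
                "accessibility": accessibility_label(rasa),
            }
        )
    return pd.DataFrame(rows)


def annotate(
    model: StructureModel,
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    n_points: int = DEFAULT_N_POINTS,
) -> pd.DataFrame:
    """Full annotation table: b_norm, flexibility, occupancy class, ASA."""
    b_norm = normalize_b_factors(model)
    asa = relative_asa(model, probe_radius=probe_radius, n_points=n_points)
    records = []
    i = 0
    for chain in model.chains:
        for res in chain.residues:
            z = b_norm[(chain.chain_id, res.res_key)]
            row = asa.iloc[i]
            records.append(
                {
                    "chain": chain.chain_id,
                    "resnum": res.res_key[0],
                    "icode": res.res_key[1],
                    "aa": res.aa,
                    "b_norm": z,
                    "flexibility": flexibility_label(z),
                    "occ_category": occupancy_category(res.occupancy),
                    "asa": row["asa"],
                    "rasa": row["rasa"],
                    "accessibility": row["accessibility"],
                }
            )
            i += 1
    return pd.DataFrame(records)
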
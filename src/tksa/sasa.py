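"""Shrake-Rupley solvent-accessible surface area.

Test points are taken from a deterministic golden-spiral spherical point
set, so areas are reproducible bit-for-bit for a fixed ``n_points``.
Hydrogens are ignored, as is usual for crystal and homology-model
structures that carry none.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .constants import MAX_ASA_TRIPEPTIDE_A2
from .structure import ProteinStructure


@dataclass
class SasaResult:
    """Per-atom and per-residue solvent-accessible areas (Angstrom^2)."""

    atom_keys: list[tuple[str, int, str]]  # (chain, seq_number, atom name)
    per_atom: np.ndarray  # parallel to atom_keys
    per_residue: dict[tuple[str, int], float]
    per_residue_norm: dict[tuple[str, int], float] = field(default_factory=dict)

    def atom_area(self, chain: str, seq_number: int, atom_name: str) -> float:
        idx = self.atom_keys.index((chain, seq_number, atom_name))
        return float(self.per_atom[idx])


def golden_spiral_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform point set on the unit sphere (n, 3)."""
    if n < 1:
        raise ValueError("need at least one point")
    k = np.arange(n, dtype=float)
    z = 1.0 - (2.0 * k + 1.0) / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    phi = k * np.pi * (3.0 - np.sqrt(5.0))  # golden angle
    return np.column_stack((r * np.cos(phi), r * np.sin(phi), z))


def shrake_rupley(structure: ProteinStructure, probe_radius: float = 1.4,
                  n_points: int = 960) -> SasaResult:
    """Per-atom SASA by counting unoccluded test points on inflated spheres.

    For each non-hydrogen atom with van der Waals radius ``r`` the area is
    ``4 pi (r + probe)^2 * n_accessible / n_points``, a test point being
    accessible when it lies outside every other atom's probe-inflated
    sphere.  Coincident duplicate atoms occlude each other completely and
    contribute zero area rather than dividing by zero.
    """
    if n_points < 16:
        raise ValueError("n_points must be >= 16")
    if probe_radius < 0:
        raise ValueError("probe_radius must be >= 0")

    atoms = [a for a in structure.atoms() if a.element != "H"]
    keys: list[tuple[str, int, str]] = []
    for res in structure.residues:
        for a in res.atoms:
            if a.element != "H":
                keys.append((res.chain, res.seq_number, a.name))

    coords = np.array([a.coordinates for a in atoms], dtype=float)
    radii = np.array([a.radius + probe_radius for a in atoms], dtype=float)
    unit_points = golden_spiral_points(n_points)

    tree = cKDTree(coords)
    max_radius = float(radii.max())
    areas = np.zeros(len(atoms))
    for i in range(len(atoms)):
        sphere_pts = coords[i] + radii[i] * unit_points
        neighbor_idx = [j for j in tree.query_ball_point(coords[i], radii[i] + max_radius)
                        if j != i]
        if neighbor_idx:
            nb_coords = coords[neighbor_idx]
            nb_radii = radii[neighbor_idx]
            d2 = ((sphere_pts[:, None, :] - nb_coords[None, :, :]) ** 2).sum(axis=2)
            # non-strict comparison so exactly coincident duplicate atoms
            # occlude each other completely (area 0, never divide-by-zero)
            buried = (d2 <= ((nb_radii**2) * (1.0 + 1e-9))[None, :]).any(axis=1)
            n_accessible = int((~buried).sum())
        else:
            n_accessible = n_points
        areas[i] = 4.0 * np.pi * radii[i] ** 2 * n_accessible / n_points

    per_residue: dict[tuple[str, int], float] = {}
    for key, area in zip(keys, areas):
        rkey = (key[0], key[1])
        per_residue[rkey] = per_residue.get(rkey, 0.0) + float(area)
    return SasaResult(atom_keys=keys, per_atom=areas, per_residue=per_residue)


def normalize_residue_sasa(result: SasaResult, structure: ProteinStructure,
                           reference_table: dict[str, float] | None = None
                           ) -> dict[tuple[str, int], float]:
    """Normalized residue accessibility: area / reference maximum, clamped to [0, 1].

    The reference is the residue's maximal accessible area in an extended
    Gly-X-Gly tripeptide.  Raises ``KeyError`` naming the residue type when
    the table has no entry.
    """
    table = MAX_ASA_TRIPEPTIDE_A2 if reference_table is None else reference_table
    norm: dict[tuple[str, int], float] = {}
    for res in structure.residues:
        rkey = (res.chain, res.seq_number)
        if rkey not in result.per_residue:
            continue
        if res.name not in table:
            raise KeyError(f"no reference accessibility for residue type {res.name!r}")
        frac = result.per_residue[rkey] / table[res.name]
        norm[rkey] = float(min(1.0, max(0.0, frac)))
    result.per_residue_norm = norm
    return norm


def sasa_table(result: SasaResult, structure: ProteinStructure) -> "list[dict]":
    """Rows (chain, seq_number, residue, area, norm) for TSV export."""
    rows = []
    for res in structure.residues:
        rkey = (res.chain, res.seq_number)
        if rkey not in result.per_residue:
            continue
        rows.append({
            "chain": res.chain,
            "seq_number": res.seq_number,
            "residue": res.name,
            "area_A2": result.per_residue[rkey],
            "norm": result.per_residue_norm.get(rkey, float("nan")),
        })
    return rows
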
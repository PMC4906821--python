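"""End-to-end orchestration: structure -> charges -> SASA -> energies."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from .energy import (InteractionMatrix, ResidueEnergyProfile, TKParameters,
                     interaction_matrix, residue_energy_profile)
from .sasa import SasaResult, normalize_residue_sasa, shrake_rupley
from .structure import (ChargeSite, ProteinStructure, SphereEmbedding,
                        embed_sphere, extract_charge_sites, read_pdb)


@dataclass
class StructureAnalysis:
    structure: ProteinStructure
    sites: list[ChargeSite]
    sphere: SphereEmbedding
    sasa: SasaResult
    matrix: InteractionMatrix
    profile: ResidueEnergyProfile


def analyze_structure(pdb_path: str | Path | ProteinStructure,
                      params: TKParameters | None = None,
                      probe_radius: float = 1.4, n_points: int = 960,
                      margin: float = 2.0, ion_shell: float = 2.0,
                      burial_depth: float = 1.0,
                      include_termini: bool = True) -> StructureAnalysis:
    """Run the full electrostatic analysis of one structure.

    Parses the PDB (or accepts an in-memory structure), extracts ionizable
    charge sites, computes normalized accessibilities, embeds the
    dielectric sphere, and evaluates the pairwise interaction matrix and
    per-residue aggregate energies.
    """
    params = params or TKParameters()
    if isinstance(pdb_path, ProteinStructure):
        structure = pdb_path
    else:
        structure = read_pdb(pdb_path)
    sites = extract_charge_sites(structure, ph=params.ph,
                                 charge_model=params.charge_model,
                                 include_termini=include_termini)
    if len(sites) < 2:
        raise ValueError("structure yields fewer than two charge sites")
    sasa = shrake_rupley(structure, probe_radius=probe_radius, n_points=n_points)
    norm = normalize_residue_sasa(sasa, structure)
    for site in sites:
        chain, seq, _ = site.residue_ref
        site.sasa_norm = norm.get((chain, seq), 0.0)
    sphere = embed_sphere(structure, sites, margin=margin, ion_shell=ion_shell,
                          burial_depth=burial_depth)
    matrix = interaction_matrix(sites, sphere, params)
    profile = residue_energy_profile(matrix)
    return StructureAnalysis(structure=structure, sites=sites, sphere=sphere,
                             sasa=sasa, matrix=matrix, profile=profile)
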
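"""Three-criterion selection of stabilizing surface-charge substitutions.

A site qualifies when (1) its aggregate charge-charge energy E_i is high
and positive (destabilizing), (2) it lies far from the catalytic center so
activity is retained, and (3) — when an alignment is supplied — the
proposed replacement residue is observed among homologs.  Each surviving
site is scored for every residue in the substitution vocabulary by
recomputing its aggregate energy with the mutated charge, keeping the
wild-type geometry and accessibility fixed.  Mutations that drive E_i from
positive to negative are the prime stabilization candidates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .constants import ONE_TO_THREE, THREE_TO_ONE
from .energy import (InteractionMatrix, ResidueEnergyProfile, TKParameters,
                     interaction_matrix, tk_pair_energy)
from .msa import Alignment, column_profile, substitution_supported
from .structure import BACKBONE_ATOMS, ChargeSite, ProteinStructure, SphereEmbedding
from .titration import formal_charge, titrate_charge

# Substitution vocabulary per wild-type charge class, with mutation class.
# Acidic sites may be neutralized (A, G) or reversed (K, R, H); basic sites
# neutralized (A) or reversed (D, E); His either reversed to D or
# neutralized.
ACIDIC_TARGETS = [("A", "neutralize"), ("K", "reverse"), ("R", "reverse"),
                  ("G", "neutralize"), ("H", "reverse")]
BASIC_TARGETS = [("A", "neutralize"), ("D", "reverse"), ("E", "reverse")]
HIS_TARGETS = [("D", "reverse"), ("A", "neutralize")]

NEUTRAL_RESIDUES = {"A", "G"}


@dataclass
class DesignConstraints:
    catalytic_residues: list[tuple[str, int]] = field(default_factory=list)
    min_catalytic_distance: float = 12.0  # Angstrom
    energy_threshold: float = 1.0  # kJ/mol
    msa_min_count: int = 1

    def __post_init__(self) -> None:
        if self.min_catalytic_distance < 0:
            raise ValueError("min_catalytic_distance must be >= 0")


@dataclass
class CandidateMutation:
    site_ref: tuple[str, int, str]  # (chain, seq_number, wild residue 3-letter)
    wild_residue: str  # 1-letter
    target_residue: str  # 1-letter
    mutation_class: str  # neutralize | reverse | other
    E_before: float  # kJ/mol
    E_after: float  # kJ/mol
    delta_E: float  # kJ/mol
    catalytic_distance: float  # Angstrom (inf if no catalytic residues given)
    msa_supported: bool | None  # None when no alignment supplied
    rank: int = 0

    @property
    def label(self) -> str:
        return f"{self.wild_residue}{self.site_ref[1]}{self.target_residue}"


def propose_substitutions(site: ChargeSite) -> list[tuple[str, str]]:
    """Substitution vocabulary for one ionizable side-chain site.

    Returns ``(target 1-letter code, mutation class)`` pairs.  Chain
    termini and non-ionizable residues are not mutable.
    """
    if site.group != "sidechain":
        raise ValueError("chain termini cannot be substituted")
    name = site.residue_ref[2]
    if name in ("ASP", "GLU"):
        return list(ACIDIC_TARGETS)
    if name in ("LYS", "ARG"):
        return list(BASIC_TARGETS)
    if name == "HIS":
        return list(HIS_TARGETS)
    raise ValueError(f"residue {name} is not an ionizable design site")


def mutated_charge(target_residue: str, params: TKParameters) -> float:
    """Charge carried by the target residue under the active charge model."""
    if target_residue in NEUTRAL_RESIDUES:
        return 0.0
    name3 = ONE_TO_THREE.get(target_residue.upper())
    if name3 is None:
        raise ValueError(f"unknown target residue {target_residue!r}")
    if params.charge_model == "formal":
        return formal_charge(name3)
    return titrate_charge(name3, params.ph)


def apply_mutation(sites: list[ChargeSite], site: ChargeSite, target_residue: str,
                   params: TKParameters) -> list[ChargeSite]:
    """Charge-site list after one substitution, geometry unchanged.

    Neutralizing targets remove the site; charged targets keep the
    position and accessibility and swap in the target residue's charge.
    """
    if site.key not in {s.key for s in sites}:
        raise ValueError(f"site {site.residue_ref} not in list")
    new_sites: list[ChargeSite] = []
    for s in sites:
        if s.key != site.key:
            new_sites.append(s)
            continue
        q = mutated_charge(target_residue, params)
        if q == 0.0:
            continue  # neutralized: the site vanishes from the charge set
        chain, seq, _ = s.residue_ref
        new_sites.append(ChargeSite(
            residue_ref=(chain, seq, ONE_TO_THREE[target_residue.upper()]),
            position=s.position.copy(), charge=q, sasa_norm=s.sasa_norm,
            radial_distance=s.radial_distance, group=s.group,
        ))
    return new_sites


def catalytic_distance(site: ChargeSite, structure: ProteinStructure,
                       catalytic_residues: list[tuple[str, int]]) -> float:
    """Distance from the site's charge point to the nearest side-chain atom
    of any catalytic residue (all atoms for Gly)."""
    best = float("inf")
    for chain, seq in catalytic_residues:
        res = structure.find_residue(chain, seq)
        if res is None:
            raise ValueError(f"catalytic residue {chain}:{seq} absent from structure")
        atoms = [a for a in res.atoms if a.name not in BACKBONE_ATOMS] or res.atoms
        for atom in atoms:
            d = float(np.linalg.norm(site.position - atom.coordinates))
            best = min(best, d)
    return best


def _site_energy_after(site_index: int, new_charge: float, target3: str,
                       sites: list[ChargeSite], sphere: SphereEmbedding,
                       params: TKParameters) -> float:
    """Aggregate energy of the mutated site: its row of the matrix recomputed
    against all unchanged partners."""
    if new_charge == 0.0:
        return 0.0
    old = sites[site_index]
    chain, seq, _ = old.residue_ref
    mutated = ChargeSite(residue_ref=(chain, seq, target3), position=old.position.copy(),
                         charge=new_charge, sasa_norm=old.sasa_norm,
                         radial_distance=old.radial_distance, group=old.group)
    total = 0.0
    for j, other in enumerate(sites):
        if j == site_index:
            continue
        total += tk_pair_energy(mutated, other, sphere, params)
    return total


def scan(structure: ProteinStructure, sites: list[ChargeSite],
         sphere: SphereEmbedding, params: TKParameters,
         matrix: InteractionMatrix, profile: ResidueEnergyProfile,
         constraints: DesignConstraints,
         alignment: Alignment | None = None,
         column_map: dict[int, int] | None = None) -> list[CandidateMutation]:
    """Rank every substitution at every destabilized, catalysis-safe site.

    Ordering is ascending E_after (most stabilized first), ties broken by
    descending E_before, then by residue number; ranks are 1-based.
    """
    candidates: list[CandidateMutation] = []
    for i, site in enumerate(sites):
        if site.group != "sidechain":
            continue
        e_before = profile.energy_of(site)
        if e_before <= constraints.energy_threshold:
            continue
        if constraints.catalytic_residues:
            cat_dist = catalytic_distance(site, structure, constraints.catalytic_residues)
            if cat_dist < constraints.min_catalytic_distance:
                continue  # criterion 2: too close to the catalytic center
        else:
            cat_dist = float("inf")
        wild1 = THREE_TO_ONE[site.residue_ref[2]]
        for target, mclass in propose_substitutions(site):
            q_new = mutated_charge(target, params)
            e_after = _site_energy_after(i, q_new, ONE_TO_THREE.get(target, "ALA"),
                                         sites, sphere, params)
            supported: bool | None = None
            if alignment is not None and column_map is not None:
                col = column_map.get(site.residue_ref[1])
                if col is None:
                    supported = False
                else:
                    prof = column_profile(alignment, col)
                    supported, _ = substitution_supported(prof, target,
                                                          constraints.msa_min_count)
            candidates.append(CandidateMutation(
                site_ref=site.residue_ref, wild_residue=wild1,
                target_residue=target, mutation_class=mclass,
                E_before=e_before, E_after=e_after, delta_E=e_after - e_before,
                catalytic_distance=cat_dist, msa_supported=supported,
            ))
    candidates.sort(key=lambda c: (c.E_after, -c.E_before, c.site_ref[1],
                                   c.target_residue))
    for rank, cand in enumerate(candidates, start=1):
        cand.rank = rank
    return candidates


REPORT_COLUMNS = ["rank", "chain", "seq", "wild", "target", "class",
                  "E_before", "E_after", "delta_E", "catalytic_distance_A",
                  "msa_supported"]


def write_report(candidates: list[CandidateMutation], metadata: dict,
                 tsv_path: str | Path, json_path: str | Path | None = None) -> None:
    """Fixed-column TSV report plus a JSON sidecar with full provenance."""
    tsv_path = Path(tsv_path)
    lines = ["\t".join(REPORT_COLUMNS)]
    for c in candidates:
        chain, seq, _ = c.site_ref
        lines.append("\t".join([
            str(c.rank), chain, str(seq), c.wild_residue, c.target_residue,
            c.mutation_class, f"{c.E_before:.6g}", f"{c.E_after:.6g}",
            f"{c.delta_E:.6g}",
            "inf" if np.isinf(c.catalytic_distance) else f"{c.catalytic_distance:.6g}",
            "" if c.msa_supported is None else str(bool(c.msa_supported)),
        ]))
    tsv_path.write_text("\n".join(lines) + "\n")
    if json_path is not None:
        payload = {
            "metadata": metadata,
            "candidates": [asdict(c) for c in candidates],
        }
        Path(json_path).write_text(json.dumps(payload, indent=2, default=str) + "\n")


def read_report(tsv_path: str | Path) -> list[CandidateMutation]:
    """Re-read a TSV report into candidate objects (round-trip of write_report)."""
    lines = Path(tsv_path).read_text().rstrip("\n").split("\n")
    header = lines[0].split("\t")
    if header != REPORT_COLUMNS:
        raise ValueError("unrecognized report header")
    out = []
    for line in lines[1:]:
        f = line.split("\t")
        if len(f) < len(REPORT_COLUMNS):
            f = f + [""] * (len(REPORT_COLUMNS) - len(f))
        out.append(CandidateMutation(
            site_ref=(f[1], int(f[2]), ONE_TO_THREE[f[3]]),
            wild_residue=f[3], target_residue=f[4], mutation_class=f[5],
            E_before=float(f[6]), E_after=float(f[7]), delta_E=float(f[8]),
            catalytic_distance=float(f[9]),
            msa_supported=None if f[10] == "" else f[10] == "True",
            rank=int(f[0]),
        ))
    return out
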
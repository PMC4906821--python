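"""Synthetic inputs with known ground truth for every pipeline stage.

Three generators: toy charge arrangements on a spherical shell (standing
in for a globular protein's surface charges, with a valid mini-PDB so the
whole read -> energy -> design pipeline runs end-to-end), assay curves
(exponential inactivation courses, logistic thermal-tolerance curves,
Michaelis-Menten rate data, single-peak DSC thermograms) with optional
seeded multiplicative noise, and toy alignments whose column composition
is fixed by construction.  All generators are pure functions of their
spec + seed; noise-free curves satisfy the generating model exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .msa import Alignment
from .structure import Atom, ChargeSite, ProteinStructure, Residue, write_pdb

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class ToyProteinSpec:
    n_sites: int = 6
    sphere_radius: float = 15.0  # Angstrom
    charge_pattern: list[int] = field(default_factory=list)  # entries in {-1, 0, +1}
    seed: int = 0
    min_separation: float = 5.0  # Angstrom

    def __post_init__(self) -> None:
        if self.n_sites < 2:
            raise ValueError("need at least 2 sites")
        if self.min_separation <= 0:
            raise ValueError("min_separation must be positive")
        if not self.charge_pattern:
            # alternate +1/-1 by default
            self.charge_pattern = [1 if i % 2 == 0 else -1 for i in range(self.n_sites)]
        if len(self.charge_pattern) != self.n_sites:
            raise ValueError("charge_pattern length must equal n_sites")


@dataclass
class AssayCurveSpec:
    model: str  # exponential_decay | logistic | michaelis_menten | gaussian_peak
    parameters: dict
    grid: list
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        g = np.asarray(self.grid, dtype=float)
        if np.any(np.diff(g) <= 0):
            raise ValueError("grid must be strictly increasing")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


# residue name and charge atoms used for each charge class:
# +1 -> Lys with its terminal amine, -1 -> Asp with its carboxylate pair
# (placed so their midpoint is the requested site position), 0 -> Gly.
def _shell_positions(spec: ToyProteinSpec) -> np.ndarray:
    rng = np.random.default_rng(spec.seed)
    shell_r = 0.9 * spec.sphere_radius
    positions: list[np.ndarray] = []
    attempts = 0
    max_attempts = 2000 * spec.n_sites
    while len(positions) < spec.n_sites:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(
                f"packing infeasible: could not place {spec.n_sites} sites at "
                f"min separation {spec.min_separation} A on a {shell_r} A shell")
        v = rng.normal(size=3)
        v /= np.linalg.norm(v)
        pos = shell_r * v
        if all(np.linalg.norm(pos - p) >= spec.min_separation for p in positions):
            positions.append(pos)
    return np.array(positions)


def make_toy_structure(spec: ToyProteinSpec, pdb_path: str | Path | None = None
                       ) -> tuple[ProteinStructure, list[ChargeSite]]:
    """Toy charge arrangement on a shell at 0.9x the sphere radius.

    Each site becomes one residue (Lys for +1, Asp for -1, Gly for 0) with
    a backbone CA slightly inside the shell and the charge-placement
    atom(s) at the site position, so the emitted PDB round-trips through
    the structure reader and charge extractor.  Deterministic for a fixed
    seed; positions are rejection-sampled to respect ``min_separation``.
    """
    positions = _shell_positions(spec)
    residues: list[Residue] = []
    sites: list[ChargeSite] = []
    serial = 0
    for i, (pos, q) in enumerate(zip(positions, spec.charge_pattern)):
        seq = i + 1
        inward = pos * (1.0 - 2.0 / np.linalg.norm(pos))  # CA ~2 A inside
        if q > 0:
            name = "LYS"
            serial += 1
            ca = Atom(serial, "CA", "C", i, inward, 1.70)
            serial += 1
            nz = Atom(serial, "NZ", "N", i, pos, 1.55)
            atoms = [ca, nz]
        elif q < 0:
            name = "ASP"
            # carboxylate oxygens straddle the site position along a tangent
            tangent = np.cross(pos, [0.0, 0.0, 1.0])
            if np.linalg.norm(tangent) < 1e-6:
                tangent = np.cross(pos, [0.0, 1.0, 0.0])
            tangent /= np.linalg.norm(tangent)
            serial += 1
            ca = Atom(serial, "CA", "C", i, inward, 1.70)
            serial += 1
            od1 = Atom(serial, "OD1", "O", i, pos + 0.6 * tangent, 1.52)
            serial += 1
            od2 = Atom(serial, "OD2", "O", i, pos - 0.6 * tangent, 1.52)
            atoms = [ca, od1, od2]
        else:
            name = "GLY"
            serial += 1
            atoms = [Atom(serial, "CA", "C", i, pos, 1.70)]
        residues.append(Residue(chain="A", seq_number=seq, name=name, atoms=atoms))
        if q != 0:
            sites.append(ChargeSite(
                residue_ref=("A", seq, name), position=pos.copy(), charge=float(q),
                radial_distance=float(np.linalg.norm(pos)),
            ))
    structure = ProteinStructure(residues=residues, source_id=f"toy-seed{spec.seed}")
    if pdb_path is not None:
        write_pdb(structure, pdb_path,
                  remarks=[f"synthetic toy structure, spec={json.dumps(_spec_dict(spec))}"])
    return structure, sites


def _spec_dict(spec) -> dict:
    from dataclasses import asdict
    return asdict(spec)


_MODELS = {
    "exponential_decay": lambda x, p: p.get("a0", 1.0) * np.exp(-p["k"] * x),
    "logistic": lambda x, p: 1.0 / (1.0 + np.exp((x - p["midpoint"]) / p["slope"])),
    "michaelis_menten": lambda x, p: p["vmax"] * x / (p["km"] + x),
    "gaussian_peak": lambda x, p: (p.get("baseline_intercept", 0.0)
                                   + p.get("baseline_slope", 0.0) * x
                                   + p["height"] * np.exp(-0.5 * ((x - p["center"])
                                                                  / p["width"]) ** 2)),
}


def make_assay_curve(spec: AssayCurveSpec) -> pd.DataFrame:
    """(x, y) table from a named model with seeded multiplicative noise.

    ``y = model(x) * (1 + eps)`` with ``eps ~ Normal(0, noise_sd)``;
    ``noise_sd = 0`` gives the exact curve.
    """
    if spec.model not in _MODELS:
        raise ValueError(f"unknown model {spec.model!r}")
    x = np.asarray(spec.grid, dtype=float)
    y = _MODELS[spec.model](x, spec.parameters)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        y = y * (1.0 + rng.normal(0.0, spec.noise_sd, size=x.shape))
    return pd.DataFrame({"x": x, "y": y})


def make_toy_alignment(n_homologs: int, length: int,
                       support_spec: dict[int, set[str]] | None = None,
                       seed: int = 0, query: str | None = None,
                       fasta_path: str | Path | None = None) -> Alignment:
    """Query + homolog rows with controlled column composition.

    Homologs copy the query except at the columns named in
    ``support_spec`` (1-based), where each homolog draws uniformly from
    the declared residue set — so substitution support at those columns is
    known by construction.  With an empty spec all non-wild substitutions
    are unsupported.
    """
    support_spec = support_spec or {}
    rng = np.random.default_rng(seed)
    if query is None:
        query = "".join(rng.choice(list(AMINO_ACIDS), size=length))
    if len(query) != length:
        raise ValueError("query length mismatch")
    for col in support_spec:
        if not 1 <= col <= length:
            raise ValueError(f"support column {col} outside alignment length {length}")
    rows = [query]
    names = ["query"]
    for h in range(n_homologs):
        row = list(query)
        for col, res_set in support_spec.items():
            row[col - 1] = str(rng.choice(sorted(res_set)))
        rows.append("".join(row))
        names.append(f"homolog{h + 1}")
    aln = Alignment(names=names, rows=rows, query_index=0)
    if fasta_path is not None:
        text = "".join(f">{n}\n{r}\n" for n, r in zip(names, rows))
        Path(fasta_path).write_text(text)
    return aln
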
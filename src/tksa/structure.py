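"""Protein structures, ionizable charge sites, and the dielectric-sphere embedding.

The electrostatic model treats the protein as a low-dielectric sphere with
point charges at (or just beneath) its surface.  This module parses a PDB
file into a light-weight structure, reduces each ionizable group to a
single point charge at a conventional placement atom, and computes the
sphere geometry (center, protein radius ``b``, ion-exclusion radius ``a``)
that the pairwise energy kernel needs.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio.PDB import PDBParser

from .constants import THREE_TO_ONE, VDW_DEFAULT_A, VDW_RADII_A
from .titration import formal_charge, titrate_charge

logger = logging.getLogger(__name__)

# Atoms used to place the point charge of each ionizable side chain.
# Midpoints are taken where the charge is delocalized over two atoms.
CHARGE_PLACEMENT_ATOMS = {
    "ASP": ("OD1", "OD2"),
    "GLU": ("OE1", "OE2"),
    "LYS": ("NZ",),
    "ARG": ("CZ",),
    "HIS": ("ND1", "NE2"),
    "CYS": ("SG",),
    "TYR": ("OH",),
}

BACKBONE_ATOMS = {"N", "CA", "C", "O", "OXT"}


@dataclass
class Atom:
    serial: int
    name: str
    element: str
    residue_index: int
    coordinates: np.ndarray  # (3,) Angstrom
    radius: float  # van der Waals radius, Angstrom

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError(f"atom {self.name}: non-finite coordinates")
        if self.radius <= 0:
            raise ValueError(f"atom {self.name}: radius must be positive")


@dataclass
class Residue:
    chain: str
    seq_number: int
    name: str  # 3-letter code
    atoms: list[Atom] = field(default_factory=list)

    @property
    def is_standard(self) -> bool:
        return self.name in THREE_TO_ONE

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None


@dataclass
class ProteinStructure:
    residues: list[Residue]
    source_id: str = ""

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError("structure has no residues")

    def atoms(self):
        for res in self.residues:
            yield from res.atoms

    def coordinates(self) -> np.ndarray:
        return np.array([a.coordinates for a in self.atoms()], dtype=float)

    def sequence(self) -> str:
        """One-letter sequence; nonstandard residues become 'X'."""
        return "".join(THREE_TO_ONE.get(r.name, "X") for r in self.residues)

    def find_residue(self, chain: str, seq_number: int) -> Residue | None:
        for r in self.residues:
            if r.chain == chain and r.seq_number == seq_number:
                return r
        return None


@dataclass
class ChargeSite:
    """A point charge standing in for one ionizable group.

    ``group`` distinguishes side-chain charges from the chain termini;
    ``radial_distance`` is the distance from the sphere center after the
    burial cap has been applied (set by :func:`embed_sphere`).
    """

    residue_ref: tuple[str, int, str]  # (chain, seq_number, residue name)
    position: np.ndarray  # (3,) Angstrom
    charge: float  # signed fraction of e
    sasa_norm: float = 0.0  # normalized residue accessibility in [0, 1]
    radial_distance: float = 0.0  # Angstrom from sphere center
    group: str = "sidechain"  # "sidechain" | "nterm" | "cterm"

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if abs(self.charge) > 1.0 + 1e-12:
            raise ValueError("charge magnitude exceeds 1 e")
        if not 0.0 <= self.sasa_norm <= 1.0:
            raise ValueError("sasa_norm outside [0, 1]")

    @property
    def key(self) -> tuple[str, int, str]:
        chain, seq, name = self.residue_ref
        return (chain, seq, self.group)


@dataclass
class SphereEmbedding:
    center: np.ndarray  # (3,) Angstrom
    b: float  # protein-sphere radius, Angstrom
    a: float  # ion-exclusion radius, Angstrom

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        if self.b <= 0:
            raise ValueError("sphere radius b must be positive")
        if self.a < self.b:
            raise ValueError("ion-exclusion radius a must be >= b")


def _element_of(bio_atom) -> str:
    elem = (bio_atom.element or "").strip().upper()
    if not elem:
        # fall back to the first alphabetic character of the atom name
        for ch in bio_atom.get_name():
            if ch.isalpha():
                elem = ch.upper()
                break
    return elem


def read_pdb(path: str | Path, source_id: str | None = None,
             include_hetero: bool = False) -> ProteinStructure:
    """Parse the first model of a PDB file into a :class:`ProteinStructure`.

    Alternate locations are resolved to the highest-occupancy conformer;
    waters and (by default) hetero groups are excluded; insertion codes
    are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"PDB file not found: {path}")
    parser = PDBParser(QUIET=True)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            bio_structure = parser.get_structure(source_id or path.stem, str(path))
    except ValueError as exc:
        raise ValueError(f"{path}: no ATOM records ({exc})") from exc
    models = list(bio_structure)
    if not models:
        raise ValueError(f"{path}: no ATOM records")
    model = models[0]

    residues: list[Residue] = []
    seen: set[tuple[str, int, str]] = set()
    index = 0
    for chain in model:
        for bio_res in chain:
            hetfield, seq_number, icode = bio_res.id
            if hetfield == "W":
                continue
            if hetfield.strip() and not include_hetero:
                continue
            if icode.strip():
                raise ValueError(
                    f"{path}: insertion code {icode!r} at {chain.id}:{seq_number} "
                    "is not supported"
                )
            res = Residue(chain=chain.id, seq_number=seq_number,
                          name=bio_res.get_resname().strip())
            for bio_atom in bio_res:
                # iterating a Bio.PDB residue yields the highest-occupancy
                # altloc of each disordered atom
                name = bio_atom.get_name()
                dup_key = (chain.id, seq_number, name)
                if dup_key in seen:
                    raise ValueError(
                        f"{path}: duplicate atom {name} in {chain.id}:{seq_number} "
                        "after altloc resolution"
                    )
                seen.add(dup_key)
                elem = _element_of(bio_atom)
                res.atoms.append(Atom(
                    serial=bio_atom.get_serial_number() or index + 1,
                    name=name,
                    element=elem,
                    residue_index=index,
                    coordinates=np.asarray(bio_atom.get_coord(), dtype=float),
                    radius=VDW_RADII_A.get(elem, VDW_DEFAULT_A),
                ))
            if res.atoms:
                residues.append(res)
                index += 1
    if not residues:
        raise ValueError(f"{path}: no ATOM records")
    return ProteinStructure(residues=residues, source_id=source_id or path.stem)


def write_pdb(structure: ProteinStructure, path: str | Path,
              remarks: list[str] | None = None) -> None:
    """Write ATOM/TER/END records in the dialect :func:`read_pdb` accepts."""
    path = Path(path)
    lines: list[str] = []
    for remark in remarks or []:
        lines.append(f"REMARK   1 {remark}"[:80])
    serial = 0
    last_chain = None
    for res in structure.residues:
        if last_chain is not None and res.chain != last_chain:
            lines.append("TER")
        last_chain = res.chain
        for atom in res.atoms:
            serial += 1
            name = atom.name if len(atom.name) == 4 else f" {atom.name:<3s}"
            x, y, z = atom.coordinates
            lines.append(
                f"ATOM  {serial:5d} {name:<4s} {res.name:<3s} {res.chain:1s}"
                f"{res.seq_number:4d}    {x:8.3f}{y:8.3f}{z:8.3f}"
                f"{1.00:6.2f}{0.00:6.2f}          {atom.element:>2s}"
            )
    lines.append("TER")
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")


def _placement_position(res: Residue, atom_names: tuple[str, ...]) -> np.ndarray | None:
    coords = []
    for name in atom_names:
        atom = res.atom(name)
        if atom is None:
            return None
        coords.append(atom.coordinates)
    return np.mean(coords, axis=0)


def extract_charge_sites(structure: ProteinStructure, ph: float = 7.0,
                         charge_model: str = "titration",
                         pka_table: dict[str, float] | None = None,
                         include_termini: bool = True,
                         include_cys_tyr: bool = False) -> list[ChargeSite]:
    """Reduce every ionizable group to a single :class:`ChargeSite`.

    Side chains of Asp/Glu/Lys/Arg/His (plus Cys/Tyr when enabled) and the
    free chain termini each contribute one site.  Charges come either from
    the formal model (the +-1 of the predominant species) or from
    Henderson-Hasselbalch titration at ``ph``.  A residue missing its
    placement atoms is skipped with a logged warning.
    """
    if not 0.0 <= ph <= 14.0:
        raise ValueError("pH must be in [0, 14]")
    if charge_model not in ("formal", "titration"):
        raise ValueError(f"unknown charge model {charge_model!r}")

    def charge_of(group: str) -> float:
        if charge_model == "formal":
            return formal_charge(group)
        return titrate_charge(group, ph, pka_table)

    sites: list[ChargeSite] = []
    for res in structure.residues:
        if res.name not in CHARGE_PLACEMENT_ATOMS:
            continue
        if res.name in ("CYS", "TYR") and not include_cys_tyr:
            continue
        pos = _placement_position(res, CHARGE_PLACEMENT_ATOMS[res.name])
        if pos is None:
            logger.warning("charge site skipped: %s:%d %s missing placement atoms",
                           res.chain, res.seq_number, res.name)
            continue
        sites.append(ChargeSite(
            residue_ref=(res.chain, res.seq_number, res.name),
            position=pos, charge=charge_of(res.name), group="sidechain",
        ))

    if include_termini:
        chains: dict[str, list[Residue]] = {}
        for res in structure.residues:
            chains.setdefault(res.chain, []).append(res)
        for chain_id, chain_res in chains.items():
            first, last = chain_res[0], chain_res[-1]
            n_atom = first.atom("N")
            if n_atom is not None:
                sites.append(ChargeSite(
                    residue_ref=(chain_id, first.seq_number, first.name),
                    position=n_atom.coordinates.copy(),
                    charge=charge_of("NTERM"), group="nterm",
                ))
            else:
                logger.warning("N-terminus of chain %s missing backbone N", chain_id)
            o_atom, oxt_atom = last.atom("O"), last.atom("OXT")
            if o_atom is not None:
                pos = (o_atom.coordinates if oxt_atom is None
                       else 0.5 * (o_atom.coordinates + oxt_atom.coordinates))
                sites.append(ChargeSite(
                    residue_ref=(chain_id, last.seq_number, last.name),
                    position=pos, charge=charge_of("CTERM"), group="cterm",
                ))
            else:
                logger.warning("C-terminus of chain %s missing backbone O", chain_id)
    return sites


def embed_sphere(structure: ProteinStructure, sites: list[ChargeSite] | None = None,
                 margin: float = 2.0, ion_shell: float = 2.0,
                 burial_depth: float = 1.0) -> SphereEmbedding:
    """Fit the dielectric sphere around the structure and cap site depths.

    The center is the unweighted mean of all atom coordinates, the protein
    radius ``b`` is the maximal atom-to-center distance plus ``margin``,
    and the ion-exclusion radius is ``a = b + ion_shell``.  Each charge
    site's ``radial_distance`` is set to
    ``min(|position - center|, b - burial_depth)`` so that every charge sits
    at least ``burial_depth`` beneath the dielectric boundary.
    """
    coords = structure.coordinates()
    center = coords.mean(axis=0)
    b = float(np.max(np.linalg.norm(coords - center, axis=1))) + margin
    sphere = SphereEmbedding(center=center, b=b, a=b + ion_shell)
    if sites is not None:
        cap = b - burial_depth
        for site in sites:
            dist = float(np.linalg.norm(site.position - center))
            site.radial_distance = min(dist, cap)
    return sphere
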
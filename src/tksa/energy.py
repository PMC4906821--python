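"""Pairwise charge-charge interaction energies in the TK-SA model.

The protein is a sphere of low dielectric ``eps_protein`` immersed in
solvent of dielectric ``eps_solvent`` with Debye screening from the ionic
strength.  The interaction energy of two embedded point charges is the
direct Coulomb term corrected by a Legendre-series image term for the
dielectric boundary and a leading-order ionic screening term, the whole
attenuated by the mean normalized solvent accessibility of the two sites:

    W_ij = K q_i q_j (A_ij - B_ij - C_ij) (1 - s_ij)

with K = 1389.35 kJ A/mol.  Positive W_ij (like charges in contact) is
destabilizing; sites whose aggregate E_i = sum_j W_ij is large and
positive are the candidates for neutralization or charge reversal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import COULOMB_K_KJ_A_MOL, KAPPA_COEF_PER_A
from .structure import ChargeSite, SphereEmbedding
from .titration import titrate_charge  # noqa: F401  (re-exported; part of this module's surface)


@dataclass
class TKParameters:
    """Dielectric, ionic, and charge-model parameters of the sphere model."""

    eps_protein: float = 4.0
    eps_solvent: float = 78.5
    ionic_strength: float = 0.10  # mol/L
    temperature: float = 298.15  # K
    ph: float = 7.0
    series_order: int = 30
    charge_model: str = "titration"  # "formal" | "titration"

    def __post_init__(self) -> None:
        if self.eps_protein <= 0 or self.eps_solvent <= 0:
            raise ValueError("dielectric constants must be positive")
        if self.ionic_strength < 0:
            raise ValueError("ionic strength must be >= 0")
        if not 0 < self.series_order <= 200:
            raise ValueError("series_order must be in (0, 200]")
        if self.charge_model not in ("formal", "titration"):
            raise ValueError(f"unknown charge model {self.charge_model!r}")


@dataclass
class InteractionMatrix:
    sites: list[ChargeSite]
    W: np.ndarray  # symmetric, zero diagonal, kJ/mol

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        n = len(self.sites)
        if self.W.shape != (n, n):
            raise ValueError("matrix shape does not match site count")
        if not np.all(np.isfinite(self.W)):
            raise ValueError("non-finite interaction energies")


@dataclass
class ResidueEnergyProfile:
    """Per-site aggregate energies E_i = sum_{j != i} W_ij, kJ/mol."""

    sites: list[ChargeSite]
    energies: np.ndarray  # parallel to sites

    def energy_of(self, site: ChargeSite) -> float:
        for s, e in zip(self.sites, self.energies):
            if s.key == site.key:
                return float(e)
        raise KeyError(f"site {site.residue_ref} not in profile")

    def as_rows(self) -> list[dict]:
        rows = []
        for site, e in zip(self.sites, self.energies):
            chain, seq, name = site.residue_ref
            rows.append({"chain": chain, "seq_number": seq, "residue": name,
                         "group": site.group, "E_i_kJ_mol": float(e)})
        return rows


def _legendre_series_sum(coef_fn, rho: float, cos_theta: float, order: int) -> float:
    """Sum_{n=0..order} coef(n) * rho^n * P_n(cos_theta) by upward recurrence."""
    p_prev, p_curr = 1.0, cos_theta  # P_0, P_1
    total = coef_fn(0) * p_prev
    rho_n = rho
    for n in range(1, order + 1):
        total += coef_fn(n) * rho_n * p_curr
        p_prev, p_curr = p_curr, ((2 * n + 1) * cos_theta * p_curr - n * p_prev) / (n + 1)
        rho_n *= rho
    return total


def tk_pair_energy(site_i: ChargeSite, site_j: ChargeSite,
                   sphere: SphereEmbedding, params: TKParameters) -> float:
    """Interaction energy W_ij (kJ/mol) of two charge sites in the sphere model."""
    if site_i.charge == 0.0 or site_j.charge == 0.0:
        return 0.0
    r_vec_i = site_i.position - sphere.center
    r_vec_j = site_j.position - sphere.center
    r_ij = float(np.linalg.norm(site_i.position - site_j.position))
    if r_ij == 0.0:
        raise ValueError(f"coincident charges: {site_i.residue_ref} / {site_j.residue_ref}")

    eps_p, eps_s, b = params.eps_protein, params.eps_solvent, sphere.b
    a_term = 1.0 / (eps_p * r_ij)

    r_i, r_j = site_i.radial_distance, site_j.radial_distance
    if r_i > b + 1e-9 or r_j > b + 1e-9:
        raise ValueError("site radial distance exceeds sphere radius")
    rho = (r_i * r_j) / (b * b)
    norm_i, norm_j = np.linalg.norm(r_vec_i), np.linalg.norm(r_vec_j)
    if norm_i == 0.0 or norm_j == 0.0:
        cos_theta = 1.0  # a site at the exact center has no defined direction
    else:
        cos_theta = float(np.clip(np.dot(r_vec_i, r_vec_j) / (norm_i * norm_j), -1.0, 1.0))

    def image_coef(n: int) -> float:
        return ((eps_p - eps_s) * (n + 1)) / (eps_p * ((n + 1) * eps_s + n * eps_p))

    b_term = _legendre_series_sum(image_coef, rho, cos_theta, params.series_order) / b

    kappa = KAPPA_COEF_PER_A * np.sqrt(params.ionic_strength)
    x = kappa * sphere.a
    c_term = (x / (eps_s * (1.0 + x))) / b

    s_ij = min(1.0, max(0.0, 0.5 * (site_i.sasa_norm + site_j.sasa_norm)))
    w = (COULOMB_K_KJ_A_MOL * site_i.charge * site_j.charge
         * (a_term - b_term - c_term) * (1.0 - s_ij))
    if not np.isfinite(w):
        raise ValueError(
            f"non-finite energy for pair {site_i.residue_ref} / {site_j.residue_ref}")
    return float(w)


def interaction_matrix(sites: list[ChargeSite], sphere: SphereEmbedding,
                       params: TKParameters) -> InteractionMatrix:
    """Symmetric zero-diagonal matrix of pairwise energies over all sites."""
    n = len(sites)
    if n < 2:
        raise ValueError("need at least two charge sites")
    W = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            try:
                w = tk_pair_energy(sites[i], sites[j], sphere, params)
            except ValueError as exc:
                raise ValueError(
                    f"pair ({sites[i].residue_ref}, {sites[j].residue_ref}): {exc}"
                ) from exc
            W[i, j] = W[j, i] = w
    return InteractionMatrix(sites=sites, W=W)


def residue_energy_profile(matrix: InteractionMatrix) -> ResidueEnergyProfile:
    """Row sums E_i of the interaction matrix, ordered by (chain, seq_number)."""
    energies = matrix.W.sum(axis=1)
    order = sorted(range(len(matrix.sites)),
                   key=lambda i: (matrix.sites[i].residue_ref[0],
                                  matrix.sites[i].residue_ref[1],
                                  matrix.sites[i].group))
    sites = [matrix.sites[i] for i in order]
    return ResidueEnergyProfile(sites=sites, energies=energies[order])
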
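"""Candidate generation, filtering, scoring, and report round-trips."""

import numpy as np
import pytest

from tksa.design import (DesignConstraints, apply_mutation,
                         catalytic_distance, mutated_charge,
                         propose_substitutions, read_report, scan,
                         write_report)
from tksa.energy import (TKParameters, interaction_matrix,
                         residue_energy_profile, tk_pair_energy)
from tksa.structure import ChargeSite, SphereEmbedding
from tksa.synth import ToyProteinSpec, make_toy_structure
from tksa.titration import titrate_charge

FORMAL = TKParameters(charge_model="formal")


def make_system(pattern, seed=3, radius=14.0):
    spec = ToyProteinSpec(n_sites=len(pattern), seed=seed, sphere_radius=radius,
                          charge_pattern=pattern)
    structure, sites = make_toy_structure(spec)
    sphere = SphereEmbedding(np.zeros(3), radius, radius + 2.0)
    matrix = interaction_matrix(sites, sphere, FORMAL)
    profile = residue_energy_profile(matrix)
    return structure, sites, sphere, matrix, profile


class TestProposeSubstitutions:
    def test_acidic_vocabulary(self):
        site = ChargeSite(("A", 1, "ASP"), np.zeros(3), -1.0)
        targets = {t for t, _ in propose_substitutions(site)}
        assert {"A", "K", "R"} <= targets
        assert {"G", "H"} <= targets  # charge removal to Gly, reversal to His

    def test_his_vocabulary_contains_asp(self):
        site = ChargeSite(("A", 58, "HIS"), np.zeros(3), +0.5)
        targets = {t for t, _ in propose_substitutions(site)}
        assert "D" in targets

    def test_basic_vocabulary(self):
        site = ChargeSite(("A", 2, "LYS"), np.zeros(3), +1.0)
        targets = {t for t, _ in propose_substitutions(site)}
        assert targets == {"A", "D", "E"}

    def test_classes_are_tagged(self):
        site = ChargeSite(("A", 1, "GLU"), np.zeros(3), -1.0)
        classes = dict(propose_substitutions(site))
        assert classes["A"] == "neutralize"
        assert classes["R"] == "reverse"

    def test_non_ionizable_site_rejected(self):
        site = ChargeSite(("A", 1, "GLY"), np.zeros(3), 0.0)
        with pytest.raises(ValueError):
            propose_substitutions(site)

    def test_terminus_not_mutable(self):
        site = ChargeSite(("A", 1, "MET"), np.zeros(3), 1.0, group="nterm")
        with pytest.raises(ValueError, match="termini"):
            propose_substitutions(site)


class TestApplyMutation:
    def test_neutralization_removes_site(self):
        _, sites, sphere, _, _ = make_system([1, -1])
        new = apply_mutation(sites, sites[0], "A", FORMAL)
        assert len(new) == 1
        assert new[0].key == sites[1].key

    def test_reversal_flips_formal_charge_in_place(self):
        _, sites, sphere, _, _ = make_system([1, -1])
        new = apply_mutation(sites, sites[0], "D", FORMAL)
        assert len(new) == 2
        mutated = next(s for s in new if s.key == sites[0].key)
        assert mutated.charge == -1.0
        np.testing.assert_allclose(mutated.position, sites[0].position)
        assert mutated.sasa_norm == sites[0].sasa_norm

    def test_titration_his_to_asp_charges(self):
        params = TKParameters(charge_model="titration", ph=7.0)
        assert mutated_charge("D", params) == pytest.approx(
            titrate_charge("ASP", 7.0))
        assert mutated_charge("D", params) == pytest.approx(
            -1.0 / (1.0 + 10.0 ** (4.0 - 7.0)))

    def test_unknown_target_rejected(self):
        _, sites, _, _, _ = make_system([1, -1])
        with pytest.raises(ValueError):
            apply_mutation(sites, sites[0], "Z", FORMAL)

    def test_site_not_in_list_rejected(self):
        _, sites, _, _, _ = make_system([1, -1])
        stray = ChargeSite(("B", 99, "ASP"), np.ones(3), -1.0)
        with pytest.raises(ValueError):
            apply_mutation(sites, stray, "A", FORMAL)


class TestScan:
    def test_sign_identity_reversal_and_neutralization(self):
        # all-positive cluster: every site has E_i > 0; under formal charges
        # reversal must give exactly -E_i and neutralization exactly 0
        structure, sites, sphere, matrix, profile = make_system([1, 1, 1, 1])
        constraints = DesignConstraints(energy_threshold=0.0)
        cands = scan(structure, sites, sphere, FORMAL, matrix, profile,
                     constraints)
        assert cands, "positive cluster must yield candidates"
        for c in cands:
            if c.mutation_class == "reverse" and c.target_residue in ("D", "E"):
                assert c.E_after == pytest.approx(-c.E_before, rel=1e-9)
            if c.mutation_class == "neutralize":
                assert c.E_after == 0.0
        # the top-ranked candidate is a reversal (goes below zero)
        assert cands[0].mutation_class == "reverse"
        assert cands[0].E_after < 0

    def test_catalytic_proximity_excludes_site(self):
        structure, sites, sphere, matrix, profile = make_system([1, 1, 1])
        near = sites[0].residue_ref
        constraints = DesignConstraints(
            catalytic_residues=[(near[0], near[1])],
            min_catalytic_distance=5.0, energy_threshold=-1e9)
        cands = scan(structure, sites, sphere, FORMAL, matrix, profile,
                     constraints)
        assert all(c.site_ref[1] != near[1] for c in cands)
        assert all(c.catalytic_distance >= 5.0 for c in cands)

    def test_catalytic_residue_absent_raises(self):
        structure, sites, sphere, matrix, profile = make_system([1, 1])
        constraints = DesignConstraints(catalytic_residues=[("A", 999)],
                                        energy_threshold=-1e9)
        with pytest.raises(ValueError, match="absent"):
            scan(structure, sites, sphere, FORMAL, matrix, profile, constraints)

    def test_all_below_threshold_gives_empty_list(self):
        structure, sites, sphere, matrix, profile = make_system([1, -1, 1, -1])
        constraints = DesignConstraints(energy_threshold=1e6)
        cands = scan(structure, sites, sphere, FORMAL, matrix, profile,
                     constraints)
        assert cands == []

    def test_filters_are_order_independent(self):
        structure, sites, sphere, matrix, profile = make_system([1, 1, 1, 1, 1])
        thresh, catal, dmin = 0.5, [("A", 1)], 8.0
        energy_pass = {s.key for s in sites
                       if s.group == "sidechain"
                       and profile.energy_of(s) > thresh}
        distance_pass = {s.key for s in sites
                         if catalytic_distance(s, structure, catal) >= dmin}
        both_then = (energy_pass & distance_pass)
        both_reversed = (distance_pass & energy_pass)
        assert both_then == both_reversed
        constraints = DesignConstraints(catalytic_residues=catal,
                                        min_catalytic_distance=dmin,
                                        energy_threshold=thresh)
        cands = scan(structure, sites, sphere, FORMAL, matrix, profile,
                     constraints)
        scanned = {(c.site_ref[0], c.site_ref[1], "sidechain") for c in cands}
        assert scanned == {(k[0], k[1], k[2]) for k in both_then}

    def test_incremental_equals_full_recomputation(self):
        # bookkeeping invariant: scan's E_after (row-restricted update) must
        # match a full matrix rebuild after apply_mutation
        structure, sites, sphere, matrix, profile = make_system([1, 1, -1, 1])
        constraints = DesignConstraints(energy_threshold=0.0)
        cands = scan(structure, sites, sphere, FORMAL, matrix, profile,
                     constraints)
        for c in cands[:6]:
            site = next(s for s in sites
                        if (s.residue_ref[0], s.residue_ref[1])
                        == (c.site_ref[0], c.site_ref[1]))
            new_sites = apply_mutation(sites, site, c.target_residue, FORMAL)
            if len(new_sites) < 2:
                continue
            full = interaction_matrix(new_sites, sphere, FORMAL)
            new_profile = residue_energy_profile(full)
            if c.mutation_class == "neutralize":
                assert c.E_after == 0.0
            else:
                mutated = next(s for s in new_sites if s.key == site.key)
                assert c.E_after == pytest.approx(
                    new_profile.energy_of(mutated), abs=1e-9)

    def test_ranking_is_deterministic_and_unique(self):
        structure, sites, sphere, matrix, profile = make_system([1, 1, 1])
        constraints = DesignConstraints(energy_threshold=0.0)
        cands = scan(structure, sites, sphere, FORMAL, matrix, profile,
                     constraints)
        assert [c.rank for c in cands] == list(range(1, len(cands) + 1))
        e_after = [c.E_after for c in cands]
        assert e_after == sorted(e_after)


class TestReport:
    def test_round_trip(self, tmp_path):
        structure, sites, sphere, matrix, profile = make_system([1, 1, -1])
        constraints = DesignConstraints(energy_threshold=0.0)
        cands = scan(structure, sites, sphere, FORMAL, matrix, profile,
                     constraints)
        tsv = tmp_path / "report.tsv"
        write_report(cands, {"note": "test"}, tsv, tmp_path / "report.json")
        back = read_report(tsv)
        assert len(back) == len(cands)
        for a, b in zip(cands, back):
            assert a.rank == b.rank
            assert a.label == b.label
            assert a.E_before == pytest.approx(b.E_before, rel=1e-5)
            assert a.E_after == pytest.approx(b.E_after, rel=1e-5)
            assert a.msa_supported == b.msa_supported

    def test_empty_candidates_give_header_only(self, tmp_path):
        tsv = tmp_path / "empty.tsv"
        write_report([], {}, tsv)
        lines = tsv.read_text().strip().split("\n")
        assert len(lines) == 1
        assert lines[0].startswith("rank\tchain")
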
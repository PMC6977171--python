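"""Chemical potentials, solubility equation, relative solubility, ranking."""

import math

import numpy as np
import pytest

from descosmo import (
    InteractionParams,
    SigmaGrid,
    SigmaPotential,
    SigmaProfile,
    SolventMixture,
    Species,
    ln_solubility_dilute,
    ln_solubility_iterative,
    make_gaussian_profile,
    mix_profiles,
    normalize_profile,
    pure_chemical_potential,
    rank_solvents,
    relative_log10_solubility,
    solute_chemical_potential,
    solve_sigma_potential,
)
from descosmo.constants import R_KJ_PER_MOL_K
from descosmo.exceptions import GridMismatchError, ValidationError
from descosmo.solubility import LN10, combinatorial_term

from .conftest import random_profile, random_species


def _zero_potential(grid, params):
    return SigmaPotential(grid, np.zeros(grid.n_bins), params.temperature, True, 0, 0.0)


class TestChemicalPotential:
    def test_zero_potential_gives_zero(self, grid, params):
        rng = np.random.default_rng(3)
        sp = random_species(rng, grid)
        mix = SolventMixture.pure(sp)
        mu = solute_chemical_potential(sp, _zero_potential(grid, params), mix, params)
        assert mu == 0.0

    def test_self_solvation_identity(self, grid, params):
        """μ of a species in its own pure liquid equals its pure-liquid μ."""
        sp = random_species(np.random.default_rng(5), grid, name="self")
        pot = solve_sigma_potential(sp.profile, params)
        mu_in_self = solute_chemical_potential(
            sp, pot, SolventMixture.pure(sp), params
        )
        assert mu_in_self == pytest.approx(
            pure_chemical_potential(sp, params), rel=1e-10
        )

    def test_quadrature_matches_naive_loop(self, grid, params):
        rng = np.random.default_rng(11)
        solute = random_species(rng, grid, name="X")
        solvent_sp = random_species(rng, grid, name="S")
        mix = SolventMixture.pure(solvent_sp)
        pot = solve_sigma_potential(solvent_sp.profile, params)
        mu = solute_chemical_potential(solute, pot, mix, params)
        oracle = sum(
            solute.profile.area_per_bin[k] * pot.mu[k] for k in range(grid.n_bins)
        )
        assert mu == pytest.approx(oracle, rel=1e-12)

    def test_grid_mismatch_rejected(self, grid, params):
        other = SigmaGrid(-0.025, 0.025, 51)
        sp = random_species(np.random.default_rng(0), other, name="X")
        solvent = random_species(np.random.default_rng(1), grid, name="S")
        pot = solve_sigma_potential(solvent.profile, params)
        with pytest.raises(GridMismatchError):
            solute_chemical_potential(sp, pot, SolventMixture.pure(solvent), params)

    def test_pure_potential_conductor_limit(self, grid, conductor_params):
        sp = random_species(np.random.default_rng(2), grid)
        assert pure_chemical_potential(sp, conductor_params) == pytest.approx(
            0.0, abs=1e-10
        )

    def test_pure_potential_delta_species(self, grid, params):
        """All solute area at σ=0 where μ(σ)=c·σ² vanishes → μ_pure = 0."""
        areas = np.zeros(grid.n_bins)
        areas[grid.index_of_zero()] = 120.0
        sp = Species("delta", 100.0, SigmaProfile(grid, areas))
        mu = pure_chemical_potential(sp, params.with_(c_hb=0.0))
        assert mu == pytest.approx(0.0, abs=1e-9)

    def test_combinatorial_vanishes_for_identical_sizes(self, grid, params):
        sp = random_species(np.random.default_rng(4), grid, cosmo_volume=200.0)
        p = params.with_(combinatorial_form="area_volume")
        assert combinatorial_term(sp, SolventMixture.pure(sp), p) == pytest.approx(
            0.0, abs=1e-12
        )

    def test_combinatorial_needs_volumes(self, grid, params):
        sp = random_species(np.random.default_rng(4), grid)  # no cosmo_volume
        p = params.with_(combinatorial_form="area_volume")
        with pytest.raises(ValidationError):
            combinatorial_term(sp, SolventMixture.pure(sp), p)


class TestDiluteSolubility:
    def test_miscible_when_potentials_match(self, grid, params):
        sp = random_species(np.random.default_rng(6), grid, name="X")
        rec = ln_solubility_dilute(sp, SolventMixture.pure(sp), params, 0.0)
        assert rec.ln_x == 0.0
        assert rec.miscible

    def test_fusion_penalty_direct_substitution(self, grid, params):
        """ΔG_fus = RT with matched chemical potentials gives ln x = −1."""
        sp = random_species(np.random.default_rng(7), grid, name="X")
        rt = R_KJ_PER_MOL_K * params.temperature
        rec = ln_solubility_dilute(sp, SolventMixture.pure(sp), params, rt)
        assert rec.ln_x == pytest.approx(-1.0, rel=1e-12)

    def test_linearity_in_fusion_energy(self, grid, params):
        rng = np.random.default_rng(8)
        solute = random_species(rng, grid, name="X")
        solvent = SolventMixture.pure(random_species(rng, grid, name="S"))
        rt = R_KJ_PER_MOL_K * params.temperature
        delta = 3.7
        r1 = ln_solubility_dilute(solute, solvent, params, 10.0)
        r2 = ln_solubility_dilute(solute, solvent, params, 10.0 + delta)
        if not (r1.miscible or r2.miscible):
            assert r1.ln_x - r2.ln_x == pytest.approx(delta / rt, rel=1e-9)

    def test_missing_fusion_energy_raises(self, grid, params):
        sp = random_species(np.random.default_rng(9), grid, name="X")
        solvent = SolventMixture.pure(random_species(np.random.default_rng(10), grid, name="S"))
        with pytest.raises(ValidationError, match="relative"):
            ln_solubility_dilute(sp, solvent, params)


class TestIterativeSolubility:
    def test_dilute_limit_agreement(self, grid, params):
        """Where the dilute estimate is tiny the self-consistent loop is inert."""
        rng = np.random.default_rng(12)
        checked = 0
        for _ in range(5):
            solute = random_species(rng, grid, name="X")
            solvent = SolventMixture.pure(random_species(rng, grid, name="S"))
            dilute = ln_solubility_dilute(solute, solvent, params, 45.0)
            if dilute.ln_x > math.log(1e-7):
                continue
            it = ln_solubility_iterative(solute, solvent, params, 45.0, tol=1e-9)
            assert it.converged
            assert abs(it.ln_x - dilute.ln_x) < 1e-6
            checked += 1
        assert checked > 0

    def test_self_solvent_is_miscible(self, grid, params):
        sp = random_species(np.random.default_rng(13), grid, name="X")
        rec = ln_solubility_iterative(sp, SolventMixture.pure(sp), params, 0.0)
        assert rec.ln_x == 0.0
        assert rec.miscible

    def test_matches_independent_outer_loop(self, grid, params):
        """Mid-solubility case against a re-implemented self-consistency loop."""
        rng = np.random.default_rng(14)
        solute = random_species(rng, grid, name="X")
        solvent_sp = random_species(rng, grid, name="S")
        solvent = SolventMixture.pure(solvent_sp)
        dg = 5.0
        rt = R_KJ_PER_MOL_K * params.temperature

        mu_pure = pure_chemical_potential(solute, params)
        ln_x = ln_solubility_dilute(solute, solvent, params, dg).ln_x
        for _ in range(200):
            x = min(1.0, math.exp(ln_x))
            areas = (1 - x) * solvent_sp.profile.area_per_bin + x * solute.profile.area_per_bin
            pot = solve_sigma_potential(SigmaProfile(grid, areas), params)
            mu_s = float(solute.profile.area_per_bin @ pot.mu)
            ln_new = min(0.0, (mu_pure - mu_s - dg) / rt)
            if abs(ln_new - ln_x) < 1e-10:
                ln_x = ln_new
                break
            ln_x = ln_new

        rec = ln_solubility_iterative(solute, solvent, params, dg, tol=1e-10)
        assert rec.converged
        assert rec.ln_x == pytest.approx(ln_x, abs=1e-6)


class TestRelativeSolubility:
    def test_same_solvent_is_exactly_zero(self, grid, params):
        rng = np.random.default_rng(15)
        solute = random_species(rng, grid, name="X")
        s = SolventMixture.pure(random_species(rng, grid, name="S"))
        rec = relative_log10_solubility(solute, s, s, params)
        assert rec.log10_relative == 0.0
        assert rec.used_gibbs_fusion == "cancelled"

    def test_antisymmetry(self, grid, params):
        rng = np.random.default_rng(16)
        solute = random_species(rng, grid, name="X")
        a = SolventMixture.pure(random_species(rng, grid, name="A"))
        b = SolventMixture.pure(random_species(rng, grid, name="B"))
        ab = relative_log10_solubility(solute, a, b, params).log10_relative
        ba = relative_log10_solubility(solute, b, a, params).log10_relative
        assert ab == pytest.approx(-ba, rel=1e-12)

    def test_consistent_with_absolute_difference(self, grid, params):
        rng = np.random.default_rng(17)
        solute = random_species(rng, grid, name="X")
        a = SolventMixture.pure(random_species(rng, grid, name="A"))
        b = SolventMixture.pure(random_species(rng, grid, name="B"))
        rel = relative_log10_solubility(solute, a, b, params).log10_relative
        dg = 20.0
        ra = ln_solubility_dilute(solute, a, params, dg)
        rb = ln_solubility_dilute(solute, b, params, dg)
        if not (ra.miscible or rb.miscible):
            assert rel == pytest.approx((ra.ln_x - rb.ln_x) / LN10, rel=1e-9)

    def test_fusion_energy_cancels_bit_identically(self, grid, params):
        """The relative prediction is the same object for any ΔG_fus input."""
        rng = np.random.default_rng(18)
        solute = random_species(rng, grid, name="X")
        a = SolventMixture.pure(random_species(rng, grid, name="A"))
        b = SolventMixture.pure(random_species(rng, grid, name="B"))
        values = []
        for dg in (0.0, 10.0, 50.0):
            solute.gibbs_fusion = dg
            values.append(
                relative_log10_solubility(solute, a, b, params).log10_relative
            )
        assert values[0] == values[1] == values[2]


class TestRanking:
    def test_identical_solvents_tie_lexicographically(self, grid, params):
        rng = np.random.default_rng(19)
        solute = random_species(rng, grid, name="X")
        base = random_species(rng, grid, name="S")
        zeta = SolventMixture.pure(base, label="zeta")
        alpha = SolventMixture.pure(base, label="alpha")
        ranking = rank_solvents(solute, [zeta, alpha], params)
        assert [name for name, _ in ranking] == ["alpha", "zeta"]
        assert ranking[0][1] == ranking[1][1]

    def test_self_solvent_ranks_first_among_apolar_competitors(self, grid, params):
        """An amphoteric solute that hydrogen-bonds with itself beats any
        solvent that cannot hydrogen-bond at all (no fusion penalty, no
        size correction)."""
        solute = Species(
            "X",
            200.0,
            make_gaussian_profile(
                grid,
                [(0.0, 0.004, 80.0), (-0.015, 0.0025, 30.0), (0.015, 0.0025, 30.0)],
            ),
        )
        competitors = [
            SolventMixture.pure(
                Species(
                    f"S{i}",
                    100.0,
                    make_gaussian_profile(grid, [(0.0, 0.002 + 0.001 * i, 90.0)]),
                ),
                label=f"S{i}",
            )
            for i in range(4)
        ]
        solvents = [SolventMixture.pure(solute, label="itself")] + competitors
        ranking = rank_solvents(solute, solvents, params)
        assert ranking[0][0] == "itself"

    def test_reference_invariance(self, grid, params):
        rng = np.random.default_rng(21)
        solute = random_species(rng, grid, name="X")
        solvents = [
            SolventMixture.pure(random_species(rng, grid, name=f"S{i}"), label=f"S{i}")
            for i in range(5)
        ]
        order_a = [n for n, _ in rank_solvents(solute, solvents, params)]
        order_b = [n for n, _ in rank_solvents(solute, solvents[::-1], params)]
        assert order_a == order_b


class TestToyPipelineOracle:
    def test_three_bin_hand_computation(self):
        """Full chain on a 3-bin grid against independently coded arithmetic."""
        grid = SigmaGrid(-0.01, 0.01, 3)
        params_small = InteractionParams(
            a_eff=2.0, c_misfit=500.0, c_hb=2000.0, sigma_hb=0.005
        )
        rt = R_KJ_PER_MOL_K * params_small.temperature

        solv_areas = np.array([1.0, 2.0, 1.0])
        solu_areas = np.array([0.5, 1.0, 0.5])
        solvent_sp = Species("solv", 50.0, SigmaProfile(grid, solv_areas))
        solute_sp = Species("solu", 100.0, SigmaProfile(grid, solu_areas))

        # hand-rolled mixture profile (single component: itself), weights
        w = solv_areas / solv_areas.sum()
        sig = np.array([-0.01, 0.0, 0.01])

        def e_int(s, t):
            mf = 2.0 * 500.0 * (s + t) ** 2
            d, a = min(s, t), max(s, t)
            hb = 2.0 * 2000.0 * min(0.0, min(0.0, d + 0.005) * max(0.0, a - 0.005))
            return mf + hb

        mu = np.zeros(3)
        for _ in range(5000):
            new = np.array(
                [
                    -(rt / 2.0)
                    * math.log(
                        sum(
                            w[l] * math.exp((2.0 * mu[l] - e_int(sig[k], sig[l])) / rt)
                            for l in range(3)
                        )
                    )
                    for k in range(3)
                ]
            )
            if np.max(np.abs(new - mu)) < 1e-14:
                mu = new
                break
            mu = 0.5 * (mu + new)  # damped: guards against 2-cycles
        mu_solution_hand = float(solu_areas @ mu)

        pot = solve_sigma_potential(solvent_sp.profile, params_small, tol=1e-14)
        mu_solution = solute_chemical_potential(
            solute_sp, pot, SolventMixture.pure(solvent_sp), params_small
        )
        assert mu_solution == pytest.approx(mu_solution_hand, abs=1e-8)

        # and through the solubility equation
        mu_pure = pure_chemical_potential(solute_sp, params_small)
        dg = 2.0
        rec = ln_solubility_dilute(
            solute_sp, SolventMixture.pure(solvent_sp), params_small, dg
        )
        expected = min(0.0, (mu_pure - mu_solution_hand - dg) / rt)
        assert rec.ln_x == pytest.approx(expected, abs=1e-8)
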
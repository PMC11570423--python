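"""Metapopulation simulator: rates, transitions, culling, conservation."""

import numpy as np
import pytest

from phagepatch.metapop import (
    MediumState,
    PatchState,
    SystemState,
    add_patches,
    cull_patches,
    event_rates,
    new_patch,
    run_cycle,
    run_simulation,
    step_patch,
)
from phagepatch.params import MetapopParams


@pytest.fixture
def params():
    return MetapopParams(
        v=0.1, r_A=0.5, r_B=0.25, phi=0.01, alpha=0.1, lam_p=0.02,
        lam_h=0.01, theta=0.005, chi=50, sigma=1e-3, beta=1e-3,
    )


class TestEventRates:
    def test_hand_computed_rates(self, params):
        patch = PatchState(x_A=50, x_B=10, A=3, B=2, G=4, S=1,
                           I_GA=1, I_GB=2, I_SA=1)
        medium = MediumState(M_A=7, M_B=0, M_G=5, M_S=2)
        r = event_rates(patch, medium, params)
        ddet_a = 0.00167 * 10 / (10 + 50)
        ddet_b = 0.00167 * 10 / (10 + 10)
        assert r["arrival_A"] == pytest.approx(0.1 * 7)
        assert r["arrival_B"] == 0.0  # no hosts B in the medium
        assert r["division_A"] == pytest.approx(0.5 * 3 * 50 / 90)
        assert r["division_B"] == pytest.approx(0.25 * 2 * 10 / 50)
        assert r["detach_A"] == pytest.approx(3 * ddet_a)
        assert r["detach_B"] == pytest.approx(2 * ddet_b)
        assert r["decay_A"] == pytest.approx(0.01 * 3)
        assert r["resource_decay_A"] == pytest.approx(1e-3 * 50)
        assert r["arrival_G"] == pytest.approx(0.01 * 5)
        assert r["arrival_S"] == pytest.approx(0.01 * 2)
        assert r["exit_G"] == pytest.approx(0.1 * 4)
        assert r["decay_S"] == pytest.approx(0.02 * 1)
        assert r["infect_GA"] == pytest.approx(0.005 * 4 * 3)
        assert r["infect_GB"] == pytest.approx(0.005 * 4 * 2)
        assert r["infect_SA"] == pytest.approx(0.005 * 1 * 3)
        assert r["burst_IGB"] == pytest.approx(1e-3 * 2)
        assert r["decay_IGA"] == pytest.approx(0.01 * 1)
        assert r["detach_IGB"] == pytest.approx(ddet_b * 2)
        assert r["detach_ISA"] == pytest.approx(ddet_a * 1)
        assert len(r) == 28

    def test_empty_patch_only_resource_decay(self, params):
        patch = new_patch(params, "both")
        medium = MediumState()
        r = event_rates(patch, medium, params)
        nonzero = r[r > 0]
        assert set(nonzero.index) == {"resource_decay_A", "resource_decay_B"}

    def test_no_resource_blocks_arrival_and_division(self, params):
        patch = PatchState(x_A=0, x_B=50, A=5, B=0)
        medium = MediumState(M_A=100, M_B=100)
        r = event_rates(patch, medium, params)
        assert r["arrival_A"] == 0.0
        assert r["division_A"] == 0.0
        assert r["arrival_B"] > 0


class TestStepPatch:
    def test_all_rates_zero_state_unchanged(self):
        p = MetapopParams(v=0, r_A=0, r_B=0, phi=0, alpha=0, lam_p=0,
                          lam_h=0, theta=0, sigma=0, beta=0, d=0)
        patch = PatchState(x_A=100, x_B=100, A=5, G=3)
        before = patch.to_array().copy()
        medium = MediumState(M_A=10)
        step_patch(patch, medium, p, 1000.0, np.random.default_rng(0))
        np.testing.assert_array_equal(patch.to_array(), before)

    def test_pure_transfer_conserves_phage(self):
        p = MetapopParams(v=0, r_A=0, r_B=0, phi=0.05, alpha=0.1, lam_p=0,
                          lam_h=0, theta=0, sigma=0, beta=0, d=0)
        patch = PatchState(x_A=100, x_B=100, G=40, S=10)
        medium = MediumState(M_G=60, M_S=5)
        rng = np.random.default_rng(1)
        for _ in range(50):
            step_patch(patch, medium, p, 1.0, rng)
        assert patch.G + medium.M_G == 100
        assert patch.S + medium.M_S == 15
        assert patch.G >= 0 and medium.M_G >= 0

    def test_single_infection_absorbing_state(self):
        p = MetapopParams(v=0, r_A=0, r_B=0, phi=0, alpha=0, lam_p=0,
                          lam_h=0, theta=0.5, sigma=0, beta=0, d=0)
        patch = PatchState(x_A=100, x_B=100, A=1, G=1)
        medium = MediumState()
        step_patch(patch, medium, p, 10_000.0, np.random.default_rng(2))
        assert (patch.A, patch.G, patch.I_GA) == (0, 0, 1)


class TestCull:
    def _system(self, params, patch):
        return SystemState(patches=[patch], medium=MediumState())

    def test_second_condition_protects_patch(self, params):
        patch = PatchState(x_A=4, x_B=4, A=3, B=3, y0_A=100, y0_B=100)
        system = self._system(params, patch)
        cull_patches(system, params, np.random.default_rng(0))
        assert len(system.patches) == 1  # 6 hosts > 5

    def test_culled_occupants_move_to_medium(self, params):
        patch = PatchState(x_A=4, x_B=4, A=3, B=2, G=7, S=1, I_SA=2,
                           y0_A=100, y0_B=100)
        system = self._system(params, patch)
        cull_patches(system, params, np.random.default_rng(0))
        assert len(system.patches) == 0
        m = system.medium
        assert (m.M_A, m.M_B, m.M_G) == (3, 2, 7)
        # the two specialist-infected cells lyse into the medium
        assert m.M_S >= 1 + 2 * 0  # free specialist always transfers
        assert m.M_S > 1  # Poisson(50) twice is almost surely > 0

    def test_fresh_patch_never_culled(self, params):
        system = self._system(params, new_patch(params, "both"))
        cull_patches(system, params, np.random.default_rng(0))
        assert len(system.patches) == 1


class TestAddPatches:
    def test_no_addition_off_schedule(self, params):
        system = SystemState(cycle=7)
        add_patches(system, params, "together")
        assert system.patches == []

    def test_together_adds_one_dual_resource_patch(self, params):
        system = SystemState(cycle=int(params.chi))
        add_patches(system, params, "together")
        assert len(system.patches) == 1
        p = system.patches[0]
        assert p.x_A == p.x_B == int(params.Y)

    def test_apart_adds_two_single_resource_patches(self, params):
        system = SystemState(cycle=0, treatment="apart")
        add_patches(system, params)
        assert len(system.patches) == 2
        endowments = sorted((p.x_A, p.x_B) for p in system.patches)
        y = int(params.Y)
        assert endowments == [(0, y), (y, 0)]


class TestRunCycle:
    def test_medium_thinning_rate(self):
        p = MetapopParams(v=0, phi=0, lam_p=0.03, lam_h=0, theta=0,
                          sigma=0, chi=10_000)
        # lam_p * dt = 0.01 -> ~1% of phage die per cycle
        system = SystemState(medium=MediumState(M_G=1_000_000))
        run_cycle(system, p, np.random.default_rng(3))
        died = 1_000_000 - system.medium.M_G
        assert died == pytest.approx(1_000_000 * (1 - np.exp(-0.01)),
                                     abs=4 * np.sqrt(1e6 * 0.01))

    def test_patch_order_randomization_consumes_shared_stream(self, params):
        def run(seed):
            system = SystemState(
                patches=[new_patch(params, "both") for _ in range(3)],
                medium=MediumState(M_A=50, M_B=50, M_G=50),
            )
            rng = np.random.default_rng(seed)
            for _ in range(30):
                run_cycle(system, params, rng)
            return [tuple(p.to_array()) for p in system.patches]

        assert run(5) == run(5)
        assert run(5) != run(6)


class TestRunSimulation:
    def test_zero_duration_returns_initial_state_only(self, params):
        df = run_simulation(params, "together", 0.0, MediumState(M_G=9),
                            np.random.default_rng(0))
        assert len(df) == 1
        assert df["M_G"].iloc[0] == 9

    def test_empty_system_stays_empty(self, params):
        df = run_simulation(params, "together", 50.0, MediumState(),
                            np.random.default_rng(0))
        for col in ("M_A", "M_B", "M_G", "M_S", "A", "B", "G", "S"):
            assert (df[col] == 0).all()
        assert (df["x_A"] > 0).any()

    def test_conservation_over_1000_cycles(self):
        """With every birth/death/infection channel off, each population
        class is exactly conserved while individuals shuttle between
        patches and medium."""
        p = MetapopParams(v=0.01, r_A=0, r_B=0, phi=0.01, alpha=0.05,
                          lam_p=0, lam_h=0, theta=0, sigma=0, beta=0,
                          d=0.5, chi=100_000)
        df = run_simulation(
            p, "together", 1000 * p.cycle_length,
            MediumState(M_A=300, M_B=200, M_G=150, M_S=50),
            np.random.default_rng(8), record_every=100,
        )
        assert ((df["M_A"] + df["A"]) == 300).all()
        assert ((df["M_B"] + df["B"]) == 200).all()
        assert ((df["M_G"] + df["G"]) == 150).all()
        assert ((df["M_S"] + df["S"]) == 50).all()

    def test_resource_ledger_and_nonnegativity(self, params):
        df = run_simulation(
            params.replace(chi=30), "together", 500.0,
            MediumState(M_A=500, M_B=500, M_G=200),
            np.random.default_rng(13),
        )
        assert (df.drop(columns="time") >= 0).all().all()
        final = df.attrs["final_state"]
        assert len(final.patches) > 0
        for patch in final.patches:
            assert patch.x_A + patch.cons_A + patch.dec_A == patch.y0_A
            assert patch.x_B + patch.cons_B + patch.dec_B == patch.y0_B
            for value in patch.to_array():
                assert value >= 0

    def test_deterministic_under_seed(self, params):
        def run(seed):
            return run_simulation(
                params, "apart", 200.0,
                MediumState(M_A=200, M_B=200, M_G=100),
                np.random.default_rng(seed), record_every=10,
            )

        a, b, c = run(21), run(21), run(22)
        assert a.equals(b)
        assert not a.equals(c)
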
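"""Cohort-component bookkeeping: survival, births, migration, accounting."""

import numpy as np
import pytest

from laborcast.cohort_engine import (
    MigrationSpec,
    N_AGES,
    PopulationState,
    apply_naturalization,
    apply_survival_and_age,
    compute_births,
    compute_emigration,
    default_addon_schedule,
    distribute_immigration,
    project_year,
)

M, F = 0, 1
GER, FOR = 0, 1


def state_with(cells, year=2013):
    counts = np.zeros((N_AGES, 2, 2))
    for (age, sex, nat), v in cells.items():
        counts[age, sex, nat] = v
    return PopulationState(year, counts)


def uniform_state(per_cell=100.0, year=2013):
    return PopulationState(year, np.full((N_AGES, 2, 2), per_cell))


class TestSurvivalAndAging:
    def test_zero_mortality_conserves_and_shifts(self):
        s = uniform_state()
        aged, deaths = apply_survival_and_age(s, np.zeros(N_AGES))
        assert deaths.sum() == 0.0
        assert aged.counts.sum() == s.counts.sum()
        # age 5 inherits age 4's occupants
        assert aged.counts[5] == pytest.approx(s.counts[4])
        assert aged.counts[0].sum() == 0.0

    def test_total_mortality_empties_population(self):
        s = uniform_state()
        aged, deaths = apply_survival_and_age(s, np.ones(N_AGES))
        assert aged.counts.sum() == 0.0
        assert deaths == pytest.approx(s.counts)

    def test_single_cohort_arithmetic(self):
        s = state_with({(40, F, GER): 1000.0})
        q = np.zeros(N_AGES)
        q[40] = 0.01
        aged, deaths = apply_survival_and_age(s, q)
        assert aged.counts[41, F, GER] == pytest.approx(990.0)
        assert deaths[40, F, GER] == pytest.approx(10.0)

    def test_open_group_absorbs(self):
        s = state_with({(89, M, GER): 10.0, (90, M, GER): 20.0})
        aged, _ = apply_survival_and_age(s, np.zeros(N_AGES))
        assert aged.counts[90, M, GER] == pytest.approx(30.0)

    def test_rate_above_one_rejected(self):
        with pytest.raises(ValueError):
            apply_survival_and_age(uniform_state(), np.full(N_AGES, 1.2))


class TestBirths:
    def test_sex_ratio_split(self):
        s = state_with({(30, F, GER): 1000.0})
        rates = np.zeros(35)
        rates[30 - 15] = 0.1
        births = compute_births(s, {"german": rates}, sex_ratio=105.0)
        assert births[M, GER] == pytest.approx(100.0 * 105 / 205)
        assert births[F, GER] == pytest.approx(100.0 * 100 / 205)
        assert births[M, GER] == pytest.approx(51.2195, abs=1e-4)

    def test_no_women_no_births(self):
        s = state_with({(30, M, GER): 1000.0})
        births = compute_births(s, {"german": np.full(35, 0.5)})
        assert births.sum() == 0.0

    def test_tfr_identity_one_woman_per_age(self):
        cells = {(a, F, GER): 1.0 for a in range(15, 50)}
        s = state_with(cells)
        r = 0.07
        births = compute_births(s, {"german": np.full(35, r)})
        assert births[:, GER].sum() == pytest.approx(35 * r)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            compute_births(uniform_state(), {"german": np.full(35, -0.1)})


class TestImmigration:
    def test_top_down_split(self):
        shares = np.zeros((N_AGES, 2))
        shares[20, M], shares[25, F] = 0.6, 0.4
        out = distribute_immigration(1000.0, shares)
        assert out[20, M] == pytest.approx(600.0)
        assert out[25, F] == pytest.approx(400.0)
        assert out.sum() == pytest.approx(1000.0)

    def test_default_addon_schedule_ramp(self):
        sched = default_addon_schedule()
        assert sched[2016] == pytest.approx(340_000.0)
        assert sched[2025] == 0.0
        diffs = np.diff([sched[y] for y in range(2016, 2026)])
        assert np.allclose(diffs, diffs[0])  # linear decline

    def test_addon_added_to_total(self):
        shares = np.zeros((N_AGES, 2))
        shares[30, F] = 1.0
        out = distribute_immigration(1000.0, shares, addon=340_000.0)
        assert out.sum() == pytest.approx(341_000.0)

    def test_deficient_shares_rejected(self):
        shares = np.zeros((N_AGES, 2))
        shares[30, F] = 0.98
        with pytest.raises(ValueError, match="sum"):
            distribute_immigration(1000.0, shares)

    def test_negative_total_rejected(self):
        shares = np.zeros((N_AGES, 2))
        shares[30, F] = 1.0
        with pytest.raises(ValueError):
            distribute_immigration(-5.0, shares)


class TestEmigration:
    def test_proportional_outflow(self):
        s = state_with({(30, M, FOR): 500.0})
        rates = np.zeros((N_AGES, 2, 2))
        rates[30, M, FOR] = 0.02
        assert compute_emigration(s, rates)[30, M, FOR] == pytest.approx(10.0)

    def test_rate_one_empties_cell(self):
        s = state_with({(30, M, FOR): 500.0})
        rates = np.zeros((N_AGES, 2, 2))
        rates[30, M, FOR] = 1.0
        emi = compute_emigration(s, rates)
        assert emi[30, M, FOR] == pytest.approx(500.0)

    def test_rate_above_one_rejected(self):
        rates = np.zeros((N_AGES, 2, 2))
        rates[0, 0, 0] = 1.2
        with pytest.raises(ValueError):
            compute_emigration(uniform_state(), rates)

    def test_never_exceeds_population(self, rng):
        s = PopulationState(2013, rng.uniform(0, 100, (N_AGES, 2, 2)))
        rates = rng.uniform(0, 1, (N_AGES, 2, 2))
        assert np.all(compute_emigration(s, rates) <= s.counts)


class TestNaturalization:
    def test_transfer_preserves_total(self):
        s = state_with({(30, F, FOR): 200.0, (30, F, GER): 50.0})
        rates = np.zeros((N_AGES, 2))
        rates[30, F] = 0.05
        out, moved = apply_naturalization(s, rates)
        assert moved[30, F] == pytest.approx(10.0)
        assert out.counts[30, F, FOR] == pytest.approx(190.0)
        assert out.counts[30, F, GER] == pytest.approx(60.0)
        assert out.counts.sum() == pytest.approx(s.counts.sum())

    def test_zero_rate_is_identity(self):
        s = uniform_state()
        out, moved = apply_naturalization(s, np.zeros((N_AGES, 2)))
        assert np.array_equal(out.counts, s.counts)
        assert moved.sum() == 0.0

    def test_all_german_population_is_noop(self):
        counts = np.zeros((N_AGES, 2, 2))
        counts[:, :, GER] = 100.0
        s = PopulationState(2013, counts)
        out, moved = apply_naturalization(s, np.full((N_AGES, 2), 0.5))
        assert np.array_equal(out.counts, s.counts)
        assert moved.sum() == 0.0


def _null_migration():
    return MigrationSpec(
        immigration_totals={}, immigration_shares={}, emigration_rates={},
        addon_schedule={},
    )


class TestProjectYear:
    def test_pure_aging_when_everything_zero(self):
        s = uniform_state()
        nxt, entry = project_year(
            s, np.zeros(N_AGES), {"german": np.zeros(35), "foreign": np.zeros(35)},
            _null_migration(),
        )
        assert nxt.year == s.year + 1
        assert nxt.counts.sum() == pytest.approx(s.counts.sum())
        assert entry.deaths.sum() == 0.0

    def test_hand_ledger_toy(self):
        # 100 women aged 40: q=0.1, fertility 0.2, 50 female immigrants at 40,
        # emigration 0.1 on the post-immigration stock, no naturalization.
        s = state_with({(40, F, GER): 100.0})
        q = np.zeros(N_AGES)
        q[40] = 0.1
        fert = np.zeros(35)
        fert[40 - 15] = 0.2
        shares = np.zeros((N_AGES, 2))
        shares[40, F] = 1.0
        mig = MigrationSpec(
            immigration_totals={"german": {2013: 50.0}},
            immigration_shares={"german": {2013: shares}},
            emigration_rates={2013: np.full((N_AGES, 2, 2), 0.1)},
            addon_schedule={},
        )
        nxt, entry = project_year(
            s, q, {"german": fert, "foreign": np.zeros(35)}, mig, sex_ratio=105.0
        )
        # hand ledger: 10 deaths; 90 survivors at 41; 20 births at age 0;
        # 50 immigrants at 40; then 10% of (90 + 50 + 20) = 16 emigrate
        assert entry.deaths.sum() == pytest.approx(10.0)
        assert entry.births.sum() == pytest.approx(20.0)
        assert entry.immigrants.sum() == pytest.approx(50.0)
        assert entry.emigrants.sum() == pytest.approx(16.0)
        assert nxt.counts[41, F, GER] == pytest.approx(81.0)
        assert nxt.counts[40, F, GER] == pytest.approx(45.0)
        assert nxt.counts[0].sum() == pytest.approx(18.0)
        assert nxt.counts.sum() == pytest.approx(100 - 10 + 20 + 50 - 16)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_accounting_identity_random_inputs(self, seed):
        rng = np.random.default_rng(seed)
        s = PopulationState(2013, rng.uniform(0, 1000, (N_AGES, 2, 2)))
        q = rng.uniform(0, 0.2, N_AGES)
        fert = {
            "german": rng.uniform(0, 0.1, 35),
            "foreign": rng.uniform(0, 0.1, 35),
        }
        shares = rng.uniform(0, 1, (N_AGES, 2))
        shares /= shares.sum()
        mig = MigrationSpec(
            immigration_totals={"german": {2013: 5000.0}, "foreign": {2013: 8000.0}},
            immigration_shares={"german": {2013: shares}, "foreign": {2013: shares}},
            emigration_rates={2013: rng.uniform(0, 0.3, (N_AGES, 2, 2))},
            addon_schedule={2013: 1000.0},
        )
        nat_rates = rng.uniform(0, 0.1, (N_AGES, 2))
        nxt, e = project_year(s, q, fert, mig, naturalization_rates=nat_rates)
        for ni, sign in ((GER, +1.0), (FOR, -1.0)):
            before = s.counts[:, :, ni].sum()
            after = nxt.counts[:, :, ni].sum()
            flows = (
                -e.deaths[:, :, ni].sum()
                + e.births[:, ni].sum()
                + e.immigrants[:, :, ni].sum()
                - e.emigrants[:, :, ni].sum()
                + sign * e.naturalizations.sum()
            )
            assert after == pytest.approx(before + flows, rel=1e-9)
        assert np.all(nxt.counts >= 0.0)

    def test_emigration_monotonicity(self):
        s = uniform_state()
        base_rates = np.full((N_AGES, 2, 2), 0.05)
        higher = base_rates.copy()
        higher[30, M, FOR] = 0.5

        def run(rates):
            mig = MigrationSpec(
                immigration_totals={}, immigration_shares={},
                emigration_rates={2013: rates}, addon_schedule={},
            )
            nxt, _ = project_year(
                s, np.zeros(N_AGES),
                {"german": np.zeros(35), "foreign": np.zeros(35)}, mig,
            )
            return nxt.counts.sum()

        assert run(higher) < run(base_rates)

    def test_open_group_only_leaves_by_death_or_emigration(self):
        s = state_with({(90, M, GER): 100.0})
        nxt, _ = project_year(
            s, np.zeros(N_AGES), {"german": np.zeros(35), "foreign": np.zeros(35)},
            _null_migration(),
        )
        assert nxt.counts[90, M, GER] == pytest.approx(100.0)
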
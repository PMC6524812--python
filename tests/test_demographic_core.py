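"""Life-cycle simulator: vital rates, fecundity, mortality, aging."""

import dataclasses

import numpy as np
import pytest

from leksim.demographic_core import (
    RealizedRates,
    SiteState,
    VitalRateSpec,
    advance_age,
    apply_mortality,
    default_vital_rates,
    draw_realized_rates,
    expected_fecundity,
    reproduce,
    simulate_site,
    step_year,
    trajectories_to_frame,
)

# the published vital-rate table (mean, sd); hatchability has no published sd
PUBLISHED_TABLE = {
    "male_adult_survival": (0.45, 0.06),
    "female_survival_breeding": (0.49, 0.05),
    "female_survival_nonbreeding": (0.73, 0.04),
    "nest_propensity": (0.95, 0.04),
    "clutch1": (10.80, 2.17),
    "nest1_SY": (0.47, 0.04),
    "nest1_ASY": (0.44, 0.05),
    "renest": (0.33, 0.15),
    "clutch2": (8.17, 2.02),
    "nest2_SY": (0.50, 0.01),
    "nest2_ASY": (0.33, 0.08),
    "hatch": (0.93, 0.0),
    "chick_survival": (0.26, 0.01),
    "juvenile_survival": (0.54, 0.09),
    "attendance_SY_male": (0.60, 0.10),
    "attendance_ASY_male": (0.80, 0.10),
    "attendance_female": (0.30, 0.10),
}

# closed-form per-sex fecundity at table means, evaluated independently by
# hand before the implementation:
#   SY:  [0.95*10.80*0.47 + 0.53*0.33*8.17*0.50] * 0.26*0.54*0.5*0.93
#   ASY: [0.95*10.80*0.44 + 0.56*0.33*8.17*0.33] * 0.26*0.54*0.5*0.93
F_SY_ORACLE = 0.36147
F_ASY_ORACLE = 0.32726


def test_default_vital_rates_match_published_table(table_rates):
    for name, pair in PUBLISHED_TABLE.items():
        assert getattr(table_rates, name) == pair


@pytest.mark.parametrize(
    "field,value",
    [
        ("male_adult_survival", (1.2, 0.05)),
        ("clutch1", (-1.0, 0.5)),
        ("renest", (0.3, -0.1)),
    ],
)
def test_invalid_vital_rates_rejected(field, value):
    with pytest.raises(ValueError):
        VitalRateSpec(**{field: value})


class TestDrawRealizedRates:
    def test_zero_variance_returns_means(self, table_rates, rng):
        spec = table_rates.with_zero_sd()
        rates = draw_realized_rates(spec, rng)
        for name, (mean, _) in spec.items():
            assert getattr(rates, name) == mean

    def test_same_seed_same_rates(self, table_rates):
        a = draw_realized_rates(table_rates, np.random.default_rng(7))
        b = draw_realized_rates(table_rates, np.random.default_rng(7))
        assert a == b

    def test_monte_carlo_mean_matches_table(self, table_rates):
        gen = np.random.default_rng(11)
        draws = np.array(
            [draw_realized_rates(table_rates, gen).nest1_SY for _ in range(10_000)]
        )
        se = 0.04 / np.sqrt(draws.size)
        assert abs(draws.mean() - 0.47) < 3 * se

    def test_truncation_respected(self, table_rates):
        gen = np.random.default_rng(13)
        for _ in range(200):
            rates = draw_realized_rates(table_rates, gen)
            assert 0.0 <= rates.renest <= 1.0
            assert rates.clutch1 >= 0.0


class TestFecundity:
    def test_closed_form_matches_hand_oracle(self, mean_rates):
        assert expected_fecundity(mean_rates, "SY") == pytest.approx(F_SY_ORACLE, abs=1e-4)
        assert expected_fecundity(mean_rates, "ASY") == pytest.approx(F_ASY_ORACLE, abs=1e-4)

    def test_zero_chick_survival_zeroes_fecundity(self, mean_rates):
        rates = dataclasses.replace(mean_rates, chick_survival=0.0)
        assert expected_fecundity(rates, "SY") == 0.0
        assert expected_fecundity(rates, "ASY") == 0.0

    def test_invalid_age_rejected(self, mean_rates):
        with pytest.raises(ValueError):
            expected_fecundity(mean_rates, "juvenile")


class TestReproduce:
    def test_no_females_no_recruits(self, mean_rates, rng):
        state = SiteState(0, 0, 10, 10)
        assert reproduce(state, mean_rates, rng) == (0, 0)

    def test_no_nesting_pathway_no_recruits(self, mean_rates, rng):
        rates = dataclasses.replace(mean_rates, nest_propensity=0.0, renest=0.0)
        state = SiteState(50, 50, 0, 0)
        assert reproduce(state, rates, rng) == (0, 0)

    def test_stagewise_mean_matches_closed_form(self, mean_rates):
        """The Bernoulli-chain simulator and the closed-form fecundity are the
        same model; per-sex recruits per female must agree at Monte-Carlo
        precision (integer clutch handling shifts the mean by < 2%)."""
        n_females = 20_000
        state = SiteState(female_sy=n_females, female_asy=0, male_sy=0, male_asy=0)
        gen = np.random.default_rng(23)
        females, males = reproduce(state, mean_rates, gen)
        per_female = females / n_females
        se = np.sqrt(F_SY_ORACLE / n_females)
        assert abs(per_female - F_SY_ORACLE) < 3 * se + 0.02 * F_SY_ORACLE
        assert abs(males / n_females - F_SY_ORACLE) < 3 * se + 0.02 * F_SY_ORACLE


class TestMortality:
    def test_certain_survival_preserves_state(self, mean_rates, rng, start_state):
        rates = dataclasses.replace(
            mean_rates,
            male_adult_survival=1.0,
            female_survival_breeding=1.0,
            female_survival_nonbreeding=1.0,
        )
        assert apply_mortality(start_state, rates, rng) == start_state

    def test_certain_death_empties_site(self, mean_rates, rng, start_state):
        rates = dataclasses.replace(
            mean_rates, male_adult_survival=0.0, female_survival_breeding=0.0
        )
        out = apply_mortality(start_state, rates, rng)
        assert out.total == 0

    def test_female_survival_is_seasonal_product(self, mean_rates):
        state = SiteState(female_sy=10_000, female_asy=0, male_sy=0, male_asy=0)
        gen = np.random.default_rng(31)
        out = apply_mortality(state, mean_rates, gen)
        p = 0.49 * 0.73
        se = np.sqrt(p * (1 - p) / 10_000)
        assert abs(out.females / 10_000 - p) < 3 * se


class TestAging:
    def test_bookkeeping_identity(self):
        state = SiteState(female_sy=3, female_asy=5, male_sy=2, male_asy=4)
        out = advance_age(state, (1, 1))
        assert (out.female_sy, out.male_sy) == (1, 1)
        assert (out.female_asy, out.male_asy) == (8, 6)
        assert out.year == state.year + 1

    def test_no_recruits_empties_sy(self, start_state):
        out = advance_age(start_state, (0, 0))
        assert out.female_sy == 0 and out.male_sy == 0

    def test_totals_conserved(self, rng):
        for _ in range(50):
            cells = rng.integers(0, 40, size=4)
            rec = tuple(int(v) for v in rng.integers(0, 10, size=2))
            state = SiteState(*map(int, cells))
            out = advance_age(state, rec)
            assert out.total == state.total + sum(rec)


class TestStepYear:
    def test_extinction_is_absorbing(self, table_rates, rng):
        state = SiteState(0, 0, 0, 0)
        for _ in range(5):
            state = step_year(state, table_rates, rng)
            assert state.total == 0

    def test_all_rates_zero_empties_site(self, table_rates, rng, start_state):
        spec = table_rates.replace(
            male_adult_survival=(0.0, 0.0),
            female_survival_breeding=(0.0, 0.0),
            nest_propensity=(0.0, 0.0),
            renest=(0.0, 0.0),
        )
        assert step_year(start_state, spec, rng).total == 0

    def test_expected_one_year_decline(self, table_rates, start_state):
        """The deterministic female multiplier (seasonal survival + F) is
        about 0.72 < 1, so the mean one-year total must drop well below the
        100-bird start."""
        gen = np.random.default_rng(37)
        totals = [step_year(start_state, table_rates, gen).total for _ in range(1000)]
        assert np.mean(totals) < 90.0
        assert 0.55 < np.mean(totals) / start_state.total < 0.85


class TestSimulateSite:
    def test_counts_stay_nonnegative_integers(self, table_rates):
        traj = simulate_site(table_rates, np.random.default_rng(41), 25)
        assert traj.dtype.kind == "i"
        assert (traj >= 0).all()

    def test_extinction_absorbing_along_trajectory(self, table_rates):
        gen = np.random.default_rng(43)
        for _ in range(20):
            totals = simulate_site(table_rates, gen, 25).sum(axis=1)
            dead = np.flatnonzero(totals == 0)
            if dead.size:
                assert (totals[dead[0]:] == 0).all()

    def test_deterministic_rates_give_declining_median(self, table_rates, mean_rates):
        """With table means, zero rate variance: the female-only multiplier
        (survival product + fecundity) is < 1 and the median trajectory over
        many sites declines to pseudo-extinction."""
        mult = 0.49 * 0.73 + max(
            expected_fecundity(mean_rates, "SY"),
            expected_fecundity(mean_rates, "ASY"),
        )
        assert mult < 1.0
        spec = table_rates.with_zero_sd()
        gen = np.random.default_rng(47)
        totals = np.stack(
            [simulate_site(spec, gen, 25).sum(axis=1) for _ in range(200)]
        )
        med = np.median(totals, axis=0)
        assert (np.diff(med) <= 0).all()
        assert med[-1] < med[0]


def test_trajectories_to_frame_layout():
    counts = np.arange(2 * 3 * 4 * 4).reshape(2, 3, 4, 4)
    frame = trajectories_to_frame(counts)
    assert list(frame.columns) == ["simulation", "site", "year", "sex", "age_class", "count"]
    assert len(frame) == 2 * 3 * 4 * 4
    row = frame[(frame.simulation == 1) & (frame.site == 1) & (frame.year == 1)]
    assert row["count"].tolist() == [0, 1, 2, 3]
    assert set(frame.sex) == {"female", "male"}
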
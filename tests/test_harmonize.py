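"""Effect-size harmonization: formula oracles and invariants."""

import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

from aglmeta.harmonize import (
    HarmonizationError,
    Paradigm,
    RawStudyStats,
    SessionStats,
    average_sd,
    ci_to_sd,
    correction_factor,
    harmonize,
    hedges_g,
    one_sample_d,
    paired_difference_d,
    pooled_mean,
    variance_g,
)


class TestCorrectionFactor:
    @pytest.mark.parametrize(
        "df, expected",
        [
            (1, 0.0),  # 1 - 3/3
            (19, 0.96),  # 1 - 3/75
            (10**6, 1.0),  # asymptotic limit
        ],
    )
    def test_known_values(self, df, expected):
        assert correction_factor(df) == pytest.approx(expected, abs=1e-5)

    def test_rejects_nonpositive_df(self):
        with pytest.raises(HarmonizationError):
            correction_factor(0)

    @given(st.integers(min_value=2, max_value=10_000))
    def test_strictly_inside_unit_interval_for_df_ge_2(self, df):
        assert 0.0 < correction_factor(df) < 1.0


class TestOneSampleD:
    @pytest.mark.parametrize(
        "mean, chance, sd, expected",
        [
            (0.5, 0.5, 0.1, 0.0),
            (0.6, 0.5, 0.1, 1.0),
            (0.4, 0.5, 0.2, -0.5),
        ],
    )
    def test_known_values(self, mean, chance, sd, expected):
        assert one_sample_d(mean, chance, sd) == pytest.approx(expected)

    def test_rejects_nonpositive_sd(self):
        with pytest.raises(HarmonizationError):
            one_sample_d(0.6, 0.5, 0.0)


class TestHedgesG:
    @pytest.mark.parametrize(
        "d, df, expected",
        [
            (0.0, 5, 0.0),
            (1.0, 19, 0.96),
            (-2.0, 7, -2.0 * (1.0 - 3.0 / 27.0)),  # = -1.7778
        ],
    )
    def test_known_values(self, d, df, expected):
        assert hedges_g(d, df) == pytest.approx(expected, abs=1e-6)

    @given(
        st.floats(min_value=-5, max_value=5, allow_nan=False),
        st.integers(min_value=2, max_value=1000),
    )
    def test_correction_shrinks_toward_zero(self, d, df):
        g = hedges_g(d, df)
        assert abs(g) <= abs(d)
        if d != 0:
            assert abs(g) < abs(d)


class TestVarianceG:
    def test_null_effect_value(self):
        # (1/25) * (1 - 3/95)^2, evaluated independently
        j = 1.0 - 3.0 / 95.0
        assert variance_g(0.0, 25, 24) == pytest.approx(0.04 * j * j, abs=1e-9)
        assert variance_g(0.0, 25, 24) == pytest.approx(0.037513, abs=1e-6)

    def test_vanishes_with_large_n(self):
        assert variance_g(1.0, 10**7, 10**7 - 1) < 1e-6

    def test_degenerate_single_subject_does_not_crash(self):
        assert variance_g(1.0, 1, 1) == 0.0  # J(1) = 0

    def test_rejects_nonpositive_n(self):
        with pytest.raises(HarmonizationError):
            variance_g(1.0, 0, 1)


class TestPooling:
    def test_pooled_mean_identity_and_weighting(self):
        one = [SessionStats(mean=0.63, sd=0.1, n=12)]
        assert pooled_mean(one) == pytest.approx(0.63)
        equal = [
            SessionStats(mean=0.6, sd=0.1, n=10),
            SessionStats(mean=0.8, sd=0.1, n=10),
        ]
        assert pooled_mean(equal) == pytest.approx(0.7)
        weighted = [
            SessionStats(mean=0.5, sd=0.1, n=10),
            SessionStats(mean=0.9, sd=0.1, n=30),
        ]
        # (10*0.5 + 30*0.9)/40 computed by hand
        assert pooled_mean(weighted) == pytest.approx(0.8)

    def test_pooled_mean_rejects_empty(self):
        with pytest.raises(HarmonizationError):
            pooled_mean([])

    def test_average_sd_known_value(self):
        sessions = [
            SessionStats(mean=0.5, sd=0.0, n=2),
            SessionStats(mean=0.5, sd=2.0, n=2),
        ]
        # sqrt((0 + 4)/2) by direct evaluation
        assert average_sd(sessions) == pytest.approx(math.sqrt(2.0), abs=1e-5)

    def test_average_sd_identity_cases(self):
        single = [SessionStats(mean=0.5, sd=0.37, n=9)]
        assert average_sd(single) == pytest.approx(0.37)
        equal = [
            SessionStats(mean=0.5, sd=1.3, n=5),
            SessionStats(mean=0.7, sd=1.3, n=11),
        ]
        assert average_sd(equal) == pytest.approx(1.3)

    def test_average_sd_rejects_zero_denominator(self):
        with pytest.raises(HarmonizationError):
            average_sd([SessionStats(mean=0.5, sd=1.0, n=1)])

    @given(
        st.lists(
            st.tuples(
                st.integers(min_value=2, max_value=50),
                st.floats(min_value=0.01, max_value=5.0),
            ),
            min_size=1,
            max_size=6,
        )
    )
    def test_average_sd_bounded_by_extremes(self, specs):
        sessions = [SessionStats(mean=0.5, sd=sd, n=n) for n, sd in specs]
        sds = [s.sd for s in sessions]
        pooled = average_sd(sessions)
        assert min(sds) - 1e-12 <= pooled <= max(sds) + 1e-12


class TestCiToSd:
    def test_known_value_against_t_table(self):
        # t_crit(15 df, 95%) = 2.1314 from a printed table
        assert ci_to_sd(16, 1.0, 0.0) == pytest.approx(
            4.0 / (2.0 * 2.1314), abs=5e-4
        )

    def test_linearity_in_interval_width(self):
        assert ci_to_sd(16, 2.0, 0.0) == pytest.approx(
            2.0 * ci_to_sd(16, 1.0, 0.0)
        )

    def test_monotone_in_n_at_fixed_width(self):
        values = [ci_to_sd(n, 1.0, 0.0) for n in range(2, 101)]
        assert all(b > a for a, b in zip(values, values[1:]))

    @pytest.mark.parametrize("n", [2, 5, 17, 100, 1000])
    def test_inverts_t_interval_construction(self, n):
        from scipy import stats

        sd = 0.73
        half = stats.t.ppf(0.975, n - 1) * sd / math.sqrt(n)
        assert ci_to_sd(n, 0.5 + half, 0.5 - half) == pytest.approx(
            sd, abs=1e-10
        )

    def test_rejects_single_subject(self):
        with pytest.raises(HarmonizationError):
            ci_to_sd(1, 1.0, 0.0)


class TestPairedDifference:
    def test_equal_means_give_zero(self):
        assert paired_difference_d(0.6, 0.6, 0.2) == 0.0

    def test_rt_sign_convention(self):
        # faster on the trained structure counts as learning
        d = paired_difference_d(
            500.0, 550.0, 100.0, Paradigm.SERIAL_REACTION_TIME
        )
        assert d == pytest.approx(0.5)

    def test_looking_time_sign_convention(self):
        # longer looking at ungrammatical (novelty) counts as learning
        d = paired_difference_d(5.0, 6.0, 2.0, Paradigm.LOOKING_TIME)
        assert d == pytest.approx(0.5)

    def test_production_sign_convention(self):
        d = paired_difference_d(0.8, 0.6, 0.2, Paradigm.SEQUENCE_PRODUCTION)
        assert d == pytest.approx(1.0)

    def test_rejects_nonpositive_sd(self):
        with pytest.raises(HarmonizationError):
            paired_difference_d(0.6, 0.5, 0.0)


def _chance_record(mean=0.6, sd=0.1, n=20, chance=0.5, resign=False):
    return RawStudyStats(
        paradigm=Paradigm.FORCED_CHOICE,
        sessions_grammatical=(SessionStats(mean=mean, sd=sd, n=n),),
        chance=chance,
        familiarity_resign=resign,
    )


class TestHarmonize:
    def test_chance_level_record_gives_null_effect(self):
        eff = harmonize(_chance_record(mean=0.5))
        assert eff.g == 0.0
        j = correction_factor(19)
        assert eff.v_g == pytest.approx(j * j / 20.0)

    def test_resign_is_sign_flip_only_and_involutive(self):
        base = harmonize(_chance_record())
        flipped = harmonize(_chance_record(resign=True))
        assert flipped.g == pytest.approx(-base.g)
        assert flipped.v_g == pytest.approx(base.v_g)
        # flipping an already-negated effect restores the original
        assert harmonize(_chance_record()).g == pytest.approx(-(-base.g))

    def test_multi_session_record_equals_manual_chain(self):
        sessions = (
            SessionStats(mean=0.62, sd=0.12, n=14),
            SessionStats(mean=0.58, sd=0.09, n=14),
            SessionStats(mean=0.66, sd=0.15, n=14),
        )
        record = RawStudyStats(
            paradigm=Paradigm.YES_NO,
            sessions_grammatical=sessions,
            chance=0.5,
        )
        eff = harmonize(record)
        # the same chain computed step by step
        m = pooled_mean(sessions)
        sd = average_sd(sessions)
        d = one_sample_d(m, 0.5, sd)
        assert eff.d == pytest.approx(d)
        assert eff.g == pytest.approx(hedges_g(d, 13))
        assert eff.v_g == pytest.approx(variance_g(d, 14, 13))

    def test_percent_scale_record_matches_proportion_scale(self):
        prop = harmonize(_chance_record(mean=0.6, sd=0.1, chance=0.5))
        percent = harmonize(_chance_record(mean=60.0, sd=10.0, chance=50.0))
        assert percent.g == pytest.approx(prop.g)
        assert percent.v_g == pytest.approx(prop.v_g)

    @given(st.floats(min_value=0.1, max_value=50.0))
    def test_scale_invariance_of_chance_comparison(self, c):
        base = harmonize(_chance_record(mean=0.6, sd=0.1, chance=0.5))
        # rescaling all summary statistics leaves the effect unchanged
        scaled = RawStudyStats(
            paradigm=Paradigm.FORCED_CHOICE,
            sessions_grammatical=(
                SessionStats(mean=0.6 * c, sd=0.1 * c, n=20),
            ),
            chance=0.5 * c,
        )
        eff = harmonize(scaled)
        assert eff.g == pytest.approx(base.g, rel=1e-9)
        assert eff.v_g == pytest.approx(base.v_g, rel=1e-9)

    def test_ci_only_session_converted_at_ingest(self):
        from scipy import stats

        n, sd = 16, 0.12
        half = stats.t.ppf(0.975, n - 1) * sd / math.sqrt(n)
        record = RawStudyStats(
            paradigm=Paradigm.GO_NOGO,
            sessions_grammatical=(
                SessionStats(
                    mean=0.6, sd=None, n=n, ci_lower=0.6 - half,
                    ci_upper=0.6 + half,
                ),
            ),
            chance=0.5,
        )
        direct = harmonize(_chance_record(mean=0.6, sd=sd, n=n))
        assert harmonize(record).g == pytest.approx(direct.g, abs=1e-10)

    def test_paired_record_uses_all_sessions_for_sd(self):
        record = RawStudyStats(
            paradigm=Paradigm.SERIAL_REACTION_TIME,
            sessions_grammatical=(
                SessionStats(mean=480.0, sd=90.0, n=12),
                SessionStats(mean=500.0, sd=110.0, n=12),
            ),
            sessions_ungrammatical=(SessionStats(mean=540.0, sd=100.0, n=12),),
        )
        eff = harmonize(record)
        all_sessions = record.sessions_grammatical + record.sessions_ungrammatical
        sd = average_sd(all_sessions)
        expected_d = -(490.0 - 540.0) / sd
        assert eff.d == pytest.approx(expected_d)
        assert eff.n == 12

    def test_missing_required_fields_are_named(self):
        with pytest.raises(HarmonizationError, match="chance"):
            RawStudyStats(
                paradigm=Paradigm.FORCED_CHOICE,
                sessions_grammatical=(SessionStats(mean=0.6, sd=0.1, n=10),),
            )
        with pytest.raises(HarmonizationError, match="ungrammatical"):
            RawStudyStats(
                paradigm=Paradigm.LOOKING_TIME,
                sessions_grammatical=(SessionStats(mean=5.0, sd=1.0, n=10),),
            )

    def test_unknown_paradigm_rejected(self):
        with pytest.raises(ValueError):
            RawStudyStats(
                paradigm="telepathy",
                sessions_grammatical=(SessionStats(mean=0.6, sd=0.1, n=10),),
                chance=0.5,
            )
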
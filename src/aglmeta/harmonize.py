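"""Standardized effect sizes for artificial-grammar-learning outcomes.

Heterogeneous study outcomes (accuracy vs. chance, go/no-go endorsement,
serial reaction times, looking times, sequence reproduction, head-turn
preferences, ...) are converted to a single standardized-mean-difference
family: Cohen's d, corrected to Hedges' g with the small-sample factor
J = 1 - 3/(4*df - 1), with sampling variance

    v_g = (1/n + d**2 / (2*n)) * J**2

following the Borenstein et al. convention. Chance-comparison paradigms use
a one-sample d = (mean - chance) / SD; paired paradigms (serial reaction
time, sequence production, looking time) use the difference between the
grammatical and ungrammatical condition divided by the pooled average SD,
which treats the two conditions as correlated at 1 and is therefore a
conservative upper bound on precision.

Session pooling weights means by participant count and pools SDs through
their variances with n_i - 1 weights. Confidence intervals reported in
place of SDs are inverted under the t-distribution model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

from scipy import stats

__all__ = [
    "Paradigm",
    "SessionStats",
    "RawStudyStats",
    "EffectSize",
    "correction_factor",
    "one_sample_d",
    "hedges_g",
    "variance_g",
    "pooled_mean",
    "average_sd",
    "ci_to_sd",
    "paired_difference_d",
    "harmonize",
    "CHANCE_PARADIGMS",
    "PAIRED_PARADIGMS",
]


class HarmonizationError(ValueError):
    """Invalid or inconsistent raw study statistics."""


class UnsupportedParadigmError(HarmonizationError):
    """Paradigm not in the supported set."""


class Paradigm(str, Enum):
    ACCURACY_VS_CHANCE = "accuracy_vs_chance"
    GO_NOGO = "go_nogo"
    YES_NO = "yes_no"
    SCALE_JUDGEMENT = "scale_judgement"
    FORCED_CHOICE = "forced_choice"
    SERIAL_REACTION_TIME = "serial_reaction_time"
    HEAD_TURN = "head_turn"
    LOOKING_TIME = "looking_time"
    SEQUENCE_PRODUCTION = "sequence_production"
    FREQUENCY_ESTIMATION = "frequency_estimation"


#: Paradigms whose d is the one-sample difference to chance responding.
CHANCE_PARADIGMS = frozenset(
    {
        Paradigm.ACCURACY_VS_CHANCE,
        Paradigm.GO_NOGO,
        Paradigm.YES_NO,
        Paradigm.SCALE_JUDGEMENT,
        Paradigm.FORCED_CHOICE,
        Paradigm.HEAD_TURN,
        Paradigm.FREQUENCY_ESTIMATION,
    }
)

#: Paradigms whose d is a paired grammatical-vs-ungrammatical difference.
PAIRED_PARADIGMS = frozenset(
    {
        Paradigm.SERIAL_REACTION_TIME,
        Paradigm.SEQUENCE_PRODUCTION,
        Paradigm.LOOKING_TIME,
    }
)

#: Sign of (grammatical - ungrammatical) that means "learning" per paradigm.
#: For RT, learning = faster (smaller) on the trained structure; for looking
#: time, learning = longer looking at the ungrammatical (novelty) stimuli.
#: Both therefore flip the raw grammatical-minus-ungrammatical difference.
PAIRED_SIGN = {
    Paradigm.SERIAL_REACTION_TIME: -1.0,
    Paradigm.LOOKING_TIME: -1.0,
    Paradigm.SEQUENCE_PRODUCTION: 1.0,
}


@dataclass(frozen=True)
class SessionStats:
    """Summary statistics for one test session (or block/condition).

    ``sd`` may be omitted when the study reports a confidence interval
    instead; the CI is converted at ingest (see :func:`ci_to_sd`).
    """

    mean: float
    sd: Optional[float]
    n: int
    ci_lower: Optional[float] = None
    ci_upper: Optional[float] = None
    ci_level: float = 0.95

    def __post_init__(self) -> None:
        if self.n < 1:
            raise HarmonizationError(f"session n must be >= 1, got {self.n}")
        if self.sd is not None and self.sd < 0:
            raise HarmonizationError(f"session sd must be >= 0, got {self.sd}")
        if self.sd is None:
            if self.ci_lower is None or self.ci_upper is None:
                raise HarmonizationError(
                    "session must report either sd or both CI limits"
                )
            if not self.ci_upper > self.ci_lower:
                raise HarmonizationError("ci_upper must exceed ci_lower")

    def resolved_sd(self) -> float:
        """The SD, converting from the reported CI if necessary."""
        if self.sd is not None:
            return self.sd
        return ci_to_sd(self.n, self.ci_upper, self.ci_lower, self.ci_level)


@dataclass(frozen=True)
class RawStudyStats:
    """Raw extracted statistics for one study/test, before harmonization."""

    paradigm: Paradigm
    sessions_grammatical: Sequence[SessionStats]
    sessions_ungrammatical: Sequence[SessionStats] = field(default_factory=tuple)
    chance: Optional[float] = None
    familiarity_resign: bool = False

    def __post_init__(self) -> None:
        paradigm = Paradigm(self.paradigm)
        object.__setattr__(self, "paradigm", paradigm)
        if not self.sessions_grammatical:
            raise HarmonizationError("at least one grammatical session required")
        if paradigm in CHANCE_PARADIGMS:
            if self.chance is None:
                raise HarmonizationError(
                    f"paradigm {paradigm.value} compares to chance; "
                    "missing field: chance"
                )
        elif paradigm in PAIRED_PARADIGMS:
            if not self.sessions_ungrammatical:
                raise HarmonizationError(
                    f"paradigm {paradigm.value} is a paired comparison; "
                    "missing field: sessions_ungrammatical"
                )


@dataclass(frozen=True)
class EffectSize:
    """A harmonized effect: Cohen's d, Hedges' g, and its sampling variance."""

    d: float
    g: float
    v_g: float
    df: int
    n: int


def correction_factor(df: int) -> float:
    """Hedges' small-sample correction J = 1 - 3/(4*df - 1).

    Strictly increasing in df; J -> 1 as df grows, J(1) = 0.
    """
    if df < 1:
        raise HarmonizationError(f"df must be >= 1, got {df}")
    return 1.0 - 3.0 / (4.0 * df - 1.0)


def one_sample_d(mean: float, chance: float, sd_within: float) -> float:
    """Cohen's d for a difference-to-chance comparison: (mean - chance)/SD."""
    if sd_within <= 0:
        raise HarmonizationError(f"sd_within must be > 0, got {sd_within}")
    return (mean - chance) / sd_within


def hedges_g(d: float, df: int) -> float:
    """Apply the small-sample correction: g = J(df) * d."""
    return correction_factor(df) * d


def variance_g(d: float, n: int, df: int) -> float:
    """Sampling variance of Hedges' g: (1/n + d^2/(2n)) * J(df)^2."""
    if n < 1:
        raise HarmonizationError(f"n must be >= 1, got {n}")
    j = correction_factor(df)
    return (1.0 / n + d * d / (2.0 * n)) * j * j


def pooled_mean(sessions: Sequence[SessionStats]) -> float:
    """Participant-weighted mean across sessions: sum(n_i m_i)/sum(n_i)."""
    if not sessions:
        raise HarmonizationError("cannot pool an empty list of sessions")
    total_n = sum(s.n for s in sessions)
    return sum(s.n * s.mean for s in sessions) / total_n


def average_sd(sessions: Sequence[SessionStats]) -> float:
    """Pooled SD: sqrt( sum((n_i-1) SD_i^2) / sum(n_i-1) ).

    Generalizes the four-session formula to any session count. Requires at
    least one session with n >= 2 so the denominator is positive.
    """
    if not sessions:
        raise HarmonizationError("cannot pool an empty list of sessions")
    denom = sum(s.n - 1 for s in sessions)
    if denom <= 0:
        raise HarmonizationError(
            "average_sd needs at least one session with n >= 2"
        )
    num = sum((s.n - 1) * s.resolved_sd() ** 2 for s in sessions)
    return math.sqrt(num / denom)


def ci_to_sd(n: int, upper: float, lower: float, ci_level: float = 0.95) -> float:
    """Recover the SD from a reported confidence interval on the mean.

    Assumes the interval was built from the t distribution with n-1 df:
    SD = sqrt(n) * (upper - lower) / (2 * tcrit).
    """
    if n < 2:
        raise HarmonizationError(f"ci_to_sd requires n >= 2, got {n}")
    if not upper > lower:
        raise HarmonizationError("upper CI limit must exceed lower")
    if not 0.0 < ci_level < 1.0:
        raise HarmonizationError(f"ci_level must be in (0, 1), got {ci_level}")
    tcrit = stats.t.ppf(0.5 + ci_level / 2.0, n - 1)
    return math.sqrt(n) * (upper - lower) / (2.0 * tcrit)


def paired_difference_d(
    mean_grammatical: float,
    mean_ungrammatical: float,
    sd_average: float,
    paradigm: Paradigm = Paradigm.SEQUENCE_PRODUCTION,
) -> float:
    """Standardized grammatical-vs-ungrammatical difference.

    Signed so that positive d means a structure-conforming advantage: for
    RT and looking time the raw difference is negated (learning shows as
    faster responses / shorter looking to the trained structure, i.e.
    longer looking at violations).
    """
    if sd_average <= 0:
        raise HarmonizationError(f"sd_average must be > 0, got {sd_average}")
    sign = PAIRED_SIGN[Paradigm(paradigm)]
    return sign * (mean_grammatical - mean_ungrammatical) / sd_average


def _normalize_chance_scale(record: RawStudyStats) -> RawStudyStats:
    # Proportions reported on 0-100 are detected by the chance value and
    # rescaled to 0-1; g is scale-invariant so this only aids validation.
    if record.chance is not None and record.chance > 1.0:
        scale = 100.0
        sessions = tuple(
            SessionStats(
                mean=s.mean / scale,
                sd=None if s.sd is None else s.sd / scale,
                n=s.n,
                ci_lower=None if s.ci_lower is None else s.ci_lower / scale,
                ci_upper=None if s.ci_upper is None else s.ci_upper / scale,
                ci_level=s.ci_level,
            )
            for s in record.sessions_grammatical
        )
        return RawStudyStats(
            paradigm=record.paradigm,
            sessions_grammatical=sessions,
            sessions_ungrammatical=record.sessions_ungrammatical,
            chance=record.chance / scale,
            familiarity_resign=record.familiarity_resign,
        )
    return record


def harmonize(record: RawStudyStats) -> EffectSize:
    """Convert one study's raw statistics into a Hedges' g effect size.

    Chance-comparison paradigms route through the one-sample d; paired
    paradigms pool each condition and standardize the difference by the
    average SD over all sessions of both conditions. df = n - 1 with n the
    total number of participants. Effects flagged ``familiarity_resign``
    (a grammatical-stimulus preference interpreted as learning) have their
    sign flipped; the variance is unchanged.
    """
    paradigm = Paradigm(record.paradigm)
    if paradigm in CHANCE_PARADIGMS:
        record = _normalize_chance_scale(record)
        sessions = record.sessions_grammatical
        mean = pooled_mean(sessions)
        if len(sessions) == 1:
            sd = sessions[0].resolved_sd()
        else:
            sd = average_sd(sessions)
        d = one_sample_d(mean, record.chance, sd)
        # Sessions re-test the same participants; n is not summed across them.
        n = max(s.n for s in sessions)
    elif paradigm in PAIRED_PARADIGMS:
        mg = pooled_mean(record.sessions_grammatical)
        mu = pooled_mean(record.sessions_ungrammatical)
        all_sessions = tuple(record.sessions_grammatical) + tuple(
            record.sessions_ungrammatical
        )
        sd = average_sd(all_sessions)
        d = paired_difference_d(mg, mu, sd, paradigm)
        n = max(s.n for s in all_sessions)
    else:  # pragma: no cover - Paradigm() above already rejects unknowns
        raise UnsupportedParadigmError(f"unsupported paradigm: {paradigm!r}")

    df = n - 1
    if df < 1:
        raise HarmonizationError(
            f"need at least 2 participants for a corrected effect (n={n})"
        )
    g = hedges_g(d, df)
    v = variance_g(d, n, df)
    if record.familiarity_resign:
        g = -g
        d = -d
    return EffectSize(d=d, g=g, v_g=v, df=df, n=n)
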
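"""Synthetic coding sheets with the statistical structure the pipeline assumes.

The generator draws from the same three-level model the estimator fits:

    g_ij = x_ij' beta + u_i + w_ij + e_ij,
    u_i ~ N(0, tau2_article),  w_ij ~ N(0, tau2_study),
    e_ij ~ N(0, v_ij),  v_ij = 1/n_ij + (x_ij' beta)^2 / (2 n_ij),

The sampling variance carries the 1/n + d^2/(2n) form of the
standardized-mean-difference family but is derived from the sample size
and the design-predicted effect, not the realized random effect: weights
that depend on the realized u_i + w_ij are correlated with the outcome
and would bias any inverse-variance-weighted estimator downward, which is
a property of the generator, not of the estimator under study.

with moderators assigned the way the real literature is structured: an
animal class per article (mostly human adults, then birds, then children
and non-human mammals), per-class species and sample-size ranges (humans
run 10-40 participants, non-humans 4-12), paradigm-linked test-response
and test-type codes, and structural/surface grammar features. Non-human
mammals are always auditory, adjacent-dependency, no-repetition studies,
mirroring the confounding that forces those moderators to be skipped in
that subgroup.

``simulate_raw_studies`` additionally emits per-paradigm raw summary
statistics (session means/SDs/ns, chance levels, or CI limits) constructed
by inverting the harmonization formulas, so that harmonizing them returns
exactly the generated effect — the generator tests the pipeline's algebra,
not trial-level behavior.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional, Union

import numpy as np
import pandas as pd

from .harmonize import (
    CHANCE_PARADIGMS,
    PAIRED_SIGN,
    Paradigm,
    RawStudyStats,
    SessionStats,
    correction_factor,
)
from .model import MetaDataset

__all__ = [
    "SyntheticConfig",
    "simulate_effects",
    "simulate_raw_studies",
    "apply_selection_bias",
    "make_selection_rule",
]

_CLASS_PROBS = {
    "human_adult": 0.64,
    "bird": 0.24,
    "human_child": 0.07,
    "nonhuman_mammal": 0.05,
}

_SPECIES = {
    "human_adult": ["homo_sapiens_adult"],
    "human_child": ["homo_sapiens_child"],
    "bird": ["zebra_finch", "budgerigar", "european_starling", "pigeon"],
    "nonhuman_mammal": ["cotton_top_tamarin", "common_marmoset", "rat"],
}

_HUMAN_N_RANGE = (10, 40)
_NONHUMAN_N_RANGE = (4, 12)

_DEFAULT_PARADIGM_MIX = {
    Paradigm.FORCED_CHOICE: 0.45,
    Paradigm.YES_NO: 0.15,
    Paradigm.GO_NOGO: 0.10,
    Paradigm.ACCURACY_VS_CHANCE: 0.10,
    Paradigm.SCALE_JUDGEMENT: 0.05,
    Paradigm.HEAD_TURN: 0.04,
    Paradigm.LOOKING_TIME: 0.04,
    Paradigm.SERIAL_REACTION_TIME: 0.04,
    Paradigm.SEQUENCE_PRODUCTION: 0.02,
    Paradigm.FREQUENCY_ESTIMATION: 0.01,
}

_PROCESSING = {
    Paradigm.LOOKING_TIME,
    Paradigm.HEAD_TURN,
    Paradigm.SERIAL_REACTION_TIME,
    Paradigm.SEQUENCE_PRODUCTION,
}


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator parameters.

    Defaults mimic the scale of the coded AGL literature: ~66 articles
    contributing ~2-3 effects each (~156 effects total), overall true
    effect 1.0 with between-article variance 0.3 and within-article
    variance 0.1.

    ``moderator_effects`` maps a continuous moderator name to a slope, or
    a categorical name to a {level: shift} map, added to the true effect.
    ``selection_bias`` optionally names a suppression rule (see
    :func:`make_selection_rule`) applied after simulation.
    """

    n_articles: int = 66
    studies_per_article: Union[int, tuple] = (1, 4)
    mu: float = 1.0
    tau2_article: float = 0.3
    tau2_study: float = 0.1
    moderator_effects: Mapping[str, object] = field(default_factory=dict)
    n_range: Optional[tuple] = None
    paradigm_mix: Optional[Mapping] = None
    selection_bias: Optional[Mapping[str, float]] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_articles < 1:
            raise ValueError("n_articles must be >= 1")
        if self.tau2_article < 0 or self.tau2_study < 0:
            raise ValueError("variance components must be >= 0")
        if self.n_range is not None:
            lo, hi = self.n_range
            if not (2 <= lo <= hi <= 10_000):
                raise ValueError("n_range must lie within [2, 10000]")
        mix = self.paradigm_mix
        if mix is not None:
            total = sum(mix.values())
            if abs(total - 1.0) > 1e-8:
                raise ValueError(f"paradigm_mix must sum to 1, got {total}")

    def resolved_mix(self) -> dict:
        mix = self.paradigm_mix or _DEFAULT_PARADIGM_MIX
        return {Paradigm(k): float(p) for k, p in mix.items()}


def _draw_n_studies(rng: np.random.Generator, spec: Union[int, tuple]) -> int:
    if isinstance(spec, int):
        return spec
    lo, hi = spec
    return int(rng.integers(lo, hi + 1))


def _draw_moderators(rng: np.random.Generator, animal_class: str) -> dict:
    mods: dict = {"animal_class": animal_class}
    mods["animal_species"] = str(rng.choice(_SPECIES[animal_class]))
    mods["human_vs_nonhuman"] = (
        animal_class if animal_class.startswith("human") else "nonhuman"
    )
    if animal_class == "nonhuman_mammal":
        # mirrors the real literature: auditory-only, adjacent, no repetition
        mods["stimulus_modality"] = "auditory"
        mods["repetition_of_items"] = "absent"
        mods["adjacent_dependencies"] = "present"
    else:
        mods["stimulus_modality"] = str(
            rng.choice(["auditory", "visual", "audiovisual"], p=[0.6, 0.35, 0.05])
        )
        mods["repetition_of_items"] = "present" if rng.random() < 0.3 else "absent"
        mods["adjacent_dependencies"] = "present" if rng.random() < 0.8 else "absent"
    mods["nonadjacent_dependencies"] = "present" if rng.random() < 0.3 else "absent"
    mods["log_training_length"] = float(
        rng.uniform(np.log(50.0), np.log(5000.0))
    )
    mods["categories_in_language"] = int(rng.integers(2, 7))
    mods["vocabulary_size"] = int(rng.integers(4, 31))
    return mods


def _moderator_shift(
    effects: Mapping[str, object], mods: Mapping[str, object]
) -> float:
    shift = 0.0
    for name, eff in effects.items():
        value = mods.get(name)
        if isinstance(eff, Mapping):
            shift += float(eff.get(value, 0.0))
        else:
            shift += float(eff) * float(value)
    return shift


def _draw_structure(config: SyntheticConfig, rng: np.random.Generator):
    """Article/study skeleton: ids, classes, moderators, true effects, n."""
    mix = config.resolved_mix()
    paradigms = list(mix.keys())
    probs = np.array([mix[p] for p in paradigms])
    classes = list(_CLASS_PROBS)
    class_probs = np.array([_CLASS_PROBS[c] for c in classes])
    rows = []
    for a in range(config.n_articles):
        article_id = f"article_{a+1:03d}"
        animal_class = str(rng.choice(classes, p=class_probs))
        u = rng.normal(0.0, np.sqrt(config.tau2_article))
        n_studies = _draw_n_studies(rng, config.studies_per_article)
        for s in range(n_studies):
            mods = _draw_moderators(rng, animal_class)
            w = rng.normal(0.0, np.sqrt(config.tau2_study))
            g_fixed = config.mu + _moderator_shift(config.moderator_effects, mods)
            g_true = g_fixed + u + w
            if config.n_range is not None:
                lo, hi = config.n_range
            else:
                lo, hi = (
                    _HUMAN_N_RANGE
                    if animal_class.startswith("human")
                    else _NONHUMAN_N_RANGE
                )
            n = int(rng.integers(lo, hi + 1))
            paradigm = paradigms[int(rng.choice(len(paradigms), p=probs))]
            mods["test_response"] = paradigm.value
            mods["test_type"] = (
                "processing" if paradigm in _PROCESSING else "reflection"
            )
            rows.append(
                {
                    "article_id": article_id,
                    "study_id": f"{article_id}_s{s+1}",
                    "paradigm": paradigm,
                    "g_true": float(g_true),
                    "g_fixed": float(g_fixed),
                    "n": n,
                    **mods,
                }
            )
    return rows


def simulate_effects(config: SyntheticConfig) -> MetaDataset:
    """Draw a harmonized-effects dataset from the three-level model.

    Deterministic under a fixed ``config.seed``. The known sampling
    variance v_g = 1/n + g_true^2/(2n) is stored alongside the noisy
    observed g.
    """
    rng = np.random.default_rng(config.seed)
    rows = _draw_structure(config, rng)
    for row in rows:
        g_true = row.pop("g_true")
        g_fixed = row.pop("g_fixed")
        n = row["n"]
        v = 1.0 / n + g_fixed**2 / (2.0 * n)
        row["v_g"] = v
        row["g"] = float(g_true + rng.normal(0.0, np.sqrt(v)))
        row.pop("paradigm")
    frame = pd.DataFrame(rows)
    ordered = ["article_id", "study_id", "g", "v_g", "n"] + [
        c
        for c in frame.columns
        if c not in ("article_id", "study_id", "g", "v_g", "n")
    ]
    dataset = MetaDataset(frame[ordered])
    if config.selection_bias is not None:
        rule = make_selection_rule(config.selection_bias)
        dataset = apply_selection_bias(
            dataset, rule, rng=np.random.default_rng(config.seed + 1)
        )
    return dataset


def _invert_to_raw(
    paradigm: Paradigm,
    g_obs: float,
    n: int,
    rng: np.random.Generator,
) -> RawStudyStats:
    """Build raw statistics whose harmonization returns exactly g_obs."""
    df = n - 1
    d = g_obs / correction_factor(df) if df >= 1 else g_obs
    resign = paradigm in (Paradigm.HEAD_TURN, Paradigm.LOOKING_TIME) and (
        rng.random() < 0.25
    )
    d_raw = -d if resign else d

    if paradigm in CHANCE_PARADIGMS:
        chance = 0.5
        sd = float(rng.uniform(0.08, 0.2))
        mean = chance + d_raw * sd
        style = rng.random()
        if style < 0.25 and n >= 2:
            # CI-only reporting: limits built under the t model invert exactly
            from scipy import stats as _st

            tcrit = _st.t.ppf(0.975, n - 1)
            half = tcrit * sd / np.sqrt(n)
            sessions = (
                SessionStats(
                    mean=mean, sd=None, n=n, ci_lower=mean - half,
                    ci_upper=mean + half,
                ),
            )
        elif style < 0.55:
            # two sessions with distinct means pooling back to the target
            delta = float(rng.uniform(0.0, 0.05))
            sessions = (
                SessionStats(mean=mean + delta, sd=sd, n=n),
                SessionStats(mean=mean - delta, sd=sd, n=n),
            )
        else:
            sessions = (SessionStats(mean=mean, sd=sd, n=n),)
        return RawStudyStats(
            paradigm=paradigm,
            sessions_grammatical=sessions,
            chance=chance,
            familiarity_resign=resign,
        )

    # paired paradigms: RT in ms, looking in s, production in proportions
    scale = {
        Paradigm.SERIAL_REACTION_TIME: (500.0, 80.0),
        Paradigm.LOOKING_TIME: (6.0, 1.5),
        Paradigm.SEQUENCE_PRODUCTION: (0.6, 0.15),
    }[paradigm]
    base, sd = scale
    sign = PAIRED_SIGN[paradigm]
    mean_u = base
    mean_g = mean_u + sign * d_raw * sd
    return RawStudyStats(
        paradigm=paradigm,
        sessions_grammatical=(SessionStats(mean=mean_g, sd=sd, n=n),),
        sessions_ungrammatical=(SessionStats(mean=mean_u, sd=sd, n=n),),
        familiarity_resign=resign,
    )


def simulate_raw_studies(config: SyntheticConfig) -> list:
    """Per-study raw statistics whose harmonization recovers the simulated g.

    Returns a list of dicts with keys ``article_id``, ``study_id``,
    ``raw`` (:class:`RawStudyStats`), ``moderators`` and ``g_target`` (the
    observed effect the raw statistics encode). Exercises multi-session
    pooling, CI-only reporting and familiarity re-signing.
    """
    rng = np.random.default_rng(config.seed)
    rows = _draw_structure(config, rng)
    noise_rng = np.random.default_rng(int(rng.integers(2**31)))
    out = []
    for row in rows:
        g_true = row["g_true"]
        n = row["n"]
        v = 1.0 / n + row["g_fixed"] ** 2 / (2.0 * n)
        g_obs = float(g_true + noise_rng.normal(0.0, np.sqrt(v)))
        raw = _invert_to_raw(row["paradigm"], g_obs, n, rng)
        mods = {
            key: row[key]
            for key in row
            if key not in ("article_id", "study_id", "paradigm", "g_true", "g_fixed", "n")
        }
        out.append(
            {
                "article_id": row["article_id"],
                "study_id": row["study_id"],
                "raw": raw,
                "moderators": mods,
                "g_target": g_obs,
                "n": n,
            }
        )
    return out


def make_selection_rule(spec: Mapping[str, float]) -> Callable[[float, float], float]:
    """Build a (g, se) -> retention-probability rule from a config map.

    The rule emulates the classic file-drawer mechanism: imprecise studies
    (se above ``se_threshold``) with effects below ``g_threshold`` are
    retained only with probability ``retain_prob``; everything else is
    always kept.
    """
    g_threshold = float(spec.get("g_threshold", 0.0))
    se_threshold = float(spec.get("se_threshold", 0.25))
    retain_prob = float(spec.get("retain_prob", 0.2))
    if not 0.0 <= retain_prob <= 1.0:
        raise ValueError("retain_prob must be in [0, 1]")

    def rule(g: float, se: float) -> float:
        if se > se_threshold and g < g_threshold:
            return retain_prob
        return 1.0

    return rule


def apply_selection_bias(
    dataset: MetaDataset,
    rule: Callable[[float, float], float],
    rng: Optional[np.random.Generator] = None,
    seed: int = 0,
) -> MetaDataset:
    """Stochastically thin a dataset with a (g, se) retention rule.

    An asymmetric rule (suppressing small imprecise effects) induces the
    small-study asymmetry that Peters' test is designed to detect.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    df = dataset.data
    keep = []
    for _, row in df.iterrows():
        prob = float(rule(row["g"], float(np.sqrt(row["v_g"]))))
        keep.append(rng.random() < prob)
    sub = df[np.array(keep, dtype=bool)].reset_index(drop=True)
    if len(sub) == 0:
        raise ValueError("selection rule removed every effect")
    return MetaDataset(sub, dict(dataset.moderator_schema))
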
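"""Publication-bias diagnostics: Peters' regression test and funnel data.

Peters' test regresses effect size on inverse total sample size. Here it is
run inside the same multilevel REML machinery as every other moderator:
1/n enters as the sole continuous moderator alongside the intercept, and
the test statistic is the t-method t of its slope with df = k - 2. A
significant slope means small studies show systematically different
effects than large ones — funnel-plot asymmetry, the classic footprint of
selective publication of significant small-sample results.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import (
    DegenerateModeratorError,
    MetaDataset,
    ModelSpec,
    reml_fit,
)

__all__ = ["BiasResult", "peters_test", "funnel_coordinates"]


@dataclass
class BiasResult:
    """Peters' test outcome: slope of g on 1/n with t-method inference."""

    t_stat: float
    df: int
    p: float
    slope: float
    intercept: float
    slope_se: float


def peters_test(dataset: MetaDataset) -> BiasResult:
    """Funnel-asymmetry test: 1/n as moderator in the multilevel model.

    Requires at least 3 effects and variation in n (a constant regressor
    makes the slope unidentifiable).
    """
    df = dataset.data
    if len(df) < 3:
        raise ValueError("Peters' test requires at least 3 effects")
    n = df["n"].to_numpy(dtype=float)
    if np.any(n <= 0):
        raise ValueError("all sample sizes must be positive")
    if np.allclose(n, n[0]):
        raise DegenerateModeratorError(
            "sample size is constant across effects; 1/n regressor degenerate"
        )
    augmented = df.copy()
    augmented["inv_n"] = 1.0 / n
    ds = MetaDataset(augmented, dict(dataset.moderator_schema))
    fit = reml_fit(ds, ModelSpec(moderators=("inv_n",), intercept=True))
    i_slope = fit.terms.index("inv_n")
    i_int = fit.terms.index("intercept")
    return BiasResult(
        t_stat=float(fit.t_stats[i_slope]),
        df=fit.df,
        p=float(fit.p_values[i_slope]),
        slope=float(fit.beta[i_slope]),
        intercept=float(fit.beta[i_int]),
        slope_se=float(fit.se[i_slope]),
    )


def funnel_coordinates(
    dataset: MetaDataset, group: str = "animal_class"
) -> tuple[pd.DataFrame, float]:
    """Plot-ready funnel data: one (g, se, group) point per effect.

    Returns the point table and the overall intercept-only multilevel
    estimate, which serves as the funnel's vertical reference line.
    """
    df = dataset.data
    points = pd.DataFrame(
        {
            "g": df["g"].to_numpy(dtype=float),
            "se": np.sqrt(df["v_g"].to_numpy(dtype=float)),
            "group": (
                df[group].astype(str)
                if group in df.columns
                else pd.Series(["all"] * len(df))
            ),
        }
    )
    if dataset.k == 1:
        # degenerate but legal: the reference line is the lone effect
        return points, float(df["g"].iloc[0])
    fit = reml_fit(dataset, ModelSpec())
    return points, float(fit.beta[0])
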
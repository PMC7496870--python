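#!/usr/bin/env python
"""Fit the overall three-level random-effects model and test heterogeneity.

The intercept-only REML fit gives the average weighted effect with
t-method CI; Cochran's Q tests whether effects are more variable than
their sampling variances allow, which motivates the moderator analyses.
"""

import json
from pathlib import Path

from aglmeta.io import read_coding_sheet
from aglmeta.model import ModelSpec, cochran_q, reml_fit

OUT = Path("results/analysis")


def main() -> None:
    dataset = read_coding_sheet(OUT / "effects.csv").dataset
    fit = reml_fit(dataset, ModelSpec())
    q = cochran_q(dataset)
    fit.summary_frame().to_csv(OUT / "overall_model.tsv", sep="\t", index=False)
    (OUT / "heterogeneity.json").write_text(
        json.dumps(
            {
                "Q": q.Q,
                "df": q.df,
                "p": q.p,
                "sigma2_article": fit.sigma2_article,
                "sigma2_study": fit.sigma2_study,
            },
            indent=2,
        )
        + "\n"
    )
    print(
        f"overall effect {fit.beta[0]:.3f} (SE {fit.se[0]:.3f}, "
        f"95% CI [{fit.ci_lower[0]:.3f}, {fit.ci_upper[0]:.3f}], "
        f"t({fit.df}) = {fit.t_stats[0]:.2f}, p = {fit.p_values[0]:.2g})"
    )
    print(
        f"variance components: article {fit.sigma2_article:.3f}, "
        f"study {fit.sigma2_study:.3f}"
    )
    print(f"Cochran's Q({q.df}) = {q.Q:.1f}, p = {q.p:.2g}")
    if q.p < 0.05:
        print("-> heterogeneity beyond sampling error; moderators warranted")


if __name__ == "__main__":
    main()
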
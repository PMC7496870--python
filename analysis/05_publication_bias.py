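#!/usr/bin/env python
"""Publication-bias diagnostics: Peters' test and the funnel plot.

Peters' test puts inverse total sample size into the multilevel model; a
significant slope means small studies report systematically different
effects. The funnel table pairs each effect with its standard error for
plotting against the overall estimate.
"""

from pathlib import Path

from aglmeta.bias import funnel_coordinates, peters_test
from aglmeta.io import read_coding_sheet

OUT = Path("results/analysis")


def main() -> None:
    dataset = read_coding_sheet(OUT / "effects.csv").dataset
    result = peters_test(dataset)
    print(
        f"Peters' test: t({result.df}) = {result.t_stat:.3f}, "
        f"p = {result.p:.3f} (slope {result.slope:.2f} per unit 1/n)"
    )
    verdict = (
        "asymmetry detected: small-study effects differ systematically"
        if result.p < 0.05
        else "no significant funnel asymmetry"
    )
    print(f"-> {verdict}")

    funnel, reference = funnel_coordinates(dataset)
    funnel.assign(reference=reference).to_csv(
        OUT / "funnel.tsv", sep="\t", index=False
    )
    print(
        f"wrote funnel.tsv: {len(funnel)} points, reference line at "
        f"g = {reference:.3f}"
    )


if __name__ == "__main__":
    main()
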
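#!/usr/bin/env python
"""Harmonize the raw coding sheet into Hedges' g effect sizes.

Each study's raw statistics are routed through the paradigm-appropriate
rule (one-sample difference to chance, or paired grammatical-vs-
ungrammatical difference), small-sample corrected, and written as one
effect row with its sampling variance and moderator codes.
"""

from pathlib import Path

from aglmeta.io import harmonize_records, read_coding_sheet, write_effects_sheet

OUT = Path("results/analysis")


def main() -> None:
    result = read_coding_sheet(OUT / "coding_sheet_raw.csv")
    assert result.kind == "raw"
    dataset = harmonize_records(result.raw_records)
    for label, reason in result.dropped:
        print(f"dropped {label}: {reason}")
    path = OUT / "effects.csv"
    write_effects_sheet(dataset, path)
    g = dataset.data["g"]
    print(f"wrote {path}: {dataset.k} effects")
    print(
        f"g: mean {g.mean():.3f}, sd {g.std():.3f}, "
        f"range [{g.min():.2f}, {g.max():.2f}]"
    )


if __name__ == "__main__":
    main()
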
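#!/usr/bin/env python
"""Moderator omnibus tests: full dataset, then per animal class.

Each moderator enters the multilevel model alongside the intercept and is
tested jointly (F with df1 = its coefficient count, df2 = k - p). Within a
class subset, moderators that are constant by construction (e.g. modality
among non-human mammals) are skipped. Subgroup mean effects per class come
from a cell-means fit sharing variance components across levels.
"""

from pathlib import Path

from aglmeta.io import read_coding_sheet
from aglmeta.model import filter_subset, subgroup_effects
from aglmeta.pipeline import FULL_MODERATORS, SUBGROUP_MODERATORS, moderator_table

OUT = Path("results/analysis")


def main() -> None:
    dataset = read_coding_sheet(OUT / "effects.csv").dataset

    table, skipped = moderator_table(dataset, FULL_MODERATORS)
    table.to_csv(OUT / "moderators_full.tsv", sep="\t", index=False)
    print("full-dataset moderators:")
    print(table.to_string(index=False))

    sub = subgroup_effects(dataset, "animal_class")
    sub.to_csv(OUT / "subgroups_animal_class.tsv", sep="\t", index=False)
    print("\nper-class mean effects:")
    print(sub.to_string(index=False))

    for level in sorted(dataset.data["animal_class"].unique()):
        subset = filter_subset(dataset, {"animal_class": level})
        if subset.k < 5:
            print(f"\n{level}: only {subset.k} effects, skipping moderators")
            continue
        sub_table, sub_skipped = moderator_table(subset, SUBGROUP_MODERATORS)
        sub_table.to_csv(
            OUT / f"moderators_{level}.tsv", sep="\t", index=False
        )
        skipped_names = [m for m, _ in sub_skipped]
        print(
            f"\n{level} ({subset.k} effects; skipped: {skipped_names}):"
        )
        print(sub_table.to_string(index=False))


if __name__ == "__main__":
    main()
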
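#!/usr/bin/env python
"""Generate the synthetic coded literature used by the downstream analyses.

Writes a raw coding sheet (long format, one row per test session) at the
scale of the coded AGL literature: ~66 articles, ~156 effects, human
samples of 10-40 participants, non-human samples of 4-12, a paradigm mix
dominated by reflection-based tasks, with multi-session reporting,
CI-only reporting, and familiarity re-signing all represented.
"""

import sys
from pathlib import Path

from aglmeta.io import raw_records_to_sheet
from aglmeta.simulate import SyntheticConfig, simulate_raw_studies

OUT = Path("results/analysis")
SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    config = SyntheticConfig(seed=SEED)
    records = simulate_raw_studies(config)
    sheet = raw_records_to_sheet(records)
    path = OUT / "coding_sheet_raw.csv"
    sheet.to_csv(path, index=False)
    n_articles = sheet["article_id"].nunique()
    n_studies = sheet.groupby(["article_id", "study_id"]).ngroups
    print(
        f"wrote {path}: {n_articles} articles, {n_studies} studies, "
        f"{len(sheet)} session rows (seed {SEED})"
    )
    print(
        "paradigm mix:",
        sheet.drop_duplicates(["article_id", "study_id"])["paradigm"]
        .value_counts()
        .to_dict(),
    )


if __name__ == "__main__":
    main()
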
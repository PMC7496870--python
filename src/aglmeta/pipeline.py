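"""End-to-end analysis pipeline: harmonize -> fit -> moderators -> bias.

``run_pipeline`` chains every stage on one coding sheet and writes a
result bundle: the harmonized effects CSV, the overall model summary, a
moderator omnibus table for the full dataset and per animal-class
subgroup (with constant moderators skipped and logged), subgroup effect
estimates, the publication-bias summary, and funnel-plot coordinates.
Runs are deterministic: the same sheet and seed produce byte-identical
outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from . import io as sheet_io
from .bias import funnel_coordinates, peters_test
from .model import (
    DegenerateModeratorError,
    MetaDataset,
    ModelSpec,
    cochran_q,
    filter_subset,
    omnibus_moderator_test,
    reml_fit,
    subgroup_effects,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "moderator_table"]

#: Omnibus-table moderators for the full dataset, in presentation order.
FULL_MODERATORS = [
    "animal_species",
    "animal_class",
    "human_vs_nonhuman",
    "log_training_length",
    "stimulus_modality",
    "test_response",
    "test_type",
    "categories_in_language",
    "vocabulary_size",
    "repetition_of_items",
    "adjacent_dependencies",
    "nonadjacent_dependencies",
]

#: Within a class, the population moderators are constant by construction.
SUBGROUP_MODERATORS = [m for m in FULL_MODERATORS if not m.startswith(("animal_", "human_"))]


@dataclass
class PipelineConfig:
    """What to run and where to write it."""

    input_sheet: str
    output_dir: str
    moderators: Sequence[str] = field(default_factory=lambda: list(FULL_MODERATORS))
    subgroup_factor: Optional[str] = "animal_class"
    funnel_group: str = "animal_class"


def moderator_table(
    dataset: MetaDataset, moderators: Sequence[str]
) -> tuple[pd.DataFrame, list]:
    """Omnibus F per moderator; constant moderators are skipped, not errors."""
    rows = []
    skipped = []
    present = set(dataset.data.columns)
    for mod in moderators:
        if mod not in present:
            skipped.append((mod, "not coded"))
            continue
        if mod in dataset.constant_moderators:
            skipped.append((mod, "constant in subset"))
            continue
        try:
            res = omnibus_moderator_test(dataset, mod)
        except DegenerateModeratorError:
            skipped.append((mod, "constant in subset"))
            continue
        rows.append(
            {
                "moderator": mod,
                "F": res.F,
                "df1": res.df1,
                "df2": res.df2,
                "p": res.p,
            }
        )
    for mod, reason in skipped:
        logger.info("skipping moderator %s: %s", mod, reason)
    return pd.DataFrame(rows), skipped


def _write_tsv(frame: pd.DataFrame, path: Path) -> None:
    frame.to_csv(path, sep="\t", index=False)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write the result bundle; returns output paths."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict = {}

    result = sheet_io.read_coding_sheet(config.input_sheet)
    if result.kind == "raw":
        dataset = sheet_io.harmonize_records(result.raw_records)
    else:
        dataset = result.dataset
    effects_path = out / "effects.csv"
    sheet_io.write_effects_sheet(dataset, effects_path)
    outputs["effects"] = effects_path

    fit = reml_fit(dataset, ModelSpec())
    summary = fit.summary_frame()
    summary_path = out / "overall_model.tsv"
    _write_tsv(summary, summary_path)
    outputs["overall_model"] = summary_path

    q = cochran_q(dataset)
    hetero = {
        "Q": q.Q,
        "Q_df": q.df,
        "Q_p": q.p,
        "sigma2_article": fit.sigma2_article,
        "sigma2_study": fit.sigma2_study,
        "k": fit.k,
        "reml_loglik": fit.reml_loglik,
    }
    hetero_path = out / "heterogeneity.json"
    hetero_path.write_text(json.dumps(hetero, indent=2, sort_keys=True) + "\n")
    outputs["heterogeneity"] = hetero_path

    table, skipped = moderator_table(dataset, config.moderators)
    table_path = out / "moderators_full.tsv"
    _write_tsv(table, table_path)
    outputs["moderators_full"] = table_path

    if config.subgroup_factor and config.subgroup_factor in dataset.data.columns:
        sub_est = subgroup_effects(dataset, config.subgroup_factor)
        sub_path = out / f"subgroups_{config.subgroup_factor}.tsv"
        _write_tsv(sub_est, sub_path)
        outputs["subgroups"] = sub_path
        for level in sorted(
            dataset.data[config.subgroup_factor].dropna().astype(str).unique()
        ):
            subset = filter_subset(dataset, {config.subgroup_factor: level})
            if subset.k < 5:
                logger.info("subgroup %s too small for moderator table", level)
                continue
            sub_table, _ = moderator_table(subset, SUBGROUP_MODERATORS)
            p = out / f"moderators_{config.subgroup_factor}_{level}.tsv"
            _write_tsv(sub_table, p)
            outputs[f"moderators_{level}"] = p

    bias = peters_test(dataset)
    bias_frame = pd.DataFrame(
        [
            {
                "t": bias.t_stat,
                "df": bias.df,
                "p": bias.p,
                "slope": bias.slope,
                "slope_se": bias.slope_se,
                "intercept": bias.intercept,
            }
        ]
    )
    bias_path = out / "bias_summary.tsv"
    _write_tsv(bias_frame, bias_path)
    outputs["bias_summary"] = bias_path

    funnel, reference = funnel_coordinates(dataset, config.funnel_group)
    funnel = funnel.assign(reference=reference)
    funnel_path = out / "funnel.tsv"
    _write_tsv(funnel, funnel_path)
    outputs["funnel"] = funnel_path

    return outputs
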
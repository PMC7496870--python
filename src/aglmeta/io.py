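"""Coding-sheet I/O and validation.

Two sheet layouts are supported, auto-detected on read:

* **harmonized**: one row per effect with ``article_id, study_id, g, v_g,
  n`` plus moderator columns — the output of harmonization and the input
  to modelling.
* **raw**: long format, one row per test session, with ``paradigm,
  session, condition`` (grammatical/ungrammatical), ``mean, sd, n`` and
  optional ``chance, ci_lower, ci_upper, ci_level, familiarity_resign``;
  moderators repeat across a study's session rows.

Categorical spellings are normalized case-insensitively at ingest. A raw
``training_length`` column (stimulus-token count) is natural-log
transformed into ``log_training_length``. Invalid rows are dropped with a
per-row reason report rather than aborting the read.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .harmonize import Paradigm, RawStudyStats, SessionStats, harmonize
from .model import MODERATOR_COLUMNS, MetaDataset

logger = logging.getLogger(__name__)

__all__ = [
    "ReadResult",
    "read_coding_sheet",
    "write_effects_sheet",
    "raw_records_to_sheet",
    "harmonize_records",
]

_EFFECT_COLUMNS = ("article_id", "study_id", "g", "v_g", "n")
_RAW_COLUMNS = ("article_id", "study_id", "paradigm", "mean", "n")

_CATEGORICAL_MODERATORS = [
    m
    for m in MODERATOR_COLUMNS
    if m
    not in ("log_training_length", "categories_in_language", "vocabulary_size")
]


@dataclass
class ReadResult:
    """Outcome of reading a coding sheet: records plus a drop report."""

    kind: str  # "harmonized" | "raw"
    dataset: Optional[MetaDataset] = None
    raw_records: Optional[list] = None
    dropped: list = field(default_factory=list)  # (row label, reason)


def _normalize_moderators(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    for col in _CATEGORICAL_MODERATORS:
        if col in df.columns:
            df[col] = df[col].astype("string").str.strip().str.lower()
    if "training_length" in df.columns and "log_training_length" not in df.columns:
        df["log_training_length"] = np.log(df["training_length"].astype(float))
        df = df.drop(columns=["training_length"])
    return df


def read_coding_sheet(
    path, column_map: Optional[Mapping[str, str]] = None
) -> ReadResult:
    """Read and validate a coding sheet, auto-detecting its layout.

    ``column_map`` optionally renames source columns to the standard
    schema before validation (a reconciliation layer for externally coded
    sheets).
    """
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    if df.empty:
        raise ValueError(f"coding sheet {path} is empty")
    if column_map:
        df = df.rename(columns=dict(column_map))
    df = _normalize_moderators(df)
    if {"g", "v_g"}.issubset(df.columns):
        return _read_harmonized(df)
    missing = [c for c in _RAW_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(
            f"sheet is neither harmonized (needs g, v_g) nor raw "
            f"(missing {missing})"
        )
    return _read_raw(df)


def _read_harmonized(df: pd.DataFrame) -> ReadResult:
    missing = [c for c in _EFFECT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"harmonized sheet missing columns: {missing}")
    dropped = []
    keep = pd.Series(True, index=df.index)
    for idx, row in df.iterrows():
        if pd.isna(row["g"]) or pd.isna(row["v_g"]):
            dropped.append((idx, "missing g or v_g"))
            keep[idx] = False
        elif row["v_g"] <= 0:
            dropped.append((idx, f"non-positive sampling variance v_g={row['v_g']}"))
            keep[idx] = False
        elif pd.isna(row["n"]) or row["n"] < 1:
            dropped.append((idx, "missing or non-positive n"))
            keep[idx] = False
    kept = df[keep].reset_index(drop=True)
    if kept.empty:
        raise ValueError("no valid rows in harmonized sheet")
    if dropped:
        logger.warning("dropped %d invalid rows from sheet", len(dropped))
    return ReadResult(
        kind="harmonized", dataset=MetaDataset(kept), dropped=dropped
    )


def _read_raw(df: pd.DataFrame) -> ReadResult:
    records = []
    dropped = []
    mod_cols = [c for c in MODERATOR_COLUMNS if c in df.columns]
    for (article_id, study_id), grp in df.groupby(
        ["article_id", "study_id"], sort=False
    ):
        label = f"{article_id}/{study_id}"
        try:
            records.append(_raw_record_from_rows(article_id, study_id, grp, mod_cols))
        except Exception as exc:  # collected, not fatal
            dropped.append((label, str(exc)))
    if not records:
        raise ValueError("no valid studies in raw sheet")
    if dropped:
        logger.warning("dropped %d invalid studies from raw sheet", len(dropped))
    return ReadResult(kind="raw", raw_records=records, dropped=dropped)


def _session_from_row(row: pd.Series) -> SessionStats:
    sd = row.get("sd")
    sd = None if pd.isna(sd) else float(sd)
    ci_l = row.get("ci_lower")
    ci_u = row.get("ci_upper")
    return SessionStats(
        mean=float(row["mean"]),
        sd=sd,
        n=int(row["n"]),
        ci_lower=None if pd.isna(ci_l) else float(ci_l),
        ci_upper=None if pd.isna(ci_u) else float(ci_u),
        ci_level=float(row.get("ci_level", 0.95))
        if not pd.isna(row.get("ci_level", 0.95))
        else 0.95,
    )


def _raw_record_from_rows(article_id, study_id, grp, mod_cols) -> dict:
    paradigm = Paradigm(str(grp["paradigm"].iloc[0]).strip().lower())
    cond = (
        grp["condition"].astype(str).str.lower()
        if "condition" in grp.columns
        else pd.Series(["grammatical"] * len(grp), index=grp.index)
    )
    gram = tuple(
        _session_from_row(row) for _, row in grp[cond == "grammatical"].iterrows()
    )
    ungram = tuple(
        _session_from_row(row)
        for _, row in grp[cond == "ungrammatical"].iterrows()
    )
    chance_col = grp.get("chance")
    chance = (
        None
        if chance_col is None or chance_col.dropna().empty
        else float(chance_col.dropna().iloc[0])
    )
    resign = False
    if "familiarity_resign" in grp.columns:
        val = grp["familiarity_resign"].iloc[0]
        resign = str(val).strip().lower() in ("true", "1", "yes")
    raw = RawStudyStats(
        paradigm=paradigm,
        sessions_grammatical=gram,
        sessions_ungrammatical=ungram,
        chance=chance,
        familiarity_resign=resign,
    )
    mods = {c: grp[c].iloc[0] for c in mod_cols}
    return {
        "article_id": article_id,
        "study_id": study_id,
        "raw": raw,
        "moderators": mods,
    }


def harmonize_records(records: Sequence[dict]) -> MetaDataset:
    """Apply harmonization to raw records and assemble a MetaDataset."""
    rows = []
    for rec in records:
        eff = harmonize(rec["raw"])
        rows.append(
            {
                "article_id": rec["article_id"],
                "study_id": rec["study_id"],
                "g": eff.g,
                "v_g": eff.v_g,
                "n": eff.n,
                **rec.get("moderators", {}),
            }
        )
    return MetaDataset(pd.DataFrame(rows))


def write_effects_sheet(dataset: MetaDataset, path) -> None:
    """Write the harmonized-effects CSV (round-trips through read)."""
    dataset.data.to_csv(path, index=False)


def raw_records_to_sheet(records: Sequence[dict]) -> pd.DataFrame:
    """Flatten raw records into the long-format session sheet."""
    rows = []
    for rec in records:
        raw: RawStudyStats = rec["raw"]
        mods = rec.get("moderators", {})
        for condition, sessions in (
            ("grammatical", raw.sessions_grammatical),
            ("ungrammatical", raw.sessions_ungrammatical),
        ):
            for s_idx, sess in enumerate(sessions, start=1):
                rows.append(
                    {
                        "article_id": rec["article_id"],
                        "study_id": rec["study_id"],
                        "paradigm": raw.paradigm.value,
                        "session": s_idx,
                        "condition": condition,
                        "mean": sess.mean,
                        "sd": sess.sd,
                        "n": sess.n,
                        "chance": raw.chance,
                        "ci_lower": sess.ci_lower,
                        "ci_upper": sess.ci_upper,
                        "ci_level": sess.ci_level,
                        "familiarity_resign": raw.familiarity_resign,
                        **mods,
                    }
                )
    return pd.DataFrame(rows)
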
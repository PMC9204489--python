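"""Bipartite compound–target interaction (CTI) table assembly.

A CTI table holds one row per (compound, target) pair with an action label
(``activatory``, ``inhibitory``, or ``other``) and a provenance label
(``validated`` — database-curated, or ``predicted`` — carrying a likelihood
score in [0, 1]).  Two filters gate the table before proximity screening:

* compounds must have a drug-likeness score QED >= 0.35 (inclusive) — the
  average QED of approved drugs, used as a bioavailability floor;
* predicted pairs must have a prediction score strictly greater than 0.82,
  the operating point at which the upstream target-prediction model showed a
  1% false-discovery rate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .errors import ValidationError

logger = logging.getLogger(__name__)

ACTIONS = ("activatory", "inhibitory", "other")
SOURCES = ("validated", "predicted")

COLUMNS = ["compound_id", "target_id", "action", "source", "score"]

DEFAULT_QED_THRESHOLD = 0.35
DEFAULT_SCORE_THRESHOLD = 0.82

__all__ = [
    "ACTIONS",
    "SOURCES",
    "COLUMNS",
    "DEFAULT_QED_THRESHOLD",
    "DEFAULT_SCORE_THRESHOLD",
    "CompoundFilter",
    "make_table",
    "validate_table",
    "read_cti_table",
    "write_cti_table",
    "filter_compounds_by_qed",
    "filter_predictions_by_score",
    "merge_validated_predicted",
    "network_stats",
]


@dataclass
class CompoundFilter:
    """Per-compound QED drug-likeness scores plus the inclusion threshold."""

    qed_scores: Mapping[str, float]
    qed_threshold: float = DEFAULT_QED_THRESHOLD

    def __post_init__(self) -> None:
        if not 0.0 <= self.qed_threshold <= 1.0:
            raise ValidationError(
                f"qed_threshold must be in [0, 1], got {self.qed_threshold}"
            )


def make_table(rows: Iterable[tuple]) -> pd.DataFrame:
    """Build a validated CTI table from (compound, target, action, source[, score]) tuples."""
    records = []
    for row in rows:
        row = tuple(row)
        score = row[4] if len(row) > 4 else None
        records.append(row[:4] + (score,))
    df = pd.DataFrame(records, columns=COLUMNS)
    df["score"] = pd.to_numeric(df["score"], errors="coerce")
    validate_table(df)
    return df


def validate_table(df: pd.DataFrame) -> pd.DataFrame:
    """Enforce the CTI invariants; returns the table unchanged if clean.

    Unknown action or source labels are rejected outright (fail-fast on dirty
    data rather than silent coercion), and every predicted row must carry a
    score in [0, 1].
    """
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"CTI table missing column(s): {missing}")
    if len(df) == 0:
        return df
    bad_action = set(df["action"]) - set(ACTIONS)
    if bad_action:
        raise ValidationError(f"unknown action label(s): {sorted(bad_action)}")
    bad_source = set(df["source"]) - set(SOURCES)
    if bad_source:
        raise ValidationError(f"unknown source label(s): {sorted(bad_source)}")
    predicted = df[df["source"] == "predicted"]
    if predicted["score"].isna().any():
        culprits = predicted.loc[predicted["score"].isna(), ["compound_id", "target_id"]]
        raise ValidationError(
            "predicted row(s) without a score: "
            + ", ".join(f"({c}, {t})" for c, t in culprits.itertuples(index=False))
        )
    scored = df["score"].dropna()
    if ((scored < 0) | (scored > 1)).any():
        raise ValidationError("scores must lie in [0, 1]")
    dup_mask = df.duplicated(subset=["compound_id", "target_id", "source"], keep=False)
    if dup_mask.any():
        dups = df.loc[dup_mask]
        conflicting = dups.groupby(["compound_id", "target_id", "source"])["action"].nunique()
        conflicts = conflicting[conflicting > 1]
        if len(conflicts):
            raise ValidationError(
                "conflicting duplicate rows within one source: "
                + ", ".join(f"({c}, {t})" for c, t, _ in conflicts.index)
            )
    return df


def read_cti_table(path: str | Path, delimiter: str = "\t") -> pd.DataFrame:
    """Read a delimited CTI file with header compound_id, target_id, action, source, score."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=delimiter, comment="#", dtype={0: str, 1: str})
    except OSError as exc:
        raise ValidationError(f"cannot read CTI table {path}: {exc}") from exc
    if "score" not in df.columns:
        df["score"] = pd.NA
    df["score"] = pd.to_numeric(df["score"], errors="coerce")
    for col in ("compound_id", "target_id"):
        if col in df.columns:
            df[col] = df[col].astype(str).str.strip()
    return validate_table(df[COLUMNS].copy())


def write_cti_table(df: pd.DataFrame, path: str | Path, delimiter: str = "\t") -> None:
    df[COLUMNS].to_csv(path, sep=delimiter, index=False)


def filter_compounds_by_qed(compounds: Iterable[str], f: CompoundFilter) -> set[str]:
    """Compounds whose QED is at or above the threshold (inclusive boundary).

    Compounds without a QED entry are excluded and logged — a missing
    drug-likeness score cannot certify bioavailability.
    """
    compounds = set(compounds)
    no_score = {c for c in compounds if c not in f.qed_scores}
    if no_score:
        logger.info("excluding %d compound(s) with no QED score", len(no_score))
    return {
        c for c in compounds - no_score if f.qed_scores[c] >= f.qed_threshold
    }


def filter_predictions_by_score(
    t: pd.DataFrame, threshold: float = DEFAULT_SCORE_THRESHOLD
) -> pd.DataFrame:
    """Keep predicted rows with score strictly greater than the threshold.

    Validated rows always survive: the score filter encodes confidence in the
    prediction model, not in curated experiments.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValidationError(f"score threshold must be in [0, 1], got {threshold}")
    validate_table(t)
    if len(t) == 0:
        return t.copy()
    keep = (t["source"] == "validated") | (t["score"] > threshold)
    out = t[keep].reset_index(drop=True)
    logger.info(
        "score filter >%g kept %d of %d rows", threshold, len(out), len(t)
    )
    return out


def merge_validated_predicted(
    validated: pd.DataFrame, predicted: pd.DataFrame
) -> pd.DataFrame:
    """Consolidate the two sources into one row per (compound, target) pair.

    When a pair occurs in both sources the row is recorded as validated. Its
    action label is the validated one, except that a validated ``other`` is
    refined by a directional (activatory/inhibitory) predicted label: the
    experiment confirms the interaction exists, the prediction supplies its
    direction.
    """
    validate_table(validated)
    validate_table(predicted)
    if (validated["source"] != "validated").any():
        raise ValidationError("first table must contain only validated rows")
    if len(predicted) and (predicted["source"] != "predicted").any():
        raise ValidationError("second table must contain only predicted rows")

    pred_by_pair = {
        (r.compound_id, r.target_id): r
        for r in predicted.itertuples(index=False)
    }
    rows = []
    seen: set[tuple[str, str]] = set()
    for r in validated.itertuples(index=False):
        pair = (r.compound_id, r.target_id)
        seen.add(pair)
        action = r.action
        score = r.score
        if pair in pred_by_pair:
            p = pred_by_pair[pair]
            if action == "other" and p.action in ("activatory", "inhibitory"):
                action = p.action
            score = p.score if pd.isna(score) else score
        rows.append((pair[0], pair[1], action, "validated", score))
    for r in predicted.itertuples(index=False):
        pair = (r.compound_id, r.target_id)
        if pair in seen:
            continue
        seen.add(pair)
        rows.append((r.compound_id, r.target_id, r.action, "predicted", r.score))
    out = pd.DataFrame(rows, columns=COLUMNS)
    out["score"] = pd.to_numeric(out["score"], errors="coerce")
    return out


@dataclass
class NetworkStats:
    """Descriptive statistics of the bipartite compound–target network."""

    n_compounds: int
    n_targets: int
    n_nodes: int
    n_edges: int
    edges_by_action: dict[str, int]
    mean_targets_per_compound: float
    targets_per_compound: dict[str, int] = field(repr=False, default_factory=dict)

    def as_dict(self) -> dict:
        d = {
            "n_compounds": self.n_compounds,
            "n_targets": self.n_targets,
            "n_nodes": self.n_nodes,
            "n_edges": self.n_edges,
            "mean_targets_per_compound": self.mean_targets_per_compound,
        }
        d.update({f"n_{a}": self.edges_by_action.get(a, 0) for a in ACTIONS})
        return d


def network_stats(t: pd.DataFrame) -> NetworkStats:
    """Node/edge counts and the per-compound target distribution.

    The bipartite network has one node per compound and per target; every
    table row is one edge. The mean target count per compound is reported to
    one decimal place.
    """
    validate_table(t)
    n_compounds = t["compound_id"].nunique()
    n_targets = t["target_id"].nunique()
    n_edges = len(t)
    by_action = t["action"].value_counts().to_dict() if n_edges else {}
    mean_targets = round(n_edges / n_compounds, 1) if n_compounds else 0.0
    per_compound = t.groupby("compound_id").size().to_dict() if n_edges else {}
    return NetworkStats(
        n_compounds=n_compounds,
        n_targets=n_targets,
        n_nodes=n_compounds + n_targets,
        n_edges=n_edges,
        edges_by_action={a: int(by_action.get(a, 0)) for a in ACTIONS},
        mean_targets_per_compound=mean_targets,
        targets_per_compound=per_compound,
    )
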
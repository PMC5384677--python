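"""Batch application to tables of study pairs and replication-project style summaries.

Input is a delimited text table (comma or tab, sniffed) with columns
``id, r_o, n_o, r_r, n_r`` and an optional ``group`` column.  Rows whose
original study is not significant at the configured level — or that fail
basic validity (|r| >= 1, n < 4, non-numeric cells) — are collected into an
exclusion report rather than silently dropped, since the correction is
undefined for nonsignificant originals.

Aggregation mirrors how replication projects are summarized: average
posterior model probabilities per snapshot and method, the distribution of
pairs over evidence categories (single snapshots with posterior > .25 and
adjacent-pair categories when exactly two neighbouring snapshots exceed
.25), and the proportions of conclusive (some posterior > .75) versus
inconclusive pairs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

from .core import (
    HYBRID,
    NAIVE,
    PosteriorResult,
    PriorWeights,
    SignificanceRule,
    SnapshotSet,
    analyze_pair,
)
from .transforms import Study

__all__ = [
    "PairRecord",
    "Exclusion",
    "ReadResult",
    "BatchSummary",
    "read_pairs",
    "write_pairs",
    "assign_category",
    "analyze_records",
    "summarize_batch",
    "summarize_by_group",
]

REQUIRED_COLUMNS = ("id", "r_o", "n_o", "r_r", "n_r")
OTHER_CATEGORY = "other"


@dataclass(frozen=True)
class PairRecord:
    """One original/replication pair, optionally tagged with a group label."""

    id: str
    original: Study
    replication: Study
    group: str | None = None


class Exclusion(NamedTuple):
    id: str
    reason: str


class ReadResult(NamedTuple):
    """Validated records plus the per-row exclusion report."""

    records: list
    excluded: list


@dataclass(frozen=True)
class BatchSummary:
    """Aggregates over the included pairs of a batch.

    ``mean_pi``, ``conclusive_props`` and ``inconclusive_prop`` are keyed
    by method; ``category_props`` maps method -> {category label ->
    proportion}.  Category proportions and conclusive-plus-inconclusive
    proportions each sum to one over included pairs.
    """

    snapshots: SnapshotSet
    mean_pi: dict
    category_props: dict
    conclusive_props: dict
    inconclusive_prop: dict
    n_pairs: int
    n_excluded: int


def read_pairs(path, alpha: float = 0.05) -> ReadResult:
    """Read and validate a delimited table of study pairs.

    Returns the records whose original study passes the two-tailed
    Fisher-z significance screen at ``alpha``, together with an exclusion
    report for every rejected row.  Raises on structural problems (missing
    columns, empty file).
    """
    df = pd.read_csv(path, sep=None, engine="python")
    if df.empty:
        raise ValueError(f"no data rows in {path}")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing required columns {missing} in {path}")
    has_group = "group" in df.columns

    records: list[PairRecord] = []
    excluded: list[Exclusion] = []
    for idx, row in df.iterrows():
        pair_id = str(row["id"])
        try:
            vals = {c: float(row[c]) for c in ("r_o", "n_o", "r_r", "n_r")}
            if any(math.isnan(v) for v in vals.values()):
                raise ValueError("non-numeric or missing cell")
            original = Study.from_r_n(vals["r_o"], vals["n_o"])
            replication = Study.from_r_n(vals["r_r"], vals["n_r"])
        except (TypeError, ValueError) as exc:
            excluded.append(Exclusion(pair_id, f"invalid row: {exc}"))
            continue
        direction = -1 if original.theta_hat < 0 else 1
        rule = SignificanceRule(alpha=alpha, direction=direction)
        if not rule.is_significant(original):
            excluded.append(
                Exclusion(
                    pair_id,
                    f"original not significant (two-tailed Fisher-z p="
                    f"{original.p_value():.4f} >= alpha={alpha})",
                )
            )
            continue
        group = str(row["group"]) if has_group and not pd.isna(row["group"]) else None
        records.append(PairRecord(pair_id, original, replication, group))
    return ReadResult(records=records, excluded=excluded)


def write_pairs(records, path, sep: str = "\t") -> None:
    """Write records back to the delimited-table schema of :func:`read_pairs`."""
    rows = [
        {
            "id": rec.id,
            "r_o": rec.original.r,
            "n_o": rec.original.n,
            "r_r": rec.replication.r,
            "n_r": rec.replication.n,
            **({"group": rec.group} if rec.group is not None else {}),
        }
        for rec in records
    ]
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False)


def assign_category(posteriors: PosteriorResult, threshold: float = 0.25) -> str:
    """Evidence category of one pair from its posterior model probabilities.

    Exactly one snapshot above the threshold maps to that snapshot's
    correlation label; exactly two *adjacent* snapshots map to the paired
    label (e.g. ``0-0.1``); any other exceedance pattern maps to
    ``"other"``.
    """
    above = np.flatnonzero(posteriors.pi > threshold)
    rho = posteriors.snapshots.rho
    if len(above) == 1:
        return f"{rho[above[0]]:g}"
    if len(above) == 2 and above[1] == above[0] + 1:
        return f"{rho[above[0]]:g}-{rho[above[1]]:g}"
    return OTHER_CATEGORY


def category_labels(snapshots: SnapshotSet = SnapshotSet()) -> list:
    """All single and adjacent-pair category labels plus ``"other"``."""
    rho = snapshots.rho
    labels = [f"{rho[0]:g}"]
    for a, b in zip(rho, rho[1:]):
        labels.extend([f"{a:g}-{b:g}", f"{b:g}"])
    labels.append(OTHER_CATEGORY)
    return labels


def analyze_records(
    records,
    snapshots: SnapshotSet = SnapshotSet(),
    alpha: float = 0.05,
    priors: PriorWeights | None = None,
    methods: tuple = (HYBRID, NAIVE),
) -> pd.DataFrame:
    """Per-pair posterior probabilities, categories and conclusiveness flags.

    One row per record; per method, one posterior column per snapshot plus
    ``<method>_category`` and ``<method>_conclusive``.
    """
    rows = []
    for rec in records:
        row: dict = {"id": rec.id}
        if rec.group is not None:
            row["group"] = rec.group
        for m in methods:
            res = analyze_pair(
                rec.original, rec.replication, snapshots, alpha, priors, method=m
            )
            for label, p in zip(snapshots.labels, res.pi):
                row[f"{m}_pi_{label}"] = p
            row[f"{m}_category"] = assign_category(res)
            row[f"{m}_conclusive"] = bool((res.pi > 0.75).any())
        rows.append(row)
    return pd.DataFrame(rows)


def summarize_batch(
    records,
    snapshots: SnapshotSet = SnapshotSet(),
    alpha: float = 0.05,
    priors: PriorWeights | None = None,
    methods: tuple = (HYBRID, NAIVE),
    n_excluded: int = 0,
) -> BatchSummary:
    """Aggregate posterior summaries over the included pairs of a batch."""
    records = list(records)
    if not records:
        raise ValueError("cannot summarize an empty batch")
    S = len(snapshots)
    cats = category_labels(snapshots)
    mean_pi = {m: np.zeros(S) for m in methods}
    cat_counts = {m: {c: 0 for c in cats} for m in methods}
    concl = {m: np.zeros(S) for m in methods}
    inconcl = {m: 0 for m in methods}
    for rec in records:
        for m in methods:
            res = analyze_pair(
                rec.original, rec.replication, snapshots, alpha, priors, method=m
            )
            mean_pi[m] += res.pi
            cat_counts[m][assign_category(res)] += 1
            exceed = res.pi > 0.75
            if exceed.any():
                concl[m] += exceed
            else:
                inconcl[m] += 1
    k = len(records)
    return BatchSummary(
        snapshots=snapshots,
        mean_pi={m: mean_pi[m] / k for m in methods},
        category_props={
            m: {c: cat_counts[m][c] / k for c in cats} for m in methods
        },
        conclusive_props={m: concl[m] / k for m in methods},
        inconclusive_prop={m: inconcl[m] / k for m in methods},
        n_pairs=k,
        n_excluded=n_excluded,
    )


def summarize_by_group(records, **kwargs) -> dict:
    """Per-group :func:`summarize_batch`; ungrouped records fall under ``None``."""
    groups: dict = {}
    for rec in records:
        groups.setdefault(rec.group, []).append(rec)
    return {g: summarize_batch(recs, **kwargs) for g, recs in groups.items()}
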
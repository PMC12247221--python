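"""Retrieval and regression metrics for spectral-similarity predictions.

All metrics operate on a *prediction table*: one row per (query spectrum,
candidate spectrum) with the model's predicted score and the ground-truth
Tanimoto similarity of the underlying structures. Three complementary
views of performance are computed:

* **RMSE**, overall and within ground-truth similarity bins, plus a
  bin-averaged RMSE over a similarity range (the unweighted mean of the
  per-bin values, so sparse high-similarity bins are not drowned out).
* **Top Candidate Similarity** — how structurally similar the best of the
  model's top-k retrievals is to the query, compared against the
  *theoretical maximum* attainable on the same candidate set.
* **Top-Rank** — where in the predicted ordering the genuinely most
  similar structures appear: the minimum predicted rank over the true
  top-k set, where ground-truth candidates sharing one structure-level
  similarity value share a (dense) rank.

Metrics are pure functions of the table; averaging across model seeds is
the caller's concern (see :func:`aggregate_tables`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "PREDICTION_COLUMNS",
    "RankingConfig",
    "rmse",
    "binned_rmse",
    "top_candidate_similarity",
    "theoretical_maximum",
    "top_rank",
    "stratify_by_tt",
    "aggregate_tables",
]

PREDICTION_COLUMNS = [
    "query_id",
    "candidate_id",
    "predicted",
    "true_similarity",
    "query_inchikey14",
    "candidate_inchikey14",
    "mean_tt_similarity",
]


@dataclass
class RankingConfig:
    """k values to report, identical-structure exclusion, and similarity
    binning for the RMSE breakdown."""

    k_values: tuple[int, ...] = (1, 3, 10)
    exclude_identical: bool = False
    n_similarity_bins: int = 10

    def __post_init__(self):
        ks = list(self.k_values)
        if ks != sorted(ks) or any(k <= 0 for k in ks):
            raise ValueError("k_values must be positive and increasing")


def _validate(table: pd.DataFrame) -> pd.DataFrame:
    if table.empty:
        raise ValueError("empty prediction table")
    if (table["query_id"] == table["candidate_id"]).any():
        raise ValueError("prediction table contains self-pairs")
    return table


def _apply_exclusion(table: pd.DataFrame, cfg: RankingConfig) -> pd.DataFrame:
    if cfg.exclude_identical:
        return table[table["query_inchikey14"] != table["candidate_inchikey14"]]
    return table


def rmse(predicted, true) -> float:
    predicted = np.asarray(predicted, dtype=float)
    true = np.asarray(true, dtype=float)
    return float(np.sqrt(np.mean((predicted - true) ** 2)))


def _bin_index(values: np.ndarray, edges: np.ndarray) -> np.ndarray:
    idx = np.searchsorted(edges, values, side="right") - 1
    return np.clip(idx, 0, len(edges) - 2)


def binned_rmse(
    table: pd.DataFrame,
    n_bins: int = 10,
    average_above: float | None = None,
) -> tuple[pd.Series, float | None]:
    """Per-bin RMSE over ground-truth similarity, plus a bin-averaged RMSE.

    Bins are equal width on [0,1], left-inclusive, top bin closed. Empty
    bins are reported as NaN and excluded from the bin average. When
    ``average_above`` is given, the bin average covers only bins whose left
    edge is >= that value (e.g. 0.6 for the structurally related regime).
    """
    _validate(table)
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    idx = _bin_index(table["true_similarity"].to_numpy(), edges)
    per_bin = pd.Series(np.nan, index=range(n_bins), name="rmse")
    for b in range(n_bins):
        rows = idx == b
        if rows.any():
            per_bin[b] = rmse(
                table["predicted"].to_numpy()[rows],
                table["true_similarity"].to_numpy()[rows],
            )
    lo = 0 if average_above is None else int(np.searchsorted(edges, average_above))
    in_range = per_bin.iloc[lo:].dropna()
    bin_avg = float(in_range.mean()) if len(in_range) else None
    return per_bin, bin_avg


def _sorted_by_prediction(group: pd.DataFrame) -> pd.DataFrame:
    """Predicted ordering: score descending, ties broken by candidate id so
    results are reproducible."""
    return group.sort_values(
        ["predicted", "candidate_id"], ascending=[False, True], kind="mergesort"
    )


def top_candidate_similarity(
    table: pd.DataFrame, cfg: RankingConfig | None = None
) -> dict[int, float]:
    """Mean over queries of the best true similarity within the top-k
    predicted candidates.

    Queries with fewer candidates than k use all available candidates (the
    shortfall is logged). Non-decreasing in k by construction.
    """
    cfg = cfg or RankingConfig()
    table = _apply_exclusion(_validate(table), cfg)
    out: dict[int, list[float]] = {k: [] for k in cfg.k_values}
    short = 0
    for _, group in table.groupby("query_id", sort=True):
        ordered = _sorted_by_prediction(group)["true_similarity"].to_numpy()
        for k in cfg.k_values:
            if len(ordered) < k:
                short += 1
            out[k].append(float(ordered[:k].max()))
    if short:
        logger.warning("%d query/k combinations had fewer candidates than k", short)
    return {k: float(np.mean(v)) for k, v in out.items()}


def theoretical_maximum(
    table: pd.DataFrame, cfg: RankingConfig | None = None, mode: str = "best"
) -> dict[int, float]:
    """Upper bound on Top Candidate Similarity for the same candidate sets.

    ``mode="best"`` (default): mean over queries of the maximum true
    similarity among eligible candidates — the bound actually attainable
    by a perfect ranker at any k, constant in k. ``mode="kth"``: mean of
    the kth-highest true similarity per query, a per-rank variant.
    """
    cfg = cfg or RankingConfig()
    table = _apply_exclusion(_validate(table), cfg)
    out: dict[int, list[float]] = {k: [] for k in cfg.k_values}
    for _, group in table.groupby("query_id", sort=True):
        sims = np.sort(group["true_similarity"].to_numpy())[::-1]
        for k in cfg.k_values:
            if mode == "best":
                out[k].append(float(sims[0]))
            elif mode == "kth":
                out[k].append(float(sims[min(k, len(sims)) - 1]))
            else:
                raise ValueError(f"unknown mode: {mode}")
    return {k: float(np.mean(v)) for k, v in out.items()}


def _dense_structure_ranks(group: pd.DataFrame) -> pd.Series:
    """Ground-truth dense rank per row, tied at the structure level:
    candidates whose structures share a true-similarity value share one
    rank, and the next most similar structures take the next rank."""
    sims = group["true_similarity"]
    return sims.rank(method="dense", ascending=False).astype(int)


def top_rank(
    table: pd.DataFrame, cfg: RankingConfig | None = None
) -> tuple[dict[int, float], dict[int, int]]:
    """Mean over queries of the minimum predicted rank over the true top-k.

    Ground-truth candidates are dense-ranked with structure-level tie
    grouping; the true top-k set contains every candidate with ground-truth
    rank <= k. Predicted ranks are 1-based positions in the predicted
    ordering. Queries with no eligible candidate after exclusion are
    skipped; the per-k skip counts are returned alongside the metric.
    """
    cfg = cfg or RankingConfig()
    _validate(table)
    all_queries = table["query_id"].nunique()
    table = _apply_exclusion(table, cfg)
    dropped = all_queries - (table["query_id"].nunique() if not table.empty else 0)
    out: dict[int, list[float]] = {k: [] for k in cfg.k_values}
    skipped: dict[int, int] = {k: dropped for k in cfg.k_values}
    for _, group in table.groupby("query_id", sort=True):
        ordered = _sorted_by_prediction(group)
        predicted_rank = pd.Series(
            np.arange(1, len(ordered) + 1), index=ordered.index
        )
        gt_rank = _dense_structure_ranks(group)
        for k in cfg.k_values:
            true_topk = gt_rank.index[gt_rank <= k]
            if len(true_topk) == 0:
                skipped[k] += 1
                continue
            out[k].append(float(predicted_rank.loc[true_topk].min()))
    metric = {k: float(np.mean(v)) if v else float("nan") for k, v in out.items()}
    return metric, skipped


def stratify_by_tt(
    table: pd.DataFrame,
    metric,
    lo: float = 0.4,
    hi: float = 1.0,
    width: float = 0.05,
) -> dict[tuple[float, float], object]:
    """Apply a metric per train-test-similarity bin.

    Rows are partitioned by ``mean_tt_similarity`` into ``width``-wide bins
    on [lo, hi] (left-inclusive; top bin closed). ``metric`` is any callable
    taking a prediction table. Empty bins are omitted.
    """
    _validate(table)
    if table["mean_tt_similarity"].isna().any():
        raise ValueError("mean_tt_similarity missing for some rows")
    n_bins = int(round((hi - lo) / width))
    edges = np.linspace(lo, hi, n_bins + 1)
    tt = table["mean_tt_similarity"].to_numpy()
    idx = np.searchsorted(edges, tt, side="right") - 1
    idx = np.where(tt == hi, n_bins - 1, idx)
    results: dict[tuple[float, float], object] = {}
    for b in range(n_bins):
        rows = table[(idx == b) & (tt >= lo) & (tt <= hi)]
        if rows.empty:
            continue
        results[(float(edges[b]), float(edges[b + 1]))] = metric(rows)
    return results


def aggregate_tables(tables: list[pd.DataFrame], metric) -> tuple[object, object]:
    """Mean and standard deviation of a scalar-or-dict metric across
    prediction tables (e.g. one per model seed)."""
    values = [metric(t) for t in tables]
    if isinstance(values[0], dict):
        keys = values[0].keys()
        mean = {k: float(np.mean([v[k] for v in values])) for k in keys}
        sd = {k: float(np.std([v[k] for v in values], ddof=1)) if len(values) > 1 else 0.0 for k in keys}
        return mean, sd
    arr = np.asarray(values, dtype=float)
    return float(arr.mean()), float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
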
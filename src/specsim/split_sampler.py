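"""Structure-aware train/validation/test splitting with coverage auditing.

Random selection of test structures mirrors the library's similarity
distribution and under-samples the region that matters most for judging
generalization: test structures far from everything in training (low
train-test similarity) that nevertheless form highly similar test pairs.
The three-phase procedure here targets that region directly:

1. *Dissimilar seeding* — bin every structure by its maximum similarity to
   any other structure and draw up to ``data_points_per_bin`` per bin, so
   isolated structures are represented.
2. *Random-walk densification* — build a graph whose edges join structures
   with Tanimoto > ``walk_edge_threshold`` and move short random walks
   from well-connected roots into the test set, guaranteeing clusters of
   highly similar test pairs.
3. *Erosion balancing* — iteratively delete training structures that keep
   test structures' train-test similarity above an underfilled bin's upper
   bound, pushing test structures down into low-similarity bins, until all
   bins are filled or a fixed fraction of the training set has been eroded.

Train-test similarity of a structure is its maximum Tanimoto similarity to
any training structure; for a test pair it is the mean over the two
structures. The coverage grid audits the resulting ordered test pairs over
(pairwise similarity x train-test similarity) cells.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

from .chemstruct import SimilarityMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "SplitConfig",
    "SplitResult",
    "CoverageGrid",
    "train_test_similarity",
    "phase1_select_dissimilar",
    "phase2_random_walk",
    "phase3_balance_by_erosion",
    "make_split",
    "coverage_grid",
    "pair_similarity_table",
]


@dataclass
class SplitConfig:
    """Parameters of the three-phase split.

    ``n_tt_bins`` evenly spaced train-test similarity bins span
    [tt_bin_lo, tt_bin_hi] for both seeding and balancing; the audit grid
    is fixed at 0.05-wide bins. ``min_root_degree`` is exclusive: walk
    roots must have degree strictly greater than it.
    """

    data_points_per_bin: int = 8
    num_test_roots: int = 10
    tt_bin_lo: float = 0.4
    tt_bin_hi: float = 1.0
    n_tt_bins: int = 12
    walk_edge_threshold: float = 0.7
    min_root_degree: int = 3
    walk_length: int = 4
    max_train_erosion: float = 0.8
    n_validation_structures: int = 500
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.max_train_erosion < 1):
            raise ValueError("max_train_erosion must be in (0,1)")
        if self.tt_bin_lo >= self.tt_bin_hi:
            raise ValueError("tt_bin_lo must be < tt_bin_hi")

    def tt_bin_edges(self) -> np.ndarray:
        return np.linspace(self.tt_bin_lo, self.tt_bin_hi, self.n_tt_bins + 1)


@dataclass
class SplitResult:
    """Disjoint train/validation/test structure sets (inchikey14) with the
    train-test similarity of every test structure."""

    train_ids: list[str]
    val_ids: list[str]
    test_ids: list[str]
    tt_similarity: dict[str, float]
    removed_ids: list[str] = field(default_factory=list)
    # (test structure id, upper bound of the bin it was moved into) for every
    # completed phase-3 move; auditable post-condition of the balancing loop
    moves: list[tuple[str, float]] = field(default_factory=list)

    def validate(self) -> None:
        train, val, test = set(self.train_ids), set(self.val_ids), set(self.test_ids)
        if train & val or train & test or val & test:
            raise ValueError("train/val/test sets are not disjoint")
        if set(self.tt_similarity) != test:
            raise ValueError("tt_similarity keys do not match test set")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "train_ids": sorted(self.train_ids),
            "val_ids": sorted(self.val_ids),
            "test_ids": sorted(self.test_ids),
            "tt_similarity": {k: round(v, 10) for k, v in sorted(self.tt_similarity.items())},
            "removed_ids": sorted(self.removed_ids),
            "moves": [[sid, round(ub, 10)] for sid, ub in self.moves],
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "SplitResult":
        d = json.loads(Path(path).read_text())
        return cls(
            train_ids=d["train_ids"],
            val_ids=d["val_ids"],
            test_ids=d["test_ids"],
            tt_similarity=d["tt_similarity"],
            removed_ids=d.get("removed_ids", []),
            moves=[(sid, ub) for sid, ub in d.get("moves", [])],
        )


@dataclass
class CoverageGrid:
    """2-D histogram of ordered test pairs over pairwise-similarity (rows,
    10 bins on [0,1]) x train-test-similarity (columns, 12 bins on
    [0.4,1]) cells. Bins are left-inclusive; the top bin of each axis also
    includes the right edge. A cell is covered at >= ``threshold`` ordered
    pairs."""

    counts: np.ndarray
    threshold: int = 200
    pairwise_bin_edges: np.ndarray = field(
        default_factory=lambda: np.linspace(0.0, 1.0, 11)
    )
    tt_bin_edges: np.ndarray = field(default_factory=lambda: np.linspace(0.4, 1.0, 13))

    @property
    def coverage(self) -> float:
        return float((self.counts >= self.threshold).mean())

    def region_of_interest_coverage(self) -> float:
        """Coverage of the 30-cell region with train-test similarity in
        (0.55, 0.85) and pairwise similarity > 0.5 — structurally related
        molecules distant from training."""
        rows = slice(5, 10)   # pairwise bins [0.5,0.6) .. [0.9,1.0]
        cols = slice(3, 9)    # tt bins [0.55,0.6) .. [0.8,0.85)
        region = self.counts[rows, cols]
        return float((region >= self.threshold).mean())

    def summary(self) -> dict:
        return {
            "coverage": self.coverage,
            "region_of_interest_coverage": self.region_of_interest_coverage(),
            "threshold": self.threshold,
            "total_pairs": int(self.counts.sum()),
        }


def train_test_similarity(
    test_id: str, train_ids: list[str] | set[str], matrix: SimilarityMatrix
) -> float:
    """Maximum Tanimoto similarity between a test structure and any
    training structure; 0.0 for an empty training set."""
    train_ids = list(train_ids)
    if not train_ids:
        return 0.0
    row = matrix.index_of(test_id)
    cols = [matrix.index_of(t) for t in train_ids]
    return float(matrix.values[row, cols].max())


def _max_similarity_to_others(matrix: SimilarityMatrix) -> np.ndarray:
    v = matrix.values.copy()
    np.fill_diagonal(v, -np.inf)
    if v.shape[0] == 1:
        return np.zeros(1)
    return v.max(axis=1)


def _bin_index(value: float, edges: np.ndarray) -> int | None:
    """Left-inclusive bin index; the top bin also includes the right edge.
    None for values outside [edges[0], edges[-1]]."""
    if value < edges[0] or value > edges[-1]:
        return None
    idx = int(np.searchsorted(edges, value, side="right")) - 1
    return min(idx, len(edges) - 2)


def phase1_select_dissimilar(matrix: SimilarityMatrix, cfg: SplitConfig) -> set[str]:
    """Seed the test set with structures spread over the similarity bins.

    Each structure is binned by its maximum similarity to any *other*
    structure; up to ``data_points_per_bin`` structures are drawn uniformly
    at random from each bin. Structures whose maximum similarity falls
    below ``tt_bin_lo`` are pooled into one underflow bin so the most
    isolated structures are always eligible.
    """
    if cfg.data_points_per_bin <= 0:
        return set()
    rng = np.random.default_rng(cfg.seed)
    edges = cfg.tt_bin_edges()
    max_sim = _max_similarity_to_others(matrix)
    bins: dict[int, list[str]] = {}
    for sid, v in zip(matrix.structure_ids, max_sim):
        idx = _bin_index(float(v), edges)
        key = -1 if idx is None and v < edges[0] else idx
        if key is None:
            continue
        bins.setdefault(key, []).append(sid)
    selected: set[str] = set()
    for key in sorted(bins):
        members = sorted(bins[key])
        take = min(cfg.data_points_per_bin, len(members))
        chosen = rng.choice(len(members), size=take, replace=False)
        selected.update(members[i] for i in chosen)
    return selected


def phase2_random_walk(matrix: SimilarityMatrix, cfg: SplitConfig) -> set[str]:
    """Move clusters of highly similar structures into the test set.

    A graph joins structures with similarity strictly above
    ``walk_edge_threshold``; ``num_test_roots`` roots are drawn without
    replacement among nodes of degree strictly greater than
    ``min_root_degree``, and each root contributes itself plus every node
    visited on a ``walk_length``-step uniform random walk.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    n = len(matrix.structure_ids)
    graph = nx.Graph()
    graph.add_nodes_from(matrix.structure_ids)
    upper = np.triu(matrix.values > cfg.walk_edge_threshold, k=1)
    for i, j in zip(*np.nonzero(upper)):
        graph.add_edge(matrix.structure_ids[i], matrix.structure_ids[j])
    eligible = sorted(nd for nd in graph if graph.degree(nd) > cfg.min_root_degree)
    if not eligible:
        return set()
    n_roots = min(cfg.num_test_roots, len(eligible))
    if n_roots < cfg.num_test_roots:
        logger.warning(
            "only %d eligible walk roots (requested %d)", len(eligible), cfg.num_test_roots
        )
    roots = [eligible[i] for i in rng.choice(len(eligible), size=n_roots, replace=False)]
    visited: set[str] = set(roots)
    for root in roots:
        node = root
        for _ in range(cfg.walk_length):
            nbrs = sorted(graph.neighbors(node))
            if not nbrs:
                break
            node = nbrs[rng.integers(len(nbrs))]
            visited.add(node)
    return visited


def _tt_vector(
    matrix: SimilarityMatrix, test_ids: list[str], train_ids: list[str]
) -> np.ndarray:
    if not train_ids:
        return np.zeros(len(test_ids))
    rows = [matrix.index_of(t) for t in test_ids]
    cols = [matrix.index_of(t) for t in train_ids]
    return matrix.values[np.ix_(rows, cols)].max(axis=1)


def phase3_balance_by_erosion(
    train: set[str], test: set[str], matrix: SimilarityMatrix, cfg: SplitConfig
) -> SplitResult:
    """Erode the training set until the train-test similarity bins fill up.

    Test structures are binned by train-test similarity into the
    ``n_tt_bins`` bins. Starting from the lowest underfilled bin, its
    deficit is drawn from the next non-empty bin above (continuing upward
    if that bin is too small); for each drawn structure, every training
    structure with similarity strictly above the underfilled bin's upper
    bound is removed, which pushes the drawn structure's train-test
    similarity to (at most) that bound. The loop stops when every bin holds
    ``data_points_per_bin`` structures or when the erosion cap
    (``max_train_erosion`` of the original training set) is reached.

    The validation set is drawn uniformly from the surviving training pool
    at the end.
    """
    rng = np.random.default_rng(cfg.seed + 2)
    train = set(train) - set(test)
    test_ids = sorted(test)
    train_ids = sorted(train)
    original_train_size = len(train_ids)
    max_removals = int(np.floor(cfg.max_train_erosion * original_train_size))
    removed: list[str] = []
    moves: list[tuple[str, float]] = []
    edges = cfg.tt_bin_edges()
    n_bins = cfg.n_tt_bins

    def current_bins() -> list[list[str]]:
        tt = _tt_vector(matrix, test_ids, train_ids)
        out: list[list[str]] = [[] for _ in range(n_bins)]
        for sid, v in zip(test_ids, tt):
            idx = _bin_index(float(v), edges)
            if idx is not None:
                out[idx].append(sid)
        return out

    while len(removed) < max_removals:
        bins = current_bins()
        deficits = [max(0, cfg.data_points_per_bin - len(b)) for b in bins]
        target_bin = next((i for i, d in enumerate(deficits) if d > 0), None)
        if target_bin is None:
            break  # all bins full
        # candidates: structures in the next non-empty bins above the target
        donors: list[str] = []
        need = deficits[target_bin]
        for j in range(target_bin + 1, n_bins):
            if bins[j]:
                pool = sorted(bins[j])
                take = min(need - len(donors), len(pool))
                idx = rng.choice(len(pool), size=take, replace=False)
                donors.extend(pool[i] for i in idx)
                if len(donors) >= need:
                    break
        if not donors:
            break  # nothing left to move down
        upper = float(edges[target_bin + 1])
        progressed = False
        for sid in donors:
            row = matrix.index_of(sid)
            to_remove = [
                t for t in train_ids if matrix.values[row, matrix.index_of(t)] > upper
            ]
            if not to_remove:
                continue
            budget = max_removals - len(removed)
            if budget <= 0:
                break
            truncated = len(to_remove) > budget
            if truncated:
                to_remove = to_remove[:budget]
            train_ids = [t for t in train_ids if t not in set(to_remove)]
            removed.extend(to_remove)
            if not truncated:
                moves.append((sid, upper))
            progressed = True
        if not progressed:
            break  # donors cannot be lowered further; avoid spinning

    if len(removed) > max_removals:  # defensive; budget logic above prevents this
        raise AssertionError("erosion cap exceeded")

    # validation set drawn uniformly from the surviving train pool
    n_val = min(cfg.n_validation_structures, len(train_ids))
    val_idx = rng.choice(len(train_ids), size=n_val, replace=False)
    val_set = {train_ids[i] for i in val_idx}
    final_train = [t for t in train_ids if t not in val_set]
    tt = _tt_vector(matrix, test_ids, final_train)
    result = SplitResult(
        train_ids=final_train,
        val_ids=sorted(val_set),
        test_ids=test_ids,
        tt_similarity={sid: float(v) for sid, v in zip(test_ids, tt)},
        removed_ids=removed,
        moves=moves,
    )
    result.validate()
    return result


def make_split(matrix: SimilarityMatrix, cfg: SplitConfig) -> SplitResult:
    """Run all three phases on a similarity matrix of unique structures."""
    test = phase1_select_dissimilar(matrix, cfg) | phase2_random_walk(matrix, cfg)
    train = set(matrix.structure_ids) - test
    return phase3_balance_by_erosion(train, test, matrix, cfg)


def pair_similarity_table(
    split: SplitResult, matrix: SimilarityMatrix
) -> tuple[np.ndarray, np.ndarray]:
    """All ordered test-structure pairs as (pairwise similarity, mean
    train-test similarity) arrays — the audit grid's input."""
    ids = [t for t in split.test_ids if t in matrix]
    idx = np.array([matrix.index_of(t) for t in ids])
    tt = np.array([split.tt_similarity[t] for t in ids])
    sims = matrix.values[np.ix_(idx, idx)]
    n = len(ids)
    mask = ~np.eye(n, dtype=bool)  # ordered pairs, no self-pairs
    pairwise = sims[mask]
    mean_tt = ((tt[:, None] + tt[None, :]) / 2.0)[mask]
    return pairwise, mean_tt


def coverage_grid(
    pairwise: np.ndarray,
    mean_tt: np.ndarray,
    threshold: int = 200,
    weights: np.ndarray | None = None,
) -> CoverageGrid:
    """Bin ordered test pairs into the 10x12 audit grid.

    Rows: pairwise similarity, 0.1-wide bins on [0,1]. Columns: mean
    train-test similarity, 0.05-wide bins on [0.4,1]. Left-inclusive bins;
    each axis' top bin also includes the right edge. Pairs with mean
    train-test similarity below 0.4 fall outside the grid and are not
    counted. ``weights`` lets a caller count spectrum-pair multiplicities
    for structure-level input.
    """
    pw_edges = np.linspace(0.0, 1.0, 11)
    tt_edges = np.linspace(0.4, 1.0, 13)
    counts = np.zeros((10, 12))
    pairwise = np.asarray(pairwise, dtype=float)
    mean_tt = np.asarray(mean_tt, dtype=float)
    w = np.ones_like(pairwise) if weights is None else np.asarray(weights, dtype=float)
    for p, t, wt in zip(pairwise, mean_tt, w):
        i = _bin_index(p, pw_edges)
        j = _bin_index(t, tt_edges)
        if i is None or j is None:
            continue
        counts[i, j] += wt
    return CoverageGrid(counts=counts, threshold=threshold)
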
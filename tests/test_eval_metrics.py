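import numpy as np
import pandas as pd
import pytest

from specsim.eval_metrics import (
    RankingConfig,
    aggregate_tables,
    binned_rmse,
    rmse,
    stratify_by_tt,
    theoretical_maximum,
    top_candidate_similarity,
    top_rank,
)


def make_table(queries, seed=0, n_candidates=50, predictor="random", tie_sims=False):
    """Prediction table with distinct (or optionally tied) true similarities."""
    rng = np.random.default_rng(seed)
    rows = []
    for q in range(queries):
        true = np.round(np.linspace(0.98, 0.02, n_candidates), 4)
        if tie_sims:
            true[1] = true[0]  # two structures tied at the top
            true[5] = true[4]
        if predictor == "oracle":
            pred = true.copy()
        elif predictor == "anti":
            pred = 1 - true
        else:
            pred = rng.uniform(0, 1, n_candidates)
        for c in range(n_candidates):
            rows.append(
                {
                    "query_id": f"q{q:02d}",
                    "candidate_id": f"q{q:02d}_c{c:02d}",
                    "predicted": pred[c],
                    "true_similarity": true[c],
                    "query_inchikey14": f"QK{q:02d}",
                    "candidate_inchikey14": f"CK{q:02d}_{c:02d}",
                    "mean_tt_similarity": rng.uniform(0.4, 1.0),
                }
            )
    return pd.DataFrame(rows)


def worked_example_table():
    """Single query whose true top-3 candidates sit at predicted ranks
    21, 42 and 13."""
    n = 50
    true = np.linspace(0.99, 0.01, n)
    assigned = {0: 21, 1: 42, 2: 13}
    rest = iter(r for r in range(1, n + 1) if r not in assigned.values())
    ranks = [assigned.get(i) or next(rest) for i in range(n)]
    return pd.DataFrame(
        {
            "query_id": "q",
            "candidate_id": [f"c{i:02d}" for i in range(n)],
            "predicted": [1.0 - r / 100 for r in ranks],
            "true_similarity": true,
            "query_inchikey14": "QK",
            "candidate_inchikey14": [f"CK{i:02d}" for i in range(n)],
            "mean_tt_similarity": 0.7,
        }
    )


class TestRmse:
    def test_perfect_predictions(self):
        t = make_table(2, predictor="oracle")
        per_bin, avg = binned_rmse(t)
        assert rmse(t["predicted"], t["true_similarity"]) == 0.0
        assert all(v == 0.0 for v in per_bin.dropna())

    def test_constant_error(self):
        t = make_table(2, predictor="oracle")
        t["predicted"] = t["true_similarity"] + 0.1
        per_bin, avg = binned_rmse(t)
        assert all(v == pytest.approx(0.1) for v in per_bin.dropna())
        assert avg == pytest.approx(0.1)

    def test_hand_computed_three_rows(self):
        pred, true = [0.5, 0.7, 0.2], [0.6, 0.6, 0.1]
        expected = np.sqrt((0.01 + 0.01 + 0.01) / 3)
        assert rmse(pred, true) == pytest.approx(expected)

    def test_bin_average_over_range(self):
        # rows only in bins [0.0,0.1) and [0.9,1.0]; averaging above 0.6
        # must use only the top bin
        t = pd.DataFrame(
            {
                "query_id": ["q"] * 4,
                "candidate_id": list("abcd"),
                "predicted": [0.0, 0.05, 0.8, 0.9],
                "true_similarity": [0.05, 0.05, 0.95, 0.95],
                "query_inchikey14": "QK",
                "candidate_inchikey14": list("wxyz"),
                "mean_tt_similarity": 0.5,
            }
        )
        per_bin, avg = binned_rmse(t, average_above=0.6)
        assert np.isnan(per_bin[5])  # empty bin reported missing
        assert avg == pytest.approx(rmse([0.8, 0.9], [0.95, 0.95]))


class TestTopCandidateSimilarity:
    def test_oracle_attains_theoretical_maximum(self):
        t = make_table(4, predictor="oracle")
        cfg = RankingConfig()
        tcs = top_candidate_similarity(t, cfg)
        theo = theoretical_maximum(t, cfg)
        for k in cfg.k_values:
            assert tcs[k] == pytest.approx(theo[k])

    def test_k_covering_all_candidates_predictor_independent(self):
        cfg = RankingConfig(k_values=(50,))
        a = top_candidate_similarity(make_table(3, seed=1), cfg)
        b = top_candidate_similarity(make_table(3, seed=2), cfg)
        assert a[50] == pytest.approx(b[50])

    def test_matches_brute_force(self):
        t = make_table(4, seed=3)
        cfg = RankingConfig(k_values=(1, 3, 10))
        got = top_candidate_similarity(t, cfg)
        for k in cfg.k_values:
            vals = []
            for q, g in t.groupby("query_id"):
                g = g.sort_values(["predicted", "candidate_id"], ascending=[False, True])
                vals.append(g["true_similarity"].head(k).max())
            assert got[k] == pytest.approx(np.mean(vals))

    def test_non_decreasing_in_k(self):
        got = top_candidate_similarity(make_table(5, seed=4))
        vals = [got[k] for k in sorted(got)]
        assert vals == sorted(vals)

    def test_row_order_invariance(self):
        t = make_table(3, seed=5)
        shuffled = t.sample(frac=1.0, random_state=9).reset_index(drop=True)
        assert top_candidate_similarity(t) == top_candidate_similarity(shuffled)


class TestTheoreticalMaximum:
    def test_identical_structure_contributes_one_until_excluded(self):
        t = make_table(1, seed=6)
        # plant a candidate with the query's own structure at similarity 1.0
        t.loc[0, "candidate_inchikey14"] = "QK00"
        t.loc[0, "true_similarity"] = 1.0
        incl = theoretical_maximum(t, RankingConfig())
        excl = theoretical_maximum(t, RankingConfig(exclude_identical=True))
        assert incl[1] == pytest.approx(1.0)
        assert excl[1] < 1.0

    def test_kth_mode_matches_sorted_oracle(self):
        t = make_table(3, seed=7)
        got = theoretical_maximum(t, RankingConfig(k_values=(1, 3)), mode="kth")
        for k in (1, 3):
            vals = [
                np.sort(g["true_similarity"].to_numpy())[::-1][k - 1]
                for _, g in t.groupby("query_id")
            ]
            assert got[k] == pytest.approx(np.mean(vals))

    def test_upper_bounds_top_candidate_similarity(self):
        t = make_table(5, seed=8)
        cfg = RankingConfig()
        tcs = top_candidate_similarity(t, cfg)
        theo = theoretical_maximum(t, cfg)
        for k in cfg.k_values:
            assert tcs[k] <= theo[k] + 1e-12


class TestTopRank:
    def test_worked_example_reports_13(self):
        metric, _ = top_rank(worked_example_table(), RankingConfig(k_values=(3,)))
        assert metric[3] == 13.0

    def test_oracle_rank_one_at_every_k(self):
        metric, _ = top_rank(make_table(4, predictor="oracle"))
        assert all(v == 1.0 for v in metric.values())

    def test_non_increasing_in_k(self):
        metric, _ = top_rank(make_table(5, seed=10))
        vals = [metric[k] for k in sorted(metric)]
        assert vals == sorted(vals, reverse=True)

    def test_ties_share_a_dense_rank(self):
        # two structures tied at the top similarity: both belong to the true
        # top-1 set, so the metric takes the better of their predicted ranks
        t = make_table(1, seed=11, tie_sims=True)
        ordered = t.sort_values(["predicted", "candidate_id"], ascending=[False, True])
        pred_rank = {cid: r + 1 for r, cid in enumerate(ordered["candidate_id"])}
        top_sim = t["true_similarity"].max()
        tied = t[t["true_similarity"] == top_sim]["candidate_id"]
        expected = min(pred_rank[c] for c in tied)
        metric, _ = top_rank(t, RankingConfig(k_values=(1,)))
        assert metric[1] == expected

    def test_matches_brute_force_dense_ranking(self):
        t = make_table(6, seed=12, tie_sims=True)
        cfg = RankingConfig(k_values=(1, 3, 10))
        got, _ = top_rank(t, cfg)
        for k in cfg.k_values:
            vals = []
            for q, g in t.groupby("query_id"):
                ordered = g.sort_values(
                    ["predicted", "candidate_id"], ascending=[False, True]
                )
                pred_rank = {c: r + 1 for r, c in enumerate(ordered["candidate_id"])}
                uniq = sorted(set(g["true_similarity"]), reverse=True)
                dense = {s: r + 1 for r, s in enumerate(uniq)}
                topk = g[g["true_similarity"].map(dense) <= k]["candidate_id"]
                vals.append(min(pred_rank[c] for c in topk))
            assert got[k] == pytest.approx(np.mean(vals))

    def test_query_skipped_when_all_candidates_excluded(self):
        t = make_table(2, seed=13)
        t.loc[t["query_id"] == "q00", "candidate_inchikey14"] = "QK00"
        metric, skipped = top_rank(t, RankingConfig(exclude_identical=True))
        assert skipped[1] == 1

    def test_self_pairs_rejected(self):
        t = make_table(1, seed=14)
        t.loc[0, "candidate_id"] = t.loc[0, "query_id"]
        with pytest.raises(ValueError):
            top_rank(t)


class TestStratification:
    def test_single_bin_equals_global(self):
        t = make_table(3, seed=15)
        t["mean_tt_similarity"] = 0.62
        metric = lambda tab: rmse(tab["predicted"], tab["true_similarity"])
        strat = stratify_by_tt(t, metric)
        assert list(strat) == [(pytest.approx(0.6), pytest.approx(0.65))]
        assert next(iter(strat.values())) == pytest.approx(metric(t))

    def test_two_bin_partition_recomputation(self):
        t = make_table(4, seed=16)
        t["mean_tt_similarity"] = np.where(
            np.arange(len(t)) % 2 == 0, 0.45, 0.95
        )
        metric = lambda tab: rmse(tab["predicted"], tab["true_similarity"])
        strat = stratify_by_tt(t, metric)
        assert len(strat) == 2
        for (lo, hi), v in strat.items():
            part = t[(t["mean_tt_similarity"] >= lo) & (t["mean_tt_similarity"] < hi + 1e-12)]
            assert v == pytest.approx(metric(part))

    def test_tt_exactly_one_lands_in_top_bin(self):
        t = make_table(1, seed=17)
        t["mean_tt_similarity"] = 1.0
        strat = stratify_by_tt(t, len)
        assert list(strat) == [(pytest.approx(0.95), pytest.approx(1.0))]


class TestAggregation:
    def test_mean_and_sd_across_seeds(self):
        tables = [make_table(2, seed=s) for s in (1, 2, 3)]
        mean, sd = aggregate_tables(
            tables, lambda t: rmse(t["predicted"], t["true_similarity"])
        )
        singles = [rmse(t["predicted"], t["true_similarity"]) for t in tables]
        assert mean == pytest.approx(np.mean(singles))
        assert sd == pytest.approx(np.std(singles, ddof=1))
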
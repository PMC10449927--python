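"""Unit and property tests for outlier exclusion, sampling and matching."""

import numpy as np
import pandas as pd
import pytest

from tests.conftest import make_subjects
from tivbias.config import MatchingConfig
from tivbias.matching import (
    balance_report,
    draw_disjoint_samples,
    exclude_tiv_outliers,
    match_pairs,
    split_train_holdout,
)


def subjects_from_rows(rows):
    df = pd.DataFrame(rows, columns=["id", "site", "sex", "age", "tiv"])
    df["gender_group"] = np.where(df["sex"] == "F", "CW", "CM")
    df["total_gmv"] = 600.0
    return df


class TestOutlierExclusion:
    def test_planted_outlier_removed(self):
        rng = np.random.default_rng(0)
        subjects = make_subjects(n_per_sex=50, seed=0).iloc[:99].copy()
        pool_mean, pool_sd = subjects["tiv"].mean(), subjects["tiv"].std(ddof=1)
        plant = subjects.iloc[0].copy()
        plant["id"], plant["tiv"] = "plant", pool_mean + 10 * pool_sd
        subjects = pd.concat([subjects, plant.to_frame().T], ignore_index=True)
        subjects["tiv"] = subjects["tiv"].astype(float)
        kept, n_removed = exclude_tiv_outliers(subjects, 3.0)
        assert n_removed == 1
        assert "plant" not in set(kept["id"])

    def test_identical_tiv_removes_none(self):
        subjects = make_subjects(n_per_sex=10, seed=1)
        subjects["tiv"] = 1400.0
        with pytest.warns(UserWarning, match="zero-variance"):
            kept, n_removed = exclude_tiv_outliers(subjects, 3.0)
        assert n_removed == 0 and len(kept) == len(subjects)

    def test_known_outlier_count_reduces_n(self):
        # construct a pool in which exactly 16 subjects sit far outside
        rng = np.random.default_rng(2)
        n = 5557
        tiv = rng.normal(1450.0, 100.0, n)
        tiv[:16] = 5000.0  # far beyond 3 pooled SDs even after inflation
        subjects = make_subjects(n_per_sex=1, seed=0).iloc[0:0]
        subjects = pd.DataFrame(
            {
                "id": [f"p{i}" for i in range(n)],
                "site": "siteA",
                "sex": "F",
                "gender_group": "CW",
                "age": 30.0,
                "tiv": tiv,
                "total_gmv": 600.0,
            }
        )
        kept, n_removed = exclude_tiv_outliers(subjects, 3.0)
        assert n_removed == 16
        assert len(kept) == n - 16


class TestDisjointSamples:
    def test_disjoint_and_quota_met(self):
        subjects = make_subjects(n_per_sex=45, sites=("siteA", "siteB", "siteC"), seed=3)
        quotas = {"siteA": 10, "siteB": 10, "siteC": 10}
        s1, s2 = draw_disjoint_samples(subjects, quotas, 2, seed=1)
        assert not set(s1["id"]) & set(s2["id"])
        for s in (s1, s2):
            assert s["site"].value_counts().to_dict() == quotas

    def test_infeasible_quota_names_site(self):
        subjects = make_subjects(n_per_sex=10, sites=("siteA",), seed=4)
        with pytest.raises(ValueError, match="siteA"):
            draw_disjoint_samples(subjects, {"siteA": 15}, 2, seed=1)

    def test_same_seed_same_membership(self):
        subjects = make_subjects(n_per_sex=30, sites=("siteA", "siteB"), seed=5)
        a = draw_disjoint_samples(subjects, {"siteA": 8, "siteB": 8}, 2, seed=9)
        b = draw_disjoint_samples(subjects, {"siteA": 8, "siteB": 8}, 2, seed=9)
        for x, y in zip(a, b):
            assert set(x["id"]) == set(y["id"])


class TestMatchPairs:
    def test_three_percent_rule_boundary(self):
        cfg = MatchingConfig(match_on_tiv=True)
        # 41/1400 = 2.93% <= 3% -> pair
        subjects = subjects_from_rows(
            [("w1", "A", "F", 30.0, 1400.0), ("m1", "A", "M", 30.0, 1441.0)]
        )
        assert match_pairs(subjects, cfg).n_pairs == 1
        # 50/1400 = 3.57% > 3% -> no pair
        subjects = subjects_from_rows(
            [("w1", "A", "F", 30.0, 1400.0), ("m1", "A", "M", 30.0, 1450.0)]
        )
        assert match_pairs(subjects, cfg).n_pairs == 0

    def test_age_tolerance_enforced(self):
        cfg = MatchingConfig(match_on_tiv=False)
        subjects = subjects_from_rows(
            [("w1", "A", "F", 30.0, 1400.0), ("m1", "A", "M", 32.0, 1400.0)]
        )
        assert match_pairs(subjects, cfg).n_pairs == 0

    def test_pairs_share_site(self):
        cfg = MatchingConfig(match_on_tiv=False)
        subjects = subjects_from_rows(
            [("w1", "A", "F", 30.0, 1400.0), ("m1", "B", "M", 30.0, 1400.0)]
        )
        assert match_pairs(subjects, cfg).n_pairs == 0

    def test_emitted_pairs_satisfy_tolerances(self, matching_config):
        subjects = make_subjects(n_per_sex=150, sites=("siteA", "siteB"), seed=6)
        for tiv_flag in (False, True):
            cfg = MatchingConfig(match_on_tiv=tiv_flag)
            matched = match_pairs(subjects, cfg)
            matched.validate()  # hard re-check
            assert (matched.pairs["age_diff"] <= cfg.age_tol + 1e-12).all()
            if tiv_flag:
                assert (matched.pairs["tiv_diff_frac"] <= cfg.tiv_tol_frac + 1e-12).all()

    def test_invariant_under_row_permutation(self):
        subjects = make_subjects(n_per_sex=60, sites=("siteA", "siteB"), seed=7)
        cfg = MatchingConfig(match_on_tiv=True)
        base = match_pairs(subjects, cfg)
        rng = np.random.default_rng(1)
        shuffled = subjects.iloc[rng.permutation(len(subjects))].reset_index(drop=True)
        perm = match_pairs(shuffled, cfg)
        key = lambda m: set(map(tuple, m.pairs[["woman_id", "man_id"]].to_numpy()))
        assert key(base) == key(perm)

    def test_greedy_equals_bruteforce_on_unique_perfect_matching(self):
        import networkx as nx

        # chain construction: women ages 1..k, men ages 2..k+1, tol=1 gives a
        # unique perfect matching (w_i - m_i) with extra distractor edges
        for k in (3, 5, 8):
            rows = [(f"w{i}", "A", "F", float(i), 1400.0) for i in range(1, k + 1)]
            rows += [(f"m{i}", "A", "M", float(i + 1), 1400.0) for i in range(1, k + 1)]
            subjects = subjects_from_rows(rows)
            cfg = MatchingConfig(match_on_tiv=False)
            matched = match_pairs(subjects, cfg)
            g = nx.Graph()
            for i in range(1, k + 1):
                for j in range(1, k + 1):
                    if abs(i - (j + 1)) <= 1:
                        g.add_edge(f"w{i}", f"m{j}")
            mx = nx.algorithms.matching.max_weight_matching(g, maxcardinality=True)
            assert matched.n_pairs == len(mx) == k
            assert set(map(tuple, matched.pairs[["woman_id", "man_id"]].to_numpy())) == {
                (f"w{i}", f"m{i}") for i in range(1, k + 1)
            }

    def test_greedy_near_optimal_on_random_small_instances(self):
        import networkx as nx

        rng = np.random.default_rng(11)
        greedy_total = optimal_total = 0
        for _ in range(200):
            nw, nm = rng.integers(2, 9, 2)
            rows = [(f"w{i}", "A", "F", float(rng.uniform(20, 30)), float(rng.normal(1400, 60)))
                    for i in range(nw)]
            rows += [(f"m{i}", "A", "M", float(rng.uniform(20, 30)), float(rng.normal(1450, 60)))
                     for i in range(nm)]
            subjects = subjects_from_rows(rows)
            cfg = MatchingConfig(match_on_tiv=True, age_tol=1.0, tiv_tol_frac=0.03)
            matched = match_pairs(subjects, cfg)
            g = nx.Graph()
            women = subjects[subjects.sex == "F"]
            men = subjects[subjects.sex == "M"]
            for w in women.itertuples():
                for m in men.itertuples():
                    if abs(w.age - m.age) <= 1.0 and abs(w.tiv - m.tiv) <= 0.03 * w.tiv:
                        g.add_edge(w.id, m.id)
            mx = nx.algorithms.matching.max_weight_matching(g, maxcardinality=True)
            greedy_total += matched.n_pairs
            optimal_total += len(mx)
            assert matched.n_pairs <= len(mx)
        assert greedy_total >= 0.9 * optimal_total


class TestSplit:
    def test_published_protocol_split_counts(self):
        pairs = pd.DataFrame(
            {
                "woman_id": [f"w{i}" for i in range(807)],
                "man_id": [f"m{i}" for i in range(807)],
                "site": "siteA",
                "age_diff": 0.0,
                "tiv_diff_frac": 0.0,
                "role": "",
            }
        )
        from tivbias.matching import MatchedSample

        subjects = pd.DataFrame(
            {
                "id": list(pairs["woman_id"]) + list(pairs["man_id"]),
                "site": "siteA",
                "sex": ["F"] * 807 + ["M"] * 807,
                "gender_group": ["CW"] * 807 + ["CM"] * 807,
                "age": 30.0,
                "tiv": 1400.0,
                "total_gmv": 600.0,
            }
        )
        matched = MatchedSample(pairs=pairs, subjects=subjects)
        split = split_train_holdout(matched, 0.2, seed=0)
        holdout = split.subject_subset("holdout")
        assert len(holdout) == 322
        assert (holdout["sex"] == "F").sum() == 161
        train = split.subject_subset("train")
        assert len(train) == 1292 and (train["sex"] == "F").sum() == 646

    def test_small_split_rounding(self):
        subjects = make_subjects(n_per_sex=40, seed=8, sites=("siteA",))
        matched = match_pairs(subjects, MatchingConfig())
        assert matched.n_pairs >= 5
        matched.pairs = matched.pairs.iloc[:5].reset_index(drop=True)
        split = split_train_holdout(matched, 0.2, seed=1)
        assert (split.pairs["role"] == "holdout").sum() == 1

    def test_partition_contract(self):
        subjects = make_subjects(n_per_sex=60, seed=9, sites=("siteA",))
        matched = match_pairs(subjects, MatchingConfig())
        split = split_train_holdout(matched, 0.2, seed=2)
        train, hold = set(split.ids("train")), set(split.ids("holdout"))
        assert not train & hold
        assert train | hold == set(split.ids())
        # no pair straddles partitions: roles are assigned per pair row
        assert set(split.pairs["role"]) == {"train", "holdout"}

    def test_degenerate_fraction_rejected(self):
        subjects = make_subjects(n_per_sex=40, seed=8, sites=("siteA",))
        matched = match_pairs(subjects, MatchingConfig())
        with pytest.raises(ValueError):
            split_train_holdout(matched, 0.001, seed=0)


class TestBalanceReport:
    def test_identical_covariates_give_null(self):
        rows = [(f"w{i}", "A", "F", 30.0 + i, 1400.0 + i) for i in range(10)]
        rows += [(f"m{i}", "A", "M", 30.0 + i, 1400.0 + i) for i in range(10)]
        subjects = subjects_from_rows(rows)
        matched = match_pairs(subjects, MatchingConfig())
        rep = balance_report(matched)
        row = rep[(rep.covariate == "age") & (rep.comparison == "F_vs_M_all")].iloc[0]
        assert row["t"] == pytest.approx(0.0, abs=1e-12)
        assert row["p"] == pytest.approx(1.0)

    def test_atm_matched_sample_balances_tiv(self):
        """Age+TIV matching should leave no detectable TIV difference."""
        nonsig = 0
        n_seeds = 20
        for seed in range(n_seeds):
            subjects = make_subjects(
                n_per_sex=900, sites=("siteA", "siteB"), seed=seed, tiv_sd=120.0
            )
            matched = match_pairs(subjects, MatchingConfig(match_on_tiv=True))
            assert matched.n_pairs >= 100
            rep = balance_report(matched)
            row = rep[(rep.covariate == "tiv") & (rep.comparison == "F_vs_M_all")].iloc[0]
            nonsig += not row["significant"]
        assert nonsig >= 0.95 * n_seeds
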
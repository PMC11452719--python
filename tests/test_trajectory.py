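"""Pseudotime rescaling, pattern clustering, target correlation, novel
filter."""

import numpy as np
import pandas as pd
import pytest

from sncatlas.simulate import (make_pattern_profiles, novel_candidate_grid,
                               simulate_pseudobulk_pairs,
                               simulate_trajectory_data)
from sncatlas.trajectory import (binned_profiles, cluster_patterns,
                                 correlate_targets, filter_novel,
                                 novel_criteria, pseudobulk,
                                 rescale_pseudotime,
                                 select_trajectory_mirnas)

from oracles import oracle_pearson_onesided


def _table(rows):
    return pd.DataFrame(rows, columns=["cell", "lineage", "pseudotime"])


def test_rescale_worked_example():
    """pre_max=2, TE_max=6, ICM_max=4: scale=2 and Psd=3 maps to 4."""
    tab = _table([("a", "pre-lineage", 2.0), ("b", "TE", 6.0),
                  ("c", "ICM", 4.0), ("d", "ICM", 3.0)])
    alignment, out = rescale_pseudotime(tab)
    assert alignment.scale_factor == 2.0
    got = out.set_index("cell")["pseudotime_rescaled"]
    assert got["d"] == 4.0
    assert got["c"] == 6.0          # ICM maximum lands on TE maximum
    assert got["a"] == 2.0 and got["b"] == 6.0


def test_rescale_identity_when_maxima_agree():
    tab = _table([("a", "pre-lineage", 2.0), ("b", "TE", 5.0),
                  ("c", "ICM", 5.0), ("d", "ICM", 3.5)])
    alignment, out = rescale_pseudotime(tab)
    assert alignment.scale_factor == 1.0
    assert (out["pseudotime_rescaled"] == out["pseudotime"]).all()


def test_rescale_degenerate_denominator():
    tab = _table([("a", "pre-lineage", 4.0), ("b", "TE", 6.0),
                  ("c", "ICM", 4.0)])
    with pytest.raises(ValueError, match="exceed"):
        rescale_pseudotime(tab)


def test_rescale_requires_all_lineages():
    tab = _table([("a", "pre-lineage", 1.0), ("c", "ICM", 4.0)])
    with pytest.raises(ValueError, match="TE"):
        rescale_pseudotime(tab)


def test_rescale_randomised_identities():
    rng = np.random.default_rng(0)
    for _ in range(200):
        pre = rng.uniform(1, 5)
        icm = pre + rng.uniform(0.5, 5)
        te = pre + rng.uniform(0.5, 5)
        tab = _table([("p", "pre-lineage", pre), ("t", "TE", te),
                      ("i", "ICM", icm),
                      ("j", "ICM", rng.uniform(pre, icm))])
        _, out = rescale_pseudotime(tab)
        got = out.set_index("cell")["pseudotime_rescaled"]
        assert abs(got["i"] - te) < 1e-12


def test_select_trajectory_mirnas_recovery():
    norm, pt, batch, assoc = simulate_trajectory_data(0, n_cells=200,
                                                      n_mirnas=40,
                                                      n_assoc=8)
    res = select_trajectory_mirnas(norm, pt, batch,
                                   de_features=set(norm.columns))
    assert set(assoc) <= set(res.index[res["selected"]])
    null = res.drop(index=assoc)
    assert null["associated"].mean() <= 0.05 + 0.05


def test_select_trajectory_intersection_rule():
    norm, pt, batch, assoc = simulate_trajectory_data(1, n_cells=150,
                                                      n_mirnas=20,
                                                      n_assoc=5)
    res = select_trajectory_mirnas(norm, pt, batch, de_features=set())
    assert not res["selected"].any()
    assert res.loc[assoc, "associated"].all()


def test_select_single_batch_warns():
    norm, pt, batch, _ = simulate_trajectory_data(2, n_cells=50,
                                                  n_mirnas=5, n_batches=1)
    with pytest.warns(UserWarning, match="single batch"):
        select_trajectory_mirnas(norm, pt, batch)


def test_cluster_patterns_labels():
    profiles, truth_labels = make_pattern_profiles(0, n_per_class=6)
    labels = cluster_patterns(profiles, seed=0)
    for name, expect in truth_labels.items():
        assert labels[name] == expect


def test_cluster_patterns_needs_three():
    profiles, _ = make_pattern_profiles(0, n_per_class=6)
    with pytest.raises(ValueError):
        cluster_patterns(profiles.iloc[:2])


def test_binned_profiles_shape():
    norm, pt, _, _ = simulate_trajectory_data(3, n_cells=100, n_mirnas=6)
    prof = binned_profiles(norm, pt, list(norm.columns), n_bins=20)
    assert prof.shape == (6, 20)
    assert not prof.isna().any().any()


def test_pseudobulk_basics():
    norm = pd.DataFrame({"f": [1.0, 3.0, 5.0]}, index=["a", "b", "c"])
    groups = pd.Series({"a": "g1", "b": "g2", "c": "g2"})
    pb = pseudobulk(norm, groups)
    assert pb.loc["g1", "f"] == 1.0
    assert pb.loc["g2", "f"] == 4.0
    # permutation invariance
    pb2 = pseudobulk(norm.iloc[::-1], groups)
    assert pb.equals(pb2.sort_index())


def test_correlate_limit_cases():
    groups = [f"g{i}" for i in range(6)]
    x = np.arange(6, dtype=float)
    mirna = pd.DataFrame({"m": x}, index=groups)
    gene = pd.DataFrame({"ganti": -x, "gflat": np.zeros(6),
                         "gind": np.array([3, 1, 4, 1, 5, 9.0])},
                        index=groups)
    pairs = pd.DataFrame({"mirna": ["m", "m", "m"],
                          "gene": ["ganti", "gflat", "gind"]})
    res = correlate_targets(mirna, gene, pairs).set_index("gene")
    assert res.loc["ganti", "r"] == -1.0
    assert res.loc["ganti", "p_negative"] == 0.0
    assert res.loc["gflat", "skipped"] == "zero_variance"


def test_correlate_r_zero_symmetric():
    groups = [f"g{i}" for i in range(4)]
    mirna = pd.DataFrame({"m": [1.0, 2.0, 1.0, 2.0]}, index=groups)
    gene = pd.DataFrame({"g": [1.0, 1.0, 2.0, 2.0]}, index=groups)
    res = correlate_targets(mirna, gene,
                            pd.DataFrame({"mirna": ["m"], "gene": ["g"]}))
    assert np.isclose(res.loc[0, "r"], 0.0)
    assert np.isclose(res.loc[0, "p_negative"], 0.5)


def test_correlate_worked_t_value():
    """r=-0.9, n=6: t=-4.129, one-sided negative p=0.00726."""
    # construct vectors with exact correlation -0.9
    x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
    xc = (x - x.mean()) / np.linalg.norm(x - x.mean())
    z = np.array([1.0, -1.0, 1.0, -1.0, 1.0, -1.0])
    z = z - z.mean() - (z @ xc) * xc
    z = z / np.linalg.norm(z)
    r = -0.9
    y = r * xc + np.sqrt(1 - r * r) * z
    mirna = pd.DataFrame({"m": x}, index=range(6))
    gene = pd.DataFrame({"g": y}, index=range(6))
    res = correlate_targets(mirna, gene,
                            pd.DataFrame({"mirna": ["m"], "gene": ["g"]}))
    assert np.isclose(res.loc[0, "r"], -0.9, atol=1e-12)
    assert np.isclose(res.loc[0, "t"], -4.129, atol=1e-3)
    assert np.isclose(res.loc[0, "p_negative"], 0.00726, atol=1e-5)


def test_correlate_matches_bruteforce():
    mirna_pb, gene_pb, pairs, _ = simulate_pseudobulk_pairs(
        7, n_pairs=100, n_planted=10)
    res = correlate_targets(mirna_pb, gene_pb, pairs)
    for _, row in res.iterrows():
        x = mirna_pb[row["mirna"]].to_numpy()
        y = gene_pb[row["gene"]].to_numpy()
        r, p_neg, p_pos = oracle_pearson_onesided(list(x), list(y))
        assert abs(row["r"] - r) <= 1e-10 * max(1, abs(r))
        assert abs(row["p_negative"] - p_neg) <= 1e-10
        assert abs(row["p_positive"] - p_pos) <= 1e-10


def test_correlate_needs_three_groups():
    df = pd.DataFrame({"m": [1.0, 2.0]}, index=["g0", "g1"])
    with pytest.raises(ValueError, match=">= 3"):
        correlate_targets(df, df.rename(columns={"m": "g"}),
                          pd.DataFrame({"mirna": ["m"], "gene": ["g"]}))


def test_filter_novel_examples():
    grid = novel_candidate_grid()
    res = filter_novel(grid).set_index("candidate_id")
    # all four criteria must hold simultaneously
    assert res["accepted"].sum() == 1
    assert res.loc["cand15", "accepted"]
    # single-criterion failures give the matching reason
    assert res.loc["cand14", "reason"] == "randfold"
    assert res.loc["cand13", "reason"] == "score"
    assert res.loc["cand11", "reason"] == "breadth"
    assert res.loc["cand07", "reason"] == "support"


def test_filter_novel_is_conjunction():
    grid = novel_candidate_grid()
    res = filter_novel(grid).set_index("candidate_id")
    for _, row in grid.iterrows():
        crit = novel_criteria(row)
        assert res.loc[row["candidate_id"], "accepted"] == all(crit.values())


def test_filter_novel_missing_field():
    df = novel_candidate_grid().head(1).copy()
    df.loc[0, "mirdeep_score"] = np.nan
    res = filter_novel(df)
    assert not res.loc[0, "accepted"]
    assert "missing" in res.loc[0, "reason"]
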
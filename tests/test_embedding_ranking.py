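import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.metrics import silhouette_score

from phenoprobe.embedding_ranking import (
    EmbeddingConfig,
    dunn_index,
    dunn_scores,
    embed_tsne,
    fold_change_ranking,
    rank_probes,
)

from conftest import make_layout, simulate_feature_screen


def _dist(p, q):
    return math.sqrt((p[0] - q[0]) ** 2 + (p[1] - q[1]) ** 2)


def brute_force_dunn(a, b):
    """Independent oracle: explicit all-pairs loops."""
    delta = min(_dist(p, q) for p in a for q in b)
    diam = 0.0
    for pts in (a, b):
        for i in range(len(pts)):
            for j in range(i + 1, len(pts)):
                diam = max(diam, _dist(pts[i], pts[j]))
    if delta == 0:
        return 0.0
    if diam == 0:
        return float("inf")
    return delta / diam


def test_dunn_hand_computed_example():
    a = np.array([[0.0, 0.0], [0.0, 1.0]])
    b = np.array([[10.0, 0.0], [10.0, 1.0]])
    assert dunn_index(a, b) == pytest.approx(10.0)


def test_dunn_sentinels():
    assert dunn_index([[0, 0], [1, 1]], [[0, 0], [5, 5]]) == 0.0
    assert dunn_index([[0, 0]], [[1, 0]]) == float("inf")
    with pytest.raises(ValueError):
        dunn_index(np.empty((0, 2)), [[0, 0]])


def test_dunn_matches_brute_force_on_200_random_instances():
    rng = np.random.default_rng(123)
    for _ in range(200):
        na, nb = rng.integers(1, 51, size=2)
        a = rng.normal(0, 3, size=(na, 2)).round(3)
        b = rng.normal(1, 3, size=(nb, 2)).round(3)
        assert dunn_index(a, b) == brute_force_dunn(a, b)


def test_dunn_scale_and_label_invariance():
    rng = np.random.default_rng(7)
    for _ in range(25):
        a = rng.normal(0, 1, size=(8, 2))
        b = rng.normal(4, 1, size=(6, 2))
        d = dunn_index(a, b)
        assert dunn_index(b, a) == d
        c = rng.uniform(0.1, 50)
        assert dunn_index(c * a, c * b) == pytest.approx(d, rel=1e-12)


def test_embedding_cardinality_and_determinism():
    rng = np.random.default_rng(0)
    X = pd.DataFrame(rng.normal(size=(40, 10)),
                     index=[f"i{k}" for k in range(40)])
    e1 = embed_tsne(X, EmbeddingConfig(seed=3))
    e2 = embed_tsne(X, EmbeddingConfig(seed=3))
    assert e1.shape == (40, 2)
    assert list(e1.index) == list(X.index)
    assert np.array_equal(e1.to_numpy(), e2.to_numpy())
    assert np.isfinite(e1.to_numpy()).all()


def test_embedding_parameter_errors():
    X = pd.DataFrame(np.random.default_rng(0).normal(size=(4, 5)))
    with pytest.raises(ValueError):
        embed_tsne(X)
    X10 = pd.DataFrame(np.random.default_rng(0).normal(size=(10, 5)))
    with pytest.raises(ValueError):
        embed_tsne(X10, EmbeddingConfig(perplexity=30,
                                        clip_perplexity=False))
    with pytest.raises(ValueError):
        embed_tsne(X10, EmbeddingConfig(perplexity=-1))


def test_two_gaussian_clouds_separate_in_embedding():
    scores = []
    for seed in range(20):
        rng = np.random.default_rng(200 + seed)
        X = np.vstack([rng.normal(0, 1, size=(30, 10)),
                       rng.normal(6, 1, size=(30, 10))])
        labels = np.repeat([0, 1], 30)
        emb = embed_tsne(pd.DataFrame(X), EmbeddingConfig(seed=seed))
        scores.append(silhouette_score(emb.to_numpy(), labels))
    assert np.median(scores) > 0.5


def test_strong_effect_probe_ranks_first_in_most_seeds():
    layout = make_layout([f"P{i}" for i in range(6)])
    wins = 0
    for seed in range(20):
        feats = simulate_feature_screen(layout, {"P3": 10.0}, seed=seed)
        emb = embed_tsne(feats, EmbeddingConfig(seed=seed))
        ranking = rank_probes(emb, layout)
        wins += ranking.iloc[0]["probe_sku"] == "P3"
    assert wins >= 18  # >= 90 % of 20 seeds


def test_null_screen_has_exchangeable_dunn_ranks():
    layout = make_layout([f"P{i}" for i in range(5)])
    per_probe: dict[str, list[float]] = {s: [] for s in layout.probe_skus}
    for seed in range(15):
        feats = simulate_feature_screen(layout, {}, seed=300 + seed)
        emb = embed_tsne(feats, EmbeddingConfig(seed=seed))
        for sku, d in dunn_scores(emb, layout).items():
            per_probe[sku].append(d)
    h = stats.kruskal(*per_probe.values())
    assert h.pvalue > 0.01


def test_relabeling_conditions_leaves_dunn_unchanged():
    layout = make_layout(["P0", "P1"])
    feats = simulate_feature_screen(layout, {"P0": 6.0}, seed=5)
    emb = embed_tsne(feats, EmbeddingConfig(seed=5))
    scores = dunn_scores(emb, layout)
    swapped_entries = []
    for m in layout.entries:
        flip = {"KO": "WT", "WT": "KO"}[m.condition]
        swapped_entries.append(
            type(m)(m.image_id, m.probe_sku, flip, m.treatment,
                    m.replicate, m.field, m.path))
    swapped = type(layout)(entries=swapped_entries, panel=layout.panel)
    assert dunn_scores(emb, swapped) == scores


def test_probe_missing_a_condition_is_excluded_with_warning():
    layout = make_layout(["P0", "P1"])
    feats = simulate_feature_screen(layout, {}, seed=1)
    # drop all KO images of P1 from the embedding
    keep = [i for i in feats.index if not i.startswith("P1_DMSO_KO")]
    emb = embed_tsne(feats.loc[keep], EmbeddingConfig(seed=1))
    with pytest.warns(UserWarning, match="P1"):
        ranking = rank_probes(emb, layout)
    assert ranking["probe_sku"].tolist() == ["P0"]


def test_identical_arms_give_fold_change_exactly_one():
    layout = make_layout(["P0", "P1"], treatments=("DMSO", "mTORi"))
    rng = np.random.default_rng(3)
    # both arms share identical embedded coordinates by construction
    coords = {}
    for m in layout.entries:
        key = (m.probe_sku, m.condition, m.replicate, m.field)
        if key not in coords:
            coords[key] = rng.normal(size=2)
    emb = pd.DataFrame(
        [coords[(m.probe_sku, m.condition, m.replicate, m.field)]
         for m in layout.entries],
        index=pd.Index([m.image_id for m in layout.entries],
                       name="image_id"),
        columns=["x", "y"])
    fc = fold_change_ranking(pd.DataFrame(), layout, treated="mTORi",
                             embedding=emb)
    assert (fc["fold_change"] == 1.0).all()


def test_null_treatment_fold_changes_center_on_one():
    layout = make_layout([f"P{i}" for i in range(5)],
                         treatments=("DMSO", "mTORi"))
    medians = []
    for seed in range(20):
        feats = simulate_feature_screen(
            layout, {s: 6.0 for s in layout.probe_skus}, seed=400 + seed,
            arm_multiplier={"DMSO": 1.0, "mTORi": 1.0})
        fc = fold_change_ranking(feats, layout, treated="mTORi",
                                 config=EmbeddingConfig(seed=seed))
        vals = fc["fold_change"].replace(np.inf, np.nan).dropna()
        medians.append(vals.median())
    assert 0.5 <= np.median(medians) <= 2.0


def test_amplified_probe_attains_max_fold_change_in_most_seeds():
    layout = make_layout([f"P{i}" for i in range(5)],
                         treatments=("DMSO", "mTORi"))
    wins = 0
    for seed in range(20):
        feats = simulate_feature_screen(
            layout, {s: 5.0 for s in layout.probe_skus}, seed=500 + seed,
            arm_multiplier={"DMSO": 1.0, "mTORi": 1.0})
        boost = simulate_feature_screen(
            layout, {"P2": 5.0}, seed=500 + seed,
            arm_multiplier={"DMSO": 1.0, "mTORi": 3.0})
        # P2's KO delta triples under treatment; others unchanged
        mixed = feats.copy()
        p2_ids = [m.image_id for m in layout.images_for("P2")]
        mixed.loc[p2_ids] = boost.loc[p2_ids]
        fc = fold_change_ranking(mixed, layout, treated="mTORi",
                                 config=EmbeddingConfig(seed=seed))
        top = fc.iloc[0]["probe_sku"]
        wins += top == "P2"
    assert wins >= 16  # >= 80 % of 20 seeds
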
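"""t-SNE phenotype embedding and Dunn-index probe ranking.

The reduced feature matrix of a whole screen is embedded once into 2D with
t-SNE (z-scored features, PCA initialisation, fixed seed).  For each probe,
its KO images and its WT images form two point sets in that single global
embedding; the Dunn index

    D = (minimum KO-WT cross distance) / (largest within-set diameter)

quantifies how cleanly the two conditions separate for that probe.  Probes
are ranked by descending Dunn index; under two treatment arms, both arms
are embedded jointly and the ratio of per-arm Dunn indices gives a
treatment fold change per probe.

Degenerate geometry is resolved explicitly: zero cross-cluster distance
gives 0, zero diameters with positive separation give ``+inf``.  t-SNE
distances are not metrically faithful, so the Dunn index may alternatively
be computed directly in the reduced feature space (``space="reduced_features"``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist, pdist
from sklearn.manifold import TSNE

from .screen_model import ScreenLayout, rank_table


@dataclass(frozen=True)
class EmbeddingConfig:
    """t-SNE settings; recorded in output provenance."""

    perplexity: float = 30.0
    seed: int = 0
    n_components: int = 2
    clip_perplexity: bool = True

    def effective_perplexity(self, n_points: int) -> float:
        if self.perplexity <= 0:
            raise ValueError("perplexity must be positive")
        if self.clip_perplexity:
            return min(self.perplexity, (n_points - 1) / 3.0)
        if self.perplexity >= n_points:
            raise ValueError(
                f"perplexity {self.perplexity} must be < n_points {n_points}"
            )
        return self.perplexity


@dataclass(frozen=True)
class DunnConfig:
    """Where the Dunn index is measured; Euclidean metric throughout."""

    space: str = "embedding"  # or "reduced_features"

    def __post_init__(self) -> None:
        if self.space not in ("embedding", "reduced_features"):
            raise ValueError(f"unknown Dunn space {self.space!r}")


def embed_tsne(
    reduced: pd.DataFrame, config: EmbeddingConfig | None = None
) -> pd.DataFrame:
    """Embed a (images x features) matrix to 2D; deterministic given seed.

    Features are z-scored first.  Returns a DataFrame indexed like
    ``reduced`` with columns ``x`` and ``y``.
    """
    config = config or EmbeddingConfig()
    n = len(reduced)
    if n < 5:
        raise ValueError("t-SNE embedding needs at least 5 images")
    X = reduced.to_numpy(dtype=float)
    sd = X.std(axis=0)
    X = (X - X.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    tsne = TSNE(
        n_components=config.n_components,
        perplexity=config.effective_perplexity(n),
        init="pca",
        learning_rate="auto",
        random_state=config.seed,
    )
    coords = tsne.fit_transform(X)
    return pd.DataFrame(coords, columns=["x", "y"], index=reduced.index)


def dunn_index(points_a: np.ndarray, points_b: np.ndarray) -> float:
    """Two-cluster Dunn index: min cross distance / max within diameter.

    Sentinels: zero separation -> 0.0; zero diameters with positive
    separation (two tight clusters) -> ``+inf``.
    """
    a = np.atleast_2d(np.asarray(points_a, dtype=float))
    b = np.atleast_2d(np.asarray(points_b, dtype=float))
    if a.size == 0 or b.size == 0:
        raise ValueError("both point sets must be nonempty")
    delta = float(cdist(a, b).min())
    diam_a = float(pdist(a).max()) if len(a) > 1 else 0.0
    diam_b = float(pdist(b).max()) if len(b) > 1 else 0.0
    diam = max(diam_a, diam_b)
    if delta == 0.0:
        return 0.0
    if diam == 0.0:
        return float("inf")
    return delta / diam


def dunn_scores(
    points: pd.DataFrame,
    layout: ScreenLayout,
    treatment: str = "DMSO",
) -> dict[str, float]:
    """Per-probe KO-vs-WT Dunn indices in the given coordinate frame.

    ``points`` is indexed by image_id (2D embedding coordinates or reduced
    feature rows).  Probes lacking images of either condition in this
    treatment arm, or whose images are absent from ``points`` (e.g.
    dropped empty images), are skipped with a warning.
    """
    scores: dict[str, float] = {}
    for sku in layout.probe_skus:
        sides = []
        ok = True
        for condition in ("KO", "WT"):
            ids = [m.image_id for m in
                   layout.images_for(sku, condition, treatment)
                   if m.image_id in points.index]
            if not ids:
                ok = False
                break
            sides.append(points.loc[ids].to_numpy(dtype=float))
        if not ok:
            warnings.warn(
                f"probe {sku!r} lacks embedded images for both conditions "
                f"in treatment {treatment!r}; excluded from ranking",
                stacklevel=2,
            )
            continue
        scores[sku] = dunn_index(sides[0], sides[1])
    return scores


def rank_probes(
    embedding: pd.DataFrame,
    layout: ScreenLayout,
    treatment: str = "DMSO",
) -> pd.DataFrame:
    """Rank probes by KO-vs-WT Dunn index on the global embedding.

    Returns a table (probe_sku, probe_name, category, dunn_index, rank)
    sorted by descending Dunn index, ties broken by ascending SKU.
    """
    scores = dunn_scores(embedding, layout, treatment)
    if not scores:
        raise ValueError(f"no probe has both conditions in arm {treatment!r}")
    return rank_table(scores, panel=layout.panel)


def fold_change_ranking(
    reduced: pd.DataFrame,
    layout: ScreenLayout,
    treated: str,
    control: str = "DMSO",
    config: EmbeddingConfig | None = None,
    embedding: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Dunn-index fold change between two treatment arms.

    Both arms are embedded **jointly** (separate embeddings would make
    Dunn ratios incomparable), then per-probe Dunn indices are computed
    within each arm and ``fold_change = dunn_treated / dunn_control``.
    Sentinels: control 0 with treated > 0 -> ``+inf``; both 0 -> 1.
    Probes absent from either arm are excluded with a warning.
    """
    arm_ids = {
        arm: {m.image_id for m in layout.entries if m.treatment == arm}
        for arm in (control, treated)
    }
    if embedding is None:
        keep = [i for i in reduced.index
                if i in arm_ids[control] | arm_ids[treated]]
        emb = embed_tsne(reduced.loc[keep], config)
    else:
        emb = embedding
    d_control = dunn_scores(emb.loc[emb.index.isin(arm_ids[control])],
                            layout, control)
    d_treated = dunn_scores(emb.loc[emb.index.isin(arm_ids[treated])],
                            layout, treated)
    rows = []
    for sku in layout.probe_skus:
        if sku not in d_control or sku not in d_treated:
            warnings.warn(f"probe {sku!r} missing from one arm; excluded",
                          stacklevel=2)
            continue
        dc, dt = d_control[sku], d_treated[sku]
        if dc == 0.0:
            fc = 1.0 if dt == 0.0 else float("inf")
        elif np.isinf(dc):
            fc = 1.0 if np.isinf(dt) else 0.0
        else:
            fc = dt / dc
        rows.append({
            "probe_sku": sku,
            "dunn_control": dc,
            "dunn_treated": dt,
            "fold_change": fc,
        })
    df = pd.DataFrame(rows)
    return df.sort_values(
        ["fold_change", "probe_sku"], ascending=[False, True]
    ).reset_index(drop=True)
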
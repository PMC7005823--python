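"""End-to-end screen analysis: images -> features -> reduction -> ranking.

Thin orchestration over the stage modules, shared by the CLI, the test
suite and the reproduction script.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import charm_features, segmentation_features
from .embedding_ranking import EmbeddingConfig, embed_tsne, rank_probes
from .feature_reduction import ReductionConfig, reduce_features
from .screen_model import ScreenLayout, load_plate_map
from .synthetic_screen import read_field

logger = logging.getLogger(__name__)

MODES = ("charm", "segmentation")


def extract_features(
    images_dir: str | Path,
    layout: ScreenLayout,
    mode: str = "charm",
    distance_n: float = segmentation_features.DEFAULT_DISTANCE_N,
) -> pd.DataFrame:
    """Per-image feature matrix for a whole screen.

    ``charm`` extracts the 923 whole-image features from the probe channel;
    ``segmentation`` runs the nuclei/Distance-N comparator and returns the
    237 per-image mean object measurements.  Images with zero segmented
    objects are dropped (logged), since all-NaN rows would poison the
    embedding.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    rows: list[np.ndarray] = []
    ids: list[str] = []
    n_empty = 0
    for meta in layout.entries:
        img = read_field(images_dir, meta)
        if mode == "charm":
            vec = charm_features.extract_charm(img[1])
        else:
            vec, empty = segmentation_features.extract_segmentation(
                img[0], img[1], distance_n=distance_n)
            if empty:
                n_empty += 1
                continue
        rows.append(vec)
        ids.append(meta.image_id)
    if n_empty:
        logger.info("dropped %d empty image(s) in segmentation mode", n_empty)
    cols = (charm_features.feature_names() if mode == "charm"
            else segmentation_features.object_feature_names())
    return pd.DataFrame(rows, index=pd.Index(ids, name="image_id"),
                        columns=cols)


def rank_screen(
    screen_dir: str | Path,
    mode: str = "charm",
    treatment: str = "DMSO",
    seed: int = 0,
    reduction: ReductionConfig | None = None,
    embedding: EmbeddingConfig | None = None,
    features: pd.DataFrame | None = None,
) -> dict:
    """Full analysis of a generated screen directory.

    Returns a dict with the feature matrix, the reduced matrix, the 2D
    embedding and the probe ranking.  Pass ``features`` to reuse an
    already-extracted matrix.
    """
    screen_dir = Path(screen_dir)
    layout = load_plate_map(screen_dir / "plate_map.csv")
    if features is None:
        features = extract_features(screen_dir, layout, mode=mode)
    arm_ids = [m.image_id for m in layout.entries if m.treatment == treatment]
    arm = features.loc[features.index.isin(arm_ids)]
    reduced = reduce_features(arm, reduction or ReductionConfig())
    emb_cfg = embedding or EmbeddingConfig(seed=seed)
    emb = embed_tsne(reduced.matrix, emb_cfg)
    ranking = rank_probes(emb, layout, treatment=treatment)
    return {
        "layout": layout,
        "features": features,
        "reduced": reduced,
        "embedding": emb,
        "ranking": ranking,
    }


def plot_embedding(embedding: pd.DataFrame, layout: ScreenLayout, path,
                   probe_sku: str | None = None) -> None:
    """t-SNE scatter coloured by condition (optionally zoomed to one probe)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    cond = {m.image_id: m.condition for m in layout.entries}
    fig, ax = plt.subplots(figsize=(5, 5))
    for condition, colour in (("WT", "tab:blue"), ("KO", "tab:red")):
        sel = [i for i in embedding.index if cond.get(i) == condition]
        pts = embedding.loc[sel]
        ax.scatter(pts["x"], pts["y"], s=8, alpha=0.3, color=colour,
                   label=condition)
    if probe_sku is not None:
        probe_ids = [m.image_id for m in layout.images_for(probe_sku)
                     if m.image_id in embedding.index]
        pts = embedding.loc[probe_ids]
        ax.scatter(pts["x"], pts["y"], s=30, facecolors="none",
                   edgecolors="black", label=probe_sku)
    ax.legend(frameon=False)
    ax.set_xlabel("t-SNE 1")
    ax.set_ylabel("t-SNE 2")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_ranking(ranking: pd.DataFrame, path, top: int | None = None) -> None:
    """Horizontal bar chart of per-probe Dunn indices."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = ranking.head(top) if top else ranking
    fig, ax = plt.subplots(figsize=(6, 0.25 * len(df) + 1.5))
    vals = df["dunn_index"].replace(np.inf, np.nan)
    vmax = np.nanmax(vals.to_numpy()) if np.isfinite(vals).any() else 1.0
    bars = vals.fillna(vmax * 1.1)
    ax.barh(df["probe_name"], bars, color="tab:purple")
    ax.invert_yaxis()
    ax.set_xlabel("Dunn index (KO vs WT)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
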
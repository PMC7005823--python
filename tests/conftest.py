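import dataclasses

import numpy as np
import pandas as pd
import pytest

from phenoprobe.screen_model import ImageMeta, ProbeEntry, ScreenLayout
from phenoprobe.synthetic_screen import default_screen_config, generate_screen


@pytest.fixture(scope="session")
def small_screen(tmp_path_factory):
    """A tiny rendered screen (4 probes, 1 true positive, 96 px fields)."""
    config = default_screen_config(
        n_probes=4, n_true_positives=1, seed=7, image_size_px=96)
    config = dataclasses.replace(config, cells_per_image=6.0)
    out = tmp_path_factory.mktemp("screen")
    screen_dir, layout = generate_screen(config, out, overwrite=True)
    return {"dir": screen_dir, "layout": layout, "config": config}


def make_layout(
    probe_skus,
    images_per_side: int = 6,
    treatments=("DMSO",),
) -> ScreenLayout:
    """Layout with images_per_side images per (probe, condition, arm)."""
    entries = []
    for sku in probe_skus:
        for trt in treatments:
            for cond in ("KO", "WT"):
                k = 0
                for rep in (1, 2):
                    for fld in range(1, images_per_side // 2 + 1):
                        k += 1
                        iid = f"{sku}_{trt}_{cond}_{k}"
                        entries.append(ImageMeta(
                            image_id=iid, probe_sku=sku, condition=cond,
                            treatment=trt, replicate=rep, field=fld,
                            path=f"{iid}.tif"))
    panel = [ProbeEntry(sku, f"probe {sku}", "Synthetic", "Synthetic")
             for sku in probe_skus]
    return ScreenLayout(entries=entries, panel=panel)


def simulate_feature_screen(
    layout: ScreenLayout,
    effect: dict[str, float],
    seed: int,
    n_features: int = 20,
    arm_multiplier: dict[str, float] | None = None,
    probe_offset_scale: float = 4.0,
) -> pd.DataFrame:
    """Gaussian feature clouds per probe; KO shifted by the probe's effect.

    Each probe gets its own random mean (probes occupy distinct regions of
    feature space, as distinct stains do); effect probes additionally shift
    their KO images along a random unit direction by ``effect[sku]``
    (scaled per treatment arm).
    """
    rng = np.random.default_rng(seed)
    arm_multiplier = arm_multiplier or {}
    rows, ids = [], []
    for sku in layout.probe_skus:
        centre = rng.normal(0, probe_offset_scale, n_features)
        direction = rng.normal(0, 1, n_features)
        direction /= np.linalg.norm(direction)
        for meta in layout.images_for(sku):
            mu = centre.copy()
            if meta.condition == "KO" and sku in effect:
                mult = arm_multiplier.get(meta.treatment, 1.0)
                mu = mu + effect[sku] * mult * direction
            rows.append(mu + rng.normal(0, 1, n_features))
            ids.append(meta.image_id)
    return pd.DataFrame(
        rows, index=pd.Index(ids, name="image_id"),
        columns=[f"f{i}" for i in range(n_features)])
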
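"""Segmentation-based comparator pipeline.

The classical alternative to whole-image profiling: nuclei are segmented in
the DNA channel, cell regions are approximated by expanding each nucleus
outward up to N pixels ("Distance-N", contested pixels going to the nearest
nucleus), and 237 per-object measurements are taken from the probe channel
within each cell region -- granularity spectra, object-neighbour
relationships, radial intensity distribution, intensity summaries and
multi-scale co-occurrence texture.  Per-object rows are averaged to one
237-value vector per image.

Unlike the whole-image bank (:mod:`.charm_features`), the intensity
measurements here are taken on the raw probe signal, so this pipeline is
sensitive to absolute brightness -- including low-intensity fluorescent
artifacts on otherwise unstained probes, the classic failure mode this
comparator exists to demonstrate.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label as sk_label
from skimage.morphology import remove_small_objects

from .charm_features import haralick_avg_range, _HARALICK_NAMES

N_OBJECT_FEATURES = 237

GRANULARITY_SCALES = 16
TEXTURE_DISTANCES = (1, 2, 3, 4, 5, 7, 10)
RADIAL_RINGS = 6
RADIAL_WEDGES = 8
DEFAULT_DISTANCE_N = 10
MIN_NUCLEUS_AREA = 20

_CROSS = ndimage.generate_binary_structure(2, 1)


@lru_cache(maxsize=1)
def segmentation_manifest() -> pd.DataFrame:
    """The ordered 237-column manifest (feature_name, category)."""
    rows: list[dict[str, str]] = []

    def add(name: str, category: str) -> None:
        rows.append({"feature_name": name, "category": category})

    for r in range(1, GRANULARITY_SCALES + 1):
        add(f"granularity_scale{r:02d}", "granularity")
    for name in ("n_neighbors", "percent_touching", "first_closest_dist",
                 "second_closest_dist", "angle_between_closest"):
        add(f"neighbors_{name}", "neighbors")
    for ring in range(1, RADIAL_RINGS + 1):
        for stat in ("frac_at_d", "mean_frac", "radial_cv"):
            add(f"radial_ring{ring}_{stat}", "intensity_distribution")
    for name in ("integrated", "mean", "std", "min", "max", "median", "mad",
                 "q1", "q3", "range", "mass_displacement", "edge_integrated",
                 "edge_mean", "edge_std", "edge_min", "edge_max"):
        add(f"intensity_{name}", "intensity")
    for d in TEXTURE_DISTANCES:
        for h in _HARALICK_NAMES:
            add(f"texture_d{d:02d}_{h}_avg", "texture")
        for h in _HARALICK_NAMES:
            add(f"texture_d{d:02d}_{h}_range", "texture")
    df = pd.DataFrame(rows)
    assert len(df) == N_OBJECT_FEATURES, len(df)
    assert df["feature_name"].is_unique
    return df


def object_feature_names() -> list[str]:
    return segmentation_manifest()["feature_name"].tolist()


# ---------------------------------------------------------------------------
# segmentation


def segment_nuclei(dna: np.ndarray, sigma: float = 2.0,
                   min_area: int = MIN_NUCLEUS_AREA) -> np.ndarray:
    """Label nuclei in the DNA channel.

    Gaussian smoothing, Otsu threshold, hole filling, minimum-area filter,
    8-connected labelling.  No declumping: touching nuclei merge into one
    object.  A blank image yields zero labels.
    """
    dna = np.asarray(dna, dtype=float)
    smooth = ndimage.gaussian_filter(dna, sigma=sigma)
    if float(smooth.max() - smooth.min()) <= 0:
        return np.zeros(dna.shape, dtype=np.int32)
    mask = smooth > threshold_otsu(smooth)
    mask = ndimage.binary_fill_holes(mask)
    mask = remove_small_objects(mask, max_size=min_area - 1)
    return sk_label(mask, connectivity=2).astype(np.int32)


def expand_cells_distance_n(nuclei: np.ndarray, n: float) -> np.ndarray:
    """Approximate cell regions by expanding nuclei up to ``n`` pixels.

    Each pixel within Euclidean distance ``n`` of some nucleus is assigned
    to the nearest nucleus; exact ties go to the lower label.  The result
    partitions the expanded area, and every cell region contains its
    nucleus.
    """
    if n < 0:
        raise ValueError("expansion distance n must be >= 0")
    nuclei = np.asarray(nuclei)
    ids = np.unique(nuclei)
    ids = ids[ids > 0]
    if ids.size == 0:
        return np.zeros_like(nuclei, dtype=np.int32)
    dists = np.stack([
        ndimage.distance_transform_edt(nuclei != i) for i in ids
    ])
    nearest = np.argmin(dists, axis=0)  # first minimum -> lower label
    min_dist = np.take_along_axis(dists, nearest[None], axis=0)[0]
    cells = np.where(min_dist <= n, ids[nearest], 0)
    return cells.astype(np.int32)


# ---------------------------------------------------------------------------
# per-object measurements


def _granularity(cells: np.ndarray, probe: np.ndarray,
                 ids: np.ndarray) -> np.ndarray:
    """Opening-spectrum granularity: % intensity removed per erosion scale."""
    base = ndimage.sum_labels(probe, cells, ids)
    base = np.where(base > 0, base, 1.0)
    eroded = probe.copy()
    prev = ndimage.sum_labels(probe, cells, ids)
    out = np.zeros((ids.size, GRANULARITY_SCALES))
    for r in range(1, GRANULARITY_SCALES + 1):
        eroded = ndimage.grey_erosion(eroded, footprint=_CROSS)
        opened = eroded
        for _ in range(r):
            opened = ndimage.grey_dilation(opened, footprint=_CROSS)
        cur = ndimage.sum_labels(opened, cells, ids)
        out[:, r - 1] = 100.0 * (prev - cur) / base
        prev = cur
    return out


def _boundaries(cells: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(is_boundary, touches_other) boolean maps for a label partition."""
    pad = np.pad(cells, 1, mode="constant")
    h, w = cells.shape
    is_boundary = np.zeros((h, w), dtype=bool)
    touches_other = np.zeros((h, w), dtype=bool)
    centre = pad[1:-1, 1:-1]
    for dy, dx in ((1, 0), (-1, 0), (0, 1), (0, -1)):
        nb = pad[1 + dy:1 + dy + h, 1 + dx:1 + dx + w]
        diff = (nb != centre) & (centre > 0)
        is_boundary |= diff
        touches_other |= diff & (nb > 0)
    return is_boundary, touches_other


def _neighbor_features(cells: np.ndarray, ids: np.ndarray) -> np.ndarray:
    out = np.zeros((ids.size, 5))
    if ids.size == 0:
        return out
    is_boundary, touches_other = _boundaries(cells)
    centroids = np.array(ndimage.center_of_mass(np.ones_like(cells), cells, ids))
    # adjacency: pairs of labels sharing a 4-neighbour border
    pad = np.pad(cells, 1, mode="constant")
    pairs: set[tuple[int, int]] = set()
    for dy, dx in ((1, 0), (0, 1)):
        a = pad[1:-1, 1:-1]
        b = pad[1 + dy:1 + dy + cells.shape[0], 1 + dx:1 + dx + cells.shape[1]]
        sel = (a > 0) & (b > 0) & (a != b)
        for x, y in zip(a[sel].ravel(), b[sel].ravel()):
            pairs.add((min(int(x), int(y)), max(int(x), int(y))))
    n_adj = {int(i): 0 for i in ids}
    for x, y in pairs:
        n_adj[x] += 1
        n_adj[y] += 1
    for k, i in enumerate(ids):
        obj = cells == i
        bnd = is_boundary & obj
        nb = bnd.sum()
        out[k, 0] = n_adj[int(i)]
        out[k, 1] = 100.0 * (touches_other & obj).sum() / nb if nb else 0.0
        d = np.hypot(*(centroids - centroids[k]).T)
        d[k] = np.inf
        order = np.argsort(d)
        if ids.size >= 2 and np.isfinite(d[order[0]]):
            out[k, 2] = d[order[0]]
        if ids.size >= 3 and np.isfinite(d[order[1]]):
            out[k, 3] = d[order[1]]
            v1 = centroids[order[0]] - centroids[k]
            v2 = centroids[order[1]] - centroids[k]
            cosang = np.dot(v1, v2) / max(np.linalg.norm(v1) * np.linalg.norm(v2),
                                          1e-12)
            out[k, 4] = float(np.degrees(np.arccos(np.clip(cosang, -1, 1))))
    return out


def _radial_features(cells: np.ndarray, probe: np.ndarray, ids: np.ndarray,
                     centres: np.ndarray) -> np.ndarray:
    out = np.zeros((ids.size, RADIAL_RINGS * 3))
    yy, xx = np.mgrid[0:cells.shape[0], 0:cells.shape[1]]
    for k, i in enumerate(ids):
        sel = cells == i
        y, x = yy[sel], xx[sel]
        v = probe[sel]
        total = v.sum()
        cy, cx = centres[k]
        r = np.hypot(y - cy, x - cx)
        rmax = r.max()
        ring = (np.minimum(r / rmax, 1.0 - 1e-9) * RADIAL_RINGS).astype(int) \
            if rmax > 0 else np.zeros_like(r, dtype=int)
        theta = np.arctan2(y - cy, x - cx) % (2 * np.pi)
        wedge = (theta / (2 * np.pi) * RADIAL_WEDGES).astype(int) % RADIAL_WEDGES
        npix = sel.sum()
        for b in range(RADIAL_RINGS):
            m = ring == b
            if not m.any():
                continue
            frac_at_d = v[m].sum() / total if total > 0 else 0.0
            frac_pix = m.sum() / npix
            mean_frac = frac_at_d / frac_pix if frac_pix > 0 else 0.0
            wsum = np.bincount(wedge[m], weights=v[m], minlength=RADIAL_WEDGES)
            wcnt = np.bincount(wedge[m], minlength=RADIAL_WEDGES)
            wmean = wsum[wcnt > 0] / wcnt[wcnt > 0]
            cv = float(wmean.std() / wmean.mean()) if wmean.size and \
                wmean.mean() > 0 else 0.0
            out[k, 3 * b:3 * b + 3] = (frac_at_d, mean_frac, cv)
    return out


def _intensity_features(cells: np.ndarray, probe: np.ndarray,
                        ids: np.ndarray) -> np.ndarray:
    out = np.zeros((ids.size, 16))
    is_boundary, _ = _boundaries(cells)
    yy, xx = np.mgrid[0:cells.shape[0], 0:cells.shape[1]]
    for k, i in enumerate(ids):
        sel = cells == i
        v = probe[sel]
        med = float(np.median(v))
        total = v.sum()
        if total > 0:
            wy = (probe[sel] * yy[sel]).sum() / total
            wx = (probe[sel] * xx[sel]).sum() / total
        else:
            wy, wx = yy[sel].mean(), xx[sel].mean()
        mass_disp = float(np.hypot(wy - yy[sel].mean(), wx - xx[sel].mean()))
        edge_sel = sel & is_boundary
        ev = probe[edge_sel] if edge_sel.any() else np.zeros(1)
        out[k] = [total, v.mean(), v.std(), v.min(), v.max(), med,
                  float(np.median(np.abs(v - med))),
                  float(np.percentile(v, 25)), float(np.percentile(v, 75)),
                  float(v.max() - v.min()), mass_disp,
                  ev.sum(), ev.mean(), ev.std(), ev.min(), ev.max()]
    return out


def _texture_features(cells: np.ndarray, probe: np.ndarray,
                      ids: np.ndarray) -> np.ndarray:
    out = np.zeros((ids.size, 26 * len(TEXTURE_DISTANCES)))
    slices = ndimage.find_objects(cells)
    for k, i in enumerate(ids):
        sl = slices[int(i) - 1]
        if sl is None:
            continue
        crop = probe[sl].copy()
        mask = cells[sl] == i
        crop[~mask] = 0.0
        vmin, vmax = crop[mask].min(), crop[mask].max()
        if vmax - vmin > 0:
            q = np.zeros(crop.shape, dtype=np.uint8)
            q[mask] = np.minimum(((crop[mask] - vmin) / (vmax - vmin) * 32)
                                 .astype(np.uint8), 31)
        else:
            q = np.zeros(crop.shape, dtype=np.uint8)
        for d_idx, d in enumerate(TEXTURE_DISTANCES):
            out[k, 26 * d_idx:26 * (d_idx + 1)] = haralick_avg_range(
                q, distance=d)
    return out


def measure_objects(cells: np.ndarray, probe: np.ndarray,
                    nuclei: np.ndarray | None = None) -> pd.DataFrame:
    """Measure all 237 per-object features within cell regions.

    ``nuclei`` (the pre-expansion mask) centres the radial intensity
    distribution on the nucleus; when omitted, object centroids are used.
    Zero objects yield an empty (0 x 237) table.
    """
    cells = np.asarray(cells)
    probe = np.asarray(probe, dtype=float)
    if cells.shape != probe.shape:
        raise ValueError("cells mask and probe image shapes differ")
    ids = np.unique(cells)
    ids = ids[ids > 0]
    cols = object_feature_names()
    if ids.size == 0:
        return pd.DataFrame(np.empty((0, N_OBJECT_FEATURES)), columns=cols)

    if nuclei is not None:
        centres = np.array(ndimage.center_of_mass(
            np.ones_like(nuclei), nuclei, ids))
    else:
        centres = np.array(ndimage.center_of_mass(
            np.ones_like(cells), cells, ids))

    blocks = [
        _granularity(cells, probe, ids),
        _neighbor_features(cells, ids),
        _radial_features(cells, probe, ids, centres),
        _intensity_features(cells, probe, ids),
        _texture_features(cells, probe, ids),
    ]
    table = np.hstack(blocks)
    table = np.where(np.isfinite(table), table, 0.0)
    df = pd.DataFrame(table, columns=cols, index=pd.Index(ids, name="label"))
    return df


def aggregate_image(objects: pd.DataFrame) -> tuple[np.ndarray, bool]:
    """Column-wise mean over objects -> one per-image vector.

    Returns ``(vector, empty_flag)``; an empty table yields an all-NaN
    vector with the flag set, and such images are dropped before
    embedding.
    """
    if len(objects) == 0:
        return np.full(N_OBJECT_FEATURES, np.nan), True
    return objects.to_numpy(dtype=float).mean(axis=0), False


def extract_segmentation(dna: np.ndarray, probe: np.ndarray,
                         distance_n: float = DEFAULT_DISTANCE_N
                         ) -> tuple[np.ndarray, bool]:
    """Full comparator path for one field: segment, expand, measure, mean."""
    nuclei = segment_nuclei(dna)
    cells = expand_cells_distance_n(nuclei, distance_n)
    objects = measure_objects(cells, probe, nuclei=nuclei)
    return aggregate_image(objects)
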
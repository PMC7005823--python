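"""Synthetic fluorescent-probe screen generator.

Renders a complete two-channel (DNA + probe) imaging screen with known
ground truth, emulating the layout of a live-cell probe-panel experiment:
each probe is imaged under two conditions (KO vs WT), two technical
replicates per condition and three fields per replicate, i.e. 12 images per
probe and treatment arm.

Phenotype classes follow what such screens actually show:

``diffuse``
    soft cytoplasmic staining around each nucleus, with probe-specific
    intensity, extent and mottled texture (each probe stains differently,
    so each probe forms its own island in a phenotype embedding);
``puncta``
    the diffuse background plus bright intracellular spots (e.g. lipid
    droplets accumulating in a knockout);
``nuclear``
    probe signal co-localised with the DNA channel;
``no_stain``
    a cell-impermeant or non-binding probe: noise floor only, optionally
    with sparse low-intensity fluorescent artifacts.

Both channels carry Poisson photon noise plus bounded Gaussian read noise
(truncated at 2.5 sigma, a clipped sensor-noise model).  Every image is a
pure function of the screen configuration, including the master seed:
per-image random streams are derived by hashing the image key, so adding
probes or treatments never perturbs existing images.
"""

from __future__ import annotations

import dataclasses
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage

from .screen_model import (
    ImageMeta,
    ProbeEntry,
    ScreenLayout,
    panel_manifest,
    write_plate_map,
)

STAIN_CLASSES = ("diffuse", "puncta", "nuclear", "no_stain")


class PlacementError(RuntimeError):
    """Non-overlapping nucleus placement failed after bounded retries."""


@dataclass(frozen=True)
class NoiseModel:
    """Poisson-Gaussian camera noise.

    ``photon_scale`` is the expected photon count at unit intensity;
    ``gaussian_sigma`` the read-noise standard deviation (intensity units).
    Read noise is truncated at 2.5 sigma so a zero-signal channel stays
    below 3 sigma everywhere.
    """

    gaussian_sigma: float = 0.01
    photon_scale: float = 400.0


@dataclass(frozen=True)
class PhenotypeSpec:
    """Generative description of one probe's staining phenotype."""

    stain_class: str = "diffuse"
    base_intensity: float = 0.35
    puncta_count: float = 0.0
    puncta_radius_px: float = 2.5
    puncta_intensity: float = 0.85
    artifact_rate: float = 0.0
    # "low-intensity fluorescent artifacts": dim speckles barely above the
    # read-noise band, visible to raw per-object intensity means but lost
    # in a contrast-stretched whole image
    artifact_intensity: float = 0.03
    # multiplicative detector/background gain applied after noise; models
    # well-group illumination differences, invisible after contrast stretch
    gain: float = 1.0
    # probe-specific style knobs (texture and extent of the stain)
    cyto_extent: float = 2.8
    mottle_scale_px: float = 8.0
    mottle_amp: float = 0.25

    def __post_init__(self) -> None:
        if self.stain_class not in STAIN_CLASSES:
            raise ValueError(f"unknown stain_class {self.stain_class!r}")
        if self.stain_class == "no_stain" and self.base_intensity > 0.02:
            # unstained probes sit at the noise floor by definition
            object.__setattr__(self, "base_intensity", 0.0)


@dataclass(frozen=True)
class EffectSpec:
    """KO-side phenotype delta for a true-positive probe.

    The KO spec is the WT spec plus these deltas (scaled by the treatment
    effect multiplier).  A positive ``d_puncta_count`` switches the KO
    stain class to ``puncta``; ``d_artifact_rate`` models condition-skewed
    speckle artifacts on an otherwise unstained probe.
    """

    d_puncta_count: float = 0.0
    d_artifact_rate: float = 0.0
    d_artifact_intensity: float = 0.0
    d_base_intensity: float = 0.0
    d_gain: float = 0.0
    wt_override: PhenotypeSpec | None = None

    @property
    def magnitude(self) -> float:
        return (abs(self.d_puncta_count) + abs(self.d_artifact_rate)
                + abs(self.d_artifact_intensity)
                + abs(self.d_base_intensity) + abs(self.d_gain))


@dataclass(frozen=True)
class ScreenConfig:
    """Full description of a synthetic screen (including its master seed)."""

    n_probes: int = 44
    n_true_positives: int = 8
    effect: dict[str, EffectSpec] = field(default_factory=dict)
    image_size_px: int = 256
    cells_per_image: float = 12.0
    nucleus_radius_px: float = 7.0
    noise: NoiseModel = field(default_factory=NoiseModel)
    treatments: tuple[str, ...] = ("DMSO",)
    treatment_effect_multiplier: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_true_positives > self.n_probes:
            raise ValueError("n_true_positives must not exceed n_probes")
        if self.image_size_px < 64:
            raise ValueError("image_size_px must be at least 64")
        for t, m in self.treatment_effect_multiplier.items():
            if m < 0:
                raise ValueError(f"multiplier for {t!r} must be >= 0")

    def multiplier(self, treatment: str) -> float:
        return self.treatment_effect_multiplier.get(treatment, 1.0)


def default_screen_config(
    n_probes: int = 44,
    n_true_positives: int = 8,
    seed: int = 0,
    image_size_px: int = 256,
    treatments: tuple[str, ...] = ("DMSO",),
    treatment_effect_multiplier: dict[str, float] | None = None,
    d_puncta_count: float = 25.0,
) -> ScreenConfig:
    """Standard study conditions: 44 probes, 8 strong puncta-forming hits.

    True positives are the first ``n_true_positives`` panel probes (the
    lipid-trafficking probes); their KO phenotype gains ~25 bright puncta
    per image on top of the probe's diffuse stain.
    """
    skus = screen_probe_skus(n_probes)
    effect = {
        sku: EffectSpec(d_puncta_count=d_puncta_count)
        for sku in skus[:n_true_positives]
    }
    return ScreenConfig(
        n_probes=n_probes,
        n_true_positives=n_true_positives,
        effect=effect,
        image_size_px=image_size_px,
        treatments=treatments,
        treatment_effect_multiplier=treatment_effect_multiplier or {},
        seed=seed,
    )


def screen_probe_skus(n_probes: int) -> list[str]:
    """SKUs used for an n-probe screen: bundled panel first, then Z-series."""
    panel = [p.sku for p in panel_manifest()]
    if n_probes <= len(panel):
        return panel[:n_probes]
    extra = [f"Z{i:03d}" for i in range(n_probes - len(panel))]
    return panel + extra


def screen_panel(n_probes: int) -> list[ProbeEntry]:
    bundled = panel_manifest()
    if n_probes <= len(bundled):
        return bundled[:n_probes]
    extra = [
        ProbeEntry(f"Z{i:03d}", f"Synthetic probe Z{i:03d}", "Organelle morphology",
                   "Synthetic")
        for i in range(n_probes - len(bundled))
    ]
    return bundled + extra


# ---------------------------------------------------------------------------
# deterministic per-image / per-probe random streams


def _stable_hash(key: str) -> int:
    return zlib.crc32(key.encode("utf-8")) & 0x7FFFFFFF


def _rng_for(seed: int, key: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed) & 0x7FFFFFFF,
                               spawn_key=(_stable_hash(key),))
    )


def probe_style(sku: str, seed: int) -> dict[str, float]:
    """Probe-specific staining style, stable across the whole screen."""
    rng = _rng_for(seed, f"style:{sku}")
    return {
        "base_intensity": float(rng.uniform(0.25, 0.5)),
        "cyto_extent": float(rng.uniform(2.3, 3.3)),
        "mottle_scale_px": float(rng.uniform(4.0, 12.0)),
        "mottle_amp": float(rng.uniform(0.15, 0.35)),
        "cell_factor": float(rng.uniform(0.85, 1.15)),
    }


def condition_spec(
    config: ScreenConfig, sku: str, condition: str, treatment: str
) -> PhenotypeSpec:
    """Resolve the phenotype a (probe, condition, treatment) cell draws from."""
    style = probe_style(sku, config.seed)
    eff = config.effect.get(sku)
    if eff is not None and eff.wt_override is not None:
        wt = eff.wt_override
    else:
        wt = PhenotypeSpec(
            stain_class="diffuse",
            base_intensity=style["base_intensity"],
            cyto_extent=style["cyto_extent"],
            mottle_scale_px=style["mottle_scale_px"],
            mottle_amp=style["mottle_amp"],
        )
    if condition == "WT" or eff is None:
        return wt
    m = config.multiplier(treatment)
    kwargs: dict[str, float | str] = {}
    if eff.d_puncta_count != 0:
        kwargs["puncta_count"] = wt.puncta_count + m * eff.d_puncta_count
        kwargs["stain_class"] = "puncta"
    if eff.d_artifact_rate != 0:
        kwargs["artifact_rate"] = max(0.0, wt.artifact_rate + m * eff.d_artifact_rate)
    if eff.d_artifact_intensity != 0:
        kwargs["artifact_intensity"] = float(np.clip(
            wt.artifact_intensity + m * eff.d_artifact_intensity, 0.0, 1.0))
    if eff.d_gain != 0:
        kwargs["gain"] = max(0.0, wt.gain + m * eff.d_gain)
    if eff.d_base_intensity != 0:
        new_base = wt.base_intensity + m * eff.d_base_intensity
        if wt.stain_class != "no_stain":
            kwargs["base_intensity"] = float(np.clip(new_base, 0.0, 1.0))
    return replace(wt, **kwargs)


# ---------------------------------------------------------------------------
# field rendering


def _place_nuclei(
    rng: np.random.Generator, cells: int, size: int, radius: float
) -> np.ndarray:
    """Rejection-sample non-overlapping nucleus centres; (n, 2) array."""
    if cells == 0:
        return np.empty((0, 2))
    margin = radius + 2
    min_sep = 2.4 * radius
    centres: list[np.ndarray] = []
    tries = 0
    max_tries = 400 * cells
    while len(centres) < cells:
        tries += 1
        if tries > max_tries:
            raise PlacementError(
                f"could not place {cells} non-overlapping nuclei of radius "
                f"{radius} in a {size}x{size} field"
            )
        c = rng.uniform(margin, size - margin, size=2)
        if all(np.hypot(*(c - p)) >= min_sep for p in centres):
            centres.append(c)
    return np.array(centres)


def _disk_stamp(img: np.ndarray, centre: np.ndarray, radius: float,
                value: float) -> None:
    """Add ``value`` inside a disk; local crop for speed."""
    r_int = int(np.ceil(radius)) + 1
    cy, cx = centre
    y0, y1 = max(0, int(cy) - r_int), min(img.shape[0], int(cy) + r_int + 1)
    x0, x1 = max(0, int(cx) - r_int), min(img.shape[1], int(cx) + r_int + 1)
    if y0 >= y1 or x0 >= x1:
        return
    yy, xx = np.ogrid[y0:y1, x0:x1]
    mask = (yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2
    img[y0:y1, x0:x1][mask] += value


def _mottle(rng: np.random.Generator, size: int, scale_px: float,
            amp: float) -> np.ndarray:
    """Smooth multiplicative texture field with mean ~1."""
    noise = rng.standard_normal((size, size))
    smooth = ndimage.gaussian_filter(noise, sigma=max(scale_px, 1.0))
    sd = smooth.std()
    if sd > 0:
        smooth = smooth / sd
    return np.clip(1.0 + amp * smooth, 0.2, 2.0)


def _apply_noise(img: np.ndarray, noise: NoiseModel,
                 rng: np.random.Generator) -> np.ndarray:
    clean = np.clip(img, 0.0, 1.0)
    shot = rng.poisson(clean * noise.photon_scale) / noise.photon_scale
    read = rng.normal(0.0, noise.gaussian_sigma, size=img.shape)
    read = np.clip(read, -2.5 * noise.gaussian_sigma, 2.5 * noise.gaussian_sigma)
    return np.clip(shot + read, 0.0, 1.0)


def render_field(
    phenotype: PhenotypeSpec,
    cells: int,
    size: int = 256,
    seed: int | np.random.Generator = 0,
    nucleus_radius_px: float = 7.0,
    noise: NoiseModel | None = None,
) -> np.ndarray:
    """Render one field as a (2, size, size) float image in [0, 1].

    Channel 0 is the DNA (nuclei) channel, channel 1 the probe channel.
    """
    if size < 64:
        raise ValueError("size must be at least 64 pixels")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    noise = noise or NoiseModel()
    r = nucleus_radius_px

    centres = _place_nuclei(rng, cells, size, r)
    dna = np.zeros((size, size))
    for c in centres:
        _disk_stamp(dna, c, r * rng.uniform(0.9, 1.1), 0.7 * rng.uniform(0.85, 1.15))
    dna = ndimage.gaussian_filter(dna, sigma=1.5)

    probe = np.zeros((size, size))
    cls = phenotype.stain_class

    if cls in ("diffuse", "puncta") and len(centres) > 0:
        cyto_r = r * phenotype.cyto_extent
        yy, xx = np.mgrid[0:size, 0:size]
        for c in centres:
            amp = phenotype.base_intensity * rng.uniform(0.8, 1.2)
            d2 = (yy - c[0]) ** 2 + (xx - c[1]) ** 2
            profile = amp * np.exp(-d2 / (2.0 * (cyto_r / 1.6) ** 2))
            # stain is cytoplasmic: dim it over the nucleus
            profile[d2 <= (0.7 * r) ** 2] *= 0.35
            # cells are disjoint compartments: a pixel carries the stain of
            # its own cell, so overlapping profiles do not add up
            probe = np.maximum(probe, profile)
        probe *= _mottle(rng, size, phenotype.mottle_scale_px,
                         phenotype.mottle_amp)

    if cls == "puncta" and len(centres) > 0 and phenotype.puncta_count > 0:
        n_puncta = rng.poisson(phenotype.puncta_count)
        spots = np.zeros((size, size))
        cyto_r = r * phenotype.cyto_extent
        for _ in range(n_puncta):
            c = centres[rng.integers(len(centres))]
            rho = rng.uniform(0.75 * r, cyto_r)
            theta = rng.uniform(0, 2 * np.pi)
            pos = c + rho * np.array([np.sin(theta), np.cos(theta)])
            if not (0 <= pos[0] < size and 0 <= pos[1] < size):
                continue
            _disk_stamp(spots, pos,
                        phenotype.puncta_radius_px * rng.uniform(0.8, 1.25),
                        phenotype.puncta_intensity * rng.uniform(0.85, 1.15))
        probe += ndimage.gaussian_filter(spots, sigma=0.8)

    if cls == "nuclear":
        probe += dna * (phenotype.base_intensity / 0.7 if phenotype.base_intensity
                        else 1.0)

    if cls == "no_stain" and phenotype.artifact_rate > 0:
        n_art = rng.poisson(phenotype.artifact_rate)
        spots = np.zeros((size, size))
        lo = 0.7 * phenotype.artifact_intensity
        hi = 1.5 * phenotype.artifact_intensity
        for _ in range(n_art):
            pos = rng.uniform(3, size - 3, size=2)
            _disk_stamp(spots, pos, rng.uniform(1.5, 3.0),
                        rng.uniform(lo, hi))
        probe += ndimage.gaussian_filter(spots, sigma=0.6)

    dna = _apply_noise(dna, noise, rng)
    probe = _apply_noise(probe, noise, rng)
    if phenotype.gain != 1.0:
        probe = np.clip(probe * phenotype.gain, 0.0, 1.0)
    return np.stack([dna, probe])


# ---------------------------------------------------------------------------
# whole-screen generation


def probe_tif_path(images_dir: str | Path, meta: ImageMeta) -> Path:
    return Path(images_dir) / meta.path


def dna_tif_path(images_dir: str | Path, meta: ImageMeta) -> Path:
    return Path(images_dir) / meta.path.replace("_probe.tif", "_dna.tif")


def generate_screen(
    config: ScreenConfig,
    out_dir: str | Path,
    overwrite: bool = False,
) -> tuple[Path, ScreenLayout]:
    """Render the full screen to ``out_dir`` and return (dir, layout).

    Writes one 16-bit grayscale TIFF per channel (``<image_id>_dna.tif``,
    ``<image_id>_probe.tif``), a ``plate_map.csv`` and a
    ``ground_truth.csv`` (probe_sku, is_true_positive, effect_delta).
    Fully reproducible: same config (incl. seed) gives byte-identical
    pixel data.
    """
    out_dir = Path(out_dir)
    if out_dir.exists() and any(out_dir.iterdir()) and not overwrite:
        raise FileExistsError(
            f"output directory {out_dir} is not empty (pass overwrite=True)"
        )
    out_dir.mkdir(parents=True, exist_ok=True)

    skus = screen_probe_skus(config.n_probes)
    panel = screen_panel(config.n_probes)
    entries: list[ImageMeta] = []
    for sku in skus:
        style = probe_style(sku, config.seed)
        cell_mean = config.cells_per_image * style["cell_factor"]
        for treatment in config.treatments:
            for condition in ("KO", "WT"):
                spec = condition_spec(config, sku, condition, treatment)
                for rep in (1, 2):
                    for fld in (1, 2, 3):
                        image_id = f"{sku}_{treatment}_{condition}_r{rep}_f{fld}"
                        rng = _rng_for(config.seed, f"img:{image_id}")
                        cells = max(1, int(rng.poisson(cell_mean)))
                        img = render_field(
                            spec, cells, config.image_size_px, rng,
                            nucleus_radius_px=config.nucleus_radius_px,
                            noise=config.noise,
                        )
                        stem = f"{image_id}"
                        for ch, name in ((0, "dna"), (1, "probe")):
                            tifffile.imwrite(
                                out_dir / f"{stem}_{name}.tif",
                                (img[ch] * 65535.0).round().astype(np.uint16),
                            )
                        entries.append(ImageMeta(
                            image_id=image_id,
                            probe_sku=sku,
                            condition=condition,
                            treatment=treatment,
                            replicate=rep,
                            field=fld,
                            path=f"{stem}_probe.tif",
                        ))
    layout = ScreenLayout(entries=entries, panel=panel)
    write_plate_map(layout, out_dir / "plate_map.csv")
    truth = pd.DataFrame({
        "probe_sku": skus,
        "is_true_positive": [sku in config.effect and
                             config.effect[sku].magnitude > 0 for sku in skus],
        "effect_delta": [config.effect[sku].magnitude if sku in config.effect
                         else 0.0 for sku in skus],
    })
    truth.to_csv(out_dir / "ground_truth.csv", index=False)
    with open(out_dir / "screen_config.json", "w", encoding="utf-8") as fh:
        fh.write(_config_json(config))
    return out_dir, layout


def _config_json(config: ScreenConfig) -> str:
    import json

    def default(o):
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            return dataclasses.asdict(o)
        raise TypeError(type(o))

    return json.dumps(dataclasses.asdict(config), default=default, indent=2,
                      sort_keys=True)


def load_ground_truth(screen_dir: str | Path) -> pd.DataFrame:
    return pd.read_csv(Path(screen_dir) / "ground_truth.csv",
                       dtype={"probe_sku": str})


def read_field(images_dir: str | Path, meta: ImageMeta) -> np.ndarray:
    """Load one field back as a (2, H, W) float array in [0, 1]."""
    dna = tifffile.imread(dna_tif_path(images_dir, meta)).astype(float) / 65535.0
    probe = tifffile.imread(probe_tif_path(images_dir, meta)).astype(float) / 65535.0
    return np.stack([dna, probe])
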
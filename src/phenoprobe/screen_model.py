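"""Data model and I/O for fluorescent-probe imaging screens.

A screen images a panel of fluorescent chemical probes, one probe per well,
under two experimental conditions (gene knockout ``KO`` vs wild-type ``WT``)
and optionally under several chemical treatments (e.g. ``DMSO`` control vs
an mTOR inhibitor).  This module defines the shared vocabulary of the whole
pipeline -- probe panel entries, per-image metadata, screen layouts and
probe rankings -- together with the CSV readers/writers used to exchange
them between pipeline stages.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

CONDITIONS = ("KO", "WT")

PLATE_MAP_COLUMNS = [
    "image_id",
    "probe_sku",
    "condition",
    "treatment",
    "replicate",
    "field",
    "path",
]

RANKING_COLUMNS = [
    "probe_sku",
    "probe_name",
    "category",
    "dunn_index",
    "rank",
]


class PlateMapSchemaError(ValueError):
    """A plate-map table is missing a required column."""


class PlateMapValidationError(ValueError):
    """A plate-map table violates a layout invariant."""


class ProbeNotFoundError(KeyError):
    """Requested probe SKU is absent from the panel."""


@dataclass(frozen=True)
class ProbeEntry:
    """One probe of the panel: catalogue SKU, human name, readout category."""

    sku: str
    name: str
    category: str
    application: str


@dataclass(frozen=True)
class ImageMeta:
    """Metadata of one acquired field (one probe channel + one DNA channel)."""

    image_id: str
    probe_sku: str
    condition: str
    treatment: str
    replicate: int
    field: int
    path: str

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise PlateMapValidationError(
                f"condition {self.condition!r} for image {self.image_id!r} "
                f"is not one of {CONDITIONS}"
            )
        if self.replicate < 1 or self.field < 1:
            raise PlateMapValidationError(
                f"replicate/field must be positive for image {self.image_id!r}"
            )


@dataclass
class ScreenLayout:
    """The plate map of a screen: image metadata plus the probe panel."""

    entries: list[ImageMeta]
    panel: list[ProbeEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        seen_ids: set[str] = set()
        dupes = []
        for e in self.entries:
            if e.image_id in seen_ids:
                dupes.append(e.image_id)
            seen_ids.add(e.image_id)
        if dupes:
            raise PlateMapValidationError(
                f"duplicate image_id values: {sorted(set(dupes))}"
            )
        keys = [
            (e.probe_sku, e.condition, e.treatment, e.replicate, e.field)
            for e in self.entries
        ]
        if len(set(keys)) != len(keys):
            dup = sorted({k for k in keys if keys.count(k) > 1})
            raise PlateMapValidationError(
                f"duplicate (probe, condition, treatment, replicate, field) "
                f"keys: {dup[:5]}"
            )
        if self.panel:
            panel_skus = {p.sku for p in self.panel}
            unknown = sorted(
                {e.probe_sku for e in self.entries} - panel_skus
            )
            if unknown:
                raise PlateMapValidationError(
                    f"plate map references SKUs absent from the panel: {unknown}"
                )
        # Per (probe, treatment) images should span both conditions; a
        # missing arm is legal input but downstream ranking skips it.
        for (sku, trt), conds in self._condition_map().items():
            if len(conds) < 2:
                warnings.warn(
                    f"probe {sku!r} (treatment {trt!r}) has images for only "
                    f"{sorted(conds)}; it will be excluded from ranking",
                    stacklevel=2,
                )

    def _condition_map(self) -> dict[tuple[str, str], set[str]]:
        out: dict[tuple[str, str], set[str]] = {}
        for e in self.entries:
            out.setdefault((e.probe_sku, e.treatment), set()).add(e.condition)
        return out

    @property
    def probe_skus(self) -> list[str]:
        seen: dict[str, None] = {}
        for e in self.entries:
            seen.setdefault(e.probe_sku)
        return list(seen)

    @property
    def treatments(self) -> list[str]:
        seen: dict[str, None] = {}
        for e in self.entries:
            seen.setdefault(e.treatment)
        return list(seen)

    def images_for(
        self,
        probe_sku: str | None = None,
        condition: str | None = None,
        treatment: str | None = None,
    ) -> list[ImageMeta]:
        out = []
        for e in self.entries:
            if probe_sku is not None and e.probe_sku != probe_sku:
                continue
            if condition is not None and e.condition != condition:
                continue
            if treatment is not None and e.treatment != treatment:
                continue
            out.append(e)
        return out

    def panel_entry(self, sku: str) -> ProbeEntry:
        for p in self.panel:
            if p.sku == sku:
                return p
        raise ProbeNotFoundError(sku)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "image_id": e.image_id,
                    "probe_sku": e.probe_sku,
                    "condition": e.condition,
                    "treatment": e.treatment,
                    "replicate": e.replicate,
                    "field": e.field,
                    "path": e.path,
                }
                for e in self.entries
            ],
            columns=PLATE_MAP_COLUMNS,
        )


def panel_manifest() -> list[ProbeEntry]:
    """Return the bundled default 44-probe panel.

    The panel mixes catalogue probes (lipid stains such as BODIPY 493 and
    NBD cholesterol, the heavy-metal indicator Phen Green FL diacetate, a
    tubulin-directed drug conjugate) with synthetic placeholder probes that
    fill the remaining readout categories (organelle morphology, ion
    concentration, cellular stress) in realistic proportions.
    """
    with resources.files("phenoprobe.data").joinpath("panel.csv").open(
        "r", encoding="utf-8"
    ) as fh:
        df = pd.read_csv(fh, dtype=str)
    return [
        ProbeEntry(
            sku=row.sku,
            name=row.name,
            category=row.category,
            application=row.application,
        )
        for row in df.itertuples(index=False)
    ]


def panel_lookup(sku: str, panel: list[ProbeEntry] | None = None) -> ProbeEntry:
    """Look a probe up by SKU in the given panel (default: bundled panel)."""
    for entry in panel if panel is not None else panel_manifest():
        if entry.sku == sku:
            return entry
    raise ProbeNotFoundError(sku)


def load_plate_map(
    path: str | Path, panel: list[ProbeEntry] | None = None
) -> ScreenLayout:
    """Read and validate a plate-map CSV into a :class:`ScreenLayout`.

    Parameters
    ----------
    path
        CSV file with columns ``image_id, probe_sku, condition, treatment,
        replicate, field, path``.
    panel
        Probe panel the map refers to.  When omitted, a panel is assembled
        from the bundled manifest for known SKUs, with minimal ad-hoc
        entries for SKUs outside the bundled panel.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype={"image_id": str, "probe_sku": str})
    missing = [c for c in PLATE_MAP_COLUMNS if c not in df.columns]
    if missing:
        raise PlateMapSchemaError(
            f"plate map {path} is missing required column(s): {missing}"
        )
    dup = df["image_id"][df["image_id"].duplicated()].tolist()
    if dup:
        raise PlateMapValidationError(f"duplicate image_id values: {dup}")
    entries = [
        ImageMeta(
            image_id=str(r.image_id),
            probe_sku=str(r.probe_sku),
            condition=str(r.condition),
            treatment=str(r.treatment),
            replicate=int(r.replicate),
            field=int(r.field),
            path=str(r.path),
        )
        for r in df.itertuples(index=False)
    ]
    if panel is None:
        bundled = {p.sku: p for p in panel_manifest()}
        panel = []
        for sku in dict.fromkeys(e.probe_sku for e in entries):
            panel.append(
                bundled.get(
                    sku, ProbeEntry(sku, f"probe {sku}", "Unknown", "Unknown")
                )
            )
    return ScreenLayout(entries=entries, panel=panel)


def write_plate_map(layout: ScreenLayout, path: str | Path) -> Path:
    """Write a layout back to plate-map CSV (inverse of load_plate_map)."""
    path = Path(path)
    layout.to_frame().to_csv(path, index=False)
    return path


def write_ranking(ranking: pd.DataFrame, path: str | Path) -> Path:
    """Write a probe ranking table to CSV.

    ``dunn_index`` may be ``+inf`` (perfect separation of two singleton
    clusters); it round-trips through the literal token ``inf``.
    """
    if len(ranking) == 0:
        raise ValueError("refusing to write an empty ranking")
    cols = [c for c in RANKING_COLUMNS if c in ranking.columns] + [
        c for c in ranking.columns if c not in RANKING_COLUMNS
    ]
    path = Path(path)
    ranking[cols].to_csv(path, index=False)
    return path


def read_ranking(path: str | Path) -> pd.DataFrame:
    """Read a ranking CSV written by :func:`write_ranking`."""
    df = pd.read_csv(path, dtype={"probe_sku": str})
    df["dunn_index"] = df["dunn_index"].astype(float)
    df["rank"] = df["rank"].astype(int)
    return df


def rank_table(
    scores: dict[str, float],
    panel: list[ProbeEntry] | None = None,
    extra: dict[str, dict[str, float]] | None = None,
) -> pd.DataFrame:
    """Assemble a ranking table from per-probe Dunn scores.

    Probes are sorted by descending Dunn index; ties break by ascending
    SKU so rankings are deterministic.  ``extra`` may carry additional
    per-probe columns (e.g. fold changes).
    """
    panel = panel if panel is not None else panel_manifest()
    by_sku = {p.sku: p for p in panel}
    # +inf sorts first under negation; NaN never appears (scores finite or inf)
    order = sorted(scores, key=lambda sku: (-scores[sku], sku))
    rows = []
    for i, sku in enumerate(order, start=1):
        entry = by_sku.get(sku)
        row = {
            "probe_sku": sku,
            "probe_name": entry.name if entry else f"probe {sku}",
            "category": entry.category if entry else "Unknown",
            "dunn_index": scores[sku],
            "rank": i,
        }
        if extra and sku in extra:
            row.update(extra[sku])
        rows.append(row)
    return pd.DataFrame(rows)
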
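"""Cell-level quantification tables.

The universal currency of every operation in this package is a table with one
row per segmented cell: a slide identifier, one non-negative intensity column
per marker channel (raw values are integer-valued median pixel intensities),
and optional biological labels (epithelium/stroma tissue class, manual
marker-positive flags, tumor-region flag).  Slides are the batch unit: all
cells on one physical slide share the same staining/imaging conditions.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

SLIDE_COL = "slide_id"
CELL_COL = "cell_id"
TISSUE_COL = "tissue_class"
TUMOR_COL = "tumor_region"
TISSUE_CLASSES = ("epithelium", "stroma")
RAW_SCALE = "raw"

#: suffix for manual marker-positive label columns, e.g. ``cd3_manual_pos``
MANUAL_POS_SUFFIX = "_manual_pos"


class SchemaError(ValueError):
    """The column-role mapping does not match the file."""


class ValidationError(ValueError):
    """The table violates a cell-quantification invariant."""


def manual_pos_col(channel: str) -> str:
    return channel + MANUAL_POS_SUFFIX


@dataclass
class CellQuantTable:
    """One row per segmented cell; slide identifier plus marker intensities.

    Parameters
    ----------
    data
        DataFrame with canonical columns: ``slide_id``, ``cell_id``, one
        column per channel, and optional ``tissue_class``, ``tumor_region``
        and ``{channel}_manual_pos`` label columns.
    channels
        Names of the intensity columns, in order.
    scale_tag
        Provenance of the intensity scale: ``"raw"`` for untouched integer
        median intensities, otherwise the name of the transformation /
        normalization applied (e.g. ``"mean_divide"``, ``"log10+combat"``).
    """

    data: pd.DataFrame
    channels: tuple[str, ...]
    scale_tag: str = RAW_SCALE
    #: (slide, channel) pairs whose raw mean is zero — mean division is
    #: undefined there; flagged at validation, handled by the transforms.
    degenerate_slide_channels: tuple[tuple[str, str], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        self.channels = tuple(self.channels)

    # -- basic accessors -------------------------------------------------
    @property
    def n_cells(self) -> int:
        return len(self.data)

    @property
    def slide_ids(self) -> list[str]:
        return list(pd.unique(self.data[SLIDE_COL]))

    @property
    def n_slides(self) -> int:
        return self.data[SLIDE_COL].nunique()

    @property
    def manual_channels(self) -> list[str]:
        return [c for c in self.channels if manual_pos_col(c) in self.data.columns]

    @property
    def has_tissue_labels(self) -> bool:
        return TISSUE_COL in self.data.columns

    def intensities(self, channel: str) -> np.ndarray:
        self._check_channel(channel)
        return self.data[channel].to_numpy(dtype=float)

    def slide_codes(self) -> tuple[np.ndarray, list[str]]:
        """Integer slide codes per row plus the slide-id order used."""
        codes, uniques = pd.factorize(self.data[SLIDE_COL])
        return codes, list(uniques)

    def _check_channel(self, channel: str) -> None:
        if channel not in self.channels:
            raise KeyError(f"unknown channel {channel!r}; have {list(self.channels)}")

    # -- construction / copies -------------------------------------------
    def with_intensities(self, values: Mapping[str, np.ndarray], scale_tag: str) -> "CellQuantTable":
        """Copy of the table with some channels replaced and a new scale tag."""
        df = self.data.copy()
        for channel, v in values.items():
            self._check_channel(channel)
            df[channel] = np.asarray(v, dtype=float)
        return CellQuantTable(df, self.channels, scale_tag=scale_tag,
                              degenerate_slide_channels=self.degenerate_slide_channels)

    # -- validation ------------------------------------------------------
    def validate(self) -> "CellQuantTable":
        """Check invariants; returns self so calls can be chained.

        Raises :class:`ValidationError` on missing or (for the raw scale)
        negative intensities.  All-zero slide-channel combinations are only
        flagged, because downstream handling depends on the transformation.
        """
        if SLIDE_COL not in self.data.columns:
            raise SchemaError("table has no slide_id column")
        if self.n_slides < 1:
            raise ValidationError("table has no slides")
        for channel in self.channels:
            col = self.data[channel]
            if not pd.api.types.is_numeric_dtype(col):
                raise ValidationError(f"channel {channel!r} is not numeric")
            if col.isna().any():
                row = int(col.isna().idxmax())
                raise ValidationError(f"missing intensity in channel {channel!r} at row {row}")
            if self.scale_tag == RAW_SCALE and (col < 0).any():
                row = int((col < 0).idxmax())
                cell = self.data[CELL_COL].iloc[row] if CELL_COL in self.data.columns else row
                raise ValidationError(
                    f"negative raw intensity {col.iloc[row]} in channel {channel!r} "
                    f"for cell {cell!r} (row {row})"
                )
        if self.scale_tag == RAW_SCALE:
            degenerate = []
            for channel in self.channels:
                means = self.data.groupby(SLIDE_COL, sort=False, observed=True)[channel].mean()
                for slide in means.index[means == 0]:
                    degenerate.append((str(slide), channel))
            self.degenerate_slide_channels = tuple(degenerate)
            if degenerate:
                warnings.warn(
                    f"all-zero slide-channel combinations (mean division undefined): {degenerate}",
                    stacklevel=2,
                )
        return self

    # -- summaries -------------------------------------------------------
    def slide_summary(self, channel: str) -> pd.DataFrame:
        """Per-slide mean intensity and cell count for one channel.

        Returns a DataFrame indexed by slide with columns ``mean`` (the slide
        mean of the cell intensities) and ``n_cells`` (number of quantified
        cells on the slide).
        """
        self._check_channel(channel)
        g = self.data.groupby(SLIDE_COL, sort=False, observed=True)[channel]
        out = pd.DataFrame({"mean": g.mean(), "n_cells": g.size()})
        out.index = out.index.astype(str)
        out.index.name = SLIDE_COL
        return out


def _meta_path(path: Path) -> Path:
    return path.with_name(path.name + ".meta.json")


def read_cell_table(path: str | Path, schema: Mapping[str, object] | None = None) -> CellQuantTable:
    """Read a cell quantification CSV and validate it.

    ``schema`` maps column roles to CSV column names::

        {"slide": "SlideID", "cell": "CellID",
         "channels": {"cd3": "Median_CD3"},     # or a plain list of names
         "tissue": "TissueType", "tumor": "InTumor",
         "manual_positive": {"cd3": "CD3_manual"}}

    Only ``slide`` and ``channels`` are required.  If ``schema`` is omitted
    the companion ``{path}.meta.json`` written by :func:`write_cell_table`
    must exist and is used instead.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    scale_tag = RAW_SCALE
    if schema is None:
        meta = _meta_path(path)
        if not meta.exists():
            raise SchemaError(f"no schema given and no metadata file {meta}")
        info = json.loads(meta.read_text())
        schema = info["schema"]
        scale_tag = info.get("scale_tag", RAW_SCALE)

    if "slide" not in schema:
        raise SchemaError("schema must name the slide column under 'slide'")
    if "channels" not in schema or not schema["channels"]:
        raise SchemaError("schema must name at least one intensity column under 'channels'")
    channels = schema["channels"]
    if not isinstance(channels, Mapping):
        channels = {str(c): str(c) for c in channels}

    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    raw = pd.read_csv(path, sep=sep)
    if schema["slide"] not in raw.columns:
        raise SchemaError(f"slide column {schema['slide']!r} not in file")
    df = pd.DataFrame({SLIDE_COL: raw[schema["slide"]].astype(str)})
    cell_src = schema.get("cell")
    df[CELL_COL] = raw[cell_src].astype(str) if cell_src else np.arange(len(raw)).astype(str)
    for channel, src in channels.items():
        if src not in raw.columns:
            raise SchemaError(f"intensity column {src!r} (channel {channel!r}) not in file")
        try:
            df[channel] = pd.to_numeric(raw[src], errors="raise")
        except (ValueError, TypeError) as exc:
            raise ValidationError(f"non-numeric intensity in channel {channel!r}: {exc}") from exc
    if schema.get("tissue"):
        df[TISSUE_COL] = raw[schema["tissue"]].astype(str)
    if schema.get("tumor"):
        df[TUMOR_COL] = raw[schema["tumor"]].astype(int)
    for channel, src in (schema.get("manual_positive") or {}).items():
        df[manual_pos_col(channel)] = raw[src].astype(int)
    return CellQuantTable(df, tuple(channels), scale_tag=scale_tag).validate()


def write_cell_table(table: CellQuantTable, path: str | Path) -> None:
    """Write the table as CSV plus a ``{path}.meta.json`` companion.

    The metadata file records the scale tag and the column-role schema so
    :func:`read_cell_table` can restore the table without arguments.
    """
    path = Path(path)
    table.data.to_csv(path, index=False)
    schema: dict[str, object] = {
        "slide": SLIDE_COL,
        "cell": CELL_COL,
        "channels": {c: c for c in table.channels},
    }
    if table.has_tissue_labels:
        schema["tissue"] = TISSUE_COL
    if TUMOR_COL in table.data.columns:
        schema["tumor"] = TUMOR_COL
    manual = {c: manual_pos_col(c) for c in table.manual_channels}
    if manual:
        schema["manual_positive"] = manual
    _meta_path(path).write_text(
        json.dumps({"scale_tag": table.scale_tag, "schema": schema}, indent=1)
    )


def slide_summary(table: CellQuantTable, channel: str) -> pd.DataFrame:
    """Module-level alias for :meth:`CellQuantTable.slide_summary`."""
    return table.slide_summary(channel)
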
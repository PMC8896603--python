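"""Scale transformations applied per slide and channel before normalization.

Three transformations of the raw integer median-cell intensities y:

* ``log10``             — log10(y + 1); the +1 keeps integer zeros finite.
* ``mean_divide``       — y / mu_ic, where mu_ic is the slide-channel mean of
  the raw values; every slide's mean becomes exactly 1.
* ``mean_divide_log10`` — log10(y / mu_ic + 1/2); values above half the slide
  mean map to positive numbers, values below to negative ones, with a hard
  lower bound of log10(1/2) at y = 0.

All three are strictly increasing, so within-slide cell rankings survive.
mu_ic is always the mean of the *raw* slide-channel values, captured when the
spec is fitted, so the same normalization can be replayed on held-out cells.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from .data_model import RAW_SCALE, SLIDE_COL, CellQuantTable

KINDS = ("none", "log10", "mean_divide", "mean_divide_log10")
_MEAN_KINDS = ("mean_divide", "mean_divide_log10")

#: Table-2-style display names for the transformation kinds.
DISPLAY_NAMES = {
    "none": "None",
    "log10": "log10",
    "mean_divide": "Mean division",
    "mean_divide_log10": "Mean division log10",
}


class DegenerateSlideError(ValueError):
    """A slide-channel mean is non-positive; mean division is undefined."""


class ScaleError(ValueError):
    """The table is not on the scale the operation expects."""


def transform_log10(y):
    """log10(y + 1) for non-negative y."""
    y = np.asarray(y, dtype=float)
    if np.any(y < 0):
        raise ValueError("log10 transform requires non-negative intensities")
    return np.log10(y + 1.0)


def transform_mean_divide(y, mu: float):
    """y / mu for a positive slide-channel mean mu."""
    if mu <= 0:
        raise DegenerateSlideError(f"slide-channel mean must be positive, got {mu}")
    return np.asarray(y, dtype=float) / mu


def transform_mean_divide_log10(y, mu: float):
    """log10(y / mu + 1/2); positive iff y exceeds half the slide mean."""
    if mu <= 0:
        raise DegenerateSlideError(f"slide-channel mean must be positive, got {mu}")
    return np.log10(np.asarray(y, dtype=float) / mu + 0.5)


@dataclass
class TransformSpec:
    """A transformation kind plus the per-slide means it was fitted with.

    ``mu[channel][slide]`` holds the raw slide-channel means captured at fit
    time (only for the mean-division kinds).
    """

    kind: str
    mu: dict[str, dict[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown transform kind {self.kind!r}; choose from {KINDS}")

    @property
    def display_name(self) -> str:
        return DISPLAY_NAMES[self.kind]

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps({"kind": self.kind, "mu": self.mu}, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "TransformSpec":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        d = json.loads(text)
        return cls(kind=d["kind"], mu=d.get("mu", {}))


def fit_transform_spec(table: CellQuantTable, kind: str) -> TransformSpec:
    """Capture per-slide raw means for ``kind`` from a raw-scale table."""
    spec = TransformSpec(kind)
    if kind not in _MEAN_KINDS:
        return spec
    if table.scale_tag != RAW_SCALE:
        raise ScaleError(
            f"mean-division transforms are fitted on the raw scale, table is {table.scale_tag!r}"
        )
    for channel in table.channels:
        summ = table.slide_summary(channel)
        bad = summ.index[summ["mean"] <= 0].tolist()
        if bad:
            raise DegenerateSlideError(
                f"channel {channel!r}: slide(s) {bad} have non-positive mean; "
                "mean division is undefined there"
            )
        spec.mu[channel] = {str(s): float(m) for s, m in summ["mean"].items()}
    return spec


def apply_transform(table: CellQuantTable, spec: TransformSpec | str) -> CellQuantTable:
    """Apply a transformation to every channel of a raw-scale table.

    Passing a kind string fits the spec on the fly.  Re-transforming an
    already transformed table raises :class:`ScaleError`.
    """
    if isinstance(spec, str):
        spec = fit_transform_spec(table, spec)
    if spec.kind == "none":
        return table
    if table.scale_tag != RAW_SCALE:
        raise ScaleError(
            f"table already carries scale {table.scale_tag!r}; transforms apply to raw data"
        )
    slides = table.data[SLIDE_COL].astype(str).to_numpy()
    new: dict[str, np.ndarray] = {}
    for channel in table.channels:
        y = table.intensities(channel)
        if spec.kind == "log10":
            new[channel] = transform_log10(y)
        else:
            mu_map = spec.mu.get(channel)
            if mu_map is None:
                raise ValueError(f"spec has no slide means for channel {channel!r}")
            try:
                mu = np.array([mu_map[s] for s in slides])
            except KeyError as exc:
                raise ValueError(f"spec has no mean for slide {exc} in channel {channel!r}") from exc
            if np.any(mu <= 0):
                raise DegenerateSlideError(f"non-positive slide mean in channel {channel!r}")
            if spec.kind == "mean_divide":
                new[channel] = y / mu
            else:
                new[channel] = np.log10(y / mu + 0.5)
    return table.with_intensities(new, scale_tag=spec.kind)
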
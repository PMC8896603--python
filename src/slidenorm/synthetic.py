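"""Synthetic multi-slide cell quantification tables with known slide effects.

The generator emulates the structure of segmented multiplexed-immuno-
fluorescence data: many slides, thousands of cells per slide, right-skewed
non-negative integer intensities (median pixel values), a bimodal marker
positive/negative mixture per channel, and slide-level mean and variance
batch effects.  On the natural-log scale each cell's intensity is

    log y = m_class + gamma_ic + delta_ic * s_class * z,    z ~ N(0, 1),

with gamma_ic ~ N(0, tau^2) the slide mean effect and delta2_ic ~
InverseGamma(omega, beta) the slide variance effect, mirroring the
location-scale batch model the ComBat fit assumes; exp(log y) is rounded to
the nearest non-negative integer.  Two latent tissue classes (epithelium /
stroma) differ in their positivity rates on four designated channels, and
immune-style channels carry noisy "manual" positive labels.

Ground truth (per-slide effects, per-cell classes and positivity) is
returned alongside the table so parameter recovery is directly testable.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .data_model import (
    CELL_COL,
    SLIDE_COL,
    TISSUE_COL,
    TUMOR_COL,
    CellQuantTable,
    manual_pos_col,
)


class ConfigError(ValueError):
    """A simulation parameter is out of its valid range (named in the message)."""


@dataclass(frozen=True)
class ChannelModel:
    """Log-normal negative/positive mixture for one marker channel.

    ``tissue_role`` ties positivity to a tissue class (the channel is "on"
    mostly in that class); ``manual_label`` emits a noisy manual
    marker-positive flag column alongside the intensities.
    """

    bg_log_mean: float = 3.0   # background ~ exp(3) ≈ 20 counts
    bg_log_sd: float = 0.6
    pos_log_mean: float = 4.5  # positive ~ exp(4.5) ≈ 90 counts
    pos_log_sd: float = 0.4
    pos_frac: float = 0.3
    tissue_role: str | None = None  # "epithelium" | "stroma" | None
    manual_label: bool = False


def default_channels() -> dict[str, ChannelModel]:
    """Six channels: four tissue-discriminating, two immune with manual labels."""
    return {
        "vimentin": ChannelModel(tissue_role="stroma"),
        "collagen": ChannelModel(tissue_role="stroma"),
        "panck": ChannelModel(tissue_role="epithelium"),
        "nakatpase": ChannelModel(tissue_role="epithelium"),
        "cd3": ChannelModel(pos_frac=0.15, manual_label=True),
        "cd8": ChannelModel(pos_frac=0.10, manual_label=True),
    }


@dataclass
class SimConfig:
    """Study-scale defaults: 20 slides x 2000 cells, slide mean effects tau=0.5."""

    n_slides: int = 20
    cells_per_slide: int | tuple[int, int] = 2000
    tau: float = 0.5           # sd of the slide mean effect, natural-log scale
    omega: float = 60.0        # inverse-gamma shape of the slide variance effect
    beta: float = 59.0         # inverse-gamma scale; mean beta/(omega-1) = 1
    channels: dict[str, ChannelModel] = field(default_factory=default_channels)
    #: positivity rates of tissue-role channels in / out of their class
    p_pos_in_class: float = 0.85
    p_pos_out_class: float = 0.05
    epithelium_frac: float = 0.5
    label_noise: float = 0.02
    tumor_frac: float = 0.3
    seed: int = 0

    def validate(self) -> "SimConfig":
        if self.n_slides < 1:
            raise ConfigError(f"n_slides must be >= 1, got {self.n_slides}")
        cells = self.cells_per_slide
        if isinstance(cells, int):
            if cells < 1:
                raise ConfigError(f"cells_per_slide must be >= 1, got {cells}")
        else:
            lo, hi = cells
            if lo < 1 or hi < lo:
                raise ConfigError(f"cells_per_slide range invalid: {cells}")
        if self.tau < 0:
            raise ConfigError(f"tau must be >= 0, got {self.tau}")
        if self.omega <= 2:
            raise ConfigError(f"omega must be > 2 for a finite variance-effect mean+variance, got {self.omega}")
        if self.beta <= 0:
            raise ConfigError(f"beta must be > 0, got {self.beta}")
        for p_name in ("p_pos_in_class", "p_pos_out_class", "epithelium_frac", "tumor_frac"):
            p = getattr(self, p_name)
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{p_name} must be in [0, 1], got {p}")
        if not 0.0 <= self.label_noise < 1.0:
            raise ConfigError(f"label_noise must be in [0, 1), got {self.label_noise}")
        for name, ch in self.channels.items():
            if ch.bg_log_sd <= 0 or ch.pos_log_sd <= 0:
                raise ConfigError(f"channel {name!r}: log-sds must be > 0")
            if not 0.0 < ch.pos_frac < 1.0:
                raise ConfigError(f"channel {name!r}: pos_frac must be in (0, 1), got {ch.pos_frac}")
            if ch.tissue_role not in (None, "epithelium", "stroma"):
                raise ConfigError(f"channel {name!r}: unknown tissue_role {ch.tissue_role!r}")
        return self


@dataclass
class SimTruth:
    """Ground truth behind a simulated table."""

    gamma: pd.DataFrame    # slide x channel true mean effects (log scale)
    delta2: pd.DataFrame   # slide x channel true variance effects
    tissue_class: pd.Series
    positive: pd.DataFrame  # cell x channel true positivity (bool)

    def to_json_dict(self) -> dict:
        return {
            "gamma": self.gamma.to_dict(orient="index"),
            "delta2": self.delta2.to_dict(orient="index"),
            "tissue_class": self.tissue_class.tolist(),
            "positive": {c: self.positive[c].astype(int).tolist() for c in self.positive.columns},
        }


def simulate_table(config: SimConfig | None = None, **overrides) -> tuple[CellQuantTable, SimTruth]:
    """Draw one table (and its ground truth) from the generative model.

    Keyword overrides are applied on top of ``config`` (or the defaults), so
    ``simulate_table(n_slides=3, seed=7)`` works without building a config.
    Fully determined by ``config.seed``.
    """
    config = replace(config or SimConfig(), **overrides).validate()
    rng = np.random.default_rng(config.seed)
    slide_ids = [f"slide{i + 1:02d}" for i in range(config.n_slides)]
    if isinstance(config.cells_per_slide, int):
        n_cells = np.full(config.n_slides, config.cells_per_slide)
    else:
        lo, hi = config.cells_per_slide
        n_cells = rng.integers(lo, hi + 1, size=config.n_slides)
    total = int(n_cells.sum())
    codes = np.repeat(np.arange(config.n_slides), n_cells)

    chan_names = list(config.channels)
    gamma = rng.normal(0.0, config.tau, size=(config.n_slides, len(chan_names)))
    # delta2 ~ InverseGamma(omega, scale=beta): reciprocal of Gamma(omega, rate=beta)
    delta2 = 1.0 / rng.gamma(config.omega, 1.0 / config.beta, size=(config.n_slides, len(chan_names)))

    tissue = np.where(rng.random(total) < config.epithelium_frac, "epithelium", "stroma")
    df = pd.DataFrame({
        SLIDE_COL: np.asarray(slide_ids, dtype=object)[codes],
        CELL_COL: [f"cell{j:06d}" for j in range(total)],
    })
    positive = {}
    for c, name in enumerate(chan_names):
        ch = config.channels[name]
        if ch.tissue_role is None:
            p = np.full(total, ch.pos_frac)
        else:
            p = np.where(tissue == ch.tissue_role, config.p_pos_in_class, config.p_pos_out_class)
        pos = rng.random(total) < p
        positive[name] = pos
        m = np.where(pos, ch.pos_log_mean, ch.bg_log_mean)
        s = np.where(pos, ch.pos_log_sd, ch.bg_log_sd)
        log_y = m + gamma[codes, c] + np.sqrt(delta2[codes, c]) * s * rng.normal(size=total)
        df[name] = np.maximum(np.rint(np.exp(log_y)), 0.0).astype(int)
    df[TISSUE_COL] = tissue
    df[TUMOR_COL] = (rng.random(total) < config.tumor_frac).astype(int)
    for name in chan_names:
        ch = config.channels[name]
        if ch.manual_label:
            flip = rng.random(total) < config.label_noise
            df[manual_pos_col(name)] = (positive[name] ^ flip).astype(int)

    table = CellQuantTable(df, tuple(chan_names)).validate()
    truth = SimTruth(
        gamma=pd.DataFrame(gamma, index=slide_ids, columns=chan_names),
        delta2=pd.DataFrame(delta2, index=slide_ids, columns=chan_names),
        tissue_class=pd.Series(tissue, name=TISSUE_COL),
        positive=pd.DataFrame(positive),
    )
    return table, truth


#: configuration of the small fixed fixture used for exact-value unit tests
FIXTURE_CONFIG = dict(n_slides=3, cells_per_slide=60, tau=0.4, seed=20_220_104)
FIXTURE_CHANNELS = ("vimentin", "cd3")


def fixture_small() -> tuple[CellQuantTable, SimTruth]:
    """A fixed 3-slide x 60-cell, 2-channel table for exact-value tests."""
    channels = {
        "vimentin": ChannelModel(tissue_role="stroma"),
        "cd3": ChannelModel(pos_frac=0.15, manual_label=True),
    }
    return simulate_table(SimConfig(channels=channels, **FIXTURE_CONFIG))


def table_checksum(table: CellQuantTable) -> str:
    """Stable content hash of a table (values + columns), for fixture contracts."""
    payload = table.data.to_csv(index=False).encode()
    return hashlib.sha256(payload).hexdigest()
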
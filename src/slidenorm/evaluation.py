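"""Quantitative evaluation of slide-to-slide normalization.

Five complementary views of how much slide-level technical variation remains
after a transformation/normalization, and how much biology survives:

* :func:`ad_ksample` — Scholz–Stephens k-sample Anderson–Darling statistic
  across slides (midrank tie correction; integer intensities are heavily
  tied).  Larger = slide distributions more separated.
* :func:`otsu_threshold` / :func:`otsu_discordance` — per-slide vs pooled
  Otsu thresholds; the discordance score is the mean proportion of cells
  whose positive/negative call flips between the two.  Lower = better.
* :func:`marker_positive_accuracy` — agreement of pooled-threshold calls
  with manual marker-positive labels.  Higher = better.
* :func:`variance_proportion` — share of variance attributable to a slide
  random intercept (REML mixed model).  Lower = better.
* :func:`embedding_ari` — UMAP + k-means label recovery measured by the
  adjusted Rand index (low is good for slide IDs, high for tissue classes).

:func:`evaluate_method` aggregates everything into an :class:`EvalReport`.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score

from .data_model import SLIDE_COL, TISSUE_COL, CellQuantTable, manual_pos_col


# ---------------------------------------------------------------------------
# k-sample Anderson–Darling
# ---------------------------------------------------------------------------

def ad_ksample(samples: Sequence[np.ndarray], standardized: bool = True) -> float:
    """Scholz–Stephens k-sample Anderson–Darling statistic with midrank ties.

    ``standardized=True`` (default) returns T = (A2 - (k-1)) / sigma_N, the
    form whose null distribution is sample-size free; ``False`` returns the
    raw A2 statistic.  Larger values indicate stronger evidence that the
    slides are drawn from different distributions.
    """
    samples = [np.asarray(s, dtype=float) for s in samples]
    k = len(samples)
    if k < 2:
        raise ValueError("need at least two samples")
    if any(s.size == 0 for s in samples):
        raise ValueError("empty sample")
    n = np.array([s.size for s in samples])
    N = int(n.sum())
    pooled = np.concatenate(samples)
    zstar, l = np.unique(pooled, return_counts=True)
    L = zstar.size
    if L < 2:
        raise ValueError("all pooled values identical; statistic undefined")
    B = np.cumsum(l) - l / 2.0  # midrank pooled counts
    denom = B * (N - B) - N * l / 4.0
    inner_w = l / N
    a2 = 0.0
    for i in range(k):
        f = np.zeros(L)
        vals, cnt = np.unique(samples[i], return_counts=True)
        f[np.searchsorted(zstar, vals)] = cnt
        M = np.cumsum(f) - f / 2.0
        a2 += (1.0 / n[i]) * np.sum(inner_w * (N * M - n[i] * B) ** 2 / denom)
    a2 *= (N - 1) / N
    if not standardized:
        return float(a2)
    H = float(np.sum(1.0 / n))
    i_range = np.arange(1, N)
    h = float(np.sum(1.0 / i_range))
    # g = sum_{i=1}^{N-2} sum_{j=i+1}^{N-1} 1 / ((N-i) j)
    inv = 1.0 / i_range  # 1/1 .. 1/(N-1)
    tail = np.cumsum(inv[::-1])[::-1]  # tail[j-1] = sum_{m=j}^{N-1} 1/m
    ii = np.arange(1, N - 1)
    g = float(np.sum((1.0 / (N - ii)) * tail[ii]))  # tail[i] = sum_{m=i+1}^{N-1} 1/m
    a = (4 * g - 6) * (k - 1) + (10 - 6 * g) * H
    b = (2 * g - 4) * k**2 + 8 * h * k + (2 * g - 14 * h - 4) * H - 8 * h + 4 * g - 6
    c = (6 * h + 2 * g - 2) * k**2 + (4 * h - 4 * g + 6) * k + (2 * h - 6) * H + 4 * h
    d = (2 * h + 6) * k**2 - 4 * h * k
    var = (a * N**3 + b * N**2 + c * N + d) / ((N - 1.0) * (N - 2.0) * (N - 3.0))
    return float((a2 - (k - 1)) / np.sqrt(var))


def ad_ksample_slides(table: CellQuantTable, channel: str, standardized: bool = True) -> float:
    """AD statistic across the slides of one channel."""
    codes, slide_ids = table.slide_codes()
    y = table.intensities(channel)
    return ad_ksample([y[codes == i] for i in range(len(slide_ids))], standardized=standardized)


# ---------------------------------------------------------------------------
# Otsu thresholding
# ---------------------------------------------------------------------------

def otsu_threshold(values: np.ndarray, nbins: int = 256) -> float:
    """Histogram Otsu threshold: the bin edge maximizing between-class variance.

    Values are binned into ``nbins`` equal-width bins over [min, max]; every
    interior bin edge t is a candidate split (class 0: y < t, class 1:
    y >= t, matching histogram bin membership), and the edge maximizing
    w0 * w1 * (m0 - m1)^2 is returned, ties broken by the smallest edge.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2 or np.min(values) == np.max(values):
        raise ValueError("Otsu threshold needs at least two distinct values")
    counts, edges = np.histogram(values, bins=nbins, range=(values.min(), values.max()))
    sums, _ = np.histogram(values, bins=nbins, range=(values.min(), values.max()), weights=values)
    n = values.size
    c0 = np.cumsum(counts)[:-1]          # cells below edge k+1, k = 0..nbins-2
    s0 = np.cumsum(sums)[:-1]
    c1 = n - c0
    s1 = values.sum() - s0
    with np.errstate(divide="ignore", invalid="ignore"):
        m0 = np.where(c0 > 0, s0 / c0, 0.0)
        m1 = np.where(c1 > 0, s1 / c1, 0.0)
    w0 = c0 / n
    w1 = c1 / n
    score = w0 * w1 * (m0 - m1) ** 2
    best = int(np.argmax(score))  # argmax takes the first (smallest edge) on ties
    return float(edges[best + 1])


def otsu_discordance(table: CellQuantTable, channel: str, nbins: int = 256
                     ) -> tuple[pd.Series, float]:
    """Per-slide threshold discordance scores and their mean for one channel.

    For each slide, the score is the proportion of its cells whose call
    I(y > threshold) differs between the slide-specific and the pooled
    (global) Otsu threshold.  Slides with a degenerate (constant) channel are
    scored 0 against the global calls with a warning.
    """
    y = table.intensities(channel)
    codes, slide_ids = table.slide_codes()
    o_global = otsu_threshold(y, nbins=nbins)
    global_calls = y > o_global
    scores = {}
    for i, slide in enumerate(slide_ids):
        mask = codes == i
        yi = y[mask]
        try:
            o_slide = otsu_threshold(yi, nbins=nbins)
        except ValueError:
            warnings.warn(
                f"slide {slide!r} is degenerate in channel {channel!r}; "
                "scoring it against the global calls", stacklevel=2,
            )
            scores[str(slide)] = 0.0
            continue
        scores[str(slide)] = float(np.mean((yi > o_slide) != global_calls[mask]))
    per_slide = pd.Series(scores, name="discordance")
    return per_slide, float(per_slide.mean())


def marker_positive_accuracy(table: CellQuantTable, channel: str,
                             labels: np.ndarray | None = None, nbins: int = 256) -> float:
    """Proportion of cells whose pooled-Otsu call matches the manual label."""
    if labels is None:
        col = manual_pos_col(channel)
        if col not in table.data.columns:
            raise ValueError(f"no manual labels for channel {channel!r}")
        labels = table.data[col].to_numpy()
    labels = np.asarray(labels).astype(bool)
    if labels.size == 0:
        raise ValueError("no labeled cells")
    y = table.intensities(channel)
    calls = y > otsu_threshold(y, nbins=nbins)
    return float(np.mean(calls == labels))


# ---------------------------------------------------------------------------
# Variance components
# ---------------------------------------------------------------------------

def _anova_variance_proportion(y: np.ndarray, codes: np.ndarray) -> float:
    # one-way random-effects method-of-moments (fallback when REML fails)
    k = codes.max() + 1
    n_i = np.bincount(codes, minlength=k).astype(float)
    N = float(y.size)
    means = np.bincount(codes, weights=y, minlength=k) / n_i
    grand = y.mean()
    ssw = float(np.sum((y - means[codes]) ** 2))
    ssb = float(np.sum(n_i * (means - grand) ** 2))
    msw = ssw / (N - k)
    msb = ssb / (k - 1)
    n0 = (N - np.sum(n_i**2) / N) / (k - 1)
    s2_slide = max(0.0, (msb - msw) / n0)
    total = s2_slide + msw
    return s2_slide / total if total > 0 else 0.0


def variance_proportion(values: np.ndarray, slide_ids: Iterable) -> float:
    """Proportion of variance at the slide level from a random-intercept model.

    Fits  y = mu + b_slide + eps  by REML (statsmodels MixedLM) and returns
    sigma2_slide / (sigma2_slide + sigma2_residual); boundary estimates of 0
    are legitimate.  Falls back to the one-way ANOVA moment estimator with a
    warning if the REML fit fails.
    """
    import statsmodels.api as sm

    y = np.asarray(values, dtype=float)
    codes, uniques = pd.factorize(np.asarray(list(slide_ids)))
    if len(uniques) < 2:
        raise ValueError("variance proportion needs at least two slides")
    model = sm.MixedLM(y, np.ones((y.size, 1)), groups=codes)
    res = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        # lbfgs can stall on a spurious boundary solution and its score is
        # singular when the slide variance is exactly zero; fit with a
        # derivative-free optimizer too and keep the higher REML likelihood.
        for method in ("lbfgs", "powell"):
            try:
                cand = model.fit(reml=True, method=method)
            except Exception:
                continue
            if not np.isfinite(cand.llf):  # singular fit masquerading as optimal
                continue
            if res is None or cand.llf > res.llf:
                res = cand
    if res is None:
        warnings.warn("REML fit failed; using the ANOVA moment estimator", stacklevel=2)
        return _anova_variance_proportion(y, codes)
    s2_slide = max(0.0, float(np.asarray(res.cov_re)[0, 0]))
    s2_res = float(res.scale)
    total = s2_slide + s2_res
    return s2_slide / total if total > 0 else 0.0


# ---------------------------------------------------------------------------
# Embeddings and the adjusted Rand index
# ---------------------------------------------------------------------------

def adjusted_rand_index(labels_a: Sequence, labels_b: Sequence) -> float:
    """Hubert–Arabie adjusted Rand index between two labelings of the same cells."""
    labels_a = np.asarray(labels_a)
    labels_b = np.asarray(labels_b)
    if labels_a.shape != labels_b.shape:
        raise ValueError("labelings must have equal length")
    if labels_a.size < 2:
        raise ValueError("need at least two items")
    return float(adjusted_rand_score(labels_a, labels_b))


def _stratified_subsample(codes: np.ndarray, frac: float, rng: np.random.Generator) -> np.ndarray:
    idx = []
    for code in np.unique(codes):
        rows = np.flatnonzero(codes == code)
        take = max(1, int(round(frac * rows.size)))
        idx.append(rng.choice(rows, size=take, replace=False))
    return np.sort(np.concatenate(idx))


def embedding_ari(
    table: CellQuantTable,
    channels: Sequence[str],
    labels: Sequence,
    frac: float = 0.10,
    seed: int = 0,
    n_neighbors: int = 15,
    min_dist: float = 0.1,
) -> tuple[np.ndarray, float]:
    """UMAP the chosen markers, k-means the embedding, score label recovery.

    A seeded subsample of ``frac`` of the cells (stratified by slide so small
    slides are kept) is embedded in 2-D; k-means with k = number of distinct
    labels clusters the embedding, and the ARI between clusters and the true
    labels of the subsampled cells is returned along with the coordinates.
    """
    import umap

    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size < 2:
        raise ValueError("need at least two label classes")
    codes, _ = table.slide_codes()
    rng = np.random.default_rng(seed)
    idx = _stratified_subsample(codes, frac, rng)
    X = np.column_stack([table.intensities(c) for c in channels])[idx]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        coords = umap.UMAP(
            n_components=2, n_neighbors=n_neighbors, min_dist=min_dist,
            metric="euclidean", random_state=seed,
        ).fit_transform(X)
        km = KMeans(n_clusters=classes.size, random_state=seed, n_init=10).fit(coords)
    ari = adjusted_rand_index(km.labels_, labels[idx])
    return coords, ari


# ---------------------------------------------------------------------------
# Aggregated report
# ---------------------------------------------------------------------------

@dataclass
class EvalReport:
    """Per-channel and cross-channel metrics for one normalization method.

    Orientation: the AD statistic, discordance, slide-ARI and slide variance
    proportion are all "smaller is better"; marker-positive accuracy and the
    tissue-class ARI are "larger is better".
    """

    method: str
    per_channel: pd.DataFrame  # index: channel; columns: ad_statistic, otsu_discordance, variance_proportion
    accuracy: dict[str, float] = field(default_factory=dict)
    ari_slide: float | None = None
    ari_tissue: float | None = None

    @property
    def mean_ad(self) -> float:
        return float(self.per_channel["ad_statistic"].mean())

    @property
    def mean_discordance(self) -> float:
        return float(self.per_channel["otsu_discordance"].mean())

    @property
    def mean_variance_proportion(self) -> float:
        return float(self.per_channel["variance_proportion"].mean())

    def to_row(self) -> pd.Series:
        """One summary row in the style of the published comparison table."""
        row = {
            "Method": self.method,
            "Mean AD test statistic": self.mean_ad,
            "Mean Otsu discordance score": self.mean_discordance,
            "Adj. Rand index (slide ID)": self.ari_slide,
            "Mean variance proportion (slide ID)": self.mean_variance_proportion,
        }
        if self.ari_tissue is not None:
            row["Adj. Rand index (tissue)"] = self.ari_tissue
        for channel, acc in self.accuracy.items():
            row[f"Accuracy ({channel})"] = acc
        return pd.Series(row)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "method": self.method,
            "per_channel": self.per_channel.to_dict(orient="index"),
            "accuracy": self.accuracy,
            "ari_slide": self.ari_slide,
            "ari_tissue": self.ari_tissue,
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "EvalReport":
        p = Path(str(source))
        d = json.loads(p.read_text() if p.exists() else str(source))
        return cls(
            method=d["method"],
            per_channel=pd.DataFrame.from_dict(d["per_channel"], orient="index"),
            accuracy=d.get("accuracy", {}),
            ari_slide=d.get("ari_slide"),
            ari_tissue=d.get("ari_tissue"),
        )


def evaluate_method(
    table_raw: CellQuantTable,
    table_norm: CellQuantTable,
    method: str | None = None,
    channels: Sequence[str] | None = None,
    nbins: int = 256,
    embedding_channels: Sequence[str] | None = None,
    frac: float = 0.10,
    seed: int = 0,
) -> EvalReport:
    """Full evaluation of a normalized table against its raw counterpart.

    Distribution metrics (AD, discordance, variance proportion) and the
    embedding ARIs are computed on the normalized table; manual labels and
    tissue classes are carried over from the raw table.  The embedding ARIs
    are only computed when ``embedding_channels`` (the 2-class-discriminating
    markers) are given, since the UMAP step dominates runtime.
    """
    if table_raw.n_cells != table_norm.n_cells or table_raw.n_slides != table_norm.n_slides:
        raise ValueError("raw and normalized tables must share cells and slides")
    channels = list(channels) if channels is not None else list(table_norm.channels)
    rows = {}
    for channel in channels:
        _, disc = otsu_discordance(table_norm, channel, nbins=nbins)
        rows[channel] = {
            "ad_statistic": ad_ksample_slides(table_norm, channel),
            "otsu_discordance": disc,
            "variance_proportion": variance_proportion(
                table_norm.intensities(channel), table_norm.data[SLIDE_COL]
            ),
        }
    report = EvalReport(
        method=method or table_norm.scale_tag,
        per_channel=pd.DataFrame.from_dict(rows, orient="index"),
    )
    for channel in table_raw.manual_channels:
        if channel in channels:
            labels = table_raw.data[manual_pos_col(channel)].to_numpy()
            report.accuracy[channel] = marker_positive_accuracy(table_norm, channel, labels)
    if embedding_channels is not None:
        _, report.ari_slide = embedding_ari(
            table_norm, embedding_channels, table_norm.data[SLIDE_COL].to_numpy(),
            frac=frac, seed=seed,
        )
        if table_raw.has_tissue_labels:
            _, report.ari_tissue = embedding_ari(
                table_norm, embedding_channels, table_raw.data[TISSUE_COL].to_numpy(),
                frac=frac, seed=seed,
            )
    return report
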
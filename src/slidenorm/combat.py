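"""Slide-level ComBat normalization for cell intensities.

The location-scale model per marker channel c is

    Y_ic(u) = alpha_c + gamma_ic + delta_ic * eps_ic(u),   eps ~ N(0, 1),

with a mean batch effect gamma_ic ~ N(gamma_bar_c, tau2_bar_c) and a variance
batch effect delta2_ic ~ InverseGamma(omega_bar_c, beta_bar_c) for each slide
i.  The fit standardizes the channel, estimates the hyperparameters by the
method of moments from the naive per-slide effects, shrinks those effects
toward the priors with an iterative empirical-Bayes fixed point, and finally
removes the shrunk effects from the data:

    Y*_ic(u) = sigma_c / delta*_ic * (Z_ic(u) - gamma*_ic) + alpha_c.

Standardization divides by the residual standard deviation sigma_c (not its
square): the Gaussian working model Z_ic(u) ~ N(gamma_ic, delta2_ic) only
holds on the sd-standardized scale, matching the original ComBat of Johnson
et al.  Zeros are kept as data throughout — on every scale used here a zero
is a meaningful low intensity, not a missing value.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .data_model import SLIDE_COL, CellQuantTable


class DegenerateChannelError(ValueError):
    """The channel is constant; standardization is impossible."""


class BatchDesignError(ValueError):
    """The slide layout cannot support a batch-effect fit."""


@dataclass
class MomHyperparams:
    """Method-of-moments hyperparameters of the slide-effect priors.

    ``gamma_bar``/``tau2_bar`` are the mean and variance of the Gaussian
    prior on mean effects; ``omega_bar``/``beta_bar`` the shape and scale of
    the inverse-gamma prior on variance effects.  ``noninformative`` marks
    the flat-variance-prior fallback used when the slide variances carry no
    spread (moment matching is then undefined and no pooling is applied).
    """

    gamma_bar: float
    tau2_bar: float
    omega_bar: float
    beta_bar: float
    noninformative: bool = False


def combat_standardize(table: CellQuantTable, channel: str):
    """Standardize one channel; returns ``(z, alpha, sigma, gamma_hat, codes, slide_ids)``.

    alpha is the cell-weighted grand mean, sigma the root of the mean squared
    within-slide residual (1/N denominator), z = (y - alpha) / sigma, and
    gamma_hat the per-slide means of z (the naive mean batch effects on the
    standardized scale; the raw-scale slide mean is alpha + sigma * gamma_hat).
    """
    y = table.intensities(channel)
    codes, slide_ids = table.slide_codes()
    n_slides = len(slide_ids)
    if n_slides < 2:
        raise BatchDesignError("ComBat needs at least two slides")
    counts = np.bincount(codes, minlength=n_slides)
    alpha = float(y.mean())
    slide_mean = np.bincount(codes, weights=y, minlength=n_slides) / counts
    resid = y - slide_mean[codes]
    sigma2 = float(np.mean(resid**2))
    if sigma2 <= 0:
        raise DegenerateChannelError(f"channel {channel!r} is constant within slides")
    sigma = math.sqrt(sigma2)
    z = (y - alpha) / sigma
    gamma_hat = np.bincount(codes, weights=z, minlength=n_slides) / counts
    return z, alpha, sigma, gamma_hat, codes, slide_ids


def combat_mom_hyperparams(gamma_hat: np.ndarray, delta2_hat: np.ndarray) -> MomHyperparams:
    """Moment-match the slide-effect priors from per-slide estimates.

    gamma_bar and tau2_bar are the sample mean and (n-1) sample variance of
    the mean effects.  For the inverse-gamma variance prior, with m and v the
    sample mean and variance of the per-slide variances, omega_bar = m^2/v + 2
    and beta_bar = m * (omega_bar - 1), so the implied prior mean is m.  If
    v = 0 the prior is set flat (omega_bar=1, beta_bar=0: the update then
    returns the within-slide mean square, i.e. no variance shrinkage).
    """
    gamma_hat = np.asarray(gamma_hat, dtype=float)
    delta2_hat = np.asarray(delta2_hat, dtype=float)
    if gamma_hat.size < 2:
        raise BatchDesignError("hyperparameter estimation needs at least two slides")
    gamma_bar = float(gamma_hat.mean())
    tau2_bar = float(gamma_hat.var(ddof=1))
    m = float(delta2_hat.mean())
    v = float(delta2_hat.var(ddof=1))
    if v <= 0:
        warnings.warn(
            "per-slide variances carry no spread; using a non-informative variance prior",
            stacklevel=2,
        )
        return MomHyperparams(gamma_bar, tau2_bar, 1.0, 0.0, noninformative=True)
    omega_bar = m * m / v + 2.0
    beta_bar = m * (omega_bar - 1.0)
    return MomHyperparams(gamma_bar, tau2_bar, omega_bar, beta_bar)


def _slide_sums(z: np.ndarray, codes: np.ndarray, n_slides: int):
    counts = np.bincount(codes, minlength=n_slides).astype(float)
    s1 = np.bincount(codes, weights=z, minlength=n_slides)
    s2 = np.bincount(codes, weights=z * z, minlength=n_slides)
    return counts, s1, s2


def combat_eb_iterate(
    z: np.ndarray,
    codes: np.ndarray,
    gamma_hat: np.ndarray,
    delta2_hat: np.ndarray,
    hyper: MomHyperparams,
    tol: float = 1e-5,
    max_iter: int = 100,
):
    """Empirical-Bayes fixed point for the shrunk slide effects, fixed priors.

    Alternates, per slide i with U_i cells,

        delta2*_i = (beta_bar + 1/2 sum_u (z_iu - gamma*_i)^2) / (U_i/2 + omega_bar - 1)
        gamma*_i  = (U_i tau2_bar ghat_i + delta2*_i gamma_bar) / (U_i tau2_bar + delta2*_i)

    from the naive estimates until the largest absolute parameter change
    drops below ``tol``.  gamma* is a convex combination of the naive slide
    mean and the prior mean, so it always lies between them (shrinkage).

    Returns ``(gamma_star, delta2_star, n_iter, converged)``; non-convergence
    warns and returns the last iterate.
    """
    n_slides = len(gamma_hat)
    counts, _, _ = _slide_sums(z, codes, n_slides)
    gamma_star = np.asarray(gamma_hat, dtype=float).copy()
    delta2_star = np.asarray(delta2_hat, dtype=float).copy()
    # per-slide sufficient statistics for sum_u (z - g)^2 = s2 - 2 g s1 + U g^2
    _, s1, s2 = _slide_sums(z, codes, n_slides)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        ssr = s2 - 2.0 * gamma_star * s1 + counts * gamma_star**2
        delta2_new = (hyper.beta_bar + 0.5 * ssr) / (counts / 2.0 + hyper.omega_bar - 1.0)
        if not np.isfinite(hyper.tau2_bar) or np.isinf(hyper.tau2_bar):
            gamma_new = np.asarray(gamma_hat, dtype=float).copy()
        else:
            num = counts * hyper.tau2_bar * gamma_hat + delta2_new * hyper.gamma_bar
            den = counts * hyper.tau2_bar + delta2_new
            gamma_new = num / den
        change = max(
            float(np.max(np.abs(gamma_new - gamma_star))),
            float(np.max(np.abs(delta2_new - delta2_star))),
        )
        gamma_star, delta2_star = gamma_new, delta2_new
        if change < tol:
            converged = True
            break
    if not converged:
        warnings.warn(f"EB fixed point not converged after {max_iter} iterations", stacklevel=2)
    return gamma_star, delta2_star, it, converged


@dataclass
class CombatChannelFit:
    """All fitted ComBat parameters for one channel."""

    channel: str
    slide_ids: list[str]
    alpha: float
    sigma: float
    n_cells: np.ndarray
    gamma_hat: np.ndarray
    delta2_hat: np.ndarray
    gamma_star: np.ndarray
    delta2_star: np.ndarray
    hyper: MomHyperparams
    n_iter: int
    converged: bool

    def to_dict(self) -> dict:
        return {
            "channel": self.channel,
            "slide_ids": list(self.slide_ids),
            "alpha": self.alpha,
            "sigma": self.sigma,
            "n_cells": self.n_cells.tolist(),
            "gamma_hat": self.gamma_hat.tolist(),
            "delta2_hat": self.delta2_hat.tolist(),
            "gamma_star": self.gamma_star.tolist(),
            "delta2_star": self.delta2_star.tolist(),
            "hyperparameters": {
                "gamma_bar": self.hyper.gamma_bar,
                "tau2_bar": self.hyper.tau2_bar,
                "omega_bar": self.hyper.omega_bar,
                "beta_bar": self.hyper.beta_bar,
                "noninformative": self.hyper.noninformative,
            },
            "n_iter": self.n_iter,
            "converged": self.converged,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CombatChannelFit":
        h = d["hyperparameters"]
        return cls(
            channel=d["channel"],
            slide_ids=list(d["slide_ids"]),
            alpha=float(d["alpha"]),
            sigma=float(d["sigma"]),
            n_cells=np.asarray(d["n_cells"], dtype=float),
            gamma_hat=np.asarray(d["gamma_hat"], dtype=float),
            delta2_hat=np.asarray(d["delta2_hat"], dtype=float),
            gamma_star=np.asarray(d["gamma_star"], dtype=float),
            delta2_star=np.asarray(d["delta2_star"], dtype=float),
            hyper=MomHyperparams(
                h["gamma_bar"], h["tau2_bar"], h["omega_bar"], h["beta_bar"],
                h.get("noninformative", False),
            ),
            n_iter=int(d["n_iter"]),
            converged=bool(d["converged"]),
        )


@dataclass
class CombatFit:
    """Per-channel ComBat fits, serializable to JSON for audit."""

    channels: dict[str, CombatChannelFit] = field(default_factory=dict)

    def __getitem__(self, channel: str) -> CombatChannelFit:
        return self.channels[channel]

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps({c: f.to_dict() for c, f in self.channels.items()}, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "CombatFit":
        p = Path(str(source))
        text = p.read_text() if p.exists() else str(source)
        d = json.loads(text)
        return cls({c: CombatChannelFit.from_dict(v) for c, v in d.items()})


def fit_combat_channel(
    table: CellQuantTable,
    channel: str,
    tol: float = 1e-5,
    max_iter: int = 100,
    reestimate_hyperparams: bool = False,
) -> tuple[CombatChannelFit, np.ndarray, np.ndarray]:
    """Full ComBat fit for one channel.

    The hyperparameters are moment-matched once from the naive per-slide
    effects, then the empirical-Bayes fixed point for (gamma*, delta2*) is
    iterated to convergence.  ``reestimate_hyperparams=True`` additionally
    re-runs the moment matching on the current shrunk effects between fixed
    points; note that moment-matching already-shrunk estimates understates
    the prior spread on every round, so this variant pools the variance
    effects completely whenever their spread is moderate — it is exposed for
    comparison, not recommended.

    Returns ``(fit, z, codes)`` so adjustment can reuse the standardization.
    """
    z, alpha, sigma, gamma_hat, codes, slide_ids = combat_standardize(table, channel)
    n_slides = len(slide_ids)
    counts = np.bincount(codes, minlength=n_slides)
    if np.any(counts < 2):
        small = [s for s, c in zip(slide_ids, counts) if c < 2]
        raise BatchDesignError(f"slide(s) {small} have fewer than 2 cells in channel {channel!r}")
    df = pd.Series(z).groupby(codes).var(ddof=1)
    delta2_hat = df.to_numpy()

    hyper = combat_mom_hyperparams(gamma_hat, delta2_hat)
    gamma_star, delta2_star, total_iter, converged = combat_eb_iterate(
        z, codes, gamma_hat, delta2_hat, hyper, tol=tol, max_iter=max_iter
    )
    if reestimate_hyperparams:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for _ in range(max_iter):
                hyper = combat_mom_hyperparams(gamma_star, delta2_star)
                g_new, d_new, it, inner_ok = combat_eb_iterate(
                    z, codes, gamma_hat, delta2_hat, hyper, tol=tol, max_iter=max_iter
                )
                total_iter += it
                change = max(
                    float(np.max(np.abs(g_new - gamma_star))),
                    float(np.max(np.abs(d_new - delta2_star))),
                )
                gamma_star, delta2_star = g_new, d_new
                if change < tol and inner_ok:
                    converged = True
                    break
    if not converged:
        warnings.warn(
            f"ComBat EB iteration for channel {channel!r} not converged after {max_iter} rounds",
            stacklevel=2,
        )
    fit = CombatChannelFit(
        channel=channel,
        slide_ids=[str(s) for s in slide_ids],
        alpha=alpha,
        sigma=sigma,
        n_cells=counts.astype(float),
        gamma_hat=gamma_hat,
        delta2_hat=delta2_hat,
        gamma_star=gamma_star,
        delta2_star=delta2_star,
        hyper=hyper,
        n_iter=total_iter,
        converged=converged,
    )
    return fit, z, codes


def combat_adjust(z: np.ndarray, codes: np.ndarray, fit: CombatChannelFit) -> np.ndarray:
    """Remove the shrunk slide effects and restore the original scale.

    Y* = sigma / delta*_i * (z - gamma*_i) + alpha per cell on slide i.
    """
    if np.any(fit.delta2_star <= 0):
        raise RuntimeError("internal invariant violated: non-positive delta2_star")
    delta_star = np.sqrt(fit.delta2_star)
    return fit.sigma / delta_star[codes] * (z - fit.gamma_star[codes]) + fit.alpha


def combat_normalize(
    table: CellQuantTable,
    channels: list[str] | None = None,
    tol: float = 1e-5,
    max_iter: int = 100,
    clip_nonnegative: bool = False,
    reestimate_hyperparams: bool = False,
) -> tuple[CellQuantTable, CombatFit]:
    """ComBat-normalize every requested channel of an (already transformed) table.

    Zeros are treated as data.  Adjusted values can be negative under the
    Gaussian model; ``clip_nonnegative`` clamps them at 0 for users who need
    raw-scale semantics.
    """
    channels = list(channels) if channels is not None else list(table.channels)
    fits = CombatFit()
    new: dict[str, np.ndarray] = {}
    for channel in channels:
        fit, z, codes = fit_combat_channel(
            table, channel, tol=tol, max_iter=max_iter,
            reestimate_hyperparams=reestimate_hyperparams,
        )
        adj = combat_adjust(z, codes, fit)
        if clip_nonnegative:
            adj = np.clip(adj, 0.0, None)
        new[channel] = adj
        fits.channels[channel] = fit
    tag = f"{table.scale_tag}+combat" if table.scale_tag != "raw" else "combat"
    return table.with_intensities(new, scale_tag=tag), fits
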
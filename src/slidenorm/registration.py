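"""Density-registration normalization of per-slide intensity distributions.

Each slide's intensity histogram (one marker channel at a time) is smoothed
into a density with a 21-function cubic B-spline basis on the pooled channel
range [a, b].  A strictly monotone warping function

    phi(x) = a + (b - a) * W(x) / W(b),
    W(x)   = integral_a^x exp{beta1 * h1(y) + beta2 * h2(y)} dy,

with h1, h2 the two hat functions of a linear B-spline basis with no interior
knots (2 degrees of freedom), is fitted per slide by minimizing the quadrature
approximation of  integral (f_slide(phi(y)) - fbar(y))^2 dy  against the
cross-slide average density fbar.  The endpoint constraints phi(a)=a,
phi(b)=b are built into the normalizing constants, and the positive integrand
makes phi strictly increasing.

Cell intensities are then transported through the warp.  The default
transport is the *inverse* warp, Y* = phi^{-1}(Y): the fitted phi satisfies
f_slide(phi(y)) ~ fbar(y), i.e. phi maps target coordinates to slide
coordinates, so observations move to the target frame through phi^{-1}
(a slide shifted right of the target is shifted back left).  The forward map
Y* = phi(Y) is exposed as ``direction="forward"`` for completeness.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.integrate import cumulative_trapezoid, trapezoid
from scipy.interpolate import BSpline
from scipy.optimize import minimize

from .data_model import CellQuantTable
from .evaluation import ad_ksample

DENSITY_DF = 21  # cubic B-spline basis size used to smooth each histogram


class RegistrationError(ValueError):
    pass


def _bspline_design(x: np.ndarray, a: float, b: float, df: int = DENSITY_DF, degree: int = 3) -> np.ndarray:
    """Design matrix of a ``df``-function B-spline basis with equally spaced knots."""
    n_interior = df - degree - 1
    interior = np.linspace(a, b, n_interior + 2)[1:-1]
    knots = np.r_[[a] * (degree + 1), interior, [b] * (degree + 1)]
    # clip to the half-open support convention so x == b is evaluable
    xc = np.clip(x, a, b - 1e-12 * max(1.0, abs(b)))
    return BSpline.design_matrix(xc, knots, degree).toarray()


def make_grid(values: np.ndarray, n: int = 512) -> np.ndarray:
    """Equally spaced evaluation grid over the pooled range of ``values``."""
    lo, hi = float(np.min(values)), float(np.max(values))
    if hi <= lo:
        raise RegistrationError("zero-width intensity range; cannot build a grid")
    return np.linspace(lo, hi, n)


def estimate_density(values: np.ndarray, grid: np.ndarray, nbins: int = 128,
                     df: int = DENSITY_DF) -> tuple[np.ndarray, np.ndarray]:
    """Smooth one slide-channel's histogram onto the common grid.

    The histogram (``nbins`` equal-width bins over the grid range) is
    least-squares projected onto the cubic B-spline basis; fitted values are
    clamped at zero and renormalized to integrate to 1 by the trapezoid rule.

    Returns ``(coefficients, density_on_grid)``.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise RegistrationError("cannot estimate a density from no values")
    if values.size < 50:
        warnings.warn(f"only {values.size} values for density estimation", stacklevel=2)
    a, b = float(grid[0]), float(grid[-1])
    hist, edges = np.histogram(values, bins=nbins, range=(a, b), density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])
    X = _bspline_design(centers, a, b, df=df)
    coef, *_ = np.linalg.lstsq(X, hist, rcond=None)
    dens = _bspline_design(grid, a, b, df=df) @ coef
    dens = np.clip(dens, 0.0, None)
    area = trapezoid(dens, grid)
    if area <= 0:
        raise RegistrationError("fitted density is identically zero")
    return coef, dens / area


@dataclass
class DensitySet:
    """Smoothed per-slide densities of one channel on a common grid."""

    channel: str
    grid: np.ndarray
    coefs: dict[str, np.ndarray]
    densities: dict[str, np.ndarray]
    target: np.ndarray = field(default=None)  # pointwise mean across slides

    @classmethod
    def fit(cls, table: CellQuantTable, channel: str, grid_size: int = 512,
            nbins: int = 128) -> "DensitySet":
        y = table.intensities(channel)
        grid = make_grid(y, grid_size)
        coefs, densities = {}, {}
        for slide in table.slide_ids:
            vals = table.data.loc[table.data["slide_id"] == slide, channel].to_numpy(dtype=float)
            coefs[str(slide)], densities[str(slide)] = estimate_density(vals, grid, nbins=nbins)
        target = np.mean(np.stack(list(densities.values())), axis=0)
        return cls(channel, grid, coefs, densities, target)


@dataclass
class WarpFunction:
    """Tabulated strictly increasing warp fixing the endpoints of [a, b]."""

    grid: np.ndarray
    phi: np.ndarray
    beta1: float
    beta2: float

    @property
    def a(self) -> float:
        return float(self.grid[0])

    @property
    def b(self) -> float:
        return float(self.grid[-1])

    def __call__(self, x) -> np.ndarray:
        return np.interp(np.asarray(x, dtype=float), self.grid, self.phi)

    def inverse(self, x) -> np.ndarray:
        # phi is strictly increasing, so the table can be read backwards
        return np.interp(np.asarray(x, dtype=float), self.phi, self.grid)

    @property
    def is_identity(self) -> bool:
        return self.beta1 == 0.0 and self.beta2 == 0.0

    def to_csv(self, path: str | Path) -> None:
        """Two-column (y, phi(y)) table for audit or pixel-level reuse."""
        np.savetxt(path, np.column_stack([self.grid, self.phi]),
                   delimiter=",", header="y,phi", comments="")


def warp_from_coefficients(beta1: float, beta2: float, grid: np.ndarray) -> WarpFunction:
    """Build the endpoint-constrained monotone warp for given exponent coefficients.

    The exponent beta1*h1 + beta2*h2 is linear in y (h1, h2 are the hat
    functions on [a, b]), so with beta1 = beta2 = 0 the integrand is 1 and
    phi is exactly the identity.
    """
    a, b = float(grid[0]), float(grid[-1])
    h2 = (grid - a) / (b - a)
    h1 = 1.0 - h2
    integrand = np.exp(beta1 * h1 + beta2 * h2)
    W = cumulative_trapezoid(integrand, grid, initial=0.0)
    phi = a + (b - a) * W / W[-1]
    return WarpFunction(grid=grid, phi=phi, beta1=float(beta1), beta2=float(beta2))


_STARTS = [(0.0, 0.0), (1.0, -1.0), (-1.0, 1.0), (2.0, 0.0), (0.0, 2.0),
           (-2.0, 0.0), (0.0, -2.0)]


def fit_warp(density: np.ndarray, target: np.ndarray, grid: np.ndarray,
             bound: float = 5.0) -> WarpFunction:
    """Fit the 2-df warp aligning one slide's density to the target.

    Minimizes  trapz (f_slide(phi(y)) - target(y))^2 dy  over (beta1, beta2)
    in [-bound, bound]^2, multi-started from the identity.  On optimizer
    failure (or if no start beats the identity) the identity warp is
    returned with a warning.
    """
    density = np.asarray(density, dtype=float)
    target = np.asarray(target, dtype=float)

    def objective(beta: np.ndarray) -> float:
        w = warp_from_coefficients(beta[0], beta[1], grid)
        f_w = np.interp(w.phi, grid, density)
        return float(trapezoid((f_w - target) ** 2, grid))

    ident = objective(np.zeros(2))
    best = (np.zeros(2), ident)
    any_ok = False
    for x0 in _STARTS:
        res = minimize(objective, np.asarray(x0), method="L-BFGS-B",
                       bounds=[(-bound, bound)] * 2)
        if res.success:
            any_ok = True
            if res.fun < best[1]:
                best = (res.x, float(res.fun))
    if not any_ok:
        warnings.warn("warp optimizer failed; returning the identity warp", stacklevel=2)
        return warp_from_coefficients(0.0, 0.0, grid)
    b1, b2 = best[0]
    return warp_from_coefficients(float(b1), float(b2), grid)


def apply_warp(values: np.ndarray, warp: WarpFunction, direction: str = "inverse") -> np.ndarray:
    """Transport intensities through a warp (clamping out-of-range values).

    ``direction="inverse"`` (default) maps observations into the target frame
    via phi^{-1}; ``"forward"`` applies phi directly.  Monotone interpolation
    of the tabulated warp preserves within-slide rank order either way.
    """
    values = np.asarray(values, dtype=float)
    n_out = int(np.sum((values < warp.a) | (values > warp.b)))
    if n_out:
        warnings.warn(f"{n_out} value(s) outside the warp domain were clamped", stacklevel=2)
    clamped = np.clip(values, warp.a, warp.b)
    if direction == "inverse":
        return warp.inverse(clamped)
    if direction == "forward":
        return warp(clamped)
    raise ValueError(f"direction must be 'inverse' or 'forward', got {direction!r}")


@dataclass
class RegistrationResult:
    """Per-channel registration artifacts and alignment diagnostics."""

    densities: dict[str, DensitySet]
    warps: dict[str, dict[str, WarpFunction]]  # channel -> slide -> warp
    ad_before: dict[str, float]
    ad_after: dict[str, float]

    def export_warps(self, directory: str | Path) -> list[Path]:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = []
        for channel, slides in self.warps.items():
            for slide, warp in slides.items():
                p = directory / f"warp_{channel}_{slide}.csv"
                warp.to_csv(p)
                paths.append(p)
        return paths

    def summary(self) -> dict:
        return {
            "ad_before": self.ad_before,
            "ad_after": self.ad_after,
            "warp_coefficients": {
                c: {s: [w.beta1, w.beta2] for s, w in slides.items()}
                for c, slides in self.warps.items()
            },
        }


def register_normalize(
    table: CellQuantTable,
    channels: list[str] | None = None,
    direction: str = "inverse",
    grid_size: int = 512,
    nbins: int = 128,
    iterations: int = 1,
) -> tuple[CellQuantTable, RegistrationResult]:
    """Register every slide's density to the cross-slide average, per channel.

    ``iterations > 1`` recomputes the target density from the warped data and
    re-registers (single pass by default).  Diagnostics record the k-sample
    Anderson-Darling statistic across slides before and after.
    """
    channels = list(channels) if channels is not None else list(table.channels)
    codes, slide_ids = table.slide_codes()
    work = table
    result = RegistrationResult({}, {}, {}, {})
    for _ in range(max(1, int(iterations))):
        new: dict[str, np.ndarray] = {}
        for channel in channels:
            dens = DensitySet.fit(work, channel, grid_size=grid_size, nbins=nbins)
            warps: dict[str, WarpFunction] = {}
            y = work.intensities(channel)
            out = np.empty_like(y)
            for k, slide in enumerate(slide_ids):
                slide = str(slide)
                warp = fit_warp(dens.densities[slide], dens.target, dens.grid)
                warps[slide] = warp
                mask = codes == k
                out[mask] = apply_warp(y[mask], warp, direction=direction)
            new[channel] = out
            by_slide_before = [y[codes == k] for k in range(len(slide_ids))]
            by_slide_after = [out[codes == k] for k in range(len(slide_ids))]
            result.densities[channel] = dens
            result.warps[channel] = warps
            result.ad_before.setdefault(channel, ad_ksample(by_slide_before))
            result.ad_after[channel] = ad_ksample(by_slide_after)
        if work.scale_tag == "raw":
            tag = "registration"
        elif work.scale_tag.endswith("+registration"):
            tag = work.scale_tag
        else:
            tag = f"{work.scale_tag}+registration"
        work = work.with_intensities(new, scale_tag=tag)
    return work, result
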
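"""Quantization of quantum-dot blinking traces into discrete emitter counts.

A spot containing k independently blinking QDs produces a 3x3-summed
intensity trace whose histogram shows k+1 levels (0..k emitters on).  The
histogram is fit by least squares to a mixture of one symmetric Gaussian
(the off-state/background level) plus 1..4 skew-normal signal components;
fits must satisfy four quality criteria, and the component count is chosen
by minimum AIC among passing fits.  The number of QDs in the spot is then
the number of fitted components minus one.

The four criteria gate out both under- and over-fitting:

1. Pearson correlation between fit and histogram >= 0.98.
2. Every component holds >= 8% of the total fitted area.
3. Overlap coefficient between any two components <= 75%.
4. Each component's fitted area agrees within 20% with the histogram mass
   in the bins where that component dominates (maximum responsibility).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.special import erf

_SQRT2 = np.sqrt(2.0)
_SQRT2PI = np.sqrt(2.0 * np.pi)


def _norm_pdf(x, loc, scale):
    z = (x - loc) / scale
    return np.exp(-0.5 * z * z) / (scale * _SQRT2PI)


def _skewnorm_pdf(x, shape, loc, scale):
    z = (x - loc) / scale
    return (
        np.exp(-0.5 * z * z)
        / (scale * _SQRT2PI)
        * (1.0 + erf(shape * z / _SQRT2))
    )

__all__ = [
    "TimeTrace",
    "TraceHistogram",
    "Component",
    "MixtureFit",
    "extract_trace",
    "fit_mixture",
    "aic",
    "count_qds_in_trace",
    "classify_single_qd",
    "single_emitter_intensity",
]

DEFAULT_N_BIN = 100
MIN_TRACE_FRAMES = 100
N_STARTS = 8

CRITERIA = (
    "correlation >= 0.98",
    "every area >= 8% of total",
    "pairwise overlap <= 75%",
    "area vs data region within 20%",
)


@dataclass
class TimeTrace:
    """3x3-summed spot intensity versus frame."""

    values: np.ndarray
    exposure_ms: float = 100.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()

    @property
    def n_frames(self) -> int:
        return len(self.values)


@dataclass
class TraceHistogram:
    edges: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.diff(self.edges) <= 0):
            raise ValueError("edges must be strictly increasing")

    @classmethod
    def from_trace(cls, trace: TimeTrace, n_bin: int = DEFAULT_N_BIN):
        counts, edges = np.histogram(trace.values, bins=n_bin)
        return cls(edges=edges, counts=counts.astype(float))

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    @property
    def bin_width(self) -> float:
        return float(self.edges[1] - self.edges[0])

    @property
    def n_bin(self) -> int:
        return len(self.counts)


@dataclass
class Component:
    """One mixture component, reported as moments of its density.

    ``mu``/``sigma`` are the distribution mean and sd (for a skew-normal
    these differ from the location/scale parameters); ``area`` is the
    fraction of total fitted histogram mass; ``skew`` is the skew-normal
    shape parameter (0 = symmetric Gaussian).
    """

    mu: float
    sigma: float
    area: float
    skew: float = 0.0
    loc: float = 0.0
    scale: float = 0.0
    mass: float = 0.0  # fitted mass in histogram counts

    def pdf(self, x: np.ndarray) -> np.ndarray:
        if self.skew == 0.0:
            return _norm_pdf(x, self.loc, self.scale)
        return _skewnorm_pdf(x, self.skew, self.loc, self.scale)


@dataclass
class MixtureFit:
    components: list[Component]  # sorted by mu ascending; first = noise
    rss: float
    n_gauss: int
    corr: float
    criteria_pass: tuple[bool, bool, bool, bool]
    aic: float
    resolvable: bool = True  # pairwise mean separation >= sigma_i + sigma_j
    status: str = "ok"  # ok | fit-failed | unresolved
    hist: TraceHistogram | None = field(default=None, repr=False)

    @property
    def all_criteria_pass(self) -> bool:
        """Four quality criteria plus the level-resolvability condition.

        Two components whose means sit closer than the sum of their
        standard deviations do not represent distinct blinking levels
        (they jointly model one level's shape), so such fits are not
        allowed to claim an extra emitter.
        """
        return all(self.criteria_pass) and self.resolvable


def extract_trace(
    movie: np.ndarray, rounded_centroid: tuple[int, int], exposure_ms: float = 100.0
) -> TimeTrace:
    """Sum the 3x3 pixel window about ([x0], [y0]) across all frames."""
    x, y = int(rounded_centroid[0]), int(rounded_centroid[1])
    n_frames, ny, nx = movie.shape
    if not (1 <= x <= nx - 2 and 1 <= y <= ny - 2):
        raise ValueError(f"3x3 window at ({x}, {y}) clipped by the frame border")
    vals = movie[:, y - 1 : y + 2, x - 1 : x + 2].sum(axis=(1, 2))
    return TimeTrace(values=vals, exposure_ms=exposure_ms)


def aic(n_bin: int, rss: float, n_gauss: int) -> float:
    """Akaike information criterion for a binned least-squares mixture fit:
    ``n_bin * ln(RSS / n_bin) + 2 (3 n_gauss - 1)``.
    """
    if n_bin <= 0 or n_gauss <= 0:
        raise ValueError("n_bin and n_gauss must be positive")
    if rss <= 0:
        raise ValueError("RSS must be > 0")
    return n_bin * np.log(rss / n_bin) + 2.0 * (3.0 * n_gauss - 1.0)


def _skewnorm_moments(loc, scale, shape):
    delta = shape / np.sqrt(1.0 + shape * shape)
    mean = loc + scale * delta * np.sqrt(2.0 / np.pi)
    sd = scale * np.sqrt(max(1.0 - 2.0 * delta * delta / np.pi, 1e-12))
    return mean, sd


# 3-point Gauss-Legendre nodes/weights on [-1/2, 1/2]: narrow components
# (a few bins wide) need the within-bin integral, not a center evaluation,
# or their masses decouple from the histogram counts they explain
_GL_NODES = np.array([-0.5, 0.0, 0.5]) * np.sqrt(3.0 / 5.0)
_GL_WEIGHTS = np.array([5.0, 8.0, 5.0]) / 18.0


def _quad_points(x, bw):
    """Quadrature abscissae (n_bin * 3,) for bin centers x of width bw."""
    return (x[:, None] + bw * _GL_NODES[None, :]).ravel()


def _model_counts(theta, k, x, bw):
    """Predicted bin counts for k components (bin-integrated).

    theta = [mass_0..k-1, loc_0..k-1, scale_0..k-1, shape_(k-n_skew)..k-1]
    (component 0 is the symmetric noise Gaussian; trailing shape
    parameters, if any, belong to the last components).
    """
    mass = theta[:k]
    loc = theta[k : 2 * k]
    scale = theta[2 * k : 3 * k]
    n_skew = len(theta) - 3 * k
    shape = np.concatenate([np.zeros(k - n_skew), theta[3 * k :]])
    xq = _quad_points(x, bw)  # (n_bin * 3,)
    z = (xq[None, :] - loc[:, None]) / scale[:, None]
    pdf = np.exp(-0.5 * z * z) / (scale[:, None] * _SQRT2PI)
    skewed = shape != 0.0
    if skewed.any():
        pdf[skewed] *= 1.0 + erf(shape[skewed, None] * z[skewed] / _SQRT2)
    mix = (mass[:, None] * pdf).sum(axis=0).reshape(len(x), 3)
    return (mix @ _GL_WEIGHTS) * bw


def _model_jac(theta, k, x, bw):
    """Analytic Jacobian of the predicted bin counts w.r.t. theta."""
    mass = theta[:k]
    loc = theta[k : 2 * k]
    scale = theta[2 * k : 3 * k]
    n_skew = len(theta) - 3 * k
    shape = np.concatenate([np.zeros(k - n_skew), theta[3 * k :]])
    xq = _quad_points(x, bw)
    z = (xq[None, :] - loc[:, None]) / scale[:, None]  # (k, n*3)
    phi = np.exp(-0.5 * z * z) / _SQRT2PI  # standard normal density
    a = 1.0 + erf(shape[:, None] * z / _SQRT2)
    da_dz = shape[:, None] * np.sqrt(2.0 / np.pi) * np.exp(
        -0.5 * (shape[:, None] * z) ** 2
    )
    g = phi * a  # scale * pdf
    dg_dz = -z * phi * a + phi * da_dz
    pdf = g / scale[:, None]
    dpdf_dloc = -dg_dz / scale[:, None] ** 2
    dpdf_dscale = -(g + z * dg_dz) / scale[:, None] ** 2
    dpdf_dshape = phi * np.sqrt(2.0 / np.pi) * z * np.exp(
        -0.5 * (shape[:, None] * z) ** 2
    ) / scale[:, None]

    def binned(rows):  # (k, n*3) -> (k, n) quadrature-integrated
        return rows.reshape(rows.shape[0], len(x), 3) @ _GL_WEIGHTS

    n = len(x)
    jac = np.empty((n, len(theta)))
    jac[:, :k] = (binned(pdf) * bw).T
    jac[:, k : 2 * k] = (mass[:, None] * binned(dpdf_dloc) * bw).T
    jac[:, 2 * k : 3 * k] = (mass[:, None] * binned(dpdf_dscale) * bw).T
    if n_skew:
        jac[:, 3 * k :] = (
            mass[k - n_skew :, None] * binned(dpdf_dshape[k - n_skew :]) * bw
        ).T
    return jac


def fit_mixture(
    hist: TraceHistogram,
    n_gauss: int,
    seed: int | np.random.Generator | None = None,
    n_starts: int = N_STARTS,
    skew_signal: bool = False,
) -> MixtureFit:
    """Least-squares fit of the histogram to a noise + (n_gauss-1) signal mixture.

    Multi-start local optimization from quantile-spaced component locations
    (seeded jitter per start); the best-RSS converged fit is kept and
    evaluated against the four quality criteria.  Non-convergence of every
    start yields a fit with status ``fit-failed`` rather than an exception.

    ``skew_signal`` gives the signal components a skew-normal shape
    parameter (used by the two-function single-QD identification fit);
    the component-count sweep itself uses symmetric Gaussians, which
    prevents mirrored half-Gaussian pairs from splitting one intensity
    level into two spuriously well-separated components.
    """
    if not 2 <= n_gauss <= 5:
        raise ValueError("n_gauss must be in 2..5")
    rng = np.random.default_rng(seed)
    x = hist.centers
    y = hist.counts
    bw = hist.bin_width
    total = float(y.sum())
    k = n_gauss
    lo_edge, hi_edge = float(hist.edges[0]), float(hist.edges[-1])
    span = hi_edge - lo_edge

    # data quantiles for initial component locations
    cdf = np.cumsum(y) / total
    def quantile(q):
        return float(np.interp(q, cdf, x))

    n_skew = (k - 1) if skew_signal else 0
    lb = np.concatenate(
        [
            np.zeros(k),  # mass
            np.full(k, lo_edge - 0.5 * span),
            np.full(k, bw / 4.0),
            np.full(n_skew, -10.0),
        ]
    )
    ub = np.concatenate(
        [
            np.full(k, 2.0 * total),
            np.full(k, hi_edge + 0.5 * span),
            np.full(k, span),
            np.full(n_skew, 10.0),
        ]
    )

    best = None
    for s in range(n_starts):
        q0 = (np.arange(k) + 0.5) / k
        if s > 0:
            q0 = np.clip(q0 + rng.uniform(-0.4 / k, 0.4 / k, size=k), 0.01, 0.99)
        locs = np.array([quantile(q) for q in np.sort(q0)])
        theta0 = np.concatenate(
            [
                np.full(k, total / k),
                locs,
                np.full(k, max(span / (6.0 * k), bw)),
                np.zeros(n_skew),
            ]
        )
        theta0 = np.clip(theta0, lb + 1e-12, ub - 1e-12)
        try:
            res = optimize.least_squares(
                lambda th: _model_counts(th, k, x, bw) - y,
                theta0,
                jac=lambda th: _model_jac(th, k, x, bw),
                bounds=(lb, ub),
                max_nfev=400,
            )
        except Exception:
            continue
        if not np.all(np.isfinite(res.x)):
            continue
        rss = float(2.0 * res.cost)
        if best is None or rss < best[0]:
            best = (rss, res.x)

    if best is None:
        return MixtureFit(
            components=[],
            rss=np.inf,
            n_gauss=k,
            corr=0.0,
            criteria_pass=(False, False, False, False),
            aic=np.inf,
            status="fit-failed",
            hist=hist,
        )

    rss, theta = best
    mass = theta[:k]
    loc = theta[k : 2 * k]
    scale = theta[2 * k : 3 * k]
    shape = np.concatenate([np.zeros(k - n_skew), theta[3 * k :]])
    comps = []
    total_mass = float(mass.sum())
    for i in range(k):
        mean, sd = _skewnorm_moments(loc[i], scale[i], shape[i])
        comps.append(
            Component(
                mu=mean,
                sigma=sd,
                area=mass[i] / total_mass if total_mass > 0 else 0.0,
                skew=float(shape[i]),
                loc=float(loc[i]),
                scale=float(scale[i]),
                mass=float(mass[i]),
            )
        )
    comps.sort(key=lambda c: c.mu)

    yhat = _model_counts(theta, k, x, bw)
    if np.std(yhat) > 0 and np.std(y) > 0:
        corr = float(np.corrcoef(y, yhat)[0, 1])
    else:
        corr = 0.0
    rss = max(rss, 1e-12)  # guard perfect fits for the log in AIC
    crit = _evaluate_criteria(comps, corr, hist)
    resolvable = all(
        comps[j].mu - comps[i].mu >= comps[i].sigma + comps[j].sigma
        for i in range(len(comps))
        for j in range(i + 1, len(comps))
    )
    return MixtureFit(
        components=comps,
        rss=rss,
        n_gauss=k,
        corr=corr,
        criteria_pass=crit,
        aic=aic(hist.n_bin, rss, k),
        resolvable=resolvable,
        hist=hist,
    )


def _overlap_coefficient(ci: Component, cj: Component, lo: float, hi: float) -> float:
    """Overlap coefficient int min(f_i, f_j) of unit-normalized densities."""
    pad = 4.0 * max(ci.sigma, cj.sigma, 1e-9)
    grid = np.linspace(min(lo, ci.mu - pad, cj.mu - pad),
                       max(hi, ci.mu + pad, cj.mu + pad), 2001)
    fi, fj = ci.pdf(grid), cj.pdf(grid)
    return float(np.trapezoid(np.minimum(fi, fj), grid))


def _evaluate_criteria(
    comps: list[Component], corr: float, hist: TraceHistogram
) -> tuple[bool, bool, bool, bool]:
    c1 = corr >= 0.98
    c2 = all(c.area >= 0.08 for c in comps)
    lo, hi = float(hist.edges[0]), float(hist.edges[-1])
    c3 = True
    for i in range(len(comps)):
        for j in range(i + 1, len(comps)):
            if _overlap_coefficient(comps[i], comps[j], lo, hi) > 0.75:
                c3 = False
    # criterion 4: fitted component mass vs histogram mass in the bins where
    # the component carries maximum responsibility
    x = hist.centers
    dens = np.array([c.mass * c.pdf(x) for c in comps])  # (k, n_bin)
    if not np.all(np.isfinite(dens)) or dens.sum() == 0:
        return (c1, c2, c3, False)
    owner = np.argmax(dens, axis=0)
    c4 = True
    total = float(hist.counts.sum())
    for i, c in enumerate(comps):
        region_mass = float(hist.counts[owner == i].sum())
        if region_mass <= 0:
            c4 = False
            continue
        if abs(c.mass - region_mass) / region_mass > 0.20:
            c4 = False
    if total <= 0:
        c4 = False
    return (c1, c2, c3, c4)


def count_qds_in_trace(
    trace: TimeTrace,
    seed: int | np.random.Generator | None = None,
    n_bin: int = DEFAULT_N_BIN,
    min_frames: int = MIN_TRACE_FRAMES,
) -> tuple[int | None, MixtureFit | None]:
    """Infer the QD count of one spot from its blinking trace.

    Fits mixtures with 2..5 components; among fits passing all four
    criteria the minimum-AIC fit wins and the QD count is its component
    count minus one (the noise level).  Returns ``(None, best_fit)`` with
    status ``unresolved`` when no fit qualifies (e.g. a non-blinking
    trace, or more levels than the model sweep covers).
    """
    if trace.n_frames < min_frames:
        raise ValueError(f"trace has {trace.n_frames} frames; need >= {min_frames}")
    rng = np.random.default_rng(seed)
    hist = TraceHistogram.from_trace(trace, n_bin)
    fits = [fit_mixture(hist, k, seed=rng) for k in range(2, 6)]
    passing = [f for f in fits if f.all_criteria_pass]
    if not passing:
        best = min(fits, key=lambda f: f.aic)
        best.status = "unresolved"
        return None, best
    best = min(passing, key=lambda f: f.aic)
    return best.n_gauss - 1, best


def classify_single_qd(
    trace: TimeTrace,
    seed: int | np.random.Generator | None = None,
    n_bin: int = DEFAULT_N_BIN,
    min_frames: int = MIN_TRACE_FRAMES,
) -> tuple[bool, MixtureFit]:
    """Decide whether a trace shows single-QD photophysics.

    A spot is accepted as a single QD when (a) the two-component fit
    (noise Gaussian + skewed-Gaussian signal) passes all four criteria,
    (b) the three-component model does not beat it under AIC while itself
    passing the criteria, and (c) the two levels are separated by at least
    the sum of their standard deviations.  This stringency errs toward
    excluding true singles rather than admitting multiplets, which only
    costs calibration statistics, never calibration accuracy.
    """
    if trace.n_frames < min_frames:
        raise ValueError(f"trace has {trace.n_frames} frames; need >= {min_frames}")
    rng = np.random.default_rng(seed)
    hist = TraceHistogram.from_trace(trace, n_bin)
    fit2 = fit_mixture(hist, 2, seed=rng, skew_signal=True)
    if not fit2.all_criteria_pass:
        return False, fit2
    fit3 = fit_mixture(hist, 3, seed=rng)
    if fit3.all_criteria_pass and fit3.aic < fit2.aic:
        return False, fit2
    noise, signal = fit2.components[0], fit2.components[1]
    if signal.mu - noise.mu < noise.sigma + signal.sigma:
        return False, fit2
    return True, fit2


def single_emitter_intensity(fit: MixtureFit, quantum_efficiency: float = 1.0) -> float:
    """Detector-corrected single-emitter intensity (mu2 - mu1) / Phi."""
    if not 0.0 < quantum_efficiency <= 1.0:
        raise ValueError("quantum_efficiency must be in (0, 1]")
    if len(fit.components) < 2:
        raise ValueError("fit has no signal component")
    noise, signal = fit.components[0], fit.components[1]
    return (signal.mu - noise.mu) / quantum_efficiency
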
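"""Theoretical scattering and goodness-of-fit.

The Debye equation gives the exact orientational average of the intensity
scattered by a set of point centres,

    I(q) = sum_j sum_k w_j w_k sin(q d_jk) / (q d_jk),

with d_jk the pairwise distances and sinc(0) = 1, so I(0) = (sum w)^2.
Above a size cutoff the double sum is accelerated by a pair-distance
histogram (first-moment binning: each bin contributes at its weighted mean
distance), with a tested error bound.

Goodness of fit uses the reduced, sigma-weighted discrepancy

    chi = sqrt( (1/N) sum_j [ (I_exp(q_j) - (c I(q_j) + b)) / sigma(q_j) ]^2 ),

where the scale c and constant background b, when fitted, minimise chi by
weighted linear least squares.  Mixtures of component curves are fitted
with non-negative weights plus an unconstrained background.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import lsq_linear
from scipy.spatial.distance import pdist
from scipy.special import spherical_jn

from .structures import Structure

__all__ = [
    "ScatteringCurve",
    "FitResult",
    "MixtureFit",
    "MixtureModel",
    "CurveError",
    "debye_profile",
    "debye_intensity",
    "sphere_profile",
    "chi_fit",
    "resample",
    "mixture_fit",
    "read_curve",
    "write_curve",
]

#: Bin width (A) of the pair-distance histogram used to accelerate the
#: Debye sum for large structures.
DEBYE_BIN_WIDTH = 0.1
#: Centre count above which the histogram path is taken by default.
DEBYE_BINNED_THRESHOLD = 2000


class CurveError(ValueError):
    """Invalid scattering-curve content or incompatible q-grids."""


@dataclass(frozen=True)
class ScatteringCurve:
    """A 1-D scattering curve: (q, I, sigma) on a strictly increasing q-grid.

    q is the momentum transfer 4*pi*sin(theta)/lambda in 1/A; I and sigma
    share units (arbitrary, or 1/cm when ``absolute_units`` is set).
    """

    q: np.ndarray
    I: np.ndarray
    sigma: np.ndarray
    absolute_units: bool = False

    def __post_init__(self) -> None:
        q = np.asarray(self.q, dtype=float)
        i = np.asarray(self.I, dtype=float)
        s = np.asarray(self.sigma, dtype=float)
        if q.ndim != 1 or q.shape != i.shape or q.shape != s.shape:
            raise CurveError("q, I, sigma must be 1-D arrays of equal length")
        if len(q) < 2:
            raise CurveError("a curve needs at least 2 points")
        if np.any(q < 0) or np.any(np.diff(q) <= 0):
            raise CurveError("q must be non-negative and strictly increasing")
        if not (np.all(np.isfinite(i)) and np.all(np.isfinite(s))):
            raise CurveError("I and sigma must be finite")
        object.__setattr__(self, "q", q)
        object.__setattr__(self, "I", i)
        object.__setattr__(self, "sigma", s)

    def __len__(self) -> int:
        return len(self.q)

    def with_sigma(self, sigma) -> "ScatteringCurve":
        return ScatteringCurve(self.q, self.I, np.asarray(sigma, float), self.absolute_units)

    def scaled(self, factor: float) -> "ScatteringCurve":
        return ScatteringCurve(self.q, self.I * factor, self.sigma * factor, self.absolute_units)


@dataclass(frozen=True)
class FitResult:
    """chi fit of one model curve against an experiment."""

    chi: float
    scale: float
    background: float
    n_points: int

    def summary(self) -> str:
        return (
            f"chi = {self.chi:.4g}  (N = {self.n_points})\n"
            f"scale c = {self.scale:.6g}\n"
            f"background b = {self.background:.6g}"
        )


@dataclass(frozen=True)
class MixtureFit:
    """Non-negative decomposition of an experiment into component curves."""

    weights: np.ndarray
    background: float
    chi: float
    n_points: int = 0
    rank_deficient: bool = False
    weight_se: np.ndarray | None = field(default=None, compare=False)

    def summary(self) -> str:
        lines = [f"mixture fit: chi = {self.chi:.4g}  (N = {self.n_points})"]
        for i, w in enumerate(self.weights):
            se = "" if self.weight_se is None else f" +/- {self.weight_se[i]:.3g}"
            lines.append(f"  component {i + 1}: weight = {w:.6g}{se}")
        lines.append(f"  background = {self.background:.6g}")
        if self.rank_deficient:
            lines.append("  warning: component curves are (near-)linearly dependent")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# Debye evaluator
# ---------------------------------------------------------------------------

def _sinc(x: np.ndarray) -> np.ndarray:
    """sin(x)/x with sinc(0) = 1 (unnormalised sinc)."""
    return np.sinc(x / np.pi)


def _sinc_dd(x: np.ndarray) -> np.ndarray:
    """Second derivative of sin(x)/x, with the x -> 0 limit -1/3."""
    x = np.asarray(x, dtype=float)
    out = np.full_like(x, -1.0 / 3.0)
    nz = np.abs(x) > 1e-4
    xs = x[nz]
    out[nz] = (2.0 / xs ** 2 - 1.0) * np.sin(xs) / xs - 2.0 * np.cos(xs) / xs ** 2
    return out


def _condensed_weight_products(w: np.ndarray) -> np.ndarray:
    """w_i * w_j for i < j, in pdist's condensed pair order."""
    n = len(w)
    return np.concatenate([w[i] * w[i + 1:] for i in range(n - 1)])


def debye_intensity(coords: np.ndarray, weights: np.ndarray, q: np.ndarray,
                    binned: bool | None = None) -> np.ndarray:
    """Debye-equation intensity of point scatterers on a q-grid.

    ``binned=None`` chooses the histogram path above
    :data:`DEBYE_BINNED_THRESHOLD` centres; True/False force it.
    """
    q = np.asarray(q, dtype=float)
    w = np.asarray(weights, dtype=float)
    n = len(coords)
    self_term = float((w ** 2).sum())
    if n == 1:
        return np.full_like(q, self_term)
    if binned is None:
        binned = n > DEBYE_BINNED_THRESHOLD
    d = pdist(np.asarray(coords, dtype=float))
    uniform = bool(np.all(w == w[0]))
    wprod = None if uniform else _condensed_weight_products(w)
    if not binned:
        # exact double sum, one q at a time to bound memory at O(n^2)
        cross = np.empty_like(q)
        buf = np.empty_like(d)
        for i, qi in enumerate(q):
            if qi == 0.0:
                total = w.sum() ** 2 - self_term if not uniform else w[0] ** 2 * (n * n - n)
                cross[i] = total
                continue
            np.multiply(d, qi, out=buf)
            np.sin(buf, out=buf)
            buf /= d
            s_sum = buf.sum() if uniform else wprod @ buf
            cross[i] = 2.0 * (w[0] ** 2 * s_sum if uniform else s_sum) / qi
    else:
        # binning with first- and second-moment corrections: each bin
        # scatters at its weighted mean distance, plus a curvature term
        # (1/2) sinc''(q dbar) q^2 var(d | bin)
        nbins = max(int(np.ceil(d.max() / DEBYE_BIN_WIDTH)), 1)
        edges = np.linspace(0.0, nbins * DEBYE_BIN_WIDTH, nbins + 1)
        hw, _ = np.histogram(d, bins=edges, weights=wprod)
        hwd, _ = np.histogram(d, bins=edges, weights=d if uniform else wprod * d)
        hwd2, _ = np.histogram(d, bins=edges, weights=d * d if uniform else wprod * d * d)
        if uniform:
            hw = hw * w[0] ** 2
            hwd = hwd * w[0] ** 2
            hwd2 = hwd2 * w[0] ** 2
        mask = hw > 0
        dbar = hwd[mask] / hw[mask]
        var = np.maximum(hwd2[mask] / hw[mask] - dbar ** 2, 0.0)
        x = np.outer(q, dbar)
        terms = hw[mask] * (_sinc(x) + 0.5 * _sinc_dd(x) * (q[:, None] ** 2) * var)
        cross = 2.0 * terms.sum(axis=1)
    return self_term + cross


def debye_profile(s: Structure, q_grid, binned: bool | None = None) -> ScatteringCurve:
    """Theoretical scattering curve of a structure via the Debye equation.

    The returned sigma is a nominal 1 (theoretical curves carry no
    counting-statistics error); I(0) = (sum of weights)^2.
    """
    q = np.asarray(q_grid, dtype=float)
    intensity = debye_intensity(s.coords, s.weights, q, binned=binned)
    return ScatteringCurve(q, intensity, np.ones_like(q))


def sphere_profile(radius: float, q_grid) -> ScatteringCurve:
    """Analytic form factor of a homogeneous sphere, normalised to I(0) = 1.

    I(q) = [3 (sin(qR) - qR cos(qR)) / (qR)^3]^2 = [3 j1(qR)/(qR)]^2.
    """
    if radius <= 0:
        raise CurveError("sphere radius must be positive")
    q = np.asarray(q_grid, dtype=float)
    x = q * radius
    amp = np.ones_like(x)
    nz = x > 0
    amp[nz] = 3.0 * spherical_jn(1, x[nz]) / x[nz]
    return ScatteringCurve(q, amp ** 2, np.ones_like(q))


# ---------------------------------------------------------------------------
# chi fitting
# ---------------------------------------------------------------------------

def _chi(resid_over_sigma: np.ndarray, n_points: int, ddof: int = 0) -> float:
    return float(np.sqrt((resid_over_sigma ** 2).sum() / (n_points - ddof)))


def chi_fit(model: ScatteringCurve, experiment: ScatteringCurve,
            fit_scale: bool = True, fit_background: bool = False,
            nminus1: bool = False) -> FitResult:
    """Reduced sigma-weighted discrepancy between model and experiment.

    The model must already live on the experiment's q-grid (use
    :func:`resample` first).  With the fit flags on, the scale c (applied
    to the model) and constant background b minimise chi analytically by
    weighted linear least squares; with them off c = 1, b = 0.
    ``nminus1`` switches the normalisation from 1/N to the CRYSOL-style
    1/(N-1).
    """
    if len(model) != len(experiment) or not np.allclose(model.q, experiment.q):
        raise CurveError("model and experiment q-grids differ; resample first")
    if np.any(experiment.sigma <= 0):
        raise CurveError("experiment sigma must be positive for chi fitting")
    n = len(experiment)
    n_free = int(fit_scale) + int(fit_background)
    if n < n_free + 1:
        raise CurveError(f"underdetermined: {n} points for {n_free} free parameter(s)")
    w = 1.0 / experiment.sigma
    cols = []
    if fit_scale:
        cols.append(model.I * w)
    if fit_background:
        cols.append(w)
    c, b = 1.0, 0.0
    if cols:
        a_mat = np.column_stack(cols)
        rhs = experiment.I * w
        if not fit_scale:
            rhs = rhs - model.I * w
        sol, *_ = np.linalg.lstsq(a_mat, rhs, rcond=None)
        if fit_scale and fit_background:
            c, b = float(sol[0]), float(sol[1])
        elif fit_scale:
            c = float(sol[0])
        else:
            b = float(sol[0])
    resid = (experiment.I - (c * model.I + b)) * w
    return FitResult(chi=_chi(resid, n, ddof=1 if nminus1 else 0),
                     scale=c, background=b, n_points=n)


def resample(curve: ScatteringCurve, q_grid) -> ScatteringCurve:
    """Linear interpolation of I and sigma onto a new q-grid (no extrapolation)."""
    q = np.asarray(q_grid, dtype=float)
    if q.min() < curve.q[0] - 1e-12 or q.max() > curve.q[-1] + 1e-12:
        raise CurveError(
            f"requested q-range [{q.min():g}, {q.max():g}] outside curve range "
            f"[{curve.q[0]:g}, {curve.q[-1]:g}]"
        )
    return ScatteringCurve(q, np.interp(q, curve.q, curve.I),
                           np.interp(q, curve.q, curve.sigma), curve.absolute_units)


# ---------------------------------------------------------------------------
# Mixture decomposition
# ---------------------------------------------------------------------------

class MixtureModel:
    """Linear decomposition of an experiment into component curves.

    Weights are constrained non-negative (they are physical fractions of
    scattering species); the constant background is unconstrained and
    absorbs flexibility and buffer mismatch.  ``fit`` minimises the same
    chi as :func:`chi_fit`.
    """

    def __init__(self, experiment: ScatteringCurve, components) -> None:
        components = list(components)
        if not components:
            raise CurveError("need at least one component curve")
        for comp in components:
            if len(comp) != len(experiment) or not np.allclose(comp.q, experiment.q):
                raise CurveError("all components must live on the experiment q-grid")
        if np.any(experiment.sigma <= 0):
            raise CurveError("experiment sigma must be positive")
        self.experiment = experiment
        self.components = components

    def fit(self) -> MixtureFit:
        exp = self.experiment
        k = len(self.components)
        w = 1.0 / exp.sigma
        design = np.column_stack([c.I for c in self.components] + [np.ones_like(exp.q)])
        a_mat = design * w[:, None]
        rhs = exp.I * w
        rank = np.linalg.matrix_rank(a_mat, tol=1e-10 * np.abs(a_mat).max())
        lb = np.concatenate([np.zeros(k), [-np.inf]])
        ub = np.full(k + 1, np.inf)
        res = lsq_linear(a_mat, rhs, bounds=(lb, ub), method="bvls")
        sol = res.x
        resid = rhs - a_mat @ sol
        chi = _chi(resid, len(exp))
        # parameter covariance from the normal equations (unconstrained
        # approximation; valid when no weight sits on its bound)
        try:
            cov = np.linalg.inv(a_mat.T @ a_mat)
            se = np.sqrt(np.diag(cov))[:k]
        except np.linalg.LinAlgError:
            se = None
        return MixtureFit(weights=sol[:k], background=float(sol[k]), chi=chi,
                          n_points=len(exp), rank_deficient=rank < k + 1,
                          weight_se=se)


def mixture_fit(components, experiment: ScatteringCurve) -> MixtureFit:
    """Functional wrapper around :class:`MixtureModel`."""
    return MixtureModel(experiment, components).fit()


# ---------------------------------------------------------------------------
# Curve I/O: 3-column text (q, I, sigma), '#' comments, comma or whitespace
# ---------------------------------------------------------------------------

def read_curve(path, absolute_units: bool = False) -> ScatteringCurve:
    """Read a 3-column (q, I, sigma) text file.

    Accepts whitespace- or comma-separated columns, '#' comments, and an
    optional non-numeric header line.
    """
    rows = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.replace(",", " ").split()
            try:
                vals = [float(p) for p in parts]
            except ValueError:
                if not rows and lineno <= 2:
                    continue  # tolerated header line
                raise CurveError(f"{path}:{lineno}: cannot parse {raw.rstrip()!r}")
            if len(vals) < 2:
                raise CurveError(f"{path}:{lineno}: need at least q and I columns")
            rows.append(vals[:3] if len(vals) >= 3 else vals + [1.0])
    if len(rows) < 2:
        raise CurveError(f"{path}: fewer than 2 data points")
    arr = np.array(rows)
    return ScatteringCurve(arr[:, 0], arr[:, 1], arr[:, 2], absolute_units)


def write_curve(curve: ScatteringCurve, path, comment: str = "") -> None:
    units = "1/cm" if curve.absolute_units else "arbitrary"
    header = f"q [1/A]  I [{units}]  sigma [{units}]"
    if comment:
        header = comment + "\n" + header
    np.savetxt(path, np.column_stack([curve.q, curve.I, curve.sigma]),
               header=header, fmt="%.8e")
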
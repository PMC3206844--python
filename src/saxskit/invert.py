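"""Model-free analysis of 1-D scattering curves.

Covers the standard solution-scattering quantities:

* Guinier analysis: I(q) ~ I(0) exp(-q^2 Rg^2 / 3), fitted on an
  iteratively shrunk low-q window with q_max * Rg <= 1.3.
* Indirect Fourier transformation (IFT): regularised inversion of I(q)
  into the pair-distance distribution p(r) on [0, Dmax], with Rg and I(0)
  read off p(r); an automatic mode scans Dmax and the smoothness weight.
* Molecular mass from forward scattering on absolute scale,
  M = I(0) N_A / (c * drho_m^2), with c the mass concentration (g/cm^3)
  and drho_m the excess scattering length per unit mass (cm/g).
* Concentration and size-exclusion-chromatography bookkeeping.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline

from .scatter import CurveError, ScatteringCurve

__all__ = [
    "GuinierFit",
    "Guinier",
    "guinier_fit",
    "PDDF",
    "PairDistanceModel",
    "ift",
    "ift_auto",
    "write_pddf",
    "MassEstimate",
    "mass_from_i0",
    "mgml_to_micromolar",
    "SECCalibration",
    "sec_mass",
    "sequence_mass",
    "AVOGADRO",
    "DEFAULT_DELTA_RHO_M",
]

AVOGADRO = 6.02214076e23  # 1/mol
#: Typical excess scattering length per unit mass for proteins, cm/g.
DEFAULT_DELTA_RHO_M = 2.0e10


class AnalysisError(ValueError):
    """Invalid input to a curve-analysis routine."""


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


# ---------------------------------------------------------------------------
# Guinier analysis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GuinierFit:
    """Result of a Guinier fit.  ``flagged`` marks a positive slope
    (inter-particle repulsion or aggregation); rg is NaN in that case."""

    rg: float
    i0: float
    q_range_used: tuple[float, float]
    r2: float
    n_points: int
    flagged: bool = False

    def summary(self) -> str:
        if self.flagged:
            return "Guinier fit flagged: non-negative slope (rg undefined)"
        return (
            f"Guinier: Rg = {self.rg:.4g} A, I(0) = {self.i0:.6g}\n"
            f"  window q in [{self.q_range_used[0]:.4g}, {self.q_range_used[1]:.4g}] "
            f"({self.n_points} points), R^2 = {self.r2:.5f}"
        )


class Guinier:
    """Guinier model for the low-q region of a scattering curve.

    ``fit`` performs a sigma-weighted linear fit of ln I versus q^2 and
    shrinks the window until q_max * Rg <= ``qrg_limit`` (default 1.3, the
    community-standard validity limit for globular particles).
    """

    MIN_POINTS = 5
    MAX_ITER = 60

    def __init__(self, curve: ScatteringCurve) -> None:
        self.curve = curve

    def fit(self, qrg_limit: float = 1.3) -> GuinierFit:
        q, i, s = self.curve.q, self.curve.I, self.curve.sigma
        pos = i > 0
        # contiguous positive-intensity prefix: ln I must exist on the window
        first_bad = np.argmin(pos) if not pos.all() else len(i)
        if first_bad < self.MIN_POINTS:
            raise AnalysisError("need >= 5 positive-intensity low-q points")
        q, i, s = q[:first_bad], i[:first_bad], s[:first_bad]
        # start from a low-q window (the Guinier regime), then let the
        # iteration grow or shrink it until q_max * Rg meets the limit
        m = min(len(q), max(self.MIN_POINTS, len(q) // 10))
        seen = {m}
        for _ in range(self.MAX_ITER):
            slope, intercept, r2 = self._wlinfit(q[:m] ** 2, np.log(i[:m]), s[:m] / i[:m])
            if slope > 1e-9:  # genuinely rising: repulsion or aggregation artefact
                return GuinierFit(rg=float("nan"), i0=float(np.exp(intercept)),
                                  q_range_used=(float(q[0]), float(q[m - 1])),
                                  r2=r2, n_points=m, flagged=True)
            rg = math.sqrt(max(-3.0 * slope, 0.0))
            if rg == 0 or q[m - 1] * rg <= qrg_limit:
                if rg == 0:
                    break
                m_new = int(np.searchsorted(q, qrg_limit / rg, side="right"))
                m_new = min(max(m_new, self.MIN_POINTS), len(q))
                if m_new <= m or m_new in seen:
                    break
            else:
                m_new = int(np.searchsorted(q, qrg_limit / rg, side="right"))
                m_new = max(m_new, self.MIN_POINTS)
                if m_new >= m or m_new in seen:
                    break
            seen.add(m_new)
            m = m_new
        return GuinierFit(rg=rg, i0=float(np.exp(intercept)),
                          q_range_used=(float(q[0]), float(q[m - 1])),
                          r2=r2, n_points=m)

    @staticmethod
    def _wlinfit(x, y, sigma_y):
        w = 1.0 / np.maximum(sigma_y, 1e-300) ** 2
        wsum = w.sum()
        xm = (w * x).sum() / wsum
        ym = (w * y).sum() / wsum
        sxx = (w * (x - xm) ** 2).sum()
        sxy = (w * (x - xm) * (y - ym)).sum()
        slope = sxy / sxx
        intercept = ym - slope * xm
        ss_res = (w * (y - slope * x - intercept) ** 2).sum()
        ss_tot = (w * (y - ym) ** 2).sum()
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
        return float(slope), float(intercept), float(r2)


def guinier_fit(curve: ScatteringCurve, qrg_limit: float = 1.3) -> GuinierFit:
    """Functional wrapper around :class:`Guinier`."""
    return Guinier(curve).fit(qrg_limit=qrg_limit)


# ---------------------------------------------------------------------------
# Indirect Fourier transformation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PDDF:
    """Pair-distance distribution p(r) on [0, Dmax] with derived quantities.

    p(0) = p(Dmax) = 0 by construction.  ``rg`` and ``i0`` come from the
    moments of p(r): Rg^2 = int r^2 p dr / (2 int p dr),
    I(0) = 4 pi int p dr.  ``chi`` is the reduced discrepancy of the IFT
    fit to the input curve.
    """

    r: np.ndarray
    p: np.ndarray
    dmax: float
    alpha: float
    rg: float
    i0: float
    chi: float
    scan: tuple = field(default=(), compare=False)

    def summary(self) -> str:
        return (
            f"IFT p(r): Dmax = {self.dmax:.4g} A, alpha = {self.alpha:.3g}\n"
            f"  Rg = {self.rg:.4g} A, I(0) = {self.i0:.6g}, fit chi = {self.chi:.4g}"
        )


class PairDistanceModel:
    """Regularised indirect Fourier transform of a scattering curve.

    p(r) is expanded in ``n_basis`` cubic B-splines on [0, Dmax] with both
    endpoints pinned to zero; the coefficients minimise

        sum_j [(I_exp(q_j) - I_model(q_j)) / sigma_j]^2
            + alpha * int p''(r)^2 dr,

    where I_model(q) = 4 pi int_0^Dmax p(r) sinc(q r) dr.  ``fit`` solves
    for a single (dmax, alpha); ``fit_auto`` scans Dmax over a geometric
    grid and alpha over decades, selecting the smallest Dmax at which the
    fit quality has stabilised (< 2 % change to the next larger Dmax) while
    p(r) stays above -1 % of its maximum.
    """

    N_R = 601  # quadrature grid for the r-integrals

    def __init__(self, curve: ScatteringCurve, n_basis: int = 30) -> None:
        if n_basis < 4:
            raise AnalysisError("need at least 4 basis splines")
        if len(curve) < n_basis:
            raise AnalysisError("curve must have at least n_basis points")
        if np.any(curve.sigma <= 0):
            raise CurveError("curve sigma must be positive for IFT")
        self.curve = curve
        self.n_basis = n_basis

    # -- single (dmax, alpha) fit ------------------------------------------

    def fit(self, dmax: float, alpha: float | None = None) -> PDDF:
        """Fit at fixed Dmax.  ``alpha=None`` picks the smoothness weight
        automatically (largest alpha within 5 % of the best chi over
        decades); alpha = 0 is the unregularised least-squares solution."""
        if dmax <= 0:
            raise AnalysisError("dmax must be positive")
        if alpha is None:
            return self._best_alpha_fit(dmax)
        if alpha < 0:
            raise AnalysisError("alpha must be >= 0")
        r, basis, bpp, wtrap = self._basis(dmax)
        a_mat = self._design(r, basis, wtrap)
        coef, chi = self._solve(a_mat, self._penalty(bpp, wtrap), alpha)
        p = basis @ coef
        rg, i0 = self._moments(r, p)
        return PDDF(r=r, p=p, dmax=float(dmax), alpha=float(alpha),
                    rg=rg, i0=i0, chi=chi)

    def fit_auto(self, dmax_range: tuple[float, float] | None = None,
                 n_dmax: int = 28) -> PDDF:
        curve = self.curve
        if dmax_range is None:
            g = Guinier(curve).fit()
            if g.flagged or not np.isfinite(g.rg) or g.rg <= 0:
                raise AnalysisError("automatic Dmax scan needs a valid Guinier Rg")
            # sphere has Dmax = 2 sqrt(5/3) Rg ~ 2.58 Rg; bracket generously
            dmax_range = (1.4 * g.rg, 6.5 * g.rg)
        lo, hi = dmax_range
        dgrid = np.geomspace(lo, hi, n_dmax)
        fits = [self._best_alpha_fit(d) for d in dgrid]
        chis = np.array([f.chi for f in fits])
        ok_neg = np.array([bool(f.p.min() >= -0.01 * f.p.max()) for f in fits])
        if not ok_neg.any():
            # delta-like p(r) (e.g. point pairs) cannot avoid Gibbs lobes;
            # fall back on fit quality alone
            ok_neg[:] = True
        # chi has stabilised once it reaches the large-Dmax plateau; the
        # plateau level is estimated robustly because per-candidate alpha
        # selection makes it noisy
        plateau = float(np.median(chis[-5:]))
        threshold = max(1.5 * plateau, 1.1 * float(chis.min()), 1e-300)
        candidates = [i for i in range(len(fits))
                      if ok_neg[i] and chis[i] <= threshold]
        if candidates:
            chosen = candidates[0]
        else:
            chosen = int(np.argmin(np.where(ok_neg, chis, np.inf)))
        f = fits[chosen]
        scan = tuple((float(d), float(c)) for d, c in zip(dgrid, chis))
        return PDDF(r=f.r, p=f.p, dmax=f.dmax, alpha=f.alpha,
                    rg=f.rg, i0=f.i0, chi=f.chi, scan=scan)

    # -- internals ---------------------------------------------------------

    def _basis(self, dmax: float):
        k = 3
        n_int = self.n_basis - 2  # internal knot intervals
        knots = np.concatenate([
            np.zeros(k + 1),
            np.linspace(0, dmax, n_int + 1)[1:-1],
            np.full(k + 1, dmax),
        ])
        n_total = len(knots) - k - 1  # == n_basis + 2
        r = np.linspace(0.0, dmax, self.N_R)
        design = BSpline.design_matrix(r, knots, k).toarray()
        # drop the two end splines: pins p(0) = p(Dmax) = 0
        basis = design[:, 1:n_total - 1]
        bpp = np.empty_like(basis)
        for m in range(basis.shape[1]):
            c = np.zeros(n_total)
            c[m + 1] = 1.0
            bpp[:, m] = BSpline(knots, c, k).derivative(2)(r)
        wtrap = np.full(self.N_R, r[1] - r[0])
        wtrap[0] *= 0.5
        wtrap[-1] *= 0.5
        return r, basis, bpp, wtrap

    def _design(self, r, basis, wtrap):
        q = self.curve.q
        qr = np.outer(q, r)
        sinc = np.sinc(qr / np.pi)
        return 4.0 * np.pi * (sinc * wtrap) @ basis

    @staticmethod
    def _penalty(bpp, wtrap):
        return bpp.T @ (bpp * wtrap[:, None])

    def _solve(self, a_mat, pen, alpha):
        w = 1.0 / self.curve.sigma
        aw = a_mat * w[:, None]
        rhs = aw.T @ (self.curve.I * w)
        lhs = aw.T @ aw + alpha * pen
        try:
            coef = np.linalg.solve(lhs, rhs)
        except np.linalg.LinAlgError:
            warnings.warn("ill-conditioned IFT normal matrix; using least squares",
                          RuntimeWarning, stacklevel=3)
            coef, *_ = np.linalg.lstsq(lhs, rhs, rcond=None)
        resid = (self.curve.I - a_mat @ coef) * w
        chi = float(np.sqrt((resid ** 2).mean()))
        return coef, chi

    def _best_alpha_fit(self, dmax: float) -> PDDF:
        """Largest alpha whose chi stays within 5 % of the best over decades
        (the smoothest solution consistent with the data)."""
        r, basis, bpp, wtrap = self._basis(dmax)
        a_mat = self._design(r, basis, wtrap)
        pen = self._penalty(bpp, wtrap)
        w = 1.0 / self.curve.sigma
        scale = np.trace((a_mat * w[:, None]).T @ (a_mat * w[:, None])) / max(np.trace(pen), 1e-300)
        alphas = scale * np.power(10.0, np.arange(-10.0, 1.0))
        sols = [self._solve(a_mat, pen, a) for a in alphas]
        chis = np.array([c for _, c in sols])
        best = chis.min()
        idx = max(i for i in range(len(alphas)) if chis[i] <= 1.05 * best + 1e-300)
        coef, chi = sols[idx]
        p = basis @ coef
        rg, i0 = self._moments(r, p)
        return PDDF(r=r, p=p, dmax=float(dmax), alpha=float(alphas[idx]),
                    rg=rg, i0=i0, chi=chi)

    @staticmethod
    def _moments(r, p):
        p_int = np.trapezoid(p, r)
        if p_int <= 0:
            return float("nan"), float(4.0 * np.pi * p_int)
        r2_int = np.trapezoid(r ** 2 * p, r)
        rg = math.sqrt(max(r2_int / (2.0 * p_int), 0.0))
        return rg, float(4.0 * np.pi * p_int)


def ift(curve: ScatteringCurve, dmax: float, alpha: float | None = None,
        n_basis: int = 30) -> PDDF:
    """Indirect Fourier transform at fixed Dmax (alpha=None: automatic)."""
    return PairDistanceModel(curve, n_basis=n_basis).fit(dmax, alpha)


def ift_auto(curve: ScatteringCurve, n_basis: int = 30) -> PDDF:
    """Indirect Fourier transform with automatic Dmax/alpha selection."""
    return PairDistanceModel(curve, n_basis=n_basis).fit_auto()


def write_pddf(pddf: PDDF, path) -> None:
    header = (
        f"pair-distance distribution\n"
        f"Dmax = {pddf.dmax:.6g} A, alpha = {pddf.alpha:.6g}, "
        f"Rg = {pddf.rg:.6g} A, I(0) = {pddf.i0:.6g}\n"
        "r [A]  p(r) [arb]"
    )
    np.savetxt(path, np.column_stack([pddf.r, pddf.p]), header=header, fmt="%.8e")


# ---------------------------------------------------------------------------
# Mass and concentration bookkeeping
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MassEstimate:
    """Molecular mass from forward scattering on absolute scale."""

    mass: float  # g/mol
    i0_abs: float  # 1/cm
    c_mass: float  # g/cm^3
    delta_rho_m: float  # cm/g
    n_avogadro: float = AVOGADRO

    def __float__(self) -> float:
        return self.mass

    @property
    def kda(self) -> float:
        return self.mass / 1000.0

    def summary(self) -> str:
        return (
            f"M = {self.kda:.2f} kDa from I(0) = {self.i0_abs:.4g} 1/cm at "
            f"c = {self.c_mass * 1000:.3g} mg/mL (drho_m = {self.delta_rho_m:.3g} cm/g)"
        )


def mass_from_i0(i0_abs: float, c_mass: float,
                 delta_rho_m: float = DEFAULT_DELTA_RHO_M) -> MassEstimate:
    """Molecular mass from absolute-scale forward scattering.

    M = I(0) * N_A / (c * drho_m^2), with I(0) in 1/cm, c in g/cm^3 and
    drho_m (excess scattering length per unit mass) in cm/g.  The
    absolute-scale calibration itself (water standard) is instrument
    metadata, not computed here.
    """
    if i0_abs <= 0 or c_mass <= 0 or delta_rho_m <= 0:
        raise AnalysisError("i0, concentration and delta_rho_m must all be positive")
    mass = i0_abs * AVOGADRO / (c_mass * delta_rho_m ** 2)
    return MassEstimate(mass=mass, i0_abs=i0_abs, c_mass=c_mass,
                        delta_rho_m=delta_rho_m)


def mgml_to_micromolar(rho_mg_ml: float, molar_mass: float,
                       rounded: bool = True) -> float | int:
    """Convert a mass concentration (mg/mL = g/L) to molar units (uM).

    c = rho / M * 1e6.  ``rounded`` applies nearest-integer half-up
    rounding, the convention used for reported concentrations.
    """
    if rho_mg_ml < 0 or molar_mass <= 0:
        raise AnalysisError("concentration must be >= 0 and molar mass > 0")
    c = rho_mg_ml / molar_mass * 1e6
    return _round_half_up(c) if rounded else c


# ---------------------------------------------------------------------------
# Size-exclusion chromatography calibration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SECCalibration:
    """Linear log10(M)-vs-elution-volume calibration from protein standards."""

    standards: tuple  # of (elution volume mL, molar mass g/mol)
    slope: float = field(init=False)
    intercept: float = field(init=False)

    def __post_init__(self) -> None:
        st = tuple((float(v), float(m)) for v, m in self.standards)
        if len(st) < 2:
            raise AnalysisError("need at least 2 calibration standards")
        v = np.array([s[0] for s in st])
        m = np.array([s[1] for s in st])
        if len(np.unique(v)) < len(v):
            raise AnalysisError("calibration standards must have distinct volumes")
        if np.any(m <= 0):
            raise AnalysisError("standard masses must be positive")
        slope, intercept = np.polyfit(v, np.log10(m), 1)
        object.__setattr__(self, "standards", st)
        object.__setattr__(self, "slope", float(slope))
        object.__setattr__(self, "intercept", float(intercept))

    def predict(self, v_e: float) -> float:
        v = np.array([s[0] for s in self.standards])
        if v_e < v.min() or v_e > v.max():
            warnings.warn(
                f"elution volume {v_e} mL outside the calibrated range "
                f"[{v.min()}, {v.max()}] mL", RuntimeWarning, stacklevel=2)
        return float(10.0 ** (self.slope * v_e + self.intercept))


def sec_mass(cal: SECCalibration, v_e: float) -> float:
    """Molar mass (g/mol) predicted from an elution volume."""
    return cal.predict(v_e)


# ---------------------------------------------------------------------------
# Sequence mass
# ---------------------------------------------------------------------------

def sequence_mass(sequence_or_path) -> float:
    """Average molecular mass (g/mol) of a protein sequence or FASTA file."""
    from Bio import SeqIO
    from Bio.SeqUtils import molecular_weight

    seq = str(sequence_or_path)
    if "." in seq or "/" in seq:  # looks like a path
        records = list(SeqIO.parse(sequence_or_path, "fasta"))
        if not records:
            raise AnalysisError(f"no FASTA records in {sequence_or_path}")
        seq = str(records[0].seq)
    return float(molecular_weight(seq, seq_type="protein"))
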
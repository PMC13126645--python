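"""Composite SAXS model: fibril-network power law + random-coil monomer.

At the plateau of the aggregation reaction the scattering curve is the
sum of two regimes.  At low momentum transfer q the heterogeneous
fibril network dominates with an empirical power law A * q**-p (the
observed exponent ~2.3 is far from the q**-1 of isolated rods,
indicating attractive fibril-fibril interactions).  Above the crossover
(~0.06 1/A) the signal is dominated by the dissolved monomer, modelled
as a Gaussian random coil with the Debye form factor

    P(q) = 2 (exp(-u) - 1 + u) / u**2,     u = (q R_g)**2,

so I(q) = A q**-p + contrast_scale * concentration * P(q; R_g) + bkg.
With an absolute intensity calibration (contrast_scale, curve units per
mM, supplied as a known constant) the forward-scattering level of the
coil term yields the monomer concentration coexisting with fibrils,
and the high-q curvature yields its radius of gyration.

Units: q in 1/A, R_g in nm (converted internally, 1 nm = 10 A),
concentration in mM.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import linregress

from .errors import FitFailureError, ParameterError

__all__ = [
    "ScatteringCurve",
    "CoilModel",
    "SaxsFit",
    "debye_form_factor",
    "composite_intensity",
    "fit_saxs",
    "power_law_slope",
]


@dataclass
class ScatteringCurve:
    """(q, I, sigma) triples; q strictly increasing, in 1/A."""

    q: np.ndarray
    I: np.ndarray
    sigma: np.ndarray | None = None

    def __post_init__(self):
        self.q = np.asarray(self.q, dtype=float)
        self.I = np.asarray(self.I, dtype=float)
        if self.q.ndim != 1 or self.q.shape != self.I.shape:
            raise ParameterError("q and I must be 1-D arrays of equal length")
        if np.any(self.q <= 0) or np.any(np.diff(self.q) <= 0):
            raise ParameterError("q must be positive and strictly increasing")
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)
            if self.sigma.shape != self.q.shape:
                raise ParameterError("sigma must match q in shape")
            if np.any(self.sigma <= 0):
                raise ParameterError("sigma must be > 0 where provided")


@dataclass(frozen=True)
class CoilModel:
    """Random-coil monomer term: R_g (nm), concentration (mM) and the
    absolute-intensity constant contrast_scale (curve units per mM)."""

    r_g: float
    concentration: float
    contrast_scale: float

    def __post_init__(self):
        if self.r_g <= 0:
            raise ParameterError("r_g must be > 0")
        if self.concentration < 0:
            raise ParameterError("concentration must be >= 0")
        if self.contrast_scale <= 0:
            raise ParameterError("contrast_scale must be > 0")


# Below this u the closed form loses precision to cancellation (the
# numerator expm1(-u)+u is O(u^2)); the truncated series is exact to
# better than 1e-12 there, so the two branches join smoothly.
_U_SMALL = 1e-4


def debye_form_factor(q, r_g_nm: float):
    """Debye random-coil form factor P(q); P(0) = 1.

    Small-u branch uses the series 1 - u/3 + u^2/12.
    """
    if r_g_nm <= 0:
        raise ParameterError("r_g must be > 0")
    q = np.asarray(q, dtype=float)
    if np.any(q < 0):
        raise ParameterError("q must be >= 0")
    u = (q * r_g_nm * 10.0) ** 2  # nm -> A
    with np.errstate(invalid="ignore", divide="ignore"):
        exact = 2.0 * (np.expm1(-u) + u) / np.where(u > 0, u * u, 1.0)
    series = 1.0 - u / 3.0 + u * u / 12.0
    out = np.where(u > _U_SMALL, exact, series)
    return float(out) if out.ndim == 0 else out


def composite_intensity(q, A: float, p: float, coil: CoilModel, bkg: float):
    """I(q) = A q^-p + contrast_scale * concentration * P_debye + bkg."""
    if A < 0 or bkg < 0:
        raise ParameterError("A and bkg must be >= 0")
    if p <= 0:
        raise ParameterError("power-law exponent must be > 0")
    q = np.asarray(q, dtype=float)
    if A > 0 and np.any(q == 0):
        raise ParameterError("q = 0 undefined for a power law")
    coil_term = coil.contrast_scale * coil.concentration * debye_form_factor(q, coil.r_g)
    with np.errstate(divide="ignore"):
        pl = A * np.where(q > 0, q, 1.0) ** (-p)
    out = pl + coil_term + bkg
    return float(out) if out.ndim == 0 else out


def power_law_slope(curve: ScatteringCurve, q_max: float) -> float:
    """Log-log regression slope of I(q) on q < q_max (the power-law
    exponent with its sign, ~ -2.3 for the fibril network here)."""
    sel = (curve.q < q_max) & (curve.I > 0)
    if np.count_nonzero(sel) < 5:
        raise FitFailureError("fewer than 5 points below q_max for the regression")
    res = linregress(np.log(curve.q[sel]), np.log(curve.I[sel]))
    return float(res.slope)


@dataclass
class SaxsFit:
    """Staged composite fit result."""

    A: float
    p: float
    coil: CoilModel
    bkg: float
    ess: float
    stderr: dict
    n_low: int
    n_high: int


def fit_saxs(
    curve: ScatteringCurve,
    contrast_scale: float,
    q_lowmax: float = 0.03,
    q_highmin: float = 0.06,
    joint_refine: bool = True,
) -> SaxsFit:
    """Staged fit of the composite model.

    (i) log-log linear regression on q < q_lowmax gives (A, p);
    (ii) weighted nonlinear least squares on q > q_highmin gives
    (R_g, concentration, bkg) with the power-law term fixed;
    (iii) joint weighted refinement of all five parameters (default on).
    ``contrast_scale`` is treated as a known calibration constant.
    """
    q, I = curve.q, curve.I
    sel_lo = (q < q_lowmax) & (I > 0)
    sel_hi = q > q_highmin
    n_low, n_high = int(np.count_nonzero(sel_lo)), int(np.count_nonzero(sel_hi))
    if n_low < 5 or n_high < 5:
        raise FitFailureError(
            f"need >= 5 points per regime (got {n_low} low-q, {n_high} high-q)"
        )
    reg = linregress(np.log(q[sel_lo]), np.log(I[sel_lo]))
    p_pl = -float(reg.slope)
    A = float(np.exp(reg.intercept))
    if p_pl <= 0:
        raise FitFailureError("low-q regression gave a non-decaying power law")

    w = 1.0 / curve.sigma if curve.sigma is not None else np.ones_like(I)

    def coil_resid(x, sel):
        r_g, conc, bkg = np.exp(x[0]), np.exp(x[1]), x[2]
        model = composite_intensity(
            q[sel], A, p_pl, CoilModel(r_g, conc, contrast_scale), max(bkg, 0.0)
        )
        return w[sel] * (model - I[sel])

    tail = float(np.median(I[-max(5, I.size // 20):]))
    conc0 = max((I[sel_hi][0] - tail) / contrast_scale, 1e-3)
    x0 = [np.log(1.0), np.log(conc0), max(tail, 1e-12)]
    res = least_squares(coil_resid, x0, args=(sel_hi,), xtol=1e-12, ftol=1e-12)
    if not res.success:
        raise FitFailureError("coil-regime fit did not converge", best=res.x)
    r_g, conc, bkg = float(np.exp(res.x[0])), float(np.exp(res.x[1])), float(max(res.x[2], 0.0))

    stderr: dict = {}
    if joint_refine:
        def full_resid(x):
            A_, p_, rg_, c_, b_ = np.exp(x[0]), x[1], np.exp(x[2]), np.exp(x[3]), x[4]
            if p_ <= 0 or b_ < 0:
                return np.full_like(I, 1e6)
            model = composite_intensity(
                q, A_, p_, CoilModel(rg_, c_, contrast_scale), b_
            )
            return w * (model - I)

        xj = [np.log(A), p_pl, np.log(r_g), np.log(conc), bkg]
        rj = least_squares(full_resid, xj, xtol=1e-12, ftol=1e-12)
        if rj.success:
            A, p_pl = float(np.exp(rj.x[0])), float(rj.x[1])
            r_g, conc = float(np.exp(rj.x[2])), float(np.exp(rj.x[3]))
            bkg = float(max(rj.x[4], 0.0))
            # Gauss-Newton covariance on the internal coordinates
            J = rj.jac
            dof = max(I.size - J.shape[1], 1)
            s2 = 2.0 * rj.cost / dof
            try:
                cov = s2 * np.linalg.inv(J.T @ J)
                sd = np.sqrt(np.diag(cov))
                stderr = {
                    "A": A * sd[0], "p": sd[1], "r_g": r_g * sd[2],
                    "concentration": conc * sd[3], "bkg": sd[4],
                }
            except np.linalg.LinAlgError:
                stderr = {}
        res = rj

    ess = float(np.sum(res.fun ** 2))
    return SaxsFit(
        A=A, p=p_pl, coil=CoilModel(r_g, conc, contrast_scale), bkg=bkg,
        ess=ess, stderr=stderr, n_low=n_low, n_high=n_high,
    )
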
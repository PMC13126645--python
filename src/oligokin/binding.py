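"""Equilibrium chaperone-oligomer binding with ligand depletion.

The supernatant-titration experiment mixes a fixed total chaperone
concentration C_JB6 (12.5 nM) with a variable volume fraction X of
oligomer-containing supernatant, so the total binding-site concentration
in the mixture is X * C_s.  Assuming independent, one-to-one binding,
the bound chaperone B satisfies the mass-action relation

    (C - B)(S - B) = K_D * B,      C = C_JB6,  S = X * C_s,

whose physical root is the depletion quadratic

    B = [(C + S + K_D) - sqrt((C + S + K_D)^2 - 4 C S)] / 2 .

Because only the chaperone is labelled, the measured diffused fraction
is a linear combination of the free and bound plateaus:

    f(X) = f_0 + (f_b - f_0) * B / C_JB6 .

C and K_D are of comparable size here, so depletion matters and the
usual hyperbolic isotherm would be wrong.  K_D is only weakly
identified on the low side (any K_D << C gives stoichiometric binding);
the error-square-sum profile over fixed K_D quantifies this one-sided
bound.  C_s is an upper limit to the oligomer concentration in the
non-diluted supernatant, reached in the limit of one chaperone-binding
site per oligomer.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

from .errors import FitFailureError, ParameterError
from .mds import ChannelCalibration, SpeciesMixture, invert_fraction, mixture_fraction

__all__ = [
    "BindingParameters",
    "TitrationPoint",
    "BindingFit",
    "ProfilePoint",
    "EssProfile",
    "bound_concentration",
    "model_fraction",
    "fit_binding",
    "ess_profile",
    "chaperone_titration_curve",
]

C_S_CAVEAT = (
    "an upper limit to the oligomer concentration in the supernatant "
    "in the limit of one JB6-binding site per oligomer"
)


@dataclass(frozen=True)
class BindingParameters:
    """Parameters of the depletion-corrected independent-binding model.

    K_D and C_s in nM; f_0/f_b are the diffused-fraction plateaus of
    free and bound chaperone; C_JB6 is the total chaperone (nM).
    """

    kd: float
    c_s: float
    f_0: float
    f_b: float
    c_jb6: float = 12.5

    def __post_init__(self):
        if self.kd < 0 or self.c_s < 0:
            raise ParameterError("K_D and C_s must be >= 0")
        if not (0 < self.f_b < self.f_0 < 0.5):
            raise ParameterError("require 0 < f_b < f_0 < 0.5")
        if self.c_jb6 <= 0:
            raise ParameterError("C_JB6 must be > 0")


@dataclass
class TitrationPoint:
    """One titration replicate: supernatant volume fraction X, fraction f."""

    X: float
    f: float
    replicate_id: str = ""

    def __post_init__(self):
        if not (0 <= self.X <= 1):
            raise ParameterError("X must be a volume fraction in [0, 1]")
        if not (0 < self.f <= 0.5):
            raise ParameterError("f must be in (0, 0.5]")


def bound_concentration(c_total, s_total, kd):
    """Bound complex B (nM) from totals C, S and K_D via the depletion
    quadratic; numerically stable form, exact in the K_D = 0 limit."""
    C = np.asarray(c_total, dtype=float)
    S = np.asarray(s_total, dtype=float)
    if np.any(C < 0) or np.any(S < 0) or kd < 0:
        raise ParameterError("concentrations and K_D must be >= 0")
    b = C + S + kd
    disc = np.sqrt(np.maximum(b * b - 4.0 * C * S, 0.0))
    # B = (b - disc)/2 rewritten as 2CS/(b + disc) to avoid cancellation
    denom = b + disc
    out = np.where(denom > 0, 2.0 * C * S / np.where(denom > 0, denom, 1.0), 0.0)
    return float(out) if out.ndim == 0 else out


def model_fraction(X, p: BindingParameters):
    """Predicted diffused fraction at supernatant volume fraction X."""
    X = np.asarray(X, dtype=float)
    if np.any(X < 0):
        raise ParameterError("X must be >= 0")
    B = bound_concentration(p.c_jb6, X * p.c_s, p.kd)
    out = p.f_0 + (p.f_b - p.f_0) * B / p.c_jb6
    return float(out) if np.ndim(out) == 0 else out


@dataclass
class BindingFit:
    """Best-fit binding parameters with e.s.s. and bootstrap errors."""

    params: BindingParameters
    ess: float
    stderr: dict
    n_points: int
    n_starts: int
    converged: bool = True
    c_s_caveat: str = C_S_CAVEAT


def _pack(p: BindingParameters) -> np.ndarray:
    return np.array([np.log10(max(p.kd, 1e-6)), np.log10(max(p.c_s, 1e-6)), p.f_0, p.f_b])


def _unpack(x, c_jb6) -> BindingParameters:
    return BindingParameters(
        kd=10.0 ** x[0], c_s=10.0 ** x[1], f_0=x[2], f_b=x[3], c_jb6=c_jb6
    )


_FRAC_LO, _FRAC_HI = 1e-4, 0.4999


def _ls(residual, x0, bounds):
    return least_squares(residual, x0=x0, bounds=bounds, xtol=1e-12, ftol=1e-12)


def fit_binding(
    points: Sequence[TitrationPoint],
    c_jb6: float = 12.5,
    kd_starts: Sequence[float] = (0.1, 1.0, 10.0, 100.0),
    n_boot: int = 200,
    seed: int | None = None,
) -> BindingFit:
    """Multistart nonlinear least squares of the depletion isotherm.

    All replicate points are fitted jointly on the diffused-fraction
    scale.  K_D is initialized over a log-spaced grid because the flat
    low-K_D e.s.s. profile makes single-start fits fragile; C_s starts
    from the transition midpoint of the data and from C_JB6 / X_max.
    Bootstrap standard errors resample replicates within each X.
    """
    points = list(points)
    X = np.array([p.X for p in points])
    f = np.array([p.f for p in points])
    if len(set(np.round(X, 12))) < 6:
        warnings.warn("fewer than 6 distinct X values; fit may be ill-posed")
    if np.ptp(X) <= 0:
        raise FitFailureError("degenerate design: all points at the same X")

    f0_init = float(np.mean(f[X <= np.quantile(X, 0.1)]))
    fb_init = float(np.mean(f[X >= np.quantile(X, 0.9)]))
    f0_init = np.clip(f0_init, _FRAC_LO * 2, _FRAC_HI)
    fb_init = np.clip(min(fb_init, f0_init * 0.9), _FRAC_LO, _FRAC_HI)
    # X where f crosses midway between the plateaus -> C_s ~ C_JB6 / X_mid
    mid = 0.5 * (f0_init + fb_init)
    below = X[f <= mid]
    cs_starts = [c_jb6 / np.max(X)]
    if below.size:
        cs_starts.append(c_jb6 / np.min(below))

    def residual(x):
        try:
            p = _unpack(x, c_jb6)
        except ParameterError:
            return np.full_like(f, 1e3)
        return model_fraction(X, p) - f

    lo = [-6.0, -6.0, _FRAC_LO, _FRAC_LO]
    hi = [6.0, 6.0, _FRAC_HI, _FRAC_HI]
    best = None
    n_starts = 0
    for kd0 in kd_starts:
        for cs0 in cs_starts:
            n_starts += 1
            x0 = np.array(
                [np.log10(kd0), np.log10(cs0), f0_init, max(fb_init, _FRAC_LO * 2)]
            )
            x0 = np.clip(x0, lo, hi)
            try:
                res = _ls(residual, x0, (lo, hi))
            except ValueError:
                continue
            if res.success and (best is None or res.cost < best.cost):
                best = res
    if best is None:
        raise FitFailureError("no multistart converged", best=None)

    # enforce f_b < f_0 ordering of the solution
    x = best.x.copy()
    if x[3] >= x[2]:
        x[2], x[3] = max(x[2], x[3]), min(x[2], x[3]) - 1e-6
    params = _unpack(x, c_jb6)
    ess = float(np.sum(residual(best.x) ** 2))

    stderr: dict = {}
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        groups: dict[float, list[int]] = {}
        for i, p in enumerate(points):
            groups.setdefault(p.X, []).append(i)
        samples = {k: [] for k in ("kd", "c_s", "f_0", "f_b")}
        for _ in range(n_boot):
            idx = np.concatenate(
                [rng.choice(g, size=len(g), replace=True) for g in groups.values()]
            )
            Xb, fb_ = X[idx], f[idx]

            def res_b(xv):
                try:
                    pb = _unpack(xv, c_jb6)
                except ParameterError:
                    return np.full_like(fb_, 1e3)
                return model_fraction(Xb, pb) - fb_

            try:
                rb = _ls(res_b, best.x, (lo, hi))
            except ValueError:
                continue
            pb = _unpack(rb.x, c_jb6)
            for k, v in zip(samples, (pb.kd, pb.c_s, pb.f_0, pb.f_b)):
                samples[k].append(v)
        stderr = {k: float(np.std(v)) for k, v in samples.items() if v}

    return BindingFit(
        params=params, ess=ess, stderr=stderr, n_points=len(points), n_starts=n_starts
    )


@dataclass
class ProfilePoint:
    kd: float
    ess: float
    ess_ratio: float
    converged: bool


@dataclass
class EssProfile:
    """e.s.s. profile over a fixed-K_D grid, normalized to the best fit."""

    points: list
    best_kd: float
    best_ess: float
    threshold: float
    interval: tuple  # (kd_low, kd_high) where ratio <= threshold

    @property
    def kd_grid(self) -> np.ndarray:
        return np.array([p.kd for p in self.points])

    @property
    def ratios(self) -> np.ndarray:
        return np.array([p.ess_ratio for p in self.points])


def ess_profile(
    points: Sequence[TitrationPoint],
    c_jb6: float = 12.5,
    kd_grid=None,
    threshold: float = 1.25,
    fit: BindingFit | None = None,
) -> EssProfile:
    """Profile the e.s.s. over fixed K_D, re-optimizing (C_s, f_0, f_b).

    Mirrors the published error analysis: a flat profile below the
    best-fit K_D with a rise above it means only an upper bound on K_D
    is supported.  Grid-point fit failures are marked, not fatal.
    """
    if kd_grid is None:
        kd_grid = np.logspace(-2, 3, 26)
    kd_grid = np.asarray(kd_grid, dtype=float)
    if fit is None:
        fit = fit_binding(points, c_jb6=c_jb6, n_boot=0)
    X = np.array([p.X for p in points])
    f = np.array([p.f for p in points])
    x_best = _pack(fit.params)
    lo = [-6.0, _FRAC_LO, _FRAC_LO]
    hi = [6.0, _FRAC_HI, _FRAC_HI]

    prof = []
    for kd in kd_grid:
        def residual(x):
            try:
                p = BindingParameters(
                    kd=kd, c_s=10.0 ** x[0], f_0=x[1], f_b=x[2], c_jb6=c_jb6
                )
            except ParameterError:
                return np.full_like(f, 1e3)
            return model_fraction(X, p) - f

        try:
            res = _ls(residual, np.clip(x_best[1:], lo, hi), (lo, hi))
            ess = float(np.sum(res.fun ** 2))
            ok = bool(res.success)
        except ValueError:
            ess, ok = np.inf, False
        prof.append(ProfilePoint(kd=float(kd), ess=ess, ess_ratio=ess / fit.ess, converged=ok))

    inside = [p.kd for p in prof if p.converged and p.ess_ratio <= threshold]
    interval = (min(inside), max(inside)) if inside else (np.nan, np.nan)
    return EssProfile(
        points=prof,
        best_kd=fit.params.kd,
        best_ess=fit.ess,
        threshold=threshold,
        interval=interval,
    )


def chaperone_titration_curve(
    c_jb6_values,
    X_fixed: float,
    p: BindingParameters,
    r_free: float,
    r_bound: float,
    cal: ChannelCalibration,
) -> np.ndarray:
    """Apparent <R_h> versus total chaperone at fixed supernatant fraction.

    At each total chaperone concentration C the bound fraction B/C from
    the depletion quadratic weights a two-species mixture (bound probe
    at ``r_bound`` nm, free probe at ``r_free`` nm); the mixture's
    intensity-weighted diffused fraction is inverted to an apparent
    radius.  Decreases from ~r_bound (all probe bound at low C) toward
    r_free (excess free probe).
    """
    if r_bound <= r_free:
        raise ParameterError("r_bound must exceed r_free")
    c_vals = np.atleast_1d(np.asarray(c_jb6_values, dtype=float))
    out = np.empty_like(c_vals)
    S = X_fixed * p.c_s
    for i, c in enumerate(c_vals):
        B = bound_concentration(c, S, p.kd)
        w_bound = min(B / c, 1.0) if c > 0 else 1.0
        mix = SpeciesMixture([(r_bound, w_bound), (r_free, 1.0 - w_bound)])
        out[i] = invert_fraction(mixture_fraction(mix, cal), cal)
    return out
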
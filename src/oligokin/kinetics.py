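"""Seeded amyloid aggregation kinetics via two-moment master equations.

The fibril population is described by its number concentration ``P``
(fibril ends / particles) and mass concentration ``M`` (monomer
equivalents).  With free monomer ``m = m_total - M`` the moments obey

    dP/dt = k_n * m**n_c + k_2 * m**n_2 * M
    dM/dt = 2 * k_plus * P * (m - m_eq)

i.e. primary nucleation, fibril-surface-catalysed secondary nucleation,
and elongation of the two ends of each fibril.  Elongation is driven by
the supersaturation ``m - m_eq`` because here the fibril solubility
(3.5 mM) is a large fraction of the 5 mM total peptide: the ThT plateau
coexists with millimolar free monomer.  Nucleation terms use ``m``
itself, a deliberate simplification documented in the methods note.

Seeds enter through the initial condition ``M(0) = seed_mass *
active_seed_fraction`` and ``P(0) = M(0) / L0`` with ``L0`` the mean
number of monomers per (sonicated) seed fibril.  ``active_seed_fraction``
is the handle for the seed-inactivation hypothesis of chaperone action.

Units: concentrations in mM, time in hours throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.interpolate import interp1d
from scipy.optimize import least_squares

from .errors import (
    FitFailureError,
    IntegrationError,
    NoCrossingError,
    NoPlateauError,
    ParameterError,
)

__all__ = [
    "RateParameters",
    "KineticState",
    "KineticTrace",
    "HypothesisFit",
    "integrate_moments",
    "oligomer_population",
    "normalize_trace",
    "halftime",
    "fit_hypothesis",
    "rank_hypotheses",
    "HYPOTHESES",
]

HYPOTHESES = ("reduce_k_plus", "reduce_k2", "inactivate_seeds")
Hypothesis = Literal["reduce_k_plus", "reduce_k2", "inactivate_seeds"]


@dataclass(frozen=True)
class RateParameters:
    """Rate constants and concentrations of the aggregation model.

    Parameters
    ----------
    k_plus : float
        Elongation rate constant (mM^-1 h^-1).
    k_n : float
        Primary nucleation rate constant (mM^(1-n_c) h^-1).
    n_c : float
        Primary nucleation reaction order (>= 1).
    k_2 : float
        Secondary nucleation rate constant (mM^(-n_2) h^-1).
    n_2 : float
        Secondary nucleation reaction order (>= 1).
    m_total : float
        Total peptide concentration (mM).
    m_eq : float
        Fibril solubility / equilibrium monomer concentration (mM).
    seed_mass_M0 : float
        Seed concentration in monomer equivalents (mM).
    seed_mean_size_L0 : float
        Mean monomers per seed fibril (> 0).
    active_seed_fraction : float
        Fraction of seeds that are active, in [0, 1].
    """

    k_plus: float = 50.0
    k_n: float = 0.0
    n_c: float = 2.0
    k_2: float = 9.928032799870731e-05
    n_2: float = 2.0
    m_total: float = 5.0
    m_eq: float = 3.5
    seed_mass_M0: float = 0.035
    seed_mean_size_L0: float = 500.0
    active_seed_fraction: float = 1.0

    def __post_init__(self):
        for name in ("k_plus", "k_n", "k_2"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        if not (self.n_c >= 1 and self.n_2 >= 1):
            raise ParameterError("reaction orders must be >= 1")
        if not (0 <= self.m_eq < self.m_total):
            raise ParameterError("require 0 <= m_eq < m_total")
        if not (0 <= self.seed_mass_M0 < self.m_total):
            raise ParameterError("require 0 <= seed_mass_M0 < m_total")
        if self.seed_mean_size_L0 <= 0:
            raise ParameterError("seed_mean_size_L0 must be > 0")
        if not (0 <= self.active_seed_fraction <= 1):
            raise ParameterError("active_seed_fraction must be in [0, 1]")

    def with_(self, **kwargs) -> "RateParameters":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


@dataclass
class KineticState:
    """Moment-equation solution on a time grid (all concentrations mM)."""

    t: np.ndarray
    m: np.ndarray
    M: np.ndarray
    P: np.ndarray
    O: np.ndarray | None = None


@dataclass
class KineticTrace:
    """A single ThT fluorescence trace (arbitrary units)."""

    t: np.ndarray
    signal: np.ndarray
    well_id: str = ""
    jb6_conc: float = 0.0  # nM

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.t.ndim != 1 or self.t.shape != self.signal.shape:
            raise ParameterError("t and signal must be 1-D arrays of equal length")
        if np.any(np.diff(self.t) <= 0):
            raise ParameterError("time grid must be strictly increasing")
        if not np.all(np.isfinite(self.signal)):
            raise ParameterError("signal must be finite")


def integrate_moments(params: RateParameters, t_grid) -> KineticState:
    """Integrate the two-moment system on ``t_grid`` (hours, from 0).

    Uses the adaptive stiff-capable LSODA integrator at rtol 1e-8 /
    atol 1e-10.  Raises :class:`IntegrationError` on non-finite output
    or negative concentrations beyond tolerance.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or t_grid[0] != 0 or np.any(np.diff(t_grid) <= 0):
        raise ParameterError("t_grid must be increasing and start at 0")
    p = params
    M0 = p.seed_mass_M0 * p.active_seed_fraction
    P0 = M0 / p.seed_mean_size_L0

    def rhs(t, y):
        P, M = y
        m = max(p.m_total - M, 0.0)
        dP = p.k_n * m ** p.n_c + p.k_2 * m ** p.n_2 * M
        dM = 2.0 * p.k_plus * P * (m - p.m_eq)
        return (dP, dM)

    sol = solve_ivp(
        rhs,
        (0.0, float(t_grid[-1])),
        (P0, M0),
        t_eval=t_grid,
        method="LSODA",
        rtol=1e-8,
        atol=1e-10,
    )
    if not sol.success:
        raise IntegrationError(f"moment integration failed: {sol.message}")
    P, M = sol.y
    if not (np.all(np.isfinite(P)) and np.all(np.isfinite(M))):
        raise IntegrationError("non-finite solution")
    if np.any(P < -1e-9) or np.any(M < -1e-9):
        raise IntegrationError("negative concentrations beyond tolerance")
    m = p.m_total - M
    return KineticState(t=t_grid, m=m, M=M, P=np.maximum(P, 0.0))


def oligomer_population(
    state: KineticState, params: RateParameters, k_loss: float
) -> np.ndarray:
    """Oligomer concentration O(t) driven by secondary nucleation.

    O obeys ``dO/dt = k_2 * (m - m_eq)_+ ** n_2 * M - k_loss * O`` with
    O(0) = 0: oligomers are generated on the fibril surface from
    supersaturated monomer and are lost (dissociation + conversion) at
    first-order rate ``k_loss``.  The supersaturation factor makes the
    source vanish at equilibrium, so O rises during the growth phase and
    decays back to zero at the plateau, as observed for the transient
    species the chaperone probe reports on.
    """
    if k_loss < 0:
        raise ParameterError("k_loss must be >= 0")
    t = state.t
    m_of = interp1d(t, state.m, kind="cubic", assume_sorted=True)
    M_of = interp1d(t, state.M, kind="cubic", assume_sorted=True)
    p = params

    def source(tt):
        ss = max(float(m_of(tt)) - p.m_eq, 0.0)
        return p.k_2 * ss ** p.n_2 * max(float(M_of(tt)), 0.0)

    sol = solve_ivp(
        lambda tt, y: (source(tt) - k_loss * y[0],),
        (float(t[0]), float(t[-1])),
        (0.0,),
        t_eval=t,
        method="LSODA",
        rtol=1e-8,
        atol=1e-14,
    )
    if not sol.success:
        raise IntegrationError(f"oligomer integration failed: {sol.message}")
    return np.maximum(sol.y[0], 0.0)


def normalize_trace(
    trace: KineticTrace,
    baseline_points: int = 5,
    plateau_frac: float = 0.1,
    drift_tol: float = 0.05,
) -> np.ndarray:
    """Affine-rescale a ThT trace to a mass-fraction-like [0, 1] series.

    baseline = mean of the first ``baseline_points`` samples; plateau =
    mean of the last ``plateau_frac`` of samples.  The plateau is
    accepted if the relative drift of the final segment (peak-to-peak
    over dynamic range) is below ``drift_tol``.  Output is clipped to
    [-0.05, 1.05].
    """
    y = trace.signal
    n = y.size
    n_pl = max(int(np.ceil(plateau_frac * n)), 2)
    base = float(np.mean(y[:baseline_points]))
    tail = y[-n_pl:]
    plat = float(np.mean(tail))
    dyn = plat - base
    if dyn <= 0 or not np.isfinite(dyn):
        raise NoPlateauError("zero or negative dynamic range")
    if np.ptp(tail) / abs(dyn) > drift_tol:
        raise NoPlateauError("final segment still drifting; plateau not reached")
    return np.clip((y - base) / dyn, -0.05, 1.05)


def halftime(t, normalized) -> float:
    """First upward 0.5-crossing of a normalized trace, interpolated.

    Parameters are the time grid (h) and the normalized mass-fraction
    series; returns t_1/2 in hours.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(normalized, dtype=float)
    above = y >= 0.5
    idx = np.nonzero(above[1:] & ~above[:-1])[0]
    if above[0]:
        raise NoCrossingError("trace starts above 0.5")
    if idx.size == 0:
        raise NoCrossingError("no upward 0.5-crossing found")
    i = int(idx[0])
    y0, y1 = y[i], y[i + 1]
    return float(t[i] + (0.5 - y0) / (y1 - y0) * (t[i + 1] - t[i]))


def _model_normalized(params: RateParameters, t_grid: np.ndarray) -> np.ndarray:
    """Model-predicted normalized fibril mass fraction on t_grid.

    Applies the same baseline/plateau estimator as :func:`normalize_trace`
    (mean of first 5 points / mean of last 10%), so model and data are
    compared on identical footing.
    """
    st = integrate_moments(params, t_grid)
    M = st.M
    n_pl = max(int(np.ceil(0.1 * M.size)), 2)
    base = float(np.mean(M[:5]))
    plat = float(np.mean(M[-n_pl:]))
    dyn = plat - base
    if dyn <= 1e-12:
        return np.zeros_like(M)
    return (M - base) / dyn


def _median_trace(group: Sequence[KineticTrace]) -> KineticTrace:
    t = group[0].t
    for tr in group[1:]:
        if tr.t.shape != t.shape or not np.allclose(tr.t, t):
            raise ParameterError("replicates must share a common time grid")
    sig = np.median(np.vstack([tr.signal for tr in group]), axis=0)
    return KineticTrace(t=t, signal=sig, well_id="median", jb6_conc=group[0].jb6_conc)


@dataclass
class HypothesisFit:
    """Result of a global hypothesis fit across chaperone concentrations."""

    hypothesis: str
    base_params: RateParameters
    per_group: dict = field(default_factory=dict)  # jb6_conc -> fitted value
    ess: float = np.inf
    converged: bool = True

    @property
    def parameter_name(self) -> str:
        return {
            "reduce_k_plus": "k_plus",
            "reduce_k2": "k_2",
            "inactivate_seeds": "active_seed_fraction",
        }[self.hypothesis]


def _group_traces(traces: Sequence[KineticTrace]) -> dict[float, list[KineticTrace]]:
    groups: dict[float, list[KineticTrace]] = {}
    for tr in traces:
        groups.setdefault(float(tr.jb6_conc), []).append(tr)
    return groups


def fit_hypothesis(
    traces: Sequence[KineticTrace],
    hypothesis: Hypothesis,
    base_params: RateParameters = RateParameters(),
    fit_baseline: bool = True,
    use_median: bool = True,
) -> HypothesisFit:
    """Global least-squares fit of one chaperone-action hypothesis.

    The 0 nM group anchors the shared rate constants (k_plus, k_2; k_n
    is held at ``base_params.k_n``).  Each non-zero chaperone
    concentration then gets a single free parameter according to the
    hypothesis: a reduced elongation rate, a reduced secondary
    nucleation rate, or a reduced active seed fraction.  Structural
    parameters (m_total, m_eq, seed mass, seed size) are taken from
    ``base_params``.  Returns the parameter table and total error
    square sum over all groups, enabling hypothesis ranking.
    """
    if hypothesis not in HYPOTHESES:
        raise ParameterError(f"unknown hypothesis {hypothesis!r}")
    groups = _group_traces(traces)
    if 0.0 not in groups:
        raise ParameterError("a 0 nM chaperone group is required as anchor")

    data: dict[float, tuple[np.ndarray, np.ndarray]] = {}
    for conc, grp in groups.items():
        reps = [_median_trace(grp)] if use_median else grp
        for tr in reps:
            data.setdefault(conc, (tr.t, []))[1].append(normalize_trace(tr))
    # stack replicate targets per group
    data = {c: (t, np.vstack(ys)) for c, (t, ys) in data.items()}

    p0 = base_params.with_(active_seed_fraction=1.0)

    def baseline_resid(log_kpk2):
        pp = p0.with_(k_plus=10.0 ** log_kpk2[0], k_2=10.0 ** log_kpk2[1])
        t, ys = data[0.0]
        model = _model_normalized(pp, t)
        return (ys - model).ravel()

    if fit_baseline:
        res0 = least_squares(
            baseline_resid,
            x0=[np.log10(p0.k_plus), np.log10(max(p0.k_2, 1e-12))],
            method="lm",
            xtol=1e-10,
        )
        if not res0.success:
            raise FitFailureError("baseline (0 nM) fit failed", best=res0.x)
        p0 = p0.with_(k_plus=10.0 ** res0.x[0], k_2=10.0 ** res0.x[1])
        ess = float(np.sum(res0.fun ** 2))
    else:
        t, ys = data[0.0]
        ess = float(np.sum((ys - _model_normalized(p0, t)) ** 2))

    fit = HypothesisFit(hypothesis=hypothesis, base_params=p0)
    fit.per_group[0.0] = {
        "reduce_k_plus": p0.k_plus,
        "reduce_k2": p0.k_2,
        "inactivate_seeds": 1.0,
    }[hypothesis]

    converged = True
    for conc in sorted(c for c in data if c > 0):
        t, ys = data[conc]

        def group_params(x):
            if hypothesis == "reduce_k_plus":
                return p0.with_(k_plus=10.0 ** x)
            if hypothesis == "reduce_k2":
                return p0.with_(k_2=10.0 ** x)
            # logistic keeps the seed fraction in (0, 1]
            return p0.with_(active_seed_fraction=1.0 / (1.0 + np.exp(-x)))

        def resid(xv):
            return (ys - _model_normalized(group_params(xv[0]), t)).ravel()

        if hypothesis == "reduce_k_plus":
            x0 = np.log10(p0.k_plus) - 1.0
        elif hypothesis == "reduce_k2":
            x0 = np.log10(max(p0.k_2, 1e-12)) - 1.0
        else:
            x0 = -3.0
        res = least_squares(resid, x0=[x0], method="lm", xtol=1e-10)
        if not res.success:
            converged = False
        pg = group_params(res.x[0])
        fit.per_group[conc] = getattr(pg, fit.parameter_name)
        ess += float(np.sum(res.fun ** 2))

    fit.ess = ess
    fit.converged = converged
    if not converged:
        raise FitFailureError(f"{hypothesis} fit did not converge", best=fit)
    return fit


def rank_hypotheses(
    traces: Sequence[KineticTrace],
    base_params: RateParameters = RateParameters(),
    **kwargs,
) -> list[HypothesisFit]:
    """Fit all three hypotheses and return them sorted by e.s.s."""
    fits = []
    for h in HYPOTHESES:
        try:
            fits.append(fit_hypothesis(traces, h, base_params=base_params, **kwargs))
        except FitFailureError as exc:  # keep the best point for ranking
            if isinstance(exc.best, HypothesisFit):
                fits.append(exc.best)
            else:
                raise
    return sorted(fits, key=lambda f: f.ess)
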
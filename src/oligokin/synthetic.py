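"""Named synthetic scenarios emulating every experimental data stream.

Each scenario generates one input stream of the analysis chain with the
statistical structure the analysis assumes, under defaults that encode
the study conditions: seeded aggregation traces at five chaperone
concentrations (``fig3a``), rise-and-fall oligomer time courses read
out through the chaperone probe (``fig4a``/``fig4b``), the chaperone-
and supernatant-titration binding curves (``fig4c``/``fig4d``),
exponential apparent-size decays at two temperatures with and without
chaperone (``fig5_37C``/``fig5_23C``), and a composite fibril + coil
scattering curve (``fig3c``).

Every generator is a pure function of its :class:`ScenarioConfig`:
identical seeds give identical output.  Defaults that the study
conditions fix are frozen constants here (half-time 6.5 h at zero
chaperone, doubling at 50 nM, free-probe anchor 0.42 at 3 nm, peak
co-oligomer radius 11 nm / 5 nm, dissociation rates 3.5/1.9 and
1.3/0.8 h^-1, K_D = 1 nM, SAXS exponent 2.3 / 3.9 mM / R_g 1 nm with
the coil-fibril crossover at 0.06 1/A); everything else is an explicit
config constant that ``overrides`` can replace.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import binding, dissociation, kinetics, mds, saxs
from .errors import ConfigError

__all__ = [
    "SCENARIOS",
    "ScenarioConfig",
    "SizingTimecourse",
    "ChaperoneTitrationPoint",
    "generate_kinetics",
    "generate_oligomer_timecourse",
    "generate_titrations",
    "generate_decays",
    "generate_saxs",
    "summarize_timecourse",
    "scenario_defaults",
]

SCENARIOS = (
    "fig3a", "fig4a", "fig4b", "fig4c", "fig4d", "fig5_37C", "fig5_23C", "fig3c",
)

# --- frozen study-condition constants ---------------------------------
# Baseline seeded-aggregation rates giving t_half = 6.5 h at 5 mM total,
# 3.5 mM solubility, 0.7% seeds (solved once from the moment equations).
_BASE_PARAMS = kinetics.RateParameters(
    k_plus=50.0, k_n=0.0, n_c=2.0, k_2=9.928032799870731e-05, n_2=2.0,
    m_total=5.0, m_eq=3.5, seed_mass_M0=0.035, seed_mean_size_L0=500.0,
)
# Seed-inactivation constant (nM): active fraction 1/(1 + [JB6]/K_inact),
# solved so that 50 nM chaperone doubles the half-time (6.5 -> 13 h).
K_INACT_NM = 0.9362535696940214

_NOISE_DEFAULTS = {
    "tht": 10.0,        # a.u. on a ~900 a.u. dynamic range
    # Absolute STD on diffused fractions, calibrated so the expected
    # e.s.s. profile of the supernatant titration reproduces the
    # reported one-sided K_D bound: ratio 1.25 at K_D = 100 nM and a
    # flat profile (ratio < 1.05) below the generating 1 nM.
    "fraction": 0.0177,
    "r_h": 0.5,         # nm, on apparent radii
    "saxs_frac": 0.02,  # fractional (lognormal) on I(q)
}

_DEFAULTS = {
    "fig3a": dict(
        jb6_concs_nM=(0.0, 50.0, 150.0, 300.0, 1000.0),
        n_replicates={0.0: 7, "other": 5},
        t_grid=np.linspace(0.0, 30.0, 301),
        tht_base=100.0, tht_per_mM=600.0,
        params=_BASE_PARAMS, k_inact_nM=K_INACT_NM,
    ),
    "fig4a": dict(
        params=_BASE_PARAMS, k_loss=3.5, t_withdraw=np.arange(0.0, 14.01, 0.5),
        r_oligomer_nm=11.0, r_free_nm=3.0, sites_peak_nM=2000.0,
        kd_nM=1.0, c_jb6_nM=12.5, n_replicates=(7, 15), size_range_id=3,
    ),
    "fig4b": dict(
        # structural emulation of the faster physiological peptide:
        # 10x secondary nucleation, smaller co-oligomers
        params=_BASE_PARAMS.with_(k_2=_BASE_PARAMS.k_2 * 10.0),
        k_loss=3.5, t_withdraw=np.arange(0.0, 6.01, 0.25),
        r_oligomer_nm=5.0, r_free_nm=3.0, sites_peak_nM=2000.0,
        kd_nM=1.0, c_jb6_nM=12.5, n_replicates=(7, 9), size_range_id=3,
    ),
    "fig4c": dict(
        c_jb6_nM=np.geomspace(3.0, 75.0, 12), X_fixed=0.025,
        kd_nM=1.0, c_s_nM=400.0, r_free_nm=3.0, r_bound_nm=11.0,
        n_replicates=(4, 6), size_range_id=3,
    ),
    "fig4d": dict(
        X=np.geomspace(1.4e-4, 0.75, 12), c_jb6_nM=12.5,
        kd_nM=1.0, c_s_nM=400.0, f_0=0.42, f_b=None,  # None -> f(11 nm)
        r_bound_nm=11.0, n_replicates=(4, 6),
    ),
    "fig5_37C": dict(
        k_off={"without_JB6": 3.5, "with_JB6": 1.9},
        a_nm=7.0, c_nm=3.0,
        t_h=np.concatenate([np.arange(0.0, 1.0, 0.125),
                            np.array([1.0, 1.25, 1.5, 1.75, 2.0])]),
        n_replicates=4, temperature_label="37C",
    ),
    "fig5_23C": dict(
        k_off={"without_JB6": 1.3, "with_JB6": 0.8},
        a_nm=7.0, c_nm=3.0,
        t_h=np.concatenate([np.arange(0.0, 2.0, 0.25),
                            np.array([2.0, 2.5, 3.0, 3.5, 4.0])]),
        n_replicates=4, temperature_label="23C",
    ),
    "fig3c": dict(
        q=np.geomspace(3e-4, 2.0, 250), p=2.3, concentration_mM=3.9,
        r_g_nm=1.0, contrast_scale=0.01, bkg=1e-4, q_crossover=0.06,
    ),
}


@dataclass
class ScenarioConfig:
    """A named scenario with seed, noise scales and parameter overrides."""

    scenario_id: str
    seed: int = 0
    noise: dict = field(default_factory=dict)
    overrides: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.scenario_id not in SCENARIOS:
            raise ConfigError(
                f"unknown scenario {self.scenario_id!r}; known: {SCENARIOS}"
            )

    def noise_scale(self, stream: str) -> float:
        s = self.noise.get(stream, _NOISE_DEFAULTS[stream])
        if s < 0:
            raise ConfigError("noise scales must be >= 0")
        return float(s)

    def param(self, name: str):
        d = _DEFAULTS[self.scenario_id]
        if name in self.overrides:
            return self.overrides[name]
        return d[name]

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def scenario_defaults(scenario_id: str) -> dict:
    """The default parameter map of a scenario (copy)."""
    if scenario_id not in SCENARIOS:
        raise ConfigError(f"unknown scenario {scenario_id!r}")
    return dict(_DEFAULTS[scenario_id])


def _require(cfg: ScenarioConfig, *allowed: str):
    if cfg.scenario_id not in allowed:
        raise ConfigError(
            f"scenario {cfg.scenario_id!r} not valid here (expected {allowed})"
        )


# --- fig3a: seeded aggregation traces ---------------------------------

def generate_kinetics(cfg: ScenarioConfig) -> list:
    """Seeded ThT traces at five chaperone concentrations (``fig3a``).

    The chaperone inactivates seeds: active_seed_fraction =
    1 / (1 + [JB6]/K_inact).  The fibril mass is mapped to ThT through
    an affine transform plus Gaussian noise; 7 replicates at 0 nM, 5
    otherwise.
    """
    _require(cfg, "fig3a")
    rng = cfg.rng()
    base = cfg.param("params")
    t = np.asarray(cfg.param("t_grid"), dtype=float)
    k_inact = float(cfg.param("k_inact_nM"))
    nrep = cfg.param("n_replicates")
    tht_base = float(cfg.param("tht_base"))
    tht_per_mM = float(cfg.param("tht_per_mM"))
    sigma = cfg.noise_scale("tht")

    traces = []
    for conc in cfg.param("jb6_concs_nM"):
        asf = 1.0 / (1.0 + conc / k_inact)
        st = kinetics.integrate_moments(base.with_(active_seed_fraction=asf), t)
        clean = tht_base + tht_per_mM * st.M
        n = nrep[conc] if conc in nrep else nrep["other"]
        for r in range(n):
            sig = clean + rng.normal(0.0, sigma, t.size) if sigma > 0 else clean.copy()
            traces.append(
                kinetics.KineticTrace(
                    t=t, signal=sig, well_id=f"jb6_{conc:g}_r{r}", jb6_conc=conc
                )
            )
    return traces


# --- fig4a/fig4b: oligomer time course through the probe --------------

@dataclass
class SizingTimecourse:
    """Per-withdrawal-time MDS replicates plus a companion ThT trace."""

    t: np.ndarray                      # withdrawal times (h)
    measurements: list                 # list (per t) of SizingMeasurement lists
    noiseless_fraction: np.ndarray     # model diffused fraction per t
    tht: kinetics.KineticTrace
    size_range_id: int = 3


def generate_oligomer_timecourse(cfg: ScenarioConfig) -> SizingTimecourse:
    """Rise-and-fall oligomer time course read out as diffused fractions.

    Runs the moment equations plus the oligomer channel; at each
    withdrawal time the chaperone probe partitions between free (3 nm)
    and oligomer-bound (11 nm for ``fig4a``, 5 nm for ``fig4b``) states
    with binding-site concentration proportional to the oligomer
    population, and the forward MDS model gives the observed fraction.
    """
    _require(cfg, "fig4a", "fig4b")
    rng = cfg.rng()
    params = cfg.param("params")
    t = np.asarray(cfg.param("t_withdraw"), dtype=float)
    cal = mds.default_calibration(cfg.param("size_range_id"))
    st = kinetics.integrate_moments(params, t)
    O = kinetics.oligomer_population(st, params, float(cfg.param("k_loss")))
    peak = float(O.max())
    sites = (O / peak) * float(cfg.param("sites_peak_nM")) if peak > 0 else O * 0.0

    c_jb6 = float(cfg.param("c_jb6_nM"))
    kd = float(cfg.param("kd_nM"))
    r_ol = float(cfg.param("r_oligomer_nm"))
    r_free = float(cfg.param("r_free_nm"))
    f_free = mds.fraction_for_radius(r_free, cal)
    f_ol = mds.fraction_for_radius(r_ol, cal)
    sigma = cfg.noise_scale("fraction")
    n_lo, n_hi = cfg.param("n_replicates")

    clean = np.empty(t.size)
    meas = []
    for i in range(t.size):
        B = binding.bound_concentration(c_jb6, sites[i], kd)
        wb = min(B / c_jb6, 1.0)
        clean[i] = wb * f_ol + (1.0 - wb) * f_free
        n = int(rng.integers(n_lo, n_hi + 1))
        reps = []
        for r in range(n):
            f = clean[i] + (rng.normal(0.0, sigma) if sigma > 0 else 0.0)
            f = min(max(f, 1e-4), 0.4999)
            reps.append(
                mds.SizingMeasurement(
                    diffused_fraction=f,
                    replicate_id=f"t{t[i]:g}_r{r}",
                    size_range_id=cal.size_range_id,
                )
            )
        meas.append(reps)

    tht_sigma = cfg.noise_scale("tht")
    tht_clean = 100.0 + 600.0 * st.M
    tht_sig = tht_clean + (rng.normal(0.0, tht_sigma, t.size) if tht_sigma > 0 else 0.0)
    tht = kinetics.KineticTrace(t=t, signal=tht_sig, well_id="companion", jb6_conc=0.0)
    return SizingTimecourse(
        t=t, measurements=meas, noiseless_fraction=clean, tht=tht,
        size_range_id=cal.size_range_id,
    )


def summarize_timecourse(tc: SizingTimecourse, cal=None):
    """Mean +/- STD apparent radius per withdrawal time.

    Each replicate fraction is inverted to a radius; returns
    (t, mean_r_h, sd_r_h, n) arrays.
    """
    cal = cal or mds.default_calibration(tc.size_range_id)
    mean, sd, n = np.empty(tc.t.size), np.empty(tc.t.size), np.empty(tc.t.size, int)
    for i, reps in enumerate(tc.measurements):
        radii = [mds.invert_fraction(m.diffused_fraction, cal) for m in reps]
        mean[i], sd[i], n[i] = np.mean(radii), np.std(radii, ddof=1) if len(radii) > 1 else 0.0, len(radii)
    return tc.t, mean, sd, n


# --- fig4c/fig4d: titrations ------------------------------------------

@dataclass
class ChaperoneTitrationPoint:
    """One probe-titration replicate: total chaperone (nM), apparent R_h."""

    c_jb6: float
    r_h: float
    replicate_id: str = ""


def generate_titrations(cfg: ScenarioConfig):
    """Binding-curve scenarios.

    ``fig4d``: supernatant volume-fraction titration at fixed 12.5 nM
    probe; returns a list of :class:`~oligokin.binding.TitrationPoint`
    (diffused fractions).  ``fig4c``: chaperone titration at fixed 2.5%
    supernatant; returns a list of :class:`ChaperoneTitrationPoint`
    (apparent radii).  4-6 replicates per abscissa in both.
    """
    _require(cfg, "fig4c", "fig4d")
    rng = cfg.rng()
    n_lo, n_hi = cfg.param("n_replicates")

    if cfg.scenario_id == "fig4d":
        cal = mds.default_calibration(3)
        f_b = cfg.param("f_b")
        if f_b is None:
            f_b = mds.fraction_for_radius(float(cfg.param("r_bound_nm")), cal)
        p = binding.BindingParameters(
            kd=float(cfg.param("kd_nM")), c_s=float(cfg.param("c_s_nM")),
            f_0=float(cfg.param("f_0")), f_b=float(f_b),
            c_jb6=float(cfg.param("c_jb6_nM")),
        )
        sigma = cfg.noise_scale("fraction")
        pts = []
        for X in np.asarray(cfg.param("X"), dtype=float):
            clean = binding.model_fraction(X, p)
            for r in range(int(rng.integers(n_lo, n_hi + 1))):
                f = clean + (rng.normal(0.0, sigma) if sigma > 0 else 0.0)
                f = min(max(f, 1e-4), 0.5)
                pts.append(binding.TitrationPoint(X=X, f=f, replicate_id=f"X{X:g}_r{r}"))
        return pts

    cal = mds.default_calibration(cfg.param("size_range_id"))
    p = binding.BindingParameters(
        kd=float(cfg.param("kd_nM")), c_s=float(cfg.param("c_s_nM")),
        f_0=0.42, f_b=0.2, c_jb6=12.5,  # plateaus unused by the radius curve
    )
    curve = binding.chaperone_titration_curve(
        np.asarray(cfg.param("c_jb6_nM"), dtype=float), float(cfg.param("X_fixed")),
        p, float(cfg.param("r_free_nm")), float(cfg.param("r_bound_nm")), cal,
    )
    sigma = cfg.noise_scale("r_h")
    pts = []
    for c, r_clean in zip(np.asarray(cfg.param("c_jb6_nM"), dtype=float), curve):
        for r in range(int(rng.integers(n_lo, n_hi + 1))):
            rh = r_clean + (rng.normal(0.0, sigma) if sigma > 0 else 0.0)
            pts.append(
                ChaperoneTitrationPoint(
                    c_jb6=float(c), r_h=float(max(rh, 0.1)), replicate_id=f"c{c:g}_r{r}"
                )
            )
    return pts


# --- fig5: dissociation decays ----------------------------------------

def generate_decays(cfg: ScenarioConfig) -> dict:
    """Apparent-size decay series with and without chaperone.

    Returns ``{"without_JB6": DecaySeries, "with_JB6": DecaySeries}``
    with replicate-level points r_h = a exp(-k_off t) + c plus Gaussian
    noise; the curve runs from ~10 nm down to the ~3 nm probe baseline.
    """
    _require(cfg, "fig5_37C", "fig5_23C")
    rng = cfg.rng()
    t = np.asarray(cfg.param("t_h"), dtype=float)
    a, c = float(cfg.param("a_nm")), float(cfg.param("c_nm"))
    nrep = int(cfg.param("n_replicates"))
    sigma = cfg.noise_scale("r_h")
    label = cfg.param("temperature_label")
    k_off_map = cfg.param("k_off")
    if not set(k_off_map) == {"without_JB6", "with_JB6"}:
        raise ConfigError("k_off map must have conditions without_JB6/with_JB6")

    out = {}
    for cond, k in k_off_map.items():
        tt = np.repeat(t, nrep)
        clean = a * np.exp(-float(k) * tt) + c
        noisy = clean + (rng.normal(0.0, sigma, tt.size) if sigma > 0 else 0.0)
        out[cond] = dissociation.DecaySeries(
            t=tt, r_h=np.maximum(noisy, 0.1), condition=cond, temperature_label=label
        )
    return out


# --- fig3c: composite scattering curve --------------------------------

def generate_saxs(cfg: ScenarioConfig) -> saxs.ScatteringCurve:
    """Composite fibril + random-coil scattering curve.

    The power-law amplitude is set by the crossover condition: the
    fibril and coil terms are equal at q = 0.06 1/A.  Noise is
    multiplicative lognormal with configurable fractional sigma; the
    sigma column carries the same fractional scale.
    """
    _require(cfg, "fig3c")
    rng = cfg.rng()
    q = np.asarray(cfg.param("q"), dtype=float)
    p = float(cfg.param("p"))
    coil = saxs.CoilModel(
        r_g=float(cfg.param("r_g_nm")),
        concentration=float(cfg.param("concentration_mM")),
        contrast_scale=float(cfg.param("contrast_scale")),
    )
    qx = float(cfg.param("q_crossover"))
    coil_at_qx = coil.contrast_scale * coil.concentration * saxs.debye_form_factor(qx, coil.r_g)
    A = coil_at_qx * qx ** p
    bkg = float(cfg.param("bkg"))
    clean = saxs.composite_intensity(q, A, p, coil, bkg)
    frac = cfg.noise_scale("saxs_frac")
    if frac > 0:
        I = clean * np.exp(rng.normal(0.0, frac, q.size))
        sigma = frac * clean
    else:
        I = clean.copy()
        sigma = np.maximum(1e-6 * clean, 1e-30)
    return saxs.ScatteringCurve(q=q, I=I, sigma=sigma)
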
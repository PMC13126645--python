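"""Forward and inverse model of microfluidic diffusional sizing (MDS).

The instrument co-flows a labelled sample stream next to buffer in a
laminar channel; labelled species diffuse sideways during transit, and
the fluorescence is read in two chambers at the channel end.  The
"diffused fraction" f — intensity in the chamber opposite the sample
inlet over total intensity — grows from 0 (no diffusion) to 1/2 (full
equilibration) with diffusivity.

We model the channel as 1-D diffusion of a step concentration profile
between two half-channels with reflecting walls.  With the dimensionless
diffusion number tau = kappa * D (kappa an effective channel constant,
s m^-2, absorbing transit time and channel width), the mass in the
initially empty half is the cosine-series solution

    f(tau) = 1/2 - (4/pi^2) * sum_{k odd} k^-2 * exp(-k^2 pi^2 tau / 4)

which is strictly increasing in tau, hence strictly decreasing in the
hydrodynamic radius R_h through the Stokes-Einstein relation
D = k_B T / (6 pi eta R_h).  A single calibration anchor — the free
chaperone monomer, R_h ~ 3 nm at diffused fraction 0.42 — fixes kappa
for the default instrument size range; the map is inverted by bisection.

For a mixture of labelled species the observed fraction is the
intensity-weighted average of the per-species fractions (the instrument
measures one fraction per sample), and the apparent <R_h> is the radius
of the single species with that fraction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache
from typing import Sequence

import numpy as np
from scipy.optimize import brentq, least_squares

from .errors import CalibrationError, MixtureError, OutOfRangeError, ParameterError, QCWarning

__all__ = [
    "BOLTZMANN",
    "ChannelCalibration",
    "SizingMeasurement",
    "SpeciesMixture",
    "stokes_einstein_D",
    "diffused_fraction",
    "fraction_for_radius",
    "calibrate_channel",
    "default_calibration",
    "mixture_fraction",
    "invert_fraction",
    "clip_fraction",
]

BOLTZMANN = 1.380649e-23  # J/K


@dataclass(frozen=True)
class ChannelCalibration:
    """Effective channel constant and physical conditions for one size range.

    ``kappa`` (s m^-2) sets the dimensionless diffusion number
    ``kappa * D``.  ``r_min``/``r_max`` (nm) bound the invertible range
    reported by :func:`invert_fraction`.
    """

    kappa: float
    size_range_id: int = 3
    temperature: float = 298.15  # K
    viscosity: float = 8.9e-4  # Pa s (water, 25 C)
    n_terms: int = 51
    r_min: float = 0.5
    r_max: float = 50.0

    def __post_init__(self):
        if self.kappa <= 0:
            raise ParameterError("kappa must be > 0")
        if self.n_terms < 1:
            raise ParameterError("n_terms must be >= 1")
        if not (0 < self.r_min < self.r_max):
            raise ParameterError("require 0 < r_min < r_max")


@dataclass
class SizingMeasurement:
    """One MDS replicate: two-chamber intensities and derived quantities."""

    diffused_fraction: float
    intensity_inlet: float | None = None
    intensity_diffused: float | None = None
    r_h_apparent: float | None = None  # nm
    replicate_id: str = ""
    size_range_id: int = 3

    @classmethod
    def from_intensities(
        cls, intensity_inlet: float, intensity_diffused: float, **kwargs
    ) -> "SizingMeasurement":
        if intensity_inlet < 0 or intensity_diffused < 0:
            raise ParameterError("intensities must be >= 0")
        tot = intensity_inlet + intensity_diffused
        if tot <= 0:
            raise ParameterError("total intensity must be > 0")
        f = clip_fraction(intensity_diffused / tot)
        return cls(
            diffused_fraction=f,
            intensity_inlet=intensity_inlet,
            intensity_diffused=intensity_diffused,
            **kwargs,
        )


def clip_fraction(f: float) -> float:
    """QC-clip a diffused fraction marginally above the physical limit 0.5."""
    if f > 0.5:
        warnings.warn(
            f"diffused fraction {f:.4f} > 0.5 clipped to 0.4999", QCWarning, stacklevel=2
        )
        return 0.4999
    return float(f)


@dataclass(frozen=True)
class SpeciesMixture:
    """Labelled species as (hydrodynamic radius nm, label fraction) pairs."""

    components: tuple

    def __init__(self, components: Sequence[tuple]):
        comps = tuple((float(r), float(w)) for r, w in components)
        if not comps:
            raise MixtureError("mixture must have at least one component")
        if any(r <= 0 for r, _ in comps):
            raise MixtureError("all radii must be > 0")
        if any(w < 0 for _, w in comps):
            raise MixtureError("label fractions must be >= 0")
        if abs(sum(w for _, w in comps) - 1.0) > 1e-9:
            raise MixtureError("label fractions must sum to 1")
        object.__setattr__(self, "components", comps)


def stokes_einstein_D(r_h_nm, temperature: float = 298.15, viscosity: float = 8.9e-4):
    """Diffusivity (m^2 s^-1) of a sphere of hydrodynamic radius r_h (nm)."""
    r = np.asarray(r_h_nm, dtype=float)
    if np.any(r <= 0) or temperature <= 0 or viscosity <= 0:
        raise ParameterError("r_h, temperature and viscosity must be > 0")
    out = BOLTZMANN * temperature / (6.0 * np.pi * viscosity * r * 1e-9)
    return float(out) if out.ndim == 0 else out


def diffused_fraction(D, cal: ChannelCalibration):
    """Forward map: diffusivity (m^2 s^-1) -> diffused fraction in (0, 0.5)."""
    D = np.asarray(D, dtype=float)
    if np.any(D <= 0):
        raise ParameterError("D must be > 0")
    tau = cal.kappa * D
    k = np.arange(1, cal.n_terms + 1, 2, dtype=float)
    terms = np.exp(-np.multiply.outer(tau, k**2) * np.pi**2 / 4.0) / k**2
    out = 0.5 - (4.0 / np.pi**2) * terms.sum(axis=-1)
    out = np.maximum(out, 0.0)
    return float(out) if out.ndim == 0 else out


def fraction_for_radius(r_h_nm, cal: ChannelCalibration):
    """Convenience composition: R_h (nm) -> diffused fraction."""
    return diffused_fraction(
        stokes_einstein_D(r_h_nm, cal.temperature, cal.viscosity), cal
    )


def calibrate_channel(
    anchors: Sequence[tuple],
    temperature: float = 298.15,
    viscosity: float = 8.9e-4,
    size_range_id: int = 3,
    **kwargs,
) -> ChannelCalibration:
    """Solve for the channel constant from (R_h nm, diffused fraction) anchors.

    A single anchor is solved exactly by bracketed root finding; several
    anchors are reconciled in least squares over log10(kappa).
    """
    anchors = [(float(r), float(f)) for r, f in anchors]
    if not anchors:
        raise CalibrationError("at least one anchor required")
    for r, f in anchors:
        if not (0.0 < f < 0.5):
            raise CalibrationError(f"anchor fraction {f} outside (0, 0.5)")
        if r <= 0:
            raise CalibrationError("anchor radius must be > 0")

    def cal_for(kappa):
        return ChannelCalibration(
            kappa=kappa,
            size_range_id=size_range_id,
            temperature=temperature,
            viscosity=viscosity,
            **kwargs,
        )

    if len(anchors) == 1:
        r, f = anchors[0]
        D = stokes_einstein_D(r, temperature, viscosity)
        kappa = brentq(
            lambda k: diffused_fraction(D, cal_for(k)) - f, 1e3, 1e14, xtol=1e-3
        )
        return cal_for(kappa)

    def resid(logk):
        c = cal_for(10.0 ** logk[0])
        return np.array([fraction_for_radius(r, c) - f for r, f in anchors])

    res = least_squares(resid, x0=[9.0], bounds=([3.0], [14.0]))
    if not res.success:
        raise CalibrationError("calibration did not converge")
    return cal_for(10.0 ** res.x[0])


# The free chaperone monomer anchor: R_h ~ 3 nm at diffused fraction 0.42.
_ANCHOR = (3.0, 0.42)
# Per-size-range scale factors on the anchored channel constant; larger
# ranges allow more diffusion time and are sensitive to larger particles.
# Together ranges 2-4 span roughly the 2-17 nm band.
_RANGE_SCALE = {2: 0.5, 3: 1.0, 4: 2.0}


@lru_cache(maxsize=None)
def default_calibration(size_range_id: int = 3) -> ChannelCalibration:
    """Shipped calibration: range 3 anchored at (3 nm, 0.42); ranges 2/4
    scaled from it."""
    if size_range_id not in _RANGE_SCALE:
        raise CalibrationError(f"unsupported size range {size_range_id} (2-4 supported)")
    base = calibrate_channel([_ANCHOR], size_range_id=3)
    if size_range_id == 3:
        return base
    return ChannelCalibration(
        kappa=base.kappa * _RANGE_SCALE[size_range_id], size_range_id=size_range_id
    )


def mixture_fraction(mix: SpeciesMixture, cal: ChannelCalibration) -> float:
    """Intensity-weighted diffused fraction of a labelled mixture."""
    return float(
        sum(w * fraction_for_radius(r, cal) for r, w in mix.components)
    )


def invert_fraction(f: float, cal: ChannelCalibration, tol_nm: float = 1e-4) -> float:
    """Invert the forward map: diffused fraction -> apparent R_h (nm).

    Bisection on the strictly monotone forward map over
    [cal.r_min, cal.r_max].  Fractions outside the invertible range
    raise :class:`OutOfRangeError` (the instrument's "size
    determination was not possible" condition).
    """
    f = float(f)
    f_hi = fraction_for_radius(cal.r_min, cal)  # small R -> large f
    f_lo = fraction_for_radius(cal.r_max, cal)
    if not (f_lo <= f <= f_hi):
        raise OutOfRangeError(
            f"fraction {f:.4f} outside invertible range "
            f"[{f_lo:.4f}, {f_hi:.4f}] for R in [{cal.r_min}, {cal.r_max}] nm"
        )
    return float(
        brentq(
            lambda r: fraction_for_radius(r, cal) - f,
            cal.r_min,
            cal.r_max,
            xtol=tol_nm,
        )
    )
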
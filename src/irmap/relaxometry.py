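"""Closed-form inversion-recovery Look-Locker (IR-LL) relaxation physics.

Under continuous low-angle excitation (flip angle ``alpha``, repetition time
``TR``) an inversion-prepared spin system relaxes with a shortened effective
time constant ``T1*`` toward a reduced steady state ``M0*``:

    1/T1*  = 1/T1 - ln(cos alpha)/TR
    M0*    = M0 * T1*/T1                      (valid for TR < T1*)
    M(t)   = M0* - (M0 + M0*) exp(-t/T1*)

and the true ``T1`` can be recovered flip-angle independently from the three
fitted parameters:

    T1 = T1* * [(M0 + M0*)/M0* - 1] = T1* * M0/M0*

All times are in milliseconds and all angles in degrees at the API boundary.
Every function broadcasts over numpy arrays.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "SequenceParams",
    "RelaxationParams",
    "effective_t1",
    "steady_state_magnetization",
    "irll_signal",
    "true_t1_from_fit",
    "recovered_fraction",
]


@dataclass(frozen=True)
class SequenceParams:
    """Spoiled gradient-echo Look-Locker sequence timing parameters.

    Parameters
    ----------
    tr : float
        Repetition time between consecutive excitations (ms).
    te : float
        Echo time (ms).  Also the inversion time of the first readout.
    alpha_nominal : float
        Nominal excitation flip angle (degrees), in (0, 90).
    n_projections : int
        Number of radial projections acquired per inversion.
    n_readout : int
        Complex samples per projection (also the Cartesian grid side).
    inversion_delay : float
        Recovery gap between repeated inversions in segmented mode (ms).
    """

    tr: float = 6.0
    te: float = 2.5
    alpha_nominal: float = 7.0
    n_projections: int = 1000
    n_readout: int = 128
    inversion_delay: float = 15000.0

    def __post_init__(self) -> None:
        if self.tr <= 0:
            raise ValueError(f"tr must be positive, got {self.tr}")
        if self.te < 0:
            raise ValueError(f"te must be non-negative, got {self.te}")
        if not 0 < self.alpha_nominal < 90:
            raise ValueError(
                f"alpha_nominal must lie in (0, 90) degrees, got {self.alpha_nominal}"
            )
        if self.n_projections < 1:
            raise ValueError("n_projections must be >= 1")
        if self.n_readout < 2:
            raise ValueError("n_readout must be >= 2")
        if self.inversion_delay < 0:
            raise ValueError("inversion_delay must be >= 0")


@dataclass(frozen=True)
class RelaxationParams:
    """A consistent set of per-pixel relaxation parameters.

    ``t1_star <= t1`` and ``m0_star <= m0`` are enforced on construction.
    """

    t1: float
    t1_star: float
    m0: float
    m0_star: float
    alpha: float

    def __post_init__(self) -> None:
        if self.t1 <= 0:
            raise ValueError("t1 must be positive")
        if not 0 < self.t1_star <= self.t1 * (1 + 1e-12):
            raise ValueError("t1_star must lie in (0, t1]")
        if self.m0 <= 0:
            raise ValueError("m0 must be positive")
        if not 0 < self.m0_star <= self.m0 * (1 + 1e-12):
            raise ValueError("m0_star must lie in (0, m0]")


def effective_t1(t1, tr, alpha):
    """Effective Look-Locker relaxation time ``T1*`` (ms).

    ``T1* = [1/T1 - ln(cos alpha)/TR]^-1``; always ``<= T1``.

    Raises
    ------
    ValueError
        If ``t1`` or ``tr`` is non-positive, or ``alpha`` is outside
        [0, 90) degrees (where ``cos alpha`` would be non-positive).
    """
    t1 = np.asarray(t1, dtype=float)
    tr = np.asarray(tr, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    if np.any(t1 <= 0):
        raise ValueError("t1 must be positive")
    if np.any(tr <= 0):
        raise ValueError("tr must be positive")
    if np.any(alpha < 0) or np.any(alpha >= 90):
        raise ValueError("alpha must lie in [0, 90) degrees")
    cos_a = np.cos(np.deg2rad(alpha))
    out = 1.0 / (1.0 / t1 - np.log(cos_a) / tr)
    if out.ndim == 0:
        return float(out)
    return out


def steady_state_magnetization(m0, t1_star, t1, tr=None):
    """Steady-state magnetization ``M0* = M0 * T1*/T1`` (same units as M0).

    The relation assumes ``TR < T1*``; when ``tr`` is supplied and violates
    this, a ``RuntimeWarning`` is emitted (the value is still returned, since
    iterative fitting may transiently visit such parameter combinations).
    """
    m0 = np.asarray(m0, dtype=float)
    t1_star = np.asarray(t1_star, dtype=float)
    t1 = np.asarray(t1, dtype=float)
    if np.any(m0 <= 0):
        raise ValueError("m0 must be positive")
    if np.any(t1_star <= 0) or np.any(t1 <= 0):
        raise ValueError("t1_star and t1 must be positive")
    if np.any(t1_star > t1 * (1 + 1e-12)):
        raise ValueError("t1_star must not exceed t1")
    if tr is not None and np.any(np.asarray(tr, dtype=float) >= t1_star):
        warnings.warn(
            "steady_state_magnetization: TR >= T1*, relation outside its "
            "validity range",
            RuntimeWarning,
            stacklevel=2,
        )
    out = m0 * t1_star / t1
    if out.ndim == 0:
        return float(out)
    return out


def irll_signal(t, m0, m0_star, t1_star):
    """IR-LL longitudinal magnetization ``M(t) = M0* - (M0+M0*) exp(-t/T1*)``.

    Vectorizes over ``t`` (and over the parameters by broadcasting).  Starts
    at ``-M0`` (perfect inversion) and approaches ``M0*`` monotonically.
    """
    t = np.asarray(t, dtype=float)
    t1_star = np.asarray(t1_star, dtype=float)
    if np.any(t1_star <= 0):
        raise ValueError("t1_star must be positive")
    if np.any(t < 0):
        raise ValueError("t must be non-negative")
    m0 = np.asarray(m0, dtype=float)
    m0_star = np.asarray(m0_star, dtype=float)
    out = m0_star - (m0 + m0_star) * np.exp(-t / t1_star)
    if out.ndim == 0:
        return float(out)
    return out


def true_t1_from_fit(t1_star, m0_star, m0):
    """Flip-angle-independent ``T1 = T1* * [(M0+M0*)/M0* - 1] = T1* M0/M0*``.

    Where ``m0_star <= 0`` the result is undefined and NaN is returned so the
    caller can flag the pixel invalid.
    """
    t1_star = np.asarray(t1_star, dtype=float)
    m0_star = np.asarray(m0_star, dtype=float)
    m0 = np.asarray(m0, dtype=float)
    if np.any(t1_star <= 0):
        raise ValueError("t1_star must be positive")
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(m0_star > 0, t1_star * m0 / np.where(m0_star > 0, m0_star, 1.0), np.nan)
    if out.ndim == 0:
        return float(out)
    return out


def recovered_fraction(t1, delay):
    """Fraction of the inversion deficit recovered after a free-relaxation gap.

    For pure mono-exponential recovery with no excitation this is
    ``(M(delay) - M(0)) / (M0 - M(0)) = 1 - exp(-delay/T1)``, in [0, 1].
    """
    t1 = np.asarray(t1, dtype=float)
    delay = np.asarray(delay, dtype=float)
    if np.any(t1 <= 0):
        raise ValueError("t1 must be positive")
    if np.any(delay < 0):
        raise ValueError("delay must be non-negative")
    out = 1.0 - np.exp(-delay / t1)
    if out.ndim == 0:
        return float(out)
    return out
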
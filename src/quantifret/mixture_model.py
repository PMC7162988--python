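"""Apparent E/S of a 1:1 FRET construct contaminated by free fluorophores.

A pixel is an ensemble: if a construct of intrinsic FRET E0 and
stoichiometry S0 is mixed with free donor at ratio r = n_free_D / n_0_D,
both observables shift:

    E_app = 1 / (1 + (1 - E0 + r) / E0) = E0 / (1 + r)
    S_app = (1 + r) / (1/S0 + r)

Eliminating r gives the mixing trajectory in the E-S histogram,

    S_app = (E0 / E_app) / (1/S0 + E0/E_app - 1),

which can be fitted to an experimental E-S cloud to recover the intrinsic
E0.  Free acceptor instead leaves E untouched and only dilutes S:
from the count definition S = n_D/(n_D + n_A), adding r free acceptors per
construct copy gives S_app = S0 / (1 + r * S0).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "MixtureSpec",
    "apparent_es_free_donor",
    "apparent_es_free_acceptor",
    "mixing_trajectory",
    "fit_intrinsic_e0",
    "E0Fit",
]


@dataclass(frozen=True)
class MixtureSpec:
    """A construct population plus free-fluorophore contamination ratios."""

    E0: float
    S0: float = 0.5
    r_free_donor: float = 0.0
    r_free_acceptor: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.E0 <= 1.0:
            raise ValueError("E0 must lie in [0, 1]")
        if not 0.0 < self.S0 < 1.0:
            raise ValueError("S0 must lie strictly between 0 and 1")
        # the contamination ratios may be scalars or arrays (trajectories)
        if np.any(np.asarray(self.r_free_donor) < 0) or \
                np.any(np.asarray(self.r_free_acceptor) < 0):
            raise ValueError("contamination ratios must be non-negative")


def apparent_es_free_donor(spec: MixtureSpec):
    """Apparent (E, S) when free donor is mixed with the construct.

    Free donor both dilutes the FRET signal (E_app < E0) and raises the
    donor fraction (S_app > S0).  Accepts array-valued ``r_free_donor``
    through numpy broadcasting if the spec carries an array.
    """
    r = np.asarray(spec.r_free_donor, dtype=float)
    if spec.E0 == 0:
        e_app = np.zeros_like(r)
    else:
        e_app = 1.0 / (1.0 + (1.0 - spec.E0 + r) / spec.E0)
    s_app = (1.0 + r) / (1.0 / spec.S0 + r)
    if np.ndim(spec.r_free_donor) == 0:
        return float(e_app), float(s_app)
    return e_app, s_app


def apparent_es_free_acceptor(spec: MixtureSpec):
    """Apparent (E, S) when free acceptor is mixed with the construct.

    Once calibrated (direct excitation removed), free acceptor emits no
    sensitized signal: E_app = E0 exactly, while the donor fraction drops,
    S_app = S0 / (1 + r * S0) with r free acceptors per construct copy.
    """
    r = np.asarray(spec.r_free_acceptor, dtype=float)
    s_app = spec.S0 / (1.0 + r * spec.S0)
    e_app = np.full_like(r, spec.E0)
    if np.ndim(spec.r_free_acceptor) == 0:
        return float(e_app), float(s_app)
    return e_app, s_app


def mixing_trajectory(e0: float, s0: float, e_app):
    """S_app on the free-donor mixing trajectory at a given apparent E.

    Requires 0 < E_app <= E0 (free donor can only lower the apparent
    FRET).  Consistent with eliminating the contamination ratio between
    the two free-donor expressions.
    """
    if not 0.0 < s0 < 1.0:
        raise ValueError("S0 must lie strictly between 0 and 1")
    e_app_arr = np.asarray(e_app, dtype=float)
    if np.any(e_app_arr <= 0):
        raise ValueError("E_app must be strictly positive")
    ratio = e0 / e_app_arr
    s_app = ratio / (1.0 / s0 + ratio - 1.0)
    if np.ndim(e_app) == 0:
        return float(s_app)
    return s_app


@dataclass
class E0Fit:
    """Result of fitting the mixing trajectory to (E_app, S_app) samples."""

    E0: float
    residual_norm: float
    rms_residual: float
    n_points: int
    poor_fit: bool


def fit_intrinsic_e0(
    e_app: np.ndarray,
    s_app: np.ndarray,
    s0: float = 0.5,
    rms_threshold: float = 0.05,
) -> E0Fit:
    """Recover the intrinsic E0 from a free-donor-contaminated E-S cloud.

    Least-squares fit of the mixing trajectory in the single parameter E0,
    with vertical (S) residuals.  Points with non-positive E_app are
    excluded.  ``poor_fit`` flags an RMS residual above ``rms_threshold``
    (e.g. a horizontal free-acceptor series, which the free-donor model
    cannot describe).
    """
    e = np.ravel(np.asarray(e_app, dtype=float))
    s = np.ravel(np.asarray(s_app, dtype=float))
    ok = np.isfinite(e) & np.isfinite(s) & (e > 0)
    e, s = e[ok], s[ok]
    if e.size < 10:
        raise ValueError("need at least 10 usable (E_app, S_app) pairs")
    if np.ptp(e) < 1e-12:
        raise ValueError("degenerate input: all points share one E_app")

    def resid(p):
        return mixing_trajectory(p[0], s0, e) - s

    x0 = min(max(float(e.max()), 1e-3), 1.0)
    sol = least_squares(resid, x0=[x0], bounds=([1e-6], [1.0]))
    r = resid(sol.x)
    rms = float(np.sqrt(np.mean(r * r)))
    return E0Fit(
        E0=float(sol.x[0]),
        residual_norm=float(np.linalg.norm(r)),
        rms_residual=rms,
        n_points=int(e.size),
        poor_fit=rms > rms_threshold,
    )
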
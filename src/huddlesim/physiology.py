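"""Closed-form developmental thermal physiology of the mouse pup.

The model reduces the first ~60 postnatal days of mouse thermal physiology
to a chain of elementary expressions driven by the exponential depletion of
brown adipose fat tissue (BAT):

* ``P(t) = exp(-t/k)`` — the BAT reserve, as a fraction of its birth value;
* ``S(t) = -k P ln P`` — the entropy associated with consuming that
  reserve, which simplifies to ``t exp(-t/k)`` and peaks at ``t = k``;
* ``G(t) = k (1 + S)`` — the mass-specific metabolic rate, with the unit
  term playing the role of basal metabolism;
* ``M(t) = k (1 - P)`` — muscle mass, growing as ``dM/dt = k - M``;
* ``N(t) = c exp(-k T1)`` — non-muscle mass, satisfying ``dN/dM = c1 N``;
* ``T1 = c1 P`` and ``T2 = c2 G N`` — the warm and cool deviations that
  compete to set the preferred ambient temperature ``Tp + T1`` (BAT-driven,
  dominant early) versus ``Tp - T2`` (dominant after roughly day 16).

The huddling drive fed to the Monte Carlo layer is ``beta (T1 - T2)``:
positive in the ectothermic neonate (warmth-seeking, group-joining) and
negative in the endothermic adult.

All functions accept a scalar or array of postnatal days ``t >= 0`` (time
is continuous; daily simulations simply sample integer days) and broadcast
like NumPy ufuncs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .constants import DEFAULT_CONSTANTS, CalibrationConstants

__all__ = [
    "bat_fraction",
    "bat_entropy",
    "metabolic_rate",
    "muscle_mass",
    "nonmuscle_mass",
    "body_mass",
    "warm_deviation",
    "cool_deviation",
    "selected_temperature",
    "huddling_drive",
    "PhysiologySnapshot",
    "snapshot",
    "development_table",
]


def _as_days(t) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("postnatal day t must be >= 0")
    return t


def _maybe_scalar(x: np.ndarray, like) -> float | np.ndarray:
    if np.isscalar(like) or np.ndim(like) == 0:
        return float(x)
    return x


def bat_fraction(t, consts: CalibrationConstants = DEFAULT_CONSTANTS):
    """BAT reserve P = exp(-t/k), a fraction of the birth value in (0, 1]."""
    td = _as_days(t)
    return _maybe_scalar(np.exp(-td / consts.k), t)


def bat_entropy(t, consts: CalibrationConstants = DEFAULT_CONSTANTS):
    """Entropy of BAT consumption, S = -k P ln P (equivalently t exp(-t/k)).

    Zero at birth, maximal at ``t = k``, decaying back towards zero as the
    reserve empties.
    """
    td = _as_days(t)
    P = np.exp(-td / consts.k)
    with np.errstate(divide="ignore", invalid="ignore"):
        S = np.where(P > 0.0, -consts.k * P * np.log(P), 0.0)
    return _maybe_scalar(S, t)


def metabolic_rate(t, consts: CalibrationConstants = DEFAULT_CONSTANTS):
    """Mass-specific metabolic rate G = k (1 + S), cal g^-1 h^-1.

    Equals the basal rate ``k`` at birth and in the adult limit; peaks at
    postnatal day ``t = k``.
    """
    td = _as_days(t)
    P = np.exp(-td / consts.k)
    with np.errstate(divide="ignore", invalid="ignore"):
        S = np.where(P > 0.0, -consts.k * P * np.log(P), 0.0)
    return _maybe_scalar(consts.k * (1.0 + S), t)


def muscle_mass(t, consts: CalibrationConstants = DEFAULT_CONSTANTS):
    """Muscle mass M = k (1 - P), grams; grows as dM/dt = k - M."""
    td = _as_days(t)
    return _maybe_scalar(consts.k * (1.0 - np.exp(-td / consts.k)), t)


def warm_deviation(t, consts: CalibrationConstants = DEFAULT_CONSTANTS):
    """Warm preferred-temperature deviation T1 = c1 P, degrees C."""
    td = _as_days(t)
    return _maybe_scalar(consts.c1 * np.exp(-td / consts.k), t)


def nonmuscle_mass(t, consts: CalibrationConstants = DEFAULT_CONSTANTS):
    """Non-muscle mass N = c exp(-k T1), grams; satisfies dN/dM = c1 N.

    Vanishingly small at birth (a known artifact of the exponent ``k T1``
    taken literally) and saturating at ``c`` in the adult.
    """
    td = _as_days(t)
    T1 = consts.c1 * np.exp(-td / consts.k)
    return _maybe_scalar(consts.c * np.exp(-consts.k * T1), t)


def body_mass(t, consts: CalibrationConstants = DEFAULT_CONSTANTS):
    """Total body mass W = M + N, grams; asymptote k + c.

    Computed as the sum of :func:`muscle_mass` and :func:`nonmuscle_mass`
    so the decomposition W = M + N holds to the last bit.
    """
    td = _as_days(t)
    W = np.asarray(muscle_mass(td, consts)) + np.asarray(nonmuscle_mass(td, consts))
    return _maybe_scalar(W, t)


def cool_deviation(t, consts: CalibrationConstants = DEFAULT_CONSTANTS):
    """Cool preferred-temperature deviation T2 = c2 G N, degrees C.

    Essentially zero at birth, rising to about ``c2 k c`` in the adult.
    """
    td = _as_days(t)
    G = np.asarray(metabolic_rate(td, consts))
    N = np.asarray(nonmuscle_mass(td, consts))
    return _maybe_scalar(consts.c2 * G * N, t)


def selected_temperature(t, consts: CalibrationConstants = DEFAULT_CONSTANTS):
    """Preferred ambient temperature on a thermocline, degrees C.

    The animal selects either ``Tp + T1`` (BAT-dominated, early) or
    ``Tp - T2`` (non-muscle-metabolism-dominated, late).  The competition is
    resolved by the dominant deviation: whichever of T1, T2 is larger wins.
    Values run from about 39 C at birth down to about 32 C at day 60.
    """
    td = _as_days(t)
    T1 = np.asarray(warm_deviation(td, consts))
    T2 = np.asarray(cool_deviation(td, consts))
    sel = np.where(T1 >= T2, consts.Tp + T1, consts.Tp - T2)
    return _maybe_scalar(sel, t)


def huddling_drive(t, consts: CalibrationConstants = DEFAULT_CONSTANTS):
    """Thermal huddling drive beta (T1 - T2), dimensionless.

    Positive at birth (0.6 with defaults), crossing zero once between days
    16 and 17 and settling near -0.81 by day 60.  This is the temperature
    parameter of the Monte Carlo layer in the non-learning control, and the
    factor that associative strengths weight in the learning condition.
    """
    td = _as_days(t)
    T1 = np.asarray(warm_deviation(td, consts))
    T2 = np.asarray(cool_deviation(td, consts))
    return _maybe_scalar(consts.beta * (T1 - T2), t)


@dataclass(frozen=True)
class PhysiologySnapshot:
    """All physiological quantities evaluated at one postnatal day."""

    t: float
    P: float
    S: float
    G: float
    M: float
    N: float
    W: float
    T1: float
    T2: float
    selected_temp: float
    drive: float


def snapshot(t: float, consts: CalibrationConstants = DEFAULT_CONSTANTS) -> PhysiologySnapshot:
    """Evaluate the full physiological state at postnatal day ``t``."""
    return PhysiologySnapshot(
        t=float(t),
        P=bat_fraction(t, consts),
        S=bat_entropy(t, consts),
        G=metabolic_rate(t, consts),
        M=muscle_mass(t, consts),
        N=nonmuscle_mass(t, consts),
        W=body_mass(t, consts),
        T1=warm_deviation(t, consts),
        T2=cool_deviation(t, consts),
        selected_temp=selected_temperature(t, consts),
        drive=huddling_drive(t, consts),
    )


def development_table(
    days: float = 60.0,
    step: float = 1.0,
    consts: CalibrationConstants = DEFAULT_CONSTANTS,
) -> pd.DataFrame:
    """Tabulate all curves on a regular grid over ``[0, days]``.

    Returns a DataFrame with columns
    ``day, P, S, G, M, N, W, T1, T2, selected_temp, drive``.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    t = np.arange(0.0, days + 0.5 * step, step)
    t = t[t <= days + 1e-12]
    return pd.DataFrame(
        {
            "day": t,
            "P": bat_fraction(t, consts),
            "S": bat_entropy(t, consts),
            "G": metabolic_rate(t, consts),
            "M": muscle_mass(t, consts),
            "N": nonmuscle_mass(t, consts),
            "W": body_mass(t, consts),
            "T1": warm_deviation(t, consts),
            "T2": cool_deviation(t, consts),
            "selected_temp": selected_temperature(t, consts),
            "drive": huddling_drive(t, consts),
        }
    )
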
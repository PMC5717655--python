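"""Synthetic developmental datasets and recovery of the model constants.

The physiological constants (k, c, c1, c2, Tp) were originally calibrated
against historical measurements of BAT weight, metabolic rate, body mass
and thermocline-selected temperature in developing mice — measurements
that exist only as scattered daily observations.  This module makes that
calibration pipeline testable end-to-end:

* :func:`generate` produces a synthetic dataset with the same structure
  (one or more observations per postnatal day of BAT percentage,
  metabolic rate, body mass and selected temperature, with additive
  Gaussian noise);
* :class:`OntogenyModel` refits the constants to such a dataset by staged
  nonlinear least squares, statsmodels-style: build the model from a
  DataFrame, call :meth:`~OntogenyModel.fit`, read estimates and
  residual diagnostics off the returned :class:`OntogenyResults`.

The fit is staged to mirror the causal structure of the model and avoid
identifiability tangles: (1) the BAT decay time constant ``k`` from the
BAT column alone; (2) the mass constants ``c, c1`` from body mass given
``k``; (3) the temperature constants ``c2`` (and optionally ``Tp``) from
the selected temperatures given everything else.  Selected-temperature
observations may lie on either the warm branch ``Tp + T1`` or the cool
branch ``Tp - T2``; each observation is scored against its nearest
branch.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import optimize

from .constants import DEFAULT_CONSTANTS, CalibrationConstants
from . import physiology

__all__ = [
    "normalize_bat",
    "SyntheticDataset",
    "generate",
    "OntogenyModel",
    "OntogenyResults",
    "fit_constants",
]

#: Columns of a developmental dataset.
COLUMNS = ("day", "bat_percent", "metabolic_rate", "body_mass", "selected_temp")

#: Synthetic BAT anchors, percent of body weight: first-measurement (birth)
#: and final-measurement values bracketing the decay, in the few-percent
#: range typical of neonatal rodent interscapular BAT.
DEFAULT_BAT_ANCHORS = (4.0, 0.8)  # (p1 at birth, p0 in the adult)


def normalize_bat(p, p0: float, p1: float):
    """Rescale raw BAT percentages to a 0-1 decay curve.

    ``p' = (p - p0) / (p1 - p0)`` maps the first measurement ``p1`` to 1
    and the final measurement ``p0`` to 0.
    """
    if p1 == p0:
        raise ValueError("degenerate anchors: p1 must differ from p0")
    return (np.asarray(p, dtype=float) - p0) / (p1 - p0)


@dataclass(frozen=True)
class SyntheticDataset:
    """A generated developmental dataset plus its provenance.

    ``frame`` holds the observations; the generating constants, noise
    level, anchors and seed are recorded so parameter recovery can be
    scored against ground truth.
    """

    frame: pd.DataFrame
    constants: CalibrationConstants
    noise: Mapping[str, float]
    anchors: tuple[float, float]
    seed: int | None

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)


def _noise_map(noise, ranges: Mapping[str, float]) -> dict[str, float]:
    """Resolve a noise spec to absolute per-column standard deviations.

    A scalar is interpreted as a fraction of each column's noiseless range
    (so 0.05 means 5%-of-range noise on every variable); a mapping gives
    absolute standard deviations per column.
    """
    cols = [c for c in COLUMNS if c != "day"]
    if noise is None:
        return {c: 0.0 for c in cols}
    if isinstance(noise, Mapping):
        bad = set(noise) - set(cols)
        if bad:
            raise ValueError(f"unknown noise columns: {sorted(bad)}")
        return {c: float(noise.get(c, 0.0)) for c in cols}
    frac = float(noise)
    if frac < 0:
        raise ValueError("noise must be non-negative")
    return {c: frac * ranges[c] for c in cols}


def generate(
    consts: CalibrationConstants = DEFAULT_CONSTANTS,
    days=None,
    noise=0.05,
    seed: int | None = None,
    anchors: tuple[float, float] = DEFAULT_BAT_ANCHORS,
) -> SyntheticDataset:
    """Generate a synthetic developmental dataset.

    Parameters
    ----------
    consts
        Generating constants (ground truth for recovery).
    days
        Sample days in [0, 60]; default one observation per day, days
        1-60, mimicking daily measurement.
    noise
        Scalar fraction-of-range, or mapping of column to absolute sd.
        Zero reproduces the model curves exactly.
    seed
        Seed for the noise generator; same seed, same dataset.
    anchors
        (birth, adult) BAT percentages: the model's normalized decay is
        mapped onto this raw scale before noise is added.
    """
    if days is None:
        days = np.arange(1, 61, dtype=float)
    days = np.asarray(days, dtype=float)
    if np.any((days < 0) | (days > 60)):
        raise ValueError("sample days must lie within [0, 60]")
    p1, p0 = anchors
    if p1 == p0:
        raise ValueError("degenerate anchors: birth and adult BAT must differ")

    clean = pd.DataFrame(
        {
            "day": days,
            "bat_percent": p0 + (p1 - p0) * physiology.bat_fraction(days, consts),
            "metabolic_rate": physiology.metabolic_rate(days, consts),
            "body_mass": physiology.body_mass(days, consts),
            "selected_temp": physiology.selected_temperature(days, consts),
        }
    )
    # noiseless dynamic range of each variable over the sampled days
    ranges = {
        c: float(clean[c].max() - clean[c].min()) for c in COLUMNS if c != "day"
    }
    sds = _noise_map(noise, ranges)
    rng = np.random.default_rng(seed)
    frame = clean.copy()
    for col, sd in sds.items():
        if sd > 0:
            frame[col] = frame[col] + rng.normal(0.0, sd, size=len(frame))
    return SyntheticDataset(
        frame=frame, constants=consts, noise=sds, anchors=anchors, seed=seed
    )


# ---------------------------------------------------------------------
# Staged least-squares fit
# ---------------------------------------------------------------------

@dataclass(frozen=True)
class StageFit:
    """One stage of the staged fit: estimates and residual diagnostics."""

    name: str
    params: dict[str, float]
    rms_residual: float
    n_obs: int


class OntogenyResults:
    """Estimates from :meth:`OntogenyModel.fit`.

    Attributes
    ----------
    params : dict
        Point estimates of ``k, c, c1, c2, Tp``.
    stages : list of StageFit
        Per-stage estimates and RMS residuals (bat, mass, temperature).
    """

    def __init__(self, model: "OntogenyModel", stages: list[StageFit]):
        self.model = model
        self.stages = stages
        self.params: dict[str, float] = {}
        for st in stages:
            self.params.update(st.params)

    @property
    def constants(self) -> CalibrationConstants:
        """The estimates packaged as a usable constants object."""
        return DEFAULT_CONSTANTS.with_(
            **{k: v for k, v in self.params.items() if k in ("k", "c", "c1", "c2", "Tp")}
        )

    def recovery_error(self, truth: CalibrationConstants) -> dict[str, float]:
        """Relative error of each estimate against known generating values."""
        out = {}
        for name, est in self.params.items():
            true = getattr(truth, name)
            out[name] = abs(est - true) / abs(true) if true != 0 else abs(est)
        return out

    def summary(self) -> str:
        lines = [
            "Ontogeny constants: staged nonlinear least squares",
            "=" * 54,
            f"{'stage':<14}{'parameter':<12}{'estimate':>12}{'RMS resid':>14}",
            "-" * 54,
        ]
        for st in self.stages:
            first = True
            for name, val in st.params.items():
                stage_label = st.name if first else ""
                rms = f"{st.rms_residual:14.5g}" if first else " " * 14
                lines.append(f"{stage_label:<14}{name:<12}{val:>12.6g}{rms}")
                first = False
        lines.append("-" * 54)
        lines.append(
            f"observations per stage: "
            + ", ".join(f"{st.name}={st.n_obs}" for st in self.stages)
        )
        return "\n".join(lines)

    def __repr__(self) -> str:
        p = ", ".join(f"{k}={v:.4g}" for k, v in self.params.items())
        return f"<OntogenyResults {p}>"


class OntogenyModel:
    """Staged least-squares model for the developmental constants.

    Parameters
    ----------
    data
        DataFrame with columns ``day, bat_percent, body_mass,
        selected_temp`` (``metabolic_rate`` may be present; it is implied
        by the BAT fit and not separately fitted), or a
        :class:`SyntheticDataset`.
    fit_tp
        Fit the adult target temperature ``Tp`` (default) or pin it.
    tp_fixed
        Value used when ``fit_tp=False``.
    reference_k
        Prior guess for the decay constant, used only to check that the
        sampled days span early (< k) and late (> 3k) development.
    """

    def __init__(
        self,
        data,
        fit_tp: bool = True,
        tp_fixed: float = 36.0,
        reference_k: float = 8.31,
    ):
        if isinstance(data, SyntheticDataset):
            data = data.frame
        if not isinstance(data, pd.DataFrame):
            raise TypeError("data must be a DataFrame or SyntheticDataset")
        missing = {"day", "bat_percent", "body_mass", "selected_temp"} - set(data.columns)
        if missing:
            raise ValueError(f"dataset is missing columns: {sorted(missing)}")
        self.data = data.reset_index(drop=True)
        self.fit_tp = fit_tp
        self.tp_fixed = float(tp_fixed)
        self._check_coverage(reference_k)

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, **kwargs) -> "OntogenyModel":
        return cls(frame, **kwargs)

    def _check_coverage(self, ref_k: float) -> None:
        days = np.asarray(self.data["day"], dtype=float)
        distinct = np.unique(np.round(days, 6))
        problems = []
        if len(distinct) < 10:
            problems.append(f"only {len(distinct)} distinct days (need >= 10)")
        if not (days.min() < ref_k):
            problems.append(
                f"no early observations: min day {days.min():.3g} >= k~{ref_k:.3g}"
            )
        if not (days.max() > 3 * ref_k):
            problems.append(
                f"no late observations: max day {days.max():.3g} <= 3k~{3 * ref_k:.3g}"
            )
        if problems:
            raise ValueError(
                "dataset does not support a staged fit: " + "; ".join(problems)
            )

    # -- stages -------------------------------------------------------
    def _fit_bat(self) -> StageFit:
        """Stage 1: k from the exponential BAT decay.

        Fits ``p(t) = p0 + (p1 - p0) exp(-t/k)`` with free anchors, i.e.
        the normalized decay with the normalization itself estimated
        (robust to noise in the first/final measurements).
        """
        t = np.asarray(self.data["day"], float)
        p = np.asarray(self.data["bat_percent"], float)

        def model(t, p0, p1, k):
            return p0 + (p1 - p0) * np.exp(-t / k)

        k0 = max((t.max() - t.min()) / 5.0, 1.0)
        popt, _ = optimize.curve_fit(
            model, t, p, p0=(p.min(), p.max(), k0), maxfev=20000
        )
        resid = p - model(t, *popt)
        return StageFit(
            name="bat",
            params={"k": float(popt[2])},
            rms_residual=float(np.sqrt(np.mean(resid**2))),
            n_obs=len(t),
        )

    def _fit_mass(self, k: float) -> StageFit:
        """Stage 2: c, c1 from the body-mass curve given k."""
        t = np.asarray(self.data["day"], float)
        w = np.asarray(self.data["body_mass"], float)

        def model(t, c, c1):
            P = np.exp(-t / k)
            return k * (1.0 - P) + c * np.exp(-k * c1 * P)

        popt, _ = optimize.curve_fit(
            model, t, w, p0=(max(w.max() - k, 1.0), 1.0), maxfev=20000
        )
        resid = w - model(t, *popt)
        return StageFit(
            name="mass",
            params={"c": float(popt[0]), "c1": float(popt[1])},
            rms_residual=float(np.sqrt(np.mean(resid**2))),
            n_obs=len(t),
        )

    def _fit_temperature(self, k: float, c: float, c1: float) -> StageFit:
        """Stage 3: c2 (and Tp) from thermocline-selected temperatures.

        Each observation is matched to its nearest branch, warm
        ``Tp + T1`` or cool ``Tp - T2``, and the signed nearest-branch
        residual is minimized.
        """
        t = np.asarray(self.data["day"], float)
        y = np.asarray(self.data["selected_temp"], float)
        P = np.exp(-t / k)
        T1 = c1 * P
        S = np.where(P > 0, -k * P * np.log(P), 0.0)
        G = k * (1.0 + S)
        N = c * np.exp(-k * c1 * P)
        GN = G * N

        def residuals(theta):
            c2 = theta[0]
            Tp = theta[1] if self.fit_tp else self.tp_fixed
            warm = Tp + T1
            cool = Tp - c2 * GN
            r_warm = y - warm
            r_cool = y - cool
            return np.where(np.abs(r_warm) <= np.abs(r_cool), r_warm, r_cool)

        x0 = [0.01, float(np.mean(y))] if self.fit_tp else [0.01]
        sol = optimize.least_squares(residuals, x0, xtol=1e-14, ftol=1e-14, gtol=1e-14)
        params = {"c2": float(sol.x[0])}
        params["Tp"] = float(sol.x[1]) if self.fit_tp else self.tp_fixed
        resid = residuals(sol.x)
        return StageFit(
            name="temperature",
            params=params,
            rms_residual=float(np.sqrt(np.mean(resid**2))),
            n_obs=len(t),
        )

    def fit(self) -> OntogenyResults:
        """Run the three fitting stages and return the results object."""
        bat = self._fit_bat()
        k = bat.params["k"]
        mass = self._fit_mass(k)
        temp = self._fit_temperature(k, mass.params["c"], mass.params["c1"])
        return OntogenyResults(self, [bat, mass, temp])


def fit_constants(dataset, **kwargs) -> OntogenyResults:
    """Convenience wrapper: ``OntogenyModel(dataset, **kwargs).fit()``."""
    return OntogenyModel(dataset, **kwargs).fit()
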
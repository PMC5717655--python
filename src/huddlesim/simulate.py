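"""Developmental huddling simulations: control vs learning conditions.

A simulation follows one litter of ``n`` pups across postnatal days
(default 0-60).  The litter starts as a single huddle.  Each day the
thermal drive ``beta (T1 - T2)`` is evaluated from the physiology model
and ``iters_per_day`` Monte Carlo encounters are run; in the learning
condition every encounter additionally trains the initiator's associative
strength for its partner.  Partition and association state persist across
days, so late behaviour reflects the whole developmental history.

Replicates are independent litters with independently seeded random
streams; daily statistics (mean group size, mean join probability) are
averaged over encounters within a day and then across replicates.

The entry points are :class:`HuddleSimulation` (configure, ``run()``) and
the convenience function :func:`run_development`.  Cross-condition
analyses — the physiological-to-filial divergence day and the late
steady-state join probability — are module-level functions operating on
results or their CSV round-trips.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .constants import CalibrationConstants
from .learning import AssociationMatrix
from .physiology import huddling_drive

__all__ = [
    "SimulationConfig",
    "DailyStats",
    "DevelopmentResults",
    "HuddleSimulation",
    "run_development",
    "detect_divergence_day",
    "steady_state_rho",
    "compare_conditions",
]

CONDITIONS = ("control", "learning")


@dataclass(frozen=True)
class SimulationConfig:
    """Configuration of one developmental run.

    ``iters_per_day=1000`` over 61 days gives about 6.1e4 encounters per
    replicate litter.  ``alpha_init`` seeds the learning condition's
    association matrix (naive pups: 0); the control condition always pins
    associations at 1.
    """

    condition: str = "control"
    day_start: int = 0
    day_end: int = 60
    iters_per_day: int = 1000
    replicates: int = 10
    seed: int = 0
    estimator: str = "groups"
    symmetric_update: bool = False
    alpha_init: float = 0.0
    constants: CalibrationConstants = field(default_factory=CalibrationConstants)

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}")
        if self.day_end < self.day_start or self.day_start < 0:
            raise ValueError("need 0 <= day_start <= day_end")
        if self.iters_per_day < 1:
            raise ValueError("iters_per_day must be >= 1")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.estimator not in ("groups", "pup_weighted"):
            raise ValueError("estimator must be 'groups' or 'pup_weighted'")

    @property
    def days(self) -> np.ndarray:
        return np.arange(self.day_start, self.day_end + 1)

    def with_(self, **changes) -> "SimulationConfig":
        return replace(self, **changes)


@dataclass(frozen=True)
class DailyStats:
    """Per-day summary, averaged over encounters and replicates."""

    day: int
    condition: str
    mean_group_size: float
    sd: float  # across replicates
    mean_rho: float


class DevelopmentResults:
    """Results of a developmental run.

    Attributes
    ----------
    stats : pandas.DataFrame
        Columns ``day, condition, mean_group_size, sd, mean_rho``; one row
        per simulated day, averaged across replicates.
    group_size, rho : ndarray, shape (replicates, n_days)
        Per-replicate daily means, for uncertainty analyses.
    alpha_history : ndarray or None
        Shape (replicates, n_days, n, n): end-of-day association
        snapshots (learning condition only).
    """

    def __init__(
        self,
        config: SimulationConfig,
        group_size: np.ndarray,
        rho: np.ndarray,
        alpha_history: np.ndarray | None,
    ):
        self.config = config
        self.group_size = group_size
        self.rho = rho
        self.alpha_history = alpha_history
        days = config.days
        self.stats = pd.DataFrame(
            {
                "day": days,
                "condition": config.condition,
                "mean_group_size": group_size.mean(axis=0),
                "sd": group_size.std(axis=0, ddof=1) if config.replicates > 1
                else np.zeros(len(days)),
                "mean_rho": rho.mean(axis=0),
            }
        )

    @property
    def daily_stats(self) -> list[DailyStats]:
        return [
            DailyStats(
                day=int(row.day),
                condition=str(row.condition),
                mean_group_size=float(row.mean_group_size),
                sd=float(row.sd),
                mean_rho=float(row.mean_rho),
            )
            for row in self.stats.itertuples()
        ]

    def final_alpha(self, replicate: int = 0) -> AssociationMatrix | None:
        if self.alpha_history is None:
            return None
        return AssociationMatrix(self.alpha_history[replicate, -1].copy())

    def alpha_long(self, replicate: int = 0) -> pd.DataFrame | None:
        """Per-day association snapshots of one replicate, long format."""
        if self.alpha_history is None:
            return None
        frames = []
        for d_idx, day in enumerate(self.config.days):
            mat = AssociationMatrix(self.alpha_history[replicate, d_idx].copy())
            frames.append(mat.to_long(day=int(day)))
        return pd.concat(frames, ignore_index=True)

    def to_csv(self, path) -> None:
        self.stats.to_csv(path, index=False)

    def summary(self) -> str:
        cfg = self.config
        late = self.stats[self.stats.day >= cfg.day_end - 15]
        lines = [
            "Developmental huddling simulation",
            "=" * 48,
            f"condition        : {cfg.condition}",
            f"days             : {cfg.day_start}..{cfg.day_end}",
            f"iters/day        : {cfg.iters_per_day}"
            f"   replicates: {cfg.replicates}   seed: {cfg.seed}",
            f"litter size n    : {cfg.constants.n}",
            f"estimator        : {cfg.estimator}",
            "-" * 48,
            f"mean group size, first day : {self.stats.mean_group_size.iloc[0]:6.3f}",
            f"mean group size, last day  : {self.stats.mean_group_size.iloc[-1]:6.3f}",
            f"mean rho, last 15 days     : {late.mean_rho.mean():6.3f}",
        ]
        return "\n".join(lines)

    def __repr__(self) -> str:
        return (
            f"<DevelopmentResults condition={self.config.condition!r} "
            f"days={self.config.day_start}..{self.config.day_end} "
            f"replicates={self.config.replicates}>"
        )


class HuddleSimulation:
    """Monte Carlo simulation of one developmental condition.

    Examples
    --------
    >>> sim = HuddleSimulation(SimulationConfig(condition="learning", seed=1))
    >>> res = sim.run()
    >>> res.stats.head()  # doctest: +SKIP
    """

    def __init__(self, config: SimulationConfig | None = None, **kwargs):
        if config is None:
            config = SimulationConfig(**kwargs)
        elif kwargs:
            config = config.with_(**kwargs)
        self.config = config

    def run(self) -> DevelopmentResults:
        cfg = self.config
        consts = cfg.constants
        n = consts.n
        days = cfg.days
        learning = cfg.condition == "learning"

        gs = np.empty((cfg.replicates, len(days)))
        rho_mean = np.empty((cfg.replicates, len(days)))
        alpha_hist = (
            np.empty((cfg.replicates, len(days), n, n)) if learning else None
        )

        bases = {int(day): huddling_drive(float(day), consts) for day in days}
        streams = np.random.SeedSequence(cfg.seed).spawn(cfg.replicates)
        for rep, stream in enumerate(streams):
            rng = np.random.default_rng(stream)
            self._run_replicate(
                rng, bases, gs[rep], rho_mean[rep],
                alpha_hist[rep] if learning else None,
            )
        return DevelopmentResults(cfg, gs, rho_mean, alpha_hist)

    def _run_replicate(self, rng, bases, gs_out, rho_out, alpha_out) -> None:
        """Simulate one litter across all days.

        The inner loop is a hand-unrolled equivalent of
        :func:`huddlesim.mc.mc_step` plus
        :func:`huddlesim.learning.delta_update`: it consumes the
        generator's uniform stream identically (three draws per
        encounter), so trajectories are bit-for-bit reproducible against
        the reference step functions (asserted in the test suite).
        """
        cfg = self.config
        consts = cfg.constants
        n = consts.n
        gamma = consts.gamma
        learning = cfg.condition == "learning"
        symmetric = cfg.symmetric_update
        pup_weighted = cfg.estimator == "pup_weighted"
        iters = cfg.iters_per_day

        # litter starts as a single huddle
        labels = [0] * n
        next_label = 1
        sizes = {0: n}
        n_groups = 1
        sum_sq = n * n
        # association state as plain lists (fast element access);
        # diagonal entries stay 0 and are excluded from row sums
        init = cfg.alpha_init if learning else 1.0
        al = [[0.0 if i == j else init for j in range(n)] for i in range(n)]
        exp = math.exp

        for d_idx, (day, base) in enumerate(bases.items()):
            u = rng.random(3 * iters).tolist()
            ui = 0
            gs_acc = 0.0
            rho_acc = 0.0
            for _ in range(iters):
                a = int(u[ui] * n)
                if a == n:
                    a = n - 1
                la = labels[a]
                cand = [i for i in range(n) if labels[i] != la]
                if not cand:
                    cand = [i for i in range(n) if i != a]
                j = int(u[ui + 1] * len(cand))
                if j == len(cand):
                    j -= 1
                b = cand[j]
                T = al[b][a] * base
                if T >= 0.0:
                    rho = 1.0 / (1.0 + exp(-T))
                else:
                    eT = exp(T)
                    rho = eT / (1.0 + eT)
                joined = u[ui + 2] < rho
                ui += 3
                if joined:
                    lb = labels[b]
                    if lb != la:
                        sa, sb = sizes.pop(la), sizes.pop(lb)
                        labels = [la if l == lb else l for l in labels]
                        sizes[la] = sa + sb
                        n_groups -= 1
                        sum_sq += 2 * sa * sb
                else:
                    s = sizes[la]
                    if s > 1:
                        labels[a] = next_label
                        sizes[la] = s - 1
                        sizes[next_label] = 1
                        next_label += 1
                        n_groups += 1
                        sum_sq += 2 - 2 * s
                if learning:
                    r = 1.0 if joined else 0.0
                    al[a][b] += gamma * (r - sum(al[a]))
                    if symmetric:
                        al[b][a] += gamma * (r - sum(al[b]))
                gs_acc += sum_sq / n if pup_weighted else n / n_groups
                rho_acc += rho
            gs_out[d_idx] = gs_acc / iters
            rho_out[d_idx] = rho_acc / iters
            if alpha_out is not None:
                alpha_out[d_idx] = al


def run_development(config: SimulationConfig) -> DevelopmentResults:
    """Run one developmental condition; see :class:`HuddleSimulation`."""
    return HuddleSimulation(config).run()


def _as_stats(trace) -> pd.DataFrame:
    if isinstance(trace, DevelopmentResults):
        return trace.stats
    if isinstance(trace, pd.DataFrame):
        return trace
    raise TypeError("expected DevelopmentResults or a stats DataFrame")


def detect_divergence_day(
    control,
    learning,
    persistence: int = 5,
) -> int | None:
    """First day from which learning group sizes persistently beat control.

    Returns the smallest day ``d`` such that the learning condition's mean
    group size strictly exceeds the control's on every grid day in
    ``[d, d + persistence)`` (the window is truncated at the end of the
    grid).  Returns ``None`` if no such day exists.  This operationalizes
    the crossing of the two developmental traces that marks the
    physiological-to-filial transition.
    """
    c = _as_stats(control)
    l = _as_stats(learning)
    if persistence < 1:
        raise ValueError("persistence must be >= 1")
    c_days = np.asarray(c["day"])
    l_days = np.asarray(l["day"])
    if len(c_days) != len(l_days) or not np.array_equal(c_days, l_days):
        raise ValueError("control and learning traces must share the same day grid")
    excess = np.asarray(l["mean_group_size"]) > np.asarray(c["mean_group_size"])
    for i, day in enumerate(c_days):
        window = excess[i : i + persistence]
        # only windows anchored at i and lying on the grid count
        in_window = (c_days[i : i + persistence] < day + persistence)
        if window[in_window].all() and window.size > 0:
            return int(day)
    return None


def steady_state_rho(
    results,
    window: tuple[int, int] | None = None,
) -> float:
    """Mean per-encounter join probability over a late developmental window.

    Averages the recorded daily mean rho over all days in
    ``[window[0], window[1]]`` and all replicates; the default window is
    the final 15 days of the trace (days 45-60 for a full run).  Each day
    contributes the same number of encounters, so the day-average equals
    the per-encounter average.
    """
    stats = _as_stats(results)
    if window is None:
        last = int(stats["day"].max())
        window = (last - 15, last)
    lo, hi = window
    mask = (stats["day"] >= lo) & (stats["day"] <= hi)
    if not mask.any():
        raise ValueError(f"no simulated days fall in window [{lo}, {hi}]")
    if isinstance(results, DevelopmentResults):
        days = results.config.days
        dmask = (days >= lo) & (days <= hi)
        return float(results.rho[:, dmask].mean())
    return float(stats.loc[mask, "mean_rho"].mean())


def compare_conditions(
    control,
    learning,
    persistence: int = 5,
    window: tuple[int, int] | None = None,
) -> dict:
    """Headline comparison of the two conditions.

    Returns the divergence day, each condition's steady-state rho over the
    late window (default: the final 15 days), and each condition's
    late-phase mean group size.
    """
    c, l = _as_stats(control), _as_stats(learning)
    if window is None:
        last = int(c["day"].max())
        window = (max(last - 15, int(c["day"].min())), last)
    lo, hi = window
    late_c = c[(c.day >= lo) & (c.day <= hi)]
    late_l = l[(l.day >= lo) & (l.day <= hi)]
    return {
        "divergence_day": detect_divergence_day(control, learning, persistence),
        "persistence": persistence,
        "window": [lo, hi],
        "steady_state_rho": {
            "control": steady_state_rho(control, window),
            "learning": steady_state_rho(learning, window),
        },
        "late_mean_group_size": {
            "control": float(late_c.mean_group_size.mean()),
            "learning": float(late_l.mean_group_size.mean()),
        },
    }


def run_both_conditions(
    seed: int = 0,
    replicates: int = 10,
    **kwargs,
) -> tuple[DevelopmentResults, DevelopmentResults]:
    """Run control and learning with identical per-replicate seeding."""
    base = SimulationConfig(seed=seed, replicates=replicates, **kwargs)
    control = run_development(base.with_(condition="control"))
    learning = run_development(base.with_(condition="learning"))
    return control, learning


def plot_development(control, learning, ax=None):
    """Plot the two developmental group-size traces (needs matplotlib)."""
    import matplotlib.pyplot as plt

    c, l = _as_stats(control), _as_stats(learning)
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    ax.plot(c.day, c.mean_group_size, color="0.6", lw=1.5, label="control")
    ax.plot(l.day, l.mean_group_size, color="0.1", lw=2.5, label="learning")
    ax.set_xlabel("postnatal day")
    ax.set_ylabel("mean group size")
    ax.legend(frameon=False)
    return ax
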
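"""Odour-heat conditioning between littermates (Delta-rule learning).

Each pup ``a`` keeps a directed associative strength ``alpha[a, b]`` for
the odour of every littermate ``b``.  Every Monte Carlo encounter is a
conditioning trial: the initiator updates its association for the partner
towards the observed reward (r = 1 if the groups combined, 0 if it was
detached) using the Delta rule with a *compound* prediction — the sum of
all of the initiator's outgoing associations:

    delta alpha[a, b] = gamma * (r - sum_i!=a alpha[a, i])

The compound sum makes total outgoing association self-limiting: it
relaxes towards the long-run reward rate, so individual associations can
grow strongly positive or negative while their sum stays bounded.  No
clamping or decay is applied.

In the learning condition the drive that gates an encounter between
initiator ``a`` and partner ``b`` is the partner's association for the
initiator's odour times the thermal drive: ``alpha[b, a] * beta * (T1 - T2)``.
In the non-learning control all associations are pinned at 1, which
reduces the gated drive to the purely physiological one.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .constants import DEFAULT_CONSTANTS, CalibrationConstants
from .physiology import huddling_drive

__all__ = ["AssociationMatrix", "pairwise_drive", "delta_update"]


class AssociationMatrix:
    """Directed pairwise associative strengths among ``n`` littermates.

    ``alpha[a, b]`` is pup ``a``'s learnt association for the odour of pup
    ``b``.  The diagonal is unused and kept at zero.  Values are
    unbounded; negative associations are meaningful (learned avoidance).
    """

    __slots__ = ("alpha",)

    def __init__(self, alpha: np.ndarray):
        alpha = np.array(alpha, dtype=float)
        if alpha.ndim != 2 or alpha.shape[0] != alpha.shape[1]:
            raise ValueError("alpha must be a square matrix")
        np.fill_diagonal(alpha, 0.0)
        self.alpha = alpha

    @classmethod
    def zeros(cls, n: int) -> "AssociationMatrix":
        """Naive litter: no associations yet (learning-condition start)."""
        return cls(np.zeros((n, n)))

    @classmethod
    def ones(cls, n: int) -> "AssociationMatrix":
        """Control condition: every association fixed at 1."""
        return cls(np.ones((n, n)))

    @classmethod
    def full(cls, n: int, value: float) -> "AssociationMatrix":
        return cls(np.full((n, n), float(value)))

    @property
    def n(self) -> int:
        return self.alpha.shape[0]

    def outgoing_sum(self, a: int) -> float:
        """Compound prediction of pup ``a``: sum of its outgoing strengths.

        Summed left to right in pup order (the diagonal is held at 0), so
        the result is bit-identical to the simulation's inner loop.
        """
        return float(sum(self.alpha[a].tolist()))

    def copy(self) -> "AssociationMatrix":
        return AssociationMatrix(self.alpha.copy())

    def to_long(self, day: float | None = None) -> pd.DataFrame:
        """Long-format (day, a, b, alpha) table over ordered pairs a != b."""
        n = self.n
        a_idx, b_idx = np.where(~np.eye(n, dtype=bool))
        frame = pd.DataFrame(
            {"a": a_idx, "b": b_idx, "alpha": self.alpha[a_idx, b_idx]}
        )
        if day is not None:
            frame.insert(0, "day", day)
        return frame

    def __repr__(self) -> str:
        return f"AssociationMatrix(n={self.n}, mean={self.alpha.mean():.4f})"


def pairwise_drive(
    a: int,
    b: int,
    t: float,
    alpha: AssociationMatrix,
    consts: CalibrationConstants = DEFAULT_CONSTANTS,
) -> float:
    """Association-gated huddling drive for initiator ``a`` meeting ``b``.

    Returns ``alpha[b, a] * beta * (T1(t) - T2(t))``: the partner's
    association for the initiator's odour scales the thermal drive.  With
    ``alpha[b, a] = 1`` this is exactly the control-condition drive.
    """
    if a == b:
        raise ValueError("a pup does not encounter itself")
    return float(alpha.alpha[b, a]) * huddling_drive(t, consts)


def delta_update(
    alpha: AssociationMatrix,
    a: int,
    b: int,
    r: int,
    consts: CalibrationConstants = DEFAULT_CONSTANTS,
) -> float:
    """Delta-rule update of ``alpha[a, b]`` from reward ``r`` (in place).

    The prediction is the compound sum of all of ``a``'s outgoing
    associations, not just ``alpha[a, b]``.  Returns the applied change.
    """
    if a == b:
        raise ValueError("a pup does not condition on its own odour")
    if r not in (0, 1):
        raise ValueError(f"reward r must be 0 or 1, got {r!r}")
    change = consts.gamma * (r - alpha.outgoing_sum(a))
    alpha.alpha[a, b] += change
    return change
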
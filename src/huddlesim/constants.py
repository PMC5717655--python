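"""Calibration constants of the huddling-ontogeny model.

All model behaviour is governed by a single small parameter set describing
the developing thermal physiology of a mouse litter and the associative
learning layer.  The defaults are the published calibration for laboratory
mice and are used throughout the package unless overridden.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Any, Mapping


@dataclass(frozen=True)
class CalibrationConstants:
    """Parameter set for physiology, huddling and learning.

    Attributes
    ----------
    k : float
        Time constant of brown-adipose-tissue (BAT) depletion, in postnatal
        days.  The same number reappears as the basal mass-specific
        metabolic rate (cal g^-1 h^-1) and as the asymptotic muscle mass
        (g); the model deliberately uses one constant for all three roles.
    c : float
        Asymptotic non-muscle body mass, grams.
    c1 : float
        Warm-preference coefficient: degrees C of preferred-temperature
        elevation per unit BAT fraction.
    c2 : float
        Cool-preference coefficient: degrees C per unit of (metabolic rate
        x non-muscle mass).
    Tp : float
        Target adult body temperature, degrees C.
    beta : float
        Dimensionless scaling of the thermal huddling drive.
    gamma : float
        Delta-rule learning rate, dimensionless.
    n : int
        Litter size (number of pups).
    """

    k: float = 8.31
    c: float = 19.0
    c1: float = 3.0
    c2: float = 0.025
    Tp: float = 36.0
    beta: float = 0.2
    gamma: float = 0.001
    n: int = 7

    def __post_init__(self) -> None:
        if not self.k > 0:
            raise ValueError(f"k must be positive, got {self.k}")
        if self.c < 0 or self.c1 < 0 or self.c2 < 0:
            raise ValueError("c, c1 and c2 must be non-negative")
        if not self.beta > 0:
            raise ValueError(f"beta must be positive, got {self.beta}")
        if not 0 <= self.gamma < 1:
            # gamma = 0 is allowed: it disables learning, which is useful
            # for equivalence checks against the control condition
            raise ValueError(f"gamma must lie in [0, 1), got {self.gamma}")
        if int(self.n) != self.n or self.n < 2:
            raise ValueError(f"litter size n must be an integer >= 2, got {self.n}")

    def with_(self, **changes: Any) -> "CalibrationConstants":
        """Return a copy with the given fields replaced."""
        return replace(self, **changes)

    def as_dict(self) -> dict[str, float]:
        return {
            "k": self.k,
            "c": self.c,
            "c1": self.c1,
            "c2": self.c2,
            "Tp": self.Tp,
            "beta": self.beta,
            "gamma": self.gamma,
            "n": self.n,
        }

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "CalibrationConstants":
        return cls(**{key: d[key] for key in cls.__dataclass_fields__ if key in d})


#: The published calibration for laboratory mice.
DEFAULT_CONSTANTS = CalibrationConstants()
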
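"""Monte Carlo group-formation dynamics over litter partitions.

The simulator's state is a set partition of the ``n`` pups into disjoint
huddle groups.  One elementary move ("encounter"):

1. pick a pup ``a`` uniformly at random;
2. pick a partner ``b`` uniformly from the pups in a *different* group
   (if the whole litter forms one group, ``b`` is any other pup);
3. with probability ``rho = sigmoid(T)`` join the groups of ``a`` and
   ``b`` into one (a no-op when they are already together), otherwise
   detach ``a`` from its group into a new singleton group.

``T`` is the (possibly pair-specific) huddling drive; higher drives make
larger huddles more likely.  A small exact-oracle routine computes the
stationary distribution of this chain at fixed drive for tiny litters by
direct eigen-analysis, which the test suite compares against long
simulated runs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Iterable, Iterator

import numpy as np
from scipy.special import expit

from .constants import DEFAULT_CONSTANTS, CalibrationConstants

__all__ = [
    "LitterPartition",
    "EncounterRecord",
    "join_probability",
    "mc_step",
    "mean_group_size",
    "set_partitions",
    "stationary_oracle",
    "partition_frequencies",
]


class LitterPartition:
    """A partition of pups ``0..n-1`` into disjoint huddle groups.

    Internally each pup carries an integer group label; labels are an
    implementation detail and equality/hashing are label-invariant.
    """

    __slots__ = ("_labels",)

    def __init__(self, labels: Iterable[int]):
        self._labels = list(labels)
        if not self._labels:
            raise ValueError("partition needs at least one pup")

    # -- constructors -------------------------------------------------
    @classmethod
    def single_group(cls, n: int) -> "LitterPartition":
        """All ``n`` pups huddled in one group (the neonatal start state)."""
        return cls([0] * n)

    @classmethod
    def singletons(cls, n: int) -> "LitterPartition":
        """Every pup isolated in its own group."""
        return cls(range(n))

    @classmethod
    def from_groups(cls, groups: Iterable[Iterable[int]]) -> "LitterPartition":
        """Build from explicit groups, e.g. ``[[0, 1, 2], [3], [4, 5]]``."""
        members: dict[int, int] = {}
        for label, group in enumerate(groups):
            for pup in group:
                if pup in members:
                    raise ValueError(f"pup {pup} appears in more than one group")
                members[pup] = label
        n = len(members)
        if sorted(members) != list(range(n)):
            raise ValueError("groups must cover pup ids 0..n-1 exactly once")
        return cls(members[i] for i in range(n))

    # -- queries ------------------------------------------------------
    @property
    def n(self) -> int:
        return len(self._labels)

    def group_of(self, pup: int) -> int:
        return self._labels[pup]

    def same_group(self, a: int, b: int) -> bool:
        return self._labels[a] == self._labels[b]

    def groups(self) -> list[list[int]]:
        """Groups as sorted lists of pup ids, largest-first then lexicographic."""
        by_label: dict[int, list[int]] = {}
        for pup, label in enumerate(self._labels):
            by_label.setdefault(label, []).append(pup)
        return sorted(by_label.values(), key=lambda g: (-len(g), g))

    def group_sizes(self) -> list[int]:
        sizes: dict[int, int] = {}
        for label in self._labels:
            sizes[label] = sizes.get(label, 0) + 1
        return sorted(sizes.values(), reverse=True)

    @property
    def n_groups(self) -> int:
        return len(set(self._labels))

    def canonical(self) -> frozenset[frozenset[int]]:
        """Label-free canonical form: a frozenset of pup-id frozensets."""
        return frozenset(frozenset(g) for g in self.groups())

    # -- moves --------------------------------------------------------
    def merge(self, a: int, b: int) -> None:
        """Join the groups of ``a`` and ``b`` (no-op if already together).

        The merged group keeps the initiator ``a``'s label.
        """
        la, lb = self._labels[a], self._labels[b]
        if la == lb:
            return
        self._labels = [la if lab == lb else lab for lab in self._labels]

    def detach(self, a: int) -> None:
        """Isolate pup ``a`` into a new group of size 1."""
        self._labels[a] = max(self._labels) + 1

    def copy(self) -> "LitterPartition":
        return LitterPartition(self._labels)

    # -- dunder -------------------------------------------------------
    def __eq__(self, other: object) -> bool:
        if not isinstance(other, LitterPartition):
            return NotImplemented
        return self.canonical() == other.canonical()

    def __hash__(self) -> int:
        return hash(self.canonical())

    def __repr__(self) -> str:
        body = "|".join("".join(str(p) for p in g) for g in self.groups())
        return f"LitterPartition({body})"

    def to_json(self) -> list[list[int]]:
        """JSON-serializable list-of-groups form (for debugging dumps)."""
        return self.groups()


@dataclass(frozen=True)
class EncounterRecord:
    """Outcome of one Monte Carlo encounter.

    ``a`` initiated contact with partner ``b``; the groups joined with
    probability ``rho`` and ``joined`` records the sampled outcome, which
    doubles as the learning reward (r = 1 on join, 0 on detach).
    """

    a: int
    b: int
    rho: float
    joined: bool


def join_probability(T) -> float | np.ndarray:
    """Probability of two groups joining: the logistic sigmoid of drive T.

    Evaluated in the numerically stable two-branch form; the scalar path
    is bit-identical to the simulation's inner loop.
    """
    if np.ndim(T) == 0:
        t = float(T)
        if not math.isfinite(t):
            raise ValueError("huddling drive T must be finite")
        if t >= 0.0:
            return 1.0 / (1.0 + math.exp(-t))
        eT = math.exp(t)
        return eT / (1.0 + eT)
    arr = np.asarray(T, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("huddling drive T must be finite")
    return expit(arr)


def mc_step(
    partition: LitterPartition,
    drive_for_pair: Callable[[int, int], float],
    rng: np.random.Generator,
    inplace: bool = False,
) -> tuple[LitterPartition, EncounterRecord]:
    """Perform one encounter and return ``(new_partition, record)``.

    ``drive_for_pair(a, b)`` supplies the drive for the sampled pair; in
    the physiological control this ignores the pair, in the learning
    condition it is the partner's learnt association for the initiator's
    odour times the thermal drive.  ``rng`` must be an explicit seedable
    generator so runs are reproducible.

    When every pup is already in one group the partner is drawn from all
    other pups; the join outcome is then a no-op (still reported with
    ``joined=True``) while the detach outcome applies as usual, keeping
    the chain irreducible.
    """
    if not isinstance(rng, np.random.Generator):
        raise TypeError("rng must be a numpy.random.Generator (explicit, seedable)")
    n = partition.n
    if n < 2:
        raise ValueError("need at least two pups to simulate encounters")
    if not inplace:
        partition = partition.copy()

    # Exactly three uniform draws per encounter, so block-based samplers
    # elsewhere in the package can reproduce this stream bit for bit.
    a = min(int(rng.random() * n), n - 1)
    la = partition.group_of(a)
    labels = partition._labels
    candidates = [i for i in range(n) if labels[i] != la]
    if not candidates:  # the whole litter is one group
        candidates = [i for i in range(n) if i != a]
    b = candidates[min(int(rng.random() * len(candidates)), len(candidates) - 1)]

    rho = join_probability(drive_for_pair(a, b))
    joined = bool(rng.random() < rho)
    if joined:
        partition.merge(a, b)
    else:
        partition.detach(a)
    return partition, EncounterRecord(a=a, b=b, rho=float(rho), joined=joined)


def mean_group_size(partition: LitterPartition, estimator: str = "groups") -> float:
    """Average huddle size of a partition.

    ``"groups"`` (default) is pups per group, ``n / #groups``.
    ``"pup_weighted"`` is the expected size of the group containing a
    randomly chosen pup, ``sum(sizes^2) / n``.  Both equal 1 on all
    singletons and ``n`` on a single huddle.
    """
    sizes = partition.group_sizes()
    n = partition.n
    if estimator == "groups":
        return n / len(sizes)
    if estimator == "pup_weighted":
        return sum(s * s for s in sizes) / n
    raise ValueError(f"unknown estimator {estimator!r}")


# ---------------------------------------------------------------------
# Exact stationary analysis for tiny litters
# ---------------------------------------------------------------------

def set_partitions(items: list[int]) -> Iterator[list[list[int]]]:
    """Yield all set partitions of ``items`` (Bell-number many)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for sub in set_partitions(rest):
        for i in range(len(sub)):
            yield sub[:i] + [[first] + sub[i]] + sub[i + 1:]
        yield [[first]] + sub


_BELL = {1: 1, 2: 2, 3: 5, 4: 15, 5: 52}


def stationary_oracle(
    n: int,
    T: float,
    return_matrix: bool = False,
) -> dict[frozenset[frozenset[int]], float] | tuple[dict, np.ndarray, list]:
    """Exact stationary distribution of the encounter chain at fixed drive.

    Enumerates every labelled set partition of ``n`` pups (``n <= 5``,
    Bell(5) = 52 states), builds the one-step transition matrix induced by
    :func:`mc_step`'s selection and outcome rules at constant drive ``T``,
    and returns the normalized leading left eigenvector as a mapping from
    canonical partition to stationary probability.

    With ``return_matrix=True`` also returns the transition matrix and the
    state list (for diagnostics).
    """
    if n < 2 or n not in _BELL:
        raise ValueError("stationary_oracle supports 2 <= n <= 5 only")
    rho = join_probability(float(T))

    states = [
        frozenset(frozenset(g) for g in p) for p in set_partitions(list(range(n)))
    ]
    index = {s: i for i, s in enumerate(states)}
    P = np.zeros((len(states), len(states)))

    for s, i in index.items():
        group_of = {pup: g for g in s for pup in g}
        for a in range(n):
            ga = group_of[a]
            candidates = [p for p in range(n) if p not in ga]
            if not candidates:
                candidates = [p for p in range(n) if p != a]
            p_pick = 1.0 / (n * len(candidates))
            for b in candidates:
                gb = group_of[b]
                if ga is gb:
                    join_state = s  # already together: join is a no-op
                else:
                    join_state = frozenset(
                        g for g in s if g is not ga and g is not gb
                    ) | {ga | gb}
                if len(ga) == 1:
                    detach_state = s  # already a singleton
                else:
                    detach_state = frozenset(
                        g for g in s if g is not ga
                    ) | {ga - {a}, frozenset({a})}
                P[i, index[join_state]] += p_pick * rho
                P[i, index[detach_state]] += p_pick * (1.0 - rho)

    assert np.allclose(P.sum(axis=1), 1.0)
    # stationary pi solves pi (P - I) = 0; use the null space of (P - I)^T
    w, v = np.linalg.eig(P.T)
    lead = int(np.argmin(np.abs(w - 1.0)))
    pi = np.real(v[:, lead])
    pi = np.abs(pi) / np.abs(pi).sum()
    if not math.isclose(float(np.real(w[lead])), 1.0, abs_tol=1e-9):
        raise RuntimeError("leading eigenvalue of the chain is not 1")
    dist = {s: float(pi[i]) for s, i in index.items()}
    if return_matrix:
        return dist, P, states
    return dist


def partition_frequencies(
    n: int,
    T: float,
    steps: int,
    rng: np.random.Generator,
    burn_in: int = 0,
    start: LitterPartition | None = None,
) -> dict[frozenset[frozenset[int]], float]:
    """Empirical visit frequencies of the chain at constant drive ``T``.

    Runs ``burn_in + steps`` encounters from ``start`` (default: all
    singletons) and returns the post-burn-in fraction of steps spent in
    each canonical partition.  Uses a block-sampled inner loop that
    consumes the generator's uniform stream exactly as repeated
    :func:`mc_step` calls would, so the two are interchangeable.
    """
    if n < 2:
        raise ValueError("need at least two pups")
    if steps < 1:
        raise ValueError("steps must be >= 1")
    rho = join_probability(float(T))
    part = start.copy() if start is not None else LitterPartition.singletons(n)
    if part.n != n:
        raise ValueError("start partition has the wrong number of pups")
    labels = list(part._labels)
    next_label = max(labels) + 1
    counts: dict[tuple, int] = {}

    total = burn_in + steps
    block = 3 * min(total, 200_000)
    done = 0
    u: list[float] = []
    ui = 0
    while done < total:
        if ui >= len(u):
            u = rng.random(min(block, 3 * (total - done))).tolist()
            ui = 0
        a = min(int(u[ui] * n), n - 1)
        la = labels[a]
        cand = [i for i in range(n) if labels[i] != la]
        if not cand:
            cand = [i for i in range(n) if i != a]
        b = cand[min(int(u[ui + 1] * len(cand)), len(cand) - 1)]
        if u[ui + 2] < rho:
            lb = labels[b]
            if lb != la:
                labels = [la if l == lb else l for l in labels]
        else:
            labels[a] = next_label
            next_label += 1
        ui += 3
        done += 1
        if done > burn_in:
            key_groups: dict[int, list[int]] = {}
            for pup, l in enumerate(labels):
                key_groups.setdefault(l, []).append(pup)
            key = tuple(sorted(tuple(g) for g in key_groups.values()))
            counts[key] = counts.get(key, 0) + 1

    return {
        frozenset(frozenset(g) for g in key): c / steps for key, c in counts.items()
    }


def constant_drive(
    t: float, consts: CalibrationConstants = DEFAULT_CONSTANTS
) -> Callable[[int, int], float]:
    """Pair-independent drive function for the control condition at day t."""
    from .physiology import huddling_drive

    T = huddling_drive(t, consts)
    return lambda a, b: T
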
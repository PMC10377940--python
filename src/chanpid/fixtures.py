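"""Deterministic generators for the worked PID examples and seeded random
instances for property tests.

The logic-gate joints (AND, SUM, COPY, IDENT_Y1, XOR) use two independent
equiprobable binary inputs and exact rational masses.  The two channel-pair
examples are stored as their printed numeric matrices:

* ``counterexample1`` — a 2×2 pair where the second channel is less noisy
  than the first although neither is a degradation of the other.
* ``ds_example`` — the 3×2 pair K(3), K(4) where K(4) is one JoinMeet step
  below K(3) but not a degradation of it.
"""

from __future__ import annotations

from fractions import Fraction

import numpy as np

from .distributions import ChannelMatrix, ChanpidError, JointDistribution, joint_from_table

__all__ = [
    "GATES",
    "gate_joint",
    "counterexample1",
    "ds_example",
    "random_channel",
    "random_joint",
    "random_degraded_pair",
]

GATES = ("AND", "SUM", "COPY", "IDENT_Y1", "XOR")


def gate_joint(name: str) -> JointDistribution:
    """Joint p(t, y1, y2) for a named gate with iid uniform binary inputs."""
    name = name.upper()
    if name not in GATES:
        raise ChanpidError("UNKNOWN_GATE", f"{name!r}; choose from {GATES}")
    target = {
        "AND": lambda a, b: a & b,
        "SUM": lambda a, b: a + b,
        "COPY": lambda a, b: (a, b),
        "IDENT_Y1": lambda a, b: a,
        "XOR": lambda a, b: a ^ b,
    }[name]
    quarter = Fraction(1, 4)
    records = []
    for y1 in (0, 1):
        for y2 in (0, 1):
            records.append(((target(y1, y2), y1, y2), float(quarter)))
    return joint_from_table(records, variable_names=("t", "y1", "y2"))


def counterexample1() -> tuple[ChannelMatrix, ChannelMatrix]:
    """The 2×2 channel pair K(1), K(2) (parameters p=0.25, ε=0.2, δ=0.1 in
    the literature; stored as the printed matrices)."""
    K1 = ChannelMatrix.from_rows(np.array([[0.25, 0.75], [0.35, 0.65]]))
    K2 = ChannelMatrix.from_rows(np.array([[0.675, 0.325], [0.745, 0.255]]))
    return K1, K2


def ds_example() -> tuple[ChannelMatrix, ChannelMatrix]:
    """The 3×2 channel pair K(3), K(4) with K(4) = ⋄_{0,1} K(3)."""
    K3 = ChannelMatrix.from_rows(np.array([[1.0, 0.0], [0.0, 1.0], [0.5, 0.5]]))
    K4 = ChannelMatrix.from_rows(np.array([[1.0, 0.0], [1.0, 0.0], [0.5, 0.5]]))
    return K3, K4


def random_channel(n_in: int, n_out: int, seed: int) -> ChannelMatrix:
    """Random channel with rows drawn from a flat Dirichlet; reproducible."""
    if n_in < 1 or n_out < 1:
        raise ChanpidError("BAD_SIZE", f"({n_in}, {n_out})")
    rng = np.random.default_rng(seed)
    return ChannelMatrix.from_rows(rng.dirichlet(np.ones(n_out), size=n_in))


def random_joint(alphabet_sizes: tuple[int, ...], seed: int) -> JointDistribution:
    """Random full-support joint over variables of the given alphabet sizes
    (target first), masses drawn from a flat Dirichlet."""
    if any(s < 1 for s in alphabet_sizes):
        raise ChanpidError("BAD_SIZE", f"{alphabet_sizes!r}")
    rng = np.random.default_rng(seed)
    outcomes = [()]
    for s in alphabet_sizes:
        outcomes = [o + (v,) for o in outcomes for v in range(s)]
    probs = rng.dirichlet(np.ones(len(outcomes)))
    return joint_from_table(list(zip(outcomes, probs)))


def random_degraded_pair(
    n_in: int, n_mid: int, n_out: int, seed: int
) -> tuple[ChannelMatrix, ChannelMatrix]:
    """A pair (W, V) with W = V @ KU by construction, so W ⪯d V holds."""
    rng = np.random.default_rng(seed)
    V = ChannelMatrix.from_rows(rng.dirichlet(np.ones(n_mid), size=n_in))
    KU = ChannelMatrix.from_rows(rng.dirichlet(np.ones(n_out), size=n_mid))
    W = V.compose(KU)
    return W, V
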
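"""Decision procedures for preorders between channels sharing an input.

Four preorders are covered, in decreasing strength (each implies the next
where an arrow exists):

* degradation / Blackwell (``W ⪯d V``): W equals V post-processed by some
  row-stochastic matrix KU, i.e. ``W = V @ KU``.  Decided exactly by a
  linear program; a HOLDS verdict carries the KU certificate.
* supermodularity (``W ⪯s V``): W is reachable from V by finitely many
  applications of the JoinMeet column operator.  Decided exactly by
  breadth-first enumeration of the (finite) reachable set.
* degradation/supermodularity (``W ⪯ds V``): finite chains alternating
  degradation and JoinMeet steps.  No complete decision condition is known;
  the checker is sound but incomplete and answers HOLDS or UNKNOWN.
* less-noisy and more-capable: defined by quantification over a continuum
  (all simplex pairs / points), so a finite grid can only certify a
  *violation*; the non-violation outcome is reported as
  NO_VIOLATION_AT_RESOLUTION, never HOLDS.

The less-noisy test uses the χ²-divergence contraction characterization:
V is less noisy than W iff χ²(pV‖qV) ≥ χ²(pW‖qW) for every pair of target
distributions (p, q).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import linprog

from .distributions import (
    ATOL,
    ChannelMatrix,
    ChanpidError,
    SimplexPoint,
    mutual_information,
)

__all__ = [
    "OrderVerdict",
    "JoinMeetStep",
    "ClosureResult",
    "simplex_grid",
    "chi2_divergence",
    "less_noisy_gap",
    "degradation_check",
    "joinmeet",
    "supermodular_closure",
    "supermodularity_check",
    "ds_check",
    "less_noisy_check",
    "more_capable_check",
]

HOLDS = "HOLDS"
VIOLATED = "VIOLATED"
NO_VIOLATION_AT_RESOLUTION = "NO_VIOLATION_AT_RESOLUTION"
UNKNOWN = "UNKNOWN"

#: default entrywise tolerance for the degradation LP residual
DEGRADATION_TOL = 1e-7
#: strict-violation margin for grid checks
VIOLATION_EPS = 1e-9


@dataclass(frozen=True)
class JoinMeetStep:
    """One application of the JoinMeet column operator on columns (i, j)."""

    i: int
    j: int


@dataclass(frozen=True)
class OrderVerdict:
    """Outcome of a preorder decision, with a checkable certificate.

    ``certificate`` is a KU :class:`ChannelMatrix` for HOLDS-degradation, a
    tuple of chain elements for HOLDS-supermodular/ds, and a (p, q) simplex
    pair (or a single p) for VIOLATED less-noisy / more-capable.
    """

    relation: str
    status: str
    certificate: object = None
    resolution: Optional[float] = None

    @property
    def holds(self) -> bool:
        return self.status == HOLDS

    @property
    def violated(self) -> bool:
        return self.status == VIOLATED


def _check_same_input(W: ChannelMatrix, V: ChannelMatrix) -> None:
    if W.rows.shape[0] != V.rows.shape[0]:
        raise ChanpidError(
            "INPUT_MISMATCH",
            f"channels have {W.rows.shape[0]} and {V.rows.shape[0]} input outcomes",
        )


# ---------------------------------------------------------------------------
# Degradation / Blackwell order
# ---------------------------------------------------------------------------


def degradation_check(
    W: ChannelMatrix, V: ChannelMatrix, tol: float = DEGRADATION_TOL
) -> OrderVerdict:
    """Decide whether W is a degradation of V (``W ⪯d V``).

    Solved as a linear program minimizing the entrywise ∞-norm residual
    ``‖W − V·KU‖∞`` over row-stochastic KU; HOLDS iff the optimum is ≤ tol.
    The LP formulation is robust to floating-point degeneracy compared with
    a pure feasibility phase.
    """
    _check_same_input(W, V)
    n_t, a = V.rows.shape
    b = W.rows.shape[1]
    nvar = a * b + 1  # KU entries then slack s

    c = np.zeros(nvar)
    c[-1] = 1.0

    A_eq = np.zeros((a, nvar))
    for r in range(a):
        A_eq[r, r * b : (r + 1) * b] = 1.0
    b_eq = np.ones(a)

    # V @ KU − W ≤ s  and  W − V @ KU ≤ s
    n_ineq = 2 * n_t * b
    A_ub = np.zeros((n_ineq, nvar))
    b_ub = np.zeros(n_ineq)
    row = 0
    for t in range(n_t):
        for z in range(b):
            for y in range(a):
                A_ub[row, y * b + z] = V.rows[t, y]
                A_ub[row + 1, y * b + z] = -V.rows[t, y]
            A_ub[row, -1] = -1.0
            A_ub[row + 1, -1] = -1.0
            b_ub[row] = W.rows[t, z]
            b_ub[row + 1] = -W.rows[t, z]
            row += 2

    res = linprog(c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq, bounds=(0, None), method="highs")
    if not res.success:  # pragma: no cover - HiGHS should always solve this LP
        raise RuntimeError(f"degradation LP failed: {res.message}")
    if res.x[-1] <= tol:
        KU = np.clip(res.x[:-1].reshape(a, b), 0.0, None)
        KU /= KU.sum(axis=1, keepdims=True)
        cert = ChannelMatrix(V.output_labels, W.output_labels, KU)
        return OrderVerdict("degradation", HOLDS, certificate=cert, resolution=tol)
    return OrderVerdict("degradation", VIOLATED, certificate=float(res.x[-1]), resolution=tol)


# ---------------------------------------------------------------------------
# JoinMeet operator and supermodularity order
# ---------------------------------------------------------------------------


def joinmeet(K: ChannelMatrix, step: JoinMeetStep) -> ChannelMatrix:
    """Apply the JoinMeet operator: column i ← max, column j ← min.

    Row sums are preserved exactly (max + min of a pair equals its sum), so
    the result is again a channel; per-row entry multisets are invariant.
    """
    i, j = step.i, step.j
    k = K.rows.shape[1]
    if i == j or not (0 <= i < k) or not (0 <= j < k):
        raise ChanpidError("BAD_INDEX", f"invalid JoinMeet columns ({i}, {j}) for {k} outputs")
    rows = K.rows.copy()
    hi = np.maximum(rows[:, i], rows[:, j])
    lo = np.minimum(rows[:, i], rows[:, j])
    rows[:, i] = hi
    rows[:, j] = lo
    return ChannelMatrix(K.input_labels, K.output_labels, rows)


@dataclass
class ClosureResult:
    """Supermodular closure of a channel: every ⋄-reachable matrix."""

    members: list[ChannelMatrix]
    paths: dict = field(repr=False)  # key -> tuple[JoinMeetStep, ...] from the seed
    truncated: bool = False

    def path_to(self, K: ChannelMatrix) -> Optional[tuple[JoinMeetStep, ...]]:
        return self.paths.get(_matrix_key(K.rows))


def _matrix_key(rows: np.ndarray) -> bytes:
    return np.round(rows, 9).tobytes()


def supermodular_closure(V: ChannelMatrix, max_nodes: int = 10_000) -> ClosureResult:
    """All channels reachable from V by finite JoinMeet compositions.

    Breadth-first search over ordered column pairs (ties broken
    lexicographically, so certificates are reproducible); terminates because
    JoinMeet permutes entries within rows, so the reachable set is finite.
    Truncates with a flag once ``max_nodes`` distinct channels are found.
    """
    if max_nodes < 1:
        raise ChanpidError("BAD_INDEX", "max_nodes must be ≥ 1")
    k = V.rows.shape[1]
    seed_key = _matrix_key(V.rows)
    members = [V]
    paths: dict = {seed_key: ()}
    frontier = [V]
    truncated = False
    while frontier and not truncated:
        nxt = []
        for K in frontier:
            for i, j in itertools.permutations(range(k), 2):
                child = joinmeet(K, JoinMeetStep(i, j))
                key = _matrix_key(child.rows)
                if key in paths:
                    continue
                paths[key] = paths[_matrix_key(K.rows)] + (JoinMeetStep(i, j),)
                members.append(child)
                nxt.append(child)
                if len(members) >= max_nodes:
                    truncated = True
                    break
            if truncated:
                break
        frontier = nxt
    return ClosureResult(members, paths, truncated)


def supermodularity_check(
    W: ChannelMatrix, V: ChannelMatrix, max_nodes: int = 10_000
) -> OrderVerdict:
    """Decide ``W ⪯s V``: is W a finite JoinMeet rewrite of V?"""
    if W.rows.shape != V.rows.shape:
        raise ChanpidError("SHAPE_MISMATCH", f"shapes {W.rows.shape} vs {V.rows.shape}")
    closure = supermodular_closure(V, max_nodes=max_nodes)
    path = closure.path_to(W)
    if path is not None:
        return OrderVerdict("supermodular", HOLDS, certificate=path)
    if closure.truncated:
        return OrderVerdict("supermodular", UNKNOWN, resolution=float(max_nodes))
    return OrderVerdict("supermodular", VIOLATED)


def ds_check(
    W: ChannelMatrix,
    V: ChannelMatrix,
    depth: int = 2,
    max_nodes: int = 10_000,
    tol: float = DEGRADATION_TOL,
) -> OrderVerdict:
    """Sound-but-incomplete test of the degradation/supermodularity order.

    Searches for a chain of degradation and JoinMeet steps from V down to W:
    depth 1 covers ``⪯d`` or ``⪯s`` alone; depth 2 additionally searches
    ``W ⪯d U ⪯s V`` over the supermodular closure members U of V.  Since no
    complete decision condition for ``⪯ds`` is known, a failed search yields
    UNKNOWN, never VIOLATED.

    The certificate is a chain ``(("d", KU) | ("s", steps), ...)`` read from
    W up to V.
    """
    _check_same_input(W, V)
    d = degradation_check(W, V, tol=tol)
    if d.holds:
        return OrderVerdict("ds", HOLDS, certificate=(("d", d.certificate),))
    if W.rows.shape == V.rows.shape:
        closure = supermodular_closure(V, max_nodes=max_nodes)
        path = closure.path_to(W)
        if path is not None:
            return OrderVerdict("ds", HOLDS, certificate=(("s", path),))
    else:
        closure = None
    if depth >= 2 and closure is not None:
        for U in closure.members[1:]:
            d = degradation_check(W, U, tol=tol)
            if d.holds:
                return OrderVerdict(
                    "ds", HOLDS, certificate=(("d", d.certificate), ("s", closure.path_to(U)))
                )
    return OrderVerdict("ds", UNKNOWN, resolution=float(depth))


# ---------------------------------------------------------------------------
# χ² divergence, simplex grids, less-noisy / more-capable grid checks
# ---------------------------------------------------------------------------


def chi2_divergence(u: Sequence[float] | SimplexPoint, v: Sequence[float] | SimplexPoint) -> float:
    """χ²(u‖v) = Σ (u_i − v_i)² / v_i, with 0/0 := 0 and positive/0 := +∞."""
    uw = u.weights if isinstance(u, SimplexPoint) else np.asarray(u, dtype=float)
    vw = v.weights if isinstance(v, SimplexPoint) else np.asarray(v, dtype=float)
    if uw.size != vw.size:
        raise ChanpidError("DIMENSION_MISMATCH", "vectors of different length")
    num = (uw - vw) ** 2
    total = 0.0
    for n, d in zip(num, vw):
        if d > 0:
            total += n / d
        elif n > ATOL**2:
            return float("inf")
    return float(total)


def simplex_grid(dim: int, step: float) -> np.ndarray:
    """All probability vectors of length ``dim`` whose entries are multiples
    of ``step`` (lexicographic order).  ``step`` must divide 1 evenly."""
    m = round(1.0 / step)
    if abs(m * step - 1.0) > 1e-9:
        raise ChanpidError("BAD_INDEX", f"grid step {step} does not divide 1")
    points = [
        comp for comp in _compositions(m, dim)
    ]
    return np.array(points, dtype=float) / m


def _compositions(total: int, parts: int):
    if parts == 1:
        yield (total,)
        return
    for first in range(total + 1):
        for rest in _compositions(total - first, parts - 1):
            yield (first,) + rest


def _pairwise_chi2(outputs: np.ndarray) -> np.ndarray:
    """χ²(outputs[i] ‖ outputs[j]) for all ordered pairs (i, j), with the
    zero conventions; result is an (m, m) matrix, +inf where undefined."""
    P = outputs[:, None, :]  # u
    Q = outputs[None, :, :]  # v
    num = (P - Q) ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(Q > 0, num / np.where(Q > 0, Q, 1.0), np.where(num > ATOL**2, np.inf, 0.0))
    return terms.sum(axis=-1)


def less_noisy_gap(
    W: ChannelMatrix, V: ChannelMatrix, p: Sequence[float], q: Sequence[float]
) -> float:
    """χ²(pV‖qV) − χ²(pW‖qW) at one simplex pair; negative means the pair
    witnesses that V is *not* less noisy than W (``W ⋠ln V``)."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    cv = chi2_divergence(p @ V.rows, q @ V.rows)
    cw = chi2_divergence(p @ W.rows, q @ W.rows)
    if np.isinf(cv):
        return float("inf")
    if np.isinf(cw):
        return float("-inf") if not np.isinf(cv) else 0.0
    return cv - cw


def less_noisy_check(
    W: ChannelMatrix, V: ChannelMatrix, grid_step: float = 0.1
) -> OrderVerdict:
    """Grid test of ``W ⪯ln V`` (V less noisy than W).

    Evaluates the χ² contraction condition on every ordered pair (p, q) of
    grid distributions with entries in multiples of ``grid_step``: VIOLATED
    with the first witnessing pair (lexicographic scan) if
    χ²(pV‖qV) < χ²(pW‖qW); otherwise NO_VIOLATION_AT_RESOLUTION.  The grid
    can certify violation only — the defining inequality quantifies over the
    whole simplex, so absence of a grid violation is not a proof of order.
    An infinite χ² through V satisfies the condition against any finite or
    infinite value.
    """
    _check_same_input(W, V)
    if not (0 < grid_step <= 0.5):
        raise ChanpidError("BAD_INDEX", f"grid_step {grid_step} outside (0, 0.5]")
    G = simplex_grid(W.rows.shape[0], grid_step)
    CV = _pairwise_chi2(G @ V.rows)
    CW = _pairwise_chi2(G @ W.rows)
    # violation where χ²V finite and strictly below χ²W (inf > anything finite)
    finite_v = np.isfinite(CV)
    bad = finite_v & (CV < CW - VIOLATION_EPS)
    if bad.any():
        i, j = np.argwhere(bad)[0]  # lexicographic first
        cert = (
            SimplexPoint.from_weights(G[i], W.input_labels),
            SimplexPoint.from_weights(G[j], W.input_labels),
        )
        return OrderVerdict("less_noisy", VIOLATED, certificate=cert, resolution=grid_step)
    return OrderVerdict("less_noisy", NO_VIOLATION_AT_RESOLUTION, resolution=grid_step)


def _mi_batch(G: np.ndarray, rows: np.ndarray) -> np.ndarray:
    """I(p; K) in bits for every grid row p of G (vectorized)."""
    out_marg = G @ rows  # (m, k)
    with np.errstate(divide="ignore", invalid="ignore"):
        h_out = -np.sum(np.where(out_marg > 0, out_marg * np.log2(np.where(out_marg > 0, out_marg, 1.0)), 0.0), axis=1)
        h_rows = -np.sum(np.where(rows > 0, rows * np.log2(np.where(rows > 0, rows, 1.0)), 0.0), axis=1)
    return h_out - G @ h_rows


def more_capable_check(
    W: ChannelMatrix,
    V: ChannelMatrix,
    grid_step: float = 0.1,
    refine: bool = False,
) -> OrderVerdict:
    """Grid test of ``W ⪯mc V``: I(p; W) ≤ I(p; V) for every target law p.

    Evaluates the gap I(p; V) − I(p; W) on the simplex grid; VIOLATED with
    the witnessing p if the gap drops below −1e-9, else
    NO_VIOLATION_AT_RESOLUTION.  With ``refine=True`` the worst grid point
    is polished by a local constrained minimization of the gap before the
    verdict (can only expose more violations, never hide one).
    """
    _check_same_input(W, V)
    if not (0 < grid_step <= 0.5):
        raise ChanpidError("BAD_INDEX", f"grid_step {grid_step} outside (0, 0.5]")
    G = simplex_grid(W.rows.shape[0], grid_step)
    gap = _mi_batch(G, V.rows) - _mi_batch(G, W.rows)
    worst = int(np.argmin(gap))
    worst_p = G[worst]
    worst_gap = float(gap[worst])
    if refine:
        from scipy.optimize import minimize

        d = W.rows.shape[0]

        def f(x):
            x = np.clip(x, 0, None)
            s = x.sum()
            if s <= 0:
                return 0.0
            p = x / s
            return float(_mi_batch(p[None, :], V.rows)[0] - _mi_batch(p[None, :], W.rows)[0])

        res = minimize(
            f,
            worst_p,
            method="SLSQP",
            bounds=[(0.0, 1.0)] * d,
            constraints=[{"type": "eq", "fun": lambda x: x.sum() - 1.0}],
            options={"maxiter": 200, "ftol": 1e-12},
        )
        if res.fun < worst_gap:
            worst_gap = float(res.fun)
            worst_p = np.clip(res.x, 0, None)
            worst_p = worst_p / worst_p.sum()
    if worst_gap < -VIOLATION_EPS:
        cert = SimplexPoint.from_weights(worst_p, W.input_labels)
        return OrderVerdict("more_capable", VIOLATED, certificate=cert, resolution=grid_step)
    return OrderVerdict("more_capable", NO_VIOLATION_AT_RESOLUTION, resolution=grid_step)
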
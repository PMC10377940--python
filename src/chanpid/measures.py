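"""Intersection-information measures and bivariate PID assembly.

Every measure here instantiates the same template: the redundancy shared by
sources Y1..Yn about a target T is the largest mutual information I(Q;T)
achievable by a channel KQ that sits *below* every source channel K(i) in a
chosen preorder,

    I∩(Y1,...,Yn) = max_{KQ : KQ ⪯ K(i) ∀i} I(Q;T).

The preorder decides what "below" means and how hard the optimization is:

* degradation (Blackwell): the constraint set {KQ = K(i)·KU(i)} is a
  polytope in the auxiliary post-processing matrices KU(i), and I(Q;T) is
  convex in KQ, so the maximum sits at a polytope vertex.  Solved exactly by
  vertex enumeration on small problems, by multistart Frank–Wolfe otherwise.
* less-noisy / more-capable: the defining constraints quantify over the
  whole target simplex, so the solver samples them (grid plus Dirichlet
  draws) and reports a *bracket*: a constructive lower bound (a source
  channel that passes the order check, else the constant channel) and the
  sampled-constraint optimum as an upper bound, clamped by the MMI cap.
* degradation/supermodularity: bracketed between the degradation value plus
  any source certified by the (sound, incomplete) ds order check, and the
  more-capable upper bound.
* deterministic (Gács–Körner style) and MMI reference measures are closed
  form.

All values are in bits.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import networkx as nx
import numpy as np
from scipy.optimize import linprog, minimize

from .distributions import (
    ChannelMatrix,
    ChanpidError,
    JointDistribution,
    SimplexPoint,
    channel_from_joint,
    entropy,
    mutual_information,
    specific_information,
    tuple_channel,
)
from .orders import (
    ds_check,
    less_noisy_check,
    more_capable_check,
    simplex_grid,
)

__all__ = [
    "SolverOptions",
    "MeasureResult",
    "PIDResult",
    "Interval",
    "CommonPartLabeling",
    "ii_degradation",
    "ii_less_noisy",
    "ii_more_capable",
    "ii_ds",
    "ii_mmi",
    "ii_deterministic",
    "common_part_labeling",
    "gacs_korner",
    "pid_bivariate",
    "MEASURES",
]

EXACT = "EXACT"
LOWER_BOUND = "LOWER_BOUND"
UPPER_BOUND = "UPPER_BOUND"
BRACKET = "BRACKET"


@dataclass(frozen=True)
class SolverOptions:
    """Tunable optimization parameters (all randomness flows from ``seed``).

    ``q_support_cap`` bounds the output alphabet of Q; by default it is
    Σ|S_Yi| − n + 1, which is provably sufficient for the degradation
    measure.  The same cap is applied to the less-noisy / more-capable
    solvers as a configurable default, although no such sufficiency proof is
    known for those orders.
    """

    seed: int = 0
    restarts: int = 200  # Frank–Wolfe multistarts for the degradation measure
    sampled_restarts: int = 12  # SLSQP multistarts for sampled-constraint solvers
    grid_step: float = 0.1
    n_dirichlet: int = 500
    max_kept_constraints: int = 500
    q_support_cap: Optional[int] = None
    vertex_combination_cap: int = 200_000
    degradation_tol: float = 1e-7
    collapse_tol: float = 1e-4
    slsqp_maxiter: int = 300


@dataclass(frozen=True)
class Interval:
    low: float
    high: float

    def __post_init__(self):
        if self.low > self.high + 1e-9:
            raise ChanpidError("DIMENSION_MISMATCH", f"interval [{self.low}, {self.high}] empty")

    @property
    def width(self) -> float:
        return self.high - self.low


@dataclass(frozen=True)
class MeasureResult:
    """Value (bits) of an intersection-information measure.

    ``value`` is the exact value when ``bound_status == EXACT``; otherwise
    the bracket endpoints carry the information and ``value`` equals the
    lower endpoint (a certified achievable redundancy).
    """

    measure: str
    value: float
    bound_status: str
    lower: float
    upper: float
    argmax_channel: Optional[ChannelMatrix] = None
    diagnostics: dict = field(default_factory=dict)

    @property
    def bracket(self) -> Interval:
        return Interval(self.lower, self.upper)


def _finalize(measure, lower, upper, argmax, diagnostics, collapse_tol) -> MeasureResult:
    lower = max(float(lower), 0.0)
    upper = max(float(upper), lower)
    if upper - lower <= collapse_tol:
        return MeasureResult(measure, upper, EXACT, lower, upper, argmax, diagnostics)
    return MeasureResult(measure, lower, BRACKET, lower, upper, argmax, diagnostics)


def _check_channels(p_t, channels) -> tuple[np.ndarray, list[np.ndarray]]:
    w = p_t.weights if isinstance(p_t, SimplexPoint) else np.asarray(p_t, dtype=float)
    mats = []
    for K in channels:
        rows = K.rows if isinstance(K, ChannelMatrix) else np.asarray(K, dtype=float)
        if rows.shape[0] != w.size:
            raise ChanpidError("INPUT_MISMATCH", "channel input alphabet does not match p(t)")
        mats.append(rows)
    if not mats:
        raise ChanpidError("INPUT_MISMATCH", "need at least one source channel")
    return w, mats


def _q_cap(mats, opts: SolverOptions) -> int:
    if opts.q_support_cap is not None:
        return opts.q_support_cap
    return sum(m.shape[1] for m in mats) - len(mats) + 1


def _as_channel(rows: np.ndarray, p_t) -> ChannelMatrix:
    labels = p_t.support_labels if isinstance(p_t, SimplexPoint) else tuple(range(rows.shape[0]))
    return ChannelMatrix(tuple(labels), tuple(range(rows.shape[1])), rows)


# ---------------------------------------------------------------------------
# MMI reference measure
# ---------------------------------------------------------------------------


def ii_mmi(p_t, channels: Sequence[ChannelMatrix]) -> MeasureResult:
    """Minimum mutual information over sources: min_i I(T;Yi).  Exact."""
    w, mats = _check_channels(p_t, channels)
    vals = [mutual_information(w, m) for m in mats]
    i = int(np.argmin(vals))
    arg = channels[i] if isinstance(channels[i], ChannelMatrix) else _as_channel(mats[i], p_t)
    return MeasureResult("mmi", vals[i], EXACT, vals[i], vals[i], arg, {"per_source": vals})


# ---------------------------------------------------------------------------
# Degradation measure: exact vertex enumeration + Frank–Wolfe fallback
# ---------------------------------------------------------------------------


def _degradation_polytope(mats: list[np.ndarray], nq: int):
    """Equality system A x = b, x ≥ 0 for x = concat_i vec(KU(i)).

    Constraints: every KU(i) is row-stochastic, and the implied
    KQ = K(i) @ KU(i) agrees across sources.
    """
    sizes = [m.shape[1] for m in mats]
    n_t = mats[0].shape[0]
    nvar = sum(s * nq for s in sizes)
    offs = np.cumsum([0] + [s * nq for s in sizes])
    rows, b = [], []
    for i, s in enumerate(sizes):
        for r in range(s):
            a = np.zeros(nvar)
            a[offs[i] + r * nq : offs[i] + (r + 1) * nq] = 1.0
            rows.append(a)
            b.append(1.0)
    for i in range(1, len(mats)):
        for t in range(n_t):
            for q in range(nq):
                a = np.zeros(nvar)
                for y in range(sizes[0]):
                    a[offs[0] + y * nq + q] += mats[0][t, y]
                for y in range(sizes[i]):
                    a[offs[i] + y * nq + q] -= mats[i][t, y]
                rows.append(a)
                b.append(0.0)
    return np.array(rows), np.array(b), offs, sizes, nvar


def _kq_from_x(x, mats, offs, nq) -> np.ndarray:
    KU0 = x[offs[0] : offs[1]].reshape(mats[0].shape[1], nq)
    KQ = mats[0] @ KU0
    return np.clip(KQ, 0.0, None)


def _mi_grad_kq(w: np.ndarray, KQ: np.ndarray) -> np.ndarray:
    """∂ I(p;KQ) / ∂ KQ[t,q] = p_t log2(KQ[t,q] / py_q), clipped at zeros."""
    py = (w[:, None] * KQ).sum(axis=0)
    with np.errstate(divide="ignore"):
        g = w[:, None] * (np.log2(np.where(KQ > 0, KQ, 1e-300)) - np.log2(np.where(py > 0, py, 1e-300))[None, :])
    return g


def ii_degradation(
    p_t, channels: Sequence[ChannelMatrix], opts: SolverOptions = SolverOptions()
) -> MeasureResult:
    """Degradation (Blackwell) intersection information, Eq.-style

        max I(Q;T)  s.t.  KQ = K(i) @ KU(i) for every source i,

    a convex maximization over a polytope in the KU(i): the optimum is
    attained at a vertex.  Exact by enumeration of basic feasible solutions
    when the basis-subset count is small; otherwise a seeded multistart
    Frank–Wolfe ascent reports a lower bound.  Always feasible: the constant
    Q satisfies every constraint.
    """
    w, mats = _check_channels(p_t, channels)
    nq = _q_cap(mats, opts)
    A, b, offs, sizes, nvar = _degradation_polytope(mats, nq)
    rank = int(np.linalg.matrix_rank(A, tol=1e-9))
    n_comb = math.comb(nvar, rank)
    diagnostics = {"nq": nq, "nvar": nvar, "rank": rank, "seed": opts.seed}

    if n_comb <= opts.vertex_combination_cap:
        best, bestKQ, n_vertices = _enumerate_vertices(A, b, rank, w, mats, offs, nq)
        diagnostics.update({"method": "vertex_enumeration", "vertices": n_vertices})
        arg = _as_channel(bestKQ, p_t)
        diagnostics["specific_info_dominance"] = _specific_dominance(w, mats, bestKQ)
        return MeasureResult("degradation", best, EXACT, best, best, arg, diagnostics)

    best, bestKQ, n_starts = _frank_wolfe_multistart(A, b, w, mats, offs, sizes, nq, nvar, opts)
    diagnostics.update({"method": "frank_wolfe", "restarts": n_starts})
    arg = _as_channel(bestKQ, p_t)
    diagnostics["specific_info_dominance"] = _specific_dominance(w, mats, bestKQ)
    mmi_cap = min(mutual_information(w, m) for m in mats)
    return MeasureResult("degradation", best, LOWER_BOUND, best, mmi_cap, arg, diagnostics)


def _enumerate_vertices(A, b, rank, w, mats, offs, nq):
    nvar = A.shape[1]
    best, bestKQ = -1.0, None
    n_vertices = 0
    for cols in itertools.combinations(range(nvar), rank):
        sub = A[:, cols]
        x_sub, _, rk, _ = np.linalg.lstsq(sub, b, rcond=None)
        if rk < rank:
            continue
        x = np.zeros(nvar)
        x[list(cols)] = x_sub
        if np.any(x < -1e-9) or np.max(np.abs(A @ x - b)) > 1e-8:
            continue
        n_vertices += 1
        KQ = _kq_from_x(np.clip(x, 0.0, None), mats, offs, nq)
        val = mutual_information(w, KQ)
        if val > best:
            best, bestKQ = val, KQ
    return best, bestKQ, n_vertices


def _frank_wolfe_multistart(A, b, w, mats, offs, sizes, nq, nvar, opts):
    rng = np.random.default_rng(opts.seed)
    starts = []
    # constant-Q starts: every KU(i) row equal to a fixed unit vector is feasible
    for q in range(nq):
        x = np.zeros(nvar)
        for i, s in enumerate(sizes):
            for r in range(s):
                x[offs[i] + r * nq + q] = 1.0
        starts.append(x)
    # source warm starts: KQ = K(j) whenever K(j) is a degradation of every
    # other source (find each KU(i) by a feasibility LP)
    for j, Kj in enumerate(mats):
        if Kj.shape[1] > nq:
            continue
        target = np.zeros((Kj.shape[0], nq))
        target[:, : Kj.shape[1]] = Kj
        x = np.zeros(nvar)
        ok = True
        for i, Ki in enumerate(mats):
            if i == j:
                KU = np.zeros((sizes[i], nq))
                KU[: min(sizes[i], nq), : min(sizes[i], nq)] = np.eye(min(sizes[i], nq))
                KU /= np.maximum(KU.sum(axis=1, keepdims=True), 1e-12)
            else:
                KU = _degradation_solve(target, Ki)
                if KU is None:
                    ok = False
                    break
            x[offs[i] : offs[i + 1]] = KU.ravel()
        if ok and np.max(np.abs(A @ x - b)) < 1e-6:
            starts.append(x)
    # random vertices from random-objective LPs
    n_random = max(opts.restarts - len(starts), 0)
    for _ in range(n_random):
        c = rng.standard_normal(nvar)
        res = linprog(-c, A_eq=A, b_eq=b, bounds=(0, None), method="highs")
        if res.success:
            starts.append(res.x)
    best, bestKQ = -1.0, None
    for x in starts:
        val, KQ = _frank_wolfe_ascent(x, A, b, w, mats, offs, nq, nvar)
        if val > best:
            best, bestKQ = val, KQ
    return best, bestKQ, len(starts)


def _degradation_solve(W: np.ndarray, V: np.ndarray, tol: float = 1e-8):
    """Row-stochastic KU with V @ KU ≈ W, or None (∞-norm residual LP)."""
    n_t, a = V.shape
    bdim = W.shape[1]
    nvar = a * bdim + 1
    c = np.zeros(nvar)
    c[-1] = 1.0
    A_eq = np.zeros((a, nvar))
    for r in range(a):
        A_eq[r, r * bdim : (r + 1) * bdim] = 1.0
    rows, rhs = [], []
    for t in range(n_t):
        for z in range(bdim):
            pos = np.zeros(nvar)
            for y in range(a):
                pos[y * bdim + z] = V[t, y]
            pos[-1] = -1.0
            rows.append(pos.copy())
            rhs.append(W[t, z])
            pos[:-1] *= -1.0
            rows.append(pos)
            rhs.append(-W[t, z])
    res = linprog(c, A_ub=np.array(rows), b_ub=np.array(rhs), A_eq=A_eq,
                  b_eq=np.ones(a), bounds=(0, None), method="highs")
    if res.success and res.x[-1] <= tol:
        KU = np.clip(res.x[:-1].reshape(a, bdim), 0.0, None)
        return KU / KU.sum(axis=1, keepdims=True)
    return None


def _frank_wolfe_ascent(x, A, b, w, mats, offs, nq, nvar, max_iter=60):
    val = mutual_information(w, _kq_from_x(x, mats, offs, nq))
    for _ in range(max_iter):
        KQ = _kq_from_x(x, mats, offs, nq)
        gKQ = _mi_grad_kq(w, KQ)
        grad = np.zeros(nvar)
        # objective depends on x only through KQ = K(0) @ KU(0)
        g0 = mats[0].T @ gKQ  # (|Y0|, nq)
        grad[offs[0] : offs[1]] = g0.ravel()
        res = linprog(-grad, A_eq=A, b_eq=b, bounds=(0, None), method="highs")
        if not res.success:
            break
        v = res.x
        new_val = mutual_information(w, _kq_from_x(v, mats, offs, nq))
        if new_val <= val + 1e-12:
            break
        x, val = v, new_val
    return val, _kq_from_x(x, mats, offs, nq)


def _specific_dominance(w, mats, KQ) -> dict:
    """Diagnostic: max over t of I(Q;T=t) − min_i I(Yi;T=t); ≤ ~0 expected
    for degradation solutions (every order here implies more-capable)."""
    p = SimplexPoint.from_weights(w)
    sq = np.array([s.value for s in specific_information(p, _as_channel(KQ, p))])
    per_source = np.array(
        [[s.value for s in specific_information(p, _as_channel(m, p))] for m in mats]
    )
    return {"max_excess": float(np.max(sq - per_source.min(axis=0)))}


# ---------------------------------------------------------------------------
# Sampled-constraint solvers (less-noisy, more-capable)
# ---------------------------------------------------------------------------


def _sample_points(dim: int, opts: SolverOptions) -> np.ndarray:
    grid = simplex_grid(dim, opts.grid_step)
    rng = np.random.default_rng(opts.seed)
    draws = rng.dirichlet(np.ones(dim), size=opts.n_dirichlet)
    return np.vstack([grid, draws])


class _RowGroups:
    """Union–find over the target alphabet: rows forced equal in KQ."""

    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, a: int) -> int:
        while self.parent[a] != a:
            self.parent[a] = self.parent[self.parent[a]]
            a = self.parent[a]
        return a

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)

    def groups(self) -> tuple[np.ndarray, int]:
        roots = sorted({self.find(i) for i in range(len(self.parent))})
        index = {r: k for k, r in enumerate(roots)}
        return np.array([index[self.find(i)] for i in range(len(self.parent))]), len(roots)


def _mi_batch_np(G: np.ndarray, rows: np.ndarray) -> np.ndarray:
    out = G @ rows
    with np.errstate(divide="ignore", invalid="ignore"):
        h_out = -np.sum(np.where(out > 0, out * np.log2(np.where(out > 0, out, 1.0)), 0.0), axis=1)
        h_rows = -np.sum(np.where(rows > 0, rows * np.log2(np.where(rows > 0, rows, 1.0)), 0.0), axis=1)
    return h_out - G @ h_rows


def _chi2_batch(P_out: np.ndarray, Q_out: np.ndarray, floor: float = 1e-12) -> np.ndarray:
    """χ²(P_out[k] ‖ Q_out[k]) per row, with zero denominators floored so the
    solver sees a large finite penalty instead of +inf."""
    num = (P_out - Q_out) ** 2
    den = np.maximum(Q_out, floor)
    terms = np.where((Q_out <= 0) & (num <= 1e-18), 0.0, num / den)
    return terms.sum(axis=1)


def _sampled_upper_bound(w, mats, nq, opts, kind: str):
    """Best local optimum of  max I(Q;T)  s.t. sampled '{kind}' constraints.

    kind == 'mc':  I(p; KQ) ≤ min_i I(p; K(i)) for sampled p.
    kind == 'ln':  χ²(pKQ‖qKQ) ≤ min_i χ²(pK(i)‖qK(i)) for sampled pairs.

    Constraints whose right-hand side is (numerically) zero are imposed
    structurally — they force rows of KQ to coincide — which both shrinks
    the search space and makes the zero constraints exact.  Of the remaining
    constraints only the tightest ``max_kept_constraints`` are kept.
    """
    n_t = w.size
    S = _sample_points(n_t, opts)
    groups = _RowGroups(n_t)
    lin_eqs: list[np.ndarray] = []  # extra (p − q) rows: (p − q) @ KQ = 0

    if kind == "mc":
        caps = np.min(np.stack([_mi_batch_np(S, m) for m in mats]), axis=0)
        zero = caps <= 1e-10
        for p in S[zero]:
            supp = np.flatnonzero(p > 1e-12)
            for a in supp[1:]:
                groups.union(int(supp[0]), int(a))
        keep = ~zero
        S_kept, caps_kept = S[keep], caps[keep]
        order = np.argsort(caps_kept)[: opts.max_kept_constraints]
        S_kept, caps_kept = S_kept[order], caps_kept[order]
        pairs = None
    else:
        # ordered pairs; cap their number before computing χ² right-hand sides
        m = S.shape[0]
        idx = np.array(list(itertools.permutations(range(m), 2)))
        outs = [S @ K for K in mats]
        caps_all = np.min(
            np.stack([_chi2_exact_pairs(o, idx) for o in outs]), axis=0
        )
        zero = caps_all <= 1e-10
        for a, bdx in idx[zero]:
            diff = S[a] - S[bdx]
            supp = np.flatnonzero(np.abs(diff) > 1e-12)
            if supp.size == 2 and abs(diff.sum()) < 1e-12:
                groups.union(int(supp[0]), int(supp[1]))
            elif supp.size > 0:
                lin_eqs.append(diff)
        finite = np.isfinite(caps_all) & ~zero
        idx_f, caps_f = idx[finite], caps_all[finite]
        order = np.argsort(caps_f)[: opts.max_kept_constraints]
        pairs = (S, idx_f[order])
        caps_kept = caps_f[order]
        S_kept = None

    gmap, g = groups.groups()
    # aggregate target weights and sampled points onto row groups
    M = np.zeros((n_t, g))
    M[np.arange(n_t), gmap] = 1.0
    w_g = w @ M
    lin_eq_g = [e @ M for e in lin_eqs]
    lin_eq_g = _dedupe_rows(lin_eq_g)

    def unpack(x):
        return x.reshape(g, nq)

    def objective(x):
        return -float(_mi_batch_np(w_g[None, :], unpack(x))[0])

    cons = [
        {"type": "eq", "fun": lambda x: unpack(x).sum(axis=1) - 1.0},
    ]
    for e in lin_eq_g:
        cons.append({"type": "eq", "fun": (lambda e: lambda x: e @ unpack(x))(e)})
    if kind == "mc" and S_kept is not None and len(S_kept) > 0:
        Sg = S_kept @ M
        cons.append({"type": "ineq", "fun": lambda x: caps_kept - _mi_batch_np(Sg, unpack(x))})
    if kind == "ln" and pairs is not None and len(caps_kept) > 0:
        S_all, idx_kept = pairs
        Sg_all = S_all @ M

        def ln_cons(x):
            out = Sg_all @ unpack(x)
            return caps_kept - _chi2_batch(out[idx_kept[:, 0]], out[idx_kept[:, 1]])

        cons.append({"type": "ineq", "fun": ln_cons})

    rng = np.random.default_rng(opts.seed + 1)
    starts = []
    for m in mats:  # source channels, rows averaged within groups, zero-padded
        K = np.zeros((g, nq))
        agg = (M.T / M.sum(axis=0)[:, None]) @ m
        K[:, : agg.shape[1]] = agg[:, :nq]
        K /= K.sum(axis=1, keepdims=True)
        starts.append(K.ravel())
    const = np.zeros((g, nq))
    const[:, 0] = 1.0
    starts.append(const.ravel())
    for _ in range(opts.sampled_restarts):
        starts.append(rng.dirichlet(np.ones(nq), size=g).ravel())

    best, bestK = 0.0, const
    for x0 in starts:
        res = minimize(
            objective,
            x0,
            method="SLSQP",
            bounds=[(0.0, 1.0)] * (g * nq),
            constraints=cons,
            options={"maxiter": opts.slsqp_maxiter, "ftol": 1e-12},
        )
        if not res.success and not np.isfinite(res.fun):
            continue
        x = np.clip(res.x, 0.0, None).reshape(g, nq)
        rs = x.sum(axis=1, keepdims=True)
        if np.any(rs <= 0):
            continue
        x = x / rs
        if _feasible(x, kind, caps_kept, S_kept @ M if kind == "mc" and S_kept is not None else None,
                     pairs, M, lin_eq_g):
            val = float(_mi_batch_np(w_g[None, :], x)[0])
            if val > best:
                best, bestK = val, x
    KQ_full = bestK[gmap]  # expand group rows back to the target alphabet
    return best, KQ_full, {"row_groups": int(g), "kept_constraints": int(len(caps_kept)),
                           "linear_equalities": len(lin_eq_g)}


def _feasible(x, kind, caps_kept, Sg, pairs, M, lin_eq_g, tol=1e-6):
    for e in lin_eq_g:
        if np.max(np.abs(e @ x)) > tol:
            return False
    if kind == "mc" and Sg is not None and len(caps_kept) > 0:
        return bool(np.all(_mi_batch_np(Sg, x) <= caps_kept + tol))
    if kind == "ln" and pairs is not None and len(caps_kept) > 0:
        S_all, idx_kept = pairs
        out = (S_all @ M) @ x
        return bool(np.all(_chi2_batch(out[idx_kept[:, 0]], out[idx_kept[:, 1]]) <= caps_kept + tol))
    return True


def _chi2_exact_pairs(out: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """χ² over ordered row pairs with the exact 0-conventions (+inf allowed)."""
    P, Q = out[idx[:, 0]], out[idx[:, 1]]
    num = (P - Q) ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(Q > 0, num / np.where(Q > 0, Q, 1.0), np.where(num > 1e-18, np.inf, 0.0))
    return terms.sum(axis=1)


def _dedupe_rows(rows: list[np.ndarray], limit: int = 50) -> list[np.ndarray]:
    seen, out = set(), []
    for r in rows:
        nrm = np.linalg.norm(r)
        if nrm < 1e-12:
            continue
        key = tuple(np.round(r / nrm * np.sign(r[np.flatnonzero(np.abs(r) > 1e-12)[0]]), 9))
        if key not in seen:
            seen.add(key)
            out.append(r)
        if len(out) >= limit:
            break
    return out


def _order_lower_bound(w, channels, mats, check) -> tuple[float, Optional[int]]:
    """Best I(T;Yj) over sources whose channel passes ``check`` against all
    other sources; 0 (the constant Q) if none does."""
    best, best_j = 0.0, None
    for j, Kj in enumerate(channels):
        ok = True
        for i, Ki in enumerate(channels):
            if i == j:
                continue
            if check(Kj, Ki):
                ok = False
                break
        if ok:
            val = mutual_information(w, mats[j])
            if val > best:
                best, best_j = val, j
    return best, best_j


def _det_lower(joint: Optional[JointDistribution]) -> float:
    """Deterministic-common-part lower bound: a Q that is a function of
    every source is below every source in all the orders used here."""
    if joint is None or joint.n_sources < 2:
        return 0.0
    return ii_deterministic(joint).value


def _bracketed_measure(name, p_t, channels, opts, kind, check, joint):
    w, mats = _check_channels(p_t, channels)
    chans = [K if isinstance(K, ChannelMatrix) else _as_channel(np.asarray(K, float), p_t)
             for K in channels]
    mmi_cap = min(mutual_information(w, m) for m in mats)
    lower, j = _order_lower_bound(w, chans, mats, check)
    det_lb = _det_lower(joint)
    lower = min(max(lower, det_lb), mmi_cap)
    diag = {"lower_bound_source": j, "deterministic_lower": det_lb,
            "seed": opts.seed, "mmi_cap": mmi_cap}
    arg = _as_channel(mats[j], p_t) if j is not None else None
    if mmi_cap - lower <= opts.collapse_tol:
        # the MMI cap already pins the value; the sampled solver cannot tighten it
        diag["sampled_optimum"] = None
        return _finalize(name, lower, mmi_cap, arg, diag, opts.collapse_tol)
    nq = _q_cap(mats, opts)
    ub, KQ, sdiag = _sampled_upper_bound(w, mats, nq, opts, kind=kind)
    diag.update(sdiag)
    diag["sampled_optimum"] = ub
    upper = min(max(ub, lower), mmi_cap)
    if arg is None:
        arg = _as_channel(KQ, p_t)
    return _finalize(name, lower, upper, arg, diag, opts.collapse_tol)


def ii_less_noisy(
    p_t,
    channels: Sequence[ChannelMatrix],
    opts: SolverOptions = SolverOptions(),
    joint: Optional[JointDistribution] = None,
) -> MeasureResult:
    """Less-noisy intersection information, as a bracket.

    Lower bound: the best certified-feasible Q — a source channel passing
    the less-noisy grid check against every other source, or the
    deterministic common part when the joint is supplied, else the constant
    channel (0).  Upper bound: the best local optimum of the
    χ²-sampled-constraint relaxation, clamped by the MMI cap.  The bracket
    collapses to EXACT when the endpoints agree within ``collapse_tol``.
    """
    return _bracketed_measure(
        "less_noisy", p_t, channels, opts, "ln",
        lambda Kj, Ki: less_noisy_check(Kj, Ki, opts.grid_step).violated, joint,
    )


def ii_more_capable(
    p_t,
    channels: Sequence[ChannelMatrix],
    opts: SolverOptions = SolverOptions(),
    joint: Optional[JointDistribution] = None,
) -> MeasureResult:
    """More-capable intersection information, as a bracket.

    Same bracket scheme as :func:`ii_less_noisy` with mutual-information
    sampled constraints I(p;KQ) ≤ min_i I(p;K(i)) in place of the χ²
    contraction constraints.
    """
    return _bracketed_measure(
        "more_capable", p_t, channels, opts, "mc",
        lambda Kj, Ki: more_capable_check(Kj, Ki, opts.grid_step).violated, joint,
    )


def ii_ds(
    p_t,
    channels: Sequence[ChannelMatrix],
    opts: SolverOptions = SolverOptions(),
    joint: Optional[JointDistribution] = None,
) -> MeasureResult:
    """Degradation/supermodularity intersection information, as a bracket.

    Lower bound: the largest of the degradation measure and the best
    I(T;Yj) among sources certified ``Yj ⪯ds Yi`` against every other
    source by the (sound) chain search.  Upper bound: the more-capable
    upper bound, since the ds order implies the more-capable order.  EXACT
    only when the endpoints meet.
    """
    w, mats = _check_channels(p_t, channels)
    chans = [K if isinstance(K, ChannelMatrix) else _as_channel(np.asarray(K, float), p_t)
             for K in channels]
    d_res = ii_degradation(p_t, channels, opts)
    lower, j = d_res.lower, None
    arg = d_res.argmax_channel
    for jj, Kj in enumerate(chans):
        if all(ds_check(Kj, Ki, tol=opts.degradation_tol).holds
               for i, Ki in enumerate(chans) if i != jj):
            val = mutual_information(w, mats[jj])
            if val > lower:
                lower, j, arg = val, jj, _as_channel(mats[jj], p_t)
    mc = ii_more_capable(p_t, channels, opts, joint=joint)
    upper = max(mc.upper, lower)
    diag = {"degradation_lower": d_res.lower, "ds_source": j,
            "more_capable_upper": mc.upper, "seed": opts.seed}
    return _finalize("ds", lower, upper, arg, diag, opts.collapse_tol)


# ---------------------------------------------------------------------------
# Deterministic (common-part) measures
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CommonPartLabeling:
    """Connected-component labels of the source co-occurrence graph.

    Outcomes of different sources are joined whenever they co-occur with
    positive probability; the component index is the maximal random variable
    Q that is a deterministic function of *every* source (the Gács–Körner
    common part).  ``labels[i]`` maps source i's outcomes to component ids;
    ``component_probs`` is the distribution of Q.
    """

    labels: tuple[dict, ...]
    component_probs: SimplexPoint
    source_indices: tuple[int, ...]

    @property
    def n_components(self) -> int:
        return len(self.component_probs)

    def q_of(self, outcome: tuple) -> int:
        """Component id for a full joint outcome tuple."""
        i = self.source_indices[0]
        return self.labels[0][outcome[i]]


def common_part_labeling(
    joint: JointDistribution, source_indices: Sequence[int] | None = None
) -> CommonPartLabeling:
    """Maximally-connected-component labeling of source outcomes.

    Build the n-partite graph whose vertices are (source, outcome) pairs,
    with an edge whenever two outcomes co-occur with positive probability;
    Q is the component index, a deterministic function of each source.
    """
    if source_indices is None:
        source_indices = tuple(range(1, joint.n_sources + 1))
    idx = tuple(source_indices)
    if len(idx) < 2:
        raise ChanpidError("INPUT_MISMATCH", "common part needs at least two sources")
    G = nx.Graph()
    for outcome, p in joint.prob.items():
        if p <= 0:
            continue
        nodes = [(i, outcome[i]) for i in idx]
        G.add_nodes_from(nodes)
        G.add_edges_from(zip(nodes, nodes[1:]))
    comp_of = {}
    comps = sorted(
        (sorted(c, key=lambda n: (n[0], str(n[1]))) for c in nx.connected_components(G)),
        key=lambda c: (c[0][0], str(c[0][1])),
    )
    for k, comp in enumerate(comps):
        for node in comp:
            comp_of[node] = k
    labels = tuple({y: comp_of[(i, y)] for (s, y) in comp_of if s == i} for i in idx)
    mass = np.zeros(len(comps))
    for outcome, p in joint.prob.items():
        if p > 0:
            mass[comp_of[(idx[0], outcome[idx[0]])]] += p
    return CommonPartLabeling(labels, SimplexPoint.from_weights(mass / mass.sum()), idx)


def gacs_korner(joint: JointDistribution, source_indices: Sequence[int] | None = None) -> float:
    """Gács–Körner common information C(Y1 ∧ Y2) in bits: the entropy of the
    component-label distribution of the co-occurrence graph."""
    return entropy(common_part_labeling(joint, source_indices).component_probs)


def ii_deterministic(
    joint: JointDistribution, source_indices: Sequence[int] | None = None
) -> MeasureResult:
    """Deterministic intersection information: max I(Q;T) over variables Q
    that are deterministic functions of every source.  The common-part
    labeling is the maximal such Q, so by data processing it is optimal;
    the result is exact.  With a single source the maximal Q is the source
    itself (self-redundancy)."""
    if source_indices is not None and len(tuple(source_indices)) == 1:
        (i,) = tuple(source_indices)
        p_t, K = channel_from_joint(joint, i)
        val = mutual_information(p_t, K)
        return MeasureResult("deterministic", val, EXACT, val, val, K,
                             {"n_components": K.rows.shape[1]})
    lab = common_part_labeling(joint, source_indices)
    # channel T -> Q from the joint
    p_t = joint.marginal([0])
    t_labels = [t for (t,) in sorted(p_t, key=lambda o: str(o[0])) if p_t[(t,)] > 0]
    row = {t: i for i, t in enumerate(t_labels)}
    K = np.zeros((len(t_labels), lab.n_components))
    for outcome, p in joint.prob.items():
        if p > 0 and outcome[0] in row:
            K[row[outcome[0]], lab.q_of(outcome)] += p
    w = np.array([p_t[(t,)] for t in t_labels])
    K /= K.sum(axis=1, keepdims=True)
    val = mutual_information(w / w.sum(), K)
    arg = ChannelMatrix(tuple(t_labels), tuple(range(lab.n_components)), K)
    return MeasureResult("deterministic", val, EXACT, val, val, arg,
                         {"n_components": lab.n_components})


# ---------------------------------------------------------------------------
# Bivariate PID assembly
# ---------------------------------------------------------------------------

MEASURES = {
    "d": "degradation",
    "ln": "less_noisy",
    "mc": "more_capable",
    "ds": "ds",
    "mmi": "mmi",
    "det": "deterministic",
}


@dataclass(frozen=True)
class PIDResult:
    """Bivariate decomposition I(T;(Y1,Y2)) = R + U1 + U2 + S.

    Each component is an :class:`Interval`; a bracketed redundancy measure
    propagates its interval to every component (midpoints are never taken).
    """

    measure_name: str
    redundancy: Interval
    unique1: Interval
    unique2: Interval
    synergy: Interval
    total: float
    bound_status: str

    @property
    def is_exact(self) -> bool:
        return self.bound_status == EXACT


def compute_measure(
    joint: JointDistribution,
    measure: str,
    opts: SolverOptions = SolverOptions(),
) -> MeasureResult:
    """Run one intersection-information measure on a joint distribution."""
    if measure not in MEASURES and measure not in MEASURES.values():
        raise ChanpidError("UNSUPPORTED_MEASURE", f"unknown measure {measure!r}")
    key = measure if measure in MEASURES else {v: k for k, v in MEASURES.items()}[measure]
    if key == "det":
        return ii_deterministic(joint)
    p_t, _ = channel_from_joint(joint, 1)
    channels = [channel_from_joint(joint, i)[1] for i in range(1, joint.n_sources + 1)]
    if key == "mmi":
        return ii_mmi(p_t, channels)
    if key == "d":
        return ii_degradation(p_t, channels, opts)
    fn = {"ln": ii_less_noisy, "mc": ii_more_capable, "ds": ii_ds}[key]
    return fn(p_t, channels, opts, joint=joint)


def pid_bivariate(
    joint: JointDistribution,
    measure: str = "d",
    opts: SolverOptions = SolverOptions(),
) -> PIDResult:
    """Bivariate PID: redundancy from the chosen measure, then
    U_i = I(T;Yi) − R and S = I(T;(Y1,Y2)) − R − U1 − U2."""
    if joint.n_sources != 2:
        raise ChanpidError("INPUT_MISMATCH", "bivariate PID needs exactly two sources")
    res = compute_measure(joint, measure, opts)
    p_t, K1 = channel_from_joint(joint, 1)
    _, K2 = channel_from_joint(joint, 2)
    _, K12 = tuple_channel(joint, [1, 2])
    i1 = mutual_information(p_t, K1)
    i2 = mutual_information(p_t, K2)
    i12 = mutual_information(p_t, K12)
    r_lo, r_hi = res.lower, min(res.upper, i1, i2)
    r_hi = max(r_hi, r_lo)
    clamp = lambda x: max(x, 0.0)
    return PIDResult(
        measure_name=res.measure,
        redundancy=Interval(clamp(r_lo), clamp(r_hi)),
        unique1=Interval(clamp(i1 - r_hi), clamp(i1 - r_lo)),
        unique2=Interval(clamp(i2 - r_hi), clamp(i2 - r_lo)),
        synergy=Interval(clamp(i12 - i1 - i2 + r_lo), clamp(i12 - i1 - i2 + r_hi)),
        total=i12,
        bound_status=res.bound_status,
    )
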
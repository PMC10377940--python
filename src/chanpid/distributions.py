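"""Discrete joint distributions, channels and Shannon information quantities.

A partial information decomposition (PID) problem is specified by a finite
joint distribution p(t, y1, ..., yn) over a *target* variable T and n
*source* variables Y1..Yn.  Everything downstream works with the equivalent
channel view: the target marginal p(t) (a point on the simplex over T's
alphabet) together with one row-stochastic channel matrix per source,
``K[t, y] = p(y | t)``.

All information quantities are in bits (log base 2).  Outcome labels are
ordered lexicographically everywhere so that matrices are reproducible
bit-for-bit across runs.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "ATOL",
    "INPUT_TOL",
    "ChanpidError",
    "JointDistribution",
    "SimplexPoint",
    "ChannelMatrix",
    "SpecificInfoVector",
    "joint_from_table",
    "read_joint_tsv",
    "write_joint_tsv",
    "read_channel_csv",
    "write_channel_csv",
    "channel_from_joint",
    "tuple_channel",
    "mutual_information",
    "entropy",
    "specific_information",
]

# Internal consistency tolerance; user-facing inputs are accepted up to
# INPUT_TOL deviation from normalization and then renormalized.
ATOL = 1e-9
INPUT_TOL = 1e-6


class ChanpidError(ValueError):
    """Validation error with a machine-readable code."""

    def __init__(self, code: str, message: str):
        self.code = code
        super().__init__(f"{code}: {message}")


def _sort_key(label):
    # Stable lexicographic order for heterogeneous labels: compare by
    # (type name, value) so ints sort among ints and tuples among tuples.
    if isinstance(label, tuple):
        return (1, tuple(_sort_key(x) for x in label))
    return (0, (type(label).__name__, label))


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SimplexPoint:
    """A probability vector over a finite alphabet (a point of the simplex)."""

    support_labels: tuple
    weights: np.ndarray

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "support_labels", tuple(self.support_labels))
        if w.ndim != 1 or len(self.support_labels) != w.size:
            raise ChanpidError("DIMENSION_MISMATCH", "labels and weights differ in length")
        if np.any(w < -ATOL):
            raise ChanpidError("NEGATIVE_PROB", "simplex point has a negative entry")
        if abs(w.sum() - 1.0) > INPUT_TOL:
            raise ChanpidError("SUM_FAR_FROM_ONE", f"weights sum to {w.sum()!r}")
        w = np.clip(w, 0.0, None)
        object.__setattr__(self, "weights", w / w.sum())

    @classmethod
    def from_weights(cls, weights: Sequence[float], labels: Sequence | None = None) -> "SimplexPoint":
        w = np.asarray(weights, dtype=float)
        if labels is None:
            labels = range(w.size)
        return cls(tuple(labels), w)

    def __len__(self) -> int:
        return self.weights.size


@dataclass(frozen=True)
class ChannelMatrix:
    """Row-stochastic conditional-probability matrix ``K[x, z] = p(z | x)``."""

    input_labels: tuple
    output_labels: tuple
    rows: np.ndarray

    def __post_init__(self):
        K = np.asarray(self.rows, dtype=float)
        object.__setattr__(self, "rows", K)
        object.__setattr__(self, "input_labels", tuple(self.input_labels))
        object.__setattr__(self, "output_labels", tuple(self.output_labels))
        if K.ndim != 2 or K.shape != (len(self.input_labels), len(self.output_labels)):
            raise ChanpidError("DIMENSION_MISMATCH", "matrix shape does not match labels")
        if np.any(K < -ATOL):
            raise ChanpidError("NEGATIVE_PROB", "channel has a negative entry")
        sums = K.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > INPUT_TOL):
            raise ChanpidError("SUM_FAR_FROM_ONE", f"row sums {sums!r} deviate from 1")
        K = np.clip(K, 0.0, None)
        object.__setattr__(self, "rows", K / K.sum(axis=1, keepdims=True))

    @classmethod
    def from_rows(cls, rows, input_labels=None, output_labels=None) -> "ChannelMatrix":
        K = np.asarray(rows, dtype=float)
        if input_labels is None:
            input_labels = range(K.shape[0])
        if output_labels is None:
            output_labels = range(K.shape[1])
        return cls(tuple(input_labels), tuple(output_labels), K)

    @property
    def shape(self) -> tuple[int, int]:
        return self.rows.shape

    def compose(self, other: "ChannelMatrix") -> "ChannelMatrix":
        """Cascade: output of ``self`` feeds ``other`` (matrix product)."""
        if self.rows.shape[1] != other.rows.shape[0]:
            raise ChanpidError("DIMENSION_MISMATCH", "inner alphabets differ")
        return ChannelMatrix(self.input_labels, other.output_labels, self.rows @ other.rows)


@dataclass(frozen=True)
class SpecificInfoVector:
    """Specific information I(Y; T=t) of one target outcome, in bits."""

    target_outcome: object
    value: float


@dataclass(frozen=True)
class JointDistribution:
    """Finite discrete joint probability table over (T, Y1, ..., Yn).

    The target variable is always the first variable.  ``prob`` maps full
    outcome tuples to probabilities; tuples absent from the map have
    probability zero.
    """

    variable_names: tuple[str, ...]
    alphabets: tuple[tuple, ...]
    prob: dict = field(repr=False)

    def __post_init__(self):
        object.__setattr__(self, "variable_names", tuple(self.variable_names))
        object.__setattr__(self, "alphabets", tuple(tuple(a) for a in self.alphabets))
        n = len(self.variable_names)
        if n != len(self.alphabets):
            raise ChanpidError("DIMENSION_MISMATCH", "one alphabet per variable required")
        total = 0.0
        for outcome, p in self.prob.items():
            if len(outcome) != n:
                raise ChanpidError("DIMENSION_MISMATCH", f"outcome {outcome!r} has wrong arity")
            if p < -ATOL:
                raise ChanpidError("NEGATIVE_PROB", f"p{outcome!r} = {p}")
            total += p
        if abs(total - 1.0) > ATOL:
            raise ChanpidError("SUM_FAR_FROM_ONE", f"probabilities sum to {total}")

    @property
    def n_sources(self) -> int:
        return len(self.variable_names) - 1

    def p(self, outcome: tuple) -> float:
        return self.prob.get(tuple(outcome), 0.0)

    def marginal(self, indices: Sequence[int]) -> dict:
        """Marginal probability table over the given variable indices."""
        out: dict = {}
        for outcome, p in self.prob.items():
            key = tuple(outcome[i] for i in indices)
            out[key] = out.get(key, 0.0) + p
        return out


# ---------------------------------------------------------------------------
# Construction and I/O
# ---------------------------------------------------------------------------


def joint_from_table(
    records: Iterable[tuple[tuple, float]],
    variable_names: Sequence[str] | None = None,
) -> JointDistribution:
    """Build a validated joint distribution from (outcome-tuple, probability) rows.

    Probabilities must be non-negative and sum to 1 within ``INPUT_TOL``
    (the table is renormalized); duplicate outcome tuples are rejected.
    """
    table: dict = {}
    for outcome, p in records:
        outcome = tuple(outcome)
        p = float(p)
        if p < 0:
            raise ChanpidError("NEGATIVE_PROB", f"p{outcome!r} = {p}")
        if outcome in table:
            raise ChanpidError("DUPLICATE_OUTCOME", f"outcome {outcome!r} listed twice")
        table[outcome] = p
    if not table:
        raise ChanpidError("SUM_FAR_FROM_ONE", "empty table")
    arities = {len(o) for o in table}
    if len(arities) != 1:
        raise ChanpidError("DIMENSION_MISMATCH", "outcome tuples of differing arity")
    total = sum(table.values())
    if abs(total - 1.0) > INPUT_TOL:
        raise ChanpidError("SUM_FAR_FROM_ONE", f"probabilities sum to {total}")
    table = {o: p / total for o, p in table.items()}
    nvar = arities.pop()
    if variable_names is None:
        variable_names = ("t",) + tuple(f"y{i}" for i in range(1, nvar))
    alphabets = tuple(
        tuple(sorted({o[i] for o in table}, key=_sort_key)) for i in range(nvar)
    )
    return JointDistribution(tuple(variable_names), alphabets, table)


def read_joint_tsv(path) -> JointDistribution:
    """Read the tab-separated joint table: header ``t  y1 ... yn  p``."""
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if not header or header[-1] != "p" or len(header) < 3:
            raise ChanpidError("BAD_FORMAT", f"{path}: expected header 't<TAB>y1...<TAB>p'")
        records = []
        for line in reader:
            if not line:
                continue
            if len(line) != len(header):
                raise ChanpidError("BAD_FORMAT", f"{path}: row {line!r} has wrong arity")
            outcome = tuple(_parse_label(v) for v in line[:-1])
            records.append((outcome, float(line[-1])))
    return joint_from_table(records, variable_names=tuple(header[:-1]))


def write_joint_tsv(joint: JointDistribution, path) -> None:
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(list(joint.variable_names) + ["p"])
        for outcome in sorted(joint.prob, key=lambda o: tuple(_sort_key(x) for x in o)):
            writer.writerow([_format_label(x) for x in outcome] + [repr(joint.prob[outcome])])


def _parse_label(text: str):
    try:
        return int(text)
    except ValueError:
        return text


def _format_label(label) -> str:
    if isinstance(label, tuple):
        return "(" + ",".join(_format_label(x) for x in label) + ")"
    return str(label)


def read_channel_csv(path) -> ChannelMatrix:
    """Read a channel from a plain CSV matrix plus an optional JSON sidecar.

    The sidecar ``<path>.json`` holds ``{"input_labels": [...],
    "output_labels": [...]}``; without it, labels default to row/column
    indices.
    """
    path = Path(path)
    rows = np.loadtxt(path, delimiter=",", dtype=float, ndmin=2)
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text(encoding="utf-8"))
        return ChannelMatrix(tuple(meta["input_labels"]), tuple(meta["output_labels"]), rows)
    return ChannelMatrix.from_rows(rows)


def write_channel_csv(K: ChannelMatrix, path) -> None:
    path = Path(path)
    np.savetxt(path, K.rows, delimiter=",", fmt="%.17g")
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(
        json.dumps({"input_labels": list(K.input_labels), "output_labels": list(K.output_labels)}),
        encoding="utf-8",
    )


# ---------------------------------------------------------------------------
# Channel extraction
# ---------------------------------------------------------------------------


def tuple_channel(
    joint: JointDistribution, source_indices: Sequence[int]
) -> tuple[SimplexPoint, ChannelMatrix]:
    """Target marginal and channel from T to the tuple (Y_i1, ..., Y_ik).

    Built directly from the joint, not from per-source channels, so it is
    exact even when the sources are dependent given T.  Target outcomes of
    zero probability are dropped from the channel input alphabet (every
    downstream measure is insensitive to zero-mass rows).
    """
    idx = tuple(source_indices)
    if len(idx) == 0:
        raise ChanpidError("DIMENSION_MISMATCH", "need at least one source index")
    if len(set(idx)) != len(idx):
        raise ChanpidError("DIMENSION_MISMATCH", f"duplicate source indices {idx!r}")
    for i in idx:
        if not (1 <= i <= joint.n_sources):
            raise ChanpidError("DIMENSION_MISMATCH", f"source index {i} out of range")

    p_t = joint.marginal([0])
    t_labels = [t for (t,) in sorted(p_t, key=lambda o: _sort_key(o[0])) if p_t[(t,)] > 0.0]
    if not t_labels:
        raise ChanpidError("EMPTY_SUPPORT", "target marginal is identically zero")

    if len(idx) == 1:
        y_alpha = list(joint.alphabets[idx[0]])
        key = lambda outcome: outcome[idx[0]]
    else:
        y_alpha = sorted(
            {tuple(o[i] for i in idx) for o in joint.prob},
            key=lambda t: tuple(_sort_key(x) for x in t),
        )
        key = lambda outcome: tuple(outcome[i] for i in idx)

    col = {y: j for j, y in enumerate(y_alpha)}
    row = {t: i for i, t in enumerate(t_labels)}
    K = np.zeros((len(t_labels), len(y_alpha)))
    for outcome, p in joint.prob.items():
        t = outcome[0]
        if t in row:
            K[row[t], col[key(outcome)]] += p
    weights = np.array([p_t[(t,)] for t in t_labels])
    K /= weights[:, None]
    return (
        SimplexPoint(tuple(t_labels), weights / weights.sum()),
        ChannelMatrix(tuple(t_labels), tuple(y_alpha), K),
    )


def channel_from_joint(
    joint: JointDistribution, source_index: int
) -> tuple[SimplexPoint, ChannelMatrix]:
    """Target marginal p(t) and the channel K(i) with K[t, y] = p(y_i | t)."""
    return tuple_channel(joint, [source_index])


# ---------------------------------------------------------------------------
# Information quantities (bits)
# ---------------------------------------------------------------------------


def entropy(p: SimplexPoint | Sequence[float]) -> float:
    """Shannon entropy in bits, with the 0·log 0 := 0 convention."""
    w = p.weights if isinstance(p, SimplexPoint) else np.asarray(p, dtype=float)
    w = w[w > 0]
    val = float(-(w * np.log2(w)).sum())
    return val if val > 0.0 else 0.0


def _as_weights_and_rows(p_t, K) -> tuple[np.ndarray, np.ndarray]:
    w = p_t.weights if isinstance(p_t, SimplexPoint) else np.asarray(p_t, dtype=float)
    rows = K.rows if isinstance(K, ChannelMatrix) else np.asarray(K, dtype=float)
    if w.size != rows.shape[0]:
        raise ChanpidError(
            "DIMENSION_MISMATCH", f"p(t) has {w.size} entries, channel has {rows.shape[0]} rows"
        )
    return w, rows


def mutual_information(p_t: SimplexPoint | Sequence[float], K: ChannelMatrix) -> float:
    """I(T; Y) in bits for target marginal p(t) and channel K[t, y] = p(y|t)."""
    w, rows = _as_weights_and_rows(p_t, K)
    joint = w[:, None] * rows
    py = joint.sum(axis=0)
    mask = joint > 0
    val = float(np.sum(joint[mask] * np.log2(joint[mask] / (w[:, None] * py[None, :])[mask])))
    return max(val, 0.0)


def specific_information(p_t: SimplexPoint, K: ChannelMatrix) -> list[SpecificInfoVector]:
    """Per-outcome specific information I(Y; T=t), Williams–Beer style.

    ``I(Y; T=t) = sum_y p(y|t) [log2 p(t|y) - log2 p(t)]``; its expectation
    under p(t) is the mutual information I(T; Y).
    """
    w, rows = _as_weights_and_rows(p_t, K)
    py = (w[:, None] * rows).sum(axis=0)
    out = []
    labels = p_t.support_labels if isinstance(p_t, SimplexPoint) else range(w.size)
    for i, t in enumerate(labels):
        acc = 0.0
        for j in range(rows.shape[1]):
            if rows[i, j] > 0 and w[i] > 0:
                post = w[i] * rows[i, j] / py[j]  # p(t|y)
                acc += rows[i, j] * (np.log2(post) - np.log2(w[i]))
        out.append(SpecificInfoVector(t, float(acc)))
    return out
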
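"""Pairwise-comparison (judgment) matrix mathematics for the analytic hierarchy process.

Implements Saaty's machinery from scratch: reciprocal-matrix validation,
priority derivation by the principal-eigenvector and normalized-column
methods, the consistency index/ratio, construction of perfectly consistent
matrices from weights, rounding of arbitrary positive judgments onto the
1-9 scale, and inverse fitting of a strict-Saaty matrix to a target
priority vector.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Literal, Sequence

import numpy as np

__all__ = [
    "SAATY_SCALE",
    "PairwiseMatrix",
    "PriorityVector",
    "ConsistencyReport",
    "Violation",
    "ConvergenceError",
    "StructuralError",
    "validate_matrix",
    "priority_eigenvector",
    "priority_column_normalization",
    "derive_priorities",
    "consistency",
    "consistent_matrix_from_weights",
    "round_to_saaty",
    "fit_saaty_matrix",
    "RANDOM_INDEX",
]

#: Admissible judgment values: 1/9 ... 1/2, 1, 2 ... 9 (17 values).
SAATY_SCALE: tuple[Fraction, ...] = tuple(
    sorted(
        {Fraction(1, k) for k in range(1, 10)} | {Fraction(k) for k in range(1, 10)}
    )
)

#: Saaty's random consistency index by matrix order.
RANDOM_INDEX: dict[int, float] = {
    1: 0.0, 2: 0.0, 3: 0.58, 4: 0.90, 5: 1.12,
    6: 1.24, 7: 1.32, 8: 1.41, 9: 1.45, 10: 1.49,
}

_RECIPROCITY_TOL = 1e-9


class StructuralError(ValueError):
    """Input is not a usable judgment matrix (non-square, bad labels, ...)."""


class ConvergenceError(RuntimeError):
    """Power iteration failed to converge; carries the last residual."""

    def __init__(self, message: str, residual: float):
        super().__init__(message)
        self.residual = residual


@dataclass(frozen=True)
class Violation:
    """One invariant violation found by :func:`validate_matrix`."""

    kind: Literal["positivity", "diagonal", "reciprocity", "saaty"]
    cell: tuple[int, int]
    message: str


@dataclass(frozen=True)
class PairwiseMatrix:
    """A square positive reciprocal matrix of judgments over labeled items.

    Parameters
    ----------
    labels
        Ordered item names, one per row/column.
    values
        The n x n array of judgments a_ij ("how much more important is
        item i than item j").
    """

    labels: tuple[str, ...]
    values: np.ndarray

    def __init__(self, labels: Sequence[str], values) -> None:
        arr = np.asarray(values, dtype=float)
        labels = tuple(str(x) for x in labels)
        if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
            raise StructuralError(f"judgment matrix must be square, got shape {arr.shape}")
        if arr.shape[0] < 2:
            raise StructuralError("judgment matrix needs at least 2 items")
        if len(labels) != arr.shape[0]:
            raise StructuralError(
                f"{len(labels)} labels for a {arr.shape[0]}x{arr.shape[0]} matrix"
            )
        if len(set(labels)) != len(labels):
            raise StructuralError("labels must be unique")
        arr = arr.copy()
        arr.flags.writeable = False
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "values", arr)

    @property
    def n(self) -> int:
        return len(self.labels)

    def __getitem__(self, ij: tuple[int, int]) -> float:
        return float(self.values[ij])


@dataclass(frozen=True)
class PriorityVector:
    """Labeled nonnegative weights summing to one."""

    labels: tuple[str, ...]
    weights: np.ndarray

    def __init__(self, labels: Sequence[str], weights) -> None:
        w = np.asarray(weights, dtype=float)
        labels = tuple(str(x) for x in labels)
        if w.ndim != 1 or len(labels) != w.size:
            raise StructuralError("labels and weights must have matching length")
        if np.any(w < 0):
            raise StructuralError("weights must be nonnegative")
        s = w.sum()
        if abs(s - 1.0) > _RECIPROCITY_TOL:
            raise StructuralError(f"weights must sum to 1, got {s!r}")
        w = w.copy()
        w.flags.writeable = False
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "weights", w)

    @classmethod
    def from_raw(cls, labels: Sequence[str], raw: Iterable[float]) -> "PriorityVector":
        """Normalize arbitrary positive weights to sum 1."""
        raw = np.asarray(list(raw), dtype=float)
        if np.any(raw <= 0):
            raise StructuralError("raw weights must be strictly positive")
        return cls(labels, raw / raw.sum())

    def __getitem__(self, label: str) -> float:
        return float(self.weights[self.labels.index(label)])

    def as_dict(self) -> dict[str, float]:
        return {lab: float(w) for lab, w in zip(self.labels, self.weights)}


@dataclass(frozen=True)
class ConsistencyReport:
    """Saaty consistency diagnostics for one judgment matrix."""

    lambda_max: float
    ci: float
    ri: float
    cr: float
    consistent: bool
    threshold: float = 0.1


def validate_matrix(m: PairwiseMatrix, strict_saaty: bool = False) -> list[Violation]:
    """Check the reciprocal-matrix invariants; return all violations found.

    An empty list means the matrix is a valid positive reciprocal matrix
    (and, with ``strict_saaty``, that every off-diagonal judgment lies on
    the 1-9 scale or its reciprocals).
    """
    a = m.values
    out: list[Violation] = []
    for i in range(m.n):
        for j in range(m.n):
            if not a[i, j] > 0:
                out.append(Violation("positivity", (i, j),
                                     f"entry ({i + 1},{j + 1}) = {a[i, j]} is not positive"))
    if any(v.kind == "positivity" for v in out):
        return out
    for i in range(m.n):
        if abs(a[i, i] - 1.0) > _RECIPROCITY_TOL:
            out.append(Violation("diagonal", (i, i),
                                 f"diagonal ({i + 1},{i + 1}) = {a[i, i]} != 1"))
    for i in range(m.n):
        for j in range(i + 1, m.n):
            if abs(a[i, j] * a[j, i] - 1.0) > _RECIPROCITY_TOL:
                out.append(Violation("reciprocity", (j, i),
                                     f"reciprocity broken at ({j + 1},{i + 1}): "
                                     f"a_ij*a_ji = {a[i, j] * a[j, i]:.6g}"))
    if strict_saaty:
        scale = np.array([float(s) for s in SAATY_SCALE])
        for i in range(m.n):
            for j in range(m.n):
                if i == j:
                    continue
                if np.min(np.abs(scale - a[i, j])) > _RECIPROCITY_TOL:
                    out.append(Violation("saaty", (i, j),
                                         f"entry ({i + 1},{j + 1}) = {a[i, j]:.6g} "
                                         "is not on the 1-9 scale"))
    return out


def _require_valid(m: PairwiseMatrix) -> None:
    bad = validate_matrix(m)
    if bad:
        raise StructuralError("invalid judgment matrix: " + "; ".join(v.message for v in bad))


def priority_eigenvector(
    m: PairwiseMatrix,
    tol: float = 1e-12,
    max_iter: int = 10_000,
) -> tuple[PriorityVector, float]:
    """Principal-eigenvector priorities (Saaty's canonical method).

    Power iteration on the positive matrix; Perron-Frobenius guarantees a
    simple dominant eigenvalue with a strictly positive eigenvector, so the
    iteration converges and the normalized vector is unique.

    Returns
    -------
    (priorities, lambda_max)
        Priorities normalized to sum 1, and the dominant eigenvalue.
    """
    _require_valid(m)
    a = m.values
    v = np.full(m.n, 1.0 / m.n)
    residual = np.inf
    for _ in range(max_iter):
        av = a @ v
        nxt = av / av.sum()
        residual = float(np.max(np.abs(nxt - v)))
        v = nxt
        if residual < tol:
            lam = float((a @ v).sum())  # v sums to 1, so sum(Av) = lambda
            return PriorityVector(m.labels, v), lam
    raise ConvergenceError(
        f"power iteration did not converge in {max_iter} iterations "
        f"(last residual {residual:.3e})", residual)


def priority_column_normalization(m: PairwiseMatrix) -> PriorityVector:
    """Normalized-column-average priorities.

    Each column is divided by its sum and the rows are averaged. Coincides
    with the eigenvector method exactly when the matrix is consistent.
    """
    _require_valid(m)
    cols = m.values / m.values.sum(axis=0, keepdims=True)
    w = cols.mean(axis=1)
    return PriorityVector(m.labels, w / w.sum())


def derive_priorities(
    m: PairwiseMatrix,
    method: Literal["eigenvector", "column_norm"] = "eigenvector",
) -> PriorityVector:
    """Dispatch between the two priority-derivation methods."""
    if method == "eigenvector":
        return priority_eigenvector(m)[0]
    if method == "column_norm":
        return priority_column_normalization(m)
    raise ValueError(f"unknown priority method {method!r}")


def consistency(m: PairwiseMatrix, threshold: float = 0.1) -> ConsistencyReport:
    """Saaty consistency check: CI = (lambda_max - n)/(n - 1), CR = CI/RI(n).

    CR below ``threshold`` (conventionally 0.1) is accepted. RI is tabulated
    for n <= 10; CR is defined as 0 where RI = 0 (n <= 2, always consistent).
    """
    if m.n > 10:
        raise ValueError(f"random index table covers n <= 10, got n = {m.n}")
    _, lam = priority_eigenvector(m)
    ci = (lam - m.n) / (m.n - 1)
    if -1e-9 < ci < 0:  # numerical negative zero on consistent matrices
        ci = 0.0
    ri = RANDOM_INDEX[m.n]
    cr = ci / ri if ri > 0 else 0.0
    return ConsistencyReport(lambda_max=lam, ci=ci, ri=ri, cr=cr,
                             consistent=cr < threshold, threshold=threshold)


def consistent_matrix_from_weights(w: PriorityVector) -> PairwiseMatrix:
    """Build the perfectly consistent matrix a_ij = w_i / w_j.

    Its principal eigenvector recovers ``w`` exactly and its consistency
    ratio is zero.
    """
    vec = w.weights
    if np.any(vec <= 0):
        raise ZeroDivisionError("all weights must be strictly positive to form ratios")
    return PairwiseMatrix(w.labels, np.outer(vec, 1.0 / vec))


def _nearest_saaty(x: float) -> Fraction:
    # ties broken toward the value nearer 1 (the less extreme judgment)
    best = min(SAATY_SCALE, key=lambda s: (abs(float(s) - x), abs(float(s) - 1.0)))
    return best


def round_to_saaty(m: PairwiseMatrix) -> PairwiseMatrix:
    """Snap every upper-triangle judgment to the nearest admissible Saaty value.

    The lower triangle is rebuilt by reciprocity and the diagonal set to 1,
    so the result is always a valid strict-Saaty reciprocal matrix.
    """
    _require_valid(m)
    out = np.eye(m.n)
    for i in range(m.n):
        for j in range(i + 1, m.n):
            s = _nearest_saaty(float(m.values[i, j]))
            out[i, j] = float(s)
            out[j, i] = float(1 / s)
    return PairwiseMatrix(m.labels, out)


def _residual(m: PairwiseMatrix, target: np.ndarray, method: str) -> float:
    return float(np.linalg.norm(derive_priorities(m, method).weights - target))


def fit_saaty_matrix(
    target: PriorityVector,
    method: Literal["eigenvector", "column_norm"] = "eigenvector",
    budget: int = 20_000,
) -> tuple[PairwiseMatrix, float]:
    """Find a strict-Saaty matrix whose derived priorities best match ``target``.

    The search minimizes the L2 distance between derived priorities and the
    target. It starts from the Saaty-rounded consistent matrix built from the
    target and refines by deterministic greedy single-cell moves (each
    upper-triangle cell tried against all 17 admissible values). For n = 3
    with ``budget`` >= 17^3 the upper triangle is enumerated exhaustively and
    the global optimum is returned.

    Returns the best matrix and its residual. The residual is zero only when
    the target is exactly representable, which printed real-world priorities
    usually are not.
    """
    n = len(target.labels)
    if n > 6:
        raise ValueError(f"fit_saaty_matrix supports n <= 6, got n = {n}")
    tvec = target.weights
    if np.any(tvec <= 0):
        raise StructuralError("target weights must be strictly positive")

    if n == 3 and budget >= len(SAATY_SCALE) ** 3:
        # seed with the rounded-consistent start so that residual ties
        # (e.g. a cyclic matrix that also yields the target) resolve toward
        # the consistent candidate
        best = round_to_saaty(consistent_matrix_from_weights(target))
        best_r = _residual(best, tvec, method)
        for a12, a13, a23 in itertools.product(SAATY_SCALE, repeat=3):
            cand = PairwiseMatrix(target.labels, [
                [1.0, float(a12), float(a13)],
                [float(1 / a12), 1.0, float(a23)],
                [float(1 / a13), float(1 / a23), 1.0],
            ])
            r = _residual(cand, tvec, method)
            if r < best_r - 1e-15:
                best, best_r = cand, r
        return best, best_r

    current = round_to_saaty(consistent_matrix_from_weights(target))
    current_r = _residual(current, tvec, method)
    evals = 1
    cells = [(i, j) for i in range(n) for j in range(i + 1, n)]
    improved = True
    while improved and evals < budget:
        improved = False
        for (i, j) in cells:
            for s in SAATY_SCALE:
                if evals >= budget:
                    break
                if abs(float(s) - current.values[i, j]) < 1e-15:
                    continue
                trial = current.values.copy()
                trial[i, j] = float(s)
                trial[j, i] = float(1 / s)
                cand = PairwiseMatrix(target.labels, trial)
                r = _residual(cand, tvec, method)
                evals += 1
                if r < current_r - 1e-12:
                    current, current_r = cand, r
                    improved = True
    return current, current_r
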
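"""Goal / criteria / alternatives hierarchy, design-space enumeration and synthesis.

A :class:`DecisionHierarchy` holds the criteria weights and, for each
criterion, a priority vector over its alternatives. Global scores are the
additive weighted synthesis standard in AHP:

    score(combination) = sum_c  w_c * p_c(choice_c)

so the top combination is always the tuple of per-criterion argmax
alternatives (additive separability). Hierarchies load from a YAML config
in which each criterion carries either a judgment matrix or explicit
priorities; priorities printed at coarse precision are accepted with a
rounding slack and renormalized.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, replace
from fractions import Fraction
from pathlib import Path
from typing import IO, Iterable, Literal, Sequence

import numpy as np
import yaml

from .matrix import (
    PairwiseMatrix,
    PriorityVector,
    derive_priorities,
    validate_matrix,
)

__all__ = [
    "Criterion",
    "DecisionHierarchy",
    "Combination",
    "ConfigError",
    "ScoringError",
    "load_hierarchy",
    "enumerate_design_space",
    "synthesize",
    "recommend",
    "ranking_rows",
]

#: Printed priorities may be rounded; accept sums off by up to this much.
SUM_SLACK = 0.005


class ConfigError(ValueError):
    """A hierarchy config is malformed; the message names the field."""


class ScoringError(KeyError):
    """A combination references an alternative unknown to its criterion."""


@dataclass(frozen=True)
class Criterion:
    """One decision criterion with its alternatives and their priorities.

    ``provenance`` records where the priorities came from: derived from a
    judgment ``matrix``, taken from ``printed`` values, or ``imputed``.
    ``imputed`` lists individual alternatives whose values were filled in
    (e.g. evenly sharing a leftover mass) rather than measured or elicited.
    """

    name: str
    alternatives: tuple[str, ...]
    priorities: PriorityVector
    provenance: Literal["matrix", "printed", "imputed"] = "printed"
    imputed: frozenset[str] = frozenset()
    matrix: PairwiseMatrix | None = None

    def __post_init__(self) -> None:
        if not self.alternatives:
            raise ConfigError(f"criterion {self.name!r}: no alternatives")
        if len(set(self.alternatives)) != len(self.alternatives):
            raise ConfigError(f"criterion {self.name!r}: duplicate alternatives")
        if self.priorities.labels != self.alternatives:
            raise ConfigError(
                f"criterion {self.name!r}: priority labels "
                f"{self.priorities.labels} do not match alternatives {self.alternatives}")


@dataclass(frozen=True)
class DecisionHierarchy:
    goal: str
    criteria: tuple[Criterion, ...]
    criteria_weights: PriorityVector
    method: Literal["eigenvector", "column_norm"] = "eigenvector"

    def __post_init__(self) -> None:
        if len(self.criteria) < 2:
            raise ConfigError("a hierarchy needs at least 2 criteria")
        names = tuple(c.name for c in self.criteria)
        if self.criteria_weights.labels != names:
            raise ConfigError(
                f"criteria_weights labels {self.criteria_weights.labels} "
                f"do not match criterion names {names}")

    def criterion(self, name: str) -> Criterion:
        for c in self.criteria:
            if c.name == name:
                return c
        raise KeyError(name)

    @property
    def design_space_size(self) -> int:
        n = 1
        for c in self.criteria:
            n *= len(c.alternatives)
        return n


@dataclass(frozen=True)
class Combination:
    """One choice of alternative per criterion, optionally scored."""

    choice: tuple[tuple[str, str], ...]  # ((criterion, alternative), ...) in order
    global_score: float | None = None

    def as_dict(self) -> dict[str, str]:
        return dict(self.choice)

    def __getitem__(self, criterion: str) -> str:
        return dict(self.choice)[criterion]


# ---------------------------------------------------------------------------
# config loading

def _parse_number(x) -> float:
    """Accept YAML numbers and fraction strings like '1/9'."""
    if isinstance(x, (int, float)):
        return float(x)
    if isinstance(x, str):
        try:
            return float(Fraction(x.strip()))
        except (ValueError, ZeroDivisionError) as e:
            raise ConfigError(f"cannot parse number {x!r}") from e
    raise ConfigError(f"cannot parse number {x!r}")


def _matrix_from_config(name: str, labels: Sequence[str], rows) -> PairwiseMatrix:
    n = len(labels)
    if len(rows) != n:
        raise ConfigError(f"criterion {name!r}: matrix has {len(rows)} rows for {n} alternatives")
    a = np.full((n, n), np.nan)
    for i, row in enumerate(rows):
        if len(row) != n:
            raise ConfigError(f"criterion {name!r}: matrix row {i + 1} has {len(row)} entries")
        for j, cell in enumerate(row):
            if cell is None:
                continue
            a[i, j] = _parse_number(cell)
    # lower triangle (and diagonal) may be omitted; fill by reciprocity
    for i in range(n):
        if np.isnan(a[i, i]):
            a[i, i] = 1.0
        for j in range(i + 1, n):
            if np.isnan(a[i, j]) and not np.isnan(a[j, i]):
                a[i, j] = 1.0 / a[j, i]
            if np.isnan(a[j, i]) and not np.isnan(a[i, j]):
                a[j, i] = 1.0 / a[i, j]
    if np.isnan(a).any():
        raise ConfigError(f"criterion {name!r}: matrix has unspecified cells")
    m = PairwiseMatrix(labels, a)
    bad = validate_matrix(m)
    if bad:
        raise ConfigError(f"criterion {name!r}: " + "; ".join(v.message for v in bad))
    return m


def _priorities_from_config(name: str, labels: Sequence[str], spec) -> PriorityVector:
    if isinstance(spec, dict):
        missing = [lab for lab in labels if lab not in spec]
        extra = [lab for lab in spec if lab not in labels]
        if missing or extra:
            raise ConfigError(
                f"criterion {name!r}: priorities labels mismatch "
                f"(missing {missing}, unexpected {extra})")
        vals = np.array([_parse_number(spec[lab]) for lab in labels])
    else:
        vals = np.array([_parse_number(v) for v in spec])
        if vals.size != len(labels):
            raise ConfigError(f"criterion {name!r}: {vals.size} priorities for {len(labels)} alternatives")
    if np.any(vals <= 0):
        raise ConfigError(f"criterion {name!r}: priorities must be positive")
    if abs(vals.sum() - 1.0) > SUM_SLACK:
        raise ConfigError(
            f"criterion {name!r}: priorities sum to {vals.sum():.4f}, "
            f"more than {SUM_SLACK} away from 1")
    return PriorityVector(labels, vals / vals.sum())


def load_hierarchy(
    source: str | Path | IO[str],
    method: Literal["eigenvector", "column_norm"] = "eigenvector",
) -> DecisionHierarchy:
    """Load a :class:`DecisionHierarchy` from a YAML config.

    The config declares ``goal``, ``criteria`` (each with ``name``,
    ``alternatives`` and either ``matrix`` or ``priorities``, optionally
    ``imputed`` labels) and ``criteria_weights`` (again a matrix or explicit
    priorities). Judgment matrices are validated and converted to priorities
    with ``method``; matrix lower triangles may be omitted and are rebuilt
    by reciprocity.
    """
    if hasattr(source, "read"):
        doc = yaml.safe_load(source)
    else:
        doc = yaml.safe_load(Path(source).read_text())
    if not isinstance(doc, dict):
        raise ConfigError("config root must be a mapping")
    try:
        goal = str(doc["goal"])
        crit_docs = doc["criteria"]
        cw_doc = doc["criteria_weights"]
    except KeyError as e:
        raise ConfigError(f"config missing required field {e.args[0]!r}") from None

    criteria: list[Criterion] = []
    for cd in crit_docs:
        name = cd.get("name")
        if not name:
            raise ConfigError("every criterion needs a name")
        alts = tuple(str(a) for a in cd.get("alternatives", ()))
        if not alts:
            raise ConfigError(f"criterion {name!r}: no alternatives")
        imputed = frozenset(str(x) for x in cd.get("imputed", ()))
        if not imputed <= set(alts):
            raise ConfigError(f"criterion {name!r}: imputed labels not among alternatives")
        if "matrix" in cd:
            m = _matrix_from_config(name, alts, cd["matrix"])
            pv = derive_priorities(m, method)
            prov = "matrix"
        elif "priorities" in cd:
            m = None
            pv = _priorities_from_config(name, alts, cd["priorities"])
            prov = "imputed" if imputed else "printed"
        else:
            raise ConfigError(f"criterion {name!r}: needs 'matrix' or 'priorities'")
        criteria.append(Criterion(name, alts, pv, prov, imputed, m))

    names = tuple(c.name for c in criteria)
    if isinstance(cw_doc, dict) and "matrix" in cw_doc:
        cw = derive_priorities(_matrix_from_config("criteria_weights", names, cw_doc["matrix"]), method)
    elif isinstance(cw_doc, dict) and "priorities" in cw_doc:
        cw = _priorities_from_config("criteria_weights", names, cw_doc["priorities"])
    else:
        cw = _priorities_from_config("criteria_weights", names, cw_doc)
    return DecisionHierarchy(goal, tuple(criteria), cw, method)


# ---------------------------------------------------------------------------
# enumeration and synthesis

def enumerate_design_space(h: DecisionHierarchy) -> list[Combination]:
    """Full-factorial enumeration of the condition space, unscored.

    Deterministic lexicographic order: criteria in declaration order, each
    cycling through its alternatives in declaration order.
    """
    names = [c.name for c in h.criteria]
    combos = []
    for picks in itertools.product(*(c.alternatives for c in h.criteria)):
        combos.append(Combination(tuple(zip(names, picks))))
    return combos


def _score(h: DecisionHierarchy, combo: Combination) -> float:
    total = 0.0
    for crit, w in zip(h.criteria, h.criteria_weights.weights):
        alt = combo[crit.name] if any(k == crit.name for k, _ in combo.choice) else None
        if alt is None:
            raise ScoringError(f"combination missing a choice for criterion {crit.name!r}")
        if alt not in crit.alternatives:
            raise ScoringError(f"criterion {crit.name!r} has no alternative {alt!r}")
        total += float(w) * crit.priorities[alt]
    return total


def synthesize(h: DecisionHierarchy, combos: Iterable[Combination]) -> list[Combination]:
    """Score combinations by additive weighted synthesis; sort descending.

    The sort is stable, so equal scores keep their enumeration order.
    """
    scored = [replace(c, global_score=_score(h, c)) for c in combos]
    return sorted(scored, key=lambda c: -c.global_score)


def recommend(h: DecisionHierarchy, k: int = 1) -> list[Combination]:
    """Top-k condition combinations over the full design space."""
    if k < 1:
        raise ValueError("k must be >= 1")
    ranked = synthesize(h, enumerate_design_space(h))
    if k > len(ranked):
        warnings.warn(
            f"k = {k} exceeds the design-space size {len(ranked)}; returning all",
            stacklevel=2)
        k = len(ranked)
    return ranked[:k]


def ranking_rows(h: DecisionHierarchy, ranked: Sequence[Combination]) -> list[dict]:
    """Flatten a ranking into CSV-ready rows (rank, one column per criterion, score)."""
    rows = []
    for rank, c in enumerate(ranked, start=1):
        row: dict = {"rank": rank}
        row.update(c.as_dict())
        row["score"] = c.global_score
        rows.append(row)
    return rows
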
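"""Equality/inequality constraint sets for informative hypotheses.

An informative hypothesis restricts a vector of model parameters
``gamma = (gamma_1, ..., gamma_G)`` with equality and order constraints,
e.g. ``mu_pos > mu_neu = mu_neg`` or ``g1 > 0 & g2 > 0``.  Constraints are
stored in matrix form: equality rows ``R_eq @ gamma == r_eq`` and
inequality rows with the convention ``R_in @ gamma > r_in``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

__all__ = ["ConstraintSet", "parse_hypothesis"]

_TOKEN = re.compile(r"\s*([<>=]|[^<>=&\s]+)\s*")
_NUMBER = re.compile(r"^[+-]?(\d+\.?\d*|\.\d+)([eE][+-]?\d+)?$")


@dataclass(frozen=True)
class ConstraintSet:
    """Matrix encoding of one informative hypothesis.

    Parameters
    ----------
    names
        Ordered parameter labels the rows refer to (length G).
    R_eq, r_eq
        Equality rows: ``R_eq @ gamma == r_eq`` (shape ``(q_e, G)``).
    R_in, r_in
        Inequality rows: ``R_in @ gamma > r_in`` (shape ``(q_in, G)``).
    """

    names: tuple[str, ...]
    R_eq: np.ndarray
    r_eq: np.ndarray
    R_in: np.ndarray
    r_in: np.ndarray
    expression: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        G = len(self.names)
        R_eq = np.atleast_2d(np.asarray(self.R_eq, dtype=float)).reshape(-1, G)
        R_in = np.atleast_2d(np.asarray(self.R_in, dtype=float)).reshape(-1, G)
        r_eq = np.asarray(self.r_eq, dtype=float).reshape(-1)
        r_in = np.asarray(self.r_in, dtype=float).reshape(-1)
        if R_eq.shape[0] != r_eq.size or R_in.shape[0] != r_in.size:
            raise ValueError("constraint matrix/vector shapes disagree")
        if R_eq.shape[0] + R_in.shape[0] < 1:
            raise ValueError("a hypothesis needs at least one constraint row")
        object.__setattr__(self, "R_eq", R_eq)
        object.__setattr__(self, "R_in", R_in)
        object.__setattr__(self, "r_eq", r_eq)
        object.__setattr__(self, "r_in", r_in)

    @property
    def q_e(self) -> int:
        return self.R_eq.shape[0]

    @property
    def q_in(self) -> int:
        return self.R_in.shape[0]

    @property
    def G(self) -> int:
        return len(self.names)

    @property
    def J(self) -> int:
        """Number of independent constraint rows (rank of the stacked matrix)."""
        stacked = np.vstack([self.R_eq, self.R_in])
        return int(np.linalg.matrix_rank(stacked))

    @property
    def equality_only(self) -> bool:
        return self.q_in == 0

    @property
    def has_equalities(self) -> bool:
        return self.q_e > 0


def _parse_clause(clause: str, names: list[str]):
    """Split one '&'-free clause into (term, op, term, op, term, ...)."""
    tokens = []
    pos = 0
    while pos < len(clause):
        m = _TOKEN.match(clause, pos)
        if m is None:  # pragma: no cover - regex consumes everything
            raise ValueError(f"cannot tokenize {clause!r}")
        tokens.append(m.group(1))
        pos = m.end()
    if not tokens:
        raise ValueError("empty constraint clause")
    if len(tokens) < 3 or len(tokens) % 2 == 0:
        raise ValueError(f"malformed constraint clause {clause!r}")
    terms, ops = tokens[0::2], tokens[1::2]
    if any(op not in "<>=" for op in ops):
        raise ValueError(f"malformed constraint clause {clause!r}")
    G = len(names)
    rows = []
    for left, op, right in zip(terms, ops, terms[1:]):
        coef = np.zeros(G)
        const = 0.0
        for term, sign in ((left, 1.0), (right, -1.0)):
            if _NUMBER.match(term):
                const -= sign * float(term)
            elif term in names:
                coef[names.index(term)] += sign
            else:
                raise ValueError(f"unknown parameter label {term!r}")
        if op == "<":
            coef, const = -coef, -const
        if not np.any(coef):
            raise ValueError(f"constraint {left}{op}{right} references no parameter")
        rows.append((op == "=", coef, const))
    return rows


def parse_hypothesis(text: str, names: list[str] | tuple[str, ...]) -> ConstraintSet:
    """Parse a constraint expression into a :class:`ConstraintSet`.

    The grammar accepts parameter labels, numeric literals, the operators
    ``>``, ``<``, ``=``, chained comparisons (``a > b > c`` expands to the
    pairwise rows ``a-b>0`` and ``b-c>0``) and conjunction with ``&``.
    ``<`` rows are negated into the ``>`` convention.

    Raises
    ------
    ValueError
        On unknown labels, empty expressions, or contradictory duplicate
        rows (e.g. ``a>b & b>a``).
    """
    names = list(names)
    if len(set(names)) != len(names):
        raise ValueError("duplicate parameter labels")
    if not text or not text.strip():
        raise ValueError("empty hypothesis expression")
    eq_rows, in_rows = [], []
    for clause in text.split("&"):
        if not clause.strip():
            raise ValueError(f"empty clause in {text!r}")
        for is_eq, coef, const in _parse_clause(clause.strip(), names):
            (eq_rows if is_eq else in_rows).append((coef, const))

    def dedup(rows):
        out = []
        for coef, const in rows:
            if not any(np.allclose(coef, c) and np.isclose(const, r) for c, r in out):
                out.append((coef, const))
        return out

    eq_rows = dedup(eq_rows)
    # equality rows are sign-symmetric: a=b duplicates b=a
    kept = []
    for coef, const in eq_rows:
        if not any(np.allclose(-coef, c) and np.isclose(-const, r) for c, r in kept):
            kept.append((coef, const))
    eq_rows = kept
    in_rows = dedup(in_rows)
    for coef, const in in_rows:
        if any(np.allclose(-coef, c) and np.isclose(-const, r) for c, r in in_rows):
            raise ValueError(f"contradictory inequality rows in {text!r}")

    G = len(names)
    R_eq = np.array([c for c, _ in eq_rows], dtype=float).reshape(-1, G)
    r_eq = np.array([r for _, r in eq_rows], dtype=float)
    R_in = np.array([c for c, _ in in_rows], dtype=float).reshape(-1, G)
    r_in = np.array([r for _, r in in_rows], dtype=float)
    return ConstraintSet(tuple(names), R_eq, r_eq, R_in, r_in, expression=text.strip())
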
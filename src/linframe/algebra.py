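"""Manifestly positive polynomial algebra over edge-label symbols.

The value domain of every spanning-forest sum in this package is a
*manifestly positive* polynomial: a sum of monomials, each a product of
parameter symbols with a positive integer coefficient.  Ratios of two such
polynomials (never auto-cancelled, so that each monomial still corresponds
to a spanning forest) represent steady-state probabilities, first-passage
time moments and splitting probabilities.

Atoms are plain strings.  Three kinds are understood at evaluation time:

* parameter symbols (``k1``, ``x``, ``on_rate``) — looked up in the
  assignment;
* positive decimal literals (``2.5``) — numeric edge labels, carried as
  atoms so polynomial coefficients stay positive integers;
* formal ratios (``q2/p3``) — used by the pipeline-kinetics expansion,
  resolved as the quotient of the two component values.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Union

__all__ = [
    "Monomial",
    "PositivePolynomial",
    "RationalFunction",
    "UnassignedSymbolError",
    "evaluate_atom",
]

_LITERAL_RE = re.compile(r"^\d+(\.\d+)?([eE][+-]?\d+)?$")


class UnassignedSymbolError(KeyError):
    """A symbol appearing in a polynomial has no value in the assignment."""


def evaluate_atom(atom: str, assignment: Mapping[str, float]) -> float:
    """Resolve one atom to a positive real under *assignment*."""
    if atom in assignment:
        value = float(assignment[atom])
    elif "/" in atom:
        num, den = atom.split("/", 1)
        return evaluate_atom(num, assignment) / evaluate_atom(den, assignment)
    elif "*" in atom:
        value = 1.0
        for part in atom.split("*"):
            value *= evaluate_atom(part, assignment)
        return value
    elif _LITERAL_RE.match(atom):
        value = float(atom)
    else:
        raise UnassignedSymbolError(f"unassigned symbol: {atom!r}")
    if not value > 0:
        raise ValueError(f"labels must be positive: {atom} = {value}")
    return value


def _key(atoms: Iterable[str]) -> tuple[str, ...]:
    return tuple(sorted(atoms))


@dataclass(frozen=True)
class Monomial:
    """A product of symbols with a positive integer coefficient."""

    atoms: tuple[str, ...]
    coefficient: int = 1

    def __post_init__(self) -> None:
        if self.coefficient < 1:
            raise ValueError("monomial coefficient must be a positive integer")
        object.__setattr__(self, "atoms", _key(self.atoms))

    @classmethod
    def one(cls) -> "Monomial":
        return cls((), 1)

    def __mul__(self, other: "Monomial") -> "Monomial":
        return Monomial(self.atoms + other.atoms, self.coefficient * other.coefficient)

    def evaluate(self, assignment: Mapping[str, float]) -> float:
        value = float(self.coefficient)
        for atom in self.atoms:
            value *= evaluate_atom(atom, assignment)
        return value

    def __str__(self) -> str:
        parts = list(self.atoms)
        if self.coefficient != 1 or not parts:
            parts = [str(self.coefficient)] + parts
        return "*".join(parts)


class PositivePolynomial:
    """Sum of monomials, all with positive integer coefficients.

    The zero polynomial is the empty term map and is distinct from the
    constant 1 (one term, no atoms).
    """

    __slots__ = ("_terms",)

    def __init__(self, terms: Mapping[tuple[str, ...], int] | None = None):
        cleaned: dict[tuple[str, ...], int] = {}
        for atoms, coeff in (terms or {}).items():
            if coeff == 0:
                continue
            if coeff < 0:
                raise ValueError("manifest positivity violated: negative coefficient")
            cleaned[_key(atoms)] = cleaned.get(_key(atoms), 0) + coeff
        self._terms = cleaned

    # -- constructors -------------------------------------------------
    @classmethod
    def zero(cls) -> "PositivePolynomial":
        return cls()

    @classmethod
    def one(cls) -> "PositivePolynomial":
        return cls({(): 1})

    @classmethod
    def from_monomial(cls, m: Monomial) -> "PositivePolynomial":
        return cls({m.atoms: m.coefficient})

    @classmethod
    def from_atoms(cls, atoms: Iterable[str]) -> "PositivePolynomial":
        return cls({_key(atoms): 1})

    # -- inspection ---------------------------------------------------
    @property
    def terms(self) -> dict[tuple[str, ...], int]:
        return dict(self._terms)

    def monomials(self) -> list[Monomial]:
        return [Monomial(a, c) for a, c in sorted(self._terms.items())]

    @property
    def is_zero(self) -> bool:
        return not self._terms

    def num_terms(self) -> int:
        return len(self._terms)

    def atoms(self) -> set[str]:
        out: set[str] = set()
        for key in self._terms:
            out.update(key)
        return out

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PositivePolynomial):
            return NotImplemented
        return self._terms == other._terms

    def __hash__(self) -> int:
        return hash(frozenset(self._terms.items()))

    # -- arithmetic ---------------------------------------------------
    def __add__(self, other: "PositivePolynomial") -> "PositivePolynomial":
        acc = Counter(self._terms)
        acc.update(other._terms)
        return PositivePolynomial(acc)

    def __mul__(self, other: Union["PositivePolynomial", int]) -> "PositivePolynomial":
        if isinstance(other, int):
            if other == 0:
                return PositivePolynomial.zero()
            return PositivePolynomial({a: c * other for a, c in self._terms.items()})
        acc: Counter = Counter()
        for a1, c1 in self._terms.items():
            for a2, c2 in other._terms.items():
                acc[_key(a1 + a2)] += c1 * c2
        return PositivePolynomial(acc)

    __rmul__ = __mul__

    def __pow__(self, k: int) -> "PositivePolynomial":
        if k < 0:
            raise ValueError("negative powers are not polynomials")
        out = PositivePolynomial.one()
        for _ in range(k):
            out = out * self
        return out

    # -- evaluation & printing ----------------------------------------
    def evaluate(self, assignment: Mapping[str, float]) -> float:
        total = 0.0
        for atoms, coeff in self._terms.items():
            value = float(coeff)
            for atom in atoms:
                value *= evaluate_atom(atom, assignment)
            total += value
        return total

    def __str__(self) -> str:
        if not self._terms:
            return "0"
        return " + ".join(str(m) for m in self.monomials())

    def __repr__(self) -> str:
        return f"PositivePolynomial({self})"


@dataclass(frozen=True)
class RationalFunction:
    """Ordered (numerator, denominator) pair of manifestly positive polynomials.

    Never auto-cancelled: each monomial keeps its one-to-one correspondence
    with a spanning forest of the underlying graph.
    """

    numerator: PositivePolynomial
    denominator: PositivePolynomial

    def __post_init__(self) -> None:
        if self.denominator.is_zero:
            raise ZeroDivisionError("denominator is the zero polynomial")

    def evaluate(self, assignment: Mapping[str, float]) -> float:
        den = self.denominator.evaluate(assignment)
        assert den > 0, "positive assignment cannot zero a manifestly positive denominator"
        return self.numerator.evaluate(assignment) / den

    def __mul__(self, other: "RationalFunction") -> "RationalFunction":
        return RationalFunction(
            self.numerator * other.numerator, self.denominator * other.denominator
        )

    def __add__(self, other: "RationalFunction") -> "RationalFunction":
        return RationalFunction(
            self.numerator * other.denominator + other.numerator * self.denominator,
            self.denominator * other.denominator,
        )

    def __str__(self) -> str:
        return f"({self.numerator}) / ({self.denominator})"
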
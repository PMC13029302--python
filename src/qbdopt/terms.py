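"""Monomial term sets for the response-surface polynomials.

A term is a vector of non-negative integer exponents, one per factor;
the intercept is the all-zero vector.  The study's published models use
bespoke term sets that mix quadratic and cubic cross terms (e.g. F1^2*F2),
so term sets are explicit rather than generated from a degree bound.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np


def _term_name(exponents: tuple, factor_names: Sequence[str]) -> str:
    parts = []
    for e, name in zip(exponents, factor_names):
        if e == 1:
            parts.append(name)
        elif e > 1:
            parts.append(f"{name}^{e}")
    return "*".join(parts) if parts else "1"


@dataclass(frozen=True)
class TermSet:
    """Ordered set of monomials over a fixed list of factors."""

    exponents: tuple  # tuple of exponent tuples
    factor_names: tuple = ("F1", "F2", "F3", "F4")

    def __post_init__(self) -> None:
        if not self.exponents:
            raise ValueError("term set must be non-empty")
        seen = set()
        for t in self.exponents:
            if len(t) != len(self.factor_names):
                raise ValueError(f"term {t} does not match factor count")
            if any(e < 0 for e in t):
                raise ValueError(f"term {t} has a negative exponent")
            if t in seen:
                raise ValueError(f"duplicate monomial {t}")
            seen.add(t)

    def __len__(self) -> int:
        return len(self.exponents)

    def __contains__(self, t) -> bool:
        return tuple(t) in self.exponents

    @property
    def names(self) -> list:
        return [_term_name(t, self.factor_names) for t in self.exponents]

    def design_matrix(self, coded: np.ndarray) -> np.ndarray:
        """Evaluate every monomial at each row of `coded` (n x factors)."""
        coded = np.asarray(coded, dtype=float)
        if coded.ndim == 1:
            coded = coded[None, :]
        if coded.shape[-1] != len(self.factor_names):
            raise ValueError(
                f"points have {coded.shape[-1]} coordinates, "
                f"term set expects {len(self.factor_names)}"
            )
        cols = [np.prod(coded ** np.asarray(t, dtype=float), axis=-1) for t in self.exponents]
        return np.stack(cols, axis=-1)


def make_term_set(exponents: Iterable[Sequence[int]],
                  factor_names: Sequence[str] = ("F1", "F2", "F3", "F4")) -> TermSet:
    return TermSet(tuple(tuple(int(e) for e in t) for t in exponents), tuple(factor_names))


def ar_terms() -> TermSet:
    """Angle-of-repose (z1) model: 13 terms incl. cubic cross terms."""
    return make_term_set([
        (0, 0, 0, 0),
        (1, 0, 0, 0), (0, 1, 0, 0), (0, 0, 1, 0), (0, 0, 0, 1),
        (2, 0, 0, 0), (0, 0, 2, 0), (0, 0, 0, 2),
        (1, 2, 0, 0), (2, 1, 0, 0), (1, 0, 2, 0), (2, 0, 1, 0), (0, 0, 2, 1),
    ])


def be_terms() -> TermSet:
    """Blending-efficiency (z2) model: 14 terms incl. two-way and cubic cross terms."""
    return make_term_set([
        (0, 0, 0, 0),
        (1, 0, 0, 0), (0, 1, 0, 0), (0, 0, 1, 0), (0, 0, 0, 1),
        (1, 0, 1, 0), (0, 1, 1, 0), (1, 0, 0, 1), (0, 0, 1, 1),
        (0, 0, 2, 0), (0, 0, 0, 2),
        (0, 2, 1, 0), (2, 0, 0, 1), (0, 2, 0, 1),
    ])


def cr_terms() -> TermSet:
    """Drug-recovery (z3) model: intercept, F1, F3, F4 linear plus F1^2, F3^2."""
    return make_term_set([
        (0, 0, 0, 0),
        (1, 0, 0, 0), (0, 0, 1, 0), (0, 0, 0, 1),
        (2, 0, 0, 0), (0, 0, 2, 0),
    ])


CANONICAL_TERM_SETS = {"ar": ar_terms, "be": be_terms, "cr": cr_terms}
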
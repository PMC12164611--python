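"""Aitchison-geometry primitives for D-part compositions.

A composition carries only relative information: a day split into
sedentary time (SED), light/moderate/vigorous physical activity
(LPA/MPA/VPA) and sleep is a point on the 4-simplex once closed to the
1440 minutes of a day.  This module provides the closure operation,
zero replacement, the centred and isometric log-ratio transforms with
pivot (sequential-binary-partition) bases, compositional centres
(geometric-mean compositions) and the pairwise log-ratio variation
matrix.  Everything is generic in the number of parts D; the movement
pipeline uses D = 5 with the canonical part order below.

All logarithms are natural.  Sample variances use the n-1 denominator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

#: Canonical behaviour order used by every table and basis in the pipeline.
PARTS: tuple[str, ...] = ("SED", "LPA", "MPA", "VPA", "Sleep")

#: Minutes in a day; the closure constant for daily compositions.
DAY_MINUTES: float = 1440.0

#: Relative tolerance for the closure invariant.
CLOSURE_RTOL: float = 1e-6


class ZeroPartError(ValueError):
    """A part is non-positive where strict positivity is required."""


class PartMismatchError(ValueError):
    """Part labels of two compositional objects do not agree."""


def _as_array(values: Iterable[float]) -> np.ndarray:
    arr = np.asarray(list(values) if not isinstance(values, np.ndarray) else values,
                     dtype=float)
    if arr.ndim != 1 or arr.size == 0:
        raise ValueError("values must be a non-empty 1-D sequence")
    return arr


@dataclass(frozen=True)
class Composition:
    """A closed D-part composition of durations.

    Parameters
    ----------
    values : ndarray of shape (D,)
        Strictly positive part durations in minutes, summing to ``total``.
    parts : tuple of str
        Ordered, unique part labels.
    total : float
        Closure constant in minutes (1440 for a day).
    """

    values: np.ndarray
    parts: tuple[str, ...] = PARTS
    total: float = DAY_MINUTES

    def __post_init__(self) -> None:
        values = _as_array(self.values)
        object.__setattr__(self, "values", values)
        parts = tuple(self.parts)
        object.__setattr__(self, "parts", parts)
        if len(parts) != values.size:
            raise ValueError(f"{len(parts)} labels for {values.size} values")
        if len(set(parts)) != len(parts):
            raise ValueError("part labels must be unique")
        if np.any(values <= 0):
            raise ZeroPartError("all parts must be strictly positive; "
                                "apply zero_replace first")
        if not np.isclose(values.sum(), self.total, rtol=CLOSURE_RTOL):
            raise ValueError(
                f"values sum to {values.sum():.6f}, expected {self.total}")

    def __getitem__(self, part: str) -> float:
        return float(self.values[self.parts.index(part)])

    def proportions(self) -> np.ndarray:
        """Parts as fractions of the total (sum to 1)."""
        return self.values / self.total

    def percent_of_day(self) -> np.ndarray:
        """Parts as percentages of the total (sum to 100)."""
        return 100.0 * self.values / self.total

    def replace(self, **minutes: float) -> "Composition":
        """Return a copy with named parts set to new values, re-closed."""
        values = self.values.copy()
        for part, v in minutes.items():
            values[self.parts.index(part)] = v
        return close(values, self.total, parts=self.parts)


def close(values: Iterable[float], total: float = DAY_MINUTES,
          parts: Sequence[str] = PARTS) -> Composition:
    """Close a positive vector so its parts sum to ``total``.

    Returns the composition proportional to ``values`` with the required
    sum.  Idempotent: closing a closed composition changes nothing.
    """
    arr = _as_array(values)
    if total <= 0:
        raise ValueError("total must be positive")
    if np.any(arr <= 0):
        raise ZeroPartError("cannot close a vector with non-positive parts")
    return Composition(arr * (total / arr.sum()), tuple(parts), float(total))


def zero_replace(values: Iterable[float], strategy: str = "fixed_floor",
                 floor: float = 0.5) -> np.ndarray:
    """Replace zeros in a non-negative vector with a small positive floor.

    Strategies
    ----------
    ``fixed_floor``
        Zeros become ``floor``; other parts untouched (the vector sum
        grows slightly; callers re-close afterwards).
    ``multiplicative``
        Zeros become ``floor`` and the non-zero parts are shrunk by the
        factor ``1 - floor * n_zeros / sum(values)`` so the original
        total is preserved exactly.

    Order of parts is preserved.  Raises on all-zero input.
    """
    arr = _as_array(values)
    if np.any(arr < 0):
        raise ValueError("values must be non-negative")
    if not np.any(arr > 0):
        raise ZeroPartError("all-zero vector cannot be zero-replaced")
    zeros = arr == 0
    if not zeros.any():
        return arr.copy()
    if floor <= 0:
        raise ValueError("floor must be positive")
    out = arr.astype(float).copy()
    if strategy == "fixed_floor":
        out[zeros] = floor
    elif strategy == "multiplicative":
        total = arr.sum()
        out[~zeros] *= 1.0 - floor * zeros.sum() / total
        out[zeros] = floor
        if np.any(out <= 0):
            raise ValueError("floor too large for multiplicative replacement")
    else:
        raise ValueError(f"unknown strategy {strategy!r}")
    return out


@dataclass(frozen=True)
class IlrBasis:
    """An orthonormal isometric log-ratio basis for D parts.

    ``contrast_matrix`` has shape (D-1, D); its rows are orthonormal
    zero-sum contrasts, so ``ilr(x) = contrast_matrix @ clr(x)``.
    """

    part_order: tuple[str, ...]
    contrast_matrix: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        V = np.asarray(self.contrast_matrix, dtype=float)
        object.__setattr__(self, "contrast_matrix", V)
        D = len(self.part_order)
        if V.shape != (D - 1, D):
            raise ValueError(f"contrast matrix must be {(D - 1, D)}, got {V.shape}")
        if not np.allclose(V @ V.T, np.eye(D - 1), atol=1e-10):
            raise ValueError("contrast rows are not orthonormal")
        if not np.allclose(V.sum(axis=1), 0.0, atol=1e-10):
            raise ValueError("contrast rows must sum to zero")

    @property
    def n_parts(self) -> int:
        return len(self.part_order)


def pivot_basis(first_part: str, remaining_order: Sequence[str] | None = None,
                parts: Sequence[str] = PARTS) -> IlrBasis:
    """Pivot (sequential-binary-partition) ILR basis with a chosen lead part.

    The first coordinate is the balance of ``first_part`` against the
    geometric mean of all remaining parts, with weight sqrt((D-1)/D) on
    the lead part and -sqrt(1/(D(D-1))) on each of the others; rows
    2..D-1 recursively pivot the remaining parts in ``remaining_order``.
    Reporting the first coordinate's regression coefficient for each
    choice of lead part gives the one-coefficient-per-behaviour summary
    used throughout the pipeline.
    """
    parts = tuple(parts)
    if remaining_order is None:
        remaining_order = tuple(p for p in parts if p != first_part)
    order = (first_part, *remaining_order)
    if sorted(order) != sorted(parts):
        raise ValueError(f"{order} is not a permutation of {parts}")
    D = len(parts)
    V = np.zeros((D - 1, D))
    col = {p: j for j, p in enumerate(parts)}
    for i in range(D - 1):
        r = D - i - 1  # number of parts after the i-th pivot
        a = np.sqrt(r / (r + 1.0))
        V[i, col[order[i]]] = a
        for p in order[i + 1:]:
            V[i, col[p]] = -a / r
    return IlrBasis(parts, V)


def clr(values: np.ndarray) -> np.ndarray:
    """Centred log-ratio transform along the last axis."""
    arr = np.asarray(values, dtype=float)
    if np.any(arr <= 0):
        raise ZeroPartError("clr requires strictly positive parts")
    logs = np.log(arr)
    return logs - logs.mean(axis=-1, keepdims=True)


def ilr_transform(comp: Composition | np.ndarray, basis: IlrBasis) -> np.ndarray:
    """Map a composition (or array of part rows) to D-1 ILR coordinates."""
    values = comp.values if isinstance(comp, Composition) else np.asarray(comp, float)
    if values.shape[-1] != basis.n_parts:
        raise ValueError("composition and basis disagree on number of parts")
    return clr(values) @ basis.contrast_matrix.T


def ilr_inverse(coords: np.ndarray, basis: IlrBasis,
                total: float = DAY_MINUTES) -> Composition | np.ndarray:
    """Map ILR coordinates back to a composition closed to ``total``.

    A 1-D coordinate vector returns a :class:`Composition`; a 2-D array
    of coordinate rows returns the corresponding array of closed part
    rows.
    """
    z = np.asarray(coords, dtype=float)
    if z.shape[-1] != basis.n_parts - 1:
        raise ValueError(f"expected {basis.n_parts - 1} coordinates, got {z.shape[-1]}")
    raw = np.exp(z @ basis.contrast_matrix)
    closed = raw * (total / raw.sum(axis=-1, keepdims=True))
    if z.ndim == 1:
        return Composition(closed, basis.part_order, float(total))
    return closed


def geometric_mean_composition(compositions: Sequence[Composition] | np.ndarray,
                               parts: Sequence[str] = PARTS,
                               total: float = DAY_MINUTES) -> Composition:
    """Part-wise geometric mean across individuals, re-closed.

    This is the compositional centre of a sample; equivalently the ILR
    inverse of the arithmetic mean of ILR coordinates in any basis.
    """
    if isinstance(compositions, np.ndarray):
        mat = np.asarray(compositions, dtype=float)
    else:
        comps = list(compositions)
        if not comps:
            raise ValueError("need at least one composition")
        ref = comps[0]
        for c in comps[1:]:
            if c.parts != ref.parts or not np.isclose(c.total, ref.total):
                raise PartMismatchError("compositions differ in parts or total")
        parts, total = ref.parts, ref.total
        mat = np.stack([c.values for c in comps])
    if mat.ndim != 2 or mat.shape[0] == 0:
        raise ValueError("need a non-empty 2-D array of part rows")
    if np.any(mat <= 0):
        raise ZeroPartError("geometric mean requires strictly positive parts")
    gm = np.exp(np.log(mat).mean(axis=0))
    return close(gm, total, parts=parts)


@dataclass(frozen=True)
class VariationMatrix:
    """Pairwise log-ratio variation: entry (i, j) = var(ln(x_i / x_j)).

    Symmetric with a zero diagonal and non-negative off-diagonal
    entries; small entries mark highly codependent parts.
    """

    labels: tuple[str, ...]
    entries: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        E = np.asarray(self.entries, dtype=float)
        object.__setattr__(self, "entries", E)
        D = len(self.labels)
        if E.shape != (D, D):
            raise ValueError("entries shape must match labels")

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i, j = (self.labels.index(p) for p in pair)
        return float(self.entries[i, j])


def variation_matrix(compositions: Sequence[Composition] | np.ndarray,
                     parts: Sequence[str] = PARTS) -> VariationMatrix:
    """Sample variation matrix of a collection of compositions (ddof=1)."""
    if isinstance(compositions, np.ndarray):
        mat = np.asarray(compositions, dtype=float)
        labels = tuple(parts)
    else:
        comps = list(compositions)
        if len(comps) >= 1:
            labels = comps[0].parts
            for c in comps[1:]:
                if c.parts != labels:
                    raise PartMismatchError("compositions differ in parts")
            mat = np.stack([c.values for c in comps])
        else:
            mat = np.empty((0, len(parts)))
            labels = tuple(parts)
    if mat.shape[0] < 2:
        raise ValueError("variation matrix needs at least two compositions")
    logs = np.log(mat)
    D = logs.shape[1]
    E = np.zeros((D, D))
    for i in range(D):
        for j in range(i + 1, D):
            v = np.var(logs[:, i] - logs[:, j], ddof=1)
            E[i, j] = E[j, i] = v
    return VariationMatrix(labels, E)
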
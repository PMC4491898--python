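"""Two-dimensional Pareto-set mathematics.

Score pairs live in ``A x B`` where both dimensions carry a total order
(maximize or minimize, fixed by an :class:`OrderSpec`).  A pair *dominates*
another if it is strictly better in one dimension and not worse in the
other.  A collection without dominated elements is a *Pareto set*; its
duplicate-free list representation is a *Pareto list*, optionally kept in
decreasing order of the first dimension (which, for a Pareto list, implies
increasing order in the second).

The module provides the definitional quadratic-time front computation
(:func:`brute_force_front`, used as a test oracle throughout), four
practical front operators with different input contracts
(:func:`pf_sort`, :func:`pf_isort`, :func:`pf_lex`, :func:`pf_smooth`,
:func:`pf_nosort`), a linear-time merge of two sorted fronts
(:func:`pareto_merge`) and the harmonic-number expectation for the front
size of random sets (:func:`harmonic`).

All operators accept arbitrary sequence items whose first two entries are
the score coordinates; extra entries (e.g. a backtrace witness) are carried
along untouched.  Duplicate coordinates are collapsed to the first
occurrence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any, Iterable, Iterator, NamedTuple, Sequence

import numpy as np

__all__ = [
    "ScorePair",
    "OrderSpec",
    "MAX_MAX",
    "ParetoFront",
    "OpStats",
    "dominates",
    "brute_force_front",
    "pf_sort",
    "pf_isort",
    "pf_lex",
    "pf_smooth",
    "pf_nosort",
    "pareto_merge",
    "harmonic",
    "PF_VARIANTS",
]


class ScorePair(NamedTuple):
    """A two-dimensional score value ``(a, b)``."""

    a: float
    b: float


@dataclass(frozen=True)
class OrderSpec:
    """Orientation of the two total orders used by domination.

    ``dir_a`` / ``dir_b`` are ``"max"`` or ``"min"``.  Minimization is
    handled by negating comparisons, never the stored scores, so reported
    values stay on their natural scale.  ``eps`` is an optional absolute
    tolerance: components within ``eps`` compare equal (opt-in; default
    exact comparison).
    """

    dir_a: str = "max"
    dir_b: str = "max"
    eps: float = 0.0

    def __post_init__(self) -> None:
        if self.dir_a not in ("max", "min") or self.dir_b not in ("max", "min"):
            raise ValueError("directions must be 'max' or 'min'")
        if self.eps < 0:
            raise ValueError("eps must be nonnegative")

    # Oriented three-way comparisons: +1 means strictly better.
    def cmp_a(self, x: float, y: float) -> int:
        if abs(x - y) <= self.eps:
            return 0
        better = x > y if self.dir_a == "max" else x < y
        return 1 if better else -1

    def cmp_b(self, x: float, y: float) -> int:
        if abs(x - y) <= self.eps:
            return 0
        better = x > y if self.dir_b == "max" else x < y
        return 1 if better else -1

    def flipped(self) -> "OrderSpec":
        flip = {"max": "min", "min": "max"}
        return OrderSpec(flip[self.dir_a], flip[self.dir_b], self.eps)

    def sort_key(self, item: Sequence) -> tuple[float, float]:
        """Key for *decreasing* lexicographic order under the oriented orders
        (best first) when sorting ascending with this key."""
        a = -item[0] if self.dir_a == "max" else item[0]
        b = -item[1] if self.dir_b == "max" else item[1]
        return (a, b)


MAX_MAX = OrderSpec("max", "max")


@dataclass
class OpStats:
    """Operation counter for hardware-independent cost measurements."""

    comparisons: int = 0
    removals: int = 0

    def add(self, other: "OpStats") -> None:
        self.comparisons += other.comparisons
        self.removals += other.removals


@dataclass(frozen=True)
class ParetoFront:
    """A duplicate-free collection of score pairs with no dominated element.

    ``sorted=True`` asserts the list is strictly decreasing in the first
    dimension (under its order) and therefore strictly increasing in the
    second.
    """

    pairs: tuple = ()
    sorted: bool = False
    orders: OrderSpec = field(default=MAX_MAX)

    def __iter__(self) -> Iterator:
        return iter(self.pairs)

    def __len__(self) -> int:
        return len(self.pairs)

    def __contains__(self, item: Any) -> bool:
        return item in self.pairs

    def coords(self) -> list[tuple[float, float]]:
        return [(p[0], p[1]) for p in self.pairs]

    def as_set(self) -> frozenset[tuple[float, float]]:
        return frozenset(self.coords())

    def validate(self) -> None:
        """Raise ``ValueError`` on duplicate, dominated or mis-sorted entries."""
        seen = set()
        for p in self.pairs:
            c = (p[0], p[1])
            if c in seen:
                raise ValueError(f"duplicate pair {c}")
            seen.add(c)
        for p in self.pairs:
            for q in self.pairs:
                if p is not q and dominates(q, p, self.orders):
                    raise ValueError(f"{(q[0], q[1])} dominates {(p[0], p[1])}")
        if self.sorted:
            for p, q in zip(self.pairs, self.pairs[1:]):
                if not (
                    self.orders.cmp_a(p[0], q[0]) > 0
                    and self.orders.cmp_b(q[1], p[1]) > 0
                ):
                    raise ValueError("sorted flag violated")


def _check_finite(p: Sequence) -> None:
    if not (math.isfinite(p[0]) and math.isfinite(p[1])):
        raise ValueError(f"non-finite score components in {(p[0], p[1])}")


def dominates(p: Sequence, q: Sequence, orders: OrderSpec = MAX_MAX) -> bool:
    """True iff ``p`` is strictly better than ``q`` in one dimension and not
    worse in the other."""
    _check_finite(p)
    _check_finite(q)
    ca = orders.cmp_a(p[0], q[0])
    cb = orders.cmp_b(p[1], q[1])
    return (ca > 0 and cb >= 0) or (ca >= 0 and cb > 0)


def _dedup(items: Iterable[Sequence]) -> list:
    out, seen = [], set()
    for it in items:
        c = (it[0], it[1])
        if c not in seen:
            seen.add(c)
            out.append(it)
    return out


def brute_force_front(
    items: Iterable[Sequence], orders: OrderSpec = MAX_MAX
) -> ParetoFront:
    """Direct all-pairs implementation of the front definition: keep exactly
    the elements not dominated by any other element.  Quadratic; serves as
    the oracle against which the practical operators are tested.
    """
    items = _dedup(items)
    for it in items:
        _check_finite(it)
    n = len(items)
    if n == 0:
        return ParetoFront((), sorted=False, orders=orders)
    if orders.eps == 0.0 and n > 64:
        # Vectorized domination test, one pass per element.
        sign_a = 1.0 if orders.dir_a == "max" else -1.0
        sign_b = 1.0 if orders.dir_b == "max" else -1.0
        av = np.array([float(it[0]) for it in items]) * sign_a
        bv = np.array([float(it[1]) for it in items]) * sign_b
        keep = []
        for i, it in enumerate(items):
            ge_a = av >= av[i]
            ge_b = bv >= bv[i]
            dom = ge_a & ge_b & ((av > av[i]) | (bv > bv[i]))
            if not dom.any():
                keep.append(it)
        return ParetoFront(tuple(keep), sorted=False, orders=orders)
    keep = [
        p
        for p in items
        if not any(q is not p and dominates(q, p, orders) for q in items)
    ]
    return ParetoFront(tuple(keep), sorted=False, orders=orders)


# ---------------------------------------------------------------------------
# pf variants.  Each works on raw lists internally; the public functions wrap
# results in ParetoFront.

def _isort_insert(front: list, p: Sequence, orders: OrderSpec, stats: OpStats | None) -> None:
    """Insert ``p`` into the sorted Pareto list ``front`` in place
    (Pareto insertion sort step)."""
    n = len(front)
    idx = 0
    while idx < n:
        x = front[idx]
        if stats is not None:
            stats.comparisons += 1
        ca = orders.cmp_a(p[0], x[0])
        if ca > 0:
            front.insert(idx, p)
            _strip_dominated_tail(front, idx + 1, orders, stats)
            return
        if ca == 0:
            if orders.cmp_b(p[1], x[1]) > 0:
                front[idx] = p
                _strip_dominated_tail(front, idx + 1, orders, stats)
            return  # equal-a, not better in b: discard p
        # p.a worse than x.a
        if orders.cmp_b(p[1], x[1]) > 0:
            idx += 1
            continue
        return  # dominated (or duplicate): discard p
    front.append(p)


def _strip_dominated_tail(
    front: list, start: int, orders: OrderSpec, stats: OpStats | None
) -> None:
    """After inserting at ``start - 1``, drop following elements whose second
    component does not exceed the new element's (they are dominated)."""
    b = front[start - 1][1]
    end = start
    n = len(front)
    while end < n:
        if stats is not None:
            stats.comparisons += 1
        if orders.cmp_b(front[end][1], b) > 0:
            break
        end += 1
    if end > start:
        if stats is not None:
            stats.removals += end - start
        del front[start:end]


def pf_isort(
    items: Iterable[Sequence],
    orders: OrderSpec = MAX_MAX,
    stats: OpStats | None = None,
) -> ParetoFront:
    """Pareto-version of insertion sort: unsorted input, sorted Pareto list
    output.  Worst case O(N^2), expected O(N log N)."""
    front: list = []
    for p in items:
        _check_finite(p)
        _isort_insert(front, p, orders, stats)
    return ParetoFront(tuple(front), sorted=True, orders=orders)


def pf_lex(
    items: Sequence,
    orders: OrderSpec = MAX_MAX,
    stats: OpStats | None = None,
    debug: bool = False,
) -> ParetoFront:
    """Linear one-pass extraction from a *lexicographically sorted* input
    (decreasing under the oriented orders).

    The precondition is checked only with ``debug=True``; production calls
    on unsorted input return garbage by contract.
    """
    if debug:
        for p, q in zip(items, items[1:]):
            ca = orders.cmp_a(p[0], q[0])
            if ca < 0 or (ca == 0 and orders.cmp_b(p[1], q[1]) < 0):
                raise ValueError("pf_lex input is not sorted")
    out: list = []
    for p in items:
        _check_finite(p)
        if out:
            if stats is not None:
                stats.comparisons += 1
            if orders.cmp_b(out[-1][1], p[1]) >= 0:
                continue
        out.append(p)
    return ParetoFront(tuple(out), sorted=True, orders=orders)


def pf_sort(
    items: Iterable[Sequence],
    orders: OrderSpec = MAX_MAX,
    stats: OpStats | None = None,
) -> ParetoFront:
    """Sort lexicographically (O(N log N)), then extract with :func:`pf_lex`."""
    ordered = sorted(items, key=orders.sort_key)
    if stats is not None:
        n = len(ordered)
        stats.comparisons += int(n * math.log2(n)) if n > 1 else 0
    return pf_lex(ordered, orders, stats)


def _up_insert(out: list, p: Sequence, orders: OrderSpec, stats: OpStats | None) -> None:
    """Insert ``p`` into the sorted Pareto list ``out`` from the low end
    (the list tail holds the worst first components)."""
    j = len(out) - 1
    while j >= 0:
        x = out[j]
        if stats is not None:
            stats.comparisons += 1
        if dominates(p, x, orders):
            del out[j]
            if stats is not None:
                stats.removals += 1
            j -= 1
            continue
        if dominates(x, p, orders) or (x[0] == p[0] and x[1] == p[1]):
            return
        if orders.cmp_a(p[0], x[0]) > 0:
            j -= 1
            continue
        out.insert(j + 1, p)
        return
    out.insert(0, p)


def pf_smooth(
    items: Sequence,
    orders: OrderSpec = MAX_MAX,
    stats: OpStats | None = None,
) -> ParetoFront:
    """:func:`pf_lex` extended with two repair rules for out-of-order
    elements.  On sorted input it performs exactly the pf_lex pass (no
    repairs); on arbitrary input it is O(N^2) worst case.

    Rule priority: the out-of-order rules are tried first, and the first of
    them fires whenever the incoming pair dominates the top of the output
    stack (not only when it is strictly better in the first dimension).
    """
    out: list = []
    i = 0
    n = len(items)
    while i < n:
        p = items[i]
        _check_finite(p)
        if not out:
            out.append(p)
            i += 1
            continue
        x = out[-1]
        if stats is not None:
            stats.comparisons += 1
        ca = orders.cmp_a(p[0], x[0])
        if (ca > 0 and orders.cmp_b(p[1], x[1]) >= 0) or (
            ca == 0 and orders.cmp_b(p[1], x[1]) > 0
        ):
            # incoming dominates the stack top: pop and retry with same input
            out.pop()
            if stats is not None:
                stats.removals += 1
            continue
        if ca > 0:  # out of order but incomparable: insert below the top
            top = out.pop()
            _up_insert(out, p, orders, stats)
            out.append(top)
            i += 1
            continue
        # in-order: plain pf_lex step
        if orders.cmp_b(x[1], p[1]) >= 0:
            i += 1
            continue
        out.append(p)
        i += 1
    return ParetoFront(tuple(out), sorted=True, orders=orders)


def pf_nosort(
    items: Iterable[Sequence],
    orders: OrderSpec = MAX_MAX,
    stats: OpStats | None = None,
) -> ParetoFront:
    """Front computation that never sorts: consumes and produces unsorted
    lists.  O(N^2) worst case."""
    front: list = []
    for p in items:
        _check_finite(p)
        keep = True
        i = 0
        while i < len(front):
            q = front[i]
            if stats is not None:
                stats.comparisons += 1
            if dominates(p, q, orders):
                del front[i]
                if stats is not None:
                    stats.removals += 1
                continue
            if dominates(q, p, orders) or (q[0] == p[0] and q[1] == p[1]):
                keep = False
                break
            i += 1
        if keep:
            front.append(p)
    return ParetoFront(tuple(front), sorted=False, orders=orders)


def pareto_merge(
    x: Sequence,
    y: Sequence,
    orders: OrderSpec = MAX_MAX,
    stats: OpStats | None = None,
    debug: bool = False,
) -> ParetoFront:
    """Merge two *sorted Pareto lists* into the front of their union in
    linear time (ten-case analysis on the leading elements, with dropWhile
    skips of newly dominated elements).

    Accepts :class:`ParetoFront` objects or raw sequences.  ``debug=True``
    validates the input invariants first.
    """
    xs = tuple(x.pairs) if isinstance(x, ParetoFront) else tuple(x)
    ys = tuple(y.pairs) if isinstance(y, ParetoFront) else tuple(y)
    if debug:
        ParetoFront(xs, sorted=True, orders=orders).validate()
        ParetoFront(ys, sorted=True, orders=orders).validate()
    out: list = []
    i = j = 0
    nx, ny = len(xs), len(ys)

    def drop(seq: Sequence, k: int, n: int, b: float) -> int:
        # dropWhile: skip elements whose second component is not better than b
        while k < n:
            if stats is not None:
                stats.comparisons += 1
            if orders.cmp_b(seq[k][1], b) > 0:
                break
            k += 1
        return k

    while i < nx and j < ny:
        p, q = xs[i], ys[j]
        if stats is not None:
            stats.comparisons += 1
        ca = orders.cmp_a(p[0], q[0])
        cb = orders.cmp_b(p[1], q[1])
        if ca > 0:
            out.append(p)
            i += 1
            if cb > 0:
                j = drop(ys, j, ny, p[1])
            elif cb == 0:
                j += 1
        elif ca == 0:
            if cb > 0:
                out.append(p)
                i += 1
                j = drop(ys, j, ny, p[1])
            elif cb == 0:
                out.append(p)  # duplicate coordinates: keep one
                i += 1
                j += 1
            else:
                out.append(q)
                j += 1
                i = drop(xs, i, nx, q[1])
        else:
            if cb > 0:
                out.append(q)
                j += 1
            elif cb == 0:
                out.append(q)
                i += 1
                j += 1
            else:
                out.append(q)
                j += 1
                i = drop(xs, i, nx, q[1])
    out.extend(xs[i:])
    out.extend(ys[j:])
    return ParetoFront(tuple(out), sorted=True, orders=orders)


def harmonic(n: int) -> float:
    """Harmonic number H(n) = sum_{i=1..n} 1/i, the expected front size of a
    random set of n pairs with i.i.d. continuous coordinates."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return float(sum(1.0 / i for i in range(1, n + 1)))


PF_VARIANTS = {
    "sort": pf_sort,
    "isort": pf_isort,
    "lex": pf_lex,
    "smooth": pf_smooth,
    "nosort": pf_nosort,
}
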
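"""A miniature algebraic dynamic-programming engine.

An algorithm is specified by three independent parts:

* a :class:`Signature` — function symbols with typed argument lists
  (``sub`` = subproblem result, ``term`` = terminal token from the input);
* a :class:`TreeGrammar` — the search-space generator: for every
  (nonterminal, subproblem key) it enumerates flat alternatives, each an
  application of one signature symbol to subproblem references and terminal
  tokens;
* an :class:`EvaluationAlgebra` — one scoring function per symbol plus a
  choice function applied at every table cell.

:func:`evaluate` runs the tabulated dynamic program; with choice = identity
it realizes the full enumeration semantics, which
:func:`enumerate_candidates` exposes as explicit candidate terms.

Two-objective products are built with :func:`product_lex`,
:func:`product_add_lambda` and :func:`product_pareto`; the Pareto product
supports three per-cell evaluation strategies (``standard``, ``sorted``,
``eager``) which must produce identical fronts.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from fractions import Fraction
from typing import Any, Callable, Iterable, Mapping, NamedTuple, Sequence

from .pareto import (
    MAX_MAX,
    OpStats,
    OrderSpec,
    ParetoFront,
    PF_VARIANTS,
    brute_force_front,
    pareto_merge,
    pf_lex,
)

__all__ = [
    "SymbolSpec",
    "Signature",
    "Sub",
    "Term",
    "Alt",
    "TreeGrammar",
    "EvaluationAlgebra",
    "ConfigError",
    "evaluate",
    "enumerate_candidates",
    "interpret",
    "term_yield",
    "counting_algebra",
    "enumeration_algebra",
    "product_lex",
    "product_add_lambda",
    "product_pareto",
    "ParetoProduct",
    "check_monotone",
    "MonotonicityReport",
    "STRATEGIES",
]


class ConfigError(ValueError):
    """Invalid grammar/algebra/strategy configuration."""


# ---------------------------------------------------------------------------
# Signatures and grammars

class SymbolSpec(NamedTuple):
    name: str
    kinds: tuple[str, ...]  # each 'sub' or 'term'

    @property
    def arity(self) -> int:
        return len(self.kinds)


@dataclass(frozen=True)
class Signature:
    name: str
    symbols: Mapping[str, SymbolSpec]

    @staticmethod
    def of(name: str, **kinds: Sequence[str]) -> "Signature":
        syms = {n: SymbolSpec(n, tuple(k)) for n, k in kinds.items()}
        for spec in syms.values():
            for kind in spec.kinds:
                if kind not in ("sub", "term"):
                    raise ConfigError(f"bad argument kind {kind!r}")
        return Signature(name, syms)


class Sub(NamedTuple):
    """Reference to a subproblem: (nonterminal, key)."""

    nonterminal: str
    key: tuple


class Term(NamedTuple):
    """A terminal token; applications put (character, position)-style data
    here so that position-indexed scoring tables can be consulted."""

    token: Any


class Alt(NamedTuple):
    """One production alternative: a signature symbol applied to arguments."""

    symbol: str
    args: tuple


class TreeGrammar:
    """Search-space generator.  Subclasses implement the production rules.

    ``nonterminals`` must be listed in within-key evaluation order: when an
    alternative of ``v`` refers to ``w`` at the *same* key, ``w`` must
    precede ``v``.  Keys are produced by :meth:`subproblem_order` in
    dependency order (increasing subword length).
    """

    signature: Signature
    nonterminals: tuple[str, ...]
    axiom: str

    def subproblem_order(self, word: Any) -> Iterable[tuple]:
        raise NotImplementedError

    def axiom_key(self, word: Any) -> tuple:
        raise NotImplementedError

    def alternatives(self, nonterminal: str, key: tuple, word: Any) -> list[Alt]:
        raise NotImplementedError

    def check_alt(self, alt: Alt) -> None:
        spec = self.signature.symbols.get(alt.symbol)
        if spec is None:
            raise ConfigError(f"unknown symbol {alt.symbol!r}")
        if len(alt.args) != spec.arity:
            raise ConfigError(f"arity mismatch for {alt.symbol!r}")
        for kind, arg in zip(spec.kinds, alt.args):
            ok = isinstance(arg, Sub) if kind == "sub" else isinstance(arg, Term)
            if not ok:
                raise ConfigError(f"argument kind mismatch in {alt.symbol!r}")


# ---------------------------------------------------------------------------
# Evaluation algebras

@dataclass(frozen=True)
class EvaluationAlgebra:
    """Interpretation of a signature plus a choice function.

    ``functions[s]`` receives one positional argument per signature
    argument: carrier values for ``sub`` positions, raw tokens for ``term``
    positions.  ``choice`` maps an answer multiset (list) to an answer
    multiset.  ``direction`` declares the optimization sense of the carrier
    order when the choice is a plain max/min; products need it to orient
    domination.
    """

    name: str
    signature: Signature
    functions: Mapping[str, Callable]
    choice: Callable[[list], list]
    direction: str | None = None  # 'max' | 'min' | None

    def apply(self, symbol: str, *args: Any) -> Any:
        return self.functions[symbol](*args)


def choice_max(values: list) -> list:
    return [max(values)] if values else []


def choice_min(values: list) -> list:
    return [min(values)] if values else []


def choice_identity(values: list) -> list:
    return values


def simple_algebra(
    name: str,
    signature: Signature,
    functions: Mapping[str, Callable],
    direction: str,
) -> EvaluationAlgebra:
    choice = choice_max if direction == "max" else choice_min
    return EvaluationAlgebra(name, signature, functions, choice, direction)


def counting_algebra(signature: Signature) -> EvaluationAlgebra:
    """Search-space size: every symbol multiplies its subproblem counts,
    the choice sums the alternatives."""

    def make(spec: SymbolSpec) -> Callable:
        sub_idx = [i for i, k in enumerate(spec.kinds) if k == "sub"]

        def f(*args: Any) -> int:
            n = 1
            for i in sub_idx:
                n *= args[i]
            return n

        return f

    fns = {name: make(spec) for name, spec in signature.symbols.items()}
    return EvaluationAlgebra(
        "count", signature, fns, lambda xs: [sum(xs)] if xs else [], None
    )


def enumeration_algebra(signature: Signature) -> EvaluationAlgebra:
    """Candidate terms themselves: symbols build ``(symbol, *args)`` tuples,
    the choice is the identity."""

    def make(name: str) -> Callable:
        return lambda *args: (name, *args)

    fns = {name: make(name) for name in signature.symbols}
    return EvaluationAlgebra("enumerate", signature, fns, choice_identity, None)


def interpret(term: tuple, algebra: EvaluationAlgebra) -> Any:
    """Evaluate a candidate term bottom-up under ``algebra`` (no choice)."""
    symbol = term[0]
    spec = algebra.signature.symbols[symbol]
    args = []
    for kind, arg in zip(spec.kinds, term[1:]):
        args.append(interpret(arg, algebra) if kind == "sub" else arg)
    return algebra.apply(symbol, *args)


def term_yield(term: tuple, signature: Signature) -> list:
    """Terminal tokens of a candidate term, left to right."""
    symbol = term[0]
    spec = signature.symbols[symbol]
    out: list = []
    for kind, arg in zip(spec.kinds, term[1:]):
        if kind == "sub":
            out.extend(term_yield(arg, signature))
        else:
            out.append(arg)
    return out


# ---------------------------------------------------------------------------
# Core evaluation

def _arg_lists(
    grammar: TreeGrammar, alt: Alt, tables: dict
) -> tuple[list[list], list[int]]:
    """Resolve an alternative's arguments: a list of value lists (singleton
    for terminals) and the indices of subproblem positions."""
    spec = grammar.signature.symbols[alt.symbol]
    lists: list[list] = []
    sub_idx: list[int] = []
    for i, (kind, arg) in enumerate(zip(spec.kinds, alt.args)):
        if kind == "sub":
            lists.append(tables[arg.nonterminal][arg.key])
            sub_idx.append(i)
        else:
            lists.append([arg.token])
    return lists, sub_idx


def evaluate(
    grammar: TreeGrammar,
    algebra: EvaluationAlgebra,
    word: Any,
    *,
    debug: bool = False,
    keep_tables: bool = False,
):
    """Tabulated dynamic programming: for every (nonterminal, key) cell,
    score all alternatives over all combinations of subproblem answers and
    apply the algebra's choice.  Returns the axiom cell's answer list.

    Pareto products (:class:`ParetoProduct`) are evaluated with their
    configured per-cell strategy; every other algebra uses the plain
    cartesian construction.
    """
    if isinstance(algebra, ParetoProduct):
        return _evaluate_pareto(
            grammar, algebra, word, debug=debug, keep_tables=keep_tables
        )
    tables: dict = {nt: {} for nt in grammar.nonterminals}
    for key in grammar.subproblem_order(word):
        for nt in grammar.nonterminals:
            items: list = []
            for alt in grammar.alternatives(nt, key, word):
                if debug:
                    grammar.check_alt(alt)
                f = algebra.functions[alt.symbol]
                lists, _ = _arg_lists(grammar, alt, tables)
                for combo in itertools.product(*lists):
                    items.append(f(*combo))
            tables[nt][key] = algebra.choice(items)
    answer = tables[grammar.axiom][grammar.axiom_key(word)]
    if keep_tables:
        return answer, tables
    return answer


def enumerate_candidates(
    grammar: TreeGrammar, word: Any, *, max_candidates: int = 200_000
) -> list[tuple]:
    """All candidate terms whose yield is ``word`` (exponential; guarded by
    a counting-algebra pre-check)."""
    count = evaluate(grammar, counting_algebra(grammar.signature), word)
    total = count[0] if count else 0
    if total > max_candidates:
        raise ValueError(
            f"search space of size {total} exceeds guard ({max_candidates})"
        )
    return evaluate(grammar, enumeration_algebra(grammar.signature), word)


# ---------------------------------------------------------------------------
# Products

def _split_pair_args(spec: SymbolSpec, args: tuple) -> tuple[list, list]:
    """Component argument lists for a product function (Eq.-21 style):
    terminal tokens are shared, subproblem pairs are split."""
    a_args, b_args = [], []
    for kind, arg in zip(spec.kinds, args):
        if kind == "sub":
            a_args.append(arg[0])
            b_args.append(arg[1])
        else:
            a_args.append(arg)
            b_args.append(arg)
    return a_args, b_args


def _product_functions(
    a: EvaluationAlgebra, b: EvaluationAlgebra, *, witness: bool
) -> dict[str, Callable]:
    fns: dict[str, Callable] = {}
    for name, spec in a.signature.symbols.items():
        fa, fb = a.functions[name], b.functions[name]

        if witness:

            def f(*args: Any, _fa=fa, _fb=fb, _spec=spec, _name=name) -> tuple:
                aa, bb = _split_pair_args(_spec, args)
                wit = (_name,) + tuple(
                    arg[2] if kind == "sub" else arg
                    for kind, arg in zip(_spec.kinds, args)
                )
                return (_fa(*aa), _fb(*bb), wit)

        else:

            def f(*args: Any, _fa=fa, _fb=fb, _spec=spec) -> tuple:
                aa, bb = _split_pair_args(_spec, args)
                return (_fa(*aa), _fb(*bb))

        fns[name] = f
    return fns


def _require_directions(a: EvaluationAlgebra, b: EvaluationAlgebra) -> OrderSpec:
    if a.direction not in ("max", "min") or b.direction not in ("max", "min"):
        raise ConfigError(
            "both algebras must declare a max/min direction for products"
        )
    return OrderSpec(a.direction, b.direction)


def product_lex(
    a: EvaluationAlgebra, b: EvaluationAlgebra, *, witness: bool = False
) -> EvaluationAlgebra:
    """Lexicographic product: optimize dimension A, break ties by B."""
    orders = _require_directions(a, b)

    def choice(items: list) -> list:
        if not items:
            return []
        best = items[0]
        for it in items[1:]:
            ca = orders.cmp_a(it[0], best[0])
            if ca > 0 or (ca == 0 and orders.cmp_b(it[1], best[1]) > 0):
                best = it
        return [best]

    return EvaluationAlgebra(
        f"{a.name}*lex*{b.name}",
        a.signature,
        _product_functions(a, b, witness=witness),
        choice,
        None,
    )


def product_add_lambda(
    a: EvaluationAlgebra,
    b: EvaluationAlgebra,
    lam: float,
    *,
    witness: bool = False,
) -> EvaluationAlgebra:
    """Weighted-sum product: single-objective optimization of
    ``lam*a + (1-lam)*b`` (scores oriented so both dimensions maximize),
    carrying the (a, b) pair for reporting.  All co-optimal distinct score
    pairs are kept."""
    if not 0.0 <= lam <= 1.0:
        raise ConfigError("lambda must lie in [0, 1]")
    orders = _require_directions(a, b)
    # exact rational arithmetic: float rounding in the weighted sum would
    # make tie detection (co-optimal pairs) path-dependent
    lam_f = Fraction(lam)
    wa = lam_f if orders.dir_a == "max" else -lam_f
    wb = (1 - lam_f) if orders.dir_b == "max" else -(1 - lam_f)

    def weighted(it: Sequence) -> Fraction:
        return wa * Fraction(it[0]) + wb * Fraction(it[1])

    def choice(items: list) -> list:
        if not items:
            return []
        best = max(weighted(it) for it in items)
        out, seen = [], set()
        for it in items:
            if weighted(it) == best and (it[0], it[1]) not in seen:
                seen.add((it[0], it[1]))
                out.append(it)
        # break weighted ties by domination so that answers always lie on
        # the Pareto front (only relevant at the boundary weights 0 and 1,
        # where ties can include dominated pairs)
        return list(brute_force_front(out, orders).pairs)

    alg = EvaluationAlgebra(
        f"{a.name}*+{lam}*{b.name}",
        a.signature,
        _product_functions(a, b, witness=witness),
        choice,
        None,
    )
    object.__setattr__(alg, "weighted", weighted)
    return alg


STRATEGIES = ("standard", "sorted", "eager")


@dataclass(frozen=True)
class ParetoProduct(EvaluationAlgebra):
    """Pareto product of two algebras: the choice is the Pareto front
    operator, evaluated per cell by one of three strategies."""

    orders: OrderSpec = field(default=MAX_MAX)
    strategy: str = "standard"
    pf_variant: str = "nosort"
    witness: bool = False
    stats: OpStats | None = None


def product_pareto(
    a: EvaluationAlgebra,
    b: EvaluationAlgebra,
    strategy: str = "standard",
    pf_variant: str | None = None,
    *,
    witness: bool = False,
    eps: float = 0.0,
    stats: OpStats | None = None,
) -> ParetoProduct:
    orders = replace(_require_directions(a, b), eps=eps)
    if strategy not in STRATEGIES:
        raise ConfigError(f"unknown strategy {strategy!r}")
    if pf_variant is None:
        pf_variant = {"standard": "nosort", "sorted": "lex", "eager": "lex"}[strategy]
    if pf_variant not in PF_VARIANTS:
        raise ConfigError(f"unknown pf variant {pf_variant!r}")
    if strategy == "standard" and pf_variant == "lex":
        raise ConfigError(
            "pf_lex requires sorted intermediate lists; use strategy='sorted' "
            "or 'eager', or another pf variant under 'standard'"
        )
    if strategy == "sorted" and pf_variant == "nosort":
        raise ConfigError(
            "pf_nosort breaks the sorted-cell invariant of strategy='sorted'"
        )
    pf = PF_VARIANTS[pf_variant]

    def choice(items: list) -> list:
        return list(pf(items, orders).pairs)

    return ParetoProduct(
        name=f"{a.name}*Par*{b.name}",
        signature=a.signature,
        functions=_product_functions(a, b, witness=witness),
        choice=choice,
        direction=None,
        orders=orders,
        strategy=strategy,
        pf_variant=pf_variant,
        witness=witness,
        stats=stats,
    )


# --- strategy combinators ---------------------------------------------------

def _merge_sorted(x: list, y: list, orders: OrderSpec) -> list:
    """Plain linear merge of two lexicographically sorted lists (keeps
    duplicates and dominated elements: multiset semantics)."""
    out: list = []
    i = j = 0
    kx = [orders.sort_key(it) for it in x]
    ky = [orders.sort_key(it) for it in y]
    while i < len(x) and j < len(y):
        if kx[i] <= ky[j]:
            out.append(x[i])
            i += 1
        else:
            out.append(y[j])
            j += 1
    out.extend(x[i:])
    out.extend(y[j:])
    return out


def _runs(f: Callable, lists: list[list], sub_idx: list[int]) -> Iterable[list]:
    """Apply ``f`` over the cartesian product of ``lists``, yielding one run
    per combination of all-but-the-first subproblem argument.  Within a run
    only the first subproblem argument varies, so if the cell lists are
    sorted Pareto lists and ``f`` is strictly monotone, every run is again
    sorted (and Pareto)."""
    if not sub_idx:
        yield [f(*[l[0] for l in lists])]
        return
    first = sub_idx[0]
    rest = [lists[i] if i != first else [None] for i in range(len(lists))]
    for combo in itertools.product(*rest):
        run = []
        for v in lists[first]:
            args = list(combo)
            args[first] = v
            run.append(f(*args))
        yield run


def _cell_standard(
    grammar: TreeGrammar, algebra: ParetoProduct, nt: str, key: tuple, word, tables
) -> list:
    items: list = []
    for alt in grammar.alternatives(nt, key, word):
        f = algebra.functions[alt.symbol]
        lists, _ = _arg_lists(grammar, alt, tables)
        for combo in itertools.product(*lists):
            items.append(f(*combo))
    return algebra.choice(items)


def _cell_sorted(
    grammar: TreeGrammar, algebra: ParetoProduct, nt: str, key: tuple, word, tables
) -> list:
    orders = algebra.orders
    merged: list = []
    for alt in grammar.alternatives(nt, key, word):
        f = algebra.functions[alt.symbol]
        lists, sub_idx = _arg_lists(grammar, alt, tables)
        if any(not lists[i] for i in sub_idx):
            continue
        alt_list: list = []
        for run in _runs(f, lists, sub_idx):
            alt_list = _merge_sorted(alt_list, run, orders)
        merged = _merge_sorted(merged, alt_list, orders)
    pf = PF_VARIANTS[algebra.pf_variant]
    return list(pf(merged, orders, stats=algebra.stats).pairs)


def _cell_eager(
    grammar: TreeGrammar,
    algebra: ParetoProduct,
    nt: str,
    key: tuple,
    word,
    tables,
    debug: bool,
) -> list:
    orders = algebra.orders
    front: list = []
    for alt in grammar.alternatives(nt, key, word):
        f = algebra.functions[alt.symbol]
        lists, sub_idx = _arg_lists(grammar, alt, tables)
        if any(not lists[i] for i in sub_idx):
            continue
        for run in _runs(f, lists, sub_idx):
            if not sub_idx:
                # constant alternative: not necessarily a Pareto list yet
                run = list(brute_force_front(run, orders).pairs)
                run.sort(key=orders.sort_key)
            front = list(pareto_merge(front, run, orders, stats=algebra.stats).pairs)
    if debug:
        # the select step is the identity: verify nothing would be removed
        if [
            (p[0], p[1]) for p in pf_lex(front, orders).pairs
        ] != [(p[0], p[1]) for p in front]:
            raise AssertionError("eager cell is not a Pareto list")
    return front


def _evaluate_pareto(
    grammar: TreeGrammar,
    algebra: ParetoProduct,
    word: Any,
    *,
    debug: bool,
    keep_tables: bool,
):
    tables: dict = {nt: {} for nt in grammar.nonterminals}
    for key in grammar.subproblem_order(word):
        for nt in grammar.nonterminals:
            if algebra.strategy == "standard":
                cell = _cell_standard(grammar, algebra, nt, key, word, tables)
            elif algebra.strategy == "sorted":
                cell = _cell_sorted(grammar, algebra, nt, key, word, tables)
            else:
                cell = _cell_eager(grammar, algebra, nt, key, word, tables, debug)
            if debug:
                fr = ParetoFront(
                    tuple(cell),
                    sorted=algebra.strategy != "standard"
                    or algebra.pf_variant != "nosort",
                    orders=algebra.orders,
                )
                fr.validate()
            tables[nt][key] = cell
    answer = tables[grammar.axiom][grammar.axiom_key(word)]
    if keep_tables:
        return answer, tables
    return answer


# ---------------------------------------------------------------------------
# Monotonicity checking

@dataclass
class MonotonicityReport:
    samples: int
    violations: list = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations


def check_monotone(
    algebra: EvaluationAlgebra,
    *,
    samples: int = 50,
    seed: int = 0,
    term_sampler: Callable | None = None,
    sub_low: float = -10.0,
    sub_high: float = 10.0,
) -> MonotonicityReport:
    """Spot-check strict monotonicity of every scoring function in each
    subproblem argument, over a numeric carrier: raising one subproblem
    argument must strictly raise the score.  Report-only (never raises).

    ``term_sampler(rng, symbol, position)`` supplies terminal tokens; it is
    required whenever the signature has terminal arguments.
    """
    import numpy as np

    rng = np.random.default_rng(seed)
    report = MonotonicityReport(samples=samples)
    for name, spec in algebra.signature.symbols.items():
        sub_positions = [i for i, k in enumerate(spec.kinds) if k == "sub"]
        if not sub_positions:
            continue
        for _ in range(samples):
            args: list[Any] = []
            for i, kind in enumerate(spec.kinds):
                if kind == "sub":
                    args.append(float(rng.uniform(sub_low, sub_high)))
                else:
                    if term_sampler is None:
                        raise ConfigError(
                            f"symbol {name!r} has terminal arguments; "
                            "provide term_sampler"
                        )
                    args.append(term_sampler(rng, name, i))
            base = algebra.apply(name, *args)
            for pos in sub_positions:
                bumped = list(args)
                bumped[pos] = args[pos] + float(rng.uniform(0.1, 2.0))
                up = algebra.apply(name, *bumped)
                if not up > base:
                    report.violations.append(
                        {
                            "symbol": name,
                            "argument": pos,
                            "args": tuple(args),
                            "score": base,
                            "bumped_score": up,
                        }
                    )
    return report
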
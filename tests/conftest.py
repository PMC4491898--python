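"""Shared fixtures: an independent definitional front oracle, toy grammars,
and seeded random instance families used by unit and acceptance tests."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest

from paretodp.engine import (
    Alt,
    EvaluationAlgebra,
    Signature,
    Sub,
    Term,
    TreeGrammar,
    choice_max,
    choice_min,
    enumerate_candidates,
    interpret,
)
from paretodp.pareto import MAX_MAX, OrderSpec


def naive_front(pairs, orders: OrderSpec = MAX_MAX) -> set:
    """Direct transcription of the front definition, independent of the
    package implementation: drop exactly the dominated coordinates."""
    sa = 1.0 if orders.dir_a == "max" else -1.0
    sb = 1.0 if orders.dir_b == "max" else -1.0

    def dom(p, q):
        pa, pb, qa, qb = sa * p[0], sb * p[1], sa * q[0], sb * q[1]
        return (pa > qa and pb >= qb) or (pa >= qa and pb > qb)

    uniq = list(dict.fromkeys((float(p[0]), float(p[1])) for p in pairs))
    return {p for p in uniq if not any(dom(q, p) for q in uniq if q != p)}


# ---------------------------------------------------------------------------
# Lemma-2.1 toy: one production W -> add(X, Y) with constant leaf answers.

TOY_SIGNATURE = Signature.of("toy", leaf=("term",), add=("sub", "sub"))


class PairToyGrammar(TreeGrammar):
    signature = TOY_SIGNATURE
    nonterminals = ("X", "Y", "W")
    axiom = "W"

    def __init__(self, xs, ys):
        self.xs, self.ys = xs, ys

    def subproblem_order(self, word):
        return [(0,)]

    def axiom_key(self, word):
        return (0,)

    def alternatives(self, nt, key, word):
        if nt == "X":
            return [Alt("leaf", (Term(t),)) for t in self.xs]
        if nt == "Y":
            return [Alt("leaf", (Term(t),)) for t in self.ys]
        return [Alt("add", (Sub("X", (0,)), Sub("Y", (0,))))]


def toy_component_algebras():
    a = EvaluationAlgebra(
        "A", TOY_SIGNATURE,
        {"leaf": lambda t: t[0], "add": lambda x, y: x + y},
        choice_max, "max",
    )
    b = EvaluationAlgebra(
        "B", TOY_SIGNATURE,
        {"leaf": lambda t: t[1], "add": lambda x, y: x + y},
        choice_max, "max",
    )
    return a, b


@pytest.fixture
def lemma_grammar():
    return PairToyGrammar([(4, 1), (3, 2)], [(3, 3), (1, 4)])


@pytest.fixture
def lemma_algebras():
    return toy_component_algebras()


# ---------------------------------------------------------------------------
# Random span grammar: T -> nil | chr(c, T) | join(T, T); exercises the
# binary-extension case with strictly monotone additive random algebras.

SPAN_SIGNATURE = Signature.of(
    "span", nil=(), chr=("term", "sub"), join=("sub", "sub")
)


class SpanGrammar(TreeGrammar):
    signature = SPAN_SIGNATURE
    nonterminals = ("T",)
    axiom = "T"

    def subproblem_order(self, word):
        n = len(word)
        for length in range(n + 1):
            for i in range(n - length + 1):
                yield (i, i + length)

    def axiom_key(self, word):
        return (0, len(word))

    def alternatives(self, nt, key, word):
        i, j = key
        if i == j:
            return [Alt("nil", ())]
        alts = [Alt("chr", (Term((word[i], i)), Sub("T", (i + 1, j))))]
        for k in range(i + 1, j):
            alts.append(Alt("join", (Sub("T", (i, k)), Sub("T", (k, j)))))
        return alts


def random_span_algebra(rng: np.random.Generator, direction: str) -> EvaluationAlgebra:
    """Additive algebra with random integer weights (exact arithmetic)."""
    letters = "ACGU"
    w = {c: int(rng.integers(0, 5)) for c in letters}
    jc = int(rng.integers(-3, 4))
    nc = int(rng.integers(-2, 3))
    fns = {
        "nil": lambda: nc,
        "chr": lambda t, x: x + w[t[0]],
        "join": lambda x, y: x + y + jc,
    }
    choice = choice_max if direction == "max" else choice_min
    return EvaluationAlgebra(f"rand_{direction}", SPAN_SIGNATURE, fns, choice, direction)


@dataclass
class ToyInstance:
    word: str
    alg_a: EvaluationAlgebra
    alg_b: EvaluationAlgebra
    orders: OrderSpec
    scores: list  # (a, b) per enumerated candidate


def make_toy_instances(n_instances: int, seed: int, max_len: int = 7) -> list[ToyInstance]:
    rng = np.random.default_rng(seed)
    grammar = SpanGrammar()
    out = []
    for _ in range(n_instances):
        length = int(rng.integers(0, max_len + 1))
        word = "".join(rng.choice(list("ACGU"), size=length))
        alg_a = random_span_algebra(rng, "max")
        alg_b = random_span_algebra(rng, "max" if rng.random() < 0.7 else "min")
        cands = enumerate_candidates(grammar, word, max_candidates=500_000)
        scores = [(interpret(c, alg_a), interpret(c, alg_b)) for c in cands]
        out.append(
            ToyInstance(
                word, alg_a, alg_b,
                OrderSpec(alg_a.direction, alg_b.direction), scores,
            )
        )
    return out


# All strategy x pf-variant combinations admissible for the Pareto product.
PARETO_COMBOS = [
    ("standard", "sort"),
    ("standard", "isort"),
    ("standard", "smooth"),
    ("standard", "nosort"),
    ("sorted", "lex"),
    ("sorted", "sort"),
    ("sorted", "isort"),
    ("sorted", "smooth"),
    ("eager", None),
]


@pytest.fixture(scope="session")
def span_grammar():
    return SpanGrammar()
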
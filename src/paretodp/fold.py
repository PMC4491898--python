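"""Single-sequence RNA folding with two competing objectives.

The search space is the classic non-crossing secondary-structure space over
a configurable pairing rule and minimum hairpin-loop size, generated by an
unambiguous grammar that distinguishes stacked from isolated-helix-opening
pairs so that a simple nearest-neighbour-style energy (per pair + per
stack) stays a strictly monotone algebra.

Two algebras score the same space: a free-energy-like score (minimized) and
an expected-accuracy score that accumulates base-pair probabilities from
the Boltzmann ensemble of the *same* model (maximized).  Their Pareto
product yields the exact front of energy/accuracy trade-offs with one
witness structure per front element.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .engine import (
    Alt,
    EvaluationAlgebra,
    Signature,
    Sub,
    Term,
    TreeGrammar,
    choice_max,
    choice_min,
    evaluate,
    product_pareto,
)
from .pareto import OpStats

__all__ = [
    "RNASequence",
    "FoldModel",
    "FoldGrammar",
    "energy_algebra",
    "mea_algebra",
    "partition_pairprobs",
    "fold_pareto",
    "FoldResult",
    "FrontEntry",
    "structure_pairs",
    "dot_bracket",
]

_ALPHABET = set("ACGU")
DEFAULT_PAIR_RULE = frozenset({"AU", "UA", "CG", "GC", "GU", "UG"})


@dataclass(frozen=True)
class RNASequence:
    """A validated RNA sequence (uppercase, T folded to U)."""

    id: str
    residues: str

    @staticmethod
    def parse(id: str, raw: str) -> "RNASequence":
        residues = raw.upper().replace("T", "U")
        bad = set(residues) - _ALPHABET
        if bad:
            raise ValueError(
                f"sequence {id!r} contains non-RNA residues {sorted(bad)}"
            )
        return RNASequence(id, residues)

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class FoldModel:
    """Simplified, configurable folding model (deliberately not a full
    nearest-neighbour parameter set): each admissible pair contributes
    ``pair_energy`` and each stacked pair additionally ``stack_energy``;
    ``beta`` scales Boltzmann weights ``exp(-beta * E)``."""

    pair_rule: frozenset[str] = DEFAULT_PAIR_RULE
    minloop: int = 3
    pair_energy: float = -1.0
    stack_energy: float = -1.0
    beta: float = 1.0
    no_lonely_pairs: bool = False

    def __post_init__(self) -> None:
        if self.minloop < 0:
            raise ValueError("minloop must be >= 0")
        if self.beta <= 0:
            raise ValueError("beta must be > 0")
        if not (math.isfinite(self.pair_energy) and math.isfinite(self.stack_energy)):
            raise ValueError("energies must be finite")

    def can_pair(self, seq: str, i: int, j: int) -> bool:
        """Admissible pair (i, j): complementary and loop large enough."""
        return j - i > self.minloop and seq[i] + seq[j] in self.pair_rule


FOLD_SIGNATURE = Signature.of(
    "fold",
    nil=(),
    unp=("term", "sub"),
    split=("sub", "sub"),
    pair=("term", "sub", "term"),
    stack=("term", "sub", "term"),
)


class FoldGrammar(TreeGrammar):
    """Unambiguous secondary-structure grammar over subwords (i, j)
    (0-based, half-open).

    ``S``: any structure; first position either unpaired or opening a
    closed substructure.  ``P``: a closed structure whose outermost pair
    spans the whole subword; derived by ``stack`` when the pair sits
    directly on another pair, else by ``pair`` over ``Q``.  ``Q``: like
    ``S`` but never a single full-span closed pair (which keeps the
    stack/pair split unambiguous).

    With ``no_lonely_pairs`` every helix must contain at least two pairs:
    closed structures reached from ``S``/``Q`` go through ``C`` whose
    outermost pair must stack on an inner pair chain ``R``.
    """

    signature = FOLD_SIGNATURE
    axiom = "S"

    def __init__(self, model: FoldModel):
        self.model = model
        if model.no_lonely_pairs:
            self.nonterminals = ("R", "C", "Q", "S")
            self._closed = "C"
        else:
            self.nonterminals = ("P", "Q", "S")
            self._closed = "P"

    def subproblem_order(self, word: str) -> Iterable[tuple]:
        n = len(word)
        for length in range(n + 1):
            for i in range(n - length + 1):
                yield (i, i + length)

    def axiom_key(self, word: str) -> tuple:
        return (0, len(word))

    def _open_alts(self, i: int, j: int, word: str, exclude_full: bool) -> list[Alt]:
        alts: list[Alt] = []
        if i == j:
            return [Alt("nil", ())]
        alts.append(Alt("unp", (Term((word[i], i)), Sub("S", (i + 1, j)))))
        last = j if not exclude_full else j - 1
        for k in range(i + 2, last + 1):
            if self.model.can_pair(word, i, k - 1):
                if self.model.no_lonely_pairs and not self.model.can_pair(
                    word, i + 1, k - 2
                ):
                    continue
                alts.append(Alt("split", (Sub(self._closed, (i, k)), Sub("S", (k, j)))))
        return alts

    def _pair_alts(self, i: int, j: int, word: str, inner: str | None) -> list[Alt]:
        """Alternatives for a closed subword: ``stack`` over an inner closed
        pair when admissible, plus (unless ``inner`` is None) ``pair`` over
        the not-fully-closed remainder."""
        if j - i < 2 or not self.model.can_pair(word, i, j - 1):
            return []
        left = Term((word[i], i))
        right = Term((word[j - 1], j - 1))
        alts: list[Alt] = []
        stack_nt = "R" if self.model.no_lonely_pairs else "P"
        if self.model.can_pair(word, i + 1, j - 2):
            alts.append(Alt("stack", (left, Sub(stack_nt, (i + 1, j - 1)), right)))
        if inner is not None:
            alts.append(Alt("pair", (left, Sub(inner, (i + 1, j - 1)), right)))
        return alts

    def alternatives(self, nt: str, key: tuple, word: str) -> list[Alt]:
        i, j = key
        if nt == "S":
            return self._open_alts(i, j, word, exclude_full=False)
        if nt == "Q":
            return self._open_alts(i, j, word, exclude_full=True)
        if nt == "P" or nt == "R":
            return self._pair_alts(i, j, word, inner="Q")
        if nt == "C":  # outermost pair of a helix: must stack
            return self._pair_alts(i, j, word, inner=None)
        raise KeyError(nt)


def energy_algebra(model: FoldModel) -> EvaluationAlgebra:
    """Free-energy-like score, minimized: per-pair plus per-stack terms."""
    pe, se = model.pair_energy, model.stack_energy
    fns = {
        "nil": lambda: 0.0,
        "unp": lambda t, x: x,
        "split": lambda x, y: x + y,
        "pair": lambda l, x, r: x + pe,
        "stack": lambda l, x, r: x + pe + se,
    }
    return EvaluationAlgebra("energy", FOLD_SIGNATURE, fns, choice_min, "min")


def mea_algebra(psi: np.ndarray) -> EvaluationAlgebra:
    """Accumulated base-pair probability of the paired positions, maximized.
    (A plain pair-probability sum; no unpaired-probability term.)"""
    fns = {
        "nil": lambda: 0.0,
        "unp": lambda t, x: x,
        "split": lambda x, y: x + y,
        "pair": lambda l, x, r: x + float(psi[l[1], r[1]]),
        "stack": lambda l, x, r: x + float(psi[l[1], r[1]]),
    }
    return EvaluationAlgebra("mea", FOLD_SIGNATURE, fns, choice_max, "max")


# ---------------------------------------------------------------------------
# Partition function / pair probabilities

def _local_energy(symbol: str, model: FoldModel) -> float:
    if symbol == "pair":
        return model.pair_energy
    if symbol == "stack":
        return model.pair_energy + model.stack_energy
    return 0.0


def partition_pairprobs(seq: RNASequence, model: FoldModel | None = None) -> np.ndarray:
    """Pair-probability matrix over the Boltzmann-weighted structure
    ensemble of ``model``: ``psi[i, j]`` is the total weight of structures
    containing pair (i, j), divided by the partition function.  Computed by
    an inside-outside pass over the folding grammar in log space; symmetric;
    zero for non-admissible pairs.
    """
    model = model or FoldModel()
    word = seq.residues
    n = len(word)
    grammar = FoldGrammar(model)
    keys = list(grammar.subproblem_order(word))
    NEG = -math.inf

    inside: dict = {nt: {} for nt in grammar.nonterminals}
    for key in keys:
        for nt in grammar.nonterminals:
            acc = NEG
            for alt in grammar.alternatives(nt, key, word):
                w = -model.beta * _local_energy(alt.symbol, model)
                spec = grammar.signature.symbols[alt.symbol]
                ok = True
                for kind, arg in zip(spec.kinds, alt.args):
                    if kind == "sub":
                        child = inside[arg.nonterminal][arg.key]
                        if child == NEG:
                            ok = False
                            break
                        w += child
                if ok:
                    acc = np.logaddexp(acc, w)
            inside[nt][key] = acc

    log_z = inside[grammar.axiom][grammar.axiom_key(word)]
    psi = np.zeros((n, n))
    if log_z == NEG:
        return psi

    outside: dict = {nt: {k: NEG for k in keys} for nt in grammar.nonterminals}
    outside[grammar.axiom][grammar.axiom_key(word)] = 0.0
    for key in reversed(keys):
        for nt in reversed(grammar.nonterminals):
            out = outside[nt][key]
            if out == NEG:
                continue
            for alt in grammar.alternatives(nt, key, word):
                base = out - model.beta * _local_energy(alt.symbol, model)
                spec = grammar.signature.symbols[alt.symbol]
                subs = [
                    arg
                    for kind, arg in zip(spec.kinds, alt.args)
                    if kind == "sub"
                ]
                ins = [inside[s.nonterminal][s.key] for s in subs]
                if any(v == NEG for v in ins):
                    continue
                total_in = sum(ins)
                for s, v in zip(subs, ins):
                    contrib = base + total_in - v
                    outside[s.nonterminal][s.key] = np.logaddexp(
                        outside[s.nonterminal][s.key], contrib
                    )

    pair_nts = ("R", "C") if model.no_lonely_pairs else ("P",)
    for nt in pair_nts:
        for (i, j), li in inside[nt].items():
            lo = outside[nt][(i, j)]
            if li == NEG or lo == NEG:
                continue
            psi[i, j - 1] += math.exp(li + lo - log_z)
    psi = psi + psi.T
    return psi


# ---------------------------------------------------------------------------
# Pareto folding

def structure_pairs(term: tuple) -> frozenset[tuple[int, int]]:
    """Base pairs (i, j), i < j, of a candidate term."""
    pairs: set[tuple[int, int]] = set()

    def walk(t: tuple) -> None:
        symbol = t[0]
        if symbol in ("pair", "stack"):
            left, inner, right = t[1], t[2], t[3]
            pairs.add((left[1], right[1]))
            walk(inner)
        elif symbol == "unp":
            walk(t[2])
        elif symbol == "split":
            walk(t[1])
            walk(t[2])

    walk(term)
    return frozenset(pairs)


def dot_bracket(pairs: Iterable[tuple[int, int]], n: int) -> str:
    out = ["."] * n
    for i, j in pairs:
        out[i] = "("
        out[j] = ")"
    return "".join(out)


@dataclass(frozen=True)
class FrontEntry:
    energy: float
    mea: float
    structure: str
    pairs: frozenset[tuple[int, int]]


@dataclass(frozen=True)
class FoldResult:
    sequence: RNASequence
    entries: tuple[FrontEntry, ...]
    psi: np.ndarray = field(repr=False, compare=False, default=None)

    def __len__(self) -> int:
        return len(self.entries)

    def coords(self) -> list[tuple[float, float]]:
        return [(e.energy, e.mea) for e in self.entries]


def fold_pareto(
    seq: RNASequence,
    model: FoldModel | None = None,
    strategy: str = "eager",
    pf_variant: str | None = None,
    *,
    psi: np.ndarray | None = None,
    max_length: int = 200,
    debug: bool = False,
    stats: OpStats | None = None,
) -> FoldResult:
    """Exact Pareto front of (energy, accumulated pair probability) over the
    folding space, with one witness structure per front element.  Entries
    are reported best-energy first."""
    model = model or FoldModel()
    if len(seq) == 0:
        raise ValueError("cannot fold an empty sequence")
    if len(seq) > max_length:
        raise ValueError(
            f"sequence {seq.id!r} has length {len(seq)} > bound {max_length}"
        )
    if psi is None:
        psi = partition_pairprobs(seq, model)
    if psi.shape != (len(seq), len(seq)):
        raise ValueError("pair-probability matrix does not match sequence length")
    grammar = FoldGrammar(model)
    algebra = product_pareto(
        energy_algebra(model),
        mea_algebra(psi),
        strategy,
        pf_variant,
        witness=True,
        stats=stats,
    )
    front = evaluate(grammar, algebra, seq.residues, debug=debug)
    entries = []
    for item in front:
        pairs = structure_pairs(item[2])
        entries.append(
            FrontEntry(
                energy=item[0],
                mea=item[1],
                structure=dot_bracket(pairs, len(seq)),
                pairs=pairs,
            )
        )
    entries.sort(key=lambda e: (e.energy, -e.mea))
    return FoldResult(seq, tuple(entries), psi)
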
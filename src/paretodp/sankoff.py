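"""Joint pairwise RNA alignment and consensus folding (the Sankoff problem)
under the Pareto product of sequence similarity and base pairing.

Candidates are alignments of two sequences (match / insert / delete
columns) decorated with a non-crossing set of consensus pairs between
match columns.  Two maximizing algebras score each candidate: ``SIM``
(match/mismatch + gap penalties, with the *corrected* variant also scoring
the paired columns for similarity, and the *schnattinger* variant leaving
them unscored) and ``PROB`` (accumulated pair probabilities of the pairs
projected onto both sequences).

Besides the grammar-based evaluation, :func:`sankoff_fronts_direct`
implements the underlying four-index recurrences directly (with a
brute-force Pareto step), serving as a cross-implementation oracle.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal

import numpy as np

from .engine import (
    Alt,
    EvaluationAlgebra,
    Signature,
    Sub,
    Term,
    TreeGrammar,
    choice_max,
    evaluate,
    product_pareto,
)
from .fold import FoldModel, RNASequence, dot_bracket, partition_pairprobs
from .pareto import OrderSpec, brute_force_front

__all__ = [
    "SankoffParams",
    "SankoffInput",
    "SankoffGrammar",
    "SANKOFF_SIGNATURE",
    "sim_algebra",
    "prob_algebra",
    "sankoff_pareto",
    "sankoff_fronts_direct",
    "SankoffResult",
    "SankoffEntry",
    "indicator_pairprobs",
    "front_size_report",
]

Variant = Literal["corrected", "schnattinger"]


@dataclass(frozen=True)
class SankoffParams:
    """Scoring parameters: gap penalty ``gamma`` (negative), match/mismatch
    scores (``sigma(a, b)`` is ``match`` if equal else ``mismatch``), the
    SIM variant and the minimum hairpin-loop size enforced inside paired
    regions on both sequences."""

    gamma: float = -3.0
    match: float = 1.0
    mismatch: float = 0.0
    variant: Variant = "corrected"
    minloop: int = 3

    def __post_init__(self) -> None:
        if self.gamma >= 0:
            raise ValueError("gamma must be negative")
        if self.match < 0 or self.mismatch < 0:
            raise ValueError("sigma scores must be nonnegative")
        if self.variant not in ("corrected", "schnattinger"):
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.minloop < 0:
            raise ValueError("minloop must be >= 0")

    def sigma(self, a: str, b: str) -> float:
        return self.match if a == b else self.mismatch


@dataclass(frozen=True)
class SankoffInput:
    x: RNASequence
    y: RNASequence
    psi_x: np.ndarray
    psi_y: np.ndarray

    def __post_init__(self) -> None:
        if self.psi_x.shape != (len(self.x), len(self.x)):
            raise ValueError("psi_x does not match sequence x")
        if self.psi_y.shape != (len(self.y), len(self.y)):
            raise ValueError("psi_y does not match sequence y")

    @staticmethod
    def build(
        x: RNASequence,
        y: RNASequence,
        psi_mode: str = "partition",
        model: FoldModel | None = None,
    ) -> "SankoffInput":
        model = model or FoldModel()
        if psi_mode == "partition":
            px = partition_pairprobs(x, model)
            py = partition_pairprobs(y, model)
        elif psi_mode == "indicator":
            px = indicator_pairprobs(x, model)
            py = indicator_pairprobs(y, model)
        else:
            raise ValueError(f"unknown psi mode {psi_mode!r}")
        return SankoffInput(x, y, px, py)


def indicator_pairprobs(seq: RNASequence, model: FoldModel | None = None) -> np.ndarray:
    """Fully discrete stand-in for pair probabilities: 1 for every
    admissible pair, 0 otherwise."""
    model = model or FoldModel()
    n = len(seq)
    psi = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if model.can_pair(seq.residues, i, j):
                psi[i, j] = psi[j, i] = 1.0
    return psi


# Tokens are columns: ((char_x, pos_x) | None, (char_y, pos_y) | None).
SANKOFF_SIGNATURE = Signature.of(
    "sankoff",
    nil=(),
    NoStr=("sub", "sub"),
    Split=("sub", "sub"),
    Pair=("term", "sub", "term"),
    Ins=("term",),
    Del=("term",),
    Match=("term",),
)


class SankoffGrammar(TreeGrammar):
    """Search space over joint subwords ``(i, j, k, l)`` (half-open windows
    of x and y).  The leftmost event is either a single column (match,
    insert or delete, wrapped by ``NoStr``) or a paired region: ``Split``
    of a closed ``P`` part — whose boundary match columns carry the
    consensus pair — and the remainder.
    """

    signature = SANKOFF_SIGNATURE
    nonterminals = ("M", "I", "D", "P", "A")
    axiom = "A"

    def __init__(self, minloop: int = 3):
        self.minloop = minloop

    def subproblem_order(self, word: tuple[str, str]) -> Iterable[tuple]:
        x, y = word
        nx, ny = len(x), len(y)
        windows_x = [(i, j) for i in range(nx + 1) for j in range(i, nx + 1)]
        windows_y = [(k, l) for k in range(ny + 1) for l in range(k, ny + 1)]
        keys = [
            (i, j, k, l) for (i, j) in windows_x for (k, l) in windows_y
        ]
        keys.sort(key=lambda t: (t[1] - t[0]) + (t[3] - t[2]))
        return keys

    def axiom_key(self, word: tuple[str, str]) -> tuple:
        x, y = word
        return (0, len(x), 0, len(y))

    def _pair_ok(self, i: int, h: int, k: int, q: int) -> bool:
        # pair x[i]..x[h-1], y[k]..y[q-1]; hairpin loops on both sides
        return h - i - 2 >= self.minloop and q - k - 2 >= self.minloop

    def alternatives(self, nt: str, key: tuple, word: tuple[str, str]) -> list[Alt]:
        x, y = word
        i, j, k, l = key
        if nt == "M":
            if j == i + 1 and l == k + 1:
                return [Alt("Match", (Term(((x[i], i), (y[k], k))),))]
            return []
        if nt == "I":
            if j == i and l == k + 1:
                return [Alt("Ins", (Term((None, (y[k], k))),))]
            return []
        if nt == "D":
            if j == i + 1 and l == k:
                return [Alt("Del", (Term(((x[i], i), None)),))]
            return []
        if nt == "P":
            if j - i >= 2 and l - k >= 2 and self._pair_ok(i, j, k, l):
                left = Term(((x[i], i), (y[k], k)))
                right = Term(((x[j - 1], j - 1), (y[l - 1], l - 1)))
                return [
                    Alt(
                        "Pair",
                        (left, Sub("A", (i + 1, j - 1, k + 1, l - 1)), right),
                    )
                ]
            return []
        if nt == "A":
            alts: list[Alt] = []
            if i == j and k == l:
                return [Alt("nil", ())]
            if i < j and k < l:
                alts.append(
                    Alt(
                        "NoStr",
                        (
                            Sub("M", (i, i + 1, k, k + 1)),
                            Sub("A", (i + 1, j, k + 1, l)),
                        ),
                    )
                )
            if k < l:
                alts.append(
                    Alt(
                        "NoStr",
                        (Sub("I", (i, i, k, k + 1)), Sub("A", (i, j, k + 1, l))),
                    )
                )
            if i < j:
                alts.append(
                    Alt(
                        "NoStr",
                        (Sub("D", (i, i + 1, k, k)), Sub("A", (i + 1, j, k, l))),
                    )
                )
            for h in range(i + 2, j + 1):
                for q in range(k + 2, l + 1):
                    if self._pair_ok(i, h, k, q):
                        alts.append(
                            Alt(
                                "Split",
                                (Sub("P", (i, h, k, q)), Sub("A", (h, j, q, l))),
                            )
                        )
            return alts
        raise KeyError(nt)


def sim_algebra(params: SankoffParams) -> EvaluationAlgebra:
    """Sequence-similarity score, maximized.  The corrected variant scores
    the two match columns consumed by ``Pair``; the schnattinger variant
    leaves them unscored (the anti-correlated historical behaviour)."""
    sigma, gamma = params.sigma, params.gamma

    # Pair tokens are ((char, pos), (char, pos)) match columns.
    def pair_fn(left, x, right):
        if params.variant == "schnattinger":
            return x
        la, lb = left
        ra, rb = right
        return x + sigma(la[0], lb[0]) + sigma(ra[0], rb[0])

    fns = {
        "nil": lambda: 0.0,
        "NoStr": lambda u, v: u + v,
        "Split": lambda u, v: u + v,
        "Pair": pair_fn,
        "Ins": lambda t: gamma,
        "Del": lambda t: gamma,
        "Match": lambda t: sigma(t[0][0], t[1][0]),
    }
    return EvaluationAlgebra("SIM", SANKOFF_SIGNATURE, fns, choice_max, "max")


def prob_algebra(inp: SankoffInput) -> EvaluationAlgebra:
    """Consensus base-pairing score, maximized: each consensus pair adds the
    pair probabilities of its projections onto both sequences (looked up by
    position)."""
    psi_x, psi_y = inp.psi_x, inp.psi_y

    def pair_fn(left, x, right):
        la, lb = left
        ra, rb = right
        return x + float(psi_x[la[1], ra[1]]) + float(psi_y[lb[1], rb[1]])

    fns = {
        "nil": lambda: 0.0,
        "NoStr": lambda u, v: u + v,
        "Split": lambda u, v: u + v,
        "Pair": pair_fn,
        "Ins": lambda t: 0.0,
        "Del": lambda t: 0.0,
        "Match": lambda t: 0.0,
    }
    return EvaluationAlgebra("PROB", SANKOFF_SIGNATURE, fns, choice_max, "max")


# ---------------------------------------------------------------------------
# Candidate decoding

@dataclass(frozen=True)
class SankoffEntry:
    sim: float
    prob: float
    aligned_x: str
    aligned_y: str
    consensus: str


@dataclass(frozen=True)
class SankoffResult:
    input: SankoffInput
    params: SankoffParams
    entries: tuple[SankoffEntry, ...]

    def __len__(self) -> int:
        return len(self.entries)

    def coords(self) -> list[tuple[float, float]]:
        return [(e.sim, e.prob) for e in self.entries]


def decode_candidate(term: tuple) -> tuple[list, set]:
    """Columns (as (x-token | None, y-token | None)) and consensus pairs (as
    column-index pairs) of a candidate term."""
    columns: list = []
    pairs: set = set()

    def walk(t: tuple) -> None:
        symbol = t[0]
        if symbol == "nil":
            return
        if symbol == "NoStr":
            walk(t[1])
            walk(t[2])
        elif symbol == "Split":
            walk(t[1])
            walk(t[2])
        elif symbol in ("Match", "Ins", "Del"):
            columns.append(t[1])
        elif symbol == "Pair":
            left_idx = len(columns)
            columns.append(t[1])
            walk(t[2])
            right_idx = len(columns)
            columns.append(t[3])
            pairs.add((left_idx, right_idx))

    walk(term)
    return columns, pairs


def _entry_from_item(item: tuple) -> SankoffEntry:
    columns, pairs = decode_candidate(item[2])
    ax = "".join(c[0][0] if c[0] else "-" for c in columns)
    ay = "".join(c[1][0] if c[1] else "-" for c in columns)
    return SankoffEntry(
        sim=item[0],
        prob=item[1],
        aligned_x=ax,
        aligned_y=ay,
        consensus=dot_bracket(pairs, len(columns)),
    )


def sankoff_pareto(
    inp: SankoffInput,
    params: SankoffParams | None = None,
    strategy: str = "eager",
    pf_variant: str | None = None,
    *,
    max_length: int = 40,
    debug: bool = False,
) -> SankoffResult:
    """Exact Pareto front of (SIM, PROB) over the joint
    alignment-and-folding space, with one witness candidate per element.
    Quartic in sequence length; refuses inputs beyond ``max_length``."""
    params = params or SankoffParams()
    if len(inp.x) > max_length or len(inp.y) > max_length:
        raise ValueError(
            f"sequences of lengths {len(inp.x)}/{len(inp.y)} exceed the bound "
            f"{max_length}; the recursion is O(n^4) cells — raise max_length "
            "explicitly if you accept the cost"
        )
    grammar = SankoffGrammar(minloop=params.minloop)
    algebra = product_pareto(
        sim_algebra(params),
        prob_algebra(inp),
        strategy,
        pf_variant,
        witness=True,
    )
    front = evaluate(grammar, algebra, (inp.x.residues, inp.y.residues), debug=debug)
    entries = tuple(
        sorted(
            (_entry_from_item(it) for it in front),
            key=lambda e: (-e.sim, -e.prob),
        )
    )
    return SankoffResult(inp, params, entries)


def sankoff_fronts_direct(
    inp: SankoffInput, params: SankoffParams | None = None
) -> frozenset[tuple[float, float]]:
    """Direct four-index implementation of the alignment-and-folding
    recurrences with a brute-force Pareto step at every cell; returns the
    front coordinates only.  Independent of the grammar machinery: used to
    cross-validate it."""
    params = params or SankoffParams()
    x, y = inp.x.residues, inp.y.residues
    nx, ny = len(x), len(y)
    orders = OrderSpec("max", "max")
    minloop = params.minloop
    sigma, gamma = params.sigma, params.gamma

    S: dict = {}
    keys = [
        (i, j, k, l)
        for i in range(nx + 1)
        for j in range(i, nx + 1)
        for k in range(ny + 1)
        for l in range(k, ny + 1)
    ]
    keys.sort(key=lambda t: (t[1] - t[0]) + (t[3] - t[2]))
    for (i, j, k, l) in keys:
        cands: list[tuple[float, float]] = []
        if i == j and k == l:
            cands.append((0.0, 0.0))
        if j > i:  # delete x[j-1]
            cands.extend((s + gamma, p) for s, p in S[(i, j - 1, k, l)])
        if l > k:  # insert y[l-1]
            cands.extend((s + gamma, p) for s, p in S[(i, j, k, l - 1)])
        if j > i and l > k:  # unpaired match column
            sc = sigma(x[j - 1], y[l - 1])
            cands.extend((s + sc, p) for s, p in S[(i, j - 1, k, l - 1)])
        # paired region as a suffix: pair (h, j-1) in x and (q, l-1) in y
        for h in range(i, j - 1):
            for q in range(k, l - 1):
                if j - 1 - h - 1 < minloop or l - 1 - q - 1 < minloop:
                    continue
                if params.variant == "schnattinger":
                    pair_sim = 0.0
                else:
                    pair_sim = sigma(x[h], y[q]) + sigma(x[j - 1], y[l - 1])
                pair_prob = float(inp.psi_x[h, j - 1]) + float(inp.psi_y[q, l - 1])
                before = S[(i, h, k, q)]
                inner = S[(h + 1, j - 1, q + 1, l - 1)]
                for s0, p0 in before:
                    for s1, p1 in inner:
                        cands.append((s0 + s1 + pair_sim, p0 + p1 + pair_prob))
        S[(i, j, k, l)] = [
            (p[0], p[1]) for p in brute_force_front(cands, orders).pairs
        ]
    return frozenset(S[(0, nx, 0, ny)])


def front_size_report(
    pairs: Iterable[tuple[RNASequence, RNASequence]],
    params: SankoffParams | None = None,
    psi_mode: str = "partition",
    model: FoldModel | None = None,
    groups: Iterable[str] | None = None,
    **kwargs,
) -> tuple[list[dict], dict[str, float]]:
    """Per-pair Pareto-front sizes plus per-group means; a small front is
    the screening signal for homologous pairs."""
    params = params or SankoffParams()
    pairs = list(pairs)
    groups = list(groups) if groups is not None else ["all"] * len(pairs)
    if len(groups) != len(pairs):
        raise ValueError("one group label per pair required")
    rows = []
    for (sx, sy), group in zip(pairs, groups):
        inp = SankoffInput.build(sx, sy, psi_mode=psi_mode, model=model)
        result = sankoff_pareto(inp, params, **kwargs)
        rows.append(
            {
                "id_x": sx.id,
                "id_y": sy.id,
                "total_length": len(sx) + len(sy),
                "front_size": len(result),
                "group": group,
            }
        )
    summary: dict[str, float] = {}
    for g in sorted(set(groups)):
        sizes = [r["front_size"] for r in rows if r["group"] == g]
        summary[g] = float(sum(sizes)) / len(sizes)
    return rows, summary
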
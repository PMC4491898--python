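"""Seeded synthetic data and the simulation / benchmarking studies.

Everything here is deterministic given its seed; the test suite and the
acceptance script draw all inputs from this module instead of external
files.
"""

from __future__ import annotations

import time
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .fold import RNASequence
from .pareto import (
    MAX_MAX,
    OpStats,
    OrderSpec,
    PF_VARIANTS,
    harmonic,
    pareto_merge,
    pf_sort,
)

__all__ = [
    "SyntheticSpec",
    "generate_sequences",
    "random_pairs",
    "anticorrelated_pairs",
    "simulate_front_size",
    "FrontSizeSim",
    "bench_pf",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Specification for a reproducible batch of random RNA sequences."""

    n_sequences: int = 10
    min_length: int = 10
    max_length: int = 10
    gc_content: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sequences < 0 or self.min_length < 0:
            raise ValueError("negative sizes")
        if self.max_length < self.min_length:
            raise ValueError("max_length < min_length")
        if not 0.0 <= self.gc_content <= 1.0:
            raise ValueError("gc_content must lie in [0, 1]")


def generate_sequences(spec: SyntheticSpec) -> list[RNASequence]:
    """Random sequences with the requested GC content; byte-identical for
    identical (spec, seed)."""
    rng = np.random.default_rng(spec.seed)
    gc = spec.gc_content
    probs = [gc / 2, gc / 2, (1 - gc) / 2, (1 - gc) / 2]
    seqs = []
    for idx in range(spec.n_sequences):
        length = int(rng.integers(spec.min_length, spec.max_length + 1))
        residues = "".join(rng.choice(list("GCAU"), size=length, p=probs))
        seqs.append(RNASequence(f"synth_{spec.seed}_{idx}", residues))
    return seqs


def random_pairs(n: int, rng: np.random.Generator) -> list[tuple[float, float]]:
    """i.i.d. continuous-uniform score pairs (ties have measure zero)."""
    arr = rng.random((n, 2))
    return [(float(a), float(b)) for a, b in arr]


def anticorrelated_pairs(
    m: int, rng: np.random.Generator | None = None
) -> list[tuple[int, int]]:
    """The adversarial integer-grid input {(i, M - i + 1)}: every element is
    on the front.  Shuffled when an rng is given."""
    pairs = [(i, m - i + 1) for i in range(1, m + 1)]
    if rng is not None:
        rng.shuffle(pairs)
    return pairs


@dataclass(frozen=True)
class FrontSizeSim:
    n: int
    replicates: int
    mean: float
    se: float
    expected: float

    @property
    def z(self) -> float:
        return (self.mean - self.expected) / self.se if self.se > 0 else 0.0


def simulate_front_size(n: int, replicates: int, seed: int = 0) -> FrontSizeSim:
    """Monte-Carlo check of the harmonic-law expectation: mean front size of
    ``replicates`` random sets of ``n`` continuous-uniform pairs, with
    standard error, against H(n)."""
    if n < 1 or replicates < 1:
        raise ValueError("n and replicates must be >= 1")
    rng = np.random.default_rng(seed)
    sizes = np.empty(replicates)
    for r in range(replicates):
        sizes[r] = len(pf_sort(random_pairs(n, rng)))
    mean = float(sizes.mean())
    se = float(sizes.std(ddof=1) / np.sqrt(replicates)) if replicates > 1 else 0.0
    return FrontSizeSim(n, replicates, mean, se, harmonic(n))


def bench_pf(
    sizes: Sequence[int],
    distributions: Sequence[str] = ("random", "sorted", "anticorrelated"),
    seed: int = 0,
    orders: OrderSpec = MAX_MAX,
) -> list[dict]:
    """Comparison-count (and informational wall-time) table for the five
    front operators and the linear merge, on random, pre-sorted and
    adversarial anti-correlated inputs.  All variants are gated on
    producing set-equal fronts.  The ``sort`` variant's count includes an
    n*log2(n) estimate for its sorting phase (the Python sort does not
    expose comparisons)."""
    rng = np.random.default_rng(seed)
    rows: list[dict] = []
    for dist in distributions:
        for n in sizes:
            if dist == "random":
                data = random_pairs(n, rng)
            elif dist == "sorted":
                data = sorted(random_pairs(n, rng), key=orders.sort_key)
            elif dist == "anticorrelated":
                data = [(float(a), float(b)) for a, b in anticorrelated_pairs(n, rng)]
            else:
                raise ValueError(f"unknown distribution {dist!r}")
            reference = None
            for name, pf in PF_VARIANTS.items():
                if name == "lex" and dist != "sorted":
                    continue  # precondition does not hold
                stats = OpStats()
                t0 = time.perf_counter()
                front = pf(data, orders, stats=stats)
                elapsed = time.perf_counter() - t0
                if reference is None:
                    reference = front.as_set()
                elif front.as_set() != reference:
                    raise AssertionError(
                        f"pf_{name} disagrees on {dist} input of size {n}"
                    )
                rows.append(
                    {
                        "operator": f"pf_{name}",
                        "distribution": dist,
                        "n": n,
                        "front_size": len(front),
                        "comparisons": stats.comparisons,
                        "seconds": elapsed,
                    }
                )
            # linear merge of two halves, both already fronts
            half = len(data) // 2
            fx = pf_sort(data[:half], orders)
            fy = pf_sort(data[half:], orders)
            stats = OpStats()
            t0 = time.perf_counter()
            merged = pareto_merge(fx, fy, orders, stats=stats)
            elapsed = time.perf_counter() - t0
            if merged.as_set() != reference:
                raise AssertionError(f"pareto_merge disagrees on {dist}/{n}")
            rows.append(
                {
                    "operator": "pareto_merge",
                    "distribution": dist,
                    "n": len(fx) + len(fy),
                    "front_size": len(merged),
                    "comparisons": stats.comparisons,
                    "seconds": elapsed,
                }
            )
    return rows
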
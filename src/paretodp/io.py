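"""FASTA input and TSV/dot-bracket/aligned-FASTA output."""

from __future__ import annotations

import sys
from pathlib import Path
from typing import IO, Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .fold import FoldResult, RNASequence
from .pareto import ParetoFront
from .sankoff import SankoffResult

__all__ = [
    "InputError",
    "read_fasta",
    "write_fasta",
    "write_front_tsv",
    "write_fold_report",
    "write_sankoff_report",
]


class InputError(ValueError):
    """Malformed input data (CLI exit code 3)."""


def read_fasta(path: str | Path) -> list[RNASequence]:
    """Parse a (possibly multi-record) FASTA file into validated RNA
    sequences.  ``T`` is stored as ``U``; case is folded.  Malformed
    records raise :class:`InputError` naming the record index."""
    records = []
    try:
        parsed = list(SeqIO.parse(str(path), "fasta"))
    except (OSError, ValueError) as exc:
        raise InputError(f"cannot read FASTA file {path}: {exc}") from exc
    for idx, rec in enumerate(parsed):
        try:
            records.append(RNASequence.parse(rec.id, str(rec.seq)))
        except ValueError as exc:
            raise InputError(f"record {idx} ({rec.id!r}): {exc}") from exc
    return records


def write_fasta(seqs: Iterable[RNASequence], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(s.residues), id=s.id, description="") for s in seqs
    ]
    SeqIO.write(records, str(path), "fasta")


def _header(out: IO[str], config: dict | None) -> None:
    if config:
        for key in sorted(config):
            out.write(f"# {key}={config[key]}\n")


def write_front_tsv(
    front: ParetoFront | Sequence,
    out: IO[str] = sys.stdout,
    labels: Sequence[str] | None = None,
    config: dict | None = None,
) -> None:
    """One row per front element: score_a, score_b and an optional label."""
    _header(out, config)
    cols = ["score_a", "score_b"] + (["label"] if labels is not None else [])
    out.write("\t".join(cols) + "\n")
    for idx, p in enumerate(front):
        row = [repr(float(p[0])), repr(float(p[1]))]
        if labels is not None:
            row.append(labels[idx])
        out.write("\t".join(row) + "\n")


def write_fold_report(
    result: FoldResult, out: IO[str] = sys.stdout, config: dict | None = None
) -> None:
    _header(out, config)
    out.write(f">{result.sequence.id}\n{result.sequence.residues}\n")
    out.write("energy\tmea\tstructure\n")
    for e in result.entries:
        out.write(f"{e.energy!r}\t{e.mea!r}\t{e.structure}\n")


def write_sankoff_report(
    result: SankoffResult, out: IO[str] = sys.stdout, config: dict | None = None
) -> None:
    _header(out, config)
    out.write("sim\tprob\talignment\n")
    for idx, e in enumerate(result.entries):
        out.write(f"{e.sim!r}\t{e.prob!r}\tcandidate_{idx}\n")
    for idx, e in enumerate(result.entries):
        out.write(f">{result.input.x.id}|candidate_{idx}\n{e.aligned_x}\n")
        out.write(f">{result.input.y.id}|candidate_{idx}\n{e.aligned_y}\n")
        out.write(f";consensus|candidate_{idx}\n{e.consensus}\n")
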
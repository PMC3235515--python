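"""FASTA input/output and nucleotide string utilities.

Contigs arrive as (optionally gzip-compressed) multi-FASTA. Records keep the
uppercased raw sequence; ambiguity codes are handled downstream by
:func:`sanitize`, which splits a sequence into maximal A/C/G/T runs so that
word counting never spans an ambiguous position.
"""

from __future__ import annotations

import gzip
import io
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Union

__all__ = [
    "SequenceRecord",
    "FastaError",
    "read_fasta",
    "write_fasta",
    "reverse_complement",
    "sanitize",
]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_ACGT_RUN = re.compile(r"[ACGT]+")
_NON_ACGT = re.compile(r"[^ACGT]")


class FastaError(ValueError):
    """Malformed FASTA input; message carries the offending line number."""


@dataclass(frozen=True)
class SequenceRecord:
    """One contig/scaffold: id (first header token), description, sequence."""

    id: str
    sequence: str
    description: str = ""

    @property
    def length(self) -> int:
        return len(self.sequence)

    def slice(self, start: int, stop: int, new_id: str | None = None) -> "SequenceRecord":
        """Subsequence as a new record (used to split genomes into regions)."""
        return SequenceRecord(
            id=new_id or f"{self.id}:{start}-{stop}",
            sequence=self.sequence[start:stop],
            description=self.description,
        )


def _open_text(path: Union[str, Path], mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path: Union[str, Path]) -> list[SequenceRecord]:
    """Read a multi-FASTA file into a list of records, in file order.

    Sequence lines are concatenated and uppercased. Raises
    :class:`FastaError` with a line number for structural problems:
    sequence data before the first header, duplicate record ids, or an
    empty file. A missing file raises :class:`FileNotFoundError`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"FASTA file not found: {path}")

    records: list[SequenceRecord] = []
    seen: dict[str, int] = {}
    header: tuple[str, str] | None = None  # (id, description)
    chunks: list[str] = []

    def flush() -> None:
        if header is not None:
            records.append(SequenceRecord(header[0], "".join(chunks).upper(), header[1]))

    with _open_text(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                chunks = []
                parts = line[1:].split(None, 1)
                if not parts:
                    raise FastaError(f"{path}:{lineno}: empty FASTA header")
                rid = parts[0]
                if rid in seen:
                    raise FastaError(
                        f"{path}:{lineno}: duplicate sequence id {rid!r} "
                        f"(first seen at line {seen[rid]})"
                    )
                seen[rid] = lineno
                header = (rid, parts[1] if len(parts) > 1 else "")
            else:
                if header is None:
                    raise FastaError(
                        f"{path}:{lineno}: sequence data before any '>' header"
                    )
                chunks.append(line)
    flush()
    if not records:
        raise FastaError(f"{path}: empty FASTA file (no records)")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: Union[str, Path], width: int = 70) -> None:
    """Write records as multi-FASTA via Biopython, wrapping at `width`."""
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord as BioRecord

    bio = [
        BioRecord(Seq(r.sequence), id=r.id, description=r.description)
        for r in records
    ]
    with _open_text(path, "wt") as fh:
        if width == 60:
            seqio_write(bio, fh, "fasta")
        else:
            # Bio's "fasta" writer fixes 60-column wrapping; honour `width`.
            for r in bio:
                desc = f" {r.description}" if r.description else ""
                fh.write(f">{r.id}{desc}\n")
                s = str(r.seq)
                for i in range(0, len(s), width):
                    fh.write(s[i : i + width] + "\n")


def reverse_complement(sequence: str) -> str:
    """Watson-Crick reverse complement of an A/C/G/T string."""
    bad = _NON_ACGT.search(sequence)
    if bad:
        raise ValueError(
            f"reverse_complement: character {bad.group()!r} at position "
            f"{bad.start()} is outside the ACGT alphabet"
        )
    return sequence.translate(_COMPLEMENT)[::-1]


def sanitize(raw: str) -> list[str]:
    """Split an IUPAC nucleotide string into maximal A/C/G/T runs.

    Every non-ACGT character (N, ambiguity codes, gaps) is a split point,
    so downstream word counting never produces a word spanning an
    ambiguous base. An all-ambiguous input yields an empty list.
    """
    return _ACGT_RUN.findall(raw.upper())
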
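"""Gzip-aware readers and writers for the sequence formats the pipelines use."""

from __future__ import annotations

import gzip
import hashlib
import io
import json
from pathlib import Path
from typing import Iterator, Tuple

from Bio.SeqIO.QualityIO import FastqGeneralIterator


def open_text(path: str | Path, mode: str = "rt"):
    """Open ``path`` as text, transparently decompressing ``.gz`` files."""
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fastq(path: str | Path) -> Iterator[Tuple[str, str, str]]:
    """Yield ``(read_id, sequence, quality)`` from a FASTQ file.

    The read id is the header up to the first whitespace.
    """
    with open_text(path) as handle:
        for title, seq, qual in FastqGeneralIterator(handle):
            yield title.split()[0], seq.upper(), qual


def read_fastq_seqs(path: str | Path) -> Iterator[Tuple[str, str]]:
    """Yield ``(read_id, sequence)`` pairs from a FASTQ file."""
    for read_id, seq, _qual in read_fastq(path):
        yield read_id, seq


def write_fastq(path: str | Path, records, quality_char: str = "I") -> int:
    """Write ``(read_id, sequence)`` records as FASTQ with constant quality."""
    n = 0
    with open_text(path, "wt") as handle:
        for read_id, seq in records:
            handle.write(f"@{read_id}\n{seq}\n+\n{quality_char * len(seq)}\n")
            n += 1
    return n


def read_single_fasta(path: str | Path) -> Tuple[str, str]:
    """Read a FASTA file that must hold exactly one record."""
    name = None
    chunks: list[str] = []
    with open_text(path) as handle:
        for line in handle:
            line = line.rstrip()
            if not line:
                continue
            if line.startswith(">"):
                if name is not None:
                    raise ValueError(
                        f"{path}: expected a single FASTA record, found more than one"
                    )
                name = line[1:].split()[0]
            else:
                if name is None:
                    raise ValueError(f"{path}: sequence data before FASTA header")
                chunks.append(line.upper())
    if name is None:
        raise ValueError(f"{path}: no FASTA record found")
    return name, "".join(chunks)


def write_fasta(path: str | Path, name: str, sequence: str, width: int = 70) -> None:
    with open_text(path, "wt") as handle:
        handle.write(f">{name}\n")
        for i in range(0, len(sequence), width):
            handle.write(sequence[i : i + width] + "\n")


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as handle:
        for block in iter(lambda: handle.read(1 << 20), b""):
            h.update(block)
    return h.hexdigest()


def write_json(path: str | Path, obj) -> None:
    with open(path, "w") as handle:
        json.dump(obj, handle, indent=2, sort_keys=True)
        handle.write("\n")


def tsv_header_comment(tool_version: str, **params) -> str:
    """One-line ``#`` header recording the tool version and parameters."""
    fields = " ".join(f"{k}={v}" for k, v in sorted(params.items()))
    return f"# preribo v{tool_version} {fields}".rstrip()
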
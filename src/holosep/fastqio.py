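"""Streamed FASTA/FASTQ readers and writers, truth tables and config.

FASTQ is read and written as strict 4-line records (Biopython's fast
``FastqGeneralIterator``); FASTA may wrap. Gzip compression is transparent on
read (by suffix) and selectable on write. Quality strings pass through
untouched — trimming happens upstream and is out of scope here.

Read-id pairing tolerates both Illumina styles: old (``name/1``, ``name/2``)
and new (mate number in a space-separated second field).
"""

from __future__ import annotations

import gzip
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, Iterable, Iterator, Optional, Tuple

import yaml
from Bio import SeqIO
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .classify import ReadFragment
from .errors import PairedFileError

__all__ = [
    "RunConfig",
    "read_fastq_pairs",
    "write_fastq",
    "read_fasta",
    "write_fasta",
    "total_sequence_length",
    "read_truth_tsv",
    "write_truth_tsv",
]


def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def normalize_read_id(title: str) -> str:
    """Strip mate designators: '/1' '/2' suffixes and space-separated fields."""
    head = title.split()[0] if title.split() else title
    if len(head) > 2 and head[-2] == "/" and head[-1] in "12":
        head = head[:-2]
    return head


def read_fastq_pairs(
    path1: str | Path, path2: str | Path | None = None
) -> Iterator[ReadFragment]:
    """Yield fragments from one FASTQ file or a mate pair, in input order.

    With two files, records are paired positionally and their normalized ids
    must agree; a count or id mismatch raises :class:`PairedFileError` naming
    the offending record.
    """
    with _open_text(path1) as h1:
        it1 = FastqGeneralIterator(h1)
        if path2 is None:
            for title, seq, qual in it1:
                yield ReadFragment(id=normalize_read_id(title), seq1=seq,
                                   qual1=qual)
            return
        with _open_text(path2) as h2:
            it2 = FastqGeneralIterator(h2)
            rec = 0
            while True:
                r1 = next(it1, None)
                r2 = next(it2, None)
                rec += 1
                if r1 is None and r2 is None:
                    return
                if r1 is None or r2 is None:
                    longer = str(path1) if r2 is None else str(path2)
                    raise PairedFileError(
                        f"mate files disagree in record count: {longer} has a "
                        f"record {rec} with no mate"
                    )
                id1 = normalize_read_id(r1[0])
                id2 = normalize_read_id(r2[0])
                if id1 != id2:
                    raise PairedFileError(
                        f"record {rec}: ids {id1!r} and {id2!r} do not pair up"
                    )
                yield ReadFragment(id=id1, seq1=r1[1], seq2=r2[1],
                                   qual1=r1[2], qual2=r2[2])


def write_fastq(
    fragments: Iterable[ReadFragment],
    path1: str | Path,
    path2: str | Path | None = None,
) -> Tuple[int, int]:
    """Write fragments as 4-line FASTQ; returns (records written, mates/record).

    Mate 2 goes to ``path2`` when given; single-end fragments in a paired
    write get no R2 record. Paths ending in .gz are gzip-compressed. Missing
    qualities are filled with 'I'.
    """
    n1 = n2 = 0
    h2 = None
    with _open_text(path1, "wt") as h1:
        try:
            if path2 is not None:
                h2 = _open_text(path2, "wt")
            for frag in fragments:
                q1 = frag.qual1 or "I" * len(frag.seq1)
                h1.write(f"@{frag.id}/1\n{frag.seq1}\n+\n{q1}\n")
                n1 += 1
                if h2 is not None and frag.seq2 is not None:
                    q2 = frag.qual2 or "I" * len(frag.seq2)
                    h2.write(f"@{frag.id}/2\n{frag.seq2}\n+\n{q2}\n")
                    n2 += 1
        finally:
            if h2 is not None:
                h2.close()
    return n1, n2


def read_fasta(path: str | Path) -> Iterator[Tuple[str, str]]:
    """Yield (id, sequence) from FASTA (wrapped lines fine, .gz fine)."""
    with _open_text(path) as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            yield rec.id, str(rec.seq)


def write_fasta(records: Iterable[Tuple[str, str]], path: str | Path,
                width: int = 70) -> int:
    n = 0
    with _open_text(path, "wt") as handle:
        for name, seq in records:
            handle.write(f">{name}\n")
            for i in range(0, len(seq), width):
                handle.write(seq[i : i + width] + "\n")
            n += 1
    return n


def total_sequence_length(path: str | Path) -> int:
    """Summed sequence length of a FASTA file (genome-size helper)."""
    return sum(len(seq) for _, seq in read_fasta(path))


def read_truth_tsv(path: str | Path) -> Dict[str, str]:
    truth: Dict[str, str] = {}
    with _open_text(path) as handle:
        for line in handle:
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("id\t"):
                continue
            fid, origin = line.split("\t")[:2]
            truth[fid] = origin
    return truth


def write_truth_tsv(truth: Dict[str, str], path: str | Path) -> None:
    with _open_text(path, "wt") as handle:
        handle.write("id\torigin\n")
        for fid, origin in truth.items():
            handle.write(f"{fid}\t{origin}\n")


@dataclass
class RunConfig:
    """Serializable run parameters; YAML round-trips losslessly."""

    k: int = 21
    canonical: bool = True
    min_count: int = 1
    host_size: float | None = None
    symbiont_size: float | None = None
    likelihood: str = "sum"
    rank_direction: str = "freq-high-first"
    seed: int = 42
    log_level: str = "INFO"
    extra: dict = field(default_factory=dict)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)
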
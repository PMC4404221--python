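"""FASTQ input/output helpers (gzip-transparent), built on Biopython."""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqIO.QualityIO import FastqGeneralIterator
from Bio.SeqRecord import SeqRecord

from .errors import FastqParseError

#: Placeholder Phred quality for simulated reads ('I' = Q40); the pipeline
#: never reads qualities, since parsing is exact-match on sequence only.
PLACEHOLDER_QUALITY = 40


def _open_text(path, mode: str):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode + "t")
    return open(path, mode)


def read_fastq(path) -> Iterator[tuple[str, str]]:
    """Yield (read_id, sequence) from a FASTQ or FASTQ.gz file.

    A malformed record raises :class:`FastqParseError` carrying the 0-based
    index of the failing record.
    """
    index = 0
    with _open_text(path, "r") as handle:
        iterator = FastqGeneralIterator(handle)
        while True:
            try:
                title, seq, _qual = next(iterator)
            except StopIteration:
                return
            except ValueError as exc:
                raise FastqParseError(index, str(exc)) from exc
            yield title.split()[0], seq.upper()
            index += 1


def write_fastq(reads: Iterable[tuple[str, str]], path) -> int:
    """Write (read_id, sequence) pairs as FASTQ with placeholder qualities.

    Returns the number of records written.  Gzip-compresses when the path
    ends in .gz.
    """
    def records():
        for read_id, seq in reads:
            rec = SeqRecord(Seq(seq), id=read_id, description="")
            rec.letter_annotations["phred_quality"] = [PLACEHOLDER_QUALITY] * len(seq)
            yield rec

    with _open_text(path, "w") as handle:
        return SeqIO.write(records(), handle, "fastq")
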
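"""Small shared helpers: rounding, reverse complement, FASTA I/O."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Dict, Iterable, Mapping

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (N-preserving)."""
    return seq.translate(_COMPLEMENT)[::-1]


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties going away from zero, as printed tables do.

    Python's builtin round() is banker's rounding; report tables here use
    the conventional half-up rule (92.55 -> 92.6, 62.5 -> 63).
    """
    quantum = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(quantum, rounding=ROUND_HALF_UP))


def read_fasta(path: str | Path) -> Dict[str, str]:
    """Load a FASTA file as an ordered {name: uppercase sequence} dict."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    records: Iterable[SeqRecord] = (
        SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()
    )
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)
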
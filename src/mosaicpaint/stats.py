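"""Assembly summary statistics (scaffold counts, N50, reference coverage)."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Mapping, Sequence

import numpy as np

from ._util import round_half_up
from .pseudomolecule import AssemblyBuild, coverage_percent


def n50(lengths: Sequence[int]) -> int:
    """Smallest length L such that pieces of length >= L hold half the bases.

    Computed by sorting descending and walking the cumulative sum until it
    reaches half the total; the answer is always one of the input lengths.
    """
    if len(lengths) == 0:
        raise ValueError("n50 of an empty length set is undefined")
    arr = np.sort(np.asarray(lengths, dtype=np.int64))[::-1]
    if (arr <= 0).any():
        raise ValueError("all lengths must be > 0")
    half = arr.sum() / 2.0
    idx = int(np.searchsorted(np.cumsum(arr), half))
    return int(arr[idx])


def total_read_bp(n_reads: int, read_len: int) -> int:
    """Total sequenced bases from a read count and uniform read length."""
    return n_reads * read_len


def sequencing_depth(total_bp: int, reference_size: int) -> float:
    """Fold coverage of a reference by raw sequence, to 1 decimal.

    Defined as total_bp / reference_size; published depth figures may use
    a different (unstated) denominator, so this is a reporting utility,
    not a reproduction of any particular printed value.
    """
    return round_half_up(total_bp / reference_size, 1)


@dataclass
class AsmStats:
    n_scaffolds: int
    total_bp: int
    mean_len: float
    max_len: int
    n50: int
    genome_size: int
    coverage_pct: Dict[str, float]


def summarize(
    scaffolds: Mapping[str, str] | Mapping[str, int],
    build: AssemblyBuild | None = None,
    reference_sizes: Mapping[str, int] | None = None,
) -> AsmStats:
    """All scaffold metrics plus per-reference coverage of the build.

    ``scaffolds`` maps id -> sequence (or id -> length).  When ``build``
    is None, genome_size falls back to total scaffold bases.
    """
    lengths = [
        len(v) if isinstance(v, str) else int(v) for v in scaffolds.values()
    ]
    if not lengths:
        raise ValueError("no scaffolds")
    total = sum(lengths)
    genome_size = build.genome_size if build is not None else total
    coverage = {
        name: coverage_percent(genome_size, size)
        for name, size in (reference_sizes or {}).items()
    }
    return AsmStats(
        n_scaffolds=len(lengths),
        total_bp=total,
        mean_len=total / len(lengths),
        max_len=max(lengths),
        n50=n50(lengths),
        genome_size=genome_size,
        coverage_pct=coverage,
    )


def write_stats(stats: AsmStats, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("metric\tvalue\n")
        fh.write(f"n_scaffolds\t{stats.n_scaffolds}\n")
        fh.write(f"total_bp\t{stats.total_bp}\n")
        fh.write(f"mean_len\t{stats.mean_len:.1f}\n")
        fh.write(f"max_len\t{stats.max_len}\n")
        fh.write(f"N50\t{stats.n50}\n")
        fh.write(f"genome_size\t{stats.genome_size}\n")
        for ref, pct in stats.coverage_pct.items():
            fh.write(f"coverage_pct_{ref}\t{pct}\n")
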
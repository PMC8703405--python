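"""Zoomed view of the painting over a region of interest.

Windows stay on the genome-anchored grid (a window partially overlapping
the region boundary is included whole, so the 50 kb and 100 kb views share
the grid of the whole-genome painting).  A region ``chrom:start-end`` is
treated with boundary-coordinate semantics: the windows kept are those
with index in (floor(start/w), ceil(end/w)], so a window ending exactly at
``start`` is outside the region.  Contiguous same-label windows are then
run-length encoded into origin segments, preserving MISSING runs.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import List, Sequence

from .paint import OriginClass, WindowBlock


@dataclass(frozen=True)
class Region:
    """A 1-based inclusive genomic interval."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"region start must be < end: {self}")


_REGION_RE = re.compile(r"^([^:]+):([\d,]+)-([\d,]+)$")


def parse_region(text: str) -> Region:
    """Parse ``chrom:start-end`` (commas in numbers allowed)."""
    m = _REGION_RE.match(text.strip())
    if not m:
        raise ValueError(f"cannot parse region {text!r}; expected chrom:start-end")
    return Region(m.group(1), int(m.group(2).replace(",", "")), int(m.group(3).replace(",", "")))


def zoom(blocks: Sequence[WindowBlock], region: Region) -> List[WindowBlock]:
    """Windows of ``region``'s chromosome lying within the region bounds.

    Labels and counts are unchanged (no clipping of the windows
    themselves); result ordered by start.  An absent chromosome returns an
    empty list with a warning.
    """
    on_chrom = [b for b in blocks if b.chrom == region.chrom]
    if not on_chrom:
        warnings.warn(
            f"chromosome {region.chrom!r} has no windows", stacklevel=2
        )
        return []
    w = on_chrom[0].end - on_chrom[0].start + 1
    first = region.start // w + 1
    last = (region.end + w - 1) // w
    return sorted(
        (b for b in on_chrom if first <= b.index <= last),
        key=lambda b: b.start,
    )


@dataclass(frozen=True)
class OriginSegment:
    """Maximal run of consecutive windows sharing one dominant label."""

    chrom: str
    start: int
    end: int
    origin: OriginClass
    n_windows: int


def segments(blocks: Sequence[WindowBlock]) -> List[OriginSegment]:
    """Run-length encode dominant labels; MISSING runs are preserved."""
    out: List[OriginSegment] = []
    for b in blocks:
        if (
            out
            and out[-1].chrom == b.chrom
            and out[-1].origin == b.dominant
            and b.start == out[-1].end + 1
        ):
            prev = out[-1]
            out[-1] = OriginSegment(
                prev.chrom, prev.start, b.end, prev.origin, prev.n_windows + 1
            )
        else:
            out.append(OriginSegment(b.chrom, b.start, b.end, b.dominant, 1))
    return out


def write_segments(segs: Sequence[OriginSegment], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\torigin\tn_windows\n")
        for s in segs:
            fh.write(f"{s.chrom}\t{s.start}\t{s.end}\t{s.origin.value}\t{s.n_windows}\n")
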
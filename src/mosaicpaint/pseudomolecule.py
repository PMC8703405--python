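"""Connect placed scaffolds into reference-ordered pseudomolecules.

Per chromosome, placements are sorted by reference start; consecutive
components are separated by an N gap equal to the projected reference gap
(zero if abutting), so pseudomolecule coordinates track the reference.
When projected intervals overlap, the lower-scoring scaffold is trimmed by
the overlap on its conflicting end (dropped entirely if fully contained in
the other).  Minus-strand scaffolds are reverse-complemented before
insertion.  The layout is recorded as AGP v2.1.

``genome_size`` counts scaffold bases only, excluding gap Ns — the
convention under which assembled-genome coverage of a reference is
reported (e.g. 345,442,284 / 373 Mb = 92.6%).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Mapping, Sequence, Tuple

from ._util import revcomp, round_half_up
from .align import Placement


@dataclass(frozen=True)
class AgpRow:
    """One AGP v2.1 row; W = scaffold component, N = gap."""

    obj: str
    obj_start: int
    obj_end: int
    part_number: int
    component_type: str  # 'W' or 'N'
    # W rows:
    component_id: str = ""
    component_start: int = 0
    component_end: int = 0
    orientation: str = "+"
    # N rows:
    gap_length: int = 0


@dataclass
class AssemblyBuild:
    pseudomolecules: Dict[str, str]
    agp: List[AgpRow]
    unplaced: List[str]
    placed_bases: int
    genome_size: int
    components: Dict[str, List[Placement]] = field(default_factory=dict)


def _trim_left(p: Placement, bp: int) -> Placement:
    """Trim ``bp`` bases off the reference-left end of a placement."""
    if p.strand == "+":
        return replace(p, ref_start=p.ref_start + bp, scf_start=p.scf_start + bp)
    return replace(p, ref_start=p.ref_start + bp, scf_end=p.scf_end - bp)


def _trim_right(p: Placement, bp: int) -> Placement:
    if p.strand == "+":
        return replace(p, ref_end=p.ref_end - bp, scf_end=p.scf_end - bp)
    return replace(p, ref_end=p.ref_end - bp, scf_start=p.scf_start + bp)


def _resolve_overlaps(
    placements: List[Placement], dropped: List[str]
) -> List[Placement]:
    """Greedy left-to-right overlap resolution; lower score loses."""
    accepted: List[Placement] = []
    for p in placements:
        while accepted:
            last = accepted[-1]
            if p.ref_start > last.ref_end:
                break
            if p.ref_end <= last.ref_end:  # containment
                if p.score <= last.score:
                    dropped.append(p.scf_id)
                    p = None  # type: ignore[assignment]
                else:
                    dropped.append(last.scf_id)
                    accepted.pop()
                    continue
                break
            overlap = last.ref_end - p.ref_start + 1
            if p.score < last.score:
                p = _trim_left(p, overlap)
                if p.ref_start > p.ref_end:
                    dropped.append(p.scf_id)
                    p = None  # type: ignore[assignment]
            else:
                trimmed = _trim_right(last, overlap)
                if trimmed.ref_start > trimmed.ref_end:
                    dropped.append(last.scf_id)
                    accepted.pop()
                    continue
                accepted[-1] = trimmed
            break
        if p is not None:
            accepted.append(p)
    return accepted


def build_pseudomolecules(
    placements: Sequence[Placement],
    scaffolds: Mapping[str, str],
    reference_lengths: Mapping[str, int] | None = None,
) -> AssemblyBuild:
    """Assemble one pseudomolecule per reference chromosome with placements.

    ``reference_lengths`` is accepted for interface completeness (the
    pseudomolecule ends at the last placed scaffold; no trailing gap is
    padded to the reference length).
    """
    seen: Dict[str, Placement] = {}
    for p in placements:
        if p.scf_id not in scaffolds:
            raise KeyError(f"placement references unknown scaffold {p.scf_id!r}")
        if p.scf_id in seen:
            raise ValueError(f"multiple placements for scaffold {p.scf_id!r}")
        seen[p.scf_id] = p

    by_chrom: Dict[str, List[Placement]] = {}
    for p in placements:
        by_chrom.setdefault(p.ref_chrom, []).append(p)

    pseudo: Dict[str, str] = {}
    agp: List[AgpRow] = []
    dropped: List[str] = []
    components: Dict[str, List[Placement]] = {}
    genome_size = 0

    for chrom in sorted(by_chrom):
        ordered = sorted(
            by_chrom[chrom], key=lambda p: (p.ref_start, p.ref_end, p.scf_id)
        )
        kept = _resolve_overlaps(ordered, dropped)
        components[chrom] = kept
        parts: List[str] = []
        obj_pos = 0
        part_no = 0
        prev_end = 0  # reference coordinate of previous component end
        for p in kept:
            gap = p.ref_start - prev_end - 1
            if gap > 0:
                part_no += 1
                agp.append(
                    AgpRow(
                        obj=chrom,
                        obj_start=obj_pos + 1,
                        obj_end=obj_pos + gap,
                        part_number=part_no,
                        component_type="N",
                        gap_length=gap,
                    )
                )
                parts.append("N" * gap)
                obj_pos += gap
            seq = scaffolds[p.scf_id][p.scf_start - 1 : p.scf_end]
            if p.strand == "-":
                seq = revcomp(seq)
            part_no += 1
            agp.append(
                AgpRow(
                    obj=chrom,
                    obj_start=obj_pos + 1,
                    obj_end=obj_pos + len(seq),
                    part_number=part_no,
                    component_type="W",
                    component_id=p.scf_id,
                    component_start=p.scf_start,
                    component_end=p.scf_end,
                    orientation=p.strand,
                )
            )
            parts.append(seq)
            obj_pos += len(seq)
            genome_size += len(seq)
            prev_end = p.ref_end
        pseudo[chrom] = "".join(parts)

    placed_ids = {p.scf_id for chrom in components for p in components[chrom]}
    unplaced = sorted(set(scaffolds) - placed_ids)
    return AssemblyBuild(
        pseudomolecules=pseudo,
        agp=agp,
        unplaced=unplaced,
        placed_bases=genome_size,
        genome_size=genome_size,
        components=components,
    )


def coverage_percent(genome_size: int, reference_size: int) -> float:
    """Assembled coverage of a reference, percent to 1 decimal (half-up)."""
    if reference_size <= 0:
        raise ValueError("reference_size must be > 0")
    return round_half_up(100.0 * genome_size / reference_size, 1)


# ---------------------------------------------------------------------------
# AGP v2.1 I/O


def write_agp(agp: Sequence[AgpRow], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##agp-version\t2.1\n")
        for r in agp:
            if r.component_type == "N":
                fh.write(
                    f"{r.obj}\t{r.obj_start}\t{r.obj_end}\t{r.part_number}\tN\t"
                    f"{r.gap_length}\tscaffold\tyes\talign_genus\n"
                )
            else:
                fh.write(
                    f"{r.obj}\t{r.obj_start}\t{r.obj_end}\t{r.part_number}\tW\t"
                    f"{r.component_id}\t{r.component_start}\t{r.component_end}\t"
                    f"{r.orientation}\n"
                )


def read_agp(path: str | Path) -> List[AgpRow]:
    rows: List[AgpRow] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if f[4] in ("N", "U"):
                rows.append(
                    AgpRow(f[0], int(f[1]), int(f[2]), int(f[3]), "N", gap_length=int(f[5]))
                )
            else:
                rows.append(
                    AgpRow(
                        f[0],
                        int(f[1]),
                        int(f[2]),
                        int(f[3]),
                        "W",
                        component_id=f[5],
                        component_start=int(f[6]),
                        component_end=int(f[7]),
                        orientation=f[8],
                    )
                )
    return rows


def sequence_from_agp(
    agp: Sequence[AgpRow], scaffolds: Mapping[str, str]
) -> Dict[str, str]:
    """Reconstruct object sequences from AGP rows + component FASTA."""
    out: Dict[str, List[str]] = {}
    for r in agp:
        parts = out.setdefault(r.obj, [])
        if r.component_type == "N":
            parts.append("N" * r.gap_length)
        else:
            seq = scaffolds[r.component_id][r.component_start - 1 : r.component_end]
            if r.orientation == "-":
                seq = revcomp(seq)
            parts.append(seq)
    return {obj: "".join(parts) for obj, parts in out.items()}
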
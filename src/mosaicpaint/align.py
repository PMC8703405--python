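"""Reference placement of scaffolds by exact k-mer anchoring + chaining.

The placement strategy is the classic seed-and-chain scheme used by
whole-genome aligners: index the reference's k-mers, collect exact-match
anchors for a query on both strands, merge anchors that lie on the same
diagonal into maximal runs, then chain colinear runs with a weighted
longest-increasing-subsequence dynamic programme.  The single best chain
per query becomes its Placement; queries with no chain above threshold are
Unplaced (a value, not an error).

Identity over the chained span is estimated without base-level alignment:
anchored columns are exact matches by construction, and each inter-anchor
interval is compared column-wise when the reference and query sides have
equal length; unequal sides contribute their length difference as
non-identity.  This O(n) estimate is exact for substitution-only
divergence, which is the regime the synthetic scaffolds live in.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

from ._util import revcomp

DEFAULT_K = 15
DEFAULT_MAX_OCC = 50
DEFAULT_MAX_GAP = 10_000
DEFAULT_MIN_CHAIN_BASES = 100
#: penalty per bp of length difference between the reference-side and
#: query-side gap separating two chained anchors
GAP_PENALTY = 0.5


@dataclass(frozen=True)
class Anchor:
    """One exact k-mer (or merged run of k-mers) match; 1-based starts."""

    ref_chrom: str
    ref_start: int
    scf_start: int
    length: int

    @property
    def ref_end(self) -> int:
        return self.ref_start + self.length - 1

    @property
    def scf_end(self) -> int:
        return self.scf_start + self.length - 1

    @property
    def diagonal(self) -> int:
        return self.ref_start - self.scf_start


@dataclass(frozen=True)
class Chain:
    """A colinear anchor chain; ``score`` is the chaining DP objective."""

    ref_chrom: str
    ref_start: int
    ref_end: int
    scf_start: int
    scf_end: int
    strand: str
    anchored_bases: int
    score: float
    anchors: Tuple[Anchor, ...]


@dataclass(frozen=True)
class Placement:
    """Best placement of one scaffold on the reference (1-based inclusive).

    ``scf_start``/``scf_end`` are coordinates on the scaffold as given
    (i.e. before any reverse complementing); ``score`` is
    anchored_bases x identity.
    """

    ref_chrom: str
    ref_start: int
    ref_end: int
    scf_id: str
    scf_start: int
    scf_end: int
    strand: str
    anchored_bases: int
    identity: float
    score: float


class KmerIndex:
    """Exact k-mer index of a reference with repeat masking.

    k-mers containing non-ACGT characters are not indexed; k-mers seen
    more than ``max_occ`` times are masked as repetitive and return no
    positions.
    """

    def __init__(
        self,
        reference: Mapping[str, str],
        k: int = DEFAULT_K,
        max_occ: int = DEFAULT_MAX_OCC,
    ) -> None:
        if not reference:
            raise ValueError("empty reference")
        if k < 2:
            raise ValueError(f"k must be >= 2, got {k}")
        # k >= 11 (odd) recommended for genome-scale references; smaller k
        # is allowed for toy sequences and enumeration checks.
        self.k = k
        self.max_occ = max_occ
        self.reference = {c: s.upper() for c, s in reference.items()}
        self._table: Dict[str, List[Tuple[str, int]]] = {}
        self.masked: set[str] = set()
        allowed = frozenset("ACGT")
        for chrom in sorted(self.reference):
            seq = self.reference[chrom]
            for i in range(len(seq) - k + 1):
                kmer = seq[i : i + k]
                if kmer in self.masked:
                    continue
                if not allowed.issuperset(kmer):
                    continue
                hits = self._table.setdefault(kmer, [])
                hits.append((chrom, i + 1))
                if len(hits) > max_occ:
                    del self._table[kmer]
                    self.masked.add(kmer)

    def lookup(self, kmer: str) -> List[Tuple[str, int]]:
        """Reference positions (chrom, 1-based start) of an exact k-mer."""
        return self._table.get(kmer, [])

    def __len__(self) -> int:
        return len(self._table)


def collect_anchors(query: str, index: KmerIndex) -> List[Anchor]:
    """All exact k-mer anchors of a (single-strand) query, merged by diagonal.

    Consecutive k-mer hits on the same diagonal are merged into maximal
    runs so a long exact match yields one anchor, keeping the chaining DP
    small.
    """
    k = index.k
    raw: Dict[Tuple[str, int], List[int]] = {}
    for i in range(len(query) - k + 1):
        for chrom, ref_pos in index.lookup(query[i : i + k]):
            raw.setdefault((chrom, ref_pos - (i + 1)), []).append(i + 1)
    anchors: List[Anchor] = []
    for (chrom, diag), starts in raw.items():
        starts.sort()
        run_start = prev = starts[0]
        for s in starts[1:]:
            if s <= prev + k:  # overlapping or abutting k-mers extend the run
                prev = s
            else:
                anchors.append(
                    Anchor(chrom, run_start + diag, run_start, prev - run_start + k)
                )
                run_start = prev = s
        anchors.append(Anchor(chrom, run_start + diag, run_start, prev - run_start + k))
    anchors.sort(key=lambda a: (a.ref_chrom, a.ref_start, a.scf_start))
    return anchors


def _gap_cost(prev: Anchor, nxt: Anchor) -> Optional[float]:
    """Chaining gap cost between two anchors, or None if incompatible."""
    dref = nxt.ref_start - prev.ref_end - 1
    dscf = nxt.scf_start - prev.scf_end - 1
    if dref < 0 or dscf < 0:
        return None
    if dref > DEFAULT_MAX_GAP or dscf > DEFAULT_MAX_GAP:
        return None
    return GAP_PENALTY * abs(dref - dscf)


def chain_anchors(
    anchors: Sequence[Anchor],
    min_chain_bases: int = DEFAULT_MIN_CHAIN_BASES,
) -> List[Chain]:
    """Best colinear chain per reference chromosome (strand handled by caller).

    Weighted LIS: maximise total anchored bases minus gap penalties over
    subsets that strictly increase and do not overlap in both coordinates,
    with both gaps bounded by ``DEFAULT_MAX_GAP``.  Returns one best chain
    per chromosome with score >= ``min_chain_bases``, sorted by descending
    score then (chrom, ref_start).
    """
    by_chrom: Dict[str, List[Anchor]] = {}
    for a in anchors:
        by_chrom.setdefault(a.ref_chrom, []).append(a)
    chains: List[Chain] = []
    for chrom in sorted(by_chrom):
        group = sorted(by_chrom[chrom], key=lambda a: (a.ref_start, a.scf_start))
        n = len(group)
        best: List[float] = [float(a.length) for a in group]
        back: List[int] = [-1] * n
        for i in range(n):
            ai = group[i]
            for j in range(i):
                cost = _gap_cost(group[j], ai)
                if cost is None:
                    continue
                cand = best[j] + ai.length - cost
                if cand > best[i]:
                    best[i] = cand
                    back[i] = j
        top = max(range(n), key=lambda i: (best[i], -group[i].ref_start))
        if best[top] < min_chain_bases:
            continue
        path = []
        i = top
        while i != -1:
            path.append(group[i])
            i = back[i]
        path.reverse()
        chains.append(
            Chain(
                ref_chrom=chrom,
                ref_start=path[0].ref_start,
                ref_end=path[-1].ref_end,
                scf_start=path[0].scf_start,
                scf_end=path[-1].scf_end,
                strand="+",
                anchored_bases=sum(a.length for a in path),
                score=best[top],
                anchors=tuple(path),
            )
        )
    chains.sort(key=lambda c: (-c.score, c.ref_chrom, c.ref_start))
    return chains


def _chain_identity(chain: Chain, query: str, index: KmerIndex) -> Tuple[float, int]:
    """(identity, matched_columns) over the chained span.

    Anchored columns match exactly; equal-length inter-anchor intervals
    are compared column by column; unequal intervals contribute their
    length difference as mismatch and their overlap compared directly.
    """
    ref = index.reference[chain.ref_chrom]
    matched = chain.anchored_bases
    for prev, nxt in zip(chain.anchors, chain.anchors[1:]):
        ref_gap = ref[prev.ref_end : nxt.ref_start - 1]
        scf_gap = query[prev.scf_end : nxt.scf_start - 1]
        matched += sum(r == s for r, s in zip(ref_gap, scf_gap))
    span = max(
        chain.ref_end - chain.ref_start + 1, chain.scf_end - chain.scf_start + 1
    )
    return matched / span, matched


def best_chains_both_strands(
    query: str, index: KmerIndex, min_chain_bases: int = DEFAULT_MIN_CHAIN_BASES
) -> List[Chain]:
    """Candidate chains for both orientations of a query.

    Minus-strand chains carry query coordinates already mapped back to the
    original (as-given) query; ties in score are broken by (chrom,
    ref_start) so output is deterministic.
    """
    candidates: List[Chain] = []
    length = len(query)
    for strand, seq in (("+", query), ("-", revcomp(query))):
        for chain in chain_anchors(collect_anchors(seq, index), min_chain_bases):
            if strand == "-":
                chain = replace(
                    chain,
                    strand="-",
                    scf_start=length - chain.scf_end + 1,
                    scf_end=length - chain.scf_start + 1,
                )
            candidates.append(chain)
    candidates.sort(key=lambda c: (-c.score, c.ref_chrom, c.ref_start, c.strand))
    return candidates


def place_scaffold(
    scf_id: str,
    scaffold: str,
    index: KmerIndex,
    min_chain_bases: int = DEFAULT_MIN_CHAIN_BASES,
) -> Optional[Placement]:
    """Best placement of one scaffold, or None (Unplaced)."""
    scaffold = scaffold.upper()
    if len(scaffold) < index.k:
        return None
    candidates = best_chains_both_strands(scaffold, index, min_chain_bases)
    if not candidates:
        return None
    best = candidates[0]
    # identity is computed on the oriented query the chain was built on
    oriented = scaffold if best.strand == "+" else revcomp(scaffold)
    measured = best
    if best.strand == "-":
        measured = replace(
            best,
            scf_start=len(scaffold) - best.scf_end + 1,
            scf_end=len(scaffold) - best.scf_start + 1,
        )
    identity, _ = _chain_identity(measured, oriented, index)
    return Placement(
        ref_chrom=best.ref_chrom,
        ref_start=best.ref_start,
        ref_end=best.ref_end,
        scf_id=scf_id,
        scf_start=best.scf_start,
        scf_end=best.scf_end,
        strand=best.strand,
        anchored_bases=best.anchored_bases,
        identity=identity,
        score=best.anchored_bases * identity,
    )


def place_all(
    scaffolds: Mapping[str, str],
    index: KmerIndex,
    min_chain_bases: int = DEFAULT_MIN_CHAIN_BASES,
) -> Tuple[List[Placement], List[str]]:
    """Place every scaffold; returns (placements, unplaced ids)."""
    placements: List[Placement] = []
    unplaced: List[str] = []
    for scf_id in sorted(scaffolds):
        p = place_scaffold(scf_id, scaffolds[scf_id], index, min_chain_bases)
        if p is None:
            unplaced.append(scf_id)
        else:
            placements.append(p)
    return placements, unplaced


PLACEMENT_COLUMNS = [
    "ref_chrom",
    "ref_start",
    "ref_end",
    "scf_id",
    "scf_start",
    "scf_end",
    "strand",
    "anchored_bases",
    "identity",
    "score",
]


def write_placements(placements: Iterable[Placement], path: str | Path) -> None:
    """coords-style TSV, 1-based inclusive on both sequences."""
    with open(path, "w") as fh:
        fh.write("\t".join(PLACEMENT_COLUMNS) + "\n")
        for p in placements:
            fh.write(
                f"{p.ref_chrom}\t{p.ref_start}\t{p.ref_end}\t{p.scf_id}\t"
                f"{p.scf_start}\t{p.scf_end}\t{p.strand}\t{p.anchored_bases}\t"
                f"{p.identity:.6f}\t{p.score:.2f}\n"
            )


def read_placements(path: str | Path) -> List[Placement]:
    placements: List[Placement] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != PLACEMENT_COLUMNS:
            raise ValueError(f"unexpected placement columns: {header}")
        for line in fh:
            f = line.rstrip("\n").split("\t")
            placements.append(
                Placement(
                    ref_chrom=f[0],
                    ref_start=int(f[1]),
                    ref_end=int(f[2]),
                    scf_id=f[3],
                    scf_start=int(f[4]),
                    scf_end=int(f[5]),
                    strand=f[6],
                    anchored_bases=int(f[7]),
                    identity=float(f[8]),
                    score=float(f[9]),
                )
            )
    return placements
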
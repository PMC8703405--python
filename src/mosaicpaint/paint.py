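"""Trio SNP classification and fixed-window chromosome painting.

Each biallelic SNP passing the QUAL filter is classified by comparing the
offspring genotype to the two parents:

* offspring = parent A != parent B  ->  PARENT_A (recurrent-parent-like)
* offspring = parent B != parent A  ->  PARENT_B (donor-parent-like)
* offspring matches neither parent  ->  OTHER (unknown source)
* all three identical, or any heterozygous/missing genotype -> uninformative
  (excluded from every count)

Classified SNPs are binned into fixed windows anchored at position 1 of
each chromosome (window i covers [(i-1)w+1, i*w]); a window's dominant
class is the argmax of its counts, with empty windows rendered MISSING and
exact ties conservatively labelled OTHER.  Genome composition is then
summarised either over raw SNPs or over the dominant labels of windows.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import pysam

from ._util import round_half_up

DEFAULT_MIN_QUAL = 30.0
DEFAULT_WINDOW_SIZES = (50_000, 100_000)


class OriginClass(str, Enum):
    """Parental-origin call for one SNP or one window."""

    PARENT_A = "parent_a"
    PARENT_B = "parent_b"
    OTHER = "other"
    UNINFORMATIVE = "uninformative"
    MISSING = "missing"


#: the classes that participate in counts and composition
CLASSIFIED = (OriginClass.PARENT_A, OriginClass.PARENT_B, OriginClass.OTHER)


@dataclass(frozen=True)
class SnpSite:
    """One trio VCF record; genotypes are allele tuples (None = missing)."""

    chrom: str
    pos: int
    qual: float
    gt_offspring: Optional[Tuple[str, ...]]
    gt_parent_a: Optional[Tuple[str, ...]]
    gt_parent_b: Optional[Tuple[str, ...]]


def _homozygous_allele(gt: Optional[Tuple[str, ...]]) -> Optional[str]:
    if not gt or any(a is None for a in gt):
        return None
    alleles = set(gt)
    if len(alleles) != 1:  # heterozygous
        return None
    return next(iter(alleles))


def classify_snp(site: SnpSite) -> OriginClass:
    """Parental origin of one site; heterozygous/missing -> UNINFORMATIVE."""
    off = _homozygous_allele(site.gt_offspring)
    pa = _homozygous_allele(site.gt_parent_a)
    pb = _homozygous_allele(site.gt_parent_b)
    if off is None or pa is None or pb is None:
        return OriginClass.UNINFORMATIVE
    if pa == pb:
        return OriginClass.UNINFORMATIVE if off == pa else OriginClass.OTHER
    if off == pa:
        return OriginClass.PARENT_A
    if off == pb:
        return OriginClass.PARENT_B
    return OriginClass.OTHER


def filter_sites(
    vcf_path: str | Path,
    min_qual: float = DEFAULT_MIN_QUAL,
    offspring: str = "offspring",
    parent_a: str = "parentA",
    parent_b: str = "parentB",
) -> List[SnpSite]:
    """Read a trio VCF keeping biallelic SNPs with QUAL >= ``min_qual``.

    Indels and multi-allelic records are excluded.  Sample names must
    match the VCF header; a mismatch raises with the available names.
    """
    sites: List[SnpSite] = []
    with pysam.VariantFile(str(vcf_path)) as vcf:
        available = list(vcf.header.samples)
        for name in (offspring, parent_a, parent_b):
            if name not in available:
                raise ValueError(
                    f"sample {name!r} not in VCF; available samples: {available}"
                )
        for rec in vcf:
            if rec.qual is None or rec.qual < min_qual:
                continue
            if rec.alts is None or len(rec.alts) != 1:
                continue
            if len(rec.ref) != 1 or len(rec.alts[0]) != 1:
                continue  # SNPs only
            def alleles(sample: str) -> Optional[Tuple[str, ...]]:
                gt = rec.samples[sample].alleles
                if gt is None or any(a is None for a in gt):
                    return None
                return tuple(gt)

            sites.append(
                SnpSite(
                    chrom=rec.chrom,
                    pos=rec.pos,
                    qual=rec.qual,
                    gt_offspring=alleles(offspring),
                    gt_parent_a=alleles(parent_a),
                    gt_parent_b=alleles(parent_b),
                )
            )
    return sites


@dataclass
class ClassifiedSite:
    chrom: str
    pos: int
    origin: OriginClass


def classify_sites(sites: Iterable[SnpSite]) -> List[ClassifiedSite]:
    """Classify sites, dropping UNINFORMATIVE ones."""
    out = []
    for s in sites:
        cls = classify_snp(s)
        if cls is not OriginClass.UNINFORMATIVE:
            out.append(ClassifiedSite(s.chrom, s.pos, cls))
    return out


@dataclass
class WindowBlock:
    """One fixed-size bin with per-class counts and its dominant label."""

    chrom: str
    index: int  # 1-based
    start: int
    end: int
    counts: Dict[OriginClass, int]
    dominant: OriginClass

    @property
    def n_classified(self) -> int:
        return sum(self.counts.values())


def _dominant(counts: Mapping[OriginClass, int]) -> OriginClass:
    total = sum(counts.values())
    if total == 0:
        return OriginClass.MISSING
    top = max(counts.values())
    winners = [c for c in CLASSIFIED if counts.get(c, 0) == top]
    if len(winners) > 1:
        return OriginClass.OTHER  # conservative tie rule
    return winners[0]


def window_paint(
    classified: Sequence[ClassifiedSite],
    chrom_lengths: Mapping[str, int],
    w: int,
) -> List[WindowBlock]:
    """Bin classified SNPs into ceil(L/w) windows per chromosome."""
    if w <= 0:
        raise ValueError("window size must be > 0")
    counts: Dict[Tuple[str, int], Dict[OriginClass, int]] = {}
    for site in classified:
        if site.chrom not in chrom_lengths:
            continue
        idx = (site.pos + w - 1) // w  # ceil(pos / w)
        key = (site.chrom, idx)
        c = counts.setdefault(key, {k: 0 for k in CLASSIFIED})
        c[site.origin] += 1
    blocks: List[WindowBlock] = []
    for chrom in sorted(chrom_lengths):
        n_win = math.ceil(chrom_lengths[chrom] / w)
        for idx in range(1, n_win + 1):
            c = counts.get((chrom, idx), {k: 0 for k in CLASSIFIED})
            blocks.append(
                WindowBlock(
                    chrom=chrom,
                    index=idx,
                    start=(idx - 1) * w + 1,
                    end=idx * w,
                    counts=c,
                    dominant=_dominant(c),
                )
            )
    return blocks


@dataclass
class CompositionSummary:
    """Per-class counts and half-up integer percentages over classified units."""

    counts: Dict[OriginClass, int]
    percentages: Dict[OriginClass, int]
    total: int


def composition_from_counts(
    n_a: int, n_b: int, n_other: int
) -> CompositionSummary:
    """Summary from raw per-class counts (SNPs or windows alike)."""
    counts = {
        OriginClass.PARENT_A: n_a,
        OriginClass.PARENT_B: n_b,
        OriginClass.OTHER: n_other,
    }
    total = n_a + n_b + n_other
    pct = {
        k: int(round_half_up(100.0 * v / total)) if total else 0
        for k, v in counts.items()
    }
    return CompositionSummary(counts=counts, percentages=pct, total=total)


def composition_from_blocks(blocks: Sequence[WindowBlock]) -> CompositionSummary:
    """Window-based composition over non-MISSING windows."""
    tallies = {k: 0 for k in CLASSIFIED}
    for b in blocks:
        if b.dominant in tallies:
            tallies[b.dominant] += 1
    return composition_from_counts(
        tallies[OriginClass.PARENT_A],
        tallies[OriginClass.PARENT_B],
        tallies[OriginClass.OTHER],
    )


def composition_from_sites(classified: Sequence[ClassifiedSite]) -> CompositionSummary:
    tallies = {k: 0 for k in CLASSIFIED}
    for s in classified:
        tallies[s.origin] += 1
    return composition_from_counts(
        tallies[OriginClass.PARENT_A],
        tallies[OriginClass.PARENT_B],
        tallies[OriginClass.OTHER],
    )


# ---------------------------------------------------------------------------
# output


def write_classified(classified: Sequence[ClassifiedSite], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tpos\torigin\n")
        for s in classified:
            fh.write(f"{s.chrom}\t{s.pos}\t{s.origin.value}\n")


def write_windows(blocks: Sequence[WindowBlock], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tn_parent_a\tn_parent_b\tn_other\tdominant\n")
        for b in blocks:
            fh.write(
                f"{b.chrom}\t{b.start}\t{b.end}\t"
                f"{b.counts[OriginClass.PARENT_A]}\t"
                f"{b.counts[OriginClass.PARENT_B]}\t"
                f"{b.counts[OriginClass.OTHER]}\t{b.dominant.value}\n"
            )


def read_windows(path: str | Path) -> List[WindowBlock]:
    blocks: List[WindowBlock] = []
    per_chrom_index: Dict[str, int] = {}
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            f = line.rstrip("\n").split("\t")
            chrom = f[0]
            per_chrom_index[chrom] = per_chrom_index.get(chrom, 0) + 1
            counts = {
                OriginClass.PARENT_A: int(f[3]),
                OriginClass.PARENT_B: int(f[4]),
                OriginClass.OTHER: int(f[5]),
            }
            blocks.append(
                WindowBlock(
                    chrom=chrom,
                    index=per_chrom_index[chrom],
                    start=int(f[1]),
                    end=int(f[2]),
                    counts=counts,
                    dominant=OriginClass(f[6]),
                )
            )
    return blocks


def write_composition(
    summaries: Mapping[str, CompositionSummary], path: str | Path
) -> None:
    """TSV with one column block per unit type (all SNPs, each window size)."""
    with open(path, "w") as fh:
        fh.write("unit\tclass\tcount\tpercent\n")
        for unit, summ in summaries.items():
            for cls in CLASSIFIED:
                fh.write(
                    f"{unit}\t{cls.value}\t{summ.counts[cls]}\t{summ.percentages[cls]}\n"
                )
            fh.write(f"{unit}\ttotal\t{summ.total}\t100\n")


_PAINT_COLORS = {
    OriginClass.PARENT_A: "#2b5fad",  # blue: recurrent parent
    OriginClass.PARENT_B: "#c23b3b",  # red: donor parent
    OriginClass.OTHER: "#3d9e4e",  # green: neither parent
    OriginClass.MISSING: "#ffffff",  # white: no classified SNP
}


def plot_painting(
    blocks: Sequence[WindowBlock],
    path: str | Path,
    title: str = "",
) -> None:
    """One horizontal bar per chromosome, windows coloured by dominant class."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    chroms = sorted({b.chrom for b in blocks})
    fig, ax = plt.subplots(figsize=(10, 0.5 * len(chroms) + 1.5))
    for row, chrom in enumerate(chroms):
        for b in (x for x in blocks if x.chrom == chrom):
            ax.barh(
                row,
                b.end - b.start + 1,
                left=b.start - 1,
                height=0.7,
                color=_PAINT_COLORS[b.dominant],
                edgecolor="none",
            )
    ax.set_yticks(range(len(chroms)), chroms)
    ax.set_xlabel("position (bp)")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
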
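"""Synthetic trio + mosaic offspring generator.

Emulates the data underlying a marker-assisted backcross experiment: two
inbred founder genomes (a recurrent parent A and a donor parent B), a third
"unknown" founder U standing in for seed admixture / pollen contamination,
and an offspring genome that is a segment-wise homozygous mosaic of the
three.  The offspring is then fragmented into scaffolds (as a short-read
assembler would produce) and a three-sample VCF is emitted, so the whole
placement -> pseudomolecule -> painting pipeline can be exercised end to
end against known truth.

Divergence model
----------------
Every polymorphic site is biallelic: an ancestral allele plus a minor
allele private to exactly one founder.  The minor-allele owner is drawn
with probabilities ``minor_founder_probs`` (default 0.25/0.25/0.50 for
A/B/U).  Giving the unknown source twice the private-allele rate models an
unrelated contaminant that is more diverged from both parents than they
are from each other; it is what makes U-derived segments classifiable as
"neither parent" rather than coin-flips between the parental classes.

All coordinates are 1-based inclusive except inside the BED writer, which
follows the BED 0-based half-open standard.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd

from ._util import revcomp, write_fasta

_BASES = np.frombuffer(b"ACGT", dtype="S1")

#: founder labels, in the order used throughout (recurrent, donor, unknown)
FOUNDERS = ("A", "B", "U")


@dataclass
class SimConfig:
    """Parameters of one synthetic dataset.

    Lengths are in bp; rates are per bp.  ``target_fracs`` are the
    probabilities with which each mosaic segment draws its founder of
    origin (A, B, U) and must sum to 1.
    """

    n_chrom: int = 10
    chrom_len: int = 500_000
    snp_rate: float = 0.005
    target_fracs: Tuple[float, float, float] = (0.61, 0.23, 0.16)
    mean_segment_len: float = 150_000.0
    min_segment_len: int = 100_000
    scaffold_len_mean: float = 25_000.0
    scaffold_len_sd: float = 15_000.0
    scaffold_error_rate: float = 0.001
    rc_prob: float = 0.5
    n_genes: int = 5
    gene_len: int = 1_500
    minor_founder_probs: Tuple[float, float, float] = (0.25, 0.25, 0.50)
    base_qual: float = 60.0
    low_qual_frac: float = 0.0
    low_qual_value: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.target_fracs) - 1.0) > 1e-9:
            raise ValueError(f"target_fracs must sum to 1, got {self.target_fracs}")
        if abs(sum(self.minor_founder_probs) - 1.0) > 1e-9:
            raise ValueError("minor_founder_probs must sum to 1")
        for name in ("n_chrom", "chrom_len", "min_segment_len", "gene_len"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("mean_segment_len", "scaffold_len_mean", "scaffold_len_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("snp_rate", "scaffold_error_rate", "rc_prob", "low_qual_frac"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0 and not (name == "rc_prob" and v == 1.0):
                raise ValueError(f"{name} must be in [0, 1), got {v}")
        if self.min_segment_len > self.mean_segment_len:
            raise ValueError("min_segment_len must not exceed mean_segment_len")

    def chrom_names(self) -> List[str]:
        return [f"chr{i + 1:02d}" for i in range(self.n_chrom)]


@dataclass(frozen=True)
class TruthSegment:
    """Ground-truth origin of one offspring interval (1-based inclusive)."""

    chrom: str
    start: int
    end: int
    origin: str  # one of FOUNDERS


@dataclass(frozen=True)
class ScaffoldTruth:
    """Where a scaffold truly came from in the offspring genome."""

    scf_id: str
    chrom: str
    start: int
    end: int
    strand: str  # '+' or '-'


@dataclass(frozen=True)
class GeneTruth:
    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str


Genome = Dict[str, np.ndarray]  # chrom -> array of dtype S1


def genome_to_str(genome: Genome) -> Dict[str, str]:
    return {c: arr.tobytes().decode() for c, arr in genome.items()}


@dataclass
class Founders:
    genomes: Dict[str, Genome]  # founder label -> genome
    catalog: pd.DataFrame  # chrom, pos, ref, alt, allele_A, allele_B, allele_U


def simulate_founders(cfg: SimConfig) -> Founders:
    """Three founder genomes identical except at catalogued biallelic SNPs.

    The catalog records, per site, the ancestral (ref) allele, the minor
    (alt) allele and each founder's allele.  Deterministic under a fixed
    ``cfg.seed``.
    """
    rng = np.random.default_rng([cfg.seed, 1])
    genomes: Dict[str, Genome] = {f: {} for f in FOUNDERS}
    frames: List[pd.DataFrame] = []
    for chrom in cfg.chrom_names():
        idx = rng.integers(0, 4, cfg.chrom_len)
        anc = _BASES[idx]
        n_snp = rng.binomial(cfg.chrom_len, cfg.snp_rate)
        pos0 = np.sort(rng.choice(cfg.chrom_len, size=n_snp, replace=False))
        minor = rng.choice(3, size=n_snp, p=cfg.minor_founder_probs)
        alt = _BASES[(idx[pos0] + rng.integers(1, 4, n_snp)) % 4]
        alleles = {}
        for i, f in enumerate(FOUNDERS):
            arr = anc.copy()
            arr[pos0[minor == i]] = alt[minor == i]
            genomes[f][chrom] = arr
            alleles[f"allele_{f}"] = np.where(minor == i, alt, anc[pos0])
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "pos": pos0 + 1,
                    "ref": anc[pos0].astype("U1"),
                    "alt": alt.astype("U1"),
                    **{k: v.astype("U1") for k, v in alleles.items()},
                }
            )
        )
    catalog = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["chrom", "pos", "ref", "alt", "allele_A", "allele_B", "allele_U"]
    )
    return Founders(genomes=genomes, catalog=catalog)


def simulate_offspring(
    founders: Founders, cfg: SimConfig
) -> Tuple[Genome, List[TruthSegment]]:
    """Copy-paste mosaic of the founders with exponential segment lengths.

    Segment lengths are ``min_segment_len`` plus an exponential with the
    complementary mean; origins are i.i.d. draws from ``target_fracs``.
    Adjacent segments with the same origin are merged, so the truth
    segments are maximal runs that tile each chromosome exactly.
    """
    rng = np.random.default_rng([cfg.seed, 2])
    offspring: Genome = {}
    truth: List[TruthSegment] = []
    extra_mean = max(cfg.mean_segment_len - cfg.min_segment_len, 1e-9)
    for chrom in cfg.chrom_names():
        length = cfg.chrom_len
        arr = np.empty(length, dtype="S1")
        segs: List[Tuple[int, int, str]] = []
        cursor = 1
        while cursor <= length:
            seg_len = cfg.min_segment_len + int(rng.exponential(extra_mean))
            end = min(cursor + seg_len - 1, length)
            origin = FOUNDERS[rng.choice(3, p=cfg.target_fracs)]
            arr[cursor - 1 : end] = founders.genomes[origin][chrom][cursor - 1 : end]
            if segs and segs[-1][2] == origin:
                segs[-1] = (segs[-1][0], end, origin)
            else:
                segs.append((cursor, end, origin))
            cursor = end + 1
        offspring[chrom] = arr
        truth.extend(TruthSegment(chrom, s, e, o) for s, e, o in segs)
    return offspring, truth


def realized_fractions(truth: Sequence[TruthSegment]) -> Dict[str, float]:
    """Base-pair fraction of each founder of origin in the truth tiling."""
    bp = {f: 0 for f in FOUNDERS}
    for seg in truth:
        bp[seg.origin] += seg.end - seg.start + 1
    total = sum(bp.values())
    return {f: bp[f] / total for f in FOUNDERS}


def fragment_to_scaffolds(
    offspring: Genome, cfg: SimConfig
) -> Tuple[Dict[str, str], List[ScaffoldTruth]]:
    """Partition the offspring into scaffolds with lognormal lengths.

    Each scaffold is independently reverse-complemented with probability
    ``rc_prob`` and perturbed by substitutions at ``scaffold_error_rate``.
    The returned truth placements give the original (forward) interval.
    """
    rng = np.random.default_rng([cfg.seed, 3])
    m, s = cfg.scaffold_len_mean, cfg.scaffold_len_sd
    sigma2 = math.log(1.0 + (s * s) / (m * m))
    mu = math.log(m) - sigma2 / 2.0
    sigma = math.sqrt(sigma2)

    scaffolds: Dict[str, str] = {}
    truth: List[ScaffoldTruth] = []
    counter = 0
    for chrom in sorted(offspring):
        length = len(offspring[chrom])
        cursor = 1
        while cursor <= length:
            scf_len = max(int(rng.lognormal(mu, sigma)), 200)
            end = min(cursor + scf_len - 1, length)
            counter += 1
            scf_id = f"scf_{counter:05d}"
            seq = offspring[chrom][cursor - 1 : end].tobytes().decode()
            n_err = rng.binomial(len(seq), cfg.scaffold_error_rate)
            if n_err:
                arr = np.frombuffer(seq.encode(), dtype="S1").copy()
                err_pos = rng.choice(len(seq), size=n_err, replace=False)
                shift = rng.integers(1, 4, n_err)
                base_idx = np.searchsorted(_BASES, arr[err_pos])
                arr[err_pos] = _BASES[(base_idx + shift) % 4]
                seq = arr.tobytes().decode()
            strand = "-" if rng.random() < cfg.rc_prob else "+"
            if strand == "-":
                seq = revcomp(seq)
            scaffolds[scf_id] = seq
            truth.append(ScaffoldTruth(scf_id, chrom, cursor, end, strand))
            cursor = end + 1
    return scaffolds, truth


def extract_genes(
    genome: Genome, cfg: SimConfig
) -> Tuple[Dict[str, str], List[GeneTruth]]:
    """Cut ``n_genes`` non-overlapping marker genes out of a genome.

    Half (on average) are emitted as the reverse complement so locating
    them exercises both strands.
    """
    rng = np.random.default_rng([cfg.seed, 4])
    chroms = sorted(genome)
    genes: Dict[str, str] = {}
    truth: List[GeneTruth] = []
    taken: Dict[str, List[Tuple[int, int]]] = {c: [] for c in chroms}
    attempts = 0
    while len(genes) < cfg.n_genes:
        attempts += 1
        if attempts > 1000 * cfg.n_genes:
            raise RuntimeError("could not place non-overlapping genes")
        chrom = chroms[rng.integers(0, len(chroms))]
        length = len(genome[chrom])
        if length < cfg.gene_len:
            continue
        start = int(rng.integers(1, length - cfg.gene_len + 2))
        end = start + cfg.gene_len - 1
        if any(s <= end and start <= e for s, e in taken[chrom]):
            continue
        taken[chrom].append((start, end))
        gene_id = f"gene_{len(genes) + 1:02d}"
        seq = genome[chrom][start - 1 : end].tobytes().decode()
        strand = "-" if rng.random() < 0.5 else "+"
        if strand == "-":
            seq = revcomp(seq)
        genes[gene_id] = seq
        truth.append(GeneTruth(gene_id, chrom, start, end, strand))
    return genes, truth


def emit_vcf(
    founders: Founders,
    offspring: Genome,
    cfg: SimConfig,
    sample_names: Tuple[str, str, str] = ("offspring", "parentA", "parentB"),
) -> str:
    """Render the trio VCF 4.2 text for all polymorphic catalogued sites.

    A site is emitted only when the three samples (offspring, parent A,
    parent B) are not all identical.  All genotypes are homozygous diploid
    (inbred lines).  QUAL is ``base_qual`` except for a ``low_qual_frac``
    fraction of sites set to ``low_qual_value`` (for filter testing).
    """
    rng = np.random.default_rng([cfg.seed, 5])
    cat = founders.catalog
    lines = [
        "##fileformat=VCFv4.2",
        "##source=mosaicpaint-simulate",
    ]
    for chrom in sorted(offspring):
        lines.append(f"##contig=<ID={chrom},length={len(offspring[chrom])}>")
    lines.append('##FILTER=<ID=PASS,Description="All filters passed">')
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(sample_names)
    )

    def fmt_qual(q: float) -> str:
        return str(int(q)) if float(q).is_integer() else f"{q:g}"

    for chrom, sub in cat.groupby("chrom", sort=True):
        pos0 = sub["pos"].to_numpy() - 1
        off = offspring[chrom][pos0].astype("U1")
        pa = sub["allele_A"].to_numpy()
        pb = sub["allele_B"].to_numpy()
        ref = sub["ref"].to_numpy()
        alt = sub["alt"].to_numpy()
        poly = ~((off == pa) & (pa == pb))
        quals = np.full(len(sub), cfg.base_qual)
        if cfg.low_qual_frac > 0:
            quals[rng.random(len(sub)) < cfg.low_qual_frac] = cfg.low_qual_value
        for i in np.flatnonzero(poly):
            gts = "\t".join(
                "1/1" if a == alt[i] else "0/0" for a in (off[i], pa[i], pb[i])
            )
            lines.append(
                f"{chrom}\t{sub['pos'].iat[i]}\t.\t{ref[i]}\t{alt[i]}\t"
                f"{fmt_qual(quals[i])}\tPASS\t.\tGT\t{gts}"
            )
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# file writers


def write_truth_bed(truth: Sequence[TruthSegment], path: str | Path) -> None:
    """BED (0-based half-open) with the founder of origin in column 4."""
    with open(path, "w") as fh:
        for seg in truth:
            fh.write(f"{seg.chrom}\t{seg.start - 1}\t{seg.end}\t{seg.origin}\n")


def write_scaffold_truth(truth: Sequence[ScaffoldTruth], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("scf_id\tchrom\tstart\tend\tstrand\n")
        for t in truth:
            fh.write(f"{t.scf_id}\t{t.chrom}\t{t.start}\t{t.end}\t{t.strand}\n")


def write_gene_truth(truth: Sequence[GeneTruth], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tchrom\tstart\tend\tstrand\n")
        for t in truth:
            fh.write(f"{t.gene_id}\t{t.chrom}\t{t.start}\t{t.end}\t{t.strand}\n")


@dataclass
class SimulatedDataset:
    """Paths to every file one simulate run produced."""

    outdir: Path
    founder_fastas: Dict[str, Path] = field(default_factory=dict)
    offspring_fasta: Path | None = None
    scaffolds_fasta: Path | None = None
    genes_fasta: Path | None = None
    vcf: Path | None = None
    truth_bed: Path | None = None
    scaffold_truth_tsv: Path | None = None
    gene_truth_tsv: Path | None = None


def simulate_dataset(cfg: SimConfig, outdir: str | Path) -> SimulatedDataset:
    """Run the full generator and write every output under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ds = SimulatedDataset(outdir=outdir)

    founders = simulate_founders(cfg)
    for f in FOUNDERS:
        path = outdir / f"founder_{f}.fasta"
        write_fasta(genome_to_str(founders.genomes[f]), path)
        ds.founder_fastas[f] = path

    offspring, truth = simulate_offspring(founders, cfg)
    ds.offspring_fasta = outdir / "offspring.fasta"
    write_fasta(genome_to_str(offspring), ds.offspring_fasta)
    ds.truth_bed = outdir / "truth_segments.bed"
    write_truth_bed(truth, ds.truth_bed)

    scaffolds, scf_truth = fragment_to_scaffolds(offspring, cfg)
    ds.scaffolds_fasta = outdir / "scaffolds.fasta"
    write_fasta(scaffolds, ds.scaffolds_fasta)
    ds.scaffold_truth_tsv = outdir / "scaffold_truth.tsv"
    write_scaffold_truth(scf_truth, ds.scaffold_truth_tsv)

    genes, gene_truth = extract_genes(offspring, cfg)
    ds.genes_fasta = outdir / "genes.fasta"
    write_fasta(genes, ds.genes_fasta)
    ds.gene_truth_tsv = outdir / "gene_truth.tsv"
    write_gene_truth(gene_truth, ds.gene_truth_tsv)

    ds.vcf = outdir / "trio.vcf"
    ds.vcf.write_text(emit_vcf(founders, offspring, cfg))
    return ds
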
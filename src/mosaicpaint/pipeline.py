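"""End-to-end orchestration: simulate -> place -> build -> stats -> locate
-> paint -> qtl, with a manifest for reproducibility.

Every stage writes plain-text outputs (FASTA/VCF/AGP/BED/TSV) into a run
directory; the manifest records the package version, a hash of the
configuration, the seed, and per-stage counts, so a rerun with the same
configuration reproduces byte-identical tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import pysam
import yaml

from . import __version__
from ._util import read_fasta, write_fasta
from .align import DEFAULT_K, DEFAULT_MAX_OCC, KmerIndex, place_all, write_placements
from .genes import DEFAULT_MIN_COVERAGE, DEFAULT_MIN_IDENTITY, gene_distance, locate_genes, write_hits
from .paint import (
    DEFAULT_MIN_QUAL,
    DEFAULT_WINDOW_SIZES,
    classify_sites,
    composition_from_blocks,
    composition_from_sites,
    filter_sites,
    window_paint,
    write_classified,
    write_composition,
    write_windows,
)
from .pseudomolecule import build_pseudomolecules, write_agp
from .qtl import Region, parse_region, segments, write_segments, zoom
from .simulate import SimConfig, simulate_dataset
from .stats import summarize, write_stats

log = logging.getLogger("mosaicpaint")

STAGES = ("simulate", "place", "build", "stats", "locate", "paint", "qtl")


@dataclass
class PipelineConfig:
    """Whole-pipeline configuration with the per-module defaults."""

    seed: int = 0
    sim: Dict = field(default_factory=dict)  # SimConfig field overrides
    window_sizes: Tuple[int, ...] = DEFAULT_WINDOW_SIZES
    min_qual: float = DEFAULT_MIN_QUAL
    k: int = DEFAULT_K
    max_occ: int = DEFAULT_MAX_OCC
    min_identity: float = DEFAULT_MIN_IDENTITY
    min_coverage: float = DEFAULT_MIN_COVERAGE
    region: str = ""  # "chrom:start-end"; empty -> middle half of chr01
    offspring: str = "offspring"
    parent_a: str = "parentA"
    parent_b: str = "parentB"

    def sim_config(self) -> SimConfig:
        kwargs = dict(self.sim)
        kwargs.setdefault("seed", self.seed)
        return SimConfig(**kwargs)

    def to_dict(self) -> Dict:
        d = dataclasses.asdict(self)
        d["window_sizes"] = list(self.window_sizes)
        return d

    @classmethod
    def from_dict(cls, d: Dict) -> "PipelineConfig":
        d = dict(d)
        if "window_sizes" in d:
            d["window_sizes"] = tuple(d["window_sizes"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def chrom_lengths_from_vcf(vcf_path: str | Path) -> Dict[str, int]:
    """Chromosome lengths from the contig lines of a VCF header."""
    with pysam.VariantFile(str(vcf_path)) as vcf:
        lengths = {name: c.length for name, c in vcf.header.contigs.items()}
    missing = [n for n, l in lengths.items() if not l]
    if missing:
        raise ValueError(f"VCF contigs without length: {missing}")
    return lengths


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> Dict:
    """Run all seven stages on a fresh synthetic dataset; returns the manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: Dict = {
        "version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "config": config.to_dict(),
        "stages": {},
    }

    def done(stage: str, **counts) -> None:
        manifest["stages"][stage] = {"status": "complete", **counts}
        log.info("stage %s complete: %s", stage, counts)

    # 1. simulate ----------------------------------------------------------
    sim_cfg = config.sim_config()
    ds = simulate_dataset(sim_cfg, outdir / "sim")
    done("simulate", n_chrom=sim_cfg.n_chrom, chrom_len=sim_cfg.chrom_len)

    # 2. place (reference = recurrent parent's genome) ---------------------
    reference = read_fasta(ds.founder_fastas["A"])
    scaffolds = read_fasta(ds.scaffolds_fasta)
    index = KmerIndex(reference, k=config.k, max_occ=config.max_occ)
    placements, unplaced_ids = place_all(scaffolds, index)
    write_placements(placements, outdir / "placements.tsv")
    done("place", placed=len(placements), unplaced=len(unplaced_ids))

    # 3. build -------------------------------------------------------------
    build = build_pseudomolecules(placements, scaffolds)
    write_fasta(build.pseudomolecules, outdir / "pseudomolecules.fasta")
    write_agp(build.agp, outdir / "assembly.agp")
    (outdir / "unplaced.tsv").write_text(
        "scf_id\n" + "".join(f"{s}\n" for s in build.unplaced)
    )
    done("build", genome_size=build.genome_size, unplaced=len(build.unplaced))

    # 4. stats -------------------------------------------------------------
    ref_sizes = {"reference": sum(len(s) for s in reference.values())}
    stats = summarize(scaffolds, build, ref_sizes)
    write_stats(stats, outdir / "assembly_stats.tsv")
    done("stats", n50=stats.n50, coverage_pct=stats.coverage_pct["reference"])

    # 5. locate ------------------------------------------------------------
    genes = read_fasta(ds.genes_fasta)
    hits = locate_genes(
        genes,
        build.pseudomolecules,
        k=config.k,
        max_occ=config.max_occ,
        min_identity=config.min_identity,
        min_coverage=config.min_coverage,
    )
    write_hits(hits, outdir / "gene_hits.tsv")
    done("locate", n_genes=len(genes), n_hits=sum(h is not None for h in hits.values()))

    # 6. paint -------------------------------------------------------------
    sites = filter_sites(
        ds.vcf,
        min_qual=config.min_qual,
        offspring=config.offspring,
        parent_a=config.parent_a,
        parent_b=config.parent_b,
    )
    classified = classify_sites(sites)
    write_classified(classified, outdir / "snp_classes.tsv")
    chrom_lengths = chrom_lengths_from_vcf(ds.vcf)
    summaries = {"all_snps": composition_from_sites(classified)}
    blocks_by_w = {}
    for w in config.window_sizes:
        blocks = window_paint(classified, chrom_lengths, w)
        blocks_by_w[w] = blocks
        write_windows(blocks, outdir / f"windows_{w}.tsv")
        summaries[f"windows_{w}"] = composition_from_blocks(blocks)
    write_composition(summaries, outdir / "composition.tsv")
    done("paint", n_sites=len(sites), n_classified=len(classified))

    # 7. qtl ---------------------------------------------------------------
    if config.region:
        region = parse_region(config.region)
    else:
        first = sorted(chrom_lengths)[0]
        length = chrom_lengths[first]
        region = Region(first, length // 4, 3 * length // 4)
    w0 = config.window_sizes[0]
    zoomed = zoom(blocks_by_w[w0], region)
    segs = segments(zoomed)
    write_segments(segs, outdir / "qtl_segments.tsv")
    done("qtl", region=f"{region.chrom}:{region.start}-{region.end}", n_segments=len(segs))

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
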
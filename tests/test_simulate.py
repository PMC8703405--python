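"""Synthetic-data generator: determinism, tiling, conservation, VCF rules."""

import math

import numpy as np
import pytest

from mosaicpaint.paint import filter_sites
from mosaicpaint.simulate import (
    FOUNDERS,
    SimConfig,
    emit_vcf,
    extract_genes,
    fragment_to_scaffolds,
    genome_to_str,
    realized_fractions,
    simulate_dataset,
    simulate_founders,
    simulate_offspring,
)
from mosaicpaint.stats import n50


def test_config_validation():
    with pytest.raises(ValueError):
        SimConfig(target_fracs=(0.5, 0.5, 0.5))
    with pytest.raises(ValueError):
        SimConfig(chrom_len=0)
    with pytest.raises(ValueError):
        SimConfig(snp_rate=1.5)


def test_zero_snp_rate_gives_identical_founders():
    cfg = SimConfig(n_chrom=1, chrom_len=5_000, snp_rate=0.0, seed=3,
                    min_segment_len=1_000, mean_segment_len=2_000)
    founders = simulate_founders(cfg)
    assert len(founders.catalog) == 0
    a, b, u = (genome_to_str(founders.genomes[f]) for f in FOUNDERS)
    assert a == b == u


def test_snp_count_within_binomial_bounds():
    cfg = SimConfig(n_chrom=1, chrom_len=100_000, snp_rate=0.005, seed=5,
                    min_segment_len=10_000, mean_segment_len=20_000)
    founders = simulate_founders(cfg)
    mean = 100_000 * 0.005
    sd = math.sqrt(100_000 * 0.005 * 0.995)
    assert abs(len(founders.catalog) - mean) <= 3 * sd


def test_catalog_alleles_are_biallelic_and_genomes_match_catalog():
    cfg = SimConfig(n_chrom=1, chrom_len=20_000, seed=8,
                    min_segment_len=5_000, mean_segment_len=8_000)
    founders = simulate_founders(cfg)
    cat = founders.catalog
    for _, row in cat.iterrows():
        alleles = {row.allele_A, row.allele_B, row.allele_U}
        assert alleles == {row.ref, row.alt}
        for f in FOUNDERS:
            seq = founders.genomes[f][row.chrom]
            assert seq[row.pos - 1].decode() == getattr(row, f"allele_{f}")
    # outside catalogued positions the founders are identical
    snp_pos = set(cat.pos)
    a = founders.genomes["A"]["chr01"]
    b = founders.genomes["B"]["chr01"]
    diff = np.flatnonzero(a != b) + 1
    assert set(diff) <= snp_pos


def test_determinism_byte_identical(tmp_path):
    cfg = SimConfig(n_chrom=1, chrom_len=30_000, seed=9,
                    min_segment_len=5_000, mean_segment_len=10_000)
    d1 = simulate_dataset(cfg, tmp_path / "r1")
    d2 = simulate_dataset(cfg, tmp_path / "r2")
    for attr in ("offspring_fasta", "scaffolds_fasta", "vcf", "truth_bed",
                 "genes_fasta"):
        assert getattr(d1, attr).read_bytes() == getattr(d2, attr).read_bytes()


def test_degenerate_fractions_give_single_founder_offspring():
    cfg = SimConfig(n_chrom=2, chrom_len=30_000, target_fracs=(1.0, 0.0, 0.0),
                    seed=4, min_segment_len=5_000, mean_segment_len=8_000)
    founders = simulate_founders(cfg)
    offspring, truth = simulate_offspring(founders, cfg)
    assert genome_to_str(offspring) == genome_to_str(founders.genomes["A"])
    # merged same-origin runs: exactly one segment per chromosome
    assert len(truth) == cfg.n_chrom
    assert all(t.origin == "A" and t.start == 1 and t.end == cfg.chrom_len
               for t in truth)


def test_truth_segments_tile_chromosomes(small_world):
    cfg, _, _, truth, _, _ = small_world
    for chrom in cfg.chrom_names():
        segs = sorted((t for t in truth if t.chrom == chrom),
                      key=lambda t: t.start)
        assert segs[0].start == 1
        assert segs[-1].end == cfg.chrom_len
        for a, b in zip(segs, segs[1:]):
            assert b.start == a.end + 1


def test_realized_fraction_tracks_target():
    cfg = SimConfig(n_chrom=10, chrom_len=500_000, seed=21,
                    target_fracs=(0.6, 0.25, 0.15),
                    min_segment_len=1_000, mean_segment_len=100_000)
    founders = simulate_founders(cfg)
    _, truth = simulate_offspring(founders, cfg)
    fr = realized_fractions(truth)
    assert abs(fr["A"] - 0.6) <= 0.10  # Monte-Carlo at fixed seed
    assert abs(sum(fr.values()) - 1.0) < 1e-12


def test_fragmentation_roundtrip_and_conservation(small_cfg):
    cfg = SimConfig(**{**small_cfg.__dict__, "rc_prob": 0.0,
                       "scaffold_error_rate": 0.0})
    founders = simulate_founders(cfg)
    offspring, _ = simulate_offspring(founders, cfg)
    scaffolds, truth = fragment_to_scaffolds(offspring, cfg)
    genome = genome_to_str(offspring)
    # total scaffold bases equal genome bases
    assert sum(map(len, scaffolds.values())) == sum(map(len, genome.values()))
    # concatenating in truth order reproduces each chromosome
    for chrom in genome:
        parts = sorted((t for t in truth if t.chrom == chrom),
                       key=lambda t: t.start)
        assert "".join(scaffolds[t.scf_id] for t in parts) == genome[chrom]
        assert parts[0].start == 1 and parts[-1].end == len(genome[chrom])


def test_scaffold_truth_matches_sequence(small_world):
    """With reverse complementing on, truth placements still decode scaffolds."""
    from mosaicpaint._util import revcomp

    cfg, _, offspring, _, scaffolds, scf_truth = small_world
    genome = genome_to_str(offspring)
    for t in scf_truth:
        expected = genome[t.chrom][t.start - 1 : t.end]
        if t.strand == "-":
            expected = revcomp(expected)
        assert scaffolds[t.scf_id] == expected


def test_scaffold_n50_near_lognormal_target():
    """~500 scaffolds of lognormal(mean 25 kb) have N50 within 30% of 25 kb."""
    cfg = SimConfig(n_chrom=25, chrom_len=500_000, snp_rate=0.001, seed=13,
                    min_segment_len=100_000, mean_segment_len=200_000)
    founders = simulate_founders(cfg)
    offspring, _ = simulate_offspring(founders, cfg)
    scaffolds, _ = fragment_to_scaffolds(offspring, cfg)
    assert len(scaffolds) > 300
    value = n50([len(s) for s in scaffolds.values()])
    assert abs(value - 25_000) <= 0.30 * 25_000


def test_vcf_only_polymorphic_catalog_sites(small_world, tmp_path):
    cfg, founders, offspring, truth, _, _ = small_world
    text = emit_vcf(founders, offspring, cfg)
    records = [l.split("\t") for l in text.splitlines() if not l.startswith("#")]
    catalog = {(r.chrom, r.pos) for r in founders.catalog.itertuples()}
    for rec in records:
        chrom, pos = rec[0], int(rec[1])
        assert (chrom, pos) in catalog
        gts = rec[9:12]
        assert len(set(gts)) >= 2  # polymorphic across the three samples
        assert all(g in ("0/0", "1/1") for g in gts)  # inbred homozygotes


def test_vcf_offspring_matches_parent_of_origin(small_world):
    cfg, founders, offspring, truth, _, _ = small_world
    text = emit_vcf(founders, offspring, cfg)

    def origin_at(chrom, pos):
        return next(s.origin for s in truth
                    if s.chrom == chrom and s.start <= pos <= s.end)

    checked = 0
    for line in text.splitlines():
        if line.startswith("#"):
            continue
        f = line.split("\t")
        chrom, pos = f[0], int(f[1])
        off, pa, pb = f[9], f[10], f[11]
        origin = origin_at(chrom, pos)
        if origin == "A":
            assert off == pa
            checked += 1
        elif origin == "B":
            assert off == pb
            checked += 1
    assert checked > 50


def test_low_qual_injection_is_filterable(tmp_path):
    cfg = SimConfig(n_chrom=1, chrom_len=50_000, seed=17, low_qual_frac=0.10,
                    min_segment_len=10_000, mean_segment_len=20_000)
    founders = simulate_founders(cfg)
    offspring, _ = simulate_offspring(founders, cfg)
    text = emit_vcf(founders, offspring, cfg)
    path = tmp_path / "trio.vcf"
    path.write_text(text)
    records = [l for l in text.splitlines() if not l.startswith("#")]
    n_low = sum(l.split("\t")[5] == "10" for l in records)
    assert 0 < n_low < len(records)
    kept = filter_sites(path, min_qual=30)
    assert len(kept) == len(records) - n_low
    assert len(filter_sites(path, min_qual=0)) == len(records)


def test_extracted_genes_are_genome_substrings(small_world):
    from mosaicpaint._util import revcomp

    cfg, _, offspring, _, _, _ = small_world
    genes, truth = extract_genes(offspring, cfg)
    genome = genome_to_str(offspring)
    assert len(genes) == cfg.n_genes
    for t in truth:
        seq = genome[t.chrom][t.start - 1 : t.end]
        if t.strand == "-":
            seq = revcomp(seq)
        assert genes[t.gene_id] == seq
        assert len(seq) == cfg.gene_len
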
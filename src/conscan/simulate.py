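"""Synthetic two-species promoter universe with planted motifs and counts.

Everything downstream (promoter extraction, conservation filtering, PWM
scanning, calibration, FPKM fold-change target calling) can be exercised
against known ground truth:

* two orthologous "genomes", one chromosome each, with genes laid out in
  non-overlapping blocks on alternating strands;
* species-B promoters derived from species-A's by i.i.d. per-base
  substitution — a low rate inside designated conserved blocks, a high rate
  elsewhere — so percent-identity ground truth is exact (no indels by
  default);
* motif instances sampled from the PWM's per-column base distributions,
  planted on a random strand inside a conserved block within the proximal
  promoter of designated target genes;
* a motif-free negative-control sequence set of i.i.d. background
  composition, emulating the second-exon pool used for threshold
  calibration;
* a negative-binomial count table (two replicates per genotype, log-normal
  gene means, per-sample depth factors) with planted down-regulation of the
  target genes in the knockout.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genome_io import FastaStore, GeneModel, GenomicInterval, write_fasta
from .motif import BASES, PWM, reverse_complement, write_jaspar

_BASE_ARR = np.frombuffer("ACGT".encode("ascii"), dtype=np.uint8)


@dataclass
class SimulationConfig:
    """Study-design parameters of the synthetic dataset.

    Defaults mirror the analysis conditions: a 10 kb upstream / 5 kb
    downstream promoter window, ~2 kb of conserved sequence per promoter,
    a ~1.5 Mbp negative-control pool, two replicates per genotype and
    4-fold knockout down-regulation of target genes.
    """

    seed: int = 0
    n_genes: int = 40
    n_targets: int = 10
    promoter_upstream_bp: int = 10_000
    promoter_downstream_bp: int = 5_000
    conserved_block_identity: float = 0.95
    diverged_identity: float = 0.60
    conserved_total_bp: int = 2_000
    n_conserved_blocks: int = 4
    motif_planting_rate: float = 1.0
    negative_control_total_bp: int = 1_500_000
    n_replicates: int = 2
    target_fold_change: float = 0.25
    dispersion: float = 0.05
    indel_rate: float = 0.0
    background_base_composition: tuple[float, float, float, float] = (
        0.25, 0.25, 0.25, 0.25,
    )

    def validate(self) -> None:
        if self.n_targets > self.n_genes:
            raise ValueError("n_targets cannot exceed n_genes")
        for name in (
            "n_genes", "promoter_upstream_bp", "promoter_downstream_bp",
            "conserved_total_bp", "negative_control_total_bp", "n_replicates",
            "n_conserved_blocks",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("conserved_block_identity", "diverged_identity"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must be in (0, 1]")
        if self.target_fold_change <= 0:
            raise ValueError("target_fold_change must be positive")
        if self.motif_planting_rate < 0 or self.dispersion < 0 or self.indel_rate < 0:
            raise ValueError("rates must be non-negative")
        bg = np.asarray(self.background_base_composition, dtype=float)
        if bg.shape != (4,) or abs(bg.sum() - 1.0) > 1e-9 or np.any(bg < 0):
            raise ValueError("background composition must be a 4-vector summing to 1")


@dataclass
class TruthTable:
    """Ground truth per gene: target status, planted sites, true fold change.

    ``planted_sites`` holds (TSS-relative offset of the site start, strand)
    pairs; strand is relative to the gene's own orientation.
    """

    is_target: dict[str, bool]
    planted_sites: dict[str, list[tuple[int, str]]]
    true_fold_change: dict[str, float]

    def to_frame(self) -> pd.DataFrame:
        genes = sorted(self.is_target)
        return pd.DataFrame(
            {
                "gene": genes,
                "is_target": [int(self.is_target[g]) for g in genes],
                "true_fold_change": [self.true_fold_change[g] for g in genes],
                "planted_sites": [
                    ";".join(f"{o}{s}" for o, s in self.planted_sites[g])
                    for g in genes
                ],
            }
        ).set_index("gene")


@dataclass
class GenomePair:
    """One simulated dataset: two genomes, gene models, orthology, truth."""

    config: SimulationConfig
    genome_a: FastaStore
    genes_a: list[GeneModel]
    genome_b: FastaStore
    genes_b: list[GeneModel]
    orthologs: dict[str, str]
    truth: TruthTable
    conserved_blocks: dict[str, list[tuple[int, int]]]  # promoter offsets, species A


def _random_bases(rng: np.random.Generator, n: int, composition) -> np.ndarray:
    return rng.choice(_BASE_ARR, size=n, p=np.asarray(composition, dtype=float))


def _arr_to_str(arr: np.ndarray) -> str:
    return arr.tobytes().decode("ascii")


def _sample_site(rng: np.random.Generator, pwm: PWM) -> str:
    """Draw one motif instance from the PWM's per-column distributions."""
    cols = [rng.choice(4, p=pwm.probabilities[:, j]) for j in range(pwm.length)]
    return "".join(BASES[c] for c in cols)


def _mutate(
    rng: np.random.Generator, promoter: np.ndarray, rates: np.ndarray
) -> np.ndarray:
    """Per-base substitution at position-specific rates; substitutions pick
    uniformly among the three other bases."""
    out = promoter.copy()
    hit = np.nonzero(rng.random(promoter.shape[0]) < rates)[0]
    if hit.size:
        codes = np.searchsorted(_BASE_ARR, out[hit])  # bases are sorted ACGT
        shift = rng.integers(1, 4, size=hit.size)
        out[hit] = _BASE_ARR[(codes + shift) % 4]
    return out


def xbox_demo_pwm() -> PWM:
    """A 14-column X-box-like demonstration matrix.

    RFX-family factors bind an imperfect palindrome resembling
    GTTGCCATGGTAAC; the column sharpness here is typical of a curated
    RFX matrix and is what the simulator plants by default.  It is a
    package fixture, not a database matrix.
    """
    #                G   T   T   G   C   C   A   T   G   G   T   A   A   C
    counts = np.array([
        [  2,   1,   2,   2,   2,   4,  90,   2,   3,   2,   2,  88,  90,   2],  # A
        [  3,   2,   2,   6,  90,  80,   4,   2,   2,   4,   6,   4,   4,  90],  # C
        [ 90,   2,   2,  86,   4,   8,   4,   2,  90,  88,   2,   4,   4,   4],  # G
        [  5,  95,  94,   6,   4,   8,   2,  94,   5,   6,  90,   4,   2,   4],  # T
    ], dtype=float)
    return PWM(counts, name="xbox_demo")


# gene-body layout constants (bp); exon2 is the "second exon" negative-control
# analogue and exon sizes are drawn per gene for realism
_EXON_RANGES = ((200, 400), (300, 900), (300, 900))
_INTRON_RANGE = (300, 1200)
_SPACER = 500


def _plan_gene(rng, cfg: SimulationConfig, cursor: int, strand: str):
    """Allot a genomic block for one gene; returns (gene plan, next cursor)."""
    exon_lens = [int(rng.integers(lo, hi + 1)) for lo, hi in _EXON_RANGES]
    intron_lens = [int(rng.integers(*_INTRON_RANGE)) for _ in range(2)]
    body = sum(exon_lens) + sum(intron_lens)
    up, down = cfg.promoter_upstream_bp, cfg.promoter_downstream_bp
    block = up + down + body + _SPACER
    if strand == "+":
        tss = cursor + up
        pos = tss
        exons = []
        for e, iv in zip(exon_lens, intron_lens + [0]):
            exons.append((pos, pos + e))
            pos += e + iv
    else:
        tss = cursor + down + body - 1
        pos = tss + 1
        exons = []
        for e, iv in zip(exon_lens, intron_lens + [0]):
            exons.append((pos - e, pos))
            pos -= e + iv
    return {"tss": tss, "strand": strand, "exons": exons, "body": body}, cursor + block


def _place_blocks(rng, cfg: SimulationConfig, prom_len: int, up: int, motif_len: int):
    """Conserved-block layout for one promoter (promoter offsets).

    The first block is placed inside the proximal window [-1000, +1000) so
    planted sites can sit in conserved & proximal sequence; the remaining
    blocks are scattered over the rest of the promoter without overlap.
    """
    n_blocks = cfg.n_conserved_blocks
    block_len = cfg.conserved_total_bp // n_blocks
    prox_lo = max(0, up - 1000)
    prox_hi = min(prom_len, up + 1000)
    s0 = int(rng.integers(prox_lo, prox_hi - block_len + 1))
    blocks = [(s0, s0 + block_len)]
    for _ in range(n_blocks - 1):
        for _try in range(200):
            s = int(rng.integers(0, prom_len - block_len + 1))
            if all(s + block_len <= lo or s >= hi for lo, hi in blocks):
                blocks.append((s, s + block_len))
                break
        else:
            raise RuntimeError("could not place conserved blocks without overlap")
    return sorted(blocks), blocks[0]


def _plant_sites(rng, cfg, pwm, prom: np.ndarray, block: tuple[int, int], up: int):
    """Plant PWM-sampled sites in the proximal part of a conserved block.

    Returns (TSS-relative offset, strand) per planted site.  The number of
    sites has mean ``motif_planting_rate``; for rates >= 1 it is
    1 + Poisson(rate - 1) so every target gene carries at least one site.
    """
    L = pwm.length
    rate = cfg.motif_planting_rate
    if rate >= 1.0:
        n_sites = 1 + int(rng.poisson(rate - 1.0))
    else:
        n_sites = int(rng.poisson(rate))
    lo = max(block[0], up - 1000)
    hi = min(block[1], up + 1000)
    if hi - lo < L:
        raise ValueError("motif longer than the usable proximal conserved block")
    placed: list[tuple[int, str]] = []
    sites = []
    for _ in range(n_sites):
        for _try in range(200):
            s = int(rng.integers(lo, hi - L + 1))
            if all(abs(s - p) >= L for p, _ in placed):
                break
        else:
            raise RuntimeError("could not place non-overlapping motif instances")
        strand = "+" if rng.random() < 0.5 else "-"
        site = _sample_site(rng, pwm)
        oriented = site if strand == "+" else reverse_complement(site)
        prom[s : s + L] = np.frombuffer(oriented.encode("ascii"), dtype=np.uint8)
        placed.append((s, strand))
        sites.append((s - up, strand))
    return sites


def simulate_genome_pair(
    config: SimulationConfig, pwm: PWM | None = None
) -> GenomePair:
    """Generate the orthologous genome pair with planted motifs and truth.

    Species-B promoters are substitution-mutated copies of species-A's:
    rate ``1 - conserved_block_identity`` inside conserved blocks and
    ``1 - diverged_identity`` elsewhere.  Identical seeds give identical
    output.
    """
    config.validate()
    pwm = pwm or xbox_demo_pwm()
    up, down = config.promoter_upstream_bp, config.promoter_downstream_bp
    if pwm.length > 2000 or pwm.length > up + down:
        raise ValueError("motif longer than the proximal promoter window")
    rng = np.random.default_rng(config.seed)
    bg = np.asarray(config.background_base_composition, dtype=float)

    plans = []
    cursor = _SPACER
    for i in range(config.n_genes):
        plan, cursor = _plan_gene(rng, config, cursor, "+" if i % 2 == 0 else "-")
        plans.append(plan)
    chrom_len = cursor + _SPACER

    seq_a = _random_bases(rng, chrom_len, bg)
    seq_b = _random_bases(rng, chrom_len, bg)

    target_idx = set(range(config.n_targets))  # deterministic: first n_targets genes
    prom_len = up + down
    rate_cons = 1.0 - config.conserved_block_identity
    rate_div = 1.0 - config.diverged_identity

    genes_a: list[GeneModel] = []
    genes_b: list[GeneModel] = []
    orthologs: dict[str, str] = {}
    truth = TruthTable({}, {}, {})
    blocks_by_gene: dict[str, list[tuple[int, int]]] = {}

    for i, plan in enumerate(plans):
        ga, gb = f"geneA_{i:03d}", f"geneB_{i:03d}"
        tss, strand = plan["tss"], plan["strand"]
        # promoter in gene orientation
        if strand == "+":
            g_lo, g_hi = tss - up, tss + down
            prom = seq_a[g_lo:g_hi].copy()
        else:
            g_lo, g_hi = tss - down + 1, tss + up + 1
            prom = np.frombuffer(
                reverse_complement(_arr_to_str(seq_a[g_lo:g_hi])).encode("ascii"),
                dtype=np.uint8,
            ).copy()
        blocks, prox_block = _place_blocks(rng, config, prom_len, up, pwm.length)
        blocks_by_gene[ga] = blocks

        is_target = i in target_idx
        sites: list[tuple[int, str]] = []
        if is_target and config.motif_planting_rate > 0:
            sites = _plant_sites(rng, config, pwm, prom, prox_block, up)

        rates = np.full(prom_len, rate_div)
        for lo, hi in blocks:
            rates[lo:hi] = rate_cons
        prom_b = _mutate(rng, prom, rates)
        if config.indel_rate > 0:
            keep = rng.random(prom_len) >= config.indel_rate
            prom_b = prom_b[keep]

        # write promoters back into the chromosomes, genome orientation
        if strand == "+":
            seq_a[g_lo:g_hi] = prom
            seq_b[g_lo : g_lo + prom_b.shape[0]] = prom_b
        else:
            seq_a[g_lo:g_hi] = np.frombuffer(
                reverse_complement(_arr_to_str(prom)).encode("ascii"), dtype=np.uint8
            )
            rc_b = np.frombuffer(
                reverse_complement(_arr_to_str(prom_b)).encode("ascii"), dtype=np.uint8
            )
            seq_b[g_hi - rc_b.shape[0] : g_hi] = rc_b

        exons_a = [GenomicInterval("chrA", lo, hi, strand) for lo, hi in plan["exons"]]
        exons_b = [GenomicInterval("chrB", lo, hi, strand) for lo, hi in plan["exons"]]
        genes_a.append(
            GeneModel(ga, "chrA", strand, tss, exons_a, exons_a[1], ortholog_id=gb)
        )
        genes_b.append(
            GeneModel(gb, "chrB", strand, tss, exons_b, exons_b[1], ortholog_id=ga)
        )
        orthologs[ga] = gb
        truth.is_target[ga] = is_target
        truth.planted_sites[ga] = sites
        truth.true_fold_change[ga] = (
            config.target_fold_change if is_target else 1.0
        )

    genome_a = FastaStore({"chrA": _arr_to_str(seq_a)})
    genome_b = FastaStore({"chrB": _arr_to_str(seq_b)})
    return GenomePair(
        config, genome_a, genes_a, genome_b, genes_b, orthologs, truth, blocks_by_gene
    )


def simulate_negative_control(config: SimulationConfig) -> list[str]:
    """Motif-free i.i.d. background sequences totalling
    ``negative_control_total_bp``, split into exon-sized records (100-2000 bp).

    Emulates the second-exon pool of protein-coding genes used to calibrate
    the match-score cutoff.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 17]))
    bg = np.asarray(config.background_base_composition, dtype=float)
    total = config.negative_control_total_bp
    seqs: list[str] = []
    remaining = total
    while remaining > 0:
        n = int(rng.integers(100, 2001))
        n = min(n, remaining)
        seqs.append(_arr_to_str(_random_bases(rng, n, bg)))
        remaining -= n
    return seqs


def simulate_counts(
    config: SimulationConfig,
    truth: TruthTable,
    gene_lengths: dict[str, int],
) -> pd.DataFrame:
    """Negative-binomial count table, two genotypes x ``n_replicates``.

    Wild-type gene means are log-normal (median ~200 fragments); knockout
    means are scaled by the gene's true fold change.  Per-sample depth
    factors (U(0.7, 1.3)) make library-size normalization consequential.
    Columns: length, WT_1..WT_r, KO_1..KO_r.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 29]))
    genes = sorted(gene_lengths)
    mu_wt = rng.lognormal(mean=np.log(200.0), sigma=1.0, size=len(genes))
    samples = [f"WT_{r + 1}" for r in range(config.n_replicates)] + [
        f"KO_{r + 1}" for r in range(config.n_replicates)
    ]
    depth = rng.uniform(0.7, 1.3, size=len(samples))
    data = {"length": [gene_lengths[g] for g in genes]}
    for s_i, s in enumerate(samples):
        fc = np.array(
            [truth.true_fold_change[g] if s.startswith("KO") else 1.0 for g in genes]
        )
        mu = mu_wt * fc * depth[s_i]
        if config.dispersion > 0:
            r = 1.0 / config.dispersion
            data[s] = rng.negative_binomial(r, r / (r + mu))
        else:
            data[s] = rng.poisson(mu)
    df = pd.DataFrame(data, index=pd.Index(genes, name="gene"))
    return df


# ---------------------------------------------------------------------------
# dataset writers


def _write_gff3(genes: list[GeneModel], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            lo = min(e.start for e in g.exons)
            hi = max(e.end for e in g.exons)
            fh.write(
                f"{g.chrom}\tconscan\tgene\t{lo + 1}\t{hi}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}\n"
            )
            t_id = f"{g.gene_id}.t1"
            fh.write(
                f"{g.chrom}\tconscan\tmRNA\t{lo + 1}\t{hi}\t.\t{g.strand}\t.\t"
                f"ID={t_id};Parent={g.gene_id}\n"
            )
            for j, e in enumerate(g.exons, start=1):
                fh.write(
                    f"{g.chrom}\tconscan\texon\t{e.start + 1}\t{e.end}\t.\t"
                    f"{g.strand}\t.\tID={t_id}.e{j};Parent={t_id}\n"
                )


def write_dataset(pair: GenomePair, outdir, pwm: PWM | None = None) -> dict[str, Path]:
    """Write the simulated dataset to standard-format files; returns paths."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta_a": out / "genome_a.fa",
        "gff_a": out / "genes_a.gff3",
        "fasta_b": out / "genome_b.fa",
        "gff_b": out / "genes_b.gff3",
        "orthologs": out / "orthologs.tsv",
        "truth": out / "truth.tsv",
        "counts": out / "counts.tsv",
        "negative": out / "negative_control.fa",
        "pfm": out / "motif.jaspar",
    }
    write_fasta(pair.genome_a, paths["fasta_a"])
    write_fasta(pair.genome_b, paths["fasta_b"])
    _write_gff3(pair.genes_a, paths["gff_a"])
    _write_gff3(pair.genes_b, paths["gff_b"])
    with open(paths["orthologs"], "w") as fh:
        fh.write("gene_a\tgene_b\n")
        for ga, gb in sorted(pair.orthologs.items()):
            fh.write(f"{ga}\t{gb}\n")
    pair.truth.to_frame().to_csv(paths["truth"], sep="\t")

    lengths = {g.gene_id: g.length_bp for g in pair.genes_a}
    counts = simulate_counts(pair.config, pair.truth, lengths)
    counts.to_csv(paths["counts"], sep="\t")

    neg = simulate_negative_control(pair.config)
    neg_store = FastaStore({f"neg_{i:04d}": s for i, s in enumerate(neg)})
    write_fasta(neg_store, paths["negative"])

    write_jaspar(pwm or xbox_demo_pwm(), paths["pfm"])
    return paths
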
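"""Ground-truth guarantees of the synthetic-data generator."""

import numpy as np
import pytest

import conscan as cs
from conscan import genome_io as gio


def promoter_pair(pair, gene_a):
    """Extract the orthologous promoter pair in gene orientation."""
    cfg = pair.config
    models_b = {g.gene_id: g for g in pair.genes_b}
    seq_a, win = gio.extract_promoter(
        pair.genome_a, gene_a, cfg.promoter_upstream_bp, cfg.promoter_downstream_bp
    )
    seq_b, _ = gio.extract_promoter(
        pair.genome_b, models_b[gene_a.ortholog_id],
        cfg.promoter_upstream_bp, cfg.promoter_downstream_bp,
    )
    return seq_a, seq_b, win


class TestConfig:
    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            cs.SimulationConfig(n_genes=4, n_targets=5).validate()
        with pytest.raises(ValueError):
            cs.SimulationConfig(conserved_block_identity=1.5).validate()
        with pytest.raises(ValueError):
            cs.SimulationConfig(
                background_base_composition=(0.5, 0.5, 0.5, 0.5)
            ).validate()
        with pytest.raises(ValueError):
            cs.SimulationConfig(target_fold_change=0.0).validate()

    def test_motif_longer_than_proximal_window_rejected(self):
        cfg = cs.SimulationConfig(promoter_upstream_bp=6, promoter_downstream_bp=4)
        with pytest.raises(ValueError, match="proximal"):
            cs.simulate_genome_pair(cfg)


class TestGenomePair:
    def test_every_target_has_proximal_planted_site(self, small_pair, xbox_pwm):
        for g, is_target in small_pair.truth.is_target.items():
            sites = small_pair.truth.planted_sites[g]
            if is_target:
                assert sites, g
                for off, strand in sites:
                    assert -1000 <= off and off + xbox_pwm.length <= 1000
            else:
                assert not sites

    def test_all_genes_targeted_when_requested(self, xbox_pwm):
        cfg = cs.SimulationConfig(
            seed=3, n_genes=4, n_targets=4,
            promoter_upstream_bp=1500, promoter_downstream_bp=800,
            conserved_total_bp=800, n_conserved_blocks=2,
        )
        pair = cs.simulate_genome_pair(cfg, xbox_pwm)
        assert all(pair.truth.planted_sites[g] for g in pair.truth.is_target)

    def test_planted_site_sequence_scores_and_validates(self, small_pair, xbox_pwm):
        """The promoter sequence at every planted offset really matches the
        motif: its score is what a direct rescan of the genome computes."""
        models = {g.gene_id: g for g in small_pair.genes_a}
        for g, sites in small_pair.truth.planted_sites.items():
            seq_a, _, win = promoter_pair(small_pair, models[g])
            for off, strand in sites:
                pos = off + win.upstream_bp
                s = cs.score_window(xbox_pwm, seq_a, pos, strand)
                assert s > 0.5  # PWM-sampled instances score high

    def test_planted_sites_inside_conserved_blocks(self, small_pair, xbox_pwm):
        for g, sites in small_pair.truth.planted_sites.items():
            blocks = small_pair.conserved_blocks[g]
            up = small_pair.config.promoter_upstream_bp
            for off, _ in sites:
                pos = off + up
                assert any(lo <= pos and pos + xbox_pwm.length <= hi
                           for lo, hi in blocks)

    def test_determinism_byte_identical(self, small_sim_config, xbox_pwm, tmp_path):
        p1 = cs.simulate_genome_pair(small_sim_config, xbox_pwm)
        p2 = cs.simulate_genome_pair(small_sim_config, xbox_pwm)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        f1 = cs.write_dataset(p1, d1, xbox_pwm)
        f2 = cs.write_dataset(p2, d2, xbox_pwm)
        for key in f1:
            assert f1[key].read_bytes() == f2[key].read_bytes(), key

    def test_conserved_block_identity_matches_config(self, small_pair):
        """Direct base-by-base comparison of the emitted pair: conserved
        blocks at the configured identity, flanks near diverged identity."""
        cfg = small_pair.config
        cons_match, cons_tot, div_match, div_tot = 0, 0, 0, 0
        models = {g.gene_id: g for g in small_pair.genes_a}
        for g, blocks in small_pair.conserved_blocks.items():
            seq_a, seq_b, _ = promoter_pair(small_pair, models[g])
            in_block = np.zeros(len(seq_a), dtype=bool)
            for lo, hi in blocks:
                in_block[lo:hi] = True
            eq = np.frombuffer(seq_a.encode(), np.uint8) == np.frombuffer(
                seq_b.encode(), np.uint8
            )
            cons_match += int(eq[in_block].sum()); cons_tot += int(in_block.sum())
            div_match += int(eq[~in_block].sum()); div_tot += int((~in_block).sum())
        assert cons_match / cons_tot == pytest.approx(
            cfg.conserved_block_identity, abs=0.02
        )
        # diverged background: identity = diverged + (1-diverged)/... none of
        # the 3 substitution alternatives restores the base, so it is exact
        assert div_match / div_tot == pytest.approx(cfg.diverged_identity, abs=0.02)

    def test_annotation_roundtrip_through_gff3(self, small_pair, tmp_path):
        paths = cs.write_dataset(small_pair, tmp_path)
        genes = cs.read_annotation(paths["gff_a"])
        by_id = {g.gene_id: g for g in genes}
        for g in small_pair.genes_a:
            back = by_id[g.gene_id]
            assert back.tss == g.tss and back.strand == g.strand
            assert [(e.start, e.end) for e in back.exons] == [
                (e.start, e.end) for e in g.exons
            ]
            assert back.second_exon.start == g.second_exon.start


class TestNegativeControl:
    def test_total_length_and_record_sizes(self):
        cfg = cs.SimulationConfig(seed=5, negative_control_total_bp=100_000)
        seqs = cs.simulate_negative_control(cfg)
        assert sum(len(s) for s in seqs) == 100_000
        assert all(len(s) <= 2000 for s in seqs)

    def test_degenerate_composition_all_a(self):
        cfg = cs.SimulationConfig(
            seed=5, negative_control_total_bp=5_000,
            background_base_composition=(1.0, 0.0, 0.0, 0.0),
        )
        assert set("".join(cs.simulate_negative_control(cfg))) == {"A"}

    def test_uniform_composition_recovered(self):
        cfg = cs.SimulationConfig(seed=5, negative_control_total_bp=1_500_000)
        joined = "".join(cs.simulate_negative_control(cfg))
        for b in "ACGT":
            assert joined.count(b) / len(joined) == pytest.approx(0.25, abs=0.01)


class TestCounts:
    def _lengths(self, n=30):
        return {f"g{i:03d}": 1000 + 37 * i for i in range(n)}

    def _truth(self, lengths, fc=0.25, n_targets=10):
        genes = sorted(lengths)
        return cs.TruthTable(
            {g: i < n_targets for i, g in enumerate(genes)},
            {g: [] for g in genes},
            {g: fc if i < n_targets else 1.0 for i, g in enumerate(genes)},
        )

    def test_null_simulation_means_agree(self):
        lengths = self._lengths()
        truth = self._truth(lengths, fc=1.0, n_targets=0)
        cfg = cs.SimulationConfig(seed=8, dispersion=0.0, target_fold_change=1.0)
        counts = cs.simulate_counts(cfg, truth, lengths)
        wt = counts[["WT_1", "WT_2"]].to_numpy().sum()
        ko = counts[["KO_1", "KO_2"]].to_numpy().sum()
        # identical genotype means up to depth factors and Poisson error
        assert abs(np.log(ko / wt)) < 0.5

    def test_planted_fold_change_recovered_from_emitted_table(self):
        # targets are a small fraction so library sizes stay comparable and
        # the FPKM ratio is not distorted by composition
        lengths = self._lengths(400)
        truth = self._truth(lengths, fc=0.25, n_targets=20)
        cfg = cs.SimulationConfig(seed=9, dispersion=0.01)
        counts = cs.simulate_counts(cfg, truth, lengths)
        fpkm = cs.compute_fpkm(counts)
        ko = fpkm[["KO_1", "KO_2"]].mean(axis=1)
        wt = fpkm[["WT_1", "WT_2"]].mean(axis=1)
        targets = [g for g in lengths if truth.is_target[g]]
        ratio = float(np.median((ko / wt)[targets]))
        assert 0.2 <= ratio <= 0.3

    def test_fixed_seed_reproducible(self):
        lengths = self._lengths()
        truth = self._truth(lengths)
        cfg = cs.SimulationConfig(seed=12)
        c1 = cs.simulate_counts(cfg, truth, lengths)
        c2 = cs.simulate_counts(cfg, truth, lengths)
        assert c1.equals(c2)
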
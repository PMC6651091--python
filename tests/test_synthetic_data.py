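import numpy as np
import pandas as pd
import pytest
from scipy import stats

from methylcontext import formats_io as fio
from methylcontext.synthetic_data import (
    MRE_MOTIFS,
    SimulationConfig,
    SimulationError,
    find_mre_sites,
    link_dmrs_to_genes,
    make_methylation_state,
    simulate_bin_dataset,
    simulate_counts,
    simulate_expression,
    simulate_genome,
)


class TestConfig:
    def test_invalid_configurations_rejected(self):
        with pytest.raises(SimulationError):
            SimulationConfig(island_gc=0.4, background_gc=0.5)
        with pytest.raises(SimulationError):
            SimulationConfig(dmr_effect=0.0)
        with pytest.raises(SimulationError):
            SimulationConfig(n_samples_per_group=0)
        with pytest.raises(SimulationError):
            SimulationConfig(dispersion=-0.1)

    def test_overfull_genome_names_the_constraint(self):
        cfg = SimulationConfig(
            genome_length=10_000, n_chroms=1, island_count=100,
            island_length_range=(300, 400), gene_count=0, planted_dmr_count=0,
        )
        with pytest.raises(SimulationError, match="island"):
            simulate_genome(cfg)


class TestGenome:
    def test_island_truth_count_conserved(self, small_config, small_genome):
        assert len(small_genome.islands) == small_config.island_count
        assert len(small_genome.genes) == small_config.gene_count

    def test_islands_are_gc_rich_in_emitted_fasta(self, tmp_path, small_config, small_genome):
        """GC recomputed from the written FASTA is higher inside truth islands."""
        fasta = tmp_path / "g.fa"
        bed = tmp_path / "isl.bed"
        fio.write_fasta(small_genome.sequences, fasta)
        fio.write_bed(small_genome.islands, bed)
        seqs = fio.read_fasta(fasta)
        islands = fio.read_bed(bed)

        def gc(s):
            return (s.count("G") + s.count("C")) / len(s)

        inside = "".join(seqs[iv.chrom][iv.start:iv.end] for iv in islands)
        masked = {c: list(s) for c, s in seqs.items()}
        for iv in islands:
            masked[iv.chrom][iv.start:iv.end] = [""] * iv.length
        outside = "".join("".join(v) for v in masked.values())
        assert gc(inside) > gc(outside)
        assert gc(inside) > 0.6  # islands planted at GC 0.70
        assert gc(outside) < 0.45

    def test_same_seed_gives_identical_fasta_bytes(self, tmp_path, small_config):
        paths = []
        for name in ("a.fa", "b.fa"):
            g = simulate_genome(small_config)
            p = tmp_path / name
            fio.write_fasta(g.sequences, p)
            paths.append(p.read_bytes())
        assert paths[0] == paths[1]

    def test_exon_chains_are_valid(self, small_genome):
        for gene in small_genome.genes:
            assert gene.exons[0].start == gene.interval.start
            assert gene.exons[-1].end == gene.interval.end


class TestMreSites:
    def test_single_motif_at_offset(self):
        # AACGTT carries exactly one recognition sequence, ACGT, whose first
        # base is the second position (0-based offset 1)
        (site,) = find_mre_sites("AACGTT")
        assert (site.interval.start, site.motif) == (1, "ACGT")

    def test_ccgg_only(self):
        sites = find_mre_sites("CCGG")
        assert [(s.interval.start, s.motif) for s in sites] == [(0, "CCGG")]

    def test_overlapping_occurrences_all_reported(self):
        # CGCGCG: CGCG at 0 and 2, GCGC at 1
        found = {(s.interval.start, s.motif) for s in find_mre_sites("CGCGCG")}
        assert found == {(0, "CGCG"), (2, "CGCG"), (1, "GCGC")}

    def test_matches_exhaustive_offset_oracle_on_random_sequence(self, rng):
        seq = "".join(rng.choice(list("ACGTN"), p=[0.27, 0.23, 0.23, 0.25, 0.02], size=10_000))
        expected = sorted(
            (i, seq[i : i + 4])
            for i in range(len(seq) - 3)
            if seq[i : i + 4] in MRE_MOTIFS
        )
        got = sorted((s.interval.start, s.motif) for s in find_mre_sites(seq))
        assert got == expected
        for start, motif in got:
            assert seq[start : start + 4] == motif


class TestCounts:
    def test_extreme_levels_silence_one_assay(self):
        """Fully methylated bins draw no MRE reads; unmethylated none in MeDIP."""
        cfg = SimulationConfig(planted_dmr_count=0, dispersion=0.0, seed=5)
        state, profile = simulate_bin_dataset(200, cfg, planted=False)
        for g in cfg.groups:
            state.levels[g][:100] = 1.0
            state.levels[g][100:] = 0.0
        from methylcontext.synthetic_data import _counts_from_arrays

        sites = np.ones(200, dtype=np.int64)
        state.cpg_per_bin[:] = 5
        profile = _counts_from_arrays(state, sites, cfg)
        assert (profile.mre_counts.values[:100] == 0).all()
        assert (profile.medip_counts.values[100:] == 0).all()

    def test_monte_carlo_mean_matches_configured_rate(self):
        """At level 0.5 and uniform covariates the empirical MeDIP mean is
        within 3 standard errors of the model mean coverage * level."""
        cfg = SimulationConfig(planted_dmr_count=0, dispersion=0.05,
                               n_samples_per_group=1, groups=("MHF",), seed=9)
        state, _ = simulate_bin_dataset(10_000, cfg, planted=False)
        state.levels["MHF"][:] = 0.5
        state.cpg_per_bin[:] = 4
        from methylcontext.synthetic_data import _counts_from_arrays

        profile = _counts_from_arrays(state, np.full(10_000, 2, dtype=np.int64), cfg)
        mu = cfg.mean_coverage * 0.5  # covariates are uniform, so ratio terms are 1
        draws = profile.medip_counts.values[:, 0]
        se = draws.std(ddof=1) / np.sqrt(draws.size)
        assert abs(draws.mean() - mu) < 3 * se

    def test_truth_flags_conserved(self, small_config, small_genome):
        from methylcontext.synthetic_data import find_mre_sites_genome

        sites = find_mre_sites_genome(small_genome.sequences)
        state = make_methylation_state(small_genome, small_config, sites)
        assert int((state.truth != "none").sum()) == small_config.planted_dmr_count
        flagged = np.flatnonzero(state.truth != "none")
        gap = np.abs(state.levels["MHF"][flagged] - state.levels["PHF"][flagged])
        assert (gap >= small_config.dmr_effect - 1e-12).all()

    def test_counts_deterministic_given_seed(self, small_config, small_genome):
        from methylcontext.synthetic_data import find_mre_sites_genome

        sites = find_mre_sites_genome(small_genome.sequences)
        state = make_methylation_state(small_genome, small_config, sites)
        p1 = simulate_counts(state, sites, small_config)
        p2 = simulate_counts(state, sites, small_config)
        assert (p1.medip_counts.values == p2.medip_counts.values).all()
        assert (p1.mre_counts.values == p2.mre_counts.values).all()


class TestExpression:
    def test_null_effect_rejects_at_nominal_rate(self, small_genome):
        """With expression_effect 0 the groups are exchangeable; per-gene
        two-sample t-tests reject at roughly the nominal 5% rate."""
        cfg = SimulationConfig(expression_effect=0.0, n_samples_per_group=10,
                               planted_dmr_count=0, seed=21)
        genes = small_genome.genes * 25  # 500 null genes
        genes = [
            fio.GeneModel(f"g{i}", g.interval, g.exons) for i, g in enumerate(genes)
        ]
        expr = simulate_expression(genes, pd.DataFrame(columns=["gene_id", "direction", "relative_position"]), cfg)
        mhf = [a for a in expr.columns if a.startswith("MHF")]
        phf = [a for a in expr.columns if a.startswith("PHF")]
        p = stats.ttest_ind(expr[mhf], expr[phf], axis=1).pvalue
        rate = (p < 0.05).mean()
        assert 0.01 < rate < 0.12  # ~ nominal within Monte-Carlo error for 500 genes

    def test_downstream_dmr_effect_sign_recovered(self, small_genome):
        """Planted downstream (rel pos > 60) PHF-higher methylation raises PHF
        expression for nearly all genes at high n."""
        cfg = SimulationConfig(expression_effect=2.0, n_samples_per_group=30,
                               planted_dmr_count=0, expression_noise_sd=0.5, seed=22)
        genes = [
            fio.GeneModel(f"g{i}", g.interval, g.exons)
            for i, g in enumerate(small_genome.genes * 10)
        ]
        links = pd.DataFrame(
            {
                "gene_id": [g.gene_id for g in genes],
                "direction": "PHF_higher",
                "relative_position": 90.0,
            }
        )
        expr = simulate_expression(genes, links, cfg)
        mhf = [a for a in expr.columns if a.startswith("MHF")]
        phf = [a for a in expr.columns if a.startswith("PHF")]
        diff = expr[phf].mean(axis=1) - expr[mhf].mean(axis=1)
        assert (diff > 0).mean() >= 0.95

    def test_expression_deterministic_given_seed(self, small_genome):
        cfg = SimulationConfig(seed=3)
        links = pd.DataFrame(columns=["gene_id", "direction", "relative_position"])
        e1 = simulate_expression(small_genome.genes, links, cfg)
        e2 = simulate_expression(small_genome.genes, links, cfg)
        pd.testing.assert_frame_equal(e1, e2)
        assert (e1.values > 0).all()

    def test_dmr_gene_links_have_positions(self, small_config, small_genome):
        from methylcontext.synthetic_data import find_mre_sites_genome

        sites = find_mre_sites_genome(small_genome.sequences)
        state = make_methylation_state(small_genome, small_config, sites)
        links = link_dmrs_to_genes(state, small_genome.genes)
        assert links["relative_position"].between(0, 100).all()
        assert links["direction"].isin(["MHF_higher", "PHF_higher"]).all()
        assert links["gene_id"].is_unique
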
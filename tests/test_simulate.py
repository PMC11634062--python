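"""Synthetic-study generators: determinism, planted structure, knob behaviour."""

import numpy as np
import pandas as pd
import pytest

from pasnv import simulate as sim
from pasnv import windows as W
from pasnv.classify import build_records, count_awtaaa
from pasnv.io import write_genome
from pasnv.scoring import SurrogateScorer


class TestSimConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_genes": 0},
            {"utr_length": 150},
            {"pas_offset_range": (-120, -15)},
            {"pas_offset_range": (-30, -3)},
            {"sel_strength": 1.5},
            {"tsg_boost": -1.0},
            {"effect_fold": 0.0},
            {"cancer_type_weights": {"a": 0.5, "b": 0.6}},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(sim.ConfigurationError):
            sim.SimConfig(seed=0, **kwargs)


class TestMakeGenome:
    def test_fixed_seed_gives_identical_fasta_bytes(self, tmp_path):
        paths = []
        for run in range(2):
            genome, _, _ = sim.make_genome(sim.SimConfig(seed=1, n_genes=5))
            path = tmp_path / f"run{run}.fa"
            write_genome(genome, path)
            paths.append(path.read_bytes())
        assert paths[0] == paths[1]

    def test_planted_hexamer_is_unique_in_proximal_region(self):
        cfg = sim.SimConfig(seed=2, n_genes=30)
        genome, sites, _ = sim.make_genome(cfg)
        for row in sites.itertuples(index=False):
            site = W.CleavageSite(site_id=row.site_id, gene_id=row.gene_id,
                                  chrom=row.chrom, strand=row.strand,
                                  cs_pos=row.cs_pos)
            win = W.extract_window(genome, site)
            assert -30 <= row.pas_offset <= -15
            hexamer = win.sequence[row.pas_offset + 102 : row.pas_offset + 108]
            assert hexamer == row.pas_kind
            # exactly one AWTAAA start anywhere in [-40, -5]
            proximal = win.sequence[-40 + 102 : -5 + 102 + 6]
            assert count_awtaaa(proximal) == 1

    def test_one_contig_and_site_per_gene(self):
        genome, sites, roles = sim.make_genome(sim.SimConfig(seed=3, n_genes=7))
        assert len(genome) == 7
        assert len(sites) == 7
        assert sites["gene_id"].is_unique
        assert set(roles["role"]) <= {"TSG", "oncogene", "both", "non-census"}


class TestMakeNormalCohort:
    def test_forced_singletons_under_full_selection(self, surrogate):
        cfg = sim.SimConfig(seed=4, n_genes=40, sel_strength=1.0)
        genome, sites, _ = sim.make_genome(cfg)
        cohort = sim.make_normal_cohort(cfg, genome, sites, surrogate)
        records, _ = build_records(cohort, sites, genome, surrogate)
        down = records[records["category"] == "DOWN"]
        assert len(down) > 5
        assert (down["ac"] == 1).all()

    def test_allele_frequencies_in_unit_interval(self, small_sim):
        cohort = small_sim["normal"]
        assert (cohort["af"] > 0).all()
        assert (cohort["af"] <= 1).all()
        assert (cohort["ac"] >= 1).all()

    def test_determinism(self):
        cfg = sim.SimConfig(seed=5, n_genes=10)
        genome, sites, _ = sim.make_genome(cfg)
        a = sim.make_normal_cohort(cfg, genome, sites)
        b = sim.make_normal_cohort(cfg, genome, sites)
        pd.testing.assert_frame_equal(a, b)


class TestMakeCancerCohort:
    def test_sample_ids_within_generated_tumour_set(self, small_sim):
        cohort = small_sim["cancer"]
        tumours = set(sim.tumour_samples(small_sim["config"]))
        assert set(cohort["sample_id"]) <= tumours
        assert set(cohort["tumour_type"]) <= set(
            small_sim["config"].cancer_type_weights
        )

    def test_unboosted_down_fraction_matches_tsg_share(self, surrogate):
        """With tsg_boost=1 the TSG share of DOWN events is binomial-null."""
        cfg = sim.SimConfig(seed=6, n_genes=100, n_tumours=200, tsg_boost=1.0)
        genome, sites, roles = sim.make_genome(cfg)
        cohort = sim.make_cancer_cohort(cfg, genome, sites, roles, surrogate)
        records, _ = build_records(cohort, sites, genome, surrogate)
        down = records[records["category"] == "DOWN"]
        tsg = set(roles.loc[roles["role"] == "TSG", "gene_id"])
        k = int(down["gene_id"].isin(tsg).sum())
        from scipy import stats
        p_share = len(tsg) / cfg.n_genes
        assert stats.binomtest(k, len(down), p_share).pvalue > 0.01

    def test_boost_enriches_tsg_events(self, surrogate):
        from scipy import stats
        cfg = sim.SimConfig(seed=7, n_genes=120, n_tumours=300, tsg_boost=5.0,
                            mut_per_tumour=3.0)
        genome, sites, roles = sim.make_genome(cfg)
        cohort = sim.make_cancer_cohort(cfg, genome, sites, roles, surrogate)
        records, _ = build_records(cohort, sites, genome, surrogate)
        tsg = set(roles.loc[roles["role"] == "TSG", "gene_id"])
        down = records[records["category"] == "DOWN"]
        bg = records[records["category"] == "BG"]
        table = [
            [int(down["gene_id"].isin(tsg).sum()), int((~down["gene_id"].isin(tsg)).sum())],
            [int(bg["gene_id"].isin(tsg).sum()), int((~bg["gene_id"].isin(tsg)).sum())],
        ]
        odds, p = stats.fisher_exact(table)
        assert odds > 1
        assert p < 0.01


class TestMakeExpression:
    def _run(self, effect_fold, seed=8, n_genes=200):
        cfg = sim.SimConfig(seed=seed, n_genes=n_genes, n_tumours=10,
                            effect_fold=effect_fold, cnv_state_probs={2: 1.0},
                            tsg_fraction=1.0, oncogene_fraction=0.0,
                            both_fraction=0.0)
        genes = [f"G{i:04d}" for i in range(n_genes)]
        roles = pd.DataFrame({"gene_id": genes, "role": "TSG", "hallmark": False})
        samples = sim.tumour_samples(cfg)
        down = pd.DataFrame({"gene_id": genes, "sample_id": samples[0]})
        expr = sim.make_expression(cfg, roles, samples, down)
        nf = expr.nfpkm
        deltas = np.log2(nf[samples[0]]) - np.log2(nf[samples[1:]].median(axis=1))
        return float(np.median(deltas)), expr

    def test_null_effect_centred_at_zero(self):
        median, expr = self._run(effect_fold=1.0)
        assert abs(median) < 0.05
        assert (expr.fpkm.to_numpy() >= 0).all()

    def test_twofold_knockdown_recovered(self):
        median, _ = self._run(effect_fold=2.0)
        assert median == pytest.approx(-1.0, abs=0.15)

    def test_cn_scaling_before_knockdown(self):
        cfg = sim.SimConfig(seed=9, n_genes=50, n_tumours=6,
                            cnv_state_probs={4: 1.0})
        genes = [f"G{i:04d}" for i in range(50)]
        roles = pd.DataFrame({"gene_id": genes, "role": "TSG", "hallmark": False})
        expr = sim.make_expression(cfg, roles, sim.tumour_samples(cfg),
                                   pd.DataFrame({"gene_id": [], "sample_id": []}))
        # all CN=4: nFPKM halves the FPKM
        assert np.allclose(expr.nfpkm.to_numpy(), expr.fpkm.to_numpy() / 2)


class TestMakeAuxTables:
    def _tables(self, cooccur_boost=1.0, seed=10, down=None):
        cfg = sim.SimConfig(seed=seed, n_genes=40, n_tumours=50,
                            cooccur_boost=cooccur_boost)
        genome, sites, roles = sim.make_genome(cfg)
        samples = sim.tumour_samples(cfg)
        if down is None:
            down = pd.DataFrame({"gene_id": [], "sample_id": []})
        return cfg, roles, sites, sim.make_aux_tables(cfg, roles, samples, down, sites)

    def test_conservation_bounded_and_peaked_at_hexamer(self):
        cfg, roles, sites, (dmg, burden, cons, cnv) = self._tables()
        assert cons["score"].between(0, 1).all()
        track = {(c, p): s for c, p, s in zip(cons["chrom"], cons["pos"], cons["score"])}
        row = sites.iloc[0]
        L = cfg.utr_length
        cs_sense = row.cs_pos if row.strand == "+" else L - row.cs_pos + 1
        sense_hex = cs_sense + row.pas_offset
        pos = sense_hex if row.strand == "+" else L - sense_hex + 1
        assert track[(row.chrom, pos)] > 0.7

    def test_burden_expected_positive(self):
        _, _, _, (dmg, burden, cons, cnv) = self._tables()
        assert (burden["expected"] > 0).all()
        assert (burden["observed"] >= 0).all()

    def test_null_inflation_gives_unit_excess_ratio(self):
        from pasnv.enrichment import excess_ratio
        cfg = sim.SimConfig(seed=11, n_genes=400, n_tumours=5)
        genome, sites, roles = sim.make_genome(cfg)
        _, burden, _, _ = sim.make_aux_tables(
            cfg, roles, sim.tumour_samples(cfg),
            pd.DataFrame({"gene_id": [], "sample_id": []}), sites,
        )
        from pasnv.enrichment import MUTATION_CLASSES
        ratios = [
            excess_ratio(burden, roles, "TSG", mclass)
            for mclass in MUTATION_CLASSES
        ]
        # each class ratio fluctuates with sd ~0.04 at this size
        assert all(abs(r - 1.0) < 0.15 for r in ratios)
        assert abs(np.mean(ratios) - 1.0) < 0.05

    def test_cooccur_boost_raises_damaging_rate_in_down_pairs(self):
        down = pd.DataFrame(
            {"gene_id": [f"G{i:04d}" for i in range(20)],
             "sample_id": [f"T{i:04d}" for i in range(20)]}
        )
        _, _, _, (dmg_null, *_rest) = self._tables(cooccur_boost=1.0, down=down)
        _, _, _, (dmg_boost, *_rest2) = self._tables(cooccur_boost=6.0, down=down)
        rate_null = np.mean([dmg_null.loc[g, s] for g, s in zip(down.gene_id, down.sample_id)])
        rate_boost = np.mean([dmg_boost.loc[g, s] for g, s in zip(down.gene_id, down.sample_id)])
        assert rate_boost > rate_null

    def test_determinism_across_calls(self):
        _, _, _, tables_a = self._tables(seed=12)
        _, _, _, tables_b = self._tables(seed=12)
        for a, b in zip(tables_a, tables_b):
            pd.testing.assert_frame_equal(a, b)
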
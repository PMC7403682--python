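"""Generator tests: crossing design, incompatibilities, traits, field fitness."""

import collections

import numpy as np
import pandas as pd
import pytest

from ecotensor.synthdata import (SimConfig, _mendel, simulate_cross_fertility,
                                 simulate_field_fitness, simulate_pedigree,
                                 simulate_traits)
from tests.conftest import small_sim_config


class TestPedigree:
    def test_f1_cross_types_all_ordered_pairs(self, small_pedigree):
        """Reciprocal crosses among 4 ecotypes give 12 distinct F1 types."""
        f1 = {r.cross_type for r in small_pedigree if r.generation == "F1"}
        assert len(f1) == 12

    def test_f2_cross_combinations(self, small_pedigree):
        """Disjoint-pair F1 matings give 24 ordered F2 combinations."""
        f2 = {r.cross_type for r in small_pedigree if r.generation == "F2"}
        assert len(f2) == 24

    def test_f2_carries_all_four_grandparental_ecotypes(self, small_pedigree, small_config):
        for r in small_pedigree:
            if r.generation == "F2":
                assert tuple(sorted(r.grandparental_ecotypes)) == \
                    tuple(sorted(small_config.ecotype_labels))

    def test_pedigree_closure_and_generation_order(self, small_pedigree):
        """Every non-founder's parents exist and come from the previous generation."""
        order = {g: i for i, g in enumerate(("P", "F1", "F2", "F3", "F4"))}
        by_id = {r.id: r for r in small_pedigree}
        for r in small_pedigree:
            if r.generation == "P":
                assert r.dam_id is None
                continue
            dam, sire = by_id[r.dam_id], by_id[r.sire_id]
            assert order[dam.generation] < order[r.generation]
            assert order[sire.generation] < order[r.generation]

    def test_f2_lines_partition(self, small_pedigree, small_config):
        lines = collections.Counter(r.line_id for r in small_pedigree
                                    if r.generation == "F2")
        assert len(lines) == small_config.f2_lines
        assert max(lines.values()) - min(lines.values()) <= 1

    def test_f4_paired_sire_design(self, small_pedigree):
        """Each F4 sire appears with at most two dams (full-sib/half-sib pairs)."""
        sires = collections.defaultdict(set)
        for r in small_pedigree:
            if r.generation == "F4":
                sires[r.sire_id].add(r.dam_id)
        assert sires and max(len(d) for d in sires.values()) <= 2

    def test_reproducible(self, small_config):
        a = simulate_pedigree(small_config)
        b = simulate_pedigree(small_config)
        assert [r.id for r in a] == [r.id for r in b]
        assert all(np.array_equal(x.genotype, y.genotype) for x, y in zip(a, b))

    def test_config_errors(self):
        with pytest.raises(ValueError, match="4 ecotype"):
            SimConfig(ecotype_labels=("a", "b", "c"),
                      trait_means=np.zeros((4, 7)))
        with pytest.raises(ValueError, match="parents per ecotype"):
            small_sim_config(n_parents_per_ecotype=1)
        with pytest.raises(ValueError, match="families requested"):
            simulate_pedigree(small_sim_config(n_parents_per_ecotype=3,
                                               f1_families_per_cross=(5, 5)))

    def test_mendelian_transmission(self, rng):
        """Het x het transmission gives dosages 0/1/2 at 1/4, 1/2, 1/4."""
        n = 20000
        dos = _mendel(rng, np.ones(n), np.ones(n))
        freq = np.bincount(dos, minlength=3) / n
        assert np.allclose(freq, [0.25, 0.5, 0.25], atol=4 * 0.5 / np.sqrt(n))


class TestCrossFertility:
    def test_no_penalty_equal_seed_means(self):
        cfg = small_sim_config(incompatibility_penalties=(0.0, 0.0))
        ped = simulate_pedigree(cfg)
        crosses = simulate_cross_fertility(ped, cfg)
        df = pd.DataFrame([(c.generation, c.n_seeds) for c in crosses],
                          columns=["g", "n"])
        means = df.groupby("g")["n"].mean()
        se = np.sqrt(cfg.baseline_seed_mean / df.groupby("g").size().min())
        assert np.ptp(means.to_numpy()) < 6 * se

    def test_f2_crash_ratio(self):
        """Default het x het penalty yields the configured 49% F2 seed-set drop."""
        cfg = small_sim_config(f1_families_per_cross=(20, 20),
                               f2_families_per_cross=(25, 25),
                               n_parents_per_ecotype=25)
        ped = simulate_pedigree(cfg)
        df = pd.DataFrame([(c.generation, c.n_seeds)
                           for c in simulate_cross_fertility(ped, cfg)],
                          columns=["g", "n"])
        assert (df.g == "F2").sum() >= 500
        ratio = df[df.g == "F2"].n.mean() / df[df.g == "F1"].n.mean()
        assert ratio == pytest.approx(0.51, abs=0.03)

    def test_total_incompatibility_zeroes_f2(self):
        cfg = small_sim_config(incompatibility_penalties=(1.0, 1.0))
        ped = simulate_pedigree(cfg)
        f2 = [c for c in simulate_cross_fertility(ped, cfg) if c.generation == "F2"]
        assert f2 and all(c.n_seeds == 0 and c.success == 0 for c in f2)

    def test_success_consistent_with_seed_count(self, small_pedigree, small_config):
        for c in simulate_cross_fertility(small_pedigree, small_config):
            assert (c.success == 1) == (c.n_seeds >= 2)


class TestTraits:
    def test_f4_mean_is_midparent_under_additivity(self, small_config):
        cfg = small_sim_config(n_f4_families=150, trait_reps_per_family=4)
        ped = simulate_pedigree(cfg)
        df, means = simulate_traits(ped, cfg)
        cols = list(cfg.trait_names)
        f4_mean = df.loc[df.generation == "F4", cols].mean().to_numpy()
        assert np.allclose(f4_mean, means.mean(axis=0), atol=0.12)

    def test_no_divergence_gives_null_d(self):
        """Identical ecotype means: downstream D is near zero."""
        from ecotensor.phenodiv import (TraitMatrix, compute_d_matrix,
                                        effective_family_size, manova_sscp)
        cfg = small_sim_config(trait_means=np.zeros((4, 7)), family_var=0.0,
                               n_parents_per_ecotype=40, trait_reps_per_family=3)
        ped = simulate_pedigree(cfg)
        ds = []
        for seed in range(10):
            cfg2 = small_sim_config(trait_means=np.zeros((4, 7)), family_var=0.0,
                                    n_parents_per_ecotype=40,
                                    trait_reps_per_family=3, rng_seed=seed)
            df, _ = simulate_traits(ped, cfg2, generations=("P",))
            tm = TraitMatrix.from_frame(df, list(cfg.trait_names))
            dec = manova_sscp(tm)
            nf = effective_family_size(dec.group_sizes.values())
            ds.append(compute_d_matrix(dec, nf).d)
        assert np.abs(np.mean(ds, axis=0)).max() < 0.05

    def test_between_ecotype_cov_is_d_estimand(self):
        """Mean D over replicates recovers the configured B matrix."""
        from ecotensor.phenodiv import (TraitMatrix, compute_d_matrix,
                                        effective_family_size, manova_sscp)
        rng = np.random.default_rng(7)
        A = rng.normal(size=(7, 7)) * 0.3
        B = A @ A.T + np.diag(np.linspace(0.2, 0.8, 7))
        ds = []
        for seed in range(40):
            cfg = small_sim_config(between_ecotype_cov=B, family_var=0.01,
                                   residual_var=0.2, n_parents_per_ecotype=25,
                                   trait_means=np.zeros((4, 7)),
                                   trait_reps_per_family=2, rng_seed=seed)
            ped = simulate_pedigree(cfg)
            df, _ = simulate_traits(ped, cfg, generations=("P",))
            tm = TraitMatrix.from_frame(df, list(cfg.trait_names))
            dec = manova_sscp(tm)
            nf = effective_family_size(dec.group_sizes.values())
            ds.append(compute_d_matrix(dec, nf).d)
        dbar = np.mean(ds, axis=0)
        # B-elements are sampled with ~B*sqrt(2/3)/sqrt(40) MC error
        scale = np.abs(B).max()
        assert np.abs(dbar - B).max() < 0.25 * scale

    def test_bad_trait_means_shape(self):
        with pytest.raises(ValueError, match="trait_means"):
            small_sim_config(trait_means=np.zeros((3, 7)))


class TestFieldFitness:
    def test_null_config_establishment_half(self):
        cfg = small_sim_config(
            habitat_intercepts=np.zeros(4), native_advantage=np.zeros(4),
            heterosis_f1=0.0, heterosis_f4=0.0, family_var_fitness=0.0,
            block_var=0.0,
            genotype_cov_by_generation={g: np.zeros((4, 4)) for g in ("P", "F1", "F4")},
            p_field_families_per_ecotype=10, seeds_per_family_habitat={"P": 20, "F1": 20, "F4": 20})
        ped = simulate_pedigree(cfg)
        fd = simulate_field_fitness(ped, cfg)
        p = fd.df.establishment.mean()
        assert p == pytest.approx(0.5, abs=3 * 0.5 / np.sqrt(len(fd.df)))

    def test_monotone_outcomes(self, small_pedigree, small_config):
        fd = simulate_field_fitness(small_pedigree, small_config)
        assert (fd.df.establishment <= fd.df.emergence).all()
        assert (fd.df.maturity <= fd.df.establishment).all()

    def test_genotype_cov_realized(self):
        """Sample covariance of the generator's own latent draws matches config."""
        cfg = small_sim_config(n_f4_families=250, n_f3_families=510,
                               f2_families_per_cross=(6, 7),
                               f4_adaptation_coupling=0.0)
        ped = simulate_pedigree(cfg)
        fd = simulate_field_fitness(ped, cfg)
        eff = np.array(list(fd.truth["latent_genotype_effects"]["F4"].values()))
        assert len(eff) >= 200
        V = np.cov(eff, rowvar=False)
        truth = cfg.genotype_cov_by_generation["F4"]
        tol = 4 * np.abs(truth).max() / np.sqrt(len(eff))
        assert np.abs(V - truth).max() < max(tol, 0.2)

    def test_native_advantage_visible(self):
        cfg = small_sim_config(
            native_advantage=np.array([1.5, 1.5, 1.5, 1.5]),
            genotype_cov_by_generation={g: 0.01 * np.eye(4) for g in ("P", "F1", "F4")},
            family_var_fitness=0.01,
            p_field_families_per_ecotype=10,
            seeds_per_family_habitat={"P": 30, "F1": 4, "F4": 4})
        ped = simulate_pedigree(cfg)
        df = simulate_field_fitness(ped, cfg).df
        p = df[df.generation == "P"]
        for h in cfg.ecotype_labels:
            sub = p[p.habitat == h]
            native = sub[sub.cross_type == h].establishment.mean()
            foreign = sub[sub.cross_type != h].establishment.mean()
            assert native > foreign

    def test_reproducible(self, small_pedigree, small_config):
        a = simulate_field_fitness(small_pedigree, small_config).df
        b = simulate_field_fitness(small_pedigree, small_config).df
        pd.testing.assert_frame_equal(a, b)

    def test_non_psd_cov_rejected(self):
        bad = np.eye(4)
        bad[0, 1] = bad[1, 0] = 2.0
        with pytest.raises(ValueError, match="not PSD"):
            small_sim_config(genotype_cov_by_generation={
                "P": bad, "F1": np.eye(4), "F4": np.eye(4)})
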
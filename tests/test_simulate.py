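"""Coalescent and mutation engine checks against closed-form expectations."""

import math

import numpy as np
import pytest

from hybridscan.simulate import (
    ContinuousMigration,
    HybridSpec,
    MigrationPulse,
    ModelError,
    SimulationConfig,
    SpeciesJoin,
    SpeciesTreeModel,
    make_f1_hybrid,
    mutate_alignment,
    simulate_dataset,
    simulate_gene_tree,
    three_species_model,
    two_species_model,
)


def one_species_model(n: float) -> SpeciesTreeModel:
    return SpeciesTreeModel(species=["A"], pop_sizes={"A": n}, joins=[])


class TestModelValidation:
    def test_nonpositive_pop_size_rejected(self):
        with pytest.raises(ModelError, match="pop_sizes"):
            SpeciesTreeModel(species=["A"], pop_sizes={"A": 0.0}, joins=[])

    def test_divergence_times_must_increase_rootward(self):
        with pytest.raises(ModelError, match="strictly increasing"):
            SpeciesTreeModel(
                species=["A", "B", "C"],
                pop_sizes={k: 100.0 for k in ("A", "B", "C", "AB", "ABC")},
                joins=[
                    SpeciesJoin(100.0, ("A", "B"), "AB"),
                    SpeciesJoin(50.0, ("AB", "C"), "ABC"),
                ],
            )

    def test_self_migration_rejected(self):
        with pytest.raises(ModelError, match="differ"):
            two_species_model(
                1000, migration=[MigrationPulse("A", "A", 0.1, 10.0)]
            )

    def test_migration_rate_bounds(self):
        with pytest.raises(ModelError, match=r"\[0, 1\)"):
            two_species_model(
                1000, migration=[MigrationPulse("A", "B", 1.0, 10.0)]
            )

    def test_hybrid_with_itself_rejected(self):
        with pytest.raises(ModelError, match="distinct"):
            HybridSpec("h", "A", "A")


class TestCoalescentExpectations:
    def test_pairwise_tmrca_matches_kingman_expectation(self):
        """For 2 haplotypes in a diploid population of size N the expected
        coalescence time is 2N generations."""
        n = 1000.0
        model = one_species_model(n)
        reps = 2500
        times = [
            simulate_gene_tree(model, {"x": "A", "y": "A"}, seed=i + 1, ploidy=1).tmrca()
            for i in range(reps)
        ]
        mean = float(np.mean(times))
        se = float(np.std(times, ddof=1) / math.sqrt(reps))
        assert abs(mean - 2 * n) < 3 * se

    def test_cross_species_coalescence_older_than_divergence(self):
        model = two_species_model(1_000_000, n=100.0)
        for seed in range(1, 30):
            g = simulate_gene_tree(model, {"a": "A", "b": "B"}, seed=seed, ploidy=1)
            assert g.tmrca() > 1_000_000

    @pytest.mark.parametrize("ratio", [0.5, 1.5, 3.0])
    def test_ils_discordance_matches_closed_form(self, ratio):
        """Probability that a 3-taxon gene tree contradicts the species tree
        is (2/3) exp(-T / 2N) for an internal branch of T generations."""
        n = 10_000.0
        t1 = 20_000.0
        t2 = t1 + ratio * 2 * n
        model = three_species_model(t1, t2, t2 + 200_000, n=n)
        reps = 800
        discord = 0
        for seed in range(1, reps + 1):
            g = simulate_gene_tree(
                model, {"a": "P1", "b": "P2", "c": "P3"}, seed=seed, ploidy=1
            )
            tree = g.ts.first()
            t_ab = tree.tmrca(0, 1)
            t_ac = tree.tmrca(0, 2)
            if t_ab >= t_ac:
                discord += 1
        p_hat = discord / reps
        p_exp = (2.0 / 3.0) * math.exp(-ratio)
        se = math.sqrt(p_exp * (1 - p_exp) / reps)
        assert abs(p_hat - p_exp) < 3 * se


class TestMutations:
    def test_zero_rate_leaves_sequences_identical(self):
        model = two_species_model(50_000, n=100.0)
        g = simulate_gene_tree(model, {"a": "A", "b": "B"}, seed=3)
        with pytest.raises(ModelError):
            SimulationConfig(
                species_model=model, n_specimens_per_species=1, n_loci=1,
                locus_length=100, mutation_rate=0.0,
            )
        aln = mutate_alignment(g, length=200, mu=1e-30, seed=5)
        seqs = list(aln.sequences.values())
        assert all(s == seqs[0] for s in seqs)

    def test_single_column_alignment(self):
        model = one_species_model(100.0)
        g = simulate_gene_tree(model, {"a": "A"}, seed=9)
        aln = mutate_alignment(g, length=1, mu=1e-9, seed=2)
        assert all(len(s) == 1 for s in aln.sequences.values())

    def test_hamming_distance_matches_jukes_cantor_closed_form(self):
        """Mean pairwise difference between two deeply split haploid tips
        follows p = (3/4)(1 - e^{-8 mu t / 3}) with t the split time (the
        within-species coalescent contribution is negligible at N=10)."""
        t_split, n, mu, length = 50_000.0, 10.0, 2e-6, 500
        model = two_species_model(t_split, n=n)
        reps = 600
        diffs = []
        for seed in range(1, reps + 1):
            g = simulate_gene_tree(model, {"a": "A", "b": "B"}, seed=seed, ploidy=1)
            t = g.tmrca()
            aln = mutate_alignment(g, length=length, mu=mu, seed=seed + 10_000)
            s1, s2 = aln.sequences.values()
            diffs.append((sum(c1 != c2 for c1, c2 in zip(s1, s2)), t))
        observed = float(np.mean([d for d, _ in diffs]))
        # average the per-genealogy JC expectation over the realised TMRCAs
        expected = float(
            np.mean(
                [0.75 * (1 - math.exp(-8 * mu * t / 3)) * length for _, t in diffs]
            )
        )
        se = float(np.std([d for d, _ in diffs], ddof=1) / math.sqrt(reps))
        assert abs(observed - expected) < 3 * se

    def test_saturation_guard_flags_fast_loci(self):
        model = two_species_model(1_000_000, n=1000.0)
        g = simulate_gene_tree(model, {"a": "A", "b": "B"}, seed=4)
        hot = mutate_alignment(g, length=100, mu=1e-3, seed=6)
        cold = mutate_alignment(g, length=100, mu=1e-9, seed=6)
        assert hot.saturated and not cold.saturated


class TestSimulateDataset:
    def test_same_seed_gives_byte_identical_alignments(self):
        model = three_species_model()
        cfg = SimulationConfig(
            species_model=model, n_specimens_per_species=2, n_loci=5,
            locus_length=300, mutation_rate=3e-8, outgroup="OUT", seed=11,
        )
        d1, d2 = simulate_dataset(cfg), simulate_dataset(cfg)
        for a1, a2 in zip(d1.alignments, d2.alignments):
            assert a1.sequences == a2.sequences

    def test_locus_and_haplotype_counts(self):
        """A 638-locus, 3 species x 5 specimen design yields 638 alignments of
        30 haplotypes each."""
        model = SpeciesTreeModel(
            species=["A", "B", "C"],
            pop_sizes={k: 10_000.0 for k in ("A", "B", "C", "AB", "R")},
            joins=[
                SpeciesJoin(50_000, ("A", "B"), "AB"),
                SpeciesJoin(100_000, ("AB", "C"), "R"),
            ],
        )
        cfg = SimulationConfig(
            species_model=model, n_specimens_per_species=5, n_loci=638,
            locus_length=20, mutation_rate=3e-8, seed=5,
        )
        ds = simulate_dataset(cfg)
        assert len(ds.alignments) == 638
        assert all(len(a.sequences) == 30 for a in ds.alignments)

    def test_within_species_diversity_matches_theta(self, ):
        """Mean pairwise diversity within a panmictic species approaches
        4 N mu per site."""
        n, mu, length = 10_000.0, 3e-8, 1000
        cfg = SimulationConfig(
            species_model=one_species_model(n),
            n_specimens_per_species=4, n_loci=500, locus_length=length,
            mutation_rate=mu, seed=77,
        )
        ds = simulate_dataset(cfg)
        per_locus = []
        for g in ds.loci:
            div = g.ts.diversity(mode="site")  # mean pairwise per site
            per_locus.append(float(div))
        mean = float(np.mean(per_locus))
        se = float(np.std(per_locus, ddof=1) / math.sqrt(len(per_locus)))
        assert abs(mean - 4 * n * mu) < 3 * se

    def test_missing_prob_masks_whole_specimen_loci(self):
        cfg = SimulationConfig(
            species_model=one_species_model(1000.0),
            n_specimens_per_species=3, n_loci=40, locus_length=100,
            mutation_rate=1e-7, seed=3, missing_prob=0.3,
        )
        ds = simulate_dataset(cfg)
        assert 0 < ds.missing_mask.sum() < ds.missing_mask.size
        aln0 = ds.alignments[0]
        for si, s in enumerate(ds.specimens):
            present = f"{s.specimen}_h0" in aln0.sequences
            assert present == (not ds.missing_mask[si, 0])


@pytest.fixture(scope="module")
def base():
    model = three_species_model(150_000, 300_000, 600_000)
    cfg = SimulationConfig(
        species_model=model,
        n_specimens_per_species={"P1": 3, "P2": 3, "P3": 2, "OUT": 1},
        n_loci=40, locus_length=500, mutation_rate=3e-8,
        outgroup="OUT", seed=13, pool_reserve_per_species=2,
    )
    return simulate_dataset(cfg)


class TestF1Hybrid:

    def test_f1_of_species_with_itself_rejected(self, base):
        with pytest.raises(ModelError, match="distinct"):
            make_f1_hybrid(base, "P1", "P1", "bad")

    def test_f1_does_not_alter_existing_specimens(self, base):
        before = {
            (a.locus, name): seq
            for a in base.alignments
            for name, seq in a.sequences.items()
        }
        ds2 = make_f1_hybrid(base, "P1", "P2", "hybX")
        for a in ds2.alignments:
            for name, seq in a.sequences.items():
                if not name.startswith("hybX"):
                    assert before[(a.locus, name)] == seq

    def test_f1_heterozygosity_exceeds_parental_means(self):
        """Every site fixed for different alleles in the parents is
        heterozygous in the F1, so across replicate datasets the hybrid's
        H_obs exceeds the parental specimen means."""
        from hybridscan.heterozygosity import observed_heterozygosity

        model = three_species_model(150_000, 300_000, 600_000)
        wins = 0
        reps = 20
        for rep in range(reps):
            cfg = SimulationConfig(
                species_model=model,
                n_specimens_per_species={"P1": 3, "P2": 3, "P3": 2, "OUT": 1},
                n_loci=30, locus_length=500, mutation_rate=3e-8,
                hybrids=[HybridSpec("hyb", "P1", "P2")],
                outgroup="OUT", seed=1000 + rep,
            )
            ds = simulate_dataset(cfg)
            gm = ds.genotype_matrix()
            h_hyb = observed_heterozygosity(gm, "hyb").h_obs
            h_parents = [
                observed_heterozygosity(gm, s.specimen).h_obs
                for s in ds.specimens
                if s.species in ("P1", "P2") and not s.is_hybrid
            ]
            if h_hyb > max(h_parents):
                wins += 1
        assert wins == reps

    def test_haplotype_count_conservation(self, base):
        for aln in base.alignments:
            for s in base.specimens:
                assert f"{s.specimen}_h0" in aln.sequences
                assert f"{s.specimen}_h1" in aln.sequences

    def test_reserves_deplete_and_error(self, base):
        ds = base
        ds = make_f1_hybrid(ds, "P1", "P2", "h1")
        ds = make_f1_hybrid(ds, "P1", "P2", "h2")
        with pytest.raises(ModelError, match="reserve"):
            make_f1_hybrid(ds, "P1", "P2", "h3")


class TestMigrationPlumbing:
    def test_continuous_migration_window_accepted(self):
        model = two_species_model(
            100_000,
            n=1000.0,
            migration=[ContinuousMigration("A", "B", 1e-4, 0.0, 50_000.0)],
        )
        g = simulate_gene_tree(model, {"a": "A", "b": "B"}, seed=2, ploidy=1)
        assert g.tmrca() > 0
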
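"""Structured-coalescent generator: closed-form oracles and contracts."""

import numpy as np
import pytest

from oligogeo.popgen import amova_structure
from oligogeo.simulate import (
    DisconnectedHistoryError,
    Genealogy,
    ScenarioConfig,
    barrier_scenario,
    drop_mutations,
    generate_dataset,
    panmictic_scenario,
    sample_reads,
    simulate_genealogy,
    simulate_otu,
)


def single_deme_config(n_lineages, theta=1.0, depth=5, L=50):
    return ScenarioConfig(
        deme_labels=("A",),
        provinces=("P",),
        latitudes=(-50.0,),
        longitudes=(0.0,),
        sample_depths=(depth,),
        n_lineages_per_deme=n_lineages,
        theta=theta,
        seq_length=L,
        error_rate=0.0,
    )


class TestGenealogy:
    def test_pairwise_tmrca_matches_exponential_expectation(self, rng):
        """Two lineages, one deme: E[TMRCA] = theta/2 (rate 2/theta)."""
        cfg = single_deme_config(2, theta=1.0)
        times = [simulate_genealogy(cfg, rng).time.max() for _ in range(2000)]
        mean = np.mean(times)
        se = np.std(times, ddof=1) / np.sqrt(len(times))
        assert abs(mean - 0.5) < 3 * se

    def test_single_lineage_is_a_tip(self, rng):
        cfg = single_deme_config(1, depth=1)
        g = simulate_genealogy(cfg, rng)
        assert g.n_tips == 1 and len(g.parent) == 1 and g.parent[0] == -1

    def test_empty_second_deme_matches_single_deme(self, rng):
        """Zero migration with lineages in one deme only still terminates and
        has the single-deme TMRCA distribution (symmetry)."""
        cfg = ScenarioConfig(
            deme_labels=("A", "B"),
            provinces=("P", "P"),
            latitudes=(-50.0, -51.0),
            longitudes=(0.0, 1.0),
            sample_depths=(2, 1),
            n_lineages_per_deme=(2, 0),
            theta=1.0,
            seq_length=20,
            error_rate=0.0,
        )
        times = [simulate_genealogy(cfg, rng).time.max() for _ in range(800)]
        mean = np.mean(times)
        se = np.std(times, ddof=1) / np.sqrt(len(times))
        assert abs(mean - 0.5) < 3 * se

    def test_disconnected_history_raises(self, rng):
        cfg = ScenarioConfig(
            deme_labels=("A", "B"),
            provinces=("P", "P"),
            latitudes=(-50.0, -51.0),
            longitudes=(0.0, 1.0),
            sample_depths=(2, 2),
            n_lineages_per_deme=2,
            theta=1.0,
            seq_length=20,
            error_rate=0.0,
        )
        with pytest.raises(DisconnectedHistoryError):
            simulate_genealogy(cfg, rng)

    def test_barrier_with_split_time_terminates(self, rng):
        cfg = barrier_scenario(sample_depths=(5, 5, 5, 5), n_lineages_per_deme=4)
        g = simulate_genealogy(cfg, rng)
        assert g.n_tips == 16
        # the vicariant merge happens at the split time, so the cross-group
        # ancestor is older than it
        assert g.time.max() >= cfg.split_time

    def test_ultrametric_and_ordered(self, rng):
        cfg = barrier_scenario(sample_depths=(5, 5, 5, 5), n_lineages_per_deme=5)
        g = simulate_genealogy(cfg, rng)
        assert (g.time[: g.n_tips] == 0).all()
        internal = g.parent >= 0
        assert (g.time[g.parent[internal]] > g.time[internal]).all() or (
            g.time[g.parent[internal]] >= g.time[internal]
        ).all()
        assert (g.branch_lengths()[g.parent >= 0] >= 0).all()


class TestMutations:
    def test_zero_theta_single_haplotype(self, rng):
        cfg = single_deme_config(8)
        g = simulate_genealogy(cfg, rng)
        truth = drop_mutations(g, 0.0, 50, rng, ("A",))
        assert len(truth.haplotypes) == 1
        assert truth.lineage_counts.sum() == 8

    def test_negative_theta_rejected(self, rng):
        cfg = single_deme_config(2)
        g = simulate_genealogy(cfg, rng)
        with pytest.raises(ValueError):
            drop_mutations(g, -1.0, 50, rng)

    def test_mean_pairwise_difference_matches_coalescent_expectation(self, rng):
        """Single deme, theta=2: E[pi] = theta^2/2 = 2 under this scaling
        (coalescence rate n(n-1)/theta, mutation rate theta/2)."""
        theta, L = 2.0, 370
        cfg = single_deme_config(6, theta=theta, L=L)
        pis = []
        for _ in range(500):
            g = simulate_genealogy(cfg, rng)
            truth = drop_mutations(g, theta, L, rng, ("A",))
            seqs = truth.sequences
            counts = truth.lineage_counts[:, 0]
            n = counts.sum()
            tot = 0.0
            for i in range(len(seqs)):
                for j in range(i + 1, len(seqs)):
                    d = sum(a != b for a, b in zip(seqs[i], seqs[j]))
                    tot += counts[i] * counts[j] * d
                tot += 0.0
            pis.append(tot / (n * (n - 1) / 2))
        mean = np.mean(pis)
        se = np.std(pis, ddof=1) / np.sqrt(len(pis))
        assert abs(mean - theta**2 / 2) < 3 * se

    def test_two_tip_differences_are_poisson(self, rng):
        """Two tips joined at depth t: #differences ~ Poisson(theta * t)
        (up to a tiny finite-sites recurrence deficit)."""
        theta, t, L = 2.0, 1.5, 370
        parent = np.array([2, 2, -1])
        time = np.array([0.0, 0.0, t])
        g = Genealogy(parent, time, np.array([0, 0]), 2)
        diffs = []
        for _ in range(1000):
            truth = drop_mutations(g, theta, L, rng, ("A",))
            seqs = truth.sequences
            if len(seqs) == 1:
                diffs.append(0)
            else:
                c = truth.lineage_counts[:, 0]
                diffs.append(sum(a != b for a, b in zip(seqs[0], seqs[1])))
        mean = np.mean(diffs)
        var = np.var(diffs, ddof=1)
        se = np.sqrt(var / len(diffs))
        assert abs(mean - theta * t) < 3 * se + 0.05  # 0.05 recurrence slack
        # Poisson: variance approximately equals the mean
        assert 0.8 * mean < var < 1.25 * mean


class TestReads:
    def test_error_free_reads_are_truth_haplotypes(self, rng):
        cfg = single_deme_config(10, theta=2.0, depth=200, L=100)
        truth, sample = simulate_otu(cfg, rng)
        assert set(sample.sequences) <= set(truth.sequences)
        assert len(sample.sequences) == 200

    def test_error_fraction_matches_binomial_closed_form(self, rng):
        """error 0.1%, L=370: P(read has >= 1 error) = 1-(1-e)^370 ~ 0.31."""
        L, e, depth = 370, 0.001, 10000
        cfg = ScenarioConfig(
            deme_labels=("A",),
            provinces=("P",),
            latitudes=(-50.0,),
            longitudes=(0.0,),
            sample_depths=(depth,),
            n_lineages_per_deme=2,
            theta=0.0,
            seq_length=L,
            error_rate=e,
        )
        g = simulate_genealogy(cfg, rng)
        truth = drop_mutations(g, 0.0, L, rng, ("A",))
        sample = sample_reads(truth, cfg, rng)
        true_seq = truth.sequences[0]
        frac = np.mean([s != true_seq for s in sample.sequences])
        expect = 1 - (1 - e) ** L
        se = np.sqrt(expect * (1 - expect) / depth)
        assert abs(frac - expect) < 3 * se

    def test_depth_one_gives_one_read(self, rng):
        cfg = single_deme_config(3, depth=1)
        truth, sample = simulate_otu(cfg, rng)
        assert len(sample.sequences) == 1

    def test_conservation_of_depths(self, rng):
        cfg = barrier_scenario(sample_depths=(31, 15, 10, 14), n_lineages_per_deme=5)
        truth, sample = simulate_otu(cfg, rng)
        from collections import Counter

        by_site = Counter(sample.samples)
        assert by_site == {"KGI": 31, "PAT1": 15, "PAT2": 10, "KER": 14}
        assert len(sample.sequences) == 31 + 15 + 10 + 14

    def test_bad_error_rate_rejected(self):
        with pytest.raises(ValueError):
            ScenarioConfig(
                deme_labels=("A",),
                provinces=("P",),
                latitudes=(0.0,),
                longitudes=(0.0,),
                sample_depths=(1,),
                n_lineages_per_deme=1,
                error_rate=1.5,
            )


class TestDataset:
    def test_same_seed_byte_identical(self, tmp_path):
        cfg = barrier_scenario(
            sample_depths=(20, 10, 10, 10), n_lineages_per_deme=5, seed=7
        )
        p1 = generate_dataset(cfg, tmp_path / "a")
        p2 = generate_dataset(cfg, tmp_path / "b")
        for key in p1:
            assert p1[key].read_bytes() == p2[key].read_bytes()

    def test_per_host_mode_splits_depths(self, rng, tmp_path):
        cfg = barrier_scenario(
            sample_depths=(20, 10, 10, 10),
            hosts_per_deme=(2, 2, 2, 2),
            n_lineages_per_deme=5,
            seed=3,
        )
        truth, sample = simulate_otu(cfg)
        from collections import Counter

        by_sample = Counter(sample.samples)
        assert by_sample["KGI.h01"] == 10 and by_sample["KGI.h02"] == 10
        assert sum(by_sample.values()) == 50


class TestIslandModelLimit:
    def test_amova_fst_matches_identity_probability_oracle(self, rng):
        """Symmetric 2-deme island model: the AMOVA Fst (identity metric)
        agrees with (f_w - f_b)/(1 - f_b) computed from simulated identity
        probabilities, averaged over 60 replicates."""
        cfg = panmictic_scenario(
            n_demes=2, depth=30, n_lineages_per_deme=15, theta=2.0, m=1.0,
            seq_length=200,
        )
        diffs = []
        for _ in range(60):
            truth, sample = simulate_otu(cfg, rng)
            counts = truth.lineage_counts.astype(float)
            seqs = truth.sequences
            import pandas as pd

            mat = pd.DataFrame(
                truth.lineage_counts,
                index=list(truth.haplotypes),
                columns=["S1", "S2"],
            )
            fst = amova_structure(mat, seqs, "fst").iloc[0, 1]
            # identity probabilities without replacement
            c1, c2 = counts[:, 0], counts[:, 1]
            n1, n2 = c1.sum(), c2.sum()
            fw1 = (c1 * (c1 - 1)).sum() / (n1 * (n1 - 1))
            fw2 = (c2 * (c2 - 1)).sum() / (n2 * (n2 - 1))
            fw = (fw1 + fw2) / 2
            fb = (c1 * c2).sum() / (n1 * n2)
            if fb < 1:
                fst_ident = max((fw - fb) / (1 - fb), 0.0)
                diffs.append(fst - fst_ident)
        mean = np.mean(diffs)
        se = np.std(diffs, ddof=1) / np.sqrt(len(diffs))
        assert abs(mean) < 3 * se + 0.01
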
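"""Simulator checks: MSC genealogy distribution, sequence evolution,
dataset reproducibility, and agreement with msprime as an independent
coalescent oracle."""

import numpy as np
import pytest
from scipy.stats import ks_2samp

from conftest import genealogy_from_heights
from mscrate.simulate import (
    SpeciesTreeParams,
    concatenate,
    generate_dataset,
    locus_rng,
    read_loci,
    simulate_alignment,
    simulate_genealogy,
    simulate_pair_counts,
    simulate_pair_heights,
)
from mscrate.substitution import SubstitutionModel, jc69_mismatch_probability


class TestGenealogy:
    def test_zero_theta_collapses_to_species_tree(self, clock_true_params):
        rng = np.random.default_rng(0)
        for _ in range(20):
            g = simulate_genealogy(clock_true_params, rng)
            assert g.t_hc == clock_true_params.tau_hc
            assert g.t_hcg == clock_true_params.tau_hcg
            assert g.t_root == clock_true_params.tau_root
            assert g.hc_sister

    def test_heights_respect_population_intervals(self):
        params = SpeciesTreeParams()
        rng = np.random.default_rng(1)
        for _ in range(200):
            g = simulate_genealogy(params, rng)
            assert g.t_hc >= params.tau_hc
            assert g.t_hcg >= params.tau_hcg
            assert g.t_root >= params.tau_root
            assert g.t_hc <= g.t_hcg <= g.t_root
            if not g.hc_sister:
                # ILS genealogies put the H-P coalescence above the HCG split
                assert g.t_hc >= params.tau_hcg

    def test_mean_pair_height_is_tau_plus_half_theta(self):
        # two-lineage reduction: closed-form mean tau + theta/2
        tau, theta, n = 0.00473, 0.00304, 10_000
        h = simulate_pair_heights(tau, theta, n, np.random.default_rng(2))
        expected = tau + theta / 2.0
        se = (theta / 2.0) / np.sqrt(n)
        assert abs(h.mean() - expected) < 3 * se

    def test_full_genealogy_mean_matches_pair_reduction(self):
        # with the HCG split far away no truncation occurs, so the 4-taxon
        # simulator must reproduce the closed-form two-lineage mean
        params = SpeciesTreeParams(
            tau_hc=0.00473, tau_hcg=1.0, tau_root=1.5,
            theta_hc=0.00304, theta_hcg=0.001, theta_root=0.001,
        )
        rng = np.random.default_rng(3)
        n = 10_000
        heights = np.array([simulate_genealogy(params, rng).t_hc for _ in range(n)])
        expected = params.tau_hc + params.theta_hc / 2.0
        se = (params.theta_hc / 2.0) / np.sqrt(n)
        assert abs(heights.mean() - expected) < 3 * se

    def test_ils_non_sister_fraction_is_two_thirds(self):
        # huge theta_HC: Homo and Pan never coalesce before the HCG split;
        # all three lineages then coalesce in a long HCG epoch, where the
        # first pairing is uniform over the 3 pairs -> 2/3 non-sister
        params = SpeciesTreeParams(
            tau_hc=0.004, tau_hcg=0.005, tau_root=5.0,
            theta_hc=100.0, theta_hcg=0.01, theta_root=0.01,
        )
        rng = np.random.default_rng(4)
        n = 3000
        non_sister = sum(
            not simulate_genealogy(params, rng).hc_sister for _ in range(n)
        )
        frac = non_sister / n
        se = np.sqrt((2 / 3) * (1 / 3) / n)
        assert abs(frac - 2 / 3) < 3 * se

    def test_matches_msprime_pair_height_distribution(self):
        # independent oracle: two populations splitting at tau, ancestral
        # theta; haploid pair coalescence rate 1/N with N = theta/2
        msprime = pytest.importorskip("msprime")
        tau, theta, n = 0.00473, 0.00304, 3000
        demography = msprime.Demography()
        demography.add_population(name="H", initial_size=theta / 2)
        demography.add_population(name="P", initial_size=theta / 2)
        demography.add_population(name="HP", initial_size=theta / 2)
        demography.add_population_split(time=tau, derived=["H", "P"], ancestral="HP")
        oracle = np.array([
            ts.max_root_time
            for ts in msprime.sim_ancestry(
                samples={"H": 1, "P": 1}, demography=demography, ploidy=1,
                num_replicates=n, random_seed=7,
            )
        ])
        ours = simulate_pair_heights(tau, theta, n, np.random.default_rng(8))
        assert ks_2samp(oracle, ours).pvalue > 0.001

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"tau_hc": -0.001},
            {"tau_hc": 0.01, "tau_hcg": 0.005},
            {"theta_hc": -1.0},
            {"tau_root": np.nan},
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SpeciesTreeParams(**{**{}, **kwargs})


class TestSequenceEvolution:
    def test_zero_branch_lengths_give_identical_sequences(self, jc69_model):
        g = genealogy_from_heights(0.0, 0.0, 0.0)
        aln = simulate_alignment(g, jc69_model, 300, np.random.default_rng(0))
        assert all(aln.sequence(t) == aln.sequence("Homo") for t in aln.taxa)

    def test_mismatch_fraction_matches_jc69_expectation(self, jc69_model):
        h = 0.00625
        g = genealogy_from_heights(h, 0.008, 0.013)
        L = 100_000
        aln = simulate_alignment(g, jc69_model, L, np.random.default_rng(1))
        a = np.array(list(aln.sequence("Homo")))
        b = np.array(list(aln.sequence("Pan")))
        p_obs = (a != b).mean()
        p_exp = jc69_mismatch_probability(2 * h)
        se = np.sqrt(p_exp * (1 - p_exp) / L)
        assert abs(p_obs - p_exp) < 3 * se

    def test_rate_mixture_model_runs(self):
        model = SubstitutionModel(name="GTR", base_freqs=(0.3, 0.2, 0.2, 0.3),
                                  exchangeabilities=(1, 3, 1, 1, 3, 1),
                                  gamma_shape=0.5, p_inv=0.2)
        g = genealogy_from_heights(0.00625, 0.008, 0.013)
        aln = simulate_alignment(g, model, 500, np.random.default_rng(2))
        assert aln.length == 500

    def test_length_must_be_positive(self, jc69_model):
        g = genealogy_from_heights(0.001, 0.002, 0.003)
        with pytest.raises(ValueError):
            simulate_alignment(g, jc69_model, 0, np.random.default_rng(0))


class TestDataset:
    def test_fixed_seed_is_byte_identical(self, tmp_path, jc69_model):
        params = SpeciesTreeParams()
        m1 = generate_dataset(params, jc69_model, 3, 100, 42, tmp_path / "a")
        m2 = generate_dataset(params, jc69_model, 3, 100, 42, tmp_path / "b")
        assert m1["loci"] == m2["loci"]
        for name in ("locus_000000.fasta", "locus_000001.fasta", "locus_000002.fasta"):
            assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()

    def test_loci_reproducible_individually(self, jc69_model):
        params = SpeciesTreeParams()
        g_again = simulate_genealogy(params, locus_rng(42, 1), "locus_000001")
        g_first = simulate_genealogy(params, locus_rng(42, 1), "locus_000001")
        assert g_again.newick == g_first.newick

    def test_roundtrip_and_concatenation(self, tmp_path, jc69_model):
        params = SpeciesTreeParams()
        manifest = generate_dataset(params, jc69_model, 4, 120, 5, tmp_path)
        loci = read_loci(tmp_path)
        assert [a.locus_id for a in loci] == [d["locus_id"] for d in manifest["loci"]]
        supermatrix = concatenate(loci)
        assert supermatrix.length == 4 * 120 == manifest["total_sites"]

    def test_zero_loci_rejected(self, tmp_path, jc69_model):
        with pytest.raises(ValueError):
            generate_dataset(SpeciesTreeParams(), jc69_model, 0, 100, 1, tmp_path)


def test_pair_counts_track_heights():
    x, L, h = simulate_pair_counts(0.005, 0.002, 2000, 1000, np.random.default_rng(9))
    assert (x <= L).all() and (x >= 0).all()
    # loci with older genealogies should show more differences on average
    old = h > np.median(h)
    assert x[old].mean() > x[~old].mean()
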
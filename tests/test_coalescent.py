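"""Structured-coalescent engine: models, priors, genealogies, expected SFS."""

import numpy as np
import pytest

from cochise import coalescent as co


def iso_params(N=100_000.0, T_D=1_000_000.0):
    return co.ParameterVector.for_model(
        "ISO", N_eS=N, N_eC=N, N_eO=N, N_eD=N, N_eA=N, T_D=T_D
    )


SINGLE_DEME = co.SampleConfig(4, 0, 0)


class TestModelCatalog:
    def test_six_models_with_expected_parameter_counts(self):
        catalog = co.model_catalog()
        assert [m.model_id for m in catalog] == list(co.MODEL_IDS)
        ks = {m.model_id: m.k for m in catalog}
        assert ks == {
            "ISO": 6, "SYM": 7, "ASYM": 8, "SON2CHI": 7, "CHI2SON": 7, "SECCONTACT": 9,
        }

    def test_migration_parameter_rejected_for_iso(self):
        with pytest.raises(ValueError, match="not free"):
            co.ParameterVector.for_model(
                "ISO", N_eS=1e5, N_eC=1e5, N_eO=1e5, N_eD=1e5, N_eA=1e5,
                T_D=8e5, m_S=1e-5,
            )

    def test_missing_parameter_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            co.ParameterVector.for_model("ISO", N_eS=1e5)

    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            iso_params(N=-5.0)
        with pytest.raises(ValueError):
            iso_params(T_D=3e6)  # beyond the fixed outgroup split


class TestPriors:
    def test_log_uniform_quantiles(self):
        rng = np.random.default_rng(0)
        spec = co.PriorSpec("log-uniform", 50_000, 1_000_000)
        draws = np.array([spec.draw(rng) for _ in range(10_000)])
        # analytic quantiles of log-uniform: lower * (upper/lower)**q
        for q in (0.05, 0.5, 0.95):
            expected = 50_000 * (20.0) ** q
            assert np.quantile(draws, q) == pytest.approx(expected, rel=0.05)

    def test_divergence_prior_bounds(self):
        priors = co.default_priors()
        model = co.get_model("ISO")
        draws = [co.draw_parameters(model, priors, s).T_D for s in range(300)]
        assert all(500_000 <= t <= 1_000_000 for t in draws)

    def test_reproducible_under_seed(self):
        priors = co.default_priors()
        model = co.get_model("SECCONTACT")
        assert co.draw_parameters(model, priors, 7) == co.draw_parameters(model, priors, 7)

    def test_missing_prior_errors(self):
        priors = co.PriorSet({"N_eS": co.PriorSpec("uniform", 1, 2)})
        with pytest.raises(KeyError, match="prior missing"):
            priors.for_model(co.get_model("ISO"))


class TestGenealogies:
    def test_pairwise_tmrca_matches_haploid_coalescent(self):
        # E[T2] = N generations for a haploid deme of size N
        N = 100_000.0
        tm = co.simulate_tmrca(
            co.get_model("ISO"), iso_params(N=N), co.SampleConfig(2, 0, 0), 20_000, 3
        )
        se = tm.std() / np.sqrt(tm.size)
        assert abs(tm.mean() - N) < 3 * se

    def test_cross_deme_tmrca_exceeds_divergence_without_migration(self):
        params = iso_params(T_D=900_000.0)
        tm = co.simulate_tmrca(
            co.get_model("ISO"), params, co.SampleConfig(1, 1, 0), 2_000, 4
        )
        assert (tm >= 900_000.0).all()

    def test_migration_allows_pre_split_coalescence(self):
        model = co.get_model("ASYM")
        params = co.ParameterVector.for_model(
            model, N_eS=1e5, N_eC=1e5, N_eO=1e5, N_eD=1e5, N_eA=1e5,
            T_D=900_000.0, m_S=1e-4, m_C=1e-4,
        )
        tm = co.simulate_tmrca(model, params, co.SampleConfig(1, 1, 0), 2_000, 5)
        assert (tm < 900_000.0).mean() > 0

    def test_reference_simulator_branch_records_consistent(self):
        records, tmrca = co.simulate_genealogy(
            co.get_model("ISO"), iso_params(), co.SampleConfig(3, 2, 1), seed=11
        )
        # n - 1 coalescences, two branch records each
        assert len(records) == 2 * 5
        assert all(r.length >= 0 for r in records)
        assert all(sum(r.counts) < 6 for r in records)  # root branch excluded
        assert tmrca > 0

    def test_total_tree_length_single_deme(self):
        # E[sum branch lengths] = N * sum_{i=1}^{n-1} 2/i for haploid size N
        N, n = 50_000.0, 5
        model = co.get_model("ISO")
        params = iso_params(N=N, T_D=1_500_000.0)
        lengths = []
        for rep in range(4_000):
            records, _ = co.simulate_genealogy(
                model, params, co.SampleConfig(n, 0, 0), seed=1_000 + rep
            )
            lengths.append(sum(r.length for r in records))
        lengths = np.array(lengths)
        expected = N * sum(2.0 / i for i in range(1, n))
        se = lengths.std() / np.sqrt(lengths.size)
        assert abs(lengths.mean() - expected) < 3 * se


def batched_expected_sfs(model, params, config, n_batches, reps, seed0):
    """Mean and standard error of the expected SFS over independent batches."""
    batches = np.stack(
        [
            co.expected_sfs(model, params, config, reps, seed0 + 1_000 * b).counts
            for b in range(n_batches)
        ]
    )
    return batches.mean(axis=0), batches.std(axis=0, ddof=1) / np.sqrt(n_batches)


class TestExpectedSfs:
    def test_neutral_single_deme_spectrum(self):
        # xi_i proportional to 1/i for a panmictic neutral deme
        mean, se = batched_expected_sfs(
            co.get_model("ISO"), iso_params(), SINGLE_DEME, 10, 4_000, 17
        )
        for i in (2, 3):
            ratio_se = 3 * (se[i, 0, 0] + se[1, 0, 0]) / mean[1, 0, 0]
            assert mean[i, 0, 0] / mean[1, 0, 0] == pytest.approx(1.0 / i, abs=ratio_se)

    def test_linear_in_mutation_rate(self):
        model = co.get_model("ISO")
        a = co.expected_sfs(model, iso_params(), SINGLE_DEME, 200, 9, mu=1e-9)
        b = co.expected_sfs(model, iso_params(), SINGLE_DEME, 200, 9, mu=2e-9)
        assert np.allclose(b.counts, 2 * a.counts)

    def test_deep_divergence_kills_shared_polymorphism(self):
        cfg = co.SampleConfig(4, 4, 0)
        model = co.get_model("ISO")
        shallow = co.expected_sfs(model, iso_params(N=2e5, T_D=5e4), cfg, 4_000, 21)
        deep = co.expected_sfs(model, iso_params(N=2e4, T_D=1.8e6), cfg, 4_000, 21)
        shared = (slice(1, 4), slice(1, 4), 0)
        assert deep.counts[shared].sum() < 0.02 * shallow.counts[shared].sum()

    def test_nested_models_identical_at_zero_migration(self):
        # with m = 0 the ASYM and SECCONTACT processes consume the same
        # random stream as ISO, so the expected SFS match exactly
        cfg = co.SampleConfig(3, 3, 1)
        iso = co.expected_sfs(co.get_model("ISO"), iso_params(), cfg, 500, 33)
        asym_p = co.ParameterVector.for_model(
            "ASYM", N_eS=1e5, N_eC=1e5, N_eO=1e5, N_eD=1e5, N_eA=1e5,
            T_D=1e6, m_S=0.0, m_C=0.0,
        )
        asym = co.expected_sfs(co.get_model("ASYM"), asym_p, cfg, 500, 33)
        sc_p = co.ParameterVector.for_model(
            "SECCONTACT", N_eS=1e5, N_eC=1e5, N_eO=1e5, N_eD=1e5, N_eA=1e5,
            T_D=1e6, T_SC=0.0, m_S=1e-4, m_C=1e-4,
        )
        sc = co.expected_sfs(co.get_model("SECCONTACT"), sc_p, cfg, 500, 33)
        assert np.array_equal(iso.counts, asym.counts)
        assert np.array_equal(iso.counts, sc.counts)

    def test_kernel_agrees_with_reference_simulator(self):
        model = co.get_model("ASYM")
        params = co.ParameterVector.for_model(
            model, N_eS=8e4, N_eC=2e5, N_eO=1e5, N_eD=3e5, N_eA=1e5,
            T_D=8e5, m_S=2e-6, m_C=1e-6,
        )
        cfg = co.SampleConfig(3, 3, 2)
        mean_k, se_k = batched_expected_sfs(model, params, cfg, 8, 2_500, 71)
        ref_batches = np.stack(
            [
                co.expected_sfs_reference(model, params, cfg, 600, 123_000 + 10_000 * b).counts
                for b in range(6)
            ]
        )
        mean_r = ref_batches.mean(axis=0)
        se_r = ref_batches.std(axis=0, ddof=1) / np.sqrt(6)
        big = mean_k > mean_k.max() * 0.01
        z = (mean_r[big] - mean_k[big]) / np.sqrt(se_k[big] ** 2 + se_r[big] ** 2)
        assert np.all(np.abs(z) < 4)


class TestSnpSampling:
    def test_sampled_sfs_matches_neutral_shape(self):
        from scipy.stats import chisquare

        sfs = co.sample_sfs(co.get_model("ISO"), iso_params(), SINGLE_DEME, 5_000, 6)
        obs = sfs.counts[1:4, 0, 0]
        p = np.array([1, 1 / 2, 1 / 3])
        stat, pval = chisquare(obs, 5_000 * p / p.sum())
        assert pval > 0.001

    def test_sample_sfs_mass_and_corners(self):
        cfg = co.SampleConfig(4, 4, 2)
        sfs = co.sample_sfs(co.get_model("ISO"), iso_params(), cfg, 1_000, 7)
        assert sfs.total_mass() == 1_000
        assert sfs.counts[0, 0, 0] == 0 and sfs.counts[4, 4, 2] == 0

    def test_genotype_matrix_reproducible_and_complete(self):
        model = co.get_model("ISO")
        gm1 = co.sample_snp_matrix(model, iso_params(), (3, 3, 1), 200, 0.0, 13)
        gm2 = co.sample_snp_matrix(model, iso_params(), (3, 3, 1), 200, 0.0, 13)
        assert np.array_equal(gm1.calls, gm2.calls)
        assert (gm1.calls != co.MISSING).all()
        assert len({s.locus_id for s in gm1.sites}) == 200

    def test_missing_rate_applied(self):
        gm = co.sample_snp_matrix(
            co.get_model("ISO"), iso_params(), (4, 4, 1), 400, 0.2, 14
        )
        frac = (gm.calls == co.MISSING).mean()
        assert 0.15 < frac < 0.25


@pytest.mark.parametrize("setting", ["isolation", "asymmetric_migration"])
def test_expected_sfs_matches_msprime(setting):
    """Entrywise agreement with an independent coalescent implementation."""
    import msprime

    N = dict(S=30_000.0, C=80_000.0, O=50_000.0, D=60_000.0, A=40_000.0)
    T_D, T_A = 60_000.0, co.T_ANCESTRAL_YEARS
    if setting == "isolation":
        model = co.get_model("ISO")
        m_S = m_C = 0.0
        params = co.ParameterVector.for_model(
            model, N_eS=N["S"], N_eC=N["C"], N_eO=N["O"], N_eD=N["D"], N_eA=N["A"], T_D=T_D
        )
    else:
        model = co.get_model("ASYM")
        m_S, m_C = 1e-5, 3e-6  # 2 N m of order 1: migration matters
        params = co.ParameterVector.for_model(
            model, N_eS=N["S"], N_eC=N["C"], N_eO=N["O"], N_eD=N["D"], N_eA=N["A"],
            T_D=T_D, m_S=m_S, m_C=m_C,
        )
    cfg = co.SampleConfig(4, 4, 2)
    mean_k, se_k = batched_expected_sfs(model, params, cfg, 10, 3_000, 55)

    demog = msprime.Demography()
    for name in ("S", "C", "O", "D", "A"):
        demog.add_population(name=name, initial_size=N[name])
    demog.add_population_split(time=T_D, derived=["S", "C"], ancestral="D")
    demog.add_population_split(time=T_A, derived=["D", "O"], ancestral="A")
    # backward per-lineage rates: our m_S moves Chihuahuan lineages into the
    # Sonoran deme, which is msprime's source=C, dest=S
    demog.set_migration_rate(source="C", dest="S", rate=m_S)
    demog.set_migration_rate(source="S", dest="C", rate=m_C)
    reps = msprime.sim_ancestry(
        samples=[
            msprime.SampleSet(4, population="S", ploidy=1),
            msprime.SampleSet(4, population="C", ploidy=1),
            msprime.SampleSet(2, population="O", ploidy=1),
        ],
        demography=demog,
        ploidy=1,
        num_replicates=600,
        random_seed=97,
    )
    mu = co.MU_PER_SITE_PER_YEAR
    afs = []
    for ts in reps:
        sets = [ts.samples(population=p) for p in range(3)]
        afs.append(
            ts.allele_frequency_spectrum(
                sample_sets=sets, mode="branch", polarised=True, span_normalise=True
            )
            * mu
        )
    afs = np.stack(afs)
    mean_m = afs.mean(axis=0)
    se_m = afs.std(axis=0, ddof=1) / np.sqrt(afs.shape[0])
    big = mean_k > mean_k.max() * 0.02
    z = (mean_k[big] - mean_m[big]) / np.sqrt(se_k[big] ** 2 + se_m[big] ** 2)
    assert np.all(np.abs(z) < 4), z
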
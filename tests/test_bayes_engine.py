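"""Grid quadrature, MCMC, Bayes factors, DIC and pattern classification."""

import numpy as np
import pytest

from trdkit import (
    FitResult,
    GenotypicParams,
    MatingCountTable,
    bayes_factor,
    classify_genotypic,
    classify_pattern,
    dic,
    fit_all_models,
    fit_model,
    grid_fit,
    run_mcmc,
    savage_dickey_bf,
    select_model,
    simulate,
    tabulate,
)
from trdkit.bayes_engine import PARAM_NAMES
from trdkit.genotype_io import assemble_trios
from trdkit.mating_model import TRD_MODELS, genotypic_cell_probs
from trdkit.synthetic_data import LocusSpec, SimConfig

from conftest import random_count_table


def _counts(**cells):
    mapping = {"abxaa_aa": ("ABxAA", 0), "abxaa_ab": ("ABxAA", 1),
               "abxab_aa": ("ABxAB", 0), "abxab_ab": ("ABxAB", 1),
               "abxab_bb": ("ABxAB", 2)}
    return MatingCountTable.from_cells(
        {mapping[k]: v for k, v in cells.items()})


class TestGridFit:
    def test_zero_counts_posterior_equals_prior(self):
        gp = grid_fit(MatingCountTable(np.zeros(11, int)), "allelic_overall")
        assert np.isclose(gp.marginal_likelihood, 1.0)
        assert np.isclose(gp.mean()[0], 0.0, atol=1e-12)
        assert np.isclose(gp.mass.sum(), 1.0, atol=1e-10)

    def test_beta_posterior_closed_form(self):
        # 10 AA : 0 AB from AB x AA -> posterior Beta(11, 1) on 0.5 + alpha
        gp = grid_fit(_counts(abxaa_aa=10), "allelic_overall", 1001)
        assert np.isclose(gp.mean()[0], 11 / 12 - 0.5, atol=1e-4)
        assert np.isclose(gp.marginal_likelihood, 1 / 11, rtol=1e-4)

    def test_resolution_floor(self):
        with pytest.raises(ValueError):
            grid_fit(_counts(abxaa_aa=1), "allelic_overall", 51)

    def test_mass_sums_to_one_all_models(self):
        rng = np.random.default_rng(2)
        c = random_count_table(rng)
        for model in TRD_MODELS:
            gp = grid_fit(c, model)
            assert np.isclose(gp.mass.sum(), 1.0, atol=1e-10)


class TestBayesFactor:
    def test_closed_form_integrals(self):
        bf10 = bayes_factor(_counts(abxaa_aa=10), "allelic_overall", 1001)
        assert np.isclose(bf10, 1024 / 11, rtol=1e-3)
        bf55 = bayes_factor(_counts(abxaa_aa=5, abxaa_ab=5),
                            "allelic_overall", 1001)
        assert np.isclose(bf55, 1024 / 2772, rtol=1e-3)

    def test_no_data_gives_unit_bf(self):
        assert np.isclose(
            bayes_factor(MatingCountTable(np.zeros(11, int)),
                         "allelic_overall"), 1.0)

    def test_savage_dickey_identity_on_grid(self):
        for c in (_counts(abxaa_aa=10), _counts(abxaa_aa=5, abxaa_ab=5),
                  _counts(abxab_aa=20, abxab_ab=60, abxab_bb=20)):
            gp = grid_fit(c, "allelic_overall", 1001)
            bf_ml = bayes_factor(c, "allelic_overall", fit=gp)
            bf_sd = savage_dickey_bf(gp)
            assert np.isclose(bf_sd, bf_ml, rtol=1e-3)

    def test_savage_dickey_identity_2d(self):
        c = _counts(abxab_aa=10, abxab_ab=50, abxab_bb=30)
        gp = grid_fit(c, "genotypic", 301)
        assert np.isclose(savage_dickey_bf(gp),
                          bayes_factor(c, "genotypic", fit=gp), rtol=1e-3)

    def test_infinite_bf_when_null_impossible(self):
        # structural zero under the null cannot happen; instead use data so
        # extreme the BF overflows the float range
        c = _counts(abxaa_aa=3000)
        assert bayes_factor(c, "allelic_overall") == np.inf


class TestMcmc:
    def test_null_data_centered_on_zero(self):
        c = _counts(abxab_aa=400, abxab_ab=800, abxab_bb=400)
        chain = run_mcmc(c, "allelic_overall", 11_000, 1_000, seed=1)
        mcse = chain.samples.std() / np.sqrt(chain.ess()[0])
        assert abs(chain.samples.mean()) < 3 * mcse + 1e-3

    def test_agrees_with_grid_oracle(self):
        c = _counts(abxaa_aa=10)
        chain = run_mcmc(c, "allelic_overall", 21_000, 1_000, seed=2)
        mcse = chain.samples.std() / np.sqrt(chain.ess()[0])
        assert abs(chain.samples.mean() - (11 / 12 - 0.5)) < 3 * mcse + 1e-3

    def test_same_seed_identical_chains(self):
        c = _counts(abxaa_aa=6, abxaa_ab=2)
        a = run_mcmc(c, "genotypic", 2_000, 500, seed=7)
        b = run_mcmc(c, "genotypic", 2_000, 500, seed=7)
        np.testing.assert_array_equal(a.samples, b.samples)

    def test_samples_stay_in_space(self):
        c = _counts(abxab_aa=5, abxab_ab=60, abxab_bb=35)
        chain = run_mcmc(c, "genotypic", 6_000, 1_000, seed=3)
        from trdkit.mating_model import genotypic_in_space
        assert genotypic_in_space(chain.samples[:, 0],
                                  chain.samples[:, 1]).all()

    def test_iterations_must_exceed_burn_in(self):
        with pytest.raises(ValueError):
            run_mcmc(_counts(abxaa_aa=1), "allelic_overall", 100, 100)

    @pytest.mark.parametrize("model", ["allelic_parent_specific", "genotypic"])
    def test_battery_matches_grid_within_mc_error(self, model):
        rng = np.random.default_rng(13)
        for _ in range(10):
            c = random_count_table(rng, n_max=150)
            gp = grid_fit(c, model)
            chain = run_mcmc(c, model, 11_000, 1_000,
                             seed=int(rng.integers(1_000_000)))
            ess = np.maximum(chain.ess(), 10.0)
            mcse = chain.samples.std(axis=0) / np.sqrt(ess)
            diff = np.abs(chain.samples.mean(axis=0) - gp.mean())
            assert np.all(diff < 4 * mcse + 0.01), (diff, mcse)


class TestDic:
    def test_null_model_has_zero_pd(self):
        c = _counts(abxaa_aa=30, abxaa_ab=20)
        d, pd_ = dic(c, "null")
        assert pd_ == 0.0
        assert np.isclose(d, -2 * 50 * np.log(0.5))

    def test_parent_specific_favored_on_sire_only_trd(self):
        sim = simulate(SimConfig(
            n_sires=100, offspring_per_sire=20, snps_per_chrom=1,
            loci=(LocusSpec("chr1", 0, "allelic", alpha_s=0.4, alpha_d=0.0,
                            carrier_frequency=0.5),), seed=21))
        counts = tabulate(assemble_trios(sim.gt, sim.pedigree, "chr1_snp0001"))
        d_ps, _ = dic(counts, "allelic_parent_specific")
        d_ov, _ = dic(counts, "allelic_overall")
        assert d_ps < d_ov - 3.0

    def test_genotypic_favored_on_recessive_lethal(self):
        sim = simulate(SimConfig(
            n_sires=100, offspring_per_sire=20, snps_per_chrom=1,
            loci=(LocusSpec("chr1", 0, "recessive_lethal",
                            carrier_frequency=0.3),), seed=22))
        counts = tabulate(assemble_trios(sim.gt, sim.pedigree, "chr1_snp0001"))
        d_g, _ = dic(counts, "genotypic")
        d_a = min(dic(counts, "allelic_overall")[0],
                  dic(counts, "allelic_parent_specific")[0])
        assert d_g < d_a - 3.0


class TestSelectModel:
    def _fits(self, dics):
        out = {}
        for m, d in dics.items():
            dim = len(PARAM_NAMES[m])
            z = np.zeros(dim)
            out[m] = FitResult(m, "grid", PARAM_NAMES[m], z, z, z, z, z,
                               log_bf=0.0, dic=d, p_d=0.0)
        return out

    def test_parsimony_below_margin(self):
        fits = self._fits({"allelic_overall": 100.0,
                           "allelic_parent_specific": 99.0})
        assert select_model(fits)[0] == "allelic_overall"

    def test_clear_winner(self):
        fits = self._fits({"allelic_overall": 100.0, "genotypic": 90.0})
        selected, delta = select_model(fits)
        assert selected == "genotypic"
        assert delta["allelic_overall"] == 10.0

    def test_needs_two_fits(self):
        with pytest.raises(ValueError):
            select_model(self._fits({"genotypic": 1.0}))


class TestClassifyPattern:
    @pytest.mark.parametrize("ag,dg,label", [
        (-0.66, 0.33, "recessive"),
        (-0.47, 0.25, "recessive"),
        (0.09, -0.04, "homozygote advantage"),
        (-0.05, 0.04, "homozygote disadvantage"),
        (0.05, 0.25, "heterosis excess"),
        (-0.40, -0.25, "heterosis deficiency"),
    ])
    def test_genotypic_labels_match_published_examples(self, ag, dg, label):
        assert classify_genotypic(ag, dg) == label

    def _allelic_fit(self, mean_s, mean_d, sig_s, sig_d):
        mean = np.array([mean_s, mean_d])
        half = np.array([0.01 if sig_s else 0.2,
                         0.01 if sig_d else 0.2])
        return FitResult("allelic_parent_specific", "grid",
                         PARAM_NAMES["allelic_parent_specific"], mean,
                         half, mean, mean - half, mean + half,
                         log_bf=0.0, dic=0.0, p_d=0.0)

    def test_allelic_branches(self):
        f = self._allelic_fit(-0.3, 0.0, True, False)
        assert classify_pattern("allelic_parent_specific", f) == "sire-TRD"
        f = self._allelic_fit(0.0, -0.3, False, True)
        assert classify_pattern("allelic_parent_specific", f) == "dam-TRD"
        f = self._allelic_fit(-0.3, -0.3, True, True)
        assert classify_pattern("allelic_parent_specific", f) == "sire+dam-TRD"
        assert classify_pattern("allelic_overall", f) == "overall-TRD"


class TestFitAllModels:
    def test_returns_all_four_models(self):
        c = _counts(abxaa_aa=30, abxaa_ab=10)
        fits = fit_all_models(c)
        assert set(fits) == {"null", *TRD_MODELS}
        assert fits["null"].p_d == 0.0

    def test_cv_infinite_at_zero_mean(self):
        gp = grid_fit(MatingCountTable(np.zeros(11, int)), "allelic_overall")
        f = fit_model(MatingCountTable(np.zeros(11, int)), "allelic_overall")
        assert np.isinf(f.cv[0]) or abs(f.mean[0]) > 0
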
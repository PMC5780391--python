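"""Gibbs sampler correctness, heritability posteriors, and the
parent-offspring regression estimator."""

import numpy as np
import pandas as pd
import pytest

from voleherit import (
    AnimalModel,
    GibbsConfig,
    Pedigree,
    PedigreeRecord,
    PosteriorSamples,
    PriorSpec,
    VarianceTruth,
    additive_relationship_matrix,
    assign_partners_strangers,
    heritability_from_samples,
    parent_offspring_regression,
    simulate_phenotypes,
)


class TestGibbsConfig:
    def test_retained_count_identity(self):
        cfg = GibbsConfig(n_iter=1000, burn_in=200, thin=8)
        assert cfg.n_retained == 100

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(n_iter=0),
            dict(n_iter=100, burn_in=100),
            dict(n_iter=100, burn_in=10, thin=7),  # not divisible
            dict(n_iter=100, burn_in=10, thin=0),
        ],
    )
    def test_invalid_schedules_rejected(self, kwargs):
        defaults = dict(n_iter=100, burn_in=0, thin=1)
        with pytest.raises(ValueError):
            GibbsConfig(**{**defaults, **kwargs})


class TestPriorSpec:
    def test_hyperparameters_must_be_positive(self):
        with pytest.raises(ValueError):
            PriorSpec(nu0_m=0.0)

    def test_defaults_are_weak_but_proper(self):
        priors = PriorSpec()
        assert priors.nu0("male") == pytest.approx(0.002)
        assert priors.S0("e") == pytest.approx(1.0)


class TestSamplerCorrectness:
    def test_intercept_only_matches_conjugate_posterior(self, identity_relationship):
        """With no genetic effects the marginal posterior of the residual
        variance is available in closed form (scaled-inverse-chi-square with
        nu0 + n - 1 degrees after integrating out the flat-prior intercept);
        the Gibbs draws must match its mean and variance to MC error."""
        rng = np.random.default_rng(11)
        y = rng.normal(5.0, 2.0, size=60)
        n = y.size
        priors = PriorSpec()
        model = AnimalModel(y, {}, identity_relationship(1), priors=priors)
        res = model.fit(GibbsConfig(n_iter=6000, burn_in=1000, thin=1, seed=1))
        draws = res.samples.frame["var_e"].to_numpy()

        nu_n = priors.nu0_e + n - 1
        scale_sum = priors.nu0_e * priors.S0_e + np.sum((y - y.mean()) ** 2)
        exact_mean = scale_sum / (nu_n - 2)
        exact_var = 2 * scale_sum**2 / ((nu_n - 2) ** 2 * (nu_n - 4))
        # thin=1 draws of var_e in this model are nearly independent
        mc_se = np.sqrt(exact_var / draws.size)
        assert abs(draws.mean() - exact_mean) < 5 * mc_se
        assert draws.var(ddof=1) == pytest.approx(exact_var, rel=0.25)

    def test_recovers_realized_variances_with_repeated_records(
        self, identity_relationship
    ):
        """200 unrelated animals x 20 records each: both variance components
        are strongly identified, and the posterior must match the realized
        between-animal and residual variances."""
        rng = np.random.default_rng(7)
        n_anim, reps = 200, 20
        A = identity_relationship(n_anim)
        u = rng.normal(0, np.sqrt(2.0), n_anim)
        males, y = [], []
        for i, a in enumerate(A.ids):
            males += [a] * reps
            y += list(10 + u[i] + rng.normal(0, 1.0, reps))
        model = AnimalModel(np.array(y), {"male": males}, A)
        res = model.fit(GibbsConfig(6000, 1000, 5, seed=1))
        post = res.posterior_mean()
        assert post["var_male"] == pytest.approx(u.var(ddof=1), rel=0.15)
        assert post["var_e"] == pytest.approx(1.0, rel=0.10)

    def test_same_seed_identical_chains(self, small_colony, small_colony_A):
        triples = assign_partners_strangers(small_colony, seed=1, A=small_colony_A)
        ds = simulate_phenotypes(
            small_colony, triples,
            VarianceTruth(beta=0, var_m=1, var_p=0.2, var_s=0.2, var_e=1),
            seed=2, A=small_colony_A,
        )
        model = AnimalModel.from_trials(ds.trials, small_colony_A)
        cfg = GibbsConfig(800, 200, 3, seed=99)
        f1 = model.fit(cfg).samples.frame
        f2 = model.fit(cfg).samples.frame
        pd.testing.assert_frame_equal(f1, f2)

    def test_all_variance_draws_positive_and_schedule_respected(
        self, small_colony, small_colony_A
    ):
        triples = assign_partners_strangers(small_colony, seed=3, A=small_colony_A)
        ds = simulate_phenotypes(
            small_colony, triples,
            VarianceTruth(beta=5, var_m=2, var_e=2), seed=4, A=small_colony_A,
        )
        cfg = GibbsConfig(600, 100, 5, seed=0)
        samples = AnimalModel.from_trials(ds.trials, small_colony_A).fit(cfg).samples
        assert samples.n_draws == cfg.n_retained
        assert (samples.frame[samples.variance_columns()].to_numpy() > 0).all()

    def test_standardized_fit_leaves_heritability_invariant(
        self, small_colony, small_colony_A
    ):
        triples = assign_partners_strangers(small_colony, seed=5, A=small_colony_A)
        ds = simulate_phenotypes(
            small_colony, triples,
            VarianceTruth(beta=100, var_m=8, var_e=8), seed=6, A=small_colony_A,
        )
        cfg = GibbsConfig(2000, 500, 5, seed=2)
        raw = AnimalModel.from_trials(ds.trials, small_colony_A, effects=("male",))
        std = AnimalModel.from_trials(
            ds.trials, small_colony_A, effects=("male",), standardize=True
        )
        h_raw = raw.fit(cfg).heritability().mean["h2_male"]
        h_std = std.fit(cfg).heritability().mean["h2_male"]
        assert h_std == pytest.approx(h_raw, abs=0.02)


def make_samples(rows, effects=("male", "partner", "stranger")):
    frame = pd.DataFrame(
        rows, columns=["beta"] + [f"var_{x}" for x in effects] + ["var_e"]
    )
    cfg = GibbsConfig(n_iter=len(rows), burn_in=0, thin=1)
    return PosteriorSamples(frame=frame, config=cfg, effects=tuple(effects))


class TestHeritability:
    def test_equal_draws_give_quarter_shares_with_zero_sd(self):
        samples = make_samples([[0, 1, 1, 1, 1]] * 5)
        h2 = heritability_from_samples(samples)
        for name in ("h2_male", "h2_partner", "h2_stranger"):
            assert h2.mean[name] == pytest.approx(0.25)
            assert h2.sd[name] == 0.0

    def test_zero_component_gives_zero_heritability(self):
        samples = make_samples([[0, 0.0, 1, 1, 2]] * 4)
        assert heritability_from_samples(samples).mean["h2_male"] == 0.0

    def test_mean_of_ratios_convention(self):
        # draws (1,0,0,1) and (3,0,0,1): mean of per-draw ratios = 0.625
        samples = make_samples([[0, 1, 0.0, 0.0, 1], [0, 3, 0.0, 0.0, 1]])
        h2 = heritability_from_samples(samples)
        assert h2.mean["h2_male"] == pytest.approx((0.5 + 0.75) / 2)

    def test_per_draw_shares_sum_to_one_with_residual(self):
        rng = np.random.default_rng(0)
        rows = np.column_stack(
            [rng.normal(size=50)] + [rng.gamma(2, 1, 50) for _ in range(4)]
        )
        samples = make_samples(rows.tolist())
        h2 = heritability_from_samples(samples)
        total = samples.total_variance()
        resid_share = samples.frame["var_e"].to_numpy() / total
        np.testing.assert_allclose(
            h2.per_draw.sum(axis=1).to_numpy() + resid_share, 1.0, atol=1e-12
        )

    def test_degenerate_total_variance_raises(self):
        frame = pd.DataFrame(
            [[0.0, 0.0, 0.0, 0.0, 0.0]],
            columns=["beta", "var_male", "var_partner", "var_stranger", "var_e"],
        )
        samples = PosteriorSamples(
            frame=frame, config=GibbsConfig(1, 0, 1),
            effects=("male", "partner", "stranger"),
        )
        with pytest.raises(ValueError, match="degenerate"):
            heritability_from_samples(samples)


def simulate_sire_son_population(h2: float, n_pairs: int, seed: int):
    """Independent sire-dam-son families with phenotype = breeding value + noise."""
    rng = np.random.default_rng(seed)
    va, ve = h2, 1 - h2
    records, rows = [], []
    for i in range(n_pairs):
        sire, dam, son = f"s{i}", f"d{i}", f"o{i}"
        records += [
            PedigreeRecord(sire, sex="M"),
            PedigreeRecord(dam, sex="F"),
            PedigreeRecord(son, sire_id=sire, dam_id=dam, sex="M"),
        ]
        a_s = rng.normal(0, np.sqrt(va)) if va else 0.0
        a_d = rng.normal(0, np.sqrt(va)) if va else 0.0
        a_o = 0.5 * (a_s + a_d) + (rng.normal(0, np.sqrt(va / 2)) if va else 0.0)
        rows.append((sire, a_s + rng.normal(0, np.sqrt(ve))))
        rows.append((son, a_o + rng.normal(0, np.sqrt(ve))))
    trials = pd.DataFrame(rows, columns=["animal", "value"])
    return Pedigree(records), trials


class TestParentOffspringRegression:
    def test_identical_sire_and_son_values_flagged(self):
        ped, _ = simulate_sire_son_population(0.5, 5, seed=0)
        values = pd.DataFrame(
            {"animal": [f"s{i}" for i in range(5)] + [f"o{i}" for i in range(5)],
             "value": list(range(5)) * 2}
        )
        result = parent_offspring_regression(values, ped)
        assert result.slope == pytest.approx(1.0)
        assert result.h2 == pytest.approx(2.0)
        assert result.out_of_range

    @pytest.mark.parametrize("h2_true", [0.0, 0.4])
    def test_monte_carlo_recovery(self, h2_true):
        ped, trials = simulate_sire_son_population(h2_true, 2000, seed=3)
        result = parent_offspring_regression(trials, ped)
        assert result.n_pairs == 2000
        assert result.h2 == pytest.approx(h2_true, abs=0.1)

    def test_constant_sire_phenotypes_rejected(self):
        ped, _ = simulate_sire_son_population(0.5, 3, seed=1)
        values = pd.DataFrame(
            {"animal": ["s0", "s1", "s2", "o0", "o1", "o2"],
             "value": [1.0, 1.0, 1.0, 0.5, 1.5, 1.0]}
        )
        with pytest.raises(ValueError, match="variation"):
            parent_offspring_regression(values, ped)

    def test_too_few_pairs_rejected(self):
        ped, _ = simulate_sire_son_population(0.5, 3, seed=1)
        values = pd.DataFrame({"animal": ["s0", "o0"], "value": [1.0, 2.0]})
        with pytest.raises(ValueError, match="at least two"):
            parent_offspring_regression(values, ped)


def test_gibbs_and_parent_offspring_estimates_agree(small_colony, small_colony_A):
    """The two heritability estimators target the same quantity; on a colony
    simulated with only a focal-male effect they must agree within their
    joint Monte-Carlo uncertainty."""
    triples = assign_partners_strangers(small_colony, seed=21, A=small_colony_A)
    truth = VarianceTruth.from_heritability(0.5, beta=0.0, total=4.0)
    ds = simulate_phenotypes(small_colony, triples, truth, seed=22, A=small_colony_A)
    model = AnimalModel.from_trials(ds.trials, small_colony_A, effects=("male",))
    res = model.fit(GibbsConfig(8000, 1000, 7, seed=23))
    h2_gibbs = res.heritability()
    po = parent_offspring_regression(ds.trials, small_colony)
    joint_se = np.sqrt(h2_gibbs.sd["h2_male"] ** 2 + po.se**2)
    assert abs(h2_gibbs.mean["h2_male"] - po.h2) < 3 * joint_se + 1e-9
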
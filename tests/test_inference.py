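"""Tests of the likelihood replay, parameter layout and posterior fitting."""

import math
from dataclasses import replace

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

import ewalearn as ew
from ewalearn.core import CUE_NAMES
from ewalearn.inference import (
    MCMCConfig,
    ModelSpec,
    ParamLayout,
    PriorSet,
    build_design,
    canonical_specs,
    spec_by_label,
)
from replay_oracle import naive_log_likelihood


def uniform_learner(J, K_lam=0.0):
    return ew.LearnerParams(lam=K_lam, phi=np.full(J, 0.2), gam=np.zeros(J),
                            f=np.ones(J), beta=np.zeros((J, len(CUE_NAMES))))


class TestLogLikelihood:
    def test_matches_naive_replay_on_tiny_fixture(self, tiny_fixture, tiny_learner):
        cfg, bouts = tiny_fixture
        total, pw = ew.log_likelihood(bouts, cfg.roster, cfg.technique_set,
                                      tiny_learner, window_days=cfg.window_days)
        ot, opw = naive_log_likelihood(bouts, cfg.roster, cfg.technique_set,
                                       tiny_learner, cfg.window_days)
        assert np.max(np.abs(pw - opw)) < 1e-10
        assert total == pytest.approx(ot, abs=1e-10)

    def test_uniform_choice_limit(self, tiny_fixture):
        cfg, bouts = tiny_fixture
        J, K = len(cfg.roster), len(cfg.technique_set)
        total, pw = ew.log_likelihood(bouts, cfg.roster, cfg.technique_set,
                                      uniform_learner(J))
        assert total == pytest.approx(len(bouts) * math.log(1.0 / K), abs=1e-10)

    def test_pointwise_are_log_probabilities(self, tiny_fixture, tiny_learner):
        cfg, bouts = tiny_fixture
        total, pw = ew.log_likelihood(bouts, cfg.roster, cfg.technique_set,
                                      tiny_learner)
        assert np.all(np.exp(pw) > 0) and np.all(np.exp(pw) <= 1)
        assert total == pytest.approx(pw.sum())

    def test_social_cues_inert_when_gam_zero(self, tiny_fixture):
        """gam = 0: the social term must not touch the likelihood at all."""
        cfg, bouts = tiny_fixture
        J = len(cfg.roster)
        base = uniform_learner(J, K_lam=3.0)
        loud = replace(base)
        loud.beta = np.full((J, len(CUE_NAMES)), 5.0)
        loud.f = np.full(J, 3.0)
        t1, p1 = ew.log_likelihood(bouts, cfg.roster, cfg.technique_set, base)
        t2, p2 = ew.log_likelihood(bouts, cfg.roster, cfg.technique_set, loud)
        assert np.max(np.abs(p1 - p2)) < 1e-12

    def test_technique_relabelling_invariance(self, tiny_fixture, tiny_learner):
        cfg, bouts = tiny_fixture
        t1, _ = ew.log_likelihood(bouts, cfg.roster, cfg.technique_set, tiny_learner)
        perm_set = ew.TechniqueSet(tuple(reversed(cfg.technique_set.names)))
        t2, _ = ew.log_likelihood(bouts, cfg.roster, perm_set, tiny_learner)
        assert t1 == pytest.approx(t2, abs=1e-10)

    def test_unsorted_bouts_rejected(self, tiny_fixture, tiny_learner):
        cfg, bouts = tiny_fixture
        disordered = [bouts[1], bouts[0]] + bouts[2:]
        with pytest.raises(ValueError, match="sorted"):
            ew.log_likelihood(disordered, cfg.roster, cfg.technique_set, tiny_learner)

    def test_unknown_actor_rejected(self, tiny_fixture, tiny_learner):
        cfg, bouts = tiny_fixture
        rogue = ew.BoutRecord(day=99, seq=1, actor="ghost", technique="fast",
                              success=True, duration_s=30.0)
        with pytest.raises(KeyError):
            build_design(bouts + [rogue], cfg.roster, cfg.technique_set)

    def test_established_monoculture_approaches_certainty(self):
        """One technique, huge lam: late choices are nearly sure (log p -> 0-)."""
        roster = pd.DataFrame({"age_years": [5.0], "matriline": ["m"],
                               "alpha": [False]}, index=pd.Index(["j"], name="id"))
        techs = ew.TechniqueSet(("only", "never"))
        bouts = [ew.BoutRecord(day=d, seq=1, actor="j", technique="only",
                               success=True, duration_s=30.0)
                 for d in range(1, 31)]
        learner = ew.LearnerParams(lam=1e3, phi=np.array([0.3]), gam=np.zeros(1),
                                   f=np.ones(1), beta=np.zeros((1, 5)))
        _, pw = ew.log_likelihood(bouts, roster, techs, learner)
        assert -1e-6 < pw[-1] <= 0  # saturates to 0 at float precision


class TestModelSpecs:
    def test_canonical_set_has_nine_strategies(self):
        specs = canonical_specs()
        assert len(specs) == 9
        assert len({s.label for s in specs}) == 9
        g = [s for s in specs if s.label == "global"][0]
        assert g.social_learning and g.frequency_dependence and g.age_effects
        assert g.cues_active == CUE_NAMES
        ind = [s for s in specs if s.label == "individual-only"][0]
        assert not ind.social_learning and not ind.cues_active

    def test_cues_require_social_learning(self):
        with pytest.raises(ValueError):
            ModelSpec(label="bad", social_learning=False, cues_active=("pay",))

    def test_label_lookup(self):
        assert spec_by_label("cue-pay").cues_active == ("pay",)
        with pytest.raises(ValueError, match="global"):
            spec_by_label("not-a-model")

    def test_layout_parameter_inventory(self):
        ages = np.zeros(5)
        lay = ParamLayout(ModelSpec.individual_only(), ages, PriorSet())
        # log_lam, a_phi, log_sigma_phi, 5 z's
        assert lay.ndim == 3 + 5
        assert "a_gam" not in lay.names
        lay_g = ParamLayout(ModelSpec.global_model(varying_effects=("phi", "gam")),
                            ages, PriorSet())
        expected = 1 + (2 + 1 + 5) + (2 + 1 + 5) + 1 + 5  # lam, phi, gam, f, betas
        assert lay_g.ndim == expected

    def test_unpack_respects_ranges(self):
        ages = np.linspace(-1, 1, 4)
        lay = ParamLayout(ModelSpec.global_model(), ages, PriorSet())
        rng = np.random.default_rng(0)
        for theta in rng.normal(size=(20, lay.ndim)):
            lp = lay.unpack(theta)
            assert lp.lam >= 0
            assert np.all((lp.phi > 0) & (lp.phi < 1))
            assert np.all((lp.gam > 0) & (lp.gam < 1))
            assert np.all(lp.f > 0)


class TestPriors:
    def test_prior_predictive_away_from_boundaries(self):
        """Learning rates implied by the priors rarely pin to 0 or 1."""
        ages = np.zeros(8)
        lay = ParamLayout(ModelSpec.global_model(varying_effects=("phi", "gam")),
                          ages, PriorSet())
        rng = np.random.default_rng(42)
        draws = lay.prior_draw(2000, rng)
        phis = np.concatenate([lay.unpack(t).phi for t in draws])
        gams = np.concatenate([lay.unpack(t).gam for t in draws])
        for v in (phis, gams):
            assert np.mean((v > 0.01) & (v < 0.99)) > 0.98

    def test_log_prior_penalizes_distance(self):
        lay = ParamLayout(ModelSpec.individual_only(), np.zeros(3), PriorSet())
        center = np.where(lay._is_ls, 0.0, lay._mean)
        assert lay.log_prior(center) > lay.log_prior(center + 3.0)


class TestFitModel:
    @pytest.fixture(scope="class")
    def tiny_fit(self, tiny_fixture):
        cfg, bouts = tiny_fixture
        spec = ModelSpec.single_cue("pay", window_days=cfg.window_days)
        mcmc = MCMCConfig(iterations=400, warmup=150, seed=7, max_draws=200)
        return ew.fit_model(bouts, cfg.roster, cfg.technique_set, spec, mcmc=mcmc)

    def test_draw_and_pointwise_shapes(self, tiny_fit, tiny_fixture):
        _, bouts = tiny_fixture
        assert tiny_fit.pointwise_loglik.shape == (len(tiny_fit.draws), len(bouts))
        assert not np.isnan(tiny_fit.pointwise_loglik).any()
        assert tiny_fit.n_points == len(bouts)

    def test_population_draws_within_ranges(self, tiny_fit):
        pop = tiny_fit.population_draws()
        assert np.all(pop["lam"] >= 0)
        assert np.all((pop["phi_mean"] > 0) & (pop["phi_mean"] < 1))
        assert np.all((pop["gam_mean"] > 0) & (pop["gam_mean"] < 1))

    def test_refit_same_seed_reproduces_draws(self, tiny_fit, tiny_fixture):
        cfg, bouts = tiny_fixture
        again = ew.fit_model(bouts, cfg.roster, cfg.technique_set, tiny_fit.spec,
                             mcmc=MCMCConfig(iterations=400, warmup=150, seed=7,
                                             max_draws=200))
        pd.testing.assert_frame_equal(tiny_fit.draws, again.draws)

    def test_diagnostics_present(self, tiny_fit):
        for key in ("max_rhat", "min_ess", "mean_acceptance", "converged"):
            assert key in tiny_fit.diagnostics


class TestRecover:
    def test_zero_replicates_gives_empty_report(self, tiny_fixture):
        cfg, _ = tiny_fixture
        report = ew.recover(cfg, ModelSpec.individual_only(), 0)
        assert len(report) == 0
        assert "coverage" in report.columns

    def test_single_replicate_report_structure(self, tiny_fixture):
        cfg, _ = tiny_fixture
        spec = ModelSpec.single_cue("pay", window_days=cfg.window_days)
        report = ew.recover(cfg, spec, 1, seeds=[5],
                            mcmc=MCMCConfig(iterations=300, warmup=100,
                                            max_draws=150))
        assert set(report["parameter"]) == {"lam", "phi_mean", "gam_mean", "b_pay"}
        assert report["coverage"].between(0, 1).all()
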
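import itertools

import numpy as np
import pytest
from scipy import optimize, stats
from scipy.special import expit, logit

from trfpathway import (
    DiseaseModel,
    EffectModelSpec,
    ForestConfig,
    LdBlockModel,
    ScenarioSpec,
    penetrance,
    run_experiment,
    simulate_case_control,
    simulate_genotypes,
    solve_alpha,
)
from trfpathway.sim import build_panel, disease_model_for
from trfpathway.setbased import pairwise_r2_matrix


def _model(alpha=0.0, beta=(0,) * 7, mafs=(0.25, 0.15, 0.15), prevalence=0.01,
           beta_extra=None, loci=(0, 1, 2)):
    return DiseaseModel(
        causal_snp_indices=tuple(loci), causal_mafs=tuple(mafs), alpha=alpha,
        beta=tuple(beta), prevalence=prevalence, beta_extra=beta_extra,
    )


class TestPenetrance:
    def test_all_zero_parameters_give_half(self):
        m = _model()
        for x in itertools.product((0, 1), repeat=3):
            assert penetrance(np.array(x), m) == pytest.approx(0.5)

    def test_zero_effects_give_expit_alpha_everywhere(self):
        m = _model(alpha=logit(0.01))
        for x in itertools.product((0, 1), repeat=3):
            assert penetrance(np.array(x), m) == pytest.approx(0.01)

    def test_main_effects_model_log_odds_difference(self):
        # three carriers vs none under main effects 0.92 each: 3 * 0.92 = 2.76
        m = _model(beta=(0.92, 0.92, 0.92, 0, 0, 0, 0))
        lo = lambda x: logit(penetrance(np.array(x), m))
        assert lo((1, 1, 1)) - lo((0, 0, 0)) == pytest.approx(2.76)

    def test_multiplicative_scheme_interaction_terms(self):
        phi = 0.22
        betas = EffectModelSpec.preset("M3").betas()
        m = _model(beta=betas)
        lo = lambda x: logit(penetrance(np.array(x), m))
        # two carriers: phi + phi + 2 phi; three: 3 phi + 3*2 phi + 3 phi
        assert lo((1, 1, 0)) - lo((0, 0, 0)) == pytest.approx(4 * phi)
        assert lo((1, 1, 1)) - lo((0, 0, 0)) == pytest.approx(12 * phi)

    def test_fourth_locus_main_effect(self):
        m = _model(beta=(0,) * 7, beta_extra=0.5, loci=(0, 1, 2, 3),
                   mafs=(0.25, 0.15, 0.15, 0.25))
        lo = lambda x: logit(penetrance(np.array(x), m))
        assert lo((0, 0, 0, 1)) - lo((0, 0, 0, 0)) == pytest.approx(0.5)


def _oracle_alpha(betas, mafs, prevalence, beta_extra=None):
    """Independent enumeration oracle for the prevalence-matching intercept."""
    q = [1 - (1 - f) ** 2 for f in mafs]
    L = len(mafs)

    def prev(a):
        total = 0.0
        for x in itertools.product((0, 1), repeat=L):
            w = 1.0
            for xi, qi in zip(x, q):
                w *= qi if xi else 1 - qi
            eta = (betas[0] * x[0] + betas[1] * x[1] + betas[2] * x[2]
                   + betas[3] * x[0] * x[1] + betas[4] * x[0] * x[2]
                   + betas[5] * x[1] * x[2] + betas[6] * x[0] * x[1] * x[2])
            if L == 4:
                eta += beta_extra * x[3]
            total += w * expit(a + eta)
        return total - prevalence

    return optimize.bisect(prev, -50, 50, xtol=1e-12)


class TestSolveAlpha:
    def test_null_model_closed_form(self):
        a = solve_alpha((0,) * 7, (0.25, 0.15, 0.15), 0.01)
        assert a == pytest.approx(logit(0.01), abs=1e-8)
        assert a == pytest.approx(-4.59512, abs=1e-5)

    @pytest.mark.parametrize("model_name", ["M1", "M2", "M3", "M4"])
    def test_agrees_with_enumeration_oracle(self, model_name):
        betas = EffectModelSpec.preset(model_name).betas()
        got = solve_alpha(betas, (0.25, 0.15, 0.15), 0.01)
        assert got == pytest.approx(
            _oracle_alpha(betas, (0.25, 0.15, 0.15), 0.01), abs=1e-8
        )

    def test_four_locus_variant_agrees_with_oracle(self):
        betas = EffectModelSpec.preset("M4").betas()
        got = solve_alpha(betas, (0.25, 0.15, 0.15, 0.25), 0.01, beta_extra=0.26)
        assert got == pytest.approx(
            _oracle_alpha(betas, (0.25, 0.15, 0.15, 0.25), 0.01, 0.26), abs=1e-8
        )

    def test_higher_prevalence_needs_larger_intercept(self):
        betas = EffectModelSpec.preset("M1").betas()
        a1 = solve_alpha(betas, (0.25, 0.15, 0.15), 0.01)
        a5 = solve_alpha(betas, (0.25, 0.15, 0.15), 0.05)
        assert a5 > a1

    def test_monte_carlo_prevalence_roundtrip(self):
        """Population prevalence implied by the solved intercept matches the
        target when carriers are drawn directly from HWE probabilities."""
        betas = EffectModelSpec.preset("M3").betas()
        mafs = (0.25, 0.15, 0.15)
        model = _model(alpha=solve_alpha(betas, mafs, 0.01), beta=betas, mafs=mafs)
        rng = np.random.default_rng(123)
        q = 1 - (1 - np.array(mafs)) ** 2
        X = (rng.random((1_000_000, 3)) < q).astype(float)
        assert penetrance(X, model).mean() == pytest.approx(0.01, abs=0.002)


class TestLdBlockGenotypes:
    def test_independent_snps_have_negligible_r2(self):
        ld = LdBlockModel(n_snps=40, block_sizes=(40,), within_block_rho=0.0, seed=1)
        G = simulate_genotypes(2000, ld, seed=2)
        r2 = pairwise_r2_matrix(G)
        off = r2[~np.eye(40, dtype=bool)]
        assert off.mean() < 0.01

    def test_high_rho_block_produces_strong_ld(self):
        ld = LdBlockModel(n_snps=10, block_sizes=(10,), within_block_rho=0.9,
                          mafs=np.full(10, 0.3), seed=3)
        G = simulate_genotypes(2000, ld, seed=4)
        r2 = pairwise_r2_matrix(G)
        assert r2[~np.eye(10, dtype=bool)].mean() > 0.4

    def test_between_block_independence(self):
        ld = LdBlockModel(n_snps=20, block_sizes=(10, 10), within_block_rho=0.9, seed=5)
        G = simulate_genotypes(2000, ld, seed=6)
        r2 = pairwise_r2_matrix(G)
        cross = r2[:10, 10:]
        assert cross.mean() < 0.01

    def test_realized_maf_concentrates_on_target(self):
        ld = LdBlockModel(
            n_snps=6, block_sizes=(6,), within_block_rho=0.7,
            mafs=np.full(6, 0.25), seed=7,
        )
        G = simulate_genotypes(5000, ld, seed=8)
        maf = G.mean(axis=0) / 2
        assert ((maf >= 0.23) & (maf <= 0.27)).all()

    def test_block_sizes_must_partition(self):
        with pytest.raises(ValueError, match="sum to n_snps"):
            LdBlockModel(n_snps=10, block_sizes=(4, 4))


class TestScenarioAndEffectSpecs:
    def test_full_scale_presets_match_study_design(self):
        s1 = ScenarioSpec.preset("S1")
        assert (s1.n_cases, s1.n_controls, s1.n_genes, s1.n_snps) == (1000, 1000, 50, 1038)
        assert s1.prevalence == 0.01
        assert s1.causal_mafs == (0.25, 0.15, 0.15)
        assert ScenarioSpec.preset("S2").n_cases == 500
        assert ScenarioSpec.preset("S3").prevalence == 0.05
        s4 = ScenarioSpec.preset("S4")
        assert (s4.n_genes, s4.n_snps) == (100, 1527)
        assert s4.causal_mafs[3] == 0.25

    def test_multiplicative_phi_scheme(self):
        for name, phi in (("M2", 0.18), ("M3", 0.22), ("M4", 0.26)):
            spec = EffectModelSpec.preset(name)
            assert spec.betas() == (phi,) * 3 + (2 * phi,) * 3 + (3 * phi,)
            assert spec.beta_extra() == phi
        assert EffectModelSpec.preset("M1").betas()[:3] == (0.92,) * 3
        assert EffectModelSpec.preset("null").betas() == (0.0,) * 7

    def test_panel_places_causal_loci_in_distinct_blocks(self):
        spec = ScenarioSpec.preset("S4").scaled(50, 50, 10, 80)
        ld, causal = build_panel(spec, seed=0)
        assert len(causal) == 4
        edges = np.concatenate([[0], np.cumsum(ld.block_sizes)])
        blocks = [int(np.searchsorted(edges, c, side="right") - 1) for c in causal]
        assert len(set(blocks)) == 4
        mafs = ld.snp_mafs()
        assert [mafs[c] for c in causal] == list(spec.causal_mafs)


class TestSimulateCaseControl:
    def test_exact_quotas_small_null(self):
        spec = ScenarioSpec.preset("S1").scaled(10, 10, 3, 12)
        m = simulate_case_control(spec, EffectModelSpec.preset("null"), seed=0)
        assert int(m.phenotype.sum()) == 10
        assert m.n_samples == 20
        assert m.n_snps == 12

    def test_null_effects_leave_causal_loci_balanced(self):
        """Under all-zero effects, case and control genotype distributions at
        the designated loci coincide (checked at 0.001 over fixed seeds)."""
        spec = ScenarioSpec.preset("S1").scaled(150, 150, 4, 24)
        ld, causal = build_panel(spec, seed=1)
        null = EffectModelSpec.preset("null")
        for seed in range(20):
            m = simulate_case_control(spec, null, ld=ld, seed=seed)
            for locus in causal:
                carrier = (m.dosages[:, locus] > 0).astype(int)
                table = [
                    [int(carrier[m.phenotype == 1].sum()),
                     int((1 - carrier[m.phenotype == 1]).sum())],
                    [int(carrier[m.phenotype == 0].sum()),
                     int((1 - carrier[m.phenotype == 0]).sum())],
                ]
                if min(min(row) for row in table) == 0:
                    continue
                p = stats.chi2_contingency(table, correction=False).pvalue
                assert p > 0.001

    def test_risk_model_enriches_carriers_in_cases(self):
        spec = ScenarioSpec.preset("S1").scaled(500, 500, 4, 24)
        ld, causal = build_panel(spec, seed=2)
        m = simulate_case_control(spec, EffectModelSpec.preset("M4"), ld=ld, seed=3)
        for locus in causal:
            carrier = m.dosages[:, locus] > 0
            f_case = carrier[m.phenotype == 1].mean()
            f_ctrl = carrier[m.phenotype == 0].mean()
            assert f_case > f_ctrl


class TestRunExperiment:
    def test_level_one_rejects_everything_and_reruns_identically(self):
        spec = ScenarioSpec.preset("S1").scaled(15, 15, 3, 12)
        kw = dict(
            n_replicates=5, alpha_levels=(0.05, 1.0), K=9, seed=42,
            forest=ForestConfig(n_trees=15),
        )
        a = run_experiment(spec, EffectModelSpec.preset("null"), "trf", **kw)
        b = run_experiment(spec, EffectModelSpec.preset("null"), "trf", **kw)
        at_one = a.table[a.table["level"] == 1.0].iloc[0]
        assert at_one["rejection_rate"] == 1.0
        assert a.table.equals(b.table)
        assert np.array_equal(a.p_values, b.p_values)
        assert a.provenance["seed"] == 42

    def test_ci_brackets_rate(self):
        spec = ScenarioSpec.preset("S1").scaled(15, 15, 3, 12)
        res = run_experiment(
            spec, EffectModelSpec.preset("null"), "setbased",
            n_replicates=8, K=19, seed=1,
        )
        row = res.table.iloc[0]
        assert row["ci_low"] <= row["rejection_rate"] <= row["ci_high"]
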
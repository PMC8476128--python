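"""Competitive regression vs normal-equations oracles, conditioning, BH, power."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from conftest import ols_oracle
from orgenrich.competitive import (
    bh_threshold,
    condition_on_constraint,
    geneset_regression,
    subsample_power,
)
from orgenrich.errors import DegenerateDesignError, InvalidConfigError
from orgenrich.genesets import GeneSet
from orgenrich.simulate import SimConfig, gen_gene_stats


def make_inputs(n=12, seed=0, member_frac=0.5, beta_member=1.0):
    rng = np.random.default_rng(seed)
    genes = [f"g{i:02d}" for i in range(n)]
    member = np.zeros(n)
    member[: int(n * member_frac)] = 1.0
    cov = pd.DataFrame(
        {
            "length": rng.lognormal(2, 0.5, n),  # kb scale keeps the design well conditioned
            "snp_density": rng.lognormal(0, 0.3, n),
            "inv_mac": rng.uniform(0.001, 0.5, n),
        },
        index=pd.Index(genes, name="gene"),
    )
    z = beta_member * member + rng.standard_normal(n)
    stats_df = pd.DataFrame({"gene": genes, "trait": "t", "z": z})
    return stats_df, GeneSet("set", frozenset(np.array(genes)[member == 1])), cov, member


def design_matrix(stats_df, cov, member):
    raw = cov.loc[stats_df["gene"]].to_numpy()
    return np.column_stack([np.ones(len(stats_df)), member, raw, np.log(raw)])


class TestGenesetRegression:
    def test_matches_normal_equations_oracle(self):
        stats_df, gs, cov, member = make_inputs(n=12, seed=1)
        res = geneset_regression(stats_df, gs, cov)
        X = design_matrix(stats_df, cov, member)
        beta, se, dof = ols_oracle(X, stats_df["z"].to_numpy())
        assert res.beta == pytest.approx(beta[1], abs=1e-10)
        assert res.se == pytest.approx(se[1], abs=1e-10)
        assert res.p_one_sided == pytest.approx(float(sps.t.sf(beta[1] / se[1], dof)), abs=1e-10)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), n=st.integers(12, 60))
    def test_oracle_property_random_designs(self, seed, n):
        stats_df, gs, cov, member = make_inputs(n=n, seed=seed, beta_member=0.3)
        res = geneset_regression(stats_df, gs, cov)
        beta, se, _ = ols_oracle(design_matrix(stats_df, cov, member), stats_df["z"].to_numpy())
        assert res.beta == pytest.approx(beta[1], abs=1e-10)
        assert res.se == pytest.approx(se[1], abs=1e-10)

    def test_constant_membership_rejected(self):
        stats_df, _, cov, _ = make_inputs()
        with pytest.raises(DegenerateDesignError):
            geneset_regression(stats_df, GeneSet("all", frozenset(stats_df["gene"])), cov)

    def test_collinear_design_named(self):
        stats_df, gs, cov, _ = make_inputs(n=20, seed=2)
        cov = cov.copy()
        cov["snp_density"] = cov["length"] * 2.0  # collinear after log transform
        with pytest.raises(DegenerateDesignError, match="length"):
            geneset_regression(stats_df, gs, cov)

    def test_control_superset_restricts_background(self):
        stats_df, gs, cov, member = make_inputs(n=40, seed=3)
        superset = GeneSet("sup", frozenset(stats_df["gene"][:30]))
        res = geneset_regression(stats_df, gs, cov, control_superset=superset)
        assert res.n_genes == 30

    def test_irrelevant_covariate_keeps_sign_on_noiseless_data(self):
        stats_df, gs, cov, member = make_inputs(n=30, seed=4)
        stats_df = stats_df.assign(z=2.0 * member)  # noiseless planted effect
        base = geneset_regression(stats_df, gs, cov)
        superset = GeneSet("sup", frozenset(stats_df["gene"][:25]))
        with_cov = geneset_regression(stats_df, gs, cov, control_superset=superset,
                                      superset_mode="covariate")
        assert np.sign(base.beta) == np.sign(with_cov.beta) == 1.0


class TestConditionOnConstraint:
    def test_orthogonal_loeuf_is_noop(self):
        stats_df, gs, cov, member = make_inputs(n=20, seed=5)
        # identical loeuf pattern inside and outside the set -> exactly orthogonal
        pattern = np.tile([0.2, 0.5, 0.8, 1.1, 1.4], 4)
        loeuf = pd.Series(pattern, index=stats_df["gene"].to_numpy())
        plain = geneset_regression(stats_df, gs, cov)
        cond = condition_on_constraint(stats_df, gs, cov, loeuf)
        assert cond.beta == pytest.approx(plain.beta, abs=1e-8)
        assert cond.se == pytest.approx(plain.se, abs=1e-8)
        assert cond.p_one_sided == pytest.approx(plain.p_one_sided, abs=1e-8)

    def test_constraint_mediated_signal_attenuated(self):
        """z driven by LOEUF only; a low-LOEUF set shows weaker conditioned enrichment."""
        wins = 0
        for rep in range(40):
            rng = np.random.default_rng(rep)
            n = 400
            genes = [f"g{i:03d}" for i in range(n)]
            loeuf_vals = rng.uniform(0.05, 2.0, n)
            members = np.array(genes)[np.argsort(loeuf_vals)[: n // 5]]  # most constrained fifth
            z = -1.2 * (loeuf_vals - loeuf_vals.mean()) + rng.standard_normal(n)
            cov = pd.DataFrame(
                {"length": rng.lognormal(10, 0.5, n), "snp_density": rng.lognormal(0, 0.3, n),
                 "inv_mac": rng.uniform(0.001, 0.5, n)},
                index=pd.Index(genes, name="gene"))
            stats_df = pd.DataFrame({"gene": genes, "trait": "t", "z": z})
            gs = GeneSet("constrained", frozenset(members))
            loeuf = pd.Series(loeuf_vals, index=genes)
            plain = geneset_regression(stats_df, gs, cov)
            cond = condition_on_constraint(stats_df, gs, cov, loeuf)
            wins += cond.p_one_sided > plain.p_one_sided
        assert wins > 30

    def test_nonpositive_loeuf_dropped_and_counted(self):
        stats_df, gs, cov, _ = make_inputs(n=20, seed=6)
        loeuf = pd.Series(np.linspace(0.1, 1.9, 20), index=stats_df["gene"].to_numpy())
        loeuf.iloc[3] = 0.0
        loeuf.iloc[7] = np.nan
        res = condition_on_constraint(stats_df, gs, cov, loeuf)
        assert res.n_dropped == 2
        assert res.n_genes == 18


class TestBhThreshold:
    def test_step_up_by_hand(self):
        out = bh_threshold([0.01, 0.02, 0.04, 0.9], fdr=0.1)
        assert out["significant"].tolist() == [True, True, True, False]

    def test_all_ones_no_discoveries(self):
        assert not bh_threshold([1.0, 1.0, 1.0], fdr=0.1)["significant"].any()

    def test_single_p_at_half_fdr(self):
        assert bh_threshold([0.05], fdr=0.1)["significant"].all()

    def test_empty_input(self):
        assert bh_threshold([], fdr=0.1).empty


class TestSubsamplePower:
    def test_size_exceeding_source_rejected(self):
        stats_df, gs, cov, _ = make_inputs(n=30)
        with pytest.raises(InvalidConfigError):
            subsample_power(stats_df, gs, cov, sizes=(200,), n_trials=2)

    def test_null_power_near_alpha(self, genes_small, covariates_small):
        """With no planted shift, mean power over datasets stays near alpha.

        Trials within one dataset share the same gene Z draw, so power is
        averaged over independent replicate datasets.
        """
        source = GeneSet("src", frozenset(genes_small["gene"][:300]))
        powers = []
        for rep in range(20):
            cfg = SimConfig(seed=500 + rep, n_genes=600, enrichment_delta=0.0)
            stats_df = gen_gene_stats(cfg, list(source.members), genes_small)
            out = subsample_power(stats_df, source, covariates_small, sizes=(60,),
                                  n_trials=30, alpha=0.05, seed=rep)
            powers.append(out.loc[0, "power"])
        assert np.mean(powers) == pytest.approx(0.05, abs=0.04)

    def test_power_increases_with_size_at_small_delta(self, covariates_small, genes_small):
        """In the responsive regime, larger subsamples give clearly higher power."""
        cfg = SimConfig(seed=43, n_genes=600, enrichment_delta=0.12)
        source = GeneSet("src", frozenset(genes_small["gene"]))
        stats_df = gen_gene_stats(cfg, list(genes_small["gene"]), genes_small)
        # every analyzed gene carries the shift; power grows with subsample size
        out = subsample_power(stats_df, GeneSet("src", frozenset(genes_small["gene"][:550])),
                              covariates_small, sizes=(40, 300), n_trials=150, seed=2)
        assert out.loc[1, "power"] > out.loc[0, "power"]

    def test_full_size_degenerate(self, genes_small, covariates_small):
        cfg = SimConfig(seed=44, n_genes=600, enrichment_delta=0.0)
        source = GeneSet("src", frozenset(genes_small["gene"][:100]))
        stats_df = gen_gene_stats(cfg, list(source.members), genes_small)
        out = subsample_power(stats_df, source, covariates_small, sizes=(100,), n_trials=5, seed=3)
        assert out.loc[0, "power"] in (0.0, 1.0)
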
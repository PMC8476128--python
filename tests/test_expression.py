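"""Tau formula, nadir thresholding, representative tissues, eQTL landscape."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from conftest import ols_oracle
from orgenrich.errors import DegenerateDesignError, InvalidConfigError
from orgenrich.expression import (
    compute_tau,
    count_landscape,
    eqtl_regression,
    find_tau_threshold,
    select_representative_tissues,
    tissue_expressed_sets,
)
from orgenrich.genesets import GeneSet
from orgenrich.simulate import SimConfig, gen_eqtl_landscape, gen_expression, gen_gene_table


def expr_frame(rows, tissues=None):
    rows = np.atleast_2d(np.asarray(rows, dtype=float))
    tissues = tissues or [f"t{i}" for i in range(rows.shape[1])]
    return pd.DataFrame(rows, index=[f"g{i}" for i in range(rows.shape[0])], columns=tissues)


class TestComputeTau:
    @pytest.mark.parametrize(
        "vec,expected",
        [
            ([5.0, 5.0, 5.0, 5.0], 0.0),       # uniform
            ([9.0, 0.0, 0.0], 1.0),            # one-hot
            ([8.0, 2.0, 0.0], 0.875),          # hand evaluation
        ],
    )
    def test_formula_values(self, vec, expected):
        assert compute_tau(expr_frame([vec])).iloc[0] == pytest.approx(expected, abs=1e-12)

    def test_low_expression_filtered(self):
        tau = compute_tau(expr_frame([[0.5, 0.2, 0.0], [0.0, 0.0, 0.0]]), min_max_tpm=1.0)
        assert tau.isna().all()

    def test_single_tissue_rejected(self):
        with pytest.raises(InvalidConfigError):
            compute_tau(expr_frame([[1.0]]))

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(scale=st.floats(0.1, 100.0), seed=st.integers(0, 999))
    def test_scale_invariance(self, scale, seed):
        rng = np.random.default_rng(seed)
        vec = rng.uniform(1.0, 50.0, size=6)
        t1 = compute_tau(expr_frame([vec])).iloc[0]
        t2 = compute_tau(expr_frame([vec * scale])).iloc[0]
        assert t1 == pytest.approx(t2, abs=1e-10)

    def test_monotone_in_concentration(self):
        base = np.array([10.0, 5.0, 3.0, 2.0])
        t0 = compute_tau(expr_frame([base])).iloc[0]
        moved = base + np.array([2.0, 0.0, 0.0, -2.0])  # mass toward the max tissue
        t1 = compute_tau(expr_frame([moved])).iloc[0]
        assert t1 >= t0


class TestTauThreshold:
    def test_bimodal_mixture_nadir(self):
        rng = np.random.default_rng(0)
        vals = np.concatenate([
            np.clip(rng.normal(0.2, 0.07, 2000), 0, 1),
            np.clip(rng.normal(0.9, 0.05, 1000), 0, 1),
        ])
        assert 0.4 <= find_tau_threshold(vals) <= 0.7

    def test_degenerate_input_falls_back(self):
        with pytest.warns(UserWarning):
            assert find_tau_threshold(np.full(200, 0.5)) == 0.76

    def test_synthetic_expression_recovers_nadir(self, cfg_small, genes_small):
        expr, _ = gen_expression(cfg_small, 0.35, genes_small)
        tau = compute_tau(expr)
        thr = find_tau_threshold(tau)
        broad_mode = tau[tau < 0.5].median()
        specific_mode = tau[tau > 0.5].median()
        assert broad_mode < thr < specific_mode

    def test_too_few_values_rejected(self):
        with pytest.raises(InvalidConfigError):
            find_tau_threshold(np.linspace(0, 1, 50))


class TestRepresentativeTissues:
    def test_single_tissue_classes_kept(self):
        expr = expr_frame([[1, 2, 3]], tissues=["a", "b", "c"])
        cmap = {"a": "ca", "b": "cb", "c": "cc"}
        assert select_representative_tissues(expr, cmap) == ["a", "b", "c"]

    def test_chosen_collapses_subtypes(self):
        tissues = [f"brain_{i}" for i in range(13)] + ["liver"]
        expr = expr_frame([list(range(14))], tissues=tissues)
        cmap = {t: "brain" for t in tissues[:13]} | {"liver": "liver"}
        kept = select_representative_tissues(expr, cmap, chosen={"brain": "brain_7"})
        assert kept == ["brain_7", "liver"]

    def test_wrong_class_choice_rejected(self):
        expr = expr_frame([[1, 2]], tissues=["a", "b"])
        with pytest.raises(InvalidConfigError):
            select_representative_tissues(expr, {"a": "ca", "b": "cb"}, chosen={"ca": "b"})

    def test_dedup_lowers_tau_for_duplicated_subtypes(self):
        # a gene expressed in one class whose subtypes are duplicated
        tissues = ["brain_1", "brain_2", "brain_3", "liver", "muscle"]
        expr = expr_frame([[50, 50, 50, 1, 1]], tissues=tissues)
        cmap = {t: "brain" for t in tissues[:3]} | {"liver": "liver", "muscle": "muscle"}
        tau_dup = compute_tau(expr).iloc[0]
        kept = select_representative_tissues(expr, cmap)
        tau_dedup = compute_tau(expr[kept]).iloc[0]
        assert tau_dedup >= tau_dup


class TestTissueExpressedSets:
    def test_top_fraction_single_gene(self):
        t = pd.DataFrame({"liver": np.arange(10)}, index=[f"g{i}" for i in range(10)])
        out = tissue_expressed_sets(t, 0.1)
        assert out["liver"].members == frozenset({"g9"})

    def test_top_fraction_one_keeps_all(self):
        t = pd.DataFrame({"liver": np.arange(10)}, index=[f"g{i}" for i in range(10)])
        assert len(tissue_expressed_sets(t, 1.0)["liver"]) == 10

    def test_invalid_fraction(self):
        t = pd.DataFrame({"liver": [1.0, 2.0]}, index=["a", "b"])
        with pytest.raises(InvalidConfigError):
            tissue_expressed_sets(t, 0.0)

    def test_ceiling_and_tie_break(self):
        t = pd.DataFrame({"x": [5, 5, 5, 1]}, index=["gd", "gb", "ga", "gc"])
        out = tissue_expressed_sets(t, 0.5)  # ceil(2) = 2; ties by identifier
        assert out["x"].members == frozenset({"ga", "gb"})

    def test_recovers_planted_specific_genes(self, cfg_small, genes_small):
        expr, _ = gen_expression(cfg_small, 0.2, genes_small)
        # t-like statistic: standardized within-gene deviation per tissue
        z = expr.sub(expr.mean(axis=1), axis=0).div(expr.std(axis=1) + 1e-9, axis=0)
        tissue = expr.columns[0]
        top = tissue_expressed_sets(z, 0.1)[tissue].members
        tau = compute_tau(expr)
        specific_here = set(expr.index[(tau > 0.8) & (expr[tissue] > 5.0)])
        assert len(specific_here & top) / max(len(specific_here), 1) > 0.9


class TestCountLandscape:
    def test_threshold_rules_strict(self):
        qv = pd.DataFrame([[0.01, 0.04, 0.2, 0.05]], index=["g0"], columns=list("abcd"))
        expr = expr_frame([[5.0, 6.0, 100.0, 0.0]], tissues=list("abcd"))
        out = count_landscape(qv, expr)
        assert out.loc[0, "n_eqtl"] == 2       # q < 0.05 strictly
        assert out.loc[0, "n_express"] == 2    # tpm > 5 strictly

    def test_representative_subset(self):
        qv = pd.DataFrame([[0.01, 0.01, 0.2]], index=["g0"], columns=list("abc"))
        expr = expr_frame([[10.0, 10.0, 10.0]], tissues=list("abc"))
        out = count_landscape(qv, expr, representative=["a", "c"])
        assert out.loc[0, "n_eqtl"] == 1 and out.loc[0, "n_express"] == 2


class TestEqtlRegression:
    def landscape(self, n=60, seed=0, effect=0.0):
        rng = np.random.default_rng(seed)
        genes = [f"g{i:02d}" for i in range(n)]
        member = np.zeros(n)
        member[: n // 3] = 1
        n_express = rng.integers(5, 40, n).astype(float)
        tau = rng.uniform(0.05, 0.95, n)
        n_eqtl = 2 + 0.4 * n_express - 2 * tau + effect * member + rng.standard_normal(n)
        df = pd.DataFrame({"gene": genes, "n_eqtl": n_eqtl, "n_express": n_express, "tau": tau})
        length = pd.Series(rng.lognormal(2, 0.4, n), index=genes)
        return df, GeneSet("org", frozenset(np.array(genes)[member == 1])), length, member

    def test_matches_normal_equations_oracle(self):
        df, org, length, member = self.landscape(seed=1, effect=1.5)
        res = eqtl_regression(df, org, length)
        X = np.column_stack([np.ones(len(df)), member, df["n_express"], df["tau"],
                             np.log(length.to_numpy()), length.to_numpy()])
        beta, se, _ = ols_oracle(X, df["n_eqtl"].to_numpy())
        assert res["beta"] == pytest.approx(beta[1], abs=1e-10)
        assert res["se"] == pytest.approx(se[1], abs=1e-10)

    def test_constant_response_gives_null(self):
        df, org, length, _ = self.landscape(seed=2)
        df["n_eqtl"] = 7.0
        res = eqtl_regression(df, org, length)
        assert res["beta"] == pytest.approx(0.0, abs=1e-8) and res["p"] == 1.0

    def test_empty_set_rejected(self):
        df, _, length, _ = self.landscape()
        with pytest.raises(DegenerateDesignError):
            eqtl_regression(df, GeneSet("none", frozenset()), length)

    def test_planted_effect_recovered(self):
        cfg = SimConfig(seed=21, n_genes=3000)
        genes = gen_gene_table(cfg)
        org = list(genes["gene"][:400])
        hits = 0
        for rep in range(10):
            cfg_r = SimConfig(seed=600 + rep, n_genes=3000)
            land = gen_eqtl_landscape(cfg_r, org, effect=2.0, genes=genes)
            res = eqtl_regression(land, frozenset(org), genes.set_index("gene")["length"])
            hits += abs(res["beta"] - 2.0) < 2.5 * res["se"]
        assert hits >= 8

    def test_null_type_one_controlled(self):
        cfg = SimConfig(seed=22, n_genes=2000)
        genes = gen_gene_table(cfg)
        org = list(genes["gene"][:300])
        rejections = 0
        for rep in range(60):
            cfg_r = SimConfig(seed=700 + rep, n_genes=2000)
            land = gen_eqtl_landscape(cfg_r, org, effect=0.0, genes=genes)
            res = eqtl_regression(land, frozenset(org), genes.set_index("gene")["length"])
            rejections += res["p"] < 0.05
        assert rejections / 60 <= 0.12
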
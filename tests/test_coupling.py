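"""Per-gene burdens, expression quartiles, and Spearman coupling tests."""
import numpy as np
import pandas as pd
import pytest

from rsmutscape import (
    CouplingFilterError,
    RsMutError,
    SampleLabel,
    coupling_test,
    expressed_variant_count,
    expression_quartiles,
    gene_profiles,
    per_gene_counts,
    recovery_coupling,
    spearman,
)
from rsmutscape.annotate import AnnotatedVariant
from _oracles import brute_force_spearman
from conftest import make_record


def _ann(gene_id, n, category="exonic", pos0=1):
    tier = "tier2" if gene_id is None else "tier1"
    cat = "intergenic" if gene_id is None else category
    return [
        AnnotatedVariant(make_record(pos=pos0 + i), cat, tier, gene_id) for i in range(n)
    ]


def _expr(fpkms, condition="HU4h"):
    return pd.DataFrame(
        {
            "gene_id": [f"G{i:04d}" for i in range(len(fpkms))],
            "condition": condition,
            "fpkm": fpkms,
        }
    )


class TestPerGeneCounts:
    def test_counts_tier1_only(self):
        ann = _ann("G1", 3) + _ann(None, 1, pos0=500)
        counts = per_gene_counts(ann)
        assert counts.to_dict() == {"G1": 3}

    def test_zero_filled_universe(self):
        counts = per_gene_counts([], gene_universe=[f"G{i}" for i in range(10)])
        assert len(counts) == 10
        assert (counts == 0).all()

    def test_sum_equals_tier1_count(self):
        ann = _ann("G1", 3) + _ann("G2", 4, pos0=100) + _ann(None, 5, pos0=900)
        assert per_gene_counts(ann).sum() == 7


class TestExpressionQuartiles:
    def test_four_genes_one_per_quartile(self):
        q = expression_quartiles(_expr([1.0, 2.0, 3.0, 4.0]), "HU4h")
        assert list(q) == ["Q1", "Q2", "Q3", "Q4"]

    def test_all_tied_collapse_to_q1(self):
        q = expression_quartiles(_expr([5.0] * 8), "HU4h")
        assert set(q) == {"Q1"}

    def test_quartile_sizes_on_continuous_fpkm(self):
        rng = np.random.default_rng(0)
        q = expression_quartiles(_expr(rng.lognormal(1, 1, 10_000)), "HU4h")
        assert (q == "Q4").sum() == 2500

    def test_too_few_genes_raise(self):
        with pytest.raises(RsMutError):
            expression_quartiles(_expr([1.0, 2.0, 3.0]), "HU4h")


class TestSpearman:
    def test_perfect_monotonicity(self):
        fpkm = np.linspace(1, 100, 20)
        profiles = pd.DataFrame(
            {
                "gene_id": [f"G{i}" for i in range(20)],
                "fpkm": fpkm,
                "mut_count_treated": np.arange(1, 21) * 2,
                "mut_count_control": 0,
                "delta": np.arange(1, 21) * 2,
                "quartile": "Q4",
            }
        )
        res = coupling_test(profiles, quartile="Q4", use_delta_filter=False)
        assert res.rho == pytest.approx(1.0)

    def test_matches_exact_permutation_oracle(self):
        rng = np.random.default_rng(5)
        for n in (5, 6, 7):
            for _ in range(3):
                x = rng.normal(size=n)
                y = rng.normal(size=n)
                rho, p = spearman(x, y)
                rho_o, p_o = brute_force_spearman(x, y)
                assert rho == pytest.approx(rho_o, abs=1e-12)
                assert p == pytest.approx(p_o, abs=1e-12)

    def test_ties_match_oracle(self):
        x = np.array([1.0, 1.0, 2.0, 3.0, 3.0, 4.0])
        y = np.array([2.0, 1.0, 1.0, 3.0, 2.0, 3.0])
        rho, p = spearman(x, y)
        rho_o, p_o = brute_force_spearman(x, y)
        assert rho == pytest.approx(rho_o, abs=1e-12)
        assert p == pytest.approx(p_o, abs=1e-12)

    def test_log_transform_does_not_change_rho(self):
        rng = np.random.default_rng(9)
        x = rng.lognormal(1, 1, 50)
        y = rng.poisson(5, 50).astype(float)
        rho_raw, _ = spearman(x, y)
        rho_log, _ = spearman(np.log10(x + 1), np.log10(y + 1))
        assert rho_raw == pytest.approx(rho_log, abs=1e-12)


class TestCouplingTest:
    def _profiles(self, n=40, seed=0):
        rng = np.random.default_rng(seed)
        fpkm = rng.lognormal(1, 1, n)
        treated = rng.poisson(5, n)
        control = rng.poisson(1, n)
        return pd.DataFrame(
            {
                "gene_id": [f"G{i:04d}" for i in range(n)],
                "fpkm": fpkm,
                "mut_count_treated": treated,
                "mut_count_control": control,
                "delta": treated - control,
                "quartile": "Q4",
            }
        )

    def test_filters_recorded_in_result(self):
        res = coupling_test(self._profiles(), quartile="Q4", delta_threshold=3)
        assert res.filters["quartile"] == "Q4"
        assert res.filters["delta_threshold"] == 3
        assert res.delta_threshold == 3
        # rerunning with recorded settings reproduces the result exactly
        res2 = coupling_test(
            self._profiles(),
            quartile=res.quartile,
            delta_threshold=res.delta_threshold,
        )
        assert (res2.rho, res2.p_value, res2.n_genes) == (res.rho, res.p_value, res.n_genes)

    def test_control_mode_skips_delta_filter(self):
        profiles = self._profiles()
        res = coupling_test(profiles, use_delta_filter=False)
        assert res.n_genes == len(profiles)
        assert res.delta_threshold is None

    def test_empty_after_filter_names_culprit(self):
        profiles = self._profiles()
        profiles["delta"] = 0
        with pytest.raises(CouplingFilterError, match="delta >= 3"):
            coupling_test(profiles, delta_threshold=3)


class TestRecoveryCoupling:
    def test_identical_sets_fail_delta_gate(self, toy_genes, toy_expression):
        ann = _ann(toy_genes[0].gene_id, 2)
        expr = toy_expression
        with pytest.raises(CouplingFilterError):
            recovery_coupling(ann, ann, expr, toy_genes, expression_condition="HU4h")

    def test_expression_condition_sets_quartiles_not_deltas(self, toy_genes, toy_config):
        from rsmutscape import generate_expression

        expr = pd.concat(
            [
                generate_expression(toy_genes, toy_config, "HU4h"),
                generate_expression(toy_genes, toy_config, "Ctrl4h"),
            ],
            ignore_index=True,
        )
        treated = _ann(toy_genes[0].gene_id, 6) + _ann(toy_genes[1].gene_id, 4, pos0=200)
        control = _ann(toy_genes[0].gene_id, 1, pos0=400)
        p_hu = gene_profiles(treated, control, expr, "HU4h", toy_genes)
        p_ctrl = gene_profiles(treated, control, expr, "Ctrl4h", toy_genes)
        assert (p_hu["delta"] == p_ctrl["delta"]).all()
        assert not (p_hu["quartile"] == p_ctrl["quartile"]).all()

    def test_missing_expression_condition_raises(self, toy_genes, toy_expression):
        with pytest.raises(RsMutError, match="T0"):
            gene_profiles([], [], toy_expression, "T0", toy_genes)


class TestExpressedVariantCount:
    def test_zero_threshold_counts_all_tier1(self):
        ann = _ann("G0000", 3) + _ann("G0001", 2, pos0=50) + _ann(None, 4, pos0=500)
        expr = _expr([0.0, 10.0, 1.0, 2.0])
        assert expressed_variant_count(ann, expr, "HU4h", fpkm_min=0.0) == 5

    def test_no_expressed_genes(self):
        ann = _ann("G0000", 3)
        expr = _expr([0.5, 0.2, 0.0, 0.1])
        assert expressed_variant_count(ann, expr, "HU4h", fpkm_min=1.0) == 0

    def test_matches_set_join_oracle(self, toy_genes, toy_expression):
        rng = np.random.default_rng(12)
        ids = [g.gene_id for g in toy_genes]
        ann = []
        pos = 1
        for _ in range(200):
            gid = ids[rng.integers(len(ids))] if rng.random() < 0.7 else None
            ann += _ann(gid, 1, pos0=pos)
            pos += 3
        got = expressed_variant_count(ann, toy_expression, "HU4h", fpkm_min=2.0)
        expressed = {
            g for g, f in zip(toy_expression["gene_id"], toy_expression["fpkm"]) if f >= 2.0
        }
        expected = sum(1 for a in ann if a.gene_id in expressed and a.tier == "tier1")
        assert got == expected
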
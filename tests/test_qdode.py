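"""qdODE decomposition: basis, selection, fitting, decomposition."""

import itertools
import math

import numpy as np
import pytest

from idopnet.allometry import fit_power
from idopnet.benchmarks import embedded_network_truth
from idopnet.qdode import (
    NetworkModelConfig,
    QdODERegressor,
    _System,
    _fit_target,
    _select_for_target,
    decompose,
    dependent_basis,
    fit_group_qdode,
    fit_qdode,
    integrate_forward,
    select_regulators,
)
from idopnet.simulate import GroundTruth, Regulation, generate_cohort


@pytest.fixture(scope="module")
def embedded():
    """One embedded 10-node system with two true regulators on m1g0."""
    truth, nodes = embedded_network_truth(0)
    coh = generate_cohort(truth, seed=1000)
    ds = coh.dataset.group("high")
    sub = ds.subset_genes(nodes)
    sys_ = _System(
        sub.values.to_numpy(), ds.ei.to_numpy(), sub.gene_ids, NetworkModelConfig()
    )
    return truth, nodes, sys_, ds


class TestDependentBasis:
    def test_order_one_is_proportional_to_rescaled_values(self):
        v = np.linspace(3.0, 9.0, 25)
        B = dependent_basis(v, 1)
        assert B.shape == (25, 1)
        x = 2 * (v - 3.0) / 6.0 - 1
        assert np.allclose(B[:, 0], x)

    def test_constant_regulator_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            dependent_basis(np.full(10, 4.0), 3)

    @pytest.mark.parametrize("order", [2, 3, 4])
    def test_polynomials_reconstructed_exactly(self, order):
        rng = np.random.default_rng(1)
        v = np.sort(rng.uniform(2, 8, 60))
        x = 2 * (v - v.min()) / (v.max() - v.min()) - 1
        target = sum(c * x**k for k, c in enumerate(rng.normal(size=order + 1)))
        B = np.column_stack([np.ones_like(x), dependent_basis(v, order)])
        coef, *_ = np.linalg.lstsq(B, target, rcond=None)
        assert np.max(np.abs(B @ coef - target)) < 1e-10


class TestFitQdode:
    def test_no_regulators_reduces_to_power_fit(self, embedded):
        truth, nodes, sys_, ds = embedded
        fit = _fit_target(sys_, "m3g0", [])
        ref = fit_power(
            ds.subset_genes(["m3g0"]).values.iloc[0].to_numpy(), ds.ei.to_numpy()
        )
        assert fit.alpha == pytest.approx(ref.alpha, rel=1e-4)
        assert fit.beta == pytest.approx(ref.beta, abs=1e-4)
        assert fit.P_dep == {}

    def test_decomposition_identity(self, embedded):
        truth, nodes, sys_, _ = embedded
        fit = _fit_target(sys_, "m1g0", ["m2g0", "m4g0"])
        recon = fit.P_ind + fit.total_dependent
        assert np.max(np.abs(fit.fitted - recon)) < 1e-8

    def test_adding_regulators_never_increases_rss(self, embedded):
        truth, nodes, sys_, _ = embedded
        rss = [
            _fit_target(sys_, "m1g0", regs).rss
            for regs in ([], ["m2g0"], ["m2g0", "m4g0"], ["m2g0", "m4g0", "m6g0"])
        ]
        for smaller, larger in zip(rss[1:], rss[:-1]):
            assert smaller <= larger + 1e-9

    def test_sample_order_invariance(self, embedded):
        truth, nodes, _, ds = embedded
        sub = ds.subset_genes(nodes)
        rng = np.random.default_rng(3)
        perm = rng.permutation(ds.n_samples)
        shuffled = sub.subset_samples([sub.sample_ids[i] for i in perm])
        ei_perm = ds.ei.iloc[perm]
        f1 = fit_qdode("m1g0", ["m2g0"], sub, ei=ds.ei)
        f2 = fit_qdode("m1g0", ["m2g0"], shuffled, ei=ei_perm)
        assert f1.rss == pytest.approx(f2.rss, rel=1e-9)
        assert f1.alpha == pytest.approx(f2.alpha, rel=1e-9)

    def test_dependent_strength_grows_with_generative_strength(self):
        means = []
        for mult in (1.0, 3.0, 9.0):
            truth, nodes = embedded_network_truth(
                3, regulated=(("m2g0", "m1g0", +1, 0.8),)
            )
            regs = [
                Regulation(r.regulator, r.target, r.group, r.sign,
                           r.strength * mult, r.shape)
                for r in truth.regulations
            ]
            scaled = GroundTruth(
                truth.module_of_gene, truth.alpha, truth.beta, regulations=regs,
                noise_sd={g: s * 0.3 for g, s in truth._noise_map().items()},
                group_sizes=truth.group_sizes, ei_range=truth.ei_range,
            )
            coh = generate_cohort(scaled, seed=77)
            ds = coh.dataset.group("high")
            fit = fit_qdode("m1g0", ["m2g0"], ds.subset_genes(nodes), ei=ds.ei)
            means.append(fit.edge_weight("m2g0"))
        assert means[0] > 0
        assert means[0] < means[1] < means[2]

    def test_fully_inhibited_target_has_nonpositive_dependent_total(self):
        truth, nodes = embedded_network_truth(
            5, regulated=(("m2g0", "m1g0", -1, 0.8), ("m4g0", "m1g0", -1, 0.5))
        )
        quiet = GroundTruth(
            truth.module_of_gene, truth.alpha, truth.beta,
            regulations=truth.regulations,
            noise_sd={g: s * 0.02 for g, s in truth._noise_map().items()},
            group_sizes=truth.group_sizes, ei_range=truth.ei_range,
        )
        coh = generate_cohort(quiet, seed=21)
        ds = coh.dataset.group("high")
        fit = fit_qdode("m1g0", ["m2g0", "m4g0"], ds.subset_genes(nodes), ei=ds.ei)
        total = sum(fit.edge_curve(r) for r in fit.regulators)
        assert total.mean() < 0
        assert (total <= np.abs(total).max() * 0.05).mean() > 0.9


class TestSelection:
    def test_true_regulators_found_with_signs(self, embedded):
        truth, nodes, sys_, _ = embedded
        sel = _select_for_target(sys_, "m1g0")
        assert "m2g0" in sel and "m4g0" in sel
        fit = _fit_target(sys_, "m1g0", sel)
        assert fit.edge_weight("m2g0") > 0
        assert fit.edge_weight("m4g0") < 0

    def test_selection_matches_best_subset_oracle(self, embedded):
        """Exhaustive best-subset search (<= 3 regulators) under the
        same design and criterion agrees with the path-based search."""
        truth, nodes, sys_, _ = embedded
        sel = _select_for_target(sys_, "m1g0")

        # independent oracle: brute-force subsets on the same design
        from idopnet._grouplasso import _Workspace, _ebic_penalties

        j = sys_.index("m1g0")
        y = sys_.Y[j]
        cand = [c for c in sys_.node_ids if c != "m1g0" and c in sys_.Zsel]
        a0, b0 = sys_.alpha0[j], sys_.beta0[j]
        U = np.hstack([(a0 * sys_.ei**b0)[:, None], sys_._smooth_axis_basis])
        groups = [sys_.Zsel[c] for c in cand]
        ws = _Workspace(y, U, groups)
        n, p, nu = ws.n, ws.p, ws.n_unpen
        ebic = _ebic_penalties(len(cand), 0.5)
        best, best_crit = (), np.inf
        for k in range(0, 4):
            for sub in itertools.combinations(range(len(cand)), k):
                idx = list(range(nu)) + [
                    nu + g * p + r for g in sub for r in range(p)
                ]
                A = ws.C[np.ix_(idx, idx)]
                b_ = ws.uy[idx]
                th = np.linalg.solve(A + 1e-10 * np.eye(len(idx)), b_)
                rss = max(ws.yty - float(b_ @ th), 0.0)
                crit = n * math.log(rss / n) + (nu + p * k) * math.log(n) + ebic[k]
                if crit < best_crit:
                    best, best_crit = sub, crit
        assert set(sel) == {cand[g] for g in best}

    def test_cap_limits_selection(self, embedded):
        truth, nodes, _, ds = embedded
        sub = ds.subset_genes(nodes)
        sel = select_regulators("m1g0", sub, cap=1, ei=ds.ei)
        assert len(sel) <= 1

    def test_too_few_samples_rejected(self, embedded):
        truth, nodes, _, ds = embedded
        few = ds.subset_genes(nodes).subset_samples(ds.sample_ids[:8])
        with pytest.raises(ValueError, match="samples"):
            select_regulators("m1g0", few, order=4)


class TestDecomposeTable:
    def test_regulator_free_fit_has_zero_dependent_column(self, embedded):
        truth, nodes, sys_, _ = embedded
        fit = _fit_target(sys_, "m3g0", [])
        table = decompose(fit)
        assert np.allclose(table["total_dependent"], 0.0)

    def test_columns_sum_to_fitted(self, embedded):
        truth, nodes, sys_, _ = embedded
        fit = _fit_target(sys_, "m1g0", ["m2g0", "m4g0"])
        table = decompose(fit)
        total = table["independent"] + table["total_dependent"]
        assert np.allclose(total, table["fitted"], atol=1e-8)
        dep_cols = [c for c in table.columns if c.startswith("dep:")]
        assert np.allclose(
            table[dep_cols].sum(axis=1), table["total_dependent"], atol=1e-10
        )


class TestIntegratedDesign:
    def test_runge_kutta_forward_solve_matches_fitted_curve(self, embedded):
        """In the integrated parameterization the fitted P curves are
        trapezoid integrals of the recovered rates; an independent RK4
        solve of those rates must agree up to quadrature error."""
        truth, nodes, _, ds = embedded
        cfg = NetworkModelConfig(dependent_design="integrated", smooth_regulators=True)
        sub = ds.subset_genes(nodes)
        sys_ = _System(sub.values.to_numpy(), ds.ei.to_numpy(), sub.gene_ids, cfg)
        fit = _fit_target(sys_, "m1g0", ["m2g0"])
        rk = integrate_forward(fit, refine=16)
        scale = np.abs(fit.fitted).mean()
        assert np.max(np.abs(rk - fit.fitted)) < 0.05 * scale

    def test_integrated_dependent_curves_are_anchored_at_zero(self, embedded):
        truth, nodes, _, ds = embedded
        cfg = NetworkModelConfig(dependent_design="integrated", smooth_regulators=True)
        sub = ds.subset_genes(nodes)
        sys_ = _System(sub.values.to_numpy(), ds.ei.to_numpy(), sub.gene_ids, cfg)
        fit = _fit_target(sys_, "m1g0", ["m2g0", "m4g0"])
        for r in fit.regulators:
            assert fit.P_dep[r][0] == pytest.approx(0.0, abs=1e-12)


class TestQdODERegressorEstimator:
    def test_fit_predict_and_params(self, embedded):
        truth, nodes, _, ds = embedded
        sub = ds.subset_genes(nodes)
        y = sub.values.loc["m1g0"].to_numpy()
        X = np.column_stack(
            [ds.ei.to_numpy()]
            + [sub.values.loc[n].to_numpy() for n in nodes if n != "m1g0"]
        )
        reg = QdODERegressor(cap=3).fit(
            X, y, candidate_ids=[n for n in nodes if n != "m1g0"]
        )
        assert reg.alpha_ > 0
        pred = reg.predict(X)
        assert pred.shape == y.shape
        params = reg.get_params()
        assert QdODERegressor().set_params(**params).get_params() == params


def test_group_fit_covers_all_nodes(embedded):
    truth, nodes, _, ds = embedded
    fits = fit_group_qdode(ds.subset_genes(nodes), NetworkModelConfig(), ei=ds.ei)
    assert set(fits) == set(nodes)
    for t, f in fits.items():
        assert t not in f.regulators  # no self-loops
        assert len(f.regulators) <= NetworkModelConfig().cap
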
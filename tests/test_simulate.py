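"""Ground-truth cohort generator: determinism, exactness, invariants."""

import numpy as np
import pytest

from idopnet.allometry import fit_power
from idopnet.simulate import (
    GroundTruth,
    Regulation,
    default_truth,
    generate_cohort,
)


def _one_module_truth(alpha=2.0, beta=1.0, noise=0.0, n_genes=3,
                      sizes=None, ei_range=(10.0, 20.0)):
    mog = {f"g{i}": 1 for i in range(n_genes)}
    a = {(1, "high"): alpha, (1, "low"): alpha}
    b = {(1, "high"): beta, (1, "low"): beta}
    return GroundTruth(
        mog, a, b, noise_sd=noise,
        group_sizes=sizes or {"high": 5, "low": 4}, ei_range=ei_range,
    )


class TestGeneration:
    def test_noiseless_identity(self):
        truth = _one_module_truth(alpha=2.0, beta=1.0)
        coh = generate_cohort(truth, seed=1)
        expected = 2.0 * coh.target_ei.to_numpy()
        assert np.allclose(coh.dataset.values.to_numpy(), expected, rtol=0, atol=0)

    def test_same_seed_bit_identical(self):
        truth = _one_module_truth(noise=0.3)
        a = generate_cohort(truth, seed=7)
        b = generate_cohort(truth, seed=7)
        assert a.dataset.values.equals(b.dataset.values)

    def test_different_seeds_differ(self):
        truth = _one_module_truth(noise=0.3)
        a = generate_cohort(truth, seed=7)
        b = generate_cohort(truth, seed=8)
        assert not a.dataset.values.equals(b.dataset.values)

    def test_noiseless_cohort_exactly_refit_by_power_regression(self):
        truth = _one_module_truth(alpha=1.3, beta=0.8, n_genes=2,
                                  ei_range=(600.0, 1400.0),
                                  sizes={"high": 30, "low": 10})
        coh = generate_cohort(truth, seed=3)
        y = coh.dataset.values.iloc[0].to_numpy()
        fit = fit_power(y, coh.target_ei.to_numpy())
        assert fit.alpha == pytest.approx(1.3, rel=1e-8)
        assert fit.beta == pytest.approx(0.8, abs=1e-8)

    def test_realized_ei_approaches_target_as_genes_grow(self):
        # with unit exponents the summed expectation equals the target
        # EI exactly, so the residual gap is pure aggregate noise and
        # must shrink as genes are added
        rel_err = []
        for n_genes in (10, 100, 1000):
            mog = {f"g{i}": 1 for i in range(n_genes)}
            a = {(1, "high"): 1.0 / n_genes, (1, "low"): 1.0 / n_genes}
            b = {(1, "high"): 1.0, (1, "low"): 1.0}
            truth = GroundTruth(
                mog, a, b, noise_sd=0.1 / n_genes * 1000,
                group_sizes={"high": 20, "low": 10}, ei_range=(600.0, 1400.0),
            )
            coh = generate_cohort(truth, seed=5)
            rel = np.abs(coh.dataset.ei - coh.target_ei) / coh.target_ei
            rel_err.append(float(rel.mean()))
        assert rel_err[0] > rel_err[1] > rel_err[2]

    def test_regulation_shifts_target_gene(self):
        mog = {"r": 1, "t": 2}
        a = {(1, "high"): 1.0, (2, "high"): 1.0, (1, "low"): 1.0, (2, "low"): 1.0}
        b = {k: 1.0 for k in a}
        base = GroundTruth(mog, a, b, noise_sd=0.0,
                           group_sizes={"high": 20, "low": 5},
                           ei_range=(600.0, 1400.0))
        reg = GroundTruth(mog, a, b,
                          regulations=[Regulation("r", "t", "high", +1, 50.0, 1.0)],
                          noise_sd=0.0,
                          group_sizes={"high": 20, "low": 5},
                          ei_range=(600.0, 1400.0))
        c0 = generate_cohort(base, seed=2)
        c1 = generate_cohort(reg, seed=2)
        diff = (c1.dataset.values.loc["t"] - c0.dataset.values.loc["t"])
        assert not np.allclose(diff, 0.0)
        assert np.allclose(c1.dataset.values.loc["r"], c0.dataset.values.loc["r"])
        # standardized response: the dependent signal has sd = strength
        assert np.std(diff[c0.dataset.risk == "high"]) == pytest.approx(50.0, rel=0.3)


class TestTruthValidation:
    def test_self_regulation_rejected(self):
        with pytest.raises(ValueError, match="self-regulation"):
            _t = _one_module_truth()
            GroundTruth(
                _t.module_of_gene, _t.alpha, _t.beta,
                regulations=[Regulation("g0", "g0", "high", 1, 1.0)],
                group_sizes=_t.group_sizes, ei_range=_t.ei_range,
            )

    def test_cap_enforced(self):
        t = _one_module_truth(n_genes=6)
        regs = [Regulation(f"g{i}", "g5", "high", 1, 1.0) for i in range(4)]
        with pytest.raises(ValueError, match="cap"):
            GroundTruth(t.module_of_gene, t.alpha, t.beta, regulations=regs,
                        group_sizes=t.group_sizes, ei_range=t.ei_range, cap=3)

    def test_nonpositive_alpha_rejected(self):
        t = _one_module_truth()
        bad = dict(t.alpha)
        bad[(1, "high")] = 0.0
        with pytest.raises(ValueError, match="alpha"):
            GroundTruth(t.module_of_gene, bad, t.beta,
                        group_sizes=t.group_sizes, ei_range=t.ei_range)

    def test_negative_noise_rejected(self):
        t = _one_module_truth()
        with pytest.raises(ValueError, match="noise_sd"):
            GroundTruth(t.module_of_gene, t.alpha, t.beta, noise_sd=-1.0,
                        group_sizes=t.group_sizes, ei_range=t.ei_range)

    def test_empty_group_rejected(self):
        t = _one_module_truth()
        with pytest.raises(ValueError, match="empty group"):
            GroundTruth(t.module_of_gene, t.alpha, t.beta,
                        group_sizes={"high": 5, "low": 0}, ei_range=t.ei_range)


class TestSerialization:
    def test_truth_json_roundtrip(self, tmp_path):
        truth = default_truth(n_modules=3, seed=4)
        path = tmp_path / "truth.json"
        truth.to_json(path)
        back = GroundTruth.from_json(path)
        assert back.module_of_gene == truth.module_of_gene
        assert back.alpha == truth.alpha
        assert back.regulations == truth.regulations
        assert back.group_sizes == truth.group_sizes
        # regenerated cohorts are identical
        a = generate_cohort(truth, 11)
        b = generate_cohort(back, 11)
        assert a.dataset.values.equals(b.dataset.values)


class TestDefaultTruth:
    def test_defaults_respect_documented_ranges(self):
        truth = default_truth(seed=0)
        sizes = {}
        for g, m in truth.module_of_gene.items():
            sizes[m] = sizes.get(m, 0) + 1
        assert len(sizes) == 6
        assert all(10 <= s <= 40 for s in sizes.values())
        assert truth.group_sizes == {"high": 60, "low": 30}
        counts = {}
        for r in truth.regulations:
            counts[(r.target, r.group)] = counts.get((r.target, r.group), 0) + 1
        assert all(c <= truth.cap for c in counts.values())

    def test_balanced_parts_sum_to_whole_at_midrange(self):
        truth = default_truth(seed=1)
        e_mid = 0.5 * (truth.ei_range[0] + truth.ei_range[1])
        for grp in truth.groups:
            total = sum(
                truth.independent_expectation(g, grp, e_mid) for g in truth.genes
            )
            assert total == pytest.approx(e_mid, rel=1e-9)


class TestSignFlipEndToEnd:
    def test_flipping_truth_sign_flips_recovered_edge(self):
        """Reversing a regulation's sign in the truth reverses the sign
        of the recovered network edge, end to end."""
        from idopnet.benchmarks import embedded_network_truth
        from idopnet.qdode import fit_qdode

        weights = {}
        for sign in (+1, -1):
            truth, nodes = embedded_network_truth(
                9, regulated=(("m2g0", "m1g0", sign, 0.8),)
            )
            coh = generate_cohort(truth, seed=33)
            ds = coh.dataset.group("high")
            fit_r = fit_qdode("m1g0", ["m2g0"], ds.subset_genes(nodes), ei=ds.ei)
            weights[sign] = fit_r.edge_weight("m2g0")
        assert weights[+1] > 0
        assert weights[-1] < 0
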
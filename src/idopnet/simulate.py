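"""Synthetic two-group expression cohorts with known network truth.

The generator mirrors the model class fitted downstream so that the
truth is recoverable: each gene's expectation is its module's power
curve of the sample's target expression index (the independent part)
plus, for each regulation acting on it, sign * strength * s(mu_reg(E))
where s is a smooth saturating function of the regulator's independent
expectation (the dependent part), plus iid Gaussian noise.  Samples are
analyzed by their realized EI (the sum of generated genes); the target
EI is only a generation device.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .io import ExpressionDataset

__all__ = ["Regulation", "GroundTruth", "SyntheticCohort", "generate_cohort", "default_truth"]


@dataclass(frozen=True)
class Regulation:
    regulator: str
    target: str
    group: str
    sign: int  # +1 promotion, -1 inhibition
    strength: float  # expression units, >= 0
    shape: float = 1.0  # response curvature: 0 linear .. 1 sigmoidal


@dataclass
class GroundTruth:
    """Generative model: module curves + sparse signed regulations.

    alpha/beta are keyed by (module, group); noise_sd maps gene -> sd
    (a scalar applies to all genes); cap bounds regulations per target
    per group (a Dunbar-style limit on incoming links).
    """

    module_of_gene: dict
    alpha: dict
    beta: dict
    regulations: list = field(default_factory=list)
    noise_sd: float | dict = 0.0
    group_sizes: dict = field(default_factory=lambda: {"high": 60, "low": 30})
    ei_range: tuple = (600.0, 1400.0)
    cap: int = 3

    def __post_init__(self):
        self.regulations = [
            r if isinstance(r, Regulation) else Regulation(*r) for r in self.regulations
        ]
        genes = set(self.module_of_gene)
        for r in self.regulations:
            if r.regulator == r.target:
                raise ValueError(f"self-regulation on {r.target}")
            if r.strength < 0:
                raise ValueError("negative regulation strength")
            if r.sign not in (-1, 1):
                raise ValueError("sign must be +1 or -1")
            if r.regulator not in genes or r.target not in genes:
                raise ValueError("regulation references unknown gene")
        counts: dict = {}
        for r in self.regulations:
            key = (r.target, r.group)
            counts[key] = counts.get(key, 0) + 1
            if counts[key] > self.cap:
                raise ValueError(f"more than cap={self.cap} regulations on {key}")
        for key, a in self.alpha.items():
            if a <= 0:
                raise ValueError(f"non-positive alpha for {key}")
        for g, sd in self._noise_map().items():
            if sd < 0:
                raise ValueError(f"negative noise_sd for {g}")
        for grp, n in self.group_sizes.items():
            if n < 1:
                raise ValueError(f"empty group {grp!r}")
        lo, hi = self.ei_range
        if not (0 < lo <= hi):
            raise ValueError("ei_range must be positive and ordered")

    # ------------------------------------------------------------------
    @property
    def genes(self) -> list[str]:
        return list(self.module_of_gene)

    @property
    def groups(self) -> list[str]:
        return sorted(self.group_sizes)

    def _noise_map(self) -> dict:
        if isinstance(self.noise_sd, dict):
            return self.noise_sd
        return {g: float(self.noise_sd) for g in self.module_of_gene}

    def independent_expectation(self, gene: str, group: str, e):
        m = self.module_of_gene[gene]
        return self.alpha[(m, group)] * np.asarray(e, float) ** self.beta[(m, group)]

    def regulations_on(self, target: str, group: str) -> list[Regulation]:
        return [r for r in self.regulations if r.target == target and r.group == group]

    # ------------------------------------------------------------------
    def to_json(self, path) -> None:
        d = {
            "module_of_gene": self.module_of_gene,
            "alpha": {f"{m}|{g}": v for (m, g), v in self.alpha.items()},
            "beta": {f"{m}|{g}": v for (m, g), v in self.beta.items()},
            "regulations": [asdict(r) for r in self.regulations],
            "noise_sd": self.noise_sd,
            "group_sizes": self.group_sizes,
            "ei_range": list(self.ei_range),
            "cap": self.cap,
        }
        Path(path).write_text(json.dumps(d, indent=1))

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        d = json.loads(Path(path).read_text())

        def unkey(m):
            out = {}
            for k, v in m.items():
                mod, grp = k.rsplit("|", 1)
                try:
                    mod = int(mod)
                except ValueError:
                    pass
                out[(mod, grp)] = v
            return out

        return cls(
            module_of_gene=d["module_of_gene"],
            alpha=unkey(d["alpha"]),
            beta=unkey(d["beta"]),
            regulations=[Regulation(**r) for r in d["regulations"]],
            noise_sd=d["noise_sd"],
            group_sizes=d["group_sizes"],
            ei_range=tuple(d["ei_range"]),
            cap=d["cap"],
        )


@dataclass
class SyntheticCohort:
    dataset: ExpressionDataset
    truth: GroundTruth
    target_ei: pd.Series  # generation-device EI, per sample


# ----------------------------------------------------------------------
_LOGISTIC_SCALE = 0.12  # transition width in range-normalized units


def _response(mu, v_lo, v_hi, shape):
    """Smooth bounded saturating response in [0, 1] of the regulator's
    expression level.

    The level is range-normalized over the cohort's EI window to t in
    [0, 1]; the response blends a linear rise with a saturating
    logistic switch centered mid-range according to ``shape``
    (0 = purely graded, 1 = purely switch-like).  Switch-like dose
    response is the biologically typical case (cooperative binding);
    statistically its steep transition is what lets the fitted model
    attribute an effect to the right regulator rather than to any
    co-monotone curve.
    """
    mu = np.asarray(mu, float)
    if v_hi - v_lo <= 0:
        return np.full_like(mu, 0.5)
    t = np.clip((mu - v_lo) / (v_hi - v_lo), 0.0, 1.0)
    switch = 1.0 / (1.0 + np.exp(-(t - 0.5) / _LOGISTIC_SCALE))
    return (1.0 - shape) * t + shape * switch


def generate_cohort(truth: GroundTruth, seed: int) -> SyntheticCohort:
    """Draw one cohort from the ground truth; same seed, same bits."""
    rng = np.random.default_rng(seed)
    lo, hi = truth.ei_range
    noise = truth._noise_map()
    genes = truth.genes

    cols, sample_ids, risk, tgt = [], [], [], []
    for grp in truth.groups:
        n = truth.group_sizes[grp]
        e_tgt = rng.uniform(lo, hi, size=n)
        tgt.append(e_tgt)
        mu0 = np.stack(
            [truth.independent_expectation(g, grp, e_tgt) for g in genes]
        )  # genes x n
        ends = {
            g: sorted(
                (
                    float(truth.independent_expectation(g, grp, lo)),
                    float(truth.independent_expectation(g, grp, hi)),
                )
            )
            for g in genes
        }
        # two-stage draw: intrinsic realized levels first, then each
        # regulation reads its regulator's intrinsic level (a gene
        # responds to the abundance actually present in the sample,
        # not to an ensemble average); staging keeps cycles well-defined
        sd = np.array([noise[g] for g in genes])[:, None]
        intrinsic = mu0 + rng.standard_normal(mu0.shape) * sd
        np.maximum(intrinsic, 0.0, out=intrinsic)
        vals = intrinsic.copy()
        gidx = {g: i for i, g in enumerate(genes)}
        e_dense = np.linspace(lo, hi, 201)
        for r in truth.regulations:
            if r.group != grp:
                continue
            v_lo, v_hi = ends[r.regulator]
            # standardize the response over the EI window (expectation
            # level) so that `strength` is the per-sample standard
            # deviation of the dependent signal: strength = k * noise_sd
            # means a k-fold signal-to-noise ratio by construction
            s_dense = _response(
                truth.independent_expectation(r.regulator, grp, e_dense),
                v_lo, v_hi, r.shape,
            )
            s_mean, s_sd = float(s_dense.mean()), float(s_dense.std())
            if s_sd <= 0:
                continue  # flat response carries no signal
            s_val = _response(intrinsic[gidx[r.regulator]], v_lo, v_hi, r.shape)
            eff = r.sign * r.strength * (s_val - s_mean) / s_sd
            vals[gidx[r.target]] += eff
        np.maximum(vals, 0.0, out=vals)  # expression is non-negative
        cols.append(pd.DataFrame(vals, index=genes))
        sample_ids += [f"{grp}_{i:03d}" for i in range(n)]
        risk += [grp] * n

    values = pd.concat(cols, axis=1)
    values.columns = sample_ids
    ds = ExpressionDataset(values, pd.Series(risk, index=sample_ids, name="risk"))
    # target EI per sample, kept for the realized-vs-target discrepancy report
    target_ei = pd.Series(np.concatenate(tgt), index=sample_ids, name="target_ei")
    return SyntheticCohort(ds, truth, target_ei)


# ----------------------------------------------------------------------
def default_truth(
    n_modules: int = 6,
    genes_per_module: tuple = (10, 40),
    group_sizes: dict | None = None,
    ei_range: tuple = (600.0, 1400.0),
    noise_cv: tuple = (0.05, 0.20),
    n_regulations: int = 12,
    strength_snr: float = 5.0,
    cap: int = 3,
    seed: int = 0,
    balance_ei: bool = True,
) -> GroundTruth:
    """Random but structured truth with field-realistic defaults.

    Module exponents beta spread around 1, per-gene noise at a coefficient
    of variation of 5-20% of the gene's mid-range expectation, at most
    ``cap`` incoming regulations per target, regulation strength set to
    ``strength_snr`` times the target's noise sd.  ``balance_ei`` rescales
    alphas so the summed independent expectations match the target EI at
    mid-range, preserving the part-whole reading.
    """
    rng = np.random.default_rng(seed)
    if group_sizes is None:
        group_sizes = {"high": 60, "low": 30}
    groups = sorted(group_sizes)
    sizes = rng.integers(genes_per_module[0], genes_per_module[1] + 1, size=n_modules)
    module_of_gene = {}
    g = 0
    for m in range(1, n_modules + 1):
        for _ in range(int(sizes[m - 1])):
            module_of_gene[f"g{g:04d}"] = m
            g += 1
    genes = list(module_of_gene)
    lo, hi = ei_range
    e_mid = 0.5 * (lo + hi)

    alpha, beta = {}, {}
    for m in range(1, n_modules + 1):
        for grp in groups:
            b = rng.uniform(0.4, 1.4)
            a = rng.uniform(0.5, 2.0)
            alpha[(m, grp)] = a
            beta[(m, grp)] = b
    if balance_ei:
        for grp in groups:
            tot = sum(
                alpha[(module_of_gene[gn], grp)] * e_mid ** beta[(module_of_gene[gn], grp)]
                for gn in genes
            )
            c = e_mid / tot
            for m in range(1, n_modules + 1):
                alpha[(m, grp)] *= c

    # per-gene noise, CV of mid-range independent expectation
    noise_sd = {}
    mid_mu = {}
    for grp in groups:
        for gn in genes:
            m = module_of_gene[gn]
            mid_mu.setdefault(gn, []).append(alpha[(m, grp)] * e_mid ** beta[(m, grp)])
    for gn in genes:
        cv = rng.uniform(*noise_cv)
        noise_sd[gn] = cv * float(np.mean(mid_mu[gn]))

    regulations = []
    incoming: dict = {}
    attempts = 0
    while len(regulations) < n_regulations and attempts < 50 * n_regulations:
        attempts += 1
        grp = groups[int(rng.integers(len(groups)))]
        r_idx, t_idx = rng.choice(len(genes), size=2, replace=False)
        reg, tgt = genes[int(r_idx)], genes[int(t_idx)]
        key = (tgt, grp)
        if incoming.get(key, 0) >= cap:
            continue
        sign = int(rng.choice([-1, 1]))
        strength = strength_snr * noise_sd[tgt]
        shape = float(rng.uniform(0.3, 1.0))
        regulations.append(Regulation(reg, tgt, grp, sign, strength, shape))
        incoming[key] = incoming.get(key, 0) + 1

    return GroundTruth(
        module_of_gene=module_of_gene,
        alpha=alpha,
        beta=beta,
        regulations=regulations,
        noise_sd=noise_sd,
        group_sizes=dict(group_sizes),
        ei_range=ei_range,
        cap=cap,
    )
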
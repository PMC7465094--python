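"""End-to-end runs: cluster, coarse network, fine networks, risk test.

Every run is driven by one RunConfig (loadable from YAML), writes its
artifacts (CSV/JSON/GraphML) under the configured output directory and
drops a manifest with the config hash, seed and library versions so a
run can be reproduced exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .clustering import ModulePartition, em_cluster, select_L
from .io import ExpressionDataset, load_dataset, module_expression
from .network import assemble, degree_powerlaw_check, hubness_table, interaction_table
from .qdode import NetworkModelConfig, fit_group_qdode
from .risk_test import lr_test
from .simulate import default_truth, generate_cohort

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_simulate", "run_coarse", "run_fine", "run_test"]


@dataclass
class RunConfig:
    matrix: str = ""
    metadata: str = ""
    gene_list: str | None = None
    out_dir: str = "idopnet_out"
    seed: int = 1
    # clustering
    L_min: int = 1
    L_max: int = 8
    criterion: str = "bic"
    n_restarts: int = 10
    # qdODE / networks
    order: int = 4
    cap: int = 5
    n_lambda: int = 12
    lambda_min_ratio: float = 1e-3
    eps_w: float | None = None
    # test
    n_perm: int = 1000

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if not (1 <= self.L_min <= self.L_max):
            raise ValueError("need 1 <= L_min <= L_max")
        if self.order < 1 or self.cap < 1 or self.n_perm < 1:
            raise ValueError("order, cap and n_perm must be positive")
        if self.criterion.lower() not in ("aic", "bic"):
            raise ValueError("criterion must be aic or bic")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**d)

    def model_config(self, level: str = "fine") -> NetworkModelConfig:
        """Model settings per granularity.  Module-level (coarse/test)
        systems are closed — the module sums are the EI — so they use
        smoothed, integrated dependent components; gene-level (fine)
        systems are embedded in the full-cohort EI and use the
        observed-expression level design."""
        closed = level in ("coarse", "test")
        return NetworkModelConfig(
            order=self.order,
            cap=self.cap,
            n_lambda=self.n_lambda,
            lambda_min_ratio=self.lambda_min_ratio,
            dependent_design="integrated" if closed else "level",
            smooth_regulators=closed,
        )

    def hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


# ----------------------------------------------------------------------
def _write_manifest(out: Path, cfg: RunConfig, stage: str, extra: dict | None = None):
    manifest = {
        "stage": stage,
        "config": asdict(cfg),
        "config_hash": cfg.hash(),
        "seed": cfg.seed,
        "versions": {
            "idopnet": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        **(extra or {}),
    }
    (out / f"manifest_{stage}.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def _load(cfg: RunConfig) -> ExpressionDataset:
    ds = load_dataset(cfg.matrix, cfg.metadata, cfg.gene_list)
    return ds.order_by_ei()


def _partition(cfg: RunConfig, ds: ExpressionDataset) -> ModulePartition:
    t0 = time.time()
    if cfg.L_min == cfg.L_max:
        part = em_cluster(ds, cfg.L_min, seed=cfg.seed, n_restarts=cfg.n_restarts)
    else:
        part = select_L(
            ds,
            range(cfg.L_min, cfg.L_max + 1),
            criterion=cfg.criterion,
            seed=cfg.seed,
            n_restarts=cfg.n_restarts,
        )
    logger.info("clustering: L=%d in %.1fs", part.L, time.time() - t0)
    return part


def _write_partition(out: Path, part: ModulePartition):
    rows = pd.DataFrame(
        {
            "gene_id": list(part.labels),
            "module": list(part.labels.values()),
            "posterior_max": part.posteriors.max(axis=1).to_numpy(),
        }
    )
    rows.to_csv(out / "partition.csv", index=False)
    if part.selection_table is not None:
        part.selection_table.to_csv(out / "criterion.csv", index=False)


def _fits_json(fits: dict) -> dict:
    out = {}
    for target, f in sorted(fits.items()):
        out[target] = {
            "alpha": f.alpha,
            "beta": f.beta,
            "sigma2": f.sigma2,
            "regulators": list(f.regulators),
            "signs": {r: int(np.sign(np.mean(f.P_dep[r]))) for r in f.regulators},
            "edge_weights": {r: float(np.mean(f.P_dep[r])) for r in f.regulators},
        }
    return out


def _network_artifacts(out: Path, tag: str, fits: dict, group: str, level: str, cfg: RunConfig):
    net = assemble(fits, at="grid-mean", group=group, level=level, eps_w=cfg.eps_w)
    net.write_edges_csv(out / f"edges_{tag}.csv")
    net.write_graphml(out / f"network_{tag}.graphml")
    hubness_table(net).to_csv(out / f"hubness_{tag}.csv", index=False)
    interaction_table(net).to_csv(out / f"interactions_{tag}.csv", index=False)
    deg = degree_powerlaw_check(net)
    (out / f"degree_check_{tag}.json").write_text(
        json.dumps(
            {
                "exponent": None if np.isnan(deg.exponent) else deg.exponent,
                "r2": None if np.isnan(deg.r2) else deg.r2,
                "inconclusive": deg.inconclusive,
                "maybe_scale_free": deg.maybe_scale_free,
            },
            indent=1,
        )
    )
    (out / f"fits_{tag}.json").write_text(json.dumps(_fits_json(fits), indent=1, sort_keys=True))
    return net


# ----------------------------------------------------------------------
def run_simulate(cfg: RunConfig, **truth_kw) -> dict:
    """Generate a synthetic cohort and write matrix/metadata/truth."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    truth = default_truth(seed=cfg.seed, **truth_kw)
    cohort = generate_cohort(truth, seed=cfg.seed)
    cohort.dataset.write(out / "matrix.tsv", out / "metadata.csv")
    truth.to_json(out / "truth.json")
    _write_manifest(out, cfg, "simulate", {"n_genes": cohort.dataset.n_genes})
    return {"matrix": str(out / "matrix.tsv"), "metadata": str(out / "metadata.csv")}


def run_coarse(cfg: RunConfig) -> dict:
    """Cluster genes into modules, fit module-level networks per group."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ds = _load(cfg)
    part = _partition(cfg, ds)
    _write_partition(out, part)
    mod_ds = module_expression(ds, part.labels)
    networks = {}
    for grp in mod_ds.groups:
        sub = mod_ds.group(grp).order_by_ei()
        fits = fit_group_qdode(sub, cfg.model_config("coarse"), group=grp)
        networks[grp] = _network_artifacts(out, f"coarse_{grp}", fits, grp, "coarse", cfg)
    manifest = _write_manifest(
        out, cfg, "coarse", {"L": part.L, "groups": list(networks)}
    )
    return {"partition": part, "networks": networks, "manifest": manifest}


def run_fine(cfg: RunConfig, module_id: int) -> dict:
    """Gene-level networks within one module (coarse partition required)."""
    out = Path(cfg.out_dir)
    part_path = out / "partition.csv"
    if not part_path.exists():
        raise FileNotFoundError("run_coarse must be run first (partition.csv missing)")
    part = pd.read_csv(part_path)
    genes = part.loc[part["module"] == int(module_id), "gene_id"].astype(str).tolist()
    if not genes:
        raise ValueError(f"unknown or empty module {module_id}")
    full = _load(cfg)
    ds = full.subset_genes(genes)
    networks = {}
    for grp in ds.groups:
        sub = ds.group(grp)
        # the EI stays the full analyzed gene set's sum, as in the
        # coarse run; the module's genes are parts of that whole
        fits = fit_group_qdode(
            sub, cfg.model_config("fine"), group=grp, ei=full.group(grp).ei
        )
        networks[grp] = _network_artifacts(
            out, f"fine_m{module_id}_{grp}", fits, grp, f"fine:{module_id}", cfg
        )
    _write_manifest(out, cfg, f"fine_m{module_id}", {"n_genes": len(genes)})
    return {"networks": networks, "genes": genes}


def run_test(cfg: RunConfig) -> dict:
    """Module-level permutation LR test of risk-specific structure."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ds = _load(cfg)
    part = _partition(cfg, ds)
    _write_partition(out, part)
    mod_ds = module_expression(ds, part.labels)
    res = lr_test(mod_ds, cfg.model_config("test"), n_perm=cfg.n_perm, seed=cfg.seed)
    pd.DataFrame({"perm_lr": res.perm_lrs}).to_csv(out / "perm_lrs.csv", index=False)
    payload = res.to_dict() | {"perm_lrs_path": str(out / "perm_lrs.csv")}
    (out / "lr_test.json").write_text(json.dumps(payload, indent=1, sort_keys=True))
    _write_manifest(out, cfg, "test", {"lr": res.lr, "threshold": res.threshold})
    return {"result": res}
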
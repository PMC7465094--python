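"""Signed, weighted, directed networks from fitted qdODE systems.

Nodes carry the independent-component value P_ind at a chosen EI (a
personalized, per-sample network) or its mean over the EI grid (a
group-summary network); a directed edge regulator -> target carries the
dependent-component curve P_dep evaluated the same way.  Pairwise
interaction types (synergism, antagonism, their directional one-sided
forms, and altruism/aggression) follow from the two directed signed
effects within a pair; hubness is the summed absolute edge weight split
into outgoing and incoming strength.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "IdopNetwork",
    "assemble",
    "classify_pair",
    "interaction_table",
    "hubness",
    "hubness_table",
    "degree_powerlaw_check",
    "PowerLawDegreeResult",
]

INTERACTION_TYPES = (
    "synergism",
    "antagonism",
    "directional synergism",
    "directional antagonism",
    "altruism/aggression",
    "none",
)


@dataclass
class IdopNetwork:
    """Directed signed weighted graph at one EI context."""

    graph: nx.DiGraph
    group: str
    context: object  # float EI value or "grid-mean"
    level: str = "coarse"

    @property
    def nodes(self) -> list:
        return list(self.graph.nodes)

    @property
    def edges(self) -> pd.DataFrame:
        rows = [
            {
                "regulator": u,
                "target": v,
                "weight": d["weight"],
                "sign": d["sign"],
                "sign_unstable": d.get("sign_unstable", False),
            }
            for u, v, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(
            rows, columns=["regulator", "target", "weight", "sign", "sign_unstable"]
        )

    def node_value(self, node) -> float:
        return self.graph.nodes[node]["value"]

    def write_graphml(self, path) -> None:
        nx.write_graphml(self.graph, path)

    def write_edges_csv(self, path) -> None:
        df = self.edges
        df["group"] = self.group
        df["level"] = self.level
        df["ei_context"] = str(self.context)
        df.to_csv(path, index=False)


# ----------------------------------------------------------------------
def assemble(fits: dict, at="grid-mean", group: str | None = None, level: str = "coarse",
             eps_w: float | None = None) -> IdopNetwork:
    """Build the network from {target: QdODEFit}.

    ``at`` is an EI value (personalized network for the sample with that
    EI) or "grid-mean" (summary network).  Edges with |weight| <= eps_w
    are dropped; eps_w defaults to 1e-6 times the mean absolute node
    value.  An EI outside the fitted grid snaps to the nearest endpoint
    with a warning.
    """
    fits = dict(fits)
    any_fit = next(iter(fits.values()))
    grp = group if group is not None else any_fit.group
    if not isinstance(at, str):
        lo, hi = float(any_fit.ei[0]), float(any_fit.ei[-1])
        if at < lo or at > hi:
            logger.warning("EI %.4g outside fitted grid [%g, %g]; clamping", at, lo, hi)
            at = min(max(at, lo), hi)

    G = nx.DiGraph()
    node_vals = {}
    for target, fit in fits.items():
        if isinstance(at, str):
            v = float(fit.P_ind.mean())
        else:
            v = float(np.interp(at, fit.ei, fit.P_ind))
        node_vals[target] = v
        G.add_node(target, value=v)

    scale = float(np.mean(np.abs(list(node_vals.values())))) if node_vals else 0.0
    eps = eps_w if eps_w is not None else 1e-6 * scale
    for target, fit in fits.items():
        for reg in fit.regulators:
            if reg == target:
                continue  # no self-loops
            w = fit.edge_weight(reg, at)
            if abs(w) <= eps:
                continue
            curve = fit.edge_curve(reg)
            frac_flip = float(np.mean(np.sign(curve) != np.sign(np.mean(curve))))
            G.add_edge(
                reg,
                target,
                weight=float(w),
                sign=int(np.sign(w)),
                sign_unstable=bool(frac_flip > 0.2),
            )
    return IdopNetwork(G, group=str(grp), context=at, level=level)


# ----------------------------------------------------------------------
def classify_pair(effect_ab: float, effect_ba: float, eps: float = 0.0) -> str:
    """Interaction type of an unordered pair from the two directed
    effects (a on b, b on a), thresholded at eps."""
    if eps < 0:
        raise ValueError("eps must be >= 0")

    def s(x):
        return 0 if abs(x) <= eps else int(np.sign(x))

    sa, sb = s(effect_ab), s(effect_ba)
    if sa == 1 and sb == 1:
        return "synergism"
    if sa == -1 and sb == -1:
        return "antagonism"
    if {sa, sb} == {1, 0}:
        return "directional synergism"
    if {sa, sb} == {-1, 0}:
        return "directional antagonism"
    if {sa, sb} == {1, -1}:
        return "altruism/aggression"
    return "none"


def interaction_table(net: IdopNetwork, eps: float | None = None) -> pd.DataFrame:
    """Classify every node pair with at least one edge between them."""
    G = net.graph
    if eps is None:
        vals = [abs(d["weight"]) for _, _, d in G.edges(data=True)]
        eps = 1e-6 * float(np.mean(vals)) if vals else 0.0
    pairs = set()
    for u, v in G.edges:
        pairs.add(tuple(sorted((u, v))))
    rows = []
    for a, b in sorted(pairs):
        eff_ab = G.edges[a, b]["weight"] if G.has_edge(a, b) else 0.0
        eff_ba = G.edges[b, a]["weight"] if G.has_edge(b, a) else 0.0
        rows.append(
            {
                "node_a": a,
                "node_b": b,
                "effect_ab": eff_ab,
                "effect_ba": eff_ba,
                "type": classify_pair(eff_ab, eff_ba, eps),
            }
        )
    return pd.DataFrame(rows, columns=["node_a", "node_b", "effect_ab", "effect_ba", "type"])


# ----------------------------------------------------------------------
def hubness(net: IdopNetwork, node) -> tuple[float, float]:
    """(outgoing, incoming) strength: summed |edge weight| on each side.
    The scalar hubness used for ranking is the outgoing strength."""
    G = net.graph
    if node not in G:
        raise KeyError(f"unknown node {node!r}")
    out_s = sum(abs(d["weight"]) for _, _, d in G.out_edges(node, data=True))
    in_s = sum(abs(d["weight"]) for _, _, d in G.in_edges(node, data=True))
    return float(out_s), float(in_s)


def hubness_table(net: IdopNetwork) -> pd.DataFrame:
    rows = []
    for node in net.graph.nodes:
        o, i = hubness(net, node)
        rows.append({"node": node, "out_strength": o, "in_strength": i, "hubness": o})
    df = pd.DataFrame(rows, columns=["node", "out_strength", "in_strength", "hubness"])
    return df.sort_values("hubness", ascending=False).reset_index(drop=True)


# ----------------------------------------------------------------------
@dataclass
class PowerLawDegreeResult:
    exponent: float
    r2: float
    inconclusive: bool
    maybe_scale_free: bool


def degree_powerlaw_check(net: IdopNetwork, min_distinct: int = 5) -> PowerLawDegreeResult:
    """Descriptive log-log regression of degree frequency on total
    degree (in + out counts).  r2 >= 0.8 is reported as "may be
    scale-free"; with few distinct degrees the check is inconclusive.
    Log-log least squares (not MLE tail fitting) is deliberate: these
    networks have tens of nodes, far too few for tail estimation.
    """
    G = net.graph
    deg = np.array([G.in_degree(n) + G.out_degree(n) for n in G.nodes])
    deg = deg[deg > 0]
    vals, counts = np.unique(deg, return_counts=True)
    if len(vals) < min_distinct:
        return PowerLawDegreeResult(np.nan, np.nan, True, False)
    x = np.log(vals.astype(float))
    y = np.log(counts.astype(float))
    slope, intercept = np.polyfit(x, y, 1)
    yhat = slope * x + intercept
    ss_res = float(((y - yhat) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
    return PowerLawDegreeResult(
        exponent=float(-slope),
        r2=float(r2),
        inconclusive=False,
        maybe_scale_free=bool(r2 >= 0.8),
    )
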
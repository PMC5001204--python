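"""Node scoring from p-values and connected-module search.

The scoring model is a beta-uniform mixture (BUM) for the p-value
distribution,

    f(p) = lambda + (1 - lambda) * a * p**(a - 1),      0 < p <= 1,

with mixing weight ``lambda`` in (0,1) and beta shape ``a`` in (0,1): a
Uniform(0,1) noise floor plus a Beta(a,1) signal spike near zero. Fitting
the mixture to the observed p-values and choosing a false discovery rate
``FDR`` yields a threshold tau(FDR) and a signed per-gene score

    s(p) = (a - 1) * (ln p - ln tau),

positive below tau and negative above it. The functional module is then the
connected subgraph maximising the sum of member scores (a maximum-weight
connected subgraph, MWCS). A second, z-score-based search recovers multiple
depth-limited modules in the style of the classic simulated-annealing /
greedy "active modules" approach.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import optimize, stats

log = logging.getLogger(__name__)

__all__ = [
    "BumFit",
    "ScoredNetwork",
    "Module",
    "FdrScanResult",
    "fit_bum",
    "bum_density",
    "tau_threshold",
    "score_nodes",
    "max_scoring_subnetwork",
    "fdr_scan",
    "active_modules",
]

# Exact subset search is used when a reduced component is at most this big;
# beyond it the prize-collecting heuristic takes over.
EXACT_SEARCH_MAX_NODES = 14


# ---------------------------------------------------------------------------
# Beta-uniform mixture
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BumFit:
    """Maximum-likelihood beta-uniform mixture parameters."""

    lambda_mix: float
    a_shape: float
    log_likelihood: float
    n_points: int

    @property
    def pi_upper(self) -> float:
        """Upper bound on the uniform (noise) density: f(1) = λ + (1−λ)a."""
        return self.lambda_mix + (1.0 - self.lambda_mix) * self.a_shape


def bum_density(p, lambda_mix: float, a_shape: float):
    p = np.asarray(p, dtype=float)
    return lambda_mix + (1.0 - lambda_mix) * a_shape * p ** (a_shape - 1.0)


def _bum_nll(params, logp, p):
    lam, a = params
    dens = lam + (1.0 - lam) * a * np.exp((a - 1.0) * logp)
    return -np.log(dens).sum()


def fit_bum(p_values) -> BumFit:
    """Fit the mixture by bounded maximum likelihood from a grid of starts.

    The (λ, a) likelihood surface is ridge-shaped near the pure-noise corner
    (λ→1 with any a, or a→1 with any λ, describe the same uniform density),
    so several deterministic starts are tried and the best retained. Raises
    on fewer than 50 points or a degenerate (all-identical) sample.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size < 50:
        raise ValueError("need at least 50 p-values to fit the mixture")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    if np.allclose(p, p[0]):
        raise ValueError("degenerate fit: all p-values identical")

    logp = np.log(p)
    eps = 1e-6
    bounds = [(eps, 1 - eps), (eps, 1 - eps)]
    best = None
    for lam0 in (0.3, 0.5, 0.7, 0.9):
        for a0 in (0.1, 0.3, 0.5, 0.7):
            res = optimize.minimize(
                _bum_nll, x0=[lam0, a0], args=(logp, p),
                method="L-BFGS-B", bounds=bounds,
            )
            if best is None or res.fun < best.fun:
                best = res
    lam, a = best.x
    return BumFit(
        lambda_mix=float(lam),
        a_shape=float(a),
        log_likelihood=float(-best.fun),
        n_points=int(p.size),
    )


def tau_threshold(fit: BumFit, fdr: float) -> float:
    """p-value at which the node score crosses zero for a given FDR.

    The mixture's estimated FDR at threshold tau is pi_upper*tau / F(tau)
    with F the mixture CDF; inverting gives

        tau = [ (pi_upper - fdr*lambda) / (fdr*(1-lambda)) ] ** (1/(a-1)),

    strictly increasing in fdr (a larger tolerated FDR admits larger
    p-values). Clamped to at most 1.
    """
    if not 0.0 < fdr < 1.0:
        raise ValueError("fdr must lie in (0, 1)")
    lam, a = fit.lambda_mix, fit.a_shape
    bracket = (fit.pi_upper - fdr * lam) / (fdr * (1.0 - lam))
    if bracket <= 0.0:
        return 1.0
    return float(min(bracket ** (1.0 / (a - 1.0)), 1.0))


@dataclass(frozen=True)
class ScoredNetwork:
    """A network with signed per-gene BUM scores at a fixed FDR."""

    network: nx.Graph
    scores: dict[str, float]
    fdr: float


def score_nodes(
    network: nx.Graph, stats_table: pd.DataFrame, fit: BumFit, fdr: float
) -> ScoredNetwork:
    """Signed score s(p) = (a−1)(ln p − ln tau) for every network node.

    Nodes without a measured p-value are assigned p = 1 (maximally
    uninformative, hence maximally negative score) and logged.
    """
    tau = tau_threshold(fit, fdr)
    a1 = fit.a_shape - 1.0
    ln_tau = math.log(tau)
    pmap = dict(zip(stats_table["gene"], stats_table["p_value"]))
    missing = [n for n in network.nodes if n not in pmap]
    if missing:
        log.info("score_nodes: %d nodes lack p-values, assigned p=1", len(missing))
    scores = {
        n: a1 * (math.log(pmap.get(n, 1.0)) - ln_tau) for n in network.nodes
    }
    return ScoredNetwork(network=network, scores=scores, fdr=fdr)


# ---------------------------------------------------------------------------
# Maximum-weight connected subgraph
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Module:
    """A connected gene subnetwork with its aggregate node score."""

    genes: frozenset
    edges: frozenset
    aggregate_score: float
    method_tag: str
    calibrated_score: float | None = None

    @property
    def size(self) -> int:
        return len(self.genes)


def _module_from_nodes(network, nodes, scores, tag, calibrated=None) -> Module:
    nodes = frozenset(nodes)
    edges = frozenset(
        tuple(sorted((u, v))) for u, v in network.subgraph(nodes).edges
    )
    return Module(
        genes=nodes,
        edges=edges,
        aggregate_score=float(sum(scores[n] for n in nodes)),
        method_tag=tag,
        calibrated_score=calibrated,
    )


_EMPTY = Module(frozenset(), frozenset(), 0.0, "max_scoring")


def _strip_nonpositive_leaves(g: nx.Graph, scores) -> nx.Graph:
    """Iteratively remove degree-<=1 nodes with non-positive score (safe)."""
    g = g.copy()
    while True:
        drop = [n for n in g.nodes if scores[n] <= 0 and g.degree(n) <= 1]
        if not drop:
            return g
        g.remove_nodes_from(drop)


def _exact_best_subgraph(g: nx.Graph, scores) -> tuple[float, set]:
    """Exact MWCS by bitmask scan over all connected induced subgraphs."""
    nodes = sorted(g.nodes)
    n = len(nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    adj = [0] * n
    for u, v in g.edges:
        adj[idx[u]] |= 1 << idx[v]
        adj[idx[v]] |= 1 << idx[u]
    w = [scores[v] for v in nodes]

    best_score, best_mask = 0.0, 0
    for mask in range(1, 1 << n):
        # connectivity flood-fill within the subset
        seed = mask & -mask
        reached = seed
        frontier = seed
        while frontier:
            nxt = 0
            m = frontier
            while m:
                b = m & -m
                nxt |= adj[b.bit_length() - 1]
                m ^= b
            frontier = nxt & mask & ~reached
            reached |= frontier
        if reached != mask:
            continue
        s = 0.0
        m = mask
        while m:
            b = m & -m
            s += w[b.bit_length() - 1]
            m ^= b
        if s > best_score + 1e-12:
            best_score, best_mask = s, mask
    return best_score, {nodes[i] for i in range(n) if best_mask >> i & 1}


def _heuristic_best_subgraph(g: nx.Graph, scores) -> tuple[float, set]:
    """Prize-collecting expansion over contracted positive components.

    Positive-score connected components are contracted to supernodes whose
    prize is their summed score. Starting from the best supernode, the
    supernode whose connection through negative connector nodes is most
    profitable (prize minus bridge cost, via multi-source node-weighted
    Dijkstra) is merged in, until no strictly profitable merge remains.
    """
    pos_nodes = {n for n in g.nodes if scores[n] > 0}
    if not pos_nodes:
        return 0.0, set()
    comps = [set(c) for c in nx.connected_components(g.subgraph(pos_nodes))]
    comps.sort(key=lambda c: min(c))
    prize = [sum(scores[n] for n in c) for c in comps]
    comp_of = {}
    for i, c in enumerate(comps):
        for n in c:
            comp_of[n] = i

    start = max(range(len(comps)), key=lambda i: (prize[i], min(comps[i])))
    tree_nodes = set(comps[start])
    in_tree_comp = {start}

    while True:
        # multi-source Dijkstra; cost of entering node v is max(-score, 0)
        import heapq

        dist = {n: 0.0 for n in tree_nodes}
        parent = {}
        heap = [(0.0, n) for n in sorted(tree_nodes)]
        heapq.heapify(heap)
        seen = set()
        while heap:
            d, u = heapq.heappop(heap)
            if u in seen:
                continue
            seen.add(u)
            for v in g.neighbors(u):
                cost = max(-scores[v], 0.0) if v not in tree_nodes else 0.0
                nd = d + cost
                if nd < dist.get(v, math.inf) - 1e-15:
                    dist[v] = nd
                    parent[v] = u
                    heapq.heappush(heap, (nd, v))

        best_gain, best_comp = 1e-12, None
        for i, c in enumerate(comps):
            if i in in_tree_comp:
                continue
            reach = min(dist.get(n, math.inf) for n in c)
            gain = prize[i] - reach
            if gain > best_gain or (
                best_comp is not None
                and abs(gain - best_gain) <= 1e-12
                and min(c) < min(comps[best_comp])
            ):
                best_gain, best_comp = gain, i
        if best_comp is None:
            break
        # walk the cheapest path back into the tree from the new component
        entry = min(
            comps[best_comp],
            key=lambda n: (dist.get(n, math.inf), n),
        )
        node = entry
        path = []
        while node not in tree_nodes:
            path.append(node)
            node = parent[node]
        tree_nodes.update(path)
        tree_nodes.update(comps[best_comp])
        in_tree_comp.add(best_comp)

    # final cleanup: shed negative leaves the bridges left behind
    sub = _strip_nonpositive_leaves(g.subgraph(tree_nodes), scores)
    total = sum(scores[n] for n in sub.nodes)
    return total, set(sub.nodes)


def max_scoring_subnetwork(scored: ScoredNetwork) -> Module:
    """Highest-scoring connected subgraph of a scored network.

    Each connected component is reduced by stripping non-positive leaves;
    small reduced components are solved exactly by subset scan, large ones
    by the prize-collecting heuristic. The best component-level answer wins;
    ties break on the lexicographically smallest gene set. With no
    positive-scoring node the empty module is returned (warned).
    """
    g, scores = scored.network, scored.scores
    if not any(s > 0 for s in scores.values()):
        log.warning("max_scoring_subnetwork: no positive-scoring node")
        return _EMPTY

    best_score, best_nodes = 0.0, set()
    for comp in nx.connected_components(g):
        if not any(scores[n] > 0 for n in comp):
            continue
        reduced = _strip_nonpositive_leaves(g.subgraph(comp), scores)
        if reduced.number_of_nodes() == 0:
            continue
        if reduced.number_of_nodes() <= EXACT_SEARCH_MAX_NODES:
            s, nodes = _exact_best_subgraph(reduced, scores)
        else:
            s, nodes = _heuristic_best_subgraph(reduced, scores)
        if s > best_score + 1e-12 or (
            abs(s - best_score) <= 1e-12
            and nodes
            and sorted(nodes) < sorted(best_nodes or {"￿"})
        ):
            best_score, best_nodes = s, nodes
    if not best_nodes:
        return _EMPTY
    return _module_from_nodes(g, best_nodes, scores, "max_scoring")


# ---------------------------------------------------------------------------
# FDR scan
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FdrScanResult:
    rows: pd.DataFrame
    module: Module
    fdr: float


def fdr_scan(
    network: nx.Graph,
    stats_table: pd.DataFrame,
    fit: BumFit | None = None,
    fdr_grid=(1e-8, 1e-6, 1e-4, 1e-3, 1e-2, 0.05, 0.1),
    truth: set | None = None,
    size_band: tuple[int, int] = (10, 300),
) -> FdrScanResult:
    """Scan FDR values, extract the max-scoring module at each, select one.

    The FDR acts as the module-size dial: a smaller FDR shrinks tau and the
    set of positive nodes. When a ground-truth gene set is supplied each row
    records true-positive rate (|module∩truth|/|truth|) and precision
    (|module∩truth|/|module|) and the F1-best row is selected (ties: smaller
    module, then smaller FDR). Without truth, the smallest FDR whose module
    size falls in ``size_band`` is selected; if none does, the row whose
    size is closest to the band midpoint wins.
    """
    grid = sorted(fdr_grid)
    if not grid:
        raise ValueError("fdr_grid must be non-empty")
    if fit is None:
        fit = fit_bum(stats_table["p_value"])

    rows, modules = [], []
    for fdr in grid:
        module = max_scoring_subnetwork(score_nodes(network, stats_table, fit, fdr))
        row = {"fdr": fdr, "module_size": module.size,
               "tp_rate": np.nan, "precision": np.nan, "f1": np.nan}
        if truth is not None and len(truth) > 0:
            inter = len(module.genes & set(truth))
            row["tp_rate"] = inter / len(truth)
            row["precision"] = inter / module.size if module.size else 0.0
            denom = row["tp_rate"] + row["precision"]
            row["f1"] = 2 * row["tp_rate"] * row["precision"] / denom if denom else 0.0
        rows.append(row)
        modules.append(module)
    table = pd.DataFrame(rows)

    if truth is not None and len(truth) > 0:
        order = sorted(
            range(len(grid)),
            key=lambda i: (-table.loc[i, "f1"], table.loc[i, "module_size"], grid[i]),
        )
        k = order[0]
    else:
        lo, hi = size_band
        in_band = [i for i in range(len(grid)) if lo <= table.loc[i, "module_size"] <= hi]
        if in_band:
            k = min(in_band)
        else:
            mid = (lo + hi) / 2
            k = min(range(len(grid)),
                    key=lambda i: (abs(table.loc[i, "module_size"] - mid), grid[i]))
    return FdrScanResult(rows=table, module=modules[k], fdr=grid[k])


# ---------------------------------------------------------------------------
# Multiple active modules (z-score search)
# ---------------------------------------------------------------------------

def active_modules(
    network: nx.Graph,
    stats_table: pd.DataFrame,
    n_modules: int = 5,
    max_depth: int = 2,
    overlap: float = 0.0,
    seed: int = 0,
    n_calibration: int = 200,
    max_size: int = 30,
) -> list[Module]:
    """Multiple depth-limited modules by calibrated z-score aggregation.

    Per-gene z = Phi^{-1}(1 - p); a candidate gene set A of size k scores
    z_A = sum(z)/sqrt(k), standardised against the Monte-Carlo mean and sd
    of z_A over random k-sets so module sizes are comparable. Search grows
    greedily from the ``n_modules`` lowest-p start genes, never leaving the
    ball of radius ``max_depth`` around the start. Returned modules are
    ranked by calibrated score and filtered to pairwise node-overlap at most
    ``overlap`` (0 means disjoint).
    """
    if n_modules < 1:
        raise ValueError("n_modules must be >= 1")
    rng = np.random.default_rng(seed)
    ptab = stats_table[stats_table["gene"].isin(network.nodes)]
    pmap = dict(zip(ptab["gene"], ptab["p_value"]))
    genes = sorted(pmap)
    if not genes:
        return []
    z = {g: float(stats.norm.isf(min(max(pmap[g], 1e-15), 1 - 1e-15)))
         for g in genes}
    zarr = np.array([z[g] for g in genes])

    calib: dict[int, tuple[float, float]] = {}

    def calibrated(total: float, k: int) -> float:
        if k not in calib:
            if k >= len(zarr):
                calib[k] = (zarr.sum() / math.sqrt(k), 1e-12)
            else:
                draws = np.array([
                    zarr[rng.choice(len(zarr), size=k, replace=False)].sum()
                    for _ in range(n_calibration)
                ]) / math.sqrt(k)
                calib[k] = (float(draws.mean()), float(max(draws.std(), 1e-12)))
        mu, sd = calib[k]
        return (total / math.sqrt(k) - mu) / sd

    starts = sorted(genes, key=lambda g: (pmap[g], g))[: n_modules * 3]
    candidates = []
    for start in starts:
        ball = set(nx.single_source_shortest_path_length(
            network, start, cutoff=max_depth))
        ball &= set(genes)
        # grow to the size cap taking the locally best neighbour each step
        # (even through dips), then keep the best-scoring prefix — plain
        # greedy stalls on plateaus of the calibrated score
        current = {start}
        total = z[start]
        trail = [(calibrated(total, 1), start)]
        while len(current) < max_size:
            frontier = sorted(
                {v for u in current for v in network.neighbors(u)} & ball - current
            )
            if not frontier:
                break
            best_v, best_s = None, -math.inf
            for v in frontier:
                s = calibrated(total + z[v], len(current) + 1)
                if s > best_s + 1e-12:
                    best_v, best_s = v, s
            current.add(best_v)
            total += z[best_v]
            trail.append((best_s, best_v))
        cut = max(range(len(trail)), key=lambda i: trail[i][0])
        nodes = {v for _, v in trail[: cut + 1]}
        score = trail[cut][0]
        candidates.append((score, nodes, sum(z[v] for v in nodes)))

    candidates.sort(key=lambda c: (-c[0], sorted(c[1])))
    kept: list[Module] = []
    for score, nodes, total in candidates:
        if len(kept) == n_modules:
            break
        ok = True
        for m in kept:
            inter = len(nodes & m.genes)
            frac = inter / min(len(nodes), len(m.genes))
            if frac > overlap:
                ok = False
                break
        if ok:
            kept.append(_module_from_nodes(
                network, nodes, z, "active", calibrated=float(score)))
    if len(kept) < n_modules:
        log.warning("active_modules: only %d non-overlapping modules found",
                    len(kept))
    return kept
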
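"""Probabilistic co-occurrence networks of core phylotypes.

For two taxa present in n_a and n_b of N sites, the number of shared sites
under random, independent placement of their presences follows a
hypergeometric distribution; the co-presence p-value is the exact upper
tail P(J >= j_obs).  Taxa pairs with p below alpha become edges; module
structure is found by walktrap (short random walks) with the cut chosen at
maximum modularity.
"""

from __future__ import annotations

import dataclasses
import logging

import igraph as ig
import numpy as np
import pandas as pd
from scipy import stats as sps

log = logging.getLogger(__name__)

EDGE_COLUMNS = ["taxon_a", "taxon_b", "n_a", "n_b", "j_obs", "p_value"]


@dataclasses.dataclass
class CooccurrenceNetwork:
    nodes: list[str]
    edges: pd.DataFrame                      # EDGE_COLUMNS
    membership: dict[str, int] = dataclasses.field(default_factory=dict)
    modularity: float | None = None
    main_modules: set[int] = dataclasses.field(default_factory=set)
    kingdom: str | None = None
    segregation: pd.DataFrame | None = None  # significant avoidance pairs (side table)
    skipped: list[str] = dataclasses.field(default_factory=list)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def module_sizes(self) -> pd.Series:
        return pd.Series(self.membership).value_counts().sort_index()


def copresence_pvalue(
    N: int, n_a: int, n_b: int, j_obs: int, inclusive: bool = True
) -> float:
    """Exact upper-tail probability of >= j_obs co-presences.

    p = sum_{j >= j_obs} C(n_a, j) C(N - n_a, n_b - j) / C(N, n_b), the
    hypergeometric survival function, evaluated in log space so it is stable
    for N well beyond 10^4.  Symmetric in (n_a, n_b).  With
    ``inclusive=False`` the tail is strict (P(J > j_obs)).
    """
    if not (0 <= n_a <= N and 0 <= n_b <= N):
        raise ValueError(f"presence counts out of range: N={N}, n_a={n_a}, n_b={n_b}")
    j_min, j_max = max(0, n_a + n_b - N), min(n_a, n_b)
    if not j_min <= j_obs <= j_max:
        raise ValueError(
            f"infeasible j_obs={j_obs}; range [{j_min}, {j_max}] for "
            f"N={N}, n_a={n_a}, n_b={n_b}"
        )
    cut = j_obs - 1 if inclusive else j_obs
    return float(sps.hypergeom.sf(cut, N, n_a, n_b))


def _pair_table(
    presence: np.ndarray, taxa: list[str], inclusive: bool
) -> pd.DataFrame:
    """All unordered pairs with presence counts, co-presence and p-values."""
    n = presence.sum(axis=1).astype(int)
    N = presence.shape[1]
    J = presence @ presence.T
    ia, ib = np.triu_indices(len(taxa), k=1)
    j_obs = J[ia, ib].astype(int)
    cut = j_obs - 1 if inclusive else j_obs
    p = sps.hypergeom.sf(cut, N, n[ia], n[ib])
    return pd.DataFrame(
        {
            "taxon_a": np.asarray(taxa, dtype=object)[ia],
            "taxon_b": np.asarray(taxa, dtype=object)[ib],
            "n_a": n[ia],
            "n_b": n[ib],
            "j_obs": j_obs,
            "p_value": p,
        }
    )


def build_network(
    presence: pd.DataFrame,
    alpha: float = 0.05,
    kingdom: str | None = None,
    inclusive: bool = True,
    fdr: bool = False,
    min_expected: float | None = None,
) -> CooccurrenceNetwork:
    """Test all unordered core-taxon pairs and keep significant co-presences.

    Taxa present in zero or in all sites are uninformative (the tail
    probability is 1 by construction) and are skipped from testing but kept
    as isolated nodes.  Only positive associations become edges; significant
    segregation (lower-tail) pairs are reported in a side table.  ``fdr``
    applies Benjamini-Hochberg to the co-presence p-values before
    thresholding; ``min_expected`` drops pairs whose expected co-occurrence
    n_a n_b / N falls below the given value.  Both are off by default.
    """
    if presence.shape[0] < 2 or presence.shape[1] < 2:
        raise ValueError("need at least 2 taxa and 2 sites")
    mat = (presence.to_numpy() > 0).astype(np.int64)
    prevalence = mat.sum(axis=1)
    informative = (prevalence > 0) & (prevalence < presence.shape[1])
    skipped = [t for t, ok in zip(presence.index, informative) if not ok]
    if skipped:
        log.info("build_network: skipped %d zero/full-prevalence taxa", len(skipped))
    taxa = [str(t) for t in presence.index[informative]]
    pairs = _pair_table(mat[informative], taxa, inclusive)
    if min_expected is not None:
        pairs = pairs[pairs.n_a * pairs.n_b / presence.shape[1] >= min_expected]
    pvals = pairs["p_value"].to_numpy()
    if fdr and len(pvals):
        order = np.argsort(pvals)
        ranked = pvals[order] * len(pvals) / (np.arange(len(pvals)) + 1)
        qvals = np.empty_like(pvals)
        qvals[order] = np.minimum.accumulate(ranked[::-1])[::-1].clip(max=1)
        keep = qvals < alpha
    else:
        keep = pvals < alpha
    edges = pairs[keep].reset_index(drop=True)

    # lower tail: significantly fewer co-presences than expected (avoidance)
    N = presence.shape[1]
    p_low = sps.hypergeom.cdf(
        pairs["j_obs"].to_numpy(), N, pairs["n_a"].to_numpy(), pairs["n_b"].to_numpy()
    )
    segregation = pairs[p_low < alpha].assign(p_lower=p_low[p_low < alpha]).reset_index(
        drop=True
    )
    return CooccurrenceNetwork(
        nodes=[str(t) for t in presence.index],
        edges=edges,
        kingdom=kingdom,
        segregation=segregation,
        skipped=[str(t) for t in skipped],
    )


def detect_modules(
    net: CooccurrenceNetwork, steps: int = 4, seed: int | None = None
) -> CooccurrenceNetwork:
    """Walktrap module detection, per connected component, cut at maximum
    modularity.  Isolated nodes become singleton modules.  Module ids are
    assigned by descending module size; modularity is reported on the full
    graph (0 by convention for an empty edge set).
    """
    idx = {t: i for i, t in enumerate(net.nodes)}
    g = ig.Graph(
        n=len(net.nodes),
        edges=[(idx[a], idx[b]) for a, b in zip(net.edges.taxon_a, net.edges.taxon_b)],
    )
    membership_raw = np.zeros(len(net.nodes), dtype=int)
    next_id = 0
    for comp in g.connected_components():
        sub = g.subgraph(comp)
        if sub.ecount() == 0:
            membership_raw[comp] = next_id
            next_id += 1
            continue
        dendro = sub.community_walktrap(steps=steps)
        clustering = dendro.as_clustering()  # cut maximizing modularity
        local = np.asarray(clustering.membership)
        for v, m in zip(comp, local):
            membership_raw[v] = next_id + m
        next_id += local.max() + 1
    sizes = pd.Series(membership_raw).value_counts()
    order = sorted(sizes.index, key=lambda m: (-sizes[m], m))
    remap = {old: new + 1 for new, old in enumerate(order)}
    membership = {t: remap[membership_raw[i]] for t, i in idx.items()}
    if g.ecount() == 0:
        modularity = 0.0
    else:
        modularity = float(g.modularity([membership[t] - 1 for t in net.nodes]))
    return dataclasses.replace(net, membership=membership, modularity=modularity)


def main_modules(net: CooccurrenceNetwork, min_size: int = 5) -> CooccurrenceNetwork:
    """Flag modules with >= min_size nodes as main; the rest form a residual
    class for reporting."""
    if not net.membership:
        raise ValueError("modules not set; run detect_modules first")
    sizes = net.module_sizes()
    main = {int(m) for m, s in sizes.items() if s >= min_size}
    return dataclasses.replace(net, main_modules=main)


def modularity_brute_force(nodes: list[str], edges: list[tuple[str, str]]) -> tuple[float, dict]:
    """Exhaustive maximum-modularity partition for tiny graphs (test oracle)."""
    idx = {t: i for i, t in enumerate(nodes)}
    g = ig.Graph(n=len(nodes), edges=[(idx[a], idx[b]) for a, b in edges])
    best_q, best_part = -1.0, None
    n = len(nodes)

    def partitions(items):
        if not items:
            yield []
            return
        first, rest = items[0], items[1:]
        for part in partitions(rest):
            for i, block in enumerate(part):
                yield part[:i] + [block + [first]] + part[i + 1:]
            yield [[first]] + part

    for part in partitions(list(range(n))):
        member = np.empty(n, dtype=int)
        for m, block in enumerate(part):
            member[block] = m
        q = g.modularity(member)
        if q > best_q:
            best_q, best_part = q, {nodes[i]: int(member[i]) for i in range(n)}
    return best_q, best_part
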
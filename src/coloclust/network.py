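"""Variant-trait Z matrix, correlation network, spinglass clustering.

Variants that colocalized with at least one trait are rows of a sparse
variant x trait matrix of association z-scores (aligned to the index trait's
effect-increasing allele); an entry survives only when the variant
colocalized with that trait and the association clears a sample-size-aware
significance gate (genome-wide 5e-8 for large studies, 1e-5 otherwise), and
is exactly 0 otherwise.  Pearson correlation between variant rows defines a
weighted network; edges below the highest cutoff at which every vertex still
keeps at least one edge are pruned; spinglass community detection (simulated
annealing on the Reichardt-Bornholdt Hamiltonian, via igraph) partitions the
variants into an emergent number of clusters, scored by weighted modularity.
Clusters smaller than ``min_cluster_size`` are excluded from the retained set
(the conventional "fewer than 4 variants" exclusion).
"""

from __future__ import annotations

import logging
import random
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class ZMatrixConfig:
    p_gate_large: float = 5e-8
    p_gate_small: float = 1e-5
    n_threshold: int = 60_000

    def __post_init__(self) -> None:
        if not self.p_gate_large < self.p_gate_small:
            raise ValueError("p_gate_large must be stricter than p_gate_small")
        if self.n_threshold <= 0:
            raise ValueError("n_threshold must be positive")


@dataclass
class ClusterConfig:
    gamma: float = 1.0
    n_restarts: int = 20
    seed: int = 0
    temp_start: float = 1.0
    temp_end: float = 0.01
    cooling: float = 0.99
    min_cluster_size: int = 4
    spins: int = 25
    require_connected: bool = False

    def __post_init__(self) -> None:
        if self.min_cluster_size < 1:
            raise ValueError("min_cluster_size must be >= 1")
        if not 0 < self.cooling < 1:
            raise ValueError("cooling factor must be in (0, 1)")


@dataclass
class ClusterSolution:
    membership: dict[str, int]          # variant -> cluster label (all variants)
    k: int
    modularity: float
    cutoff: float
    retained: list[int]                 # labels with >= min_cluster_size members
    signature: pd.DataFrame | None = None

    def labels(self, ids: list[str]) -> np.ndarray:
        return np.array([self.membership[v] for v in ids])

    def retained_members(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {c: [] for c in self.retained}
        for v, c in self.membership.items():
            if c in out:
                out[c].append(v)
        return out


# ---------------------------------------------------------------------------
# Z matrix
# ---------------------------------------------------------------------------


def build_zmatrix(events, sumstats: dict[str, pd.DataFrame], cfg: ZMatrixConfig | None = None,
                  traits: list[str] | None = None, index_trait: str | None = None) -> pd.DataFrame:
    """Sparse variant x trait matrix of colocalized, gate-passing z-scores.

    ``events`` is a list of accepted ColocEvents; ``sumstats`` maps trait
    label to a harmonized table (canonical columns + Z) indexed or indexable
    by SNP.  The entry (lead variant, trait) is the trait's z at the lead,
    aligned to the index-trait effect-increasing allele, when the trait
    colocalized there and p clears its sample-size gate; 0 otherwise.
    """
    cfg = cfg or ZMatrixConfig()
    lookups = {}
    for t, df in sumstats.items():
        lookups[t] = df if df.index.name == "SNP" else df.set_index("SNP")
    if traits is None:
        traits = sorted({t for ev in events for t in ev.traits if t != index_trait})
    variant_ids: list[str] = []
    for ev in events:
        if ev.lead_id is not None and ev.lead_id not in variant_ids:
            variant_ids.append(ev.lead_id)
    zmat = pd.DataFrame(0.0, index=variant_ids, columns=traits)
    for ev in events:
        if ev.lead_id is None:
            continue
        for t in ev.traits:
            if t == index_trait or t not in traits:
                continue
            table = lookups.get(t)
            if table is None or ev.lead_id not in table.index:
                raise KeyError(f"lead variant {ev.lead_id} unresolvable in trait {t!r}")
            row = table.loc[ev.lead_id]
            if isinstance(row, pd.DataFrame):   # duplicated id across regions
                row = row.iloc[0]
            gate = cfg.p_gate_large if float(row["N"]) > cfg.n_threshold else cfg.p_gate_small
            if float(row["P"]) < gate:
                zmat.loc[ev.lead_id, t] = float(row["Z"])
    zmat.index.name = "SNP"
    return zmat


def snp_correlation(zmat: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation between variant rows (zeros count as values).

    Rows with zero variance get correlation 0 to all others (logged).
    """
    if zmat.shape[1] < 2:
        raise ValueError("need at least 2 traits to correlate variant profiles")
    values = zmat.to_numpy(dtype=float)
    sd = values.std(axis=1)
    degenerate = sd == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(values)
    corr = np.where(np.isnan(corr), 0.0, corr)
    corr = (corr + corr.T) / 2.0
    if degenerate.any():
        logger.info("snp_correlation: %d zero-variance rows set to correlation 0",
                    int(degenerate.sum()))
        corr[degenerate, :] = 0.0
        corr[:, degenerate] = 0.0
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=zmat.index, columns=zmat.index)


# ---------------------------------------------------------------------------
# Threshold search
# ---------------------------------------------------------------------------


def min_degree_threshold(corr: pd.DataFrame | np.ndarray) -> float:
    """Highest |correlation| cutoff at which every vertex keeps >= 1 edge.

    Edges are {|corr| >= c}; the search runs over the unique absolute
    off-diagonal values.  Vertices with all-zero correlations are reported and
    excluded before the search.  At cutoff c a vertex keeps an edge iff its
    largest off-diagonal |corr| is >= c, so the answer is the minimum over
    vertices of the per-row maximum.
    """
    if isinstance(corr, pd.DataFrame):
        names = list(corr.index)
        A = corr.to_numpy(dtype=float)
    else:
        A = np.asarray(corr, dtype=float)
        names = list(range(A.shape[0]))
    if A.shape[0] < 2:
        raise ValueError("need at least 2 variants")
    A = np.abs((A + A.T) / 2.0)     # guard against 1-ulp asymmetry
    np.fill_diagonal(A, 0.0)
    row_max = A.max(axis=1)
    isolated = row_max == 0
    if isolated.any():
        logger.warning("min_degree_threshold: excluding isolated vertices %s",
                       [names[i] for i in np.flatnonzero(isolated)])
        if isolated.all():
            raise ValueError("all vertices are isolated")
        keep = ~isolated
        A = A[np.ix_(keep, keep)]
        row_max = A.max(axis=1)
    return float(row_max.min())


# ---------------------------------------------------------------------------
# Modularity and spinglass clustering
# ---------------------------------------------------------------------------


def modularity(graph: pd.DataFrame | np.ndarray, membership) -> float:
    """Weighted Newman modularity Q = sum_c [ w_c/W - (d_c / 2W)^2 ].

    ``graph`` is a symmetric non-negative weight matrix (zero diagonal
    assumed); ``membership`` maps node order to community labels (array-like,
    or dict keyed by the DataFrame index).
    """
    if isinstance(graph, pd.DataFrame):
        A = graph.to_numpy(dtype=float)
        if isinstance(membership, dict):
            membership = [membership[v] for v in graph.index]
    else:
        A = np.asarray(graph, dtype=float)
        if isinstance(membership, dict):
            membership = [membership[i] for i in range(A.shape[0])]
    labels = np.asarray(membership)
    if labels.shape[0] != A.shape[0]:
        raise ValueError("membership does not cover all nodes")
    A = A.copy()
    np.fill_diagonal(A, 0.0)
    two_w = A.sum()                      # = 2W for a symmetric matrix
    if two_w == 0:
        return 0.0
    degrees = A.sum(axis=1)
    q = 0.0
    for c in np.unique(labels):
        mask = labels == c
        w_c = A[np.ix_(mask, mask)].sum() / 2.0
        d_c = degrees[mask].sum()
        q += w_c / (two_w / 2.0) - (d_c / two_w) ** 2
    return float(q)


def _prune(corr: pd.DataFrame, cutoff: float) -> tuple[list[str], np.ndarray]:
    """Adjacency of the pruned graph: edges |corr| >= cutoff, signed weights
    retained, negative weights clipped to 0 for the spinglass null model."""
    names = list(corr.index)
    A = corr.to_numpy(dtype=float)
    A = (A + A.T) / 2.0
    np.fill_diagonal(A, 0.0)
    A[np.abs(A) < cutoff] = 0.0
    A = np.clip(A, 0.0, None)
    return names, A


def spinglass_cluster(corr: pd.DataFrame, cutoff: float,
                      cfg: ClusterConfig | None = None) -> ClusterSolution:
    """Spinglass community detection on the pruned correlation network.

    Runs ``n_restarts`` independently seeded annealing runs per connected
    component (labels offset across components) and keeps the partition with
    maximal weighted modularity; the number of clusters is emergent.  Clusters
    below ``min_cluster_size`` stay in the membership but are excluded from
    ``retained``.
    """
    import igraph as ig

    cfg = cfg or ClusterConfig()
    names, A = _prune(corr, cutoff)
    g = ig.Graph.Weighted_Adjacency(A.tolist(), mode="undirected", attr="weight", loops=False)
    g.vs["name"] = names
    if g.ecount() == 0:
        raise ValueError("pruned graph has no edges")

    components = g.connected_components()
    if len(components) > 1:
        if cfg.require_connected:
            raise ValueError(f"pruned graph is disconnected ({len(components)} components)")
        logger.info("pruned graph has %d components; clustering each independently",
                    len(components))

    membership_arr = np.zeros(g.vcount(), dtype=int)
    offset = 0
    for comp in components:
        sub = g.induced_subgraph(comp)
        # spinglass is degenerate (and can spin forever) below 3 nodes
        if sub.vcount() <= 2 or sub.ecount() == 0:
            for v in comp:
                membership_arr[v] = offset
            offset += 1
            continue
        best_labels, best_q = None, -np.inf
        sub_adj = np.asarray(sub.get_adjacency(attribute="weight").data, dtype=float)
        spins = min(cfg.spins, sub.vcount())
        for s in range(cfg.seed, cfg.seed + cfg.n_restarts):
            ig.set_random_number_generator(random.Random(s))
            part = sub.community_spinglass(
                weights="weight", spins=spins, gamma=cfg.gamma, update_rule="config",
                start_temp=cfg.temp_start, stop_temp=cfg.temp_end, cool_fact=cfg.cooling,
            )
            q = modularity(sub_adj, np.asarray(part.membership))
            if q > best_q:
                best_q, best_labels = q, np.asarray(part.membership)
        ig.set_random_number_generator(None)    # restore igraph's default RNG
        for v, lab in zip(comp, best_labels):
            membership_arr[v] = offset + int(lab)
        offset += int(best_labels.max()) + 1

    q_total = modularity(A, membership_arr)
    counts = pd.Series(membership_arr).value_counts()
    retained = sorted(int(c) for c, n in counts.items() if n >= cfg.min_cluster_size)
    dropped = [int(c) for c in counts.index if c not in retained]
    if dropped:
        logger.info("clusters %s below min size %d excluded from retained set",
                    dropped, cfg.min_cluster_size)
    return ClusterSolution(
        membership={v: int(c) for v, c in zip(names, membership_arr)},
        k=int(counts.size),
        modularity=float(q_total),
        cutoff=float(cutoff),
        retained=retained,
    )


def summarize_clusters(zmat: pd.DataFrame, solution: ClusterSolution) -> pd.DataFrame:
    """Mean z per (retained cluster, trait), sorted by cluster then trait."""
    rows = []
    for c, members in sorted(solution.retained_members().items()):
        means = zmat.loc[members].mean(axis=0)
        for trait in sorted(zmat.columns):
            rows.append({"CLUSTER": c, "TRAIT": trait, "MEAN_Z": float(means[trait]),
                         "N_VARIANTS": len(members)})
    return pd.DataFrame(rows, columns=["CLUSTER", "TRAIT", "MEAN_Z", "N_VARIANTS"])


def plot_signature_heatmap(signature: pd.DataFrame, ax=None):
    """Basic heatmap of the cluster x trait mean-z signature table."""
    import matplotlib.pyplot as plt

    wide = signature.pivot(index="CLUSTER", columns="TRAIT", values="MEAN_Z")
    if ax is None:
        _, ax = plt.subplots(figsize=(1 + 0.6 * wide.shape[1], 1 + 0.5 * wide.shape[0]))
    vmax = np.nanmax(np.abs(wide.to_numpy())) or 1.0
    im = ax.imshow(wide.to_numpy(), cmap="RdBu_r", vmin=-vmax, vmax=vmax)
    ax.set_xticks(range(wide.shape[1]), wide.columns, rotation=45, ha="right")
    ax.set_yticks(range(wide.shape[0]), [f"cluster {c}" for c in wide.index])
    ax.figure.colorbar(im, ax=ax, label="mean z")
    return ax
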
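"""Gene-to-gene connection network statistics.

From primer-assigned RACEfrags a directed connection graph is built: an
edge A -> B in sample t means a fragment of sample t assigned to a primer
of gene A falls within the locus boundaries of gene B.  On this graph the
module computes reciprocity classes (pure / composite), map composition
and sensitivity, clique counts against a degree-preserving randomized
null, covariate-aware hub detection, expression coordination of connected
genes, and the power-law fit of primer-to-fragment distances.
"""

from __future__ import annotations

import math
import warnings
from collections import defaultdict
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import GeneModel, GenomicInterval, interval_gap

__all__ = [
    "ConnectionGraph",
    "HubReport",
    "PowerLawFit",
    "build_graph",
    "reciprocal_connections",
    "map_statistics",
    "clique_analysis",
    "randomize_network",
    "hub_detection",
    "expression_coordination",
    "fit_powerlaw",
    "gene_gene_distance",
]

#: Genomic distance bins used for genome-scale connection tallies (nt gaps).
DEFAULT_DISTANCE_BINS = (150_000, 1_000_000, 5_000_000)


@dataclass
class ConnectionGraph:
    """Directed per-sample gene connection graph plus node covariates."""

    digraph: nx.DiGraph
    genes: dict[str, GeneModel] = field(default_factory=dict)

    def samples(self) -> set[str]:
        out: set[str] = set()
        for _u, _v, data in self.digraph.edges(data=True):
            out |= data["samples"]
        return out

    def undirected(self) -> nx.Graph:
        """Collapse direction: an undirected edge per connected gene pair."""
        g = nx.Graph()
        g.add_nodes_from(self.digraph.nodes(data=True))
        for u, v, data in self.digraph.edges(data=True):
            if g.has_edge(u, v):
                g[u][v]["samples"] = g[u][v]["samples"] | data["samples"]
            else:
                g.add_edge(u, v, samples=set(data["samples"]))
        return g

    def reciprocal_graph(self) -> nx.Graph:
        """Undirected graph restricted to reciprocally connected pairs."""
        g = nx.Graph()
        g.add_nodes_from(self.digraph.nodes(data=True))
        for u, v in self.digraph.edges():
            if u < v and self.digraph.has_edge(v, u):
                s_ab = self.digraph[u][v]["samples"]
                s_ba = self.digraph[v][u]["samples"]
                g.add_edge(
                    u, v,
                    samples=s_ab | s_ba,
                    pure=bool(s_ab & s_ba),
                    shared_samples=s_ab & s_ba,
                )
        return g


def build_graph(assignments, genes: list[GeneModel], primers=None) -> ConnectionGraph:
    """Build the directed connection graph from assignments.

    Edge A -> B in sample t iff a sample-t fragment assigned to a primer of
    A overlaps the locus of B (B != A); multiplicity within a sample
    collapses to presence.  Node attributes carry locus, gene length and
    primer count (used by the hub null model).
    """
    n_primers: dict[str, int] = defaultdict(int)
    for p in primers or ():
        n_primers[p.gene_id] += 1
    dg = nx.DiGraph()
    gene_map = {g.gene_id: g for g in genes}
    for g in genes:
        dg.add_node(
            g.gene_id,
            locus=g.locus,
            length=len(g.locus),
            n_primers=max(1, n_primers.get(g.gene_id, 0)),
        )
    for a in assignments:
        src = a.locus_id
        iv = a.frag.interval
        sample = a.frag.experiment.sample_id
        for g in genes:
            if g.gene_id == src:
                continue
            if g.locus.overlaps(iv):
                if dg.has_edge(src, g.gene_id):
                    dg[src][g.gene_id]["samples"].add(sample)
                else:
                    dg.add_edge(src, g.gene_id, samples={sample})
    return ConnectionGraph(digraph=dg, genes=gene_map)


def gene_gene_distance(a: GenomicInterval, b: GenomicInterval) -> float:
    """Nearest-edge gap between two loci; 0 if overlapping, inf across
    chromosomes."""
    if a.chrom != b.chrom:
        return math.inf
    return float(interval_gap(a, b))


def reciprocal_connections(
    g: ConnectionGraph,
    distance_bins: tuple[int, ...] = DEFAULT_DISTANCE_BINS,
) -> dict:
    """Label reciprocal pairs and tally them per sample and distance bin.

    A pair (A, B) is reciprocal iff both directions are present; *pure* iff
    both directions co-occur in at least one sample, *composite* when its
    reciprocity can only be deduced from different samples.  A pair is
    *unique* to a sample when that is the only sample supporting it.
    """
    rg = g.reciprocal_graph()
    rows = []
    for u, v, data in rg.edges(data=True):
        a, b = sorted((u, v))
        dist = gene_gene_distance(g.digraph.nodes[a]["locus"], g.digraph.nodes[b]["locus"])
        rows.append(
            {
                "gene_a": a,
                "gene_b": b,
                "label": "pure" if data["pure"] else "composite",
                "samples": ",".join(sorted(data["samples"])),
                "n_samples": len(data["samples"]),
                "unique_sample": next(iter(data["samples"])) if len(data["samples"]) == 1 else "",
                "distance_nt": dist,
                "distance_bin": _bin_label(dist, distance_bins),
            }
        )
    pairs = pd.DataFrame(
        rows,
        columns=["gene_a", "gene_b", "label", "samples", "n_samples",
                 "unique_sample", "distance_nt", "distance_bin"],
    )
    per_sample: dict[str, int] = defaultdict(int)
    for _u, _v, data in rg.edges(data=True):
        for s in data["samples"]:
            per_sample[s] += 1
    n_total = len(pairs)
    n_specific = int((pairs["n_samples"] == 1).sum()) if n_total else 0
    return {
        "pairs": pairs,
        "n_reciprocal": n_total,
        "n_pure": int((pairs["label"] == "pure").sum()) if n_total else 0,
        "cell_type_specific_fraction": n_specific / n_total if n_total else float("nan"),
        "per_sample_counts": dict(per_sample),
        "bin_counts": pairs["distance_bin"].value_counts().to_dict() if n_total else {},
    }


def _bin_label(dist: float, edges: tuple[int, ...]) -> str:
    if math.isinf(dist):
        return "trans"
    prev = 0
    for e in edges:
        if dist < e:
            return f"{prev}-{e}"
        prev = e
    return f">{edges[-1]}"


def map_statistics(assignments, genes: list[GeneModel], primers) -> dict:
    """Fragment map composition and exon-connection sensitivity.

    Composition classifies each assigned fragment as internal to its index
    gene / external genic / intergenic, and exonic vs intronic.
    Sensitivity: a same-transcript exon pair (e1, e2) is *detectable* when
    a primer inside one exon points at the other; it is *detected* when a
    fragment assigned to such a primer overlaps the partner exon.
    """
    exon_unions = {g.gene_id: g.exon_union() for g in genes}
    rows = []
    for a in assignments:
        iv = a.frag.interval
        host = next(
            (g for g in genes if g.gene_id == a.locus_id and g.locus.overlaps(iv)), None
        )
        if host is not None:
            location = "internal"
        else:
            host = next((g for g in genes if g.locus.overlaps(iv)), None)
            location = "external_genic" if host is not None else "intergenic"
        exonic = bool(
            host and any(iv.overlaps(ex) for ex in exon_unions[host.gene_id])
        )
        rows.append(
            {"location": location, "structure": "exonic" if exonic else
             ("intronic" if host else "intergenic")}
        )
    composition = pd.DataFrame(rows, columns=["location", "structure"])

    frags_by_primer: dict[str, list[GenomicInterval]] = defaultdict(list)
    for a in assignments:
        frags_by_primer[a.primer_id].append(a.frag.interval)
    by_gene_primers: dict[str, list] = defaultdict(list)
    for p in primers:
        by_gene_primers[p.gene_id].append(p)
    detectable = detected = 0
    for g in genes:
        for tx in g.transcripts:
            for i, e1 in enumerate(tx):
                for e2 in tx[i + 1:]:
                    qualifying = [
                        p for p in by_gene_primers[g.gene_id]
                        for anchor, partner in ((e1, e2), (e2, e1))
                        if anchor.overlaps(p.span) and _points_at(p, partner)
                    ]
                    if not qualifying:
                        continue
                    detectable += 1
                    if any(
                        iv.overlaps(partner)
                        for p in qualifying
                        for anchor, partner in ((e1, e2), (e2, e1))
                        if anchor.overlaps(p.span) and _points_at(p, partner)
                        for iv in frags_by_primer.get(p.primer_id, ())
                    ):
                        detected += 1
    return {
        "composition": composition,
        "composition_counts": composition.value_counts().to_dict() if len(composition) else {},
        "detectable_exon_connections": detectable,
        "detected_exon_connections": detected,
        "sensitivity": detected / detectable if detectable else float("nan"),
    }


def _points_at(primer, target: GenomicInterval) -> bool:
    if primer.span.chrom != target.chrom:
        return False
    if primer.amp_direction == "+":
        return target.end > primer.span.start
    return target.start < primer.span.end


def _clique_counts(g: nx.Graph, k_max: int) -> dict[int, int]:
    counts = {k: 0 for k in range(2, k_max + 1)}
    for clique in nx.enumerate_all_cliques(g):
        k = len(clique)
        if k > k_max:
            break  # enumerate_all_cliques yields in non-decreasing size
        if k >= 2:
            counts[k] += 1
    return counts


def randomize_network(g: nx.Graph, seed: int, n_swaps: int | None = None) -> nx.Graph:
    """Degree-preserving randomization by double edge swaps.

    Performs ``n_swaps`` accepted swaps (default 10x the edge count); the
    degree sequence is preserved exactly and no self-loops or multi-edges
    are introduced.  Graphs with fewer than 2 edges are returned unchanged
    with a warning.
    """
    out = g.copy()
    m = out.number_of_edges()
    if m < 2:
        warnings.warn("graph has < 2 edges; returned unchanged", stacklevel=2)
        return out
    if n_swaps is None:
        n_swaps = 10 * m
    try:
        nx.double_edge_swap(out, nswap=n_swaps, max_tries=max(1000, 100 * n_swaps), seed=seed)
    except nx.NetworkXError as e:  # e.g. no valid swap exists (tiny path graphs)
        warnings.warn(f"double edge swap aborted: {e}", stacklevel=2)
    except nx.NetworkXAlgorithmError:
        pass  # max_tries exhausted after some accepted swaps; still degree-preserving
    return out


def clique_analysis(
    g: ConnectionGraph | nx.Graph,
    k_max: int = 7,
    n_rand: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Clique census against a degree-preserving null.

    Counts complete subgraphs of each size 2..k_max (all k-cliques) and
    separately maximal cliques, then the same counts on ``n_rand``
    randomized networks; enrichment is observed / null mean.
    """
    if k_max < 2:
        raise ValueError("k_max must be >= 2")
    ug = g.reciprocal_graph() if isinstance(g, ConnectionGraph) else g
    obs = _clique_counts(ug, k_max)
    obs_maximal = {k: 0 for k in range(2, k_max + 1)}
    for clique in nx.find_cliques(ug):
        k = len(clique)
        if 2 <= k <= k_max:
            obs_maximal[k] += 1
    null = {k: [] for k in range(2, k_max + 1)}
    for r in range(n_rand):
        rand = randomize_network(ug, seed=seed + r)
        rc = _clique_counts(rand, k_max)
        for k in null:
            null[k].append(rc[k])
    rows = []
    for k in range(2, k_max + 1):
        arr = np.array(null[k], float)
        mean = float(arr.mean()) if arr.size else float("nan")
        rows.append(
            {
                "size": k,
                "observed": obs[k],
                "observed_maximal": obs_maximal[k],
                "null_mean": mean,
                "null_sd": float(arr.std(ddof=1)) if arr.size > 1 else float("nan"),
                "enrichment": obs[k] / mean if mean else float("nan"),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class HubReport:
    """Per-gene observed vs expected connectivity and hub flags."""

    table: pd.DataFrame  # gene_id, observed, expected, score, hub
    hub_quantile: float

    @property
    def hubs(self) -> list[str]:
        return self.table.loc[self.table["hub"], "gene_id"].tolist()


def hub_detection(
    g: ConnectionGraph,
    n_rand: int = 200,
    seed: int = 0,
    hub_quantile: float = 0.83,
) -> HubReport:
    """Find genes with more connections than their covariates explain.

    The null redraws the observed number of undirected edges with endpoint
    probabilities proportional to gene length x primer count (no
    self-loops); the expected connectivity of a gene is its mean degree
    over ``n_rand`` such draws.  Score = observed - expected; hubs are the
    genes whose score exceeds the ``hub_quantile`` quantile of the score
    distribution.
    """
    ug = g.undirected()
    nodes = list(ug.nodes())
    n = len(nodes)
    observed = np.array([ug.degree(v) for v in nodes], float)
    w = np.array(
        [ug.nodes[v]["length"] * ug.nodes[v].get("n_primers", 1) for v in nodes], float
    )
    p = w / w.sum()
    m = ug.number_of_edges()
    rng = np.random.default_rng(seed)
    counts = np.zeros(n, float)
    for _ in range(n_rand):
        u_idx = rng.choice(n, size=m, p=p)
        v_idx = rng.choice(n, size=m, p=p)
        bad = u_idx == v_idx
        while bad.any():  # redraw self-loops
            v_idx[bad] = rng.choice(n, size=int(bad.sum()), p=p)
            bad = u_idx == v_idx
        counts += np.bincount(u_idx, minlength=n) + np.bincount(v_idx, minlength=n)
    expected = counts / max(1, n_rand)
    score = observed - expected
    threshold = float(np.quantile(score, hub_quantile)) if n else float("nan")
    table = pd.DataFrame(
        {
            "gene_id": nodes,
            "observed": observed,
            "expected": expected,
            "score": score,
            "hub": score > threshold,
        }
    )
    return HubReport(table=table, hub_quantile=hub_quantile)


def expression_coordination(
    expr: pd.DataFrame,
    g: ConnectionGraph,
    cliques: list[set[str]] | None = None,
) -> dict:
    """Expression coordination of connected vs non-connected gene pairs.

    ``expr``: genes x samples expression matrix (index = gene ids).
    Reports group mean Pearson correlations, clique stratification (within
    -clique pairs and the correlation of pair r with clique size), and a
    distance-adjusted linear model r ~ connected + log10(gap+1) whose
    connectivity coefficient stands in for the covariance-adjusted group
    comparison.  Pairs with a constant profile are skipped and counted.
    """
    import statsmodels.api as sm

    ug = g.undirected()
    genes = [x for x in expr.index if x in ug]
    x = expr.loc[genes].to_numpy(float)
    sd = x.std(axis=1)
    keep = sd > 0
    skipped = int((~keep).sum())
    genes = [gid for gid, k in zip(genes, keep) if k]
    x = x[keep]
    r_matrix = np.corrcoef(x)
    clique_size_of_pair: dict[tuple[str, str], int] = {}
    for cl in cliques or []:
        members = sorted(cl)
        for i, a in enumerate(members):
            for b in members[i + 1:]:
                key = (a, b)
                clique_size_of_pair[key] = max(clique_size_of_pair.get(key, 0), len(cl))
    rows = []
    for i, a in enumerate(genes):
        for j in range(i + 1, len(genes)):
            b = genes[j]
            key = (a, b) if a < b else (b, a)
            dist = gene_gene_distance(g.digraph.nodes[a]["locus"], g.digraph.nodes[b]["locus"])
            rows.append(
                {
                    "gene_a": key[0], "gene_b": key[1],
                    "r": float(r_matrix[i, j]),
                    "connected": ug.has_edge(a, b),
                    "clique_size": clique_size_of_pair.get(key, 0),
                    "distance_nt": dist,
                }
            )
    pairs = pd.DataFrame(rows)
    conn = pairs.loc[pairs["connected"], "r"]
    nonconn = pairs.loc[~pairs["connected"], "r"]
    in_clique = pairs.loc[pairs["clique_size"] >= 3, "r"]
    conn_not_clique = pairs.loc[pairs["connected"] & (pairs["clique_size"] < 3), "r"]
    trend_r = trend_p = float("nan")
    cl_pairs = pairs.loc[pairs["clique_size"] >= 2]
    if len(cl_pairs) >= 3 and cl_pairs["clique_size"].nunique() > 1:
        trend_r, trend_p = sps.pearsonr(cl_pairs["clique_size"], cl_pairs["r"])
    effect = pvalue = float("nan")
    finite = pairs.loc[np.isfinite(pairs["distance_nt"])]
    if len(finite) >= 10 and finite["connected"].nunique() > 1:
        X = sm.add_constant(
            np.column_stack(
                [finite["connected"].astype(float), np.log10(finite["distance_nt"] + 1.0)]
            )
        )
        fit = sm.OLS(finite["r"].to_numpy(), X).fit()
        effect, pvalue = float(fit.params[1]), float(fit.pvalues[1])
    return {
        "pairs": pairs,
        "mean_r_connected": float(conn.mean()) if len(conn) else float("nan"),
        "mean_r_nonconnected": float(nonconn.mean()) if len(nonconn) else float("nan"),
        "mean_r_in_clique": float(in_clique.mean()) if len(in_clique) else float("nan"),
        "mean_r_connected_not_in_clique": float(conn_not_clique.mean())
        if len(conn_not_clique) else float("nan"),
        "clique_size_trend_r": float(trend_r),
        "clique_size_trend_p": float(trend_p),
        "distance_adjusted_effect": effect,
        "distance_adjusted_p": pvalue,
        "n_skipped_constant": skipped,
    }


@dataclass
class PowerLawFit:
    exponent: float  # reported as the negative exponent, e.g. -1.5
    method: str
    x_min: float
    n: int
    ks_statistic: float


def fit_powerlaw(distances, x_min: float | None = None, method: str = "mle") -> PowerLawFit:
    """Fit a continuous power law to primer-fragment distances.

    ``mle``: alpha = 1 + n / sum(ln(x_i / x_min)) (continuous maximum
    likelihood), reported as the negative exponent -alpha.  ``ls``: slope
    of a least-squares line through the log-log binned histogram.  Zero
    distances are excluded; n < 10 or an all-equal sample raises.
    """
    x = np.asarray([d for d in distances if d > 0 and np.isfinite(d)], float)
    if x.size < 10:
        raise ValueError(f"need >= 10 positive distances, got {x.size}")
    if x_min is None:
        x_min = float(x.min())
    x = x[x >= x_min]
    if np.allclose(x, x[0]):
        raise ValueError("degenerate sample: all distances equal")
    if method == "mle":
        alpha = 1.0 + x.size / float(np.sum(np.log(x / x_min)))
    elif method == "ls":
        hist, edges = np.histogram(x, bins=np.logspace(np.log10(x_min), np.log10(x.max()), 25))
        centers = np.sqrt(edges[:-1] * edges[1:])
        widths = np.diff(edges)
        dens = hist / widths
        mask = dens > 0
        slope, _ = np.polyfit(np.log10(centers[mask]), np.log10(dens[mask]), 1)
        alpha = -float(slope)
    else:
        raise ValueError(f"unknown method {method!r}")
    xs = np.sort(x)
    emp_cdf = np.arange(1, xs.size + 1) / xs.size
    fit_cdf = 1.0 - (xs / x_min) ** (1.0 - alpha)
    ks = float(np.max(np.abs(emp_cdf - fit_cdf)))
    return PowerLawFit(exponent=-alpha, method=method, x_min=x_min, n=int(x.size), ks_statistic=ks)
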
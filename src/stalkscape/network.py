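"""Weighted gene co-expression network construction and module analysis.

Implements the standard weighted-network workflow from scratch: an unsigned
adjacency a_ij = |cor(x_i, x_j)|^beta with the soft power beta chosen by a
scale-free topology scan, the topological overlap matrix (TOM), module
detection by average-linkage clustering of 1 - TOM with a simplified
dynamic hybrid tree cut, module eigengenes, module-trait correlation
statistics, module membership / gene significance, and hub-gene subnetwork
extraction by intramodular connectivity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

__all__ = [
    "correlation_matrix",
    "adjacency_matrix",
    "scale_free_fit",
    "PowerScan",
    "power_scan",
    "compute_tom",
    "detect_modules",
    "module_colors",
    "module_eigengene",
    "ModuleTraitResult",
    "module_trait",
    "membership_significance",
    "HubNetwork",
    "hub_network",
    "gene_gene_correlation",
]

# The conventional module color sequence (largest module first); unassigned
# genes are "grey".
_COLORS = (
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan", "midnightblue",
    "lightcyan", "grey60", "lightgreen", "lightyellow", "royalblue", "darkred",
    "darkgreen", "darkturquoise", "darkgrey", "orange", "darkorange", "white",
    "skyblue", "saddlebrown", "steelblue",
)


def correlation_matrix(x: pd.DataFrame) -> np.ndarray:
    """Pearson correlation between gene rows; constant genes correlate 0."""
    arr = np.asarray(x, dtype=float)
    sd = arr.std(axis=1)
    const = sd == 0
    if const.any():
        warnings.warn(
            f"{int(const.sum())} constant gene(s); their correlations are set to 0",
            stacklevel=2,
        )
        arr = arr.copy()
        arr[const] = 0.0
        arr[const, 0] = 1.0  # dummy variance; rows zeroed below
    with np.errstate(invalid="ignore"):
        c = np.corrcoef(arr)
    c = np.nan_to_num(c, nan=0.0)
    if const.any():
        c[const, :] = 0.0
        c[:, const] = 0.0
    np.fill_diagonal(c, 1.0)
    return c


def adjacency_matrix(x: pd.DataFrame, beta: int) -> np.ndarray:
    """Unsigned soft-threshold adjacency |cor|^beta with unit diagonal."""
    a = np.abs(correlation_matrix(x)) ** beta
    np.fill_diagonal(a, 1.0)
    return a


def scale_free_fit(k: np.ndarray, n_bins: int = 10) -> tuple[float, float]:
    """Scale-free topology fit of a connectivity vector.

    Connectivities are pooled into logarithmically spaced bins; R^2 is the
    squared correlation of log10(frequency) vs log10(mean k) over occupied
    bins, returned with the fitted slope.
    """
    k = np.asarray(k, dtype=float)
    k = k[k > 0]
    if k.size < 3 or np.isclose(k.min(), k.max()):
        return float("nan"), float("nan")
    edges = np.geomspace(k.min(), k.max() * (1 + 1e-12), n_bins + 1)
    idx = np.clip(np.digitize(k, edges) - 1, 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        sel = idx == b
        if sel.any():
            xs.append(np.log10(k[sel].mean()))
            ys.append(np.log10(sel.sum() / k.size))
    if len(xs) < 3:
        return float("nan"), float("nan")
    slope, _, r, _, _ = stats.linregress(xs, ys)
    return float(r**2), float(slope)


@dataclass
class PowerScan:
    """Per-beta scale-free fit and connectivity summary, plus the chosen beta."""

    table: pd.DataFrame  # beta, r2, slope, mean_k, median_k, max_k
    chosen_beta: int | None
    r2_threshold: float
    mean_k_threshold: float


def power_scan(
    x: pd.DataFrame,
    betas=tuple(range(1, 21)),
    r2_threshold: float = 0.85,
    mean_k_threshold: float | None = None,
) -> PowerScan:
    """Scan candidate soft powers for approximate scale-free topology.

    For each beta the unsigned adjacency is formed and the connectivity
    k_i = sum_{j != i} a_ij summarized. The chosen beta is the smallest one
    with fit R^2 > ``r2_threshold`` and mean connectivity below
    ``mean_k_threshold``. The connectivity criterion of 100 refers to a
    ~20k-gene network; by default it is rescaled proportionally to the gene
    count (``100 * n_genes / 20000``).
    """
    if x.shape[1] < 4:
        raise ValueError("power_scan needs at least 4 samples")
    n = x.shape[0]
    if mean_k_threshold is None:
        mean_k_threshold = 100.0 * n / 20000.0
    ac = np.abs(correlation_matrix(x))
    rows = []
    chosen = None
    for beta in betas:
        a = ac**beta
        np.fill_diagonal(a, 0.0)
        k = a.sum(axis=1)
        r2, slope = scale_free_fit(k)
        rows.append(
            {
                "beta": beta,
                "r2": r2,
                "slope": slope,
                "mean_k": float(k.mean()),
                "median_k": float(np.median(k)),
                "max_k": float(k.max()),
            }
        )
        if (
            chosen is None
            and np.isfinite(r2)
            and r2 > r2_threshold
            and slope < 0
            and k.mean() < mean_k_threshold
        ):
            chosen = int(beta)
    return PowerScan(pd.DataFrame(rows), chosen, r2_threshold, mean_k_threshold)


def compute_tom(adjacency: np.ndarray) -> np.ndarray:
    """Topological overlap matrix of a symmetric adjacency with unit diagonal.

    TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij) where
    l_ij = sum_{u != i,j} a_iu a_uj and k_i = sum_{u != i} a_iu; diagonal 1.
    """
    a = np.asarray(adjacency, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.allclose(a, a.T, atol=1e-10):
        raise ValueError("adjacency must be symmetric")
    a = a.copy()
    np.fill_diagonal(a, 1.0)
    sq = a @ a
    l = sq - 2.0 * a  # removes the u=i and u=j terms (diag = 1)
    k = a.sum(axis=0) - 1.0
    denom = np.minimum.outer(k, k) + 1.0 - a
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = (l + a) / denom
    tom = np.nan_to_num(tom, nan=0.0)
    np.fill_diagonal(tom, 1.0)
    return np.clip(tom, 0.0, 1.0)


def detect_modules(
    tom: np.ndarray,
    gene_ids=None,
    min_module_size: int = 50,
    cut_height: float = 0.95,
    strength_fraction: float = 0.5,
) -> pd.Series:
    """Detect co-expression modules from a TOM.

    Average-linkage hierarchical clustering of the dissimilarity 1 - TOM,
    followed by a simplified dynamic hybrid cut: a static cut of the
    dendrogram at ``cut_height`` yields branch cores, branches of at least
    ``min_module_size`` genes become module cores, and every gene's final
    membership is then decided by topological proximity: a gene joins the
    core it has the highest mean TOM to, provided that mean reaches
    ``strength_fraction`` times the core's median member-to-core similarity.
    This both reattaches genes split off on small branches and rejects
    weakly attached passengers. Genes failing every core form the
    unassigned pool (label 0, conventionally "grey"); modules falling below
    ``min_module_size`` after refinement are dissolved into it.

    Returns an integer label Series (1 = largest module, 0 = unassigned).
    """
    tom = np.asarray(tom, dtype=float)
    n = tom.shape[0]
    if gene_ids is None:
        gene_ids = pd.RangeIndex(n)
    dis = 1.0 - tom
    np.fill_diagonal(dis, 0.0)
    z = linkage(squareform(dis, checks=False), method="average")
    branches = fcluster(z, t=cut_height, criterion="distance")

    labels = np.zeros(n, dtype=int)
    sizes = pd.Series(branches).value_counts()
    big = sorted(
        (b for b in sizes.index if sizes[b] >= min_module_size),
        key=lambda b: -sizes[b],
    )
    for new, b in enumerate(big, start=1):
        labels[branches == b] = new

    if big:
        cores = [np.where(labels == m)[0] for m in range(1, len(big) + 1)]
        is_core = np.zeros((n, len(big)), dtype=bool)
        strength = np.empty((n, len(big)))
        thresholds = np.empty(len(big))
        for mi, idx in enumerate(cores):
            is_core[idx, mi] = True
            total = tom[:, idx].sum(axis=1)
            # members exclude their own (diagonal) contribution
            strength[:, mi] = np.where(
                is_core[:, mi],
                (total - 1.0) / max(len(idx) - 1, 1),
                total / len(idx),
            )
            thresholds[mi] = strength_fraction * float(
                np.median(strength[idx, mi])
            )
        best = np.argmax(strength, axis=1)
        ok = strength[np.arange(n), best] >= thresholds[best]
        labels = np.where(ok, best + 1, 0)

    # dissolve undersized modules, relabel by final size (largest first)
    out = np.zeros(n, dtype=int)
    final = pd.Series(labels[labels > 0]).value_counts()
    new = 1
    for old in final.index:
        if final[old] >= min_module_size:
            out[labels == old] = new
            new += 1
    return pd.Series(out, index=gene_ids, name="module")


def module_colors(labels: pd.Series) -> pd.Series:
    """Map integer module labels to conventional color names (0 -> grey)."""

    def color(m: int) -> str:
        if m == 0:
            return "grey"
        if m <= len(_COLORS):
            return _COLORS[m - 1]
        return f"module{m}"

    return labels.map(color).rename("color")


def module_eigengene(x: pd.DataFrame, labels: pd.Series) -> pd.DataFrame:
    """First principal component of each module's standardized submatrix.

    Returns a samples x modules DataFrame of unit-norm eigengenes. The sign
    is fixed so each eigengene correlates positively with the module's mean
    standardized profile; if that mean is degenerate (near zero), the
    eigengene is aligned with the module's first gene. Rank-0 modules yield
    a zero vector with a warning.
    """
    mes = {}
    for m in sorted(set(labels) - {0}):
        genes = labels.index[labels == m]
        sub = x.loc[genes]
        arr = np.asarray(sub, dtype=float)
        mu = arr.mean(axis=1, keepdims=True)
        sd = arr.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        zs = (arr - mu) / sd
        if not np.any(zs):
            warnings.warn(f"module {m} is rank-0; eigengene set to zero", stacklevel=2)
            mes[m] = np.zeros(x.shape[1])
            continue
        _, _, vt = np.linalg.svd(zs, full_matrices=False)
        me = vt[0]
        ref = zs.mean(axis=0)
        align = float(me @ ref)
        if abs(align) < 1e-10:
            align = float(me @ zs[0])
        if align < 0:
            me = -me
        mes[m] = me
    return pd.DataFrame(mes, index=x.columns).rename(columns=lambda m: f"ME{m}")


def _pearson_with_p(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Pearson r with the two-sided Student-t p-value on n-2 df."""
    res = stats.pearsonr(a, b)
    return float(res.statistic), float(res.pvalue)


@dataclass
class ModuleTraitResult:
    """Module-trait correlations and per-gene MM/GS statistics."""

    correlations: pd.DataFrame  # module, trait, r, p
    membership: pd.DataFrame | None = None  # gene, module, MM
    significance: pd.DataFrame | None = None  # gene, trait, GS


def module_trait(eigengenes: pd.DataFrame, traits: pd.DataFrame) -> ModuleTraitResult:
    """Pearson correlation of each module eigengene with each trait.

    p-values are two-sided from t = r sqrt((n-2)/(1-r^2)) on n-2 degrees
    of freedom. Trait rows must align with the eigengene sample index.
    """
    if eigengenes.shape[0] < 3:
        raise ValueError("module-trait correlation needs at least 3 samples")
    traits = traits.loc[eigengenes.index]
    rows = []
    for me in eigengenes.columns:
        for tr in traits.columns:
            r, p = _pearson_with_p(
                eigengenes[me].to_numpy(), traits[tr].to_numpy(dtype=float)
            )
            rows.append({"module": me, "trait": tr, "r": r, "p": p})
    return ModuleTraitResult(pd.DataFrame(rows))


def membership_significance(
    x: pd.DataFrame,
    eigengenes: pd.DataFrame,
    labels: pd.Series,
    trait: pd.Series,
) -> pd.DataFrame:
    """Per-gene module membership (cor with own eigengene) and gene
    significance (cor with the trait)."""
    trait_v = trait.loc[x.columns].to_numpy(dtype=float)
    rows = []
    for g in x.index:
        m = int(labels.loc[g])
        prof = x.loc[g].to_numpy(dtype=float)
        mm = np.nan
        if m > 0 and f"ME{m}" in eigengenes.columns:
            mm = float(np.corrcoef(prof, eigengenes[f"ME{m}"].to_numpy())[0, 1])
        gs = float(np.corrcoef(prof, trait_v)[0, 1])
        rows.append({"gene_id": g, "module": m, "MM": mm, "GS": gs})
    return pd.DataFrame(rows).set_index("gene_id")


@dataclass
class HubNetwork:
    """Top-connectivity subnetwork of one module."""

    module: int
    nodes: pd.DataFrame  # gene_id index; connectivity, flagged
    edges: pd.DataFrame  # source, target, weight

    @property
    def top_flagged(self) -> str | None:
        """Highest-connectivity flagged node, if any."""
        fl = self.nodes[self.nodes["flagged"]]
        return None if fl.empty else str(fl["connectivity"].idxmax())

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        for gene, row in self.nodes.iterrows():
            g.add_node(gene, connectivity=row["connectivity"], flagged=bool(row["flagged"]))
        for _, e in self.edges.iterrows():
            g.add_edge(e["source"], e["target"], weight=e["weight"])
        return g


def hub_network(
    tom: np.ndarray,
    labels: pd.Series,
    module: int,
    top_n: int = 100,
    flagged_genes=(),
    edge_quantile: float = 0.95,
) -> HubNetwork:
    """Extract the top-``top_n`` intramodular-connectivity genes of a module.

    Intramodular connectivity is k_i = sum_{j in module} TOM_ij. Flagged
    genes belonging to the module are always included. Edges with TOM weight
    above the ``edge_quantile`` quantile of within-subnetwork weights are
    exported.
    """
    gene_ids = np.asarray(labels.index)
    members = np.where(labels.to_numpy() == module)[0]
    if members.size == 0:
        raise ValueError(f"module {module} does not exist")
    if top_n > members.size:
        warnings.warn(
            f"top_n={top_n} exceeds module size {members.size}; using the whole module",
            stacklevel=2,
        )
        top_n = members.size
    sub = tom[np.ix_(members, members)]
    k = sub.sum(axis=1) - 1.0
    order = np.argsort(-k)
    keep = set(order[:top_n].tolist())
    flagged = set(flagged_genes)
    for i, g in enumerate(gene_ids[members]):
        if g in flagged:
            keep.add(i)
    keep_idx = sorted(keep, key=lambda i: -k[i])
    names = gene_ids[members][keep_idx]
    nodes = pd.DataFrame(
        {
            "connectivity": k[keep_idx],
            "flagged": [g in flagged for g in names],
        },
        index=pd.Index(names, name="gene_id"),
    )
    w = sub[np.ix_(keep_idx, keep_idx)]
    iu = np.triu_indices(len(keep_idx), 1)
    weights = w[iu]
    thr = np.quantile(weights, edge_quantile) if weights.size else 0.0
    sel = weights >= thr
    edges = pd.DataFrame(
        {
            "source": names[iu[0][sel]],
            "target": names[iu[1][sel]],
            "weight": weights[sel],
        }
    )
    return HubNetwork(module, nodes, edges)


def gene_gene_correlation(x: pd.DataFrame, set_a, set_b) -> pd.DataFrame:
    """Pearson r for every pair in set_a x set_b across samples (long form)."""
    rows = []
    for a in set_a:
        pa = x.loc[a].to_numpy(dtype=float)
        for b in set_b:
            pb = x.loc[b].to_numpy(dtype=float)
            rows.append(
                {"gene_a": a, "gene_b": b, "r": float(np.corrcoef(pa, pb)[0, 1])}
            )
    return pd.DataFrame(rows)
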
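"""High-variation gene selection, developmental-zone assignment, and
fuzzy c-means expression clustering.

HVGs are genes whose expression varies strongly across the 19 internodes,
selected by an (unscaled) median absolute deviation cutoff on the
log2(TPM+1) matrix. Internode samples are grouped into four developmental
zones (I-IV) by average-linkage hierarchical clustering of their
transcriptomes, and HVGs are partitioned into soft co-expression clusters
(C1..Cc) with the fuzzy c-means algorithm.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import cdist

from .expression import ExpressionMatrix, STAGE_ORDER, parse_internode_label

__all__ = [
    "HVGSet",
    "ZoneAssignment",
    "FuzzyClustering",
    "select_hvgs",
    "assign_zones",
    "estimate_fuzzifier",
    "fuzzy_cmeans",
    "cluster_mean_profiles",
]

ROMAN = ("I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X")


def mad(values: np.ndarray, axis: int = -1) -> np.ndarray:
    """Unscaled median absolute deviation: median_j |x_j - median_j x_j|.

    No 1.4826 normal-consistency factor is applied; the cutoff is on the
    plain MAD of log2 expression.
    """
    med = np.median(values, axis=axis, keepdims=True)
    return np.median(np.abs(values - med), axis=axis)


@dataclass
class HVGSet:
    """Genes passing ``MAD > cutoff`` plus the per-gene MAD values."""

    mad_values: pd.Series
    cutoff: float

    @property
    def genes(self) -> list[str]:
        return list(self.mad_values.index[self.mad_values > self.cutoff])

    def __len__(self) -> int:
        return int((self.mad_values > self.cutoff).sum())

    def to_tsv(self, path) -> None:
        out = self.mad_values.loc[self.genes].rename("mad")
        out.to_csv(path, sep="\t", index_label="gene_id")


def select_hvgs(em: ExpressionMatrix, cutoff: float = 1.0) -> HVGSet:
    """Select high-variation genes by unscaled MAD on the log matrix."""
    if not em.log_transformed:
        raise ValueError("HVG selection expects a log-transformed matrix")
    vals = mad(em.data.to_numpy(), axis=1)
    mads = pd.Series(vals, index=em.data.index, name="mad")
    hs = HVGSet(mads, cutoff)
    if len(hs) == 0:
        warnings.warn(f"no gene passes MAD > {cutoff}", stacklevel=2)
    return hs


@dataclass
class ZoneAssignment:
    """Internode -> zone labels plus the dendrogram and PCA variance fractions."""

    zones: pd.Series
    linkage_matrix: np.ndarray
    pca_variance_explained: np.ndarray

    @property
    def pc12_variance(self) -> float:
        """Fraction of sample variance carried by the first two PCs."""
        return float(self.pca_variance_explained[:2].sum())

    def to_tsv(self, path) -> None:
        self.zones.rename("zone").to_csv(path, sep="\t", index_label="internode")


def _stage_rank(label: str) -> tuple[int, int]:
    try:
        stage, idx = parse_internode_label(label)
        return STAGE_ORDER[stage], idx
    except (ValueError, KeyError):
        return 0, 0


def assign_zones(em: ExpressionMatrix, k: int = 4) -> ZoneAssignment:
    """Group internode samples into ``k`` developmental zones.

    Genes are standardized, samples are clustered by average-linkage
    hierarchical clustering on Euclidean distance, and the tree is cut at
    ``k`` groups. PCA variance fractions of the same matrix are reported.
    Zone labels are ordered by the mean developmental position (stage, then
    internode index) of their members, earliest first, so the earliest-stage
    cluster becomes Zone I.
    """
    if k > em.n_samples:
        raise ValueError(f"k={k} exceeds the {em.n_samples} samples")
    z = em.standardized()
    cols = z.to_numpy().T  # samples x genes
    lm = linkage(cols, method="average", metric="euclidean")
    raw = fcluster(lm, t=k, criterion="maxclust")

    # PCA on samples: center sample points in gene space, SVD spectrum
    centered = cols - cols.mean(axis=0, keepdims=True)
    sv = np.linalg.svd(centered, compute_uv=False)
    var = sv**2
    frac = var / var.sum() if var.sum() > 0 else var

    samples = list(z.columns)
    order_key = {}
    for cl in np.unique(raw):
        members = [samples[i] for i in np.where(raw == cl)[0]]
        ranks = [_stage_rank(s) for s in members]
        order_key[cl] = (
            float(np.mean([r[0] for r in ranks])),
            float(np.mean([r[1] for r in ranks])),
        )
    ordered = sorted(order_key, key=lambda cl: order_key[cl])
    name = {cl: ROMAN[i] for i, cl in enumerate(ordered)}
    zones = pd.Series([name[c] for c in raw], index=samples, name="zone")
    return ZoneAssignment(zones, lm, frac)


def estimate_fuzzifier(n_genes: int, n_dims: int) -> float:
    """Dimension/size-based default for the fuzzifier m.

    The heuristic of Schwaemmle & Jensen (the rule behind Mfuzz's
    ``mestimate``): m grows as dimensionality shrinks, approaching 1 for
    wide data so that clusters stay informative.
    """
    n, d = float(n_genes), float(n_dims)
    return float(
        1.0
        + (1418.0 / n + 22.05) * d**-2
        + (12.33 / n + 0.243) * d ** (-0.0406 * np.log(n) - 0.1134)
    )


@dataclass
class FuzzyClustering:
    """Soft clustering of genes: membership matrix, centroids, and metadata."""

    membership: pd.DataFrame  # genes x clusters, rows sum to 1
    centroids: pd.DataFrame  # clusters x samples
    fuzzifier_m: float
    n_iter: int
    objective: list[float] = field(default_factory=list)

    @property
    def c(self) -> int:
        return self.membership.shape[1]

    @property
    def hard_labels(self) -> pd.Series:
        return self.membership.idxmax(axis=1).rename("cluster")

    @property
    def max_membership(self) -> pd.Series:
        return self.membership.max(axis=1).rename("membership")

    def to_tsv(self, membership_path=None, clusters_path=None) -> None:
        if membership_path is not None:
            self.membership.to_csv(membership_path, sep="\t", index_label="gene_id")
        if clusters_path is not None:
            out = pd.DataFrame(
                {"cluster": self.hard_labels, "membership": self.max_membership}
            )
            out.to_csv(clusters_path, sep="\t", index_label="gene_id")


def _fcm_memberships(d2: np.ndarray, m: float) -> np.ndarray:
    """Membership update from squared distances; exact-hit rows become one-hot."""
    with np.errstate(divide="ignore", over="ignore", invalid="ignore"):
        inv = d2 ** (-1.0 / (m - 1.0))
        hit = ~np.isfinite(inv).all(axis=1)
        u = inv / inv.sum(axis=1, keepdims=True)
    if hit.any():
        u[hit] = 0.0
        u[hit, np.argmin(d2[hit], axis=1)] = 1.0
    return u


def _fcm_run(
    x: np.ndarray, c: int, m: float, max_iter: int, tol: float, rng, init: str
) -> tuple[np.ndarray, np.ndarray, int, list[float]]:
    n = x.shape[0]
    if init == "sample":
        centroids = x[rng.choice(n, size=c, replace=False)].copy()
        u = _fcm_memberships(np.maximum(cdist(x, centroids, "sqeuclidean"), 1e-300), m)
    elif init == "random":
        u = rng.random((n, c))
        u /= u.sum(axis=1, keepdims=True)
        centroids = None
    else:
        raise ValueError(f"unknown init {init!r}")
    obj_hist: list[float] = []
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        um = u**m
        mass = um.sum(axis=0)
        # a cluster may lose all mass on degenerate data; keep its centroid
        dead = mass <= 0
        new_centroids = (um.T @ x) / np.where(dead, 1.0, mass)[:, None]
        if dead.any() and centroids is not None:
            new_centroids[dead] = centroids[dead]
        centroids = new_centroids
        d2 = np.maximum(cdist(x, centroids, "sqeuclidean"), 1e-300)
        obj_hist.append(float((um * d2).sum()))
        u_new = _fcm_memberships(d2, m)
        shift = float(np.abs(u_new - u).max())
        u = u_new
        if shift < tol:
            break
    return u, centroids, n_iter, obj_hist


def fuzzy_cmeans(
    em: ExpressionMatrix | pd.DataFrame,
    c: int = 12,
    fuzzifier_m: float | None = None,
    max_iter: int = 200,
    tol: float = 1e-4,
    seed: int | None = None,
    n_init: int = 4,
    init: str = "sample",
) -> FuzzyClustering:
    """Fuzzy c-means clustering of per-gene standardized expression profiles.

    The classic alternating scheme: centroids v_i = sum_g u_gi^m x_g /
    sum_g u_gi^m, memberships u_gi = 1 / sum_k (d_gi/d_gk)^(2/(m-1)).
    A gene coinciding exactly with a centroid receives membership 1 there.
    Runs ``n_init`` seeded restarts and keeps the lowest objective; the
    objective sum u^m d^2 is non-increasing within each run. Clusters are
    renamed C1..Cc by the position of their centroid peak for stable naming.

    ``seed`` is required for reproducibility.
    """
    if seed is None:
        raise ValueError("fuzzy_cmeans requires an explicit seed")
    z = em.standardized() if isinstance(em, ExpressionMatrix) else em
    x = np.asarray(z, dtype=float)
    if c > x.shape[0]:
        raise ValueError(f"c={c} exceeds the {x.shape[0]} genes")
    m = estimate_fuzzifier(*x.shape) if fuzzifier_m is None else float(fuzzifier_m)
    if m <= 1:
        raise ValueError("fuzzifier m must be > 1")

    rng = np.random.default_rng(seed)
    best = None
    for _ in range(max(1, n_init)):
        u, cent, n_iter, hist = _fcm_run(x, c, m, max_iter, tol, rng, init)
        if best is None or hist[-1] < best[3][-1]:
            best = (u, cent, n_iter, hist)
    u, cent, n_iter, hist = best

    # stable naming: order clusters by centroid argmax position (then mean)
    order = sorted(
        range(c), key=lambda i: (int(np.argmax(cent[i])), -float(cent[i].max()))
    )
    names = [f"C{j + 1}" for j in range(c)]
    u = u[:, order]
    cent = cent[order]
    membership = pd.DataFrame(u, index=z.index, columns=names)
    centroids = pd.DataFrame(cent, index=names, columns=z.columns)
    return FuzzyClustering(membership, centroids, m, n_iter, hist)


def cluster_mean_profiles(
    fc: FuzzyClustering, em: ExpressionMatrix | pd.DataFrame
) -> pd.DataFrame:
    """Membership-weighted mean standardized profile per cluster."""
    z = em.standardized() if isinstance(em, ExpressionMatrix) else em
    u = fc.membership.to_numpy()
    x = z.loc[fc.membership.index].to_numpy()
    w = u.sum(axis=0)
    prof = (u.T @ x) / np.where(w > 0, w, 1.0)[:, None]
    return pd.DataFrame(prof, index=fc.membership.columns, columns=z.columns)
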
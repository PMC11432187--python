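"""Transcription-factor family summaries of the high-variation gene set.

Computes per-family counts of high-variation TFs (HVTFs), groups HVTFs into
expression groups (G1..Gk) by hierarchical clustering of their standardized
profiles, and tests each family for overrepresentation within each group
with a one-sided hypergeometric test plus Benjamini-Hochberg correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .expression import ExpressionMatrix
from .hvg import HVGSet

__all__ = [
    "FamilyRatioTable",
    "family_ratios",
    "group_hvtfs",
    "family_overrepresentation",
]


@dataclass
class FamilyRatioTable:
    """Per-family TF and HVTF counts with the HVTF ratio."""

    table: pd.DataFrame  # family index; n_tfs, n_hvtfs, ratio
    n_tfs_total: int
    n_hvtfs_total: int

    @property
    def global_fraction(self) -> float:
        """Overall HVTF share of all annotated TFs."""
        return self.n_hvtfs_total / self.n_tfs_total if self.n_tfs_total else 0.0

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index_label="family")


def family_ratios(hvgs: HVGSet | list, annotation: pd.Series) -> FamilyRatioTable:
    """Per-family HVTF counts and ratios over an annotated TF universe.

    ``annotation`` maps every TF gene to a single family. The ratio is the
    number of high-variation members divided by the family's TF count;
    families with zero TFs cannot occur by construction.
    """
    hv = set(hvgs.genes if isinstance(hvgs, HVGSet) else hvgs)
    is_hv = annotation.index.isin(hv)
    df = pd.DataFrame({"family": annotation.values, "hv": is_hv})
    agg = df.groupby("family")["hv"].agg(n_hvtfs="sum", n_tfs="count")
    agg["ratio"] = agg["n_hvtfs"] / agg["n_tfs"]
    agg = agg[["n_tfs", "n_hvtfs", "ratio"]].sort_values("ratio", ascending=False)
    return FamilyRatioTable(agg, int(len(annotation)), int(is_hv.sum()))


def group_hvtfs(em: ExpressionMatrix | pd.DataFrame, k: int = 6) -> tuple[pd.Series, np.ndarray]:
    """Cluster HVTF expression profiles into ``k`` groups (G1..Gk).

    Standardized per-gene profiles are clustered with average-linkage
    hierarchical clustering on Euclidean distance, cut at ``k`` groups.
    Groups are named by the mean position of their members' peak expression
    (earliest peak first) so labels are stable. Returns the label Series and
    the linkage matrix.
    """
    z = em.standardized() if isinstance(em, ExpressionMatrix) else em
    if k > z.shape[0]:
        raise ValueError(f"k={k} exceeds the {z.shape[0]} HVTFs")
    lm = linkage(np.asarray(z, dtype=float), method="average", metric="euclidean")
    raw = fcluster(lm, t=k, criterion="maxclust")
    peak = np.argmax(np.asarray(z), axis=1)
    order = sorted(
        np.unique(raw), key=lambda cl: float(np.mean(peak[raw == cl]))
    )
    name = {cl: f"G{i + 1}" for i, cl in enumerate(order)}
    return pd.Series([name[c] for c in raw], index=z.index, name="group"), lm


def family_overrepresentation(
    groups: pd.Series, annotation: pd.Series
) -> pd.DataFrame:
    """Hypergeometric family overrepresentation per expression group.

    For each (group, family): draw the group's size from the HVTF background
    and test whether the family count in the group is unexpectedly high
    (one-sided survival probability). Benjamini-Hochberg adjusted q-values
    are reported alongside.
    """
    fam = annotation.reindex(groups.index)
    bg = fam.dropna()
    n_bg = len(bg)
    rows = []
    for g, members in groups.groupby(groups):
        fam_in_g = bg.reindex(members.index).dropna()
        n_g = len(fam_in_g)
        for family, n_fam_bg in bg.value_counts().items():
            x = int((fam_in_g == family).sum())
            if x == 0:
                p = 1.0
            else:
                p = float(hypergeom.sf(x - 1, n_bg, int(n_fam_bg), n_g))
            rows.append(
                {"group": g, "family": family, "count": x,
                 "family_total": int(n_fam_bg), "group_size": n_g, "p": p}
            )
    out = pd.DataFrame(rows)
    if not out.empty:
        out["q"] = multipletests(out["p"], method="fdr_bh")[1]
    return out
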
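"""Differential-expression screening and biomarker-panel selection.

Differential expression is scored on the log2(FPKM+1) scale: the log2 fold
change is the case-group mean minus the control-group mean, and the p-value
comes from a two-sided Welch t-test (unequal variances).  An optional
moderated-variance mode shrinks per-group gene variances toward the
across-gene mean variance, a light-weight empirical-Bayes stabilisation for
small cohorts.

The screening rule keeps genes with |log2FC| > 1 and p < 0.01 (strict
inequalities); the classifier panel is the top-n up- and down-regulated
survivors ranked by |log2FC|, with ties broken by smaller p then gene id.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

from .cohort import log2p1

logger = logging.getLogger(__name__)

DE_COLUMNS = ("gene_id", "log2FC", "p_value", "mean_case", "mean_control")


@dataclasses.dataclass(frozen=True)
class BiomarkerPanel:
    """Selected markers: ``positive`` are up- and ``negative`` down-regulated.

    Each entry is ``(gene_id, log2FC)``; lists are ordered by |log2FC|
    descending and are disjoint.
    """

    positive: tuple[tuple[str, float], ...]
    negative: tuple[tuple[str, float], ...]

    def __post_init__(self):
        pos_ids = [g for g, _ in self.positive]
        neg_ids = [g for g, _ in self.negative]
        if set(pos_ids) & set(neg_ids):
            raise ValueError("positive and negative marker lists overlap")
        if any(fc <= 0 for _, fc in self.positive):
            raise ValueError("positive markers must have log2FC > 0")
        if any(fc >= 0 for _, fc in self.negative):
            raise ValueError("negative markers must have log2FC < 0")

    @property
    def genes(self) -> tuple[str, ...]:
        return tuple(g for g, _ in self.positive) + tuple(g for g, _ in self.negative)

    def to_dict(self) -> dict:
        return {
            "positive": [[g, fc] for g, fc in self.positive],
            "negative": [[g, fc] for g, fc in self.negative],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BiomarkerPanel":
        return cls(
            positive=tuple((g, float(fc)) for g, fc in d["positive"]),
            negative=tuple((g, float(fc)) for g, fc in d["negative"]),
        )


def _group_columns(expr: pd.DataFrame, clinical: pd.DataFrame, label: str) -> list[str]:
    ids = clinical.loc[clinical["group"] == label, "sample_id"].tolist()
    missing = [s for s in ids if s not in expr.columns]
    if missing:
        raise ValueError(f"samples {missing[:3]} not in expression matrix")
    return ids


def compute_de(
    expr: pd.DataFrame,
    clinical: pd.DataFrame,
    case_label: str = "tumor",
    control_label: str = "normal",
    eb_shrink: bool = False,
    prior_df: float = 4.0,
) -> pd.DataFrame:
    """Welch-t differential expression on the log2(FPKM+1) scale.

    Returns a DataFrame with columns ``gene_id, log2FC, p_value, mean_case,
    mean_control``.  Genes constant across all samples get p = 1.  With
    ``eb_shrink`` per-group variances are shrunk toward their across-gene
    means with ``prior_df`` pseudo-degrees of freedom.
    """
    case_cols = _group_columns(expr, clinical, case_label)
    ctrl_cols = _group_columns(expr, clinical, control_label)
    n1, n0 = len(case_cols), len(ctrl_cols)
    if n1 < 2 or n0 < 2:
        raise ValueError(f"need >= 2 samples per group, got case={n1}, control={n0}")

    L1 = log2p1(expr[case_cols].values)
    L0 = log2p1(expr[ctrl_cols].values)
    m1, m0 = L1.mean(axis=1), L0.mean(axis=1)
    v1, v0 = L1.var(axis=1, ddof=1), L0.var(axis=1, ddof=1)
    if eb_shrink:
        d1, d0 = n1 - 1.0, n0 - 1.0
        v1 = (prior_df * v1.mean() + d1 * v1) / (prior_df + d1)
        v0 = (prior_df * v0.mean() + d0 * v0) / (prior_df + d0)

    lfc = m1 - m0
    se2 = v1 / n1 + v0 / n0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = lfc / np.sqrt(se2)
        df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v0 / n0) ** 2 / (n0 - 1))
        p = 2.0 * stats.t.sf(np.abs(t), df)
    # degenerate variances: identical means -> p=1, separated means -> p=0
    zero_se = se2 == 0
    p = np.where(zero_se & (lfc == 0), 1.0, p)
    p = np.where(zero_se & (lfc != 0), 0.0, p)
    const = np.concatenate([L1, L0], axis=1).std(axis=1) == 0
    if const.any():
        logger.warning("%d gene(s) constant across all samples; p set to 1", const.sum())
        p = np.where(const, 1.0, p)

    return pd.DataFrame(
        {
            "gene_id": expr.index.to_numpy(),
            "log2FC": lfc,
            "p_value": p,
            "mean_case": m1,
            "mean_control": m0,
        }
    )


def filter_degs(
    de: pd.DataFrame, logfc_threshold: float = 1.0, p_threshold: float = 0.01
) -> pd.DataFrame:
    """Keep rows with |log2FC| > logfc_threshold AND p < p_threshold (strict)."""
    if logfc_threshold <= 0 or p_threshold <= 0:
        raise ValueError("thresholds must be > 0")
    keep = (de["log2FC"].abs() > logfc_threshold) & (de["p_value"] < p_threshold)
    return de.loc[keep].reset_index(drop=True)


def select_top_markers(degs: pd.DataFrame, n_up: int = 2, n_down: int = 2) -> BiomarkerPanel:
    """Top markers by |log2FC| within each direction.

    Ties broken by smaller p-value, then lexicographic gene id.  Raises if a
    direction has fewer candidates than requested.
    """
    def _top(rows: pd.DataFrame, n: int, direction: str):
        if len(rows) < n:
            raise ValueError(
                f"only {len(rows)} {direction}-regulated candidate(s), need {n}"
            )
        key = rows.assign(_a=rows["log2FC"].abs())
        key = key.sort_values(["_a", "p_value", "gene_id"], ascending=[False, True, True])
        return tuple(
            (str(r.gene_id), float(r.log2FC)) for r in key.head(n).itertuples()
        )

    up = degs.loc[degs["log2FC"] > 0]
    down = degs.loc[degs["log2FC"] < 0]
    return BiomarkerPanel(positive=_top(up, n_up, "up"), negative=_top(down, n_down, "down"))


def representative_cases(
    expr: pd.DataFrame,
    clinical: pd.DataFrame,
    k: int = 10,
    seed: int = 0,
) -> dict[str, list[str]]:
    """K-means representative samples per clinical group.

    Each group's samples are clustered (K-means, k-means++ seeding from
    ``seed``) on their log2(FPKM+1) profiles; the medoid of each cluster —
    the member sample nearest its centroid in Euclidean distance, ties broken
    by sample id — is returned.  With two groups and default k this yields
    the 2k representative cases used for validation.
    """
    out: dict[str, list[str]] = {}
    for label in sorted(clinical["group"].unique()):
        ids = _group_columns(expr, clinical, label)
        if k > len(ids):
            raise ValueError(f"k={k} exceeds group {label!r} size {len(ids)}")
        X = log2p1(expr[ids].values).T
        km = KMeans(n_clusters=k, n_init=10, max_iter=300, random_state=seed)
        assign = km.fit_predict(X)
        medoids = []
        for c in range(k):
            members = np.flatnonzero(assign == c)
            d = np.linalg.norm(X[members] - km.cluster_centers_[c], axis=1)
            best = min(zip(d, (ids[i] for i in members)), key=lambda t: (t[0], t[1]))
            medoids.append(best[1])
        out[label] = medoids
    return out


def write_de_table(de: pd.DataFrame, path) -> None:
    de.to_csv(path, sep="\t", index=False, float_format="%.12g")
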
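"""Weighted gene co-expression network analysis.

Implements the standard WGCNA-style stack on log2(FPKM+1) profiles:

* soft-thresholded adjacency ``a_ij = |cor(x_i, x_j)|^beta`` (unsigned by
  default; a signed variant ``((1+cor)/2)^beta`` is available);
* soft-power selection by the scale-free topology fit index — for each power
  the connectivity distribution is binned on a log10 scale and log10(freq)
  regressed on log10(mean connectivity); the fit is the signed R^2 (negated
  when the slope is positive) and the smallest power reaching the target
  (default 0.8) wins;
* Ravasz-style topological overlap
  ``TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij)``;
* module detection by average-linkage hierarchical clustering of ``1 - TOM``
  with a static cut (deterministic; no randomized dynamic cut);
* module eigengenes (first principal component of the z-scored module
  submatrix, oriented to correlate positively with its members);
* module-trait Pearson correlations and (optionally trait-weighted)
  intramodular hub genes.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .cohort import log2p1

#: label given to genes not assigned to any module
UNASSIGNED = 0


def _correlation(expr: pd.DataFrame) -> np.ndarray:
    """Gene-gene Pearson correlation of log2(FPKM+1) profiles.

    Zero-variance genes get correlation 0 with everything (warning issued).
    """
    L = log2p1(expr.values)
    sd = L.std(axis=1)
    if np.all(sd == 0):
        raise ValueError("all genes are constant; no network can be built")
    if np.any(sd == 0):
        warnings.warn(
            f"{int((sd == 0).sum())} zero-variance gene(s); their correlations set to 0",
            stacklevel=3,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        C = np.corrcoef(L)
    C[~np.isfinite(C)] = 0.0
    np.fill_diagonal(C, 1.0)
    return C


def adjacency_matrix(expr: pd.DataFrame, beta: int, signed: bool = False) -> pd.DataFrame:
    """Soft-thresholded adjacency with zero diagonal, values in [0, 1]."""
    if expr.shape[1] < 3:
        raise ValueError("need >= 3 samples to estimate correlations")
    if beta < 1:
        raise ValueError("beta must be >= 1")
    C = _correlation(expr)
    A = ((1.0 + C) / 2.0) ** beta if signed else np.abs(C) ** beta
    np.fill_diagonal(A, 0.0)
    ids = expr.index
    return pd.DataFrame(A, index=ids.copy(), columns=ids.copy())


def scale_free_fit(connectivity: np.ndarray, n_bins: int = 10) -> tuple[float, float]:
    """Scale-free topology fit of a connectivity vector.

    Bins k into ``n_bins`` equal-width bins on the raw scale (the WGCNA
    convention; zero-count bins dropped), regresses log10(frequency) on
    log10(mean k per bin) and returns ``(signed_r2, slope)`` where the R^2
    is negated if the slope is positive.
    """
    k = np.asarray(connectivity, dtype=float)
    k = k[k > 0]
    if k.size < 2 or np.ptp(k) == 0:
        return 0.0, 0.0
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    which = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        mask = which == b
        if not mask.any():
            continue
        xs.append(np.log10(np.mean(k[mask])))
        ys.append(np.log10(mask.sum() / k.size))
    if len(xs) < 3:
        return 0.0, 0.0
    fit = stats.linregress(xs, ys)
    r2 = float(fit.rvalue**2)
    return (-r2 if fit.slope > 0 else r2), float(fit.slope)


@dataclasses.dataclass(frozen=True)
class SoftThresholdResult:
    """Chosen power plus the full fit curve.

    ``warning`` is True when no power reached the target and the argmax of
    the fit index was returned instead.
    """

    beta: int
    fit_table: pd.DataFrame  # columns: power, fit_r2, slope, mean_k
    warning: bool

    @property
    def fit_r2(self) -> float:
        row = self.fit_table.loc[self.fit_table["power"] == self.beta]
        return float(row["fit_r2"].iloc[0])


def pick_soft_threshold(
    expr: pd.DataFrame,
    powers=range(1, 21),
    r2_target: float = 0.8,
    signed: bool = False,
    n_bins: int = 10,
) -> SoftThresholdResult:
    """Smallest power whose scale-free fit reaches ``r2_target``.

    Falls back to the argmax of the fit curve (with ``warning=True``) when no
    power reaches the target.
    """
    powers = list(powers)
    if not powers:
        raise ValueError("powers must be non-empty")
    C = _correlation(expr)
    base = ((1.0 + C) / 2.0) if signed else np.abs(C)
    np.fill_diagonal(base, 0.0)
    rows = []
    for beta in powers:
        A = base**beta
        k = A.sum(axis=0)
        fit, slope = scale_free_fit(k, n_bins=n_bins)
        rows.append((beta, fit, slope, float(k.mean())))
    table = pd.DataFrame(rows, columns=["power", "fit_r2", "slope", "mean_k"])
    reaching = table.loc[table["fit_r2"] >= r2_target]
    if len(reaching):
        beta = int(reaching["power"].iloc[0])
        return SoftThresholdResult(beta=beta, fit_table=table, warning=False)
    beta = int(table.loc[table["fit_r2"].idxmax(), "power"])
    warnings.warn(
        f"no power in {powers[0]}..{powers[-1]} reached fit {r2_target}; "
        f"returning argmax power {beta}",
        stacklevel=2,
    )
    return SoftThresholdResult(beta=beta, fit_table=table, warning=True)


def topological_overlap(adjacency: pd.DataFrame) -> pd.DataFrame:
    """Topological overlap matrix; TOM_ii = 1, values in [0, 1]."""
    A = np.asarray(adjacency, dtype=float)
    if A.shape[0] != A.shape[1] or not np.allclose(A, A.T, atol=1e-10):
        raise ValueError("adjacency must be square and symmetric")
    k = A.sum(axis=1)
    shared = A @ A
    denom = np.minimum.outer(k, k) + 1.0 - A
    with np.errstate(divide="ignore", invalid="ignore"):
        T = (shared + A) / denom
    T[~np.isfinite(T)] = 0.0
    np.fill_diagonal(T, 1.0)
    T = np.clip(T, 0.0, 1.0)
    if isinstance(adjacency, pd.DataFrame):
        return pd.DataFrame(T, index=adjacency.index.copy(), columns=adjacency.columns.copy())
    return pd.DataFrame(T)


def detect_modules(
    tom: pd.DataFrame, cut_height: float = 0.95, min_module_size: int = 30
) -> pd.Series:
    """Average-linkage clustering of 1-TOM with a static cut.

    Clusters smaller than ``min_module_size`` are relabeled ``UNASSIGNED``
    (0, the "grey" convention); surviving modules are renumbered 1, 2, ... by
    decreasing size.  Fully deterministic.
    """
    if not (0.0 < cut_height <= 1.0):
        raise ValueError("cut_height must lie in (0, 1]")
    T = np.asarray(tom, dtype=float)
    D = 1.0 - T
    np.fill_diagonal(D, 0.0)
    D = (D + D.T) / 2.0
    Z = linkage(squareform(D, checks=False), method="average")
    raw = fcluster(Z, t=cut_height, criterion="distance")
    labels = np.zeros(len(raw), dtype=int)
    sizes = pd.Series(raw).value_counts()
    kept = sizes[sizes >= min_module_size].sort_values(ascending=False)
    for new, old in enumerate(kept.index, start=1):
        labels[raw == old] = new
    index = tom.index if isinstance(tom, pd.DataFrame) else pd.RangeIndex(len(labels))
    return pd.Series(labels, index=index.copy(), name="module_label")


def module_eigengene(expr: pd.DataFrame, labels: pd.Series) -> pd.DataFrame:
    """First principal component of each module (modules x samples).

    Member genes are z-scored on the log2(FPKM+1) scale first; the component
    is sign-oriented so its mean correlation with member genes is positive,
    and scaled to unit variance.  Rows are indexed ``ME<label>``.
    """
    labels = labels.reindex(expr.index)
    L = log2p1(expr.values)
    rows = {}
    for lab in sorted(set(labels) - {UNASSIGNED}):
        idx = np.flatnonzero((labels == lab).values)
        if len(idx) < 2:
            raise ValueError(f"module {lab} has fewer than 2 genes")
        sub = L[idx]
        sd = sub.std(axis=1)
        if np.all(sd == 0):
            raise ValueError(f"module {lab} contains only zero-variance genes")
        keep = sd > 0
        Z = (sub[keep] - sub[keep].mean(axis=1, keepdims=True)) / sd[keep, None]
        _, _, Vt = np.linalg.svd(Z, full_matrices=False)
        v = Vt[0]
        member_cor = np.array([np.corrcoef(v, z)[0, 1] for z in Z])
        if member_cor.mean() < 0:
            v = -v
        rows[f"ME{lab}"] = v / v.std(ddof=1)
    return pd.DataFrame(rows, index=expr.columns.copy()).T


def module_trait_correlation(
    eigengenes: pd.DataFrame, clinical: pd.DataFrame, traits=None
) -> pd.DataFrame:
    """Pearson r and two-sided p for every module x trait pair.

    Numeric traits are used as-is; binary traits are expected 0/1-coded.  A
    constant trait yields r = 0, p = 1 with a warning.
    """
    clin = clinical.set_index("sample_id") if "sample_id" in clinical.columns else clinical
    clin = clin.loc[list(eigengenes.columns)]
    if traits is None:
        traits = [
            c for c in clin.columns if c != "group" and pd.api.types.is_numeric_dtype(clin[c])
        ]
    rows = []
    for me in eigengenes.index:
        e = eigengenes.loc[me].values.astype(float)
        for trait in traits:
            t = clin[trait].values.astype(float)
            if np.std(t) == 0:
                warnings.warn(f"trait {trait!r} is constant; r reported as 0", stacklevel=2)
                r, p = 0.0, 1.0
            else:
                r, p = stats.pearsonr(e, t)
            rows.append((me, trait, float(r), float(p)))
    return pd.DataFrame(rows, columns=["module", "trait", "pearson_r", "p_value"])


def intramodular_connectivity(adjacency: pd.DataFrame, labels: pd.Series) -> pd.Series:
    """kWithin: per-gene sum of adjacency to co-members of its module."""
    labels = labels.reindex(adjacency.index)
    k = pd.Series(0.0, index=adjacency.index, name="kWithin")
    for lab in set(labels):
        members = labels.index[labels == lab]
        sub = adjacency.loc[members, members]
        k.loc[members] = sub.sum(axis=1)
    return k


def hub_gene(
    adjacency: pd.DataFrame,
    labels: pd.Series,
    module: int,
    trait_correlations: pd.Series | None = None,
) -> str:
    """Hub of a module: argmax of kWithin, optionally trait-weighted.

    With ``trait_correlations`` (per-gene correlation with a clinical trait)
    the score becomes ``kWithin * |cor|``, so the hub can change with the
    trait under study.  Ties broken by lexicographic gene id.
    """
    labels = labels.reindex(adjacency.index)
    members = labels.index[labels == module]
    if len(members) == 0:
        raise ValueError(f"unknown or empty module label {module!r}")
    score = adjacency.loc[members, members].sum(axis=1)
    if trait_correlations is not None:
        score = score * trait_correlations.reindex(members).abs()
    best = score.max()
    return str(min(score.index[score == best]))


def write_module_tables(
    adjacency: pd.DataFrame,
    labels: pd.Series,
    trait_table: pd.DataFrame | None,
    modules_path,
    traits_path=None,
) -> None:
    """Write `gene_id, module_label, kWithin` and the module-trait TSV."""
    k = intramodular_connectivity(adjacency, labels)
    out = pd.DataFrame(
        {"gene_id": adjacency.index, "module_label": labels.values, "kWithin": k.values}
    )
    out.to_csv(modules_path, sep="\t", index=False, float_format="%.12g")
    if trait_table is not None and traits_path is not None:
        trait_table.to_csv(traits_path, sep="\t", index=False, float_format="%.12g")
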
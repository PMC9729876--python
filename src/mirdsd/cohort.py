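"""Synthetic miRNA expression cohorts with planted structure.

Generates gene-by-sample FPKM matrices for a two-group (tumor/normal) design
with three layers of planted signal:

* differential markers — selected genes whose case-group mean is shifted by a
  chosen log2 fold change on the log2(FPKM+1) scale;
* co-expression modules — gene sets driven by a per-sample latent factor with
  per-gene loadings, producing block-correlated expression;
* clinical traits — per-sample values (lymph-node counts, a binary
  tissue-collection indicator) derived from module latent factors plus noise,
  so that module–trait correlations exist by construction.

The noise model is Gaussian on the log2(FPKM+1) scale; values are
back-transformed and floored at zero.  The downstream circuit mapping consumes
continuous FPKM magnitudes, so no count-level (negative binomial) realism is
attempted.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

#: pseudocount used in every log2 transform in the package
PSEUDOCOUNT = 1.0

#: largest lymph-node count on the clinical scale
LYMPH_NODE_MAX = 105

#: clinical trait names with a known scale mapping
KNOWN_TRAITS = ("lymph_node_count", "tissue_indicator")

# A single cohort seed fans out to per-stage child seeds by these fixed
# offsets, so each stage draws from an independent, reproducible stream.
SEED_OFFSET_BASELINE = 1
SEED_OFFSET_NOISE = 2
SEED_OFFSET_FACTORS = 3
SEED_OFFSET_TRAITS = 4


def log2p1(x):
    """log2(x + 1), the transform used throughout the pipeline."""
    return np.log2(np.asarray(x, dtype=float) + PSEUDOCOUNT)


def inv_log2p1(y):
    """Back-transform log2(x+1) -> x, floored at 0."""
    return np.maximum(np.exp2(np.asarray(y, dtype=float)) - PSEUDOCOUNT, 0.0)


@dataclasses.dataclass(frozen=True)
class ModulePlan:
    """Plan for one planted co-expression module.

    Parameters
    ----------
    members : tuple of int
        Gene indices belonging to the module.
    loadings : tuple of float
        Per-member weight of the latent factor, each in [0.3, 1].  The member
        with the maximal loading is the planted hub.
    trait_name : str or None
        Clinical trait driven by this module's factor (one of
        ``KNOWN_TRAITS``), or None for a trait-free module.
    trait_noise_sd : float
        SD of Gaussian noise added to the continuous trait.
    trait_sign : int
        +1 or -1; sign with which the factor enters the trait.
    """

    members: tuple[int, ...]
    loadings: tuple[float, ...]
    trait_name: str | None = None
    trait_noise_sd: float = 0.0
    trait_sign: int = 1

    def __post_init__(self):
        object.__setattr__(self, "members", tuple(int(i) for i in self.members))
        object.__setattr__(self, "loadings", tuple(float(x) for x in self.loadings))

    @property
    def hub_index(self) -> int:
        """Gene index of the planted hub (maximal loading)."""
        return self.members[int(np.argmax(self.loadings))]

    def validate(self, n_genes: int) -> None:
        if len(self.members) != len(self.loadings):
            raise ValueError(
                f"module has {len(self.members)} members but "
                f"{len(self.loadings)} loadings"
            )
        if len(set(self.members)) != len(self.members):
            raise ValueError("module member indices must be unique")
        if any(i < 0 or i >= n_genes for i in self.members):
            raise ValueError("module member index out of gene range")
        if any(not (0.3 <= l <= 1.0) for l in self.loadings):
            raise ValueError("module loadings must lie in [0.3, 1]")
        if self.trait_noise_sd < 0:
            raise ValueError("trait_noise_sd must be >= 0")
        if self.trait_sign not in (+1, -1):
            raise ValueError("trait_sign must be +1 or -1")
        if self.trait_name is not None and self.trait_name not in KNOWN_TRAITS:
            raise ValueError(
                f"unknown trait_name {self.trait_name!r}; known: {KNOWN_TRAITS}"
            )


@dataclasses.dataclass(frozen=True)
class CohortSpec:
    """Full recipe for one synthetic cohort.

    ``planted_markers`` is a sequence of ``(gene_index, direction, log2fc)``
    with direction "up" or "down" and log2fc > 0; "up" shifts the case group
    by +log2fc on the log2(FPKM+1) scale, "down" by -log2fc.

    ``baseline_mu`` is the per-gene log2(FPKM+1) mean: a scalar (shared), a
    per-gene sequence, or None to draw Normal(4, 1) per gene.
    """

    n_genes: int
    n_case: int
    n_control: int
    planted_markers: tuple[tuple[int, str, float], ...] = ()
    baseline_mu: float | Sequence[float] | None = 4.0
    sigma: float = 0.5
    modules: tuple[ModulePlan, ...] = ()
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(
            self,
            "planted_markers",
            tuple((int(i), str(d), float(f)) for i, d, f in self.planted_markers),
        )
        object.__setattr__(self, "modules", tuple(self.modules))

    def validate(self) -> None:
        if self.n_genes < 1 or self.n_case < 1 or self.n_control < 1:
            raise ValueError("n_genes, n_case and n_control must all be >= 1")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        idx = [i for i, _, _ in self.planted_markers]
        if len(set(idx)) != len(idx):
            raise ValueError("planted marker gene indices must be unique")
        for i, direction, fc in self.planted_markers:
            if i < 0 or i >= self.n_genes:
                raise ValueError(f"marker index {i} out of range")
            if direction not in ("up", "down"):
                raise ValueError(f"marker direction must be 'up' or 'down', got {direction!r}")
            if fc <= 0:
                raise ValueError("log2FC magnitudes must be > 0")
        seen: set[int] = set()
        for m in self.modules:
            m.validate(self.n_genes)
            overlap = seen.intersection(m.members)
            if overlap:
                raise ValueError(f"modules overlap at gene indices {sorted(overlap)}")
            seen.update(m.members)
        collision = seen.intersection(idx)
        if collision:
            raise ValueError(
                f"planted markers collide with module members at indices {sorted(collision)}"
            )


def _baseline(spec: CohortSpec) -> np.ndarray:
    if spec.baseline_mu is None:
        rng = np.random.default_rng(spec.seed + SEED_OFFSET_BASELINE)
        return rng.normal(4.0, 1.0, size=spec.n_genes)
    mu = np.asarray(spec.baseline_mu, dtype=float)
    if mu.ndim == 0:
        return np.full(spec.n_genes, float(mu))
    if mu.shape != (spec.n_genes,):
        raise ValueError(f"baseline_mu has shape {mu.shape}, expected ({spec.n_genes},)")
    return mu.copy()


def _scale_trait(name: str, t: np.ndarray) -> np.ndarray:
    """Map a continuous latent trait onto its clinical scale."""
    if name == "lymph_node_count":
        lo, hi = t.min(), t.max()
        if hi == lo:
            return np.full(t.shape, LYMPH_NODE_MAX // 2, dtype=int)
        return np.rint((t - lo) / (hi - lo) * LYMPH_NODE_MAX).astype(int)
    if name == "tissue_indicator":
        return (t > 0).astype(int)
    raise ValueError(f"unknown trait name {name!r}; known: {KNOWN_TRAITS}")


def _continuous_traits(
    modules: Sequence[ModulePlan], factors: np.ndarray, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """Signed sum of module factors per trait name, plus Gaussian noise.

    When several modules drive the same trait their signed factors add; the
    noise SD of the first such module is used.
    """
    traits: dict[str, np.ndarray] = {}
    noise_sd: dict[str, float] = {}
    for mi, m in enumerate(modules):
        if m.trait_name is None:
            continue
        contrib = m.trait_sign * factors[mi]
        if m.trait_name in traits:
            traits[m.trait_name] = traits[m.trait_name] + contrib
        else:
            traits[m.trait_name] = contrib.copy()
            noise_sd[m.trait_name] = m.trait_noise_sd
    for name in sorted(traits):
        if noise_sd[name] > 0:
            traits[name] = traits[name] + rng.normal(0.0, noise_sd[name], traits[name].shape)
    return traits


def generate_cohort(
    spec: CohortSpec, return_latent: bool = False
) -> tuple[pd.DataFrame, pd.DataFrame] | tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Generate an expression matrix and clinical table from a cohort spec.

    Returns
    -------
    expr : DataFrame
        genes x samples FPKM matrix (non-negative), index named ``gene_id``.
    clinical : DataFrame
        columns ``sample_id, group, lymph_node_count, tissue_indicator``.
    latent : dict, only if ``return_latent``
        ``factors`` (modules x samples array) and ``continuous_traits``.

    Deterministic given ``spec.seed``; the seed fans out to independent
    per-stage streams by the fixed ``SEED_OFFSET_*`` constants.
    """
    spec.validate()
    n_s = spec.n_case + spec.n_control
    sample_ids = [f"tumor_{i:04d}" for i in range(spec.n_case)] + [
        f"normal_{i:04d}" for i in range(spec.n_control)
    ]
    gene_ids = [f"mir-{i:04d}" for i in range(spec.n_genes)]
    case_mask = np.zeros(n_s, dtype=bool)
    case_mask[: spec.n_case] = True

    L = np.tile(_baseline(spec)[:, None], (1, n_s))
    for i, direction, fc in spec.planted_markers:
        L[i, case_mask] += fc if direction == "up" else -fc

    rng_factors = np.random.default_rng(spec.seed + SEED_OFFSET_FACTORS)
    factors = rng_factors.standard_normal((len(spec.modules), n_s))
    for mi, m in enumerate(spec.modules):
        L[np.asarray(m.members)] += np.outer(m.loadings, factors[mi])

    if spec.sigma > 0:
        rng_noise = np.random.default_rng(spec.seed + SEED_OFFSET_NOISE)
        L += rng_noise.normal(0.0, spec.sigma, size=L.shape)

    expr = pd.DataFrame(inv_log2p1(L), index=gene_ids, columns=sample_ids)
    expr.index.name = "gene_id"

    rng_traits = np.random.default_rng(spec.seed + SEED_OFFSET_TRAITS)
    cont = _continuous_traits(spec.modules, factors, rng_traits)
    # trait columns not driven by any module get uninformative defaults
    lymph = (
        _scale_trait("lymph_node_count", cont["lymph_node_count"])
        if "lymph_node_count" in cont
        else rng_traits.integers(0, LYMPH_NODE_MAX + 1, size=n_s)
    )
    indicator = (
        _scale_trait("tissue_indicator", cont["tissue_indicator"])
        if "tissue_indicator" in cont
        else rng_traits.integers(0, 2, size=n_s)
    )
    clinical = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "group": np.where(case_mask, "tumor", "normal"),
            "lymph_node_count": np.asarray(lymph, dtype=int),
            "tissue_indicator": np.asarray(indicator, dtype=int),
        }
    )
    if return_latent:
        return expr, clinical, {"factors": factors, "continuous_traits": cont}
    return expr, clinical


def generate_traits(
    expr: pd.DataFrame,
    modules: Sequence[ModulePlan],
    seed: int,
    factors: np.ndarray | None = None,
    return_continuous: bool = False,
) -> pd.DataFrame | tuple[pd.DataFrame, dict[str, np.ndarray]]:
    """Derive clinical-trait columns from module activity in ``expr``.

    If the true latent ``factors`` are not supplied, each module's factor is
    estimated as the loading-weighted mean of the z-scored log2 member
    profiles (exact when expression noise is zero).
    """
    for m in modules:
        m.validate(expr.shape[0])
    if factors is None:
        L = log2p1(expr.values)
        factors = np.zeros((len(modules), expr.shape[1]))
        for mi, m in enumerate(modules):
            sub = L[np.asarray(m.members)]
            sd = sub.std(axis=1)
            if np.all(sd == 0):
                raise ValueError(f"module {mi}: all member genes are constant")
            keep = sd > 0
            z = (sub[keep] - sub[keep].mean(axis=1, keepdims=True)) / sd[keep, None]
            w = np.asarray(m.loadings)[keep]
            factors[mi] = z.T @ (w / w.sum())
    rng = np.random.default_rng(seed + SEED_OFFSET_TRAITS)
    cont = _continuous_traits(modules, np.asarray(factors, dtype=float), rng)
    out = pd.DataFrame(
        {name: _scale_trait(name, t) for name, t in sorted(cont.items())},
        index=list(expr.columns),
    )
    out.index.name = "sample_id"
    if return_continuous:
        return out, cont
    return out


# ---------------------------------------------------------------------------
# TSV round trip

CLINICAL_COLUMNS = ("sample_id", "group", "lymph_node_count", "tissue_indicator")


def write_cohort(expr: pd.DataFrame, clinical: pd.DataFrame, expr_path, clinical_path) -> None:
    """Write expression and clinical tables as TSV (>= 12 significant digits)."""
    expr.to_csv(expr_path, sep="\t", float_format="%.12g")
    clinical.to_csv(clinical_path, sep="\t", index=False)


def read_cohort(expr_path, clinical_path=None):
    """Read an expression TSV (and optionally a clinical TSV), validating both.

    Raises ``ValueError`` naming the offending row/column for duplicate gene
    ids, non-numeric cells, negative values or ragged rows.
    """
    expr = _read_expression(expr_path)
    if clinical_path is None:
        return expr
    clinical = _read_clinical(clinical_path, expr)
    return expr, clinical


def _read_expression(path) -> pd.DataFrame:
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    if raw.index.name != "gene_id":
        raise ValueError(f"first column must be 'gene_id', got {raw.index.name!r}")
    dup = raw.index[raw.index.duplicated()].unique()
    if len(dup):
        raise ValueError(f"duplicate gene ids: {list(dup)[:5]}")
    if raw.columns.duplicated().any():
        raise ValueError("duplicate sample ids in header")
    values = np.empty(raw.shape, dtype=float)
    for j, col in enumerate(raw.columns):
        numeric = pd.to_numeric(raw[col], errors="coerce")
        bad = numeric.isna() | (raw[col].str.strip() == "")
        if bad.any():
            gene = raw.index[int(np.argmax(bad.values))]
            raise ValueError(
                f"non-numeric or missing value at gene {gene!r}, sample column {col!r}"
            )
        values[:, j] = numeric.values
    neg = np.argwhere(values < 0)
    if len(neg):
        i, j = neg[0]
        raise ValueError(
            f"negative FPKM at gene {raw.index[i]!r}, sample column {raw.columns[j]!r}"
        )
    expr = pd.DataFrame(values, index=raw.index.copy(), columns=raw.columns.copy())
    expr.index.name = "gene_id"
    return expr


def _read_clinical(path, expr: pd.DataFrame) -> pd.DataFrame:
    clinical = pd.read_csv(path, sep="\t")
    missing = [c for c in CLINICAL_COLUMNS if c not in clinical.columns]
    if missing:
        raise ValueError(f"clinical table missing columns: {missing}")
    unknown_groups = set(clinical["group"]) - {"tumor", "normal"}
    if unknown_groups:
        raise ValueError(f"unknown group labels: {sorted(unknown_groups)}")
    if set(clinical["sample_id"]) != set(expr.columns):
        raise ValueError("clinical sample_ids do not match the expression matrix columns")
    counts = clinical["lymph_node_count"]
    if (counts < 0).any() or (counts > LYMPH_NODE_MAX).any():
        raise ValueError(f"lymph_node_count outside [0, {LYMPH_NODE_MAX}]")
    if not set(clinical["tissue_indicator"]).issubset({0, 1}):
        raise ValueError("tissue_indicator must be 0 or 1")
    return clinical
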
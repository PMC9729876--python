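"""Reference study conditions built on the synthetic-cohort generator.

These presets pin down the cohorts used by the validation suite and the
reproduction script, so every consumer measures the same thing:

``diagnostic_marker_cohort``
    Two-group cohort with four planted diagnostic markers (two up-, two
    down-regulated).  Up-markers start from a low baseline and rise in
    tumors; down-markers start high and fall — the asymmetry that makes a
    marker informative in both groups, as with the tumor-marker/health-marker
    pairs the diagnostic circuit compares.

``scale_free_module_cohort``
    Cohort whose co-expression structure is five planted modules covering
    all genes, with loadings drawn so that soft-thresholded connectivity is
    heavy-tailed (few strong hub-like members, many weak ones).  Loadings
    are sampled so that u = l / sqrt(l^2 + sigma^2) — the factor-model
    correlation a member carries — follows a truncated Pareto law, which
    makes the connectivity distribution approximately scale-free after
    soft thresholding.  The hub of each module has loading 1.0; other
    members are capped at 0.8 so the hub is identifiable.
"""

from __future__ import annotations

import numpy as np

from .cohort import CohortSpec, ModulePlan

#: default planted log2 fold changes of the four diagnostic markers
MARKER_LOG2FC = (2.5, 1.8)

#: network-recovery preset: static-cut height used with these conditions
MODULE_CUT_HEIGHT = 0.99
MODULE_MIN_SIZE = 30


def diagnostic_marker_cohort(
    seed: int,
    n_case: int = 60,
    n_control: int = 20,
    n_genes: int = 300,
    log2fc: tuple[float, float] = MARKER_LOG2FC,
    sigma: float = 0.5,
    informative_baselines: bool = False,
) -> tuple[CohortSpec, dict[str, list[str]]]:
    """Cohort spec with two planted up- and two down-regulated markers.

    Markers occupy gene indices 0..3 (up: 0, 1; down: 2, 3).  With
    ``informative_baselines`` the up-markers start low (baseline 3.0) and
    the down-markers high (5.0) against a background of 4.0, so that each
    group's dominant channel also dominates in absolute concentration —
    the regime the winner-take-all circuit requires.  Returns the spec and
    the planted marker gene ids per direction.
    """
    fc_hi, fc_lo = log2fc
    markers = (
        (0, "up", fc_hi),
        (1, "up", fc_lo),
        (2, "down", fc_hi),
        (3, "down", fc_lo),
    )
    if informative_baselines:
        mu = np.full(n_genes, 4.0)
        mu[[0, 1]] = 3.0
        mu[[2, 3]] = 5.0
    else:
        mu = None  # drawn Normal(4, 1) per gene
    spec = CohortSpec(
        n_genes=n_genes,
        n_case=n_case,
        n_control=n_control,
        planted_markers=markers,
        baseline_mu=mu,
        sigma=sigma,
        seed=seed,
    )
    planted = {
        "up": [f"mir-{i:04d}" for i in (0, 1)],
        "down": [f"mir-{i:04d}" for i in (2, 3)],
    }
    return spec, planted


def _pareto_u_loadings(
    rng: np.random.Generator,
    n: int,
    sigma: float,
    alpha: float,
    l_lo: float,
    l_hi: float,
) -> np.ndarray:
    """Member loadings whose factor-correlation u is truncated-Pareto.

    u = l / sqrt(l^2 + sigma^2) is the correlation a loading-l member has
    with its module factor (up to noise); sampling u ~ Pareto(alpha) on
    [u(l_lo), u(l_hi)] and mapping back gives few strong and many weak
    members — the connectivity shape of scale-free co-expression networks.
    """
    u_lo = l_lo / np.hypot(l_lo, sigma)
    u_hi = l_hi / np.hypot(l_hi, sigma)
    q = rng.uniform(0.0, 1.0, n)
    u = (u_lo**-alpha - q * (u_lo**-alpha - u_hi**-alpha)) ** (-1.0 / alpha)
    return sigma * u / np.sqrt(1.0 - u**2)


def scale_free_module_cohort(
    seed: int,
    n_modules: int = 5,
    module_size: int = 100,
    n_samples: int = 150,
    sigma: float = 0.35,
    alpha: float = 6.0,
    member_loading_range: tuple[float, float] = (0.3, 0.8),
) -> tuple[CohortSpec, np.ndarray, list[str]]:
    """Cohort spec with planted scale-free co-expression modules.

    All genes belong to one of ``n_modules`` equally sized modules; each
    module's hub carries loading 1.0, the remaining members get Pareto-tail
    loadings in ``member_loading_range``.  Returns the spec, the planted
    per-gene module labels (1-based) and the planted hub gene ids.
    """
    rng = np.random.default_rng(seed + 50_000)
    l_lo, l_hi = member_loading_range
    modules = []
    start = 0
    for _ in range(n_modules):
        members = tuple(range(start, start + module_size))
        start += module_size
        loadings = np.concatenate(
            [[1.0], _pareto_u_loadings(rng, module_size - 1, sigma, alpha, l_lo, l_hi)]
        )
        modules.append(ModulePlan(members=members, loadings=tuple(loadings)))
    spec = CohortSpec(
        n_genes=n_modules * module_size,
        n_case=n_samples // 2,
        n_control=n_samples - n_samples // 2,
        baseline_mu=4.0,
        sigma=sigma,
        modules=tuple(modules),
        seed=seed,
    )
    planted_labels = np.repeat(np.arange(1, n_modules + 1), module_size)
    hubs = [f"mir-{m.hub_index:04d}" for m in modules]
    return spec, planted_labels, hubs
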
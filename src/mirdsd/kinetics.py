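"""Mass-action simulation of compiled strand-displacement circuits.

Deterministic trajectories come from integrating d[x]/dt = S v(x) with a
stiff-capable adaptive solver (LSODA; rtol 1e-8, atol 1e-10 nM), sampled on
the circuit's readout grid.  An independent Gillespie direct-method
stochastic simulator serves as a cross-check at finite molecule counts, and
conserved strand moieties (left null vectors of the stoichiometry matrix)
verify mass balance of every simulated trajectory.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import linalg
from scipy.integrate import solve_ivp

from .circuit import CircuitSpec, validate_circuit

RTOL_DEFAULT = 1e-8
ATOL_DEFAULT = 1e-10  # nM
VOLUME_SCALE_DEFAULT = 100.0  # molecules per nM
CONSERVATION_TOL = 1e-6  # nM


@dataclasses.dataclass
class TrajectorySet:
    """Sampled concentrations (species x time, nM) on a fixed grid."""

    times: np.ndarray
    species_ids: tuple[str, ...]
    concentrations: np.ndarray  # shape (n_species, n_times)

    def get(self, species_id: str) -> np.ndarray:
        return self.concentrations[self.species_ids.index(species_id)]

    def at_time(self, t: float) -> np.ndarray:
        idx = np.flatnonzero(np.isclose(self.times, t, rtol=0.0, atol=1e-9))
        if len(idx) == 0:
            raise ValueError(f"time {t} s is not on the sampling grid")
        return self.concentrations[:, idx[0]]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            np.clip(self.concentrations.T, 0.0, None),
            columns=list(self.species_ids),
        )
        df.insert(0, "time_s", self.times)
        return df

    def to_csv(self, path) -> None:
        """Export with first column ``time_s``; concentrations clipped at 0."""
        self.to_frame().to_csv(path, index=False, float_format="%.10g")


def build_stoichiometry(spec: CircuitSpec):
    """Stoichiometry matrix S (species x reactions) plus rate metadata.

    Returns ``(S, rates, reactant_pairs)`` where ``reactant_pairs`` holds the
    species indices of each reaction's two reactants; the mass-action
    propensity of reaction r with reactants (A, B) is ``k_r [A] [B]``.
    """
    findings = validate_circuit(spec)
    if findings:
        raise ValueError(f"invalid circuit spec: {findings}")
    index = spec.species_index()
    S = np.zeros((len(spec.species), len(spec.reactions)), dtype=int)
    pairs = np.zeros((len(spec.reactions), 2), dtype=int)
    rates = np.zeros(len(spec.reactions))
    for r, rxn in enumerate(spec.reactions):
        for sid in rxn.reactants:
            S[index[sid], r] -= 1
        for sid in rxn.products:
            S[index[sid], r] += 1
        pairs[r] = [index[rxn.reactants[0]], index[rxn.reactants[1]]]
        rates[r] = rxn.k
    return S, rates, pairs


def simulate_ode(
    spec: CircuitSpec, rtol: float = RTOL_DEFAULT, atol: float = ATOL_DEFAULT
) -> TrajectorySet:
    """Integrate the mass-action ODE system on the spec's sampling grid."""
    S, rates, pairs = build_stoichiometry(spec)
    Sf = S.astype(float)
    i, j = pairs[:, 0], pairs[:, 1]

    def rhs(_t, y):
        return Sf @ (rates * y[i] * y[j])

    times = spec.sample_times()
    y0 = spec.initial_concentrations()
    if len(spec.reactions) == 0:
        return TrajectorySet(times, spec.species_ids(), np.tile(y0[:, None], len(times)))
    sol = solve_ivp(
        rhs,
        (0.0, float(times[-1])),
        y0,
        method="LSODA",
        t_eval=times,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise RuntimeError(f"ODE integration failed at t={sol.t[-1]:.3g} s: {sol.message}")
    y = sol.y.copy()
    y[:, 0] = y0  # the grid starts at t=0: pin the exact initial state
    return TrajectorySet(times, spec.species_ids(), y)


@dataclasses.dataclass
class SSAResult:
    """Stochastic trajectories: molecule counts per run on the sampling grid."""

    times: np.ndarray
    species_ids: tuple[str, ...]
    counts: np.ndarray  # shape (n_runs, n_species, n_times)
    volume_scale: float  # molecules per nM

    def mean_concentrations(self) -> np.ndarray:
        return self.counts.mean(axis=0) / self.volume_scale

    def sem_concentrations(self) -> np.ndarray:
        n = self.counts.shape[0]
        return self.counts.std(axis=0, ddof=1) / np.sqrt(n) / self.volume_scale


def simulate_ssa(
    spec: CircuitSpec,
    volume_scale: float = VOLUME_SCALE_DEFAULT,
    seed: int = 0,
    n_runs: int = 1,
) -> SSAResult:
    """Gillespie direct-method simulation of the circuit.

    ``volume_scale`` converts nM to molecule counts; every nonzero initial
    concentration must map to >= 1 molecule.  Bimolecular propensities are
    ``(k / volume_scale) nA nB`` for distinct reactants and
    ``(k / volume_scale) nA (nA - 1) / 2`` for identical ones.  Deterministic
    given ``seed`` (each run uses the child stream ``(seed, run)``).
    """
    S, rates, pairs = build_stoichiometry(spec)
    times = spec.sample_times()
    y0 = spec.initial_concentrations()
    n0 = np.rint(y0 * volume_scale).astype(np.int64)
    bad = (y0 > 0) & (n0 < 1)
    if bad.any():
        which = [spec.species_ids()[k] for k in np.flatnonzero(bad)]
        raise ValueError(f"volume_scale too small: species {which} map to < 1 molecule")
    kc = rates / volume_scale
    same = pairs[:, 0] == pairs[:, 1]
    counts = np.empty((n_runs, len(y0), len(times)), dtype=np.int64)
    for run in range(n_runs):
        rng = np.random.default_rng([seed, run])
        n = n0.copy()
        t = 0.0
        grid_idx = 0
        while True:
            na, nb = n[pairs[:, 0]], n[pairs[:, 1]]
            props = np.where(same, kc * na * (na - 1) / 2.0, kc * na * nb)
            a0 = props.sum()
            if a0 <= 0.0:
                counts[run, :, grid_idx:] = n[:, None]
                break
            t_next = t + rng.exponential(1.0 / a0)
            while grid_idx < len(times) and times[grid_idx] <= t_next:
                counts[run, :, grid_idx] = n
                grid_idx += 1
            if grid_idx >= len(times):
                break
            r = rng.choice(len(props), p=props / a0)
            n += S[:, r]
            t = t_next
    return SSAResult(times, spec.species_ids(), counts, volume_scale)


@dataclasses.dataclass
class ConservationReport:
    """Drift of each conserved moiety along a trajectory."""

    moieties: np.ndarray  # (n_moieties, n_species), orthonormal left-null basis
    drifts: np.ndarray  # max |c.x(t) - c.x(0)| per moiety, nM
    tolerance: float

    @property
    def max_drift(self) -> float:
        return float(self.drifts.max()) if len(self.drifts) else 0.0

    @property
    def passed(self) -> bool:
        return self.max_drift <= self.tolerance


def conservation_check(
    traj: TrajectorySet, spec: CircuitSpec, tolerance: float = CONSERVATION_TOL
) -> ConservationReport:
    """Verify mass balance: left null vectors of S stay constant in time."""
    S, _, _ = build_stoichiometry(spec)
    if len(spec.reactions) == 0:
        basis = np.eye(len(spec.species))
    else:
        basis = linalg.null_space(S.T.astype(float)).T
    if basis.size == 0:
        return ConservationReport(basis, np.zeros(0), tolerance)
    totals = basis @ traj.concentrations
    drifts = np.abs(totals - totals[:, [0]]).max(axis=1)
    return ConservationReport(basis, drifts, tolerance)
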
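"""Trajectory readout, winner-take-all calls and cohort-level metrics.

A sample's compiled circuit is simulated and read out at the end of the
sampling grid: the FAM (tumor) and ROX (health) signal concentrations are
compared.  If both stay below a detection floor the case is indeterminate
(the circuit went dark — inputs below the gate-3 threshold); if the margin
is within a tie tolerance the case is indeterminate; otherwise the larger
channel wins.  Indeterminate is a first-class outcome: the confusion summary
counts it separately and also reports a binary accuracy over decided calls.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping

import pandas as pd

from .circuit import CircuitSpec, compile_diagnostic_circuit, compile_trait_circuit
from .kinetics import TrajectorySet, simulate_ode

FLOOR_DELTA_DEFAULT = 0.5  # nM: below this on both channels the circuit is dark
MARGIN_EPS_DEFAULT = 1e-3  # nM: |FAM - ROX| ties within this are indeterminate

#: which fluorescence channel encodes which call
CALL_CHANNEL = {"positive": "FAM", "negative": "ROX"}
CHANNEL_CALL = {v: k for k, v in CALL_CHANNEL.items()}

#: expected dominant channel per true diagnostic class
CLASS_CALL = {"tumor": "positive", "normal": "negative"}


def read_out(
    traj: TrajectorySet, spec: CircuitSpec, readout_time: float | None = None
) -> tuple[float, float]:
    """(FAM, ROX) signal concentrations at ``readout_time`` (default t_end)."""
    if readout_time is None:
        readout_time = float(traj.times[-1])
    state = traj.at_time(readout_time)
    out = []
    for channel in ("FAM", "ROX"):
        if channel not in spec.readout:
            raise KeyError(f"circuit has no readout species for channel {channel!r}")
        out.append(max(float(state[spec.species_ids().index(spec.readout[channel])]), 0.0))
    return out[0], out[1]


def call_sample(
    fam: float,
    rox: float,
    floor_delta: float = FLOOR_DELTA_DEFAULT,
    margin_eps: float = MARGIN_EPS_DEFAULT,
) -> str:
    """Winner-take-all decision from the two endpoint signals."""
    if fam < 0 or rox < 0:
        raise ValueError("signal concentrations must be >= 0")
    if max(fam, rox) < floor_delta:
        return "indeterminate"
    if abs(fam - rox) <= margin_eps:
        return "indeterminate"
    return "positive" if fam > rox else "negative"


@dataclasses.dataclass
class ConfusionSummary:
    """Per-true-class call counts plus accuracies.

    ``overall_accuracy`` scores indeterminates as errors; ``binary_accuracy``
    is computed over decided calls only (NaN when none are decided).
    """

    table: pd.DataFrame  # index: true class, columns: positive/negative/indeterminate
    per_class_accuracy: dict[str, float]
    overall_accuracy: float
    binary_accuracy: float
    n: int

    def to_dict(self) -> dict:
        return {
            "counts": {c: self.table.loc[c].to_dict() for c in self.table.index},
            "per_class_accuracy": self.per_class_accuracy,
            "overall_accuracy": self.overall_accuracy,
            "binary_accuracy": self.binary_accuracy,
            "n": self.n,
        }


def summarize_calls(results: pd.DataFrame) -> ConfusionSummary:
    """Confusion bookkeeping over a results table (true_class, call)."""
    calls = ("positive", "negative", "indeterminate")
    classes = sorted(results["true_class"].unique())
    table = pd.DataFrame(0, index=pd.Index(classes, name="true_class"), columns=list(calls))
    for cls, call in zip(results["true_class"], results["call"]):
        table.loc[cls, call] += 1
    per_class = {}
    n_correct = 0
    for cls in classes:
        expected = CLASS_CALL.get(cls)
        total = int(table.loc[cls].sum())
        correct = int(table.loc[cls, expected]) if expected in calls else 0
        per_class[cls] = correct / total if total else float("nan")
        n_correct += correct
    n = len(results)
    decided = int(results["call"].isin(["positive", "negative"]).sum())
    decided_correct = int(
        (
            results["call"]
            == results["true_class"].map(CLASS_CALL).fillna("__none__")
        ).sum()
    )
    return ConfusionSummary(
        table=table,
        per_class_accuracy=per_class,
        overall_accuracy=n_correct / n if n else float("nan"),
        binary_accuracy=decided_correct / decided if decided else float("nan"),
        n=n,
    )


def classify_cohort(
    expr: pd.DataFrame,
    clinical: pd.DataFrame,
    panel,
    k_default: float = 0.003,
    topology: str = "shared_gate",
    gate3_nM: float | None = None,
    t_end: float = 1000.0,
    sample_interval: float = 10.0,
    floor_delta: float = FLOOR_DELTA_DEFAULT,
    margin_eps: float = MARGIN_EPS_DEFAULT,
    trajectory_dir=None,
) -> tuple[pd.DataFrame, ConfusionSummary]:
    """Compile, simulate and call every sample; return results + summary.

    ``trajectory_dir``, if given, receives one trajectory CSV per sample.
    """
    missing = [g for g in panel.genes if g not in expr.index]
    if missing:
        raise ValueError(f"panel genes {missing} not in the expression matrix")
    rows = []
    for rec in clinical.itertuples():
        sample = rec.sample_id
        try:
            fpkm = expr[sample].to_dict()
            spec = compile_diagnostic_circuit(
                panel,
                fpkm,
                k_default=k_default,
                topology=topology,
                gate3_nM=gate3_nM,
                t_end=t_end,
                sample_interval=sample_interval,
            )
            traj = simulate_ode(spec)
        except Exception as exc:
            raise RuntimeError(f"sample {sample!r}: {exc}") from exc
        if trajectory_dir is not None:
            traj.to_csv(f"{trajectory_dir}/{sample}.csv")
        fam, rox = read_out(traj, spec)
        rows.append(
            {
                "sample_id": sample,
                "true_class": rec.group,
                "fam_final_nM": fam,
                "rox_final_nM": rox,
                "margin_nM": fam - rox,
                "call": call_sample(fam, rox, floor_delta, margin_eps),
            }
        )
    results = pd.DataFrame(rows)
    return results, summarize_calls(results)


# ---------------------------------------------------------------------------
# Clinical-trait circuits


@dataclasses.dataclass(frozen=True)
class NodeBinning:
    """Lymph-node count bins: <=15, 16-28, >=29 by default.

    The count 15 sits in part1 because 15 is the conventional survival
    threshold in node-count prognosis; both boundaries are configurable.
    """

    boundaries: tuple[int, int] = (15, 28)
    labels: tuple[str, str, str] = ("part1", "part2", "part3")

    def __post_init__(self):
        lo, hi = self.boundaries
        if not lo < hi:
            raise ValueError("binning boundaries must be strictly increasing")

    def bin(self, count: int) -> str:
        if count < 0:
            raise ValueError("lymph-node count must be >= 0")
        lo, hi = self.boundaries
        if count <= lo:
            return self.labels[0]
        if count <= hi:
            return self.labels[1]
        return self.labels[2]


def bin_lymph_nodes(count: int, binning: NodeBinning | None = None) -> str:
    """Map a lymph-node count onto its part label."""
    return (binning or NodeBinning()).bin(count)


#: default expected dominant channel per trait level
EXPECTED_CHANNEL_LYMPH = {"part1": "FAM", "part2": "FAM", "part3": "ROX"}
EXPECTED_CHANNEL_INDICATOR = {1: "FAM", 0: "ROX"}


def classify_trait_cohort(
    expr: pd.DataFrame,
    clinical: pd.DataFrame,
    pos_hub: str,
    neg_hub: str,
    trait: str,
    binning: NodeBinning | None = None,
    expected_channel: Mapping | None = None,
    k_default: float = 0.003,
    rate_scale: Mapping[str, float] | None = None,
    topology: str = "shared_gate",
    gate3_nM: float | None = None,
    t_end: float = 1000.0,
    sample_interval: float = 10.0,
    floor_delta: float = FLOOR_DELTA_DEFAULT,
    margin_eps: float = MARGIN_EPS_DEFAULT,
) -> pd.DataFrame:
    """Per-part accuracy of the two-hub trait circuit.

    Each sample is binned by its trait level (lymph counts via ``binning``,
    a binary indicator by its value), simulated through the trait circuit and
    called; a call is correct when its channel matches the expected dominant
    channel for the sample's part.  Empty parts report accuracy NaN.
    """
    for g in (pos_hub, neg_hub):
        if g not in expr.index:
            raise ValueError(f"hub gene {g!r} not in the expression matrix")
    if trait not in clinical.columns:
        raise ValueError(f"trait column {trait!r} missing from the clinical table")
    if expected_channel is None:
        expected_channel = (
            EXPECTED_CHANNEL_LYMPH if trait == "lymph_node_count" else EXPECTED_CHANNEL_INDICATOR
        )
    binning = binning or NodeBinning()
    parts = list(dict.fromkeys(expected_channel))
    tally = {p: {"n": 0, "n_correct": 0, "n_indeterminate": 0} for p in parts}
    for rec in clinical.itertuples():
        level = getattr(rec, trait)
        part = binning.bin(int(level)) if trait == "lymph_node_count" else level
        if part not in tally:
            raise ValueError(f"no expected channel configured for trait level {part!r}")
        try:
            spec = compile_trait_circuit(
                pos_hub,
                neg_hub,
                expr[rec.sample_id].to_dict(),
                k_default=k_default,
                rate_scale=rate_scale,
                topology=topology,
                gate3_nM=gate3_nM,
                t_end=t_end,
                sample_interval=sample_interval,
            )
            traj = simulate_ode(spec)
        except Exception as exc:
            raise RuntimeError(f"sample {rec.sample_id!r}: {exc}") from exc
        fam, rox = read_out(traj, spec)
        call = call_sample(fam, rox, floor_delta, margin_eps)
        tally[part]["n"] += 1
        if call == "indeterminate":
            tally[part]["n_indeterminate"] += 1
        elif CALL_CHANNEL[call] == expected_channel[part]:
            tally[part]["n_correct"] += 1
    rows = []
    for part in parts:
        t = tally[part]
        rows.append(
            {
                "part": part,
                "expected_channel": expected_channel[part],
                "n": t["n"],
                "n_correct": t["n_correct"],
                "n_indeterminate": t["n_indeterminate"],
                "accuracy": t["n_correct"] / t["n"] if t["n"] else float("nan"),
            }
        )
    return pd.DataFrame(rows)
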
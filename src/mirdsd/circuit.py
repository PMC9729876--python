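"""DNA strand-displacement circuit representation and compilation.

A toehold-mediated strand-displacement (DSD) gate is modeled as a single
irreversible bimolecular step (long-toehold regime): an input strand binds a
gate complex and releases the incumbent output strand.  The diagnostic
circuit is the two-layer winner-take-all design:

* layer 1 — each tumor-marker input reacts with gate 1 to release a
  tumor-side output strand at rate ``|log2FC| * k``; each health-marker input
  reacts with gate 2 to release a health-side output.  Gate 1/2 pools are
  stoichiometrically non-limiting (initialised to the total input on their
  channel) so layer 1 converts inputs faithfully.
* layer 2 — the two output pools are compared.  Three explicit topologies
  encode the comparison, since the mechanism admits more than one reading:
  ``shared_gate`` (default): both outputs compete for a limiting gate 3 whose
  consumption releases the FAM (tumor) or ROX (health) fluorophore;
  ``annihilation``: outputs annihilate pairwise, survivors report through
  per-channel reporters; ``threshold_subtract``: the health output first
  feeds a fast thresholding complex, the remainder reports.

Concentrations are in nM with FPKM mapped to nM by the identity; rate
constants in nM^-1 s^-1 with default k = 0.003; gate 3 defaults to the mean
concentration of the health-channel inputs (the printed example: inputs at
20 and 14 nM give the 17 nM threshold).
"""

from __future__ import annotations

import dataclasses
import json
from typing import Mapping, Sequence

import numpy as np
import yaml

#: default toehold binding rate constant, nM^-1 s^-1
K_DEFAULT = 0.003

#: default readout horizon and sampling interval, seconds (100 samples of 10 s)
T_END_DEFAULT = 1000.0
DT_DEFAULT = 10.0

#: thresholding step speed multiplier for the threshold_subtract topology
THRESHOLD_RATE_FACTOR = 10.0

ROLES = ("input", "intermediate_output", "gate_complex", "reporter_complex", "signal", "waste")
CHANNELS = ("FAM", "ROX", "none")
TOPOLOGIES = ("shared_gate", "annihilation", "threshold_subtract")


@dataclasses.dataclass(frozen=True)
class Species:
    id: str
    role: str
    channel: str = "none"
    initial_nM: float = 0.0


@dataclasses.dataclass(frozen=True)
class Reaction:
    """Irreversible bimolecular mass-action reaction (2 reactants, 1-2 products)."""

    reactants: tuple[str, str]
    products: tuple[str, ...]
    k: float  # nM^-1 s^-1


@dataclasses.dataclass(frozen=True)
class CircuitSpec:
    species: tuple[Species, ...]
    reactions: tuple[Reaction, ...]
    readout: Mapping[str, str]  # channel -> signal species id
    t_end: float = T_END_DEFAULT
    sample_interval: float = DT_DEFAULT
    topology: str = "shared_gate"

    def species_ids(self) -> tuple[str, ...]:
        return tuple(s.id for s in self.species)

    def species_index(self) -> dict[str, int]:
        return {s.id: i for i, s in enumerate(self.species)}

    def initial_concentrations(self) -> np.ndarray:
        return np.array([s.initial_nM for s in self.species], dtype=float)

    def sample_times(self) -> np.ndarray:
        return np.arange(0.0, self.t_end + self.sample_interval / 2, self.sample_interval)

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "species": [
                {"id": s.id, "role": s.role, "channel": s.channel, "conc_nM": s.initial_nM}
                for s in self.species
            ],
            "reactions": [
                {"reactants": list(r.reactants), "products": list(r.products), "k_nM_s": r.k}
                for r in self.reactions
            ],
            "readout": dict(self.readout),
            "t_end_s": self.t_end,
            "dt_s": self.sample_interval,
            "topology": self.topology,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CircuitSpec":
        return cls(
            species=tuple(
                Species(s["id"], s["role"], s.get("channel", "none"), float(s["conc_nM"]))
                for s in d["species"]
            ),
            reactions=tuple(
                Reaction(tuple(r["reactants"]), tuple(r["products"]), float(r["k_nM_s"]))
                for r in d["reactions"]
            ),
            readout=dict(d["readout"]),
            t_end=float(d["t_end_s"]),
            sample_interval=float(d["dt_s"]),
            topology=d.get("topology", "shared_gate"),
        )

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=False)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, path) -> "CircuitSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def validate_circuit(spec: CircuitSpec) -> list[str]:
    """Return a list of invariant violations (empty iff the spec is valid)."""
    findings: list[str] = []
    ids = [s.id for s in spec.species]
    seen = set()
    for sid in ids:
        if sid in seen:
            findings.append(f"duplicate species id {sid!r}")
        seen.add(sid)
    for s in spec.species:
        if s.role not in ROLES:
            findings.append(f"species {s.id!r}: unknown role {s.role!r}")
        if s.channel not in CHANNELS:
            findings.append(f"species {s.id!r}: unknown channel {s.channel!r}")
        if s.initial_nM < 0:
            findings.append(f"species {s.id!r}: negative initial concentration")
        if s.role == "signal" and s.channel == "none":
            findings.append(f"signal species {s.id!r} carries no channel")
        if s.role == "input" and s.channel != "none":
            findings.append(f"input species {s.id!r} must carry channel 'none'")
    for i, r in enumerate(spec.reactions):
        if len(r.reactants) != 2:
            findings.append(f"reaction {i}: needs exactly 2 reactants")
        if not (1 <= len(r.products) <= 2):
            findings.append(f"reaction {i}: needs 1-2 products")
        for sid in tuple(r.reactants) + tuple(r.products):
            if sid not in seen:
                findings.append(f"reaction {i}: undeclared species {sid!r}")
        if not (np.isfinite(r.k) and r.k > 0):
            findings.append(f"reaction {i}: rate constant must be finite and > 0")
    for channel, sid in spec.readout.items():
        if sid not in seen:
            findings.append(f"readout channel {channel!r}: undeclared species {sid!r}")
    if spec.t_end <= 0:
        findings.append("t_end must be > 0")
    if spec.sample_interval <= 0:
        findings.append("sample_interval must be > 0")
    return findings


def _input_conc(sample_fpkm: Mapping[str, float], gene: str) -> float:
    if gene not in sample_fpkm:
        raise ValueError(f"gene {gene!r} missing from the sample expression values")
    return max(float(sample_fpkm[gene]), 0.0)


def _compile(
    pos_inputs: Sequence[tuple[str, float, float]],  # (gene, conc_nM, rate)
    neg_inputs: Sequence[tuple[str, float, float]],
    k_default: float,
    topology: str,
    gate3_nM: float | None,
    t_end: float,
    dt: float,
) -> CircuitSpec:
    if topology not in TOPOLOGIES:
        raise ValueError(f"unknown topology {topology!r}; choose from {TOPOLOGIES}")
    if k_default <= 0:
        raise ValueError("k_default must be > 0")
    pos_total = sum(c for _, c, _ in pos_inputs)
    neg_total = sum(c for _, c, _ in neg_inputs)
    gate3 = float(np.mean([c for _, c, _ in neg_inputs])) if gate3_nM is None else float(gate3_nM)

    species = [
        Species("gate1", "gate_complex", "none", pos_total),
        Species("gate2", "gate_complex", "none", neg_total),
        Species("out_tumor", "intermediate_output", "none", 0.0),
        Species("out_health", "intermediate_output", "none", 0.0),
        Species("sig_FAM", "signal", "FAM", 0.0),
        Species("sig_ROX", "signal", "ROX", 0.0),
    ]
    reactions = []
    for gene, conc, rate in pos_inputs:
        species.append(Species(f"in_pos:{gene}", "input", "none", conc))
        reactions.append(Reaction((f"in_pos:{gene}", "gate1"), ("out_tumor",), rate))
    for gene, conc, rate in neg_inputs:
        species.append(Species(f"in_neg:{gene}", "input", "none", conc))
        reactions.append(Reaction((f"in_neg:{gene}", "gate2"), ("out_health",), rate))

    if topology == "shared_gate":
        species.append(Species("gate3", "gate_complex", "none", gate3))
        reactions.append(Reaction(("out_tumor", "gate3"), ("sig_FAM",), k_default))
        reactions.append(Reaction(("out_health", "gate3"), ("sig_ROX",), k_default))
    elif topology == "annihilation":
        species.append(Species("waste", "waste", "none", 0.0))
        species.append(Species("rep_FAM", "reporter_complex", "none", gate3))
        species.append(Species("rep_ROX", "reporter_complex", "none", gate3))
        reactions.append(Reaction(("out_tumor", "out_health"), ("waste",), k_default))
        reactions.append(Reaction(("out_tumor", "rep_FAM"), ("sig_FAM",), k_default))
        reactions.append(Reaction(("out_health", "rep_ROX"), ("sig_ROX",), k_default))
    else:  # threshold_subtract
        species.append(Species("waste", "waste", "none", 0.0))
        species.append(Species("thresh", "gate_complex", "none", gate3))
        species.append(Species("rep_FAM", "reporter_complex", "none", pos_total + neg_total))
        species.append(Species("rep_ROX", "reporter_complex", "none", pos_total + neg_total))
        reactions.append(
            Reaction(("out_health", "thresh"), ("waste",), THRESHOLD_RATE_FACTOR * k_default)
        )
        reactions.append(Reaction(("out_tumor", "rep_FAM"), ("sig_FAM",), k_default))
        reactions.append(Reaction(("out_health", "rep_ROX"), ("sig_ROX",), k_default))

    spec = CircuitSpec(
        species=tuple(sorted(species, key=lambda s: s.id)),
        reactions=tuple(reactions),
        readout={"FAM": "sig_FAM", "ROX": "sig_ROX"},
        t_end=t_end,
        sample_interval=dt,
        topology=topology,
    )
    findings = validate_circuit(spec)
    if findings:  # pragma: no cover - compiler bug guard
        raise AssertionError(f"compiled circuit invalid: {findings}")
    return spec


def compile_diagnostic_circuit(
    panel,
    sample_fpkm: Mapping[str, float],
    k_default: float = K_DEFAULT,
    topology: str = "shared_gate",
    gate3_nM: float | None = None,
    t_end: float = T_END_DEFAULT,
    sample_interval: float = DT_DEFAULT,
) -> CircuitSpec:
    """Compile a biomarker panel plus one sample into the 4-input WTA circuit.

    Input concentrations are the sample's FPKM values taken as nM (identity
    map, floored at 0).  Layer-1 rates are ``|log2FC| * k_default`` — the
    magnitude is used for down-regulated (health) markers, whose log2FC is
    negative.  Gate 3 defaults to the mean of the health-channel input
    concentrations unless ``gate3_nM`` overrides it.
    """
    def _entries(markers):
        out = []
        for gene, lfc in markers:
            if lfc == 0:
                raise ValueError(f"marker {gene!r} has log2FC 0; its rate would vanish")
            out.append((gene, _input_conc(sample_fpkm, gene), abs(lfc) * k_default))
        return out

    return _compile(
        _entries(panel.positive),
        _entries(panel.negative),
        k_default,
        topology,
        gate3_nM,
        t_end,
        sample_interval,
    )


def compile_trait_circuit(
    pos_hub: str,
    neg_hub: str,
    sample_fpkm: Mapping[str, float],
    k_default: float = K_DEFAULT,
    rate_scale: Mapping[str, float] | None = None,
    topology: str = "shared_gate",
    gate3_nM: float | None = None,
    t_end: float = T_END_DEFAULT,
    sample_interval: float = DT_DEFAULT,
) -> CircuitSpec:
    """Two-input trait circuit: one hub gene per channel.

    Rates are ``k_default`` unless ``rate_scale`` supplies per-gene
    multipliers (e.g. |module-trait correlation|).  Gate 3 is the
    health-channel input concentration (the mean of a singleton).
    """
    def _rate(gene):
        scale = 1.0 if rate_scale is None else float(rate_scale[gene])
        if scale <= 0:
            raise ValueError(f"rate scale for {gene!r} must be > 0")
        return scale * k_default

    return _compile(
        [(pos_hub, _input_conc(sample_fpkm, pos_hub), _rate(pos_hub))],
        [(neg_hub, _input_conc(sample_fpkm, neg_hub), _rate(neg_hub))],
        k_default,
        topology,
        gate3_nM,
        t_end,
        sample_interval,
    )
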
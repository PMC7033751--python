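"""Synthetic V(D)J recombination with known ground truth.

Emulates the recombination process behind pro B cell Igh amplicon
repertoires: a V gene trimmed at its 3' end, an optionally absent D segment
trimmed at both ends, a J gene trimmed at its 5' end, and non-templated (N)
nucleotides added at the joints by Tdt. Fetal-liver repertoires are modeled
by ``tdt_on=False`` (no N-addition); adult bone-marrow repertoires by
``tdt_on=True``. Clonal read replication gives the skewed duplicate
structure dereplication and rarefaction operate on.

Trimming lengths are geometric (support 0,1,2,...) with configurable means;
N block lengths are Poisson; N letters are uniform over A/C/G/T. Trims that
would destroy the FR3 Cys codon or FR4 Trp codon are resampled. An optional
``y101_target`` enforces, by rejection-sampling whole rearrangements, the
probability that a productive clone carries tyrosine at CDR-H3 position
101 — the statistic pre-BCR selection acts on — without editing sequences,
so joint trimming/usage statistics stay internally consistent.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd
import yaml

from .airr_io import D_LESS, RearrangementRecord
from .cdr3 import call_productivity, residue_at
from .reference import Reference, translate_nt

__all__ = [
    "SimulatorConfig",
    "SimulatedTruth",
    "simulate_rearrangement",
    "simulate_repertoire",
    "reassemble_truth",
    "truth_frame",
    "write_truth",
]


@dataclass
class SimulatorConfig:
    """Parameters of one simulated repertoire (one sorted subset).

    ``clone_size`` names a clone-size distribution: ``{"distribution":
    "geometric", "mean": m}`` (support 1,2,..., mean m) or ``{"distribution":
    "constant", "size": k}``. Weights mappings must sum to 1; ``d_weights``
    may include a ``"D-less"`` pseudo-gene for direct V-to-J joins.
    """

    seed: int = 0
    n_clones: int = 1000
    clone_size: dict[str, Any] = field(
        default_factory=lambda: {"distribution": "geometric", "mean": 3.0}
    )
    v_weights: dict[str, float] | None = None
    d_weights: dict[str, float] | None = None
    j_weights: dict[str, float] | None = None
    trim_mean_v3: float = 0.5
    trim_mean_d5: float = 1.0
    trim_mean_d3: float = 1.0
    trim_mean_j5: float = 1.0
    tdt_on: bool = False
    n_insert_mean: float = 4.0
    y101_target: float | None = None
    max_rejections: int = 5000
    subset_label: str = ""

    def validate(self) -> None:
        if self.n_clones <= 0:
            raise ValueError("n_clones must be positive")
        for name in ("trim_mean_v3", "trim_mean_d5", "trim_mean_d3", "trim_mean_j5"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.n_insert_mean < 0:
            raise ValueError("n_insert_mean must be non-negative")
        if self.y101_target is not None and not (0.0 <= self.y101_target <= 1.0):
            raise ValueError("y101_target must be in [0, 1]")
        for name in ("v_weights", "d_weights", "j_weights"):
            w = getattr(self, name)
            if w is not None:
                if any(p < 0 for p in w.values()):
                    raise ValueError(f"{name} has negative entries")
                if abs(sum(w.values()) - 1.0) > 1e-9:
                    raise ValueError(f"{name} must sum to 1 (got {sum(w.values())})")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulatorConfig":
        with open(path) as handle:
            data = yaml.safe_load(handle) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as handle:
            yaml.safe_dump(dataclasses.asdict(self), handle, sort_keys=True)


@dataclass
class SimulatedTruth:
    """Ground truth for one clone; re-assembles to the emitted sequence."""

    clone_id: str
    n_reads: int
    v_gene: str
    d_gene: str  # "D-less" for direct V-J joins
    j_gene: str
    trim_v3: int
    trim_d5: int
    trim_d3: int
    trim_j5: int
    n1: str
    n2: str
    productive: bool | None
    sequence: str


def _geometric0(rng: np.random.Generator, mean: float) -> int:
    """Geometric on 0,1,2,... with the given mean."""
    if mean <= 0:
        return 0
    return int(rng.geometric(1.0 / (mean + 1.0))) - 1


def _bounded_geometric(rng: np.random.Generator, mean: float, upper: int) -> int:
    for _ in range(100):
        x = _geometric0(rng, mean)
        if x <= upper:
            return x
    return upper


def _n_block(rng: np.random.Generator, cfg: SimulatorConfig) -> str:
    if not cfg.tdt_on:
        return ""
    n = int(rng.poisson(cfg.n_insert_mean))
    if n == 0:
        return ""
    return "".join(rng.choice(["A", "C", "G", "T"], size=n))


def _resolve_weights(
    cfg: SimulatorConfig, reference: Reference
) -> dict[str, tuple[list[str], np.ndarray]]:
    def resolved(weights: dict[str, float] | None, genes: list[str]):
        if weights is None:
            weights = {g: 1.0 / len(genes) for g in genes}
        names = sorted(weights)
        probs = np.array([weights[n] for n in names], dtype=float)
        return names, probs / probs.sum()

    return {
        "v": resolved(cfg.v_weights, reference.v_genes),
        "d": resolved(cfg.d_weights, reference.d_genes),
        "j": resolved(cfg.j_weights, reference.j_genes),
    }


def simulate_rearrangement(
    config: SimulatorConfig,
    reference: Reference,
    rng: np.random.Generator,
    weights: dict[str, tuple[list[str], np.ndarray]] | None = None,
) -> tuple[RearrangementRecord, SimulatedTruth]:
    """Draw one rearrangement and its ground truth.

    The emitted sequence is ``V[: len-t_v3] + N1 + D[t_d5 : len-t_d3] + N2 +
    J[t_j5:]`` (D and N2 omitted for D-less joins; N blocks empty when Tdt is
    off). Trims never remove the Cys96 or FR4 Trp anchor codons.
    """
    if weights is None:
        weights = _resolve_weights(config, reference)
    v_names, v_p = weights["v"]
    d_names, d_p = weights["d"]
    j_names, j_p = weights["j"]
    v_gene = v_names[int(rng.choice(len(v_names), p=v_p))]
    d_gene = d_names[int(rng.choice(len(d_names), p=d_p))]
    j_gene = j_names[int(rng.choice(len(j_names), p=j_p))]

    vseg = reference.get_v(v_gene)
    jseg = reference.get_j(j_gene)
    v_nt, j_nt = vseg.nt_sequence, jseg.nt_sequence

    max_v3 = len(v_nt) - (vseg.cys96_codon_start + 3)
    t_v3 = _bounded_geometric(rng, config.trim_mean_v3, max_v3)
    t_j5 = _bounded_geometric(rng, config.trim_mean_j5, jseg.fr4_trp_offset)

    n1 = _n_block(rng, config)
    if d_gene == D_LESS:
        t_d5 = t_d3 = 0
        d_part = ""
        n2 = ""
    else:
        d_nt = reference.get_d(d_gene).nt_sequence
        for _ in range(100):
            t_d5 = _geometric0(rng, config.trim_mean_d5)
            t_d3 = _geometric0(rng, config.trim_mean_d3)
            if t_d5 + t_d3 <= len(d_nt):
                break
        else:
            t_d5 = t_d3 = 0
        d_part = d_nt[t_d5 : len(d_nt) - t_d3]
        n2 = _n_block(rng, config)

    sequence = v_nt[: len(v_nt) - t_v3] + n1 + d_part + n2 + j_nt[t_j5:]
    js = vseg.cys96_codon_start
    je = len(sequence) - (len(j_nt) - jseg.fr4_trp_offset - 3)
    junction = sequence[js:je]
    junction_aa = translate_nt(junction) if len(junction) % 3 == 0 else ""

    record = RearrangementRecord(
        sequence_id="",
        sequence=sequence,
        v_call=v_gene,
        d_call=d_gene,
        j_call=j_gene,
        junction=junction,
        junction_aa=junction_aa,
        productive=None,
        duplicate_count=1,
        subset_label=config.subset_label,
        junction_start=js,
        junction_end=je,
    )
    record.productive = call_productivity(record, reference)
    truth = SimulatedTruth(
        clone_id="",
        n_reads=0,
        v_gene=v_gene,
        d_gene=d_gene,
        j_gene=j_gene,
        trim_v3=t_v3,
        trim_d5=t_d5,
        trim_d3=t_d3,
        trim_j5=t_j5,
        n1=n1,
        n2=n2,
        productive=record.productive,
        sequence=sequence,
    )
    return record, truth


def _residue_101(record: RearrangementRecord) -> str | None:
    """Residue at CDR-H3 position 101 of a productive record, else None."""
    if record.productive is not True or len(record.junction_aa) < 2:
        return None
    return residue_at(record.junction_aa[1:-1], 101)


def _clone_size(rng: np.random.Generator, spec: dict[str, Any]) -> int:
    dist = spec.get("distribution", "geometric")
    if dist == "constant":
        return int(spec["size"])
    if dist == "geometric":
        mean = float(spec.get("mean", 3.0))
        if mean <= 1.0:
            return 1
        return int(rng.geometric(1.0 / mean))
    raise ValueError(f"unknown clone-size distribution {dist!r}")


def simulate_repertoire(
    config: SimulatorConfig, reference: Reference
) -> tuple[list[RearrangementRecord], list[SimulatedTruth]]:
    """Simulate ``n_clones`` clones, each replicated to >=1 identical reads.

    Deterministic for a fixed ``config.seed``. When ``y101_target`` is set,
    each clone whose first draw is productive with a position-101 residue is
    assigned Y/non-Y status by a Bernoulli(``y101_target``) coin and redrawn
    until the realized residue class matches; clones that are non-productive
    or too short on first draw are accepted as-is, so marginal productivity
    and length statistics are untouched.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    weights = _resolve_weights(config, reference)

    records: list[RearrangementRecord] = []
    truths: list[SimulatedTruth] = []
    for i in range(config.n_clones):
        rec, truth = simulate_rearrangement(config, reference, rng, weights)
        if config.y101_target is not None:
            r101 = _residue_101(rec)
            if r101 is not None:
                want_y = bool(rng.random() < config.y101_target)
                rejections = 0
                while (r101 == "Y") != want_y:
                    rejections += 1
                    if rejections > config.max_rejections:
                        rate = 1.0 / (rejections + 1)
                        raise RuntimeError(
                            f"y101_target={config.y101_target}: exceeded "
                            f"{config.max_rejections} rejections for clone {i} "
                            f"(acceptance rate ~{rate:.2e})"
                        )
                    cand_rec, cand_truth = simulate_rearrangement(
                        config, reference, rng, weights
                    )
                    cand_101 = _residue_101(cand_rec)
                    if cand_101 is None:
                        continue
                    rec, truth, r101 = cand_rec, cand_truth, cand_101
        clone_id = f"clone{i:05d}"
        size = _clone_size(rng, config.clone_size)
        truth.clone_id = clone_id
        truth.n_reads = size
        truths.append(truth)
        for k in range(size):
            records.append(
                dataclasses.replace(rec, sequence_id=f"{clone_id}_r{k:03d}")
            )
    return records, truths


def reassemble_truth(truth: SimulatedTruth, reference: Reference) -> str:
    """Rebuild the emitted nucleotide sequence from the truth fields."""
    v_nt = reference.get_v(truth.v_gene).nt_sequence
    j_nt = reference.get_j(truth.j_gene).nt_sequence
    if truth.d_gene == D_LESS:
        d_part = ""
    else:
        d_nt = reference.get_d(truth.d_gene).nt_sequence
        d_part = d_nt[truth.trim_d5 : len(d_nt) - truth.trim_d3]
    return (
        v_nt[: len(v_nt) - truth.trim_v3]
        + truth.n1
        + d_part
        + truth.n2
        + j_nt[truth.trim_j5 :]
    )


def truth_frame(truths: Sequence[SimulatedTruth]) -> pd.DataFrame:
    frame = pd.DataFrame([dataclasses.asdict(t) for t in truths])
    frame["productive"] = [
        "" if t.productive is None else ("T" if t.productive else "F")
        for t in truths
    ]
    return frame


def write_truth(truths: Sequence[SimulatedTruth], path: str | Path) -> None:
    truth_frame(truths).to_csv(path, sep="\t", index=False)
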
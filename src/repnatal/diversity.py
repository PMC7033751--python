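"""Usage, productivity-quotient, trimming and Shannon-rarefaction statistics.

Productivity quotients divide unique productive by unique dereplicated
sequences at a chosen aggregation level (VH family, V gene, D gene, J gene,
or Ighv locus domain); records whose productivity is undetermined are
reported separately and excluded from both numerator and denominator.

Diversity is the Shannon index H = -sum p_i ln p_i (nats by default) over
CDR-H3 species, and rarefaction subsamples *replicated reads* (duplicate-
count weighted) without replacement at a grid of depths so repertoires of
unequal size can be compared.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .airr_io import D_LESS, RearrangementRecord
from .reference import Reference, strip_allele

logger = logging.getLogger(__name__)

__all__ = [
    "UsageTable",
    "usage_and_productivity",
    "j_trimming_stats",
    "shannon_index",
    "RarefactionCurve",
    "rarefy_shannon",
    "cdr3_species",
    "default_depths",
]

USAGE_LEVELS = ("family", "gene", "d_gene", "j_gene", "domain")


@dataclass
class UsageTable:
    """Per-name usage and productivity quotients at one aggregation level."""

    level: str
    table: pd.DataFrame  # name, n_unique_dereplicated, n_unique_productive, ...
    overall_quotient: float

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def _level_name(rec: RearrangementRecord, level: str, reference: Reference) -> str:
    gene = strip_allele(rec.v_call)
    if level == "gene":
        return gene
    if level == "family":
        return reference.family_map.get(gene, "unknown")
    if level == "domain":
        d = reference.domain_map.get(gene)
        return f"domain{d}" if d is not None else "unassigned"
    if level == "d_gene":
        return rec.d_call if rec.d_call else D_LESS
    if level == "j_gene":
        return strip_allele(rec.j_call)
    raise ValueError(f"unknown level {level!r}; choose from {USAGE_LEVELS}")


def usage_and_productivity(
    records: Sequence[RearrangementRecord], reference: Reference, level: str = "family"
) -> UsageTable:
    """Tabulate unique-sequence usage and productivity quotients.

    ``usage_freq`` is the fraction of unique dereplicated sequences per
    name (sums to 1); the quotient is unique-productive over determined
    unique sequences. D-less joins form their own row at the d_gene level.
    """
    if not records:
        raise ValueError("no records")
    rows: dict[str, dict[str, int]] = {}
    for rec in records:
        name = _level_name(rec, level, reference)
        row = rows.setdefault(
            name, {"derep": 0, "productive": 0, "undetermined": 0}
        )
        row["derep"] += 1
        if rec.productive is None:
            row["undetermined"] += 1
        elif rec.productive:
            row["productive"] += 1
    total = sum(r["derep"] for r in rows.values())
    names = sorted(rows)
    determined = {n: rows[n]["derep"] - rows[n]["undetermined"] for n in names}
    table = pd.DataFrame(
        {
            "name": names,
            "n_unique_dereplicated": [rows[n]["derep"] for n in names],
            "n_unique_productive": [rows[n]["productive"] for n in names],
            "n_undetermined": [rows[n]["undetermined"] for n in names],
            "productivity_quotient": [
                rows[n]["productive"] / determined[n] if determined[n] else float("nan")
                for n in names
            ],
            "usage_freq": [rows[n]["derep"] / total for n in names],
        }
    )
    total_det = sum(determined.values())
    overall = (
        sum(rows[n]["productive"] for n in names) / total_det
        if total_det
        else float("nan")
    )
    return UsageTable(level=level, table=table, overall_quotient=overall)


def j_trimming_stats(
    records: Sequence[RearrangementRecord], reference: Reference
) -> tuple[pd.DataFrame, dict]:
    """Per-record J 5' trimming (nt) and CDR-H3 length (aa), with summaries.

    The trim is the smallest germline J offset whose suffix matches the read
    end exactly (minimal-trim convention — the same ambiguity any annotator
    faces when an N nucleotide happens to extend the germline match).
    Records whose J suffix cannot be matched are skipped and counted.
    """
    rows = []
    skipped = 0
    for rec in records:
        try:
            jseg = reference.get_j(rec.j_call)
        except KeyError:
            skipped += 1
            continue
        j_nt = jseg.nt_sequence
        trim = None
        for t in range(0, jseg.fr4_trp_offset + 1):
            if rec.sequence.endswith(j_nt[t:]):
                trim = t
                break
        if trim is None:
            skipped += 1
            continue
        cdr3_len = len(rec.junction_aa) - 2 if len(rec.junction_aa) >= 2 else None
        rows.append(
            {
                "sequence_id": rec.sequence_id,
                "j_call": strip_allele(rec.j_call),
                "j_trim": trim,
                "cdr3_length": cdr3_len,
            }
        )
    if skipped:
        logger.info("j_trimming_stats: skipped %d records", skipped)
    per_record = pd.DataFrame(rows, columns=["sequence_id", "j_call", "j_trim", "cdr3_length"])
    trims = per_record["j_trim"]
    lengths = per_record["cdr3_length"].dropna()
    summary = {
        "n": int(len(per_record)),
        "n_skipped": int(skipped),
        "mean_trim": float(trims.mean()) if len(trims) else float("nan"),
        "median_trim": float(trims.median()) if len(trims) else float("nan"),
        "trim_histogram": trims.value_counts().sort_index().to_dict(),
        "mean_cdr3_length": float(lengths.mean()) if len(lengths) else float("nan"),
        "median_cdr3_length": float(lengths.median()) if len(lengths) else float("nan"),
    }
    return per_record, summary


def shannon_index(abundances: Sequence[int], base: float | None = None) -> float:
    """Shannon index H = -sum p_i log p_i over species abundances.

    Natural log (nats) by default; pass ``base=2`` for bits.
    """
    counts = np.asarray(list(abundances), dtype=float)
    if counts.size == 0:
        raise ValueError("empty abundance vector")
    if np.any(counts < 1):
        raise ValueError("abundances must be positive counts")
    return float(stats.entropy(counts, base=base))


def cdr3_species(records: Sequence[RearrangementRecord], level: str = "aa") -> list[str]:
    """Species label per record for diversity: the CDR-H3 segment.

    ``aa``: amino-acid CDR-H3 for in-frame junctions, falling back to the
    nucleotide junction (out-of-frame reads still occupy a species), then to
    the full read. ``nt``: nucleotide junction, falling back to the read.
    """
    labels = []
    for rec in records:
        if level == "aa" and len(rec.junction_aa) >= 2:
            labels.append(rec.junction_aa[1:-1])
        elif rec.junction:
            labels.append(rec.junction)
        else:
            labels.append(rec.sequence)
    return labels


@dataclass
class RarefactionCurve:
    depths: list[int]
    mean_H: list[float]
    sd_H: list[float]
    n_replicates: int
    seed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"depth": self.depths, "mean_H": self.mean_H, "sd_H": self.sd_H}
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def default_depths(total: int, n_points: int = 10, start: int = 10) -> list[int]:
    """Log-spaced subsampling depths from ``start`` to the total read count."""
    if total < start:
        return [total]
    grid = np.unique(
        np.round(np.logspace(np.log10(start), np.log10(total), n_points)).astype(int)
    )
    return [int(d) for d in grid]


def rarefy_shannon(
    records: Sequence[RearrangementRecord],
    depths: Sequence[int],
    n_replicates: int = 200,
    seed: int = 0,
    species_level: str = "aa",
) -> RarefactionCurve:
    """Shannon index under repeated subsampling of replicated reads.

    Reads are expanded by ``duplicate_count``; at each depth, reads are
    drawn without replacement ``n_replicates`` times and the Shannon index
    of the CDR-H3 species counts in the subsample is recorded. Deterministic
    for a fixed seed.
    """
    depths = sorted(int(d) for d in depths)
    labels = cdr3_species(records, species_level)
    counts = np.array([r.duplicate_count for r in records], dtype=int)
    codes = pd.Categorical(labels).codes
    pool = np.repeat(codes, counts)
    total = pool.size
    if not depths or depths[-1] > total:
        raise ValueError(f"max depth exceeds total reads ({total})")
    rng = np.random.default_rng(seed)
    n_species = codes.max() + 1
    mean_h, sd_h = [], []
    for depth in depths:
        values = np.empty(n_replicates)
        for r in range(n_replicates):
            sub = rng.choice(pool, size=depth, replace=False)
            tab = np.bincount(sub, minlength=n_species)
            values[r] = stats.entropy(tab[tab > 0])
        mean_h.append(float(values.mean()))
        sd_h.append(float(values.std()))
    return RarefactionCurve(
        depths=depths,
        mean_H=mean_h,
        sd_H=sd_h,
        n_replicates=n_replicates,
        seed=seed,
    )
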
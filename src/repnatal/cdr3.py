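"""Productivity calling, CDR-H3 extraction, composition and Y101 statistics.

The CDR-H3 is the stretch of residues strictly between the conserved FR3
cysteine (position 96) and the FR4 tryptophan. Numbering is a linear offset
from that cysteine: the first CDR-H3 residue is position 97, so position 101
is the fifth CDR-H3 residue. Tyrosine at position 101 contacts the VpreB
"sensing site" of the surrogate light chain and favours pre-BCR checkpoint
passage; genes whose modal residue at 101 is not tyrosine are classified
non-Y101 and annotated with the biochemical class of that modal residue.

A rearrangement is productive iff (i) the junction (Cys codon start through
Trp codon end) has nucleotide length divisible by 3, (ii) translation of the
read in the V reading frame is stop-free, and (iii) both anchor residues are
present. Ambiguous nucleotides never fabricate a stop/non-stop call: any N
in the frame makes the record's productivity undetermined.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .airr_io import RearrangementRecord
from .reference import Reference, strip_allele, translate_nt

logger = logging.getLogger(__name__)

__all__ = [
    "AA_ALPHABET",
    "CDR3_FIRST_POSITION",
    "biochemical_class",
    "call_productivity",
    "extract_cdr3",
    "residue_at",
    "Cdr3Profile",
    "position_profile",
    "GeneY101Summary",
    "classify_genes_y101",
]

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
CDR3_FIRST_POSITION = 97  # FR3 Cys is position 96

# Kyte-Doolittle-style partition with His counted as charged. Tyrosine sits in
# the neutral class; its role at position 101 is tracked by the Y101 statistic.
CHARGED = frozenset("DEKRH")
HYDROPHOBIC = frozenset("AVLIMFC")
NEUTRAL = frozenset("GSTNQPWY")


def biochemical_class(aa: str) -> str:
    """Classify one standard residue as hydrophobic, charged or neutral."""
    if aa in CHARGED:
        return "charged"
    if aa in HYDROPHOBIC:
        return "hydrophobic"
    if aa in NEUTRAL:
        return "neutral"
    raise ValueError(f"not a standard amino acid: {aa!r}")


def _junction_bounds(
    record: RearrangementRecord, reference: Reference
) -> tuple[int, int] | None:
    """Resolve junction coordinates from explicit fields or germline anchors.

    Falls back on the amplicon structure: the read starts at the V 5' end
    (so the Cys codon sits at the germline offset) and ends at the J 3' end
    (so the Trp codon end is a fixed distance from the read end, independent
    of the J 5' trim).
    """
    try:
        vseg = reference.get_v(record.v_call)
        jseg = reference.get_j(record.j_call)
    except KeyError:
        return None
    js = record.junction_start
    if js is None:
        js = vseg.cys96_codon_start
    je = record.junction_end
    if je is None:
        if record.junction:
            je = js + len(record.junction)
        else:
            je = len(record.sequence) - (
                len(jseg.nt_sequence) - jseg.fr4_trp_offset - 3
            )
    if not (0 <= js < je <= len(record.sequence)):
        return None
    return js, je


def call_productivity(
    record: RearrangementRecord, reference: Reference
) -> bool | None:
    """Call a rearrangement productive / non-productive / undetermined (None).

    Undetermined means the anchors cannot be resolved (missing calls, bounds
    outside the read, frame-ambiguous start) or ambiguous nucleotides
    preclude an honest stop scan. Anchors that resolve but encode the wrong
    residue make the record non-productive.
    """
    bounds = _junction_bounds(record, reference)
    if bounds is None:
        return None
    js, je = bounds
    if js % 3 != 0:  # read does not start on a V codon boundary
        return None
    seq = record.sequence
    cys_codon = seq[js : js + 3]
    trp_codon = seq[je - 3 : je]
    if "N" in cys_codon or "N" in trp_codon:
        return None
    if translate_nt(cys_codon) != "C" or translate_nt(trp_codon) != "W":
        return False
    if (je - js) % 3 != 0:
        return False
    if "*" in translate_nt(seq):
        return False
    if "N" in seq:
        return None  # N codons treated as non-stop; call stays undetermined
    return True


def extract_cdr3(record: RearrangementRecord, reference: Reference | None = None) -> str:
    """Residues strictly between Cys96 and the FR4 Trp of a productive record.

    The returned string is numbered implicitly: residue ``i`` (0-based) is
    position ``97 + i``. Empty when Cys and Trp are adjacent. Raises on
    non-productive input; callers must filter first.
    """
    if record.productive is not True:
        raise ValueError(
            f"{record.sequence_id or '<record>'}: CDR-H3 defined only for productive rearrangements"
        )
    junction_aa = record.junction_aa
    if not junction_aa and record.junction and len(record.junction) % 3 == 0:
        junction_aa = translate_nt(record.junction)
    if len(junction_aa) < 2:
        raise ValueError(f"{record.sequence_id}: junction too short for CDR-H3")
    return junction_aa[1:-1]


def residue_at(cdr3: str, position: int) -> str | None:
    """Residue at a CDR-H3 position (97-based numbering), None if too short."""
    idx = position - CDR3_FIRST_POSITION
    if idx < 0 or idx >= len(cdr3):
        return None
    return cdr3[idx]


@dataclass
class Cdr3Profile:
    """Per-position amino-acid frequency matrix over CDR-H3 positions.

    ``freq`` rows are positions, columns the 20 standard residues; each row
    sums to 1 over the sequences long enough to contribute at that position
    (``n_per_position``).
    """

    positions: list[int]
    freq: pd.DataFrame
    n_per_position: pd.Series

    def to_tsv(self, path) -> None:
        out = self.freq.copy()
        out.insert(0, "n", self.n_per_position)
        out.to_csv(path, sep="\t", index_label="position")


def position_profile(
    cdr3_set: Sequence[str], positions: Iterable[int] = range(99, 104)
) -> Cdr3Profile:
    """Frequency of amino acids at each requested CDR-H3 position.

    Sequences too short to possess a position simply do not contribute
    there; non-standard letters (e.g. X from ambiguous codons) are excluded
    from that position's denominator.
    """
    cdr3_set = list(cdr3_set)
    if not cdr3_set:
        raise ValueError("empty CDR-H3 set")
    positions = list(positions)
    counts = pd.DataFrame(
        0, index=positions, columns=list(AA_ALPHABET), dtype=float
    )
    for s in cdr3_set:
        for p in positions:
            aa = residue_at(s, p)
            if aa is not None and aa in counts.columns:
                counts.at[p, aa] += 1
    n = counts.sum(axis=1)
    freq = counts.div(n.where(n > 0, other=1), axis=0)
    return Cdr3Profile(positions=positions, freq=freq, n_per_position=n.astype(int))


@dataclass
class GeneY101Summary:
    """Per-gene summary of residue usage at CDR-H3 position 101."""

    gene: str
    subset: str
    n_unique_productive: int
    n_with_101: int
    y101_freq: float
    modal_residue_101: str
    predominance: str  # "Y101" or "non-Y101"
    biochemical_class: str


def _summarize_gene(
    gene: str, subset: str, cdr3s: Sequence[str]
) -> GeneY101Summary | None:
    tallies: dict[str, int] = {}
    for s in cdr3s:
        aa = residue_at(s, 101)
        if aa is not None and aa in AA_ALPHABET:
            tallies[aa] = tallies.get(aa, 0) + 1
    n101 = sum(tallies.values())
    if n101 == 0:
        logger.warning("gene %s (%s): no sequence reaches position 101", gene, subset)
        return None
    top = max(tallies.values())
    tied = sorted(aa for aa, c in tallies.items() if c == top)
    # ties involving Y resolve to Y (conservative toward Y101 predominance),
    # otherwise lexicographically
    modal = "Y" if "Y" in tied else tied[0]
    y_freq = tallies.get("Y", 0) / n101
    return GeneY101Summary(
        gene=gene,
        subset=subset,
        n_unique_productive=len(cdr3s),
        n_with_101=n101,
        y101_freq=y_freq,
        modal_residue_101=modal,
        predominance="Y101" if modal == "Y" else "non-Y101",
        biochemical_class=biochemical_class(modal),
    )


def classify_genes_y101(
    records_by_subset: Mapping[str, Sequence[RearrangementRecord]],
    reference: Reference,
    min_n: int = 50,
) -> tuple[dict[str, list[GeneY101Summary]], pd.DataFrame]:
    """Rank shared V genes by Y101 frequency and flag non-Y101 predominance.

    Inputs are unique productive records (post-dereplication). A gene is
    retained only when its unique-productive count strictly exceeds
    ``min_n`` in every subset. Per subset, summaries are sorted ascending by
    Y101 frequency; duplicate counts are ignored throughout (statistics are
    over unique sequences). Returns the per-subset summaries and a tidy
    shared-gene table.
    """
    per_subset_cdr3: dict[str, dict[str, list[str]]] = {}
    for label, records in records_by_subset.items():
        by_gene: dict[str, list[str]] = {}
        for rec in records:
            if rec.productive is not True:
                continue
            gene = strip_allele(rec.v_call)
            by_gene.setdefault(gene, []).append(extract_cdr3(rec))
        per_subset_cdr3[label] = by_gene

    labels = list(records_by_subset)
    shared = sorted(
        g
        for g in set().union(*(set(d) for d in per_subset_cdr3.values()))
        if all(len(per_subset_cdr3[l].get(g, [])) > min_n for l in labels)
    )
    if not shared:
        logger.warning(
            "no gene exceeds %d unique productive sequences in all subsets", min_n
        )
        return {l: [] for l in labels}, pd.DataFrame(
            columns=[
                "gene",
                "subset",
                "n_unique_productive",
                "n_with_101",
                "y101_freq",
                "modal_residue_101",
                "predominance",
                "biochemical_class",
            ]
        )

    summaries: dict[str, list[GeneY101Summary]] = {}
    rows = []
    for label in labels:
        subset_summaries = []
        for gene in shared:
            summ = _summarize_gene(gene, label, per_subset_cdr3[label][gene])
            if summ is not None:
                subset_summaries.append(summ)
        subset_summaries.sort(key=lambda s: (s.y101_freq, s.gene))
        summaries[label] = subset_summaries
        rows.extend(dataclasses_to_row(s) for s in subset_summaries)
    table = pd.DataFrame(rows)
    return summaries, table


def dataclasses_to_row(summary: GeneY101Summary) -> dict:
    return {
        "gene": summary.gene,
        "subset": summary.subset,
        "n_unique_productive": summary.n_unique_productive,
        "n_with_101": summary.n_with_101,
        "y101_freq": summary.y101_freq,
        "modal_residue_101": summary.modal_residue_101,
        "predominance": summary.predominance,
        "biochemical_class": summary.biochemical_class,
    }
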
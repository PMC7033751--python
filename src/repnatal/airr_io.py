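"""Rearrangement-table I/O, dereplication and a naive closed-loop annotator.

The on-disk format is an AIRR-style rearrangement TSV with the columns
``sequence_id, sequence, v_call, d_call, j_call, junction, junction_aa,
productive, duplicate_count, subset_label``. Only the first four are
mandatory on read; everything else degrades to "undetermined" rather than
crashing. A small dialect map translates IMGT HighV-QUEST summary headers
onto the AIRR names so IMGT summary exports can be ingested directly.

The naive annotator is a deliberately simple ungapped matcher used to close
the loop on simulated data without an external annotation server; it is not
a general-purpose aligner.
"""

from __future__ import annotations

import dataclasses
import logging
from collections import OrderedDict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .reference import Reference, strip_allele, translate_nt

logger = logging.getLogger(__name__)

__all__ = [
    "RearrangementRecord",
    "read_airr",
    "write_airr",
    "read_fasta",
    "filter_fastq",
    "dereplicate",
    "naive_annotate",
    "annotate_records",
]

MANDATORY_COLUMNS = ["sequence_id", "sequence", "v_call", "j_call"]
COLUMNS = [
    "sequence_id",
    "sequence",
    "v_call",
    "d_call",
    "j_call",
    "junction",
    "junction_aa",
    "productive",
    "duplicate_count",
    "subset_label",
]

# IMGT HighV-QUEST summary-table dialect -> AIRR names.
IMGT_COLUMN_MAP = {
    "Sequence ID": "sequence_id",
    "Sequence": "sequence",
    "V-GENE and allele": "v_call",
    "D-GENE and allele": "d_call",
    "J-GENE and allele": "j_call",
    "JUNCTION": "junction",
    "AA JUNCTION": "junction_aa",
    "Functionality": "productive",
}

D_LESS = "D-less"


@dataclass
class RearrangementRecord:
    """One read (or dereplicated clone) of a V(D)J rearrangement.

    ``productive`` is True/False when called, None when undetermined.
    ``junction_start``/``junction_end`` are optional 0-based half-open
    coordinates of the junction (FR3 Cys codon start to FR4 Trp codon end)
    within ``sequence``; they are populated by the simulator and the naive
    annotator and are not serialized.
    """

    sequence_id: str
    sequence: str
    v_call: str = ""
    d_call: str = ""
    j_call: str = ""
    junction: str = ""
    junction_aa: str = ""
    productive: bool | None = None
    duplicate_count: int = 1
    subset_label: str = ""
    junction_start: int | None = None
    junction_end: int | None = None


def _parse_productive(value: str) -> bool | None:
    v = value.strip().lower()
    if v in {"t", "true", "productive", "yes", "1"}:
        return True
    if v in {"f", "false", "unproductive", "non-productive", "no", "0"}:
        return False
    return None


def read_airr(path: str | Path) -> list[RearrangementRecord]:
    """Read a rearrangement TSV (AIRR or IMGT-summary dialect) into records.

    Gene calls are allele-stripped; a missing ``junction_aa`` is filled by
    translation whenever the junction length is a multiple of 3. Raises on
    missing mandatory columns, naming the columns actually found.
    """
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    imgt = {c: IMGT_COLUMN_MAP[c] for c in frame.columns if c in IMGT_COLUMN_MAP}
    if imgt:
        frame = frame.rename(columns=imgt)
    unknown = [c for c in frame.columns if c not in COLUMNS]
    if unknown:
        logger.warning("ignoring unknown columns: %s", unknown)
    missing = [c for c in MANDATORY_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(
            f"missing mandatory column(s) {missing}; columns found: {list(frame.columns)}"
        )
    records = []
    for row in frame.itertuples(index=False):
        get = lambda col: getattr(row, col, "")  # noqa: E731
        junction = get("junction").upper()
        junction_aa = get("junction_aa")
        if junction and not junction_aa and len(junction) % 3 == 0:
            junction_aa = translate_nt(junction)
        dup = get("duplicate_count")
        d_call = get("d_call")
        records.append(
            RearrangementRecord(
                sequence_id=row.sequence_id,
                sequence=row.sequence.upper(),
                v_call=strip_allele(row.v_call),
                d_call=d_call if d_call == D_LESS else strip_allele(d_call),
                j_call=strip_allele(row.j_call),
                junction=junction,
                junction_aa=junction_aa,
                productive=_parse_productive(get("productive")),
                duplicate_count=int(dup) if dup else 1,
                subset_label=get("subset_label"),
            )
        )
    return records


def write_airr(records: Iterable[RearrangementRecord], path: str | Path) -> None:
    records = list(records)
    frame = pd.DataFrame(
        {
            "sequence_id": [r.sequence_id for r in records],
            "sequence": [r.sequence for r in records],
            "v_call": [r.v_call for r in records],
            "d_call": [r.d_call for r in records],
            "j_call": [r.j_call for r in records],
            "junction": [r.junction for r in records],
            "junction_aa": [r.junction_aa for r in records],
            "productive": [
                "" if r.productive is None else ("T" if r.productive else "F")
                for r in records
            ],
            "duplicate_count": [r.duplicate_count for r in records],
            "subset_label": [r.subset_label for r in records],
        },
        columns=COLUMNS,
    )
    frame.to_csv(path, sep="\t", index=False)


def read_fasta(path: str | Path) -> list[RearrangementRecord]:
    """Read raw amplicons; only sequence_id and sequence are populated."""
    return [
        RearrangementRecord(sequence_id=rec.id, sequence=str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def filter_fastq(path: str | Path, min_mean_q: float = 30.0) -> list[RearrangementRecord]:
    """Quality pre-filter hook: keep reads with mean Phred >= ``min_mean_q``.

    Ingests already-assembled single reads; paired-end merging is out of scope.
    """
    kept = []
    for rec in SeqIO.parse(str(path), "fastq"):
        quals = rec.letter_annotations["phred_quality"]
        if quals and float(np.mean(quals)) >= min_mean_q:
            kept.append(
                RearrangementRecord(sequence_id=rec.id, sequence=str(rec.seq).upper())
            )
    return kept


def dereplicate(records: Sequence[RearrangementRecord]) -> list[RearrangementRecord]:
    """Collapse reads by exact full-length nucleotide identity.

    One representative per identity class (annotations of the first member
    are kept) with ``duplicate_count`` equal to the summed input counts.
    Output order: descending duplicate_count, ties broken by sequence.
    """
    classes: "OrderedDict[str, RearrangementRecord]" = OrderedDict()
    for rec in records:
        if rec.sequence in classes:
            classes[rec.sequence].duplicate_count += rec.duplicate_count
        else:
            classes[rec.sequence] = dataclasses.replace(rec)
    out = list(classes.values())
    out.sort(key=lambda r: (-r.duplicate_count, r.sequence))
    return out


class Annotation(NamedTuple):
    v_call: str | None
    j_call: str | None
    junction_start: int | None
    junction_end: int | None


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def _best_match(
    read: np.ndarray,
    refs: dict[str, np.ndarray],
    *,
    suffix: bool,
    max_shift: int,
    min_identity: float,
    min_len: int,
) -> tuple[str | None, int]:
    """Best ungapped match of germline prefixes (or suffixes) to the read.

    Returns (gene, matches); genes are scanned in sorted order and only a
    strictly better match replaces the incumbent, so ties resolve to the
    lexicographically first gene. ``suffix=True`` aligns reference ends to
    the read end (offset = nt clipped from the reference 5' side).
    """
    best_gene, best_matches = None, -1
    for gene in sorted(refs):
        ref = refs[gene]
        for shift in range(-max_shift, max_shift + 1):
            if suffix:
                # reference[shift:] against the read tail, ends aligned
                if shift < 0 or shift >= len(ref):
                    continue
                ov = min(len(read), len(ref) - shift)
                if ov < min_len:
                    continue
                a = read[len(read) - ov :]
                b = ref[len(ref) - ov :]
            else:
                # reference index r sits at read index r + shift
                start_r = max(0, -shift)
                end_r = min(len(ref), len(read) - shift)
                ov = end_r - start_r
                if ov < min_len:
                    continue
                a = read[start_r + shift : end_r + shift]
                b = ref[start_r:end_r]
            matches = int((a == b).sum())
            if matches / ov >= min_identity and matches > best_matches:
                best_gene, best_matches = gene, matches
    return best_gene, best_matches


def naive_annotate(
    sequence: str,
    reference: Reference,
    *,
    max_shift: int = 15,
    min_identity: float = 0.8,
    min_len: int = 30,
) -> Annotation:
    """Call V and J genes by best ungapped identity; derive junction bounds.

    Assumes the read spans the V 5' end through the J 3' end (the amplicon
    structure the simulator emits). The junction runs from the V gene's FR3
    Cys codon start through the FR4 Trp codon end; the latter is located
    from the read end and the germline J length, which is independent of
    the (unknown) J 5' trim. Calls are undetermined when no germline
    reaches ``min_identity`` over at least ``min_len`` nt.
    """
    read = _encode(sequence)
    v_refs = {g: _encode(reference.get_v(g).nt_sequence) for g in reference.v_genes}
    j_refs = {g: _encode(reference.get_j(g).nt_sequence) for g in reference.j_genes}
    v_gene, _ = _best_match(
        read, v_refs, suffix=False, max_shift=max_shift,
        min_identity=min_identity, min_len=min_len,
    )
    j_gene, _ = _best_match(
        read, j_refs, suffix=True, max_shift=max_shift,
        min_identity=min_identity, min_len=min_len,
    )
    if v_gene is None or j_gene is None:
        return Annotation(None, None, None, None)
    vseg = reference.get_v(v_gene)
    jseg = reference.get_j(j_gene)
    js = vseg.cys96_codon_start
    je = len(sequence) - (len(jseg.nt_sequence) - jseg.fr4_trp_offset - 3)
    if not (0 <= js < je <= len(sequence)):
        return Annotation(None, None, None, None)
    return Annotation(v_gene, j_gene, js, je)


def annotate_records(
    records: Sequence[RearrangementRecord], reference: Reference
) -> list[RearrangementRecord]:
    """Annotate raw records in place of an external server; returns new records."""
    from .cdr3 import call_productivity  # deferred: cdr3 imports this module's types

    out = []
    for rec in records:
        ann = naive_annotate(rec.sequence, reference)
        new = dataclasses.replace(rec)
        if ann.v_call is None:
            new.productive = None
            out.append(new)
            continue
        new.v_call, new.j_call = ann.v_call, ann.j_call
        new.junction_start, new.junction_end = ann.junction_start, ann.junction_end
        new.junction = rec.sequence[ann.junction_start : ann.junction_end]
        new.junction_aa = (
            translate_nt(new.junction) if len(new.junction) % 3 == 0 else ""
        )
        new.productive = call_productivity(new, reference)
        out.append(new)
    return out
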
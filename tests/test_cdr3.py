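import dataclasses
import random

import pytest

from conftest import make_join
from repnatal.airr_io import RearrangementRecord
from repnatal.cdr3 import (
    AA_ALPHABET,
    CHARGED,
    HYDROPHOBIC,
    NEUTRAL,
    biochemical_class,
    call_productivity,
    classify_genes_y101,
    extract_cdr3,
    position_profile,
    residue_at,
)
from repnatal.simulate import SimulatorConfig, simulate_repertoire


def test_zero_trim_toy_join_is_productive(reference):
    rec = make_join(reference, "Ighv5-2", "Ighd1-1", "Ighj1")
    assert call_productivity(rec, reference) is True


def test_single_inserted_nt_shifts_frame(reference):
    rec = make_join(reference, "Ighv5-2", "Ighd1-1", "Ighj1", n1="G")
    assert call_productivity(rec, reference) is False


def test_ambiguous_nt_in_junction_is_undetermined(reference):
    rec = make_join(reference, "Ighv5-2", "Ighd1-1", "Ighj1", n1="NNN")
    assert call_productivity(rec, reference) is None


def test_unresolvable_calls_are_undetermined(reference):
    rec = RearrangementRecord("x", "ACGT" * 30, v_call="Ighv99-9", j_call="Ighj1")
    assert call_productivity(rec, reference) is None


def test_productivity_trichotomy(reference):
    records = [
        make_join(reference, "Ighv5-2", "Ighd1-1", "Ighj1"),
        make_join(reference, "Ighv5-2", "Ighd1-1", "Ighj1", n1="G"),
        make_join(reference, "Ighv5-2", "Ighd1-1", "Ighj1", n2="NNN"),
        make_join(reference, "Ighv2-3", "Ighd2-3", "Ighj2"),
    ]
    calls = [call_productivity(r, reference) for r in records]
    n_prod = sum(c is True for c in calls)
    n_nonprod = sum(c is False for c in calls)
    n_undet = sum(c is None for c in calls)
    assert n_prod + n_nonprod + n_undet == len(records)
    assert n_prod >= 1 and n_nonprod >= 1 and n_undet >= 1


def _aa_record(junction_aa, gene="Ighv1-26", productive=True):
    return RearrangementRecord(
        sequence_id=junction_aa,
        sequence="",
        v_call=gene,
        j_call="Ighj1",
        junction_aa=junction_aa,
        productive=productive,
    )


@pytest.mark.parametrize(
    "junction_aa,cdr3,res101",
    [
        ("CASGYW", "ASGY", None),  # only positions 97-100 exist
        ("CARDYYGSSYW", "ARDYYGSSY", "Y"),  # 101 is the 5th CDR-H3 residue
        ("CW", "", None),  # Cys and Trp adjacent
    ],
)
def test_extract_cdr3_numbering(junction_aa, cdr3, res101):
    record = _aa_record(junction_aa)
    extracted = extract_cdr3(record)
    assert extracted == cdr3
    assert residue_at(extracted, 101) == res101


def test_extract_cdr3_requires_productive():
    with pytest.raises(ValueError, match="productive"):
        extract_cdr3(_aa_record("CARDYW", productive=False))


def test_position_profile_degenerate_and_split():
    profile = position_profile(["ARDYY"] * 10)
    assert profile.freq.at[101, "Y"] == 1.0
    assert profile.n_per_position[101] == 10

    # position 101 is the 5th CDR-H3 residue: Y in one sequence, G in the other
    profile = position_profile(["ARDYY", "ARDGG"])
    assert profile.freq.at[101, "Y"] == 0.5
    assert profile.freq.at[101, "G"] == 0.5


def test_position_profile_rows_sum_to_one_and_match_tally(reference):
    cfg = SimulatorConfig(
        seed=21, n_clones=500, clone_size={"distribution": "constant", "size": 1},
        tdt_on=True, n_insert_mean=2.0,
    )
    records, _ = simulate_repertoire(cfg, reference)
    cdr3s = [extract_cdr3(r) for r in records if r.productive is True]
    assert len(cdr3s) > 100
    profile = position_profile(cdr3s)
    # brute-force per-position tally oracle
    for pos in profile.positions:
        tally = {}
        for s in cdr3s:
            idx = pos - 97
            if idx < len(s) and s[idx] in AA_ALPHABET:
                tally[s[idx]] = tally.get(s[idx], 0) + 1
        n = sum(tally.values())
        assert profile.n_per_position[pos] == n
        assert abs(profile.freq.loc[pos].sum() - 1.0) < 1e-9
        for aa, count in tally.items():
            assert profile.freq.at[pos, aa] == pytest.approx(count / n)


def test_position_profile_rejects_empty():
    with pytest.raises(ValueError, match="empty"):
        position_profile([])


def test_biochemical_partition():
    assert biochemical_class("R") == "charged"
    assert biochemical_class("V") == "hydrophobic"
    assert biochemical_class("Y") == "neutral"
    assert CHARGED | HYDROPHOBIC | NEUTRAL == set(AA_ALPHABET)
    assert not (CHARGED & HYDROPHOBIC or CHARGED & NEUTRAL or HYDROPHOBIC & NEUTRAL)
    with pytest.raises(ValueError):
        biochemical_class("B")


def _records_with_101(gene, residues):
    """One unique productive record per residue, with that residue at 101."""
    return [
        _aa_record("C" + "ARDG"[:4] + aa + f"W", gene=gene)
        for aa in residues
    ]


def test_classify_majority_y101(reference):
    residues = ["Y"] * 60 + ["G"] * 40
    recs = _records_with_101("Ighv1-26", residues)
    groups = {"a": recs, "b": recs}
    summaries, table = classify_genes_y101(groups, reference, min_n=50)
    summ = summaries["a"][0]
    assert summ.n_unique_productive == 100
    assert summ.y101_freq == pytest.approx(0.60)
    assert summ.predominance == "Y101"
    assert set(table["subset"]) == {"a", "b"}


def test_classify_modal_non_y101_and_class(reference):
    residues = ["G"] * 30 + ["Y"] * 25 + ["R"] * 5
    recs = _records_with_101("Ighv11-2", residues)
    summaries, _ = classify_genes_y101({"a": recs, "b": recs}, reference, min_n=50)
    summ = summaries["a"][0]
    assert summ.modal_residue_101 == "G"
    assert summ.predominance == "non-Y101"
    assert summ.biochemical_class == "neutral"
    assert summ.y101_freq == pytest.approx(25 / 60)


def test_classify_tie_involving_y_resolves_to_y(reference):
    residues = ["Y"] * 30 + ["A"] * 30
    recs = _records_with_101("Ighv5-2", residues)
    summaries, _ = classify_genes_y101({"a": recs, "b": recs}, reference, min_n=50)
    assert summaries["a"][0].predominance == "Y101"


def test_classify_strict_min_n_filter(reference):
    exactly_50 = _records_with_101("Ighv2-3", ["Y"] * 50)
    over_50 = _records_with_101("Ighv7-1", ["Y"] * 51)
    groups = {"a": exactly_50 + over_50, "b": exactly_50 + over_50}
    summaries, table = classify_genes_y101(groups, reference, min_n=50)
    assert set(table["gene"]) == {"Ighv7-1"}  # legend's ">50" is strict


def test_classify_gene_must_pass_in_both_subsets(reference):
    many = _records_with_101("Ighv1-55", ["Y"] * 80)
    few = _records_with_101("Ighv1-55", ["Y"] * 10)
    _, table = classify_genes_y101({"a": many, "b": few}, reference, min_n=50)
    assert len(table) == 0  # warning, not an error


def test_classify_invariant_to_order_and_duplicates(reference):
    residues = ["Y"] * 40 + ["G"] * 30
    recs = _records_with_101("Ighv12-3", residues)
    shuffled = recs.copy()
    random.Random(4).shuffle(shuffled)
    heavy = [dataclasses.replace(r, duplicate_count=9) for r in recs]
    base = classify_genes_y101({"a": recs, "b": recs}, reference, min_n=50)[1]
    perm = classify_genes_y101({"a": shuffled, "b": shuffled}, reference, min_n=50)[1]
    dup = classify_genes_y101({"a": heavy, "b": heavy}, reference, min_n=50)[1]
    assert base.equals(perm)
    assert base.equals(dup)
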
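import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_join
from repnatal.airr_io import RearrangementRecord
from repnatal.cdr3 import call_productivity
from repnatal.diversity import (
    default_depths,
    j_trimming_stats,
    rarefy_shannon,
    shannon_index,
    usage_and_productivity,
)
from repnatal.simulate import SimulatorConfig, simulate_repertoire


def _unique_records(reference, n=10, n_productive=3):
    records = []
    for i in range(n):
        rec = make_join(reference, "Ighv5-2", "Ighd1-1", "Ighj1")
        rec.sequence_id = f"u{i}"
        rec.sequence = rec.sequence + "A" * i  # make sequences distinct
        rec.productive = i < n_productive
        records.append(rec)
    return records


def test_overall_productivity_quotient(reference):
    table = usage_and_productivity(_unique_records(reference), reference, "family")
    assert table.overall_quotient == pytest.approx(0.30)
    assert table.table["usage_freq"].sum() == pytest.approx(1.0)
    assert ((table.table["productivity_quotient"].dropna() >= 0)
            & (table.table["productivity_quotient"].dropna() <= 1)).all()


def test_all_dless_degenerate_usage(reference):
    records = _unique_records(reference)
    for rec in records:
        rec.d_call = "D-less"
    table = usage_and_productivity(records, reference, "d_gene")
    assert list(table.table["name"]) == ["D-less"]
    assert table.table["usage_freq"].iloc[0] == pytest.approx(1.0)


def test_usage_levels_all_sum_to_one(reference):
    cfg = SimulatorConfig(seed=8, n_clones=300,
                          clone_size={"distribution": "constant", "size": 1})
    records, _ = simulate_repertoire(cfg, reference)
    for level in ("family", "gene", "d_gene", "j_gene", "domain"):
        table = usage_and_productivity(records, reference, level)
        assert table.table["usage_freq"].sum() == pytest.approx(1.0)


def test_undetermined_excluded_from_quotient(reference):
    records = _unique_records(reference, n=10, n_productive=3)
    records[-1].productive = None
    table = usage_and_productivity(records, reference, "family")
    assert table.overall_quotient == pytest.approx(3 / 9)
    assert table.table["n_undetermined"].sum() == 1


def test_usage_rejects_empty(reference):
    with pytest.raises(ValueError):
        usage_and_productivity([], reference, "family")


def test_j_trim_recovered_from_suffix(reference):
    # Ighd4-1 ends in G while Ighj1[2] is C, so a 3-nt J trim cannot be
    # mistaken for a shorter one by coincidental suffix extension
    records = [
        make_join(reference, "Ighv5-2", "Ighd4-1", "Ighj1", t_j5=3)
        for _ in range(4)
    ]
    per_record, summary = j_trimming_stats(records, reference)
    assert (per_record["j_trim"] == 3).all()
    assert summary["mean_trim"] == pytest.approx(3.0)


def test_zero_trim_cdr3_length_is_germline_encoded(reference):
    rec = make_join(reference, "Ighv5-2", "Ighd1-1", "Ighj1")
    rec.junction = rec.sequence[
        reference.get_v("Ighv5-2").cys96_codon_start :
        len(rec.sequence) - (len(reference.get_j("Ighj1").nt_sequence)
                             - reference.get_j("Ighj1").fr4_trp_offset - 3)
    ]
    from repnatal.reference import translate_nt

    rec.junction_aa = translate_nt(rec.junction)
    rec.productive = call_productivity(rec, reference)
    _, summary = j_trimming_stats([rec], reference)
    # 1 aa V tail + 18/3 aa from D + 12/3 aa from the J prefix
    assert summary["mean_cdr3_length"] == pytest.approx(11.0)


def test_shannon_closed_forms():
    assert shannon_index([17]) == 0.0
    assert shannon_index([3] * 8) == pytest.approx(math.log(8), abs=1e-12)
    # independent direct evaluation of -sum p ln p
    counts = (5, 3, 2)
    total = sum(counts)
    expected = -sum((c / total) * math.log(c / total) for c in counts)
    assert shannon_index(counts) == pytest.approx(expected, abs=1e-12)
    assert shannon_index([4, 4], base=2) == pytest.approx(1.0)


def test_shannon_input_validation():
    with pytest.raises(ValueError):
        shannon_index([])
    with pytest.raises(ValueError):
        shannon_index([3, 0])


@settings(max_examples=80, derandomize=True, deadline=None)
@given(st.lists(st.integers(min_value=1, max_value=50), min_size=1, max_size=20))
def test_shannon_bounds_and_permutation_invariance(counts):
    h = shannon_index(counts)
    assert 0.0 <= h <= math.log(len(counts)) + 1e-12
    assert shannon_index(sorted(counts, reverse=True)) == pytest.approx(h)


def _replicated_records(reference, n_clones, size, seed=13):
    cfg = SimulatorConfig(
        seed=seed,
        n_clones=n_clones,
        clone_size={"distribution": "constant", "size": size},
        tdt_on=True,
        n_insert_mean=2.0,
    )
    records, _ = simulate_repertoire(cfg, reference)
    return records


def test_rarefaction_boundaries(reference):
    records = _replicated_records(reference, 60, 3)
    total = sum(r.duplicate_count for r in records)
    curve = rarefy_shannon(records, [1, total], n_replicates=25, seed=0)
    from repnatal.diversity import cdr3_species

    species = cdr3_species(records)
    plug_in = shannon_index(
        list(np.unique(np.repeat(species, [r.duplicate_count for r in records]),
                       return_counts=True)[1])
    )
    assert curve.mean_H[0] == 0.0  # a single read has one species
    assert curve.mean_H[-1] == pytest.approx(plug_in, abs=1e-12)
    assert curve.sd_H[-1] == 0.0

    with pytest.raises(ValueError, match="depth"):
        rarefy_shannon(records, [total + 1], n_replicates=5, seed=0)


def test_rarefaction_deterministic_and_monotone(reference):
    records = _replicated_records(reference, 150, 4)
    total = sum(r.duplicate_count for r in records)
    depths = default_depths(total)
    a = rarefy_shannon(records, depths, n_replicates=200, seed=3)
    b = rarefy_shannon(records, depths, n_replicates=200, seed=3)
    assert a == b
    for i in range(len(depths) - 1):
        se = math.hypot(a.sd_H[i], a.sd_H[i + 1]) / math.sqrt(a.n_replicates)
        assert a.mean_H[i + 1] >= a.mean_H[i] - 2 * se


def test_more_clones_give_higher_rarefaction_curve(reference):
    small = _replicated_records(reference, 100, 4, seed=19)
    large = _replicated_records(reference, 1000, 4, seed=23)
    depths = [50, 100, 200, 400]
    c_small = rarefy_shannon(small, depths, n_replicates=200, seed=1)
    c_large = rarefy_shannon(large, depths, n_replicates=200, seed=1)
    for hs, hl in zip(c_small.mean_H, c_large.mean_H):
        assert hl > hs
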
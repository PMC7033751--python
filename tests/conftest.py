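import pytest

from repnatal.airr_io import RearrangementRecord
from repnatal.reference import Reference, build_toy_reference


@pytest.fixture(scope="session")
def toy():
    """Toy germline segments + domain map (seed 1)."""
    return build_toy_reference(1)


@pytest.fixture(scope="session")
def reference(toy):
    return Reference(toy[0])


def make_join(reference, v, d, j, n1="", n2="", t_v3=0, t_d5=0, t_d3=0, t_j5=0):
    """Assemble a record for a given join the same way an annotator would see it.

    Junction coordinates are left implicit so productivity calling resolves
    them from the germline anchors.
    """
    v_nt = reference.get_v(v).nt_sequence
    j_nt = reference.get_j(j).nt_sequence
    if d == "D-less":
        d_part = ""
    else:
        d_nt = reference.get_d(d).nt_sequence
        d_part = d_nt[t_d5 : len(d_nt) - t_d3]
    seq = v_nt[: len(v_nt) - t_v3] + n1 + d_part + n2 + j_nt[t_j5:]
    return RearrangementRecord(
        sequence_id=f"{v}|{d}|{j}", sequence=seq, v_call=v, d_call=d, j_call=j
    )
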
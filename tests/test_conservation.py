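import itertools

import pytest

from domainevol.conservation import (
    ConservationError,
    DomainPartition,
    domain_summary,
    group_vs_modal,
    heatmap_table,
    modal_sequence,
    site_conservation,
)
from domainevol.seqio import Alignment, SequenceRecord


def aln_from(rows, ids=None):
    ids = ids or [f"s{i}" for i in range(len(rows))]
    return Alignment([SequenceRecord(i, r) for i, r in zip(ids, rows)])


def test_site_conservation_percentages():
    aln = aln_from(["AAA", "AAA", "AAV", "VAV"])
    prof = site_conservation(aln, reference="s0")
    assert prof.percent == [75.0, 100.0, 50.0]
    assert prof.modal == ["A", "A", "A"]  # col3 tie A/V -> alphabetical


def test_tie_break_is_order_invariant():
    rows = ["AV", "AV", "VA", "VA"]
    for perm in itertools.permutations(range(4)):
        aln = aln_from([rows[i] for i in perm])
        prof = site_conservation(aln, reference=aln.ids[0])
        assert prof.percent == [50.0, 50.0]
        assert prof.modal == ["A", "A"]


def test_domain_summary_means():
    aln = aln_from(["AAB", "AVB", "ZVB", "ZVB"])
    # col conservation: 50, 75, 100
    prof = site_conservation(aln, reference="s0")
    part = DomainPartition("s0", {"pro": (1, 2), "mature": (3, 3)})
    summary = domain_summary(prof, part).set_index("domain")
    assert summary.loc["pro", "mean_conservation_pct"] == pytest.approx(62.5)
    assert summary.loc["mature", "mean_conservation_pct"] == pytest.approx(100.0)
    assert summary.loc["pro", "n_columns"] == 2


def test_single_domain_equals_global_mean():
    aln = aln_from(["AAB", "AVB", "ZVB", "ZVB"])
    prof = site_conservation(aln, reference="s0")
    part = DomainPartition("s0", {"pro": (1, 3)})
    mean = domain_summary(prof, part)["mean_conservation_pct"].iloc[0]
    assert mean == pytest.approx(sum(prof.percent) / 3)


def test_interval_outside_alignment_errors():
    aln = aln_from(["AA", "AA"])
    prof = site_conservation(aln, reference="s0")
    part = DomainPartition("s0", {"pro": (1, 5)})
    with pytest.raises(ConservationError):
        domain_summary(prof, part)


def test_partition_validation():
    with pytest.raises(ConservationError, match="overlap"):
        DomainPartition("r", {"pro": (1, 10), "mature": (5, 20)})
    with pytest.raises(ConservationError, match="inside pro"):
        DomainPartition("r", {"pro": (1, 10), "mature": (11, 20), "NLS": (8, 12)})
    DomainPartition("r", {"pro": (1, 112), "mature": (113, 271),
                          "HCPR": (1, 40), "NLS": (70, 85)})


def test_modal_sequence_examples():
    aln = aln_from(["AK", "AR", "VR"])
    assert modal_sequence(aln, aln.ids) == "AR"
    sub = aln_from(["AK", "AK"])
    assert modal_sequence(sub, sub.ids) == "AK"  # identical subset -> itself
    gappy = aln_from(["-A", "-A", "-A"])
    assert modal_sequence(gappy, gappy.ids) == "-A"


def test_group_vs_modal_identity_and_exclusion():
    ref_rows = ["AAAAAAAAAA", "AAAAAAAAAA", "AAAAAAAAAA"]
    part = DomainPartition("r0", {"pro": (1, 10)})
    # focal identical -> 100
    aln = aln_from(ref_rows + ["AAAAAAAAAA"], ids=["r0", "r1", "r2", "f"])
    t = group_vs_modal(aln, ["f"], ["r0", "r1", "r2"], part)
    assert t["identity_pct"].iloc[0] == 100.0
    # one mismatch of ten -> 90
    aln = aln_from(ref_rows + ["AAAAAAAAAV"], ids=["r0", "r1", "r2", "f"])
    t = group_vs_modal(aln, ["f"], ["r0", "r1", "r2"], part)
    assert t["identity_pct"].iloc[0] == 90.0
    # two gap columns excluded from numerator and denominator -> 100 over 8
    aln = aln_from(ref_rows + ["--AAAAAAAA"], ids=["r0", "r1", "r2", "f"])
    t = group_vs_modal(aln, ["f"], ["r0", "r1", "r2"], part)
    assert t["identity_pct"].iloc[0] == 100.0
    assert t["n_columns"].iloc[0] == 8


def test_group_vs_modal_requires_disjoint_sets():
    aln = aln_from(["AA", "AA"])
    part = DomainPartition("s0", {"pro": (1, 2)})
    with pytest.raises(ConservationError, match="disjoint"):
        group_vs_modal(aln, ["s0"], ["s0", "s1"], part)


def test_heatmap_table_passthrough():
    aln = aln_from(["AAA", "AAA", "AAV", "VAV"])
    prof = site_conservation(aln, reference="s0")
    part = DomainPartition("s0", {"pro": (1, 2), "mature": (3, 3)})
    table = heatmap_table(prof, part)
    assert list(table["conservation_pct"]) == prof.percent
    assert list(table["domain"]) == ["pro", "pro", "mature"]
    assert (table["scale_min"] == 25.0).all() and (table["scale_max"] == 100.0).all()


def test_mean_invariant_to_reorder_and_duplication():
    rows = ["AAB", "AVB", "ZVB"]
    base = site_conservation(aln_from(rows), reference="s0")
    shuffled = site_conservation(
        aln_from(rows[::-1], ids=["s2", "s1", "s0"]), reference="s0"
    )
    assert sum(base.percent) == pytest.approx(sum(shuffled.percent))
    doubled = site_conservation(
        aln_from(rows + rows, ids=["a", "b", "c", "d", "e", "f"]), reference="a"
    )
    assert doubled.percent == base.percent


def test_duplicating_a_sequence_never_decreases_conservation():
    rows = ["AAB", "AVB", "ZVB"]
    base = site_conservation(aln_from(rows), reference="s0")
    for dup in rows:
        extended = site_conservation(
            aln_from(rows + [dup], ids=["a", "b", "c", "d"]), reference="a"
        )
        # the duplicated row matches the mode at its own residues; global
        # mean over columns where it matched the mode cannot drop
        for old, new, ch, modal in zip(
            base.percent, extended.percent, dup, base.modal
        ):
            if ch == modal:
                assert new >= old


def test_reference_gap_columns_have_no_domain():
    aln = aln_from(["A-B", "AVB", "AVB"])
    prof = site_conservation(aln, reference="s0")
    assert prof.ref_coords == [1, None, 2]
    part = DomainPartition("s0", {"pro": (1, 2)})
    table = heatmap_table(prof, part)
    assert table["domain"].iloc[1] is None
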
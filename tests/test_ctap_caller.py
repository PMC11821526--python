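"""PSM annotation, site calling, category cross-tabs, noise control."""

import math
import random

import pytest

from ctapkit.ctap_caller import (
    AnnotatedPsm,
    annotate_psms,
    call_sites,
    category_stats,
    overlap_sites,
    shift_noise_control,
)
from ctapkit.digest import EnzymaticStatus, TerminusClass
from ctapkit.masses import AMIDATION_DELTA_DA, ShiftLadder
from ctapkit.sequence_io import ProteinRecord, PsmRow


@pytest.fixture
def db():
    return [ProteinRecord("P1", "toy", "MKARPGEK"), ProteinRecord("P2", "toy", "AAAEDGWAAK")]


def psm(peptide, start, end, delta=0.0, protein="P1", prob=0.99, sample="s1"):
    return PsmRow(
        sample_id=sample,
        peptide=peptide,
        protein_id=protein,
        start=start,
        end=end,
        cterm_delta_da=delta,
        probability=prob,
    )


def test_annotate_semi_tryptic_amidated(db):
    out = annotate_psms([psm("ARPGE", 3, 7, delta=-0.9840)], db)
    assert len(out) == 1
    a = out[0]
    assert a.c_class is TerminusClass.NEO and a.status is EnzymaticStatus.SEMI
    assert a.amidated and a.shift_bin == -1


def test_annotate_full_unmodified(db):
    (a,) = annotate_psms([psm("MK", 1, 2)], db)
    assert a.status is EnzymaticStatus.FULL and not a.amidated and a.shift_bin is None


def test_annotate_drops_invalid_rows_with_reasons(db):
    dropped = []
    out = annotate_psms(
        [
            psm("ARPGX", 3, 7),  # sequence mismatch
            psm("MK", 1, 2, protein="NOPE"),  # unknown protein
            psm("MK", 1, 2, prob=0.2),  # below threshold
            psm("MK", 1, 2),
        ],
        db,
        dropped=dropped,
    )
    assert len(out) == 1
    reasons = [r for _, r in dropped]
    assert reasons == ["sequence mismatch", "unknown protein 'NOPE'", "below probability threshold"]
    with pytest.raises(ValueError, match="sequence mismatch"):
        annotate_psms([psm("ARPGX", 3, 7)], db, strict=True)


def test_call_sites_groups_by_position(db):
    rows = [psm("ARPGE", 3, 7, delta=AMIDATION_DELTA_DA, sample=f"s{i}") for i in range(3)]
    rows += [psm("AAAEDGW", 1, 7, delta=AMIDATION_DELTA_DA, protein="P2")]
    sites = call_sites(annotate_psms(rows, db))
    assert [(s.protein_id, s.position, s.n_psms) for s in sites] == [("P1", 7, 3), ("P2", 7, 1)]
    assert sites[0].residue == "E"
    assert sites[0].samples == frozenset({"s0", "s1", "s2"})


def test_amidated_enzymatic_terminus_yields_no_site(db):
    # MK ends on a tryptic bond: amidation there cannot support a site
    sites = call_sites(annotate_psms([psm("MK", 1, 2, delta=AMIDATION_DELTA_DA)], db))
    assert sites == []
    assert call_sites([]) == []


def test_site_calling_deterministic_under_row_shuffling(db):
    rows = [
        psm("ARPGE", 3, 7, delta=AMIDATION_DELTA_DA, sample=f"s{i % 3}") for i in range(6)
    ] + [psm("AAAEDGW", 1, 7, delta=AMIDATION_DELTA_DA, protein="P2"), psm("MK", 1, 2)]
    reference = call_sites(annotate_psms(rows, db))
    shuffled = rows[:]
    random.Random(7).shuffle(shuffled)
    assert call_sites(annotate_psms(shuffled, db)) == reference


def test_psm_conservation_across_sites(db):
    rows = [psm("ARPGE", 3, 7, delta=AMIDATION_DELTA_DA) for _ in range(4)]
    rows += [psm("AAAEDGW", 1, 7, delta=AMIDATION_DELTA_DA, protein="P2") for _ in range(2)]
    rows += [psm("MK", 1, 2), psm("MK", 1, 2, delta=AMIDATION_DELTA_DA)]
    annotated = annotate_psms(rows, db)
    sites = call_sites(annotated)
    n_amidated_neo = sum(
        1 for a in annotated if a.amidated and a.c_class is TerminusClass.NEO and not a.ambiguous
    )
    assert sum(s.n_psms for s in sites) == n_amidated_neo == 6


def test_ambiguous_peptides_excluded_from_sites():
    # "AAAW" occurs in both proteins -> ambiguous, never supports a site
    db = [ProteinRecord("P1", "", "GKAAAWGGGK"), ProteinRecord("P2", "", "CCAAAWCCCC")]
    rows = [psm("AAAW", 3, 6, delta=AMIDATION_DELTA_DA, protein="P1")]
    annotated = annotate_psms(rows, db)
    assert annotated[0].ambiguous
    assert call_sites(annotated) == []
    relaxed = annotate_psms(rows, db, exclude_ambiguous=False)
    assert len(call_sites(relaxed)) == 1


def test_category_stats_cross_tab(db):
    rows = [psm("MK", 1, 2) for _ in range(100)]
    rows += [psm("ARPGE", 3, 7, delta=AMIDATION_DELTA_DA) for _ in range(8)]
    rows += [psm("ARPGE", 3, 7) for _ in range(2)]
    table = category_stats(annotate_psms(rows, db))
    assert table.n_total == {"ANNOTATED_C": 0, "ENZYMATIC": 100, "NEO": 10}
    assert table.fraction_amidated["ENZYMATIC"] == 0.0
    assert table.fraction_amidated["NEO"] == pytest.approx(0.8)
    assert table.share_among_amidated["NEO"] == pytest.approx(1.0)
    assert sum(table.n_total.values()) == 110


def test_category_stats_all_unmodified(db):
    table = category_stats(annotate_psms([psm("MK", 1, 2)], db))
    assert all(v == 0.0 for v in table.fraction_amidated.values())


def _annotated_with_bin(k, c_class=TerminusClass.NEO):
    row = PsmRow(sample_id="s", peptide="AA", protein_id="P", start=3, end=4)
    return AnnotatedPsm(
        psm=row,
        n_class=TerminusClass.ENZYMATIC,
        c_class=c_class,
        status=EnzymaticStatus.SEMI,
        amidated=k == -1,
        shift_bin=k,
    )


def test_noise_control_signal_ratio():
    annotated = (
        [_annotated_with_bin(-1)] * 10 + [_annotated_with_bin(1)] + [_annotated_with_bin(-2)]
    )
    report = shift_noise_control(annotated)
    assert report.counts == {-3: 0, -2: 1, -1: 10, 1: 1, 2: 0, 3: 0}
    assert report.signal_ratio == pytest.approx(25.0)  # 10 / mean(1,1,0,0,0)


def test_noise_control_degenerate_cases():
    assert shift_noise_control([]).signal_ratio == 0.0
    assert shift_noise_control([_annotated_with_bin(-1)] * 5).signal_ratio == math.inf
    # enzymatic-terminus PSMs never enter the noise control
    report = shift_noise_control([_annotated_with_bin(-1, c_class=TerminusClass.ENZYMATIC)])
    assert report.signal_ratio == 0.0


def test_overlap_sites():
    a = [("P", 3), ("P", 7)]
    b = [("P", 7)]
    report = overlap_sites(a, b)
    assert (report.n_a, report.n_b, report.shared) == (2, 1, 1)
    assert report.jaccard == pytest.approx(0.5)
    assert overlap_sites(a, a).jaccard == 1.0
    assert overlap_sites(a, [("Q", 1)]).jaccard == 0.0
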
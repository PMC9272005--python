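"""Domain filtering, alignment, conserved-site checks and family tallies."""

import math
import random

import pytest
from hypothesis import given, settings, strategies as st

from conftest import protein_from_domain
from glyi.catalog import DomainSpan, ProteinRecord
from glyi.classify import (Alignment, ClassifyError, Scoring, VocabularyError,
                           align_global, check_sites, classify_family,
                           domain_architecture, filter_candidates,
                           localization_consensus, map_reference_sites,
                           site_results_from_table, site_results_to_table)
from glyi.synthetic import fixture_path

SCORING = Scoring()
SUB = SCORING.substitution()

DISCARDED_IDS = {"TdGLYI-4B-2.2", "TdGLYI-1A-3.1", "TdGLYI-1A-1.1",
                 "TdGLYI-1B-1.1", "TdGLYI-3B-1.2", "TdGLYI-5A-2.2"}


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------

def test_filter_family_fixture(family_catalog):
    """60 candidate variants reduce to 54 after the domain filter."""
    kept, discarded = filter_candidates(family_catalog.proteins)
    assert len(kept) == 54
    assert {p.protein_id for p, _ in discarded} == DISCARDED_IDS
    reasons = dict((p.protein_id, r) for p, r in discarded)
    assert reasons["TdGLYI-4B-2.2"] == "domain absent"
    assert all(r == "domain too short" for pid, r in reasons.items()
               if pid != "TdGLYI-4B-2.2")


def test_filter_threshold_and_partition():
    short = ProteinRecord("p99", 200, domains=[DomainSpan(length=99)])
    exact = ProteinRecord("p100", 200, domains=[DomainSpan(length=100)])
    double = ProteinRecord("p2", 400, domains=[DomainSpan(length=80),
                                               DomainSpan(length=130)])
    kept, discarded = filter_candidates([short, exact, double])
    assert [p.protein_id for p in kept] == ["p100", "p2"]   # longest span rules
    assert [p.protein_id for p, _ in discarded] == ["p99"]
    assert len(kept) + len(discarded) == 3
    assert filter_candidates([]) == ([], [])


# ---------------------------------------------------------------------------
# global alignment
# ---------------------------------------------------------------------------

def test_align_identity_is_gapfree():
    seq = "MKTAYIAKQR"
    aln = align_global(seq, seq, SCORING)
    assert aln.aligned_candidate == aln.aligned_reference == seq
    assert aln.score == sum(float(SUB[a, a]) for a in seq)
    assert aln.position_map == {i + 1: i + 1 for i in range(len(seq))}


def test_align_single_residues_mismatch_column():
    aln = align_global("A", "G", SCORING)
    assert (aln.aligned_candidate, aln.aligned_reference) == ("A", "G")
    assert aln.score == float(SUB["A", "G"])


def test_align_empty_rejected():
    with pytest.raises(ClassifyError):
        align_global("", "ACD", SCORING)


def brute_force_score(a: str, b: str, scoring: Scoring) -> float:
    """Exhaustive enumeration over every gapped global alignment."""
    sub = scoring.substitution()
    open_, ext = scoring.gap_open, scoring.gap_extend
    best = -math.inf

    def rec(i, j, prev, score):
        nonlocal best
        if i == len(a) and j == len(b):
            best = max(best, score)
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, "M", score + float(sub[a[i], b[j]]))
        if i < len(a):
            cost = ext if prev == "X" else open_ + ext
            rec(i + 1, j, "X", score - cost)
        if j < len(b):
            cost = ext if prev == "Y" else open_ + ext
            rec(i, j + 1, "Y", score - cost)

    rec(0, 0, None, 0.0)
    return best


@settings(max_examples=150, deadline=None, derandomize=True)
@given(st.text(alphabet="ACDE", min_size=1, max_size=6),
       st.text(alphabet="ACDE", min_size=1, max_size=6))
def test_align_matches_brute_force_oracle(a, b):
    """DP optimum equals exhaustive enumeration on short 4-letter pairs."""
    aln = align_global(a, b, SCORING)
    assert aln.score == pytest.approx(brute_force_score(a, b, SCORING))
    # ungapping each aligned string recovers its input
    assert aln.candidate == a
    assert aln.reference == b


def test_align_score_matches_rescoring_of_alignment():
    a, b = "ACDEAC", "ADEACC"
    aln = align_global(a, b, SCORING)
    score, gap_run = 0.0, 0
    for ca, cb in zip(aln.aligned_candidate, aln.aligned_reference):
        if "-" in (ca, cb):
            score -= SCORING.gap_extend + (0 if gap_run else SCORING.gap_open)
            gap_run += 1
        else:
            score += float(SUB[ca, cb])
            gap_run = 0
    assert score == pytest.approx(aln.score)


# ---------------------------------------------------------------------------
# site mapping
# ---------------------------------------------------------------------------

def test_map_sites_identity(profiles):
    hs = profiles["HsGLYI"]
    aln = align_global(hs.domain_sequence, hs.domain_sequence, SCORING)
    mapped = map_reference_sites(aln, hs)
    assert mapped[34] == (34, "Q")
    assert mapped[100] == (100, "E")
    assert mapped[127] == (127, "H")
    assert mapped[173] == (173, "E")
    assert mapped[38] == (38, "R")
    assert mapped[104] == (104, "N")
    assert mapped[106] == (106, "G")


def test_map_sites_insertion_shifts_positions(profiles):
    hs = profiles["HsGLYI"]
    cand = "W" + hs.domain_sequence          # one insertion before everything
    aln = Alignment(cand, "-" + hs.domain_sequence, score=0.0)
    mapped = map_reference_sites(aln, hs)
    assert mapped[34] == (35, "Q")
    assert mapped[173] == (174, "E")


def test_map_sites_gap_in_candidate(profiles):
    hs = profiles["HsGLYI"]
    ref = hs.domain_sequence
    cand_aligned = ref[:33] + "-" + ref[34:]   # site 34 deleted in candidate
    aln = Alignment(cand_aligned, ref, score=0.0)
    assert map_reference_sites(aln, hs)[34] == (None, None)


def test_map_sites_requires_matching_reference(profiles):
    aln = align_global("ACDE", "ACDE", SCORING)
    with pytest.raises(ClassifyError):
        map_reference_sites(aln, profiles["HsGLYI"])


# ---------------------------------------------------------------------------
# check_sites
# ---------------------------------------------------------------------------

def test_reference_domains_self_check(profiles):
    """Each reference domain is called active with its own metal type."""
    ec = protein_from_domain("EC", profiles["EcGLYI"].domain_sequence)
    hs = protein_from_domain("HS", profiles["HsGLYI"].domain_sequence)
    r_ec = check_sites(ec, profiles)
    r_hs = check_sites(hs, profiles)
    assert (r_ec.active, r_ec.predicted_metal) == (True, "Ni")
    assert (r_hs.active, r_hs.predicted_metal) == (True, "Zn")


@pytest.mark.parametrize("profile_name", ["HsGLYI", "EcGLYI"])
def test_single_site_knockout_inactivates(profiles, profile_name):
    """Mutating any one of the 7 conserved residues flips the activity call."""
    profile = profiles[profile_name]
    for _kind, pos, _expected in profile.all_sites:
        domain = list(profile.domain_sequence)
        domain[pos - 1] = "A"
        prot = protein_from_domain(f"mut{pos}", "".join(domain))
        res = check_sites(prot, profiles)
        assert not res.active, f"{profile_name} site {pos} knockout missed"
        assert res.predicted_metal == "none"


def test_check_sites_flanked_and_two_domain(profiles):
    """Only the N-terminal qualifying domain feeds the site check."""
    hs = profiles["HsGLYI"].domain_sequence
    ec = profiles["EcGLYI"].domain_sequence
    degenerate = ec[:55] + "A" + ec[56:]      # E56 knocked out in C-term copy
    seq = "MKT" + ec + "GSGS" + degenerate + "WL"
    prot = ProteinRecord(
        "two", len(seq), sequence=seq,
        domains=[
            DomainSpan(length=len(ec), start=4, end=3 + len(ec)),
            DomainSpan(length=len(degenerate), start=8 + len(ec),
                       end=7 + len(ec) + len(degenerate)),
        ])
    res = check_sites(prot, profiles)
    assert res.active and res.predicted_metal == "Ni"
    assert domain_architecture(prot) == "two-domain"
    one = protein_from_domain("one", hs, nflank="MA", cflank="KL")
    assert domain_architecture(one) == "one-domain"
    assert check_sites(one, profiles).predicted_metal == "Zn"


def test_check_sites_not_checkable_distinct_from_inactive():
    prot = ProteinRecord("noseq", 150, domains=[DomainSpan(length=120)])
    res = check_sites(prot)
    assert not res.checkable
    assert not res.active


def test_zn_call_requires_long_domain(profiles):
    """Q at the cofactor site without a long domain is not called Zn."""
    hs = profiles["HsGLYI"].domain_sequence
    short = hs[:130]     # keeps Q34/R38/E100/N104/G106/H127, loses E173
    res = check_sites(protein_from_domain("short", short), profiles)
    assert res.predicted_metal == "none"
    assert not res.active


# ---------------------------------------------------------------------------
# family summary
# ---------------------------------------------------------------------------

def test_family_summary_from_site_table(site_table_results, family_catalog):
    """28 active variants: 23 Ni-type, 5 Zn-type, from nine genes."""
    fam = classify_family(site_table_results, family_catalog)
    assert fam.n_filtered == 54
    assert fam.n_active == 28
    assert fam.n_ni == 23
    assert fam.n_zn == 5
    assert fam.n_active == fam.n_ni + fam.n_zn
    assert fam.n_active_genes == 9


def test_family_summary_permutation_invariant(site_table_results):
    shuffled = list(site_table_results)
    random.Random(3).shuffle(shuffled)
    a = classify_family(site_table_results)
    b = classify_family(shuffled)
    assert (a.n_active, a.n_ni, a.n_zn) == (b.n_active, b.n_ni, b.n_zn)


def test_family_summary_all_absent_and_join_error(family_catalog):
    import pandas as pd
    absent = site_results_from_table(pd.DataFrame({
        "protein_id": ["x.1"], "metal_site": ["Absent"], "gsh_site": ["Absent"],
        "dimer": ["Absent"], "metal": ["Absent"], "active": ["Absent"],
    }))
    assert classify_family(absent).n_active == 0
    active_unknown = site_results_from_table(pd.DataFrame({
        "protein_id": ["nope.1"], "metal_site": ["Present"],
        "gsh_site": ["Present"], "dimer": ["Present"], "metal": ["Ni"],
        "active": ["Present"],
    }))
    with pytest.raises(ClassifyError, match="join"):
        classify_family(active_unknown, family_catalog)


def test_site_table_round_trip(site_table_results):
    df = site_results_to_table(site_table_results)
    again = site_results_from_table(df)
    assert [(r.protein_id, r.active, r.predicted_metal)
            for r in site_table_results] == \
           [(r.protein_id, r.active, r.predicted_metal) for r in again]


# ---------------------------------------------------------------------------
# localization consensus
# ---------------------------------------------------------------------------

def test_localization_fixture_counts():
    """Organellar splice-variant counts: 7, 3, 2, 2 for the four genes
    named in the study, 17 organellar variants over five genes in total."""
    cons = localization_consensus(fixture_path("table3"))
    assert cons.per_gene["TdGLYI-1B-4"] == 7
    assert cons.per_gene["TdGLYI-2A-1"] == 3
    assert cons.per_gene["TdGLYI-2B-1"] == 2
    assert cons.per_gene["TdGLYI-5B-1"] == 2
    assert sum(cons.per_gene.values()) == 17
    assert sum(1 for c in cons.per_gene.values() if c) == 5
    assert cons.per_gene["TdGLYI-7A-1"] == 0          # cytosolic gene


def test_localization_split_and_edge_rules():
    import pandas as pd
    df = pd.DataFrame({"protein_id": ["g.1", "g.2", "g.3"],
                       "tool": ["C/M", "-", "Cyt/M"]})
    cons = localization_consensus(df)
    row1 = cons.per_variant.iloc[0]
    assert row1["supports_C"] and row1["supports_M"] and row1["organellar"]
    assert not cons.per_variant.iloc[1]["organellar"]       # all-dash row
    assert not cons.per_variant.iloc[2]["organellar"]       # Cyt-conflicted
    with pytest.raises(VocabularyError):
        localization_consensus(pd.DataFrame({"protein_id": ["g.1"],
                                             "tool": ["Chloro"]}))
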
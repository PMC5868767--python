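"""Family expansion, redundancy filters, candidate pairing, path
verification and the homology verdict machinery."""

import numpy as np
import pytest

from superfam.alignment import AlnParams
from superfam.sequence import FamilySet, ProteinRecord
from superfam.synthetic import (
    FamilySpec,
    generate_family,
    generate_membrane_protein,
    mutate_sequence,
    rate_for_identity,
)
from superfam.transitivity import (
    DomainHit,
    DomainHitTable,
    PathRejected,
    TransitivityPath,
    common_match_overlap,
    domain_presence_fraction,
    expand_family,
    find_distant_members,
    protocol2,
    redundancy_reduce,
    rescue_domain,
    verify_path,
)


@pytest.fixture(scope="module")
def query_protein():
    rec, tms = generate_membrane_protein(FamilySpec(), seed=101, record_id="Q1")
    return rec


class TestExpansion:
    def test_planted_homolog_at_half_coverage_is_hit(self, query_protein):
        half = ProteinRecord("H1", query_protein.seq[: len(query_protein.seq) // 2])
        hits = expand_family([query_protein], [half])
        assert [h.hit_id for h in hits] == ["H1"]
        assert hits[0].query_coverage >= 0.45

    def test_forty_percent_coverage_rejected(self, query_protein):
        short = ProteinRecord("H2", query_protein.seq[: int(len(query_protein.seq) * 0.40)])
        assert expand_family([query_protein], [short]) == []

    def test_empty_database_is_empty_result(self, query_protein):
        assert expand_family([query_protein], []) == []

    def test_empty_queries_is_error(self, query_protein):
        with pytest.raises(ValueError):
            expand_family([], [query_protein])

    def test_region_extraction_matches_hit_interval(self, query_protein):
        half = ProteinRecord("H1", query_protein.seq[50:400])
        hits = expand_family([query_protein], [half])
        h = hits[0]
        assert h.aligned_region == half.seq[h.hit_start : h.hit_end]


class TestRedundancyReduce:
    def _mutant(self, seq, n_subs, seed):
        rng = np.random.default_rng(seed)
        s = list(seq)
        aa = list("ACDEFGHIKLMNPQRSTVWY")
        for i in rng.choice(len(s), n_subs, replace=False):
            s[i] = str(rng.choice([c for c in aa if c != s[i]]))
        return "".join(s)

    def test_identical_sequences_collapse(self, query_protein):
        seqs = [ProteinRecord(f"s{i}", query_protein.seq) for i in range(5)]
        assert len(redundancy_reduce(seqs)) == 1

    def test_ninety_five_percent_identity_collapses(self, query_protein):
        seq = query_protein.seq
        other = self._mutant(seq, int(0.05 * len(seq)), 0)
        kept = redundancy_reduce(
            [ProteinRecord("a", seq), ProteinRecord("b", other)]
        )
        assert len(kept) == 1

    def test_length_ratio_exception_keeps_fragment(self, query_protein):
        seq = query_protein.seq
        frag = seq[: len(seq) // 2][: int(len(seq) / 2)]
        # make the pair ratio exceed 1.8: long vs its first 45%
        frag = seq[: int(len(seq) * 0.45)]
        kept = redundancy_reduce(
            [ProteinRecord("long", seq), ProteinRecord("frag", frag)],
            length_ratio_exception=1.8,
        )
        assert {r.id for r in kept} == {"long", "frag"}

    def test_representatives_in_first_occurrence_order(self, query_protein):
        a = ProteinRecord("a", query_protein.seq)
        b = ProteinRecord("b", query_protein.seq[::-1])
        assert [r.id for r in redundancy_reduce([a, b])] == ["a", "b"]

    def test_no_retained_pair_above_threshold(self, tiny_family):
        from superfam.alignment import local_align

        members = list(tiny_family.family.members)
        kept = redundancy_reduce(members, id_threshold=0.90)
        for i in range(len(kept)):
            for j in range(i + 1, len(kept)):
                aln = local_align(kept[i].seq, kept[j].seq)
                matches = sum(
                    1 for x, y in zip(aln.aligned_a, aln.aligned_b)
                    if x == y and x != "-"
                )
                ident = matches / min(len(kept[i].seq), len(kept[j].seq))
                ratio = max(len(kept[i].seq), len(kept[j].seq)) / min(
                    len(kept[i].seq), len(kept[j].seq)
                )
                assert ident < 0.90 or ratio > 1.8


class TestProtocol2:
    def test_self_pair_is_top_ranked(self, query_protein):
        other, _ = generate_membrane_protein(FamilySpec(), seed=555, record_id="O1")
        cands = protocol2([query_protein, other], [query_protein], pre_shuffles=100)
        assert cands[0].record_a.id == "Q1"
        assert cands[0].record_b.id == "Q1"
        assert cands[0].z > 50

    def test_shared_region_tms_overlap(self):
        """Two proteins sharing six interior TMSs overlap in exactly the
        shared hydrophobic segments."""
        spec = FamilySpec(n_tms=8)
        anc, tms = generate_membrane_protein(spec, seed=77, record_id="anc")
        # family 2 shares TMSs 3-8 of the ancestor (drop the first two)
        shared_start = tms[2][0] - 20
        b = ProteinRecord("B", anc.seq[shared_start:])
        cands = protocol2([anc], [b], pre_shuffles=100)
        assert cands[0].overlapping_tms == 6

    def test_empty_list_rejected(self, query_protein):
        with pytest.raises(ValueError):
            protocol2([], [query_protein])


class TestVerifyPath:
    def test_comparison_score_is_minimum(self):
        p = TransitivityPath("F1", "b", "c", "F2", 72.9, 34.3, 168.4, 9)
        assert p.comparison_score == 34.3

    def test_min_of_equal_scores(self):
        p = TransitivityPath("F1", "b", "c", "F2", 20.0, 20.0, 20.0, 5)
        assert p.comparison_score == 20.0

    def test_short_alignment_rejected_naming_length(self, rng):
        aa = list("ACDEFGHIKLMNPQRSTVWY")
        short = [ProteinRecord(f"s{i}", "".join(rng.choice(aa, 120))) for i in range(4)]
        with pytest.raises(PathRejected, match="150"):
            verify_path(*short, shuffles=100, min_tms=0, min_len=150)

    def test_few_overlapping_tms_rejected(self, rng):
        aa = list("ACDEFGHIKLMNPQRSTVWY")
        soluble = [ProteinRecord(f"s{i}", "".join(rng.choice(aa, 300))) for i in range(4)]
        with pytest.raises(PathRejected, match="TMS"):
            verify_path(*soluble, shuffles=100, min_tms=5, min_len=150)

    def test_self_bridge_counts_all_tms(self, query_protein, tiny_family):
        rep = tiny_family.family.members[0]
        path = verify_path(
            rep, query_protein, query_protein, rep,
            shuffles=100, min_tms=0, min_len=0, seed=3,
        )
        assert path.aligned_tms == 10
        assert path.z_bc > 50


class TestDomainRescue:
    @pytest.fixture()
    def family_with_domain(self, rng):
        """Three members carrying a 200-residue domain, one target without
        a recorded hit but containing a diverged copy."""
        aa = list("ACDEFGHIKLMNPQRSTVWY")
        domain = "".join(rng.choice(aa, 200))
        members, table = [], DomainHitTable()
        for i in range(3):
            pre = "".join(rng.choice(aa, 50))
            post = "".join(rng.choice(aa, 50))
            members.append(ProteinRecord(f"d{i}", pre + domain + post))
            table.rows.append(DomainHit(f"d{i}", "DUF9", 50, 250, 1e-40))
        diverged = list(domain)
        for j in rng.choice(200, 30, replace=False):  # 85% identity copy
            diverged[j] = str(rng.choice(aa))
        target = ProteinRecord("t", "".join(rng.choice(aa, 60)) + "".join(diverged))
        return members, table, target, domain

    def test_target_with_existing_hit_unchanged(self, family_with_domain):
        members, table, _, _ = family_with_domain
        out = rescue_domain(members[0], members, table, "DUF9")
        assert out is table

    def test_diverged_copy_rescued_at_planted_location(self, family_with_domain):
        members, table, target, _ = family_with_domain
        out = rescue_domain(target, members, table, "DUF9")
        rescued = [r for r in out.rows if r.rescued]
        assert len(rescued) == 1
        assert rescued[0].member_id == "t"
        assert abs(rescued[0].start - 60) <= 5
        assert abs(rescued[0].end - 260) <= 5
        assert rescued[0].donor_id in {m.id for m in members}

    def test_partial_copy_not_rescued(self, family_with_domain, rng):
        members, table, _, domain = family_with_domain
        aa = list("ACDEFGHIKLMNPQRSTVWY")
        # only 60% of the domain present: below the 70% overlap requirement
        partial = ProteinRecord("p", "".join(rng.choice(aa, 80)) + domain[: int(0.60 * 200)])
        out = rescue_domain(partial, members, table, "DUF9", min_overlap=0.70)
        assert not any(r.member_id == "p" for r in out.rows)

    def test_presence_fraction(self, family_with_domain):
        members, table, target, _ = family_with_domain
        fam = FamilySet("9.S.6.1", [
            ProteinRecord(f"9.S.6.1.{i + 1}", m.seq) for i, m in enumerate(members + [target])
        ])
        table2 = DomainHitTable(
            [DomainHit(f"9.S.6.1.{i + 1}", "DUF9", 50, 250, 1e-40) for i in range(3)]
        )
        assert domain_presence_fraction(table2, "DUF9", fam) == pytest.approx(0.75)


class TestDistantMembers:
    def test_cascade_filters(self, rng):
        """Known members (tiny E) drop at step 1; low-TMS candidates drop at
        step 2; a diverged 10-TMS relative survives to the curation table."""
        spec = FamilySpec(label="9.S.7.1", n_members=3,
                          substitution_rate=rate_for_identity(0.95))
        fam_sample = generate_family(spec, seed=900)
        fam = fam_sample.family
        # distant relative: deep mutation of the ancestor, TMSs conserved
        anc = fam_sample.ancestor.seq
        tms = [(s, e) for s, e in fam_sample.tms_truth[fam.members[0].id]]
        distant_seq = mutate_sequence(
            anc, 0.55, np.random.default_rng(5), tms_intervals=tms
        )
        distant_rec = ProteinRecord("DIST1", distant_seq)
        aa = list("ACDEFGHIKLMNPQRSTVWY")
        soluble = ProteinRecord("SOL1", "".join(rng.choice(aa, 700)))
        db = list(fam.members) + [distant_rec, soluble]
        # the known-member threshold sits between the within-family E-values
        # (smaller) and the distant candidate's E-value (larger); pick it
        # from the observed distant hit so the cascade's comparisons are the
        # thing under test, not the absolute Karlin-Altschul magnitudes
        probe = expand_family(fam.members, db, min_coverage=0.70, exclude_self=True)
        dist_e = min(h.evalue for h in probe if h.hit_id == "DIST1")
        fam_e = max(
            h.evalue for h in probe if h.hit_id in {m.id for m in fam.members}
        )
        assert fam_e < dist_e
        table = find_distant_members(fam, db, known_evalue=dist_e / 10, min_tms=8)
        assert "DIST1" in set(table.hit_id)
        assert set(table.hit_id).isdisjoint({m.id for m in fam.members})
        assert "SOL1" not in set(table.hit_id)

    def test_best_reference_family_check(self):
        """A candidate whose best reference match is another family is
        discarded."""
        other = generate_family(
            FamilySpec(label="9.S.7.2", n_members=2,
                       substitution_rate=rate_for_identity(0.95)), seed=901
        )
        fam = generate_family(
            FamilySpec(label="9.S.7.3", n_members=2,
                       substitution_rate=rate_for_identity(0.95)), seed=902
        )
        # a mild variant of the OTHER family's ancestor, searched from fam
        stray_seq = mutate_sequence(
            other.ancestor.seq, 0.25, np.random.default_rng(7),
            tms_intervals=other.tms_truth[other.family.members[0].id],
        )
        stray = ProteinRecord("STRAY1", stray_seq)
        db = list(fam.family.members) + [stray]
        # permissive early filters so the reference-family check is what
        # rejects the stray
        table = find_distant_members(
            fam.family, db, known_evalue=1e-300, min_tms=8,
            tcdb_ref=[fam.family, other.family],
            expansion_min_coverage=0.20,
        )
        assert "STRAY1" not in set(table.hit_id)


class TestCommonMatchOverlap:
    def _hit(self, hid, start, end):
        from superfam.transitivity import ExpansionHit

        return ExpansionHit("q", hid, 1e-20, 0.9, "A" * (end - start), 800, start, end)

    def test_no_common_hits(self):
        assert common_match_overlap([self._hit("x", 0, 100)], [self._hit("y", 0, 100)]).empty

    def test_interval_intersection(self):
        table = common_match_overlap(
            [self._hit("x", 100, 500)], [self._hit("x", 300, 700)]
        )
        assert list(table.overlap) == [200]

    def test_disjoint_intervals_zero(self):
        table = common_match_overlap(
            [self._hit("x", 0, 100)], [self._hit("x", 200, 300)]
        )
        assert list(table.overlap) == [0]


class TestVerdictProperties:
    def test_threshold_monotonicity(self, tiny_family):
        """Raising the threshold never converts not_demonstrated into
        homologous."""
        from superfam.transitivity import are_families_homologous

        fam = tiny_family.family
        half = len(fam.members) // 2
        fa = FamilySet("9.S.4.1", fam.members[:2])
        fb_members = [
            ProteinRecord(f"9.S.9.9.{i + 1}", m.seq) for i, m in enumerate(fam.members[2:])
        ]
        fb = FamilySet("9.S.9.9", fb_members)
        db = list(fa.members) + list(fb.members)
        verdicts = []
        for thr in (5.0, 40.0, 400.0):
            v = are_families_homologous(fa, fb, db, threshold=thr, seed=2)
            verdicts.append(v.is_homologous)
        assert verdicts == sorted(verdicts, reverse=True)
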
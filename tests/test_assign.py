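"""Strict-filter search, naive LCA, library accounting, length benchmark."""

import math

import numpy as np
import pytest

import coicap as cc
from coicap.assign import DEFAULT_SCORING, _exact_substring_hit
from coicap.refdb import Lineage, ReferenceDB, TaxonRecord


def random_dna(n, rng):
    return "".join("ACGT"[c] for c in rng.integers(0, 4, n))


class TestScoringScheme:
    def test_bit_scores_of_perfect_matches(self):
        sc = cc.ScoringScheme()
        # 140 bp perfect match clears the 230-bit floor, 120 bp does not
        assert sc.bit_score(2 * 140) == pytest.approx(253.8, abs=0.1)
        assert sc.bit_score(2 * 120) == pytest.approx(217.7, abs=0.1)
        assert sc.bit_score(2 * 120) < 230 <= sc.bit_score(2 * 140)

    def test_invalid_scheme_rejected(self):
        with pytest.raises(ValueError):
            cc.ScoringScheme(match=-1)
        with pytest.raises(ValueError):
            cc.ScoringScheme(lam=0)


class TestLocalAlign:
    def test_exact_140bp_match(self):
        rng = np.random.default_rng(3)
        subject = random_dna(650, rng)
        read = subject[200:340]
        hit = cc.local_align(read, subject)
        assert hit.raw_score == 280
        assert hit.bit_score == pytest.approx(253.8, abs=0.1)
        assert hit.identity == 1.0
        assert hit.aligned_read_fraction == 1.0
        assert hit.subject_span == (200, 340)

    def test_one_mismatch_identity(self):
        rng = np.random.default_rng(4)
        subject = random_dna(650, rng)
        read = list(subject[100:240])
        read[70] = "ACGT"[("ACGT".index(read[70]) + 2) % 4]
        hit = cc.local_align("".join(read), subject)
        assert hit.identity == pytest.approx(139 / 140, abs=1e-9)
        assert hit.identity >= 0.99
        assert hit.raw_score == 139 * 2 - 3

    def test_unrelated_sequences_score_low(self):
        rng = np.random.default_rng(5)
        hit = cc.local_align(random_dna(140, rng), random_dna(650, rng))
        assert hit.bit_score < 100

    def test_exact_substring_shortcut_matches_dp(self):
        rng = np.random.default_rng(6)
        subject = random_dna(500, rng)
        read = subject[50:175]
        fast = _exact_substring_hit(read, subject, DEFAULT_SCORING, "", "")
        slow = cc.local_align(read, subject)
        assert (fast.raw_score, fast.identity, fast.subject_span) == \
               (slow.raw_score, slow.identity, slow.subject_span)

    def test_gap_columns_count_against_identity(self):
        rng = np.random.default_rng(7)
        subject = random_dna(400, rng)
        read = subject[100:170] + subject[172:240]  # 2 bp deletion
        hit = cc.local_align(read, subject)
        assert hit.identity < 1.0
        assert hit.subject_span[1] - hit.subject_span[0] >= 140

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            cc.local_align("", "ACGT")


def shared_region_db(rng):
    """Two congeneric records sharing a verbatim 250 bp block, plus an
    unrelated species."""
    shared = random_dna(250, rng)
    a = random_dna(200, rng) + shared + random_dna(200, rng)
    b = random_dna(180, rng) + shared + random_dna(220, rng)
    c = random_dna(650, rng)
    return ReferenceDB([
        TaxonRecord("H1", Lineage("Hoplias_malabaricus", "Hoplias",
                                  "Erythrinidae", "Characiformes"), a),
        TaxonRecord("H2", Lineage("Hoplias_curupira", "Hoplias",
                                  "Erythrinidae", "Characiformes"), b),
        TaxonRecord("Z1", Lineage("Zungaro_zungaro", "Zungaro",
                                  "Pimelodidae", "Siluriformes"), c),
    ])


class TestSearch:
    def test_unique_substring_finds_its_reference(self, clade20):
        rec = clade20.records[5]
        read = rec.sequence[100:240]
        hits = cc.search(read, clade20)
        assert hits and hits[0].subject_accession == rec.accession
        assert hits[0].identity == 1.0

    def test_shared_region_yields_tied_top_hits(self):
        db = shared_region_db(np.random.default_rng(8))
        read = db.records[0].sequence[260:400]  # inside the shared block
        hits = cc.search(read, db)
        assert {h.subject_accession for h in hits} == {"H1", "H2"}
        assert hits[0].bit_score == hits[1].bit_score

    def test_bit_floor_is_inclusive(self, clade20):
        rec = clade20.records[0]
        read = rec.sequence[0:140]
        bit = DEFAULT_SCORING.bit_score(280)
        assert cc.search(read, clade20, min_bit=bit) != []
        assert cc.search(read, clade20, min_bit=bit + 1e-6) == []

    def test_empty_hit_list_is_valid(self, clade20):
        rng = np.random.default_rng(9)
        # a random read will essentially never pass 99% identity
        assert cc.search(random_dna(140, rng), clade20) == []

    def test_prefilter_matches_exhaustive_alignment(self, clade20):
        """The seed prefilter must not change search results (oracle)."""
        rng = np.random.default_rng(10)
        comm = cc.MockCommunity.equimolar(clade20, clade20.species_labels())
        reads = cc.simulate_community_reads(comm, 30, 140, error_rate=0.01,
                                            seed=11)
        index = cc.KmerIndex(clade20)
        for read in reads:
            fast = cc.search(read, clade20, index=index)
            slow = []
            for rec in clade20.records:
                hit = cc.local_align(read.sequence, rec.sequence,
                                     read_id=read.read_id,
                                     subject_accession=rec.accession)
                if (hit.bit_score >= 230 and hit.identity >= 0.99
                        and hit.aligned_read_fraction >= 0.9):
                    slow.append(hit)
            slow.sort(key=lambda h: (-h.bit_score, h.subject_accession))
            assert [(h.subject_accession, h.raw_score) for h in fast] == \
                   [(h.subject_accession, h.raw_score) for h in slow]


def lca_oracle(hits, db, top_percent=0.10):
    """Brute-force LCA: intersect lineage labels walking order -> species."""
    if not hits:
        return ("no_hit", "", "")
    best = max(h.bit_score for h in hits)
    lineages = [db.index[h.subject_accession].lineage for h in hits
                if h.bit_score >= (1 - top_percent) * best]
    call = ("hit_unassigned", "", "")
    for rank in reversed(Lineage.RANKS):  # order first, species last
        labels = {lin.at(rank) for lin in lineages}
        if len(labels) == 1 and next(iter(labels)) != "unknown":
            call = ("assigned", next(iter(labels)), rank)
        # keep descending: the lowest agreeing rank wins
    return call


def fake_hit(acc, bit):
    return cc.AlignmentHit("r", acc, int(bit), float(bit), 1.0, 1.0, (0, 1))


class TestNaiveLCA:
    def test_agreement_at_each_rank(self, lineage_db):
        cases = [
            (["L001"], ("s1", "species")),
            (["L001", "L002"], ("G1", "genus")),       # two species, one genus
            (["L001", "L003"], ("F1", "family")),      # two genera, one family
            (["L001", "L004"], ("O1", "order")),       # two families, one order
        ]
        for accs, (taxon, rank) in cases:
            res = cc.naive_lca([fake_hit(a, 250) for a in accs], lineage_db)
            assert (res.taxon, res.rank) == (taxon, rank)
            assert res.status == "assigned"

    def test_disagreement_at_order_is_unassigned(self, lineage_db):
        res = cc.naive_lca([fake_hit("L001", 250), fake_hit("L005", 250)],
                           lineage_db)
        assert res.status == "hit_unassigned"
        assert res.supporting_hits == 2

    def test_empty_hits_is_no_hit(self, lineage_db):
        res = cc.naive_lca([], lineage_db)
        assert res.status == "no_hit"
        assert res.supporting_hits == 0

    def test_top_percent_band_drops_weak_hits(self, lineage_db):
        # the weak cross-order hit is outside the 10% band, so it cannot
        # push the call up to order
        hits = [fake_hit("L001", 250), fake_hit("L005", 220)]
        res = cc.naive_lca(hits, lineage_db)
        assert (res.taxon, res.rank) == ("s1", "species")

    def test_matches_brute_force_oracle_on_random_hit_sets(self, lineage_db):
        rng = np.random.default_rng(12)
        accs = [r.accession for r in lineage_db.records]
        for _ in range(300):
            n = int(rng.integers(1, 6))
            hits = [fake_hit(accs[int(rng.integers(0, len(accs)))],
                             float(rng.uniform(200, 260)))
                    for _ in range(n)]
            res = cc.naive_lca(hits, lineage_db)
            assert (res.status, res.taxon, res.rank) == \
                lca_oracle(hits, lineage_db)

    def test_unknown_subject_is_an_error(self, lineage_db):
        with pytest.raises(KeyError):
            cc.naive_lca([fake_hit("GHOST", 250)], lineage_db)


class TestClassifyLibrary:
    def test_zero_reads(self, clade20):
        results, tally = cc.classify_library([], clade20)
        assert results == []
        assert (tally.n_total, tally.n_with_hit, tally.n_assigned) == (0, 0, 0)

    def test_status_percentages(self, lineage_db):
        rng = np.random.default_rng(13)
        reads = []
        # 2 assigned: exact 140 bp substrings
        for rec in lineage_db.records[:2]:
            reads.append((f"hit_{rec.accession}", rec.sequence[50:190]))
        # 3 hit_unassigned: share seeds but fail the 99% identity filter
        for i in range(3):
            src = list(lineage_db.records[i].sequence[50:190])
            for site in rng.choice(140, size=20, replace=False):
                src[site] = "ACGT"[("ACGT".index(src[site]) + 1) % 4]
            reads.append((f"weak{i}", "".join(src)))
        # 5 no-hit: random reads sharing no 11-mer with the database
        index = cc.KmerIndex(lineage_db)
        n_added = 0
        while n_added < 5:
            cand = random_dna(140, rng)
            if not index.candidate_runs(cand):
                reads.append((f"none{n_added}", cand))
                n_added += 1
        results, tally = cc.classify_library(reads, lineage_db)
        by_status = {}
        for res in results:
            by_status[res.status] = by_status.get(res.status, 0) + 1
        assert by_status == {"assigned": 2, "hit_unassigned": 3, "no_hit": 5}
        assert tally.pct_with_hit == pytest.approx(50.0)
        assert tally.pct_assigned == pytest.approx(20.0)

    def test_self_assignment_of_full_length_references(self, clade20):
        reads = cc.fragment_references(clade20, "full")
        results, tally = cc.classify_library(reads, clade20)
        assert tally.n_assigned == len(clade20)
        for read, res in zip(reads, results):
            assert (res.taxon, res.rank) == (read.truth_species, "species")

    def test_monotone_in_filters(self, clade20):
        comm = cc.MockCommunity.equimolar(clade20, clade20.species_labels())
        reads = cc.simulate_community_reads(comm, 60, 140, error_rate=0.01,
                                            seed=14)
        index = cc.KmerIndex(clade20)
        prev_hit, prev_assigned = math.inf, math.inf
        for min_bit in (230.0, 245.0, 252.0):
            _, tally = cc.classify_library(reads, clade20, min_bit=min_bit,
                                           index=index)
            assert tally.n_with_hit <= prev_hit
            assert tally.n_assigned <= prev_assigned
            prev_hit, prev_assigned = tally.n_with_hit, tally.n_assigned
        prev_hit, prev_assigned = math.inf, math.inf
        for min_identity in (0.95, 0.99, 0.999):
            _, tally = cc.classify_library(reads, clade20,
                                           min_identity=min_identity,
                                           index=index)
            assert tally.n_with_hit <= prev_hit
            assert tally.n_assigned <= prev_assigned
            prev_hit, prev_assigned = tally.n_with_hit, tally.n_assigned


class TestLengthBenchmark:
    def test_single_species_database(self):
        rng = np.random.default_rng(15)
        db = ReferenceDB([TaxonRecord("A1", Lineage("Solo_fish", "Solo"),
                                      random_dna(650, rng))])
        rows = cc.length_benchmark(db, ["Solo_fish"], [140])
        assert rows[0].pct_assigned_at_species == 100.0
        assert rows[0].species_tpr == 1.0
        assert rows[0].n_false_positive_species == 0

    def test_error_free_clade_is_fully_recovered(self, clade20):
        rows = cc.length_benchmark(clade20, clade20.species_labels(), [140])
        assert rows[0].species_tpr == 1.0
        assert rows[0].n_false_positive_species == 0

    def test_longer_fragments_assign_no_worse(self, clade20):
        rows = cc.length_benchmark(clade20, clade20.species_labels(),
                                   [50, 100, 140, 250])
        rates = [r.pct_assigned_at_species for r in rows]
        assert rates == sorted(rates)

    def test_unknown_focal_species_rejected(self, clade20):
        with pytest.raises(ValueError):
            cc.length_benchmark(clade20, ["Ghost_fish"], [140])
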
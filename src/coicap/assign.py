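"""Strict-filter read search and naive-LCA taxonomic assignment.

Reads are aligned locally (Gotoh affine Smith-Waterman, BLASTN-like scoring)
against every reference that survives an exact 11-mer seed prefilter.  A hit
is kept only under three strict filters: a minimum bit score (default 230,
which a perfect match can only reach from ~127 aligned bp), a minimum
identity over aligned columns (default 99%), and a minimum fraction of the
read covered by the alignment (default 90%).  Jointly these encode the
regime in which essentially the whole read must match a reference near
perfectly.  The surviving hits feed a naive lowest-common-ancestor call: the
read is assigned to the lowest rank at which every retained hit (those
within a bit-score band below the best hit) agrees.

The module also provides library-level accounting (no-hit / hit-but-
unassigned / assigned tallies) and the read-length assignment benchmark,
which fragments reference barcodes into fixed-length error-free reads and
measures how often they come back at species rank.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from . import _align
from .refdb import Lineage, ReferenceDB
from .simulate import SimulatedRead, fragment_references

logger = logging.getLogger(__name__)

KMER_SIZE = 11


@dataclass(frozen=True)
class ScoringScheme:
    """BLASTN-like local alignment scoring with Karlin-Altschul constants.

    A gap of length k costs gap_open + k * gap_extend (both stored as the
    conventional negative penalties).  The bit score of a raw score S is
    (lambda * S - ln K) / ln 2.
    """

    match: int = 2
    mismatch: int = -3
    gap_open: int = -5
    gap_extend: int = -2
    lam: float = 0.625
    k_const: float = 0.41

    def __post_init__(self):
        if not (self.match > 0 > self.mismatch):
            raise ValueError("need match > 0 > mismatch")
        if self.lam <= 0 or self.k_const <= 0:
            raise ValueError("lambda and K must be positive")

    def bit_score(self, raw_score: float) -> float:
        return (self.lam * raw_score - math.log(self.k_const)) / math.log(2.0)


DEFAULT_SCORING = ScoringScheme()
DEFAULT_MIN_BIT = 230.0
DEFAULT_MIN_IDENTITY = 0.99
DEFAULT_MIN_READ_COVERAGE = 0.9
DEFAULT_TOP_PERCENT = 0.10


@dataclass(frozen=True)
class AlignmentHit:
    read_id: str
    subject_accession: str
    raw_score: int
    bit_score: float
    identity: float               # matches / aligned columns (gaps included)
    aligned_read_fraction: float  # read chars in the alignment / read length
    subject_span: tuple[int, int]  # 0-based half-open on the subject


@dataclass(frozen=True)
class AssignmentResult:
    read_id: str
    status: str                   # "no_hit" | "hit_unassigned" | "assigned"
    taxon: str = ""
    rank: str = ""
    supporting_hits: int = 0
    best_bit: float = 0.0

    def __post_init__(self):
        assigned = self.status == "assigned"
        if assigned != bool(self.taxon and self.rank):
            raise ValueError("taxon/rank must be set iff status is 'assigned'")
        if self.status == "no_hit" and self.supporting_hits != 0:
            raise ValueError("no_hit implies zero supporting hits")


# ---------------------------------------------------------------------------
# alignment

def local_align(read: str, subject: str, scoring: ScoringScheme = DEFAULT_SCORING,
                read_id: str = "", subject_accession: str = "") -> AlignmentHit:
    """Optimal local alignment of a read against one subject.

    Identity is counted over all aligned columns including gap columns;
    ambiguity codes never count as matches.  Trace-back ties prefer the
    diagonal, then the vertical (gap in subject), then the horizontal move.
    """
    if not read or not subject:
        raise ValueError("cannot align an empty sequence")
    read, subject = read.upper(), subject.upper()
    raw, r_idx, s_idx = _align.sw_align(
        _align.encode(read), _align.encode(subject), scoring.match,
        scoring.mismatch, -scoring.gap_open, -scoring.gap_extend)
    return _hit_from_traceback(read, subject, raw, r_idx, s_idx, scoring,
                               read_id, subject_accession)


def _hit_from_traceback(read, subject, raw, r_idx, s_idx, scoring,
                        read_id, subject_accession) -> AlignmentHit:
    n_cols = len(r_idx)
    if n_cols == 0:
        return AlignmentHit(read_id, subject_accession, 0, scoring.bit_score(0),
                            0.0, 0.0, (0, 0))
    matches = 0
    for ri, si in zip(r_idx, s_idx):
        if ri >= 0 and si >= 0:
            cr, cs = read[ri], subject[si]
            if cr == cs and cr in "ACGT":
                matches += 1
    read_pos = r_idx[r_idx >= 0]
    subj_pos = s_idx[s_idx >= 0]
    arf = (int(read_pos.max()) - int(read_pos.min()) + 1) / len(read)
    span = (int(subj_pos.min()), int(subj_pos.max()) + 1)
    return AlignmentHit(read_id, subject_accession, raw, scoring.bit_score(raw),
                        matches / n_cols, arf, span)


def _exact_substring_hit(read: str, subject: str, scoring: ScoringScheme,
                         read_id: str, subject_accession: str) -> AlignmentHit | None:
    """Shortcut when the read occurs verbatim in the subject.

    A full exact match is the unique optimal local alignment (score
    match * L, the maximum any alignment of the read can reach), so the DP
    can be skipped; the first occurrence matches the DP tie-break.
    """
    pos = subject.find(read)
    if pos < 0:
        return None
    raw = scoring.match * len(read)
    return AlignmentHit(read_id, subject_accession, raw, scoring.bit_score(raw),
                        1.0, 1.0, (pos, pos + len(read)))


# ---------------------------------------------------------------------------
# k-mer prefilter

class KmerIndex:
    """Exact k-mer index over the reference database (plus strand)."""

    def __init__(self, db: ReferenceDB, k: int = KMER_SIZE):
        self.db = db
        self.k = k
        self.kmer_to_subjects: dict[str, set[int]] = {}
        for idx, rec in enumerate(db.records):
            seq = rec.sequence
            seen: set[str] = set()
            for i in range(len(seq) - k + 1):
                kmer = seq[i:i + k]
                if kmer not in seen:
                    seen.add(kmer)
                    self.kmer_to_subjects.setdefault(kmer, set()).add(idx)

    def candidate_runs(self, read: str) -> dict[int, int]:
        """Per candidate subject, the longest streak of consecutive read
        k-mer windows that all occur somewhere in that subject.

        If the read and a subject share an exact substring of length R >= k,
        the subject's streak is at least R - k + 1, which makes the streak a
        sound screen for long near-exact matches.
        """
        k = self.k
        best: dict[int, int] = {}
        cur: dict[int, int] = {}
        last: dict[int, int] = {}
        for w in range(len(read) - k + 1):
            subjects = self.kmer_to_subjects.get(read[w:w + k])
            if not subjects:
                continue
            for c in subjects:
                run = cur.get(c, 0) + 1 if last.get(c) == w - 1 else 1
                cur[c] = run
                last[c] = w
                if run > best.get(c, 0):
                    best[c] = run
        return best


def _required_run(read_len: int, min_identity: float,
                  min_read_coverage: float, k: int) -> int:
    """Minimum window streak any hit passing the filters must exhibit.

    A kept hit aligns at least ceil(c*L) read characters with at most
    A = floor((1-q)/q * L) non-match columns, so its match columns contain
    an exact common substring of length >= (c*L - A)/(A + 1).  The bound is
    relaxed by a two-window margin and never below a single shared k-mer.
    """
    if min_identity <= 0 or min_read_coverage <= 0:
        return 1
    A = math.floor((1.0 - min_identity) / min_identity * read_len)
    substring = (min_read_coverage * read_len - A) / (A + 1)
    return max(1, int(substring) - (k - 1) - 2)


def search(read: SimulatedRead | tuple[str, str] | str, db: ReferenceDB,
           scoring: ScoringScheme = DEFAULT_SCORING,
           min_bit: float = DEFAULT_MIN_BIT,
           min_identity: float = DEFAULT_MIN_IDENTITY,
           min_read_coverage: float = DEFAULT_MIN_READ_COVERAGE,
           index: KmerIndex | None = None) -> list[AlignmentHit]:
    """All strict-filter hits of one read against the database.

    Subjects must share an 11-mer with the read (seed prefilter) before
    being aligned; hits must pass the bit-score, identity and read-coverage
    filters jointly.  Hits come back sorted by descending bit score, ties by
    ascending accession.  An empty list is a valid result.
    """
    if len(db) == 0:
        raise ValueError("reference database is empty")
    read_id, seq = _read_parts(read)
    seq = seq.upper()
    if index is None:
        index = KmerIndex(db)
    runs = index.candidate_runs(seq)
    need = _required_run(len(seq), min_identity, min_read_coverage, index.k)
    hits: list[AlignmentHit] = []
    for subj_idx in sorted(runs):
        if runs[subj_idx] < need:
            continue
        rec = db.records[subj_idx]
        hit = _exact_substring_hit(seq, rec.sequence, scoring, read_id,
                                   rec.accession)
        if hit is None:
            hit = local_align(seq, rec.sequence, scoring, read_id, rec.accession)
        if (hit.bit_score >= min_bit and hit.identity >= min_identity
                and hit.aligned_read_fraction >= min_read_coverage):
            hits.append(hit)
    hits.sort(key=lambda h: (-h.bit_score, h.subject_accession))
    return hits


def _read_parts(read) -> tuple[str, str]:
    if isinstance(read, SimulatedRead):
        return read.read_id, read.sequence
    if isinstance(read, tuple):
        return read
    return "", read


# ---------------------------------------------------------------------------
# naive LCA

def naive_lca(hits: Sequence[AlignmentHit], db: ReferenceDB,
              top_percent: float = DEFAULT_TOP_PERCENT) -> AssignmentResult:
    """Assign the lowest rank on which all retained hits agree.

    Hits within ``top_percent`` of the best bit score are retained; the
    lineages of their subjects are intersected walking species -> genus ->
    family -> order.  A rank whose only shared label is "unknown" does not
    count as agreement.  Disagreement all the way to order leaves the read
    with similarity but no assignment.
    """
    if not hits:
        return AssignmentResult("", "no_hit")
    read_id = hits[0].read_id
    best = max(h.bit_score for h in hits)
    retained = [h for h in hits if h.bit_score >= (1.0 - top_percent) * best]
    lineages = []
    for h in retained:
        try:
            lineages.append(db.index[h.subject_accession].lineage)
        except KeyError:
            raise KeyError(f"hit subject {h.subject_accession!r} absent from database")
    for rank in Lineage.RANKS:
        labels = {lin.at(rank) for lin in lineages}
        if len(labels) == 1:
            label = labels.pop()
            if label != "unknown":
                return AssignmentResult(read_id, "assigned", label, rank,
                                        len(retained), best)
    return AssignmentResult(read_id, "hit_unassigned",
                            supporting_hits=len(retained), best_bit=best)


# ---------------------------------------------------------------------------
# library-level accounting

@dataclass(frozen=True)
class LibraryTally:
    n_total: int
    n_with_hit: int
    n_assigned: int

    @property
    def pct_with_hit(self) -> float:
        return 100.0 * self.n_with_hit / self.n_total if self.n_total else 0.0

    @property
    def pct_assigned(self) -> float:
        return 100.0 * self.n_assigned / self.n_total if self.n_total else 0.0


def classify_library(reads: Iterable, db: ReferenceDB,
                     scoring: ScoringScheme = DEFAULT_SCORING,
                     min_bit: float = DEFAULT_MIN_BIT,
                     min_identity: float = DEFAULT_MIN_IDENTITY,
                     min_read_coverage: float = DEFAULT_MIN_READ_COVERAGE,
                     top_percent: float = DEFAULT_TOP_PERCENT,
                     index: KmerIndex | None = None,
                     ) -> tuple[list[AssignmentResult], LibraryTally]:
    """Assign every read and tally statuses.

    A read counts as "with hit" when it shares at least one seed k-mer with
    some reference (similarity in the loose sense); it is "assigned" only
    when a strict-filter hit survives and the LCA resolves to a taxon.
    Reads with similarity whose hits fail the strict filters, or whose
    retained hits disagree at every rank, are "hit_unassigned".
    """
    if index is None:
        index = KmerIndex(db)
    results: list[AssignmentResult] = []
    n_with_hit = n_assigned = n_total = 0
    for read in reads:
        n_total += 1
        read_id, seq = _read_parts(read)
        hits = search(read, db, scoring, min_bit, min_identity,
                      min_read_coverage, index=index)
        res = naive_lca(hits, db, top_percent)
        if res.status == "no_hit":
            # similarity without a passing hit still counts as a hit
            if index.candidate_runs(seq.upper()):
                res = AssignmentResult(read_id, "hit_unassigned")
            else:
                res = replace(res, read_id=read_id)
        if res.status != "no_hit":
            n_with_hit += 1
        if res.status == "assigned":
            n_assigned += 1
        results.append(res)
    return results, LibraryTally(n_total, n_with_hit, n_assigned)


# ---------------------------------------------------------------------------
# read-length benchmark

@dataclass(frozen=True)
class LengthBenchmarkRow:
    length: int | str
    n_fragments: int
    pct_assigned_at_species: float
    species_tpr: float
    n_false_positive_species: int
    false_positive_species: tuple[str, ...] = ()


def length_benchmark(db: ReferenceDB, focal_species: Sequence[str],
                     lengths: Sequence[int | str],
                     scoring: ScoringScheme = DEFAULT_SCORING,
                     min_bit: float = DEFAULT_MIN_BIT,
                     min_identity: float = DEFAULT_MIN_IDENTITY,
                     min_read_coverage: float = DEFAULT_MIN_READ_COVERAGE,
                     top_percent: float = DEFAULT_TOP_PERCENT,
                     ) -> list[LengthBenchmarkRow]:
    """How well do fixed-length fragments of known species come back?

    One representative barcode per focal species is tiled into error-free
    fragments of each length (or taken whole for "full") and searched
    against the complete database.  Because an absolute bit-score floor is
    unreachable for reads shorter than it can express, the floor applied to
    each fragment is min(min_bit, bit score of a perfect match over 90% of
    the fragment); the identity and read-coverage filters are unchanged.

    Per length: the fraction of fragments assigned at species rank, the
    fraction of focal species recovered as themselves by at least one
    fragment, and the non-focal species that appear in any species-rank
    assignment (false positives).
    """
    focal = set(focal_species)
    db_species = set(db.species_labels())
    unknown = focal - db_species
    if unknown:
        raise ValueError(f"focal species not in database: {sorted(unknown)[:5]}")
    focal_reps = [rec for rec in db.representatives() if rec.lineage.species in focal]
    focal_db = ReferenceDB(focal_reps)
    index = KmerIndex(db)
    rows: list[LengthBenchmarkRow] = []
    for L in lengths:
        frags = fragment_references(focal_db, L, mode="tiling")
        n_species_rank = 0
        detected: set[str] = set()
        fp_species: set[str] = set()
        for frag in frags:
            floor = min(min_bit,
                        scoring.bit_score(scoring.match * 0.9 * frag.length))
            hits = search(frag, db, scoring, floor, min_identity,
                          min_read_coverage, index=index)
            res = naive_lca(hits, db, top_percent)
            if res.rank == "species":
                n_species_rank += 1
                if res.taxon == frag.truth_species:
                    detected.add(frag.truth_species)
                if res.taxon not in focal:
                    fp_species.add(res.taxon)
        n = len(frags)
        rows.append(LengthBenchmarkRow(
            L, n, 100.0 * n_species_rank / n if n else 0.0,
            len(detected) / len(focal) if focal else 0.0,
            len(fp_species), tuple(sorted(fp_species))))
    return rows
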
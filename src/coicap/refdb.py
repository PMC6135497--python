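"""Reference barcode database: model, import, curation, in-silico PCR.

The search target of the whole toolkit is a collection of species-labelled
COI barcode sequences, each carrying a four-rank lineage
(species -> genus -> family -> order).  This module models that collection,
imports it from FASTA (with taxonomy either tokenised in the headers or in a
sidecar TSV), summarises it, subsets and curates it, and extracts probe
amplicons by in-silico PCR with degenerate-aware primer matching.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

IUPAC_DNA = set("ACGTRYSWKMBDHVN")

# IUPAC code -> set of bases it denotes; used for primer-site matching
_IUPAC_SETS = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

# species labels that do not name a formal species
_UNNAMED_RE = re.compile(r"(\bsp\b\.?|_sp(_|\d|\.|$)|\bcf\b\.?|_cf(_|\.)|\baff\b\.?|_aff(_|\.))",
                         re.IGNORECASE)


class RefDbError(Exception):
    """Base class for reference-database errors."""


class HeaderParseError(RefDbError):
    pass


class DuplicateAccessionError(RefDbError):
    pass


class NoAmpliconError(RefDbError):
    """Raised when neither primer site is found within the mismatch budget."""


def normalize_label(label: str) -> str:
    """Canonical species/genus label: stripped, spaces folded to underscores."""
    return "_".join(label.strip().split())


def is_named_species(label: str) -> bool:
    """True unless the label carries an open-nomenclature tag (sp., cf., aff.)."""
    return _UNNAMED_RE.search(label) is None


@dataclass(frozen=True)
class Lineage:
    """Four-rank taxonomic lineage, species upward."""

    species: str
    genus: str
    family: str = "unknown"
    order: str = "unknown"

    RANKS = ("species", "genus", "family", "order")

    def __post_init__(self):
        if not self.species:
            raise ValueError("species label must be non-empty")
        if not self.genus:
            raise ValueError("genus label must be non-empty")

    def at(self, rank: str) -> str:
        return getattr(self, rank)


@dataclass(frozen=True)
class TaxonRecord:
    """One reference barcode: accession, lineage and its DNA sequence."""

    accession: str
    lineage: Lineage
    sequence: str

    def __post_init__(self):
        if not self.sequence:
            raise ValueError(f"{self.accession}: empty sequence")
        bad = set(self.sequence) - IUPAC_DNA
        if bad:
            raise ValueError(f"{self.accession}: non-IUPAC characters {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ImportReport:
    n_parsed: int = 0
    n_rejected_alphabet: int = 0
    n_rejected_n_fraction: int = 0
    warnings: tuple = ()


@dataclass
class ReferenceDB:
    """An ordered collection of :class:`TaxonRecord` with unique accessions."""

    records: list[TaxonRecord] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.index: dict[str, TaxonRecord] = {}
        for rec in self.records:
            if rec.accession in self.index:
                raise DuplicateAccessionError(rec.accession)
            self.index[rec.accession] = rec

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def species_labels(self) -> list[str]:
        seen: dict[str, None] = {}
        for rec in self.records:
            seen.setdefault(rec.lineage.species)
        return list(seen)

    def representatives(self) -> list[TaxonRecord]:
        """One record per species: the lowest accession, sorted by species."""
        best: dict[str, TaxonRecord] = {}
        for rec in self.records:
            sp = rec.lineage.species
            if sp not in best or rec.accession < best[sp].accession:
                best[sp] = rec
        return [best[sp] for sp in sorted(best)]


# ---------------------------------------------------------------------------
# import / export

def _record_from_parts(accession: str, lineage: Lineage, seq: str,
                       max_n_fraction: float) -> TaxonRecord | None:
    """Normalise and validate one entry; None means rejected."""
    seq = seq.upper().replace("U", "T")
    if set(seq) - IUPAC_DNA or not seq:
        return None
    if seq.count("N") > max_n_fraction * len(seq):
        return None
    return TaxonRecord(accession, lineage, seq)


def read_taxonomy_tsv(path: str | Path) -> dict[str, Lineage]:
    """Read an accession -> lineage map from a taxonomy TSV.

    Columns: accession, species, genus[, family[, order]]; missing upper
    ranks default to "unknown".
    """
    table: dict[str, Lineage] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise HeaderParseError(f"taxonomy row needs >= 3 columns: {line!r}")
        acc, species, genus = parts[0], normalize_label(parts[1]), normalize_label(parts[2])
        family = normalize_label(parts[3]) if len(parts) > 3 and parts[3] else "unknown"
        order = normalize_label(parts[4]) if len(parts) > 4 and parts[4] else "unknown"
        table[acc] = Lineage(species, genus, family, order)
    return table


def parse_reference_fasta(fasta_path: str | Path,
                          taxonomy: str | Path = "tokens",
                          max_n_fraction: float = 0.10) -> ReferenceDB:
    """Import a reference FASTA into a :class:`ReferenceDB`.

    ``taxonomy`` selects the header dialect: the literal string ``"tokens"``
    parses ``>accession Genus_species ...`` headers (genus taken as the first
    token of the species label); any other value is treated as the path of a
    sidecar taxonomy TSV, the canonical interchange format.

    Sequences are upper-cased and U folded to T.  Entries with characters
    outside the IUPAC alphabet, or with more than ``max_n_fraction`` N, are
    rejected; the counts are kept in ``db.meta["import_report"]``.
    """
    fasta_path = Path(fasta_path)
    if not fasta_path.exists():
        raise FileNotFoundError(fasta_path)
    sidecar = None if taxonomy == "tokens" else read_taxonomy_tsv(taxonomy)

    records: list[TaxonRecord] = []
    n_alpha = n_nfrac = 0
    warnings: list[str] = []
    for entry in SeqIO.parse(str(fasta_path), "fasta"):
        acc = entry.id
        if sidecar is not None:
            try:
                lineage = sidecar[acc]
            except KeyError:
                raise HeaderParseError(f"accession {acc!r} absent from taxonomy TSV")
        else:
            tokens = entry.description.split()
            if len(tokens) < 2:
                raise HeaderParseError(
                    f"header {entry.description!r} lacks a species token")
            # ">acc Genus_species" or ">acc Genus species ..." both resolve
            if "_" in tokens[1] or len(tokens) < 3:
                species = normalize_label(tokens[1])
            else:
                species = normalize_label("_".join(tokens[1:3]))
            genus = species.split("_")[0]
            lineage = Lineage(species, genus)
        seq = str(entry.seq).upper().replace("U", "T")
        if not seq or set(seq) - IUPAC_DNA:
            n_alpha += 1
            continue
        if seq.count("N") > max_n_fraction * len(seq):
            n_nfrac += 1
            continue
        records.append(TaxonRecord(acc, lineage, seq))
    if not records:
        warnings.append("empty reference database")
        logger.warning("parsed %s: no usable records", fasta_path)
    db = ReferenceDB(records)
    db.meta["import_report"] = ImportReport(
        n_parsed=len(records), n_rejected_alphabet=n_alpha,
        n_rejected_n_fraction=n_nfrac, warnings=tuple(warnings))
    if n_alpha or n_nfrac:
        logger.info("rejected %d records (alphabet) and %d (>%.0f%% N)",
                    n_alpha, n_nfrac, 100 * max_n_fraction)
    return db


def write_reference_fasta(db: ReferenceDB, fasta_path: str | Path,
                          taxonomy_path: str | Path | None = None) -> None:
    """Write the database as FASTA plus (optionally) its taxonomy TSV."""
    with open(fasta_path, "w") as fh:
        for rec in db.records:
            fh.write(f">{rec.accession} {rec.lineage.species}\n")
            for i in range(0, len(rec.sequence), 80):
                fh.write(rec.sequence[i:i + 80] + "\n")
    if taxonomy_path is not None:
        with open(taxonomy_path, "w") as fh:
            for rec in db.records:
                lin = rec.lineage
                fh.write("\t".join([rec.accession, lin.species, lin.genus,
                                    lin.family, lin.order]) + "\n")


# ---------------------------------------------------------------------------
# summaries, subsetting, curation

@dataclass(frozen=True)
class DbStats:
    n_sequences: int
    n_species: int
    n_named_species: int
    n_genera: int


def db_stats(db: ReferenceDB) -> DbStats:
    """Sequence/species/genus counts over distinct lineage labels."""
    species = {rec.lineage.species for rec in db.records}
    genera = {rec.lineage.genus for rec in db.records}
    named = {sp for sp in species if is_named_species(sp)}
    return DbStats(len(db), len(species), len(named), len(genera))


def subset_by_species_list(db: ReferenceDB, species: Iterable[str]) -> ReferenceDB:
    """Restrict the database to the given species labels.

    Labels are folded the same way as at import (case-insensitive,
    space/underscore-insensitive).  Labels that match no record are kept in
    ``subset.meta["missing_species"]``.
    """
    wanted = {normalize_label(s).lower(): normalize_label(s) for s in species}
    present: set[str] = set()
    kept = []
    for rec in db.records:
        key = rec.lineage.species.lower()
        if key in wanted:
            kept.append(rec)
            present.add(key)
    missing = [wanted[k] for k in wanted if k not in present]
    if missing:
        logger.warning("%d species labels not found in database", len(missing))
    sub = ReferenceDB(kept)
    sub.meta["missing_species"] = missing
    return sub


def curate(db: ReferenceDB, remove: Sequence[str] = (),
           add: Sequence[TaxonRecord] = ()) -> ReferenceDB:
    """Apply a manual curation list: drop accessions, append records.

    The curation log (one line per action, including removals requested for
    absent accessions) is kept in ``curated.meta["curation_log"]``.
    """
    log: list[str] = []
    drop = set(remove)
    kept = []
    for rec in db.records:
        if rec.accession in drop:
            log.append(f"removed {rec.accession} ({rec.lineage.species})")
            drop.discard(rec.accession)
        else:
            kept.append(rec)
    for acc in sorted(drop):
        log.append(f"remove requested but absent: {acc}")
    index = {rec.accession for rec in kept}
    for rec in add:
        if rec.accession in index:
            raise DuplicateAccessionError(rec.accession)
        kept.append(rec)
        index.add(rec.accession)
        log.append(f"added {rec.accession} ({rec.lineage.species})")
    out = ReferenceDB(kept)
    out.meta["curation_log"] = log
    return out


# ---------------------------------------------------------------------------
# in-silico PCR

def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def _primer_sites(template: str, primer: str, max_mismatch: int) -> list[int]:
    """Start offsets where the primer matches with <= max_mismatch mismatches.

    A position matches when the IUPAC base sets of primer and template
    intersect, so degenerate primers and ambiguous template bases pair up.
    """
    lp = len(primer)
    psets = [set(_IUPAC_SETS.get(c, "")) for c in primer]
    sites = []
    for start in range(len(template) - lp + 1):
        mm = 0
        for k in range(lp):
            tset = _IUPAC_SETS.get(template[start + k], "")
            if not psets[k].intersection(tset):
                mm += 1
                if mm > max_mismatch:
                    break
        else:
            sites.append(start)
    return sites


@dataclass(frozen=True)
class Amplicon:
    sequence: str
    start: int  # 0-based, inclusive (forward-primer start)
    end: int    # 0-based, exclusive (end of reverse-primer site)

    @property
    def length(self) -> int:
        return self.end - self.start


def extract_amplicon(record: TaxonRecord | str, fwd_primer: str, rev_primer: str,
                     max_mismatch: int = 2) -> Amplicon:
    """In-silico PCR: the product spanned by a primer pair, primers included.

    The forward primer is searched on the plus strand; the reverse primer is
    reverse-complemented and searched on the plus strand.  When several site
    pairs exist, the shortest product longer than twice the primer length
    wins (ties resolve to the left-most forward site).
    """
    if len(fwd_primer) < 15 or len(rev_primer) < 15:
        raise ValueError("primers must be at least 15 bp")
    if max_mismatch < 0:
        raise ValueError("max_mismatch must be >= 0")
    template = record.sequence if isinstance(record, TaxonRecord) else record.upper()
    fwd_sites = _primer_sites(template, fwd_primer.upper(), max_mismatch)
    rc_rev = reverse_complement(rev_primer.upper())
    rev_sites = _primer_sites(template, rc_rev, max_mismatch)
    if not fwd_sites or not rev_sites:
        raise NoAmpliconError(
            f"no {'forward' if not fwd_sites else 'reverse'} primer site within "
            f"{max_mismatch} mismatches")
    min_len = 2 * max(len(fwd_primer), len(rev_primer))
    best: Amplicon | None = None
    for f in fwd_sites:
        for r in rev_sites:
            end = r + len(rc_rev)
            length = end - f
            if length <= min_len:
                continue
            if best is None or length < best.length or (
                    length == best.length and f < best.start):
                best = Amplicon(template[f:end], f, end)
    if best is None:
        raise NoAmpliconError("primer sites found but no product above the "
                              "minimum length")
    return best
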
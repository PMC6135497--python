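"""End-to-end workflow: demultiplex, quality-filter, assign, quantify.

The pipeline mirrors how a capture-metabarcoding sequencing run is turned
into species profiles: reads are routed to samples by an exact 6-bp internal
index, discarded when their mean Phred quality falls below 30, searched
against the reference database under the strict filters, assigned by naive
LCA, and summarised as per-sample profiles.  When a truth composition is
supplied (e.g. a mock community identified larva-by-larva), the maxSSS read
count threshold is computed, applied, and the thresholded profile compared
to the truth.

Adapter trimming is delegated to external tools; the pipeline expects
already-trimmed Phred+33 FASTQ.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO

from .assign import (DEFAULT_MIN_BIT, DEFAULT_MIN_IDENTITY,
                     DEFAULT_MIN_READ_COVERAGE, DEFAULT_TOP_PERCENT,
                     DEFAULT_SCORING, AssignmentResult, KmerIndex,
                     LibraryTally, ScoringScheme, classify_library)
from .quantify import (CommunityProfile, ComparisonReport, ThresholdResult,
                       apply_threshold, compare_profiles, maxsss_threshold,
                       profile_from_assignments)
from .refdb import ReferenceDB, parse_reference_fasta

logger = logging.getLogger(__name__)

INDEX_LENGTH = 6


class ConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    """Everything the end-to-end run needs; thresholds default to the
    strict-assignment values (bit 230, identity 99%, mean Q30)."""

    db_path: str | Path
    taxonomy: str | Path = "tokens"
    probe_path: str | Path | None = None
    index_map: dict[str, str] = field(default_factory=dict)
    min_mean_q: float = 30.0
    scoring: ScoringScheme = field(default_factory=ScoringScheme)
    min_bit: float = DEFAULT_MIN_BIT
    min_identity: float = DEFAULT_MIN_IDENTITY
    min_read_coverage: float = DEFAULT_MIN_READ_COVERAGE
    top_percent: float = DEFAULT_TOP_PERCENT
    seed: int = 0

    def __post_init__(self):
        for idx in self.index_map:
            if len(idx) != INDEX_LENGTH:
                raise ConfigError(f"index {idx!r} is not {INDEX_LENGTH} bp")
        samples = list(self.index_map.values())
        if len(set(self.index_map)) != len(self.index_map):
            raise ConfigError("duplicate demultiplexing index")
        if not 0 < self.min_identity <= 1:
            raise ConfigError("min_identity must be in (0, 1]")
        if self.min_mean_q < 0:
            raise ConfigError("min_mean_q must be >= 0")


@dataclass
class FastqRead:
    read_id: str
    sequence: str
    qualities: list[int]

    def mean_quality(self) -> float:
        return sum(self.qualities) / len(self.qualities) if self.qualities else 0.0


def read_fastq(path: str | Path) -> Iterator[FastqRead]:
    """Stream a Phred+33 FASTQ file."""
    for rec in SeqIO.parse(str(path), "fastq"):
        yield FastqRead(rec.id, str(rec.seq).upper(),
                        rec.letter_annotations["phred_quality"])


def demultiplex(reads: Iterable[FastqRead],
                index_map: dict[str, str]) -> dict[str, list[FastqRead]]:
    """Route reads to samples by exact match of their first 6 bases.

    The matched index is trimmed from sequence and qualities.  Reads whose
    prefix matches no index (including reads shorter than the index) land in
    the ``"unassigned"`` bin.  Every read lands in exactly one bin.
    """
    # several indexes may map to one sample; duplicate indexes are already
    # impossible as dict keys
    bins: dict[str, list[FastqRead]] = {s: [] for s in index_map.values()}
    bins["unassigned"] = []
    for read in reads:
        prefix = read.sequence[:INDEX_LENGTH]
        sample = index_map.get(prefix)
        if sample is None or len(read.sequence) < INDEX_LENGTH:
            bins["unassigned"].append(read)
        else:
            bins[sample].append(FastqRead(read.read_id,
                                          read.sequence[INDEX_LENGTH:],
                                          read.qualities[INDEX_LENGTH:]))
    return bins


def quality_filter(reads: Iterable[FastqRead],
                   min_mean_q: float = 30.0) -> tuple[list[FastqRead], int]:
    """Keep reads whose arithmetic mean Phred score is >= the floor."""
    kept: list[FastqRead] = []
    n_discarded = 0
    for read in reads:
        if len(read.qualities) != len(read.sequence):
            raise ValueError(f"{read.read_id}: quality/sequence length mismatch")
        if read.mean_quality() >= min_mean_q:
            kept.append(read)
        else:
            n_discarded += 1
    return kept, n_discarded


def read_truth_tsv(path: str | Path) -> dict[str, dict[str, int]]:
    """Truth composition TSV: ``species<TAB>count`` rows (applied to every
    sample) or ``sample<TAB>species<TAB>count`` rows."""
    per_sample: dict[str, dict[str, int]] = {}
    shared: dict[str, int] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) == 2:
            shared[parts[0]] = shared.get(parts[0], 0) + int(parts[1])
        elif len(parts) == 3:
            per_sample.setdefault(parts[0], {})
            per_sample[parts[0]][parts[1]] = int(parts[2])
        else:
            raise ValueError(f"truth row needs 2 or 3 columns: {line!r}")
    if shared and per_sample:
        raise ValueError("truth TSV mixes 2- and 3-column rows")
    return per_sample if per_sample else {"*": shared}


@dataclass
class SampleResult:
    sample: str
    n_input: int
    n_q30_kept: int
    tally: LibraryTally
    assignments: list[AssignmentResult]
    profile: CommunityProfile
    threshold: ThresholdResult | None = None
    thresholded_profile: CommunityProfile | None = None
    comparison: ComparisonReport | None = None


@dataclass
class PipelineResult:
    samples: dict[str, SampleResult]
    n_input_reads: int
    n_unassigned_index: int
    ledger: list[str]


def run_pipeline(config: PipelineConfig, fastq_path: str | Path,
                 truth_path: str | Path | None = None) -> PipelineResult:
    """Run demultiplex -> Q30 filter -> search/LCA -> profile (-> maxSSS).

    The per-stage read-count ledger (input, per-sample demultiplexed,
    quality-kept, with-hit, assigned) is returned and logged, so read
    conservation can be audited at every stage.
    """
    db = parse_reference_fasta(config.db_path, config.taxonomy)
    if len(db) == 0:
        raise ConfigError(f"reference database {config.db_path} is empty")
    index = KmerIndex(db)
    truth = read_truth_tsv(truth_path) if truth_path else {}

    reads = list(read_fastq(fastq_path))
    ledger = [f"input\t{len(reads)}"]
    bins = demultiplex(reads, config.index_map) if config.index_map \
        else {"sample": reads, "unassigned": []}
    n_unassigned = len(bins.get("unassigned", []))
    ledger.append(f"demultiplex_unassigned\t{n_unassigned}")

    samples: dict[str, SampleResult] = {}
    for sample, sample_reads in bins.items():
        if sample == "unassigned":
            continue
        kept, n_discarded = quality_filter(sample_reads, config.min_mean_q)
        ledger.append(f"{sample}\tdemultiplexed\t{len(sample_reads)}")
        ledger.append(f"{sample}\tq{config.min_mean_q:g}_kept\t{len(kept)}")
        results, tally = classify_library(
            [(r.read_id, r.sequence) for r in kept], db,
            scoring=config.scoring, min_bit=config.min_bit,
            min_identity=config.min_identity,
            min_read_coverage=config.min_read_coverage,
            top_percent=config.top_percent, index=index)
        ledger.append(f"{sample}\twith_hit\t{tally.n_with_hit}")
        ledger.append(f"{sample}\tassigned\t{tally.n_assigned}")
        profile = profile_from_assignments(results)
        res = SampleResult(sample, len(sample_reads), len(kept), tally,
                           results, profile)
        sample_truth = truth.get(sample, truth.get("*"))
        if sample_truth and not profile.is_empty:
            truth_profile = CommunityProfile(dict(sample_truth))
            truth_species = truth_profile.species()
            if profile.species() - truth_species:
                thr = maxsss_threshold(profile.counts, truth_species)
                res.threshold = thr
                res.thresholded_profile = apply_threshold(profile, thr.t_star)
                ledger.append(f"{sample}\tmaxsss_threshold\t{thr.t_star}")
            else:
                # no truth-absent candidate: specificity (hence maxSSS) is
                # undefined, so the raw profile stands
                res.thresholded_profile = profile
                ledger.append(f"{sample}\tmaxsss_threshold\tundefined")
            res.comparison = compare_profiles(res.thresholded_profile,
                                              truth_profile)
        samples[sample] = res
    for line in ledger:
        logger.info("%s", line)
    return PipelineResult(samples, len(reads), n_unassigned, ledger)
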
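"""Synthetic data: read fragmentation, mock communities, synthetic clades.

Everything downstream of the reference database can be exercised without any
download: a two-level (genus/species) Jukes-Cantor clade generator emulates
the statistical structure of a regional barcode set with a controlled mean
pairwise divergence; a fragmenter cuts references into fixed-length reads
(the in-silico read-length benchmark); and a mock-community simulator draws
reads from a known species abundance vector, mimicking an equimolar pool of
individually identified DNAs sequenced after capture.

Every generator is a pure function of its arguments including the seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import brentq

from .refdb import Lineage, ReferenceDB, TaxonRecord

logger = logging.getLogger(__name__)

_BASES = "ACGT"


@dataclass(frozen=True)
class SimulatedRead:
    """A read cut from a known reference, with its truth label attached."""

    read_id: str
    source_accession: str
    source_species: str
    start: int
    length: int
    sequence: str
    truth_species: str

    def __post_init__(self):
        if len(self.sequence) != self.length:
            raise ValueError("sequence length disagrees with stated length")


@dataclass
class MockCommunity:
    """Species relative abundances plus the references they are drawn from."""

    members: dict[str, float]
    source: ReferenceDB

    def __post_init__(self):
        if not self.members:
            raise ValueError("community has no members")
        total = sum(self.members.values())
        if any(v <= 0 for v in self.members.values()):
            raise ValueError("abundances must be positive")
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"abundances sum to {total}, not 1")
        by_species: dict[str, list[TaxonRecord]] = {}
        for rec in self.source.records:
            by_species.setdefault(rec.lineage.species, []).append(rec)
        for sp in self.members:
            if sp not in by_species:
                raise ValueError(f"member {sp!r} has no source sequence")
        self._by_species = by_species

    @classmethod
    def from_abundances(cls, db: ReferenceDB, abundances: dict[str, float]) -> "MockCommunity":
        total = sum(abundances.values())
        members = {sp: a / total for sp, a in abundances.items()}
        from .refdb import subset_by_species_list
        return cls(members, subset_by_species_list(db, list(members)))

    @classmethod
    def equimolar(cls, db: ReferenceDB, species: Iterable[str]) -> "MockCommunity":
        species = list(species)
        return cls.from_abundances(db, {sp: 1.0 for sp in species})


# ---------------------------------------------------------------------------
# fragmentation

def _tiling_starts(seq_len: int, read_length: int, step: int) -> list[int]:
    starts = list(range(0, seq_len - read_length + 1, step))
    flush = seq_len - read_length
    if starts[-1] != flush:
        starts.append(flush)
    return starts


def fragment_references(db: ReferenceDB, read_length: int | str,
                        mode: str = "tiling", step: int | None = None,
                        n_per_seq: int = 1, seed: int = 0) -> list[SimulatedRead]:
    """Cut every reference into error-free fragments of a fixed length.

    ``read_length`` may be the string ``"full"`` (one read per sequence).
    Tiling places windows at offsets 0, step, 2*step, ... plus a final window
    flush with the 3' end, so every base is covered when step <= read_length.
    Random mode draws ``n_per_seq`` uniform start positions per sequence from
    the seeded generator.  Sequences shorter than the read length are skipped
    and counted in the log.
    """
    reads: list[SimulatedRead] = []
    rng = np.random.default_rng(seed)
    n_skipped = 0
    for rec in db.records:
        if read_length == "full":
            reads.append(SimulatedRead(
                f"{rec.accession}|0|{rec.length}", rec.accession,
                rec.lineage.species, 0, rec.length, rec.sequence,
                rec.lineage.species))
            continue
        L = int(read_length)
        if rec.length < L:
            n_skipped += 1
            continue
        if mode == "tiling":
            eff_step = step if step is not None else L
            if eff_step <= 0:
                raise ValueError("step must be positive")
            starts = _tiling_starts(rec.length, L, eff_step)
        elif mode == "random":
            if n_per_seq <= 0:
                raise ValueError("n_per_seq must be positive in random mode")
            starts = sorted(int(s) for s in
                            rng.integers(0, rec.length - L + 1, size=n_per_seq))
        else:
            raise ValueError(f"unknown mode {mode!r}")
        for k, s in enumerate(starts):
            reads.append(SimulatedRead(
                f"{rec.accession}|{s}|{L}|{k}", rec.accession,
                rec.lineage.species, s, L, rec.sequence[s:s + L],
                rec.lineage.species))
    if n_skipped:
        logger.info("skipped %d sequences shorter than %s bp", n_skipped, read_length)
    return reads


# ---------------------------------------------------------------------------
# mock-community reads

def _mutate(seq: str, error_rate: float, rng: np.random.Generator) -> str:
    """Apply i.i.d. substitutions, uniform over the three alternative bases."""
    if error_rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hit = np.nonzero(rng.random(arr.shape[0]) < error_rate)[0]
    if hit.size == 0:
        return seq
    code = {65: 0, 67: 1, 71: 2, 84: 3}
    back = np.frombuffer(b"ACGT", dtype=np.uint8)
    for i in hit:
        old = code.get(int(arr[i]))
        if old is None:  # leave ambiguity codes untouched
            continue
        arr[i] = back[(old + 1 + rng.integers(0, 3)) % 4]
    return arr.tobytes().decode()


def simulate_community_reads(community: MockCommunity, n_reads: int,
                             read_length: int, error_rate: float = 0.0,
                             seed: int = 0) -> list[SimulatedRead]:
    """Draw reads from a mock community's abundance vector.

    Species counts are multinomial in the abundances; the source record per
    read is uniform among that species' sequences; start positions are
    uniform; substitution errors are i.i.d. per base.
    """
    if n_reads <= 0:
        raise ValueError("n_reads must be positive")
    if not 0 <= error_rate < 0.25:
        raise ValueError("error_rate must be in [0, 0.25)")
    rng = np.random.default_rng(seed)
    species = sorted(community.members)
    probs = np.array([community.members[sp] for sp in species])
    counts = rng.multinomial(n_reads, probs)
    reads: list[SimulatedRead] = []
    idx = 0
    for sp, k in zip(species, counts):
        sources = [r for r in community._by_species[sp] if r.length >= read_length]
        if not sources:
            raise ValueError(f"no source of {sp!r} is >= {read_length} bp")
        for _ in range(int(k)):
            rec = sources[int(rng.integers(0, len(sources)))]
            start = int(rng.integers(0, rec.length - read_length + 1))
            frag = _mutate(rec.sequence[start:start + read_length], error_rate, rng)
            reads.append(SimulatedRead(
                f"read{idx:06d}", rec.accession, sp, start, read_length, frag, sp))
            idx += 1
    return reads


# ---------------------------------------------------------------------------
# synthetic clades

def _jc_expected_p(path_length: float) -> float:
    """Expected p-distance between two sequences separated by this path."""
    return 0.75 * (1.0 - np.exp(-4.0 * path_length / 3.0))


def _jc_evolve(parent: np.ndarray, t: float, rng: np.random.Generator,
               fixed_count: bool = False) -> np.ndarray:
    """Jukes-Cantor transition over branch length t (subs/site).

    Each site changes with the exact JC probability (3/4)(1 - e^(-4t/3)),
    uniformly to one of the three other bases; chains of such transitions
    compose exactly (the JC semigroup).  With ``fixed_count`` the number of
    changed sites is conditioned on its expectation (rounded), which keeps
    realized divergences tight around the calibrated target without
    changing per-site marginals beyond rounding.
    """
    if t <= 0:
        return parent.copy()
    p_change = 0.75 * (1.0 - np.exp(-4.0 * t / 3.0))
    child = parent.copy()
    L = parent.shape[0]
    if fixed_count:
        k = int(round(L * p_change))
        hit = rng.choice(L, size=k, replace=False)
    else:
        hit = np.nonzero(rng.random(L) < p_change)[0]
    child[hit] = (child[hit] + 1 + rng.integers(0, 3, size=hit.size)) % 4
    return child


def generate_synthetic_clade(n_species: int, seq_length: int = 650,
                             mean_pairwise_distance: float = 0.2,
                             n_genera: int | None = None,
                             seed: int = 0) -> ReferenceDB:
    """A species-labelled barcode set with a controlled mean divergence.

    Species hang off genus ancestors which hang off a single root (a star of
    stars).  Branch lengths are calibrated analytically so the expected mean
    pairwise p-distance over all species pairs equals the target; the
    species-level branch is a quarter of the genus-level branch, giving
    congeners roughly 40% of the cross-genus divergence.  A target of 0
    returns identical sequences.
    """
    if n_species < 2:
        raise ValueError("need at least two species")
    if not 0 <= mean_pairwise_distance < 0.6:
        raise ValueError("mean pairwise distance must be in [0, 0.6)")
    if n_genera is None:
        n_genera = max(2, -(-n_species // 3))
    n_genera = min(n_genera, n_species)

    genus_of = [i % n_genera for i in range(n_species)]
    n_within = sum(1 for i in range(n_species) for j in range(i + 1, n_species)
                   if genus_of[i] == genus_of[j])
    n_pairs = n_species * (n_species - 1) // 2
    n_cross = n_pairs - n_within

    ratio = 0.25  # species branch / genus branch

    def expected_mean(tg: float) -> float:
        ts = ratio * tg
        within = _jc_expected_p(2 * ts)
        cross = _jc_expected_p(2 * (tg + ts))
        return (n_within * within + n_cross * cross) / n_pairs

    if mean_pairwise_distance == 0:
        tg = 0.0
    else:
        tg = brentq(lambda t: expected_mean(t) - mean_pairwise_distance, 1e-9, 50.0)
    ts = ratio * tg

    rng = np.random.default_rng(seed)
    root = rng.integers(0, 4, size=seq_length).astype(np.int64)
    genus_seqs = [_jc_evolve(root, tg, rng, fixed_count=True)
                  for _ in range(n_genera)]
    records = []
    for i in range(n_species):
        g = genus_of[i]
        arr = _jc_evolve(genus_seqs[g], ts, rng, fixed_count=True)
        seq = "".join(_BASES[c] for c in arr)
        lineage = Lineage(species=f"Genus{g:02d}_species{i:03d}",
                          genus=f"Genus{g:02d}",
                          family=f"Family{g % max(1, n_genera // 2):02d}",
                          order="Order00")
        records.append(TaxonRecord(f"SYN{i:05d}", lineage, seq))
    return ReferenceDB(records)


# ---------------------------------------------------------------------------
# writers

def reads_to_fasta(reads: Sequence[SimulatedRead], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f">{r.read_id}\n{r.sequence}\n")


def reads_to_fastq(reads: Sequence[SimulatedRead], path: str | Path,
                   quality: int = 40, index: str = "") -> None:
    """Write reads as Phred+33 FASTQ with constant qualities.

    ``index`` optionally prepends a demultiplexing index to every read.
    """
    qchar = chr(quality + 33)
    with open(path, "w") as fh:
        for r in reads:
            seq = index + r.sequence
            fh.write(f"@{r.read_id}\n{seq}\n+\n{qchar * len(seq)}\n")


def truth_table_to_tsv(reads: Sequence[SimulatedRead], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\ttruth_species\tsource_accession\tstart\tlength\n")
        for r in reads:
            fh.write(f"{r.read_id}\t{r.truth_species}\t{r.source_accession}\t"
                     f"{r.start}\t{r.length}\n")
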
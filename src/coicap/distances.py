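"""Pairwise genetic distances and probe equidistance reports.

A good capture probe for a whole clade is one that is *equally* divergent
from every target barcode: hybridisation efficiency falls with divergence,
so an equidistant probe enriches all species with comparable efficiency and
keeps relative read counts quantitative.  This module computes pairwise
p-distances and Jukes-Cantor (1969) corrected distances from per-pair global
alignments, summarises a candidate probe's distance profile (mean, SD,
coefficient of variation, maximum), ranks candidate probes by equidistance,
and measures the average spacing of segregating sites between species — the
quantity that sets how informative a short read is.

Distances use pairwise deletion: alignment columns containing a gap or an
ambiguity code are excluded from both the compared-site and the difference
counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from . import _align
from .refdb import ReferenceDB


class SaturationError(ValueError):
    """p-distance at or beyond the Jukes-Cantor pole (p >= 0.75)."""


class ZeroComparableSitesError(ValueError):
    """No alignment column where both sequences carry an unambiguous base."""


@dataclass(frozen=True)
class PairwiseAlignment:
    """A gapped pairwise alignment with pairwise-deletion site counts."""

    aligned_a: str
    aligned_b: str
    n_compared_sites: int
    n_differences: int
    score: int = 0

    def __post_init__(self):
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("gapped sequences differ in length")
        if self.n_differences > self.n_compared_sites:
            raise ValueError("more differences than compared sites")


DEFAULT_MATCH, DEFAULT_MISMATCH, DEFAULT_GAP = 1, -1, -2
_ACGT = frozenset("ACGT")


def global_align(a: str, b: str, match: int = DEFAULT_MATCH,
                 mismatch: int = DEFAULT_MISMATCH,
                 gap: int = DEFAULT_GAP) -> PairwiseAlignment:
    """Optimal global alignment with free end gaps (linear gap cost).

    Tie-breaks are deterministic: a substitution is preferred over a gap,
    and a gap in ``a`` over a gap in ``b``.  End gaps are unpenalised, which
    suits barcodes trimmed to slightly different windows.
    """
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    a, b = a.upper(), b.upper()
    score, a_idx, b_idx = _align.nw_align(_align.encode(a), _align.encode(b),
                                          match, mismatch, gap)
    ga = "".join("-" if i < 0 else a[i] for i in a_idx)
    gb = "".join("-" if j < 0 else b[j] for j in b_idx)
    compared = diffs = 0
    for ca, cb in zip(ga, gb):
        if ca in _ACGT and cb in _ACGT:
            compared += 1
            if ca != cb:
                diffs += 1
    return PairwiseAlignment(ga, gb, compared, diffs, score)


def p_distance(aln: PairwiseAlignment) -> float:
    """Proportion of differing sites under pairwise deletion."""
    if aln.n_compared_sites == 0:
        raise ZeroComparableSitesError("no comparable (unambiguous, ungapped) sites")
    return aln.n_differences / aln.n_compared_sites


def jc69(p: float) -> float:
    """Jukes-Cantor 1969 correction, d = -(3/4) ln(1 - 4p/3).

    Valid for 0 <= p < 0.75; beyond that the expected-substitution distance
    is undefined (saturation).
    """
    if p < 0:
        raise ValueError("p-distance cannot be negative")
    if p >= 0.75:
        raise SaturationError(f"p = {p} is at or beyond the JC69 pole (0.75)")
    return -0.75 * math.log1p(-4.0 * p / 3.0)


@dataclass(frozen=True)
class ProbeReport:
    """Distance profile of one candidate probe against a target clade."""

    probe_id: str
    per_species_distance: dict[str, float]
    mean: float
    sd: float
    cv_percent: float
    max_distance: float

    def sort_key(self):
        return (self.cv_percent, self.max_distance, self.mean)


def probe_report(probe: str, targets: ReferenceDB,
                 probe_id: str = "probe") -> ProbeReport:
    """JC69 distance of a probe to one representative barcode per species.

    The representative is the record with the lowest accession.  The
    coefficient of variation uses the sample SD (n-1 denominator); a probe
    identical to every target reports CV 0.
    """
    reps = targets.representatives()
    if len(reps) < 2:
        raise ValueError("need at least two target species")
    dists: dict[str, float] = {}
    for rec in reps:
        try:
            dists[rec.lineage.species] = jc69(p_distance(global_align(probe, rec.sequence)))
        except (SaturationError, ZeroComparableSitesError) as exc:
            raise type(exc)(f"{rec.lineage.species}: {exc}") from exc
    return report_from_distances(probe_id, dists)


def report_from_distances(probe_id: str,
                          per_species_distance: dict[str, float]) -> ProbeReport:
    """Summarise a per-species distance profile (mean, sample SD, CV%, max).

    A probe at the same distance from every target has CV 0; so does, by
    convention, a probe at distance 0 from everything.
    """
    if len(per_species_distance) < 2:
        raise ValueError("need at least two target species")
    values = np.array(list(per_species_distance.values()))
    mean = float(values.mean())
    sd = float(values.std(ddof=1))
    cv = 100.0 * sd / mean if mean > 0 else 0.0
    return ProbeReport(probe_id, dict(per_species_distance), mean, sd, cv,
                       float(values.max()))


def rank_probes(candidates: Sequence[tuple[str, str]],
                targets: ReferenceDB) -> list[ProbeReport]:
    """Rank candidate probes by equidistance: ascending CV, then max, then mean."""
    if not candidates:
        raise ValueError("need at least one candidate probe")
    reports = [probe_report(seq, targets, probe_id=pid) for pid, seq in candidates]
    return sorted(reports, key=ProbeReport.sort_key)


@dataclass(frozen=True)
class SpacingReport:
    """Average density and spacing of segregating sites between species."""

    mean_density: float       # differences per compared bp, averaged over pairs
    mean_spacing: float       # bp per difference; inf when no pair differs
    n_pairs: int


def segregating_site_spacing(targets: ReferenceDB) -> SpacingReport:
    """All-pairs divergence density across species representatives.

    Identical pairs contribute density 0 and are included in the average.
    """
    reps = targets.representatives()
    if len(reps) < 2:
        raise ValueError("need at least two species")
    densities = []
    for i in range(len(reps)):
        for j in range(i + 1, len(reps)):
            aln = global_align(reps[i].sequence, reps[j].sequence)
            densities.append(p_distance(aln))
    mean_density = float(np.mean(densities))
    spacing = 1.0 / mean_density if mean_density > 0 else math.inf
    return SpacingReport(mean_density, spacing, len(densities))
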
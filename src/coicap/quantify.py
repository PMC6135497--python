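"""Species profiles, presence thresholding, frequency comparison, rarefaction.

Species-rank read counts become relative frequencies; a per-library minimum
read-count threshold is chosen by maximising sensitivity + specificity
against a known (mock) composition (the maxSSS criterion on the ROC curve of
"present iff count >= t"); thresholded profiles are compared to the truth by
Pearson correlation and presence sensitivity/specificity; rarefaction curves
give the expected species richness at reduced sequencing depth (both by
seeded subsampling and by the exact hypergeometric expectation); and capture
efficiency is summarised as the X-fold enrichment of on-target read
percentages over an unenriched library.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.special import gammaln
from scipy.stats import pearsonr

from .assign import AssignmentResult

logger = logging.getLogger(__name__)


@dataclass
class CommunityProfile:
    """Per-species read counts and relative frequencies for one library."""

    counts: dict[str, int]
    is_empty: bool = False

    def __post_init__(self):
        if any(c < 0 for c in self.counts.values()):
            raise ValueError("counts must be non-negative")
        self.n_assigned = sum(self.counts.values())
        self.is_empty = self.n_assigned == 0
        if self.is_empty:
            self.frequencies: dict[str, float] = {}
        else:
            self.frequencies = {sp: c / self.n_assigned
                                for sp, c in self.counts.items()}

    def species(self) -> set[str]:
        return {sp for sp, c in self.counts.items() if c > 0}


def profile_from_assignments(results: Iterable[AssignmentResult]) -> CommunityProfile:
    """Count species-rank assignments only; higher-rank calls are ignored."""
    counts: dict[str, int] = {}
    for res in results:
        if res.status == "assigned" and res.rank == "species":
            counts[res.taxon] = counts.get(res.taxon, 0) + 1
    profile = CommunityProfile(counts)
    if profile.is_empty:
        logger.warning("no species-rank assignments: empty profile")
    return profile


# ---------------------------------------------------------------------------
# maxSSS presence threshold

@dataclass(frozen=True)
class ThresholdResult:
    candidate_thresholds: tuple[int, ...]
    sens_at: dict[int, float]
    spec_at: dict[int, float]
    t_star: int
    sss_max: float


def maxsss_threshold(counts: Mapping[str, int],
                     truth_present: Iterable[str]) -> ThresholdResult:
    """Minimum read count for presence, by maximum sensitivity + specificity.

    ``counts`` must cover every candidate species (truth species absent from
    the library are implicitly at count 0).  A species is called present
    when its count >= t; candidate thresholds are the distinct observed
    counts plus max + 1 (call everything absent).  Ties resolve to the
    smallest threshold, the most sensitive call.
    """
    truth = set(truth_present)
    candidates = set(counts) | truth
    absent = candidates - truth
    if not truth:
        raise ValueError("truth set is empty")
    if not absent:
        raise ValueError("specificity undefined: every candidate species is "
                         "in the truth set")
    full_counts = {sp: int(counts.get(sp, 0)) for sp in candidates}
    values = sorted(set(full_counts.values()))
    thresholds = tuple(values + [max(values) + 1])
    sens_at: dict[int, float] = {}
    spec_at: dict[int, float] = {}
    best_t, best_sss = thresholds[0], -1.0
    for t in thresholds:
        present = {sp for sp, c in full_counts.items() if c >= t}
        tp = len(present & truth)
        fn = len(truth) - tp
        fp = len(present & absent)
        tn = len(absent) - fp
        sens = tp / (tp + fn)
        spec = tn / (tn + fp)
        sens_at[t] = sens
        spec_at[t] = spec
        if sens + spec > best_sss + 1e-12:
            best_sss = sens + spec
            best_t = t
    return ThresholdResult(thresholds, sens_at, spec_at, best_t, best_sss)


def apply_threshold(profile: CommunityProfile, t_star: int) -> CommunityProfile:
    """Drop species below the read-count threshold and renormalise."""
    if t_star < 0:
        raise ValueError("threshold must be >= 0")
    kept = {sp: c for sp, c in profile.counts.items() if c >= t_star and c > 0}
    out = CommunityProfile(kept)
    if out.is_empty and not profile.is_empty:
        logger.warning("threshold %d removed every species", t_star)
    return out


# ---------------------------------------------------------------------------
# profile comparison

@dataclass(frozen=True)
class ComparisonReport:
    pearson_r: float | None      # None when either vector has zero variance
    n_pairs: int
    sensitivity: float
    specificity: float | None    # None when no truth-absent candidates exist
    false_positive_species: tuple[str, ...]
    false_negative_species: tuple[str, ...]


def compare_profiles(estimated: CommunityProfile,
                     truth: CommunityProfile) -> ComparisonReport:
    """Estimated vs true composition over the union of their species.

    Frequencies are paired over the species union with absentees at 0;
    presence sensitivity/specificity use truth presence as the reference.
    """
    union = sorted(estimated.species() | truth.species())
    if len(union) < 2:
        raise ValueError("need at least two species across the two profiles")
    est = np.array([estimated.frequencies.get(sp, 0.0) for sp in union])
    tru = np.array([truth.frequencies.get(sp, 0.0) for sp in union])
    if est.std() == 0 or tru.std() == 0:
        r = None
    else:
        r = float(pearsonr(est, tru)[0])
    truth_set = truth.species()
    est_set = estimated.species()
    tp = len(est_set & truth_set)
    fn_set = truth_set - est_set
    fp_set = est_set - truth_set
    absent = set(union) - truth_set
    sens = tp / len(truth_set) if truth_set else 1.0
    spec = (len(absent - est_set) / len(absent)) if absent else None
    return ComparisonReport(r, len(union), sens, spec,
                            tuple(sorted(fp_set)), tuple(sorted(fn_set)))


# ---------------------------------------------------------------------------
# rarefaction

@dataclass(frozen=True)
class RarefactionCurve:
    depths: tuple[int, ...]
    mean_observed: tuple[float, ...]   # subsampling mean over replicates
    expected: tuple[float, ...]        # exact hypergeometric expectation


def _expected_richness(species_counts: np.ndarray, depth: int) -> float:
    """E[species seen in a without-replacement sample of ``depth`` reads].

    E[S_d] = sum_s 1 - C(N - n_s, d) / C(N, d), via log-gamma for stability.
    """
    N = int(species_counts.sum())
    total = 0.0
    for n_s in species_counts:
        if N - n_s < depth:
            total += 1.0
        else:
            log_miss = (gammaln(N - n_s + 1) - gammaln(N - n_s - depth + 1)
                        - gammaln(N + 1) + gammaln(N - depth + 1))
            total += 1.0 - math.exp(log_miss)
    return total


def rarefaction(species_labels_per_read: Sequence[str], depths: Sequence[int],
                n_replicates: int = 200, seed: int = 0) -> RarefactionCurve:
    """Species detected vs sequencing depth, without replacement.

    Returns both the subsampling mean over seeded replicates and the exact
    analytic expectation.  Sampling at the full depth returns the observed
    richness exactly.
    """
    labels = np.asarray(species_labels_per_read)
    N = labels.shape[0]
    if any(d > N for d in depths):
        raise ValueError("depth exceeds the number of reads")
    if any(d < 0 for d in depths):
        raise ValueError("depths must be non-negative")
    _, counts = np.unique(labels, return_counts=True)
    rng = np.random.default_rng(seed)
    means, expects = [], []
    for d in depths:
        expects.append(_expected_richness(counts, d))
        if d == N:
            means.append(float(counts.shape[0]))
            continue
        obs = [np.unique(labels[rng.choice(N, size=d, replace=False)]).shape[0]
               for _ in range(n_replicates)]
        means.append(float(np.mean(obs)))
    return RarefactionCurve(tuple(int(d) for d in depths),
                            tuple(means), tuple(expects))


# ---------------------------------------------------------------------------
# enrichment

def enrichment_fold(pct_hit_enriched: float, pct_hit_unenriched: float) -> float:
    """X-fold enrichment: ratio of on-target read percentages."""
    if pct_hit_unenriched <= 0:
        raise ValueError("unenriched on-target percentage must be positive")
    return pct_hit_enriched / pct_hit_unenriched
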
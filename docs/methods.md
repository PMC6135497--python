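# Methods

This note records the statistical model, the defaults and their rationale,
what the synthetic-data generator does and does not emulate, and the
numerical choices. Any number quoted here is computed by the test suite or
by `scripts/acceptance.py`; nothing is an empirical claim about real
sequencing data.

## Distance model

Pairwise distances use a free-end-gap (semi-global) Needleman–Wunsch
alignment (match +1, mismatch −1, gap −2; ties broken substitution >
gap-in-first > gap-in-second so alignments are deterministic). The
p-distance is mismatches over *comparable* columns: columns containing a
gap or an ambiguity code are excluded (pairwise deletion). Zero comparable
columns is an error, not a distance.

The Jukes–Cantor 1969 correction `d = −(3/4)·ln(1 − 4p/3)` assumes equal
base frequencies and a single substitution rate; it diverges as
`p → 3/4`, so `p ≥ 0.75` raises a saturation error rather than returning
a number. `d(p)` is strictly increasing and convex on `[0, 0.75)` and
`d ≈ p` for small `p` (tangent at the origin); both properties are tested
on a grid.

## Probe equidistance

A capture probe is scored against one representative barcode per species
(the record with the lexicographically smallest accession, so the choice
is deterministic). The report gives the mean, sample SD (n−1), coefficient
of variation (CV% = 100·SD/mean, defined as 0 when the mean is 0) and the
maximum of the per-species JC69 distances. Probes are ranked by ascending
CV, then maximum, then mean: a probe equally far from everything
hybridizes most evenly across the clade. Segregating-site spacing (mean
pairwise difference density and its reciprocal in bp per difference)
summarizes how informative the region is.

## Read assignment

Reads are aligned with an affine-gap Smith–Waterman (Gotoh) using a
BLASTN-like scheme: match +2, mismatch −3, gap of length `k` costs
`5 + 2k`. Raw scores are converted to bits with the Karlin–Altschul form
`(λS − ln K)/ln 2`, `λ = 0.625`, `K = 0.41`. Defaults and why:

| parameter | default | rationale |
|---|---|---|
| `min_bit` | 230 | a perfect 140 bp read scores ≈ 253.8 bits, a perfect 120 bp read ≈ 217.7, so the floor forces near-full-length alignment of ~140 bp reads |
| `min_identity` | 0.99 | at 140 aligned columns this allows at most one mismatch or gap (139/140 ≈ 0.993); congeners in a clade at mean divergence 0.2 sit far below it |
| `min_read_coverage` | 0.9 | at least 90% of the read's bases must be inside the local alignment, rejecting short high-identity islands |
| `top_percent` | 0.10 | hits within 10% of the best bit score enter the LCA band (MEGAN-style top-percent) |
| `k` (seed size) | 11 | smallest exact-match length guaranteed by the identity/coverage filters is far above 11 for 140 bp reads, so the seed never excludes a passable hit |

Identity is matches over aligned columns *including* gap columns; read
coverage is the fraction of read bases inside the local alignment.

The naive LCA keeps hits within the top-percent band and walks species →
genus → family → order, assigning the first rank on which all retained
subjects agree; the placeholder label "unknown" never counts as
agreement. Reads with band disagreement through order are counted as
"with hit" but unassigned. "With hit" itself means sharing at least one
11-mer seed with some reference — a deliberately loose similarity notion,
distinct from passing the strict filters.

### Seed prefilter soundness

For a read of length `L` under identity floor `q` and coverage floor `c`,
any passable alignment has at most `A = ⌊L·(1−q)/q⌋` non-match columns
spread over at least `c·L` read bases, so it contains an exact run of at
least `⌈(c·L − A)/(A + 1)⌉` bases; subjects are only aligned if they share
a consecutive k-mer streak at least that long (minus `k − 1`, with a
safety margin of 2). The prefilter therefore never discards a subject
that could pass the filters — verified by an exhaustive-alignment oracle
test. Error-free reads that occur verbatim in a subject take an exact
substring fast path whose score (2L) is the unique optimum.

## Quantification

Only species-rank assignments enter the community profile; counts are
renormalized to frequencies. The presence threshold `t*` maximizes
`sensitivity(t) + specificity(t)` over integer candidate thresholds drawn
from the observed counts and the truth set (a species is present iff its
count ≥ `t`; ties resolve to the smallest threshold). When every candidate
species is in the truth set, specificity is undefined and thresholding is
skipped (the pipeline notes this in its ledger) rather than silently
returning a value. Profile agreement is summarized by the Pearson
correlation of frequencies over the union of species (undefined and
reported as `None` under zero variance), sensitivity, specificity and
explicit false-positive/negative species lists.

Rarefaction uses the exact hypergeometric expectation
`E[S_d] = Σ_s (1 − C(N−n_s, d)/C(N, d))` evaluated with `gammaln` for
numerical range, cross-checked by seeded subsampling without replacement;
at `d = N` both return the observed richness exactly.

## What the generator emulates — and what it does not

`generate_synthetic_clade` builds a two-level star phylogeny (species
branches off genus ancestors off a single root) with exact Jukes–Cantor
transitions per branch. Branch lengths are calibrated by Brent
root-finding on the closed-form expected mean pairwise p-distance; the
species branch is fixed at ¼ of the genus branch so congeners are closer
than cross-genus pairs. The number of substituted sites per branch is
conditioned on its rounded expectation (variance reduction), which keeps
realized divergence within a few percent of the target without changing
per-site marginals beyond rounding.

It emulates: a species-labelled regional barcode set with controlled mean
divergence and genus structure; uniform fragment positions; i.i.d.
substitution sequencing error; multinomial read sampling from known
abundances; constant-quality Phred+33 FASTQ with a 6-bp demultiplexing
index.

It does not emulate: rate heterogeneity across sites or lineages, unequal
base composition, indel sequencing errors, quality-score profiles along
the read, chimeras, PCR/capture bias, contamination, or intraspecific
variation (one haplotype per species). Abundance recovery results on this
generator are therefore best-case: they demonstrate that the pipeline adds
no distortion of its own, not that real libraries behave this way.

## Numerical and engineering choices

- Dynamic-programming kernels are numba-compiled (`cache=True`) over int8
  sequence encodings (ACGT → 0–3; any ambiguity code → 4, which never
  matches anything). Traceback tie-breaks are fixed (diagonal > up > left;
  best cell = first strictly greater scanning rows then columns) so
  results are bit-reproducible across runs and platforms.
- All simulation randomness flows through `numpy.random.default_rng`
  seeded explicitly; every generator is a pure function of its arguments.
- The read-length benchmark cannot apply a 230-bit floor to fragments too
  short to express it, so each fragment's floor is
  `min(230, bits(match·0.9·L))` — the absolute floor whenever reachable,
  otherwise a 90%-of-perfect relative floor.
- File I/O (FASTA/FASTQ) uses Biopython; statistics use numpy/scipy.

## Limitations

- Assignment quality on synthetic clades bounds real-data performance
  from above (see generator scope).
- The LCA is the naive intersection; no weighting by bit score or
  E-value within the band.
- Demultiplexing is exact-match on the 6-bp index, with no mismatch
  tolerance or error correction.
- Single-end reads only; no pair merging, adapter trimming, or chimera
  detection — reads are assumed pre-trimmed.
- JC69 is the only substitution model offered for distances and for the
  clade generator.
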
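# Methods

## Absolute quantification model

The pipeline's central assumption is that a synthetic spike-in oligo added
to total RNA before library preparation experiences the same per-molecule
probability of ending up as a deduplicated read as an endogenous miRNA.
Under that assumption, with `spikein_added` moles of pool yielding
`spikein_reads` deduplicated reads, a feature with `miRNA_reads` reads
corresponds to

```
molecules per 10 pg total RNA
  = miRNA_reads × spikein_added(mol) × N_A × 10 / (spikein_reads × total_RNA_added(pg))
```

with N_A = 6.022 × 10²³. The estimate is exact in expectation only when
adapter-ligation efficiency is sequence-independent; with ligation bias the
recovered abundance is proportional to (true molecules × per-sequence
efficiency), which is why library chemistry that minimizes bias (randomized
adapter ends, crowding agents) is a precondition the simulator models
explicitly. Two normalization anchors are implemented: the default pools all
spike oligos (total moles / total reads — a ratio of sums robust to
single-oligo dropout), and a per-oligo mode averages each detected oligo's
own moles/reads scale. The two agree exactly for uniform counts and differ
under bias; the pooled mode is the package default.

Replicates are summarized as arithmetic mean ± sample SD (n−1 denominator),
with SD omitted at n = 1.

## Read model and processing rules

A raw read is `5′-UMI block + insert + 3′-UMI block + constant 3′ adapter`,
truncated to the read length (79 nt by default). Each UMI block is 15 nt:
three 3-nt random stretches interleaved with two fixed 3-nt anchors
(`NNN GTC NNN TAG NNN` on the 3′ adapter; `NNN CGA NNN TAC NNN` or
`NNN ATC NNN AGT NNN` on the 5′ adapter, one of the two variants chosen per
molecule). The combined UMI is therefore 18 nt.

Processing order and rules:

1. **Adapter trimming** — leftmost full occurrence of the 21-nt constant
   adapter; if absent, the longest adapter prefix (≥10 nt) terminating the
   read. Reads with no such match are rejected (`no_adapter`).
2. **UMI validation** — both fixed anchors in each block must match exactly
   (`bad_umi` otherwise). No UMI error correction is performed: duplicates
   are collapsed on exact (insert, UMI) identity, matching collapse on exact
   identifiers; 1-edit UMI merging would trade under-collapsing for
   over-collapsing and is deliberately not done.
3. **Insert length** — accepted range 14–54 nt (`length` otherwise).
4. **rRNA filtering** — an insert matching any decoy window on either strand
   with ≤1 mismatch is removed (the substring-Hamming analogue of a one-
   mismatch alignment against an rRNA database, at decoy-set scale).
5. **Spike-in counting** — exact, full-length, zero-mismatch equality; a
   read matching both a spike-in and a hairpin is counted as spike-in with a
   warning (impossible for simulated pools, which exclude hairpin
   substrings, but possible for user data).
6. **Hairpin mapping** — sense strand only; a hit needs zero mismatches or a
   single mismatch at the insert's final 3′ position (accommodating one
   non-templated 3′ nucleotide). Multi-mapping inserts take a deterministic
   winner: exact beats terminal-mismatch, then lowest hairpin id, then
   lowest start. Each read is counted once, keeping count sums conserved;
   the number of ambiguous inserts is reported in the processing stats. A
   `multimap=all` variant was considered and rejected because it breaks the
   conservation identity the stats table guarantees:
   `raw = no_adapter + bad_umi + length + pcr_duplicates + rrna_removed +
   spikein + unmapped + assigned`.
7. **5′ isomiR grouping** — deduplicated assigned reads sharing
   (hairpin, 5′ start) are one species; 3′ heterogeneity (trimming variants,
   non-templated additions) is deliberately collapsed. The mature annotation
   is attached when the 5′ start falls inside a mature interval; other
   placements are kept but unannotated.

Coordinates are 0-based half-open throughout; all sequences are DNA-alphabet
(T not U), as sequencers report.

## Synthetic data generator

The generator emulates the features of spike-in-doped small RNA libraries
that the processing rules exist to handle, with known truth for every one:

- **Sampling** — each feature's read probability is proportional to
  (molecules × ligation efficiency); efficiencies live in (0, 1]. Reads are
  drawn multinomially at the requested depth.
- **5′ isomiRs** — offsets around the annotated mature start, default
  distribution {−2: 0.05, −1: 0.15, 0: 0.60, +1: 0.15, +2: 0.05}; the
  empirical distribution is not pinned by any reference value, so this is a
  configurable default representing heterogeneity concentrated at the
  annotated position.
- **Non-templated additions** — with probability `nta_rate`, one nucleotide
  drawn uniformly from the three bases differing from the templated next
  hairpin position is appended. NTA is applied to miRNA inserts only:
  spike-in matching is exact by contract, so NTA'd spike reads would
  silently vanish from the normalization anchor. The reference generator
  keeps mature 3′ ends at least 2 nt inside the hairpin so a templated next
  base always exists.
- **PCR duplicates** — each sampled molecule is emitted 1 + Poisson(rate)
  times, duplicating the complete read including UMIs.
- **Repression datasets** — model value plus Gaussian noise, clipped to
  [0, 1.5]; the ceiling is above 1.0 because normalized levels exceeding the
  control occur in real noisy data.
- **Tissue panels** — background rows are log-uniform in [0.1, 300]
  molecules/10 pg, representing the low-abundance bulk of a tissue panel
  (most annotated miRNAs sit far below screening thresholds in every
  tissue); planted rows are set literally.

What the generator does **not** model: sequencing errors and quality scores,
adapter dimers, 3′ isomiR-specific biology beyond single NTAs, paired-end
reads, genome-scale references, and UMI saturation. Passing recovery tests
therefore demonstrates correctness of the counting and conversion logic
under the stated noise sources, not robustness to base-calling error or
reference incompleteness.

## Dose–response model

The normalized reporter level L at miRNA abundance c follows

```
L(c) = 1 / (1 + exp(slope × (IC50 − c)))
```

with slope ≤ 0, so L(0) ≈ 1 (unrepressed), L(IC50) = 0.5, and L → 0 at high
abundance. The fitted quantity is the **normalized reporter level** (control
= 1), the only orientation consistent with a non-positive slope producing a
curve that decreases with abundance. A helper normalizes raw reporter
abundances by the control reporter, each first divided by its transfected-
cell fraction.

The fit is bounded nonlinear least squares (Trust Region Reflective),
−100 ≤ slope ≤ 0 and 1 ≤ IC50 ≤ 10,000, at most 10,000 function
evaluations. Initialization: IC50 at the concentration whose observed level
is nearest 0.5; slope at −4/IC50 (the logistic transition-width heuristic).
Two uncertainty estimates are reported: the covariance-based SE from the
final Jacobian (which can blow up when the slope is unidentifiable, e.g.
when the transition falls between sparse doses) and the spread of IC50
across independent per-replicate fits. R² = 1 − SS_res/SS_tot; the raw value
(possibly negative) is stored, a clamped-at-zero copy is provided for
reporting, and flat data (zero variance) is flagged degenerate rather than
fitted. Requirements: ≥3 observations over ≥2 distinct concentrations.

## Screens

All screens use strict inequalities (a value exactly at a threshold fails)
on replicate-mean abundances. Defaults: on = 1700 and off = 340
molecules/10 pg for the specificity screens (the cleavage threshold for
highly expressed targets, and a five-fold margin below it), floor = 1000 and
ceiling = 300 for detargeting. When a tissue→group mapping is supplied
(e.g. eight brain regions → "brain"), a group is *on* when its maximum
member is, *off* only when every member is below the off threshold, and the
detargeting floor requires every member region above it — the conservative
direction in each case. An isomiR-collapse option sums rows sharing a family
name, since specificity conclusions may be drawn at the family level.

## Numerical choices and problem sizes

- Quantiles (bias IQR) use linear interpolation, the common statistical
  default.
- The per-nucleotide RNA residue mass in the mass-fraction mRNA route is
  340 g/mol (configurable); the spike-in route is the canonical one, and the
  two routes are only expected to agree within ~2× because they rest on
  independent assumptions (spike recovery vs mass bookkeeping).
- The exponent in the logistic is clipped at ±700 to avoid overflow.
- Recovery tests and the acceptance script use libraries of 10⁵ reads
  (50,000 for the replicate and bias runs), 12 hairpins / 20 mature
  features, 9- and 36-oligo spike pools, and 100 simulated dose–response
  datasets — sizes at which binomial error bands are tight enough to detect
  real defects while the full suite stays fast on one CPU.
- Recovery assertions use 3-standard-deviation bands derived from the
  binomial/multinomial sampling model (delta method for read-count ratios),
  not ad hoc tolerances.

## Known limitations

- The rRNA filter is substring-Hamming against a small decoy set, not an
  aligner against a full rRNA database; it shares the contract (≤1 mismatch,
  both strands) but not the scale.
- Hairpin mapping is exhaustive scanning, suitable for references of
  hundreds of hairpins, not genome-scale search.
- The mass-fraction mRNA route ignores non-rRNA/non-mRNA classes unless
  passed explicitly via `other_reads`.
- The dose–response covariance SE is unreliable near parameter bounds; the
  replicate-fit spread is the robust alternative and both are exposed.
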
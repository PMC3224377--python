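# Methods

## Elastic model of DNA

A base-pair step is a rigid-body transformation between consecutive base
pairs, parameterized by three translations (shift, slide, rise; Å) and
three rotations (tilt, roll, twist; degrees), in that fixed order
throughout the package. Around its sequence-dependent equilibrium μ the
step is treated harmonically: the 6×6 stiffness matrix is
Θ = kT·C⁻¹, with C the covariance of the helical parameters over a
conformational ensemble and kT = 0.593 kcal/mol at 298 K (configurable).
`stiffness_from_covariance` validates symmetry and positive
definiteness before inverting and symmetrizes the result to 1e-9.

Two summaries are built on the per-step model:

* **k_total** — the product of the six diagonal ("pure") stiffness
  constants. The six constants carry heterogeneous units, so the product
  is reported unitless-by-convention; it is a rough single-number
  ranking of step deformability (larger = stiffer), not an energy.
* **Deformation energy** — the cost of forcing a 147 bp window from its
  equilibrium into a target nucleosome-wrapped conformation:
  E = Σ over the 146 steps of ½ (xₛ−μₛ)ᵀ Θₛ (xₛ−μₛ), in kcal/mol.
  Because Θ is per-step, the window's 876×876 super-matrix is block
  diagonal and the quadratic form separates; the profile code
  pre-computes the ½(x−μ)ᵀΘ(x−μ) contribution of every (context, window
  position) pair and evaluates a genome as 146 shifted vector adds.
  The tests verify this against the explicit block-diagonal product.

**Strand symmetry.** Reading a step on the opposite strand reverses its
context and flips the signs of shift and tilt. Tables store only the 10
(dinucleotide) or 136 (tetramer) canonical contexts; `canonical_context`
resolves any context via its lexicographically smaller reverse
complement and the lookup applies the sign flips to μ and the
corresponding rows/columns of Θ. k_total is invariant under the flips.
Energy profiles of a reverse-complemented chromosome equal the
position-reversed originals *provided the target shape is dyad
symmetric* (roll/twist/rise even, tilt/shift odd about the centre) —
the packaged ideal shape is constructed that way.

**Context conventions.** At dinucleotide level step i has context
`seq[i:i+2]`; at tetramer level `seq[i-1:i+3]` (central-step
convention), so the two terminal steps of an isolated 147 bp window
have no tetramer context and are skipped — identically in
`deformation_energy` and `energy_profile`, which keeps the two routes
exactly consistent. Windows containing N get missing (NaN) energy;
missing values are never zero-filled.

## Stiffness table and target shape

The paper-grade MD-fitted parameter tables are not redistributable, so
the package ships a **synthetic** dinucleotide table
(`data/dinucleotide_stiffness_synthetic.tsv`, loaded by
`load_dinucleotide_table`) with literature-flavoured magnitudes:
translations ~1–3.6 kcal/mol/Å² (rise 3.8–8.4), rotations
~0.013–0.09 kcal/mol/deg², equilibrium twist 30.5–36.9°. Couplings are
confined to the strand-symmetric pairs (shift,tilt), (slide,rise),
(roll,twist), keeping every matrix SPD by diagonal dominance. Two
qualitative features are deliberate design goals rather than fits:
pyrimidine–purine steps (TA, CA, CG) are the softest, and A-tract steps
(AA, AT) are ~2.5× stiffer than average so that homopolymeric
poly(dA:dT) resists nucleosome wrapping — the property the
depleted-region prediction demonstrates. Tests never depend on
individual numbers, only on format and algebraic invariants. Users can
supply their own dinucleotide or tetramer TSV (same 28-column layout:
context, six equilibria, 21 upper-triangle Θ entries);
`tetramer_table_from_dinucleotide` expands a dinucleotide table to the
136 canonical tetramers by central-step inheritance for exercising the
tetramer machinery.

The target wrapped conformation is likewise an input, not a
computation. The packaged default (`NucleosomeShape.ideal()`) is an
idealized 146-step shape: roll = 6·cos and tilt = 3·sin of a 10.25 bp
period phase-locked to the dyad (bending direction rotating with the
helix), twist 34.3°, rise 3.32 Å, shift/slide 0. A structure-derived
146×6 TSV can be substituted.

## MNase read analysis

Reads are 0-based half-open intervals from BED6 or headerless SAM text.
A single-end read certifies only the fragment's 5′ cleavage: the cut at
coordinate i severs the bond 5′ of base i and its tetramer is
`genome[i-2:i+2]`, read on the fragment strand (reverse complement for
minus reads) and collapsed into one of 136 canonical pairs labelled
`"ABCD.WXYZ"` with the smaller member first. By default only 5′ ends
are counted (the 3′ read end is a sequencing-length artifact); 3′ or
both-end counting is available. Sites within 2 bp of a chromosome end
or containing N are skipped and tallied.

Enrichment per pair is ratio = (observed/sites)/p₀ against the raw
genomic 4-mer background (forward counts plus reverse-complement counts,
normalized), with a two-sided binomial p-value — exact for n ≤ 10⁵,
normal approximation with continuity correction beyond — floored at
1e-18 to mirror "< 10⁻¹⁸" reporting conventions.

Duplicate capping groups reads by (chrom, start, strand) and keeps the
first ⌈mean + k·SD⌉ occurrences (k = 5), removing PCR towers
deterministically. Coverage is the diff-array count of reads covering
each position, normalized to reads per million; normalizing twice is an
error. For fragment-level (nucleosome) coverage, 54 bp reads are first
extended to 147 bp in their 3′ direction (`extend_reads`) — raw
read coverage peaks at footprint *edges*, since that is where the
5′ cuts sit.

## Regions, smoothing, calling

**LRs** are maximal runs of non-zero coverage at or below the
per-chromosome q-quantile of non-zero values (zero positions carry no
degradation evidence and never qualify; merging bridges only short
all-zero gaps, never above-threshold coverage), kept at ≥ min_len. The
pinned edge case: an all-equal positive track yields one
chromosome-spanning LR, because the quantile equals the constant.
Defaults q = 0.05, min_len = 50, merge_gap = 20 target real-genome
scale; the synthetic recovery experiments use q = 0.25 because planted
NDR tracts occupy ~20% of the toy genome. **CLRs** are the base-pair
intersection of two LR sets.

**Bias correction** divides the nucleosomal profile by the naked-DNA
degradation profile: log₂((nuc+α)/(naked+α)) by default (symmetric,
additive; α = 0.5 r.p.m.), plain ratio behind a flag. For *peak
calling* on corrected tracks the package's own experiments use ratio
mode against a broadly smoothed naked background with α scaled to 10%
of the mean r.p.m.: the log transform turns deep NDR valleys into
cliffs whose Gibbs ringing under Fourier smoothing displaces
neighbouring peaks by tens of bp, degrading dyad recovery on synthetic
calibration runs, while the α default of 0.5 r.p.m. is calibrated to
genome-scale read depth and is negligible on a deep toy genome.

**Smoothing** keeps the lowest ⌊keep_fraction·n/2⌋ positive Fourier
components plus DC (default 0.02 → shortest surviving period ≈100 bp,
just below the ~165 bp nucleosome repeat); the DC term is untouched so
the mean is preserved exactly.

**Calling**: dyads are strict local maxima of the smoothed track above
the height_threshold_quantile (0.25) of chromosome values; each call is
a fixed 147 bp footprint [dyad−73, dyad+74) and carries a height score
equal to the empirical quantile rank of its smoothed peak value.
Footprints clipped by a chromosome edge are dropped.

**Classification**: a call is *fuzzy* if (i) its footprint overlaps a
neighbour's by > 50 bp, (ii) its height score is below 0.4, or
(iii) its *peak contrast* — height above the mean of the smoothed
signal at dyad ± 74, normalized by the chromosome's 10–90 percentile
range — is below 0.2; otherwise it is *well-positioned*. The contrast
term was a genuinely open design point: height and overlap alone
cannot flag delocalized nucleosomes, because smoothing at the default
band forbids two maxima closer than ~100 bp (so the overlap rule never
fires for genuine clusters) and plateau peaks from delocalized,
partially occupied nucleosomes can be as high as phased ones. A broad
plateau is exactly what low contrast detects, and combining a height
score with a width-like score follows the peak-calling literature this
module emulates. The 0.2 default was chosen on synthetic calibration
runs where planted sharp and delocalized classes separate at ~0.2 with
margin on both sides.

## Metagene aggregation

Windows of ±flank (default 1000 bp) around TSS or TTS anchors are
extracted, minus-strand windows reversed so +x is downstream in gene
orientation, and averaged per offset over anchors with out-of-bounds
positions ignored (per-offset counts reported). Genes weigh equally;
region profiles use midpoints, strandless. 0–1 min-max scaling is
provided for cross-profile comparison and refuses constant vectors.

## Synthetic-digestion generator

The generator defines the study conditions for every desk-scale claim.

**Genome** (defaults): one 60 kb chromosome, i.i.d. background at
GC 0.39 (yeast-like), 30 non-overlapping 1 kb genes evenly spaced, each
flanked on both sides by a 200 bp homopolymeric poly(dA) cassette — the
canonical yeast NDR element — so planted regulatory sequence occupies
~20% of the genome, a compressed, gene-dense toy layout chosen so that
genome-wide rank statistics carry signal at desk scale. An optional
sinusoidal GC wave (amplitude 0 by default; 0.2 with 500 bp period in
the bias-correction experiment) plants regional composition bias shared
by both samples. A homopolymeric cassette rather than a 10 bp
alternating one matters: a 10 bp repeat beats against the 10.25 bp
helical period of the target shape and fragments the high-energy runs.

**Nucleosomes**: gene bodies carry phased ("sharp") dyads starting
linker+74 after the TSS at 165 bp spacing (18 bp linkers); intergenic
non-NDR background carries "jittered" dyads on the same grid displaced
uniformly by ±40 bp. No footprint intersects an NDR.

**Digestion**: cuts form a Poisson process over inter-base positions
with intensity proportional to a per-pair tetramer weight map,
normalized to a genomic mean rate of 1/150 bp (naked; fragments ≈150 bp
as in gentle naked-DNA digests) or 1/25 bp (chromatin; linkers digested
to completion). Fragments are the intervals between consecutive cuts of
one digestion pass, size-selected to 120–180 bp — this is what makes
protected footprints dominate the chromatin library: unprotected DNA is
cut below the size window. Sharp footprints multiply the interior cut
intensity by `protection` (0.05); jittered dyads are modelled as
population heterogeneity — their protection is smeared over the ±40 bp
envelope at occupancy 0.4, producing the broad, partially protected
plateaus that real fuzzy nucleosomes leave. Fragment ends are then
trimmed inward by a geometric number of bases (mean 2) with the landing
position re-weighted by the same tetramer map (exonuclease nibbling),
and each fragment yields one 54 bp read from its 5′ end on a uniformly
chosen strand. The default weight map prefers central A/T steps
(TA 8, AT 6, AA/TT 3, else 1); it deliberately collapses endo- and
exonucleolytic preference into one map, which makes A/T tracts both
preferred cut sites and preferentially degraded — the LR behaviour the
recovery experiments test — at the cost of not reproducing the
avoidance of AAAA at *primary* cut sites seen in fine-grained naked-DNA
data. Recovery tests of the enrichment statistics always use planted
random weights, never the defaults.

All randomness flows through numpy's PCG64 (`default_rng`) seeded from
`SimConfig.seed` with fixed per-stage spawn keys; outputs are
byte-identical across runs and platforms for a given seed.

**Ground truth and metrics** (`truth_report`): dyad recovery is the
fraction of planted dyads with a called dyad within ±20 bp. Sharp
classification is scored per dyad (nearest call within ±74 bp must be
well-positioned); jittered classification per *cluster* (calls inside
the cluster span mostly fuzzy) because delocalized envelopes merge
peaks and a per-dyad denominator would be meaningless. NDR recovery is
the mean best-Jaccard of planted NDRs against detected LRs of the
chromatin sample. `occupancy_track` gives the population-expected
occupancy (sharp footprints at 1, jittered envelopes at 0.4), window-
averaged over 147 bp so it is commensurate with the per-dyad energy
track it is correlated against.

## Problem sizes and numerical choices

The shipped experiments run on 60–200 kb genomes with 2×10⁵ fragments
(10⁶ for the cut-bias statistics), sizes at which every rank statistic
is stable across seeds while the whole suite completes in well under a
minute on one core. Quantile thresholds use numpy's linear-interpolation
quantiles; region runs are maximal and half-open; strict inequalities
at prediction thresholds make a constant track yield no regions. Ties
in smoothed tracks (floats) are not specially handled — strict maxima
suffice. Degenerate inputs (all-zero chromosomes, sub-147 bp
chromosomes, constant vectors, singular covariances, double
normalization) raise or warn explicitly rather than returning silent
zeros.

## Known limitations

* The digestion model is a single Poisson snapshot with size selection,
  not digestion kinetics; depletion contrast in *naked* samples
  saturates well above zero coverage, so NDR→LR recovery is evaluated
  on the chromatin sample.
* The generator's background sequence is i.i.d. (plus an optional GC
  wave); real genomes have richer composition structure, so passing
  recovery tests here does not certify performance on real data with
  strong regional biases beyond the modelled one.
* The synthetic stiffness table is constructed, not fitted; absolute
  energies are meaningful only relative to each other and to that
  table.
* Classification thresholds (h_min 0.4, contrast 0.2, overlap 50 bp)
  were calibrated on this generator's phenotypes; real-data use should
  re-examine them.
* Single-end 54 bp reads are assumed; paired-end fragment handling is
  limited to what `extend_reads` approximates.
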
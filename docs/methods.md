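# Methods

## Assay and data model

A Bind-n-Seq experiment exposes a pool of SNP-centered oligos to a purified
TF at a series of concentrations (default 0, 100, 500, 1000, 1500, 2000,
3000 nM), separates bound from unbound molecules on a native gel, and
sequences both bands per concentration plus the input library, in two
replicates. Each oligo is

    left adapter (25 nt) · UMI (2 nt) · 40-nt genomic window · UMI (2 nt) · right adapter (33 nt)

for 102 bp total, with the SNP at 0-based index 19 of the window (printed
1-based as position 20). Every variant is permuted to all four central
bases; alleles are labelled Ref, Alt1 (the GWAS tag allele where known),
then Alt2/Alt3 in A<C<G<T order, which fixes the labels deterministically.
UMIs are stripped and ignored — counting is frequency-based, not
deduplicated.

Read processing anchors on the constant right adapter (exact match on the
full 33-mer by default; a prefix length is configurable for 3′ quality
loss), takes the 44 bases upstream, strips the UMIs, and looks the 40-mer
up in a catalog keyed by the window with the SNP base removed, so any
sequenced central base maps to that variant's allele. Catalog keys claimed
by two variants are never assigned (counted as `collision`); reads are
searched on the given strand only. Per-sample totals N are defined as
*assigned* reads — discarded reads (no anchor, no catalog match, ambiguous
SNP base) are tallied per reason and never enter normalization. Users who
prefer raw-read totals can reconstruct them from the discard report.

## Enrichment and baseline QC

For sequence i at concentration j,

    enrichment = [(n_B + p_B)/N_B] / [(n_U + p_U)/N_U],   p = 2.5·N/10⁶

i.e. the ratio of pseudo-count-adjusted relative frequencies in the bound
vs unbound band. The pseudo-count (2.5 reads per million, scaled by each
sample's total) keeps the ratio finite and damps shot noise.

Five filters on the 0 nM and library samples remove sequences whose
baseline behaviour would corrupt the fit; protein-positive samples can
never change the outcome:

1. 0 nM unbound-to-library ppm ratio ≤ 0.2 or ≥ 2 (gel irregularities).
   The filter *excludes the extremes* and retains the open interval
   (0.2, 2); the alternative reading (keep only the extremes) is
   configurable but contradicts the filter's purpose.
2. 0 nM unbound < 5 ppm — fails only if violated in **both** replicates.
3. Library < 5 ppm — fails on violation in **either** library sequencing.
4. 0 nM bound-to-unbound ratio ≤ 0.2 or ≥ 5 — either replicate.
5. Any of the variant's four allele sequences < 5 ppm in the library
   (applied to the library sample; both replicates must be in violation).

Ratio filters use raw ppm without pseudo-counts; a zero denominator fails
the filter. A separate recovery flag marks sequences whose 0 nM bound +
unbound fractions recover less than r_min (default 0.5) of their library
fraction — informational only, never an exclusion, since the well-retention
parameter below models exactly this loss.

Replicate concordance is reported as the R² of an ordinary least-squares
fit of replicate-2 on replicate-1 enrichments pooled over positive
concentrations (0 nM is excluded: no specific binding is expected there).

## Affinity model

Occupancy under non-cooperative single-site equilibrium binding is
P = K·C/(1+K·C) with K in nM⁻¹. The well-retention parameter w ∈ [0, 1] is
the probability that a molecule is unavailable to the bound band (stuck in
the well, uneven migration): the bound expectation is scaled by (1 − w)
while the unbound expectation is left unscaled. (Prose descriptions of such
parameters are easy to invert; this package's convention is exactly the
expected-count equations above — w = 1 means nothing reaches the bound
band.)

Expected counts per replicate r:

    λ_B(i,j,r) = N_B(j,r) · f_i(r) / D_j  · (1−w_i) · P(K_i, C_j)
    λ_U(i,j,r) = N_U(j,r) · f_i(r) / D_uj · (1 − P(K_i, C_j))
    λ_L(i,r)   = N_L(r) · f_i(r)

with f_i(r) the pseudo-count-free library fraction of the replicate's
library sequencing (a single library file is shared across replicates when
only one was sequenced). All counts are independent Poisson; the objective
is Σ(λ − n·log λ) over bound and unbound cells at retained positive
concentrations plus the library cells (the log n! terms are data-only and
dropped; the library terms do not depend on (K, w) and act as reported
data-consistency terms).

Fitting alternates per-sequence likelihood maximization with global
denominator refreshes:

- **Phase 1** — w fixed at 0; each sequence's log₁₀K is maximized by
  L-BFGS-B with an analytic gradient, then D_j ← Σᵢ f̄ᵢ P_ij and
  D_uj ← Σᵢ f̄ᵢ(1−P_ij) (f̄ = replicate-mean library fraction; QC-failing
  sequences are removed before the sums). Iterate until the maximum
  relative denominator change < 10⁻⁴ or 1000 rounds.
- **Phase 2** — per-sequence (log₁₀K, w) maximization alternating with the
  same denominator refresh, for exactly 10 rounds (configurable; refreshing
  can be frozen). Denominators are frozen within a round, so per-sequence
  optimizations are independent and order-invariant, and the full
  denominator trajectory is kept so convergence plateaus can be inspected.

Numerical choices: optimization over log₁₀K (bounds [−7, 1], start −3)
conditions the problem and enforces K > 0; w is box-bounded in [0, 1];
λ is floored at 10⁻¹² inside logs, and a λ = 0 cell with observed counts
contributes a large finite sentinel (10³⁰) rather than ±inf so the
optimizer can back away. The denominator update makes Σᵢ λ_B(i,j) match
N_B(j) (exactly when replicates share f, to sampling noise otherwise).

Choices where the design was genuinely open: the unbound denominators are
updated by the symmetric rule (a freeze option exists); phase 2 refreshes
denominators every round by default; denominators are initialized per
concentration as 0.9 / max retained replicate-averaged enrichment, with
D_uj starting at 1. 0 nM samples are excluded from the likelihood by
default because the model predicts zero bound signal there (they serve QC
instead); no additive background term is fitted. Concentrations whose total
bound count falls below `min_bound_total` (default 10⁴) are excluded from
fitting with a recorded reason, and manual exclusions are honored.

## Allelic calls and motif impact

Fold change is alt/ref on fitted K; direction is `increase` at fold ≥ t,
`decrease` at fold ≤ 1/t (default t = 2), `none` otherwise. The call is a
pure fold-change rule with no significance test attached — a deliberate
match to how such thresholds are used on deeply sequenced in-vitro data.
All alternate alleles are reported; a variant is allelic for a TF when any
alternate allele's direction ≠ none, and multi-TF variants are surfaced by
the intersection report. Ranking by affinity breaks ties by rsid then
allele, so top-n lists are reproducible.

Motif impact scans ref/alt 40-mers against PWMs (MEME minimal format;
probabilities floored at 10⁻³ and renormalized so log-odds stay finite) on
both strands at every offset, scoring Σ log₂(p/background). Ties go to the
smallest offset, + strand first. A motif is *present* when the best window
reaches `presence_threshold` (default 0.8) of the PWM's maximum achievable
score — the presence rule is the one genuinely free knob in the
classification and is surfaced prominently. `created` requires presence in
alt only with the SNP inside alt's best window; `disrupted` is the mirror;
everything else is `unaffected`. Minus-strand hits are tested for SNP
overlap in forward coordinates (they cover the same forward interval), and
histogram positions are counted along the hit's strand so position 1 is
always the motif's 5′ end. Positional histograms use the changed allele's
hit (alt for created, ref for disrupted) and conserve totals over
SNP-overlapping affected calls.

## Simulator

The generator is the model's generative twin: it draws per-sequence truth
(default K log-uniform over [10⁻⁴, 10⁻²] nM⁻¹ — Kd 100 nM to 10 µM,
spanning weakly to strongly bound sequences over the concentration series;
w ≡ 0; symmetric-Dirichlet library composition with α = 10), computes
self-consistent denominators D_j = Σ f·(1−w)·P and D_uj = Σ f·(1−P), and
draws every cell independently Poisson at 2×10⁶ expected reads per sample,
two replicates, the full seven-point concentration series. Variants can be
planted with a fold-change on the tag alternate allele and optionally with
a motif consensus embedded around the SNP (broken by the reference base,
completed by the alternate), giving known-answer inputs for call
sensitivity and motif analyses. A multinomial mode (fixed sample totals) is
provided for realism and is off-model relative to the likelihood.

The 0 nM bound lane is modelled as non-specific carryover with library
composition: a real zero-protein bound band contains material (that is what
the baseline QC ratios are computed from), and pure-model behaviour (an
empty lane) is available via `zero_bound_background=False`.

FASTQ emission inverts read processing — UMI + window + UMI + right adapter
(left adapter optional), uniform per-base substitution errors, constant
quality — and is byte-deterministic per seed; every draw in the simulator
flows from the single seed.

What the simulator does *not* emulate: PCR amplification bias, gel
migration physics, position- or quality-dependent sequencing error,
cross-sample contamination, and real genomic sequence composition (contexts
are uniform-random). Passing recovery tests therefore demonstrate that the
estimator inverts its own generative model at realistic depths — not that
the model captures every artifact of gel-based data; the QC filters and the
w parameter exist precisely because real data deviate.

## Problem sizes in the test suite

The suite exercises recovery at 200 sequences × 30 samples × 2×10⁶ reads
(the scale at which per-sequence counts are in the thousands, matching a
deeply sequenced pooled assay) and keeps everything else at few-variant
scale; the FASTQ round trip runs at reduced depth since its guarantee
(bit-exact re-counting at zero error rate) is depth-independent. The
library-arithmetic check builds the full 3,232-variant / 12,928-sequence
library to verify permutation accounting at production scale.

## Known limitations

- Single-site, non-cooperative binding only; no multi-site or cooperative
  models, and no confidence intervals on K.
- K is identified only relative to the shared denominators; comparisons are
  meaningful within a fit (one TF, one library), which is all the allelic
  fold-change calls require.
- Exact-match read assignment: reads with errors in the 39 constant window
  bases are discarded, not rescued (anchor-prefix length is the only
  mismatch tolerance knob).
- Motif calls depend on the externally supplied PWMs and the presence
  threshold; variants acting through flanking sequence or low-affinity
  sites outside the core motif are reported as `unaffected` by design.
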
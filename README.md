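# bindnseq

Allele-resolved transcription-factor (TF) binding analysis for Bind-n-Seq
experiments.

In a Bind-n-Seq assay, a purified TF is equilibrated with a pool of
SNP-centered DNA oligos across a series of protein concentrations; bound and
unbound molecules are separated on a native gel, and both fractions are
sequenced together with the input library. This package takes the raw
bound/unbound/library FASTQ files (or a simulated twin of the experiment)
and produces, for every allele of every variant:

- read counts and pseudo-count-adjusted **enrichment** per concentration and
  replicate, with baseline quality filters;
- a maximum-likelihood **binding affinity** K (nM⁻¹) and a well-retention
  parameter w from a joint Poisson model of all fractions;
- **allele-biased binding calls** (≥2-fold change in K between an alternate
  and the reference allele) and their intersection across TFs;
- **motif creation/disruption** classifications of each variant against
  PWMs, with positional histograms of where impactful SNPs fall in a motif.

It is aimed at regulatory-genomics groups quantifying how non-coding,
disease-associated SNPs change TF–DNA binding in vitro.

## The model

Each 102-bp oligo carries a 40-bp genomic window with the SNP at position
20, flanked by 2-nt UMIs and constant adapters. Under non-cooperative
single-site binding, a sequence with association constant K is occupied at
free-TF concentration C with probability

    P = K·C / (1 + K·C)

A per-sequence parameter w ∈ [0, 1] is the probability that a molecule
never reaches the bound band (stuck in the gel well), scaling the bound
expectation by (1 − w). Expected read counts follow from the library
composition fᵢ, per-sample depths N, and per-concentration normalizers
D_j / D_uj:

    λ_B(i,j) = N_B(j) · fᵢ / D_j  · (1 − wᵢ) · P(Kᵢ, C_j)
    λ_U(i,j) = N_U(j) · fᵢ / D_uj · (1 − P(Kᵢ, C_j))
    λ_L(i)   = N_L · fᵢ

Counts are Poisson; (K, w) are estimated per sequence by L-BFGS-B on the
joint negative log-likelihood, alternating with denominator refreshes
D_j = Σᵢ fᵢ(1 − wᵢ)P_ij in two phases (K-only until the denominators
plateau, then (K, w) for a fixed number of refinement rounds). Enrichment
is the ratio of pseudo-count-adjusted relative frequencies in bound vs
unbound at the same concentration, with the pseudo-count equal to
2.5 reads per million scaled by each sample's total.

See `docs/methods.md` for assumptions, parameter defaults, and numerical
details.

## Worked example

Simulate a 20-variant library (80 allele sequences, two replicates at
0–3000 nM, 2×10⁶ reads per sample) in which 4 variants carry a planted
4-fold affinity gain on their tag alternate allele, then run the analysis:

```python
import bindnseq as bq
from scipy.stats import spearmanr

truth = bq.simulate_truth(n_variants=20, seed=7, depth=2_000_000,
                          allele_mode="shared", n_planted=4, plant_fold=4.0)
counts = bq.simulate_counts(truth)
flags = bq.apply_filters(counts)
enr = bq.enrichment_table(counts)
fits, dens = bq.fit(counts, flags, truth.series)
calls = bq.call_allelic(fits, truth.variants, threshold=2.0)
```

Output (abridged):

```
sequences passing QC: 80/80
replicate R^2: {'TF1': 0.999}
Spearman(true K, fitted K) = 0.999
allelic calls: 4 of 60 (planted: 4)
    rsid allele allele_label  fold_change direction
rs000001      A         Alt1         4.03  increase
rs000002      A         Alt1         4.02  increase
rs000003      A         Alt1         4.07  increase
rs000004      C         Alt1         4.06  increase
```

All 80 sequences pass the baseline filters, the two replicates agree
(R² = 0.999), fitted affinities track the generating values (Spearman
0.999), and the 2-fold rule recovers exactly the four planted allelic
variants at their true ~4-fold changes — with no false calls among the 56
fold-1 alternate alleles.

The same pipeline runs from the shell on FASTQ input or a simulation
config:

```bash
bindnseq all --config config.yaml --seed 7 --outdir run/
bindnseq fit --outdir run/        # re-run one stage from its on-disk inputs
```

Each stage writes plain TSVs (`counts.tsv`, `enrichment.tsv`, `qc.tsv`,
`fits.tsv`, `calls.tsv`, `motif_calls.tsv`, …) plus the resolved config and
a log, so every run is reproducible and each stage restartable.

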
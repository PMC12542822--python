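# Methods

## Scope and data model

`phoskit` analyzes two experimental designs: (i) a 6-plex isobaric
(TMT-style) phosphoproteomics contrast — two conditions, three
biological replicates each, one reporter channel per replicate — and
(ii) a label-free DIA time course — two conditions crossed with meiotic
stages, two biological and three technical replicates per cell.  Inputs
are text tables in search-engine dialects: an evidence (PSM) table with
six corrected reporter intensities, a posterior error probability (PEP),
decoy/contaminant flags, and a per-residue phospho-STY localization
string (`"S3:0.9;T5:0.1"`); a protein-group table with the same six
channels; DIA report rows or a pre-aggregated protein-quantity matrix
(protein-level aggregation such as MaxLFQ happens upstream and is
consumed as input).  A reporter intensity of 0 is treated as missing
throughout: search engines emit 0 for absent signal, and a zero would
poison the log-ratios.

## Confidence filtering

PSMs are removed if flagged as decoy or contaminant or if PEP ≥ 0.01
(the boundary itself is removed).  A record failing several rules is
counted once under the priority decoy > contaminant > PEP so that filter
reports are deterministic and conserve the input count.  Protein groups
are only screened for decoy/contaminant flags — deliberately not
post-filtered by peptide counts or q-values — so that as many
phosphopeptides as possible retain a parent intensity for normalization;
the achieved fraction is reported as the match rate.

## Ratio normalization

The quantification unit is the sequence-PTM combination (one modified
sequence).  PSM intensities are summed per unit and channel; each unit's
channel intensity is divided by its parent protein group's intensity and
log2-transformed.  Ratios are computed per channel, never on
channel-summed intensities, because the differential model compares
per-channel ratios between conditions.  Dividing per channel makes the
construction invariant to any per-channel global scaling (the log2 k
cancels), which the tests assert exactly.  Units whose parent group has
no positive intensity in any channel are excluded from the matrix but
kept in the match-rate denominator.

## Moderated differential testing

Per feature, a (weighted) least-squares two-group fit gives
β = mean(treatment) − mean(control), residual variance s² on d = n − 2
degrees of freedom; with equal weights this is exactly the pooled
two-sample estimator.  Features with fewer than two usable observations
per condition are excluded before prior estimation (their residual
variance is undefined).

Variance moderation assumes s²_g | σ²_g ~ σ²_g·χ²_d/d with a scaled
inverse-chi-square prior σ²_g ~ s₀²·d₀/χ²_{d₀}.  The hyperparameters are
estimated by method of moments on e_g = log s²_g − ψ(d_g/2) + log(d_g/2):
the equation ψ′(d₀/2) = var(e) − mean(ψ′(d_g/2)) is solved by Newton
inversion of the trigamma function (tolerance 1e-8, with asymptotic
starting values); if the observed spread does not exceed the sampling
contribution, d₀ = ∞ and s₀² = exp(mean e) (all features share one
variance).  The posterior variance is the degrees-of-freedom-weighted
blend s̃² = (d₀ s₀² + d s²)/(d₀ + d), always between s² and s₀²; the
moderated t = β/√(s̃²·v) with v = 1/n_c + 1/n_t (sums of weights when
weighted) is referred to t(d₀ + d), or the normal when d₀ = ∞.  P-values
are two-sided — both phosphorylation gains and losses are biologically
meaningful — and BH-adjusted (step-up; implemented via
`statsmodels.stats.multitest`, cross-checked in the tests against a
literal brute-force step-up and against the Bioconductor reference
implementation of the whole moderation chain).  The significance bound
p_adj ≤ 0.05 is inclusive.  No fold-change threshold is applied in the
isobaric experiment; the DIA arm adds one (below).

Zero residual variances are excluded from prior estimation (their log is
undefined); an all-zero input raises a degenerate-data error rather than
returning a sham prior.

## Phosphosite localization and motifs

Localization probability vectors are aggregated per plain peptide
sequence: the per-position mean over **all** of the peptide's PSMs, a
position absent from one PSM's vector contributing 0 for that PSM (every
PSM enters the denominator).  The argmax of the means is the peptide's
site; exact ties break to the lowest position for determinism.  Peptides
whose PSMs carry no probabilities at all are flagged unlocalizable.

Motif windows are ±7 residues (15-mers) around the phosphosite in the
parent protein — the conventional kinase-motif window — padded with a
gap symbol beyond the termini; gaps are excluded from frequency counts.
The motif matrix is enrichment-only: per position and residue,
f·log2(f/b) with foreground/background frequencies f, b, clipped below
at 0 and divided by log2(20), so a residue fixed in the foreground
against a uniform background scores exactly 1.  A foreground residue
absent from an unpseudocounted background is scored against a floor
frequency 1/(n_background + 20) and logged; a pseudocount option avoids
the floor entirely.  In the pipeline, the foreground is the
significantly dephosphorylated peptides and the background all tested
peptides with negative estimated fold change ("all dephosphorylated").
Kinase-specific foregrounds subset peptides having the kinase of
interest within the top 10 (inclusive) externally predicted kinases;
prediction itself is external and consumed as a rank table.

## Enrichment and clustering

Over-representation uses the one-sided upper-tail hypergeometric test of
the query (proteins carrying at least one significant peptide) against
each gene set restricted to the universe of quantified, annotated
proteins, BH-adjusted across terms.  BH is used uniformly — including
where external web services apply proprietary adjustments — and the
choice is recorded in the result metadata.

Heatmap rows are scaled to mean 0, SD 1 (n−1 denominator); constant rows
are emitted as zeros and flagged.  Clustering is Ward's minimum-variance
agglomeration in the ward.D2 convention: the Lance–Williams recurrence
on squared Euclidean dissimilarities, merge heights reported as square
roots.  It is implemented in-package with a deterministic smallest-index
tie-break, and verified in the tests against both a brute-force
minimum-variance oracle on explicit point sets and `scipy`'s Ward
linkage.  Columns (samples) cluster with the same method.

## DIA time course

Report rows are kept iff PSM-level q ≤ 0.001 **and** protein-group
q ≤ 0.05 (both inclusive).  Quantities are log10-transformed (the
storage and display scale); technical replicates are averaged within
each (condition, stage, biological replicate) unit before modeling, so
the model's observations are biological replicates and no hierarchical
model is needed.  Missing units are imputed conservatively by the
minimum observed value among the protein's replicates in the same
(condition, stage) group — a low value local to the replicate group —
falling back to the protein-wide minimum when the whole group is
missing; imputed cells carry weight 0.05 against 1 for observed cells,
and observed cells are never altered.  Proteins observed nowhere are
dropped and reported.  Each stage is contrasted treatment vs control by
the weighted moderated fit; the fitted log10 difference is converted to
log2 units (× log2 10), and a protein is called reliably changed iff
p_adj ≤ 0.05 and |log2FC| ≥ 0.5 (inclusive, for determinism at the
printed bound).  With no missingness the weighted path reduces exactly
to the unweighted one, which the tests assert cell-for-cell.
Whether the "minimal replicate intensity" should be group-local or
global is a genuine ambiguity; the group-local reading was chosen as the
more conservative and is applied uniformly.

## Synthetic data generator

The simulator emulates the statistical structure of both designs with a
single seeded configuration; identical config and seed give
byte-identical tables.

Phospho arm: per-protein log2 baselines ~ N(17, 1.5); protein reporter
intensities log-normal around the baseline with SD `reporter_noise_sd`
(default 0.25 on the log2 scale, a typical isobaric reporter CV);
peptide features ride multiplicatively on their parent protein's channel
intensity with a stoichiometry offset ~ N(−1.5, 0.8) and their own
log-normal noise, so protein-level noise cancels in the ratio exactly as
the normalization intends.  A fraction `effect_fraction` (default 0.1)
of features receives `effect_log2fc` (default −1, dephosphorylation
only, matching the strong down/up asymmetry kinase inhibition produces)
in the treated channels.  Feature intensities are split across 1 +
Poisson PSMs with channel-independent Dirichlet shares, so summing PSMs
recovers the feature exactly and losing a PSM shifts all channels
equally (no effect bias).  Localization vectors are Dirichlet over the
peptide's S/T/Y positions, peaked (mass 0.85) at the true site with
concentration 20.  PEP values come from a two-component mixture: 90%
Beta(0.5, 500) (confident identifications, essentially all below 0.01)
and 10% Beta(2, 8) (a low-confidence tail that exercises the filter).
Decoy and contaminant rows are appended at their configured fractions
(1% each by default) with distinct protein ids.  Parent protein
sequences are concatenations of their peptides, so window extraction
works by exact substring placement.

DIA arm: log10 baselines ~ N(6.5, 0.5); flat across stages except for an
`effect_fraction` minority, each changed at exactly one random stage in
the treatment arm; technical noise shares `reporter_noise_sd` (converted
to log10); missingness at `missing_rate` overall, with per-protein
probability decreasing in abundance rank (missing-not-at-random, as in
real DIA data).

What the simulator does **not** emulate: isotope-impurity leakage
between channels (intensities are emitted "already corrected"),
chromatographic or spectral raw structure, peptide-level interference,
shared/razor-peptide ambiguity (each PSM carries one group id), or
correlated biological variance components (a `between_replicate_sd`
knob exists but defaults to 0, as replicate variance components are
otherwise unconstrained).  Passing tests therefore demonstrate
correctness of the statistical machinery under a faithful error model,
not robustness to every artifact of real spectra.

## Problem sizes and determinism

The verification runs use ≈3000 features × 20 seeds for null
calibration, ≈2000 features for effect recovery, 5000 variances for
prior inversion, and 600 proteins × 24 runs for the DIA course — sizes
at which Monte-Carlo bounds are tight while a full verification pass
completes in well under a minute per component.  All randomness flows
from a single integer seed through `numpy`'s Generator; the pipelines
write a JSON manifest (version, seed, thresholds, per-stage counts
satisfying input = retained + removed) and all outputs are reproducible
bit-for-bit from (inputs, config, seed).

## Known limitations

- Only two-group designs; no covariates, paired fits, or multi-factor
  contrasts (the two-group fit matches the "difference between group
  means" framing of the target analysis; a paired option is left
  unimplemented).
- Site localization is aggregated per plain peptide sequence, not per
  modified sequence; multiply-phosphorylated peptides yield one top site.
- ORA ignores the GO DAG (no term propagation or deduplication).
- The DIA model fits one contrast per stage rather than a joint
  across-stage trend model.
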
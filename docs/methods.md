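# Methods

This note documents the models, parameter choices, and numerical decisions
behind `sctile`, and what the synthetic-data generators do and do not
emulate.

## Coordinates and library geometry

All coordinates are 1-based; residue spans are inclusive (`ResidueSpan(127,
332)` covers 206 residues).  A tiling guide is anchored by the CDS
nucleotide of its predicted SpCas9 cut site — the blunt cut 3 nt 5′ of the
PAM, expressed on the coding strand — and maps to residue
`ceil(cds_cut_nt / 3)`.  The CDS length may count the stop codon
(`3 × (protein_length + 1)`, the default) or not; the convention is
recorded per library and affects only density accounting.  Whether the
per-guide anchor is the cut site or the protospacer midpoint changes
nothing downstream at tiling densities of a few bp per guide, so the cut
site is used throughout.

## Survival screens

**Counting.**  Spacers are recovered from raw amplicon reads by their
backbone context: the 20-mer after the first `CACCG` whose +25 window ends
in `GTTT`; occurrences failing that layout are passed over in a single
deterministic left-to-right pass.  Counting is an exact (0-mismatch)
dictionary lookup against the library.  An aligner adds nothing here
because only perfect matches are retained anyway; the dictionary makes the
rule explicit and order-independent.

**Frequency filter.**  Expected frequency is uniform (`1/|library|`) —
the only definition available without a plasmid-pool reference column,
which can be supplied instead via the `reference` argument.  Guides below
5% of expected in the reference (early) sample are excluded from *all*
samples, so fold-changes are never computed against an unreliable
baseline.

**CRISPR score.**  `CS = log10` of the pseudocounted frequency ratio with
pseudocount 0.5 (configurable); the pseudocount enters both numerator
counts and the totals (`+ 0.5 × N`).  This is the named quantity itself —
a log10 fold-change in frequency — computed directly rather than through a
negative-binomial regression fit, which keeps the estimator deterministic
and self-contained.  Replicates are averaged on the CS scale.

**Normalization.**  `NCS = (CS − med_neg) / (med_neg − med_pos)` with
medians over the spiked-in control classes (mean of central values for
even counts).  The control medians map to exactly 0.00 and −1.00 by
construction, which is asserted rather than approximated in the tests.
NCS is affine in CS, so guide ranks are unchanged and normalization
commutes with smoothing.  When two screening arms (e.g. vehicle vs drug)
are compared, each arm is normalized against its own control medians by
default; the day-matched contrast is then the difference of the two
normalized residue tracks.

**Smoothing.**  The Nadaraya–Watson estimator with Gaussian kernel is
evaluated at every CDS nucleotide, then averaged over each codon's three
nucleotides.  The default bandwidth is the maximum gap between consecutive
distinct cut positions, which guarantees every nucleotide has
non-vanishing weight; no truncation window is applied (full Gaussian
tails).  If a caller forces a bandwidth so small that all weights
underflow at some position, the bandwidth is doubled with a warning rather
than emitting NaNs.  Smoothed values are convex combinations of guide
scores, hence bounded by the input range and affine-equivariant.

## Single-cell stage

**Guide assignment.**  A guide is detected in a cell when its capture UMI
count is ≥ 3 (`min_umi`, configurable) — a guard against ambient guide
RNA, which typically contributes one or two UMIs.  Exactly one detected
guide ⇒ assignable; zero or ≥ 2 ⇒ excluded.

**QC.**  200 ≤ genes detected ≤ 4500 and mitochondrial fraction ≤ 10%.
When several criteria fail, the reported label follows the order gene
count → mitochondrial fraction → guide multiplicity.

**Normalization.**  Counts per cell scaled to 10,000 then `log(1 + x)`.

**Pseudotime.**  Full trajectory inference is deliberately out of scope;
the pseudotime here is the first principal component of the centered,
log-normalized signature-gene submatrix (the top ≤ 100 genes responsive to
inhibition of the target), min–max scaled to [0, 1].  The sign is fixed by
requiring positive correlation with the mean expression of
differentiation markers (negative with leukemia markers when no
differentiation markers are annotated), making the score fully
deterministic — no stochastic embedding, no seed.  An externally computed
per-cell pseudotime column is accepted verbatim for users who prefer a
dedicated trajectory tool.  Per-guide summaries use the median over that
guide's cells and require ≥ 3 cells (`min_cells`); at ~7 cells per guide,
smaller guides must be droppable without failing, and their absence simply
enlarges the gaps the kernel bridges.

**Pseudobulk profiles and the correlation map.**  For each signature gene,
per-guide mean log-normalized expression is smoothed along the gene body;
all genes share one smoother matrix, so the residue × gene profile is a
single matrix product.  The position-ordered correlation map is the
Pearson correlation between residue rows **after centering each gene by
its mean across residues**: without centering, the per-gene baseline
(absolute expression level) dominates every row and all positions
correlate near 1 regardless of perturbation effects.  Centering makes the
map reflect position-specific expression *shifts*; functionally coupled
regions then correlate strongly while unperturbed regions do not (and
typically anticorrelate weakly with perturbed ones, since the gene means
sit between the two).  Zero-variance rows are reported as missing rather
than imputed.  The per-residue PC1 score is computed on the same
gene-centered matrix and sign-oriented against the pseudotime residue
track (or by making the largest gene loading positive when no orientation
track is given).

**Differential expression.**  Wilcoxon rank-sum per gene between
region-targeting cells and negative-control cells, Benjamini–Hochberg
FDR, calls at FDR < 0.05, effect size as the difference of mean
log-normalized expression.  Rank-sum + BH is the standard
distribution-free choice for single-cell group comparisons.  Note the
effects are relative to library-size normalization: a strong shift
concentrated in genes that carry a large share of counts depresses the
apparent expression of all other genes (compositional bias), which is a
property of depth normalization itself, not of the test.

**Visualization.**  A 2-D embedding hook (`embed_2d`, PCA) exists for
plotting convenience only; no computed result depends on it and it is not
validated numerically.

## Structure annotation

Cross-species transfer uses a global pairwise alignment with BLOSUM62, gap
open 10, gap extension 0.5 — fixed, reproducible parameters in place of an
interactive workbench alignment.  Aligned non-gap columns give a strictly
colinear residue mapping; unmapped target residues are missing, never
interpolated.  Attribute files use the Chimera "define attribute" dialect
with raw scores; the painted PDB rescales scores linearly to [0, 100] in
the temperature-factor column (columns 61–66 — the only columns modified),
with unannotated residues at 0.00 and a constant track written as 50.00.
Residue numbering is taken from the coordinate file as-is; insertion codes
are rejected with a clear error rather than silently renumbered.

## Phenotype arithmetic

Relative proliferation is the FP⁺ odds ratio between a timepoint and the
day-3 baseline.  The live-cell counts printed in the definition cancel
algebraically; both forms are computed and required to agree to 1e-12,
and FP% of exactly 0 or 100 is an error (undefined odds).  The resistance
index compares day-9 relative proliferation (timepoint configurable)
under drug to the control construct, after averaging replicates on the RP
scale; the control row is exactly 100% at every dose.

## Synthetic data: what it emulates, and what it does not

Defaults mirror the study conditions the package models:

| parameter | default | rationale |
|---|---|---|
| protein / guides | 1537 aa, 602 tiling guides | 4614-nt CDS (stop included) → 7.7 bp per guide |
| controls | 25 negative + 25 positive | odd counts make control medians exact guide scores |
| functional windows | 127–332 at −0.25/day; 460–555 at −0.10 (−0.30 under drug); 558–662 at 0 (+0.15 under drug) | catalytic core, drug-sensitizing and drug-resistance elements |
| screen | 600,000 reads/sample, days 0 and 12, lognormal σ = 0.5 baseline abundances | ~1000× coverage; −0.25/day over 12 days gives CS = log10(2⁻³) ≈ −0.90 |
| single cell | 4943 cells, 8% multiplets, 4% unassigned | ≈ 88% single-guide cells; ~7 QC-passed cells per guide |
| genes | 100 signature (half up-, half down-regulated), 3 + 3 markers, 10 mitochondrial, 300 background; NB dispersion 0.15 | enough genes that passing cells clear the 200-gene floor; over-dispersion exercises QC and DE |
| planted failures | 2% low-gene cells (150 genes kept), 2% high-mito cells (~25% mito load) | far enough from the 200-gene and 10% thresholds that planted labels are recovered exactly |

Selection acts multiplicatively on frequency (`f ∝ f₀ · 2^(fitness·day)`),
and the ledger's expected CS includes the exact pool-renormalization term:
as depleted guides vanish, surviving frequencies rise, so the naive
`fitness × days × log10 2` closed form holds only when the depleted slice
of the pool is small.  The latent differentiation state is
Beta-distributed (baseline Beta(2, 6), shifted to Beta(6, 2) at effect
size 1 for cells whose guide hits a shifting window) and drives marker and
signature genes log-linearly with slope 1.2.

All randomness derives from one integer seed (per-stage child generators),
so outputs are bit-identical across runs.

Not emulated: barcode chemistry and UMI collision/dedup, sequencing error
models beyond uniform-random decoy reads, doublet transcriptome mixing
(multiplets are labeled but their expression follows a single latent
state), ambient mRNA contamination, guide efficiency heterogeneity and
in-frame repair outcomes, batch effects, and trajectory branching.
Passing the recovery suites therefore shows the estimators are correct
under a faithful but idealized generative model, not that real screens
are free of these artifacts.

## Problem sizes used in the test suite

Recovery suites run at study scale: 50 seeded replicates of the full
602-guide screen for planted-window localization (Jaccard ≥ 0.5 against
the planted window in ≥ 90% of replicates), 20 seeded replicates of the
~4900-cell dataset for pseudotime recovery (Spearman ≥ 0.8 per
replicate), and single study-scale datasets for the correlation-map and
differential-expression checks.  Closed-form CS recovery uses a 30-codon
window so the renormalization bias stays well inside the assertion
tolerance.  Unit tests use a 50-codon toy library with one guide per
codon, where every smoothing result can be checked against an explicit
double-loop oracle to 1e-10.

## Known limitations

- Exclusion of low-baseline guides uses a single reference sample; a
  plasmid-pool column is supported but the two are not reconciled.
- The pseudotime is one-dimensional by construction; branching fates
  would need an external trajectory column.
- `group_de` inherits the compositional bias of depth normalization (see
  above); effects should be read as relative abundance changes.
- PDB handling covers ATOM/HETATM records without insertion codes; mmCIF
  is out of scope.
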
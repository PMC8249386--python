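# sctile

Analysis toolkit for **single-cell CRISPR gene-tiling screens**: experiments
that saturate a gene's coding exons with sgRNAs and read out, per guide,
either survival (pooled amplicon sequencing before/after culture) or a
single-cell transcriptome with direct guide capture.  The package turns
those per-guide readouts into smoothed per-residue functional score tracks,
position-ordered transcriptomic correlation maps across the protein, and
3-D structure annotations, and implements the flow-cytometry
growth-competition arithmetic used to validate hits.  It was built around
tiling screens of the H3K79 methyltransferase DOT1L in MLL-rearranged
leukemia cells, but nothing in it is specific to that gene.

## What it computes

**Survival scans.**  Spacers are extracted from raw reads by their vector
backbone (5′-`CACCG`, 3′-`GTTT`), counted by exact match against the
library, and converted to frequencies; guides below 5% of the expected
uniform frequency at the baseline timepoint are excluded.  The CRISPR score
of guide *g* is the log10 fold-change of its frequency between the early
and a late timepoint,

```
CS(g) = log10( f_late(g) / f_early(g) )
```

computed with a pseudocount so zero counts stay finite.  The normalized
CRISPR score anchors CS to the spiked-in controls,

```
NCS(g) = (CS(g) − med_neg) / (med_neg − med_pos)
```

so the median of the negative controls (non-targeting) is exactly 0.00 and
the median of the positive controls (pan-essential gene) exactly −1.00.

**Gene-body smoothing.**  Per-guide values are interpolated along the CDS
by Gaussian (Nadaraya–Watson) kernel smoothing evaluated at every
nucleotide, with the bandwidth defaulting to the maximum gap between
consecutive guide cut sites; the per-residue score is the average over each
trinucleotide codon.

**Single-cell stage.**  Cells are assigned the single guide whose capture
UMIs reach threshold (multiplets and unassigned cells are dropped),
filtered on 200–4500 detected genes and ≤10% mitochondrial reads, and
depth-normalized (10,000 counts, log1p).  A deterministic differentiation
pseudotime — PC1 of the signature-gene submatrix, oriented by myeloid
differentiation markers — is summarized per guide by its median and
smoothed into a residue track.  Per-guide pseudobulk profiles of the
signature genes yield a residue × residue Pearson correlation map and a
per-residue transcriptomic PC1 score; rank-sum differential expression with
Benjamini–Hochberg correction compares region-targeting cells with
negative-control cells.

**Structure annotation.**  Tracks are transferred between orthologs by
global pairwise alignment (BLOSUM62, gap open 10 / extend 0.5) and exported
as a Chimera attribute file plus a PDB copy with the score rescaled to
[0, 100] in the B-factor column.

**Phenotype arithmetic.**  Relative proliferation from flow counts,
`RP = odds(FP⁺, t) / odds(FP⁺, d3)`, and the resistance index
`RI = 100 × RP(x, m) / RP(con, m)`.

A seeded synthetic-data module (`sctile.simulate`) generates tiling
libraries, survival screens (FASTQ or count matrices), and single-cell
datasets with known ground truth for every stage.

## Worked example

```python
from sctile import *

cfg = SimConfig(seed=1)                      # study-scale defaults
lib, _ = simulate_library(cfg)
print(f"library: {len(lib.tiling)} tiling guides, "
      f"{targeting_density(lib):.1f} bp/sgRNA")

sim = simulate_screen(cfg, lib)              # 12-day survival screen
track, scores = scan_pipeline(sim.counts, lib, early="d0", late="d12")
s = track.to_series()
print(f"smoothed NCS, catalytic core 127-332: {s.loc[127:332].mean():+.2f}")
print(f"smoothed NCS, C-terminal 100 aa:      {s.loc[1438:1537].mean():+.2f}")

ds, ledger = simulate_sc(cfg, lib)           # single-cell stage
qc = compute_qc(ds)
print(f"single-guide cells: {single_assignment_rate(qc):.1f}%")
kept = qc_cells(ds, qc)
pt_track = pseudotime_residue_track(signature_pseudotime(kept), lib)
t = pt_track.to_series()
print(f"pseudotime, core 127-332: {t.loc[127:332].mean():.2f} vs "
      f"C-module 901-1537: {t.loc[901:1537].mean():.2f}")
```

prints

```
library: 602 tiling guides, 7.7 bp/sgRNA
smoothed NCS, catalytic core 127-332: -0.98
smoothed NCS, C-terminal 100 aa:      +0.01
single-guide cells: 87.4%
pseudotime, core 127-332: 0.73 vs C-module 901-1537: 0.26
```

The planted essential core drops to NCS ≈ −1 (as depleted as the
pan-essential positive controls) while the non-essential C-terminus stays
at the negative-control level, and cells whose guides hit the core sit high
on the differentiation pseudotime — the signatures the method is designed
to reveal.

The same steps are available from the shell:

```sh
sctile simulate screen --seed 1 --out screen/
sctile scan --counts screen/counts.tsv --library screen/library.tsv \
            --early d0 --late d12 --out track.tsv
```

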
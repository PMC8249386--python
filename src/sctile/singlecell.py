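"""Single-cell stage: guide assignment, QC, pseudotime, per-residue profiles.

Cells from a direct-capture perturb-seq style experiment arrive as a
cell x gene count matrix plus a cell x guide UMI capture matrix.  A guide is
"detected" in a cell when its capture UMIs reach ``min_umi``; only cells
with exactly one detected guide are kept (multiplets and unassigned cells
are excluded), alongside standard transcriptome QC (200-4500 genes
detected, <=10% mitochondrial reads).

The differentiation pseudotime used here is a deterministic, lightweight
trajectory score: the first principal component of the log-normalized
signature-gene submatrix (the top genes responsive to target inhibition),
min-max scaled to [0,1] and sign-oriented so that it increases with
myeloid-differentiation markers (Cd11b, Gr1, Ltf) and hence decreases with
leukemia markers (Meis1, Hoxa9, Myc).  An externally computed per-cell
pseudotime (e.g. from a full trajectory tool) can be supplied instead.

Per-guide pseudotime medians and per-guide mean expression profiles are
projected onto protein residues with the same Gaussian gene-body smoother
used for survival screens, giving a residue x signature-gene pseudobulk
matrix, its position-ordered Pearson correlation map, and a per-residue
transcriptomic PC1 score.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .library import GuideLibrary, ResidueSpan, cut_codon
from .scan import ResidueTrack, default_bandwidth, smoother_matrix

__all__ = [
    "CellDataset",
    "PseudotimeTable",
    "PseudobulkMatrix",
    "CorrelationMatrix",
    "assign_guides",
    "compute_qc",
    "qc_cells",
    "single_assignment_rate",
    "normalize_log",
    "signature_pseudotime",
    "pseudotime_residue_track",
    "pseudobulk_profiles",
    "position_correlation",
    "residue_pc1",
    "group_de",
    "embed_2d",
]

GENE_META_COLUMNS = ("mito", "signature", "leukemia_marker", "diff_marker")


@dataclass
class CellDataset:
    """Cell x gene counts with guide captures and gene annotations.

    ``gene_meta`` is indexed by gene and carries boolean flags: ``mito``,
    ``signature`` (top inhibitor-responsive genes, at most 100),
    ``leukemia_marker`` and ``diff_marker``.  ``cell_guide`` (cell ->
    guide_id) is populated by :func:`qc_cells` once every remaining cell
    carries exactly one guide.
    """

    expr: pd.DataFrame
    guide_umi: pd.DataFrame
    gene_meta: pd.DataFrame
    cell_guide: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.expr.index.has_duplicates or self.expr.columns.has_duplicates:
            raise ValueError("cell and gene identifiers must be unique")
        if not self.guide_umi.index.equals(self.expr.index):
            raise ValueError("guide_umi rows must match expr cells")
        missing = set(GENE_META_COLUMNS) - set(self.gene_meta.columns)
        if missing:
            raise ValueError(f"gene_meta lacks columns {sorted(missing)}")
        if not self.gene_meta.index.equals(self.expr.columns):
            raise ValueError("gene_meta index must match expr genes")
        if int(self.gene_meta["signature"].sum()) > 100:
            raise ValueError("signature gene set exceeds 100 genes")

    @property
    def n_cells(self) -> int:
        return len(self.expr.index)

    def genes(self, flag: str) -> pd.Index:
        return self.gene_meta.index[self.gene_meta[flag].astype(bool)]

    def to_anndata(self):
        """AnnData view (X = counts, obsm['guide_umi'], var = gene_meta)."""
        import anndata as ad

        adata = ad.AnnData(
            X=self.expr.to_numpy(dtype=np.float32),
            obs=pd.DataFrame(index=self.expr.index),
            var=self.gene_meta.copy(),
        )
        adata.obsm["guide_umi"] = self.guide_umi.to_numpy(dtype=np.float32)
        adata.uns["guide_ids"] = list(self.guide_umi.columns)
        if self.cell_guide is not None:
            adata.obs["guide"] = self.cell_guide
        return adata


def assign_guides(ds: CellDataset, min_umi: int = 3) -> pd.DataFrame:
    """Detect guides per cell and classify assignment status.

    Returns a per-cell frame with ``n_guides_detected``, ``assigned_guide``
    (the single detected guide, else NA) and ``guide_status`` in
    {``single``, ``none``, ``multi``}.
    """
    detected = ds.guide_umi.to_numpy() >= min_umi
    n = detected.sum(axis=1)
    cols = ds.guide_umi.columns.to_numpy()
    assigned = np.where(n == 1, cols[detected.argmax(axis=1)], None)
    status = np.where(n == 1, "single", np.where(n == 0, "none", "multi"))
    return pd.DataFrame(
        {
            "n_guides_detected": n,
            "assigned_guide": assigned,
            "guide_status": status,
        },
        index=ds.expr.index,
    )


def compute_qc(
    ds: CellDataset,
    min_umi: int = 3,
    min_genes: int = 200,
    max_genes: int = 4500,
    max_mito: float = 0.10,
) -> pd.DataFrame:
    """Per-cell QC table combining transcriptome and guide criteria.

    ``status`` is ``pass`` or the first failed criterion in the order
    gene count, mitochondrial fraction, guide multiplicity
    (``fail_genes`` / ``fail_mito`` / ``fail_multi`` / ``fail_none``).
    """
    counts = ds.expr.to_numpy()
    genes_detected = (counts > 0).sum(axis=1)
    total = counts.sum(axis=1)
    mito_counts = ds.expr[ds.genes("mito")].sum(axis=1).to_numpy()
    with np.errstate(invalid="ignore"):
        mito_fraction = np.where(total > 0, mito_counts / np.maximum(total, 1), 0.0)
    qc = assign_guides(ds, min_umi=min_umi)
    qc.insert(0, "genes_detected", genes_detected)
    qc.insert(1, "mito_fraction", mito_fraction)
    status = np.full(ds.n_cells, "pass", dtype=object)
    guide_fail = np.where(
        qc["guide_status"] == "multi",
        "fail_multi",
        np.where(qc["guide_status"] == "none", "fail_none", "pass"),
    )
    status = np.where(guide_fail != "pass", guide_fail, status)
    status = np.where(mito_fraction > max_mito, "fail_mito", status)
    bad_genes = (genes_detected < min_genes) | (genes_detected > max_genes)
    status = np.where(bad_genes, "fail_genes", status)
    qc["status"] = status
    return qc


def qc_cells(ds: CellDataset, qc: pd.DataFrame) -> CellDataset:
    """Keep exactly the ``status == pass`` cells; record their guide."""
    keep = qc.index[qc["status"] == "pass"]
    if len(keep) == 0:
        tally = qc["status"].value_counts().to_dict()
        raise ValueError(f"all cells failed QC: {tally}")
    return CellDataset(
        expr=ds.expr.loc[keep],
        guide_umi=ds.guide_umi.loc[keep],
        gene_meta=ds.gene_meta,
        cell_guide=qc.loc[keep, "assigned_guide"].rename("guide"),
    )


def single_assignment_rate(qc_or_n_single, n_cells: int | None = None) -> float:
    """Percent of cells assigned exactly one guide.

    Accepts either a QC frame from :func:`assign_guides`/:func:`compute_qc`
    or the two raw totals (cells with a single guide, total cells).
    """
    if n_cells is None:
        qc = qc_or_n_single
        n_single = int((qc["guide_status"] == "single").sum())
        n_cells = len(qc.index)
    else:
        n_single = int(qc_or_n_single)
    if n_cells <= 0:
        raise ValueError("no cells")
    return 100.0 * n_single / n_cells


def normalize_log(ds: CellDataset, target_sum: float = 1e4) -> pd.DataFrame:
    """Depth-normalize to ``target_sum`` counts per cell, then log(1 + x)."""
    totals = ds.expr.sum(axis=1)
    if (totals == 0).any():
        zero = list(totals.index[totals == 0][:5])
        raise ValueError(f"zero-count cells (should have failed QC): {zero}")
    return np.log1p(ds.expr.div(totals, axis=0) * target_sum)


@dataclass
class PseudotimeTable:
    """Per-cell pseudotime tau in [0,1] plus per-guide medians."""

    tau: pd.Series
    per_guide_median: pd.Series
    min_cells: int = 3


def _pc1_scores(centered: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """First principal component scores and loadings of a centered matrix."""
    from sklearn.decomposition import PCA

    if np.allclose(centered, 0):
        raise ValueError("degenerate (zero-variance) matrix")
    pca = PCA(n_components=1, svd_solver="full")
    scores = pca.fit_transform(centered)[:, 0]
    return scores, pca.components_[0]


def signature_pseudotime(
    ds: CellDataset,
    min_cells: int = 3,
    external_tau: pd.Series | None = None,
) -> PseudotimeTable:
    """Differentiation pseudotime per cell plus per-guide medians.

    tau is the min-max-scaled PC1 of the centered log-normalized
    signature-gene submatrix, oriented to correlate positively with the
    mean differentiation-marker expression (negatively with leukemia
    markers when no differentiation markers are annotated).  If
    ``external_tau`` is given it is used verbatim (after [0,1] check)
    instead of the PC1 score.  Guides with fewer than ``min_cells`` cells
    are dropped from the median table.
    """
    if ds.cell_guide is None:
        raise ValueError("dataset has no per-cell guide; run qc_cells first")
    norm = normalize_log(ds)
    if external_tau is not None:
        tau = external_tau.reindex(ds.expr.index).astype(float)
        if tau.isna().any() or (tau < 0).any() or (tau > 1).any():
            raise ValueError("external tau must cover all cells within [0,1]")
    else:
        sig = ds.genes("signature")
        if len(sig) < 2:
            raise ValueError("need >= 2 signature genes")
        if ds.n_cells < 10:
            raise ValueError("need >= 10 QC-passed cells")
        x = norm[sig].to_numpy()
        raw, _ = _pc1_scores(x - x.mean(axis=0))
        lo, hi = raw.min(), raw.max()
        if hi == lo:
            raise ValueError("degenerate (zero-variance) signature matrix")
        tau = pd.Series((raw - lo) / (hi - lo), index=ds.expr.index, name="tau")
        diff_genes = ds.genes("diff_marker")
        leuk_genes = ds.genes("leukemia_marker")
        if len(diff_genes):
            anchor = norm[diff_genes].mean(axis=1)
            flip = np.corrcoef(tau, anchor)[0, 1] < 0
        elif len(leuk_genes):
            anchor = norm[leuk_genes].mean(axis=1)
            flip = np.corrcoef(tau, anchor)[0, 1] > 0
        else:
            flip = False
        if flip:
            tau = 1.0 - tau
    medians = tau.groupby(ds.cell_guide).median()
    sizes = ds.cell_guide.value_counts()
    keep = sizes.index[sizes >= min_cells]
    return PseudotimeTable(
        tau=tau,
        per_guide_median=medians.loc[medians.index.isin(keep)],
        min_cells=min_cells,
    )


def pseudotime_residue_track(
    pt: PseudotimeTable,
    lib: GuideLibrary,
    bandwidth_nt: float | None = None,
) -> ResidueTrack:
    """Smooth per-guide pseudotime medians along the gene body.

    Guides without enough cells are simply absent, which enlarges the
    effective gaps the kernel must bridge.
    """
    from .scan import kernel_smooth

    tiling_ids = {g.guide_id for g in lib.tiling}
    values = pt.per_guide_median[pt.per_guide_median.index.isin(tiling_ids)]
    if len(values) < 2:
        raise ValueError("need per-guide medians for >= 2 tiling guides")
    return kernel_smooth(values, lib, bandwidth_nt=bandwidth_nt, source="pseudotime")


@dataclass
class PseudobulkMatrix:
    """Residue x signature-gene smoothed pseudobulk expression profiles."""

    profile: pd.DataFrame  # index 1..protein_length_aa, columns genes
    bandwidth_nt: float

    @property
    def n_residues(self) -> int:
        return len(self.profile.index)


def pseudobulk_profiles(
    ds: CellDataset,
    lib: GuideLibrary,
    min_cells: int = 3,
    bandwidth_nt: float | None = None,
) -> PseudobulkMatrix:
    """Per-gene smoothed gene-body expression tracks.

    For each signature gene, the per-guide mean of log-normalized
    expression over that guide's cells is kernel-smoothed along the CDS;
    every gene shares the same guide set, so one smoother matrix maps the
    guide x gene mean matrix to the residue x gene profile.
    """
    if ds.cell_guide is None:
        raise ValueError("dataset has no per-cell guide; run qc_cells first")
    sig = ds.genes("signature")
    if len(sig) < 2:
        raise ValueError("need >= 2 signature genes")
    norm = normalize_log(ds)[sig]
    means = norm.groupby(ds.cell_guide).mean()
    sizes = ds.cell_guide.value_counts()
    tiling_ids = {g.guide_id for g in lib.tiling}
    keep = [
        gid
        for gid in means.index
        if gid in tiling_ids and sizes[gid] >= min_cells
    ]
    if len(keep) < 2:
        raise ValueError("need >= 2 tiling guides with enough cells")
    h = float(bandwidth_nt) if bandwidth_nt is not None else default_bandwidth(lib)
    m = smoother_matrix(lib, keep, h)
    profile = pd.DataFrame(
        m @ means.loc[keep].to_numpy(),
        index=pd.RangeIndex(1, lib.protein_length_aa + 1, name="residue"),
        columns=sig,
    )
    return PseudobulkMatrix(profile=profile, bandwidth_nt=h)


@dataclass
class CorrelationMatrix:
    """Residue x residue Pearson correlations of pseudobulk profiles."""

    r: pd.DataFrame

    def __post_init__(self) -> None:
        vals = self.r.to_numpy()
        finite = np.isfinite(vals)
        if ((vals[finite] < -1 - 1e-12) | (vals[finite] > 1 + 1e-12)).any():
            raise ValueError("correlations outside [-1, 1]")


def position_correlation(pm: PseudobulkMatrix) -> CorrelationMatrix:
    """Position-ordered Pearson correlation matrix between residue profiles.

    Each gene column is centered by its mean across residues first, so the
    correlations reflect position-specific expression shifts rather than
    the shared per-gene baseline (absolute expression levels would make
    every pair of positions look alike).  Zero-variance residue rows have
    undefined correlation and are emitted as missing (NaN); the diagonal
    of defined rows is exactly 1 and values are clamped to [-1, 1].
    """
    x = pm.profile.to_numpy()
    if x.shape[1] < 2:
        raise ValueError("need >= 2 signature genes (columns)")
    x = x - x.mean(axis=0)
    sd = x.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(x)
    r = np.clip(r, -1.0, 1.0)
    bad = sd == 0
    r[bad, :] = np.nan
    r[:, bad] = np.nan
    np.fill_diagonal(r, np.where(bad, np.nan, 1.0))
    idx = pm.profile.index
    return CorrelationMatrix(r=pd.DataFrame(r, index=idx, columns=idx))


def residue_pc1(
    pm: PseudobulkMatrix,
    orient_track: ResidueTrack | np.ndarray | None = None,
) -> ResidueTrack:
    """Per-residue score on the first principal component of the profiles.

    Columns (genes) are centered across residues before the decomposition.
    When an orientation track (typically the pseudotime residue track) is
    supplied, the sign is flipped if needed so that PC1 correlates
    positively with it; otherwise the sign is fixed deterministically by
    making the largest-magnitude gene loading positive.
    """
    x = pm.profile.to_numpy()
    scores, loadings = _pc1_scores(x - x.mean(axis=0))
    if orient_track is not None:
        ref = (
            orient_track.scores
            if isinstance(orient_track, ResidueTrack)
            else np.asarray(orient_track, dtype=float)
        )
        if len(ref) != len(scores):
            raise ValueError("orientation track length mismatch")
        if np.corrcoef(scores, ref)[0, 1] < 0:
            scores = -scores
    elif loadings[np.argmax(np.abs(loadings))] < 0:
        scores = -scores
    return ResidueTrack(
        scores=scores, bandwidth_nt=pm.bandwidth_nt, source="expression:PC1"
    )


def group_de(
    ds: CellDataset,
    lib: GuideLibrary,
    region_a: ResidueSpan,
    reference: str | ResidueSpan = "neg_control",
    min_cells_group: int = 10,
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Differential expression: region-targeting cells vs reference cells.

    Cells are grouped by the cut codon of their assigned guide
    (``region_a``) against cells carrying negative-control guides (or a
    second residue span).  Per gene: mean log-normalized difference
    (region - reference), Wilcoxon rank-sum p-value, Benjamini-Hochberg
    FDR, and a ``significant`` call at ``fdr_threshold``.
    """
    from statsmodels.stats.multitest import multipletests

    if ds.cell_guide is None:
        raise ValueError("dataset has no per-cell guide; run qc_cells first")

    def _cells_for(sel: str | ResidueSpan) -> pd.Index:
        if isinstance(sel, ResidueSpan):
            ids = {
                g.guide_id for g in lib.tiling if cut_codon(g) in sel
            }
        else:
            ids = {g.guide_id for g in lib.guides if g.category == sel}
        return ds.expr.index[ds.cell_guide.isin(ids)]

    cells_a = _cells_for(region_a)
    cells_ref = _cells_for(reference)
    for name, cells in (("region", cells_a), ("reference", cells_ref)):
        if len(cells) < min_cells_group:
            raise ValueError(
                f"{name} group has {len(cells)} cells (< {min_cells_group})"
            )
    norm = normalize_log(ds)
    xa = norm.loc[cells_a].to_numpy()
    xr = norm.loc[cells_ref].to_numpy()
    diff = xa.mean(axis=0) - xr.mean(axis=0)
    flat = np.array(
        [np.ptp(np.concatenate([xa[:, j], xr[:, j]])) == 0 for j in range(xa.shape[1])]
    )
    pvals = np.ones(xa.shape[1])
    if (~flat).any():
        res = sps.mannwhitneyu(
            xa[:, ~flat], xr[:, ~flat], alternative="two-sided", axis=0
        )
        pvals[~flat] = res.pvalue
    _, fdr, _, _ = multipletests(pvals, method="fdr_bh")
    return pd.DataFrame(
        {
            "mean_diff": diff,
            "pvalue": pvals,
            "fdr": fdr,
            "significant": fdr < fdr_threshold,
        },
        index=norm.columns.rename("gene"),
    )


def embed_2d(norm: pd.DataFrame, random_state: int = 0) -> np.ndarray:
    """Generic 2-D embedding hook (PCA) for visualization only."""
    from sklearn.decomposition import PCA

    x = norm.to_numpy()
    return PCA(n_components=2, random_state=random_state).fit_transform(
        x - x.mean(axis=0)
    )
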
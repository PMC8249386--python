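"""Survival tiling-screen scoring and gene-body smoothing.

The CRISPR score (CS) of a guide is the log10 fold-change of its library
frequency between the early (day 0) and a late screen timepoint, computed
as a pseudocounted count ratio so that zero counts stay finite::

    CS(g) = log10( (c_late + pc) / (T_late + pc*N)
                 / ((c_early + pc) / (T_early + pc*N)) )

The normalized CRISPR score (NCS) anchors CS to the spiked-in controls:
the negative-control median maps to 0.00 and the positive-control
(essential-gene) median to -1.00, i.e. ``NCS = (CS - med_neg) /
(med_neg - med_pos)``.  NCS is an affine map of CS, so guide rank order is
preserved and smoothing commutes with the normalization.

Per-residue tracks are obtained by Gaussian (Nadaraya-Watson) kernel
smoothing of per-guide values along the CDS: the smoothed signal is
evaluated at every nucleotide, with the bandwidth defaulting to the maximum
gap between consecutive guide cut sites (so no region is out of reach of
the kernel), then averaged over each trinucleotide codon to give one value
per peptide position.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .counting import FrequencyTable, ReadCountMatrix, to_frequencies
from .library import GuideLibrary, cut_codon

__all__ = [
    "ScoreTrack",
    "ResidueTrack",
    "crispr_score",
    "normalize_ncs",
    "default_bandwidth",
    "smoother_matrix",
    "kernel_smooth",
    "scan_pipeline",
]


@dataclass
class ScoreTrack:
    """Per-guide scores (CS or NCS) for one condition/timepoint contrast."""

    values: pd.Series  # guide_id -> score; excluded guides absent
    condition: str = ""
    timepoint: str = ""
    normalized: bool = False

    def __post_init__(self) -> None:
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise ValueError("non-finite guide scores")

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class ResidueTrack:
    """Smoothed per-residue scores over the whole protein."""

    scores: np.ndarray  # shape (protein_length_aa,), residue r at index r-1
    bandwidth_nt: float
    source: str = "survival"
    condition: str = ""

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)

    def __len__(self) -> int:
        return len(self.scores)

    def to_series(self) -> pd.Series:
        return pd.Series(
            self.scores, index=np.arange(1, len(self.scores) + 1), name="score"
        ).rename_axis("residue")

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"# bandwidth_nt={self.bandwidth_nt}\n")
            fh.write(f"# source={self.source}\n")
            if self.condition:
                fh.write(f"# condition={self.condition}\n")
            self.to_series().to_frame().to_csv(fh, sep="\t")


def crispr_score(
    freqs: FrequencyTable,
    early: str,
    late: str,
    pseudocount: float = 0.5,
) -> ScoreTrack:
    """CS per guide: log10 frequency fold-change late vs early.

    Guides in the exclusion set are absent from the result (not zero).
    """
    for s in (early, late):
        if s not in freqs.counts.columns:
            raise ValueError(f"sample {s!r} not present")
    kept = freqs.kept
    n = freqs.n_guides
    pc = pseudocount
    c_e = freqs.counts.loc[kept, early].to_numpy(dtype=float)
    c_l = freqs.counts.loc[kept, late].to_numpy(dtype=float)
    t_e = float(freqs.totals[early])
    t_l = float(freqs.totals[late])
    f_e = (c_e + pc) / (t_e + pc * n)
    f_l = (c_l + pc) / (t_l + pc * n)
    cs = np.log10(f_l / f_e)
    return ScoreTrack(
        values=pd.Series(cs, index=kept, name="cs"),
        timepoint=f"{early}->{late}",
    )


def normalize_ncs(cs: ScoreTrack, lib: GuideLibrary) -> ScoreTrack:
    """Anchor CS to the control guides (neg median -> 0, pos median -> -1)."""
    neg = [g.guide_id for g in lib.neg_controls if g.guide_id in cs.values.index]
    pos = [g.guide_id for g in lib.pos_controls if g.guide_id in cs.values.index]
    if not neg or not pos:
        raise ValueError(
            "normalization needs scored guides of both control classes "
            f"(neg={len(neg)}, pos={len(pos)})"
        )
    med_neg = float(np.median(cs.values[neg]))
    med_pos = float(np.median(cs.values[pos]))
    if med_neg == med_pos:
        raise ValueError("degenerate controls: identical class medians")
    ncs = (cs.values - med_neg) / (med_neg - med_pos)
    return ScoreTrack(
        values=ncs.rename("ncs"),
        condition=cs.condition,
        timepoint=cs.timepoint,
        normalized=True,
    )


def default_bandwidth(lib: GuideLibrary) -> float:
    """Maximum gap (nt) between consecutive distinct tiling cut sites."""
    cuts = np.unique([g.cds_cut_nt for g in lib.tiling])
    if len(cuts) < 2:
        raise ValueError("need >= 2 distinct tiling cut positions")
    return float(np.diff(cuts).max())


def smoother_matrix(
    lib: GuideLibrary,
    guide_ids: Sequence[str],
    bandwidth_nt: float | None = None,
) -> np.ndarray:
    """Residue x guide convex-weight matrix of the codon-averaged kernel.

    Row r (0-based residue r+1) holds the weights that map per-guide values
    to the smoothed score of that residue; rows sum to 1.  Smoothing any
    value vector is then a single matrix product, which also makes the
    per-gene pseudobulk smoothing a one-shot operation.
    """
    by_id = {g.guide_id: g for g in lib.tiling}
    missing = [gid for gid in guide_ids if gid not in by_id]
    if missing:
        raise ValueError(f"not tiling guides of this library: {missing[:5]}")
    if len(guide_ids) < 2:
        raise ValueError("need >= 2 scored tiling guides to smooth")
    x = np.array([by_id[gid].cds_cut_nt for gid in guide_ids], dtype=float)
    h = float(bandwidth_nt) if bandwidth_nt is not None else default_bandwidth(lib)
    if h <= 0:
        raise ValueError("bandwidth must be positive")
    n_res = lib.protein_length_aa
    p = np.arange(1, 3 * n_res + 1, dtype=float)
    while True:
        w = np.exp(-((p[:, None] - x[None, :]) ** 2) / (2.0 * h * h))
        rowsum = w.sum(axis=1)
        if (rowsum > 0).all():
            break
        # Tails underflow when guides are much farther than h from some
        # nucleotide; cannot occur with the max-gap default.
        h *= 2.0
        warnings.warn(
            f"kernel weights underflowed; widening bandwidth to {h} nt"
        )
    w /= rowsum[:, None]
    # codon averaging: residue r = mean over nucleotides 3r-2, 3r-1, 3r
    return w.reshape(n_res, 3, len(guide_ids)).mean(axis=1)


def kernel_smooth(
    track: ScoreTrack | pd.Series,
    lib: GuideLibrary,
    bandwidth_nt: float | None = None,
    source: str = "survival",
) -> ResidueTrack:
    """Gaussian-kernel smooth per-guide values into a per-residue track."""
    values = track.values if isinstance(track, ScoreTrack) else track
    tiling_ids = {g.guide_id for g in lib.tiling}
    values = values[values.index.isin(tiling_ids)]
    h = float(bandwidth_nt) if bandwidth_nt is not None else default_bandwidth(lib)
    m = smoother_matrix(lib, list(values.index), h)
    cond = track.condition if isinstance(track, ScoreTrack) else ""
    return ResidueTrack(
        scores=m @ values.to_numpy(dtype=float),
        bandwidth_nt=h,
        source=source,
        condition=cond,
    )


def scan_pipeline(
    counts: ReadCountMatrix,
    lib: GuideLibrary,
    early: str | Sequence[str],
    late: str | Sequence[str],
    normalize: bool = True,
    bandwidth_nt: float | None = None,
    pseudocount: float = 0.5,
    min_frac_of_expected: float = 0.05,
) -> tuple[ResidueTrack, ScoreTrack]:
    """Counts -> (smoothed residue track, per-guide score track).

    ``early``/``late`` may be lists of replicate sample ids (paired in
    order); replicate CS columns are averaged on the CS scale before
    normalization and smoothing.
    """
    earlies = [early] if isinstance(early, str) else list(early)
    lates = [late] if isinstance(late, str) else list(late)
    if len(earlies) != len(lates):
        raise ValueError("early/late replicate lists must pair up")
    freqs = to_frequencies(
        counts, lib, min_frac_of_expected=min_frac_of_expected,
        reference=earlies[0],
    )
    reps = [
        crispr_score(freqs, e, l, pseudocount=pseudocount).values
        for e, l in zip(earlies, lates)
    ]
    cs = ScoreTrack(
        values=pd.concat(reps, axis=1).mean(axis=1).rename("cs"),
        timepoint=f"{earlies[0]}->{lates[0]}",
    )
    guide_track = normalize_ncs(cs, lib) if normalize else cs
    residue_track = kernel_smooth(guide_track, lib, bandwidth_nt=bandwidth_nt)
    return residue_track, guide_track
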
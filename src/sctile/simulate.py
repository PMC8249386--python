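"""Seeded synthetic-data generators with ground-truth ledgers.

Every downstream stage of the pipeline is exercised against data whose
truth is known: a jittered-grid tiling library, pooled survival screens in
which designated residue windows carry a per-day fitness cost (frequency of
a guide decays as ``2^(fitness * day)``), raw amplicon reads wrapping each
spacer in its vector backbone, and single-cell datasets in which a latent
differentiation state, shifted by guides that hit essential windows, drives
signature and marker genes through negative-binomial counts, with planted
multiplets, unassigned cells, mitochondrial contamination and low-gene
failures.

Default parameters mirror the study conditions this package models: a
1537-aa target protein tiled by 602 guides (7.7 bp per guide over the
4614-nt CDS including the stop codon), 25 negative + 25 positive controls,
a 12-day screen at roughly 1000x read coverage, functional windows at
residues 127-332 (catalytic core), 460-555 and 558-662 (regulatory
elements, the latter drug-interacting), and ~4900 cells with an 8%
multiplet rate (~88% of cells carrying exactly one guide).

All randomness flows from a single integer seed; a fixed seed reproduces
bit-identical outputs.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .counting import ReadCountMatrix
from .library import GuideLibrary, GuideRecord, ResidueSpan, cut_codon

__all__ = [
    "WindowEffect",
    "SimConfig",
    "ScreenSim",
    "simulate_library",
    "simulate_screen",
    "write_screen_fastq",
    "simulate_sc",
    "simulate_flow",
]

_SALTS = {"library": 0, "control": 1, "drug": 2, "sc": 3, "fastq": 4, "flow": 5}


def _rng(seed: int, stage: str) -> np.random.Generator:
    salt = _SALTS.get(stage)
    if salt is None:
        salt = 10 + zlib.crc32(stage.encode()) % 65536
    return np.random.default_rng([int(seed), salt])


@dataclass(frozen=True)
class WindowEffect:
    """A residue window with a planted phenotype.

    ``fitness_per_day`` (<= 0) is the log2 frequency change per day of
    guides cutting inside the window in the control arm;
    ``drug_fitness_per_day`` replaces it under the drug condition (default:
    same as control).  ``shifts_differentiation`` controls whether the
    window's guides push cells along the latent differentiation axis in
    the single-cell simulation.
    """

    span: ResidueSpan
    fitness_per_day: float
    drug_fitness_per_day: float | None = None
    shifts_differentiation: bool = True

    def __post_init__(self) -> None:
        if self.fitness_per_day > 0:
            raise ValueError("control-arm fitness must be <= 0")

    def fitness(self, condition: str) -> float:
        if condition == "drug" and self.drug_fitness_per_day is not None:
            return self.drug_fitness_per_day
        return self.fitness_per_day


def _default_windows() -> tuple[WindowEffect, ...]:
    return (
        WindowEffect(ResidueSpan(127, 332), -0.25),  # catalytic core
        WindowEffect(ResidueSpan(460, 555), -0.10, drug_fitness_per_day=-0.30),
        WindowEffect(
            ResidueSpan(558, 662),
            0.0,
            drug_fitness_per_day=0.15,
            shifts_differentiation=False,
        ),
    )


@dataclass
class SimConfig:
    """All knobs of the synthetic study, with study-scale defaults."""

    seed: int
    # library geometry
    protein_length_aa: int = 1537
    n_guides: int = 602
    n_neg: int = 25
    n_pos: int = 25
    stop_included: bool = True
    jitter: bool = True
    essential_windows: tuple[WindowEffect, ...] = field(
        default_factory=_default_windows
    )
    # survival screen
    reads_per_sample: int = 600_000
    days: tuple[int, ...] = (0, 12)
    abundance_sigma: float = 0.5
    pos_control_fitness: float = -0.25
    dropout_fraction: float = 0.0
    decoy_fraction: float = 0.05
    # single-cell stage
    n_cells: int = 4943
    n_signature: int = 100
    n_background: int = 300
    n_mito: int = 10
    multiplet_rate: float = 0.08
    no_guide_rate: float = 0.04
    sc_effect_size: float = 1.0
    nb_dispersion: float = 0.15
    mean_counts_per_cell: float = 3000.0
    guide_umi_mean: float = 20.0
    mito_base_fraction: float = 0.03
    mito_fail_fraction: float = 0.25
    mito_fail_rate: float = 0.02
    low_gene_fail_rate: float = 0.02
    marker_slope: float = 1.2

    def __post_init__(self) -> None:
        self.essential_windows = tuple(
            self._coerce_window(w) for w in self.essential_windows
        )
        for name in (
            "multiplet_rate",
            "no_guide_rate",
            "dropout_fraction",
            "decoy_fraction",
            "mito_fail_rate",
            "low_gene_fail_rate",
        ):
            if not (0.0 <= getattr(self, name) <= 1.0):
                raise ValueError(f"{name} must be a rate in [0, 1]")
        if self.n_signature > 100:
            raise ValueError("signature set is capped at 100 genes")
        for w in self.essential_windows:
            if w.span.end_aa > self.protein_length_aa:
                raise ValueError(f"window {w.span} outside the protein")

    @staticmethod
    def _coerce_window(w) -> WindowEffect:
        """Accept WindowEffect objects, [start, end, fitness, ...] lists, or
        dicts (e.g. from a JSON config)."""
        if isinstance(w, WindowEffect):
            return w
        if isinstance(w, dict):
            w = dict(w)
            span = ResidueSpan(int(w.pop("start_aa")), int(w.pop("end_aa")))
            return WindowEffect(span=span, **w)
        start, end, fitness, *rest = w
        return WindowEffect(ResidueSpan(int(start), int(end)), float(fitness), *rest)

    @property
    def cds_length_nt(self) -> int:
        extra = 1 if self.stop_included else 0
        return 3 * (self.protein_length_aa + extra)


def _random_spacers(rng: np.random.Generator, n: int) -> list[str]:
    letters = np.array(list("ACGT"))
    out: set[str] = set()
    while len(out) < n:
        block = letters[rng.integers(0, 4, size=(n - len(out), 20))]
        out.update("".join(row) for row in block)
    ordered = sorted(out)
    rng.shuffle(ordered)  # type: ignore[arg-type]
    return list(ordered)[:n]


def simulate_library(cfg: SimConfig) -> tuple[GuideLibrary, dict]:
    """Jittered-grid tiling library plus its window-membership ledger."""
    cds = cfg.cds_length_nt
    if cfg.n_guides > cds:
        raise ValueError(
            f"cannot place {cfg.n_guides} distinct guides on a {cds}-nt CDS"
        )
    rng = _rng(cfg.seed, "library")
    spacing = cds / cfg.n_guides
    base = np.round((np.arange(cfg.n_guides) + 0.5) * spacing).astype(int)
    j = int(spacing // 3) if cfg.jitter else 0
    pos = base + (rng.integers(-j, j + 1, size=cfg.n_guides) if j else 0)
    pos = np.clip(pos, 1, cds)
    for i in range(1, len(pos)):  # keep positions strictly increasing
        if pos[i] <= pos[i - 1]:
            pos[i] = pos[i - 1] + 1
    for i in range(len(pos) - 1, 0, -1):
        if pos[i] > cds:
            pos[i] = cds
        if pos[i - 1] >= pos[i]:
            pos[i - 1] = pos[i] - 1
    if pos[0] < 1:
        raise ValueError("infeasible tiling density")

    spacers = iter(_random_spacers(rng, cfg.n_guides + cfg.n_neg + cfg.n_pos))
    guides = [
        GuideRecord(
            guide_id=f"T{i + 1:04d}",
            spacer=next(spacers),
            category="tiling",
            cds_cut_nt=int(p),
            strand="+" if rng.random() < 0.5 else "-",
        )
        for i, p in enumerate(pos)
    ]
    guides += [
        GuideRecord(f"NEG{i + 1:02d}", next(spacers), "neg_control")
        for i in range(cfg.n_neg)
    ]
    guides += [
        GuideRecord(f"POS{i + 1:02d}", next(spacers), "pos_control")
        for i in range(cfg.n_pos)
    ]
    lib = GuideLibrary(
        guides=guides,
        cds_length_nt=cds,
        protein_length_aa=cfg.protein_length_aa,
    )
    window_of_guide = {}
    for g in lib.tiling:
        codon = cut_codon(g)
        window_of_guide[g.guide_id] = next(
            (k for k, w in enumerate(cfg.essential_windows) if codon in w.span),
            None,
        )
    ledger = {
        "window_of_guide": window_of_guide,
        "spacing_nt": spacing,
        "jitter_nt": j,
    }
    return lib, ledger


def guide_fitness(
    cfg: SimConfig, lib: GuideLibrary, condition: str = "control"
) -> pd.Series:
    """Planted per-day log2 frequency slope of every guide."""
    out = {}
    for g in lib.guides:
        if g.category == "neg_control":
            f = 0.0
        elif g.category == "pos_control":
            f = cfg.pos_control_fitness
        else:
            codon = cut_codon(g)
            f = 0.0
            for w in cfg.essential_windows:
                if codon in w.span:
                    f = w.fitness(condition)
                    break
        out[g.guide_id] = f
    return pd.Series(out, name="fitness_per_day")


@dataclass
class ScreenSim:
    """Simulated pooled screen with its truth ledger."""

    counts: ReadCountMatrix
    fitness: pd.Series
    expected_cs: pd.Series
    baseline_freq: pd.Series
    dropout: frozenset[str]
    condition: str


def simulate_screen(
    cfg: SimConfig, lib: GuideLibrary, condition: str = "control"
) -> ScreenSim:
    """Multinomial read counts per timepoint under exponential selection.

    Baseline guide abundances are lognormal; at day ``t`` the expected
    frequency of guide ``g`` is proportional to ``f0(g) * 2^(fitness_g *
    t)``.  ``expected_cs`` is the exact expected log10 frequency
    fold-change between the first and last configured day, including the
    pool-renormalization term (as depleted guides vanish, every surviving
    guide's frequency rises, so the naive ``fitness * days * log10(2)``
    closed form only holds when the depleted fraction of the pool is
    small).
    """
    rng = _rng(cfg.seed, condition)
    ids = lib.guide_ids
    w0 = rng.lognormal(mean=0.0, sigma=cfg.abundance_sigma, size=len(ids))
    dropout: frozenset[str] = frozenset()
    if cfg.dropout_fraction > 0:
        tiling_ids = [g.guide_id for g in lib.tiling]
        k = int(round(cfg.dropout_fraction * len(tiling_ids)))
        chosen = rng.choice(len(tiling_ids), size=k, replace=False)
        dropout = frozenset(tiling_ids[i] for i in chosen)
        mask = np.array([gid in dropout for gid in ids])
        w0 = np.where(mask, w0 * 1e-4, w0)
    fitness = guide_fitness(cfg, lib, condition)
    f = fitness.loc[ids].to_numpy()
    cols = {}
    for t in cfg.days:
        w = w0 * np.power(2.0, f * t)
        cols[f"d{t}"] = rng.multinomial(cfg.reads_per_sample, w / w.sum())
    counts = pd.DataFrame(cols, index=pd.Index(ids, name="guide_id"), dtype=np.int64)
    stats = pd.DataFrame(
        {
            "reads_seen": counts.sum(axis=0),
            "with_backbone": counts.sum(axis=0),
            "matched": counts.sum(axis=0),
            "discarded": 0,
        }
    )
    t_early, t_late = cfg.days[0], cfg.days[-1]
    z_early = (w0 * np.power(2.0, f * t_early)).sum()
    z_late = (w0 * np.power(2.0, f * t_late)).sum()
    expected_cs = (
        fitness * (t_late - t_early) * np.log10(2.0) + np.log10(z_early / z_late)
    ).rename("expected_cs")
    return ScreenSim(
        counts=ReadCountMatrix(counts=counts, stats=stats),
        fitness=fitness,
        expected_cs=expected_cs,
        baseline_freq=pd.Series(w0 / w0.sum(), index=ids, name="f0"),
        dropout=dropout,
        condition=condition,
    )


def write_screen_fastq(
    counts: pd.Series,
    lib: GuideLibrary,
    path: str | Path,
    decoy_fraction: float = 0.05,
    seed: int = 0,
) -> dict:
    """Emit a FASTQ whose exact-match counts reproduce ``counts``.

    Each library read embeds its spacer in the ``CACCG...GTTT`` backbone
    with random flanks; decoys (the requested fraction of the final file)
    are split between backbone reads carrying a random non-library spacer
    and backbone-free random sequence.  Returns a ledger with the true
    per-guide counts and decoy tally.
    """
    rng = _rng(seed, "fastq")
    letters = np.array(list("ACGT"))

    def _rand_seq(n: int) -> str:
        return "".join(letters[rng.integers(0, 4, size=n)])

    spacer_of = {g.guide_id: g.spacer for g in lib.guides}
    known = set(spacer_of.values())
    reads: list[str] = []
    for gid, c in counts.items():
        for _ in range(int(c)):
            reads.append(
                _rand_seq(int(rng.integers(2, 9)))
                + "CACCG"
                + spacer_of[gid]
                + "GTTT"
                + _rand_seq(10)
            )
    n_lib = len(reads)
    n_decoy = int(round(n_lib * decoy_fraction / (1.0 - decoy_fraction)))
    for k in range(n_decoy):
        if k % 2 == 0:
            while True:  # backbone with an out-of-library spacer
                fake = _rand_seq(20)
                if fake not in known:
                    break
            reads.append(
                _rand_seq(int(rng.integers(2, 9))) + "CACCG" + fake + "GTTT"
                + _rand_seq(10)
            )
        else:
            reads.append(_rand_seq(45))
    order = rng.permutation(len(reads))
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        for i, idx in enumerate(order):
            seq = reads[idx]
            fh.write(f"@read{i}\n{seq}\n+\n{'I' * len(seq)}\n")
    return {
        "true_counts": {gid: int(c) for gid, c in counts.items()},
        "n_library_reads": n_lib,
        "n_decoys": n_decoy,
    }


def simulate_sc(cfg: SimConfig, lib: GuideLibrary):
    """Single-cell dataset with latent differentiation and planted failures.

    Each cell receives one guide (a multiplet pair at ``multiplet_rate``,
    none at ``no_guide_rate``).  A latent differentiation state ``d`` in
    [0, 1] is Beta-distributed: baseline Beta(2, 6) (undifferentiated,
    leukemia-like), shifted toward Beta(2 + 4*effect, 6 - 4*effect) for
    cells whose guide cuts a differentiation-shifting window.  Leukemia
    markers and half the signature genes decrease log-linearly in ``d``;
    differentiation markers and the other half increase.  Counts are
    negative-binomial (gamma-Poisson).  QC failures are planted at set
    rates: low-gene cells keep only 150 expressed genes; high-mito cells
    have their mitochondrial load boosted to ~16% of reads.

    Returns ``(CellDataset, ledger)`` where the ledger records the true
    tau (latent d), the guides of every cell, the planted QC label, and
    the realized multiplet fraction.
    """
    from .singlecell import CellDataset

    rng = _rng(cfg.seed, "sc")
    n = cfg.n_cells
    ids = lib.guide_ids
    n_guides = len(ids)

    u = rng.random(n)
    is_multi = u < cfg.multiplet_rate
    is_none = (~is_multi) & (u < cfg.multiplet_rate + cfg.no_guide_rate)
    primary = rng.integers(0, n_guides, size=n)
    second = (primary + 1 + rng.integers(0, n_guides - 1, size=n)) % n_guides

    shifting = np.zeros(n_guides, dtype=bool)
    for i, g in enumerate(lib.guides):
        if g.category == "tiling":
            codon = cut_codon(g)
            shifting[i] = any(
                codon in w.span and w.shifts_differentiation
                for w in cfg.essential_windows
            )
    cell_shift = np.where(
        is_none,
        False,
        shifting[primary] | (is_multi & shifting[second]),
    )
    e = cfg.sc_effect_size
    a = np.where(cell_shift, 2.0 + 4.0 * e, 2.0)
    b = np.where(cell_shift, max(6.0 - 4.0 * e, 0.5), 6.0)
    d = rng.beta(a, b)

    # gene panel
    mito_genes = [f"mt-g{i + 1:02d}" for i in range(cfg.n_mito)]
    leuk = ["Meis1", "Hoxa9", "Myc"]
    diff = ["Cd11b", "Gr1", "Ltf"]
    sig = [f"SIG{i + 1:03d}" for i in range(cfg.n_signature)]
    background = [f"BG{i + 1:03d}" for i in range(cfg.n_background)]
    genes = mito_genes + leuk + diff + sig + background
    gene_index = pd.Index(genes, name="gene")
    n_genes = len(genes)

    base = rng.lognormal(mean=0.0, sigma=1.0, size=n_genes)
    mito_slice = slice(0, cfg.n_mito)
    non_mito_sum = base[cfg.n_mito :].sum()
    base[mito_slice] *= (
        cfg.mito_base_fraction
        / (1.0 - cfg.mito_base_fraction)
        * non_mito_sum
        / base[mito_slice].sum()
    )
    slope = np.zeros(n_genes)
    off = cfg.n_mito
    slope[off : off + 3] = -cfg.marker_slope  # leukemia markers fall with d
    slope[off + 3 : off + 6] = cfg.marker_slope  # differentiation markers rise
    half = cfg.n_signature // 2
    slope[off + 6 : off + 6 + half] = cfg.marker_slope
    slope[off + 6 + half : off + 6 + cfg.n_signature] = -cfg.marker_slope

    # planted QC failures, disjoint sets
    perm = rng.permutation(n)
    n_lowgene = int(round(cfg.low_gene_fail_rate * n))
    n_mitofail = int(round(cfg.mito_fail_rate * n))
    lowgene_cells = perm[:n_lowgene]
    mitofail_cells = perm[n_lowgene : n_lowgene + n_mitofail]

    rates = base[None, :] * np.exp(slope[None, :] * (d[:, None] - 0.5) * 2.0)
    boost = (
        cfg.mito_fail_fraction
        / (1.0 - cfg.mito_fail_fraction)
        / (cfg.mito_base_fraction / (1.0 - cfg.mito_base_fraction))
    )
    rates[mitofail_cells, mito_slice] *= boost
    totals = rng.lognormal(np.log(cfg.mean_counts_per_cell), 0.25, size=n)
    lam = rates / rates.sum(axis=1, keepdims=True) * totals[:, None]
    if cfg.nb_dispersion > 0:
        lam = lam * rng.gamma(
            1.0 / cfg.nb_dispersion, cfg.nb_dispersion, size=lam.shape
        )
    counts = rng.poisson(lam).astype(np.int64)
    for c in lowgene_cells:  # keep 150 genes, silence the rest
        keep = rng.choice(n_genes, size=150, replace=False)
        mask = np.ones(n_genes, dtype=bool)
        mask[keep] = False
        counts[c, mask] = 0

    # guide captures: assigned guides always detectable, ambient never
    umi = np.zeros((n, n_guides), dtype=np.int64)
    assigned_umi = 3 + rng.poisson(max(cfg.guide_umi_mean - 3.0, 0.0), size=n)
    second_umi = 3 + rng.poisson(max(cfg.guide_umi_mean - 3.0, 0.0), size=n)
    rows = np.arange(n)
    has_primary = ~is_none
    umi[rows[has_primary], primary[has_primary]] = assigned_umi[has_primary]
    umi[rows[is_multi], second[is_multi]] = second_umi[is_multi]
    n_ambient = rng.poisson(1.0, size=n)
    for c in range(n):
        if n_ambient[c]:
            hit = rng.integers(0, n_guides, size=n_ambient[c])
            for g_idx in hit:
                if umi[c, g_idx] == 0:
                    umi[c, g_idx] = rng.integers(1, 3)

    cells = pd.Index([f"CELL{i + 1:05d}" for i in range(n)], name="cell")
    gene_meta = pd.DataFrame(
        {
            "mito": [g in set(mito_genes) for g in genes],
            "signature": [g in set(sig) for g in genes],
            "leukemia_marker": [g in set(leuk) for g in genes],
            "diff_marker": [g in set(diff) for g in genes],
        },
        index=gene_index,
    )
    ds = CellDataset(
        expr=pd.DataFrame(counts, index=cells, columns=gene_index),
        guide_umi=pd.DataFrame(
            umi, index=cells, columns=pd.Index(ids, name="guide_id")
        ),
        gene_meta=gene_meta,
    )

    labels = np.full(n, "pass", dtype=object)
    labels[is_multi] = "fail_multi"
    labels[is_none] = "fail_none"
    labels[mitofail_cells] = "fail_mito"
    labels[lowgene_cells] = "fail_genes"
    cell_guides = {
        cells[c]: (
            []
            if is_none[c]
            else sorted({ids[primary[c]]} | ({ids[second[c]]} if is_multi[c] else set()))
        )
        for c in range(n)
    }
    ledger = {
        "tau": pd.Series(d, index=cells, name="true_tau"),
        "cell_guides": cell_guides,
        "qc_status": pd.Series(labels, index=cells, name="true_status"),
        "multiplet_fraction": float(is_multi.mean()),
        "shifted_cells": pd.Series(cell_shift, index=cells, name="shifted"),
    }
    return ds, ledger


def simulate_flow(
    seed: int,
    sensitivities: dict[str, float] | None = None,
    doses: Sequence[float] = (0.0, 0.25, 0.5, 1.0),
    days: Sequence[float] = (3, 6, 9, 12),
    n_replicates: int = 4,
    fp0_percent: float = 50.0,
    n0: float = 10_000.0,
    noise_sd: float = 0.02,
) -> pd.DataFrame:
    """Dose x day flow-count table for the competition-assay arithmetic.

    Each construct's FP+ odds decay as ``2^(-s * m * (t - 3))`` where ``s``
    is its drug sensitivity (per uM per day) — the control default of 1/3
    halves relative proliferation by day 9 at 0.5 uM, while a fully
    resistant construct (s = 0) keeps RP at 1.  Multiplicative lognormal
    noise perturbs the odds; live counts are arbitrary (they cancel).
    """
    if sensitivities is None:
        sensitivities = {"sg-Luc": 1.0 / 3.0, "V": 0.0}
    rng = _rng(seed, "flow")
    odds0 = fp0_percent / (100.0 - fp0_percent)
    rows = []
    for construct, s in sensitivities.items():
        for rep in range(1, n_replicates + 1):
            for m in doses:
                for t in days:
                    odds = odds0 * 2.0 ** (-s * m * (t - 3.0))
                    odds *= np.exp(rng.normal(0.0, noise_sd))
                    fp = 100.0 * odds / (1.0 + odds)
                    rows.append(
                        {
                            "construct": construct,
                            "replicate": f"r{rep}",
                            "day": float(t),
                            "live_count": float(n0 * rng.lognormal(0.0, 0.1)),
                            "fp_percent": fp,
                            "drug_um": float(m),
                        }
                    )
    return pd.DataFrame(rows)
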
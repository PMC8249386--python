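"""Shared fixtures: toy libraries, toy cell datasets, brute-force oracles."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from sctile.library import GuideLibrary, GuideRecord
from sctile.singlecell import CellDataset

_LETTERS = np.array(list("ACGT"))


def random_spacer(rng: np.random.Generator) -> str:
    return "".join(_LETTERS[rng.integers(0, 4, size=20)])


def make_uniform_library(
    n_codons: int = 50,
    cut_offset: int = 2,
    n_neg: int = 3,
    n_pos: int = 3,
    seed: int = 0,
) -> GuideLibrary:
    """One tiling guide per codon (cut at the offset-th codon nt), plus controls."""
    rng = np.random.default_rng(seed)
    guides = [
        GuideRecord(
            guide_id=f"T{r:03d}",
            spacer=random_spacer(rng),
            category="tiling",
            cds_cut_nt=3 * (r - 1) + cut_offset,
        )
        for r in range(1, n_codons + 1)
    ]
    guides += [
        GuideRecord(f"NEG{i}", random_spacer(rng), "neg_control")
        for i in range(1, n_neg + 1)
    ]
    guides += [
        GuideRecord(f"POS{i}", random_spacer(rng), "pos_control")
        for i in range(1, n_pos + 1)
    ]
    return GuideLibrary(
        guides=guides,
        cds_length_nt=3 * (n_codons + 1),
        protein_length_aa=n_codons,
    )


@pytest.fixture
def toy_lib() -> GuideLibrary:
    return make_uniform_library()


def brute_force_smooth(
    lib: GuideLibrary, values: pd.Series, bandwidth: float
) -> np.ndarray:
    """Independent Nadaraya-Watson oracle: explicit double loop over
    nucleotides and guides, then plain codon averaging."""
    cuts = {g.guide_id: g.cds_cut_nt for g in lib.tiling}
    xs = [cuts[g] for g in values.index]
    vs = list(values.to_numpy())
    n_res = lib.protein_length_aa
    per_nt = []
    for p in range(1, 3 * n_res + 1):
        num = den = 0.0
        for x, v in zip(xs, vs):
            w = np.exp(-((p - x) ** 2) / (2 * bandwidth**2))
            num += w * v
            den += w
        per_nt.append(num / den)
    out = []
    for r in range(1, n_res + 1):
        out.append(sum(per_nt[3 * (r - 1) : 3 * r]) / 3.0)
    return np.array(out)


@pytest.fixture
def smoothing_oracle():
    return brute_force_smooth


def make_cell_dataset(
    expr: pd.DataFrame,
    guide_umi: pd.DataFrame,
    mito: list[str] = (),
    signature: list[str] = (),
    leukemia: list[str] = (),
    diff: list[str] = (),
    cell_guide: pd.Series | None = None,
) -> CellDataset:
    genes = expr.columns
    meta = pd.DataFrame(
        {
            "mito": genes.isin(mito),
            "signature": genes.isin(signature),
            "leukemia_marker": genes.isin(leukemia),
            "diff_marker": genes.isin(diff),
        },
        index=genes,
    )
    return CellDataset(
        expr=expr, guide_umi=guide_umi, gene_meta=meta, cell_guide=cell_guide
    )
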
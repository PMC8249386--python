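"""Amplicon read counting for pooled tiling screens.

Spacer sequences are recovered from raw reads by their vector backbone
context (5'-CACCG upstream, GTTT immediately downstream of the 20-mer) and
counted against the library by exact dictionary lookup — the same
perfect-match rule used when amplicon reads are aligned and only 0-mismatch
hits are kept.  Guide frequencies are read counts over the per-sample total
matched to the library; guides whose baseline frequency falls below 5% of
the uniform expectation (1/|library|) are excluded from all downstream
analysis so that fold-changes are never computed on unreliable baselines.
"""

from __future__ import annotations

import gzip
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

from .library import GuideLibrary

__all__ = [
    "extract_spacer",
    "count_guides",
    "count_samples",
    "to_frequencies",
    "ReadCountMatrix",
    "FrequencyTable",
]

_BACKBONE_5 = "CACCG"
_BACKBONE_3 = "GTTT"
_SPACER_LEN = 20


def extract_spacer(read: str) -> str | None:
    """Pull the 20-nt spacer out of an amplicon read, or ``None``.

    The spacer is the 20-mer between the first ``CACCG`` occurrence that is
    followed, exactly 20 nt downstream, by ``GTTT``.  Occurrences whose +25
    window does not match this layout are passed over (single deterministic
    left-to-right pass), so a stray ``CACCG`` inside the spacer of a
    differently-positioned read cannot shadow the true site.
    """
    read = read.upper()
    start = 0
    while True:
        i = read.find(_BACKBONE_5, start)
        if i < 0:
            return None
        lo = i + len(_BACKBONE_5)
        hi = lo + _SPACER_LEN
        if read[hi : hi + len(_BACKBONE_3)] == _BACKBONE_3:
            return read[lo:hi]
        start = i + 1


@dataclass
class ReadCountMatrix:
    """Per-guide, per-sample exact-match read counts.

    ``counts`` is guides x samples (integer); ``stats`` records, per sample,
    how many reads were seen, carried an extractable backbone, matched the
    library, or were discarded (extractable but not in the library).
    """

    counts: pd.DataFrame
    stats: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative read counts")

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def total_matched(self, sample: str) -> int:
        return int(self.counts[sample].sum())

    def write_tsv(self, path: str | Path) -> None:
        self.counts.to_csv(path, sep="\t", index_label="guide_id")

    def write_stats_json(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(
                {s: self.stats.loc[s].to_dict() for s in self.stats.index},
                fh,
                indent=2,
                default=int,
            )

    @classmethod
    def read_tsv(cls, path: str | Path) -> "ReadCountMatrix":
        counts = pd.read_csv(path, sep="\t", index_col="guide_id")
        stats = pd.DataFrame(
            {
                "reads_seen": counts.sum(axis=0),
                "with_backbone": counts.sum(axis=0),
                "matched": counts.sum(axis=0),
                "discarded": 0,
            }
        )
        return cls(counts=counts.astype(np.int64), stats=stats)


def _iter_fastq(source: str | Path | Iterable[str]) -> Iterator[str]:
    """Yield read sequences from a FASTQ path (optionally gzipped) or from
    an iterable of raw sequence strings."""
    if isinstance(source, (str, Path)):
        from Bio import SeqIO

        path = Path(source)
        opener = gzip.open if path.suffix == ".gz" else open
        with opener(path, "rt") as fh:  # type: ignore[operator]
            for rec in SeqIO.parse(fh, "fastq"):
                yield str(rec.seq)
    else:
        yield from source


def count_guides(
    reads: str | Path | Iterable[str],
    lib: GuideLibrary,
    sample_id: str,
) -> tuple[pd.Series, dict[str, int]]:
    """Count perfect spacer matches for one sample.

    Returns the per-guide count column (indexed like the library, zeros
    included) and a stats dict (reads_seen / with_backbone / matched /
    discarded).  Reads whose extracted spacer is not in the library are
    discarded and tallied; reads with no extractable spacer only count
    toward ``reads_seen``.
    """
    index = lib.spacer_index()
    counts: dict[str, int] = dict.fromkeys(lib.guide_ids, 0)
    stats = {"reads_seen": 0, "with_backbone": 0, "matched": 0, "discarded": 0}
    for seq in _iter_fastq(reads):
        stats["reads_seen"] += 1
        spacer = extract_spacer(seq)
        if spacer is None:
            continue
        stats["with_backbone"] += 1
        gid = index.get(spacer)
        if gid is None:
            stats["discarded"] += 1
        else:
            stats["matched"] += 1
            counts[gid] += 1
    if stats["reads_seen"] == 0:
        warnings.warn(f"sample {sample_id!r}: empty FASTQ, zero counts")
    col = pd.Series(counts, name=sample_id, dtype=np.int64)
    return col, stats


def count_samples(
    sources: Mapping[str, str | Path | Iterable[str]],
    lib: GuideLibrary,
) -> ReadCountMatrix:
    """Count several samples (sample_id -> FASTQ path or read iterable)."""
    cols, stat_rows = [], {}
    for sample_id, src in sources.items():
        col, stats = count_guides(src, lib, sample_id)
        cols.append(col)
        stat_rows[sample_id] = stats
    counts = pd.concat(cols, axis=1)
    stats = pd.DataFrame.from_dict(stat_rows, orient="index")
    return ReadCountMatrix(counts=counts, stats=stats)


@dataclass
class FrequencyTable:
    """Guide frequencies with the low-baseline exclusion set.

    ``freq`` keeps the raw counts/total ratio for every guide (excluded ones
    included, for inspection); ``excluded`` is the set of guide ids whose
    frequency in the reference (early) sample fell below
    ``min_frac_of_expected / |library|`` and that are dropped from every
    sample downstream.  ``counts``/``totals`` are retained because the
    pseudocounted score works on counts, not ratios.
    """

    freq: pd.DataFrame
    counts: pd.DataFrame
    totals: pd.Series
    excluded: frozenset[str]
    reference: str

    @property
    def n_guides(self) -> int:
        return len(self.freq.index)

    @property
    def kept(self) -> pd.Index:
        return self.freq.index[~self.freq.index.isin(self.excluded)]

    def excluded_pairs(self) -> set[tuple[str, str]]:
        return {(g, s) for g in self.excluded for s in self.freq.columns}

    def renormalized(self) -> pd.DataFrame:
        """Frequencies over non-excluded guides, re-summing to 1/sample."""
        sub = self.freq.loc[self.kept]
        return sub / sub.sum(axis=0)


def to_frequencies(
    m: ReadCountMatrix,
    lib: GuideLibrary | None = None,
    min_frac_of_expected: float = 0.05,
    reference: str | None = None,
) -> FrequencyTable:
    """Counts -> frequencies with the <5%-of-expected baseline filter.

    Expected frequency is uniform, 1/|library|.  Exclusion is decided on the
    reference sample (first column by default — the early timepoint) and
    propagated to all samples.
    """
    totals = m.counts.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(
            f"samples with no matched reads: {list(zero.index)}"
        )
    reference = reference or m.counts.columns[0]
    if reference not in m.counts.columns:
        raise ValueError(f"reference sample {reference!r} not in matrix")
    freq = m.counts / totals
    n = len(m.counts.index)
    threshold = min_frac_of_expected / n
    excluded = frozenset(freq.index[freq[reference] < threshold])
    return FrequencyTable(
        freq=freq,
        counts=m.counts,
        totals=totals.astype(np.int64),
        excluded=excluded,
        reference=reference,
    )
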
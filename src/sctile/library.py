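"""Tiling sgRNA library: guide records, residue coordinates, and library I/O.

A gene-tiling library saturates a coding sequence (CDS) with sgRNAs so that
per-guide phenotypes can be read out as a function of position along the
encoded protein.  Each tiling guide is anchored by the CDS nucleotide of its
predicted Cas9 cut site (blunt cut 3 nt 5' of the PAM, on the coding strand);
spiked-in negative controls (non-targeting: Luc/Ren/GFP/RFP/Rosa26-style) and
positive controls (targeting a pan-essential gene such as Rpa3) anchor score
normalization downstream.

Coordinates are 1-based throughout and residue spans are inclusive, matching
the "residues M127-P332" style used in the field.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import ceil
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "CATEGORIES",
    "GuideRecord",
    "GuideLibrary",
    "ResidueSpan",
    "cut_codon",
    "guides_in_span",
    "span_length",
    "targeting_density",
    "parse_library",
    "write_library",
]

CATEGORIES = ("tiling", "neg_control", "pos_control")
_DNA = frozenset("ACGT")


class LibraryError(ValueError):
    """Malformed guide library or guide record."""


@dataclass(frozen=True)
class GuideRecord:
    """One sgRNA of the tiling library.

    Parameters
    ----------
    guide_id
        Unique identifier.
    spacer
        20-nt protospacer sequence (A/C/G/T).
    category
        ``tiling`` (targets the CDS), ``neg_control`` or ``pos_control``.
    cds_cut_nt
        1-based CDS nucleotide of the predicted cut site; required for
        tiling guides, absent for controls.
    strand
        Targeted strand relative to the CDS; the cut coordinate is already
        expressed on the coding strand, so downstream scores ignore it.
    """

    guide_id: str
    spacer: str
    category: str
    cds_cut_nt: int | None = None
    strand: str = "+"

    def __post_init__(self) -> None:
        if len(self.spacer) != 20 or not _DNA.issuperset(self.spacer):
            raise LibraryError(
                f"guide {self.guide_id!r}: spacer must be a 20-nt A/C/G/T "
                f"string, got {self.spacer!r}"
            )
        if self.category not in CATEGORIES:
            raise LibraryError(
                f"guide {self.guide_id!r}: unknown category {self.category!r}"
            )
        if self.category == "tiling":
            if self.cds_cut_nt is None:
                raise LibraryError(
                    f"tiling guide {self.guide_id!r} lacks a cds_cut_nt"
                )
            if self.cds_cut_nt < 1:
                raise LibraryError(
                    f"guide {self.guide_id!r}: cds_cut_nt must be >= 1"
                )
        elif self.cds_cut_nt is not None:
            raise LibraryError(
                f"control guide {self.guide_id!r} must not carry a cds_cut_nt"
            )
        if self.strand not in ("+", "-"):
            raise LibraryError(
                f"guide {self.guide_id!r}: strand must be '+' or '-'"
            )

    @property
    def is_tiling(self) -> bool:
        return self.category == "tiling"


@dataclass(frozen=True)
class ResidueSpan:
    """Inclusive 1-based residue interval ``[start_aa, end_aa]``."""

    start_aa: int
    end_aa: int

    def __post_init__(self) -> None:
        if not (1 <= self.start_aa <= self.end_aa):
            raise LibraryError(
                f"invalid span ({self.start_aa}, {self.end_aa}): need "
                f"1 <= start <= end"
            )

    def __len__(self) -> int:
        return self.end_aa - self.start_aa + 1

    def __contains__(self, residue: int) -> bool:
        return self.start_aa <= residue <= self.end_aa


@dataclass
class GuideLibrary:
    """Validated tiling library with its CDS/protein geometry.

    ``cds_length_nt`` may equal ``3 * protein_length_aa`` or
    ``3 * (protein_length_aa + 1)`` (stop codon counted); the convention in
    force is exposed as :attr:`stop_included` and kept constant per library.
    """

    guides: list[GuideRecord]
    cds_length_nt: int
    protein_length_aa: int

    def __post_init__(self) -> None:
        if self.protein_length_aa < 1:
            raise LibraryError("protein_length_aa must be positive")
        if self.cds_length_nt not in (
            3 * self.protein_length_aa,
            3 * (self.protein_length_aa + 1),
        ):
            raise LibraryError(
                f"cds_length_nt={self.cds_length_nt} is neither 3*"
                f"{self.protein_length_aa} nor 3*({self.protein_length_aa}+1)"
            )
        seen: set[str] = set()
        for g in self.guides:
            if g.guide_id in seen:
                raise LibraryError(f"duplicate guide_id {g.guide_id!r}")
            seen.add(g.guide_id)
            if g.is_tiling and not (1 <= g.cds_cut_nt <= self.cds_length_nt):
                raise LibraryError(
                    f"guide {g.guide_id!r}: cds_cut_nt {g.cds_cut_nt} outside "
                    f"CDS of length {self.cds_length_nt}"
                )

    @property
    def stop_included(self) -> bool:
        return self.cds_length_nt == 3 * (self.protein_length_aa + 1)

    @property
    def tiling(self) -> list[GuideRecord]:
        return [g for g in self.guides if g.category == "tiling"]

    @property
    def neg_controls(self) -> list[GuideRecord]:
        return [g for g in self.guides if g.category == "neg_control"]

    @property
    def pos_controls(self) -> list[GuideRecord]:
        return [g for g in self.guides if g.category == "pos_control"]

    @property
    def guide_ids(self) -> list[str]:
        return [g.guide_id for g in self.guides]

    def __len__(self) -> int:
        return len(self.guides)

    def __getitem__(self, guide_id: str) -> GuideRecord:
        for g in self.guides:
            if g.guide_id == guide_id:
                return g
        raise KeyError(guide_id)

    def spacer_index(self) -> dict[str, str]:
        """spacer -> guide_id map for exact-match read counting."""
        idx: dict[str, str] = {}
        for g in self.guides:
            if g.spacer in idx:
                raise LibraryError(
                    f"spacer {g.spacer!r} shared by {idx[g.spacer]!r} and "
                    f"{g.guide_id!r}; exact-match counting is ambiguous"
                )
            idx[g.spacer] = g.guide_id
        return idx


def cut_codon(g: GuideRecord) -> int:
    """1-based residue (codon) index containing a tiling guide's cut site.

    ``ceil(cds_cut_nt / 3)``; independent of strand.
    """
    if not g.is_tiling:
        raise LibraryError(f"guide {g.guide_id!r} has no genomic target")
    return ceil(g.cds_cut_nt / 3)


def guides_in_span(lib: GuideLibrary, span: ResidueSpan) -> list[GuideRecord]:
    """Tiling guides whose cut codon falls inside ``span``, 5'->3' order."""
    hits = [g for g in lib.tiling if cut_codon(g) in span]
    return sorted(hits, key=lambda g: g.cds_cut_nt)


def span_length(span: ResidueSpan) -> int:
    """Number of residues covered by an inclusive span."""
    return len(span)


def targeting_density(lib: GuideLibrary) -> float:
    """Average bp of CDS per tiling guide (e.g. 4614 nt / 602 ~= 7.7)."""
    n = len(lib.tiling)
    if n == 0:
        raise LibraryError("library has no tiling guides")
    return lib.cds_length_nt / n


_COLUMNS = ["guide_id", "spacer", "category", "cds_cut_nt", "strand"]


def parse_library(
    path: str | Path,
    cds_length_nt: int | None = None,
    protein_length_aa: int | None = None,
) -> GuideLibrary:
    """Read a tab-delimited guide library table.

    The file carries columns ``guide_id, spacer, category, cds_cut_nt,
    strand``; lines starting with ``#`` are ignored, except that header
    comments of the form ``# key=value`` may record ``cds_length_nt`` and
    ``protein_length_aa`` (explicit arguments take precedence).  Row order is
    preserved.
    """
    path = Path(path)
    meta: dict[str, int] = {}
    rows: list[str] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("#"):
                stripped = line[1:].strip()
                if "=" in stripped:
                    key, _, val = stripped.partition("=")
                    key = key.strip()
                    if key in ("cds_length_nt", "protein_length_aa"):
                        meta[key] = int(val.strip())
                continue
            if line.strip():
                rows.append(line)
    if not rows:
        raise LibraryError(f"{path}: no table rows")
    from io import StringIO

    df = pd.read_csv(StringIO("".join(rows)), sep="\t", dtype=str)
    missing = {"guide_id", "spacer", "category"} - set(df.columns)
    if missing:
        raise LibraryError(f"{path}: missing columns {sorted(missing)}")

    cds_length_nt = cds_length_nt or meta.get("cds_length_nt")
    protein_length_aa = protein_length_aa or meta.get("protein_length_aa")
    if cds_length_nt is None or protein_length_aa is None:
        raise LibraryError(
            f"{path}: cds_length_nt/protein_length_aa must be given as "
            f"arguments or '# key=value' header comments"
        )

    guides: list[GuideRecord] = []
    for i, row in df.iterrows():
        cut = row.get("cds_cut_nt")
        cut_val: int | None
        if cut is None or pd.isna(cut) or str(cut).strip() in ("", "."):
            cut_val = None
        else:
            cut_val = int(float(cut))
        strand = row.get("strand")
        if strand is None or pd.isna(strand):
            strand = "+"
        try:
            guides.append(
                GuideRecord(
                    guide_id=str(row["guide_id"]),
                    spacer=str(row["spacer"]).upper(),
                    category=str(row["category"]),
                    cds_cut_nt=cut_val,
                    strand=str(strand),
                )
            )
        except LibraryError as err:
            raise LibraryError(f"{path} row {i + 2}: {err}") from err
    return GuideLibrary(
        guides=guides,
        cds_length_nt=int(cds_length_nt),
        protein_length_aa=int(protein_length_aa),
    )


def write_library(lib: GuideLibrary, path: str | Path) -> None:
    """Write a library as the tab-delimited format read by `parse_library`."""
    path = Path(path)
    records = [
        {
            "guide_id": g.guide_id,
            "spacer": g.spacer,
            "category": g.category,
            "cds_cut_nt": "" if g.cds_cut_nt is None else g.cds_cut_nt,
            "strand": g.strand,
        }
        for g in lib.guides
    ]
    df = pd.DataFrame.from_records(records, columns=_COLUMNS)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# cds_length_nt={lib.cds_length_nt}\n")
        fh.write(f"# protein_length_aa={lib.protein_length_aa}\n")
        df.to_csv(fh, sep="\t", index=False)
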
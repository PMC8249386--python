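"""Cross-species residue mapping and 3-D structure annotation.

Per-residue tracks computed on one ortholog (e.g. mouse Dot1l) are carried
onto another (e.g. human DOT1L, whose experimental structures exist) via a
global pairwise protein alignment (BLOSUM62, gap open 10 / extend 0.5);
aligned non-gap column pairs define a strictly colinear residue mapping.

Scores are exported two ways: a Chimera-style "define attribute" text file
(for Render-by-Attribute coloring) and a copy of the PDB file whose
temperature-factor column carries the score rescaled linearly to [0, 100]
so any molecular viewer can color by score.  The PDB copy differs from the
input only in columns 61-66 of ATOM/HETATM records; structure residue
numbering is taken from the coordinate file as-is.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .scan import ResidueTrack

__all__ = [
    "ResidueMapping",
    "StructureAttribution",
    "align_pair",
    "transfer_track",
    "write_attributes",
    "parse_attributes",
]


@dataclass
class ResidueMapping:
    """Colinear 1-based residue correspondence between two proteins."""

    pairs: list[tuple[int, int]]
    identity_fraction: float
    score: float = float("nan")

    def __post_init__(self) -> None:
        prev_s, prev_t = 0, 0
        for s, t in self.pairs:
            if s <= prev_s or t <= prev_t:
                raise ValueError("mapping pairs must strictly increase")
            prev_s, prev_t = s, t
        if not (0.0 <= self.identity_fraction <= 1.0):
            raise ValueError("identity_fraction outside [0, 1]")

    def inverse(self) -> "ResidueMapping":
        return ResidueMapping(
            pairs=[(t, s) for s, t in self.pairs],
            identity_fraction=self.identity_fraction,
            score=self.score,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.pairs, columns=["source_residue", "target_residue"])


def _as_seq(seq) -> str:
    s = str(getattr(seq, "seq", seq)).upper()
    if not s:
        raise ValueError("empty sequence")
    return s


def align_pair(src_seq, tgt_seq) -> ResidueMapping:
    """Global protein alignment (BLOSUM62, open 10, extend 0.5) -> mapping.

    Accepts plain strings or Bio.SeqRecord objects.  Identity fraction is
    the fraction of aligned (non-gap) column pairs with identical residues.
    """
    from Bio import Align
    from Bio.Align import substitution_matrices

    src, tgt = _as_seq(src_seq), _as_seq(tgt_seq)
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    aln = aligner.align(src, tgt)[0]
    pairs: list[tuple[int, int]] = []
    identical = 0
    src_blocks, tgt_blocks = aln.aligned
    for (s0, s1), (t0, t1) in zip(src_blocks, tgt_blocks):
        for ds in range(s1 - s0):
            i, j = s0 + ds, t0 + ds
            pairs.append((i + 1, j + 1))
            identical += src[i] == tgt[j]
    identity = identical / len(pairs) if pairs else 0.0
    return ResidueMapping(pairs=pairs, identity_fraction=identity, score=float(aln.score))


def transfer_track(
    track: ResidueTrack | pd.Series,
    mapping: ResidueMapping,
    target_length: int | None = None,
) -> pd.Series:
    """Carry a per-residue track onto the target numbering.

    Target residue ``t`` receives the score of its mapped source residue;
    unmapped target residues are missing (NaN).
    """
    values = track.to_series() if isinstance(track, ResidueTrack) else track
    n_src = int(values.index.max())
    if any(s > n_src for s, _ in mapping.pairs):
        raise ValueError("mapping refers to residues beyond the track")
    n_tgt = target_length or max((t for _, t in mapping.pairs), default=0)
    out = pd.Series(
        np.nan, index=pd.RangeIndex(1, n_tgt + 1, name="residue"), name="score"
    )
    for s, t in mapping.pairs:
        if s in values.index:
            out.loc[t] = values.loc[s]
    return out


@dataclass
class StructureAttribution:
    """Residue-level score assignments on a coordinate model."""

    assignments: dict[tuple[str, int], float]
    attribute_name: str
    unannotated: list[tuple[str, int]]


def _chain_residues(pdb_lines: list[str]) -> dict[str, list[int]]:
    """Ordered residue numbers per chain from ATOM/HETATM fixed columns."""
    seen: dict[str, list[int]] = {}
    for line in pdb_lines:
        if line.startswith(("ATOM", "HETATM")):
            chain = line[21]
            icode = line[26] if len(line) > 26 else " "
            if icode != " ":
                raise ValueError(
                    f"insertion code {icode!r} at residue {line[22:27].strip()} "
                    f"is not supported"
                )
            resnum = int(line[22:26])
            bucket = seen.setdefault(chain, [])
            if not bucket or bucket[-1] != resnum:
                bucket.append(resnum)
    return seen


def write_attributes(
    track: ResidueTrack | pd.Series,
    model: str | Path,
    chain: str,
    attribute_name: str = "scTilingScore",
    out_attr: str | Path | None = None,
    out_pdb: str | Path | None = None,
) -> StructureAttribution:
    """Export a residue track as a Chimera attribute file + painted PDB.

    The attribute file lists raw scores; the PDB copy carries the scores
    linearly rescaled to [0, 100] in the temperature-factor column (columns
    61-66), with unannotated residues set to 0.00.  Nothing else in the PDB
    is modified.
    """
    values = track.to_series() if isinstance(track, ResidueTrack) else track
    values = values.dropna()
    model = Path(model)
    lines = model.read_text().splitlines(keepends=True)
    chains = _chain_residues(lines)
    if chain not in chains:
        raise ValueError(
            f"chain {chain!r} not in model; available: {sorted(chains)}"
        )
    assignments = {
        (chain, r): float(values.loc[r]) for r in chains[chain] if r in values.index
    }
    unannotated = [(chain, r) for r in chains[chain] if r not in values.index]
    if not assignments:
        raise ValueError(f"no track residues present in chain {chain!r}")

    if out_attr is not None:
        with open(out_attr, "w", encoding="utf-8") as fh:
            fh.write(f"attribute: {attribute_name}\n")
            fh.write("match mode: 1-to-1\n")
            fh.write("recipient: residues\n")
            for (ch, resnum), val in assignments.items():
                fh.write(f"\t/{ch}:{resnum}\t{val:g}\n")

    if out_pdb is not None:
        vals = np.array(list(assignments.values()))
        lo, hi = vals.min(), vals.max()
        span = hi - lo

        def _scaled(v: float) -> float:
            # degenerate constant track: midpoint of the display range
            return 50.0 if span == 0 else 100.0 * (v - lo) / span

        out_lines = []
        for line in lines:
            if line.startswith(("ATOM", "HETATM")):
                key = (line[21], int(line[22:26]))
                b = _scaled(assignments[key]) if key in assignments else 0.0
                line = line[:60] + f"{b:6.2f}" + line[66:]
            out_lines.append(line)
        Path(out_pdb).write_text("".join(out_lines))

    return StructureAttribution(
        assignments=assignments,
        attribute_name=attribute_name,
        unannotated=unannotated,
    )


def parse_attributes(path: str | Path) -> tuple[str, dict[tuple[str, int], float]]:
    """Read back an attribute file written by :func:`write_attributes`."""
    name = ""
    assignments: dict[tuple[str, int], float] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("attribute:"):
                name = line.split(":", 1)[1].strip()
            elif line.startswith("\t/"):
                spec, val = line.strip().split("\t")
                ch, resnum = spec.lstrip("/").split(":")
                assignments[(ch, int(resnum))] = float(val)
    return name, assignments
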
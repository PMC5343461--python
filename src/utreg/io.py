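"""Readers and writers for the formats the pipeline consumes.

Sequences live internally on the DNA alphabet {A, C, G, T, N}; RNA input is
transliterated (U -> T) on ingestion and may be rendered back as RNA in
reports.  All user-facing coordinates are 1-based inclusive; internal
coordinates are 0-based half-open, with :func:`to_one_based` /
:func:`to_zero_based` as the single audited conversion point.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "SequenceRecord",
    "read_fasta",
    "write_fasta",
    "filter_short",
    "read_expression",
    "write_expression",
    "read_motifs_meme",
    "write_motifs",
    "to_one_based",
    "to_zero_based",
    "to_rna",
    "to_dna",
]

_VALID_SEQ = re.compile(r"^[ACGTN]+$")

FRACTIONS = ("transcriptome", "translatome")
CONDITIONS = ("control", "treated")


class FastaFormatError(ValueError):
    """Raised on malformed FASTA input or contract violations."""


@dataclass(frozen=True)
class SequenceRecord:
    """One UTR sequence.

    Attributes
    ----------
    id : str
        Gene identifier (AGI style, e.g. ``AT3G25660``).
    seq : str
        Uppercase DNA sequence over {A, C, G, T, N}.
    region : str
        Either ``"utr5"`` or ``"utr3"``.
    """

    id: str
    seq: str
    region: str = "utr3"

    def __post_init__(self) -> None:
        if not self.id:
            raise FastaFormatError("sequence record with empty id")
        if self.region not in ("utr5", "utr3"):
            raise ValueError(f"unknown region tag {self.region!r}")

    def __len__(self) -> int:
        return len(self.seq)


def to_dna(seq: str) -> str:
    """Uppercase and transliterate RNA (U) to DNA (T)."""
    return seq.upper().replace("U", "T")


def to_rna(seq: str) -> str:
    """Render a DNA string as RNA for reports."""
    return seq.upper().replace("T", "U")


def to_one_based(start0: int, end0: int) -> tuple[int, int]:
    """Convert a 0-based half-open interval to 1-based inclusive."""
    return start0 + 1, end0


def to_zero_based(start1: int, end1: int) -> tuple[int, int]:
    """Convert a 1-based inclusive interval to 0-based half-open."""
    return start1 - 1, end1


def read_fasta(path: str | Path, region: str = "utr3") -> list[SequenceRecord]:
    """Read a FASTA file into normalized :class:`SequenceRecord` objects.

    Sequences are uppercased, U is transliterated to T, and duplicate ids
    are rejected.  Characters outside {A, C, G, T, N} raise
    :class:`FastaFormatError` naming the offending record.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FastaFormatError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = to_dna(str(rec.seq))
        if not seq:
            raise FastaFormatError(f"record {rec.id!r} in {path} has empty sequence")
        if not _VALID_SEQ.match(seq):
            bad = sorted(set(seq) - set("ACGTN"))
            raise FastaFormatError(
                f"record {rec.id!r} in {path} contains invalid characters {bad}"
            )
        records.append(SequenceRecord(rec.id, seq, region))
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, *, rna: bool = False) -> None:
    """Write records as FASTA; set ``rna=True`` to render U instead of T."""
    with open(path, "w") as fh:
        for rec in records:
            seq = to_rna(rec.seq) if rna else rec.seq
            fh.write(f">{rec.id}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def filter_short(
    records: Sequence[SequenceRecord], min_len: int = 10
) -> tuple[list[SequenceRecord], int]:
    """Drop sequences shorter than ``min_len`` nucleotides.

    Mirrors the UTR pre-filter applied before any scanning: records with
    fewer than ``min_len`` bases (including empty ones) are removed, a
    record of exactly ``min_len`` survives.

    Returns
    -------
    (kept, dropped_count)
    """
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    kept = [r for r in records if len(r) >= min_len]
    return kept, len(records) - len(kept)


# ---------------------------------------------------------------------------
# Expression tables
# ---------------------------------------------------------------------------

def read_expression(path: str | Path) -> pd.DataFrame:
    """Read a per-gene FPKM table.

    The TSV has a ``gene`` column plus one column per replicate named
    ``<fraction>.<condition>.<rep>`` with fraction in {transcriptome,
    translatome} and condition in {control, treated}.  Returns a DataFrame
    indexed by gene with a (fraction, condition, replicate) column
    MultiIndex; validates that all four fraction x condition cells are
    present with equal replicate counts per cell and non-negative values.
    """
    df = pd.read_csv(path, sep="\t")
    if "gene" not in df.columns:
        raise ValueError(f"expression table {path} lacks a 'gene' column")
    df = df.set_index("gene")
    return _validate_expression(df_from_flat(df))


def df_from_flat(df: pd.DataFrame) -> pd.DataFrame:
    """Convert flat ``fraction.condition.rep`` columns to a MultiIndex."""
    cols = []
    for c in df.columns:
        parts = str(c).split(".")
        if len(parts) != 3:
            raise ValueError(f"expression column {c!r} is not fraction.condition.rep")
        frac, cond, rep = parts
        cols.append((frac, cond, int(rep)))
    out = df.copy()
    out.columns = pd.MultiIndex.from_tuples(cols, names=["fraction", "condition", "replicate"])
    return out


def _validate_expression(df: pd.DataFrame) -> pd.DataFrame:
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene ids in expression table: {dups[:5]}")
    if (df.to_numpy() < 0).any():
        raise ValueError("negative FPKM values in expression table")
    counts = {}
    for frac in FRACTIONS:
        for cond in CONDITIONS:
            if (frac, cond) not in {(f, c) for f, c, _ in df.columns}:
                raise ValueError(f"expression table missing {frac}.{cond} columns")
            counts[(frac, cond)] = len(df[frac][cond].columns)
    # replicate-paired TE ratios need matching translatome/transcriptome
    # replicate counts within each condition
    for cond in CONDITIONS:
        if counts[("transcriptome", cond)] != counts[("translatome", cond)]:
            raise ValueError(
                f"unequal transcriptome/translatome replicate counts in {cond}"
            )
    return df.sort_index(axis=1)


def write_expression(df: pd.DataFrame, path: str | Path) -> None:
    """Write an expression DataFrame back to flat TSV."""
    flat = df.copy()
    flat.columns = [f"{f}.{c}.{r}" for f, c, r in df.columns]
    flat.index.name = "gene"
    flat.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# MEME minimal motif format
# ---------------------------------------------------------------------------

_ALPHA = "ACGT"


def write_motifs(pwms, path: str | Path, *, background=None) -> None:
    """Write PWMs in MEME minimal motif format.

    Every matrix must be row-normalized (each position summing to 1 within
    1e-6); violations raise ``ValueError`` so that malformed motifs never
    reach downstream tools.
    """
    lines = [
        "MEME version 4",
        "",
        "ALPHABET= ACGT",
        "",
        "strands: + -",
        "",
        "Background letter frequencies",
    ]
    bg = background if background is not None else [0.25] * 4
    lines.append(" ".join(f"{a} {b:.6f}" for a, b in zip(_ALPHA, bg)))
    lines.append("")
    for pwm in pwms:
        mat = np.asarray(pwm.matrix, dtype=float)
        if mat.ndim != 2 or mat.shape[1] != 4:
            raise ValueError(f"motif {pwm.name!r}: matrix must be width x 4")
        sums = mat.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-6):
            raise ValueError(
                f"motif {pwm.name!r} is not row-normalized (row sums {sums})"
            )
        nsites = getattr(pwm, "n_sites", 20) or 20
        lines.append(f"MOTIF {pwm.name}")
        lines.append(
            f"letter-probability matrix: alength= 4 w= {mat.shape[0]} "
            f"nsites= {nsites} E= 0"
        )
        for row in mat:
            lines.append(" ".join(f"{v:.9f}" for v in row))
        lines.append("")
    Path(path).write_text("\n".join(lines))


def read_motifs_meme(path: str | Path):
    """Read MEME minimal motifs into (name, matrix, nsites) tuples.

    The letter-probability rows are read at full precision (Biopython's
    minimal parser quantizes them into integer counts), so matrices
    round-trip with :func:`write_motifs` to within 1e-9.
    """
    out = []
    name = None
    width = nsites = None
    rows: list[list[float]] = []

    def flush():
        nonlocal name, rows, width, nsites
        if name is not None:
            mat = np.array(rows, dtype=float)
            if width is not None and mat.shape[0] != width:
                raise ValueError(f"motif {name!r}: expected {width} rows, got {mat.shape[0]}")
            out.append((name, mat, nsites or 0))
        name, rows, width, nsites = None, [], None, None

    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line.startswith("MOTIF"):
            flush()
            name = line.split(None, 2)[1]
        elif line.startswith("letter-probability matrix"):
            m = re.search(r"w=\s*(\d+)", line)
            width = int(m.group(1)) if m else None
            m = re.search(r"nsites=\s*(\d+)", line)
            nsites = int(m.group(1)) if m else 0
        elif name is not None and line and line[0] in "0123456789.":
            rows.append([float(v) for v in line.split()])
    flush()
    return out
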
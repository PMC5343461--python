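"""PWM comparison, clustering, scanning, and known-motif matching.

Discovered motifs are compared pairwise by the mean per-column Pearson
correlation over the best ungapped alignment (both orientations, minimum
overlap enforced); significance comes from a permutation null built by
sampling column pairs from a background column pool, with a Bonferroni-style
E-value over the candidate alignments.  Motifs that match are clustered by
single linkage and each cluster is collapsed to an averaged matrix, which
can then be scanned over sequences or matched against literature motifs
given as degenerate IUPAC patterns (e.g. the Pumilio element UGUA(A/C/U)AUA
or the Bruno-like element U(G/A)U(A/G)U(G/A)U).
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
from Bio.Data.IUPACData import ambiguous_dna_values
from Bio.Seq import reverse_complement

from .io import SequenceRecord, to_dna

__all__ = [
    "PWM",
    "KnownMotif",
    "CompareResult",
    "compare_pwms",
    "cluster_average",
    "scan_pwm",
    "iupac_scan",
    "info_content",
    "pattern_to_pwm",
]

_ALPHA = "ACGT"
_CODE = {b: i for i, b in enumerate(_ALPHA)}


@dataclass
class PWM:
    """A position weight matrix: per-position probabilities over ACGT."""

    name: str
    matrix: np.ndarray  # (width, 4)
    n_sites: int = 0

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError(f"PWM {self.name!r}: matrix must be width x 4")
        if not np.allclose(self.matrix.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError(f"PWM {self.name!r}: rows must sum to 1")

    @property
    def width(self) -> int:
        return self.matrix.shape[0]

    def reverse_complement(self) -> "PWM":
        return PWM(self.name + "_rc", self.matrix[::-1, ::-1], self.n_sites)

    def consensus(self) -> str:
        return "".join(_ALPHA[i] for i in self.matrix.argmax(axis=1))


@dataclass(frozen=True)
class KnownMotif:
    """A literature motif as a degenerate IUPAC pattern (RNA or DNA)."""

    name: str
    pattern: str
    source: str = ""

    def __post_init__(self) -> None:
        dna = to_dna(self.pattern)
        bad = set(dna) - set(ambiguous_dna_values)
        if bad:
            raise ValueError(f"motif {self.name!r}: invalid IUPAC codes {sorted(bad)}")


@dataclass(frozen=True)
class CompareResult:
    offset: int
    orientation: str  # "fwd" or "rc"
    score: float
    p: float
    evalue: float
    match: bool
    overlap: int


def _column_corr(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation of two probability columns; zero-variance columns
    compare as 1 if equal else 0."""
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return 1.0 if np.allclose(a, b) else 0.0
    return float(np.corrcoef(a, b)[0, 1])


def _alignment_score(ma: np.ndarray, mb: np.ndarray, offset: int, min_overlap: int):
    """Mean column correlation of b shifted by ``offset`` against a."""
    start_a = max(0, offset)
    start_b = max(0, -offset)
    overlap = min(ma.shape[0] - start_a, mb.shape[0] - start_b)
    if overlap < min_overlap:
        return None, 0
    cols = [
        _column_corr(ma[start_a + i], mb[start_b + i]) for i in range(overlap)
    ]
    return float(np.mean(cols)), overlap


def _candidate_alignments(wa: int, wb: int, min_overlap: int):
    for offset in range(-(wb - min_overlap), wa - min_overlap + 1):
        yield offset


def best_alignment(a: PWM, b: PWM, min_overlap: int = 7):
    """Best (score, offset, orientation, overlap) of b against a."""
    best = None
    for orient, mb in (("fwd", b.matrix), ("rc", b.reverse_complement().matrix)):
        for offset in _candidate_alignments(a.width, b.width, min_overlap):
            score, overlap = _alignment_score(a.matrix, mb, offset, min_overlap)
            if score is None:
                continue
            if best is None or score > best[0]:
                best = (score, offset, orient, overlap)
    if best is None:
        raise ValueError("no alignment satisfies the minimum overlap")
    return best


def compare_pwms(
    a: PWM,
    b: PWM,
    min_overlap: int = 7,
    alpha: float = 0.05,
    n_null: int = 10000,
    rng: np.random.Generator | int | None = 0,
    column_pool: np.ndarray | None = None,
) -> CompareResult:
    """Best-alignment similarity of two PWMs with a permutation E-value.

    The score is the mean per-column Pearson correlation over the best
    offset/orientation with at least ``min_overlap`` aligned columns.  The
    null samples ``overlap``-sized column sets from a pooled background
    column collection (Dirichlet(1,1,1,1) columns by default, or a caller
    supplied pool); E = p x number of candidate offset/orientation pairs,
    and the motifs match when E <= alpha.
    """
    if a.width < min_overlap or b.width < min_overlap:
        raise ValueError("PWM width below the minimum overlap")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    n_candidates = 2 * len(list(_candidate_alignments(a.width, b.width, min_overlap)))
    score, offset, orient, overlap = best_alignment(a, b, min_overlap)
    if column_pool is None:
        column_pool = rng.dirichlet(np.ones(4), size=max(4 * n_null, 1000))
    ia = rng.integers(0, len(column_pool), size=(n_null, overlap))
    ib = rng.integers(0, len(column_pool), size=(n_null, overlap))
    ca = column_pool[ia] - column_pool[ia].mean(axis=2, keepdims=True)
    cb = column_pool[ib] - column_pool[ib].mean(axis=2, keepdims=True)
    denom = np.sqrt((ca**2).sum(axis=2) * (cb**2).sum(axis=2))
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = np.where(denom > 0, (ca * cb).sum(axis=2) / denom, 0.0)
    null = corr.mean(axis=1)
    p = (1 + int((null >= score - 1e-12).sum())) / (n_null + 1)
    evalue = p * n_candidates
    return CompareResult(
        offset=offset,
        orientation=orient,
        score=score,
        p=float(p),
        evalue=float(evalue),
        match=bool(evalue <= alpha),
        overlap=overlap,
    )


def cluster_average(
    pwms: list[PWM],
    min_overlap: int = 7,
    alpha: float = 0.05,
    n_null: int = 2000,
    rng: np.random.Generator | int | None = 0,
) -> list[tuple[list[PWM], PWM]]:
    """Single-linkage clustering on the pairwise match relation.

    Each cluster is averaged: members are aligned to the cluster's seed
    member (its widest, then first, member) at their best offset and
    orientation, probabilities are averaged position-wise over the members
    covering each seed position, and rows renormalized.  Returns
    (members, averaged PWM) per cluster; singleton clusters return their
    member unchanged.
    """
    if not pwms:
        raise ValueError("no PWMs to cluster")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    n = len(pwms)
    # shared column pool makes match() symmetric under the seeded null
    pool = rng.dirichlet(np.ones(4), size=max(4 * n_null, 1000))
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            res = compare_pwms(
                pwms[i], pwms[j], min_overlap, alpha, n_null,
                rng=np.random.default_rng(12345), column_pool=pool,
            )
            if res.match:
                parent[find(i)] = find(j)
    clusters: dict[int, list[int]] = {}
    for i in range(n):
        clusters.setdefault(find(i), []).append(i)
    out = []
    for members in clusters.values():
        mem_pwms = [pwms[i] for i in members]
        if len(members) == 1:
            out.append((mem_pwms, mem_pwms[0]))
            continue
        seed_i = max(members, key=lambda i: (pwms[i].width, -i))
        seed = pwms[seed_i]
        acc = np.zeros((seed.width, 4))
        cov = np.zeros(seed.width)
        for i in members:
            if i == seed_i:
                mat, offset = seed.matrix, 0
            else:
                _, offset, orient, _ = best_alignment(seed, pwms[i], min_overlap)
                mat = (
                    pwms[i].reverse_complement().matrix
                    if orient == "rc"
                    else pwms[i].matrix
                )
            start_s = max(0, offset)
            start_m = max(0, -offset)
            overlap = min(seed.width - start_s, mat.shape[0] - start_m)
            acc[start_s : start_s + overlap] += mat[start_m : start_m + overlap]
            cov[start_s : start_s + overlap] += 1
        cov = np.maximum(cov, 1)
        avg = acc / cov[:, None]
        avg = avg / avg.sum(axis=1, keepdims=True)
        out.append(
            (mem_pwms, PWM(f"cluster_{seed.name}", avg, sum(p.n_sites for p in mem_pwms)))
        )
    return out


def scan_pwm(
    pwm: PWM,
    seqs: list[SequenceRecord],
    score_threshold: float = 0.8,
    search_rc: bool = False,
) -> list[tuple[str, int, str, float]]:
    """Log-odds scan of sequences; hits score >= threshold x max score.

    Scores are log2 odds against a uniform background; the threshold is a
    fraction of the PWM's maximum achievable score.  Returns (gene,
    1-based position, orientation, score).  Windows containing N are
    skipped.
    """
    if not 0 < score_threshold <= 1:
        raise ValueError("score_threshold must be in (0, 1]")
    floor = 1e-6  # avoid -inf for indicator matrices
    logodds = np.log2(np.maximum(pwm.matrix, floor) / 0.25)
    max_score = logodds.max(axis=1).sum()
    cutoff = score_threshold * max_score - 1e-9
    mats = [("fwd", logodds)]
    if search_rc:
        mats.append(("rc", logodds[::-1, ::-1]))
    w = pwm.width
    hits = []
    for rec in seqs:
        seq = rec.seq
        for start in range(len(seq) - w + 1):
            window = seq[start : start + w]
            if "N" in window:
                continue
            idx = [_CODE[c] for c in window]
            for orient, mat in mats:
                s = float(mat[np.arange(w), idx].sum())
                if s >= cutoff:
                    hits.append((rec.id, start + 1, orient, s))
    return hits


def _iupac_regex(pattern_dna: str) -> str:
    return "".join(
        f"[{ambiguous_dna_values[c]}]" if len(ambiguous_dna_values[c]) > 1 else c
        for c in pattern_dna
    )


def iupac_scan(
    motif: KnownMotif | str, seq: str | SequenceRecord, search_rc: bool = False
) -> list[tuple[int, str]]:
    """All exact degenerate matches of an IUPAC pattern in a sequence.

    Returns (1-based position, orientation); with ``search_rc`` the
    reverse complement of the pattern is also scanned.  Overlapping
    matches are all reported.
    """
    pattern = motif.pattern if isinstance(motif, KnownMotif) else motif
    s = seq.seq if isinstance(seq, SequenceRecord) else to_dna(seq)
    pat = to_dna(pattern)
    if set(pat) - set(ambiguous_dna_values):
        raise ValueError(f"invalid IUPAC codes in pattern {pattern!r}")
    out = [
        (m.start() + 1, "fwd")
        for m in re.finditer(f"(?=({_iupac_regex(pat)}))", s)
    ]
    if search_rc:
        rc = reverse_complement(pat)
        out += [
            (m.start() + 1, "rc")
            for m in re.finditer(f"(?=({_iupac_regex(rc)}))", s)
        ]
    return sorted(out)


def pattern_to_pwm(motif: KnownMotif, pseudocount: float = 0.01) -> PWM:
    """Indicator-style PWM for a degenerate pattern.

    Allowed bases at a position share the probability mass equally, with a
    small pseudocount on disallowed bases — the representation used when a
    discovered matrix is matched against a literature motif.
    """
    pat = to_dna(motif.pattern)
    mat = np.full((len(pat), 4), pseudocount)
    for i, c in enumerate(pat):
        allowed = ambiguous_dna_values[c]
        for b in allowed:
            mat[i, _CODE[b]] = 1.0 / len(allowed)
    mat = mat / mat.sum(axis=1, keepdims=True)
    return PWM(motif.name, mat)


def info_content(pwm: PWM) -> np.ndarray:
    """Per-position information content in bits against uniform background:
    2 + sum_b p log2 p (0 log 0 = 0)."""
    m = pwm.matrix
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(m > 0, m * np.log2(m), 0.0)
    return 2.0 + term.sum(axis=1)
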
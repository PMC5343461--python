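"""Upstream ORF detection in 5' UTRs with Kozak-context classification.

A uORF is an ATG-initiated reading frame in the 5' leader that reaches its
first in-frame stop codon before the main coding sequence begins.  Scanning
reports maximal ORFs: when several in-frame ATGs share one stop codon only
the 5'-most is reported, with the internal ATGs counted as nested starts.

The Kozak context of a start codon looks at the base 3 nt upstream of the
A (position -3) and the base immediately after the G (position +4, with the
A of ATG as +1): a purine at -3 and G at +4 is a strong context, exactly
one of the two is sub-optimal, neither is weak.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from statsmodels.stats.proportion import proportions_ztest

from .io import SequenceRecord

__all__ = [
    "UORF",
    "scan_uorfs",
    "kozak_classify",
    "positional_features",
    "prevalence_ztest",
]

STOPS = ("TAA", "TAG", "TGA")


@dataclass(frozen=True)
class UORF:
    """An upstream ORF; coordinates are 1-based inclusive within the UTR.

    ``start`` is the first base of the ATG, ``end`` the last base of the
    stop codon; ``dist_from_cap`` counts leader nucleotides 5' of the ATG
    and ``dist_to_main_orf`` the nucleotides between the stop codon and the
    main start codon (the UTR 3' end).
    """

    gene: str
    start: int
    end: int
    kozak: str
    nested_starts: int = 0

    @property
    def length_nt(self) -> int:
        return self.end - self.start + 1

    @property
    def codons(self) -> int:
        return self.length_nt // 3

    @property
    def dist_from_cap(self) -> int:
        return self.start - 1

    def dist_to_main_orf(self, utr_length: int) -> int:
        return utr_length - self.end


def scan_uorfs(utr5: SequenceRecord, min_len_nt: int = 60) -> list[UORF]:
    """Find all maximal uORFs of at least ``min_len_nt`` nt (stop included).

    Every ATG is extended codon by codon to its first in-frame stop; ORFs
    whose stop lies beyond the UTR are discarded (a uORF must terminate in
    the leader).  ATGs that reach a stop already claimed by a 5'-more ATG
    in the same frame are folded into that ORF's ``nested_starts`` count.
    Codons containing N never match ATG or a stop codon.
    """
    seq = utr5.seq
    if set(seq) - set("ACGTN"):
        raise ValueError(f"{utr5.id}: sequence contains non-ACGTN characters")
    # stop position (0-based index of stop codon) -> list of ATG starts
    by_stop: dict[int, list[int]] = {}
    for i in range(len(seq) - 2):
        if seq[i : i + 3] != "ATG":
            continue
        j = i + 3
        while j + 3 <= len(seq):
            if seq[j : j + 3] in STOPS:
                by_stop.setdefault(j, []).append(i)
                break
            j += 3
    out = []
    for stop, starts in by_stop.items():
        first = min(starts)
        length = stop + 3 - first
        if length >= min_len_nt:
            out.append(
                UORF(
                    gene=utr5.id,
                    start=first + 1,
                    end=stop + 3,
                    kozak=kozak_classify(seq, first + 1),
                    nested_starts=sum(
                        1 for s in starts if s != first and stop + 3 - s >= min_len_nt
                    ),
                )
            )
    return sorted(out, key=lambda u: u.start)


def kozak_classify(seq: str, atg_start: int) -> str:
    """Classify the Kozak context of the ATG at 1-based ``atg_start``.

    strong: purine (A/G) at -3 AND G at +4; sub-optimal: exactly one of the
    two; weak: neither.  Positions falling outside the sequence fail their
    criterion.
    """
    i = atg_start - 1
    if seq[i : i + 3] != "ATG":
        raise ValueError(f"no ATG at position {atg_start}")
    minus3 = seq[i - 3] if i - 3 >= 0 else ""
    plus4 = seq[i + 3] if i + 3 < len(seq) else ""
    hits = (minus3 in ("A", "G")) + (plus4 == "G")
    return ("weak", "suboptimal", "strong")[hits]


def positional_features(uorf: UORF, utr_length: int) -> dict:
    """Leader-position features of a uORF within its UTR.

    ``leader_ge_20``: at least 20 nt of leader upstream of the uORF (room
    for cap-proximal scanning); ``near_main_orf``: the uORF stop lies
    within 20 nt of the main start codon, close enough for reinitiation
    coupling.
    """
    if uorf.start < 1 or uorf.end > utr_length:
        raise ValueError("uORF outside the UTR")
    d_cap = uorf.dist_from_cap
    d_main = uorf.dist_to_main_orf(utr_length)
    return {
        "dist_from_cap": d_cap,
        "dist_to_main_orf": d_main,
        "leader_ge_20": d_cap >= 20,
        "near_main_orf": d_main <= 20,
    }


def prevalence_ztest(
    k_fore: int, n_fore: int, k_back: int, n_back: int
) -> tuple[float, float, str]:
    """Two-proportion pooled z-test of uORF prevalence.

    Compares the fraction of foreground genes carrying at least one uORF
    against a background gene universe.  Returns (z, two-sided p,
    direction), direction being "higher"/"lower"/"equal" for the
    foreground relative to background.  A degenerate pooled proportion
    (0 or 1) makes the statistic undefined; p is reported as 1 with a
    warning.
    """
    for k, n in ((k_fore, n_fore), (k_back, n_back)):
        if n <= 0 or not 0 <= k <= n:
            raise ValueError("need 0 <= k <= n and n > 0")
    pooled = (k_fore + k_back) / (n_fore + n_back)
    diff = k_fore / n_fore - k_back / n_back
    direction = "higher" if diff > 0 else ("lower" if diff < 0 else "equal")
    if pooled in (0.0, 1.0):
        warnings.warn("degenerate pooled proportion; z-test undefined, p set to 1")
        return 0.0, 1.0, direction
    z, p = proportions_ztest([k_fore, k_back], [n_fore, n_back])
    return float(z), float(p), direction
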
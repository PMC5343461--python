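"""Plant miRNA target-site prediction in 3' UTRs.

Each window of the UTR the length of the miRNA is paired, ungapped, against
the miRNA: miRNA position 1 (its 5' end) pairs the window's 3'-most base.
Every duplex position is a Watson-Crick match, a G:U wobble, or a
mismatch; the expectation score is the penalty sum (mismatch 1.0, wobble
0.5, penalties doubled within the miRNA seed region) and sites with
expectation at or below the cap (default 3.0) are reported.

Perfect pairing across the duplex's central region (miRNA positions 9-11)
leaves the site open to Argonaute-mediated cleavage; any central mismatch
or wobble instead predicts translational inhibition.

The target-accessibility (un-pairing energy, UPE) filter of the original
prediction server is recorded in configuration for provenance but not
computed; no site is rejected on accessibility grounds.
"""

from __future__ import annotations

from dataclasses import dataclass

from .io import SequenceRecord, to_dna, to_rna

__all__ = [
    "DuplexSite",
    "ScoringConfig",
    "pair_states",
    "score_window",
    "classify_action",
    "scan_targets",
    "render_duplex",
]

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

MATCH, WOBBLE, MISMATCH = "match", "wobble", "mismatch"


@dataclass(frozen=True)
class ScoringConfig:
    """Penalty scheme and thresholds for duplex scoring.

    ``seed_range`` is the miRNA-position interval whose penalties are
    multiplied by ``seed_multiplier``; ``central_range`` is the interval
    whose pairing decides cleavage versus translational inhibition.
    ``upe_threshold`` documents the accessibility cap of the original
    server; it is not evaluated.
    """

    max_expectation: float = 3.0
    mismatch_penalty: float = 1.0
    wobble_penalty: float = 0.5
    seed_range: tuple[int, int] = (2, 13)
    seed_multiplier: float = 2.0
    central_range: tuple[int, int] = (9, 11)
    upe_threshold: float = 25.0


@dataclass(frozen=True)
class DuplexSite:
    """A scored miRNA binding site; UTR coordinates 1-based inclusive."""

    gene: str
    mirna: str
    site_start: int
    site_end: int
    states: tuple[str, ...]
    expectation: float
    action: str
    site_seq: str = ""


def pair_states(mirna_dna: str, window: str) -> tuple[str, ...]:
    """Pairing state at each miRNA position 1..L against a UTR window.

    Both inputs are DNA, 5'->3'.  miRNA position i pairs the window base at
    offset L - i (antiparallel duplex).  Wobble detection is
    orientation-aware: miRNA G opposite target T, or miRNA T opposite
    target G.
    """
    L = len(mirna_dna)
    if len(window) != L:
        raise ValueError("window length must equal miRNA length")
    states = []
    for i, m in enumerate(mirna_dna):  # i = miRNA position - 1
        u = window[L - 1 - i]
        if _COMPLEMENT.get(m) == u:
            states.append(MATCH)
        elif (m == "G" and u == "T") or (m == "T" and u == "G"):
            states.append(WOBBLE)
        else:
            states.append(MISMATCH)
    return tuple(states)


def score_window(states: tuple[str, ...], config: ScoringConfig = ScoringConfig()) -> float:
    """Expectation penalty of a duplex: sum of per-position penalties."""
    lo, hi = config.seed_range
    total = 0.0
    for pos, state in enumerate(states, start=1):
        if state == MATCH:
            continue
        pen = config.mismatch_penalty if state == MISMATCH else config.wobble_penalty
        if lo <= pos <= hi:
            pen *= config.seed_multiplier
        total += pen
    return total


def classify_action(states: tuple[str, ...], config: ScoringConfig = ScoringConfig()) -> str:
    """Cleavage if the central region pairs perfectly, else inhibition."""
    lo, hi = config.central_range
    central = states[lo - 1 : hi]
    return "cleavage" if all(s == MATCH for s in central) else "translational_inhibition"


def scan_targets(
    mirna_seq: str,
    utr3: SequenceRecord,
    config: ScoringConfig = ScoringConfig(),
    mirna_id: str = "miRNA",
) -> list[DuplexSite]:
    """Score every UTR window against the miRNA, keep passing sites.

    Sites are sorted by expectation then position; overlapping windows are
    allowed.  Windows containing N are skipped.  The miRNA must be 18-24 nt
    (mature plant miRNA length range).
    """
    m = to_dna(mirna_seq)
    if not 18 <= len(m) <= 24:
        raise ValueError(f"miRNA length {len(m)} outside 18-24 nt")
    L = len(m)
    seq = utr3.seq
    sites = []
    for start in range(len(seq) - L + 1):
        window = seq[start : start + L]
        if "N" in window:
            continue
        states = pair_states(m, window)
        e = score_window(states, config)
        if e <= config.max_expectation:
            sites.append(
                DuplexSite(
                    gene=utr3.id,
                    mirna=mirna_id,
                    site_start=start + 1,
                    site_end=start + L,
                    states=states,
                    expectation=e,
                    action=classify_action(states, config),
                    site_seq=window,
                )
            )
    return sorted(sites, key=lambda s: (s.expectation, s.site_start))


_PAIR_CHAR = {MATCH: "|", WOBBLE: "o", MISMATCH: " "}


def render_duplex(site: DuplexSite, mirna_seq: str) -> str:
    """Three-row RNA rendering of a duplex (target 5'->3' on top)."""
    m = to_dna(mirna_seq)
    target = to_rna(site.site_seq)
    pairs = "".join(_PAIR_CHAR[s] for s in reversed(site.states))
    mirna_row = to_rna(m[::-1])  # 3'->5' under the target
    return (
        f"target 5' {target} 3'\n"
        f"          {pairs}\n"
        f"miRNA  3' {mirna_row} 5'"
    )
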
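"""Synthetic inputs with known ground truth for every pipeline stage.

The generator emits the same FASTA/TSV formats the pipeline reads:

* expression tables with genes planted into the six translational-
  efficiency groups, replicate noise drawn from a negative-binomial count
  model and rescaled to FPKM;
* UTR sequence sets of i.i.d. nucleotides at a target GC content with
  motifs, uORFs (constructed Kozak contexts) and miRNA complementary
  sites planted by substitution at recorded, non-overlapping positions;
* a plain background sequence set for building k-mer background models.

Every generator is bit-reproducible under its rng seed, and every planted
element is recoverable by the corresponding scanner at the recorded
coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import SequenceRecord, to_dna
from .mirna import ScoringConfig, pair_states, score_window, classify_action
from Bio.Data.IUPACData import ambiguous_dna_values

__all__ = [
    "SimulationSpec",
    "GroundTruth",
    "simulate_expression",
    "simulate_utrs",
    "simulate_background",
    "DEFAULT_GROUP_COUNTS",
]

STOPS = ("TAA", "TAG", "TGA")

# Planted group sizes default to the study's six-group census
# (total 514 regulated genes out of a larger gene universe).
DEFAULT_GROUP_COUNTS = {
    "YNup": 65,
    "YNdown": 58,
    "NYup": 90,
    "NYdown": 265,
    "YYup": 12,
    "YYdown": 24,
}


@dataclass
class SimulationSpec:
    """Study conditions for the generators.

    Defaults mirror the experimental design being emulated: paired
    transcriptome/translatome FPKM in two conditions with three
    replicates, a 2-fold-per-unit log2 TE effect for regulated genes, and
    moderate negative-binomial overdispersion.
    """

    n_genes: int = 2000
    group_counts: dict = field(default_factory=lambda: dict(DEFAULT_GROUP_COUNTS))
    replicates: int = 3
    log2_effect: float = 2.0
    dispersion: float = 0.05
    utr_len_min: int = 60
    utr_len_max: int = 400
    gc: float = 0.35  # plant UTRs are AT-rich
    seed: int = 0

    def __post_init__(self) -> None:
        if sum(self.group_counts.values()) > self.n_genes:
            raise ValueError("planted group counts exceed n_genes")
        if not 0 < self.gc < 1:
            raise ValueError("gc must be in (0,1)")
        if self.replicates < 1 or self.dispersion <= 0 or self.n_genes < 1:
            raise ValueError("invalid simulation spec")


@dataclass
class GroundTruth:
    """What was planted where."""

    groups: dict = field(default_factory=dict)  # gene -> group
    motifs: dict = field(default_factory=dict)  # gene -> list[(pattern, start1)]
    uorfs: dict = field(default_factory=dict)   # gene -> list[dict]
    mirna_sites: dict = field(default_factory=dict)  # gene -> list[dict]


def _gene_ids(n: int) -> list[str]:
    return [f"ATSIM{i:05d}" for i in range(1, n + 1)]


def _nb_fpkm(rng: np.random.Generator, mean: np.ndarray, dispersion: float, depth: float = 100.0):
    """FPKM replicates via a gamma-scaled negative-binomial count draw.

    Counts ~ NB(mean = FPKM x depth, dispersion a) sampled as
    Poisson(Gamma(shape 1/a, scale a x mean)), then rescaled by depth.
    """
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, (mean * depth) / shape)
    counts = rng.poisson(lam)
    return counts / depth


def simulate_expression(spec: SimulationSpec) -> tuple[pd.DataFrame, GroundTruth]:
    """Expression table with genes planted into the six TE groups.

    Transcriptome means are log-uniform over [10, 1000] FPKM; a planted
    gene's translatome mean is its transcriptome mean times
    2**(+/- log2_effect) in the condition(s) its group dictates, and equal
    to it elsewhere.
    """
    rng = np.random.default_rng(spec.seed)
    genes = _gene_ids(spec.n_genes)
    groups = []
    for g, cnt in spec.group_counts.items():
        groups += [g] * cnt
    groups += ["none"] * (spec.n_genes - len(groups))
    rng.shuffle(groups)
    truth = GroundTruth(groups=dict(zip(genes, groups)))

    tc_mean = 10 ** rng.uniform(np.log10(10), np.log10(1000), size=spec.n_genes)
    effect = {}
    for cond in ("control", "treated"):
        e = np.zeros(spec.n_genes)
        for i, g in enumerate(groups):
            if g == "none":
                continue
            sign = 1.0 if g.endswith("up") else -1.0
            in_control = g.startswith(("NY", "YY"))
            in_treated = g.startswith(("YN", "YY"))
            if (cond == "control" and in_control) or (cond == "treated" and in_treated):
                e[i] = sign * spec.log2_effect
        effect[cond] = e

    # the stated dispersion is the replicate-level dispersion of the TE
    # *ratio*; each fraction carries half of the variance budget
    frac_disp = spec.dispersion / 2.0
    cols = {}
    for cond in ("control", "treated"):
        tl_mean = tc_mean * 2.0 ** effect[cond]
        for rep in range(1, spec.replicates + 1):
            cols[("transcriptome", cond, rep)] = _nb_fpkm(rng, tc_mean, frac_disp)
            cols[("translatome", cond, rep)] = _nb_fpkm(rng, tl_mean, frac_disp)
    df = pd.DataFrame(cols, index=pd.Index(genes, name="gene"))
    df.columns = pd.MultiIndex.from_tuples(
        df.columns, names=["fraction", "condition", "replicate"]
    )
    return df.sort_index(axis=1), truth


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=length, p=p)


def _concretize(rng: np.random.Generator, pattern: str) -> str:
    """Sample one concrete DNA word from an IUPAC pattern."""
    return "".join(rng.choice(list(ambiguous_dna_values[c])) for c in to_dna(pattern))


def _free_slot(
    rng: np.random.Generator, length: int, width: int, occupied: list, lo: int = 0, hi: int | None = None
) -> int | None:
    """A start position (0-based) whose [start, start+width) avoids all
    occupied intervals; None after too many rejections."""
    hi = length - width if hi is None else min(hi, length - width)
    if hi < lo:
        return None
    for _ in range(200):
        s = int(rng.integers(lo, hi + 1))
        if all(s + width <= a or s >= b for a, b in occupied):
            occupied.append((s, s + width))
            return s
    return None


def _build_uorf(rng, n_codons: int) -> str:
    """ATG + random non-stop codons + stop; total length 3*(n_codons)."""
    body = []
    for _ in range(n_codons - 2):
        while True:
            codon = "".join(rng.choice(list("ACGT"), size=3))
            if codon not in STOPS and codon != "ATG":
                break
        body.append(codon)
    return "ATG" + "".join(body) + str(rng.choice(STOPS))


_KOZAK_BASE = {"strong": ("A", "G"), "suboptimal": ("A", "C"), "weak": ("C", "C")}


def simulate_utrs(
    spec: SimulationSpec,
    region: str,
    n_seqs: int | None = None,
    motif: str | None = None,
    motif_fraction: float = 0.0,
    uorf_codons: int = 0,
    uorf_kozak: str = "strong",
    uorf_leader: int | None = None,
    mirna: str | None = None,
    mirna_mismatch_positions: tuple[int, ...] = (),
    mirna_wobble_positions: tuple[int, ...] = (),
    scoring: ScoringConfig = ScoringConfig(),
) -> tuple[list[SequenceRecord], GroundTruth]:
    """Random UTR set with planted elements at recorded positions.

    ``motif`` is an IUPAC pattern planted (one concretized copy) in a
    ``motif_fraction`` of sequences; ``uorf_codons`` > 0 plants one uORF
    per sequence with the requested Kozak class and leader length;
    ``mirna`` plants one complementary site per sequence with mismatches/
    wobbles at the given duplex positions (1 = miRNA 5' end).  Planted
    elements never overlap.
    """
    if region not in ("utr5", "utr3"):
        raise ValueError("region must be utr5 or utr3")
    rng = np.random.default_rng(spec.seed + 1)
    n = n_seqs if n_seqs is not None else spec.n_genes
    truth = GroundTruth()
    records = []
    n_with_motif = int(round(motif_fraction * n)) if motif else 0
    for i in range(n):
        gid = f"ATSIM{i + 1:05d}"
        length = int(rng.integers(spec.utr_len_min, spec.utr_len_max + 1))
        needed = 0
        if uorf_codons:
            needed += 3 * uorf_codons + (uorf_leader or 20) + 8
        if mirna:
            needed += len(mirna) + 2
        if motif:
            needed += len(motif) + 2
        length = max(length, needed)
        arr = _random_seq(rng, length, spec.gc)
        occupied: list[tuple[int, int]] = []

        if uorf_codons:
            word = _build_uorf(rng, uorf_codons)
            leader = uorf_leader if uorf_leader is not None else 20
            if leader + len(word) + 4 > length:
                raise ValueError("planted uORF longer than sequence")
            start = leader
            occupied.append((start - 4, start + len(word) + 1))
            arr[start : start + len(word)] = np.frombuffer(word.encode(), dtype=np.uint8)
            b3, b4 = _KOZAK_BASE[uorf_kozak]
            if start >= 3:
                arr[start - 3] = ord(b3)
            # +4 is the base right after the ATG, i.e. the first base of
            # codon 2 inside the uORF body
            arr[start + 3] = ord(b4)
            # ensure codon 2 did not become a stop/start after the edit
            codon2 = bytes(arr[start + 3 : start + 6]).decode()
            while codon2 in STOPS or codon2 == "ATG":
                arr[start + 4] = ord(str(rng.choice(list("ACGT"))))
                codon2 = bytes(arr[start + 3 : start + 6]).decode()
            # scrub upstream in-frame ATGs sharing this uORF's stop and any
            # accidental earlier ATG inside the leader
            truth.uorfs.setdefault(gid, []).append(
                {
                    "start": start + 1,
                    "end": start + len(word),
                    "kozak": uorf_kozak,
                    "dist_from_cap": start,
                }
            )

        if mirna:
            m = to_dna(mirna)
            site = _make_site(rng, m, mirna_mismatch_positions, mirna_wobble_positions)
            pos = _free_slot(rng, length, len(site), occupied)
            if pos is None:
                raise ValueError("no room for planted miRNA site")
            arr[pos : pos + len(site)] = np.frombuffer(site.encode(), dtype=np.uint8)
            states = pair_states(m, site)
            truth.mirna_sites.setdefault(gid, []).append(
                {
                    "start": pos + 1,
                    "end": pos + len(site),
                    "expectation": score_window(states, scoring),
                    "action": classify_action(states, scoring),
                }
            )

        if motif and i < n_with_motif:
            word = _concretize(rng, motif)
            pos = _free_slot(rng, length, len(word), occupied)
            if pos is None:
                raise ValueError("no room for planted motif")
            arr[pos : pos + len(word)] = np.frombuffer(word.encode(), dtype=np.uint8)
            truth.motifs.setdefault(gid, []).append((motif, pos + 1))

        seq = bytes(arr).decode()
        if uorf_codons:
            planted = truth.uorfs[gid][-1]
            seq = _scrub_spurious_atg(rng, seq, planted)
            seq = _repair_kozak(seq, planted, *_KOZAK_BASE[uorf_kozak])
        records.append(SequenceRecord(gid, seq, region))
    return records, truth


def _make_site(rng, mirna_dna: str, mismatch_pos, wobble_pos) -> str:
    """Target window perfectly complementary to the miRNA except at the
    requested duplex positions (1 = miRNA 5' end)."""
    L = len(mirna_dna)
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    site = [""] * L
    for i, m in enumerate(mirna_dna):  # duplex position i+1 -> site index L-1-i
        j = L - 1 - i
        pos = i + 1
        if pos in wobble_pos:
            if m == "G":
                site[j] = "T"
            elif m == "T":
                site[j] = "G"
            else:
                raise ValueError(f"no G:U wobble possible at position {pos} (miRNA base {m})")
        elif pos in mismatch_pos:
            choices = [b for b in "ACGT" if b != comp[m] and not (
                (m == "G" and b == "T") or (m == "T" and b == "G"))]
            site[j] = str(rng.choice(choices))
        else:
            site[j] = comp[m]
    return "".join(site)


def _repair_kozak(seq: str, uorf: dict, b3: str, b4: str) -> str:
    """Re-assert the planted Kozak bases after ATG scrubbing.

    Setting -3 to A can itself spell an in-frame upstream ATG (A at -3
    followed by TG); the -2 base is then rewritten to C, which cannot
    complete any other ATG."""
    s = list(seq)
    start0 = uorf["start"] - 1
    if start0 >= 3:
        s[start0 - 3] = b3
        if b3 == "A" and s[start0 - 2] == "T" and s[start0 - 1] == "G":
            s[start0 - 2] = "C"
    s[start0 + 3] = b4
    return "".join(s)


def _scrub_spurious_atg(rng, seq: str, uorf: dict) -> str:
    """Remove chance ATGs that would extend or shadow the planted uORF.

    Any ATG upstream of (and in frame with) the planted start that reaches
    the planted stop would make the planted uORF non-maximal; rewrite such
    ATGs.  Out-of-frame or downstream ATGs are left alone — they are part
    of realistic background.
    """
    s = list(seq)
    start0 = uorf["start"] - 1
    changed = True
    while changed:
        changed = False
        for i in range(start0):
            if "".join(s[i : i + 3]) == "ATG" and (start0 - i) % 3 == 0:
                # check it reaches the planted stop without an earlier stop
                j = i + 3
                blocked = False
                while j < start0:
                    if "".join(s[j : j + 3]) in STOPS:
                        blocked = True
                        break
                    j += 3
                if not blocked:
                    s[i] = str(rng.choice(["C", "G"]))
                    changed = True
    return "".join(s)


def simulate_background(
    n_seqs: int, length: int, gc: float = 0.35, seed: int = 0
) -> list[SequenceRecord]:
    """Plain background sequences (no planted elements), i.i.d. at ``gc``."""
    if n_seqs < 1:
        raise ValueError("n_seqs must be >= 1")
    rng = np.random.default_rng(seed)
    return [
        SequenceRecord(f"BG{i + 1:05d}", bytes(_random_seq(rng, length, gc)).decode(), "utr3")
        for i in range(n_seqs)
    ]
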
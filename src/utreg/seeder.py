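"""Seed-based de novo motif discovery with an empirical background null.

The method scores a fixed-length seed (a 6- or 8-mer) against a sequence
by the minimum Hamming distance between the seed and any window of the
sequence.  On a large genome-wide background set of UTRs, each seed gets
an empirical probability mass function over distances {0..k}: the fraction
of background sequences whose best match sits at each distance.

Foreground gene lists are resampled into many small subgroups.  Within a
subgroup of m sequences a seed's score S is the sum of its m per-sequence
minimum distances; under the null that the subgroup looks like background,
S is distributed as the m-fold convolution of the seed's background pmf,
so the left-tail enrichment p-value P(S_null <= S_obs) is exact — no
sampling.  p-values are Benjamini-Hochberg corrected across all seeds
tested within a subgroup and seeds with q below threshold are reported,
aggregated across subgroups with each seed keeping its best q.  A reported
seed is extended to a position weight matrix from the best-match window of
each subgroup sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import logging

import numpy as np
from statsmodels.stats.multitest import multipletests

from .io import SequenceRecord

__all__ = [
    "BackgroundModel",
    "SubgroupScheme",
    "EnrichedMotif",
    "build_background",
    "make_subgroups",
    "seed_pvalue",
    "null_cdf",
    "discover",
    "extend_to_pwm",
    "min_distances",
    "seed_to_string",
    "string_to_seed",
]

logger = logging.getLogger(__name__)

_BASES = "ACGT"
_CODE = {b: i for i, b in enumerate(_BASES)}


def string_to_seed(s: str) -> int:
    """Index of a k-mer in the lexicographic 4**k enumeration."""
    idx = 0
    for ch in s:
        idx = idx * 4 + _CODE[ch]
    return idx


def seed_to_string(idx: int, k: int) -> str:
    out = []
    for _ in range(k):
        out.append(_BASES[idx % 4])
        idx //= 4
    return "".join(reversed(out))


def _encode(seq: str) -> np.ndarray:
    """Base codes (A=0..T=3), N encoded as 4 so it never matches."""
    trans = str.maketrans("ACGTN", "\x00\x01\x02\x03\x04")
    return np.frombuffer(seq.translate(trans).encode("latin1"), dtype=np.uint8)


def _seed_matrix(k: int, seeds: np.ndarray | None = None) -> np.ndarray:
    """(n_seeds, k) base-code matrix for the given seed indices (or all 4^k)."""
    if seeds is None:
        seeds = np.arange(4**k, dtype=np.int64)
    mat = np.empty((len(seeds), k), dtype=np.uint8)
    rem = np.asarray(seeds, dtype=np.int64).copy()
    for j in range(k - 1, -1, -1):
        mat[:, j] = rem % 4
        rem //= 4
    return mat


def min_distances(seq: str, k: int, seed_mat: np.ndarray) -> np.ndarray:
    """Per-seed minimum Hamming distance to any window of ``seq``.

    Windows containing N count as distance k at N positions (N matches
    nothing), so an all-N sequence gives distance k.  Sequences shorter
    than k yield distance k for every seed.
    """
    codes = _encode(seq)
    n_win = len(codes) - k + 1
    if n_win <= 0:
        return np.full(seed_mat.shape[0], k, dtype=np.int64)
    windows = np.lib.stride_tricks.sliding_window_view(codes, k)  # (n_win, k)
    # (n_seeds, 1, k) vs (1, n_win, k) -> mismatch counts (n_seeds, n_win)
    mism = (seed_mat[:, None, :] != windows[None, :, :]).sum(axis=2)
    return mism.min(axis=1).astype(np.int64)


@dataclass
class BackgroundModel:
    """Empirical per-seed distance distributions on a background set.

    ``pmf[i, d]`` is the fraction of background sequences whose minimum
    Hamming distance to seed ``seeds[i]`` is d; each row sums to 1.
    """

    k: int
    seeds: np.ndarray  # seed indices covered, shape (n_seeds,)
    pmf: np.ndarray  # shape (n_seeds, k + 1)
    n_background: int

    def __post_init__(self) -> None:
        self._index = {int(s): i for i, s in enumerate(self.seeds)}

    def pmf_for(self, seed: int | str) -> np.ndarray:
        if isinstance(seed, str):
            seed = string_to_seed(seed)
        return self.pmf[self._index[int(seed)]]


def build_background(
    background_seqs: list[SequenceRecord] | list[str],
    k: int,
    seeds: np.ndarray | list[int] | None = None,
) -> BackgroundModel:
    """Estimate per-seed background pmfs of best-match distances.

    With ``seeds=None`` all 4**k seeds are enumerated (intended for k=6);
    for k=8 pass the restricted seed set of interest — full enumeration of
    65,536 seeds is supported but slow.  Sequences shorter than k
    contribute nothing.
    """
    if k not in (6, 8):
        raise ValueError("seed length k must be 6 or 8")
    seqs = [r.seq if isinstance(r, SequenceRecord) else r for r in background_seqs]
    seqs = [s for s in seqs if len(s) >= k]
    if not seqs:
        raise ValueError("background set empty (after dropping sequences < k)")
    seed_idx = (
        np.arange(4**k, dtype=np.int64)
        if seeds is None
        else np.asarray(sorted(set(int(s) for s in seeds)), dtype=np.int64)
    )
    seed_mat = _seed_matrix(k, seed_idx)
    counts = np.zeros((len(seed_idx), k + 1), dtype=np.int64)
    for s in seqs:
        d = min_distances(s, k, seed_mat)
        np.add.at(counts, (np.arange(len(seed_idx)), d), 1)
    pmf = counts / counts.sum(axis=1, keepdims=True)
    return BackgroundModel(k=k, seeds=seed_idx, pmf=pmf, n_background=len(seqs))


@dataclass(frozen=True)
class SubgroupScheme:
    """Resampling plan: ``n_subgroups`` draws of ``subgroup_size`` sequences."""

    n_subgroups: int = 500
    subgroup_size: int = 10
    seed: int = 0


def make_subgroups(
    seqs: list[SequenceRecord], scheme: SubgroupScheme = SubgroupScheme()
) -> list[list[SequenceRecord]]:
    """Draw random subgroups, each without replacement within itself.

    Subgroups are drawn independently of each other; when the set holds
    fewer than ``subgroup_size`` sequences every subgroup takes the whole
    set (with a warning).  Deterministic under the scheme's rng seed.
    """
    if not seqs:
        raise ValueError("cannot subgroup an empty sequence set")
    size = min(scheme.subgroup_size, len(seqs))
    if size < scheme.subgroup_size:
        logger.warning(
            "only %d sequences available; subgroup size reduced to %d",
            len(seqs), size,
        )
    rng = np.random.default_rng(scheme.seed)
    out = []
    for _ in range(scheme.n_subgroups):
        idx = rng.choice(len(seqs), size=size, replace=False)
        out.append([seqs[i] for i in idx])
    return out


def null_cdf(pmf: np.ndarray, m: int) -> np.ndarray:
    """CDF of the sum of m i.i.d. draws from ``pmf`` (exact convolution)."""
    dist = np.asarray(pmf, dtype=float)
    out = np.array([1.0])
    base = dist
    mm = m
    # exponentiation by squaring keeps this cheap even for large m
    while mm:
        if mm & 1:
            out = np.convolve(out, base)
        mm >>= 1
        if mm:
            base = np.convolve(base, base)
    return np.cumsum(out)


def seed_pvalue(s_observed: int, m: int, pmf: np.ndarray) -> float:
    """Exact left-tail enrichment p-value P(S_null <= S_observed)."""
    if m < 1:
        raise ValueError("subgroup size m must be >= 1")
    cdf = null_cdf(pmf, m)
    s = int(s_observed)
    if s < 0:
        s = 0
    # floor keeps p strictly positive when the empirical null puts no mass
    # at or below the observed score
    return float(max(min(cdf[min(s, len(cdf) - 1)], 1.0), 1e-300))


@dataclass
class EnrichedMotif:
    """A seed reported as enriched, with its best subgroup's evidence."""

    seed: str
    k: int
    best_q: float
    best_p: float
    best_score: int
    n_subgroups_significant: int
    subgroup_id: int
    sites: list[tuple[str, int]] = field(default_factory=list)  # (gene, 1-based pos)
    pwm: np.ndarray | None = None


def _subgroup_distance_table(
    subgroup: list[SequenceRecord],
    seed_mat: np.ndarray,
    k: int,
    cache: dict[str, np.ndarray],
) -> np.ndarray:
    rows = []
    for rec in subgroup:
        if rec.id not in cache:
            cache[rec.id] = min_distances(rec.seq, k, seed_mat)
        rows.append(cache[rec.id])
    return np.vstack(rows)  # (m, n_seeds)


def discover(
    subgroups: list[list[SequenceRecord]],
    background: BackgroundModel,
    q_threshold: float = 0.05,
) -> list[EnrichedMotif]:
    """Score every background-covered seed in every subgroup.

    Within a subgroup: exact convolution p-value per seed, BH correction
    across the seeds tested, keep q <= threshold.  Across subgroups each
    seed retains its minimum q (with that subgroup's sites and PWM) plus
    the count of subgroups where it passed.  Sequences shorter than k are
    ignored inside a subgroup.
    """
    k = background.k
    seed_mat = _seed_matrix(k, background.seeds)
    cache: dict[str, np.ndarray] = {}
    cdf_cache: dict[int, np.ndarray] = {}
    best: dict[int, EnrichedMotif] = {}
    for gid, group in enumerate(subgroups):
        group = [r for r in group if len(r.seq) >= k]
        if not group:
            continue
        m = len(group)
        dists = _subgroup_distance_table(group, seed_mat, k, cache)
        scores = dists.sum(axis=0)  # (n_seeds,)
        if m not in cdf_cache:
            # one CDF per (seed, m); rows stacked as (n_seeds, m*k + 1)
            cdf_cache[m] = np.vstack(
                [null_cdf(background.pmf[i], m) for i in range(len(background.seeds))]
            )
        cdfs = cdf_cache[m]
        pvals = np.clip(
            cdfs[np.arange(len(scores)), np.minimum(scores, cdfs.shape[1] - 1)],
            1e-300, 1.0,
        )
        _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
        hits = np.flatnonzero(qvals <= q_threshold)
        for h in hits:
            seed_idx = int(background.seeds[h])
            prev = best.get(seed_idx)
            if prev is None:
                seed_str = seed_to_string(seed_idx, k)
                sites = _best_sites(seed_str, group)
                best[seed_idx] = EnrichedMotif(
                    seed=seed_str,
                    k=k,
                    best_q=float(qvals[h]),
                    best_p=float(pvals[h]),
                    best_score=int(scores[h]),
                    n_subgroups_significant=1,
                    subgroup_id=gid,
                    sites=sites,
                    pwm=extend_to_pwm(seed_str, group),
                )
            else:
                prev.n_subgroups_significant += 1
                if qvals[h] < prev.best_q:
                    prev.best_q = float(qvals[h])
                    prev.best_p = float(pvals[h])
                    prev.best_score = int(scores[h])
                    prev.subgroup_id = gid
                    prev.sites = _best_sites(prev.seed, group)
                    prev.pwm = extend_to_pwm(prev.seed, group)
    return sorted(best.values(), key=lambda mo: (mo.best_q, mo.seed))


def _best_match_pos(seed: str, seq: str) -> int:
    """0-based position of the best-matching window (leftmost tie-break)."""
    k = len(seed)
    mat = _seed_matrix(k, np.array([string_to_seed(seed)]))
    codes = _encode(seq)
    windows = np.lib.stride_tricks.sliding_window_view(codes, k)
    mism = (mat[0][None, :] != windows).sum(axis=1)
    return int(np.argmin(mism))


def _best_sites(seed: str, group: list[SequenceRecord]) -> list[tuple[str, int]]:
    return [(rec.id, _best_match_pos(seed, rec.seq) + 1) for rec in group]


def extend_to_pwm(
    seed: str, group: list[SequenceRecord], pseudocount: float = 0.25
) -> np.ndarray:
    """PWM (k x 4, rows normalized) from each sequence's best-match window."""
    k = len(seed)
    counts = np.full((k, 4), pseudocount, dtype=float)
    for rec in group:
        pos = _best_match_pos(seed, rec.seq)
        window = rec.seq[pos : pos + k]
        for j, ch in enumerate(window):
            if ch in _CODE:
                counts[j, _CODE[ch]] += 1
    return counts / counts.sum(axis=1, keepdims=True)
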
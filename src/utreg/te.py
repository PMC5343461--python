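"""Translational-efficiency classification.

Translational efficiency (TE) of a gene is the ratio of its ribosome-bound
(translatome) FPKM to its total-mRNA (transcriptome) FPKM.  Under purely
transcriptional regulation TE is ~1 in both conditions.  A gene is labelled
``Y`` in a condition when its TE deviates significantly from 1 there, ``N``
otherwise, and the two labels plus the direction of the deviation place it
in one of six groups:

========  =============================================================
YNup/dn   significant TE deviation only under treatment (up / down)
NYup/dn   significant TE deviation only in the control condition
YYup/dn   significant, same-sign deviation in both conditions
========  =============================================================

Genes significant in both conditions with opposite signs are reported as
``discordant`` rather than forced into a YY group; genes significant in
neither are ``none``.

Significance is a moderated one-sample two-sided t-test of replicate log2
TE against 0 (gene-wise variances squeezed toward an empirical-Bayes
prior), Benjamini-Hochberg corrected across genes within each condition,
with an effect-size floor on |mean log2 TE|.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import filter_short

__all__ = [
    "compute_te",
    "replicate_log2_te",
    "test_te",
    "assign_group",
    "classify",
    "group_accounting",
    "GROUPS",
]

GROUPS = ("YNup", "YNdown", "NYup", "NYdown", "YYup", "YYdown")


def compute_te(
    translatome_fpkm: float, transcriptome_fpkm: float, pseudocount: float = 0.5
) -> float:
    """TE ratio (translatome + pc) / (transcriptome + pc).

    The pseudocount (default 0.5 FPKM) keeps the ratio finite when the
    transcriptome FPKM is 0 while preserving ordering.
    """
    if translatome_fpkm < 0 or transcriptome_fpkm < 0:
        raise ValueError("FPKM values must be non-negative")
    if pseudocount < 0 or (pseudocount == 0 and transcriptome_fpkm == 0):
        raise ValueError("pseudocount must be positive when transcriptome FPKM is 0")
    return (translatome_fpkm + pseudocount) / (transcriptome_fpkm + pseudocount)


def replicate_log2_te(
    expression: pd.DataFrame, condition: str, pseudocount: float = 0.5
) -> pd.DataFrame:
    """Per-replicate log2 TE for one condition (genes x replicates).

    Replicate i of the translatome is paired with replicate i of the
    transcriptome.
    """
    tl = expression["translatome"][condition].to_numpy(dtype=float)
    tc = expression["transcriptome"][condition].to_numpy(dtype=float)
    ratios = np.log2((tl + pseudocount) / (tc + pseudocount))
    return pd.DataFrame(ratios, index=expression.index)


def _trigamma_inverse(y: float, tol: float = 1e-8) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton iterations)."""
    from scipy.special import polygamma

    if y <= 0:
        return np.inf
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = float(polygamma(1, x))
        dif = tri * (1 - tri / y) / float(polygamma(2, x))
        x += dif
        if abs(dif) < tol * x:
            break
    return x


def _moderate_variances(s2: np.ndarray, df: int) -> tuple[np.ndarray, float]:
    """Empirical-Bayes squeeze of gene-wise variances.

    Fits a scaled inverse-chi-square prior (s0^2, d0) to the observed
    variances by matching the moments of log s^2 (the limma recipe) and
    returns the posterior variances (d0*s0^2 + df*s2)/(d0 + df) together
    with the prior degrees of freedom d0 (inf when the variances are
    essentially exchangeable).
    """
    from scipy.special import digamma, polygamma

    pos = s2[s2 > 0]
    if len(pos) < 2:
        return s2, 0.0
    z = np.log(pos)
    var_z = float(np.var(z, ddof=1)) - float(polygamma(1, df / 2.0))
    d0 = 2.0 * _trigamma_inverse(var_z)
    mean_z = float(np.mean(z)) - float(digamma(df / 2.0)) + np.log(df / 2.0)
    if np.isfinite(d0):
        log_s02 = mean_z + float(digamma(d0 / 2.0)) - np.log(d0 / 2.0)
        s02 = float(np.exp(log_s02))
        post = (d0 * s02 + df * s2) / (d0 + df)
    else:
        s02 = float(np.exp(mean_z))
        post = np.full_like(s2, s02)
    return post, d0


def test_te(
    log2te: pd.DataFrame, alpha: float = 0.05, effect_floor: float = 0.5
) -> pd.DataFrame:
    """Test per-gene replicate log2 TE against 0 with BH correction.

    The test is a moderated one-sample two-sided t-test: gene-wise
    variances are squeezed toward an empirical-Bayes prior estimated from
    all genes, adding the prior degrees of freedom to the residual ones.
    With only a handful of replicates per gene this pooling is what makes
    small p-values attainable at all; with many replicates it converges to
    the ordinary t-test.

    Returns a DataFrame with columns ``log2te`` (replicate mean), ``p``,
    ``q`` and boolean ``significant`` (q <= alpha and |mean| >= floor).
    With a single replicate the parametric test is unavailable and the
    rule degrades to the effect floor alone (p = q = NaN).
    """
    arr = log2te.to_numpy(dtype=float)
    n = arr.shape[1]
    if n < 1:
        raise ValueError("at least one replicate required")
    mean = arr.mean(axis=1)
    if n >= 2:
        df_resid = n - 1
        s2 = arr.var(axis=1, ddof=1)
        s2_post, d0 = _moderate_variances(s2, df_resid)
        df_total = d0 + df_resid
        se = np.sqrt(s2_post / n)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(se > 0, mean / se, np.where(mean == 0.0, 0.0, np.inf))
        if np.isfinite(df_total):
            p = 2.0 * stats.t.sf(np.abs(t), df_total)
        else:
            p = 2.0 * stats.norm.sf(np.abs(t))
        p = np.clip(p, 0.0, 1.0)
        _, q, _, _ = multipletests(p, method="fdr_bh")
        significant = (q <= alpha) & (np.abs(mean) >= effect_floor)
    else:
        p = np.full(len(mean), np.nan)
        q = np.full(len(mean), np.nan)
        significant = np.abs(mean) >= effect_floor
    return pd.DataFrame(
        {"log2te": mean, "p": p, "q": q, "significant": significant},
        index=log2te.index,
    )


def assign_group(
    label_control: str,
    label_treated: str,
    log2te_control: float,
    log2te_treated: float,
) -> str:
    """Map the two Y/N labels and deviation signs to a group name."""
    yc = label_control == "Y"
    yt = label_treated == "Y"
    if yt and not yc:
        return "YNup" if log2te_treated > 0 else "YNdown"
    if yc and not yt:
        return "NYup" if log2te_control > 0 else "NYdown"
    if yc and yt:
        if np.sign(log2te_control) == np.sign(log2te_treated):
            return "YYup" if log2te_treated > 0 else "YYdown"
        return "discordant"
    return "none"


def classify(
    expression: pd.DataFrame,
    alpha: float = 0.05,
    effect_floor: float = 0.5,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Full per-gene TE classification from an expression table.

    Returns a DataFrame indexed by gene with TE ratios, log2 TE, p/q values
    and labels per condition, and the final ``group`` assignment.
    """
    out = {}
    for cond in ("control", "treated"):
        l2 = replicate_log2_te(expression, cond, pseudocount)
        res = test_te(l2, alpha=alpha, effect_floor=effect_floor)
        out[cond] = res
    df = pd.DataFrame(index=expression.index)
    for cond in ("control", "treated"):
        df[f"te_{cond}"] = 2.0 ** out[cond]["log2te"]
        df[f"log2te_{cond}"] = out[cond]["log2te"]
        df[f"p_{cond}"] = out[cond]["p"]
        df[f"q_{cond}"] = out[cond]["q"]
        df[f"label_{cond}"] = np.where(out[cond]["significant"], "Y", "N")
        df[f"direction_{cond}"] = np.where(
            out[cond]["significant"],
            np.where(out[cond]["log2te"] > 0, "up", "down"),
            "none",
        )
    df["group"] = [
        assign_group(lc, lt, c, t)
        for lc, lt, c, t in zip(
            df["label_control"], df["label_treated"],
            df["log2te_control"], df["log2te_treated"],
        )
    ]
    return df


def group_accounting(
    classifications: pd.DataFrame,
    utr5_records=None,
    utr3_records=None,
    min_len: int = 10,
) -> pd.DataFrame:
    """Per-group gene counts, optionally with UTR-retention counts.

    Rows: genes per group; genes retaining a 3' UTR and a 5' UTR after the
    short-sequence filter (when the corresponding record sets are given).
    A ``total`` column sums the six groups.
    """
    counts = {g: int((classifications["group"] == g).sum()) for g in GROUPS}
    rows = {"genes": counts}
    for name, records in (("genes_with_utr3", utr3_records), ("genes_with_utr5", utr5_records)):
        if records is None:
            continue
        kept, _ = filter_short(list(records), min_len)
        ids = {r.id for r in kept}
        rows[name] = {
            g: int(
                classifications.index[classifications["group"] == g].isin(ids).sum()
            )
            for g in GROUPS
        }
    table = pd.DataFrame(rows).T[list(GROUPS)]
    table["total"] = table.sum(axis=1)
    return table


def group_gene_lists(classifications: pd.DataFrame) -> dict[str, list[str]]:
    """Gene ids per group, for export as per-group list files."""
    return {
        g: classifications.index[classifications["group"] == g].tolist()
        for g in GROUPS
    }
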
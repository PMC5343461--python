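"""End-to-end orchestration: classify -> filter -> scan -> discover -> match.

A :class:`RunConfig` carries every threshold the stages use plus the rng
seed; :func:`run_pipeline` executes the enabled stages in order and writes
TSV/JSON outputs together with a machine-readable run manifest, so that
any report line can be traced back to its parameters.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import io as fio
from . import te as te_mod
from . import uorf as uorf_mod
from . import mirna as mirna_mod
from . import seeder
from . import pwm as pwm_mod

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "make_report"]

ALL_STAGES = ("classify", "uorf", "mirna", "motifs", "compare")


@dataclass
class RunConfig:
    """Inputs, outputs and thresholds for a pipeline run."""

    # inputs
    expression: str | None = None
    utr5_fasta: str | None = None
    utr3_fasta: str | None = None
    mirna_fasta: str | None = None
    background_fasta: str | None = None
    known_motifs: str | None = None  # TSV: name <tab> IUPAC pattern
    outdir: str = "utreg_out"
    # thresholds
    alpha: float = 0.05
    effect_floor: float = 0.5
    pseudocount: float = 0.5
    min_utr_len: int = 10
    uorf_min_len: int = 60
    max_expectation: float = 3.0
    central_range: tuple[int, int] = (9, 11)
    seed_lengths: tuple[int, ...] = (6,)
    n_subgroups: int = 500
    subgroup_size: int = 10
    q_threshold: float = 0.05
    compare_evalue: float = 0.05
    min_overlap: int = 7
    pwm_scan_threshold: float = 0.8
    # misc
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**data)
        for key in ("central_range", "seed_lengths", "stages"):
            setattr(cfg, key, tuple(getattr(cfg, key)))
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        for key in ("central_range", "seed_lengths", "stages"):
            d[key] = list(d[key])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    def validate(self) -> None:
        if not 0 < self.alpha < 1 or not 0 < self.q_threshold < 1:
            raise ValueError("alpha and q_threshold must be in (0,1)")
        if self.min_utr_len < 1 or self.uorf_min_len < 3:
            raise ValueError("length thresholds out of range")
        if self.max_expectation < 0 or self.min_overlap < 1:
            raise ValueError("thresholds out of range")
        needs = {
            "classify": ["expression"],
            "uorf": ["utr5_fasta"],
            "mirna": ["utr3_fasta", "mirna_fasta"],
            "motifs": ["utr3_fasta", "background_fasta"],
            "compare": [],
        }
        for stage in self.stages:
            if stage not in ALL_STAGES:
                raise ValueError(f"unknown stage {stage!r}")
            for attr in needs[stage]:
                path = getattr(self, attr)
                if path is None or not Path(path).exists():
                    raise FileNotFoundError(
                        f"stage {stage!r} needs input {attr} ({path})"
                    )


def _load_known_motifs(path: str | Path) -> list[pwm_mod.KnownMotif]:
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise ValueError(f"known-motif line needs name<TAB>pattern: {line!r}")
        out.append(pwm_mod.KnownMotif(parts[0], parts[1], parts[2] if len(parts) > 2 else ""))
    return out


def run_pipeline(config: RunConfig) -> dict:
    """Run the enabled stages in order and return the report dict.

    Validates every enabled stage's inputs before any stage runs; writes
    stage outputs plus ``report.json`` and ``manifest.json`` under
    ``config.outdir``.  Deterministic under ``config.seed``.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict = {}

    classifications = None
    groups_of: dict[str, str] = {}
    if "classify" in config.stages:
        expr = fio.read_expression(config.expression)
        classifications = te_mod.classify(
            expr, alpha=config.alpha, effect_floor=config.effect_floor,
            pseudocount=config.pseudocount,
        )
        classifications.to_csv(outdir / "te_classification.tsv", sep="\t")
        groups_of = classifications["group"].to_dict()
        outputs["classify"] = classifications
        for grp, genes in te_mod.group_gene_lists(classifications).items():
            (outdir / f"genes_{grp}.txt").write_text("\n".join(genes) + "\n")

    utr5 = utr3 = None
    if config.utr5_fasta and Path(config.utr5_fasta).exists():
        utr5, _ = fio.filter_short(
            fio.read_fasta(config.utr5_fasta, "utr5"), config.min_utr_len
        )
    if config.utr3_fasta and Path(config.utr3_fasta).exists():
        utr3, _ = fio.filter_short(
            fio.read_fasta(config.utr3_fasta, "utr3"), config.min_utr_len
        )

    if "uorf" in config.stages:
        rows = []
        for rec in utr5:
            for u in uorf_mod.scan_uorfs(rec, config.uorf_min_len):
                feats = uorf_mod.positional_features(u, len(rec))
                rows.append(
                    {
                        "gene": u.gene,
                        "group": groups_of.get(u.gene, "NA"),
                        "start": u.start,
                        "end": u.end,
                        "length_nt": u.length_nt,
                        "codons": u.codons,
                        "kozak": u.kozak,
                        **feats,
                    }
                )
        uorf_df = pd.DataFrame(
            rows,
            columns=["gene", "group", "start", "end", "length_nt", "codons",
                     "kozak", "dist_from_cap", "dist_to_main_orf",
                     "leader_ge_20", "near_main_orf"],
        )
        uorf_df.to_csv(outdir / "uorfs.tsv", sep="\t", index=False)
        outputs["uorf"] = uorf_df

    if "mirna" in config.stages:
        mirnas = fio.read_fasta(config.mirna_fasta, "utr3")
        scoring = mirna_mod.ScoringConfig(
            max_expectation=config.max_expectation,
            central_range=config.central_range,
        )
        rows = []
        for mi in mirnas:
            for rec in utr3:
                for s in mirna_mod.scan_targets(mi.seq, rec, scoring, mirna_id=mi.id):
                    rows.append(
                        {
                            "gene": s.gene,
                            "group": groups_of.get(s.gene, "NA"),
                            "mirna": s.mirna,
                            "site_start": s.site_start,
                            "site_end": s.site_end,
                            "expectation": s.expectation,
                            "action": s.action,
                        }
                    )
        site_df = pd.DataFrame(
            rows, columns=["gene", "group", "mirna", "site_start", "site_end",
                           "expectation", "action"],
        )
        site_df.to_csv(outdir / "mirna_sites.tsv", sep="\t", index=False)
        outputs["mirna"] = site_df

    motifs_found: list[seeder.EnrichedMotif] = []
    if "motifs" in config.stages:
        background_seqs = fio.read_fasta(config.background_fasta, "utr3")
        scheme = seeder.SubgroupScheme(
            n_subgroups=config.n_subgroups,
            subgroup_size=config.subgroup_size,
            seed=config.seed,
        )
        for k in config.seed_lengths:
            if k == 6:
                bg = seeder.build_background(background_seqs, k)
            else:
                observed = _observed_seeds(utr3, k)
                bg = seeder.build_background(background_seqs, k, seeds=observed)
            subgroups = seeder.make_subgroups(utr3, scheme)
            motifs_found += seeder.discover(subgroups, bg, config.q_threshold)
        pwms = [
            pwm_mod.PWM(f"S{i + 1}_{m.seed}", m.pwm, n_sites=len(m.sites))
            for i, m in enumerate(motifs_found)
        ]
        fio.write_motifs(pwms, outdir / "motifs.meme")
        pd.DataFrame(
            [
                {
                    "seed": m.seed,
                    "k": m.k,
                    "best_q": m.best_q,
                    "n_subgroups_significant": m.n_subgroups_significant,
                }
                for m in motifs_found
            ],
            columns=["seed", "k", "best_q", "n_subgroups_significant"],
        ).to_csv(outdir / "motifs.tsv", sep="\t", index=False)
        outputs["motifs"] = motifs_found

        if "compare" in config.stages and pwms:
            min_w = min(p.width for p in pwms)
            overlap = min(config.min_overlap, min_w)
            clusters = pwm_mod.cluster_average(
                pwms, min_overlap=overlap, alpha=config.compare_evalue,
                rng=config.seed,
            )
            avg_pwms = [c[1] for c in clusters]
            fio.write_motifs(avg_pwms, outdir / "clusters.meme")
            outputs["clusters"] = clusters
            if config.known_motifs:
                known = _load_known_motifs(config.known_motifs)
                matches = []
                for avg in avg_pwms:
                    for km in known:
                        kp = pwm_mod.pattern_to_pwm(km)
                        ov = min(overlap, kp.width, avg.width)
                        res = pwm_mod.compare_pwms(
                            avg, kp, min_overlap=ov,
                            alpha=config.compare_evalue, rng=config.seed,
                        )
                        if res.match:
                            matches.append(
                                {
                                    "cluster": avg.name,
                                    "known_motif": km.name,
                                    "score": res.score,
                                    "evalue": res.evalue,
                                    "orientation": res.orientation,
                                }
                            )
                match_df = pd.DataFrame(
                    matches,
                    columns=["cluster", "known_motif", "score", "evalue", "orientation"],
                )
                match_df.to_csv(outdir / "known_matches.tsv", sep="\t", index=False)
                outputs["known_matches"] = match_df

    report = make_report(outputs)
    (outdir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    manifest = dataclasses.asdict(config)
    for key in ("central_range", "seed_lengths", "stages"):
        manifest[key] = list(manifest[key])
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return report


def _observed_seeds(records, k: int) -> list[int]:
    """Seeds observed exactly in the foreground plus 1-mismatch neighbors."""
    seen: set[int] = set()
    for rec in records:
        s = rec.seq
        for i in range(len(s) - k + 1):
            w = s[i : i + k]
            if "N" in w:
                continue
            seen.add(seeder.string_to_seed(w))
    out = set(seen)
    for idx in seen:
        word = seeder.seed_to_string(idx, k)
        for pos in range(k):
            for b in "ACGT":
                if b != word[pos]:
                    out.add(seeder.string_to_seed(word[:pos] + b + word[pos + 1:]))
    return sorted(out)


def make_report(outputs: dict) -> dict:
    """Summary counts per group: genes, uORFs, miRNA sites, motifs.

    Each section reports per-group entries plus a total equal to the sum
    of its parts; fraction entries carry their raw numerator and
    denominator.
    """
    report: dict = {}
    if "classify" in outputs:
        cls = outputs["classify"]
        counts = {g: int((cls["group"] == g).sum()) for g in te_mod.GROUPS}
        report["groups"] = {**counts, "total": sum(counts.values())}
    if "uorf" in outputs:
        df = outputs["uorf"]
        per_group_u = df.groupby("group").size().to_dict() if len(df) else {}
        genes_by_group = (
            df.drop_duplicates("gene").groupby("group").size().to_dict() if len(df) else {}
        )
        report["uorfs"] = {
            "uorfs_per_group": {k: int(v) for k, v in per_group_u.items()},
            "uorf_total": int(len(df)),
            "genes_with_uorf_per_group": {k: int(v) for k, v in genes_by_group.items()},
            "genes_with_uorf_total": int(df["gene"].nunique()) if len(df) else 0,
        }
    if "mirna" in outputs:
        df = outputs["mirna"]
        per_group = df.groupby("group").size().to_dict() if len(df) else {}
        report["mirna_sites"] = {
            "sites_per_group": {k: int(v) for k, v in per_group.items()},
            "site_total": int(len(df)),
            "genes_with_site_total": int(df["gene"].nunique()) if len(df) else 0,
        }
    if "motifs" in outputs:
        motifs = outputs["motifs"]
        report["motifs"] = {
            "n_enriched_seeds": len(motifs),
            "n_clusters": len(outputs.get("clusters", [])) or None,
        }
        if "known_matches" in outputs:
            report["motifs"]["n_known_matches"] = int(len(outputs["known_matches"]))
    return report
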
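"""End-to-end orchestration of the discovery and design stages.

A flat key=value config (or a `PipelineConfig` built in code) drives the
stages; every output TSV is reproducible byte-for-byte from (inputs,
config, seed), and each run writes a manifest recording the config hash
and seed.  The single global seed fans out to per-stage seeds by fixed
offsets so stages stay reproducible in isolation.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

from . import __version__
from .design import (
    DEFAULT_FILTER_RANGES, build_peptides, filter_candidates, rank_designs,
    score_all_trios,
)
from .discovery import (
    DEFAULT_CF_THRESHOLD, DEFAULT_K_MAX, DEFAULT_K_MIN,
    discover, discover_per_family, motif_set_summary, per_region_counts,
)
from .io import (
    extract_region_sequences, read_fasta, read_motif_list, read_regions,
    write_fasta, write_motif_table, write_regions,
)
from .params import NOT_APPLICABLE
from .synthetic import GeneratorConfig, generate_database

log = logging.getLogger(__name__)

SEED_OFFSET_SIMULATE = 1
SEED_OFFSET_DESIGN = 2


@dataclass
class PipelineConfig:
    positive_fasta: str = ""
    region_tsv: str = ""
    negative_fasta: str = ""
    motif_list: str = ""
    output_dir: str = "results"
    k_min: int = DEFAULT_K_MIN
    k_max: int = DEFAULT_K_MAX
    cf_threshold: float = DEFAULT_CF_THRESHOLD
    top_k_trios: int = 100
    filter_ranges: dict = field(default_factory=lambda: dict(DEFAULT_FILTER_RANGES))
    kappa_na_policy: str = "pass"
    simulate: bool = False
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    seed: int = 0

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        """Load from a flat key=value text file ('#' comments ignored)."""
        config = cls()
        casts = {int: int, float: float, bool: lambda v: v.lower() in ("1", "true", "yes")}
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#") or "=" not in line:
                    continue
                key, _, value = line.partition("=")
                key, value = key.strip(), value.strip()
                if not hasattr(config, key):
                    raise ValueError(f"unknown config key {key!r}")
                current = getattr(config, key)
                cast = casts.get(type(current), str)
                setattr(config, key, cast(value))
        return config

    def manifest(self) -> dict:
        payload = {k: v for k, v in asdict(self).items() if k != "generator"}
        digest = hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()
        return {"config": payload, "config_sha256": digest,
                "seed": self.seed, "version": __version__}


def _load_inputs(config: PipelineConfig):
    if config.simulate:
        gen = config.generator
        gen.seed = config.seed + SEED_OFFSET_SIMULATE
        records, regions = generate_database(gen)
    else:
        for path in (config.positive_fasta, config.region_tsv, config.negative_fasta):
            if not path or not Path(path).exists():
                raise FileNotFoundError(f"required input missing: {path!r}")
        records = read_fasta(config.positive_fasta)
        if config.negative_fasta != config.positive_fasta:
            # a single combined FASTA (set= header tokens) is also accepted
            records += read_fasta(config.negative_fasta)
        regions = extract_region_sequences(records, read_regions(config.region_tsv))
    return records, regions


def _write_manifest(config: PipelineConfig, outdir: Path, stage: str) -> None:
    with open(outdir / f"manifest_{stage}.json", "w", encoding="utf-8") as fh:
        json.dump(config.manifest() | {"stage": stage}, fh, indent=2, sort_keys=True)
        fh.write("\n")


def run_discover(config: PipelineConfig) -> Path:
    """Run motif discovery; write motif-stats, per-region, per-family and
    summary TSVs plus a manifest.  Returns the output directory."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    records, regions = _load_inputs(config)
    if config.simulate:
        write_fasta(records, outdir / "database.fasta")
        write_regions(regions, outdir / "regions.tsv")

    dprs = [r for r in regions if r.kind == "DPR"]
    nodprs = [r.subsequence for r in regions if r.kind == "NODPR"]
    negatives = [rec.sequence for rec in records if rec.source_set == "negative"]
    stats, selected = discover(
        [r.subsequence for r in dprs], negatives, nodprs,
        k_min=config.k_min, k_max=config.k_max, cf_threshold=config.cf_threshold,
    )
    write_motif_table(selected, outdir / "motifs_selected.tsv")

    with open(outdir / "per_region_counts.tsv", "w", encoding="utf-8") as fh:
        fh.write("motif\tregion_id\tcount\n")
        for row in per_region_counts([s.motif for s in selected], dprs):
            fh.write(f"{row.motif}\t{row.region_id}\t{row.count}\n")

    per_family = discover_per_family(
        records, regions, negatives,
        k_min=config.k_min, k_max=config.k_max, cf_threshold=config.cf_threshold,
    )
    with open(outdir / "motifs_per_family.tsv", "w", encoding="utf-8") as fh:
        fh.write("family\tmotif\tCF\n")
        for family in sorted(per_family):
            for s in per_family[family]:
                fh.write(f"{family}\t{s.motif}\t{s.cf:.6f}\n")

    if selected:
        length_pct, membership_pct = motif_set_summary([s.motif for s in selected])
        with open(outdir / "motif_set_summary.tsv", "w", encoding="utf-8") as fh:
            fh.write("kind\tkey\tpercent\n")
            for k, v in length_pct.items():
                fh.write(f"length\t{k}\t{v:.2f}\n")
            for a, v in membership_pct.items():
                fh.write(f"membership\t{a}\t{v:.2f}\n")
    _write_manifest(config, outdir, "discover")
    log.info("discovery: %d candidates, %d selected", len(stats), len(selected))
    return outdir


def run_design(config: PipelineConfig) -> Path:
    """Score trios of a motif list over DPRs, build and rank peptides."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    if config.motif_list:
        motifs = read_motif_list(config.motif_list)
    else:
        motifs = read_motif_list(outdir / "motifs_selected.tsv")
    if len(motifs) < 3:
        raise ValueError(f"motif list has {len(motifs)} motifs; need at least 3")
    records, regions = _load_inputs(config)
    dpr_seqs = [r.subsequence for r in regions if r.kind == "DPR"]

    scores = score_all_trios(motifs, dpr_seqs)
    with open(outdir / "trio_scores.tsv", "w", encoding="utf-8") as fh:
        fh.write("motif_a\tmotif_b\tmotif_c\tn_ab\tn_ac\tn_bc\tn_abc\t"
                 "coverage\tsymmetry\tFS\n")
        for s in scores:
            fh.write("\t".join(s.motifs) +
                     f"\t{s.n_ab}\t{s.n_ac}\t{s.n_bc}\t{s.n_abc}"
                     f"\t{s.coverage:.6f}\t{s.symmetry:.6f}\t{s.fs:.2f}\n")

    designs = []
    for s in scores[: config.top_k_trios]:
        for cand in build_peptides(s.motifs):
            cand.fs = s.fs
            designs.append(cand)
    designs = rank_designs(
        filter_candidates(designs, config.filter_ranges, config.kappa_na_policy)
    )
    with open(outdir / "designs.tsv", "w", encoding="utf-8") as fh:
        fh.write("sequence\tlength\ttrio\tordering\tFS\tfcr\tncpr\tkappa\t"
                 "mean_hydropathy\tdisorder_fraction\tpasses_filter\tfailures\n")
        for d in designs:
            p = d.params
            kappa = "NA" if p.kappa is NOT_APPLICABLE else f"{p.kappa:.4f}"
            fh.write(
                f"{d.sequence}\t{len(d.sequence)}\t{'+'.join(d.source_motifs)}\t"
                f"{'+'.join(d.ordering)}\t{d.fs:.2f}\t{p.fcr:.4f}\t{p.ncpr:.4f}\t"
                f"{kappa}\t{p.mean_hydropathy:.4f}\t{p.disorder_fraction:.4f}\t"
                f"{int(d.passes_filter)}\t{','.join(d.filter_failures)}\n"
            )
    _write_manifest(config, outdir, "design")
    log.info("design: %d trios scored, %d peptides written", len(scores), len(designs))
    return outdir
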
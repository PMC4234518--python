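"""End-to-end pipeline: matrix → mine (two-pass) → characterize → classify.

A :class:`RunConfig` is one declarative document holding every stage's
parameters; each run writes its resolved config next to its outputs so any
result can be reproduced byte-identically.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .bmf import MinerConfig, mine, two_pass_mining, write_clusters
from .clusters import cluster_targets, overlap_matrix
from .interactions import (
    Dialect,
    build_matrix,
    filter_by_evidence,
    filter_by_expression,
    read_interactions,
    summarize,
    write_edge_list,
)
from .ontology import elim_enrichment, parse_obo, read_annotations
from .sites import KernelParams, SVMConfig, pairwise_report

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid or inconsistent run configuration (exit code 2)."""


class DataError(ValueError):
    """Missing or malformed input data (exit code 3)."""


@dataclass
class RunConfig:
    interactions: str | None = None
    out_dir: str = "rbpmine_out"
    evidence: list[str] | None = None
    expressed_targets: str | None = None  # path to ID list
    expressed_factors: str | None = None
    k: int = 25
    tau: float = 0.6
    tau_pass2: float = 0.4
    score_mode: str = "unbalanced"
    two_pass: bool = True
    alpha: float = 0.05
    obo: str | None = None
    annotations: str | None = None
    namespace: str = "MF"
    top_clusters: int = 5
    sites_per_rbp: dict = field(default_factory=dict)  # rbp -> FASTA-ish seq list path
    kernel_radius: int = 2
    kernel_distance: int = 4
    kernel_bits: int = 20
    folds: int = 10
    seed: int = 42
    version: str = __version__

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["timestamp"] = time.strftime("%Y-%m-%dT%H:%M:%S")
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        d = json.loads(text)
        d.pop("timestamp", None)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def validate(self) -> None:
        if self.interactions is None:
            raise ConfigError("config must name an interactions file")
        if not Path(self.interactions).exists():
            raise ConfigError(f"interactions file not found: {self.interactions}")
        if (self.obo is None) != (self.annotations is None):
            raise ConfigError("GO analysis needs both --obo and --annotations")
        if self.obo is not None and not Path(self.obo).exists():
            raise ConfigError(f"ontology file not found: {self.obo}")
        if self.annotations is not None and not Path(self.annotations).exists():
            raise ConfigError(f"annotation file not found: {self.annotations}")


def _read_id_list(path) -> set[str]:
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip()}


def run_pipeline(config: RunConfig) -> Path:
    """Execute every configured stage, writing all artifacts to out_dir."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "run_config.json").write_text(config.to_json())

    # stage 1: interaction matrix
    records = read_interactions(config.interactions, Dialect(evidence="evidence"))
    if config.evidence:
        records = filter_by_evidence(records, config.evidence)
    if config.expressed_targets or config.expressed_factors:
        records = filter_by_expression(
            records,
            _read_id_list(config.expressed_targets) if config.expressed_targets else None,
            _read_id_list(config.expressed_factors) if config.expressed_factors else None,
        )
    if not records:
        raise DataError("no interaction records survive the configured filters")
    matrix = build_matrix(records)
    (out / "matrix_summary.json").write_text(summarize(matrix).to_json())
    write_edge_list(matrix, out / "matrix_edges.tsv")

    # stage 2: mining
    cfg1 = MinerConfig(k=config.k, tau=config.tau, score_mode=config.score_mode)
    if config.two_pass:
        pass1, sporadic = two_pass_mining(
            matrix, cfg1, MinerConfig(k=config.k, tau=config.tau_pass2, score_mode=config.score_mode)
        )
        write_clusters(pass1.clusters, out / "clusters_recurrent.tsv")
        write_clusters(sporadic.clusters, out / "clusters_sporadic.tsv")
        results = {"R": pass1, "S": sporadic}
    else:
        pass1 = mine(matrix, cfg1)
        write_clusters(pass1.clusters, out / "clusters.tsv")
        results = {"R": pass1}

    # stage 3: biological characterization
    for tag, res in results.items():
        non_singleton = [c for c in res.clusters if not c.is_singleton]
        tsets = {c.cluster_id: cluster_targets(c, matrix).genes for c in non_singleton}
        if len(tsets) >= 2:
            ov = overlap_matrix(tsets, top_n=config.top_clusters)
            ov.to_csv(out / f"overlap_targets_{tag}.tsv", sep="\t")
        if config.obo is not None:
            dag = parse_obo(config.obo)
            ann = read_annotations(config.annotations)
            background = set(matrix.row_labels) & set(ann)
            for c in non_singleton[: config.top_clusters]:
                study = set(tsets[c.cluster_id]) & background
                if not study:
                    continue
                rows = elim_enrichment(
                    study, background, ann, dag, alpha=config.alpha,
                    namespace=config.namespace,
                )
                with open(out / f"enrichment_{c.cluster_id}.tsv", "w") as fh:
                    fh.write("term_id\tp_value\tstudy_hits\tstudy_size\tbg_hits\tbg_size\tsignificant\n")
                    for r in rows:
                        fh.write(
                            f"{r.term_id}\t{r.p_value:.6g}\t{r.study_hits}\t{r.study_size}"
                            f"\t{r.background_hits}\t{r.background_size}\t{r.significant}\n"
                        )

    # stage 4: binding-site classification (optional)
    if config.sites_per_rbp:
        from .sites import SiteSequence

        rbp_sites = {}
        for rbp, path in config.sites_per_rbp.items():
            seqs = _read_fasta(path)
            rbp_sites[rbp] = [
                SiteSequence(site_id=name, rbp_id=rbp, sequence=seq)
                for name, seq in seqs.items()
            ]
        params = KernelParams(
            max_radius=config.kernel_radius,
            max_distance=config.kernel_distance,
            hash_bits=config.kernel_bits,
        )
        _, half = pairwise_report(
            rbp_sites, params, SVMConfig(folds=config.folds, seed=config.seed)
        )
        half.to_csv(out / "pairwise_auroc_f1.tsv", sep="\t")
    return out


def _read_fasta(path) -> dict[str, str]:
    seqs: dict[str, str] = {}
    name = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                name = line[1:].split()[0]
                seqs[name] = ""
            elif name is not None:
                seqs[name] += line
    if not seqs:
        raise DataError(f"no sequences in {path}")
    return seqs
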
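"""End-to-end pipeline driver.

One configuration object drives the full analysis per group — network
estimation, bootstrap edge accuracy, shortest pathways — plus the
cross-group descriptive comparison, and writes every artifact with a
run manifest sufficient to regenerate the outputs byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .bootstrap import bootstrap_edges
from .datasets import CM_NODES, ED_SPECIFIC_NODES
from .descriptives import DEFAULT_CM_CUTOFFS, group_comparison_table
from .estimation import NetworkConfig, estimate_network
from .io import (
    read_scores,
    write_bootstrap,
    write_comparison,
    write_network,
    write_paths,
)
from .pathways import shortest_pathways

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid pipeline configuration."""


@dataclass
class PipelineConfig:
    """Every tunable of the full analysis in one place.

    Defaults follow the study setup: EBIC gamma = 0.5, B = 2500
    bootstrap replicates, maltreatment nodes as pathway sources and the
    ED-specific symptoms as targets.
    """

    scores_csv: str = "scores.csv"
    group_col: str | None = "group"
    method: str = "pearson"
    gamma: float = 0.5
    n_lambda: int = 100
    min_ratio: float = 0.01
    refit: bool = False
    B: int = 2500
    ci_levels: tuple[float, float] = (0.025, 0.975)
    seed: int = 0
    sources: list[str] = field(default_factory=lambda: list(CM_NODES))
    targets: list[str] = field(default_factory=lambda: list(ED_SPECIFIC_NODES))
    unweighted_paths: bool = False
    fix_lambda: bool = False
    cutoffs: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_CM_CUTOFFS))
    out_dir: str = "symptomnet_out"

    def __post_init__(self) -> None:
        if self.gamma < 0:
            raise ConfigError("gamma must be nonnegative")
        if self.B < 1:
            raise ConfigError("B must be at least 1")
        lo, hi = self.ci_levels
        if not (0 < lo < hi < 1):
            raise ConfigError("ci_levels must satisfy 0 < low < high < 1")
        if set(self.sources) & set(self.targets):
            raise ConfigError("sources and targets must be disjoint")

    def network_config(self) -> NetworkConfig:
        return NetworkConfig(
            method=self.method,
            gamma=self.gamma,
            n_lambda=self.n_lambda,
            min_ratio=self.min_ratio,
            refit=self.refit,
        )

    # -- YAML round-trip ---------------------------------------------------

    def to_yaml(self) -> str:
        d = asdict(self)
        d["ci_levels"] = list(self.ci_levels)
        return yaml.safe_dump(d, sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        d = yaml.safe_load(text) or {}
        if "ci_levels" in d:
            d["ci_levels"] = tuple(d["ci_levels"])
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_yaml(Path(path).read_text())


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis and write all artifacts.

    Per group: network files (adjacency/edge-list/metadata/GraphML),
    bootstrap table CSV, pathway JSON + GraphML.  Across groups (when
    exactly two are present): the descriptive comparison table.  A
    ``manifest.json`` captures config, seed, package version and input
    checksum; re-running from the same manifest reproduces every output
    byte-for-byte (no timestamps enter any artifact).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scores_path = Path(config.scores_csv)
    groups = read_scores(scores_path, group_col=config.group_col)
    net_config = config.network_config()

    artifacts: dict = {"groups": {}}
    outputs: list[str] = []
    for label, data in sorted(groups.items()):
        tag = label if label else "all"
        t0 = time.perf_counter()
        net = estimate_network(data, net_config)
        logger.info(
            "[%s] network: %d edges, lambda=%.4g (%.2fs)",
            tag, net.n_edges, net.lambda_selected, time.perf_counter() - t0,
        )
        files = write_network(net, out / f"net_{tag}_")

        t0 = time.perf_counter()
        boots = bootstrap_edges(
            data,
            net_config,
            B=config.B,
            seed=config.seed,
            ci_levels=config.ci_levels,
            fix_lambda=config.fix_lambda,
            full_network=net,
        )
        logger.info("[%s] bootstrap: B=%d (%.2fs)", tag, config.B, time.perf_counter() - t0)
        boot_path = out / f"boots_{tag}.csv"
        write_bootstrap(boots, boot_path)

        sources = [s for s in config.sources if s in net.node_names]
        targets = [t for t in config.targets if t in net.node_names]
        results, union = shortest_pathways(
            net, sources=sources, targets=targets, unweighted=config.unweighted_paths
        )
        paths_json = out / f"paths_{tag}.json"
        paths_gml = out / f"paths_{tag}.graphml"
        write_paths(results, union, net, paths_json, paths_gml)

        artifacts["groups"][tag] = {
            "network": net,
            "bootstrap": boots,
            "paths": results,
        }
        outputs += [f.name for f in files] + [boot_path.name, paths_json.name, paths_gml.name]

    labels = sorted(groups)
    if len(labels) == 2:
        table = group_comparison_table(
            groups[labels[0]], groups[labels[1]], cutoffs=config.cutoffs
        )
        cmp_path = out / "comparison.csv"
        write_comparison(table, cmp_path)
        artifacts["comparison"] = table
        outputs.append(cmp_path.name)

    manifest = {
        "config": json.loads(json.dumps(asdict(config))),
        "version": __version__,
        "input_sha256": _sha256(scores_path),
        "outputs": sorted(outputs),
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    artifacts["manifest"] = manifest
    return artifacts
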
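"""Reading and writing the pipeline's file formats.

Tables travel as CSV, specifications and pathway reports as JSON, and
networks additionally as GraphML so they can be opened in standard graph
tools.  Score ingestion is strict about schema (the 16 expected subscale
columns, matched by name through an alias map) and complete-case about
missing cells.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .bootstrap import EdgeBootstrapTable
from .datasets import ALL_NODES, SubscaleDataset, default_roles
from .estimation import EDGE_TOL, RegularizedNetwork
from .pathways import PathResult, pathway_report

logger = logging.getLogger(__name__)


class SchemaError(ValueError):
    """Input file does not match the expected score schema."""


#: Common alternative spellings of the subscale names.
DEFAULT_ALIASES: dict[str, str] = {
    "drive_to_thinness": "drive_for_thinness",
    "maturity_fears": "maturity_fear",
    "ascetism": "asceticism",
    "interoceptive_ability": "interoceptive_awareness",
    "en": "emotional_neglect",
    "ea": "emotional_abuse",
    "sa": "sexual_abuse",
    "pn": "physical_neglect",
    "pa": "physical_abuse",
}


def _canonical(name: str, aliases: dict[str, str]) -> str:
    key = name.strip().lower().replace(" ", "_").replace("-", "_")
    return aliases.get(key, key)


def read_scores(
    path: str | Path,
    group_col: str | None = None,
    expected: tuple[str, ...] = ALL_NODES,
    aliases: dict[str, str] | None = None,
) -> dict[str, SubscaleDataset]:
    """Load integer subscale scores from CSV.

    Columns are matched to ``expected`` by canonicalized name
    (order-insensitive; ``aliases`` maps variant spellings).  Rows with
    any missing cell are dropped (complete-case) with the count logged;
    non-numeric cells are an error naming the row and column.

    Returns a dict group label -> dataset; without ``group_col`` the
    single dataset is keyed ``""``.
    """
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"no such file: {path}")
    raw = pd.read_csv(path)
    alias_map = {**DEFAULT_ALIASES, **(aliases or {})}
    rename = {c: _canonical(c, alias_map) for c in raw.columns}
    raw = raw.rename(columns=rename)
    missing = [c for c in expected if c not in raw.columns]
    if missing:
        raise SchemaError(
            f"missing column(s) {missing}; expected variables: {list(expected)}"
        )
    if group_col is not None and group_col not in raw.columns:
        raise SchemaError(f"missing group column {group_col!r}")

    cols = list(expected)
    for c in cols:
        coerced = pd.to_numeric(raw[c], errors="coerce")
        bad = coerced.isna() & raw[c].notna()
        if bad.any():
            row = int(bad.idxmax())
            raise SchemaError(
                f"non-numeric cell at row {row}, column {c!r}: {raw.loc[row, c]!r}"
            )
        raw[c] = coerced

    before = len(raw)
    keep = raw[cols].notna().all(axis=1)
    if group_col is not None:
        keep &= raw[group_col].notna()
    raw = raw[keep]
    dropped = before - len(raw)
    if dropped:
        logger.warning("dropped %d row(s) with missing cells (complete-case)", dropped)

    def build(frame: pd.DataFrame, label: str) -> SubscaleDataset:
        scores = frame[cols].round().astype(np.int64)
        return SubscaleDataset(
            scores=scores.reset_index(drop=True),
            variable_role=default_roles(cols),
            group_label=label,
            provenance=f"file({path.name})",
        )

    if group_col is None:
        return {"": build(raw, "")}
    return {
        str(label): build(sub, str(label))
        for label, sub in raw.groupby(group_col, sort=True)
    }


def write_scores(
    datasets: dict[str, SubscaleDataset] | SubscaleDataset,
    path: str | Path,
    group_col: str = "group",
) -> None:
    """Write one or more groups of scores to a single CSV."""
    if isinstance(datasets, SubscaleDataset):
        datasets = {datasets.group_label: datasets}
    frames = []
    multi = len(datasets) > 1 or any(k for k in datasets)
    for label, ds in sorted(datasets.items()):
        frame = ds.scores.copy()
        if multi:
            frame.insert(0, group_col, label)
        frames.append(frame)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# network artifacts
# ---------------------------------------------------------------------------


def network_to_graph(
    net: RegularizedNetwork, union: nx.Graph | None = None
) -> nx.Graph:
    """Weighted graph of a network; optionally marks shortest-path edges."""
    G = nx.Graph()
    for name in net.node_names:
        G.add_node(name)
    for a, b, w in net.edge_list():
        on_path = bool(union is not None and union.has_edge(a, b))
        G.add_edge(a, b, weight=w, on_shortest_path=on_path)
    return G


def write_network(net: RegularizedNetwork, prefix: str | Path) -> list[Path]:
    """Write adjacency CSV, edge-list CSV, metadata JSON and GraphML."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    adj = pd.DataFrame(net.W, index=net.node_names, columns=net.node_names)
    adj_path = prefix.with_name(prefix.name + "adjacency.csv")
    adj.to_csv(adj_path)
    edges = pd.DataFrame(net.edge_list(), columns=["node_i", "node_j", "weight"])
    edge_path = prefix.with_name(prefix.name + "edges.csv")
    edges.to_csv(edge_path, index=False)
    meta = {
        "group_label": net.group_label,
        "lambda_selected": net.lambda_selected,
        "gamma": net.gamma,
        "n": net.n,
        "n_edges": net.n_edges,
        **{k: v for k, v in net.metadata.items()},
    }
    meta_path = prefix.with_name(prefix.name + "metadata.json")
    meta_path.write_text(json.dumps(meta, indent=2, sort_keys=True, default=str))
    gml_path = prefix.with_name(prefix.name + "network.graphml")
    nx.write_graphml(network_to_graph(net), gml_path)
    return [adj_path, edge_path, meta_path, gml_path]


def read_adjacency(path: str | Path) -> RegularizedNetwork:
    """Rebuild a network object from an adjacency CSV (for the CLI)."""
    adj = pd.read_csv(path, index_col=0)
    names = list(adj.columns)
    W = adj.to_numpy(dtype=float)
    if W.shape[0] != W.shape[1] or list(adj.index) != names:
        raise SchemaError("adjacency CSV must be square with matching row/col names")
    W = (W + W.T) / 2.0
    np.fill_diagonal(W, 0.0)
    return RegularizedNetwork(
        node_names=names,
        W=W,
        lambda_selected=float("nan"),
        gamma=float("nan"),
        n=0,
        metadata={"source": str(path)},
    )


def write_bootstrap(table: EdgeBootstrapTable, path: str | Path) -> None:
    table.table.to_csv(path, index=False)


def write_paths(
    results: list[PathResult],
    union: nx.Graph,
    net: RegularizedNetwork,
    json_path: str | Path,
    graphml_path: str | Path | None = None,
) -> None:
    """Pathway report JSON plus a GraphML with shortest-path membership.

    The GraphML carries the full network with a boolean edge attribute
    ``on_shortest_path`` — the continuous-vs-dotted distinction of
    shortest-pathway figures.
    """
    Path(json_path).write_text(
        json.dumps(pathway_report(results), indent=2, sort_keys=True)
    )
    if graphml_path is not None:
        nx.write_graphml(network_to_graph(net, union=union), graphml_path)


def write_comparison(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False)
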
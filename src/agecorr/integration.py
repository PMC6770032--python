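"""miRNA-mRNA anti-correlation integration network.

Given the tumor-specific candidate miRNAs from the age screen and a database
target table, every (candidate miRNA, annotated target gene) pair is tested
for Spearman anti-correlation across the shared tumor samples.  Pairs with
``rho < 0`` and ``p < alpha`` become edges of a bipartite miRNA -> gene
network whose edge weight is the (negative) correlation; the magnitude
``|rho|`` drives rendered link thickness downstream.  No |rho| magnitude
threshold is applied to edges — the sign and the significance level alone
define membership (a ``rho_max`` knob is available for sensitivity analysis).

Exports are Cytoscape-compatible: SIF plus an edge-attribute table, GraphML
with node ``kind`` and edge ``rho``/``p``/``width`` attributes, and a plain
edge-list TSV as the primary machine-readable output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .correlation import DEFAULT_EDGEWORTH_MAX, DEFAULT_EXACT_MAX, _p_values

__all__ = [
    "IntegrationConfig",
    "IntegrationNetwork",
    "integrate",
    "export_network",
    "read_graphml",
    "SIF_RELATION",
    "EXPORT_FORMATS",
]

SIF_RELATION = "repressed-by-correlation"
EXPORT_FORMATS = ("tsv", "sif", "graphml")

_EDGE_COLUMNS = ["mirna", "gene", "rho", "p", "n", "method", "ties"]


@dataclass(frozen=True)
class IntegrationConfig:
    """Edge-retention settings.

    alpha
        Significance level for the per-pair Spearman test.
    scope
        ``"tumor"`` restricts the correlations to tumor samples (the
        candidate set is tumor-derived); ``"all"`` uses every shared sample.
    rho_max
        Edges require ``rho < rho_max``; the default 0.0 retains any
        significant anti-correlation.  Set e.g. -0.3 for a magnitude-filtered
        sensitivity analysis.
    """

    alpha: float = 0.05
    scope: str = "tumor"
    rho_max: float = 0.0
    n_exact_max: int = DEFAULT_EXACT_MAX
    edgeworth_max: int = DEFAULT_EDGEWORTH_MAX

    def __post_init__(self):
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.scope not in ("tumor", "all"):
            raise ValueError(f"scope must be 'tumor' or 'all', got {self.scope!r}")


@dataclass(frozen=True)
class IntegrationNetwork:
    """Bipartite miRNA -> gene network of retained anti-correlation edges."""

    edges: pd.DataFrame
    candidates_without_targets: frozenset = frozenset()
    n_samples: int = 0

    @property
    def mirna_nodes(self) -> frozenset:
        return frozenset(self.edges["mirna"])

    @property
    def gene_nodes(self) -> frozenset:
        return frozenset(self.edges["gene"])

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def targets_per_mirna(self) -> dict:
        return self.edges.groupby("mirna").size().to_dict()

    def edge_set(self) -> frozenset:
        return frozenset(zip(self.edges["mirna"], self.edges["gene"]))

    def to_graph(self) -> nx.Graph:
        g = nx.Graph()
        for m in sorted(self.mirna_nodes):
            g.add_node(m, kind="mirna")
        for t in sorted(self.gene_nodes):
            g.add_node(t, kind="gene")
        for row in self.edges.itertuples(index=False):
            g.add_edge(
                row.mirna,
                row.gene,
                rho=float(row.rho),
                p=float(row.p),
                width=abs(float(row.rho)),
            )
        return g


def integrate(
    mirna_matrix,
    gene_matrix,
    candidates,
    targets,
    samples,
    config: IntegrationConfig | None = None,
) -> IntegrationNetwork:
    """Test every (candidate miRNA, database target) pair for anti-correlation.

    Samples are aligned between the two matrices by id (never by position);
    the pair correlations run over the shared samples of the configured scope.
    Candidates with no database target are reported, not fatal; a network with
    zero retained edges is valid and triggers a warning only.
    """
    config = config or IntegrationConfig()
    candidates = sorted(candidates)
    missing = [m for m in candidates if m not in mirna_matrix.feature_ids]
    if missing:
        raise ValueError(f"candidate not in miRNA matrix: {missing[0]!r}")

    by_id = {s.sample_id: s for s in samples}
    shared = [
        sid
        for sid in mirna_matrix.sample_ids
        if sid in set(gene_matrix.sample_ids) and sid in by_id
    ]
    if config.scope == "tumor":
        shared = [sid for sid in shared if by_id[sid].tissue == "tumor"]
    if len(shared) < 3:
        raise ValueError(
            f"need >= 3 shared {config.scope} samples between matrices, found {len(shared)}"
        )
    n = len(shared)

    gene_features = set(gene_matrix.feature_ids)
    no_targets = frozenset(
        m for m in candidates if not (targets.genes_for(m) & gene_features)
    )

    rows = []
    for mirna in candidates:
        genes = sorted(targets.genes_for(mirna) & gene_features)
        if not genes:
            continue
        x = mirna_matrix.data.loc[mirna, shared].to_numpy(dtype=float)
        rx = stats.rankdata(x)
        if rx.std() == 0.0:
            warnings.warn(f"candidate {mirna!r} constant across samples; skipped")
            continue
        zx = rx - rx.mean()
        zx_norm = np.sqrt((zx ** 2).sum())
        gvals = gene_matrix.data.loc[genes, shared].to_numpy(dtype=float)
        granks = np.apply_along_axis(stats.rankdata, 1, gvals)
        zg = granks - granks.mean(axis=1, keepdims=True)
        norms = np.sqrt((zg ** 2).sum(axis=1))
        ok = norms > 0.0
        rho = np.full(len(genes), np.nan)
        with np.errstate(invalid="ignore", divide="ignore"):
            rho[ok] = np.clip((zg[ok] @ zx) / (norms[ok] * zx_norm), -1.0, 1.0)
        p = np.full(len(genes), np.nan)
        p[ok], method = _p_values(rho[ok], n, config.n_exact_max, config.edgeworth_max)
        x_ties = len(np.unique(x)) < n
        for j, gene in enumerate(genes):
            if not ok[j]:
                continue
            if rho[j] < config.rho_max and p[j] < config.alpha:
                rows.append(
                    {
                        "mirna": mirna,
                        "gene": gene,
                        "rho": rho[j],
                        "p": p[j],
                        "n": n,
                        "method": method,
                        "ties": bool(x_ties or len(np.unique(gvals[j])) < n),
                    }
                )

    edges = pd.DataFrame(rows, columns=_EDGE_COLUMNS)
    if edges.empty:
        warnings.warn("integration produced an empty network (no retained edges)")
    return IntegrationNetwork(
        edges=edges, candidates_without_targets=no_targets, n_samples=n
    )


def export_network(net: IntegrationNetwork, path, fmt: str) -> list:
    """Write the network in one of EXPORT_FORMATS; returns written paths.

    ``sif`` additionally writes ``<path>.attrs.tsv`` carrying rho and p per
    edge (SIF itself holds only the interaction triples).
    """
    if fmt not in EXPORT_FORMATS:
        raise ValueError(
            f"unknown export format {fmt!r}; supported: {', '.join(EXPORT_FORMATS)}"
        )
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if fmt == "tsv":
        net.edges.to_csv(path, sep="\t", index=False)
        return [path]
    if fmt == "sif":
        with open(path, "w") as fh:
            for row in net.edges.itertuples(index=False):
                fh.write(f"{row.mirna}\t{SIF_RELATION}\t{row.gene}\n")
        attrs = path.with_name(path.name + ".attrs.tsv")
        net.edges[["mirna", "gene", "rho", "p"]].to_csv(attrs, sep="\t", index=False)
        return [path, attrs]
    nx.write_graphml(net.to_graph(), path)
    return [path]


def read_graphml(path) -> IntegrationNetwork:
    """Re-import a GraphML export (round-trip helper)."""
    g = nx.read_graphml(path)
    rows = []
    for u, v, data in g.edges(data=True):
        if g.nodes[u].get("kind") == "mirna":
            mirna, gene = u, v
        else:
            mirna, gene = v, u
        rows.append(
            {
                "mirna": mirna,
                "gene": gene,
                "rho": float(data["rho"]),
                "p": float(data["p"]),
                "n": 0,
                "method": "imported",
                "ties": False,
            }
        )
    return IntegrationNetwork(edges=pd.DataFrame(rows, columns=_EDGE_COLUMNS))
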
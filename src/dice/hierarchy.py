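"""Multi-resolution assembly map: nested Louvain clustering into a containment DAG.

The fused embedding is clustered at several Louvain resolutions (low = coarse,
high = fine). Clusters surviving a minimum-size filter become assembly nodes;
a fine node is attached to the smallest coarser node containing (at least a
threshold fraction of) its members, and a root over all proteins closes the
DAG. Nodes are annotated by hypergeometric enrichment against a gene-set
collection (e.g. cellular-component terms) with Benjamini-Hochberg control of
the FDR across all node x term tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

from .data_io import GeneSetCollection
from .evaluation import knn_similarity_graph, louvain_modules

__all__ = [
    "Hierarchy",
    "NodeAnnotation",
    "build_hierarchy",
    "enrich",
    "annotate_hierarchy",
    "write_hierarchy",
    "DEFAULT_HIERARCHY_RESOLUTIONS",
]

DEFAULT_HIERARCHY_RESOLUTIONS = (0.2, 0.5, 1.0, 2.0, 5.0)
ROOT = "root"


@dataclass
class NodeAnnotation:
    term: str
    overlap: int
    p_value: float
    q_value: float

    @property
    def significant(self) -> bool:
        return self.q_value < 0.05


@dataclass
class Hierarchy:
    """Containment DAG of protein assemblies."""

    nodes: dict[str, frozenset[str]]              # node id -> member set
    edges: list[tuple[str, str]]                  # (parent, child)
    annotations: dict[str, NodeAnnotation] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if ROOT not in self.nodes:
            raise ValueError("hierarchy must contain a root node")
        seen: dict[frozenset, str] = {}
        for nid, members in self.nodes.items():
            if members in seen:
                raise ValueError(f"duplicate member set: {nid} == {seen[members]}")
            seen[members] = nid
            if nid != ROOT and not members < self.nodes[ROOT]:
                raise ValueError(f"node {nid} is not a strict subset of the root")

    def children(self, node_id: str) -> list[str]:
        return [c for p, c in self.edges if p == node_id]

    def assemblies(self, min_size: int = 1) -> list[str]:
        return [n for n, m in self.nodes.items() if n != ROOT and len(m) >= min_size]


def build_hierarchy(
    embedding: np.ndarray,
    ids: list[str],
    resolutions: tuple[float, ...] = DEFAULT_HIERARCHY_RESOLUTIONS,
    k: int = 10,
    containment_threshold: float = 0.75,
    min_size: int = 2,
    seed: int = 0,
) -> Hierarchy:
    """Cluster at every resolution and assemble the containment DAG.

    Resolutions are processed coarse to fine (ascending). Clusters below
    ``min_size`` are discarded and duplicate member sets keep their coarsest
    occurrence. A parent->child edge is added when the overlap covers at least
    ``containment_threshold`` of the child and the parent is the smallest such
    coarser node; orphans attach to the root.
    """
    embedding = np.asarray(embedding, dtype=float)
    if embedding.size == 0:
        raise ValueError("empty embedding")
    if not 0 < containment_threshold <= 1:
        raise ValueError("containment_threshold must lie in (0, 1]")
    all_ids = frozenset(ids)
    nodes: dict[str, frozenset[str]] = {ROOT: all_ids}
    level_of: dict[str, int] = {ROOT: -1}
    seen: set[frozenset] = {all_ids}
    graph = knn_similarity_graph(embedding, ids, k)
    for level, res in enumerate(sorted(resolutions)):
        part = louvain_modules(graph, resolution=res, seed=seed)
        clusters: dict[object, set[str]] = {}
        for pid, lab in part.assignment.items():
            clusters.setdefault(lab, set()).add(pid)
        for lab in sorted(clusters, key=lambda l: (-len(clusters[l]), str(l))):
            members = frozenset(clusters[lab])
            if len(members) < min_size or members in seen:
                continue
            nid = f"r{level}_c{len([n for n in nodes if level_of[n] == level])}"
            nodes[nid] = members
            level_of[nid] = level
            seen.add(members)

    edges: list[tuple[str, str]] = []
    for nid, members in nodes.items():
        if nid == ROOT:
            continue
        best: str | None = None
        for pid, pmembers in nodes.items():
            if pid == ROOT or level_of[pid] >= level_of[nid]:
                continue
            if len(members & pmembers) / len(members) >= containment_threshold:
                if best is None or len(pmembers) < len(nodes[best]) or (
                    len(pmembers) == len(nodes[best]) and pid < best
                ):
                    best = pid
        edges.append((best if best is not None else ROOT, nid))
    return Hierarchy(nodes=nodes, edges=edges)


def _hypergeom_pvalues(
    members: frozenset[str], terms: GeneSetCollection, background: frozenset[str]
) -> dict[str, tuple[int, float]]:
    """Upper-tail hypergeometric p per term: P(overlap >= observed)."""
    if not terms.sets:
        raise ValueError("empty term collection")
    if not members <= background:
        raise ValueError("node members must lie inside the background")
    N = len(background)
    s = len(members)
    out: dict[str, tuple[int, float]] = {}
    for name in sorted(terms.sets):
        tmem = terms.sets[name] & background
        a = len(members & tmem)
        # P(X >= a) with X ~ Hypergeom(N, |term|, |node|); a=0 gives p=1
        p = float(stats.hypergeom.sf(a - 1, N, len(tmem), s))
        out[name] = (a, min(p, 1.0))
    return out


def enrich(
    members: frozenset[str] | set[str],
    terms: GeneSetCollection,
    background: frozenset[str] | set[str],
) -> NodeAnnotation:
    """Best-term enrichment of one node, BH-corrected across this call's terms."""
    members = frozenset(members)
    background = frozenset(background)
    ptable = _hypergeom_pvalues(members, terms, background)
    names = sorted(ptable)
    ps = np.array([ptable[n][1] for n in names])
    qs = stats.false_discovery_control(ps, method="bh")
    best = min(names, key=lambda n: (ptable[n][1], n))
    i = names.index(best)
    return NodeAnnotation(best, ptable[best][0], float(ps[i]), float(qs[i]))


def annotate_hierarchy(
    hierarchy: Hierarchy,
    terms: GeneSetCollection,
    background: frozenset[str] | None = None,
) -> Hierarchy:
    """Annotate every non-root node; BH across all node x term tests jointly.

    Background defaults to the embedded protein set (the root), not the whole
    genome, so enrichment asks whether a term concentrates within an assembly
    relative to the analysed cohort.
    """
    bg = frozenset(background) if background is not None else hierarchy.nodes[ROOT]
    tests: list[tuple[str, str, int, float]] = []
    for nid in sorted(hierarchy.nodes):
        if nid == ROOT:
            continue
        for name, (a, p) in _hypergeom_pvalues(hierarchy.nodes[nid], terms, bg).items():
            tests.append((nid, name, a, p))
    if not tests:
        return hierarchy
    qs = stats.false_discovery_control(np.array([t[3] for t in tests]), method="bh")
    best: dict[str, NodeAnnotation] = {}
    for (nid, name, a, p), q in zip(tests, qs):
        cur = best.get(nid)
        if cur is None or (p, name) < (cur.p_value, cur.term):
            best[nid] = NodeAnnotation(name, a, p, float(q))
    hierarchy.annotations = best
    return hierarchy


def write_hierarchy(hierarchy: Hierarchy, out_dir: str | Path) -> None:
    """Write nodes.tsv (id, size, members, best term, q) and edges.tsv."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    with open(out_dir / "nodes.tsv", "w") as fh:
        fh.write("node\tsize\tmembers\tbest_term\toverlap\tp\tq\n")
        for nid in sorted(hierarchy.nodes):
            members = ";".join(sorted(hierarchy.nodes[nid]))
            ann = hierarchy.annotations.get(nid)
            if ann is None:
                fh.write(f"{nid}\t{len(hierarchy.nodes[nid])}\t{members}\t\t\t\t\n")
            else:
                fh.write(
                    f"{nid}\t{len(hierarchy.nodes[nid])}\t{members}\t"
                    f"{ann.term}\t{ann.overlap}\t{ann.p_value:.6g}\t{ann.q_value:.6g}\n"
                )
    with open(out_dir / "edges.tsv", "w") as fh:
        fh.write("parent\tchild\n")
        for p, c in sorted(hierarchy.edges):
            fh.write(f"{p}\t{c}\n")
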
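"""Over-representation analysis and the shared-gene term graph.

Hit groups from the screen are tested for over-representation of annotation
terms (one-sided hypergeometric / Fisher p per term, Benjamini-Hochberg
correction across terms, enrichment at q < 0.05).  Enriched terms are then
arranged as a graph in which two terms are connected when they share
annotated genes; node size grows with enrichment significance
(-log10 q), edge opacity with the shared-gene count, and nodes are colored
by keyword matches against the term's description or, failing that, its
ancestors' descriptions.

Annotations are used as given — genes are not propagated to ancestor
terms; the (optional, acyclic) parent mapping is consulted only for node
coloring.
"""

from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass
class AnnotationSet:
    """term_id -> (description, gene set), with an optional parent DAG."""

    terms: dict[str, tuple[str, frozenset]]
    parents: dict[str, set] | None = None

    def __post_init__(self) -> None:
        for tid, (_, genes) in self.terms.items():
            if not genes:
                raise ValueError(f"term {tid} has an empty gene set")
        if self.parents:
            self._check_acyclic()

    def _check_acyclic(self) -> None:
        g = nx.DiGraph()
        for child, ps in self.parents.items():
            for p in ps:
                g.add_edge(child, p)
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("parent mapping contains a cycle")

    def description(self, term_id: str) -> str:
        entry = self.terms.get(term_id)
        return entry[0] if entry else ""

    def ancestors_bfs(self, term_id: str) -> list[str]:
        """Ancestor term ids in breadth-first order (nearest first)."""
        if not self.parents:
            return []
        out, seen = [], {term_id}
        queue = deque(sorted(self.parents.get(term_id, ())))
        while queue:
            t = queue.popleft()
            if t in seen:
                continue
            seen.add(t)
            out.append(t)
            queue.extend(sorted(self.parents.get(t, ())))
        return out


def read_annotations(path) -> AnnotationSet:
    """Annotation TSV with columns term_id, description, gene_id (one row per pair)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    terms = {}
    for tid, grp in df.groupby("term_id", sort=True):
        terms[str(tid)] = (str(grp["description"].iloc[0]),
                           frozenset(grp["gene_id"]))
    return AnnotationSet(terms)


def read_parents(path) -> dict[str, set]:
    """Parent TSV with columns term_id, parent_id."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    parents: dict[str, set] = {}
    for t in df.itertuples():
        parents.setdefault(str(t.term_id), set()).add(str(t.parent_id))
    return parents


def read_obo_subset(path) -> tuple[dict[str, str], dict[str, set]]:
    """Minimal OBO reader: [Term] stanzas, id / name / is_a lines only.

    Returns (term_id -> name, term_id -> parent ids).  Obsolete-term
    handling and relationships beyond is_a are out of scope.
    """
    names: dict[str, str] = {}
    parents: dict[str, set] = {}
    current = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line == "[Term]":
                current = None
            elif line.startswith("id:") and current is None:
                current = line[3:].strip()
            elif line.startswith("name:") and current:
                names[current] = line[5:].strip()
            elif line.startswith("is_a:") and current:
                parent = line[5:].strip().split("!")[0].strip()
                parents.setdefault(current, set()).add(parent)
    return names, parents


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    q_(i) = min_{j >= i} p_(j) * m / j over the ascending order statistics,
    clipped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    m = len(p)
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def enrich(
    study_genes: Iterable[str],
    population_genes: Iterable[str],
    annotations: AnnotationSet,
    q_threshold: float = 0.05,
) -> pd.DataFrame:
    """Per-term over-representation of the study set within the population.

    For each term with at least one population gene, p is the upper tail of
    the hypergeometric distribution (probability of drawing at least the
    observed number of term genes in a study-sized sample); q is the BH
    adjustment across all tested terms; a term is enriched iff
    q < q_threshold.
    """
    study = set(study_genes)
    population = set(population_genes)
    if not study:
        raise ValueError("empty study set")
    if not study <= population:
        raise ValueError("study genes must be a subset of the population")

    rows = []
    for tid in sorted(annotations.terms):
        desc, genes = annotations.terms[tid]
        pop_count = len(genes & population)
        if pop_count == 0:
            continue
        study_count = len(genes & study)
        p = float(stats.hypergeom.sf(study_count - 1, len(population),
                                     pop_count, len(study)))
        rows.append((tid, desc, study_count, len(study), pop_count,
                     len(population), p))
    out = pd.DataFrame(rows, columns=[
        "term_id", "description", "study_count", "study_n",
        "pop_count", "pop_n", "p_value",
    ])
    out["q_value"] = bh_adjust(out["p_value"].to_numpy())
    out["enriched"] = out["q_value"] < q_threshold
    return out.sort_values(["p_value", "term_id"], ignore_index=True)


def _node_color(term_id: str, annotations: AnnotationSet,
                color_keywords: Sequence[str]) -> str:
    texts = [annotations.description(term_id)]
    texts += [annotations.description(a) for a in annotations.ancestors_bfs(term_id)]
    for text in texts:
        low = text.lower()
        for kw in color_keywords:
            if kw.lower() in low:
                return kw
    return "other"


def build_term_graph(
    enriched_terms: pd.DataFrame,
    annotations: AnnotationSet,
    color_keywords: Sequence[str] = (),
    size_min: float = 10.0,
    size_scale: float = 5.0,
) -> nx.Graph:
    """Shared-gene graph over enriched terms.

    Nodes carry size = size_min + size_scale * (-log10 q), the q-value, a
    color label (first keyword matching the term's description or, breadth-
    first, an ancestor's description; else "other") and the description.
    Edges connect term pairs sharing at least one annotated gene, with
    shared_genes and opacity = shared/max_shared in (0, 1].
    """
    g = nx.Graph()
    ids = list(enriched_terms["term_id"])
    qs = dict(zip(enriched_terms["term_id"], enriched_terms["q_value"]))
    for tid in ids:
        q = max(float(qs[tid]), 1e-300)
        g.add_node(
            tid,
            size=size_min + size_scale * (-np.log10(q)),
            q_value=float(qs[tid]),
            color=_node_color(tid, annotations, color_keywords),
            description=annotations.description(tid),
        )
    shared: dict[tuple[str, str], int] = {}
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            n = len(annotations.terms[a][1] & annotations.terms[b][1])
            if n >= 1:
                shared[(a, b)] = n
    if shared:
        max_shared = max(shared.values())
        for (a, b), n in shared.items():
            g.add_edge(a, b, shared_genes=n, opacity=n / max_shared)
    return g


def write_term_graph(graph: nx.Graph, graphml_path=None, edges_path=None) -> None:
    """Export the term graph as GraphML and/or a flat edge-list TSV."""
    if graphml_path is not None:
        nx.write_graphml(graph, graphml_path)
    if edges_path is not None:
        rows = [
            (a, b, d["shared_genes"], d["opacity"])
            for a, b, d in sorted(graph.edges(data=True))
        ]
        pd.DataFrame(rows, columns=["term_a", "term_b", "shared_genes", "opacity"]) \
            .to_csv(edges_path, sep="\t", index=False, float_format="%.6g")
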
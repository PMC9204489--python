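"""Mechanism-level outputs: compound subnetworks and overrepresentation.

A mechanism subnetwork shows how one compound's targets touch the disease
module: its nodes are the compound's targets plus every disease protein
directly interacting with at least one target, its edges are the interactome
edges within that node set plus the compound→target links. One-hop bridge
proteins (neither target nor disease protein, but adjacent to both) can be
admitted on request to surface indirect routes.

Overrepresentation analysis (ORA) scores a query protein set against
annotation term sets with one-sided Fisher exact tests and Benjamini-
Hochberg false-discovery-rate correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError
from .proximity import DiseaseProteinSet

__all__ = [
    "MechanismSubnetwork",
    "EnrichmentRow",
    "extract_subnetwork",
    "overrepresentation",
    "benjamini_hochberg",
    "assign_process_group",
    "read_term_sets",
]


@dataclass
class MechanismSubnetwork:
    """Compound → target → disease-protein subnetwork.

    ``edges`` holds (u, v, kind) with kind "ppi" for interactome edges and
    "cti" for compound–target links; ``node_labels`` records, per protein,
    whether it is a target, a disease protein, a bridge, and its process
    group. A node may be a target and a disease protein at once.
    """

    compound_id: str
    target_nodes: set[str]
    disease_nodes: set[str]
    bridge_nodes: set[str] = field(default_factory=set)
    edges: set[tuple] = field(default_factory=set)
    node_labels: dict[str, dict] = field(default_factory=dict)

    @property
    def protein_nodes(self) -> set[str]:
        return self.target_nodes | self.disease_nodes | self.bridge_nodes

    def validate(self, g: nx.Graph) -> None:
        """Check the structural invariants against the source interactome."""
        nodes = self.protein_nodes
        for u, v, kind in self.edges:
            if kind == "ppi":
                if u not in nodes or v not in nodes:
                    raise ValidationError(f"ppi edge ({u}, {v}) leaves the subnetwork")
                if not g.has_edge(u, v):
                    raise ValidationError(f"ppi edge ({u}, {v}) absent from interactome")
            elif kind == "cti":
                if u != self.compound_id or v not in self.target_nodes:
                    raise ValidationError(f"cti edge ({u}, {v}) is not compound→target")
            else:
                raise ValidationError(f"unknown edge kind {kind!r}")

    def node_table(self) -> pd.DataFrame:
        rows = [
            {
                "node": n,
                "is_target": lab.get("is_target", False),
                "is_disease": lab.get("is_disease", False),
                "is_bridge": lab.get("is_bridge", False),
                "process_group": lab.get("process_group", ""),
            }
            for n, lab in sorted(self.node_labels.items())
        ]
        return pd.DataFrame(rows)

    def edge_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            sorted(self.edges), columns=["source", "target", "kind"]
        )

    def write(self, prefix: str | Path, delimiter: str = "\t") -> None:
        """Write node and edge tables (``<prefix>_nodes.tsv``, ``<prefix>_edges.tsv``)."""
        prefix = Path(prefix)
        self.node_table().to_csv(f"{prefix}_nodes.tsv", sep=delimiter, index=False)
        self.edge_table().to_csv(f"{prefix}_edges.tsv", sep=delimiter, index=False)


def extract_subnetwork(
    compound_id: str,
    cti: pd.DataFrame,
    disease: DiseaseProteinSet,
    g: nx.Graph,
    include_bridges: bool = False,
) -> MechanismSubnetwork:
    """Build the mechanism subnetwork for one compound.

    Disease proteins are admitted only when directly adjacent to a target;
    with ``include_bridges`` set, proteins adjacent to both a target and a
    disease protein are added (labelled bridges) together with the disease
    proteins they reach, exposing one-hop indirect routes.
    """
    targets_all = set(cti.loc[cti["compound_id"] == compound_id, "target_id"])
    if not targets_all:
        raise ValidationError(f"unknown compound {compound_id!r}")
    targets = targets_all & set(g.nodes)
    if not targets:
        raise ValidationError(
            f"compound {compound_id!r} has no target in the network"
        )
    S = disease.proteins & set(g.nodes)
    # targets that are themselves disease proteins count on both sides
    disease_nodes = {s for s in S if any(t in g.adj[s] for t in targets)}
    disease_nodes |= targets & S
    bridge_nodes: set[str] = set()
    if include_bridges:
        candidates = {
            b
            for t in targets
            for b in g.adj[t]
            if b not in targets and b not in S
        }
        for b in candidates:
            touched = S & set(g.adj[b])
            if touched:
                bridge_nodes.add(b)
                disease_nodes |= touched

    node_set = targets | disease_nodes | bridge_nodes
    edges: set[tuple] = set()
    for u, v in g.subgraph(node_set).edges():
        a, b = sorted((u, v))
        edges.add((a, b, "ppi"))
    for t in sorted(targets):
        edges.add((compound_id, t, "cti"))

    labels = {
        n: {
            "is_target": n in targets,
            "is_disease": n in S,
            "is_bridge": n in bridge_nodes,
            "process_group": disease.group_of(n) if n in S else "",
        }
        for n in node_set
    }
    sub = MechanismSubnetwork(
        compound_id=compound_id,
        target_nodes=targets,
        disease_nodes=disease_nodes,
        bridge_nodes=bridge_nodes,
        edges=edges,
        node_labels=labels,
    )
    sub.validate(g)
    return sub


@dataclass
class EnrichmentRow:
    """One annotation term's overrepresentation result."""

    term_id: str
    term_name: str
    n_universe: int
    n_term: int
    n_query: int
    n_hit: int
    fold_enrichment: float
    p_fisher: float
    p_adjusted: float


def benjamini_hochberg(p_values: Sequence[float]) -> list[float]:
    """Step-up FDR adjustment; output order matches input order."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    return list(multipletests(p, method="fdr_bh")[1])


def overrepresentation(
    query: Iterable[str],
    term_sets: Mapping[str, Iterable[str]],
    universe: Iterable[str],
    term_names: Mapping[str, str] | None = None,
) -> list[EnrichmentRow]:
    """One-sided Fisher exact enrichment of a query set against term sets.

    Per term: k = |query ∩ term| (membership intersected with the universe),
    the over-representation tail p (equal to the hypergeometric P(X >= k)),
    and the fold enrichment (k/n)/(K/N). BH adjustment runs across all
    tested terms; rows come back sorted by adjusted p, then term id.
    """
    universe = set(universe)
    if not universe:
        raise ValidationError("universe must be non-empty")
    query = set(query)
    stray = query - universe
    if stray:
        raise ValidationError(f"query protein(s) outside universe: {sorted(stray)[:5]}")
    N, n = len(universe), len(query)
    raw: list[tuple[str, int, int, float, float]] = []
    for term_id in sorted(term_sets):
        members = set(term_sets[term_id]) & universe
        K = len(members)
        k = len(query & members)
        table = [[k, n - k], [K - k, N - K - (n - k)]]
        _, p = stats.fisher_exact(table, alternative="greater")
        fold = (k / n) / (K / N) if K > 0 and n > 0 else float("nan")
        raw.append((term_id, K, k, fold, float(p)))
    adjusted = benjamini_hochberg([r[4] for r in raw])
    names = term_names or {}
    rows = [
        EnrichmentRow(
            term_id=term_id,
            term_name=names.get(term_id, term_id),
            n_universe=N,
            n_term=K,
            n_query=n,
            n_hit=k,
            fold_enrichment=fold,
            p_fisher=p,
            p_adjusted=p_adj,
        )
        for (term_id, K, k, fold, p), p_adj in zip(raw, adjusted)
    ]
    rows.sort(key=lambda r: (r.p_adjusted, r.term_id))
    return rows


def assign_process_group(
    protein: str, groups: Mapping[str, Iterable[str]]
) -> str:
    """First matching group in the mapping's order, else "other".

    The mapping order encodes the priority used to resolve proteins belonging
    to several groups (e.g. lipid metabolism before inflammation before
    oxidative stress).
    """
    for label, members in groups.items():
        if protein in set(members):
            return label
    return "other"


def read_term_sets(
    path: str | Path, delimiter: str = "\t"
) -> tuple[dict[str, set[str]], dict[str, str]]:
    """Read annotation term membership from two-column or GMT-style files.

    Two-column: ``term_id<tab>protein_id`` per line. GMT:
    ``term_id<tab>term_name<tab>protein...`` — detected when a line has 3+
    fields and its third field is not a repeated (term, protein) pattern; in
    practice GMT is detected by lines having >2 fields. Returns
    (term -> protein set, term -> name).
    """
    path = Path(path)
    try:
        text = path.read_text()
    except OSError as exc:
        raise ValidationError(f"cannot read term file {path}: {exc}") from exc
    terms: dict[str, set[str]] = {}
    names: dict[str, str] = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = [f.strip() for f in line.split(delimiter) if f.strip()]
        if len(fields) < 2:
            raise ValidationError(f"{path}:{lineno}: term line needs >= 2 fields")
        if len(fields) == 2:
            terms.setdefault(fields[0], set()).add(fields[1])
        else:  # GMT: term, description, members...
            terms.setdefault(fields[0], set()).update(fields[2:])
            names[fields[0]] = fields[1]
    return terms, names
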
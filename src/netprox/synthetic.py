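"""Synthetic study scenarios with known proximity ground truth.

Every pipeline stage can be exercised offline with generated inputs that
mimic the statistical structure of the real ones: a degree-heterogeneous
(preferential-attachment) interactome, a connected planted disease module,
compound cohorts whose targets sit at a controlled distance from the module
(proximal vs distal ground truth), prediction scores that straddle the 0.82
confidence threshold, and annotation term sets with one deliberately
enriched term.

Default parameters describe the reference scenario used throughout the test
suite: a 500-node attachment-3 network, a 30-protein module, 20 proximal
(radius-1) and 20 distal compounds with 10–30 targets each.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
import networkx as nx
import numpy as np
import pandas as pd
import yaml

from .cti import make_table
from .errors import ValidationError
from .interactome import _bfs_from, adjacency_dict
from .proximity import PROCESS_GROUPS, DiseaseProteinSet

__all__ = [
    "ScenarioParams",
    "SyntheticScenario",
    "generate_interactome",
    "plant_disease_module",
    "generate_compound_cohorts",
    "generate_annotations",
    "generate_scenario",
]

# Action-label mix for generated CTI rows, mirroring the heavy dominance of
# inhibitory calls in real compound-target predictions.
_ACTION_PROBS = {"activatory": 0.09, "inhibitory": 0.87, "other": 0.04}


@dataclass(frozen=True)
class ScenarioParams:
    """Full generator parameter record; defaults define the reference scenario."""

    n_nodes: int = 500
    attachment: int = 3
    module_size: int = 30
    n_proximal: int = 20
    n_distal: int = 20
    targets_per_compound: tuple[int, int] = (10, 30)
    proximity_radius: int = 1
    n_terms: int = 20
    term_size_range: tuple[int, int] = (30, 60)
    enrichment_fold: float = 5.0

    def as_dict(self) -> dict:
        return {
            "n_nodes": self.n_nodes,
            "attachment": self.attachment,
            "module_size": self.module_size,
            "n_proximal": self.n_proximal,
            "n_distal": self.n_distal,
            "targets_per_compound": list(self.targets_per_compound),
            "proximity_radius": self.proximity_radius,
            "n_terms": self.n_terms,
            "term_size_range": list(self.term_size_range),
            "enrichment_fold": self.enrichment_fold,
        }


@dataclass
class SyntheticScenario:
    """A complete generated study: network, module, compounds, scores, terms."""

    interactome: nx.Graph
    disease_module: DiseaseProteinSet
    compounds: dict[str, tuple[set[str], str]]  # id -> (targets, cohort)
    scores: dict[tuple[str, str], float]
    annotations: dict[str, set[str]]
    seed: int
    params: ScenarioParams = field(default_factory=ScenarioParams)

    def cti_table(self, rng: np.random.Generator | None = None) -> pd.DataFrame:
        """Scenario CTIs as a predicted-source table carrying the scores."""
        rng = rng if rng is not None else np.random.default_rng(self.seed + 1)
        actions = list(_ACTION_PROBS)
        probs = list(_ACTION_PROBS.values())
        rows = []
        for compound in sorted(self.compounds):
            targets, _ = self.compounds[compound]
            for t in sorted(targets):
                action = actions[rng.choice(len(actions), p=probs)]
                rows.append((compound, t, action, "predicted", self.scores[(compound, t)]))
        return make_table(rows)

    def cohort_of(self, compound: str) -> str:
        return self.compounds[compound][1]

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write the scenario in the same dialects the pipeline reads.

        Emits edge list, CTI table, disease-protein list, annotation file,
        and a parameter manifest; returns the path of each artifact.
        """
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "interactome": outdir / "interactome_edges.tsv",
            "cti": outdir / "cti_table.tsv",
            "disease": outdir / "disease_proteins.tsv",
            "annotations": outdir / "annotations.tsv",
            "manifest": outdir / "scenario_params.yaml",
        }
        with open(paths["interactome"], "w") as fh:
            fh.write("# synthetic interactome edge list\n")
            for u, v in sorted(tuple(sorted(e)) for e in self.interactome.edges()):
                fh.write(f"{u}\t{v}\n")
        self.cti_table().to_csv(paths["cti"], sep="\t", index=False)
        with open(paths["disease"], "w") as fh:
            fh.write("protein_id\tprocess_group\n")
            for p in sorted(self.disease_module.proteins):
                fh.write(f"{p}\t{self.disease_module.group_of(p)}\n")
        with open(paths["annotations"], "w") as fh:
            for term in sorted(self.annotations):
                for p in sorted(self.annotations[term]):
                    fh.write(f"{term}\t{p}\n")
        manifest = {"seed": self.seed, "params": self.params.as_dict()}
        paths["manifest"].write_text(yaml.safe_dump(manifest, sort_keys=True))
        return paths


def _node_name(i: int) -> str:
    return f"P{i:04d}"


def generate_interactome(
    n_nodes: int, attachment: int, seed: int | np.random.Generator
) -> nx.Graph:
    """Connected preferential-attachment network with heavy-tailed degrees.

    Nodes join one at a time, each wiring to ``attachment`` existing nodes
    chosen proportional to current degree (the growth process starts from a
    star over the first ``attachment + 1`` nodes), giving exactly
    ``attachment * (n_nodes - attachment)`` edges and guaranteed
    connectivity. ``attachment=1`` yields a tree.
    """
    if n_nodes < attachment + 1:
        raise ValidationError(
            f"need n_nodes >= attachment + 1, got {n_nodes} and {attachment}"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    g = nx.barabasi_albert_graph(n_nodes, attachment, seed=rng)
    return nx.relabel_nodes(g, {i: _node_name(i) for i in g.nodes()})


def plant_disease_module(
    g: nx.Graph, size: int, seed: int | np.random.Generator
) -> DiseaseProteinSet:
    """Connected disease module grown breadth-first from a random seed node.

    Frontier ties are broken by the random stream; process-group labels are
    assigned uniformly at random among the four standard labels.
    """
    if size > g.number_of_nodes():
        raise ValidationError(
            f"module size {size} exceeds node count {g.number_of_nodes()}"
        )
    if size < 1:
        raise ValidationError("module size must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    nodes = sorted(g.nodes)
    start = nodes[rng.integers(len(nodes))]
    chosen = [start]
    chosen_set = {start}
    frontier = sorted(g.adj[start])
    while len(chosen) < size and frontier:
        frontier = [v for v in frontier if v not in chosen_set]
        if not frontier:
            break
        pick = frontier.pop(rng.integers(len(frontier)))
        chosen.append(pick)
        chosen_set.add(pick)
        frontier.extend(v for v in sorted(g.adj[pick]) if v not in chosen_set)
    if len(chosen) < size:  # disconnected remainder cannot happen on PA graphs
        raise ValidationError("could not grow a connected module of the requested size")
    groups = {
        p: PROCESS_GROUPS[rng.integers(len(PROCESS_GROUPS))] for p in sorted(chosen_set)
    }
    return DiseaseProteinSet(proteins=chosen_set, process_group=groups)


def generate_compound_cohorts(
    g: nx.Graph,
    module: DiseaseProteinSet,
    n_proximal: int,
    n_distal: int,
    targets_per_compound: tuple[int, int],
    proximity_radius: int,
    seed: int | np.random.Generator,
) -> tuple[dict[str, tuple[set[str], str]], dict[tuple[str, str], float]]:
    """Compound cohorts with planted proximity ground truth plus scores.

    Proximal compounds draw targets from nodes within ``proximity_radius``
    hops of the module (radius 0 restricts targets to the module itself, so
    their closest distance is exactly 0); distal compounds draw from nodes
    strictly farther away — if that pool is smaller than the largest target
    set, it falls back to the complement of the module and its neighbours.
    Prediction scores straddle the 0.82 confidence threshold by design:
    proximal pairs ~ U(0.82, 1.0), distal pairs ~ U(0.5, 0.95).
    """
    if n_proximal < 0 or n_distal < 0:
        raise ValidationError("cohort sizes must be >= 0")
    if proximity_radius < 0:
        raise ValidationError("proximity_radius must be >= 0")
    lo, hi = targets_per_compound
    if not 1 <= lo <= hi:
        raise ValidationError("targets_per_compound must satisfy 1 <= lo <= hi")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    dist = _bfs_from(adjacency_dict(g), module.proteins)
    near = sorted(v for v, d in dist.items() if d <= proximity_radius)
    far = sorted(v for v, d in dist.items() if d > proximity_radius)
    if len(far) < hi:
        neighbours = {w for p in module.proteins for w in g.adj[p]}
        far = sorted(set(g.nodes) - module.proteins - neighbours)
    if n_proximal and len(near) < hi:
        raise ValidationError(
            "proximal pool too small; increase radius or shrink target sets"
        )
    if n_distal and len(far) < hi:
        raise ValidationError(
            "distal pool too small; shrink target sets or the module"
        )

    compounds: dict[str, tuple[set[str], str]] = {}
    scores: dict[tuple[str, str], float] = {}
    specs = [("proximal", i, near, (0.82, 1.0)) for i in range(n_proximal)]
    specs += [("distal", i, far, (0.5, 0.95)) for i in range(n_distal)]
    for cohort, i, pool, (s_lo, s_hi) in specs:
        name = f"{cohort}_{i:02d}"
        size = int(rng.integers(lo, hi + 1))
        idx = rng.choice(len(pool), size=size, replace=False)
        targets = {pool[j] for j in idx}
        compounds[name] = (targets, cohort)
        for t in sorted(targets):
            scores[(name, t)] = float(rng.uniform(s_lo, s_hi))
    return compounds, scores


def generate_annotations(
    g: nx.Graph,
    module: DiseaseProteinSet,
    n_terms: int,
    term_size_range: tuple[int, int],
    enrich_first_term_in: set[str],
    seed: int | np.random.Generator,
    enrichment_fold: float = 5.0,
) -> dict[str, set[str]]:
    """Random annotation term sets with one deliberately enriched term.

    Members of the first term are drawn from the given protein set at
    ``enrichment_fold`` times the baseline rate: under a uniform random term
    the expected fraction of members inside the set is |set|/N, so the
    planted term draws each member from the set with probability
    min(1, fold * |set| / N) (a binomial count, then uniform picks inside
    and outside the set). The remaining terms are uniform random subsets of
    the network's nodes. With the enrichment set equal to the whole universe
    the first term degenerates to an ordinary random subset — no signal.
    """
    lo, hi = term_size_range
    universe = sorted(g.nodes)
    if not 1 <= lo <= hi <= len(universe):
        raise ValidationError("infeasible term size range")
    if n_terms < 1:
        raise ValidationError("n_terms must be >= 1")
    enrich = sorted(set(enrich_first_term_in))
    if not set(enrich) <= set(universe):
        raise ValidationError("enrichment set must be drawn from the network")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    outside = sorted(set(universe) - set(enrich))
    rate = min(1.0, enrichment_fold * len(enrich) / len(universe))
    terms: dict[str, set[str]] = {}
    for i in range(n_terms):
        size = int(rng.integers(lo, hi + 1))
        if i == 0:
            n_in = int(rng.binomial(size, rate))
            n_in = min(n_in, len(enrich), size)
            n_in = max(n_in, size - len(outside))
            idx_in = (
                rng.choice(len(enrich), size=n_in, replace=False) if n_in else []
            )
            idx_out = (
                rng.choice(len(outside), size=size - n_in, replace=False)
                if size - n_in else []
            )
            term = {enrich[j] for j in idx_in} | {outside[j] for j in idx_out}
        else:
            idx = rng.choice(len(universe), size=size, replace=False)
            term = {universe[j] for j in idx}
        terms[f"TERM{i:03d}"] = term
    return terms


def generate_scenario(
    params: ScenarioParams | None = None, seed: int = 0, **overrides
) -> SyntheticScenario:
    """Generate a full scenario; same (params, seed) reproduces it exactly.

    Keyword overrides patch individual :class:`ScenarioParams` fields. Each
    generation stage consumes its own child stream spawned from ``seed``, so
    the stages stay independent and reproducible.
    """
    if params is None:
        params = ScenarioParams(**overrides)
    elif overrides:
        params = replace(params, **overrides)
    streams = np.random.SeedSequence(seed).spawn(4)
    g = generate_interactome(
        params.n_nodes, params.attachment, np.random.default_rng(streams[0])
    )
    module = plant_disease_module(
        g, params.module_size, np.random.default_rng(streams[1])
    )
    compounds, scores = generate_compound_cohorts(
        g,
        module,
        params.n_proximal,
        params.n_distal,
        params.targets_per_compound,
        params.proximity_radius,
        np.random.default_rng(streams[2]),
    )
    annotations = generate_annotations(
        g,
        module,
        params.n_terms,
        params.term_size_range,
        module.proteins,
        np.random.default_rng(streams[3]),
        enrichment_fold=params.enrichment_fold,
    )
    return SyntheticScenario(
        interactome=g,
        disease_module=module,
        compounds=compounds,
        scores=scores,
        annotations=annotations,
        seed=seed,
        params=params,
    )
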
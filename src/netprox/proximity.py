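"""Network proximity: closest distance, degree-matched null, z-score, screen.

The closest measure between a disease-protein set S and a compound's target
set T on the interactome is

    d_c(S, T) = (1 / |T|) * sum over t in T of  min over s in S of  d(s, t)

with d(s, t) the unweighted shortest-path length. A target that is itself a
disease protein contributes 0. The raw distance is standardized against a
reference distribution obtained by repeatedly redrawing both sets at random
while matching their sizes and degree profiles (degree-binned sampling, so
the null respects hub bias):

    Z_dc = (d_c - mu) / sigma

with mu and sigma the mean and standard deviation of the null ensemble.
More negative Z_dc means the compound's targets sit closer to the disease
module than size- and degree-matched chance.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .errors import AnalysisError, ValidationError
from .interactome import DegreeBins, _bfs_from, adjacency_dict, build_degree_bins

logger = logging.getLogger(__name__)

DEFAULT_N_ITERATIONS = 1000
DEFAULT_MIN_BIN_SIZE = 100
SIGMA_TOLERANCE = 1e-12

PROCESS_GROUPS = ("lipid metabolism", "inflammation", "oxidative stress", "other")

__all__ = [
    "DEFAULT_N_ITERATIONS",
    "DEFAULT_MIN_BIN_SIZE",
    "SIGMA_TOLERANCE",
    "PROCESS_GROUPS",
    "DiseaseProteinSet",
    "ProximityResult",
    "closest_distance",
    "degree_matched_sample",
    "reference_distribution",
    "proximity_zscore",
    "screen_compounds",
    "results_to_frame",
]


@dataclass
class DiseaseProteinSet:
    """The disease-associated protein set S, optionally labelled by process.

    ``process_group`` maps a protein to one of ``PROCESS_GROUPS`` (e.g. lipid
    metabolism / inflammation / oxidative stress / other for a fatty-liver
    module); proteins absent from the mapping default to "other".
    """

    proteins: set[str]
    process_group: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.proteins = set(self.proteins)
        bad = set(self.process_group.values()) - set(PROCESS_GROUPS)
        if bad:
            raise ValidationError(f"unknown process group label(s): {sorted(bad)}")

    def group_of(self, protein: str) -> str:
        return self.process_group.get(protein, "other")


@dataclass
class ProximityResult:
    """Proximity of one compound's target set to the disease proteins."""

    compound_id: str
    d_c: float
    mu: float
    sigma: float
    z: float | None
    n_targets_used: int
    n_targets_dropped: int
    n_direct_interactions: int
    n_iterations: int
    seed: int


def _restrict(members: Iterable[str], nodes: set, label: str) -> tuple[set, int]:
    members = set(members)
    kept = members & nodes
    dropped = len(members) - len(kept)
    if dropped:
        logger.info("%s: dropped %d protein(s) outside the network", label, dropped)
    if not kept:
        raise AnalysisError(f"{label} is empty after restriction to the network")
    return kept, dropped


def closest_distance(
    S: Iterable[str],
    T: Iterable[str],
    g: nx.Graph,
    _adj: Mapping | None = None,
) -> float:
    """Average over targets of the hop distance to the nearest disease protein.

    Proteins outside the graph are dropped (and counted via logging); an
    empty set after restriction raises :class:`AnalysisError`. Targets with
    no path to any member of S are ignored with a warning — restricting the
    graph to its largest connected component beforehand avoids this.
    """
    nodes = set(g.nodes)
    S_used, _ = _restrict(S, nodes, "disease set S")
    T_used, _ = _restrict(T, nodes, "target set T")
    adj = _adj if _adj is not None else adjacency_dict(g)
    dist = _bfs_from(adj, S_used)
    reached = [dist[t] for t in T_used if t in dist]
    if not reached:
        raise AnalysisError("no target is reachable from the disease set")
    if len(reached) < len(T_used):
        logger.warning(
            "%d target(s) unreachable from S ignored", len(T_used) - len(reached)
        )
    return float(sum(reached)) / len(reached)


def degree_matched_sample(
    reference_set: Iterable[str],
    bins: DegreeBins,
    degree_of: Mapping[str, int],
    rng: np.random.Generator,
) -> set[str]:
    """Random protein set matching the reference in size and degree profile.

    For each reference protein one protein is drawn uniformly from that
    protein's degree bin, without replacement across the whole sample. An
    exhausted bin is temporarily widened to its neighbouring bins (logged).
    Reference proteins themselves are legitimate draws.
    """
    reference = sorted(set(reference_set))
    n_bins = len(bins.intervals)
    total = sum(len(m) for m in bins.members)
    if len(reference) > total:
        raise ValidationError(
            f"cannot sample {len(reference)} proteins from a {total}-node graph"
        )
    chosen: set[str] = set()
    for protein in reference:
        if protein not in degree_of:
            raise ValidationError(f"reference protein {protein!r} not in the graph")
        idx = bins.bin_index(degree_of[protein])
        pick = None
        # Try the home bin first with rejection sampling (the used set is
        # small relative to a bin), then fall back to an explicit candidate
        # list, then widen outward bin by bin.
        members = bins.members[idx]
        for _ in range(20):
            cand = members[rng.integers(len(members))]
            if cand not in chosen:
                pick = cand
                break
        if pick is None:
            for radius in range(n_bins):
                lo, hi = max(0, idx - radius), min(n_bins - 1, idx + radius)
                pool = [
                    m
                    for j in range(lo, hi + 1)
                    for m in bins.members[j]
                    if m not in chosen
                ]
                if pool:
                    if radius > 0:
                        logger.info(
                            "degree bin %d exhausted; widened by %d bin(s)", idx, radius
                        )
                    pick = pool[rng.integers(len(pool))]
                    break
        if pick is None:
            raise AnalysisError("sampling exhausted every degree bin")
        chosen.add(pick)
    return chosen


def reference_distribution(
    S: Iterable[str],
    T: Iterable[str],
    g: nx.Graph,
    bins: DegreeBins,
    n_iterations: int,
    rng: np.random.Generator,
    _adj: Mapping | None = None,
    _degree_of: Mapping[str, int] | None = None,
) -> tuple[float, float, list[float]]:
    """Null ensemble of closest distances for size/degree-matched random sets.

    Each iteration independently redraws S* and T* with
    :func:`degree_matched_sample` and records d_c(S*, T*). Returns the sample
    mean, the population (denominator-n) standard deviation, and the full
    sample list for diagnostics. The population convention is used because
    the drawn ensemble *is* the null population being described, not a sample
    from a larger one.
    """
    if n_iterations < 2:
        raise ValidationError("n_iterations must be >= 2")
    adj = _adj if _adj is not None else adjacency_dict(g)
    degree_of = _degree_of if _degree_of is not None else dict(g.degree())
    S = set(S)
    T = set(T)
    samples: list[float] = []
    for _ in range(n_iterations):
        S_star = degree_matched_sample(S, bins, degree_of, rng)
        T_star = degree_matched_sample(T, bins, degree_of, rng)
        dist = _bfs_from(adj, S_star)
        reached = [dist[t] for t in T_star if t in dist]
        if not reached:
            continue
        samples.append(float(sum(reached)) / len(reached))
    if len(samples) < 2:
        raise AnalysisError("null ensemble degenerate: fewer than 2 usable draws")
    arr = np.asarray(samples)
    return float(arr.mean()), float(arr.std(ddof=0)), samples


def proximity_zscore(d_c: float, mu: float, sigma: float) -> float | None:
    """Standardized proximity (d_c - mu) / sigma, or None when sigma ~ 0.

    A null ensemble that admits only a single distance value carries no
    scale; the z-score is then undefined and reported as None rather than
    +/-infinity so sorting and serialization stay well-defined.
    """
    if sigma < 0:
        raise ValidationError("sigma must be non-negative")
    if sigma <= SIGMA_TOLERANCE:
        return None
    return (d_c - mu) / sigma


def screen_compounds(
    cti: pd.DataFrame,
    disease: DiseaseProteinSet,
    g: nx.Graph,
    n_iterations: int = DEFAULT_N_ITERATIONS,
    min_bin_size: int = DEFAULT_MIN_BIN_SIZE,
    seed: int = 0,
    bins: DegreeBins | None = None,
) -> list[ProximityResult]:
    """Rank every compound in the CTI table by proximity to the disease set.

    Per compound: targets outside the network are dropped (counted in the
    result); d_c, the degree-matched null (mu, sigma), Z_dc, and the direct-
    interaction count |T ∩ S| are computed. The returned list is ordered by z
    ascending (most negative = most proximal), ties by d_c then compound id;
    compounds with an undefined z come last, ordered by d_c. Compounds whose
    whole target set falls outside the network are skipped with a warning.

    Each compound consumes an independent child stream spawned from ``seed``,
    so results are reproducible compound-by-compound regardless of screen
    order.
    """
    if len(cti) == 0:
        raise ValidationError("CTI table is empty")
    nodes = set(g.nodes)
    S_used, s_dropped = _restrict(disease.proteins, nodes, "disease set S")
    if s_dropped:
        logger.warning("disease set: %d protein(s) outside the network", s_dropped)
    if bins is None:
        bins = build_degree_bins(g, min_bin_size=min_bin_size)
    adj = adjacency_dict(g)
    degree_of = dict(g.degree())

    targets_by_compound: dict[str, set] = {}
    for r in cti.itertuples(index=False):
        targets_by_compound.setdefault(r.compound_id, set()).add(r.target_id)

    compounds = sorted(targets_by_compound)
    streams = np.random.SeedSequence(seed).spawn(len(compounds))
    results: list[ProximityResult] = []
    for compound, ss in zip(compounds, streams):
        raw_targets = targets_by_compound[compound]
        T_used = raw_targets & nodes
        n_dropped = len(raw_targets) - len(T_used)
        if not T_used:
            logger.warning("compound %s has no target in the network; skipped", compound)
            continue
        rng = np.random.default_rng(ss)
        d_c = closest_distance(S_used, T_used, g, _adj=adj)
        mu, sigma, _ = reference_distribution(
            S_used, T_used, g, bins, n_iterations, rng,
            _adj=adj, _degree_of=degree_of,
        )
        z = proximity_zscore(d_c, mu, sigma)
        results.append(
            ProximityResult(
                compound_id=compound,
                d_c=d_c,
                mu=mu,
                sigma=sigma,
                z=z,
                n_targets_used=len(T_used),
                n_targets_dropped=n_dropped,
                n_direct_interactions=len(T_used & S_used),
                n_iterations=n_iterations,
                seed=seed,
            )
        )
    results.sort(
        key=lambda r: (
            (0, r.z, r.d_c, r.compound_id)
            if r.z is not None
            else (1, math.inf, r.d_c, r.compound_id)
        )
    )
    return results


def results_to_frame(results: Sequence[ProximityResult]) -> pd.DataFrame:
    """Ranked screen output as a DataFrame (None z serialized as NaN)."""
    return pd.DataFrame(
        [
            {
                "compound_id": r.compound_id,
                "n_targets_used": r.n_targets_used,
                "n_targets_dropped": r.n_targets_dropped,
                "d_c": r.d_c,
                "mu": r.mu,
                "sigma": r.sigma,
                "z": np.nan if r.z is None else r.z,
                "n_direct_interactions": r.n_direct_interactions,
                "seed": r.seed,
                "n_iterations": r.n_iterations,
            }
            for r in results
        ]
    )
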
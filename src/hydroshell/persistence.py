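"""Cross-condition water persistence analysis.

Water oxygens from structures solved under several conditions (pH values)
are superposed into a common frame and clustered by single-linkage
agglomeration at a distance cutoff (default 1.0 Å, strict ``<``). A cluster
seen in one condition is a *lone* site, in ≥2 conditions *persistent*, and in
all conditions *most persistent*. Sites are annotated with the nearest
protein residue (3.6 Å cutoff) and the categories are compared through their
nearest water–water distance distributions with exact two-sample
Kolmogorov–Smirnov statistics.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .core import AMINO_ACIDS, ModelError, StructureModel

CATEGORY_LONE = "lone"
CATEGORY_PERSISTENT = "persistent"
CATEGORY_MOST_PERSISTENT = "most_persistent"


class EnsembleError(ModelError):
    """The model ensemble is not ready for cross-condition analysis."""


@dataclass
class WaterObservation:
    """One modeled water oxygen in the common (superposed) frame."""
    position: np.ndarray
    condition_label: str
    source_residue_id: int
    occupancy: float = 1.0


@dataclass
class NearestResidue:
    residue_name: str
    residue_id: int
    chain: str
    distance: float


@dataclass
class WaterSiteCluster:
    """A cross-condition water site: the clustered observations, their
    unweighted centroid, and the persistence category derived from the number
    of distinct conditions represented."""
    members: list[WaterObservation]
    centroid: np.ndarray
    n_conditions: int
    category: str
    nearest_residue: NearestResidue | None = None

    def __len__(self) -> int:
        return len(self.members)


def categorize(n_conditions: int, n_total: int) -> str:
    if n_conditions <= 0:
        raise ValueError("a cluster must span at least one condition")
    if n_conditions == 1:
        return CATEGORY_LONE
    if n_conditions == n_total:
        return CATEGORY_MOST_PERSISTENT
    return CATEGORY_PERSISTENT


def single_linkage_labels(positions: np.ndarray, cutoff: float) -> np.ndarray:
    """Connected components of the graph linking points at distance < cutoff
    (strict: a pair exactly at the cutoff does not link)."""
    n = len(positions)
    if n == 0:
        return np.empty(0, dtype=int)
    tree = cKDTree(positions)
    pairs = tree.query_pairs(r=cutoff, output_type="ndarray")
    if len(pairs):
        d = np.linalg.norm(positions[pairs[:, 0]] - positions[pairs[:, 1]], axis=1)
        pairs = pairs[d < cutoff]
    if len(pairs):
        graph = sparse.coo_matrix(
            (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n))
    else:
        graph = sparse.coo_matrix((n, n))
    _, labels = connected_components(graph, directed=False)
    return labels


def collect_water_observations(models: Sequence[StructureModel]) -> list[WaterObservation]:
    obs = []
    for m in models:
        for w in m.water_oxygens():
            obs.append(WaterObservation(position=w.position.copy(),
                                        condition_label=m.condition_label,
                                        source_residue_id=w.residue_id,
                                        occupancy=w.occupancy))
    return obs


def cluster_waters(models: Sequence[StructureModel], cutoff: float = 1.0,
                   require_superposed: bool = True) -> list[WaterSiteCluster]:
    """Cluster water oxygens across superposed models.

    Single-linkage agglomeration at strict ``distance < cutoff``; every water
    oxygen ends up in exactly one cluster. A cluster may contain two waters
    of the same condition when they are bridged by linkage; ``n_conditions``
    counts distinct condition labels. Output is sorted by descending
    ``n_conditions``, then lexicographically by centroid, so results are
    deterministic and independent of input model order.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    labels_set = [m.condition_label for m in models]
    if len(set(labels_set)) != len(labels_set):
        raise EnsembleError("condition labels must be unique within the ensemble")
    if require_superposed:
        bad = [m.condition_label for m in models if not m.superposed]
        if bad:
            raise EnsembleError(
                f"models not superposed to a common frame: {bad}; superpose "
                "first or pass require_superposed=False for data generated "
                "in a shared frame")
    obs = collect_water_observations(models)
    n_total = len(models)
    if not obs:
        return []
    positions = np.array([o.position for o in obs])
    labels = single_linkage_labels(positions, cutoff)
    clusters: list[WaterSiteCluster] = []
    for lab in np.unique(labels):
        members = [obs[i] for i in np.flatnonzero(labels == lab)]
        centroid = np.mean([m.position for m in members], axis=0)
        nc = len({m.condition_label for m in members})
        clusters.append(WaterSiteCluster(
            members=members, centroid=centroid, n_conditions=nc,
            category=categorize(nc, n_total)))
    clusters.sort(key=lambda c: (-c.n_conditions, tuple(np.round(c.centroid, 6))))
    return clusters


@dataclass
class PersistenceSummary:
    """Per-condition water counts by persistence class and the global
    histogram of clusters by the number of conditions they span."""
    histogram: dict[int, int]
    per_condition: dict[str, dict[str, int]]
    n_conditions_total: int


def classify_persistence(clusters: Sequence[WaterSiteCluster],
                         condition_labels: Sequence[str]) -> PersistenceSummary:
    """Count clusters by span and waters by persistence class per condition."""
    n_total = len(condition_labels)
    if n_total < 1:
        raise ValueError("need at least one condition")
    known = set(condition_labels)
    histogram = {k: 0 for k in range(1, n_total + 1)}
    per_condition = {lab: {CATEGORY_LONE: 0, CATEGORY_PERSISTENT: 0,
                           CATEGORY_MOST_PERSISTENT: 0} for lab in condition_labels}
    for c in clusters:
        for m in c.members:
            if m.condition_label not in known:
                raise EnsembleError(
                    f"cluster references unknown condition {m.condition_label!r}")
        histogram[c.n_conditions] += 1
        for m in c.members:
            per_condition[m.condition_label][c.category] += 1
    return PersistenceSummary(histogram=histogram, per_condition=per_condition,
                              n_conditions_total=n_total)


def assign_nearest_residue(cluster: WaterSiteCluster, model: StructureModel,
                           cutoff: float = 3.6) -> NearestResidue | None:
    """Nearest protein heavy atom's residue, if within the cutoff of the
    cluster centroid; ``None`` (unassigned) otherwise."""
    atoms = model.protein_atoms(heavy_only=True)
    if not atoms:
        return None
    coords = np.array([a.position for a in atoms])
    d = np.linalg.norm(coords - cluster.centroid, axis=1)
    i = int(np.argmin(d))
    if d[i] > cutoff:
        return None
    a = atoms[i]
    return NearestResidue(residue_name=a.residue_name, residue_id=a.residue_id,
                          chain=a.chain_id, distance=float(d[i]))


def assign_nearest_residues(clusters: Iterable[WaterSiteCluster],
                            model: StructureModel, cutoff: float = 3.6) -> None:
    """Annotate clusters in place against a reference model."""
    atoms = model.protein_atoms(heavy_only=True)
    if not atoms:
        return
    coords = np.array([a.position for a in atoms])
    tree = cKDTree(coords)
    for c in clusters:
        d, i = tree.query(c.centroid)
        if d <= cutoff:
            a = atoms[int(i)]
            c.nearest_residue = NearestResidue(a.residue_name, a.residue_id,
                                               a.chain_id, float(d))
        else:
            c.nearest_residue = None


UNASSIGNED = "unassigned"


def residue_preferences(clusters: Iterable[WaterSiteCluster]) -> dict[str, int]:
    """Histogram of nearest-residue amino-acid types over a set of clusters
    (typically the most-persistent subset); totals conserve cluster count."""
    hist = {aa: 0 for aa in sorted(AMINO_ACIDS)}
    hist[UNASSIGNED] = 0
    for c in clusters:
        nr = c.nearest_residue
        if nr is None or nr.residue_name not in AMINO_ACIDS:
            hist[UNASSIGNED] += 1
        else:
            hist[nr.residue_name] += 1
    return hist


# ---------------------------------------------------------------------------
# Water–water distance distributions and KS statistics
# ---------------------------------------------------------------------------

@dataclass
class DistanceDistribution:
    """Nearest water–water distances pooled for one persistence category."""
    category: str
    values: np.ndarray
    degenerate: bool = False

    @property
    def summary(self) -> dict:
        if len(self.values) == 0:
            return {"count": 0, "median": float("nan"),
                    "q1": float("nan"), "q3": float("nan")}
        q1, med, q3 = np.percentile(self.values, [25, 50, 75])
        return {"count": int(len(self.values)), "median": float(med),
                "q1": float(q1), "q3": float(q3)}


def ks_statistic(sample1: Sequence[float], sample2: Sequence[float]) -> float:
    """Exact two-sample Kolmogorov–Smirnov statistic: the supremum of
    |ECDF₁ − ECDF₂| evaluated on the pooled sorted values."""
    x = np.sort(np.asarray(sample1, float))
    y = np.sort(np.asarray(sample2, float))
    if len(x) == 0 or len(y) == 0:
        raise ValueError("KS statistic requires non-empty samples")
    pooled = np.concatenate([x, y])
    cdf1 = np.searchsorted(x, pooled, side="right") / len(x)
    cdf2 = np.searchsorted(y, pooled, side="right") / len(y)
    return float(np.max(np.abs(cdf1 - cdf2)))


def nearest_water_distances(clusters: Sequence[WaterSiteCluster],
                            models: Sequence[StructureModel]
                            ) -> tuple[dict[str, DistanceDistribution], dict[tuple[str, str], float]]:
    """Nearest water–water distances pooled by persistence category.

    For each condition, every realized water oxygen gets the distance to its
    nearest other water in the same condition; distances are then pooled by
    the persistence category of the cluster the water belongs to. Returns the
    three distributions plus the pairwise exact KS statistics between
    categories (categories with <2 values are flagged degenerate and skipped
    in the KS matrix).
    """
    # map each observation (by identity) to its cluster category
    category_of: dict[int, str] = {}
    for c in clusters:
        for m in c.members:
            category_of[id(m)] = c.category
    # group observations by condition, preserving cluster membership identity
    by_condition: dict[str, list[WaterObservation]] = {}
    for c in clusters:
        for m in c.members:
            by_condition.setdefault(m.condition_label, []).append(m)

    pooled: dict[str, list[float]] = {CATEGORY_LONE: [], CATEGORY_PERSISTENT: [],
                                      CATEGORY_MOST_PERSISTENT: []}
    for label, obs in by_condition.items():
        if len(obs) < 2:
            continue
        pos = np.array([o.position for o in obs])
        tree = cKDTree(pos)
        d, _ = tree.query(pos, k=2)
        nearest = d[:, 1]
        for o, dist in zip(obs, nearest):
            pooled[category_of[id(o)]].append(float(dist))

    distributions = {}
    for cat, vals in pooled.items():
        arr = np.array(sorted(vals))
        distributions[cat] = DistanceDistribution(
            category=cat, values=arr, degenerate=len(arr) < 2)
    ks: dict[tuple[str, str], float] = {}
    cats = [CATEGORY_LONE, CATEGORY_PERSISTENT, CATEGORY_MOST_PERSISTENT]
    for i, a in enumerate(cats):
        for b in cats[i + 1:]:
            if not distributions[a].degenerate and not distributions[b].degenerate:
                ks[(a, b)] = ks_statistic(distributions[a].values,
                                          distributions[b].values)
    return distributions, ks
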
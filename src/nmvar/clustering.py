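"""Structural hotspot clustering, delta-G cross-correlation and Ward trees.

Variants are first grouped into possibly-overlapping structural clusters
("hotspots"): a cluster is any maximal greedily-grown set whose mean
member distance to the cluster's center of mass stays below a threshold
(default 15 Angstrom).  Within each hotspot, per-subunit entropy-difference
profiles are compared by Pearson cross-correlation, converted to the
distance d = sqrt(2 (1 - r)) and clustered with the Ward algorithm.  A
Spearman concordance score between cophenetic distances and phenotype
severity differences quantifies how well the tree orders variants along
the clinical continuum.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import squareform
from scipy.stats import spearmanr

from .catalog import VariantRecord
from .enm import DeltaGProfile
from .structure import CoarseStructure, StructureError

__all__ = [
    "ClusterError",
    "StructuralCluster",
    "CorrelationMatrix",
    "CorrelationDendrogram",
    "ConcordanceReport",
    "variant_positions",
    "structural_clusters",
    "position_distance_matrix",
    "pairwise_profile_correlation",
    "correlation_to_distance",
    "ward_dendrogram",
    "cut_dendrogram",
    "cophenetic_matrix",
    "concordance_score",
    "permutation_null_scores",
    "transition_report",
    "export_matrix_tsv",
]

DEFAULT_CLUSTER_THRESHOLD = 15.0


class ClusterError(ValueError):
    """Raised for invalid clustering inputs."""


def _canonical(variants) -> list[VariantRecord]:
    return sorted(variants, key=lambda v: (v.position, v.protein_change))


def variant_positions(
    structure: CoarseStructure,
    variants: Sequence[VariantRecord],
    position_map: Mapping[int, int] | None = None,
) -> dict[VariantRecord, np.ndarray]:
    """C-alpha coordinate of each variant's mutated residue on the
    mutable chain.  Variants at the same position share coordinates."""
    chain = structure.mutable_chain
    if chain is None:
        raise ClusterError("structure has no mutable chain; call assign_subunits")
    out: dict[VariantRecord, np.ndarray] = {}
    for v in variants:
        pos = v.position
        if position_map is not None:
            if pos not in position_map:
                raise ClusterError(
                    f"variant {v.protein_change} cannot be mapped onto chain {chain}"
                )
            pos = position_map[pos]
        try:
            idx = structure.node_index(chain, pos)
        except StructureError as exc:
            raise ClusterError(f"variant {v.protein_change}: {exc}") from exc
        out[v] = np.asarray(structure.nodes[idx].coords, dtype=float)
    return out


@dataclass(frozen=True)
class StructuralCluster:
    """A hotspot: variants whose mean distance to the common center of
    mass is below the threshold.  Clusters may share members."""

    label: str
    member_variants: tuple[VariantRecord, ...]
    center_of_mass: tuple[float, float, float]
    mean_member_distance: float

    @property
    def member_names(self) -> tuple[str, ...]:
        return tuple(v.protein_change for v in self.member_variants)


def _mean_dist_to_com(coords: np.ndarray) -> tuple[np.ndarray, float]:
    com = coords.mean(axis=0)
    return com, float(np.linalg.norm(coords - com, axis=1).mean())


def structural_clusters(
    positions: Mapping[VariantRecord, np.ndarray],
    threshold: float = DEFAULT_CLUSTER_THRESHOLD,
) -> list[StructuralCluster]:
    """Greedy seeded hotspot search.

    Every variant seeds a cluster; the nearest remaining variant (to the
    current center of mass) is added while the mean member-to-center
    distance stays below the threshold.  Maximal member sets are
    deduplicated, sorted by their smallest member residue number, and
    labeled a, b, c, ...  Order-independent: candidates are scanned in a
    canonical (position, name) order with distance ties broken the same
    way.
    """
    if not positions:
        raise ClusterError("no variant positions given")
    if threshold <= 0:
        raise ClusterError("threshold must be positive")
    order = _canonical(positions)
    seen: dict[frozenset, tuple[list[VariantRecord], np.ndarray, float]] = {}
    for seed in order:
        members = [seed]
        coords = [np.asarray(positions[seed], dtype=float)]
        remaining = [v for v in order if v is not seed]
        com, mean_d = _mean_dist_to_com(np.asarray(coords))
        while remaining:
            dists = [float(np.linalg.norm(positions[v] - com)) for v in remaining]
            best = int(np.argmin(dists))  # ties -> earliest canonical index
            cand = remaining[best]
            trial = np.vstack([coords, positions[cand]])
            trial_com, trial_mean = _mean_dist_to_com(trial)
            if trial_mean >= threshold:
                break
            members.append(cand)
            coords.append(np.asarray(positions[cand], dtype=float))
            com, mean_d = trial_com, trial_mean
            remaining.pop(best)
        key = frozenset(v.protein_change for v in members)
        if key not in seen:
            seen[key] = (_canonical(members), com, mean_d)
    # drop member sets strictly contained in another cluster (maximality)
    keys = list(seen)
    maximal = [
        k for k in keys
        if not any(k < other for other in keys)
    ]
    ordered = sorted(
        maximal, key=lambda k: min(v.position for v in seen[k][0])
    )
    clusters = []
    for i, k in enumerate(ordered):
        members, com, mean_d = seen[k]
        label = chr(ord("a") + i) if i < 26 else f"z{i}"
        clusters.append(StructuralCluster(
            label=label,
            member_variants=tuple(members),
            center_of_mass=tuple(float(x) for x in com),
            mean_member_distance=mean_d,
        ))
    return clusters


def position_distance_matrix(
    positions: Mapping[VariantRecord, np.ndarray],
    severity: Mapping[str, int] | None = None,
) -> tuple[list[VariantRecord], np.ndarray]:
    """Pairwise Euclidean distances, ordered phenotype-group-then-position
    (heatmap-ready ordering)."""
    if severity is None:
        variants = _canonical(positions)
    else:
        variants = sorted(
            positions,
            key=lambda v: (severity.get(v.phenotype_group, -1), v.position,
                           v.protein_change),
        )
    X = np.asarray([positions[v] for v in variants], dtype=float)
    diff = X[:, None, :] - X[None, :, :]
    return variants, np.sqrt((diff ** 2).sum(axis=-1))


@dataclass(frozen=True)
class CorrelationMatrix:
    """Symmetric Pearson cross-correlation of delta-G profiles."""

    variants: tuple[VariantRecord, ...]
    subunit: str
    values: np.ndarray

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(v.protein_change for v in self.variants)


def pairwise_profile_correlation(
    profiles: Sequence[DeltaGProfile],
    subunit: str = "combined",
    constant_policy: str = "error",
) -> CorrelationMatrix:
    """Pearson correlation between every pair of variant delta-G vectors
    on one subunit (or the concatenation over all subunits, "combined").

    A constant (zero-variance) vector leaves Pearson r undefined; the
    default policy raises, naming the variant.  ``constant_policy="zero"``
    instead reports r = 0 against everything (and 1 on the diagonal),
    which is the honest "no information" value for null synthetic panels.
    """
    if constant_policy not in ("error", "zero"):
        raise ClusterError(f"unknown constant_policy {constant_policy!r}")
    variants = []
    vectors = []
    for p in profiles:
        if p.variant is None:
            raise ClusterError("profile without variant metadata")
        variants.append(p.variant)
        vec = p.combined() if subunit == "combined" else np.asarray(
            p.per_subunit[subunit], dtype=float
        )
        vectors.append(vec)
    sizes = {v.size for v in vectors}
    if len(sizes) != 1:
        raise ClusterError("profiles do not share the subunit's node set")
    X = np.asarray(vectors, dtype=float)
    sd = X.std(axis=1)
    constant = sd == 0
    if constant.any() and constant_policy == "error":
        bad = [variants[i].protein_change for i in np.flatnonzero(constant)]
        raise ClusterError(
            f"constant delta-G vector(s) for {bad}: correlation undefined"
        )
    n = len(variants)
    R = np.eye(n)
    ok = ~constant
    if ok.sum() >= 2:
        sub = np.corrcoef(X[ok])
        R[np.ix_(ok, ok)] = sub
    np.fill_diagonal(R, 1.0)
    R = np.clip((R + R.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(R, 1.0)
    return CorrelationMatrix(variants=tuple(variants), subunit=subunit, values=R)


def correlation_to_distance(r: np.ndarray) -> np.ndarray:
    """d = sqrt(2 (1 - r)): identical profiles merge at 0, perfectly
    anticorrelated ones sit at the maximal distance 2."""
    d = np.sqrt(np.clip(2.0 * (1.0 - np.asarray(r, dtype=float)), 0.0, None))
    np.fill_diagonal(d, 0.0)
    return d


@dataclass(frozen=True)
class CorrelationDendrogram:
    """Ward tree over correlation distances of one structural cluster."""

    cluster_label: str
    subunit: str
    linkage: np.ndarray
    leaf_order: tuple[VariantRecord, ...]
    variants: tuple[VariantRecord, ...]
    newick: str


def _linkage_to_newick(Z: np.ndarray, names: Sequence[str]) -> str:
    n = len(names)

    def height(i: int) -> float:
        return 0.0 if i < n else float(Z[i - n, 2])

    def render(i: int, parent_h: float) -> str:
        if i < n:
            return f"{names[i]}:{parent_h:.6g}"
        left, right, h = int(Z[i - n, 0]), int(Z[i - n, 1]), height(i)
        return (f"({render(left, h - height(left))},"
                f"{render(right, h - height(right))}):{parent_h - h:.6g}")

    root = n + Z.shape[0] - 1
    return render(root, height(root)).rsplit(":", 1)[0] + ";"


def ward_dendrogram(
    corr: CorrelationMatrix,
    cluster_label: str = "",
) -> CorrelationDendrogram:
    """Agglomerative Ward linkage (Lance–Williams update) on the
    correlation distance d = sqrt(2 (1 - r)).  Deterministic: input order
    is the canonical variant order and ties resolve to the lowest pair."""
    n = len(corr.variants)
    if n < 2:
        raise ClusterError("need at least 2 variants for a dendrogram")
    D = correlation_to_distance(corr.values)
    Z = sch.linkage(squareform(D, checks=False), method="ward")
    leaves = sch.leaves_list(Z)
    names = corr.names
    return CorrelationDendrogram(
        cluster_label=cluster_label,
        subunit=corr.subunit,
        linkage=Z,
        leaf_order=tuple(corr.variants[i] for i in leaves),
        variants=corr.variants,
        newick=_linkage_to_newick(Z, names),
    )


def cut_dendrogram(dendro: CorrelationDendrogram, k: int) -> dict[VariantRecord, int]:
    """Flat partition into k groups (maxclust cut)."""
    labels = sch.fcluster(dendro.linkage, t=k, criterion="maxclust")
    return {v: int(c) for v, c in zip(dendro.variants, labels)}


def cophenetic_matrix(dendro: CorrelationDendrogram) -> np.ndarray:
    return squareform(sch.cophenet(dendro.linkage))


def concordance_score(
    dendro: CorrelationDendrogram,
    groups: Mapping[str, float],
) -> float:
    """Spearman rank correlation between cophenetic distance and absolute
    severity difference over all variant pairs.

    1 means the tree orders variants exactly along the severity scale
    (nearby in the tree <-> similar phenotype); 0 means no relation.
    ``groups`` maps protein_change -> ordinal severity.
    """
    names = dendro.variants
    if len(names) < 3:
        raise ClusterError("need >= 3 variants for a concordance score")
    sev = np.asarray([groups[v.protein_change] for v in names], dtype=float)
    if np.unique(sev).size < 2:
        raise ClusterError("all variants share one severity group: not scored")
    C = cophenetic_matrix(dendro)
    iu = np.triu_indices(len(names), k=1)
    rho = spearmanr(C[iu], np.abs(sev[:, None] - sev[None, :])[iu]).statistic
    return float(rho)


def permutation_null_scores(
    dendro: CorrelationDendrogram,
    groups: Mapping[str, float],
    n_permutations: int = 1000,
    seed: int = 0,
) -> np.ndarray:
    """Concordance scores under random severity-label permutation."""
    rng = np.random.default_rng(seed)
    names = [v.protein_change for v in dendro.variants]
    sev = np.asarray([groups[n] for n in names], dtype=float)
    C = cophenetic_matrix(dendro)
    iu = np.triu_indices(len(names), k=1)
    coph = C[iu]
    out = np.empty(n_permutations)
    for b in range(n_permutations):
        p = rng.permutation(sev)
        out[b] = spearmanr(coph, np.abs(p[:, None] - p[None, :])[iu]).statistic
    return out


@dataclass(frozen=True)
class ConcordanceReport:
    """Per-cluster best subunit + score, and overlap transition flags."""

    per_cluster: Mapping[str, tuple[str, float]]
    transitions: tuple[tuple[str, str, tuple[str, ...]], ...]
    interrupted_transitions: tuple[tuple[str, str], ...]

    def to_dict(self) -> dict:
        return {
            "per_cluster": {
                c: {"best_subunit": s, "concordance": score}
                for c, (s, score) in self.per_cluster.items()
            },
            "transitions": [
                {"clusters": [a, b], "shared_variants": list(shared)}
                for a, b, shared in self.transitions
            ],
            "interrupted_transitions": [list(t) for t in self.interrupted_transitions],
        }


def transition_report(
    clusters: Sequence[StructuralCluster],
    panel_distance: tuple[Sequence[VariantRecord], np.ndarray] | None = None,
    quantile: float = 0.25,
) -> tuple[tuple[tuple[str, str, tuple[str, ...]], ...], tuple[tuple[str, str], ...]]:
    """Cluster pairs sharing variants, plus "interrupted" transitions.

    A transition is interrupted when two variants in the shared overlap
    have a small delta-G distance (below the given quantile of all
    pairwise panel distances) yet belong to different phenotype groups —
    entropically similar but clinically distinct.
    """
    transitions = []
    interrupted = []
    thr = None
    dist_of: dict[frozenset, float] = {}
    if panel_distance is not None:
        variants, D = panel_distance
        iu = np.triu_indices(len(variants), k=1)
        offdiag = np.asarray(D)[iu]
        if offdiag.size:
            thr = float(np.quantile(offdiag, quantile))
        for i, u in enumerate(variants):
            for j, v in enumerate(variants):
                if i < j:
                    dist_of[frozenset((u.protein_change, v.protein_change))] = float(D[i, j])
    for a_i in range(len(clusters)):
        for b_i in range(a_i + 1, len(clusters)):
            ca, cb = clusters[a_i], clusters[b_i]
            shared = sorted(set(ca.member_names) & set(cb.member_names))
            if not shared:
                continue
            transitions.append((ca.label, cb.label, tuple(shared)))
            if thr is None:
                continue
            group_of = {
                v.protein_change: v.phenotype_group
                for v in ca.member_variants + cb.member_variants
            }
            broken = False
            for i, u in enumerate(shared):
                for v in shared[i + 1:]:
                    d = dist_of.get(frozenset((u, v)))
                    if d is not None and d < thr and group_of[u] != group_of[v]:
                        broken = True
            if broken:
                interrupted.append((ca.label, cb.label))
    return tuple(transitions), tuple(interrupted)


def export_matrix_tsv(
    names: Sequence[str],
    values: np.ndarray,
    path: str | Path,
) -> None:
    """Square matrix with a variant-id header row and column."""
    values = np.asarray(values)
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("variant\t" + "\t".join(names) + "\n")
        for name, row in zip(names, values):
            fh.write(name + "\t" + "\t".join(f"{x:.10g}" for x in row) + "\n")
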
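"""Sequence-aware coarse-grained elastic network model and entropy profiles.

The network places springs between coarse nodes: stiff springs along the
backbone (sequential residues of a chain) and softer distance-cutoff
springs between all other node pairs.  Nonbonded stiffness is modulated by
a symmetric residue-type pair weight table, so a point mutation changes
the vibrational spectrum *without moving any atom* — the property that
makes entropy differences between wild-type and mutant informative.

The default weight table is a contact-propensity surrogate built from
Kyte–Doolittle hydrophobicity (hydrophobic pairs interact more strongly),
exponentiated and normalized to mean 1.  It is injectable: any symmetric
positive table (e.g. one derived from Miyazawa–Jernigan contact energies)
can be passed in through :class:`EnmParams`.

The per-node "entropic profile" is the harmonic mean-square-fluctuation
surrogate sum(|v_m,i|^2 / lambda_m) over non-rigid modes — the diagonal of
the Hessian pseudo-inverse aggregated per node.  The scalar counterpart
-sum(ln lambda_m) is exported alongside.  Units are arbitrary; only
differences (variant minus wild type) and their correlations are used
downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import scipy.linalg
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree
from Bio.SeqUtils.ProtParamData import kd as _KD_HYDROPHOBICITY

from .catalog import VariantRecord
from .structure import LIGAND_TYPE, CoarseStructure, StructureError, aa1_to_3

__all__ = [
    "EnmError",
    "WeightTable",
    "default_weight_table",
    "uniform_weight_table",
    "EnmParams",
    "ElasticNetwork",
    "ModeSpectrum",
    "EntropyProfile",
    "DeltaGProfile",
    "build_network",
    "hessian",
    "normal_modes",
    "entropy_profile",
    "delta_g",
    "variant_delta_g",
    "export_delta_g_tsv",
]


class EnmError(ValueError):
    """Raised for invalid elastic networks or mode computations."""


class WeightTable:
    """Symmetric residue-type pair weights for nonbonded springs.

    Stored as a mapping over unordered type pairs with a default for
    unlisted pairs.  All weights must be positive.
    """

    def __init__(self, pairs: Mapping[tuple[str, str], float] | None = None,
                 default: float = 1.0) -> None:
        if default <= 0:
            raise EnmError("default weight must be positive")
        self.default = float(default)
        self._pairs: dict[tuple[str, str], float] = {}
        for (a, b), w in (pairs or {}).items():
            if w <= 0:
                raise EnmError(f"non-positive weight for pair ({a}, {b})")
            self._pairs[self._key(a, b)] = float(w)

    @staticmethod
    def _key(a: str, b: str) -> tuple[str, str]:
        a, b = a.upper(), b.upper()
        return (a, b) if a <= b else (b, a)

    def get(self, a: str, b: str) -> float:
        return self._pairs.get(self._key(a, b), self.default)

    def scaled_row(self, residue_type: str, factor: float,
                   partner_types: Iterable[str]) -> "WeightTable":
        """New table with every pair involving ``residue_type`` multiplied
        by ``factor`` — used by the synthetic panel generator."""
        if factor <= 0:
            raise EnmError("scale factor must be positive")
        pairs = dict(self._pairs)
        for other in partner_types:
            k = self._key(residue_type, other)
            pairs[k] = pairs.get(k, self.default) * factor
        return WeightTable(pairs, default=self.default)

    def to_dict(self) -> dict:
        return {
            "default": self.default,
            "pairs": {f"{a}|{b}": w for (a, b), w in sorted(self._pairs.items())},
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "WeightTable":
        pairs = {}
        for key, w in (d.get("pairs") or {}).items():
            a, b = key.split("|")
            pairs[(a, b)] = float(w)
        return cls(pairs, default=float(d.get("default", 1.0)))


_AA1 = "ACDEFGHIKLMNPQRSTVWY"


def default_weight_table(beta: float = 0.15) -> WeightTable:
    """Contact-propensity weight table from Kyte–Doolittle hydrophobicity.

    w(a, b) = exp(beta * (h_a + h_b) / 2), normalized to mean 1 over the
    20x20 table.  With the default beta the weights span roughly 0.5-2,
    i.e. hydrophobic-core contacts are up to ~4x stiffer than contacts
    between the most polar residues — the qualitative shape of knowledge-
    based contact potentials.
    """
    raw: dict[tuple[str, str], float] = {}
    for a in _AA1:
        for b in _AA1:
            key = tuple(sorted((aa1_to_3(a), aa1_to_3(b))))
            h = 0.5 * (_KD_HYDROPHOBICITY[a] + _KD_HYDROPHOBICITY[b])
            raw[key] = float(np.exp(beta * h))
    mean = float(np.mean([
        raw[tuple(sorted((aa1_to_3(a), aa1_to_3(b))))]
        for a in _AA1 for b in _AA1
    ]))
    return WeightTable({k: v / mean for k, v in raw.items()}, default=1.0)


def uniform_weight_table() -> WeightTable:
    """All pair weights 1: a sequence-blind anisotropic network."""
    return WeightTable({}, default=1.0)


@dataclass(frozen=True)
class EnmParams:
    """Elastic-network parameters.

    cutoff_radius : nonbonded interaction cutoff, Angstrom.
    epsilon_nonbonded : base nonbonded stiffness scale.
    k_backbone : stiffness of sequential-neighbor springs (default 100x
        epsilon, keeping the chain much stiffer than packing contacts).
    weight_table : symmetric residue-type pair weights (None -> default
        hydrophobicity-derived table).
    ligand_weight : weight for any pair involving a ligand node.
    zero_mode_tol : relative eigenvalue threshold below which a mode
        counts as rigid-body.
    """

    cutoff_radius: float = 12.0
    epsilon_nonbonded: float = 1.0
    k_backbone: float = 100.0
    weight_table: WeightTable | None = None
    ligand_weight: float = 1.0
    zero_mode_tol: float = 1e-8
    dense_warn_nodes: int = 3000

    def __post_init__(self) -> None:
        if self.cutoff_radius <= 0:
            raise EnmError("cutoff_radius must be positive")
        if self.epsilon_nonbonded <= 0 or self.ligand_weight <= 0:
            raise EnmError("stiffness scales must be positive")
        if self.k_backbone < self.epsilon_nonbonded:
            raise EnmError("k_backbone must be >= epsilon_nonbonded")

    @property
    def weights(self) -> WeightTable:
        return self.weight_table if self.weight_table is not None else _DEFAULT_TABLE

    def pair_weight(self, type_a: str, type_b: str) -> float:
        if type_a == LIGAND_TYPE or type_b == LIGAND_TYPE:
            return self.ligand_weight
        return self.weights.get(type_a, type_b)

    def to_dict(self) -> dict:
        d = {
            "cutoff_radius": self.cutoff_radius,
            "epsilon_nonbonded": self.epsilon_nonbonded,
            "k_backbone": self.k_backbone,
            "ligand_weight": self.ligand_weight,
            "zero_mode_tol": self.zero_mode_tol,
        }
        if self.weight_table is not None:
            d["weight_table"] = self.weight_table.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "EnmParams":
        d = dict(d)
        wt = d.pop("weight_table", None)
        if wt is not None:
            d["weight_table"] = WeightTable.from_dict(wt)
        return cls(**d)


_DEFAULT_TABLE = default_weight_table()


@dataclass(frozen=True)
class ElasticNetwork:
    """Springs (i, j, rest_length, stiffness) over a coarse structure."""

    structure: CoarseStructure
    springs: tuple[tuple[int, int, float, float], ...]
    n_components: int

    @property
    def n_nodes(self) -> int:
        return self.structure.n_nodes

    @property
    def connected(self) -> bool:
        return self.n_components == 1


def _component_labels(n_nodes: int, springs) -> tuple[int, np.ndarray]:
    if not springs:
        return n_nodes, np.arange(n_nodes)
    ii = [s[0] for s in springs]
    jj = [s[1] for s in springs]
    adj = coo_matrix((np.ones(len(springs)), (ii, jj)), shape=(n_nodes, n_nodes))
    return connected_components(adj, directed=False)


def build_network(
    structure: CoarseStructure,
    params: EnmParams | None = None,
    on_disconnected: str = "error",
) -> ElasticNetwork:
    """Assemble backbone and distance-cutoff nonbonded springs.

    ``on_disconnected`` controls what happens when the spring graph splits
    into more than one component: ``"error"`` (default) rejects it,
    ``"largest"`` restricts the network to the largest component, and
    ``"keep"`` returns the network with ``connected == False``.
    """
    params = params or EnmParams()
    if structure.n_nodes < 2:
        raise EnmError("need at least 2 nodes to build a network")
    if on_disconnected not in ("error", "largest", "keep"):
        raise EnmError(f"unknown on_disconnected policy {on_disconnected!r}")
    coords = structure.coords
    nodes = structure.nodes
    backbone: set[tuple[int, int]] = set()
    springs: list[tuple[int, int, float, float]] = []
    # backbone springs: sequential residues (author numbering) of a chain
    by_chain: dict[str, list[int]] = {}
    for i, nd in enumerate(nodes):
        if not nd.is_ligand:
            by_chain.setdefault(nd.chain_id, []).append(i)
    for idxs in by_chain.values():
        for a, b in zip(idxs, idxs[1:]):
            if nodes[b].residue_index - nodes[a].residue_index == 1:
                backbone.add((a, b))
    # nonbonded springs within the cutoff
    tree = cKDTree(coords)
    pairs = sorted(tree.query_pairs(params.cutoff_radius))
    for i, j in pairs:
        if (i, j) in backbone:
            continue
        r = float(np.linalg.norm(coords[j] - coords[i]))
        w = params.pair_weight(nodes[i].residue_type, nodes[j].residue_type)
        springs.append((i, j, r, params.epsilon_nonbonded * w))
    for i, j in sorted(backbone):
        r = float(np.linalg.norm(coords[j] - coords[i]))
        springs.append((i, j, r, params.k_backbone))
    springs.sort()
    n_comp, labels = _component_labels(structure.n_nodes, springs)
    if n_comp > 1:
        if on_disconnected == "error":
            sizes = np.bincount(labels)
            raise EnmError(
                f"elastic network is disconnected ({n_comp} components, "
                f"sizes {sorted(sizes, reverse=True)}); pass "
                f"on_disconnected='largest' to analyze the main component"
            )
        if on_disconnected == "largest":
            keep = labels == np.bincount(labels).argmax()
            old_to_new = -np.ones(structure.n_nodes, dtype=int)
            old_to_new[keep] = np.arange(int(keep.sum()))
            sub_nodes = tuple(nd for k, nd in zip(keep, nodes) if k)
            sub = CoarseStructure(nodes=sub_nodes,
                                  mutable_chain=structure.mutable_chain)
            sub_springs = tuple(
                (int(old_to_new[i]), int(old_to_new[j]), r, k)
                for i, j, r, k in springs if keep[i] and keep[j]
            )
            return ElasticNetwork(structure=sub, springs=sub_springs,
                                  n_components=1)
    return ElasticNetwork(structure=structure, springs=tuple(springs),
                          n_components=int(n_comp))


def hessian(network: ElasticNetwork) -> np.ndarray:
    """Dense 3N x 3N second-derivative matrix of the harmonic energy.

    Each spring contributes -k (r_hat r_hat^T) off-diagonal blocks; the
    diagonal blocks enforce zero row-block sums, making the matrix
    symmetric positive semidefinite with rigid-body null modes.
    """
    coords = network.structure.coords
    n = network.n_nodes
    H = np.zeros((3 * n, 3 * n))
    for i, j, _rest, k in network.springs:
        d = coords[j] - coords[i]
        r = np.linalg.norm(d)
        if r < 1e-6:
            raise EnmError(
                f"spring between coincident nodes {i} and {j} "
                f"(distance {r:.2e} A): direction undefined"
            )
        rhat = d / r
        block = k * np.outer(rhat, rhat)
        sl_i, sl_j = slice(3 * i, 3 * i + 3), slice(3 * j, 3 * j + 3)
        H[sl_i, sl_j] -= block
        H[sl_j, sl_i] -= block
        H[sl_i, sl_i] += block
        H[sl_j, sl_j] += block
    return H


@dataclass(frozen=True)
class ModeSpectrum:
    """Eigen-decomposition of the (unit-mass) Hessian.

    ``eigenvalues`` ascend; the first ``n_rigid`` are rigid-body (zero)
    modes excluded from entropy sums.  ``eigenvectors[:, m]`` is mode m.
    """

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    n_rigid: int

    @property
    def n_modes(self) -> int:
        return self.eigenvalues.size


def normal_modes(H: np.ndarray, params: EnmParams | None = None) -> ModeSpectrum:
    """Full dense symmetric eigendecomposition with unit masses.

    Modes with eigenvalue below ``zero_mode_tol * max(eigenvalue)`` are
    counted as rigid.  A connected non-collinear network has exactly 6.
    """
    params = params or EnmParams()
    H = np.asarray(H, dtype=float)
    if H.ndim != 2 or H.shape[0] != H.shape[1]:
        raise EnmError("Hessian must be square")
    if not np.allclose(H, H.T, atol=1e-10 * max(1.0, float(np.abs(H).max()))):
        raise EnmError("Hessian must be symmetric")
    eigenvalues, eigenvectors = scipy.linalg.eigh(H)
    lam_max = float(eigenvalues[-1])
    if lam_max <= 0:
        raise EnmError("all modes are rigid (zero Hessian)")
    n_rigid = int(np.sum(eigenvalues < params.zero_mode_tol * lam_max))
    return ModeSpectrum(eigenvalues=eigenvalues, eigenvectors=eigenvectors,
                        n_rigid=n_rigid)


@dataclass(frozen=True)
class EntropyProfile:
    """Per-node harmonic fluctuation profile (arbitrary entropic units)."""

    per_node: np.ndarray
    scalar_pseudo_entropy: float


def entropy_profile(modes: ModeSpectrum) -> EntropyProfile:
    """Per-node sum over non-rigid modes of |v_m,i|^2 / lambda_m.

    Equals the per-node trace of the Hessian pseudo-inverse, i.e. the
    classical harmonic mean-square-fluctuation profile.
    """
    if modes.n_rigid >= modes.n_modes:
        raise EnmError("all modes are rigid; entropy profile undefined")
    lam = modes.eigenvalues[modes.n_rigid:]
    V = modes.eigenvectors[:, modes.n_rigid:]
    contrib = (V ** 2) / lam[np.newaxis, :]   # (3N, n_soft)
    per_coord = contrib.sum(axis=1)
    per_node = per_coord.reshape(-1, 3).sum(axis=1)
    scalar = float(-np.sum(np.log(lam)))
    return EntropyProfile(per_node=per_node, scalar_pseudo_entropy=scalar)


@dataclass(frozen=True)
class DeltaGProfile:
    """Per-subunit entropy difference, variant minus wild type.

    Restricted to the bystander subunits (the mutated chain is excluded),
    mirroring how allosteric effects of a mutation are read off the rest
    of the complex.  Sign convention: positive means the variant is more
    mobile (higher fluctuation entropy) at that node.
    """

    variant: VariantRecord | None
    per_subunit: Mapping[str, np.ndarray]

    @property
    def subunits(self) -> tuple[str, ...]:
        return tuple(sorted(self.per_subunit))

    def combined(self, subunits: Sequence[str] | None = None) -> np.ndarray:
        labels = tuple(subunits) if subunits is not None else self.subunits
        return np.concatenate([np.asarray(self.per_subunit[s]) for s in labels])


def delta_g(
    wt: EntropyProfile,
    mut: EntropyProfile,
    structure: CoarseStructure,
    variant: VariantRecord | None = None,
) -> DeltaGProfile:
    """Subunit-restricted difference of entropy profiles (variant - WT)."""
    if wt.per_node.shape != mut.per_node.shape:
        raise EnmError(
            f"profile size mismatch: WT {wt.per_node.size} vs "
            f"variant {mut.per_node.size} nodes"
        )
    if not structure.subunit_map:
        raise EnmError("structure has no subunit map; call assign_subunits first")
    diff = mut.per_node - wt.per_node
    per_subunit = {
        label: diff[np.asarray(idxs, dtype=int)]
        for label, idxs in structure.subunit_map.items()
    }
    return DeltaGProfile(variant=variant, per_subunit=per_subunit)


def variant_delta_g(
    wt_structure: CoarseStructure,
    variant: VariantRecord,
    params: EnmParams | None = None,
    position_map: Mapping[int, int] | None = None,
    wt_profile: EntropyProfile | None = None,
) -> DeltaGProfile:
    """Full single-variant chain: mutate -> network -> modes -> entropy -> dG.

    ``position_map`` translates catalog (human) positions into chain
    numbering of the structure; identity when omitted.  ``wt_profile``
    lets callers reuse one wild-type decomposition across a panel.
    """
    from .structure import apply_point_mutation  # local to avoid cycle noise

    params = params or EnmParams()
    if wt_structure.mutable_chain is None:
        raise EnmError("structure has no mutable chain; call assign_subunits first")
    if position_map is not None:
        if variant.position not in position_map:
            raise EnmError(
                f"variant {variant.protein_change} position "
                f"{variant.position} does not map onto chain "
                f"{wt_structure.mutable_chain}"
            )
        position = position_map[variant.position]
    else:
        position = variant.position
    mutated = apply_point_mutation(
        wt_structure, wt_structure.mutable_chain, position,
        variant.ref_aa, variant.alt_aa,
    )
    if wt_profile is None:
        wt_profile = entropy_profile(
            normal_modes(hessian(build_network(wt_structure, params)), params)
        )
    mut_profile = entropy_profile(
        normal_modes(hessian(build_network(mutated, params)), params)
    )
    return delta_g(wt_profile, mut_profile, wt_structure, variant)


def export_delta_g_tsv(
    profiles: Sequence[DeltaGProfile],
    structure: CoarseStructure,
    path: str | Path,
) -> None:
    """TSV export: variant, subunit, node key, delta-G value."""
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("variant\tsubunit\tnode\tdelta_g\n")
        for prof in profiles:
            name = prof.variant.protein_change if prof.variant else "NA"
            for label in prof.subunits:
                idxs = structure.subunit_map[label]
                for idx, value in zip(idxs, prof.per_subunit[label]):
                    fh.write(
                        f"{name}\t{label}\t{structure.nodes[idx].key}\t"
                        f"{value:.10g}\n"
                    )
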
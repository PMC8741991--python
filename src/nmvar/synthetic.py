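"""Desk-scale synthetic complexes and variant panels with known ground truth.

The generator emulates the shape of the real analysis input — a small
multi-chain coarse-grained complex with a ligand-like node group bound
near the mutable chain, and a panel of missense variants falling into
"perturbation families".  All members of a family substitute to the same
characteristic residue type, whose nonbonded weights are scaled up
(stiffening) or down (softening) by an amount controlled by
``effect_size``; at effect size zero the weight table is uniform and
every variant is an exact null (delta-G identically zero).  Because a
family's members perturb the network in the same direction, their
entropy-difference profiles correlate — the testable stand-in for the
assumption that variants with similar entropic profiles share a
phenotype.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .catalog import VariantRecord, format_protein_change
from .enm import (DeltaGProfile, EnmParams, WeightTable, build_network,
                  entropy_profile, hessian, normal_modes, uniform_weight_table,
                  variant_delta_g)
from .structure import LIGAND_TYPE, CoarseStructure, Node, aa1_to_3

__all__ = [
    "SyntheticError",
    "ToyComplexSpec",
    "VariantPanelSpec",
    "SyntheticPanel",
    "make_toy_complex",
    "make_variant_panel",
    "panel_delta_g_profiles",
    "recover_families",
]

_AA1 = "ACDEFGHIKLMNPQRSTVWY"
#: Residue types reserved as family-characteristic substitution targets.
_FAMILY_ALT_TYPES = ("TRP", "CYS", "GLN", "HIS", "LYS", "PHE", "GLU", "MET")
#: Family index -> phenotype-group label (catalog vocabulary).
_FAMILY_GROUPS = ("1", "4", "3a", "3b", "2", "5")


class SyntheticError(ValueError):
    """Raised for invalid synthetic-data specifications."""


@dataclass(frozen=True)
class ToyComplexSpec:
    """Geometry of a generated multi-chain complex.

    Chains are labeled A, B, C, ... ; ``ligand_nodes`` heavy-atom-like
    sites are packed into a compact cluster next to the middle of chain B
    (the future GTP-like subunit K).
    """

    n_chains: int = 5
    residues_per_chain: int = 40
    geometry: str = "helical_bundle"
    ligand_nodes: int = 10
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_chains < 2:
            raise SyntheticError("need at least 2 chains")
        if self.geometry not in ("helical_bundle", "ring", "lattice"):
            raise SyntheticError(f"unknown geometry {self.geometry!r}")
        if self.ligand_nodes < 0:
            raise SyntheticError("ligand_nodes must be >= 0")
        total = self.n_chains * self.residues_per_chain + self.ligand_nodes
        if total > 2000:
            raise SyntheticError(f"{total} nodes exceeds the 2000-node guard")


def _chain_coords(spec: ToyComplexSpec, chain_index: int) -> np.ndarray:
    """Backbone trace for one chain: a compact helix-like curve."""
    n = spec.residues_per_chain
    t = np.arange(n, dtype=float)
    if spec.geometry == "helical_bundle":
        # helical axes on a circle; ~5.4 A pitch, 2.3 A helix radius
        axis_r = max(6.0, 2.2 * spec.n_chains)
        phi = 2.0 * np.pi * chain_index / spec.n_chains
        cx, cy = axis_r * np.cos(phi), axis_r * np.sin(phi)
        ang = 2.0 * np.pi * t / 3.6
        return np.column_stack([
            cx + 2.3 * np.cos(ang),
            cy + 2.3 * np.sin(ang),
            1.5 * t,
        ])
    if spec.geometry == "ring":
        # chains are consecutive arcs of one large ring, 3.8 A arc step
        total = spec.n_chains * n
        ring_r = 3.8 * total / (2.0 * np.pi)
        theta = 2.0 * np.pi * (chain_index * n + t) / total
        return np.column_stack([
            ring_r * np.cos(theta),
            ring_r * np.sin(theta),
            np.zeros(n),
        ])
    # lattice: each chain one row of a 3.8 A cubic grid, folded in x
    side = int(np.ceil(np.sqrt(n)))
    xi, yi = t % side, t // side
    return np.column_stack([
        3.8 * xi,
        3.8 * yi,
        np.full(n, 5.0 * chain_index),
    ])


def make_toy_complex(spec: ToyComplexSpec) -> CoarseStructure:
    """Deterministic (seeded) generation of a toy coarse complex."""
    rng = np.random.default_rng(spec.rng_seed)
    chain_nodes: dict[str, list[Node]] = {}
    for c in range(spec.n_chains):
        chain_id = chr(ord("A") + c)
        coords = _chain_coords(spec, c)
        types = rng.choice(list(_AA1), size=spec.residues_per_chain)
        chain_nodes[chain_id] = [
            Node(
                chain_id=chain_id, residue_index=i + 1,
                residue_type=aa1_to_3(str(types[i])),
                # quantize to PDB precision so the PDB round trip is exact
                coords=tuple(round(float(v), 3) for v in coords[i]),
            )
            for i in range(spec.residues_per_chain)
        ]
    if spec.ligand_nodes:
        protein_xyz = np.asarray(
            [nd.coords for nds in chain_nodes.values() for nd in nds], dtype=float
        )
        b_coords = np.asarray([nd.coords for nd in chain_nodes["B"]], dtype=float)
        center = b_coords[len(b_coords) // 2]
        # offset the ligand pocket away from the chain, then pack atoms
        offset = center + np.array([4.0, 4.0, 0.0])
        for attempt in range(50):
            lig = offset + rng.normal(scale=1.8, size=(spec.ligand_nodes, 3))
            all_xyz = np.vstack([protein_xyz, lig])
            diff = all_xyz[:, None, :] - all_xyz[None, :, :]
            d = np.sqrt((diff ** 2).sum(-1))
            np.fill_diagonal(d, np.inf)
            if d.min() > 1.0:
                break
        else:
            raise SyntheticError("could not place ligand nodes without clashes")
        # ligand sits inside chain B's record block so that file round trips
        # through a PDB parser (which groups residues by chain) keep order
        chain_nodes["B"].extend(
            Node(
                chain_id="B", residue_index=900,
                residue_type=LIGAND_TYPE,
                coords=tuple(round(float(v), 3) for v in lig[a]),
                is_ligand=True, atom_name=f"C{a + 1:02d}",
            )
            for a in range(spec.ligand_nodes)
        )
    nodes = [nd for cid in sorted(chain_nodes) for nd in chain_nodes[cid]]
    structure = CoarseStructure(nodes=tuple(nodes))
    xyz = structure.coords
    diff = xyz[:, None, :] - xyz[None, :, :]
    d = np.sqrt((diff ** 2).sum(-1))
    np.fill_diagonal(d, np.inf)
    if d.min() <= 1.0:
        raise SyntheticError(
            f"generated geometry has clashing nodes (min distance {d.min():.2f} A)"
        )
    return structure


@dataclass(frozen=True)
class VariantPanelSpec:
    """Ground-truth layout of a synthetic variant panel.

    ``effect_size`` is the relative shift of nonbonded weights caused by
    a family's characteristic substitution: family weights are scaled by
    (1 + effect_size) (stiffening families) or 1 / (1 + effect_size)
    (softening families).  Zero produces exact null variants.
    """

    n_families: int = 2
    variants_per_family: int = 4
    effect_size: float = 2.0
    placement: str = "clustered"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_families < 1:
            raise SyntheticError("need at least 1 family")
        if self.variants_per_family < 1:
            raise SyntheticError("need at least 1 variant per family")
        if self.effect_size < 0:
            raise SyntheticError("effect_size must be >= 0")
        if self.placement not in ("clustered", "dispersed"):
            raise SyntheticError(f"unknown placement {self.placement!r}")
        if self.n_families > len(_FAMILY_ALT_TYPES):
            raise SyntheticError(
                f"at most {len(_FAMILY_ALT_TYPES)} families supported"
            )


@dataclass(frozen=True)
class SyntheticPanel:
    """Generated variants, their ground-truth families, and the elastic
    network parameters (weight table) that realize the family effects."""

    variants: tuple[VariantRecord, ...]
    family_of: Mapping[str, int]
    enm_params: EnmParams
    spec: VariantPanelSpec = field(default=None)


def _family_factor(family: int, effect_size: float) -> float:
    """Alternating stiffen/soften, growing magnitude for later families."""
    magnitude = (1.0 + effect_size) ** (1 + family // 2)
    return magnitude if family % 2 == 0 else 1.0 / magnitude


def make_variant_panel(
    structure: CoarseStructure,
    spec: VariantPanelSpec,
    mutable_chain: str = "B",
    base_params: EnmParams | None = None,
) -> SyntheticPanel:
    """Seeded panel generation on the mutable chain.

    "clustered" placement packs each family's positions around a family
    center (so the 15 A hotspot search can recover them); "dispersed"
    spreads positions uniformly.  Each family substitutes to its own
    characteristic residue type; the returned ``EnmParams`` carry the
    weight table in which those types stiffen or soften contacts in
    proportion to ``effect_size``.
    """
    rng = np.random.default_rng(spec.rng_seed)
    chain_idxs = structure.chain_node_indices(mutable_chain)
    if not chain_idxs:
        raise SyntheticError(f"chain {mutable_chain!r} has no protein residues")
    needed = spec.n_families * spec.variants_per_family
    usable = [
        i for i in chain_idxs
        if structure.nodes[i].residue_type not in _FAMILY_ALT_TYPES
    ]
    if len(usable) < needed:
        raise SyntheticError(
            f"chain {mutable_chain} has {len(usable)} usable residues, "
            f"need {needed}"
        )
    coords = structure.coords
    available = list(usable)
    positions_by_family: dict[int, list[int]] = {}
    if spec.placement == "clustered":
        centers: list[int] = [int(rng.choice(available))]
        while len(centers) < spec.n_families:
            dmin = np.array([
                min(np.linalg.norm(coords[i] - coords[c]) for c in centers)
                for i in available
            ])
            centers.append(available[int(dmin.argmax())])
        for f, center in enumerate(centers):
            order = sorted(
                available,
                key=lambda i: float(np.linalg.norm(coords[i] - coords[center])),
            )
            chosen = order[:spec.variants_per_family]
            positions_by_family[f] = chosen
            available = [i for i in available if i not in chosen]
    else:
        perm = rng.permutation(len(available))
        flat = [available[int(k)] for k in perm[:needed]]
        for f in range(spec.n_families):
            positions_by_family[f] = flat[
                f * spec.variants_per_family:(f + 1) * spec.variants_per_family
            ]
    all_types = [aa1_to_3(a) for a in _AA1]
    table: WeightTable = (base_params.weights if base_params
                          else uniform_weight_table())
    variants: list[VariantRecord] = []
    family_of: dict[str, int] = {}
    for f in range(spec.n_families):
        alt3 = _FAMILY_ALT_TYPES[f]
        if spec.effect_size > 0:
            table = table.scaled_row(
                alt3, _family_factor(f, spec.effect_size), all_types + [alt3]
            )
        for i in sorted(positions_by_family[f]):
            nd = structure.nodes[i]
            ref = nd.residue_type.capitalize()
            alt = alt3.capitalize()
            rec = VariantRecord.from_protein_change(
                format_protein_change(ref, nd.residue_index, alt),
                cdna_change="synthetic",
                phenotype_group=_FAMILY_GROUPS[f % len(_FAMILY_GROUPS)],
                patient_count=1,
                sources=(f"synthetic family {f}",),
            )
            variants.append(rec)
            family_of[rec.protein_change] = f
    base = base_params or EnmParams()
    params = EnmParams(
        cutoff_radius=base.cutoff_radius,
        epsilon_nonbonded=base.epsilon_nonbonded,
        k_backbone=base.k_backbone,
        weight_table=table,
        ligand_weight=base.ligand_weight,
        zero_mode_tol=base.zero_mode_tol,
    )
    return SyntheticPanel(
        variants=tuple(variants), family_of=family_of,
        enm_params=params, spec=spec,
    )


def panel_delta_g_profiles(
    structure: CoarseStructure,
    panel: SyntheticPanel,
) -> list[DeltaGProfile]:
    """Delta-G profile of every panel variant (wild type computed once).

    The structure must already have subunits assigned."""
    wt_profile = entropy_profile(normal_modes(
        hessian(build_network(structure, panel.enm_params)), panel.enm_params
    ))
    return [
        variant_delta_g(structure, v, panel.enm_params, wt_profile=wt_profile)
        for v in panel.variants
    ]


def recover_families(
    structure: CoarseStructure,
    panel: SyntheticPanel,
    n_clusters: int | None = None,
    profiles: Sequence[DeltaGProfile] | None = None,
) -> dict[str, int]:
    """Cut the combined-profile Ward dendrogram at the family count.

    Null panels (zero effect size) produce constant delta-G vectors;
    those are handled with the "no information" correlation policy so the
    recovery is well-defined and behaves like chance.
    """
    from .clustering import (cut_dendrogram, pairwise_profile_correlation,
                             ward_dendrogram)

    if n_clusters is None:
        n_clusters = panel.spec.n_families if panel.spec else 2
    if profiles is None:
        profiles = panel_delta_g_profiles(structure, panel)
    corr = pairwise_profile_correlation(
        profiles, subunit="combined", constant_policy="zero"
    )
    dendro = ward_dendrogram(corr)
    return {
        v.protein_change: c for v, c in cut_dendrogram(dendro, n_clusters).items()
    }
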
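"""Shared fixtures: small generated complexes and variant panels."""

from __future__ import annotations

import numpy as np
import pytest

from nmvar.enm import EnmParams, uniform_weight_table
from nmvar.structure import CoarseStructure, Node, assign_subunits
from nmvar.synthetic import ToyComplexSpec, VariantPanelSpec, make_toy_complex, make_variant_panel


def make_nodes(coords, chain="A", types=None, start_resi=1):
    """Protein nodes at given coordinates (helper for tiny fixtures)."""
    types = types or ["ALA"] * len(coords)
    return tuple(
        Node(chain_id=chain, residue_index=start_resi + i,
             residue_type=t, coords=tuple(float(x) for x in c))
        for i, (c, t) in enumerate(zip(coords, types))
    )


@pytest.fixture(scope="session")
def uniform_params():
    return EnmParams(weight_table=uniform_weight_table())


@pytest.fixture(scope="session")
def two_node_structure():
    """Two nodes on different chains: a single nonbonded unit spring."""
    return CoarseStructure(nodes=(
        Node(chain_id="A", residue_index=1, residue_type="ALA",
             coords=(0.0, 0.0, 0.0)),
        Node(chain_id="B", residue_index=1, residue_type="ALA",
             coords=(5.0, 0.0, 0.0)),
    ))


@pytest.fixture(scope="session")
def small_complex():
    """5 chains x 30 residues + 6 ligand nodes (156 nodes), subunits set.

    Long enough (~45 A along the bundle axis) that clustered variant
    families land in distinct 15 A hotspots."""
    s = make_toy_complex(ToyComplexSpec(
        n_chains=5, residues_per_chain=30, ligand_nodes=6, rng_seed=7,
    ))
    return assign_subunits(s, "B", "K")


@pytest.fixture(scope="session")
def small_panel(small_complex):
    return make_variant_panel(small_complex, VariantPanelSpec(
        n_families=2, variants_per_family=3, effect_size=2.0, rng_seed=7,
    ))


@pytest.fixture(scope="session")
def random_cloud_structure():
    """12 nodes in a compact random cloud (connected at 12 A cutoff)."""
    rng = np.random.default_rng(11)
    coords = rng.uniform(0, 9.0, size=(12, 3))
    types = list(rng.choice(
        ["ALA", "TRP", "GLY", "LYS", "PHE", "SER"], size=12
    ))
    return CoarseStructure(nodes=make_nodes(coords, types=types))
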
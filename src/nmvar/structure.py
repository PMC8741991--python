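"""Coarse-grained multi-chain structure model.

A structure is reduced to one node per amino-acid residue (at its C-alpha
position) plus one node per heavy atom of each bound ligand (e.g. GTP).
Sequence "humanization" and in-silico point mutagenesis operate purely on
residue identity: coordinates are never moved, so a mutated model retains
the geometry of the crystal structure and only the sequence-aware elastic
network (see :mod:`nmvar.enm`) feels the change.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from Bio.PDB import PDBParser
from Bio.PDB.Polypeptide import protein_letters_3to1

__all__ = [
    "Node",
    "CoarseStructure",
    "SequenceAlignmentResult",
    "StructureError",
    "aa3_to_1",
    "aa1_to_3",
    "read_pdb",
    "write_pdb",
    "assign_subunits",
    "humanize_chain",
    "humanization_position_map",
    "apply_point_mutation",
    "global_sequence_identity",
]

LIGAND_TYPE = "LIG"
DEFAULT_LIGAND_CODES = frozenset({"GTP", "GDP"})
_WATER = frozenset({"HOH", "WAT", "H2O", "DOD"})

_3TO1 = {k.upper(): v for k, v in protein_letters_3to1.items()}
_1TO3 = {v: k for k, v in _3TO1.items() if len(v) == 1}


class StructureError(ValueError):
    """Raised for invalid structures or failed structure operations."""


def aa3_to_1(code: str) -> str:
    try:
        return _3TO1[code.upper()]
    except KeyError:
        raise StructureError(f"unknown amino-acid code {code!r}") from None


def aa1_to_3(letter: str) -> str:
    try:
        return _1TO3[letter.upper()]
    except KeyError:
        raise StructureError(f"unknown amino-acid letter {letter!r}") from None


@dataclass(frozen=True)
class Node:
    """One coarse-grained site: a residue C-alpha or a ligand heavy atom."""

    chain_id: str
    residue_index: int
    residue_type: str  # 3-letter upper-case code, or "LIG"
    coords: tuple[float, float, float]
    is_ligand: bool = False
    icode: str = ""
    atom_name: str = "CA"

    def __post_init__(self) -> None:
        if not all(np.isfinite(self.coords)):
            raise StructureError(
                f"non-finite coordinates at {self.chain_id}:{self.residue_index}"
            )
        if not self.is_ligand and self.residue_type not in _3TO1:
            raise StructureError(
                f"non-canonical residue type {self.residue_type!r} "
                f"at {self.chain_id}:{self.residue_index}"
            )

    @property
    def key(self) -> str:
        return f"{self.chain_id}:{self.residue_index}{self.icode}:{self.atom_name}"


@dataclass(frozen=True)
class CoarseStructure:
    """Ordered node list plus an optional subunit labelling.

    Node order is stable: chains in file order, residues in file order
    within a chain.  ``subunit_map`` (filled by :func:`assign_subunits`)
    maps a subunit label (e.g. "A", "C", "D", "E", "K") to the indices of
    its nodes; the mutable chain is deliberately absent from it.
    """

    nodes: tuple[Node, ...]
    subunit_map: Mapping[str, tuple[int, ...]] = field(default_factory=dict)
    mutable_chain: str | None = None

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def chains(self) -> tuple[str, ...]:
        seen: list[str] = []
        for nd in self.nodes:
            if nd.chain_id not in seen:
                seen.append(nd.chain_id)
        return tuple(seen)

    @property
    def coords(self) -> np.ndarray:
        return np.asarray([nd.coords for nd in self.nodes], dtype=float)

    def chain_node_indices(self, chain: str, protein_only: bool = True) -> list[int]:
        return [
            i for i, nd in enumerate(self.nodes)
            if nd.chain_id == chain and not (protein_only and nd.is_ligand)
        ]

    def chain_sequence(self, chain: str) -> str:
        return "".join(
            aa3_to_1(self.nodes[i].residue_type)
            for i in self.chain_node_indices(chain)
        )

    def node_index(self, chain: str, residue_index: int, icode: str = "") -> int:
        for i, nd in enumerate(self.nodes):
            if (nd.chain_id == chain and nd.residue_index == residue_index
                    and nd.icode == icode and not nd.is_ligand):
                return i
        raise StructureError(f"no protein node at {chain}:{residue_index}{icode}")

    def with_residue_type(self, index: int, residue_type: str) -> "CoarseStructure":
        nodes = list(self.nodes)
        nodes[index] = replace(nodes[index], residue_type=residue_type)
        return replace(self, nodes=tuple(nodes))

    def to_tsv(self, path: str | Path) -> None:
        """Serialize for inspection: chain, resi, type, x, y, z, subunit."""
        subunit_of = {}
        for label, idxs in self.subunit_map.items():
            for i in idxs:
                subunit_of[i] = label
        with Path(path).open("w", encoding="utf-8") as fh:
            fh.write("chain\tresi\ttype\tx\ty\tz\tsubunit\n")
            for i, nd in enumerate(self.nodes):
                x, y, z = nd.coords
                fh.write(
                    f"{nd.chain_id}\t{nd.residue_index}{nd.icode}\t"
                    f"{nd.residue_type}\t{x:.3f}\t{y:.3f}\t{z:.3f}\t"
                    f"{subunit_of.get(i, self.mutable_chain or '')}\n"
                )


def _pick_highest_occupancy(atom):
    if atom.is_disordered():
        children = sorted(
            atom.child_dict.values(),
            key=lambda a: (a.get_occupancy() or 0.0),
            reverse=True,
        )
        return children[0]
    return atom


def read_pdb(
    path: str | Path,
    ligand_codes: Iterable[str] = DEFAULT_LIGAND_CODES,
    model_index: int = 0,
) -> CoarseStructure:
    """Read a PDB file into a coarse-grained structure.

    Protein residues contribute one node at the C-alpha; residues whose
    name is in ``ligand_codes`` contribute one node per heavy atom
    (typed ``"LIG"``).  Waters and unrecognized heteroatoms are ignored.
    Alternate locations resolve to the highest-occupancy conformer.
    """
    path = Path(path)
    ligand_codes = {c.upper() for c in ligand_codes}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        parsed = PDBParser(QUIET=True).get_structure("s", str(path))
        try:
            model = parsed[model_index]
        except KeyError:
            raise StructureError(f"{path.name}: no model in file") from None
    nodes: list[Node] = []
    for chain in model:
        for res in chain:
            hetflag, resseq, icode = res.id
            resname = res.get_resname().strip().upper()
            if resname in _WATER:
                continue
            if resname in ligand_codes:
                for atom in res:
                    atom = _pick_highest_occupancy(atom)
                    if atom.element == "H":
                        continue
                    nodes.append(Node(
                        chain_id=chain.id, residue_index=resseq,
                        residue_type=LIGAND_TYPE,
                        coords=tuple(round(float(v), 3) for v in atom.coord),
                        is_ligand=True, icode=icode.strip(),
                        atom_name=atom.get_name(),
                    ))
            elif hetflag == " ":
                if "CA" not in res:
                    raise StructureError(
                        f"{path.name}: residue {chain.id}:{resseq}{icode.strip()} "
                        f"({resname}) has no C-alpha atom"
                    )
                ca = _pick_highest_occupancy(res["CA"])
                nodes.append(Node(
                    chain_id=chain.id, residue_index=resseq,
                    residue_type=resname,
                    # PDB stores 3 decimals; round so re-reads are bit-stable
                    coords=tuple(round(float(v), 3) for v in ca.coord),
                    icode=icode.strip(),
                ))
            # other het groups (ions, buffer) are skipped
    if not nodes:
        raise StructureError(f"{path.name}: no usable residues found")
    return CoarseStructure(nodes=tuple(nodes))


def write_pdb(structure: CoarseStructure, path: str | Path,
              ligand_resname: str = "GTP") -> None:
    """Write the coarse structure as a minimal PDB (CA atoms + ligand)."""
    with Path(path).open("w", encoding="utf-8") as fh:
        serial = 0
        for nd in structure.nodes:
            serial += 1
            record = "HETATM" if nd.is_ligand else "ATOM  "
            resname = ligand_resname if nd.is_ligand else nd.residue_type
            name = nd.atom_name
            # PDB atom-name column quirk: 1-3 char names start in column 14
            name_f = f" {name:<3s}" if len(name) < 4 else name
            element = name[0]
            x, y, z = nd.coords
            fh.write(
                f"{record}{serial:5d} {name_f:4s} {resname:>3s} "
                f"{nd.chain_id}{nd.residue_index:4d}{nd.icode or ' '}   "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}"
                f"          {element:>2s}\n"
            )
        fh.write("END\n")


def assign_subunits(
    structure: CoarseStructure,
    mutable_chain: str = "B",
    ligand_label: str = "K",
) -> CoarseStructure:
    """Label every non-mutable protein chain as one subunit and gather all
    ligand nodes into a single ligand subunit (the GTP group, "K").

    The mutable chain carries the mutation and is excluded from the
    subunit map, so downstream entropy differences are computed over
    bystander subunits only.
    """
    chains = structure.chains
    protein_chains = [
        c for c in chains if any(
            not nd.is_ligand for nd in structure.nodes if nd.chain_id == c
        )
    ]
    if mutable_chain not in protein_chains:
        raise StructureError(
            f"mutable chain {mutable_chain!r} not found (chains: {protein_chains})"
        )
    if ligand_label in protein_chains:
        raise StructureError(f"ligand label {ligand_label!r} collides with a chain")
    subunit_map: dict[str, tuple[int, ...]] = {}
    for c in protein_chains:
        if c == mutable_chain:
            continue
        idxs = tuple(
            i for i, nd in enumerate(structure.nodes)
            if nd.chain_id == c and not nd.is_ligand
        )
        if idxs:
            subunit_map[c] = idxs
    lig = tuple(i for i, nd in enumerate(structure.nodes) if nd.is_ligand)
    if lig:
        subunit_map[ligand_label] = lig
    return replace(structure, subunit_map=subunit_map, mutable_chain=mutable_chain)


@dataclass(frozen=True)
class SequenceAlignmentResult:
    """Global pairwise alignment summary.

    ``aligned_pairs`` holds 0-based ``(i1, i2)`` tuples with ``None`` on
    the gapped side.  Identity and similarity are percentages over all
    alignment columns (gaps included), BLAST-style; "similar" means the
    substitution score of the aligned pair is positive.
    """

    aligned_pairs: tuple[tuple[int | None, int | None], ...]
    percent_identity: float
    percent_similarity: float
    score: float


def _make_aligner(matrix_name: str, open_gap: float, extend_gap: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(matrix_name)
    aligner.open_gap_score = open_gap
    aligner.extend_gap_score = extend_gap
    return aligner


def global_sequence_identity(
    seq1: str,
    seq2: str,
    matrix_name: str = "BLOSUM62",
    open_gap: float = -11.0,
    extend_gap: float = -1.0,
) -> SequenceAlignmentResult:
    """Optimal global alignment with percent identity and similarity.

    Similarity counts identical pairs plus conservative substitutions,
    where "conservative" is fixed by the substitution matrix (pair score
    > 0), mirroring BLAST "positives".
    """
    for label, s in (("seq1", seq1), ("seq2", seq2)):
        if not s:
            raise StructureError(f"{label} is empty")
        bad = set(s.upper()) - set(_1TO3)
        if bad:
            raise StructureError(f"{label} has non-amino-acid characters {sorted(bad)}")
    seq1, seq2 = seq1.upper(), seq2.upper()
    aligner = _make_aligner(matrix_name, open_gap, extend_gap)
    alignment = aligner.align(seq1, seq2)[0]
    row1, row2 = str(alignment[0]), str(alignment[1])
    matrix = aligner.substitution_matrix
    pairs: list[tuple[int | None, int | None]] = []
    i1 = i2 = 0
    n_cols = n_ident = n_similar = 0
    for a, b in zip(row1, row2):
        n_cols += 1
        if a == "-":
            pairs.append((None, i2)); i2 += 1
        elif b == "-":
            pairs.append((i1, None)); i1 += 1
        else:
            pairs.append((i1, i2))
            if a == b:
                n_ident += 1
                n_similar += 1
            elif matrix[a, b] > 0:
                n_similar += 1
            i1 += 1; i2 += 1
    return SequenceAlignmentResult(
        aligned_pairs=tuple(pairs),
        percent_identity=100.0 * n_ident / n_cols,
        percent_similarity=100.0 * n_similar / n_cols,
        score=float(alignment.score),
    )


def _align_chain_to_target(
    structure: CoarseStructure,
    chain: str,
    target_sequence: str,
    identity_floor: float,
    max_internal_gap: int,
) -> tuple[list[int], SequenceAlignmentResult]:
    chain_idxs = structure.chain_node_indices(chain)
    if not chain_idxs:
        raise StructureError(f"chain {chain!r} not found or has no protein nodes")
    result = global_sequence_identity(structure.chain_sequence(chain), target_sequence)
    if result.percent_identity < identity_floor:
        raise StructureError(
            f"chain {chain} aligns to target at "
            f"{result.percent_identity:.1f}% identity, below the "
            f"{identity_floor:.0f}% floor — sequences look unrelated"
        )
    # reject long internal gap runs (alignment would be unreliable there)
    gap_run = longest = 0
    interior = [p for p in result.aligned_pairs]
    while interior and (interior[0][0] is None or interior[0][1] is None):
        interior.pop(0)
    while interior and (interior[-1][0] is None or interior[-1][1] is None):
        interior.pop()
    for p in interior:
        if p[0] is None or p[1] is None:
            gap_run += 1
            longest = max(longest, gap_run)
        else:
            gap_run = 0
    if longest > max_internal_gap:
        raise StructureError(
            f"alignment of chain {chain} has an internal gap of {longest} "
            f"columns (limit {max_internal_gap})"
        )
    return chain_idxs, result


def humanize_chain(
    structure: CoarseStructure,
    chain: str,
    target_sequence: str,
    identity_floor: float = 70.0,
    max_internal_gap: int = 10,
) -> CoarseStructure:
    """Replace residue identities of ``chain`` by those of the target
    sequence at every aligned mismatch.  Coordinates are untouched, so the
    humanized model keeps the original crystal geometry.
    """
    chain_idxs, result = _align_chain_to_target(
        structure, chain, target_sequence, identity_floor, max_internal_gap
    )
    target = target_sequence.upper()
    nodes = list(structure.nodes)
    for i1, i2 in result.aligned_pairs:
        if i1 is None or i2 is None:
            continue
        node_idx = chain_idxs[i1]
        target_type = aa1_to_3(target[i2])
        if nodes[node_idx].residue_type != target_type:
            nodes[node_idx] = replace(nodes[node_idx], residue_type=target_type)
    return replace(structure, nodes=tuple(nodes))


def humanization_position_map(
    structure: CoarseStructure,
    chain: str,
    target_sequence: str,
    identity_floor: float = 70.0,
    max_internal_gap: int = 10,
) -> dict[int, int]:
    """Map 1-based positions of the target (human) sequence to residue
    indices of ``chain`` in the structure's author numbering, via the
    humanization alignment.  Unaligned target positions are absent."""
    chain_idxs, result = _align_chain_to_target(
        structure, chain, target_sequence, identity_floor, max_internal_gap
    )
    mapping: dict[int, int] = {}
    for i1, i2 in result.aligned_pairs:
        if i1 is None or i2 is None:
            continue
        mapping[i2 + 1] = structure.nodes[chain_idxs[i1]].residue_index
    return mapping


def apply_point_mutation(
    structure: CoarseStructure,
    chain: str,
    position: int,
    ref_aa: str,
    alt_aa: str,
) -> CoarseStructure:
    """In-silico point mutagenesis: set the residue type at
    ``chain:position`` from ``ref_aa`` to ``alt_aa``, geometry unchanged.

    The reference identity is asserted to guard against numbering drift
    between the variant catalog and the structure.
    """
    ref3, alt3 = ref_aa.upper(), alt_aa.upper()
    if len(ref_aa) == 1:
        ref3 = aa1_to_3(ref_aa)
    if len(alt_aa) == 1:
        alt3 = aa1_to_3(alt_aa)
    idx = structure.node_index(chain, position)
    found = structure.nodes[idx].residue_type
    if found != ref3:
        raise StructureError(
            f"reference mismatch at {chain}:{position}: expected {ref3} found {found}"
        )
    return structure.with_residue_type(idx, alt3)
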
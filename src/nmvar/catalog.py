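"""Curated missense-variant catalog: parsing, validation and summary counts.

The catalog pairs protein-level missense variants of a gene of interest
(here TUBB4A, transcript NM_006087.4) with a clinical phenotype subgroup
label and the number of reported patients.  Pathogenic variants carry
groups "1"-"5" (group 3 split into "3a"/"3b"); benign, likely-benign and
common population variants used as controls carry group "0".
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

__all__ = [
    "AA3",
    "PHENOTYPE_GROUPS",
    "DEFAULT_SEVERITY_ORDER",
    "VariantRecord",
    "CatalogSummary",
    "CatalogError",
    "ParseError",
    "parse_protein_change",
    "format_protein_change",
    "load_catalog",
    "write_catalog",
    "packaged_catalog_path",
    "load_packaged_catalog",
    "summarize_catalog",
    "severity_map",
    "private_variant_count",
]

#: Canonical 3-letter amino-acid codes (IUPAC), title-case as used in HGVS.
AA3 = (
    "Ala", "Arg", "Asn", "Asp", "Cys", "Gln", "Glu", "Gly", "His", "Ile",
    "Leu", "Lys", "Met", "Phe", "Pro", "Ser", "Thr", "Trp", "Tyr", "Val",
)
_AA3_SET = frozenset(AA3)

PHENOTYPE_GROUPS = ("0", "1", "2", "3a", "3b", "4", "5")

#: Default ordinal severity scale used for concordance scoring.  Group 3b
#: (later onset / preserved ambulation) is ranked below 3a; controls are 0.
#: The order is configurable wherever it is consumed because clinical
#: severity is a continuum, not a strict total order.
DEFAULT_SEVERITY_ORDER = ("0", "1", "2", "3b", "3a", "4", "5")


class CatalogError(ValueError):
    """Raised for invalid catalog files or records."""


class ParseError(CatalogError):
    """Raised for malformed protein-change strings."""


_PCHANGE_RE = re.compile(r"^p\.([A-Z][a-z]{2})(\d+)([A-Z][a-z]{2})$")


def parse_protein_change(text: str) -> tuple[str, int, str]:
    """Parse an HGVS-style protein missense notation.

    ``"p.Asp249Asn"`` -> ``("Asp", 249, "Asn")``.  Only single-residue
    missense substitutions are accepted; frameshift/nonsense/indel
    notations are rejected.
    """
    m = _PCHANGE_RE.match(text.strip())
    if m is None:
        raise ParseError(f"not a missense protein change: {text!r}")
    ref_aa, pos_s, alt_aa = m.groups()
    for token in (ref_aa, alt_aa):
        if token not in _AA3_SET:
            raise ParseError(f"unknown amino-acid code {token!r} in {text!r}")
    position = int(pos_s)
    if position < 1:
        raise ParseError(f"position must be >= 1 in {text!r}")
    if ref_aa == alt_aa:
        raise ParseError(f"reference equals alternate ({ref_aa!r}) in {text!r}")
    return ref_aa, position, alt_aa


def format_protein_change(ref_aa: str, position: int, alt_aa: str) -> str:
    """Inverse of :func:`parse_protein_change`."""
    return f"p.{ref_aa}{position}{alt_aa}"


@dataclass(frozen=True)
class VariantRecord:
    """One curated missense variant with its phenotype annotation."""

    protein_change: str
    ref_aa: str
    position: int
    alt_aa: str
    cdna_change: str = ""
    phenotype_group: str = "0"
    patient_count: int = 0
    sources: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        ref, pos, alt = parse_protein_change(self.protein_change)
        if (ref, pos, alt) != (self.ref_aa, self.position, self.alt_aa):
            raise CatalogError(
                f"{self.protein_change!r} does not match components "
                f"({self.ref_aa}, {self.position}, {self.alt_aa})"
            )
        if self.phenotype_group not in PHENOTYPE_GROUPS:
            raise CatalogError(
                f"invalid phenotype group {self.phenotype_group!r} "
                f"for {self.protein_change}"
            )
        if self.patient_count < 0:
            raise CatalogError(f"negative patient count for {self.protein_change}")
        if self.phenotype_group != "0" and self.patient_count < 1:
            raise CatalogError(
                f"pathogenic variant {self.protein_change} requires >= 1 patient"
            )

    @property
    def is_control(self) -> bool:
        return self.phenotype_group == "0"

    @classmethod
    def from_protein_change(cls, protein_change: str, **kwargs) -> "VariantRecord":
        ref, pos, alt = parse_protein_change(protein_change)
        return cls(protein_change=protein_change, ref_aa=ref, position=pos,
                   alt_aa=alt, **kwargs)

    def with_position(self, position: int) -> "VariantRecord":
        """Same variant renumbered (e.g. mapped onto structure numbering)."""
        return replace(
            self,
            position=position,
            protein_change=format_protein_change(self.ref_aa, position, self.alt_aa),
        )


@dataclass(frozen=True)
class CatalogSummary:
    n_variants: int
    n_patients: int
    n_top_level_groups: int
    per_group_variant_counts: Mapping[str, int]
    per_group_patient_counts: Mapping[str, int]


_REQUIRED_COLUMNS = ("protein_change", "cdna_change", "group", "patients", "sources")


def load_catalog(path: str | Path) -> list[VariantRecord]:
    """Load a TSV variant catalog, validating every row.

    Expected header: ``protein_change  cdna_change  group  patients  sources``.
    Duplicate ``protein_change`` values and invalid group labels are
    rejected with the offending row number.
    """
    path = Path(path)
    records: list[VariantRecord] = []
    seen: set[str] = set()
    with path.open(encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            raise CatalogError(f"{path}: empty file (no header)")
        missing = [c for c in _REQUIRED_COLUMNS if c not in reader.fieldnames]
        if missing:
            raise CatalogError(f"{path}: missing column(s) {missing}")
        for lineno, row in enumerate(reader, start=2):
            try:
                pchange = row["protein_change"].strip()
                if pchange in seen:
                    raise CatalogError(f"duplicate variant {pchange!r}")
                seen.add(pchange)
                sources = tuple(
                    s.strip() for s in row["sources"].split(";") if s.strip()
                )
                rec = VariantRecord.from_protein_change(
                    pchange,
                    cdna_change=row["cdna_change"].strip(),
                    phenotype_group=row["group"].strip(),
                    patient_count=int(row["patients"]),
                    sources=sources,
                )
            except (CatalogError, KeyError, ValueError) as exc:
                raise CatalogError(f"{path}, row {lineno}: {exc}") from exc
            records.append(rec)
    return records


def write_catalog(records: Iterable[VariantRecord], path: str | Path) -> None:
    """Write records in the TSV catalog format accepted by :func:`load_catalog`."""
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("\t".join(_REQUIRED_COLUMNS) + "\n")
        for r in records:
            fh.write(
                f"{r.protein_change}\t{r.cdna_change}\t{r.phenotype_group}\t"
                f"{r.patient_count}\t{'; '.join(r.sources)}\n"
            )


def packaged_catalog_path() -> Path:
    """Path of the packaged TUBB4A catalog (41 pathogenic + 3 controls)."""
    return Path(resources.files("nmvar").joinpath("data/tubb4a_catalog.tsv"))


def load_packaged_catalog() -> list[VariantRecord]:
    return load_catalog(packaged_catalog_path())


def _top_level(group: str) -> str:
    return "3" if group in ("3a", "3b") else group


def summarize_catalog(records: Iterable[VariantRecord]) -> CatalogSummary:
    """Summary counts over the pathogenic records (groups 1-5).

    ``n_top_level_groups`` merges 3a/3b into a single group 3.
    """
    pathogenic = [r for r in records if not r.is_control]
    per_group_v: dict[str, int] = {}
    per_group_p: dict[str, int] = {}
    for rec in pathogenic:
        g = rec.phenotype_group
        per_group_v[g] = per_group_v.get(g, 0) + 1
        per_group_p[g] = per_group_p.get(g, 0) + rec.patient_count
    return CatalogSummary(
        n_variants=len({r.protein_change for r in pathogenic}),
        n_patients=sum(r.patient_count for r in pathogenic),
        n_top_level_groups=len({_top_level(g) for g in per_group_v}),
        per_group_variant_counts=dict(sorted(per_group_v.items())),
        per_group_patient_counts=dict(sorted(per_group_p.items())),
    )


def severity_map(order: Iterable[str] = DEFAULT_SEVERITY_ORDER) -> dict[str, int]:
    """Map phenotype-group label -> ordinal severity rank (0 = mildest)."""
    return {g: i for i, g in enumerate(order)}


def private_variant_count(records: Iterable[VariantRecord]) -> int:
    """Number of pathogenic variants reported in a single patient.

    Exposed for inspection only: the literature's notion of a "private"
    mutation (single patient vs. single family) is ambiguous, so this
    statistic carries no validation guarantee.
    """
    return sum(1 for r in records if not r.is_control and r.patient_count == 1)
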
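"""End-to-end orchestration: structure + catalog -> hotspots, delta-G
cross-correlation dendrograms and a genotype-phenotype concordance report.

Every stage writes a plain-text artifact (TSV, Newick, JSON) into the
output directory, and the run manifest records a SHA-256 checksum per
output so that reruns with an identical configuration are verifiably
byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from . import catalog as cat
from . import clustering as clu
from . import enm
from . import structure as struc

__all__ = ["RunConfig", "RunManifest", "PipelineError", "run_pipeline"]

log = logging.getLogger("nmvar")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and culprit."""


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one full pipeline run (YAML-serializable)."""

    structure_path: str
    catalog_path: str
    out_dir: str
    mutable_chain: str = "B"
    ligand_codes: tuple[str, ...] = ("GTP", "GDP")
    ligand_label: str = "K"
    enm_params: enm.EnmParams = field(default_factory=enm.EnmParams)
    cluster_threshold: float = clu.DEFAULT_CLUSTER_THRESHOLD
    subunits: tuple[str, ...] | None = None  # None -> all + "combined"
    humanize_chains: tuple[str, ...] = ()
    target_sequence_path: str | None = None  # FASTA, used for humanization
    severity_order: tuple[str, ...] = cat.DEFAULT_SEVERITY_ORDER
    transition_quantile: float = 0.25
    constant_policy: str = "error"
    on_disconnected: str = "error"
    rng_seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.cluster_threshold <= 0:
            raise PipelineError("cluster_threshold must be positive")

    def to_dict(self) -> dict:
        d = {
            "structure_path": self.structure_path,
            "catalog_path": self.catalog_path,
            "out_dir": self.out_dir,
            "mutable_chain": self.mutable_chain,
            "ligand_codes": list(self.ligand_codes),
            "ligand_label": self.ligand_label,
            "enm_params": self.enm_params.to_dict(),
            "cluster_threshold": self.cluster_threshold,
            "subunits": list(self.subunits) if self.subunits else None,
            "humanize_chains": list(self.humanize_chains),
            "target_sequence_path": self.target_sequence_path,
            "severity_order": list(self.severity_order),
            "transition_quantile": self.transition_quantile,
            "constant_policy": self.constant_policy,
            "on_disconnected": self.on_disconnected,
            "rng_seed": self.rng_seed,
            "log_level": self.log_level,
        }
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "RunConfig":
        d = dict(d)
        if "enm_params" in d and not isinstance(d["enm_params"], enm.EnmParams):
            d["enm_params"] = enm.EnmParams.from_dict(d["enm_params"])
        for key in ("ligand_codes", "subunits", "humanize_chains", "severity_order"):
            if d.get(key) is not None:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with Path(path).open(encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path: str | Path) -> None:
        with Path(path).open("w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


@dataclass(frozen=True)
class RunManifest:
    """Paths and checksums of every artifact produced by a run."""

    out_dir: str
    outputs: Mapping[str, str]  # relative path -> sha256
    report_path: str

    def to_dict(self) -> dict:
        return {"out_dir": self.out_dir, "outputs": dict(self.outputs),
                "report": self.report_path}


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _read_single_fasta(path: str | Path) -> str:
    from Bio import SeqIO
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise PipelineError(f"no sequences in FASTA {path}")
    return str(records[0].seq)


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute the full workflow and return the output manifest.

    Stages: read structure -> (optional) humanize -> wild-type NMA ->
    per-variant mutate + NMA + delta-G -> structural hotspots ->
    per-hotspot correlation + Ward dendrograms -> concordance and
    transition report.  Deterministic for a fixed configuration.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), 20))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, str] = {}

    def emit(relpath: str) -> None:
        outputs[relpath] = _sha256(out / relpath)

    stage = "load_catalog"
    try:
        records = cat.load_catalog(config.catalog_path)
        severity = cat.severity_map(config.severity_order)

        stage = "read_structure"
        structure = struc.read_pdb(config.structure_path, config.ligand_codes)
        structure = struc.assign_subunits(
            structure, config.mutable_chain, config.ligand_label
        )

        stage = "humanize"
        position_map: dict[int, int] | None = None
        if config.target_sequence_path:
            target = _read_single_fasta(config.target_sequence_path)
            chains = config.humanize_chains or (config.mutable_chain,)
            for chain in chains:
                structure = struc.humanize_chain(structure, chain, target)
            position_map = struc.humanization_position_map(
                structure, config.mutable_chain, target
            )

        stage = "wild_type_nma"
        t0 = time.perf_counter()
        network = enm.build_network(
            structure, config.enm_params, on_disconnected=config.on_disconnected
        )
        modes = enm.normal_modes(enm.hessian(network), config.enm_params)
        wt_profile = enm.entropy_profile(modes)
        log.info(
            "wild-type NMA: %d nodes, %d modes (%d rigid), %.2fs",
            network.n_nodes, modes.n_modes, modes.n_rigid,
            time.perf_counter() - t0,
        )
        structure.to_tsv(out / "structure_nodes.tsv")
        emit("structure_nodes.tsv")

        stage = "variant_delta_g"
        profiles: list[enm.DeltaGProfile] = []
        for rec in records:
            t0 = time.perf_counter()
            try:
                prof = enm.variant_delta_g(
                    structure, rec, config.enm_params,
                    position_map=position_map, wt_profile=wt_profile,
                )
            except (enm.EnmError, struc.StructureError) as exc:
                raise PipelineError(
                    f"stage {stage}: variant {rec.protein_change}: {exc}"
                ) from exc
            profiles.append(prof)
            log.info("delta-G %s: %.2fs", rec.protein_change,
                     time.perf_counter() - t0)
        enm.export_delta_g_tsv(profiles, structure, out / "delta_g.tsv")
        emit("delta_g.tsv")

        stage = "structural_clusters"
        positions = clu.variant_positions(structure, records, position_map)
        clusters = clu.structural_clusters(positions, config.cluster_threshold)
        for c in clusters:
            assert c.mean_member_distance < config.cluster_threshold
        with (out / "clusters.tsv").open("w", encoding="utf-8") as fh:
            fh.write("cluster\tvariant\tgroup\tmean_member_distance\n")
            for c in clusters:
                for v in c.member_variants:
                    fh.write(f"{c.label}\t{v.protein_change}\t"
                             f"{v.phenotype_group}\t{c.mean_member_distance:.4f}\n")
        emit("clusters.tsv")

        ordered, dist = clu.position_distance_matrix(positions, severity)
        clu.export_matrix_tsv(
            [v.protein_change for v in ordered], dist,
            out / "position_distance.tsv",
        )
        emit("position_distance.tsv")

        stage = "panel_correlation"
        profile_of = {p.variant.protein_change: p for p in profiles}
        panel_corr = clu.pairwise_profile_correlation(
            profiles, "combined", constant_policy=config.constant_policy
        )
        clu.export_matrix_tsv(panel_corr.names, panel_corr.values,
                              out / "panel_correlation_combined.tsv")
        emit("panel_correlation_combined.tsv")
        panel_D = clu.correlation_to_distance(panel_corr.values)

        stage = "cluster_dendrograms"
        subunit_labels = (
            list(config.subunits) if config.subunits
            else sorted(structure.subunit_map) + ["combined"]
        )
        per_cluster: dict[str, tuple[str, float]] = {}
        for c in clusters:
            if len(c.member_variants) < 2:
                continue
            members = [profile_of[n] for n in c.member_names]
            best: tuple[str, float] | None = None
            for sub in subunit_labels:
                corr = clu.pairwise_profile_correlation(
                    members, sub, constant_policy=config.constant_policy
                )
                dendro = clu.ward_dendrogram(corr, cluster_label=c.label)
                prefix = f"cluster_{c.label}_{sub}"
                clu.export_matrix_tsv(corr.names, corr.values,
                                      out / f"{prefix}_correlation.tsv")
                emit(f"{prefix}_correlation.tsv")
                (out / f"{prefix}.nwk").write_text(dendro.newick + "\n")
                emit(f"{prefix}.nwk")
                linkage_dump = {
                    "cluster": c.label, "subunit": sub,
                    "leaves": list(corr.names),
                    "linkage": [[int(a), int(b), float(h), int(s)]
                                for a, b, h, s in dendro.linkage],
                }
                (out / f"{prefix}_linkage.json").write_text(
                    json.dumps(linkage_dump, indent=1) + "\n"
                )
                emit(f"{prefix}_linkage.json")
                groups = {
                    v.protein_change: severity.get(v.phenotype_group, -1)
                    for v in c.member_variants
                }
                try:
                    score = clu.concordance_score(dendro, groups)
                except clu.ClusterError:
                    continue
                if best is None or score > best[1]:
                    best = (sub, score)
            if best is not None:
                per_cluster[c.label] = best

        stage = "transition_report"
        transitions, interrupted = clu.transition_report(
            clusters, (panel_corr.variants, panel_D),
            quantile=config.transition_quantile,
        )
        report = clu.ConcordanceReport(
            per_cluster=per_cluster,
            transitions=transitions,
            interrupted_transitions=interrupted,
        )
        summary = cat.summarize_catalog(records)
        report_doc = {
            "catalog": {
                "n_variants": summary.n_variants,
                "n_patients": summary.n_patients,
                "n_top_level_groups": summary.n_top_level_groups,
            },
            "n_structural_clusters": len(clusters),
            "clusters": {
                c.label: {
                    "members": list(c.member_names),
                    "mean_member_distance": c.mean_member_distance,
                    "center_of_mass": list(c.center_of_mass),
                }
                for c in clusters
            },
            "concordance": report.to_dict(),
        }
        (out / "report.json").write_text(json.dumps(report_doc, indent=1) + "\n")
        emit("report.json")
    except PipelineError:
        raise
    except (cat.CatalogError, struc.StructureError, enm.EnmError,
            clu.ClusterError, OSError) as exc:
        raise PipelineError(f"stage {stage}: {exc}") from exc

    manifest = RunManifest(
        out_dir=str(out), outputs=outputs, report_path="report.json"
    )
    (out / "manifest.json").write_text(
        json.dumps(manifest.to_dict(), indent=1, sort_keys=True) + "\n"
    )
    return manifest
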
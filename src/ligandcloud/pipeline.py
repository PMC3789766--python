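"""End-to-end analysis pipeline and human-readable report rendering.

Composes the stages in dependency order -- obtain a trajectory (load a
multi-model PDB plus topology, or run the synthetic generator), dSASA
binding analysis, RMSD clustering with ligand clouds, interaction
matrices, chain metrics, and free-energy bookkeeping -- writing every
table to an output directory together with a manifest that records the
parameters and seed needed to reproduce the run bit-identically.

The command-line interface in :mod:`ligandcloud.cli` is a thin wrapper
over :func:`run_pipeline` and :func:`render_report`.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import yaml

from . import __version__
from .core import Trajectory, read_pdb_models, read_topology, write_pdb_models, write_topology
from .errors import ConfigurationError
from .synth import ChainSpec, LigandSpec, SimulationParams, simulate_cg
from .sasa import SasaParams, binding_summary
from .cluster import cluster_population_report, daura_cluster, ligand_cloud, pairwise_rmsd_matrix
from .interactions import ContactCriterion, contact_map, pair_energy_matrices, peptide_ligand_profile
from .metrics import assign_secondary_structure, rg_distribution, ss_content_and_propensity
from .thermo import compare, read_thermo_table

logger = logging.getLogger("ligandcloud")

__all__ = ["RunConfig", "Report", "run_pipeline", "render_report", "load_config"]


@dataclass
class RunConfig:
    """Pipeline configuration.

    Exactly one of ``trajectory`` (a multi-model PDB path, with
    ``topology`` and ``chain_roles``) or ``synthetic`` (keyword blocks for
    the coarse-grained generator: ``chain``, ``ligand``, ``params``) must
    be given.  Stage toggles select which analyses run; every threshold
    carries its conventional default (dSASA > 10 A^2, events >= 10 ns,
    2.0 A cluster cutoff, 4.0 A contacts with j > i+2, 300 K).
    """

    output_dir: str | Path = "ligandcloud_out"
    trajectory: str | None = None
    topology: str | None = None
    chain_roles: Mapping[str, str] | None = None
    time_spacing: float = 20.0
    synthetic: Mapping[str, Any] | None = None

    stages: tuple[str, ...] = ("sasa", "cluster", "interactions", "metrics")

    # stage parameters
    sasa_probe_radius: float = 1.4
    sasa_n_points: int = 256
    dsasa_threshold: float = 10.0
    min_event_duration: float = 10.0     # ns
    site_min_pct: float = 15.0
    site_max_gap: int = 1
    cluster_cutoff: float = 2.0
    contact_cutoff: float = 4.0
    contact_separation: int = 2
    temperature: float = 300.0
    thermo_table: str | None = None      # enables the energetics stage

    def __post_init__(self) -> None:
        has_traj = self.trajectory is not None
        has_synth = self.synthetic is not None
        if has_traj == has_synth:
            raise ConfigurationError(
                "exactly one of 'trajectory' and 'synthetic' must be configured"
            )
        if has_traj and self.chain_roles is None:
            raise ConfigurationError("a trajectory input needs a chain_roles mapping")
        bad = [s for s in self.stages
               if s not in ("sasa", "cluster", "interactions", "metrics", "energetics")]
        if bad:
            raise ConfigurationError(f"unknown stages {bad}")


@dataclass
class Report:
    """Manifest of produced files plus the provenance block."""

    output_dir: Path
    manifest: dict[str, str]
    provenance: dict[str, Any]
    summary_data: dict[str, Any] = field(default_factory=dict)

    def save(self) -> Path:
        path = Path(self.output_dir) / "manifest.json"
        payload = {
            "files": self.manifest,
            "provenance": self.provenance,
            "summary": self.summary_data,
        }
        path.write_text(json.dumps(payload, indent=2, sort_keys=True, default=str))
        return path

    @classmethod
    def load(cls, output_dir: str | Path) -> "Report":
        output_dir = Path(output_dir)
        payload = json.loads((output_dir / "manifest.json").read_text())
        return cls(output_dir, payload["files"], payload["provenance"],
                   payload.get("summary", {}))


def load_config(path: str | Path) -> RunConfig:
    """Read a YAML key-value configuration file into a :class:`RunConfig`."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigurationError("configuration must be a mapping")
    if "stages" in raw:
        raw["stages"] = tuple(raw["stages"])
    try:
        return RunConfig(**raw)
    except TypeError as exc:
        raise ConfigurationError(str(exc)) from exc


def _obtain_trajectory(config: RunConfig) -> Trajectory:
    if config.trajectory is not None:
        topology = read_topology(config.topology) if config.topology else None
        return read_pdb_models(config.trajectory, dict(config.chain_roles),
                               topology, config.time_spacing)
    synth = dict(config.synthetic)
    chain = ChainSpec(**synth.get("chain", {}))
    ligand = LigandSpec(**synth["ligand"]) if synth.get("ligand") is not None else None
    params = SimulationParams(**synth.get("params", {}))
    return simulate_cg(chain, ligand, params)


def run_pipeline(config: RunConfig) -> Report:
    """Execute the configured stages and write all outputs plus a manifest.

    Stage failures abort the run with the failing stage named; the
    manifest of a successful run lists every file written.  Runs with the
    same configuration (including the synthetic seed) are bit-identical on
    all seeded outputs.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}
    summary: dict[str, Any] = {}

    def _save(name: str, fn) -> None:
        t0 = time.perf_counter()
        try:
            fn()
        except Exception as exc:
            raise RuntimeError(f"stage '{name}' failed: {exc}") from exc
        logger.info("stage %s finished in %.2f s", name, time.perf_counter() - t0)

    traj: Trajectory | None = None

    def _input_stage() -> None:
        nonlocal traj
        traj = _obtain_trajectory(config)
        if config.synthetic is not None:
            write_pdb_models(traj, out / "trajectory.pdb")
            write_topology(traj.topology, out / "topology.tsv")
            manifest["trajectory"] = "trajectory.pdb"
            manifest["topology"] = "topology.tsv"

    _save("input", _input_stage)

    if "sasa" in config.stages and traj.has_ligand:
        def _sasa_stage() -> None:
            params = SasaParams(config.sasa_probe_radius, config.sasa_n_points)
            bs = binding_summary(
                traj, params, config.dsasa_threshold, config.min_event_duration,
                config.site_min_pct, config.site_max_gap,
            )
            bs.percentages.to_csv(out / "binding_percentage.tsv", sep="\t")
            bs.events_frame().to_csv(out / "binding_events.tsv", sep="\t", index=False)
            manifest["binding_percentage"] = "binding_percentage.tsv"
            manifest["binding_events"] = "binding_events.tsv"
            summary["sites"] = [
                {"start": s.start, "end": s.end, "rank": s.rank,
                 "mean_pct": round(s.mean_percentage, 1)}
                for s in bs.sites
            ]

        _save("sasa", _sasa_stage)

    if "cluster" in config.stages:
        def _cluster_stage() -> None:
            rmsd = pairwise_rmsd_matrix(traj)
            clusters = daura_cluster(rmsd, config.cluster_cutoff)
            clusters.to_frame().to_csv(out / "clusters.tsv", sep="\t", index=False)
            manifest["clusters"] = "clusters.tsv"
            table, cumulative = cluster_population_report(clusters, top_k=8)
            summary["top_clusters_pct"] = table["population_pct"].tolist()
            summary["cumulative_top8_pct"] = cumulative
            if traj.has_ligand:
                cloud = ligand_cloud(traj, clusters)
                cloud.to_frame().to_csv(out / "ligand_cloud.tsv", sep="\t", index=False)
                manifest["ligand_cloud"] = "ligand_cloud.tsv"

        _save("cluster", _cluster_stage)

    if "interactions" in config.stages:
        def _interactions_stage() -> None:
            crit = ContactCriterion(config.contact_cutoff, config.contact_separation)
            cm = contact_map(traj, crit)
            cm.to_csv(out / "contact_map.tsv", sep="\t")
            lj, coulomb = pair_energy_matrices(traj)
            lj.to_csv(out / "lj_matrix.tsv", sep="\t")
            coulomb.to_csv(out / "coulomb_matrix.tsv", sep="\t")
            manifest["contact_map"] = "contact_map.tsv"
            manifest["lj_matrix"] = "lj_matrix.tsv"
            manifest["coulomb_matrix"] = "coulomb_matrix.tsv"
            if traj.has_ligand:
                profile = peptide_ligand_profile(traj)
                profile.to_csv(out / "ligand_profile.tsv", sep="\t")
                manifest["ligand_profile"] = "ligand_profile.tsv"

        _save("interactions", _interactions_stage)

    if "metrics" in config.stages:
        def _metrics_stage() -> None:
            rg = rg_distribution(traj)
            rg.to_frame().to_csv(out / "rg_histogram.tsv", sep="\t", index=False)
            manifest["rg_histogram"] = "rg_histogram.tsv"
            summary["rg_mean"] = round(rg.mean, 2)
            summary["rg_sd"] = round(rg.sd, 2)
            assign = assign_secondary_structure(traj)
            content, propensity = ss_content_and_propensity(assign)
            content.to_csv(out / "ss_content.tsv", sep="\t", index=False)
            propensity.to_csv(out / "helix_propensity.tsv", sep="\t")
            manifest["ss_content"] = "ss_content.tsv"
            manifest["helix_propensity"] = "helix_propensity.tsv"
            helix = content.loc[content["class"] == "H"].iloc[0]
            summary["helix_pct"] = round(float(helix["mean_pct"]), 1)

        _save("metrics", _metrics_stage)

    if "energetics" in config.stages or config.thermo_table:
        def _energetics_stage() -> None:
            if not config.thermo_table:
                raise ConfigurationError("energetics stage needs a thermo_table path")
            records = read_thermo_table(config.thermo_table)
            comparisons = []
            for a in records:
                for b in records:
                    if a.label < b.label:
                        c = compare(a, b, config.temperature)
                        comparisons.append({
                            "a": a.label, "b": b.label,
                            "ddG": round(c.ddG, 1), "ddH": round(c.ddH, 1),
                            "dU": round(c.dU, 1),
                            "affinity_ratio": round(c.affinity_ratio, 1),
                        })
            (out / "thermo_comparisons.json").write_text(
                json.dumps(comparisons, indent=2)
            )
            manifest["thermo_comparisons"] = "thermo_comparisons.json"
            summary["thermo_comparisons"] = comparisons

        _save("energetics", _energetics_stage)

    provenance = {
        "tool": "ligandcloud",
        "version": __version__,
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in vars(config).items()
            if not isinstance(v, Path)
        },
    }
    report = Report(out, manifest, provenance, summary)
    report.save()
    return report


def render_report(report: Report) -> str:
    """Render a deterministic markdown summary of a completed run.

    Missing manifest entries are an error listing the absent files.
    """
    missing = [
        name for name, rel in report.manifest.items()
        if not (Path(report.output_dir) / rel).exists()
    ]
    if missing:
        raise ConfigurationError(f"manifest entries missing on disk: {missing}")

    lines = ["# ligandcloud report", ""]
    s = report.summary_data
    if "sites" in s:
        lines.append("## Binding sites (by dSASA binding-time percentage)")
        if s["sites"]:
            for site in s["sites"]:
                lines.append(
                    f"- rank {site['rank']}: residues {site['start']}-{site['end']}"
                    f" (mean {site['mean_pct']}%)"
                )
        else:
            lines.append("- no sites above threshold")
        lines.append("")
    if "top_clusters_pct" in s:
        lines.append("## Conformational clusters")
        pops = ", ".join(f"{p:.1f}%" for p in s["top_clusters_pct"])
        lines.append(f"- top cluster populations: {pops}")
        lines.append(f"- cumulative top-8 occupancy: {s['cumulative_top8_pct']}%")
        lines.append("")
    if "rg_mean" in s:
        lines.append("## Chain dimensions and secondary structure")
        lines.append(f"- mean radius of gyration: {s['rg_mean']} +/- {s['rg_sd']} A")
        if "helix_pct" in s:
            lines.append(f"- mean helix content: {s['helix_pct']}%")
        lines.append("")
    if "thermo_comparisons" in s:
        lines.append("## Thermodynamic comparisons")
        for c in s["thermo_comparisons"]:
            lines.append(
                f"- {c['a']} vs {c['b']}: ddG {c['ddG']}, ddH {c['ddH']}, "
                f"dU {c['dU']} kcal/mol; affinity ratio {c['affinity_ratio']}"
            )
        lines.append("")
    return "\n".join(lines)
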
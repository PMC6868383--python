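"""Configuration-driven orchestration of the full analysis over many systems.

Stages: (1) load or synthesize per-system ensembles; (2) per-frame carbonyl
exposure under one shared normalization; (3) master-ensemble construction
(2' and 3' systems joined separately on the cluster backbone, subsampled) and
greedy clustering at 0.5 A; (4) per-system state assignment against the top
two cluster centers at 1.5 A; (5) COG contact profiles; (6) assembly of the
cross-system table and the correlation / multiple-regression / PRE layer.

All outputs are TSV/CSV/JSON with a provenance header (version, parameters,
seed); reruns with the same config and seed are byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core_io import (
    AtomRecord,
    Ensemble,
    SystemDescriptor,
    Topology,
    read_multimodel_pdb,
    select,
    subsample,
    write_ensemble,
)
from .conformers import (
    DEFAULT_ASSIGN_CUTOFF,
    DEFAULT_CLUSTER_CUTOFF,
    assign_states,
    gromos_cluster,
)
from .geometry import kabsch_superpose
from .interactions import CONTACT_CUTOFF, STACK_CUTOFF, contact_profile
from .sasa import DEFAULT_NORMALIZATION, RadiiTable, carbonyl_exposure_many
from .stats import PREDICTOR_ORDER, build_system_table, correlation_screen, ols
from .synth import SynthSpec, build_templates, generate_ensemble

logger = logging.getLogger("triacyl")

__all__ = ["RunConfig", "SystemEntry", "run_pipeline", "load_config"]


@dataclass
class SystemEntry:
    """One system: a multi-model PDB path or a synthetic mixture spec."""

    system: SystemDescriptor
    pdb_path: str | None = None
    synth: SynthSpec | None = None

    def __post_init__(self) -> None:
        if (self.pdb_path is None) == (self.synth is None):
            raise ValueError("each system entry needs exactly one of pdb_path or synth")


@dataclass
class RunConfig:
    systems: list[SystemEntry] = field(default_factory=list)
    cluster_cutoff: float = DEFAULT_CLUSTER_CUTOFF
    assign_cutoff: float = DEFAULT_ASSIGN_CUTOFF
    stack_cutoff: float = STACK_CUTOFF
    contact_cutoff: float = CONTACT_CUTOFF
    probe_radius: float = 1.4
    n_sphere_points: int = 196
    normalization: float | str = DEFAULT_NORMALIZATION
    master_stride: int = 1
    annotations: str | None = None
    outdir: str = "triacyl_out"
    seed: int = 0
    verbosity: int = 1

    def validate(self) -> None:
        for name in ("cluster_cutoff", "assign_cutoff", "stack_cutoff",
                     "contact_cutoff"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.probe_radius < 0:
            raise ValueError("probe_radius must be >= 0")
        if self.n_sphere_points < 12:
            raise ValueError("n_sphere_points must be >= 12")
        if self.master_stride < 1:
            raise ValueError("master_stride must be >= 1")
        if not isinstance(self.normalization, str) and self.normalization <= 0:
            raise ValueError("normalization constant must be > 0")
        if not self.systems:
            raise ValueError("config lists no systems")


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML/JSON run configuration."""
    raw = yaml.safe_load(Path(path).read_text())
    entries = []
    for item in raw.pop("systems", []):
        system = SystemDescriptor(**item["system"])
        synth_spec = item.get("synth")
        entries.append(
            SystemEntry(
                system=system,
                pdb_path=item.get("pdb_path"),
                synth=SynthSpec(
                    weights=tuple(synth_spec["weights"]),
                    jitter_sigma=synth_spec.get("jitter_sigma", 0.3),
                    n_frames=synth_spec.get("n_frames", 500),
                    seed=synth_spec.get("seed", 0),
                    rigid_scramble=synth_spec.get("rigid_scramble", False),
                )
                if synth_spec
                else None,
            )
        )
    return RunConfig(systems=entries, **raw)


def _provenance(config: RunConfig) -> str:
    params = {
        k: v for k, v in asdict(config).items() if k not in ("systems", "outdir")
    }
    return f"# triacyl {__version__} | seed={config.seed} | params={json.dumps(params, sort_keys=True)}\n"


def _write_table(df: pd.DataFrame, path: Path, header: str, sep: str = "\t") -> None:
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, sep=sep, index=False, float_format="%.6g")


def _backbone_topology(source: Ensemble, atoms: list[int]) -> Topology:
    """Reduced topology for a backbone-only master ensemble."""
    records = [source.topology.atoms[i] for i in atoms]
    nuc = [k for k, i in enumerate(atoms) if i in set(source.topology.groups["nuc_backbone"])]
    aa = [k for k, i in enumerate(atoms) if i in set(source.topology.groups["aa_backbone"])]
    groups = {
        "nuc_backbone": nuc, "aa_backbone": aa,
        "base1": [], "base2": [], "base3": [], "sidechain": [], "carbonyl": [],
    }
    return Topology(records, groups, source.topology.system)


def _load_systems(config: RunConfig) -> tuple[list[Ensemble], list[np.ndarray | None]]:
    ensembles, truths = [], []
    for entry in config.systems:
        label = entry.system.label()
        if entry.pdb_path is not None:
            logger.info("loading %s from %s", label, entry.pdb_path)
            ensembles.append(read_multimodel_pdb(entry.pdb_path, system=entry.system))
            truths.append(None)
        else:
            logger.info("synthesizing %s (%d frames)", label, entry.synth.n_frames)
            templates = build_templates(entry.system)
            ens, labels = generate_ensemble(templates, entry.synth)
            ensembles.append(ens)
            truths.append(labels)
    return ensembles, truths


def _master_cluster(
    config: RunConfig, ensembles: list[Ensemble], attachment: str, outdir: Path, header: str
):
    """Join one attachment class on the cluster backbone and cluster it."""
    members = [
        (i, e) for i, (entry, e) in enumerate(zip(config.systems, ensembles))
        if entry.system.attachment == attachment
    ]
    if len(members) == 0:
        return None
    coords, origin = [], []
    topo = None
    for i, ens in members:
        atoms = select(ens, "cluster_backbone")
        sub = subsample(ens, config.master_stride)
        coords.append(sub.coords[:, atoms, :])
        origin.extend((i, f * config.master_stride) for f in range(sub.n_frames))
        if topo is None:
            topo = _backbone_topology(ens, atoms)
    master = Ensemble(topology=topo, coords=np.concatenate(coords, axis=0))
    if master.n_frames < 2:
        return None
    result = gromos_cluster(master, np.arange(master.n_atoms), config.cluster_cutoff)
    report = pd.DataFrame(
        {
            "rank": np.arange(len(result.clusters)),
            "size": result.sizes,
            "fraction": np.asarray(result.sizes) / master.n_frames,
            "center_system": [origin[c.center_frame][0] for c in result.clusters],
            "center_frame": [origin[c.center_frame][1] for c in result.clusters],
            "middle_system": [origin[c.middle_frame][0] for c in result.clusters],
            "middle_frame": [origin[c.middle_frame][1] for c in result.clusters],
        }
    )
    _write_table(report, outdir / f"clusters_{attachment}.tsv", header)
    centers = [master.coords[c.middle_frame] for c in result.clusters[:2]]
    for rank, center in enumerate(centers):
        ref = Ensemble(topology=topo, coords=center[None])
        write_ensemble(ref, outdir / f"center_{attachment}_rank{rank}.pdb")
    return master, result, centers


def _identify_states(
    centers: list[np.ndarray], entry: SystemEntry, master_topology: Topology
) -> tuple[np.ndarray, np.ndarray]:
    """Map the two top cluster centers onto (collapsed, extended) references.

    For synthetic systems the generator templates disambiguate which center
    is which; for externally supplied ensembles the most populated cluster is
    taken as collapsed (the dominant state).
    """
    if entry.synth is None:
        return centers[0], centers[1]
    templates = build_templates(entry.system)
    bb = templates.backbone_atoms
    d_col = [kabsch_superpose(templates.collapsed[bb], c).rmsd for c in centers]
    d_ext = [kabsch_superpose(templates.extended[bb], c).rmsd for c in centers]
    if d_col[0] + d_ext[1] <= d_col[1] + d_ext[0]:
        return centers[0], centers[1]
    return centers[1], centers[0]


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute all stages and write the report bundle to ``config.outdir``.

    Returns a summary dictionary (system table, correlation frame, regression
    results and output paths).  Any stage failure aborts with the system and
    stage named; a MANIFEST file in the output directory records which
    outputs were completed.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    header = _provenance(config)
    manifest: list[str] = []
    log_lines: list[str] = []

    def done(name: str) -> None:
        manifest.append(name)
        (outdir / "MANIFEST").write_text("".join(f"{m}\n" for m in manifest))

    stage = "load"
    try:
        ensembles, truths = _load_systems(config)
        done("systems loaded")

        stage = "exposure"
        acylated = [
            (i, e) for i, e in enumerate(ensembles)
            if e.topology.system.is_aminoacylated
        ]
        radii = RadiiTable(
            probe_radius=config.probe_radius, n_sphere_points=config.n_sphere_points
        )
        exposures = dict(
            zip(
                [i for i, _ in acylated],
                carbonyl_exposure_many(
                    [e for _, e in acylated], radii, config.normalization
                ),
            )
        )
        for i, series in exposures.items():
            label = config.systems[i].system.label()
            df = pd.DataFrame(
                {
                    "frame": np.arange(series.carbonyl_sasa.size),
                    "carbonyl_sasa_A2": series.carbonyl_sasa,
                    "relative_exposure": series.relative_exposure,
                }
            )
            _write_table(df, outdir / f"exposure_{label}.tsv", header)
            if series.n_exceeding_unity:
                log_lines.append(
                    f"WARNING {label}: {series.n_exceeding_unity} frames exceed "
                    "relative exposure 1.0 under the fixed normalization"
                )
        done("exposure series")

        stage = "master clustering"
        masters = {}
        for attachment in ("2p", "3p"):
            built = _master_cluster(config, ensembles, attachment, outdir, header)
            if built is not None:
                masters[attachment] = built
        done("master clustering")

        stage = "state assignment"
        assignments = {}
        for i, (entry, ens) in enumerate(zip(config.systems, ensembles)):
            att = entry.system.attachment
            if att not in masters:
                continue
            _, _, centers = masters[att]
            if len(centers) < 2:
                log_lines.append(
                    f"WARNING {entry.system.label()}: fewer than 2 master clusters; "
                    "state assignment skipped"
                )
                continue
            collapsed_ref, extended_ref = _identify_states(
                centers, entry, masters[att][0].topology
            )
            atoms = select(ens, "cluster_backbone")
            assignment = assign_states(
                ens, collapsed_ref, extended_ref, atoms, config.assign_cutoff
            )
            assignments[i] = assignment
            label = entry.system.label()
            df = pd.DataFrame(
                {
                    "frame": np.arange(ens.n_frames),
                    "label": assignment.labels,
                    "rmsd_to_collapsed": assignment.rmsd_to_collapsed,
                    "rmsd_to_extended": assignment.rmsd_to_extended,
                }
            )
            _write_table(df, outdir / f"assignment_{label}.tsv", header)
        done("state assignment")

        stage = "contact profiles"
        profiles = {i: contact_profile(e, config.stack_cutoff, config.contact_cutoff)
                    for i, e in enumerate(ensembles)}
        done("contact profiles")

        stage = "system table"
        records = []
        n_undefined_preference = 0
        for i, entry in enumerate(config.systems):
            desc = entry.system
            record: dict[str, Any] = {
                "triplet": desc.triplet,
                "amino_acid": desc.amino_acid,
                "attachment": desc.attachment,
                "chirality": desc.chirality,
                "is_cca": desc.triplet == "CCA",
                "mean_relative_exposure": (
                    exposures[i].mean_relative_exposure if i in exposures else np.nan
                ),
            }
            if i in assignments:
                a = assignments[i]
                record.update(
                    f_collapsed=a.f_collapsed,
                    f_extended=a.f_extended,
                    f_other=a.f_other,
                    preference=a.preference,
                )
                if not a.preference_defined:
                    n_undefined_preference += 1
            for key, value in profiles[i].as_dict().items():
                record[key] = np.nan if value is None else value
            records.append(record)
        table = build_system_table(records)
        if config.annotations:
            annot = pd.read_csv(config.annotations)
            table = table.merge(
                annot, how="left",
                on=[c for c in ("triplet", "amino_acid", "attachment", "chirality")
                    if c in annot.columns],
            )
        if n_undefined_preference:
            log_lines.append(
                f"INFO: {n_undefined_preference} systems with undefined preference "
                "(zero occupancy) excluded from preference-based statistics"
            )
        _write_table(table, outdir / "system_table.csv", header, sep=",")
        done("system table")

        stage = "statistics"
        predictors = [p for p in PREDICTOR_ORDER if p in table.columns]
        stats_out: dict[str, Any] = {}
        screen = None
        if "mean_relative_exposure" in table.columns:
            screen = correlation_screen(
                table, "mean_relative_exposure", predictors, strata="attachment"
            )
            _write_table(screen, outdir / "correlations.tsv", header)
        usable = table.dropna(subset=["mean_relative_exposure"] + predictors)
        if len(usable) > len(predictors) + 2:
            x = usable[predictors].to_numpy()
            try:
                fit = ols(x, usable["mean_relative_exposure"].to_numpy(), compute_pre=True)
                stats_out["exposure_regression"] = {
                    "coefficients": dict(
                        zip(["intercept", *predictors], fit.coefficients.tolist())
                    ),
                    "r_squared": fit.r_squared,
                    "f_statistic": fit.f_statistic,
                    "f_p_value": fit.f_p_value,
                    "pre": {predictors[j]: v for j, v in fit.pre.items()},
                    "n": int(len(usable)),
                }
            except ValueError as exc:
                log_lines.append(f"WARNING: exposure regression skipped ({exc})")
        with open(outdir / "report.json", "w") as fh:
            json.dump(stats_out, fh, indent=2, sort_keys=True)
        done("statistics")
    except Exception as exc:
        log_lines.append(f"ERROR in stage '{stage}': {exc}")
        (outdir / "run.log").write_text(header + "".join(f"{l}\n" for l in log_lines))
        raise RuntimeError(f"pipeline failed in stage '{stage}': {exc}") from exc

    (outdir / "run.log").write_text(header + "".join(f"{l}\n" for l in log_lines))
    done("run complete")
    return {
        "system_table": table,
        "correlations": screen,
        "statistics": stats_out,
        "outdir": str(outdir),
    }
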
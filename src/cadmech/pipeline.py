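"""End-to-end orchestration: run the analysis stages from one config.

A run config is a YAML mapping.  Each stage either reads an input path or
consumes the artifact of the ``generate`` stage; a referenced path that
does not exist and has no generator block is a validation error raised
before any stage runs.  All randomness flows from the single config seed.
The report is deterministic for a fixed config and seed (no timestamps).
"""

from __future__ import annotations

import json
import logging
from importlib.metadata import version as _pkg_version
from pathlib import Path

import numpy as np
import yaml

from . import force_curves as fc
from . import geometry as geo
from . import io_formats as iof
from . import linker_motifs as lm
from . import mech_model as mm
from . import synthetic_data as syn

__all__ = ["RunConfig", "StageError", "load_config", "run_report"]

log = logging.getLogger("cadmech")

_STAGES = ("generate", "scan_motifs", "geometry", "forcecurve", "mechmodel")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


class RunConfig:
    """Validated run configuration."""

    def __init__(self, data: dict):
        if not isinstance(data, dict):
            raise ValueError("config must be a mapping")
        self.data = data
        self.seed = int(data.get("seed", 0))
        self.stages = list(data.get("stages", _STAGES))
        unknown = [s for s in self.stages if s not in _STAGES]
        if unknown:
            raise ValueError(f"unknown stage(s) {unknown}; known: {list(_STAGES)}")
        self.inputs = dict(data.get("inputs", {}))
        self.generate = dict(data.get("generate", {}))
        self.validate()

    def validate(self) -> None:
        """Every referenced input path must exist, or a generator block
        must be able to supply the artifact."""
        for key, path in self.inputs.items():
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(
                    f"input {key!r}: path {path} does not exist and no generator supplies it"
                )
        needs = {
            "scan_motifs": "sequences",
            "geometry": "structure",
            "forcecurve": "force_trace",
        }
        for stage, artifact in needs.items():
            if stage in self.stages and artifact not in self.inputs and artifact not in self.generate:
                raise ValueError(
                    f"stage {stage!r} needs input {artifact!r}: give a path under 'inputs' "
                    "or a generator block under 'generate'"
                )


def load_config(path: str | Path) -> RunConfig:
    return RunConfig(yaml.safe_load(Path(path).read_text()))


def _stage_generate(cfg: RunConfig, outdir: Path, report: dict) -> dict:
    artifacts: dict = {}
    summary: dict = {}
    if "structure" in cfg.generate:
        kw = dict(cfg.generate["structure"])
        kw.setdefault("seed", cfg.seed)
        if "ca_spacings" in kw:
            kw["ca_spacings"] = tuple(kw["ca_spacings"])
        structure, truth = syn.gen_two_domain_structure(**kw)
        path = outdir / "structure.pdb"
        iof.write_structure(structure, path)
        truth.to_json(outdir / "structure.truth.json")
        artifacts["structure"] = (structure, truth, path)
        summary["structure_atoms"] = len(structure)
    if "trajectory" in cfg.generate:
        kw = dict(cfg.generate["trajectory"])
        kw.setdefault("seed", cfg.seed)
        traj, truth = syn.gen_domain_trajectory(**kw)
        path = outdir / "trajectory.pdb"
        iof.write_trajectory(traj, path)
        truth.to_json(outdir / "trajectory.truth.json")
        artifacts["trajectory"] = (traj, truth, path)
        summary["trajectory_frames"] = len(traj)
    if "force_trace" in cfg.generate:
        kw = dict(cfg.generate["force_trace"])
        kw.setdefault("seed", cfg.seed)
        if "peaks" in kw:
            kw["peaks"] = [tuple(p) for p in kw["peaks"]]
        trace, truth = syn.gen_force_trace(**kw)
        path = outdir / "force_trace.tsv"
        iof.write_force_trace(trace, path)
        truth.to_json(outdir / "force_trace.truth.json")
        artifacts["force_trace"] = (trace, truth, path)
        summary["force_trace_points"] = len(trace)
    if "sequences" in cfg.generate:
        kw = dict(cfg.generate["sequences"])
        kw.setdefault("seed", cfg.seed)
        if "class_mix" in kw:
            kw["class_mix"] = tuple(kw["class_mix"])
        seqs, truth = syn.gen_linker_sequences(**kw)
        path = outdir / "sequences.fasta"
        iof.write_fasta(seqs, path)
        truth.to_json(outdir / "sequences.truth.json")
        artifacts["sequences"] = (seqs, truth, path)
        summary["n_sequences"] = len(seqs)
    report["generate"] = {"status": "ok", **summary}
    return artifacts


def _stage_scan_motifs(cfg: RunConfig, outdir: Path, report: dict, artifacts: dict) -> None:
    if "sequences" in artifacts:
        seqs, truth, _ = artifacts["sequences"]
        boundary = truth.labels["boundary"]
        truth_records = truth.labels["records"]
    else:
        seqs = iof.read_fasta(cfg.inputs["sequences"])
        boundary = int(cfg.data.get("scan_motifs", {}).get("boundary", 100))
        truth_records = None
    annotations = lm.scan_fasta_pairs(seqs, boundary)
    rows = ["id\tlinker_class\tn_intact\tpredicted_sites\t" + "\t".join(
        m.name for m in lm.DEFAULT_MOTIFS)]
    counts: dict[str, int] = {}
    n_correct = 0
    for rid, ann in annotations.items():
        counts[ann.linker_class] = counts.get(ann.linker_class, 0) + 1
        if truth_records is not None and truth_records[rid]["linker_class"] == ann.linker_class:
            n_correct += 1
        rows.append(
            f"{rid}\t{ann.linker_class}\t{ann.n_intact}\t{ann.predicted_sites}\t"
            + "\t".join(ann.motifs[m.name].status for m in lm.DEFAULT_MOTIFS)
        )
    (outdir / "motif_report.tsv").write_text("\n".join(rows) + "\n")
    summary = {"status": "ok", "class_counts": counts}
    if truth_records is not None and annotations:
        summary["accuracy_vs_truth"] = n_correct / len(annotations)
    report["scan_motifs"] = summary


def _stage_geometry(cfg: RunConfig, outdir: Path, report: dict, artifacts: dict) -> None:
    opts = dict(cfg.data.get("geometry", {}))
    if "structure" in artifacts:
        structure, truth, _ = artifacts["structure"]
        doms = {
            k: iof.DomainDefinition(**v) for k, v in truth.labels["domains"].items()
        }
        dom_a, dom_b = doms["domain1"], doms["domain2"]
        linker = (doms["linker"].first_residue, doms["linker"].last_residue)
    else:
        structure = iof.read_structure(cfg.inputs["structure"])
        table = opts.get("domains")
        if table:
            defs = [iof.DomainDefinition(**d) for d in table]
            iof.check_domains_disjoint(defs)
            dom_a, dom_b = defs[0], defs[1]
        else:
            chain = structure.chains()[0]
            d = geo.pcdh15_domains(chain)
            dom_a, dom_b = d["EC9"], d["EC10"]
        linker = tuple(opts.get("linker", geo.PCDH15_LINKERS["EC8-9"]))
    summary: dict = {"status": "ok"}
    summary["bend_angle_deg"] = geo.bend_angle(structure, dom_a, dom_b)
    sites = geo.locate_ca_sites(structure, linker)
    summary["n_ca_sites"] = sites.n_sites
    summary["d23_A"] = sites.d23
    summary["radius_of_gyration_A"] = geo.radius_of_gyration(structure)
    if opts.get("buried_surface", True):
        bsa = geo.buried_surface(structure, dom_a, dom_b)
        summary["bsa_A2"] = bsa["bsa"]
        summary["n_interface_residues"] = len(bsa["interface_residues"])
    report["geometry"] = summary


def _stage_forcecurve(cfg: RunConfig, outdir: Path, report: dict, artifacts: dict) -> None:
    opts = dict(cfg.data.get("forcecurve", {}))
    if "force_trace" in artifacts:
        trace, _, _ = artifacts["force_trace"]
    else:
        trace = iof.read_force_trace(cfg.inputs["force_trace"])
    smoothed, binned = fc.smooth_and_bin(
        trace,
        window_ps=float(opts.get("window_ps", 50.0)),
        bin_width_a=float(opts.get("bin_width_a", 1.0)),
    )
    fit = fc.segment_phases_fit(binned.extension, binned.mean)
    peaks = fc.detect_force_peaks(smoothed, prominence=float(opts.get("prominence", 50.0)))
    fit_dict = {
        "breakpoint_nm": fit.breakpoint_extension,
        "k_phase1_mN_m": fit.k_phase1,
        "k_phase2_mN_m": fit.k_phase2,
        "single_phase": fit.single_phase,
    }
    (outdir / "phase_fit.json").write_text(json.dumps(fit_dict, indent=2) + "\n")
    report["forcecurve"] = {
        "status": "ok",
        **fit_dict,
        "n_peaks": len(peaks),
        "max_peak_force_pN": max((p.height for p in peaks), default=None),
    }


def _stage_mechmodel(cfg: RunConfig, outdir: Path, report: dict) -> None:
    opts = dict(cfg.data.get("mechmodel", {}))
    linker = mm.ThreeStateLinker(**opts.get("linker", {}))
    segments = [mm.Segment(**s) for s in opts.get("segments", [{}, {}, {}])]
    n_strands = int(opts.get("n_strands", 1))
    model = mm.MechModel(segments=segments, linkers=[linker], n_strands=n_strands)
    forces = np.asarray(opts.get("forces_pN", [0, 5, 10, 15, 20, 25, 30, 40, 50]), dtype=float)
    ext = mm.quasistatic_force_extension(model, forces)
    gillespie_force = float(opts.get("gillespie_force_pN", 25.0))
    gillespie_ns = float(opts.get("gillespie_duration_ns", 2000.0))
    traj = mm.gillespie_constant_force(model, gillespie_force, gillespie_ns, seed=cfg.seed)
    summary = {
        "status": "ok",
        "chain_stiffness_mN_m": model.chain_stiffness,
        "dimer_phase1_bound_mN_m": mm.compose_stiffness([8.4], n_strands=2),
        "quasistatic_extension_nm": {float(f): float(e) for f, e in zip(forces, ext)},
        "gillespie_occupancy": traj.occupancy().tolist(),
        "unbending_extension_nm": mm.geometric_extension(
            [s.length for s in segments], [0.0, 90.0][: len(segments) - 1],
            [0.0, 0.0][: len(segments) - 1],
        ),
    }
    (outdir / "mechmodel_summary.json").write_text(json.dumps(summary, indent=2) + "\n")
    report["mechmodel"] = summary


def run_report(config: RunConfig, outdir: str | Path) -> dict:
    """Execute the configured stages in dependency order and write
    ``report.json``.  A stage failure is logged with the stage name, the
    run halts, and partial artifacts are retained."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "package": "cadmech",
        "version": _pkg_version("cadmech"),
        "seed": config.seed,
        "stages": config.stages,
    }
    artifacts: dict = {}
    runners = {
        "generate": lambda: artifacts.update(_stage_generate(config, outdir, report)),
        "scan_motifs": lambda: _stage_scan_motifs(config, outdir, report, artifacts),
        "geometry": lambda: _stage_geometry(config, outdir, report, artifacts),
        "forcecurve": lambda: _stage_forcecurve(config, outdir, report, artifacts),
        "mechmodel": lambda: _stage_mechmodel(config, outdir, report),
    }
    for stage in _STAGES:
        if stage not in config.stages:
            continue
        log.info("running stage %s", stage)
        try:
            runners[stage]()
        except Exception as exc:
            log.error("stage %s failed: %s", stage, exc)
            report[stage] = {"status": "error", "error": str(exc)}
            (outdir / "report.json").write_text(json.dumps(report, indent=2) + "\n")
            raise StageError(stage, exc) from exc
    (outdir / "report.json").write_text(json.dumps(report, indent=2) + "\n")
    return report
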
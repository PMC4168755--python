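"""End-to-end orchestration: run the analysis stages from a YAML config.

Stage order follows the experimental logic: secondary shifts -> PRE
restraints -> dynamics -> amphiphilicity -> topology reconstruction ->
ensemble analysis.  Every numeric in the run report is reproducible from
the config plus inputs; seeds are explicit and the config hash is recorded.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import yaml

from . import amphiphilicity as amph
from . import io_formats as iof
from . import pre_restraints as prem
from . import relaxation_dynamics as dyn
from . import shift_analysis as shifts_mod
from . import topology_ensemble as topo

logger = logging.getLogger(__name__)

STAGES = ("shifts", "pre", "dynamics", "amphi", "reconstruct", "ensemble")


@dataclass
class PipelineConfig:
    """All stage parameters with defaults; round-trips through YAML."""

    input_dir: str = "."
    out_dir: str = "results"
    seed: int = 0
    stages: list[str] = field(default_factory=lambda: list(STAGES))

    # shift stage
    shift_table: str = "shifts_micelle.tsv"
    helix_threshold: float = shifts_mod.DEFAULT_HELIX_THRESHOLD
    helix_min_len: int = shifts_mod.DEFAULT_MIN_LEN
    helix_max_gap: int = shifts_mod.DEFAULT_MAX_GAP

    # PRE stage
    pre_glob: str = "pre_site*.tsv"
    r2_dia: float = 20.0
    t_inept: float = 0.010
    tau_c: float = 15e-9
    spectrometer_mhz: float = 800.0
    ratio_cutoff: float = 0.85
    vanish_cutoff: float = 0.15
    bound_width: float = 4.0

    # dynamics stage
    hnoe_table: str = "hnoe_micelle.tsv"
    cpmg_table: str = "cpmg.tsv"
    titration_table: str = "titration.tsv"
    flag_moderate: float = dyn.DEFAULT_FLAG_MODERATE
    flag_strong: float = dyn.DEFAULT_FLAG_STRONG
    access_cutoff: float = dyn.DEFAULT_ACCESS_CUTOFF

    # amphiphilicity stage
    fasta: str = "sequence.fasta"
    tm_scale: str = "biological_tm"
    moment_scale: str = "eisenberg_consensus"
    tm_window: int = amph.DEFAULT_TM_WINDOW
    moment_window: int = amph.DEFAULT_MOMENT_WINDOW
    mu_threshold: float = amph.DEFAULT_MU_THRESHOLD

    # reconstruction stage
    n_restarts: int = 6
    n_models: int = 5

    # ensemble stage
    ensemble_pdb: str = ""
    helix_selection: str = ""     # e.g. "3-7,22-30,90-94,98-107,116-125"
    rmsd_convention: str = "to_mean"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    def content_hash(self) -> str:
        blob = yaml.safe_dump(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def pre_params(self) -> prem.PREParams:
        import math
        return prem.PREParams(
            r2_dia=self.r2_dia, t_inept=self.t_inept, tau_c=self.tau_c,
            omega_h=2 * math.pi * self.spectrometer_mhz * 1e6,
            ratio_cutoff=self.ratio_cutoff, vanish_cutoff=self.vanish_cutoff,
            bound_width=self.bound_width,
        )


@dataclass
class RunReport:
    config_hash: str
    seed: int
    completed_stages: list[str] = field(default_factory=list)
    values: dict[str, Any] = field(default_factory=dict)

    def flat(self) -> dict[str, Any]:
        out = {"config_hash": self.config_hash, "seed": self.seed,
               "completed_stages": ",".join(self.completed_stages)}
        out.update(self.values)
        return out

    def write(self, path) -> None:
        with open(path, "w") as fh:
            for key, value in sorted(self.flat().items()):
                fh.write(f"{key}\t{value}\n")


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute the enabled stages in order and write all stage outputs.

    A failing stage aborts with an error naming the completed stages.
    Identical config and inputs give a bit-identical report.
    """
    unknown = set(config.stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    in_dir = Path(config.input_dir)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report = RunReport(config_hash=config.content_hash(), seed=config.seed)

    # fail early on missing inputs for the enabled stages
    needed = {
        "shifts": [config.shift_table],
        "dynamics": [config.hnoe_table, config.cpmg_table, config.titration_table],
        "amphi": [config.fasta],
        "ensemble": [config.ensemble_pdb] if config.ensemble_pdb else [],
    }
    for stage in config.stages:
        for rel in needed.get(stage, []):
            if rel and not (in_dir / rel).exists():
                raise FileNotFoundError(f"stage {stage!r}: missing input {in_dir / rel}")
    if "pre" in config.stages and not sorted(in_dir.glob(config.pre_glob)):
        raise FileNotFoundError(f"stage 'pre': no files match {config.pre_glob}")

    helices: list[shifts_mod.HelixSegment] = []
    restraints: list[iof.PRERestraint] = []
    try:
        if "shifts" in config.stages:
            helices = _stage_shifts(config, in_dir, out_dir, report)
        if "pre" in config.stages:
            restraints = _stage_pre(config, in_dir, out_dir, report)
        if "dynamics" in config.stages:
            _stage_dynamics(config, in_dir, out_dir, report)
        if "amphi" in config.stages:
            _stage_amphi(config, in_dir, out_dir, report)
        if "reconstruct" in config.stages:
            _stage_reconstruct(config, out_dir, report, restraints, helices)
        if "ensemble" in config.stages:
            _stage_ensemble(config, in_dir, out_dir, report)
    except Exception as exc:
        raise RuntimeError(
            f"pipeline aborted after stages {report.completed_stages}: {exc}"
        ) from exc
    report.write(out_dir / "summary.tsv")
    config.to_yaml(out_dir / "config_used.yaml")
    return report


def _stage_shifts(config, in_dir, out_dir, report):
    table = iof.read_shift_table(in_dir / config.shift_table)
    profile = shifts_mod.secondary_shifts(table)
    segments = shifts_mod.call_helices(
        profile, config.helix_threshold, config.helix_min_len, config.helix_max_gap)
    shifts_mod.write_profile_tsv(profile, segments, out_dir / "secondary_shifts.tsv")
    shifts_mod.write_segments_tsv(segments, out_dir / "helix_segments.tsv")
    report.values["shifts.n_helices"] = len(segments)
    report.values["shifts.segments"] = ";".join(f"{s.start}-{s.end}" for s in segments)
    report.values["shifts.reference_set"] = profile.reference_set_name
    report.completed_stages.append("shifts")
    return segments


def _stage_pre(config, in_dir, out_dir, report):
    params = config.pre_params()
    all_restraints = []
    for path in sorted(in_dir.glob(config.pre_glob)):
        pairs = iof.read_peak_pairs(path)
        site_index = int("".join(ch for ch in path.stem if ch.isdigit()))
        aa = next((p.residue.aa for p in pairs if p.residue.index == site_index), "X")
        site = iof.SpinLabelSite(iof.ResidueId(site_index, aa))
        meas = prem.classify_pairs(pairs, site, params)
        restraints, qc = prem.build_restraints(meas, params)
        all_restraints.extend(restraints)
        for klass, count in sorted(qc.counts.items()):
            report.values[f"pre.site{site_index}.{klass}"] = count
    writable = [r for r in all_restraints if r.klass != "unrestrained"]
    if writable:
        iof.write_distance_restraints(writable, out_dir / "pre_restraints.tsv", "tsv")
        iof.write_distance_restraints(writable, out_dir / "pre_restraints.xplor", "xplor")
    report.values["pre.n_restraints"] = len(writable)
    report.values["pre.n_bounded"] = sum(1 for r in writable if r.klass == "bounded")
    report.values["pre.n_upper_only"] = sum(1 for r in writable if r.klass == "upper_only")
    report.completed_stages.append("pre")
    return all_restraints


def _read_hnoe_table(path):
    records = []
    with open(path) as fh:
        fh.readline()
        for line in fh:
            f = line.split()
            if f:
                records.append(dyn.HNOERecord(iof.ResidueId(int(f[0]), "X"),
                                              float(f[1]), float(f[2])))
    return records


def _read_titration_table(path):
    gado, mn = {}, {}
    with open(path) as fh:
        fh.readline()
        for line in fh:
            f = line.split()
            if not f:
                continue
            target = gado if f[1].lower().startswith("gado") else mn
            target[int(f[0])] = float(f[2])
    return gado, mn


def _stage_dynamics(config, in_dir, out_dir, report):
    from .synthetic_data import read_cpmg_table

    records = _read_hnoe_table(in_dir / config.hnoe_table)
    series = read_cpmg_table(in_dir / config.cpmg_table)
    profiles = [dyn.dispersion_profile(s, config.flag_moderate, config.flag_strong)
                for s in series]
    gado, mn = _read_titration_table(in_dir / config.titration_table)
    access = dyn.classify_accessibility(gado, mn, config.access_cutoff)
    dyn.write_dynamics_tsv(records, profiles, access, out_dir / "dynamics.tsv")
    values = [r.hnoe for r in records]
    report.values["dynamics.hnoe_mean"] = round(sum(values) / len(values), 4)
    for flag in ("none", "moderate", "strong"):
        report.values[f"dynamics.exchange_{flag}"] = sum(
            1 for p in profiles if p.exchange_flag == flag)
    for klass, count in sorted(dyn.accessibility_counts(access).items()):
        report.values[f"dynamics.access_{klass}"] = count
    report.completed_stages.append("dynamics")


def _stage_amphi(config, in_dir, out_dir, report):
    seqs = iof.read_fasta(in_dir / config.fasta)
    name, seq = next(iter(seqs.items()))
    tm_scale = amph.load_scale(config.tm_scale)
    mom_scale = amph.load_scale(config.moment_scale)
    tm_profile = amph.windowed_hydropathy(seq, tm_scale, config.tm_window)
    profile = amph.moment_profile(seq, mom_scale, config.moment_window)
    amph.write_profile_tsv(tm_profile, out_dir / "tm_profile.tsv")
    amph.write_profile_tsv(profile, out_dir / "moment_profile.tsv")
    segments = amph.detect_amphiphilic_segments(profile, config.mu_threshold)
    shifts_mod.write_segments_tsv(segments, out_dir / "amphiphilic_segments.tsv")
    report.values["amphi.sequence"] = name
    report.values["amphi.n_segments"] = len(segments)
    report.values["amphi.segments"] = ";".join(f"{s.start}-{s.end}" for s in segments)
    report.values["amphi.max_mu_per_res"] = round(float(profile.mu_h.max()), 4)
    report.values["amphi.tm_peak_position"] = int(
        tm_profile.positions[tm_profile.mean_h.argmax()])
    report.completed_stages.append("amphi")


def _stage_reconstruct(config, out_dir, report, restraints, helices):
    if not restraints:
        raise ValueError("reconstruction needs the 'pre' stage restraints")
    indices = sorted({r.residue.index for r in restraints}
                     | {r.site.residue.index for r in restraints})
    full = list(range(min(indices), max(indices) + 1))
    models = topo.reconstruct_topology(
        restraints, helices, full,
        n_restarts=config.n_restarts, n_models=config.n_models, seed=config.seed)
    iof.write_ca_models([m.coords for m in models], out_dir / "reconstructed_ca.pdb",
                        energies=[m.energy for m in models])
    best = models[0]
    violations = topo.restraint_violations(best, restraints)
    with open(out_dir / "violations.tsv", "w") as fh:
        fh.write("site\tresidue\tviolation\n")
        for r, v in violations.per_restraint:
            fh.write(f"{r.site.residue.index}\t{r.residue.index}\t{v:.3f}\n")
    report.values["reconstruct.n_models"] = len(models)
    report.values["reconstruct.best_energy"] = round(best.energy, 3)
    report.values["reconstruct.low_confidence"] = best.low_confidence
    report.values["reconstruct.violations"] = violations.n_violated
    report.values["reconstruct.violation_sum"] = round(violations.total_violation, 3)
    report.completed_stages.append("reconstruct")


def _stage_ensemble(config, in_dir, out_dir, report):
    if not config.ensemble_pdb:
        logger.info("no ensemble PDB configured; skipping ensemble stage")
        return
    ens = iof.read_ensemble(in_dir / config.ensemble_pdb)
    report.values["ensemble.n_models"] = ens.n_models
    if config.helix_selection:
        residues = topo.AtomSelection.from_ranges(config.helix_selection).residues
    else:
        residues = frozenset(ens.residue_indices())
    if ens.n_models >= 2:
        sel = topo.AtomSelection(residues, "backbone")
        for klass in ("backbone", "heavy", "all"):
            rmsd = topo.ensemble_rmsd(ens, sel, report_atoms=klass,
                                      convention=config.rmsd_convention)
            report.values[f"ensemble.rmsd_{klass}"] = round(rmsd, 3)
    else:
        logger.warning("single-model ensemble: RMSD statistics skipped")
    segs = topo.call_helices_geometric(
        {i: r.atoms["CA"] for i, r in ens.models[0].items() if "CA" in r.atoms})
    report.values["ensemble.geometric_helices"] = ";".join(
        f"{s.start}-{s.end}" for s in segs)
    report.completed_stages.append("ensemble")
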
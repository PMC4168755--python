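"""Forward models generating every pipeline input from a known ground truth.

The generator emulates the data-generating process of a micelle-embedded
helical bundle studied by solution NMR: a Calpha ground-truth structure
(ideal helices joined by random-coil loops), per-residue rigidity and
burial-depth classes, exchange parameters for a subset of residues, and
seven nitroxide spin-label sites.  Each ``simulate_*`` function produces
exactly the tables the analysis modules read, with stated noise models, and
is deterministic given its seed.  Noise-free closed loops through the
corresponding analysis operation are identities, which the test suite
exploits throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .io_formats import (
    ModelResidue,
    PeakPair,
    ResidueId,
    ShiftEntry,
    ShiftTable,
    SpinLabelSite,
    StructureEnsemble,
    write_ca_models,
    write_peak_pairs,
    write_shift_table,
)
from .pre_restraints import PREParams, r2sp_from_distance
from .relaxation_dynamics import HNOERecord, CPMGSeries
from .shift_analysis import HelixSegment, load_random_coil_refs
from .topology_ensemble import CaModel

HELIX_RISE = 1.5        # Angstrom per residue along the axis
HELIX_TWIST = 100.0     # degrees per residue
HELIX_RADIUS = 2.3      # Angstrom, Calpha radius of an ideal alpha-helix
CHAIN_STEP = 3.8        # Angstrom, consecutive Calpha distance

# the standard study: CPMG frequencies with the duplicated planes
DEFAULT_CPMG_NUS = (40.0, 80.0, 120.0, 120.0, 160.0, 200.0, 240.0, 320.0,
                    400.0, 480.0, 560.0, 640.0, 720.0, 800.0, 960.0, 960.0)
DEFAULT_T_CP = 0.050    # s

STUDY_HELICES = [HelixSegment(3, 7), HelixSegment(22, 30), HelixSegment(90, 94),
                 HelixSegment(98, 107), HelixSegment(116, 125)]
STUDY_LABEL_SITES = (6, 24, 53, 68, 89, 102, 121)


@dataclass
class GroundTruth:
    """Everything the forward models need: structure, classes, parameters."""

    structure: CaModel
    helices: list[HelixSegment]
    label_sites: list[SpinLabelSite]
    sequence: str
    rigidity: dict[int, str] = field(default_factory=dict)   # rigid | flexible
    depth: dict[int, str] = field(default_factory=dict)      # water_exposed | headgroup | buried_or_bonded
    exchange: dict[int, tuple[float, float, float]] = field(default_factory=dict)
    # residue -> (p_minor, delta_omega rad/s, k_ex s^-1)

    def __post_init__(self) -> None:
        n = len(self.structure.coords)
        for h in self.helices:
            if h.start < 1 or h.end > n:
                raise ValueError(f"helix {h} outside structure of {n} residues")
        for s in self.label_sites:
            if s.residue.index not in self.structure.coords:
                raise ValueError(f"label site {s.residue.index} outside structure")

    @property
    def n_residues(self) -> int:
        return len(self.structure.coords)

    def residue(self, index: int) -> ResidueId:
        return ResidueId(index, self.sequence[index - 1])


def _ideal_helix(n: int) -> np.ndarray:
    """Ideal alpha-helical Calpha trace along +z, centred on the axis."""
    k = np.arange(n)
    ang = np.deg2rad(HELIX_TWIST) * k
    return np.column_stack([
        HELIX_RADIUS * np.cos(ang),
        HELIX_RADIUS * np.sin(ang),
        HELIX_RISE * k,
    ])


def _guided_walk(start: np.ndarray, end: np.ndarray, n_steps: int,
                 rng: np.random.Generator) -> np.ndarray:
    """Random walk of fixed 3.8 A steps from start towards end.

    Returns the n_steps-1 intermediate points of a coil whose last generated
    point lands one chain step from ``end``.  The walk mixes a random
    direction with the direction to the target, weighting the target more
    as the remaining steps run out.
    """
    points = []
    pos = start.copy()
    for k in range(n_steps - 1):
        remaining = n_steps - k
        to_target = end - pos
        dist = np.linalg.norm(to_target)
        # weight pulls the walk in when slack runs out
        slack = remaining * CHAIN_STEP - dist
        w = float(np.clip(1.0 - slack / (4 * CHAIN_STEP), 0.1, 1.0))
        direction = w * to_target / max(dist, 1e-9) + (1 - w) * rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        pos = pos + CHAIN_STEP * direction
        points.append(pos.copy())
    return np.array(points) if points else np.zeros((0, 3))


def make_bundle(
    helix_segments: Sequence[HelixSegment],
    n_residues: int,
    seed: int = 0,
    bundle_radius: float = 8.5,
) -> CaModel:
    """Build a helical-bundle Calpha ground truth.

    Helices are ideal (rise 1.5 A, 100 degrees per residue); their axes sit
    on a circle of ``bundle_radius``, alternating up/down so consecutive
    helices run antiparallel; loops are guided random coils.  Deterministic
    per seed.  Overlapping segments raise an error.
    """
    segs = sorted(helix_segments, key=lambda s: s.start)
    for a, b in zip(segs, segs[1:]):
        if a.end >= b.start:
            raise ValueError(f"overlapping helix segments {a} and {b}")
    if segs and segs[-1].end > n_residues:
        raise ValueError("helix segment outside residue range")
    rng = np.random.default_rng(seed)
    coords: dict[int, np.ndarray] = {}
    n_h = len(segs)
    for k, seg in enumerate(segs):
        length = len(seg)
        trace = _ideal_helix(length)
        if k % 2 == 1:          # antiparallel: flip z (improper is fine for a truth)
            trace = trace * np.array([1.0, -1.0, -1.0])
            trace[:, 2] -= trace[-1, 2]
        ang = 2 * math.pi * k / max(n_h, 1)
        offset = np.array([bundle_radius * math.cos(ang),
                           bundle_radius * math.sin(ang), 0.0])
        trace = trace + offset
        for i, idx in enumerate(range(seg.start, seg.end + 1)):
            coords[idx] = trace[i]
    # loops and termini as guided walks between fixed helix ends
    if segs:
        first = segs[0]
        if first.start > 1:
            tail = _guided_walk(coords[first.start],
                                coords[first.start] + np.array([0, 0, CHAIN_STEP * first.start]),
                                first.start, rng)
            for i, idx in enumerate(range(first.start - 1, 0, -1)):
                coords[idx] = tail[i]
        for a, b in zip(segs, segs[1:]):
            n_gap = b.start - a.end
            walk = _guided_walk(coords[a.end], coords[b.start], n_gap, rng)
            for i, idx in enumerate(range(a.end + 1, b.start)):
                coords[idx] = walk[i]
        last = segs[-1]
        if last.end < n_residues:
            n_tail = n_residues - last.end
            target = coords[last.end] + np.array([0, 0, -CHAIN_STEP * (n_tail + 1)])
            walk = _guided_walk(coords[last.end], target, n_tail + 1, rng)
            for i, idx in enumerate(range(last.end + 1, n_residues + 1)):
                coords[idx] = walk[i]
    else:
        walk = _guided_walk(np.zeros(3), np.array([0, 0, CHAIN_STEP * n_residues]),
                            n_residues + 1, rng)
        for i in range(1, n_residues + 1):
            coords[i] = walk[i - 1] if i - 1 < len(walk) else walk[-1]
    helix_residues = {i for s in segs for i in range(s.start, s.end + 1)}
    _relax_loops(coords, helix_residues, n_residues)
    return CaModel({i: coords[i] for i in range(1, n_residues + 1)})


def _relax_loops(coords: dict[int, np.ndarray], fixed: set[int], n_residues: int,
                 n_iter: int = 200) -> None:
    """Iteratively regularize consecutive Calpha distances of non-helix
    residues towards 3.8 A, keeping helix coordinates fixed."""
    for _ in range(n_iter):
        worst = 0.0
        for i in range(1, n_residues):
            a, b = coords[i], coords[i + 1]
            diff = b - a
            d = float(np.linalg.norm(diff))
            err = d - CHAIN_STEP
            worst = max(worst, abs(err))
            if abs(err) < 0.05:
                continue
            corr = 0.5 * err * diff / max(d, 1e-9)
            if i not in fixed:
                coords[i] = a + corr
            if i + 1 not in fixed:
                coords[i + 1] = b - corr
        if worst < 0.1:
            break


def assign_depth_classes(structure: CaModel,
                         exposed_frac: float = 0.15,
                         headgroup_frac: float = 0.25) -> dict[int, str]:
    """Depth classes from the bundle geometry: the top of the bundle (largest
    z) is water-exposed, a band below it sits in the headgroup region, the
    rest is buried in the hydrocarbon phase."""
    idx = sorted(structure.coords)
    z = np.array([structure.coords[i][2] for i in idx])
    z_exposed = np.quantile(z, 1.0 - exposed_frac)
    z_head = np.quantile(z, 1.0 - exposed_frac - headgroup_frac)
    out = {}
    for i, zi in zip(idx, z):
        if zi >= z_exposed:
            out[i] = "water_exposed"
        elif zi >= z_head:
            out[i] = "headgroup"
        else:
            out[i] = "buried_or_bonded"
    return out


def study_truth(seed: int = 0, sequence: Optional[str] = None) -> GroundTruth:
    """The five-helix, 125-residue, seven-label study configuration.

    Helices 3-7, 22-30, 90-94, 98-107 and 116-125; spin labels at residues
    6, 24, 53, 68, 89, 102 and 121; exchange on loop residues 44-47
    (moderate) and 66-76 (strong); helical residues rigid, the long loop
    flexible.
    """
    if sequence is None:
        from .amphiphilicity import load_packaged_sequence
        sequence = load_packaged_sequence("vapb_p56s_synthetic")[:125]
    structure = make_bundle(STUDY_HELICES, 125, seed=seed)
    helical = {i for h in STUDY_HELICES for i in range(h.start, h.end + 1)}
    rigidity = {i: ("rigid" if i in helical else "flexible") for i in range(1, 126)}
    exchange = {}
    for i in range(44, 48):       # moderate exchange, dR2 a few s^-1
        exchange[i] = (0.03, 2 * math.pi * 250.0, 9000.0)
    for i in range(66, 77):       # strong exchange, dR2 well above 6 s^-1
        exchange[i] = (0.08, 2 * math.pi * 400.0, 8000.0)
    sites = [SpinLabelSite(ResidueId(i, sequence[i - 1])) for i in STUDY_LABEL_SITES]
    return GroundTruth(
        structure=structure,
        helices=list(STUDY_HELICES),
        label_sites=sites,
        sequence=sequence,
        rigidity=rigidity,
        depth=assign_depth_classes(structure),
        exchange=exchange,
    )


# ---------------------------------------------------------------------------
# Forward models
# ---------------------------------------------------------------------------

def forward_pre_ratio(distance: float, params: PREParams) -> float:
    """Distance -> expected paramagnetic/diamagnetic intensity ratio."""
    d = max(distance, 1e-3)
    r2sp = r2sp_from_distance(d, params)
    return params.r2_dia * math.exp(-r2sp * params.t_inept) / (params.r2_dia + r2sp)


def simulate_pre(
    truth: GroundTruth,
    site: SpinLabelSite,
    params: PREParams = PREParams(),
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> list[PeakPair]:
    """Simulate one spin-label site's paired peak-height table.

    The label sits on the Calpha of the site residue (no explicit linker
    ensemble, matching the analysis-side proxy).  Diamagnetic peak heights
    are drawn log-normal to mimic realistic heterogeneity; both peaks get
    multiplicative Gaussian noise of relative width ``noise_sigma``.
    """
    if site.residue.index not in truth.structure.coords:
        raise ValueError(f"site {site.residue.index} not in truth structure")
    rng = np.random.default_rng(seed)
    label_pos = truth.structure.coords[site.residue.index]
    pairs = []
    for idx in sorted(truth.structure.coords):
        d = float(np.linalg.norm(truth.structure.coords[idx] - label_pos))
        ratio = forward_pre_ratio(d, params)
        i_dia_true = float(rng.lognormal(mean=0.0, sigma=0.3))
        i_dia = i_dia_true * (1.0 + noise_sigma * rng.normal())
        i_para = i_dia_true * ratio * (1.0 + noise_sigma * rng.normal())
        pairs.append(PeakPair(truth.residue(idx), max(i_para, 0.0),
                              max(i_dia, 1e-6), noise_sigma * i_dia_true))
    return pairs


def simulate_shifts(
    truth: GroundTruth,
    helix_offset: float = 3.0,
    noise_sigma: float = 0.0,
    seed: int = 0,
    condition_label: str = "micelle",
) -> ShiftTable:
    """Simulate a Calpha/Cbeta shift table: random-coil values plus a
    positive Calpha offset inside helices, plus Gaussian noise.

    Glycine gets the offset on its (only) Calpha shift and no Cbeta entry.
    """
    if helix_offset < 0:
        raise ValueError("helix_offset must be non-negative")
    refs, _ = load_random_coil_refs()
    rng = np.random.default_rng(seed)
    helical = {i for h in truth.helices for i in range(h.start, h.end + 1)}
    entries = []
    for idx in range(1, truth.n_residues + 1):
        aa = truth.sequence[idx - 1]
        ref = refs[aa]
        offset = helix_offset if idx in helical else 0.0
        ca = ref["CA"] + offset + noise_sigma * rng.normal()
        cb = None
        if aa != "G":
            cb = ref["CB"] + noise_sigma * rng.normal()
        entries.append(ShiftEntry(truth.residue(idx), ca, cb))
    return ShiftTable(entries=entries, condition_label=condition_label)


def luz_meiboom_r2eff(nu: float, r20: float, p_minor: float,
                      delta_omega: float, k_ex: float) -> float:
    """Fast-exchange dispersion closed form.

    R2eff(nu) = R2_0 + (p_a p_b domega^2 / k_ex) *
                (1 - (4 nu / k_ex) * tanh(k_ex / (4 nu)))
    """
    if p_minor == 0.0:
        return r20
    p_a = 1.0 - p_minor
    phi = p_a * p_minor * delta_omega ** 2 / k_ex
    x = 4.0 * nu / k_ex
    return r20 + phi * (1.0 - x * math.tanh(1.0 / x))


def simulate_cpmg(
    residue: ResidueId,
    exchange: Optional[tuple[float, float, float]],
    r20: float = 18.0,
    t_cp: float = DEFAULT_T_CP,
    nus: Sequence[float] = DEFAULT_CPMG_NUS,
    i0: float = 1.0,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> CPMGSeries:
    """Simulate one residue's constant-time CPMG intensity series.

    R2eff(nu) follows the fast-exchange closed form (flat when ``exchange``
    is None); intensities are back-computed by inverting the constant-time
    relation and carry multiplicative Gaussian noise.
    """
    rng = np.random.default_rng(seed)
    p_minor, d_omega, k_ex = exchange if exchange is not None else (0.0, 0.0, 1.0)
    points = []
    for nu in nus:
        rate = luz_meiboom_r2eff(nu, r20, p_minor, d_omega, k_ex)
        inten = i0 * math.exp(-rate * t_cp) * (1.0 + noise_sigma * rng.normal())
        points.append((float(nu), inten))
    return CPMGSeries(residue=residue, t_cp=t_cp, points=points, i0=i0)


_DEPTH_RATIOS = {
    # (gadodiamide ratio, Mn2+ ratio) at the titration endpoint
    "water_exposed": (0.25, 0.20),
    "headgroup": (0.85, 0.25),
    "buried_or_bonded": (0.90, 0.88),
}


def simulate_hnoe_and_titration(
    truth: GroundTruth,
    rigid_mean: float = 0.71,
    flexible_mean: float = 0.60,
    noise: float = 0.0,
    seed: int = 0,
) -> tuple[list[HNOERecord], dict[int, float], dict[int, float]]:
    """Simulate hNOE records and paramagnetic-titration attenuation maps.

    hNOE values are drawn per rigidity class (Gaussian around the class
    mean); titration endpoint ratios are drawn per burial-depth class:
    water-exposed amides are attenuated by gadodiamide (and Mn2+),
    headgroup amides by Mn2+ only, buried ones by neither.
    """
    if not (-0.5 <= flexible_mean <= 1.0 and -0.5 <= rigid_mean <= 1.0):
        raise ValueError("class means must lie in [-0.5, 1.0]")
    rng = np.random.default_rng(seed)
    records = []
    gado: dict[int, float] = {}
    mn: dict[int, float] = {}
    for idx in range(1, truth.n_residues + 1):
        mean = rigid_mean if truth.rigidity.get(idx, "rigid") == "rigid" else flexible_mean
        value = mean + noise * rng.normal()
        i_ref = float(rng.lognormal(0.0, 0.2))
        records.append(HNOERecord(truth.residue(idx), i_sat=value * i_ref, i_ref=i_ref))
        g0, m0 = _DEPTH_RATIOS[truth.depth.get(idx, "buried_or_bonded")]
        gado[idx] = float(np.clip(g0 + noise * rng.normal(), 0.0, 1.2))
        mn[idx] = float(np.clip(m0 + noise * rng.normal(), 0.0, 1.2))
    return records, gado, mn


def make_synthetic_ensemble(
    truth: GroundTruth,
    n_models: int = 10,
    helix_sigma: float = 0.4,
    loop_sigma: float = 3.0,
    sidechain_extra: float = 0.6,
    hydrogen_extra: float = 0.4,
    seed: int = 0,
) -> StructureEnsemble:
    """Expand the Calpha truth into a noisy multi-model pseudo-atom ensemble.

    Each residue gets pseudo-backbone atoms (N, CA, C, O), a side-chain
    heavy atom (CB) and two hydrogens (H, HA) placed at fixed offsets from
    the Calpha.  Per-model Gaussian noise is small inside helices and large
    in loops, with side chains noisier than backbone and hydrogens noisier
    still, so ensemble-disorder ordering (all >= heavy >= backbone) holds by
    construction.
    """
    rng = np.random.default_rng(seed)
    helical = {i for h in truth.helices for i in range(h.start, h.end + 1)}
    offsets = {
        "N": np.array([-0.9, 0.8, 0.0]), "CA": np.zeros(3),
        "C": np.array([0.9, 0.9, 0.4]), "O": np.array([1.4, 1.8, 0.4]),
        "CB": np.array([0.4, -1.4, 0.6]),
        "H": np.array([-1.6, 1.2, -0.3]), "HA": np.array([-0.4, -0.5, -1.0]),
    }
    elements = {k: ("H" if k.startswith("H") else k[0]) for k in offsets}
    models = []
    for _ in range(n_models):
        model: dict[int, ModelResidue] = {}
        for idx in sorted(truth.structure.coords):
            base = truth.structure.coords[idx]
            sigma = helix_sigma if idx in helical else loop_sigma
            wobble = rng.normal(scale=sigma, size=3)
            atoms = {}
            for name, off in offsets.items():
                extra = 0.0
                if name == "CB":
                    extra = sidechain_extra
                elif name.startswith("H"):
                    extra = sidechain_extra + hydrogen_extra
                jitter = rng.normal(scale=extra, size=3) if extra else 0.0
                atoms[name] = base + off + wobble + jitter
            aa = truth.sequence[idx - 1]
            if aa == "G":
                atoms.pop("CB")
            model[idx] = ModelResidue(truth.residue(idx), atoms,
                                      {n: elements[n] for n in atoms})
        models.append(model)
    return StructureEnsemble(models=models, source_id="synthetic_bundle")


# ---------------------------------------------------------------------------
# Study-directory generation
# ---------------------------------------------------------------------------

def generate_study(
    out_dir,
    seed: int = 0,
    noise_sigma: float = 0.02,
    pre_params: PREParams = PREParams(),
) -> GroundTruth:
    """Write a complete synthetic study directory in the dialects the io
    layer reads: shift table, per-site PRE tables, hNOE, CPMG, titration
    maps, sequence FASTA and ground-truth coordinates."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    truth = study_truth(seed=seed)
    rng = np.random.default_rng(seed)

    write_shift_table(simulate_shifts(truth, noise_sigma=10 * noise_sigma,
                                      seed=int(rng.integers(2**31))),
                      out / "shifts_micelle.tsv")
    for site in truth.label_sites:
        pairs = simulate_pre(truth, site, pre_params, noise_sigma,
                             seed=int(rng.integers(2**31)))
        write_peak_pairs(pairs, out / f"pre_site{site.residue.index}.tsv")

    records, gado, mn = simulate_hnoe_and_titration(
        truth, noise=noise_sigma, seed=int(rng.integers(2**31)))
    with open(out / "hnoe_micelle.tsv", "w") as fh:
        fh.write("residue\ti_sat\ti_ref\n")
        for r in records:
            fh.write(f"{r.residue.index}\t{r.i_sat:.6g}\t{r.i_ref:.6g}\n")
    with open(out / "titration.tsv", "w") as fh:
        fh.write("residue\tprobe\tratio\n")
        for idx in sorted(gado):
            fh.write(f"{idx}\tgadodiamide\t{gado[idx]:.4f}\n")
        for idx in sorted(mn):
            fh.write(f"{idx}\tmn\t{mn[idx]:.4f}\n")

    with open(out / "cpmg.tsv", "w") as fh:
        fh.write("residue\tnu\tintensity\ti0\tt_cp\n")
        for idx in range(1, truth.n_residues + 1):
            series = simulate_cpmg(truth.residue(idx), truth.exchange.get(idx),
                                   noise_sigma=noise_sigma,
                                   seed=int(rng.integers(2**31)))
            for nu, inten in series.points:
                fh.write(f"{idx}\t{nu:g}\t{inten:.6g}\t{series.i0:g}\t{series.t_cp:g}\n")

    with open(out / "sequence.fasta", "w") as fh:
        fh.write(">synthetic_study 125-residue synthetic helical bundle\n")
        for i in range(0, len(truth.sequence), 60):
            fh.write(truth.sequence[i:i + 60] + "\n")
    write_ca_models([truth.structure.coords], out / "truth_ca.pdb",
                    sequence=truth.sequence)
    return truth


def read_cpmg_table(path) -> list[CPMGSeries]:
    """Read back the cpmg.tsv dialect written by :func:`generate_study`."""
    rows: dict[int, dict] = {}
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            f = line.split()
            if not f:
                continue
            idx = int(f[0])
            rec = rows.setdefault(idx, {"points": [], "i0": float(f[3]),
                                        "t_cp": float(f[4])})
            rec["points"].append((float(f[1]), float(f[2])))
    return [CPMGSeries(ResidueId(idx, "X"), rec["t_cp"], rec["points"], rec["i0"])
            for idx, rec in sorted(rows.items())]
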
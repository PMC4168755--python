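"""Ensemble superposition/RMSD, restraint-violation scoring, and a
coarse-grained Calpha topology reconstruction from distance restraints.

The reconstruction stands in for a full all-atom simulated-annealing
refinement: it folds a Calpha trace from random coil by minimizing
flat-bottom PRE restraint terms plus chain-connectivity (3.8 Angstrom
between consecutive residues) and local helix-geometry terms
(i,i+3 ~ 5.1 A and i,i+4 ~ 6.2 A inside declared helices), under a
geometric-cooling perturb/minimize/Metropolis schedule.  Distance-only
information cannot fix chirality, so recovery metrics are always taken as
the minimum over a model and its mirror image.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.distance import pdist, squareform
from scipy.spatial.transform import Rotation

from .io_formats import PRERestraint, StructureEnsemble, ValidationError
from .shift_analysis import HelixSegment, SecondaryShiftProfile, call_helices

logger = logging.getLogger(__name__)

CHAIN_TARGET = 3.8       # Angstrom, consecutive Calpha distance
HELIX_I3 = 5.1           # Angstrom, Calpha(i)-Calpha(i+3) in an alpha-helix
HELIX_I4 = 6.2           # Angstrom, Calpha(i)-Calpha(i+4)
DEFAULT_LINKER_PAD = 3.0  # Angstrom widening absorbing the nitroxide linker


@dataclass(frozen=True)
class AtomSelection:
    """Residue set plus atom class used for superposition or reporting."""

    residues: frozenset[int]
    atom_class: str = "ca_only"   # backbone | heavy | all | ca_only

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValidationError("selection must be non-empty")
        if self.atom_class not in ("backbone", "heavy", "all", "ca_only"):
            raise ValueError(f"unknown atom class {self.atom_class!r}")

    @classmethod
    def from_ranges(cls, text: str, atom_class: str = "ca_only") -> "AtomSelection":
        """Parse printed range syntax like ``3-7,22-30,90-94``."""
        residues: set[int] = set()
        for chunk in text.replace(" ", "").split(","):
            if not chunk:
                continue
            if "-" in chunk:
                lo, hi = chunk.split("-")
                residues.update(range(int(lo), int(hi) + 1))
            else:
                residues.add(int(chunk))
        return cls(frozenset(residues), atom_class)

    @classmethod
    def from_segments(cls, segments: Iterable[HelixSegment],
                      atom_class: str = "ca_only") -> "AtomSelection":
        residues: set[int] = set()
        for s in segments:
            residues.update(range(s.start, s.end + 1))
        return cls(frozenset(residues), atom_class)


@dataclass
class CaModel:
    """Calpha-only coordinates keyed by residue index."""

    coords: dict[int, np.ndarray]
    energy: Optional[float] = None
    low_confidence: bool = False

    def as_array(self, indices: Optional[list[int]] = None) -> np.ndarray:
        idx = sorted(self.coords) if indices is None else indices
        return np.array([self.coords[i] for i in idx])

    def mirrored(self) -> "CaModel":
        return CaModel({i: xyz * np.array([1.0, 1.0, -1.0]) for i, xyz in self.coords.items()},
                       self.energy, self.low_confidence)


# ---------------------------------------------------------------------------
# Superposition and ensemble RMSD
# ---------------------------------------------------------------------------

def superpose(mobile: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of paired coordinate sets.

    Returns (rotation matrix with det +1, translation, post-fit RMSD) such
    that ``mobile @ R.T + t`` best matches ``target``.  Requires at least 3
    non-collinear atom pairs.
    """
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    if mobile.shape != target.shape or mobile.shape[0] < 3:
        raise ValidationError("superposition needs >= 3 paired atoms")
    cm, ct = mobile.mean(axis=0), target.mean(axis=0)
    a, b = mobile - cm, target - ct
    if np.linalg.matrix_rank(a, tol=1e-8) < 2:
        raise ValidationError("selection is collinear; superposition is degenerate")
    rot, _ = Rotation.align_vectors(b, a)
    r = rot.as_matrix()
    t = ct - cm @ r.T
    moved = mobile @ r.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - target) ** 2, axis=1))))
    return r, t, rmsd


def _atom_list(ensemble: StructureEnsemble, residues: Iterable[int],
               atom_class: str) -> list[tuple[int, str]]:
    """Paired (residue, atom-name) list present in model 1 for a selection."""
    model = ensemble.models[0]
    out = []
    for idx in sorted(residues):
        if idx not in model:
            raise ValidationError(f"residue {idx} absent from ensemble")
        res = model[idx]
        for name in sorted(res.atoms):
            if atom_class == "ca_only" and name != "CA":
                continue
            if atom_class == "backbone" and name not in ("N", "CA", "C", "O"):
                continue
            if atom_class == "heavy" and res.is_hydrogen(name):
                continue
            out.append((idx, name))
    if not out:
        raise ValidationError("selection matches no atoms")
    return out


def _coords(model: dict, atoms: list[tuple[int, str]]) -> np.ndarray:
    return np.array([model[idx].atoms[name] for idx, name in atoms])


def ensemble_rmsd(
    ensemble: StructureEnsemble,
    selection: AtomSelection,
    report_atoms: str = "backbone",
    report_residues: Optional[Iterable[int]] = None,
    convention: str = "to_mean",
    tol: float = 1e-6,
    max_iter: int = 100,
) -> float:
    """Average RMSD of an ensemble, superposed over ``selection``.

    ``to_mean`` iteratively superposes every model on the evolving mean
    coordinates over the selection (until the mean moves by less than
    ``tol`` Angstrom RMS), then averages each model's RMSD to the mean over
    the ``report_atoms`` class.  ``pairwise`` instead averages RMSD over all
    model pairs, each pair superposed over the selection.  ``report_residues``
    defaults to the selection's residues.
    """
    if ensemble.n_models < 2:
        raise ValidationError("ensemble RMSD needs >= 2 models")
    fit_atoms = _atom_list(ensemble, selection.residues, selection.atom_class)
    rep_res = selection.residues if report_residues is None else report_residues
    rep_atoms = _atom_list(ensemble, rep_res, report_atoms)

    fit = np.stack([_coords(m, fit_atoms) for m in ensemble.models])
    rep = np.stack([_coords(m, rep_atoms) for m in ensemble.models])

    if convention == "pairwise":
        n = ensemble.n_models
        total, pairs = 0.0, 0
        for i in range(n):
            for j in range(i + 1, n):
                r, t, _ = superpose(fit[j], fit[i])
                moved = rep[j] @ r.T + t
                total += float(np.sqrt(np.mean(np.sum((moved - rep[i]) ** 2, axis=1))))
                pairs += 1
        return total / pairs
    if convention != "to_mean":
        raise ValueError(f"unknown convention {convention!r}")

    mean = fit[0].copy()
    for _ in range(max_iter):
        new_fit, new_rep = [], []
        for k in range(ensemble.n_models):
            r, t, _ = superpose(fit[k], mean)
            new_fit.append(fit[k] @ r.T + t)
            new_rep.append(rep[k] @ r.T + t)
        fit = np.stack(new_fit)
        rep = np.stack(new_rep)
        new_mean = fit.mean(axis=0)
        shift = float(np.sqrt(np.mean(np.sum((new_mean - mean) ** 2, axis=1))))
        mean = new_mean
        if shift < tol:
            break
    rep_mean = rep.mean(axis=0)
    per_model = np.sqrt(np.mean(np.sum((rep - rep_mean) ** 2, axis=2), axis=1))
    return float(per_model.mean())


# ---------------------------------------------------------------------------
# Geometric helix calling on a Calpha trace
# ---------------------------------------------------------------------------

def geometric_helix_profile(coords: dict[int, np.ndarray],
                            i3_tol: float = 0.6, i4_tol: float = 0.8) -> SecondaryShiftProfile:
    """Binary helicity profile from Calpha geometry alone (DSSP-free).

    Residues i..i+3 of every window whose Calpha(i)-Calpha(i+3) and
    Calpha(i)-Calpha(i+4) distances fall within tolerance of ideal
    alpha-helical values are marked helical (value 1.0, else 0.0).  The
    result feeds the same segment caller used for chemical-shift profiles.
    """
    indices = sorted(coords)
    helical: set[int] = set()
    for i in indices:
        if i + 4 not in coords or any(i + k not in coords for k in range(1, 4)):
            continue
        d3 = float(np.linalg.norm(coords[i + 3] - coords[i]))
        d4 = float(np.linalg.norm(coords[i + 4] - coords[i]))
        if abs(d3 - HELIX_I3) <= i3_tol and abs(d4 - HELIX_I4) <= i4_tol:
            helical.update(range(i, i + 5))
    values = {i: (1.0 if i in helical else 0.0) for i in indices}
    return SecondaryShiftProfile(values=values, aa={i: "X" for i in indices},
                                 reference_set_name="geometric")


def call_helices_geometric(coords: dict[int, np.ndarray],
                           min_len: int = 4, max_gap: int = 1) -> list[HelixSegment]:
    profile = geometric_helix_profile(coords)
    return call_helices(profile, threshold=0.5, min_len=min_len, max_gap=max_gap)


# ---------------------------------------------------------------------------
# Restraint violations
# ---------------------------------------------------------------------------

@dataclass
class ViolationReport:
    n_restraints: int
    n_violated: int
    total_violation: float            # Angstrom
    per_restraint: list[tuple[PRERestraint, float]] = field(default_factory=list)
    unscorable: list[PRERestraint] = field(default_factory=list)


def restraint_violations(model: CaModel, restraints: list[PRERestraint],
                         linker_pad: float = DEFAULT_LINKER_PAD) -> ViolationReport:
    """Score flat-bottom violations of PRE restraints on a Calpha model.

    The Calpha-Calpha distance proxies the label-amide distance; bounds are
    widened by ``linker_pad`` to absorb the spin-label linker.  Restraints
    touching residues missing from the model are listed as unscorable.
    """
    per, unscorable = [], []
    total = 0.0
    scored = 0
    for r in restraints:
        if r.klass == "unrestrained":
            continue
        i, j = r.site.residue.index, r.residue.index
        if i not in model.coords or j not in model.coords:
            unscorable.append(r)
            continue
        d = float(np.linalg.norm(model.coords[i] - model.coords[j]))
        v = 0.0
        if r.upper is not None:
            v += max(0.0, d - (r.upper + linker_pad))
        if r.lower is not None and r.klass == "bounded":
            v += max(0.0, (r.lower - linker_pad) - d)
        scored += 1
        if v > 0:
            per.append((r, v))
            total += v
    return ViolationReport(scored, len(per), total, per, unscorable)


# ---------------------------------------------------------------------------
# Coarse-grained reconstruction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AnnealSchedule:
    """Geometric-cooling schedule for the perturb/minimize/accept loop."""

    t0: float = 20.0
    cooling: float = 0.55
    n_stages: int = 10
    perturb0: float = 6.0      # Angstrom, initial perturbation scale
    minimize_iter: int = 300
    w_chain: float = 10.0
    w_helix: float = 10.0
    w_pre: float = 1.0
    w_repulse: float = 1.0
    repulse_dist: float = 4.0


def _pair_terms(n_res: int, index_of: dict[int, int],
                helices: list[HelixSegment]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(i, j, target) arrays for chain and helix harmonic terms."""
    ii, jj, tt = [], [], []
    indices = sorted(index_of)
    for a, b in zip(indices, indices[1:]):
        if b == a + 1:
            ii.append(index_of[a]); jj.append(index_of[b]); tt.append(CHAIN_TARGET)
    for h in helices:
        for i in range(h.start, h.end - 2):
            if i in index_of and i + 3 in index_of and i + 3 <= h.end:
                ii.append(index_of[i]); jj.append(index_of[i + 3]); tt.append(HELIX_I3)
        for i in range(h.start, h.end - 3):
            if i in index_of and i + 4 in index_of and i + 4 <= h.end:
                ii.append(index_of[i]); jj.append(index_of[i + 4]); tt.append(HELIX_I4)
    return np.array(ii, int), np.array(jj, int), np.array(tt, float)


def _restraint_arrays(restraints, index_of):
    ii, jj, lo, hi = [], [], [], []
    for r in restraints:
        if r.klass == "unrestrained":
            continue
        a, b = r.site.residue.index, r.residue.index
        if a not in index_of or b not in index_of:
            continue
        ii.append(index_of[a]); jj.append(index_of[b])
        lo.append(r.lower if (r.klass == "bounded" and r.lower is not None) else 0.0)
        hi.append(r.upper)
    return (np.array(ii, int), np.array(jj, int),
            np.array(lo, float), np.array(hi, float))


def _energy_grad(x: np.ndarray, n: int, harm, pre, sched: AnnealSchedule):
    coords = x.reshape(n, 3)
    grad = np.zeros_like(coords)
    energy = 0.0

    def add_pair(i, j, f_d, df_d):
        # f_d: per-pair energy given distances; df_d: dE/dd
        diff = coords[i] - coords[j]
        d = np.sqrt(np.sum(diff * diff, axis=1))
        d = np.maximum(d, 1e-8)
        e = f_d(d)
        energy_local = float(np.sum(e))
        g = (df_d(d) / d)[:, None] * diff
        np.add.at(grad, i, g)
        np.add.at(grad, j, -g)
        return energy_local

    hi_, hj_, ht_ = harm
    if hi_.size:
        energy += add_pair(hi_, hj_,
                           lambda d: sched.w_chain * (d - ht_) ** 2,
                           lambda d: 2 * sched.w_chain * (d - ht_))
    ri, rj, rlo, rhi = pre
    if ri.size:
        def f_pre(d):
            over = np.maximum(0.0, d - rhi)
            under = np.maximum(0.0, rlo - d)
            return sched.w_pre * (over ** 2 + under ** 2)

        def df_pre(d):
            return sched.w_pre * 2 * (np.maximum(0.0, d - rhi) - np.maximum(0.0, rlo - d))

        energy += add_pair(ri, rj, f_pre, df_pre)

    # soft excluded volume between non-adjacent residues
    dmat = squareform(pdist(coords))
    np.fill_diagonal(dmat, np.inf)
    for k in (1,):
        idx = np.arange(n - k)
        dmat[idx, idx + k] = np.inf
        dmat[idx + k, idx] = np.inf
    close_i, close_j = np.where(np.triu(dmat < sched.repulse_dist, k=2))
    if close_i.size:
        energy += add_pair(close_i, close_j,
                           lambda d: sched.w_repulse * (sched.repulse_dist - d) ** 2,
                           lambda d: -2 * sched.w_repulse * (sched.repulse_dist - d))
    return energy, grad.ravel()


def _random_coil(n: int, rng: np.random.Generator) -> np.ndarray:
    steps = rng.normal(size=(n, 3))
    steps /= np.linalg.norm(steps, axis=1, keepdims=True)
    return np.cumsum(steps * CHAIN_TARGET, axis=0)


def _embed_init(n: int, harm, pre) -> np.ndarray:
    """Distance-geometry starting coordinates.

    Builds a sparse graph of distance estimates (chain, helix and restraint
    centres/uppers), completes it by all-pairs shortest paths (a
    triangle-inequality upper-bound metric) and embeds the result in 3-D by
    classical multidimensional scaling.
    """
    from scipy.sparse.csgraph import shortest_path

    w = np.full((n, n), np.inf)
    np.fill_diagonal(w, 0.0)

    def add(i, j, d):
        w[i, j] = min(w[i, j], d)
        w[j, i] = w[i, j]

    hi_, hj_, ht_ = harm
    for i, j, t in zip(hi_, hj_, ht_):
        add(i, j, t)
    ri, rj, rlo, rhi = pre
    for i, j, lo, hi in zip(ri, rj, rlo, rhi):
        add(i, j, hi if lo == 0.0 else 0.5 * (lo + hi))
    dist = shortest_path(w, method="FW", directed=False)
    dist[~np.isfinite(dist)] = CHAIN_TARGET * n  # disconnected: push far apart
    j_c = np.eye(n) - np.ones((n, n)) / n
    gram = -0.5 * j_c @ (dist ** 2) @ j_c
    evals, evecs = np.linalg.eigh(gram)
    return evecs[:, -3:] * np.sqrt(np.maximum(evals[-3:], 0.0))


def reconstruct_topology(
    restraints: list[PRERestraint],
    helices: list[HelixSegment],
    residue_indices: list[int],
    n_restarts: int = 8,
    n_models: int = 5,
    seed: int = 0,
    schedule: AnnealSchedule = AnnealSchedule(),
) -> list[CaModel]:
    """Fold a Calpha trace from restraints by annealed minimization.

    Runs ``n_restarts`` independent anneals from random-coil starts and
    returns the ``n_models`` lowest-energy models, ranked.  Deterministic
    for a fixed seed.  With no long-range restraints the result is flagged
    low-confidence: chain and helix terms alone cannot define a topology.
    """
    indices = sorted(residue_indices)
    n = len(indices)
    index_of = {res: k for k, res in enumerate(indices)}
    harm = _pair_terms(n, index_of, helices)
    pre = _restraint_arrays(restraints, index_of)
    sites = {r.site.residue.index for r in restraints if r.klass != "unrestrained"}
    low_confidence = len(sites) < 2
    if low_confidence:
        logger.warning("fewer than 2 restrained label sites: topology is low-confidence")

    rng = np.random.default_rng(seed)
    embedded = _embed_init(n, harm, pre)
    results = []
    for restart in range(n_restarts):
        if restart == 0:
            x = embedded.ravel()
        elif restart % 2 == 1:
            x = (embedded + rng.normal(scale=3.0, size=embedded.shape)).ravel()
        else:
            x = _random_coil(n, rng).ravel()
        res = minimize(_energy_grad, x, args=(n, harm, pre, schedule), jac=True,
                       method="L-BFGS-B", options={"maxiter": schedule.minimize_iter})
        best_x, best_e = res.x, res.fun
        cur_x, cur_e = best_x, best_e
        t = schedule.t0
        for _ in range(schedule.n_stages):
            scale = schedule.perturb0 * t / schedule.t0
            trial = cur_x + rng.normal(scale=scale, size=cur_x.shape)
            res = minimize(_energy_grad, trial, args=(n, harm, pre, schedule), jac=True,
                           method="L-BFGS-B", options={"maxiter": schedule.minimize_iter})
            accept = res.fun < cur_e or rng.random() < np.exp(-(res.fun - cur_e) / max(t, 1e-9))
            if accept:
                cur_x, cur_e = res.x, res.fun
            if res.fun < best_e:
                best_x, best_e = res.x, res.fun
            t *= schedule.cooling
        results.append((best_e, best_x))
    results.sort(key=lambda r: r[0])
    models = []
    for e, x in results[:n_models]:
        coords = {res: x.reshape(n, 3)[k].copy() for res, k in index_of.items()}
        models.append(CaModel(coords, energy=float(e), low_confidence=low_confidence))
    return models


def ca_rmsd(model: CaModel, reference: CaModel,
            residues: Optional[Iterable[int]] = None,
            allow_mirror: bool = True) -> float:
    """Calpha RMSD of a model to a reference after superposition.

    With ``allow_mirror`` the minimum over the model and its mirror image is
    returned, since distance-only restraints cannot fix chirality.
    """
    idx = sorted(set(model.coords) & set(reference.coords)
                 if residues is None else residues)
    target = reference.as_array(idx)
    candidates = [model] + ([model.mirrored()] if allow_mirror else [])
    best = np.inf
    for cand in candidates:
        _, _, rmsd = superpose(cand.as_array(idx), target)
        best = min(best, rmsd)
    return float(best)
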
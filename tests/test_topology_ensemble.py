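import math

import numpy as np
import pytest

from nmrtopo import pre_restraints as prem
from nmrtopo import synthetic_data as sd
from nmrtopo import topology_ensemble as te
from nmrtopo.io_formats import ValidationError
from nmrtopo.shift_analysis import HelixSegment


# ---------------------------------------------------------------------------
# selections
# ---------------------------------------------------------------------------

def test_range_parsing():
    sel = te.AtomSelection.from_ranges("3-5, 9, 12-13")
    assert sorted(sel.residues) == [3, 4, 5, 9, 12, 13]


def test_empty_selection_rejected():
    with pytest.raises(ValidationError):
        te.AtomSelection(frozenset())


def test_selection_from_segments():
    sel = te.AtomSelection.from_segments([HelixSegment(1, 3), HelixSegment(7, 8)])
    assert sorted(sel.residues) == [1, 2, 3, 7, 8]


# ---------------------------------------------------------------------------
# superposition
# ---------------------------------------------------------------------------

def _random_coords(n, seed):
    return np.random.default_rng(seed).normal(scale=5.0, size=(n, 3))


def test_superpose_recovers_known_rigid_motion():
    target = _random_coords(12, 0)
    ang = np.deg2rad(40.0)
    r_true = np.array([[math.cos(ang), -math.sin(ang), 0],
                       [math.sin(ang), math.cos(ang), 0],
                       [0, 0, 1.0]])
    t_true = np.array([1.0, -2.0, 3.0])
    mobile = (target - t_true) @ r_true   # so mobile @ r_true.T + t_true = target
    r, t, rmsd = te.superpose(mobile, target)
    assert rmsd == pytest.approx(0.0, abs=1e-9)
    np.testing.assert_allclose(r, r_true, atol=1e-9)
    np.testing.assert_allclose(t, t_true, atol=1e-9)
    assert np.linalg.det(r) == pytest.approx(1.0)


def test_superpose_never_uses_reflection():
    target = _random_coords(10, 3)
    mobile = target * np.array([1.0, 1.0, -1.0])
    r, t, rmsd = te.superpose(mobile, target)
    assert np.linalg.det(r) == pytest.approx(1.0)
    assert rmsd > 0.5


def test_collinear_selection_rejected():
    line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
    with pytest.raises(ValidationError, match="collinear"):
        te.superpose(line, line)


# ---------------------------------------------------------------------------
# ensemble RMSD
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def small_ensemble():
    truth = sd.study_truth(seed=2)
    return truth, sd.make_synthetic_ensemble(truth, n_models=6, seed=4)


def test_two_identical_models_have_zero_rmsd(small_ensemble):
    truth, ens = small_ensemble
    import copy
    twin = copy.deepcopy(ens)
    twin.models = [ens.models[0], ens.models[0]]
    sel = te.AtomSelection.from_segments(truth.helices, atom_class="backbone")
    assert te.ensemble_rmsd(twin, sel) == pytest.approx(0.0, abs=1e-9)


def test_rmsd_invariant_to_rigid_motion_of_one_model(small_ensemble):
    truth, ens = small_ensemble
    import copy
    sel = te.AtomSelection.from_segments(truth.helices, atom_class="backbone")
    base = te.ensemble_rmsd(ens, sel)
    moved = copy.deepcopy(ens)
    ang = np.deg2rad(25.0)
    r = np.array([[1, 0, 0],
                  [0, math.cos(ang), -math.sin(ang)],
                  [0, math.sin(ang), math.cos(ang)]])
    t = np.array([4.0, -1.0, 2.0])
    for res in moved.models[0].values():
        for name in res.atoms:
            res.atoms[name] = res.atoms[name] @ r.T + t
    assert te.ensemble_rmsd(moved, sel) == pytest.approx(base, abs=1e-6)


def test_disorder_ordering_backbone_heavy_all(small_ensemble):
    """Reporting over noisier atom classes gives larger spread: the generator
    adds extra jitter to side chains and more to hydrogens."""
    truth, ens = small_ensemble
    sel = te.AtomSelection.from_segments(truth.helices, atom_class="backbone")
    bb = te.ensemble_rmsd(ens, sel, report_atoms="backbone")
    heavy = te.ensemble_rmsd(ens, sel, report_atoms="heavy")
    al = te.ensemble_rmsd(ens, sel, report_atoms="all")
    assert bb <= heavy <= al


def test_helix_selection_tighter_than_full_chain(small_ensemble):
    truth, ens = small_ensemble
    helix_sel = te.AtomSelection.from_segments(truth.helices, atom_class="backbone")
    all_sel = te.AtomSelection(frozenset(range(1, 126)), atom_class="backbone")
    tight = te.ensemble_rmsd(ens, helix_sel)
    loose = te.ensemble_rmsd(ens, all_sel)
    assert tight < loose


def test_pairwise_convention_exceeds_to_mean(small_ensemble):
    # pairwise spread is sqrt(2N/(N-1)) times the to-mean spread for Gaussian
    # scatter, so it must come out strictly larger
    truth, ens = small_ensemble
    sel = te.AtomSelection.from_segments(truth.helices, atom_class="backbone")
    to_mean = te.ensemble_rmsd(ens, sel, convention="to_mean")
    pairwise = te.ensemble_rmsd(ens, sel, convention="pairwise")
    assert pairwise > to_mean


def test_single_model_ensemble_rejected(small_ensemble):
    truth, ens = small_ensemble
    import copy
    one = copy.deepcopy(ens)
    one.models = one.models[:1]
    sel = te.AtomSelection.from_segments(truth.helices)
    with pytest.raises(ValidationError):
        te.ensemble_rmsd(one, sel)


# ---------------------------------------------------------------------------
# geometric helix calling
# ---------------------------------------------------------------------------

def test_geometric_calling_recovers_truth_helices(study_truth):
    segs = te.call_helices_geometric(study_truth.structure.coords)
    for true in study_truth.helices:
        assert any(s.overlap(true) >= len(true) - 1 for s in segs), true


def test_straight_chain_has_no_geometric_helices():
    coords = {i: np.array([3.8 * i, 0.0, 0.01 * i**2]) for i in range(1, 30)}
    assert te.call_helices_geometric(coords) == []


# ---------------------------------------------------------------------------
# violations
# ---------------------------------------------------------------------------

def test_truth_structure_satisfies_noise_free_restraints(study_truth, noise_free_restraints):
    report = te.restraint_violations(study_truth.structure, noise_free_restraints)
    assert report.n_violated == 0
    assert report.total_violation == 0.0
    assert report.n_restraints > 100


def test_violations_appear_when_model_is_wrong(study_truth, noise_free_restraints):
    stretched = te.CaModel({i: xyz * 2.0 for i, xyz in study_truth.structure.coords.items()})
    report = te.restraint_violations(stretched, noise_free_restraints)
    assert report.n_violated > 0
    assert report.total_violation > 0


def test_missing_residues_are_unscorable(study_truth, noise_free_restraints):
    partial = te.CaModel({i: xyz for i, xyz in study_truth.structure.coords.items() if i > 50})
    report = te.restraint_violations(partial, noise_free_restraints)
    assert report.unscorable
    assert report.n_restraints + len(report.unscorable) == sum(
        1 for r in noise_free_restraints if r.klass != "unrestrained")


# ---------------------------------------------------------------------------
# reconstruction
# ---------------------------------------------------------------------------

def test_reconstruction_recovers_topology(study_truth, noise_free_restraints):
    """From noise-free restraints plus helix definitions the annealer folds
    the bundle to within 4.0 A mirror-corrected Calpha RMSD over helical
    residues.  Loops are restrained only by chain connectivity, so recovery
    is judged where the data actually constrain the topology."""
    models = te.reconstruct_topology(
        noise_free_restraints, study_truth.helices,
        list(range(1, 126)), n_restarts=6, n_models=2, seed=1)
    assert models[0].energy <= models[-1].energy
    helical = sorted({i for h in study_truth.helices
                      for i in range(h.start, h.end + 1)})
    best = te.ca_rmsd(models[0], study_truth.structure, residues=helical)
    assert best < 4.0


def test_reconstruction_without_restraints_is_low_confidence(study_truth):
    models = te.reconstruct_topology([], study_truth.helices,
                                     list(range(1, 126)), n_restarts=1,
                                     n_models=1, seed=0)
    assert models[0].low_confidence


def test_reconstruction_is_deterministic(study_truth, noise_free_restraints):
    kwargs = dict(helices=study_truth.helices, residue_indices=list(range(1, 126)),
                  n_restarts=1, n_models=1, seed=9)
    a = te.reconstruct_topology(noise_free_restraints, **kwargs)[0]
    b = te.reconstruct_topology(noise_free_restraints, **kwargs)[0]
    assert a.energy == b.energy
    np.testing.assert_array_equal(a.as_array(), b.as_array())


def test_ca_rmsd_mirror_correction(study_truth):
    mirrored = study_truth.structure.mirrored()
    with_mirror = te.ca_rmsd(mirrored, study_truth.structure, allow_mirror=True)
    without = te.ca_rmsd(mirrored, study_truth.structure, allow_mirror=False)
    assert with_mirror == pytest.approx(0.0, abs=1e-9)
    assert without > 1.0
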
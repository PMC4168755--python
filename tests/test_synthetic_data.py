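import math

import numpy as np
import pytest

from nmrtopo import synthetic_data as sd
from nmrtopo import relaxation_dynamics as rd
from nmrtopo.io_formats import read_ensemble, read_fasta, read_peak_pairs, read_shift_table
from nmrtopo.shift_analysis import HelixSegment


# ---------------------------------------------------------------------------
# bundle geometry
# ---------------------------------------------------------------------------

def test_bundle_is_deterministic_per_seed():
    a = sd.make_bundle(sd.STUDY_HELICES, 125, seed=5)
    b = sd.make_bundle(sd.STUDY_HELICES, 125, seed=5)
    np.testing.assert_array_equal(a.as_array(), b.as_array())
    c = sd.make_bundle(sd.STUDY_HELICES, 125, seed=6)
    assert not np.allclose(a.as_array(), c.as_array())


def test_bundle_chain_connectivity():
    model = sd.make_bundle(sd.STUDY_HELICES, 125, seed=1)
    xyz = model.as_array()
    steps = np.linalg.norm(np.diff(xyz, axis=0), axis=1)
    assert steps.min() > 3.0 and steps.max() < 4.6


def test_bundle_helices_have_ideal_local_geometry():
    model = sd.make_bundle(sd.STUDY_HELICES, 125, seed=1)
    for h in sd.STUDY_HELICES:
        for i in range(h.start, h.end - 3):
            d3 = np.linalg.norm(model.coords[i + 3] - model.coords[i])
            assert d3 == pytest.approx(5.1, abs=0.5)
        for i in range(h.start, h.end - 4):
            d4 = np.linalg.norm(model.coords[i + 4] - model.coords[i])
            assert d4 == pytest.approx(6.2, abs=0.7)


def test_overlapping_segments_rejected():
    with pytest.raises(ValueError, match="overlap"):
        sd.make_bundle([HelixSegment(1, 10), HelixSegment(8, 15)], 20)


def test_depth_classes_partition_and_follow_z():
    model = sd.make_bundle(sd.STUDY_HELICES, 125, seed=1)
    depth = sd.assign_depth_classes(model)
    assert set(depth) == set(range(1, 126))
    z = {k: ("water_exposed", "headgroup", "buried_or_bonded").index(v)
         for k, v in depth.items()}
    # class index increases as z decreases
    zs = sorted(model.coords, key=lambda i: -model.coords[i][2])
    ranks = [z[i] for i in zs]
    assert ranks == sorted(ranks)


def test_study_truth_configuration(study_truth):
    assert study_truth.n_residues == 125
    assert [s.residue.index for s in study_truth.label_sites] == list(sd.STUDY_LABEL_SITES)
    assert study_truth.helices == sd.STUDY_HELICES
    assert set(study_truth.exchange) == set(range(44, 48)) | set(range(66, 77))


# ---------------------------------------------------------------------------
# forward models
# ---------------------------------------------------------------------------

def test_forward_pre_ratio_monotone_in_distance(pre_params):
    ds = np.linspace(5.0, 40.0, 50)
    ratios = [sd.forward_pre_ratio(d, pre_params) for d in ds]
    assert all(a <= b for a, b in zip(ratios, ratios[1:]))
    assert ratios[0] < 0.01 and ratios[-1] > 0.9


def test_simulate_pre_noise_free_ratio_is_exact(study_truth, pre_params):
    site = study_truth.label_sites[2]
    pairs = sd.simulate_pre(study_truth, site, pre_params, 0.0, seed=13)
    label = study_truth.structure.coords[site.residue.index]
    for p in pairs:
        d = float(np.linalg.norm(study_truth.structure.coords[p.residue.index] - label))
        assert p.i_para / p.i_dia == pytest.approx(sd.forward_pre_ratio(d, pre_params),
                                                   rel=1e-9)


def test_simulate_shifts_offset_only_in_helices(study_truth):
    table = sd.simulate_shifts(study_truth, helix_offset=3.0, noise_sigma=0.0)
    from nmrtopo.shift_analysis import secondary_shifts
    profile = secondary_shifts(table)
    helical = {i for h in study_truth.helices for i in range(h.start, h.end + 1)}
    for idx, v in profile.values.items():
        assert v == pytest.approx(3.0 if idx in helical else 0.0, abs=1e-9)


def test_luz_meiboom_limits():
    r20 = 18.0
    # no exchange: flat
    assert sd.luz_meiboom_r2eff(80.0, r20, 0.0, 1e3, 1e4) == r20
    # nu -> infinity refocuses everything
    assert sd.luz_meiboom_r2eff(1e9, r20, 0.08, 2e3, 8e3) == pytest.approx(r20, abs=1e-3)
    # nu -> 0 approaches full exchange contribution p_a*p_b*dw^2/kex
    p, dw, kex = 0.08, 2e3, 8e3
    full = r20 + (1 - p) * p * dw**2 / kex
    assert sd.luz_meiboom_r2eff(1e-3, r20, p, dw, kex) == pytest.approx(full, rel=1e-3)


def test_exchange_classes_flag_as_designed(study_truth):
    """Noise-free CPMG simulation flags the moderate loop as moderate and the
    strong loop as strong, and no exchange-free residue is flagged."""
    for idx in (10, 44, 70):
        series = sd.simulate_cpmg(study_truth.residue(idx),
                                  study_truth.exchange.get(idx), noise_sigma=0.0)
        prof = rd.dispersion_profile(series)
        expected = "none" if idx == 10 else ("moderate" if idx == 44 else "strong")
        assert prof.exchange_flag == expected, idx


def test_hnoe_class_means_are_exact_when_noise_free(study_truth):
    records, _, _ = sd.simulate_hnoe_and_titration(study_truth, noise=0.0, seed=2)
    for r in records:
        expected = 0.71 if study_truth.rigidity[r.residue.index] == "rigid" else 0.60
        assert r.hnoe == pytest.approx(expected, rel=1e-9)


def test_synthetic_ensemble_rosters_and_glycine(study_truth):
    ens = sd.make_synthetic_ensemble(study_truth, n_models=3, seed=0)
    assert ens.n_models == 3
    assert ens.residue_indices() == list(range(1, 126))
    for idx, res in ens.models[0].items():
        if study_truth.sequence[idx - 1] == "G":
            assert "CB" not in res.atoms
        else:
            assert "CB" in res.atoms


# ---------------------------------------------------------------------------
# study directory
# ---------------------------------------------------------------------------

def test_generate_study_writes_readable_files(study_dir):
    table = read_shift_table(study_dir / "shifts_micelle.tsv")
    assert len(table) == 125
    for site in sd.STUDY_LABEL_SITES:
        pairs = read_peak_pairs(study_dir / f"pre_site{site}.tsv")
        assert len(pairs) == 125
    seqs = read_fasta(study_dir / "sequence.fasta")
    assert len(next(iter(seqs.values()))) == 125
    ens = read_ensemble(study_dir / "truth_ca.pdb")
    assert ens.n_models == 1
    series = sd.read_cpmg_table(study_dir / "cpmg.tsv")
    assert len(series) == 125
    assert len(series[0].points) == len(sd.DEFAULT_CPMG_NUS)


def test_generate_study_is_deterministic(tmp_path):
    a, b = tmp_path / "a", tmp_path / "b"
    sd.generate_study(a, seed=21)
    sd.generate_study(b, seed=21)
    for f in sorted(a.iterdir()):
        assert f.read_bytes() == (b / f.name).read_bytes(), f.name
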
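# nmrtopo

Membrane-protein topology and dynamics from solution-NMR observables.

`nmrtopo` implements the computational chain that turns per-residue NMR
measurements on a micelle-embedded protein domain into a coarse-grained,
membrane-embedded topology model with per-residue dynamics and accessibility
annotation:

1. **Secondary chemical shifts** (ΔCα − ΔCβ against random-coil references)
   → α-helix segment calling.
2. **Paramagnetic relaxation enhancement (PRE)** from nitroxide spin labels:
   paramagnetic/diamagnetic peak-intensity ratios → transverse relaxation
   contributions (numerical inversion of the intensity-ratio relation) →
   Solomon–Bloembergen distances → flat-bottom distance restraints.
3. **Backbone dynamics**: steady-state heteronuclear NOE (ps–ns rigidity),
   constant-time CPMG relaxation dispersion (µs–ms exchange, flagged at
   moderate/strong tiers), and differential attenuation by water-soluble
   (gadodiamide) versus headgroup-partitioning (Mn²⁺) paramagnetic titrants
   (water-exposed / headgroup / buried classification).
4. **Sequence amphiphilicity**: windowed hydropathy, membrane-insertion
   propensity, and Eisenberg per-residue hydrophobic moments, with detection
   of amphiphilic helical segments against a mellitin reference.
5. **Topology reconstruction**: a Cα trace folded from the PRE restraints
   plus helix-geometry and chain-connectivity terms by distance-geometry
   embedding followed by annealed minimization.
6. **Ensemble analysis**: multi-model PDB parsing, iterative superposition,
   ensemble RMSD (to-mean and pairwise conventions), DSSP-free geometric
   helix calling, and restraint-violation scoring.

A synthetic-data generator (`nmrtopo.synthetic_data`) forward-models every
input from a known ground-truth helical bundle, so the entire chain is
verifiable end-to-end without any experimental data or downloads.  The
packaged VAPB-like sequences are **synthetic stand-ins** (see file headers);
only their engineered composition properties are meaningful.

## Worked example

Generate a synthetic study and run the full pipeline:

```
$ nmrtopo generate --seed 3 --out study/
$ nmrtopo run-all --input-dir study/ --out results/ --seed 3
$ cat results/summary.tsv
```

Key lines of the summary (seed 3):

```
shifts.n_helices        5
shifts.segments         3-7;22-30;90-94;98-107;116-125
pre.n_restraints        834
dynamics.exchange_moderate      4
dynamics.exchange_strong        11
dynamics.access_buried_or_bonded        75
dynamics.access_headgroup       30
dynamics.access_water_exposed   20
reconstruct.violations  0
```

The five called helix segments match the generator's ground truth exactly;
the exchange and accessibility counts reproduce the designed residue
classes; the reconstructed topology satisfies every PRE restraint.

The same chain is available as a Python API:

```python
import nmrtopo

table = nmrtopo.read_shift_table("study/shifts_micelle.tsv")
profile = nmrtopo.secondary_shifts(table)
helices = nmrtopo.call_helices(profile)        # [HelixSegment(3, 7), ...]

pairs = nmrtopo.io_formats.read_peak_pairs("study/pre_site89.tsv")
site = nmrtopo.SpinLabelSite(nmrtopo.ResidueId(89, "M"))
from nmrtopo.pre_restraints import classify_pairs
restraints, qc = nmrtopo.build_restraints(
    classify_pairs(pairs, site, nmrtopo.PREParams()))
```

## Reproduction

`scripts/acceptance.py` runs the full synthetic study end to end and writes
the main computed quantities as JSON:

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

Every random draw derives from `--seed`; the script needs no network access
and finishes in well under a minute.

The acceptance tests in `tests/test_acceptance.py` include three audits of
the deposited 10-model NMR ensemble (PDB accession 2MDK).  The file is not
redistributed here; place a copy at `data/2MDK.pdb` (or point `NMRTOPO_2MDK`
at it) to enable them.  Without it they fail with an actionable message —
this is expected in offline environments, and all machinery they exercise is
covered against synthetic ensembles in the unit suite.

## Documentation

See `docs/methods.md` for the underlying models, parameter defaults and
their rationale, numerical choices, and known limitations.
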
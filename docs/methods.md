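# Methods

This document records the models implemented in `nmrtopo`, the parameter
defaults and why they were chosen, the scope of the synthetic-data
generator, numerical choices, and known limitations.

## 1. Secondary chemical shifts and helix calling (`shift_analysis`)

The per-residue helicity indicator is the secondary-shift difference

    s(i) = [δCα(i) − δCα,rc(aa)] − [δCβ(i) − δCβ,rc(aa)]

against packaged random-coil references (Wishart-style table,
`data/random_coil_shifts.tsv`, tagged `wishart1995` in outputs).  Glycine
has no Cβ, so it contributes ΔCα alone; a glycine row carrying a Cβ shift is
rejected as a data error.

Helix segments are maximal runs of residues with `s(i) ≥ threshold`,
bridging internal gaps of at most `max_gap` residues (observed sub-threshold
or missing), trimmed back to qualifying residues at both ends, and dropped
when shorter than `min_len`.

Defaults: `threshold = 1.4 ppm` (a robust helix indicator well above typical
shift noise of ~0.3 ppm while below the ~3 ppm plateau of a formed helix),
`min_len = 4` (one helical turn), `max_gap = 1` (tolerates a single missing
or noisy residue without merging distinct helices).  Strand calling is the
mirrored rule on `s(i) ≤ −threshold`.

## 2. PRE distance restraints (`pre_restraints`)

For each spin-label site, paired paramagnetic/diamagnetic peak heights give
the intensity ratio `I_para/I_dia`.  The paramagnetic contribution to
transverse relaxation, `R2sp`, follows from numerically inverting

    ratio = R2_dia · exp(−R2sp · t_INEPT) / (R2_dia + R2sp)

(the INEPT-transfer attenuation model), solved with `scipy.optimize.brentq`
to 1e-10 relative tolerance — the right-hand side is strictly monotone in
`R2sp`, so the root is unique.  `R2sp` converts to distance through the
Solomon–Bloembergen relation

    d = [ K / R2sp · (4τc + 3τc / (1 + ω_H² τc²)) ]^(1/6)

Classification of each residue:

| intensity ratio | class          | restraint                         |
|-----------------|----------------|-----------------------------------|
| > 0.85          | `unrestrained` | none (too weak to bound reliably) |
| ≤ 0.15          | `upper_only`   | d ≤ d(0.15) ≈ 15.4 Å              |
| otherwise       | `bounded`      | d ± `bound_width`                 |

Defaults (`PREParams`): `r2_dia = 20 s⁻¹`, `t_inept = 10 ms`, `τc = 15 ns`
(a micelle-bound domain), `ω_H = 2π·800 MHz`, `K = 1.23e16 Å⁶ s⁻²`,
`ratio_cutoff = 0.85`, `vanish_cutoff = 0.15`, `bound_width = 4 Å`.  With
these, d(0.15) ≈ 15.4 Å and d(0.85) ≈ 25.2 Å bracket the informative PRE
range.  The residue carrying the label is excluded from its own site's
restraints and logged.  Per-site class counts must partition the input
(tested invariant).

## 3. Backbone dynamics (`relaxation_dynamics`)

* **hNOE** = `I_sat / I_ref`, unclamped (negative values mean a highly
  flexible amide and are preserved).
* **CPMG**: `R2eff(ν) = −ln(I(ν)/I0) / T_CP` with `T_CP = 50 ms`.  Repeated
  frequency planes (the duplicated 120 and 960 Hz points) are averaged in
  intensity first.  The exchange indicator is
  `ΔR2 = R2eff(80 Hz) − R2eff(960 Hz)`, flagged `moderate` above 2 s⁻¹ and
  `strong` above 6 s⁻¹; if either anchor plane is missing or the peak
  vanished, the residue is `unobserved`.  The Luz–Meiboom fast-exchange
  closed form serves as the forward model and test oracle.
* **Accessibility**: endpoint attenuation below 0.5 by gadodiamide ⇒
  `water_exposed` (gadodiamide takes precedence), else below 0.5 by Mn²⁺ ⇒
  `headgroup`, else `buried_or_bonded`.

## 4. Amphiphilicity (`amphiphilicity`)

Three packaged scales: Kyte–Doolittle hydropathy, a biological
membrane-insertion propensity scale (stored negated so positive windowed
means favour insertion; threshold 0), and the Eisenberg consensus scale for
moments.  The per-residue hydrophobic moment of a window is

    μH/N = |Σ H_n exp(i·δ·n)| / N,   δ = 100°/residue (α-helix)

Windows: 19 residues for transmembrane propensity (a membrane-spanning
helix), 11 for moments (three helical turns).  Amphiphilic segments are
runs of window centres with `μH/N ≥ 0.35`, expanded by the half-window and
dropped below 6 residues.  `compare_profiles` marks a segment "comparable"
to a reference peptide (mellitin, packaged; peak μH/N ≈ 0.568) when its peak
reaches 90 % of the reference's global peak.

## 5. Topology reconstruction and ensemble analysis (`topology_ensemble`)

**Reconstruction.**  The Cα trace is folded by minimizing

    E = w_chain Σ (d(i,i+1) − 3.8)²                     (chain connectivity)
      + w_helix Σ (d(i,i+3) − 5.1)² + (d(i,i+4) − 6.2)² (declared helices)
      + w_pre   Σ flat-bottom violations of PRE bounds
      + w_rep   Σ (4.0 − d)² over non-adjacent pairs closer than 4 Å

with analytic gradients, using L-BFGS-B inside a geometric-cooling
perturb/minimize/Metropolis schedule (T₀ = 20, ratio 0.55, 10 stages,
initial perturbation 6 Å).  Restart 0 starts from a distance-geometry
embedding: a sparse graph of chain/helix/restraint distance estimates is
completed by all-pairs shortest paths (a triangle-inequality upper-bound
metric) and embedded in 3-D by classical MDS; odd restarts perturb that
embedding, even restarts start from random coils.  The lowest-energy models
are returned ranked.  With fewer than two restrained label sites the result
is flagged `low_confidence` — chain and helix terms alone cannot define a
topology.

Distance-only information cannot fix chirality, so all recovery metrics
(`ca_rmsd`) take the minimum over a model and its mirror image.  Recovery is
assessed over helical residues: loops carry only connectivity information
and are not expected to be determined by the data.

**Ensemble RMSD.**  `to_mean` iteratively superposes every model on the
evolving mean over the fit selection until the mean stabilizes (RMS shift
< 1e-6 Å), then averages per-model RMSD to the mean over the reporting atom
class; `pairwise` averages over all superposed model pairs.  Both are
provided because published per-ensemble figures do not always state the
convention; for Gaussian scatter `pairwise ≈ sqrt(2N/(N−1)) × to_mean`.
Superposition uses `scipy.spatial.transform.Rotation.align_vectors`
(proper rotations only; reflections are never used).

**Geometric helix calling.**  A residue window is helical when
`d(Cα_i, Cα_i+3) = 5.1 ± 0.6 Å` and `d(Cα_i, Cα_i+4) = 6.2 ± 0.8 Å`; the
binary profile feeds the same segment caller as chemical shifts.

**Violation scoring.**  Cα–Cα distance proxies the label–amide distance;
bounds are widened by `linker_pad = 3 Å` to absorb the nitroxide linker.

## 6. Synthetic-data generator (`synthetic_data`)

Ground truth: ideal helices (rise 1.5 Å/residue, 100°/residue, Cα radius
2.3 Å) with axes on a circle of radius 8.5 Å, alternating up/down
(antiparallel), joined by guided random-walk loops regularized to 3.8 Å
steps.  The standard configuration has five helices (3–7, 22–30, 90–94,
98–107, 116–125), seven label sites (6, 24, 53, 68, 89, 102, 121), moderate
exchange on residues 44–47 and strong exchange on 66–76, helical residues
rigid, and burial-depth classes assigned from z-quantiles (top 15 %
water-exposed, next 25 % headgroup).

Forward models (all deterministic per seed):

* PRE: label at the site's Cα; exact forward ratio times log-normal
  diamagnetic heights with multiplicative Gaussian noise.
* Shifts: random-coil references plus a +3 ppm Cα offset inside helices.
* CPMG: Luz–Meiboom rates inverted to intensities on the experimental
  frequency grid (40–960 Hz, 120 and 960 Hz duplicated).
* hNOE/titration: class means (rigid 0.71 / flexible 0.60; depth-class
  endpoint ratios) plus Gaussian noise.
* Pseudo-atom ensembles: per-residue N/CA/C/O/CB/H/HA at fixed offsets with
  noise small in helices, large in loops, extra on side chains and more on
  hydrogens, so the disorder ordering all ≥ heavy ≥ backbone holds by
  construction.

Noise-free closed loops through the corresponding analysis operations are
identities; the test suite exploits this throughout.  The packaged
`vapb_*_synthetic.fasta` sequences are engineered stand-ins (labelled as
such in their headers): they reproduce the composition *properties* the
analysis depends on — an amphiphilic structured domain with no
transmembrane window in residues 1–125 and a C-terminal transmembrane
anchor — but are not natural sequences.

## 7. Pipeline (`pipeline`, `cli`)

Stages run in experimental-logic order: `shifts → pre → dynamics → amphi →
reconstruct → ensemble`, configured by a YAML file that round-trips through
`PipelineConfig` (unknown keys rejected).  Missing inputs fail before any
stage runs; a failing stage aborts naming the stages already completed.
The summary report records a 16-hex-digit SHA-256 hash of the full config;
identical config and inputs give bit-identical computed values.  The
ensemble stage skips RMSD statistics (with a warning) for single-model
files.

## 8. Open design decisions and limitations

* The spin label is placed at the site residue's Cα with no explicit linker
  ensemble; the 3 Å `linker_pad` and 4 Å `bound_width` absorb linker
  geometry.  A rotamer-library label model would be more faithful.
* The reconstruction is Cα-only and coarse: it recovers topology (helix
  packing), not side-chain detail; typical recovery is 3–4 Å over helical
  residues.  Loops are unconstrained beyond connectivity.
* Chirality is undetermined by distance data; mirror correction is applied
  in metrics, and reported models may be either hand.
* Exchange flagging uses the two-point ΔR2 indicator, not a full dispersion
  fit; `kex`, `Δω` and populations are not estimated.
* The NMR-STAR reader is a minimal loop parser covering assigned
  chemical-shift loops only, not the full STAR grammar.
* Published ensemble RMSD conventions vary; both implemented conventions
  are tried by the acceptance audit, and tolerances account for this.
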
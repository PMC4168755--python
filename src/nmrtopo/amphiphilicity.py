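"""Sequence hydrophobicity, transmembrane propensity and hydrophobic moment.

Three packaged scales cover the classic uses: ``kyte_doolittle`` (hydropathy),
``biological_tm`` (membrane-insertion propensity, stored so that positive
windowed means favour insertion) and ``eisenberg_consensus`` (the normalized
consensus scale conventionally used for hydrophobic moments).

The hydrophobic moment of a window of residues with scores H_n is the
magnitude of the helical-wheel vector sum

    mu_H = sqrt[ (sum_n H_n sin(n*delta))^2 + (sum_n H_n cos(n*delta))^2 ]

with delta = 100 degrees per residue for an alpha-helix (160 degrees for a
beta-strand).  Moments are reported per residue (mu_H / N) so windows of
different lengths are comparable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional

import numpy as np

from .shift_analysis import HelixSegment

DELTA_ALPHA = 100.0   # degrees per residue around an alpha-helical wheel
DELTA_BETA = 160.0
DEFAULT_TM_WINDOW = 19
DEFAULT_MOMENT_WINDOW = 11
DEFAULT_MU_THRESHOLD = 0.35   # per-residue consensus-scale moment
DEFAULT_TM_THRESHOLD = 0.0    # windowed insertion propensity above 0 favours TM
DEFAULT_COMPARABLE_FRACTION = 0.9

_SCALE_FILES = {
    "kyte_doolittle": "scale_kyte_doolittle.tsv",
    "biological_tm": "scale_biological_tm.tsv",
    "eisenberg_consensus": "scale_eisenberg_consensus.tsv",
}


@dataclass(frozen=True)
class HydropathyScale:
    name: str
    values: dict[str, float]

    def __post_init__(self) -> None:
        missing = set("ACDEFGHIKLMNPQRSTVWY") - set(self.values)
        if missing:
            raise ValueError(f"scale {self.name!r} missing residues {sorted(missing)}")

    def score(self, seq: str) -> np.ndarray:
        try:
            return np.array([self.values[a] for a in seq], dtype=float)
        except KeyError as exc:
            raise ValueError(f"residue {exc.args[0]!r} not in scale {self.name!r}") from exc


@dataclass
class HydropathyProfile:
    """Windowed mean hydrophobicity and (optionally) per-residue moment."""

    positions: np.ndarray          # 1-based window centres
    mean_h: np.ndarray
    mu_h: Optional[np.ndarray]     # per-residue moment, same length, or None
    window: int
    delta: float
    scale_name: str
    seq_len: int


def load_scale(name: str) -> HydropathyScale:
    """Load one of the packaged hydropathy scales by name."""
    if name not in _SCALE_FILES:
        raise KeyError(f"unknown scale {name!r}; packaged: {sorted(_SCALE_FILES)}")
    text = resources.files("nmrtopo.data").joinpath(_SCALE_FILES[name]).read_text()
    values = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        aa, val = line.split("\t")
        values[aa] = float(val)
    return HydropathyScale(name=name, values=values)


def windowed_hydropathy(seq: str, scale: HydropathyScale, window: int,
                        delta: float = DELTA_ALPHA) -> HydropathyProfile:
    """Sliding arithmetic mean of per-residue scores.

    ``window`` must be odd and between 3 and the sequence length; window
    centres are 1-based sequence positions.
    """
    n = len(seq)
    if window % 2 == 0 or not (3 <= window <= n):
        raise ValueError(f"window must be odd and in [3, {n}], got {window}")
    scores = scale.score(seq)
    kernel = np.ones(window) / window
    mean_h = np.convolve(scores, kernel, mode="valid")
    half = window // 2
    positions = np.arange(1 + half, n - half + 1)
    return HydropathyProfile(positions, mean_h, None, window, delta, scale.name, n)


def hydrophobic_moment(seq_window: str, scale: HydropathyScale,
                       delta: float = DELTA_ALPHA) -> float:
    """Per-residue hydrophobic moment (mu_H / N) of one window."""
    if not seq_window:
        raise ValueError("window must be non-empty")
    h = scale.score(seq_window)
    n = np.arange(1, len(h) + 1)
    ang = np.deg2rad(delta) * n
    mu = math.hypot(float(np.dot(h, np.sin(ang))), float(np.dot(h, np.cos(ang))))
    return mu / len(h)


def moment_profile(seq: str, scale: HydropathyScale,
                   window: int = DEFAULT_MOMENT_WINDOW,
                   delta: float = DELTA_ALPHA) -> HydropathyProfile:
    """Windowed mean hydrophobicity plus per-residue moment along a sequence."""
    profile = windowed_hydropathy(seq, scale, window, delta)
    half = window // 2
    mu = np.array([
        hydrophobic_moment(seq[c - 1 - half: c + half], scale, delta)
        for c in profile.positions
    ])
    profile.mu_h = mu
    return profile


def detect_amphiphilic_segments(
    profile: HydropathyProfile,
    mu_threshold: float = DEFAULT_MU_THRESHOLD,
    min_len: int = 6,
) -> list[HelixSegment]:
    """Maximal runs of window centres with mu_H/N >= threshold.

    Segments are reported in sequence coordinates, expanded to the full
    extent covered by the qualifying windows and clipped to the sequence;
    runs shorter than ``min_len`` residues after expansion are dropped.
    """
    if mu_threshold <= 0:
        raise ValueError("threshold must be positive")
    if profile.mu_h is None:
        raise ValueError("profile has no moment track; use moment_profile")
    half = profile.window // 2
    qualifying = profile.positions[profile.mu_h >= mu_threshold]
    if qualifying.size == 0:
        return []
    segments: list[HelixSegment] = []
    start = prev = int(qualifying[0])
    for c in qualifying[1:]:
        c = int(c)
        if c == prev + 1:
            prev = c
        else:
            segments.append(HelixSegment(max(1, start - half), min(profile.seq_len, prev + half)))
            start = prev = c
    segments.append(HelixSegment(max(1, start - half), min(profile.seq_len, prev + half)))
    return [s for s in segments if len(s) >= min_len]


@dataclass
class ProfileComparison:
    max_a: float
    max_b: float
    segment_peaks: list[tuple[HelixSegment, float, bool]]
    comparable_fraction: float

    @property
    def comparable_segments(self) -> list[HelixSegment]:
        return [s for s, _, ok in self.segment_peaks if ok]


def compare_profiles(
    a: HydropathyProfile,
    b: HydropathyProfile,
    segments: Optional[list[HelixSegment]] = None,
    fraction: float = DEFAULT_COMPARABLE_FRACTION,
) -> ProfileComparison:
    """Compare the moment track of profile ``a`` against reference ``b``.

    A segment of ``a`` is "comparable" to the reference when its peak
    per-residue moment reaches at least ``fraction`` of the reference's
    global peak.  Both profiles must use the same scale and helix twist.
    """
    if a.scale_name != b.scale_name or a.delta != b.delta:
        raise ValueError("profiles must share scale and delta")
    if a.mu_h is None or b.mu_h is None:
        raise ValueError("both profiles need a moment track")
    max_a = float(a.mu_h.max())
    max_b = float(b.mu_h.max())
    if segments is None:
        segments = detect_amphiphilic_segments(a)
    peaks = []
    for seg in segments:
        mask = (a.positions >= seg.start) & (a.positions <= seg.end)
        peak = float(a.mu_h[mask].max()) if mask.any() else 0.0
        peaks.append((seg, peak, max_b > 0 and peak >= fraction * max_b))
    return ProfileComparison(max_a, max_b, peaks, fraction)


def load_packaged_sequence(name: str) -> str:
    """Load a packaged FASTA sequence (mellitin, alpha_synuclein,
    vapb_wt_synthetic, vapb_p56s_synthetic)."""
    from Bio import SeqIO
    from io import StringIO

    text = resources.files("nmrtopo.data").joinpath(f"{name}.fasta").read_text()
    rec = next(SeqIO.parse(StringIO(text), "fasta"))
    return str(rec.seq).upper()


def write_profile_tsv(profile: HydropathyProfile, path) -> None:
    with open(path, "w") as fh:
        fh.write("position\tmean_h\tmu_h_per_res\n")
        for i, pos in enumerate(profile.positions):
            mu = "" if profile.mu_h is None else f"{profile.mu_h[i]:.4f}"
            fh.write(f"{pos}\t{profile.mean_h[i]:.4f}\t{mu}\n")
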
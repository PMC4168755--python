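"""Secondary chemical shifts and helix-segment calling.

The secondary-shift index used here is the difference of Calpha and Cbeta
secondary shifts, (Cα_obs − Cα_rc) − (Cβ_obs − Cβ_rc).  Sustained positive
runs of this index mark α-helix; sustained negative runs mark β-strand.
Glycine has no Cβ, so its index is the Cα secondary shift alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Optional

from .io_formats import ShiftTable, ValidationError

DEFAULT_HELIX_THRESHOLD = 1.4  # ppm
DEFAULT_MIN_LEN = 4
DEFAULT_MAX_GAP = 1


@dataclass(frozen=True)
class HelixSegment:
    """Inclusive residue range forming one helix."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValidationError(f"segment end {self.end} < start {self.start}")

    def __len__(self) -> int:
        return self.end - self.start + 1

    def overlap(self, other: "HelixSegment") -> int:
        return max(0, min(self.end, other.end) - max(self.start, other.start) + 1)

    def __contains__(self, index: int) -> bool:
        return self.start <= index <= self.end


@dataclass
class SecondaryShiftProfile:
    """Per-residue (ΔCα−ΔCβ) values in ppm; absent residues are simply missing."""

    values: dict[int, float]
    aa: dict[int, str] = field(default_factory=dict)
    reference_set_name: str = ""


def load_random_coil_refs() -> tuple[dict[str, dict[str, float]], str]:
    """Load the packaged random-coil Cα/Cβ reference table.

    Returns (refs, reference_set_name) where refs maps one-letter code to
    {'CA': ppm, 'CB': ppm} (glycine has no 'CB' key).
    """
    refs: dict[str, dict[str, float]] = {}
    text = resources.files("nmrtopo.data").joinpath("random_coil_shifts.tsv").read_text()
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#") or line.startswith("aa"):
            continue
        fields = line.split("\t")
        entry = {"CA": float(fields[1])}
        if len(fields) > 2 and fields[2]:
            entry["CB"] = float(fields[2])
        refs[fields[0]] = entry
    return refs, "wishart1995"


def secondary_shifts(
    shifts: ShiftTable,
    refs: Optional[dict[str, dict[str, float]]] = None,
    reference_set_name: Optional[str] = None,
) -> SecondaryShiftProfile:
    """Compute per-residue (ΔCα−ΔCβ) against a random-coil reference.

    Glycine contributes its Cα secondary shift only.  A residue whose
    observed or reference shift is missing gets no value.  Residue types
    absent from the reference raise an error naming the residue.
    """
    if refs is None:
        refs, reference_set_name = load_random_coil_refs()
    values: dict[int, float] = {}
    aa_map: dict[int, str] = {}
    for entry in shifts.entries:
        aa = entry.residue.aa
        aa_map[entry.residue.index] = aa
        if aa not in refs:
            raise ValidationError(
                f"residue type {aa!r} at position {entry.residue.index} "
                "is missing from the random-coil reference"
            )
        ref = refs[aa]
        if aa == "G":
            if entry.ca_shift is None:
                continue
            values[entry.residue.index] = entry.ca_shift - ref["CA"]
            continue
        if entry.ca_shift is None or entry.cb_shift is None:
            continue
        if "CB" not in ref:
            raise ValidationError(f"reference lacks CB for residue type {aa!r}")
        values[entry.residue.index] = (entry.ca_shift - ref["CA"]) - (
            entry.cb_shift - ref["CB"]
        )
    return SecondaryShiftProfile(
        values=values, aa=aa_map, reference_set_name=reference_set_name or "custom"
    )


def call_helices(
    profile: SecondaryShiftProfile,
    threshold: float = DEFAULT_HELIX_THRESHOLD,
    min_len: int = DEFAULT_MIN_LEN,
    max_gap: int = DEFAULT_MAX_GAP,
    sense: int = +1,
) -> list[HelixSegment]:
    """Call maximal helical segments from a secondary-shift profile.

    A segment is a maximal run of residues whose index value is >= threshold
    (for ``sense=+1``; <= -threshold for strand calling with ``sense=-1``),
    tolerating up to ``max_gap`` consecutive sub-threshold or absent residues
    inside the run.  Segments always start and end on qualifying residues;
    runs spanning fewer than ``min_len`` residues are dropped.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if min_len < 3:
        raise ValueError("min_len must be >= 3")
    qualifying = sorted(
        idx for idx, v in profile.values.items() if sense * v >= threshold
    )
    if not qualifying:
        return []
    segments: list[HelixSegment] = []
    start = prev = qualifying[0]
    for idx in qualifying[1:]:
        if idx - prev - 1 <= max_gap:
            prev = idx
        else:
            segments.append(HelixSegment(start, prev))
            start = prev = idx
    segments.append(HelixSegment(start, prev))
    return [s for s in segments if len(s) >= min_len]


def call_strands(
    profile: SecondaryShiftProfile,
    threshold: float = DEFAULT_HELIX_THRESHOLD,
    min_len: int = DEFAULT_MIN_LEN,
    max_gap: int = DEFAULT_MAX_GAP,
) -> list[HelixSegment]:
    """Symmetric strand caller (runs of values <= -threshold); off by default
    in the pipeline."""
    return call_helices(profile, threshold, min_len, max_gap, sense=-1)


def write_profile_tsv(profile: SecondaryShiftProfile, segments: list[HelixSegment], path) -> None:
    in_helix = set()
    for s in segments:
        in_helix.update(range(s.start, s.end + 1))
    with open(path, "w") as fh:
        fh.write("residue\taa\tdelta_ca_cb\thelix_flag\n")
        for idx in sorted(profile.aa):
            v = profile.values.get(idx)
            vtxt = "" if v is None else f"{v:.3f}"
            fh.write(f"{idx}\t{profile.aa[idx]}\t{vtxt}\t{int(idx in in_helix)}\n")


def write_segments_tsv(segments: list[HelixSegment], path) -> None:
    with open(path, "w") as fh:
        fh.write("start\tend\tlength\n")
        for s in segments:
            fh.write(f"{s.start}\t{s.end}\t{len(s)}\n")
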
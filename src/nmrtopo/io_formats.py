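"""Readers and writers for the tables and coordinate files the pipeline touches.

Everything downstream shares one residue-numbering convention: 1-based
sequence positions, one-letter amino-acid codes.  Coordinate files are
trusted for their own numbering and are never renumbered silently.
Intensities are unitless; only ratios are ever interpreted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import gemmi
import numpy as np
from Bio import SeqIO

logger = logging.getLogger(__name__)

AA1 = set("ACDEFGHIKLMNPQRSTVWY")

AA3_TO_1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AA1_TO_3 = {v: k for k, v in AA3_TO_1.items()}

BACKBONE_ATOMS = ("N", "CA", "C", "O")


class ParseError(ValueError):
    """A file could not be parsed under the named dialect."""


class ValidationError(ValueError):
    """Parsed content violates a structural invariant."""


@dataclass(frozen=True, order=True)
class ResidueId:
    """1-based sequence position plus one-letter amino-acid code."""

    index: int
    aa: str

    def __post_init__(self) -> None:
        if self.index < 1:
            raise ValidationError(f"residue index must be >= 1, got {self.index}")
        if self.aa not in AA1 and self.aa != "X":
            raise ValidationError(f"unknown amino-acid code {self.aa!r}")


@dataclass(frozen=True)
class ShiftEntry:
    residue: ResidueId
    ca_shift: Optional[float]  # ppm
    cb_shift: Optional[float]  # ppm


@dataclass
class ShiftTable:
    """Per-residue observed Calpha/Cbeta chemical shifts under one condition."""

    entries: list[ShiftEntry]
    condition_label: str = ""

    def __post_init__(self) -> None:
        indices = [e.residue.index for e in self.entries]
        if len(set(indices)) != len(indices):
            dup = sorted({i for i in indices if indices.count(i) > 1})
            raise ValidationError(f"duplicate residue indices: {dup}")
        if indices != sorted(indices):
            raise ValidationError("residue indices must be strictly increasing")
        for e in self.entries:
            if e.residue.aa == "G" and e.cb_shift is not None:
                raise ValidationError(
                    f"glycine at position {e.residue.index} cannot carry a Cbeta shift"
                )

    def __len__(self) -> int:
        return len(self.entries)


@dataclass(frozen=True)
class PeakPair:
    """Paired paramagnetic/diamagnetic peak heights for one amide."""

    residue: ResidueId
    i_para: float
    i_dia: float
    sigma: float = 0.0

    def __post_init__(self) -> None:
        if self.i_dia <= 0:
            raise ValidationError(
                f"diamagnetic intensity must be positive (residue {self.residue.index})"
            )
        if self.sigma < 0:
            raise ValidationError("sigma must be non-negative")


@dataclass(frozen=True)
class SpinLabelSite:
    """Cysteine-engineered nitroxide attachment point."""

    residue: ResidueId
    label_name: str = "MTSSL"


@dataclass(frozen=True)
class PRERestraint:
    """One label-site -> amide distance bound derived from an intensity ratio.

    ``d`` is the centre distance in Angstrom; ``lower``/``upper`` bracket it.
    Class ``unrestrained`` entries carry no distance (all three are None).
    """

    site: SpinLabelSite
    residue: ResidueId
    d: Optional[float]
    lower: Optional[float]
    upper: Optional[float]
    klass: str  # unrestrained | bounded | upper_only | vanished

    def __post_init__(self) -> None:
        if self.klass in ("bounded", "upper_only"):
            if self.d is None or self.d <= 0:
                raise ValidationError("restrained entries need a positive distance")
            if not (self.lower <= self.d <= self.upper):
                raise ValidationError("restraint bounds must bracket the distance")
        elif self.klass == "unrestrained":
            if self.d is not None:
                raise ValidationError("unrestrained entries carry no distance")


# ---------------------------------------------------------------------------
# Structure ensembles
# ---------------------------------------------------------------------------

@dataclass
class StructureEnsemble:
    """Multi-model coordinates with a shared residue/atom roster.

    ``models`` maps, per model, residue index -> ``ModelResidue``.
    """

    models: list[dict[int, "ModelResidue"]]
    source_id: str = ""

    def __post_init__(self) -> None:
        if not self.models:
            raise ValidationError("ensemble needs at least one model")
        roster = self.roster()
        for m, model in enumerate(self.models[1:], start=2):
            other = {i: tuple(sorted(r.atoms)) for i, r in model.items()}
            if other != roster:
                missing = set(roster) ^ set(other)
                detail = f"residues {sorted(missing)}" if missing else "atom names differ"
                raise ValidationError(
                    f"model {m} roster differs from model 1: {detail}"
                )

    def roster(self) -> dict[int, tuple[str, ...]]:
        return {i: tuple(sorted(r.atoms)) for i, r in self.models[0].items()}

    @property
    def n_models(self) -> int:
        return len(self.models)

    def residue_indices(self) -> list[int]:
        return sorted(self.models[0])


@dataclass
class ModelResidue:
    residue: ResidueId
    atoms: dict[str, np.ndarray]          # atom name -> xyz (Angstrom)
    elements: dict[str, str] = field(default_factory=dict)

    def is_hydrogen(self, name: str) -> bool:
        el = self.elements.get(name, "")
        if el:
            return el.upper() in ("H", "D")
        return name.lstrip("0123456789").startswith(("H", "D"))


# ---------------------------------------------------------------------------
# Shift tables
# ---------------------------------------------------------------------------

_MISSING = {"", ".", "na", "nan", "none", "-"}


def _parse_shift(token: str, path: str, lineno: int) -> Optional[float]:
    if token.strip().lower() in _MISSING:
        return None
    try:
        return float(token)
    except ValueError as exc:
        raise ParseError(f"{path}:{lineno}: bad shift value {token!r}") from exc


def read_shift_table(path, dialect: str = "tsv", condition_label: str = "") -> ShiftTable:
    """Read a per-residue Calpha/Cbeta shift table.

    ``tsv`` expects columns residue, aa, CA, CB (header optional, tab or
    whitespace separated).  ``nmrstar-lite`` accepts a STAR loop carrying the
    standard Atom_chem_shift tags.  Rows missing both Calpha and Cbeta are
    dropped with a logged warning.
    """
    path = Path(path)
    if dialect == "tsv":
        entries = _read_shift_tsv(path)
    elif dialect == "nmrstar-lite":
        entries = _read_shift_star(path)
    else:
        raise ValueError(f"unknown shift-table dialect {dialect!r}")

    kept = []
    for e in entries:
        if e.ca_shift is None and e.cb_shift is None:
            logger.warning("dropping residue %d: no CA or CB shift", e.residue.index)
            continue
        kept.append(e)
    if not kept:
        logger.warning("shift table %s has no usable rows", path)
    return ShiftTable(entries=kept, condition_label=condition_label)


def _read_shift_tsv(path: Path) -> list[ShiftEntry]:
    entries = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if lineno == 1 and not fields[0].lstrip("-").isdigit():
                continue  # header row
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected >= 3 columns, got {len(fields)}")
            try:
                idx = int(fields[0])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: bad residue index {fields[0]!r}") from exc
            aa = fields[1].strip().upper()
            if len(aa) == 3:
                aa = AA3_TO_1.get(aa, "X")
            ca = _parse_shift(fields[2], str(path), lineno)
            cb = _parse_shift(fields[3], str(path), lineno) if len(fields) > 3 else None
            entries.append(ShiftEntry(ResidueId(idx, aa), ca, cb))
    return entries


_STAR_TAGS = {
    "_atom_chem_shift.comp_index_id": "index",
    "_atom_chem_shift.seq_id": "index",
    "_atom_chem_shift.comp_id": "comp",
    "_atom_chem_shift.atom_id": "atom",
    "_atom_chem_shift.val": "val",
}


def _read_shift_star(path: Path) -> list[ShiftEntry]:
    """Minimal NMR-STAR loop reader for Atom_chem_shift rows (CA/CB only)."""
    columns: list[str] = []
    rows: list[list[str]] = []
    in_loop = False
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if line == "loop_":
                in_loop, columns = True, []
                continue
            if line in ("stop_",) or line.startswith("save_"):
                in_loop = False
                continue
            if in_loop and line.startswith("_"):
                columns.append(line.split()[0].lower())
                continue
            if in_loop and columns:
                if not any(c in _STAR_TAGS for c in columns):
                    continue
                vals = line.split()
                if len(vals) != len(columns):
                    raise ParseError(f"{path}:{lineno}: row width {len(vals)} != loop width {len(columns)}")
                rows.append(vals)

    want = {c: _STAR_TAGS[c] for c in columns if c in _STAR_TAGS}
    if not want:
        raise ParseError(f"{path}: no Atom_chem_shift loop found")
    pos = {role: columns.index(tag) for tag, role in want.items()}
    per_res: dict[int, dict[str, object]] = {}
    for vals in rows:
        atom = vals[pos["atom"]].upper()
        if atom not in ("CA", "CB"):
            continue
        idx = int(vals[pos["index"]])
        comp = vals[pos["comp"]].upper()
        aa = AA3_TO_1.get(comp, comp if comp in AA1 else "X")
        rec = per_res.setdefault(idx, {"aa": aa, "CA": None, "CB": None})
        rec[atom] = float(vals[pos["val"]])
    return [
        ShiftEntry(ResidueId(i, rec["aa"]), rec["CA"], rec["CB"])
        for i, rec in sorted(per_res.items())
    ]


def write_shift_table(table: ShiftTable, path) -> None:
    with open(path, "w") as fh:
        fh.write("residue\taa\tCA\tCB\n")
        for e in table.entries:
            ca = "" if e.ca_shift is None else f"{e.ca_shift:.3f}"
            cb = "" if e.cb_shift is None else f"{e.cb_shift:.3f}"
            fh.write(f"{e.residue.index}\t{e.residue.aa}\t{ca}\t{cb}\n")


# ---------------------------------------------------------------------------
# Peak-pair tables (per spin-label site)
# ---------------------------------------------------------------------------

def read_peak_pairs(path, sequence: Optional[str] = None) -> list[PeakPair]:
    """Read a per-site TSV of columns residue, aa, i_para, i_dia, sigma."""
    pairs = []
    seen: set[int] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if lineno == 1 and not fields[0].lstrip("-").isdigit():
                continue
            if len(fields) < 4:
                raise ParseError(f"{path}:{lineno}: expected >= 4 columns")
            idx = int(fields[0])
            if idx in seen:
                raise ValidationError(f"{path}:{lineno}: duplicate residue index {idx}")
            seen.add(idx)
            aa = fields[1].strip().upper()
            if len(aa) == 3:
                aa = AA3_TO_1.get(aa, "X")
            sigma = float(fields[4]) if len(fields) > 4 else 0.0
            pairs.append(PeakPair(ResidueId(idx, aa), float(fields[2]), float(fields[3]), sigma))
    return pairs


def write_peak_pairs(pairs: Iterable[PeakPair], path) -> None:
    pairs = sorted(pairs, key=lambda p: p.residue.index)
    with open(path, "w") as fh:
        fh.write("residue\taa\ti_para\ti_dia\tsigma\n")
        for p in pairs:
            fh.write(
                f"{p.residue.index}\t{p.residue.aa}\t{p.i_para:.6g}\t{p.i_dia:.6g}\t{p.sigma:.6g}\n"
            )


# ---------------------------------------------------------------------------
# Distance restraints
# ---------------------------------------------------------------------------

def write_distance_restraints(restraints: list[PRERestraint], path, format: str = "tsv") -> None:
    """Write PRE distance restraints as a TSV or Xplor-style assign text.

    Unrestrained entries are skipped with a logged count.  The TSV dialect
    round-trips bit-exactly through :func:`read_distance_restraints`.
    """
    if not restraints:
        raise ValueError("refusing to write an empty restraint list")
    writable = [r for r in restraints if r.klass != "unrestrained"]
    skipped = len(restraints) - len(writable)
    if skipped:
        logger.info("skipping %d unrestrained entries", skipped)
    writable = sorted(writable, key=lambda r: (r.site.residue.index, r.residue.index))
    if format == "tsv":
        with open(path, "w") as fh:
            fh.write("site\tsite_aa\tresidue\taa\td\tlower\tupper\tclass\n")
            for r in writable:
                fh.write(
                    f"{r.site.residue.index}\t{r.site.residue.aa}\t"
                    f"{r.residue.index}\t{r.residue.aa}\t"
                    f"{r.d!r}\t{r.lower!r}\t{r.upper!r}\t{r.klass}\n"
                )
    elif format == "xplor":
        with open(path, "w") as fh:
            for r in writable:
                d, lower, upper = r.d, r.lower, r.upper
                dminus = d - lower
                dplus = upper - d
                fh.write(
                    f"assign (resid {r.site.residue.index:4d} and name CA ) "
                    f"(resid {r.residue.index:4d} and name HN ) "
                    f"{d:7.2f} {dminus:6.2f} {dplus:6.2f}\n"
                )
    else:
        raise ValueError(f"unknown restraint format {format!r}")


def read_distance_restraints(path) -> list[PRERestraint]:
    """Read back the TSV dialect of :func:`write_distance_restraints`."""
    out = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("site"):
            raise ParseError(f"{path}: missing restraint header")
        for lineno, raw in enumerate(fh, start=2):
            line = raw.rstrip("\n")
            if not line:
                continue
            f = line.split("\t")
            if len(f) != 8:
                raise ParseError(f"{path}:{lineno}: expected 8 columns")
            parse = lambda s: None if s == "None" else float(s)
            out.append(
                PRERestraint(
                    site=SpinLabelSite(ResidueId(int(f[0]), f[1])),
                    residue=ResidueId(int(f[2]), f[3]),
                    d=parse(f[4]), lower=parse(f[5]), upper=parse(f[6]),
                    klass=f[7],
                )
            )
    return out


# ---------------------------------------------------------------------------
# PDB ensembles
# ---------------------------------------------------------------------------

def read_ensemble(path) -> StructureEnsemble:
    """Read a (possibly multi-MODEL) PDB file into a StructureEnsemble.

    HETATM records and waters are excluded; altloc 'A' or blank is kept.  A
    file with ATOM records but no MODEL records yields a single-model
    ensemble.  Models with differing atom rosters raise a validation error.
    """
    st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    st.setup_entities()
    models = []
    for model in st:
        residues: dict[int, ModelResidue] = {}
        for chain in model:
            for res in chain:
                if res.het_flag != "A" or res.name in ("HOH", "WAT", "DOD"):
                    continue
                aa = AA3_TO_1.get(res.name.upper(), "X")
                idx = res.seqid.num
                atoms: dict[str, np.ndarray] = {}
                elements: dict[str, str] = {}
                for atom in res:
                    if atom.has_altloc() and atom.altloc != "A":
                        continue
                    xyz = np.array([atom.pos.x, atom.pos.y, atom.pos.z], dtype=float)
                    if not np.all(np.isfinite(xyz)):
                        raise ValidationError(f"non-finite coordinates at residue {idx}")
                    atoms[atom.name] = xyz
                    elements[atom.name] = atom.element.name
                if idx in residues:
                    raise ValidationError(f"duplicate residue number {idx} within one model")
                residues[idx] = ModelResidue(ResidueId(idx, aa), atoms, elements)
        if residues:
            models.append(residues)
    if not models:
        raise ParseError(f"{path}: no coordinates found")
    return StructureEnsemble(models=models, source_id=Path(str(path)).stem)


def write_ca_models(models: list[dict[int, np.ndarray]], path,
                    sequence: Optional[str] = None, energies: Optional[list[float]] = None) -> None:
    """Write ranked Calpha-only models as a multi-MODEL PDB file."""
    with open(path, "w") as fh:
        for m, coords in enumerate(models, start=1):
            if energies is not None:
                fh.write(f"REMARK   3 MODEL {m} ENERGY {energies[m - 1]:.3f}\n")
            fh.write(f"MODEL     {m:4d}\n")
            serial = 1
            for idx in sorted(coords):
                x, y, z = coords[idx]
                aa1 = sequence[idx - 1] if sequence and idx <= len(sequence) else "G"
                res3 = AA1_TO_3.get(aa1, "GLY")
                fh.write(
                    f"ATOM  {serial:5d}  CA  {res3} A{idx:4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C\n"
                )
                serial += 1
            fh.write("ENDMDL\n")
        fh.write("END\n")


# ---------------------------------------------------------------------------
# Sequences and helix HELIX-record helpers
# ---------------------------------------------------------------------------

def read_fasta(path) -> dict[str, str]:
    """Read sequences keyed by record id."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def read_helix_records(path) -> list[tuple[int, int]]:
    """Extract (start, end) residue ranges from PDB HELIX records."""
    segments = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("HELIX"):
                segments.append((int(line[21:25]), int(line[33:37])))
    return sorted(segments)
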
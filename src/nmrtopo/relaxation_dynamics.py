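"""Backbone dynamics: heteronuclear NOE, CPMG dispersion, probe accessibility.

hNOE (saturated/reference intensity ratio) reports ps-ns backbone rigidity:
values near 1 mean a rigid amide, small or negative values a flexible one.
Constant-time CPMG dispersion reports micro-to-millisecond exchange through
R2eff(nu) = -ln(I(nu)/I0)/T_CP; the exchange indicator is
dR2 = R2eff(80 Hz) - R2eff(960 Hz), flagged at the 2 and 6 s^-1 tiers.
Differential attenuation by a water-soluble (gadodiamide) versus a
headgroup-partitioning (Mn2+) paramagnetic titrant classifies each amide as
water-exposed, headgroup-located, or buried/hydrogen-bonded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

from .io_formats import ResidueId

DEFAULT_FLAG_MODERATE = 2.0   # s^-1
DEFAULT_FLAG_STRONG = 6.0     # s^-1
DEFAULT_LOW_NU = 80.0         # Hz
DEFAULT_HIGH_NU = 960.0       # Hz
DEFAULT_ACCESS_CUTOFF = 0.5   # titration-endpoint intensity ratio


@dataclass(frozen=True)
class HNOERecord:
    residue: ResidueId
    i_sat: float
    i_ref: float

    @property
    def hnoe(self) -> float:
        return hnoe(self.i_sat, self.i_ref)


@dataclass
class CPMGSeries:
    """Intensity versus CPMG refocusing frequency for one residue."""

    residue: ResidueId
    t_cp: float                       # s
    points: list[tuple[float, float]]  # (nu_cpmg Hz, intensity); repeats allowed
    i0: float                          # reference-plane intensity

    def __post_init__(self) -> None:
        if self.t_cp <= 0:
            raise ValueError("t_cp must be positive")
        if self.i0 <= 0:
            raise ValueError("reference intensity must be positive")
        if any(nu <= 0 for nu, _ in self.points):
            raise ValueError("CPMG frequencies must be positive")


@dataclass
class DispersionProfile:
    residue: ResidueId
    r2eff: dict[float, float]          # nu_cpmg -> s^-1
    delta_r2: Optional[float]          # s^-1; None when 80 or 960 Hz absent
    exchange_flag: str                 # none | moderate | strong | unobserved
    unquantifiable: list[float] = field(default_factory=list)


@dataclass(frozen=True)
class AccessibilityRecord:
    residue_index: int
    klass: str   # water_exposed | headgroup | buried_or_bonded | unobserved


def hnoe(i_sat: float, i_ref: float) -> float:
    """Steady-state heteronuclear NOE: saturated over reference intensity.

    Negative values are meaningful (highly flexible amides) and are not
    clamped.
    """
    if i_ref == 0:
        raise ValueError("reference intensity must be nonzero")
    return i_sat / i_ref


def r2eff(intensity: float, i0: float, t_cp: float) -> float:
    """Effective transverse relaxation rate from constant-time CPMG.

    R2eff = -ln(I(nu)/I0) / T_CP.  Non-positive intensities mean the peak
    vanished and the rate is unquantifiable; callers at pipeline level mark
    the point rather than raising.
    """
    if i0 <= 0 or t_cp <= 0:
        raise ValueError("i0 and t_cp must be positive")
    if intensity <= 0:
        raise ValueError("non-positive intensity: peak unquantifiable")
    return -math.log(intensity / i0) / t_cp


def dispersion_profile(
    series: CPMGSeries,
    flag_moderate: float = DEFAULT_FLAG_MODERATE,
    flag_strong: float = DEFAULT_FLAG_STRONG,
    low_nu: float = DEFAULT_LOW_NU,
    high_nu: float = DEFAULT_HIGH_NU,
) -> DispersionProfile:
    """Convert a CPMG intensity series into R2eff(nu) and an exchange flag.

    Repeated frequencies (e.g. the duplicated 120 and 960 Hz planes) are
    averaged in intensity before conversion.  The exchange indicator
    delta_r2 = R2eff(low_nu) - R2eff(high_nu) requires both planes; if either
    is missing or unquantifiable the flag is ``unobserved``.
    """
    by_nu: dict[float, list[float]] = {}
    for nu, inten in series.points:
        by_nu.setdefault(nu, []).append(inten)
    rates: dict[float, float] = {}
    unquantifiable: list[float] = []
    for nu, vals in sorted(by_nu.items()):
        mean = sum(vals) / len(vals)
        if mean <= 0:
            unquantifiable.append(nu)
            continue
        rates[nu] = r2eff(mean, series.i0, series.t_cp)
    if low_nu in rates and high_nu in rates:
        delta = rates[low_nu] - rates[high_nu]
        if delta > flag_strong:
            flag = "strong"
        elif delta > flag_moderate:
            flag = "moderate"
        else:
            flag = "none"
    else:
        delta, flag = None, "unobserved"
    return DispersionProfile(series.residue, rates, delta, flag, unquantifiable)


def classify_accessibility(
    gado_ratios: dict[int, float],
    mn_ratios: dict[int, float],
    cutoff: float = DEFAULT_ACCESS_CUTOFF,
    roster: Optional[list[int]] = None,
) -> list[AccessibilityRecord]:
    """Classify residues by differential paramagnetic-titrant attenuation.

    A residue attenuated below ``cutoff`` by gadodiamide is water-exposed
    (gadodiamide takes precedence even if Mn2+ also attenuates it); one
    attenuated only by Mn2+ sits in the headgroup region; one attenuated by
    neither is buried in the hydrocarbon phase or hydrogen-bonded.  Residues
    absent from both maps are unobserved.
    """
    if not (0.0 < cutoff < 1.0):
        raise ValueError("cutoff must lie in (0, 1)")
    indices = roster if roster is not None else sorted(set(gado_ratios) | set(mn_ratios))
    records = []
    for idx in indices:
        gado = gado_ratios.get(idx)
        mn = mn_ratios.get(idx)
        if gado is None and mn is None:
            klass = "unobserved"
        elif gado is not None and gado < cutoff:
            klass = "water_exposed"
        elif mn is not None and mn < cutoff:
            klass = "headgroup"
        else:
            klass = "buried_or_bonded"
        records.append(AccessibilityRecord(idx, klass))
    return records


def accessibility_counts(records: list[AccessibilityRecord]) -> dict[str, int]:
    counts: dict[str, int] = {}
    for r in records:
        counts[r.klass] = counts.get(r.klass, 0) + 1
    return counts


def write_dynamics_tsv(
    hnoe_records: list[HNOERecord],
    profiles: list[DispersionProfile],
    access: list[AccessibilityRecord],
    path,
) -> None:
    """One row per residue: hnoe, delta_r2, exchange flag, accessibility class."""
    hn = {r.residue.index: r.hnoe for r in hnoe_records}
    dp = {p.residue.index: p for p in profiles}
    ac = {r.residue_index: r.klass for r in access}
    with open(path, "w") as fh:
        fh.write("residue\thnoe\tdelta_r2\texchange_flag\taccessibility_class\n")
        for idx in sorted(set(hn) | set(dp) | set(ac)):
            p = dp.get(idx)
            delta = "" if p is None or p.delta_r2 is None else f"{p.delta_r2:.3f}"
            flag = "" if p is None else p.exchange_flag
            h = "" if idx not in hn else f"{hn[idx]:.3f}"
            fh.write(f"{idx}\t{h}\t{delta}\t{flag}\t{ac.get(idx, '')}\n")
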
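"""Paramagnetic relaxation enhancement: intensity ratios -> rates -> distances.

The conversion chain is the standard two-step procedure for nitroxide
spin labels:

1. the paramagnetic/diamagnetic peak-height ratio is inverted through
   ``ratio = R2_dia * exp(-R2sp * t) / (R2_dia + R2sp)`` to obtain the
   label-induced transverse relaxation rate R2sp (the extra broadening the
   unpaired electron adds during the INEPT evolution time ``t``), and
2. R2sp is converted to an electron-amide distance through the r^-6
   dipolar relation
   ``d = [ K/R2sp * (4*tau_c + 3*tau_c / (1 + omega_h^2 tau_c^2)) ]^(1/6)``.

Peaks with ratio above ``ratio_cutoff`` (default 0.85) are unaffected by the
probe and are not restrained; peaks vanishing below ``vanish_cutoff`` give an
upper bound only.  Distances scale only as tau_c^(1/6), but tau_c for a
protein-micelle complex is still the least certain parameter here — it is
config-exposed and recorded in every output.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional

from scipy.optimize import brentq

from .io_formats import PeakPair, PRERestraint, ResidueId, SpinLabelSite

logger = logging.getLogger(__name__)

# standard nitroxide-proton PRE constant, Angstrom^6 s^-2
DEFAULT_K_CONST = 1.23e16


@dataclass(frozen=True)
class PREParams:
    """Conversion parameters for the ratio -> distance chain."""

    r2_dia: float = 20.0          # s^-1, diamagnetic linewidth
    t_inept: float = 0.010        # s, INEPT evolution during which PRE acts
    tau_c: float = 15e-9          # s, rotational correlation time of the complex
    omega_h: float = 2 * math.pi * 800e6   # rad/s, proton Larmor frequency
    k_const: float = DEFAULT_K_CONST       # Angstrom^6 s^-2
    ratio_cutoff: float = 0.85    # above: peak unaffected, not restrained
    vanish_cutoff: float = 0.15   # below: peak vanished, upper bound only
    bound_width: float = 4.0      # Angstrom, +/- width of bounded restraints


@dataclass(frozen=True)
class PREMeasurement:
    site: SpinLabelSite
    residue: ResidueId
    ratio: float
    ratio_err: float = 0.0
    r2sp: Optional[float] = None
    klass: str = "bounded"   # unrestrained | bounded | upper_only | vanished


@dataclass
class SiteReport:
    """Per-site QC summary: how each residue was classified."""

    site: SpinLabelSite
    n_input: int = 0
    counts: dict[str, int] = field(default_factory=dict)

    def total(self) -> int:
        return sum(self.counts.values())


def intensity_ratio(pair: PeakPair) -> tuple[float, float]:
    """Return (I_para/I_dia, propagated uncertainty).

    Negative paramagnetic intensities are noise-floor artefacts and are
    clamped to zero with a warning.  First-order propagation assumes the same
    intensity noise ``sigma`` on both peaks.
    """
    i_para = pair.i_para
    if i_para < 0:
        logger.warning(
            "residue %d: negative paramagnetic intensity %.3g clamped to 0",
            pair.residue.index, i_para,
        )
        i_para = 0.0
    ratio = i_para / pair.i_dia
    err = (pair.sigma / pair.i_dia) * math.sqrt(1.0 + ratio * ratio)
    return ratio, err


def ratio_to_r2sp(ratio: float, r2_dia: float, t_inept: float) -> float:
    """Invert the intensity-ratio relation for the PRE rate R2sp.

    Solves ``ratio = r2_dia * exp(-r2sp * t_inept) / (r2_dia + r2sp)`` for
    the unique root r2sp in (0, inf), to relative tolerance 1e-8.  Ratios at
    or beyond the [0, 1) open interval are rejected: ratio >= 1 means the
    peak is unaffected (handled upstream as unrestrained) and ratio = 0
    means the peak vanished (handled upstream as an upper bound).
    """
    if not (0.0 < ratio < 1.0):
        raise ValueError(f"ratio must lie strictly in (0, 1), got {ratio}")
    if r2_dia <= 0 or t_inept <= 0:
        raise ValueError("r2_dia and t_inept must be positive")

    def f(r2sp: float) -> float:
        return r2_dia * math.exp(-r2sp * t_inept) / (r2_dia + r2sp) - ratio

    hi = 1.0
    while f(hi) > 0:
        hi *= 2.0
        if hi > 1e9:  # pragma: no cover - unreachable for ratio > 0
            raise RuntimeError("failed to bracket R2sp root")
    return brentq(f, 0.0, hi, rtol=1e-10, xtol=1e-12)


def r2sp_from_distance(d: float, params: PREParams) -> float:
    """Forward r^-6 dipolar relation: distance (Angstrom) -> R2sp (s^-1)."""
    tau = params.tau_c
    spectral = 4.0 * tau + 3.0 * tau / (1.0 + (params.omega_h * tau) ** 2)
    return params.k_const * spectral / d**6


def r2sp_to_distance(r2sp: float, tau_c: float, omega_h: float,
                     k_const: float = DEFAULT_K_CONST) -> float:
    """Invert the r^-6 dipolar relation: R2sp (s^-1) -> distance (Angstrom)."""
    if min(r2sp, tau_c, omega_h, k_const) <= 0:
        raise ValueError("all arguments must be positive")
    spectral = 4.0 * tau_c + 3.0 * tau_c / (1.0 + (omega_h * tau_c) ** 2)
    return (k_const / r2sp * spectral) ** (1.0 / 6.0)


def ratio_to_distance(ratio: float, params: PREParams) -> float:
    """Two-step conversion: intensity ratio -> R2sp -> distance."""
    r2sp = ratio_to_r2sp(ratio, params.r2_dia, params.t_inept)
    return r2sp_to_distance(r2sp, params.tau_c, params.omega_h, params.k_const)


def classify_pairs(pairs: list[PeakPair], site: SpinLabelSite,
                   params: PREParams) -> list[PREMeasurement]:
    """Turn raw peak pairs for one spin-label site into classified measurements."""
    out = []
    for pair in pairs:
        ratio, err = intensity_ratio(pair)
        if ratio > params.ratio_cutoff:
            klass, r2sp = "unrestrained", None
        elif ratio < params.vanish_cutoff:
            klass, r2sp = "vanished", None
        else:
            klass = "bounded"
            r2sp = ratio_to_r2sp(ratio, params.r2_dia, params.t_inept)
        out.append(PREMeasurement(site, pair.residue, ratio, err, r2sp, klass))
    return out


def build_restraints(
    measurements: list[PREMeasurement],
    params: PREParams = PREParams(),
) -> tuple[list[PRERestraint], SiteReport]:
    """Convert classified measurements into distance restraints.

    Returns the restraint list plus a per-site QC report.  Residues
    coinciding with the label site are excluded (the label replaces their
    side chain) with a logged note; every other input appears exactly once,
    so the report's class counts plus the excluded count equal the input
    size.
    """
    if not measurements:
        return [], SiteReport(site=None)
    site = measurements[0].site
    if any(m.site != site for m in measurements):
        raise ValueError("build_restraints expects measurements for a single site")
    report = SiteReport(site=site, n_input=len(measurements))
    vanish_distance = ratio_to_distance(params.vanish_cutoff, params)
    restraints = []
    for m in measurements:
        if m.residue.index == site.residue.index:
            logger.info("excluding residue %d: coincides with label site", m.residue.index)
            report.counts["excluded"] = report.counts.get("excluded", 0) + 1
            continue
        if m.klass == "unrestrained":
            restraints.append(PRERestraint(site, m.residue, None, None, None, "unrestrained"))
            report.counts["unrestrained"] = report.counts.get("unrestrained", 0) + 1
        elif m.klass == "vanished":
            upper = vanish_distance
            restraints.append(
                PRERestraint(site, m.residue, upper, 0.0, upper, "upper_only")
            )
            report.counts["upper_only"] = report.counts.get("upper_only", 0) + 1
        else:
            d = r2sp_to_distance(m.r2sp, params.tau_c, params.omega_h, params.k_const)
            lower = max(0.0, d - params.bound_width)
            upper = d + params.bound_width
            restraints.append(PRERestraint(site, m.residue, d, lower, upper, "bounded"))
            report.counts["bounded"] = report.counts.get("bounded", 0) + 1
    return restraints, report
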
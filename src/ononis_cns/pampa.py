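"""PAMPA-BBB: effective permeability, membrane retention, classification.

A donor and an acceptor compartment are separated by a lipid-coated
filter.  From the donor concentration at t = 0 and the donor/acceptor
concentrations at incubation time t, the mass balance gives the
membrane retention

    MR = 1 - C_D(t)/C_D(0) - (V_A/V_D) * C_A(t)/C_D(0)

and the effective permeability (cm/s)

    Pe = -2.303 / (A (t - tau_ss)) * (V_A V_D / (V_A + V_D))
         * log10[ 1 - ((V_A + V_D) / ((1 - MR) V_D)) * C_A(t)/C_D(0) ]

where A is the filter area, V_D/V_A the compartment volumes, tau_ss the
steady-state lag, and retained mass is treated as removed from the
transport equilibrium (the (1 - MR) correction).  Only the ratio
C_A(t)/C_D(0) enters, so concentrations need only share a unit.

Three literature cutoff schemes convert log Pe into BBB+/BBB-/uncertain
calls; the zone bounds are held as Pe values and compared on the Pe
scale, with boundaries belonging to the more permeable category.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "PampaGeometry",
    "PampaWell",
    "PampaResult",
    "PampaAggregate",
    "StandardCompound",
    "CalibrationResult",
    "SCHEMES",
    "retention_factor",
    "membrane_retention",
    "effective_permeability",
    "log_pe",
    "classify_bbb",
    "analyze_well",
    "aggregate_pampa",
    "skeleton_mean_MR",
    "calibrate_standards",
]

#: negative-MR clamp window: small negative estimates are measurement
#: noise around MR = 0; anything below is a mass-balance violation
MR_NOISE_TOLERANCE = 0.02

#: classification scheme names
SCHEMES = ("konczol", "di", "mensch")

# Pe-scale cutoffs. The "konczol" discriminator is stated as
# log Pe = -6.0; the "di" uncertain zone spans 2e-6..4e-6 cm/s (the
# printed log bounds -5.69/-5.39 are truncations of -5.699/-5.398).
KONCZOL_CUTOFF_PE = 1e-6
DI_LOWER_PE = 2e-6
DI_UPPER_PE = 4e-6
#: default in vitro BBB+ threshold for the "mensch" scheme (cm/s)
MENSCH_DEFAULT_CUTOFF_PE = 4e-6


@dataclass(frozen=True)
class PampaGeometry:
    """Plate geometry and timing. Units: cm^2, cm^3, s."""

    A: float = 0.24
    V_D: float = 0.15
    V_A: float = 0.18
    t: float = 4 * 3600.0
    tau_ss: float = 240.0

    def __post_init__(self) -> None:
        for name in ("A", "V_D", "V_A", "t", "tau_ss"):
            if getattr(self, name) <= 0:
                raise ValueError(f"geometry field {name} must be positive")
        if self.t <= self.tau_ss:
            raise ValueError(f"incubation time t={self.t} must exceed tau_ss={self.tau_ss}")


@dataclass(frozen=True)
class PampaWell:
    """Concentrations of one well (any consistent unit)."""

    C_D0: float
    C_Dt: float
    C_At: float
    compound_id: str | None = None
    day: int | None = None
    replicate: int | None = None

    def __post_init__(self) -> None:
        if self.C_D0 <= 0:
            raise ValueError(f"C_D0 must be positive, got {self.C_D0}")
        if self.C_Dt < 0 or self.C_At < 0:
            raise ValueError("concentrations at time t must be nonnegative")

    def label(self) -> str:
        parts = [self.compound_id or "well"]
        if self.day is not None:
            parts.append(f"day {self.day}")
        if self.replicate is not None:
            parts.append(f"replicate {self.replicate}")
        return ", ".join(parts)


@dataclass(frozen=True)
class PampaResult:
    """Derived quantities for one well."""

    Pe: float
    logPe: float
    MR: float
    classifications: Mapping[str, str] = field(default_factory=dict)
    compound_id: str | None = None
    day: int | None = None
    replicate: int | None = None


@dataclass(frozen=True)
class PampaAggregate:
    mean_logPe: float
    sd_logPe: float
    mean_MR: float
    n: int


@dataclass(frozen=True)
class StandardCompound:
    """A calibration standard with a literature log BB value."""

    name: str
    logBB_literature: float
    logPe: float


@dataclass(frozen=True)
class CalibrationResult:
    slope: float
    intercept: float
    r_squared: float
    n: int


def retention_factor(tR: float, t0: float) -> float:
    """Chromatographic retention (capacity) factor k = (tR - t0)/t0."""
    if t0 <= 0:
        raise ValueError(f"dead time t0 must be positive, got {t0}")
    if tR < t0:
        raise ValueError(f"retention time tR={tR} cannot precede dead time t0={t0}")
    return (tR - t0) / t0


def membrane_retention(w: PampaWell, g: PampaGeometry) -> float:
    """Membrane-retained mass fraction from the well mass balance.

    Small negative estimates (>= -0.02) are clamped to 0 with a warning;
    larger violations raise, as does retained+recovered mass exceeding
    the initial donor mass by more than the same tolerance.
    """
    mr = 1.0 - w.C_Dt / w.C_D0 - (g.V_A / g.V_D) * (w.C_At / w.C_D0)
    if mr < -MR_NOISE_TOLERANCE:
        raise ValueError(
            f"mass balance violated in {w.label()}: recovered mass exceeds initial "
            f"donor mass (MR = {mr:.4f} < -{MR_NOISE_TOLERANCE})"
        )
    if -1e-12 < mr < 0.0:  # pure float roundoff, not a noise signal
        return 0.0
    if mr < 0.0:
        warnings.warn(
            f"negative membrane retention {mr:.4f} in {w.label()} clamped to 0 "
            "(within noise tolerance)",
            stacklevel=2,
        )
        return 0.0
    return mr


def effective_permeability(w: PampaWell, g: PampaGeometry, MR: float) -> float:
    """Effective permeability Pe (cm/s) of one well given its MR.

    Pe = 0 exactly when no compound reached the acceptor.  Raises when
    the log argument is non-positive, i.e. the acceptor concentration
    exceeds the MR-corrected equilibrium value.
    """
    if not 0.0 <= MR < 1.0:
        raise ValueError(f"MR must be in [0, 1), got {MR}")
    if w.C_At == 0.0:
        return 0.0
    ratio = w.C_At / w.C_D0
    arg = 1.0 - ((g.V_A + g.V_D) / ((1.0 - MR) * g.V_D)) * ratio
    if arg <= 0.0:
        raise ValueError(
            f"invalid transport state in {w.label()}: acceptor concentration "
            f"exceeds the MR-corrected equilibrium (log argument {arg:.3e} <= 0)"
        )
    prefactor = -2.303 / (g.A * (g.t - g.tau_ss)) * (g.V_A * g.V_D / (g.V_A + g.V_D))
    return prefactor * math.log10(arg)


def log_pe(Pe: float) -> float:
    """log10 of the effective permeability; requires Pe > 0."""
    if Pe <= 0:
        raise ValueError(f"Pe must be positive to take log10, got {Pe}")
    return math.log10(Pe)


def classify_bbb(
    logPe: float,
    scheme: str,
    mensch_cutoff_pe: float = MENSCH_DEFAULT_CUTOFF_PE,
) -> str:
    """Classify one log Pe as 'BBB+', 'BBB-' or 'uncertain'.

    konczol : single discriminator at log Pe = -6.0.
    di      : uncertain zone between Pe = 2e-6 and 4e-6 cm/s.
    mensch  : single Pe cutoff, default 4e-6 cm/s (configurable).

    Exact boundary values fall into the more permeable category.
    """
    if not math.isfinite(logPe):
        raise ValueError(f"logPe must be finite, got {logPe}")
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; expected one of {SCHEMES}")
    pe = 10.0**logPe
    if scheme == "konczol":
        return "BBB+" if pe >= KONCZOL_CUTOFF_PE else "BBB-"
    if scheme == "di":
        if pe >= DI_UPPER_PE:
            return "BBB+"
        if pe >= DI_LOWER_PE:
            return "uncertain"
        return "BBB-"
    return "BBB+" if pe >= mensch_cutoff_pe else "BBB-"


def analyze_well(
    w: PampaWell,
    g: PampaGeometry | None = None,
    mensch_cutoff_pe: float = MENSCH_DEFAULT_CUTOFF_PE,
) -> PampaResult:
    """MR, Pe, log Pe and the three scheme verdicts for one well."""
    g = g or PampaGeometry()
    mr = membrane_retention(w, g)
    pe = effective_permeability(w, g, mr)
    lpe = log_pe(pe) if pe > 0 else -math.inf
    cls = (
        {s: classify_bbb(lpe, s, mensch_cutoff_pe) for s in SCHEMES}
        if math.isfinite(lpe)
        else {s: "BBB-" for s in SCHEMES}
    )
    return PampaResult(
        Pe=pe,
        logPe=lpe,
        MR=mr,
        classifications=cls,
        compound_id=w.compound_id,
        day=w.day,
        replicate=w.replicate,
    )


def aggregate_pampa(
    grouped: Mapping[str, Sequence[PampaResult]],
) -> dict[str, PampaAggregate]:
    """Per-compound mean/SD of log Pe and mean MR across wells and days.

    Averaging happens on the log10 scale, jointly pooling replicates and
    days; no cross-compound pooling.
    """
    out: dict[str, PampaAggregate] = {}
    for compound, results in grouped.items():
        if len(results) == 0:
            raise ValueError(f"empty result group for compound {compound!r}")
        lpe = np.asarray([r.logPe for r in results], dtype=float)
        mr = np.asarray([r.MR for r in results], dtype=float)
        sd = float(lpe.std(ddof=1)) if lpe.size > 1 else 0.0
        out[compound] = PampaAggregate(
            mean_logPe=float(lpe.mean()),
            sd_logPe=sd,
            mean_MR=float(mr.mean()),
            n=lpe.size,
        )
    return out


def skeleton_mean_MR(
    mr_by_compound: Mapping[str, float],
    class_by_compound: Mapping[str, str],
) -> dict[str, float]:
    """Mean membrane retention per skeleton class, in percent."""
    sums: dict[str, list[float]] = {}
    for compound, mr in mr_by_compound.items():
        if compound not in class_by_compound:
            raise ValueError(f"no skeleton class for compound {compound!r}")
        sums.setdefault(class_by_compound[compound], []).append(mr)
    return {cls: 100.0 * float(np.mean(vals)) for cls, vals in sums.items()}


def calibrate_standards(standards: Sequence[StandardCompound]) -> CalibrationResult:
    """OLS of measured log Pe on literature log BB over the standards."""
    if len(standards) < 3:
        raise ValueError(f"need at least 3 standards, got {len(standards)}")
    x = np.asarray([s.logBB_literature for s in standards], dtype=float)
    y = np.asarray([s.logPe for s in standards], dtype=float)
    if np.ptp(x) == 0.0:
        raise ValueError("degenerate calibration: all standards share one log BB")
    fit = stats.linregress(x, y)
    return CalibrationResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue) ** 2,
        n=len(standards),
    )
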
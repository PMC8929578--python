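"""Shake-flask octanol/water partitioning: log D^pH and log P estimation.

The distribution coefficient at the measurement pH is inferred from the
drop in aqueous-phase absorbance after equilibration with n-octanol:

    log D^pH = log10( ((A0 - A1) / A1) * R )

with A0/A1 the aqueous absorbance before/after partitioning and R the
aqueous-to-octanol phase-volume ratio.  The mass-balance derivation
places R inside the logarithm: the octanol concentration is
(A0 - A1) * R per unit aqueous signal, so the estimate is independent of
the phase ratio used.

Ionization is handled through the Henderson-Hasselbalch relation for a
monoprotic acid; the true partition coefficient log P is assigned from
the measurement pH at which the compound is essentially unionized.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "ShakeFlaskRecord",
    "ReplicateSummary",
    "PartitionResult",
    "LogPAssignment",
    "logD_shake_flask",
    "aggregate_replicates",
    "fraction_ionized",
    "assign_logP",
]

# relative absorbance drop below which the partitioning signal is
# dominated by measurement noise
LOW_SIGNAL_FRACTION = 0.005


@dataclass(frozen=True)
class ShakeFlaskRecord:
    """One shake-flask partition experiment.

    A0, A1 : aqueous absorbance before / after partitioning (a.u.)
    R      : phase ratio V_aqueous / V_octanol (e.g. 10 mL / 0.1 mL = 100)
    pH     : buffer pH of the aqueous phase
    """

    A0: float
    A1: float
    R: float
    pH: float
    wavelength_nm: float | None = None

    def __post_init__(self) -> None:
        if not (self.A0 > 0 and self.A1 > 0):
            raise ValueError(f"absorbances must be positive: A0={self.A0}, A1={self.A1}")
        if self.A1 >= self.A0:
            raise ValueError(
                f"A1 ({self.A1}) must be below A0 ({self.A0}): no measurable partitioning"
            )
        if self.R <= 0:
            raise ValueError(f"phase ratio R must be positive, got {self.R}")


@dataclass(frozen=True)
class ReplicateSummary:
    mean: float
    sd: float
    se: float
    n: int


@dataclass(frozen=True)
class PartitionResult:
    """Replicate-aggregated log D at one pH."""

    pH: float
    logD: float
    sd: float
    se: float
    n: int


@dataclass(frozen=True)
class LogPAssignment:
    """log P taken from the most-unionized measured pH."""

    logP: float
    pH_used: float
    pKa_used: float
    fraction_ionized: float


def logD_shake_flask(rec: ShakeFlaskRecord) -> float:
    """log D at ``rec.pH`` from one absorbance record.

    Warns when the absorbance drop is below ~0.5% of A0 (low signal).
    """
    drop = (rec.A0 - rec.A1) / rec.A0
    if drop < LOW_SIGNAL_FRACTION:
        warnings.warn(
            f"absorbance drop {drop:.2e} below {LOW_SIGNAL_FRACTION:.1%}: "
            "log D estimate is noise-dominated",
            stacklevel=2,
        )
    return math.log10((rec.A0 - rec.A1) / rec.A1 * rec.R)


def aggregate_replicates(values: Sequence[float]) -> ReplicateSummary:
    """Mean and sample SD (n-1 denominator) over parallel experiments.

    A single replicate yields SD = SE = 0 with a warning (no dispersion
    estimate is possible at n = 1).
    """
    if len(values) == 0:
        raise ValueError("no replicate values to aggregate")
    arr = np.asarray(values, dtype=float)
    n = arr.size
    mean = float(arr.mean())
    if n == 1:
        warnings.warn("single replicate: SD is undefined, reporting 0", stacklevel=2)
        return ReplicateSummary(mean=mean, sd=0.0, se=0.0, n=1)
    sd = float(arr.std(ddof=1))
    return ReplicateSummary(mean=mean, sd=sd, se=sd / math.sqrt(n), n=n)


def fraction_ionized(pH: float, pKa: float) -> float:
    """Ionized fraction of a monoprotic acid at the given pH.

    10^(pH-pKa) / (1 + 10^(pH-pKa)); strictly increasing in pH, range (0, 1).
    """
    # branch keeps the exponent nonpositive: no overflow at extreme pH
    x = math.log(10.0) * (pH - pKa)
    if x >= 0:
        return 1.0 / (1.0 + math.exp(-x))
    ex = math.exp(x)
    return ex / (1.0 + ex)


def assign_logP(
    results: Mapping[float, "PartitionResult | float"],
    pKa: float | Sequence[float],
    threshold_unionized: float = 0.05,
) -> LogPAssignment:
    """Assign log P = log D at the most-unionized measured pH.

    ``results`` maps pH -> PartitionResult (or bare log D value).  For
    multiprotic compounds only the lowest pKa governs the ionized
    fraction (the second ionization is negligible below pH ~8).  If no
    measured pH has an ionized fraction below ``threshold_unionized``,
    an error asks for an explicit ionization correction instead of
    silently reporting a log D as log P.
    """
    if not results:
        raise ValueError("no partition results supplied")
    pka1 = min(pKa) if isinstance(pKa, (list, tuple, np.ndarray)) else float(pKa)
    best_pH = min(results, key=lambda ph: fraction_ionized(ph, pka1))
    f_ion = fraction_ionized(best_pH, pka1)
    if f_ion >= threshold_unionized:
        raise ValueError(
            f"no sufficiently-unionized measurement: lowest ionized fraction is "
            f"{f_ion:.2f} at pH {best_pH} (pKa {pka1}); apply an explicit "
            "ionization correction or measure at lower pH"
        )
    res = results[best_pH]
    logD = res.logD if isinstance(res, PartitionResult) else float(res)
    return LogPAssignment(
        logP=logD, pH_used=best_pH, pKa_used=pka1, fraction_ionized=f_ion
    )
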
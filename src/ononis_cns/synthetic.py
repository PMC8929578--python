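"""Ground-truth synthetic data for every analysis stage.

Each generator inverts the corresponding estimator exactly at zero
noise, so round-trip recovery is a property of the pipeline rather than
a fitted outcome:

* shake-flask records follow the aqueous mass balance
  A1 = A0 / (1 + D/R) with D = 10^logD and
  logD(pH) = logP - log10(1 + 10^(pH - pKa));
* PAMPA wells follow a two-compartment diffusion model in which
  membrane retention is an instantaneous initial partition of donor
  mass (the (1 - MR) correction of the permeability equation treats
  retained mass as removed from the transport equilibrium, which makes
  the estimator exactly self-consistent);
* reference clouds are Gaussian clusters in 8-D whose MAO-B IC50 varies
  log-linearly with the lipophilicity axis (PC3) and whose selectivity
  varies with PC1, so local kNN averages track a known smooth field;
* calibration standards lie on a known log Pe vs log BB line with
  optional scatter.

Noise is multiplicative Gaussian on concentrations/absorbances
(relative error), reflecting spectroscopic and HPLC quantification
behavior.  Every generator is deterministic under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .chemspace import ChemSpacePoint
from .pampa import PampaGeometry, PampaWell, StandardCompound
from .partition import ShakeFlaskRecord

__all__ = [
    "GeneratorConfig",
    "true_logD",
    "gen_shake_flask",
    "simulate_pampa_transport",
    "gen_reference_cloud",
    "true_ic50_field",
    "true_si_field",
    "gen_standards",
    "STANDARD_NAMES",
]

#: the six system-suitability standards with literature log BB values
STANDARD_NAMES = ("caffeine", "daidzein", "naringenin", "quinine", "rutin", "salicylic_acid")

# IC50 field: log10 IC50[nM] = IC50_FIELD_BASE + IC50_FIELD_PC3_SLOPE * PC3
# (more lipophilic compounds, higher PC3, are more potent -> lower IC50)
IC50_FIELD_BASE = 3.0
IC50_FIELD_PC3_SLOPE = -0.6
# selectivity field: log10 SI = SI_FIELD_PC1_SLOPE * PC1 (A_over_B convention)
SI_FIELD_PC1_SLOPE = 0.3


@dataclass(frozen=True)
class GeneratorConfig:
    """Reference-cloud parameters.

    n_points 2000 and 8 clusters of SD 0.6 around centers drawn from
    N(0, 1.5^2) give a cloud whose ED<1 neighborhoods hold tens to a
    few hundred compounds, the occupancy regime of curated inhibitor
    sets; ic50_noise_sd is the SD of lognormal (base-10) scatter around
    the smooth potency field.
    """

    seed: int = 0
    n_points: int = 2000
    n_clusters: int = 8
    cluster_sd: float = 0.6
    center_sd: float = 1.5
    ic50_noise_sd: float = 0.0
    annotate_maoa_fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.n_points < 1:
            raise ValueError("n_points must be >= 1")
        if self.n_clusters < 1:
            raise ValueError("n_clusters must be >= 1")
        if self.cluster_sd < 0 or self.center_sd < 0 or self.ic50_noise_sd < 0:
            raise ValueError("spread parameters must be nonnegative")
        if not 0.0 <= self.annotate_maoa_fraction <= 1.0:
            raise ValueError("annotate_maoa_fraction must be in [0, 1]")


def true_logD(true_logP: float, pKa: float, pH: float) -> float:
    """Distribution coefficient of a monoprotic acid at the given pH."""
    return true_logP - math.log10(1.0 + 10.0 ** (pH - pKa))


def gen_shake_flask(
    true_logP: float,
    pKa: float,
    pH: float,
    R: float,
    noise_sd: float = 0.0,
    n: int = 4,
    seed: int = 0,
) -> list[ShakeFlaskRecord]:
    """Synthetic shake-flask replicates from a known log P.

    A0 is drawn uniformly in [0.5, 1.5] per replicate; A1 follows the
    partition mass balance with multiplicative Gaussian noise of
    relative SD ``noise_sd``.
    """
    if R <= 0:
        raise ValueError("phase ratio R must be positive")
    if n < 1:
        raise ValueError("need at least one replicate")
    rng = np.random.default_rng(seed)
    D = 10.0 ** true_logD(true_logP, pKa, pH)
    records = []
    for _ in range(n):
        A0 = float(rng.uniform(0.5, 1.5))
        A1 = A0 / (1.0 + D / R)
        if noise_sd > 0:
            A1 *= 1.0 + noise_sd * float(rng.standard_normal())
        if A1 <= 0 or A1 >= A0:
            raise ValueError(
                "noise realization produced an unphysical A1; lower noise_sd "
                "or use a larger phase ratio"
            )
        records.append(ShakeFlaskRecord(A0=A0, A1=A1, R=R, pH=pH))
    return records


def simulate_pampa_transport(
    true_Pe: float,
    true_MR: float,
    g: PampaGeometry | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    C_D0: float = 1e-7,
    compound_id: str | None = None,
    day: int | None = None,
    replicate: int | None = None,
) -> PampaWell:
    """Forward-simulate one PAMPA well from known Pe and MR.

    A fraction ``true_MR`` of the donor mass partitions into the
    membrane at t = tau_ss; the remaining mobile mass then diffuses
    between the compartments with rate constant
    Pe * A * (1/V_D + 1/V_A).  The closed-form endpoint concentrations
    satisfy mass conservation and are inverted exactly by the MR and Pe
    estimators at zero noise.
    """
    if not 0.0 <= true_MR < 1.0:
        raise ValueError(f"true_MR must be in [0, 1), got {true_MR}")
    if true_Pe < 0:
        raise ValueError("true_Pe must be nonnegative")
    g = g or PampaGeometry()
    mobile = C_D0 * (1.0 - true_MR)  # donor concentration after membrane uptake
    k = true_Pe * g.A * (1.0 / g.V_D + 1.0 / g.V_A)
    # base-10 decay with the printed 2.303 prefactor so the permeability
    # estimator inverts this forward model exactly; it differs from the
    # exact exponential (ln 10) by < 0.02%
    decay = 10.0 ** (-k * (g.t - g.tau_ss) / 2.303)
    C_eq = mobile * g.V_D / (g.V_D + g.V_A)
    C_Dt = C_eq + (mobile - C_eq) * decay
    C_At = (mobile * g.V_D - C_Dt * g.V_D) / g.V_A
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        C_Dt *= 1.0 + noise_sd * float(rng.standard_normal())
        C_At *= 1.0 + noise_sd * float(rng.standard_normal())
        C_Dt = max(C_Dt, 0.0)
        C_At = max(C_At, 0.0)
    return PampaWell(
        C_D0=C_D0,
        C_Dt=C_Dt,
        C_At=C_At,
        compound_id=compound_id,
        day=day,
        replicate=replicate,
    )


def true_ic50_field(coords: np.ndarray) -> np.ndarray:
    """Noise-free MAO-B IC50 (nM) at given 8-D positions (log-linear in PC3)."""
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    return 10.0 ** (IC50_FIELD_BASE + IC50_FIELD_PC3_SLOPE * coords[:, 2])


def true_si_field(coords: np.ndarray) -> np.ndarray:
    """Noise-free selectivity index (A_over_B) at given positions."""
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    return 10.0 ** (SI_FIELD_PC1_SLOPE * coords[:, 0])


def gen_reference_cloud(cfg: GeneratorConfig) -> list[ChemSpacePoint]:
    """Gaussian-cluster reference cloud with smooth IC50/selectivity fields.

    MAO-B IC50 follows :func:`true_ic50_field` at each point (with
    optional lognormal scatter of SD ``ic50_noise_sd`` decades); MAO-A
    IC50 is the MAO-B value times the position-dependent selectivity
    index, annotated on a configurable fraction of points.
    """
    rng = np.random.default_rng(cfg.seed)
    centers = rng.normal(0.0, cfg.center_sd, size=(cfg.n_clusters, 8))
    assignments = rng.integers(0, cfg.n_clusters, size=cfg.n_points)
    coords = centers[assignments] + rng.normal(0.0, cfg.cluster_sd, size=(cfg.n_points, 8))
    ic50_b = true_ic50_field(coords)
    if cfg.ic50_noise_sd > 0:
        ic50_b = ic50_b * 10.0 ** rng.normal(0.0, cfg.ic50_noise_sd, size=cfg.n_points)
    si = true_si_field(coords)
    has_maoa = rng.random(cfg.n_points) < cfg.annotate_maoa_fraction
    width = len(str(cfg.n_points - 1))
    return [
        ChemSpacePoint(
            id=f"ref{i:0{width}d}",
            coords=tuple(coords[i]),
            ic50_maob=float(ic50_b[i]),
            ic50_maoa=float(ic50_b[i] * si[i]) if has_maoa[i] else None,
        )
        for i in range(cfg.n_points)
    ]


def gen_standards(
    slope: float = 1.0,
    intercept: float = -5.0,
    scatter_sd: float = 0.0,
    seed: int = 0,
) -> list[StandardCompound]:
    """Six named calibration standards on a known log Pe vs log BB line.

    log BB values sit on an even grid over [-1.5, 1.0] (the span of the
    usual system-suitability panel from hydrophilic rutin to lipophilic
    daidzein); ``scatter_sd`` adds Gaussian noise to log Pe.
    """
    rng = np.random.default_rng(seed)
    logbb = np.linspace(-1.5, 1.0, len(STANDARD_NAMES))
    noise = rng.normal(0.0, scatter_sd, size=len(STANDARD_NAMES)) if scatter_sd > 0 else np.zeros(len(STANDARD_NAMES))
    return [
        StandardCompound(
            name=name,
            logBB_literature=float(bb),
            logPe=float(slope * bb + intercept + e),
        )
        for name, bb, e in zip(STANDARD_NAMES, logbb, noise)
    ]
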
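"""Physico-chemical descriptors and CNS drug-likeness screening.

Molecular weight from Hill-notation formulas, fragment-based topological
polar surface area (TPSA), hydrogen-bond-donor counts, and a six-rule
screen of the property ranges recommended for blood-brain-barrier
penetration (MW < 450 Da, PSA < 70 A^2, HBD 0-1, log P 2-4,
log D^7.4 2-4, log Pe > -5.50).

TPSA is computed from a curated polar-fragment profile (carbonyl,
ether-type and hydroxyl oxygens) with Ertl fragment contributions rather
than from structure perception; a profile is part of each compound
record.  All ether-type oxygens (pyranone ring O, methoxy,
methylenedioxy, pterocarpan ring O) share the single two-coordinate
ether contribution.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping

__all__ = [
    "ATOMIC_WEIGHTS",
    "TPSA_CARBONYL_O",
    "TPSA_ETHER_O",
    "TPSA_HYDROXYL",
    "MolecularFormula",
    "FragmentTerm",
    "FragmentProfile",
    "BBBProfile",
    "parse_formula",
    "molecular_weight",
    "tpsa",
    "count_hbd",
    "screen_bbb_rules",
    "round_half_up",
]

# IUPAC standard atomic weights (abridged, 2021)
ATOMIC_WEIGHTS: dict[str, float] = {
    "H": 1.008,
    "B": 10.81,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "F": 18.998,
    "Na": 22.990,
    "Mg": 24.305,
    "P": 30.974,
    "S": 32.06,
    "Cl": 35.45,
    "K": 39.098,
    "Ca": 40.078,
    "Br": 79.904,
    "I": 126.904,
}

# Ertl fragment contributions (A^2) for the oxygen environments present
# in isoflavonoid aglycones: C=O, two-coordinate ether O, and O-H.
TPSA_CARBONYL_O = 17.07
TPSA_ETHER_O = 9.23
TPSA_HYDROXYL = 20.23

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round with ties away from zero, as printed descriptor tables do."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class MolecularFormula:
    """Element -> count map parsed from Hill notation."""

    element_counts: Mapping[str, int]

    def __post_init__(self) -> None:
        for el, n in self.element_counts.items():
            if el not in ATOMIC_WEIGHTS:
                raise ValueError(f"unrecognized element symbol: {el!r}")
            if n < 1:
                raise ValueError(f"element {el} has non-positive count {n}")

    def hill(self) -> str:
        """Canonical Hill string: C first, H second, then alphabetical.

        Carbon-free formulas are ordered purely alphabetically, per the
        Hill convention.
        """
        counts = dict(self.element_counts)
        if "C" in counts:
            order = ["C", "H"] + sorted(e for e in counts if e not in ("C", "H"))
        else:
            order = sorted(counts)
        parts: list[str] = []
        for el in order:
            if el in counts:
                n = counts[el]
                parts.append(el if n == 1 else f"{el}{n}")
        return "".join(parts)


def parse_formula(formula: str) -> MolecularFormula:
    """Parse a Hill-notation molecular formula such as ``C16H12O5``.

    Raises ``ValueError`` on empty input, unknown element symbols or an
    explicit zero count.  The result round-trips through
    :meth:`MolecularFormula.hill`.
    """
    s = formula.strip()
    if not s:
        raise ValueError("empty molecular formula")
    counts: dict[str, int] = {}
    pos = 0
    while pos < len(s):
        m = _FORMULA_TOKEN.match(s, pos)
        if m is None or m.start() != pos or not m.group(1):
            raise ValueError(f"cannot parse formula {formula!r} at position {pos}")
        el, digits = m.group(1), m.group(2)
        if el not in ATOMIC_WEIGHTS:
            raise ValueError(f"unrecognized element symbol {el!r} in {formula!r}")
        n = int(digits) if digits else 1
        if n == 0:
            raise ValueError(f"zero count for element {el} in {formula!r}")
        counts[el] = counts.get(el, 0) + n
        pos = m.end()
    return MolecularFormula(counts)


def molecular_weight(f: MolecularFormula | str) -> float:
    """Molecular weight in Da: sum of count x standard atomic weight.

    Accepts a parsed formula or a Hill string.  Reported to 2 decimals
    (half-up), matching how descriptor tables print MW.
    """
    if isinstance(f, str):
        f = parse_formula(f)
    mw = sum(n * ATOMIC_WEIGHTS[el] for el, n in f.element_counts.items())
    return round_half_up(mw, 2)


@dataclass(frozen=True)
class FragmentTerm:
    """One extra polar fragment: count, TPSA contribution, HBD per unit."""

    count: int
    tpsa_each: float
    hbd_each: int = 0


@dataclass(frozen=True)
class FragmentProfile:
    """Counts of the polar oxygen environments of one compound.

    ``extra`` extends the scheme to further polar fragments (e.g. N-H)
    without changing the three-oxygen core contract.
    """

    n_carbonyl_O: int = 0
    n_ether_O: int = 0
    n_hydroxyl: int = 0
    extra: Mapping[str, FragmentTerm] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, n in [
            ("n_carbonyl_O", self.n_carbonyl_O),
            ("n_ether_O", self.n_ether_O),
            ("n_hydroxyl", self.n_hydroxyl),
        ]:
            if n < 0:
                raise ValueError(f"{name} must be >= 0, got {n}")
        for key, term in self.extra.items():
            if term.count < 0:
                raise ValueError(f"extra fragment {key!r} has negative count")


def tpsa(p: FragmentProfile) -> float:
    """Fragment-additive topological polar surface area in A^2.

    17.07 per carbonyl O + 9.23 per ether-type O + 20.23 per hydroxyl,
    plus any extra fragment terms; reported to 2 decimals.
    """
    area = (
        TPSA_CARBONYL_O * p.n_carbonyl_O
        + TPSA_ETHER_O * p.n_ether_O
        + TPSA_HYDROXYL * p.n_hydroxyl
        + sum(t.count * t.tpsa_each for t in p.extra.values())
    )
    return round_half_up(area, 2)


def count_hbd(p: FragmentProfile) -> int:
    """Hydrogen-bond-donor count: hydroxyls plus donor terms in ``extra``."""
    return p.n_hydroxyl + sum(t.count * t.hbd_each for t in p.extra.values())


# Rule predicates on UNROUNDED values.  Boundary conventions: "<450" and
# "<70" strict, "0-1" and "2-4" inclusive, ">-5.50" strict.
_BBB_RULES = {
    "mw_lt_450": lambda v: v["mw"] < 450.0,
    "psa_lt_70": lambda v: v["psa"] < 70.0,
    "hbd_0_to_1": lambda v: 0 <= v["hbd"] <= 1,
    "logp_2_to_4": lambda v: 2.0 <= v["logP"] <= 4.0,
    "logd74_2_to_4": lambda v: 2.0 <= v["logD74"] <= 4.0,
    "logpe_gt_m5p50": lambda v: v["logPe"] > -5.50,
}


@dataclass(frozen=True)
class BBBProfile:
    """Descriptor values plus the six-rule BBB screening verdicts."""

    mw: float
    psa: float
    hbd: int
    logP: float
    logD74: float
    logPe: float
    verdicts: Mapping[str, bool]
    n_outliers: int


def screen_bbb_rules(
    mw: float,
    psa: float,
    hbd: int,
    logP: float,
    logD74: float,
    logPe: float,
) -> BBBProfile:
    """Evaluate one compound against the six BBB-penetration rules.

    Every value must be present and finite; a missing descriptor is an
    error, never a silent pass.  ``n_outliers`` counts failed rules.
    """
    values = {
        "mw": mw,
        "psa": psa,
        "hbd": hbd,
        "logP": logP,
        "logD74": logD74,
        "logPe": logPe,
    }
    for name, v in values.items():
        if v is None:
            raise ValueError(f"missing descriptor value: {name}")
        fv = float(v)
        if fv != fv:  # NaN
            raise ValueError(f"descriptor value {name} is NaN")
    verdicts = {rule: bool(pred(values)) for rule, pred in _BBB_RULES.items()}
    return BBBProfile(
        mw=mw,
        psa=psa,
        hbd=hbd,
        logP=logP,
        logD74=logD74,
        logPe=logPe,
        verdicts=verdicts,
        n_outliers=sum(not ok for ok in verdicts.values()),
    )
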
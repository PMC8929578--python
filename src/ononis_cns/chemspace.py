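"""Nearest-neighbor activity prediction in 8-D chemical space.

Compounds are points in the fixed 8-dimensional principal-component
projection produced by the ChemGPS-NP chemical-space model (PC1 size /
shape / polarizability, PC2 aromaticity / conjugation, PC3 lipophilicity
/ polarity / H-bonding, ...).  A reference set of enzyme inhibitors with
known IC50 values is filtered by potency, and for each query compound
the module reports

  * the census of references closer than a Euclidean-distance radius
    (default ED < 1, the field's closeness criterion),
  * the mean ED and mean annotated value (IC50 or selectivity index)
    of the k closest references (k = 5 and 10 by default).

All eight coordinates always enter the distances; the first three are
only a visualization export.  The selectivity index defaults to
IC50(MAO-A)/IC50(MAO-B) so that SI > 1 marks a MAO-B-selective
inhibitor.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "N_DIMENSIONS",
    "ChemSpacePoint",
    "KnnResult",
    "NeighborReport",
    "euclidean_distance",
    "selectivity_index",
    "filter_reference_set",
    "neighborhood_census",
    "knn_report",
    "neighbor_table",
]

N_DIMENSIONS = 8

SIConvention = Literal["A_over_B", "B_over_A"]


@dataclass(frozen=True)
class ChemSpacePoint:
    """One compound's chemical-space position with optional IC50s (nM)."""

    id: str
    coords: tuple[float, ...]
    ic50_maob: float | None = None
    ic50_maoa: float | None = None

    def __post_init__(self) -> None:
        coords = tuple(float(c) for c in self.coords)
        if len(coords) != N_DIMENSIONS:
            raise ValueError(
                f"point {self.id!r} has {len(coords)} coordinates, expected {N_DIMENSIONS}"
            )
        if not all(math.isfinite(c) for c in coords):
            raise ValueError(f"point {self.id!r} has non-finite coordinates")
        object.__setattr__(self, "coords", coords)
        for name in ("ic50_maob", "ic50_maoa"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValueError(f"point {self.id!r}: {name} must be positive, got {v}")


@dataclass(frozen=True)
class KnnResult:
    """The k closest references and their averaged annotation."""

    query_id: str
    k: int
    neighbor_ids: tuple[str, ...]
    avg_ed: float
    avg_value: float
    value_kind: str
    has_coincident_neighbor: bool


@dataclass(frozen=True)
class NeighborReport:
    """Per-query summary mirroring a proximity/potency table row."""

    query_id: str
    n_within_radius: int
    radius: float
    avg_ed: dict[int, float]
    avg_value: dict[int, float]
    value_kind: str


def euclidean_distance(P: ChemSpacePoint, Q: ChemSpacePoint) -> float:
    """Euclidean distance between two 8-D chemical-space points."""
    if len(P.coords) != len(Q.coords):
        raise ValueError("dimension mismatch between points")
    return float(
        np.linalg.norm(np.asarray(P.coords, dtype=float) - np.asarray(Q.coords, dtype=float))
    )


def selectivity_index(
    ic50_maoa: float,
    ic50_maob: float,
    convention: SIConvention = "A_over_B",
) -> float:
    """Isoform selectivity index from the two IC50 values.

    Under the default ``A_over_B`` convention (IC50 MAO-A / IC50 MAO-B)
    a value above 1 means the compound inhibits MAO-B at lower
    concentration, i.e. is MAO-B selective.
    """
    if ic50_maoa <= 0 or ic50_maob <= 0:
        raise ValueError("IC50 values must be positive")
    if convention == "A_over_B":
        return ic50_maoa / ic50_maob
    if convention == "B_over_A":
        return ic50_maob / ic50_maoa
    raise ValueError(f"unknown SI convention {convention!r}")


def filter_reference_set(
    points: Sequence[ChemSpacePoint],
    cutoff_nM: float = 10_000.0,
    require_both: bool = False,
) -> list[ChemSpacePoint]:
    """Keep references with MAO-B IC50 below the potency cutoff.

    ``require_both`` additionally demands a known MAO-A IC50, as needed
    for selectivity analysis.
    """
    if cutoff_nM <= 0:
        raise ValueError(f"cutoff must be positive, got {cutoff_nM}")
    kept = [
        p
        for p in points
        if p.ic50_maob is not None and p.ic50_maob < cutoff_nM
    ]
    if require_both:
        kept = [p for p in kept if p.ic50_maoa is not None]
    return kept


def _distances(query: ChemSpacePoint, refs: Sequence[ChemSpacePoint]) -> np.ndarray:
    q = np.asarray(query.coords, dtype=float)
    mat = np.asarray([r.coords for r in refs], dtype=float)
    return np.linalg.norm(mat - q, axis=1)


def _exclude_self(
    query: ChemSpacePoint, refs: Sequence[ChemSpacePoint]
) -> list[ChemSpacePoint]:
    # self-matches removed by id, not by distance: a distinct compound
    # projecting onto the same coordinates stays a legitimate neighbor
    return [r for r in refs if r.id != query.id]


def neighborhood_census(
    query: ChemSpacePoint,
    refs: Sequence[ChemSpacePoint],
    radius: float = 1.0,
) -> int:
    """Number of references strictly within ``radius`` of the query."""
    if radius <= 0:
        raise ValueError(f"radius must be positive, got {radius}")
    others = _exclude_self(query, refs)
    if not others:
        return 0
    return int(np.count_nonzero(_distances(query, others) < radius))


def knn_report(
    query: ChemSpacePoint,
    refs: Sequence[ChemSpacePoint],
    k: int,
    value: str = "ic50_maob",
    si_convention: SIConvention = "A_over_B",
) -> KnnResult:
    """Mean ED and mean annotation of the k closest references.

    ``value`` is ``'ic50_maob'`` or ``'selectivity_index'``.  Distance
    ties at the k-th rank are broken by reference id for
    reproducibility.  Coincident references (ED = 0) are kept as
    ordinary neighbors but flagged.
    """
    if value not in ("ic50_maob", "selectivity_index"):
        raise ValueError(f"unknown value kind {value!r}")
    others = _exclude_self(query, refs)
    if len(others) < k:
        raise ValueError(
            f"need at least k={k} references for query {query.id!r}, "
            f"have {len(others)} (after self-exclusion)"
        )
    d = _distances(query, others)
    order = sorted(range(len(others)), key=lambda i: (d[i], others[i].id))
    chosen = order[:k]
    vals = []
    for i in chosen:
        r = others[i]
        if value == "ic50_maob":
            if r.ic50_maob is None:
                raise ValueError(f"reference {r.id!r} lacks a MAO-B IC50 annotation")
            vals.append(r.ic50_maob)
        else:
            if r.ic50_maoa is None or r.ic50_maob is None:
                raise ValueError(f"reference {r.id!r} lacks both IC50 annotations")
            vals.append(selectivity_index(r.ic50_maoa, r.ic50_maob, si_convention))
    coincident = any(d[i] == 0.0 for i in chosen)
    if coincident:
        warnings.warn(
            f"query {query.id!r} has a coincident reference (ED = 0) among its "
            f"{k} nearest neighbors",
            stacklevel=2,
        )
    return KnnResult(
        query_id=query.id,
        k=k,
        neighbor_ids=tuple(others[i].id for i in chosen),
        avg_ed=float(np.mean([d[i] for i in chosen])),
        avg_value=float(np.mean(vals)),
        value_kind=value,
        has_coincident_neighbor=coincident,
    )


def neighbor_table(
    queries: Sequence[ChemSpacePoint],
    refs: Sequence[ChemSpacePoint],
    ks: Sequence[int] = (5, 10),
    radius: float = 1.0,
    value: str = "ic50_maob",
    si_convention: SIConvention = "A_over_B",
) -> list[NeighborReport]:
    """One NeighborReport per query: ED<radius census plus k-NN averages."""
    reports = []
    for q in queries:
        avg_ed: dict[int, float] = {}
        avg_value: dict[int, float] = {}
        for k in ks:
            res = knn_report(q, refs, k, value=value, si_convention=si_convention)
            avg_ed[k] = res.avg_ed
            avg_value[k] = res.avg_value
        reports.append(
            NeighborReport(
                query_id=q.id,
                n_within_radius=neighborhood_census(q, refs, radius),
                radius=radius,
                avg_ed=avg_ed,
                avg_value=avg_value,
                value_kind=value,
            )
        )
    return reports
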
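"""Readers and writers for the pipeline's tabular interchange formats.

Analysis outputs are comma-separated UTF-8 with "." decimals; chemical-
space coordinate files are tab-separated with an id column followed by
eight principal-component columns, the dialect produced by the
ChemGPS-NP web service.  Readers validate eagerly and report the file
and row of the first problem.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Sequence

import pandas as pd

from .chemspace import N_DIMENSIONS, ChemSpacePoint, NeighborReport
from .descriptors import FragmentProfile
from .pampa import PampaWell, StandardCompound
from .partition import ShakeFlaskRecord

__all__ = [
    "CompoundRecord",
    "read_compound_table",
    "load_fixture_compounds",
    "read_shake_flask_csv",
    "read_plate_csv",
    "read_standards_csv",
    "read_coordinates",
    "read_ic50_annotations",
    "attach_annotations",
    "write_coordinates",
    "write_neighbor_table",
    "write_scatter_export",
]


@dataclass(frozen=True)
class CompoundRecord:
    """Identity and curated structural profile of one analyte."""

    id: str
    name: str
    formula: str
    skeleton_class: str
    profile: FragmentProfile
    pka: tuple[float, ...] = ()
    logP: float | None = None
    logD74: float | None = None
    logPe: float | None = None


_COMPOUND_COLUMNS = [
    "id",
    "name",
    "formula",
    "skeleton_class",
    "n_carbonyl_O",
    "n_ether_O",
    "n_hydroxyl",
]
_SKELETON_CLASSES = {"isoflavone", "isoflavanone", "pterocarpan"}


def _require_columns(df: pd.DataFrame, required: Sequence[str], path: str | Path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s): {', '.join(missing)}")


def _opt_float(value) -> float | None:
    return None if pd.isna(value) else float(value)


def read_compound_table(path: str | Path) -> list[CompoundRecord]:
    """Read a compound table (CSV) into CompoundRecords."""
    df = pd.read_csv(path)
    _require_columns(df, _COMPOUND_COLUMNS, path)
    records = []
    for idx, row in df.iterrows():
        if row["skeleton_class"] not in _SKELETON_CLASSES:
            raise ValueError(
                f"{path} row {idx + 2}: unknown skeleton_class "
                f"{row['skeleton_class']!r} (expected one of {sorted(_SKELETON_CLASSES)})"
            )
        pka_raw = row.get("pka_list")
        pka = (
            tuple(float(x) for x in str(pka_raw).split(";") if x.strip())
            if pd.notna(pka_raw) and str(pka_raw).strip()
            else ()
        )
        records.append(
            CompoundRecord(
                id=str(row["id"]),
                name=str(row["name"]),
                formula=str(row["formula"]),
                skeleton_class=str(row["skeleton_class"]),
                profile=FragmentProfile(
                    n_carbonyl_O=int(row["n_carbonyl_O"]),
                    n_ether_O=int(row["n_ether_O"]),
                    n_hydroxyl=int(row["n_hydroxyl"]),
                ),
                pka=pka,
                logP=_opt_float(row.get("logP")),
                logD74=_opt_float(row.get("logD74")),
                logPe=_opt_float(row.get("logPe")),
            )
        )
    return records


def load_fixture_compounds() -> list[CompoundRecord]:
    """The bundled eight-compound isoflavonoid panel.

    Six characterized aglycones (calycosin D, formononetin, sativanone,
    onogenin, medicarpin, maackiain) with measured log P / log D^7.4 /
    log Pe, plus pseudobaptigenin and calycosin with structural
    profiles only.
    """
    with resources.as_file(
        resources.files("ononis_cns").joinpath("data/compounds.csv")
    ) as p:
        return read_compound_table(p)


def read_shake_flask_csv(path: str | Path) -> dict[tuple[str, float], list[ShakeFlaskRecord]]:
    """Shake-flask CSV -> records grouped by (compound_id, pH)."""
    df = pd.read_csv(path)
    _require_columns(df, ["compound_id", "A0", "A1", "R", "pH"], path)
    grouped: dict[tuple[str, float], list[ShakeFlaskRecord]] = {}
    for idx, row in df.iterrows():
        try:
            rec = ShakeFlaskRecord(
                A0=float(row["A0"]),
                A1=float(row["A1"]),
                R=float(row["R"]),
                pH=float(row["pH"]),
                wavelength_nm=_opt_float(row.get("wavelength_nm")),
            )
        except ValueError as e:
            raise ValueError(f"{path} row {idx + 2}: {e}") from e
        grouped.setdefault((str(row["compound_id"]), float(row["pH"])), []).append(rec)
    return grouped


def read_plate_csv(path: str | Path) -> list[PampaWell]:
    """PAMPA plate CSV -> wells with compound/day/replicate labels."""
    df = pd.read_csv(path)
    _require_columns(df, ["compound_id", "C_D0", "C_Dt", "C_At"], path)
    wells = []
    for idx, row in df.iterrows():
        try:
            wells.append(
                PampaWell(
                    C_D0=float(row["C_D0"]),
                    C_Dt=float(row["C_Dt"]),
                    C_At=float(row["C_At"]),
                    compound_id=str(row["compound_id"]),
                    day=int(row["day"]) if "day" in df.columns and pd.notna(row["day"]) else None,
                    replicate=int(row["replicate"])
                    if "replicate" in df.columns and pd.notna(row["replicate"])
                    else None,
                )
            )
        except ValueError as e:
            raise ValueError(f"{path} row {idx + 2}: {e}") from e
    return wells


def read_standards_csv(path: str | Path) -> list[StandardCompound]:
    """Standards CSV (name, logBB, logPe) -> StandardCompounds."""
    df = pd.read_csv(path)
    _require_columns(df, ["name", "logBB", "logPe"], path)
    return [
        StandardCompound(
            name=str(r["name"]),
            logBB_literature=float(r["logBB"]),
            logPe=float(r["logPe"]),
        )
        for _, r in df.iterrows()
    ]


def read_coordinates(path: str | Path) -> list[ChemSpacePoint]:
    """Tab-separated coordinate file -> validated 8-D points.

    Expects a header row with an id column followed by exactly eight
    coordinate columns.  Duplicate ids are kept (with a warning) so
    that distinct compounds sharing a projection remain distinct rows.
    """
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] != N_DIMENSIONS + 1:
        raise ValueError(
            f"{path}: expected 1 id column + {N_DIMENSIONS} coordinate columns, "
            f"found {df.shape[1]} columns"
        )
    id_col = df.columns[0]
    coord_cols = list(df.columns[1:])
    points = []
    for idx, row in df.iterrows():
        try:
            coords = tuple(float(row[c]) for c in coord_cols)
        except (TypeError, ValueError) as e:
            raise ValueError(f"{path} row {idx + 2}: non-numeric coordinate") from e
        points.append(ChemSpacePoint(id=str(row[id_col]), coords=coords))
    ids = [p.id for p in points]
    dupes = {i for i in ids if ids.count(i) > 1}
    if dupes:
        warnings.warn(
            f"{path}: duplicate compound id(s) kept as-is: {sorted(dupes)}",
            stacklevel=2,
        )
    return points


def read_ic50_annotations(path: str | Path) -> pd.DataFrame:
    """Annotation CSV: id, ic50_maob_nM and optional ic50_maoa_nM."""
    df = pd.read_csv(path)
    _require_columns(df, ["id", "ic50_maob_nM"], path)
    return df


def attach_annotations(
    points: Sequence[ChemSpacePoint], annotations: pd.DataFrame
) -> list[ChemSpacePoint]:
    """Merge IC50 annotations into coordinate points by id."""
    by_id = annotations.set_index(annotations["id"].astype(str))
    out = []
    for p in points:
        if p.id in by_id.index:
            row = by_id.loc[p.id]
            out.append(
                ChemSpacePoint(
                    id=p.id,
                    coords=p.coords,
                    ic50_maob=_opt_float(row.get("ic50_maob_nM")),
                    ic50_maoa=_opt_float(row.get("ic50_maoa_nM")),
                )
            )
        else:
            out.append(p)
    return out


def write_coordinates(points: Sequence[ChemSpacePoint], path: str | Path) -> None:
    """Write points in the tab-separated coordinate dialect."""
    df = pd.DataFrame(
        [{"id": p.id, **{f"PC{i + 1}": c for i, c in enumerate(p.coords)}} for p in points]
    )
    df.to_csv(path, sep="\t", index=False)


def write_neighbor_table(reports: Sequence[NeighborReport], path: str | Path) -> None:
    """NeighborReports -> CSV mirroring the proximity/potency tables."""
    rows = []
    for r in reports:
        row = {"id": r.query_id, f"n_within_ed_{r.radius:g}": r.n_within_radius}
        for k in sorted(r.avg_ed):
            row[f"avg_ed_{k}"] = r.avg_ed[k]
            row[f"avg_{r.value_kind}_{k}"] = r.avg_value[k]
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def write_scatter_export(
    points: Sequence[ChemSpacePoint],
    path: str | Path,
    color_values: Sequence[float] | None = None,
) -> None:
    """First-three-coordinate export (id, PC1-PC3, color) for 3-D plots."""
    rows = []
    for i, p in enumerate(points):
        row = {"id": p.id, "PC1": p.coords[0], "PC2": p.coords[1], "PC3": p.coords[2]}
        if color_values is not None:
            row["color"] = color_values[i]
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
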
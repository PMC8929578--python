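"""High-level report builders tying the analysis stages together."""

from __future__ import annotations

from typing import Sequence

import pandas as pd

from . import descriptors, pampa
from .io import CompoundRecord

__all__ = ["descriptor_report", "classification_report"]


def descriptor_report(records: Sequence[CompoundRecord]) -> pd.DataFrame:
    """Descriptor table with BBB rule verdicts for characterized compounds.

    One row per compound: MW, PSA, HBD from the structural profile;
    measured log P / log D^7.4 / log Pe where available; the six-rule
    screen and outlier count for fully characterized compounds.
    """
    rows = []
    for rec in records:
        mw = descriptors.molecular_weight(rec.formula)
        psa = descriptors.tpsa(rec.profile)
        hbd = descriptors.count_hbd(rec.profile)
        row: dict = {
            "id": rec.id,
            "name": rec.name,
            "skeleton_class": rec.skeleton_class,
            "mw": mw,
            "psa": psa,
            "hbd": hbd,
            "logP": rec.logP,
            "logD74": rec.logD74,
            "logPe": rec.logPe,
        }
        if rec.logP is not None and rec.logD74 is not None and rec.logPe is not None:
            profile = descriptors.screen_bbb_rules(
                mw=mw, psa=psa, hbd=hbd, logP=rec.logP, logD74=rec.logD74, logPe=rec.logPe
            )
            row.update({f"rule_{k}": v for k, v in profile.verdicts.items()})
            row["n_outliers"] = profile.n_outliers
        rows.append(row)
    return pd.DataFrame(rows)


def classification_report(
    records: Sequence[CompoundRecord],
    mensch_cutoff_pe: float = pampa.MENSCH_DEFAULT_CUTOFF_PE,
) -> pd.DataFrame:
    """Per-scheme BBB verdicts for compounds with a measured log Pe."""
    rows = []
    for rec in records:
        if rec.logPe is None:
            continue
        rows.append(
            {
                "id": rec.id,
                "logPe": rec.logPe,
                **{
                    scheme: pampa.classify_bbb(rec.logPe, scheme, mensch_cutoff_pe)
                    for scheme in pampa.SCHEMES
                },
            }
        )
    return pd.DataFrame(rows)
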
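"""Biochemical data handling: LOD substitution, replicates, class totals.

Ten phenolic compounds are quantified per fruit flesh sample (µg per g fresh
weight).  The handling rules are fixed and ordered: sub-LOD measurements are
imputed as LOD/2, the two extraction replicates are averaged, compounds are
summed into five phenolic classes, and anthocyanins may finally be
log-transformed for modelling.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "COMPOUNDS",
    "CLASS_MEMBERS",
    "LOD_NG",
    "LOQ_NG",
    "BiochemProfile",
    "apply_lod_rule",
    "water_content",
    "replicate_mean",
    "class_totals",
    "log_transform",
]

#: The ten quantified phenolic compounds.
COMPOUNDS = (
    "procyanidin B1",
    "(+)-catechin",
    "procyanidin B2",
    "(-)-epicatechin",
    "chlorogenic acid",
    "cyanidin 3-galactoside",
    "4-p-coumaroylquinic acid",
    "procyanidin C1",
    "phlorizin",
    "quercetin 3-galactoside",
)

#: Phenolic class membership used for the per-class totals.
CLASS_MEMBERS = {
    "flavanols": (
        "(+)-catechin",
        "(-)-epicatechin",
        "procyanidin B1",
        "procyanidin B2",
        "procyanidin C1",
    ),
    "hydroxycinnamic_acids": ("chlorogenic acid", "4-p-coumaroylquinic acid"),
    "anthocyanins": ("cyanidin 3-galactoside",),
    "flavonols": ("quercetin 3-galactoside",),
    "dihydrochalcones": ("phlorizin",),
}

#: On-column detection / quantification limits (ng) of the UPLC-UV method.
LOD_NG = {
    "procyanidin B1": 0.24,
    "(+)-catechin": 0.50,
    "procyanidin B2": 0.24,
    "(-)-epicatechin": 0.25,
    "chlorogenic acid": 0.49,
    "cyanidin 3-galactoside": 2.40,
    "4-p-coumaroylquinic acid": 0.13,
    "procyanidin C1": 0.90,
    "phlorizin": 0.09,
    "quercetin 3-galactoside": 0.24,
}
LOQ_NG = {
    "procyanidin B1": 0.47,
    "(+)-catechin": 1.0,
    "procyanidin B2": 0.48,
    "(-)-epicatechin": 0.49,
    "chlorogenic acid": 0.99,
    "cyanidin 3-galactoside": 4.7,
    "4-p-coumaroylquinic acid": 0.25,
    "procyanidin C1": 2.3,
    "phlorizin": 0.23,
    "quercetin 3-galactoside": 0.47,
}


@dataclass
class BiochemProfile:
    """Genotype-level biochemical factors entering the statistical models."""

    genotype_id: str
    anthocyanins: float
    flavanols: float
    flavonols: float
    hydroxycinnamic_acids: float
    dihydrochalcones: float
    pH: float | None = None
    water_content: float | None = None
    colour_index: float | None = None

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def apply_lod_rule(value: float | None, lod: float, *, below_lod: bool = False) -> float:
    """Impute sub-LOD measurements as LOD/2; leave everything else unchanged.

    ``value=None`` (no quantifiable signal) or an explicit ``below_lod`` flag
    triggers the substitution, as does a reported value strictly below
    ``lod``; a value exactly at the LOD is kept.
    """
    if lod <= 0:
        raise ValueError("lod must be positive")
    if value is None or below_lod:
        return lod / 2.0
    if value < 0:
        raise ValueError(f"negative concentration: {value}")
    return lod / 2.0 if value < lod else float(value)


def water_content(fw: float, dw: float) -> float:
    """WC = 1 − DW/FW from fresh and dry sample weights (grams)."""
    if dw <= 0 or fw <= 0:
        raise ValueError("weights must be positive")
    if dw > fw:
        raise ValueError(f"dry weight {dw} exceeds fresh weight {fw}")
    return 1.0 - dw / fw


def replicate_mean(
    rep1: Mapping[str, float], rep2: Mapping[str, float]
) -> dict[str, float]:
    """Average two extraction replicates compound-by-compound."""
    if set(rep1) != set(rep2):
        missing = set(rep1) ^ set(rep2)
        raise KeyError(f"replicates quantify different compounds: {sorted(missing)}")
    return {c: (rep1[c] + rep2[c]) / 2.0 for c in rep1}


def class_totals(concentrations: Mapping[str, float]) -> dict[str, float]:
    """Sum the ten compounds into the five phenolic class totals (µg/g FW)."""
    missing = [c for c in COMPOUNDS if c not in concentrations]
    if missing:
        raise KeyError(f"missing compounds: {missing}")
    return {
        cls: float(sum(concentrations[c] for c in members))
        for cls, members in CLASS_MEMBERS.items()
    }


def log_transform(profile: Mapping[str, float], fields: Iterable[str]) -> dict:
    """Natural-log named fields (e.g. anthocyanins) and pass the rest through.

    The LOD/2 rule guarantees strictly positive concentrations, so the log is
    always defined on rule-processed data.
    """
    out = dict(profile)
    for name in fields:
        v = out[name]
        if not (isinstance(v, (int, float)) and v > 0):
            raise ValueError(f"cannot log-transform non-positive {name}={v!r}")
        out[name] = math.log(v)
    return out


def build_profiles(
    samples: pd.DataFrame,
    *,
    sample_col: str = "sample_id",
    compound_col: str = "compound",
    value_col: str = "concentration",
    replicate_col: str = "replicate",
) -> pd.DataFrame:
    """Long quantification table → per-sample class-total table.

    Applies the fixed rule order: LOD/2 substitution (NaN or sub-LOD values),
    replicate averaging, then class totals.  One row per sample, columns are
    the five class names.
    """
    df = samples.copy()
    df[value_col] = [
        apply_lod_rule(None if pd.isna(v) else float(v), LOD_NG[c])
        for v, c in zip(df[value_col], df[compound_col])
    ]
    per_rep = df.pivot_table(
        index=[sample_col, compound_col],
        columns=replicate_col if replicate_col in df.columns else None,
        values=value_col,
        aggfunc="mean",
    )
    means = per_rep.mean(axis=1).unstack(compound_col)
    rows = {sid: class_totals(row.to_dict()) for sid, row in means.iterrows()}
    out = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    out.index.name = sample_col
    return out
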
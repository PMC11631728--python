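"""Survival-table IO and data-eligibility screening.

The survival CSV is a flat table with one row per measured point:

    cell_line, publication, beam_type {pristine|sobp|photon},
    radiation {proton|photon}, let_kev_um (empty for photon),
    dose_gy, sf

Rows sharing (cell_line, publication, beam_type, let_kev_um) form one
``SurvivalDataset``.  Zero-dose rows are retained in storage; fitting
excludes them downstream.

Eligibility screening encodes the reliability rules applied before any
fitting: pristine beams above ~33 keV/µm and SOBP beams above ~10 keV/µm
have unreliable nominal LETs (LET rises sharply as slow protons cross a
cell monolayer; SOBP spectra mix many LETs), short curves carry too little
information, and cell lines with too few proton curves cannot constrain
the LET response.  These gates are distinct from the post-fit Det-based
outlier flags.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .survival import DomainError, SurvivalDataset, SurvivalPoint

__all__ = [
    "CSV_COLUMNS",
    "EligibilityRules",
    "FilterReport",
    "read_survival_csv",
    "write_survival_csv",
    "datasets_to_frame",
    "apply_eligibility_filters",
]

CSV_COLUMNS = (
    "cell_line", "publication", "beam_type", "radiation",
    "let_kev_um", "dose_gy", "sf",
)


@dataclass(frozen=True)
class EligibilityRules:
    """Pre-fit data-eligibility thresholds (all strictly positive)."""

    max_pristine_let: float = 33.0
    max_sobp_let: float = 10.0
    min_proton_datasets_per_line: int = 4
    min_dose_points: int = 4
    excluded_sources: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        for name in ("max_pristine_let", "max_sobp_let",
                     "min_proton_datasets_per_line", "min_dose_points"):
            if getattr(self, name) <= 0:
                raise DomainError(f"{name} must be > 0")


@dataclass
class FilterReport:
    """Partition of the input into kept ids and (excluded id, rule) pairs."""

    kept: list[str]
    excluded: list[tuple[str, str]]
    kept_datasets: list[SurvivalDataset] = field(default_factory=list)


def read_survival_csv(path) -> list[SurvivalDataset]:
    """Parse a survival CSV into datasets grouped by curve.

    Raises a descriptive error (with the offending row number, counting
    the header as row 1) for missing columns, non-numeric dose/SF, or
    non-positive SF.
    """
    df = pd.read_csv(path, dtype={"cell_line": str, "publication": str,
                                  "beam_type": str, "radiation": str})
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise DomainError(f"{path}: missing column(s) {missing}")
    df["let_kev_um"] = pd.to_numeric(df["let_kev_um"], errors="coerce").fillna(0.0)
    for col in ("dose_gy", "sf"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() & df[col].notna() | df[col].isna()
        if bad.any():
            row = int(bad.idxmax()) + 2  # +1 header, +1 zero-based
            raise DomainError(f"{path}: non-numeric {col} at row {row}")
        df[col] = vals
    nonpos = df["sf"] <= 0
    if nonpos.any():
        row = int(nonpos.idxmax()) + 2
        raise DomainError(
            f"{path}: surviving fraction <= 0 at row {row} (log-scale data; "
            "zero survival cannot be represented)"
        )

    datasets = []
    keys = ["cell_line", "publication", "beam_type", "let_kev_um"]
    for (cell, pub, beam, let), grp in df.groupby(keys, sort=True):
        radiation = grp["radiation"].iloc[0]
        points = [SurvivalPoint(float(d), float(s))
                  for d, s in zip(grp["dose_gy"], grp["sf"])]
        datasets.append(SurvivalDataset(
            cell_line=cell, publication=pub, beam_type=beam,
            radiation=radiation, let_kev_um=float(let), points=points,
        ))
    return datasets


def datasets_to_frame(datasets: list[SurvivalDataset]) -> pd.DataFrame:
    rows = []
    for d in datasets:
        for p in d.points:
            rows.append({
                "cell_line": d.cell_line, "publication": d.publication,
                "beam_type": d.beam_type, "radiation": d.radiation,
                "let_kev_um": d.let_kev_um, "dose_gy": p.dose, "sf": p.sf_observed,
            })
    return pd.DataFrame(rows, columns=list(CSV_COLUMNS))


def write_survival_csv(datasets: list[SurvivalDataset], path) -> None:
    datasets_to_frame(datasets).to_csv(path, index=False)


def apply_eligibility_filters(
    datasets: list[SurvivalDataset], rules: EligibilityRules = EligibilityRules()
) -> FilterReport:
    """Screen datasets against the eligibility rules.

    Exclusion order (first matching rule is recorded): excluded source,
    pristine-LET ceiling, SOBP-LET ceiling, minimum dose points (proton
    curves), then minimum proton curves per cell line — a line failing
    that last gate loses all its datasets, photon reference included.
    """
    excluded: list[tuple[str, str]] = []
    survivors: list[SurvivalDataset] = []
    for d in datasets:
        if d.publication in rules.excluded_sources:
            excluded.append((d.label, "excluded_source"))
        elif d.beam_type == "pristine" and d.let_kev_um > rules.max_pristine_let:
            excluded.append((d.label, "max_pristine_let"))
        elif d.beam_type == "sobp" and d.let_kev_um > rules.max_sobp_let:
            excluded.append((d.label, "max_sobp_let"))
        elif d.radiation == "proton" and d.n_fit_points < rules.min_dose_points:
            excluded.append((d.label, "min_dose_points"))
        else:
            survivors.append(d)

    counts: dict[str, int] = {}
    for d in survivors:
        if d.radiation == "proton":
            counts[d.cell_line] = counts.get(d.cell_line, 0) + 1
    kept_datasets = []
    for d in survivors:
        if counts.get(d.cell_line, 0) < rules.min_proton_datasets_per_line:
            excluded.append((d.label, "min_proton_datasets_per_line"))
        else:
            kept_datasets.append(d)

    return FilterReport(
        kept=[d.label for d in kept_datasets],
        excluded=excluded,
        kept_datasets=kept_datasets,
    )
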
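"""Published reference values from the PIDE-derived proton survival study.

Two small tables a user of the comprehensive RBE model needs at hand:

* the roster of eligible experimental survival datasets (publication,
  cell line, beam type, counts, LET range) after the reliability and
  completeness screens;
* the per-cell-line multi-curve-fit coefficients (a_alpha, b_alpha,
  a_beta, b_beta), the single-variable refit slope b_beta^#, and the
  photon reference alpha_x.

These are literature values, not package output; the fitting module can
re-derive their cross-cell-line summary statistics from them.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "RosterEntry",
    "CellLineFit",
    "DATASET_ROSTER",
    "CELL_LINE_FITS",
    "total_proton_datasets",
    "total_photon_datasets",
]


@dataclass(frozen=True)
class RosterEntry:
    publication: str
    cell_line: str
    beam_type: str
    n_proton_datasets: int
    n_photon_datasets: int
    let_min_kev_um: float
    let_max_kev_um: float


@dataclass(frozen=True)
class CellLineFit:
    cell_line: str
    a_alpha: float
    b_alpha: float
    a_beta: float
    b_beta: float
    b_beta_hash: float
    alpha_x: float


#: Eligible dataset roster (63 proton + 8 photon datasets, 4 cell lines).
DATASET_ROSTER: tuple[RosterEntry, ...] = (
    RosterEntry("Chaudhary", "AG01522", "pristine", 6, 1, 1.1, 22.6),
    RosterEntry("Chaudhary", "AG01522", "sobp", 6, 1, 1.2, 25.9),
    RosterEntry("Chaudhary", "U87", "pristine", 6, 1, 1.1, 22.6),
    RosterEntry("Chaudhary", "U87", "sobp", 6, 1, 1.2, 25.9),
    RosterEntry("Wouters15", "V79", "sobp", 11, 1, 2.33, 6.23),
    RosterEntry("Wouters96", "V79", "sobp", 10, 1, 1.03, 4.74),
    RosterEntry("Folkard96", "V79", "pristine", 3, 0, 10.1, 27.6),
    RosterEntry("Belli96", "V79", "pristine", 4, 1, 7.7, 30.5),
    RosterEntry("Prise90", "V79", "pristine", 3, 0, 16.9, 31.0),
    RosterEntry("Folkard89", "V79", "pristine", 3, 0, 17.0, 32.0),
    RosterEntry("Bettega", "C3H10T1/2", "pristine", 5, 1, 17.0, 32.0),
)

#: Per-cell-line MCF coefficients, single-variable refit slope b_beta^#,
#: and photon alpha_x.  (The companion text reports the U87 b_beta^# as
#: 0.019 where the table prints 0.020; the tabulated value is kept here.)
CELL_LINE_FITS: tuple[CellLineFit, ...] = (
    CellLineFit("AG01522", 1.09, 0.0010, 0.96, 0.033, 0.033, 2.34),
    CellLineFit("U87", 1.10, 0.0015, 1.03, 0.023, 0.020, 1.45),
    CellLineFit("V79", 1.12, 0.0025, 0.99, 0.0085, 0.010, 1.32),
    CellLineFit("C3H10T1/2", 1.17, 0.0025, 0.99, 0.013, 0.014, 1.18),
)


def total_proton_datasets() -> int:
    return sum(e.n_proton_datasets for e in DATASET_ROSTER)


def total_photon_datasets() -> int:
    return sum(e.n_photon_datasets for e in DATASET_ROSTER)
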
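"""Packaged reference tables for the rutin-cyclodextrin worked example.

These are the published measurements for the UV standard curve of rutin in
ethanol, the phase-solubility absorbances of rutin in aqueous beta-CD,
HP-beta-CD and DM-beta-CD, the Hildebrand solubility parameters of the four
materials, and the partial-charge atom classes used for hydrogen-bond
typing.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .energetics import AtomClass, AtomClassTable
from .solubility import AbsorbanceSeries

__all__ = [
    "load_calibration_table",
    "load_calibration_series",
    "load_isotherm_table",
    "load_solubility_parameters",
    "load_atom_class_table",
]


def _read(name: str) -> pd.DataFrame:
    with resources.files("hostguest.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def load_calibration_table() -> pd.DataFrame:
    """Rutin UV dilution series: concentration_mM, absorbance (8 points)."""
    return _read("calibration_rutin.csv")


def load_calibration_series() -> AbsorbanceSeries:
    df = load_calibration_table()
    return AbsorbanceSeries(
        concentrations=df["concentration_mM"].to_numpy(),
        absorbances=df["absorbance"].to_numpy(),
        wavelength=265.0,
    )


def load_isotherm_table() -> pd.DataFrame:
    """Phase-solubility absorbances: system, host_conc_mM, absorbance."""
    return _read("isotherms_rutin_cd.csv")


def load_solubility_parameters() -> dict[str, float]:
    """Hildebrand delta per material, (cal/cm³)^1/2."""
    df = _read("solubility_parameters.csv")
    return dict(zip(df["material"], df["delta_cal_cm3_half"]))


def load_atom_class_table() -> AtomClassTable:
    """Rutin/cyclodextrin charge classes (acceptor oxygens, hydroxyl H)."""
    return atom_class_table_from_frame(_read("atom_classes_rutin_cd.csv"))


def atom_class_table_from_frame(df: pd.DataFrame) -> AtomClassTable:
    entries = tuple(
        AtomClass(label=str(r.label), role=str(r.role),
                  charge=float(r.charge), kind=str(r.kind))
        for r in df.itertuples()
    )
    return AtomClassTable(entries=entries)
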
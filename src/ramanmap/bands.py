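"""Biomolecular Raman band tables.

Maps chemical entities (glycogen, protein, lipid, nucleobases, ...) to their
characteristic band centers in the fingerprint region.  Band-to-entity
assignment in loading interpretation requires at least two bands of an entity
to co-occur on the same side of a component, because single fingerprint bands
overlap heavily between biomolecules; entities listed with fewer than two
bands are therefore unusable for assignment and trigger a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset import FINGERPRINT_WINDOW

#: Default matching half-width (cm^-1) between a band center and a loading
#: extremum.  Literature band positions are quoted to within a few cm^-1.
DEFAULT_TOLERANCE = 6.0


class BandTableError(ValueError):
    """Raised for invalid band tables."""


@dataclass
class BandTable:
    """Entities mapped to characteristic band centers with a match tolerance."""

    entries: pd.DataFrame  # columns: entity, band_center_cm1, note
    tolerance: float = DEFAULT_TOLERANCE
    warnings_: list = field(default_factory=list)

    def __post_init__(self):
        df = self.entries.copy()
        required = {"entity", "band_center_cm1"}
        if not required.issubset(df.columns):
            raise BandTableError(f"band table needs columns {sorted(required)}")
        if "note" not in df.columns:
            df["note"] = ""
        df["band_center_cm1"] = pd.to_numeric(df["band_center_cm1"])
        lo, hi = FINGERPRINT_WINDOW
        out = df[(df["band_center_cm1"] < lo) | (df["band_center_cm1"] > hi)]
        if len(out):
            raise BandTableError(
                f"band centers outside axis range [{lo:g}, {hi:g}]: "
                f"{out['band_center_cm1'].tolist()}"
            )
        if not self.tolerance > 0:
            raise BandTableError("tolerance must be > 0")
        self.entries = df.reset_index(drop=True)
        counts = df.groupby("entity").size()
        for entity in counts[counts < 2].index:
            msg = (
                f"entity {entity!r} has fewer than 2 bands and can never be "
                "assigned to a loading side"
            )
            self.warnings_.append(msg)
            warnings.warn(msg, stacklevel=2)

    @property
    def entities(self) -> list:
        return sorted(self.entries["entity"].unique())

    @property
    def usable_entities(self) -> list:
        counts = self.entries.groupby("entity").size()
        return sorted(counts[counts >= 2].index)

    def bands(self, entity: str) -> np.ndarray:
        sel = self.entries[self.entries["entity"] == entity]
        if sel.empty:
            raise BandTableError(f"unknown entity {entity!r}")
        return np.sort(sel["band_center_cm1"].to_numpy(dtype=float))

    def subset(self, entities) -> "BandTable":
        sel = self.entries[self.entries["entity"].isin(list(entities))]
        return BandTable(entries=sel.reset_index(drop=True), tolerance=self.tolerance)


# Characteristic fingerprint band centers (cm^-1) of the biomolecular
# entities tracked by the analysis.  Glycogen is the radiation-response
# marker cluster; protein covers Amide III / CH deformation / Amide I;
# lipid covers CC / CH / ester carbonyl modes.
_DEFAULT_BANDS = [
    ("glycogen", 482, "skeletal"),
    ("glycogen", 850, "C-O-C"),
    ("glycogen", 940, "C-O-C"),
    ("glycogen", 1042, "C-O"),
    ("glycogen", 1083, "C-O/C-C"),
    ("glycogen", 1129, "C-O/C-C"),
    ("glycogen", 1385, "CH3 def"),
    ("protein", 1240, "Amide III random coil/beta sheet"),
    ("protein", 1265, "Amide III alpha helix"),
    ("protein", 1297, "Amide III alpha helix"),
    ("protein", 1447, "CH deformation (with lipid overlap)"),
    ("protein", 1661, "Amide I alpha helix"),
    ("lipid", 1087, "C-C"),
    ("lipid", 1272, "C-C/=CH"),
    ("lipid", 1301, "CH2 twist"),
    ("lipid", 1740, "ester C=O"),
    ("phenylalanine", 1004, "ring breathing"),
    ("phenylalanine", 1047, "C-H in-plane"),
    ("phenylalanine", 1180, "C-H bend"),
    ("phenylalanine", 1210, "C-C6H5 stretch"),
    ("tryptophan", 729, "ring"),
    ("tryptophan", 1338, "ring"),
    ("tryptophan", 1374, "ring"),
    ("tryptophan", 1576, "ring"),
    ("tryptophan", 1621, "ring"),
    ("guanine", 669, "ring breathing"),
    ("guanine", 1328, "ring"),
    ("guanine", 1342, "ring"),
    ("guanine", 1374, "ring"),
    ("guanine", 1576, "ring"),
    ("adenine", 729, "ring breathing"),
    ("adenine", 1342, "ring"),
    ("adenine", 1374, "ring"),
    ("adenine", 1576, "ring"),
    ("thymine", 669, "ring"),
    ("thymine", 784, "ring breathing"),
    ("thymine", 1365, "ring"),
    ("choline", 716, "C-N symmetric stretch"),
    ("choline", 825, "C-N asymmetric stretch"),
]


def default_band_table(tolerance: float = DEFAULT_TOLERANCE) -> BandTable:
    """Band table assembled from canonical fingerprint band positions."""
    df = pd.DataFrame(_DEFAULT_BANDS, columns=["entity", "band_center_cm1", "note"])
    return BandTable(entries=df, tolerance=tolerance)
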
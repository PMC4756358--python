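"""Core containers for hyperspectral Raman map data.

A :class:`SpectralDataset` holds many spectra on one shared wavenumber grid
together with per-spectrum acquisition metadata (subject, dose, map position).
Spectra flagged by quality control are *retained* in the dataset but excluded
from every downstream statistic, mirroring the usual chemometric workflow
where artifact spectra are removed from analysis but kept for audit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Default fingerprint window (cm^-1) for biological Raman spectra.
FINGERPRINT_WINDOW = (460.0, 1800.0)

#: Allowed processing states, in pipeline order.
PROCESSING_STATES = ("raw", "baseline_subtracted", "aligned", "normalized")

#: Recognised quality-control flags.  ``degenerate`` marks spectra that a
#: processing stage could not handle (constant trace, failed peak fit,
#: non-positive normalization area).
QC_FLAG_NAMES = frozenset({"cosmic_ray", "saturated", "manual_exclude", "degenerate"})

METADATA_COLUMNS = ("subject_id", "dose_Gy", "section_id", "map_id", "x_um", "y_um")


class AxisError(ValueError):
    """Raised for invalid wavenumber axes."""


class DatasetError(ValueError):
    """Raised for inconsistent dataset construction or metadata."""


class StateError(ValueError):
    """Raised when an operation is applied to a spectrum in the wrong state."""


def validate_axis(
    values,
    window: tuple[float, float] = FINGERPRINT_WINDOW,
    min_points: int = 16,
) -> np.ndarray:
    """Validate a wavenumber axis and return it as a float array.

    The axis must be finite, strictly increasing, contain at least
    ``min_points`` points and lie inside ``window`` (the configured
    fingerprint range).
    """
    axis = np.asarray(values, dtype=float)
    if axis.ndim != 1:
        raise AxisError(f"axis must be one-dimensional, got shape {axis.shape}")
    if axis.size < min_points:
        raise AxisError(f"axis needs >= {min_points} points, got {axis.size}")
    if not np.all(np.isfinite(axis)):
        raise AxisError("axis contains non-finite values")
    if np.any(np.diff(axis) <= 0):
        raise AxisError("axis must be strictly increasing")
    lo, hi = window
    if axis[0] < lo - 1e-9 or axis[-1] > hi + 1e-9:
        raise AxisError(
            f"axis range [{axis[0]:g}, {axis[-1]:g}] outside window [{lo:g}, {hi:g}]"
        )
    return axis


@dataclass(frozen=True)
class WavenumberAxis:
    """A validated, strictly increasing Raman-shift axis in cm^-1."""

    values: np.ndarray
    window: tuple[float, float] = FINGERPRINT_WINDOW

    def __post_init__(self):
        object.__setattr__(self, "values", validate_axis(self.values, self.window))

    def __len__(self) -> int:
        return self.values.size

    def __array__(self, dtype=None, copy=None):
        return np.asarray(self.values, dtype=dtype)

    @property
    def step(self) -> float:
        """Median grid spacing (cm^-1)."""
        return float(np.median(np.diff(self.values)))


def advance_state(current: str, new: str) -> str:
    """Check a state transition along raw -> baseline_subtracted -> aligned -> normalized."""
    if new not in PROCESSING_STATES or current not in PROCESSING_STATES:
        raise StateError(f"unknown state transition {current!r} -> {new!r}")
    if PROCESSING_STATES.index(new) <= PROCESSING_STATES.index(current):
        raise StateError(f"cannot move from state {current!r} back to {new!r}")
    return new


@dataclass
class Spectrum:
    """One wavenumber-indexed intensity trace with identity and QC state."""

    spectrum_id: str
    axis: np.ndarray
    intensity: np.ndarray
    qc_flags: set = field(default_factory=set)
    state: str = "raw"

    def __post_init__(self):
        self.axis = np.asarray(self.axis, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.shape != self.axis.shape:
            raise DatasetError(
                f"spectrum {self.spectrum_id!r}: intensity length "
                f"{self.intensity.size} != axis length {self.axis.size}"
            )
        if not np.all(np.isfinite(self.intensity)):
            raise DatasetError(f"spectrum {self.spectrum_id!r}: non-finite intensity")
        unknown = set(self.qc_flags) - QC_FLAG_NAMES
        if unknown:
            raise DatasetError(f"unknown qc flags {sorted(unknown)}")
        if self.state not in PROCESSING_STATES:
            raise DatasetError(f"unknown state {self.state!r}")

    @property
    def excluded(self) -> bool:
        return bool(self.qc_flags)


def _validate_metadata(metadata: pd.DataFrame) -> pd.DataFrame:
    md = metadata.copy()
    missing = [c for c in METADATA_COLUMNS if c not in md.columns]
    if missing:
        raise DatasetError(f"metadata missing columns {missing}")
    if md.index.has_duplicates:
        dups = md.index[md.index.duplicated()].unique().tolist()
        raise DatasetError(f"duplicate spectrum_id in metadata: {dups[:5]}")
    md["dose_Gy"] = pd.to_numeric(md["dose_Gy"])
    if (md["dose_Gy"] < 0).any():
        raise DatasetError("dose_Gy must be non-negative")
    md["x_um"] = pd.to_numeric(md["x_um"])
    md["y_um"] = pd.to_numeric(md["y_um"])
    # one dose per subject
    per_subject = md.groupby("subject_id")["dose_Gy"].nunique()
    bad = per_subject[per_subject > 1]
    if len(bad):
        raise DatasetError(f"subjects with multiple doses: {bad.index.tolist()}")
    # unique stage position within a map
    dup = md.duplicated(subset=["map_id", "x_um", "y_um"])
    if dup.any():
        raise DatasetError(
            "duplicate (map_id, x_um, y_um) positions: "
            f"{md.index[dup].tolist()[:5]}"
        )
    return md


@dataclass
class SpectralDataset:
    """Many spectra on one axis plus per-spectrum metadata and QC flags.

    ``intensities`` is an (n_spectra, n_points) matrix aligned with
    ``metadata.index`` (the spectrum ids).  Rows are kept in canonical order:
    lexicographic by (subject_id, map_id, y_um, x_um, spectrum_id), so that
    downstream score tables are reproducibly indexed regardless of input
    file order.
    """

    axis: np.ndarray
    intensities: np.ndarray
    metadata: pd.DataFrame
    qc_flags: dict = field(default_factory=dict)
    state: str = "raw"
    provenance: list = field(default_factory=list)

    def __post_init__(self):
        self.axis = validate_axis(self.axis)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 2:
            raise DatasetError("intensities must be a 2-D matrix")
        self.metadata = _validate_metadata(self.metadata)
        if self.intensities.shape[0] != len(self.metadata):
            raise DatasetError(
                f"{self.intensities.shape[0]} spectra vs "
                f"{len(self.metadata)} metadata rows"
            )
        if self.intensities.shape[1] != self.axis.size:
            raise DatasetError("intensity columns do not match axis length")
        if not np.all(np.isfinite(self.intensities)):
            raise DatasetError("non-finite intensities in dataset")
        for sid, flags in self.qc_flags.items():
            if sid not in self.metadata.index:
                raise DatasetError(f"qc flag for unknown spectrum {sid!r}")
            unknown = set(flags) - QC_FLAG_NAMES
            if unknown:
                raise DatasetError(f"unknown qc flags {sorted(unknown)}")
        self._canonical_order()

    def _canonical_order(self):
        order = self.metadata.sort_values(
            ["subject_id", "map_id", "y_um", "x_um"],
            kind="mergesort",
        ).index
        # stable tiebreak on spectrum_id via mergesort + index uniqueness
        pos = self.metadata.index.get_indexer(order)
        self.metadata = self.metadata.loc[order]
        self.intensities = self.intensities[pos]

    # -- identity -----------------------------------------------------------
    @property
    def ids(self) -> list:
        return self.metadata.index.tolist()

    @property
    def n_spectra(self) -> int:
        return len(self.metadata)

    def flags_for(self, spectrum_id: str) -> set:
        return set(self.qc_flags.get(spectrum_id, set()))

    @property
    def surviving_mask(self) -> np.ndarray:
        return np.array([not self.qc_flags.get(sid) for sid in self.ids], dtype=bool)

    @property
    def surviving_ids(self) -> list:
        mask = self.surviving_mask
        return [sid for sid, ok in zip(self.ids, mask) if ok]

    @property
    def excluded_ids(self) -> list:
        mask = self.surviving_mask
        return [sid for sid, ok in zip(self.ids, mask) if not ok]

    def surviving_matrix(self) -> np.ndarray:
        return self.intensities[self.surviving_mask]

    def spectrum(self, spectrum_id: str) -> Spectrum:
        if spectrum_id not in self.metadata.index:
            raise DatasetError(f"unknown spectrum id {spectrum_id!r}")
        i = self.metadata.index.get_loc(spectrum_id)
        return Spectrum(
            spectrum_id=spectrum_id,
            axis=self.axis,
            intensity=self.intensities[i].copy(),
            qc_flags=self.flags_for(spectrum_id),
            state=self.state,
        )

    def set_intensity(self, spectrum_id: str, values: np.ndarray):
        i = self.metadata.index.get_loc(spectrum_id)
        self.intensities[i] = np.asarray(values, dtype=float)

    def add_flag(self, spectrum_id: str, flag: str):
        if flag not in QC_FLAG_NAMES:
            raise DatasetError(f"unknown qc flag {flag!r}")
        if spectrum_id not in self.metadata.index:
            raise DatasetError(f"unknown spectrum id {spectrum_id!r}")
        self.qc_flags.setdefault(spectrum_id, set()).add(flag)

    def clear_flags(self, spectrum_id: str):
        self.qc_flags.pop(spectrum_id, None)

    def log(self, message: str):
        self.provenance.append(message)

    def copy(self) -> "SpectralDataset":
        return SpectralDataset(
            axis=self.axis.copy(),
            intensities=self.intensities.copy(),
            metadata=self.metadata.copy(),
            qc_flags={k: set(v) for k, v in self.qc_flags.items()},
            state=self.state,
            provenance=list(self.provenance),
        )
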
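"""Plain-text readers/writers for spectra, metadata, band tables and matrices.

Dialect: UTF-8, comma- or tab-separated (sniffed), ``#`` comment lines,
mandatory header row.  Spectra are exchanged in long format
(``spectrum_id, wavenumber, intensity``); matrices (loadings, scores, map
grids) as wide tables whose floats are printed with 17 significant digits so
that a write/read round trip is bit-identical.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .bands import DEFAULT_TOLERANCE, BandTable
from .dataset import METADATA_COLUMNS, DatasetError, SpectralDataset

#: float format preserving full float64 precision through text
FLOAT_FMT = "%.17g"


class IOError_(ValueError):
    """Raised for malformed input files."""


@dataclass
class IOConfig:
    """Options for dataset assembly.

    resample_tol
        Maximum per-point wavenumber discrepancy (cm^-1) between a spectrum's
        own axis and the dataset axis that is bridged by linear interpolation;
        larger discrepancies are treated as data errors.
    """

    resample_tol: float = 0.5


def _read_table(path) -> pd.DataFrame:
    """Read a CSV/TSV table with sniffed delimiter and '#' comments."""
    path = Path(path)
    with open(path, "r", encoding="utf-8") as fh:
        sample = fh.read(4096)
    if not sample.strip():
        raise IOError_(f"{path}: empty file")
    try:
        dialect = csv.Sniffer().sniff(sample.splitlines()[0], delimiters=",\t")
        sep = dialect.delimiter
    except csv.Error:
        sep = ","
    return pd.read_csv(
        path, sep=sep, comment="#", encoding="utf-8", float_precision="round_trip"
    )


def read_dataset(spectra_path, metadata_path, config: IOConfig | None = None) -> SpectralDataset:
    """Assemble a :class:`SpectralDataset` from long-format spectra + metadata.

    Spectra whose axes differ from the first spectrum's axis by less than
    ``config.resample_tol`` are linearly resampled onto it (recorded in the
    dataset provenance log); larger mismatches raise.
    """
    config = config or IOConfig()
    spectra = _read_table(spectra_path)
    metadata = _read_table(metadata_path)

    need = {"spectrum_id", "wavenumber", "intensity"}
    if not need.issubset(spectra.columns):
        raise IOError_(f"spectra table needs columns {sorted(need)}")
    for col in ("wavenumber", "intensity"):
        vals = pd.to_numeric(spectra[col], errors="coerce")
        if vals.isna().any():
            bad = spectra.loc[vals.isna(), "spectrum_id"].iloc[0]
            raise IOError_(f"non-numeric {col} for spectrum {bad!r}")
        spectra[col] = vals

    if "spectrum_id" not in metadata.columns:
        raise IOError_("metadata table needs a spectrum_id column")
    missing_cols = [c for c in METADATA_COLUMNS if c not in metadata.columns]
    if missing_cols:
        raise IOError_(f"metadata table missing columns {missing_cols}")
    metadata = metadata.set_index("spectrum_id")
    if metadata.index.has_duplicates:
        dup = metadata.index[metadata.index.duplicated()].unique().tolist()
        raise IOError_(f"duplicate spectrum_id in metadata: {dup[:5]}")

    spec_ids = list(dict.fromkeys(spectra["spectrum_id"]))  # file order
    md_ids = set(metadata.index)
    orphan_spectra = [s for s in spec_ids if s not in md_ids]
    if orphan_spectra:
        raise IOError_(f"spectra without metadata row: {orphan_spectra[:5]}")
    orphan_md = [s for s in metadata.index if s not in set(spec_ids)]
    if orphan_md:
        raise IOError_(f"metadata rows without spectra: {orphan_md[:5]}")

    groups = {sid: g for sid, g in spectra.groupby("spectrum_id", sort=False)}
    axis = groups[spec_ids[0]]["wavenumber"].to_numpy(dtype=float)
    if np.any(np.diff(axis) <= 0):
        raise IOError_(f"non-monotonic wavenumbers for spectrum {spec_ids[0]!r}")

    provenance = []
    rows = np.empty((len(spec_ids), axis.size))
    for i, sid in enumerate(spec_ids):
        g = groups[sid]
        wn = g["wavenumber"].to_numpy(dtype=float)
        inten = g["intensity"].to_numpy(dtype=float)
        if np.any(np.diff(wn) <= 0):
            raise IOError_(f"non-monotonic wavenumbers for spectrum {sid!r}")
        if wn.size == axis.size and np.array_equal(wn, axis):
            rows[i] = inten
            continue
        if wn.size != axis.size or np.max(np.abs(wn - axis)) >= config.resample_tol:
            raise IOError_(
                f"spectrum {sid!r}: axis differs from dataset axis beyond "
                f"resample tolerance {config.resample_tol} cm^-1"
            )
        rows[i] = np.interp(axis, wn, inten)
        provenance.append(
            f"resampled {sid} onto dataset axis "
            f"(max offset {np.max(np.abs(wn - axis)):.4g} cm^-1)"
        )

    ds = SpectralDataset(
        axis=axis,
        intensities=rows,
        metadata=metadata.loc[spec_ids],
        provenance=provenance,
    )
    return ds


def write_dataset(dataset: SpectralDataset, spectra_path, metadata_path):
    """Write a dataset back to long-format spectra + metadata tables."""
    n, p = dataset.intensities.shape
    if n == 0:
        raise IOError_("refusing to write an empty dataset")
    long = pd.DataFrame(
        {
            "spectrum_id": np.repeat(dataset.ids, p),
            "wavenumber": np.tile(dataset.axis, n),
            "intensity": dataset.intensities.ravel(),
        }
    )
    long.to_csv(spectra_path, index=False, float_format=FLOAT_FMT)
    md = dataset.metadata.reset_index()
    if "spectrum_id" not in md.columns:  # index name fallback
        md = md.rename(columns={md.columns[0]: "spectrum_id"})
    md.to_csv(metadata_path, index=False, float_format=FLOAT_FMT)


def write_matrix(ids, names, values, path, id_column: str = "id"):
    """Write a labelled matrix as CSV, round-trippable at full precision.

    ``ids`` label rows, ``names`` label columns (e.g. wavenumbers for a
    loadings matrix, PC names for scores).
    """
    values = np.asarray(values, dtype=float)
    ids = list(ids)
    names = list(names)
    if len(ids) == 0:
        raise IOError_("refusing to write a matrix with no rows")
    if values.shape != (len(ids), len(names)):
        raise IOError_(
            f"matrix shape {values.shape} inconsistent with "
            f"{len(ids)} ids x {len(names)} names"
        )
    df = pd.DataFrame(values, columns=[str(n) for n in names])
    df.insert(0, id_column, ids)
    df.to_csv(path, index=False, float_format=FLOAT_FMT)


def read_matrix(path):
    """Read a matrix written by :func:`write_matrix`.

    Returns (ids, names, values); names are strings (caller converts
    wavenumber columns back to float where appropriate).
    """
    df = _read_table(path)
    if df.shape[1] < 2:
        raise IOError_(f"{path}: not a matrix table")
    ids = df.iloc[:, 0].tolist()
    names = df.columns[1:].tolist()
    values = df.iloc[:, 1:].to_numpy(dtype=float)
    return ids, names, values


def read_band_table(path, tolerance: float | None = None) -> BandTable:
    """Read a band table CSV with columns entity, band_center_cm1[, note].

    The tolerance may be given as a ``# tolerance_cm1 = X`` comment header or
    via the ``tolerance`` argument; the argument wins.
    """
    path = Path(path)
    header_tol = None
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            text = line.lstrip("#").strip()
            if text.lower().startswith("tolerance_cm1"):
                header_tol = float(text.split("=", 1)[1])
    df = _read_table(path)
    if "band_center" in df.columns and "band_center_cm1" not in df.columns:
        df = df.rename(columns={"band_center": "band_center_cm1"})
    tol = tolerance if tolerance is not None else (header_tol or DEFAULT_TOLERANCE)
    return BandTable(entries=df, tolerance=tol)


def write_band_table(table: BandTable, path):
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# tolerance_cm1 = {table.tolerance:g}\n")
        table.entries.to_csv(fh, index=False)


def read_loading_vector(path):
    """Read one loading vector: returns (axis, values).

    Accepts either a two-column table (wavenumber, value) or the first row of
    a :func:`write_matrix` loadings file (columns = wavenumbers).
    """
    df = _read_table(path)
    cols = [c.lower() for c in df.columns]
    if "wavenumber" in cols:
        wn = df.iloc[:, cols.index("wavenumber")].to_numpy(dtype=float)
        other = [i for i in range(df.shape[1]) if i != cols.index("wavenumber")]
        vals = df.iloc[:, other[0]].to_numpy(dtype=float)
        return wn, vals
    ids, names, values = read_matrix(path)
    try:
        wn = np.array([float(n) for n in names])
    except ValueError as exc:
        raise IOError_(f"{path}: cannot interpret columns as wavenumbers") from exc
    return wn, values[0]
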
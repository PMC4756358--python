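"""Rasterize per-spectrum PC scores into 2-D tissue maps.

Map grids follow the image convention: row-major, y increasing downward,
origin at (min x, min y) of the mapping region.  Cells whose spectrum was
excluded by quality control are masked — the rendered analog of hatched
"no data" pixels in score-map figures.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .io import FLOAT_FMT


class SpatialError(ValueError):
    pass


@dataclass
class ScoreMap:
    """One PC's scores on the acquisition lattice of a single map region."""

    map_id: str
    grid: np.ndarray          # (rows, cols) float, NaN where masked
    mask: np.ndarray          # (rows, cols) bool, True = score available
    spectrum_ids: np.ndarray  # (rows, cols) object, None where no spectrum
    origin: tuple             # (x0, y0) in um
    step: float               # um
    pc_index: int

    def __post_init__(self):
        if self.grid.shape != self.mask.shape or self.grid.shape != self.spectrum_ids.shape:
            raise SpatialError("grid/mask/id arrays must be congruent")
        if np.isfinite(self.grid[~self.mask]).any():
            raise SpatialError("masked cells must carry no score")

    @property
    def shape(self) -> tuple:
        return self.grid.shape

    def unmasked_items(self) -> list:
        """(spectrum_id, score) pairs of all available cells, row-major."""
        out = []
        rows, cols = self.grid.shape
        for i in range(rows):
            for j in range(cols):
                if self.mask[i, j]:
                    out.append((self.spectrum_ids[i, j], float(self.grid[i, j])))
        return out


def build_score_map(scores: pd.Series, metadata: pd.DataFrame, map_id: str,
                    pc_index: int = 1, step: float = 15.0,
                    snap_tol_fraction: float = 0.5) -> ScoreMap:
    """Place scores of one mapping region onto its acquisition lattice.

    ``scores`` is indexed by spectrum_id and holds scores of *surviving*
    spectra only; spectra of the map that are absent from ``scores`` (i.e.
    excluded) produce masked cells.  Stage coordinates must sit on a lattice
    of the given step within ``snap_tol_fraction * step`` (exclusive);
    larger offsets and cell collisions are data errors.
    """
    region = metadata[metadata["map_id"] == map_id]
    if region.empty:
        raise SpatialError(f"no spectra with map_id {map_id!r}")
    x = region["x_um"].to_numpy(dtype=float)
    y = region["y_um"].to_numpy(dtype=float)
    x0, y0 = float(x.min()), float(y.min())
    jj = np.round((x - x0) / step).astype(int)
    ii = np.round((y - y0) / step).astype(int)
    resid = np.hypot(x - (x0 + jj * step), y - (y0 + ii * step))
    tol = snap_tol_fraction * step
    bad = resid >= tol - 1e-9
    if bad.any():
        sid = region.index[bad][0]
        raise SpatialError(
            f"spectrum {sid!r} at ({x[bad][0]:g}, {y[bad][0]:g}) um is "
            f"{resid[bad][0]:.3g} um off the {step:g} um lattice"
        )
    rows, cols = int(ii.max()) + 1, int(jj.max()) + 1
    grid = np.full((rows, cols), np.nan)
    mask = np.zeros((rows, cols), dtype=bool)
    ids = np.full((rows, cols), None, dtype=object)
    for sid, i, j in zip(region.index, ii, jj):
        if ids[i, j] is not None:
            raise SpatialError(
                f"spectra {ids[i, j]!r} and {sid!r} map to the same cell "
                f"({i}, {j}) of map {map_id!r}"
            )
        ids[i, j] = sid
        if sid in scores.index:
            grid[i, j] = float(scores.loc[sid])
            mask[i, j] = True
    return ScoreMap(
        map_id=str(map_id), grid=grid, mask=mask, spectrum_ids=ids,
        origin=(x0, y0), step=float(step), pc_index=int(pc_index),
    )


@dataclass
class MapSummary:
    map_id: str
    n: int
    median: float
    iqr: float
    range: float
    frac_beyond: float | None


def heterogeneity_summary(maps: list, threshold: float | None = None) -> dict:
    """Intra-map and between-map score-spread summary for one subject.

    Per map: IQR, range and (optionally) the fraction of scores beyond
    ``threshold`` in absolute value.  Across maps: spread (IQR and range) of
    the per-map medians, the between-region component of intra-tumour
    heterogeneity.
    """
    if not maps:
        raise SpatialError("need at least one map")
    per_map = []
    for m in maps:
        vals = m.grid[m.mask]
        if vals.size == 0:
            raise SpatialError(f"map {m.map_id!r} has no available scores")
        q25, med, q75 = np.percentile(vals, [25, 50, 75])
        per_map.append(
            MapSummary(
                map_id=m.map_id,
                n=int(vals.size),
                median=float(med),
                iqr=float(q75 - q25),
                range=float(vals.max() - vals.min()),
                frac_beyond=(
                    float(np.mean(np.abs(vals) > threshold))
                    if threshold is not None else None
                ),
            )
        )
    medians = np.array([s.median for s in per_map])
    q25, q75 = np.percentile(medians, [25, 75])
    return {
        "per_map": per_map,
        "between_map_median_iqr": float(q75 - q25),
        "between_map_median_range": float(medians.max() - medians.min()),
    }


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------

def write_score_map(score_map: ScoreMap, out_dir, stem: str | None = None):
    """Write grid CSV (NaN-marked), mask CSV and a JSON sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stem = stem or f"map_{score_map.map_id}_pc{score_map.pc_index}"
    pd.DataFrame(score_map.grid).to_csv(
        out_dir / f"{stem}_grid.csv", index=False, header=False,
        float_format=FLOAT_FMT,
    )
    pd.DataFrame(score_map.mask.astype(int)).to_csv(
        out_dir / f"{stem}_mask.csv", index=False, header=False
    )
    sidecar = {
        "map_id": score_map.map_id,
        "origin_x_um": score_map.origin[0],
        "origin_y_um": score_map.origin[1],
        "step_um": score_map.step,
        "pc_index": score_map.pc_index,
        "shape": list(score_map.shape),
    }
    with open(out_dir / f"{stem}.json", "w", encoding="utf-8") as fh:
        json.dump(sidecar, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return [out_dir / f"{stem}_grid.csv", out_dir / f"{stem}_mask.csv", out_dir / f"{stem}.json"]


def render_score_map(score_map: ScoreMap, path):
    """Optional grayscale PNG (dark = negative score, masked cells hatched)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    data = np.ma.masked_array(score_map.grid, mask=~score_map.mask)
    im = ax.imshow(data, cmap="gray", origin="upper")
    for (i, j), ok in np.ndenumerate(score_map.mask):
        if not ok:
            ax.plot([j - 0.4, j + 0.4], [i + 0.4, i - 0.4], color="red", lw=1)
    fig.colorbar(im, ax=ax, label=f"PC{score_map.pc_index} score")
    ax.set_title(f"map {score_map.map_id}")
    fig.savefig(path, dpi=150)
    plt.close(fig)
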
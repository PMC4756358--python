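"""Ground-truthed synthetic Raman tissue-map generator.

Emulates the statistical structure of an irradiated-xenograft Raman mapping
study: fingerprint spectra (460-1800 cm^-1) composed of biomolecular basis
spectra on a broad fluorescence baseline, per-spectrum wavenumber drift
below 1 cm^-1, cosmic-ray spikes and saturated traces, dose-dependent and
spatially patchy glycogen enrichment, per-subject (per-tumour) random
effects, and a 3-dose x 4-subject x several-map grid design.

Every draw derives from a single seeded generator, so a (config, seed) pair
reproduces the dataset bit-identically, and the returned
:class:`GroundTruth` is the oracle against which the processing pipeline is
tested.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .bands import BandTable, default_band_table
from .dataset import SpectralDataset


class SimulationError(ValueError):
    pass


#: Relative mixing weights of the biomolecular bases in unirradiated tissue.
DEFAULT_ENTITY_WEIGHTS = {
    "glycogen": 0.6,
    "protein": 1.0,
    "lipid": 0.7,
    "phenylalanine": 0.3,
    "tryptophan": 0.2,
    "guanine": 0.15,
    "adenine": 0.15,
    "thymine": 0.1,
    "choline": 0.15,
}


@dataclass
class SimulationConfig:
    """Study-design and noise parameters of the generator.

    Defaults mirror the emulated study design: doses (0, 5, 15) Gy, four
    subjects per dose, five mapping regions per subject on a 15 um grid,
    axis 460-1800 cm^-1 at 1 cm^-1.  ``dose_effect`` is the per-Gy
    multiplicative increment of the glycogen weight; ``drift_max`` < 1 cm^-1
    matches the calibration drift the alignment stage is built for.
    """

    seed: int = 0
    doses: tuple = (0.0, 5.0, 15.0)
    subjects_per_dose: int = 4
    maps_per_subject: int = 5
    sections_per_subject: int = 3
    grid_rows: int = 8
    grid_cols: int = 8
    step_um: float = 15.0
    axis_min: float = 460.0
    axis_max: float = 1800.0
    axis_step: float = 1.0
    peak_sigma: float = 4.0
    entity_weights: dict = field(default_factory=lambda: dict(DEFAULT_ENTITY_WEIGHTS))
    dose_effect: float = 0.06
    dose_effect_entity: str = "glycogen"
    subject_sd: float = 0.15
    spatial_corr_len: float = 2.0
    spatial_sd: float = 0.35
    noise_sd: float = 0.03
    baseline_coeffs: tuple = (1.0, -0.6, 0.15, 0.35)
    baseline_amplitude: float = 5.0
    baseline_amp_jitter: float = 0.1
    drift_max: float = 0.9
    cosmic_rate: float = 0.03
    cosmic_channels: tuple = (1, 2)
    cosmic_amp_range: tuple = (10.0, 100.0)
    saturation_rate: float = 0.02

    def __post_init__(self):
        for name in ("cosmic_rate", "saturation_rate"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise SimulationError(f"{name} must be in [0, 1]")
        if self.dose_effect < 0:
            raise SimulationError("dose_effect must be >= 0")
        if not (0 <= self.drift_max < 1):
            raise SimulationError("drift_max must be in [0, 1) cm^-1")

    def axis(self) -> np.ndarray:
        return np.arange(self.axis_min, self.axis_max + 0.5 * self.axis_step,
                         self.axis_step)


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must recover."""

    weights: pd.DataFrame          # per-spectrum true entity weights
    baselines: np.ndarray          # (n, p) true fluorescence baselines
    clean_signals: np.ndarray      # (n, p) true Raman signal, pre-drift
    shifts: pd.Series              # per-spectrum rigid drift (cm^-1)
    cosmic_channels: dict          # spectrum_id -> list of spiked channels
    saturated_ids: list
    saturation_ceiling: float | None
    noise_sd_abs: float
    subject_effects: pd.Series     # per-subject log-weight effect on the marker entity
    spatial_fields: dict           # map_id -> (rows, cols) log-weight field
    bases: pd.DataFrame            # columns = entities, index = wavenumber
    config: SimulationConfig

    @property
    def artifact_ids(self) -> list:
        return sorted(set(self.cosmic_channels) | set(self.saturated_ids))


def make_basis_spectra(table: BandTable, axis: np.ndarray,
                       peak_sigma: float = 4.0) -> pd.DataFrame:
    """Unit-area Gaussian-comb basis spectrum per entity.

    Each basis is the sum of Gaussians (width ``peak_sigma`` cm^-1) at the
    entity's band centers, scaled to unit trapezoidal area over the axis.
    """
    axis = np.asarray(axis, dtype=float)
    bases = {}
    for entity in table.entities:
        bands = table.bands(entity)
        if bands.size < 2:
            raise SimulationError(f"entity {entity!r} has fewer than 2 bands")
        v = np.zeros_like(axis)
        for c in bands:
            v += np.exp(-0.5 * ((axis - c) / peak_sigma) ** 2)
        area = np.trapezoid(v, axis)
        bases[entity] = v / area
    return pd.DataFrame(bases, index=pd.Index(axis, name="wavenumber"))


def _spatial_field(rng, rows, cols, corr_len, sd) -> np.ndarray:
    """Kernel-smoothed white noise, standardized to mean 0 / sd ``sd``."""
    white = rng.standard_normal((rows, cols))
    if sd == 0:
        return np.zeros((rows, cols))
    if corr_len > 0:
        smooth = ndimage.gaussian_filter(white, sigma=corr_len, mode="reflect")
    else:
        smooth = white
    s = smooth.std()
    if s == 0:  # degenerate 1x1 grid
        return np.zeros((rows, cols))
    return (smooth - smooth.mean()) / s * sd


def simulate_dataset(config: SimulationConfig | None = None,
                     seed: int | None = None,
                     band_table: BandTable | None = None):
    """Generate a raw-state dataset plus its full ground truth.

    Per spectrum the marker entity's weight (glycogen by default) is
    ``w0 * exp(subject_effect + spatial_field) * (1 + dose_effect * dose)``
    — inter-tumour and intra-tumour heterogeneity both act on the
    dose-responsive marker, the other entity weights stay at ``w0``; the clean
    signal (weights x bases) is stacked on a cubic-polynomial fluorescence
    baseline, rigidly drifted by Uniform(-drift_max, drift_max) cm^-1 via
    linear interpolation, and corrupted with Gaussian noise, cosmic spikes
    and saturation clipping at the configured rates.
    """
    config = config or SimulationConfig()
    if seed is not None:
        config = SimulationConfig(**{**config.__dict__, "seed": seed})
    rng = np.random.default_rng(config.seed)
    axis = config.axis()
    table = band_table or default_band_table()
    entities = list(config.entity_weights)
    if config.dose_effect_entity not in entities:
        raise SimulationError(
            f"dose_effect_entity {config.dose_effect_entity!r} not among entities"
        )
    bases_df = make_basis_spectra(table.subset(entities), axis, config.peak_sigma)
    bases_df = bases_df[entities]
    B = bases_df.to_numpy().T  # (E, p)
    w0 = np.array([config.entity_weights[e] for e in entities])

    # ---- design ---------------------------------------------------------
    subject_ids = []
    for d_i, dose in enumerate(config.doses):
        for s_i in range(config.subjects_per_dose):
            subject_ids.append((f"S{d_i}{s_i:02d}", dose))
    # inter-tumour heterogeneity acts on the marker entity: some subjects
    # express the dose-responsive signature more than others
    effects = rng.normal(0.0, config.subject_sd, size=len(subject_ids))
    subject_effects = pd.Series(
        effects,
        index=pd.Index([s for s, _ in subject_ids], name="subject_id"),
        name="log_weight_effect",
    )

    spatial_fields = {}
    log_w = []
    meta = []
    for (subject, dose), eff in zip(subject_ids, effects):
        for m_i in range(config.maps_per_subject):
            map_id = f"{subject}_M{m_i:02d}"
            section = f"{subject}_T{m_i % config.sections_per_subject}"
            fld = _spatial_field(
                rng, config.grid_rows, config.grid_cols,
                config.spatial_corr_len, config.spatial_sd,
            )
            spatial_fields[map_id] = fld
            gi = entities.index(config.dose_effect_entity)
            for r in range(config.grid_rows):
                for c in range(config.grid_cols):
                    sid = f"{map_id}_{r:02d}_{c:02d}"
                    lw = np.log(w0).copy()
                    lw[gi] += eff + fld[r, c] + np.log1p(config.dose_effect * dose)
                    log_w.append(lw)
                    meta.append(
                        {
                            "spectrum_id": sid,
                            "subject_id": subject,
                            "dose_Gy": dose,
                            "section_id": section,
                            "map_id": map_id,
                            "x_um": c * config.step_um,
                            "y_um": r * config.step_um,
                        }
                    )
    W = np.exp(np.array(log_w))  # (n, E), positive by construction
    metadata = pd.DataFrame(meta).set_index("spectrum_id")
    n = len(metadata)

    clean = W @ B  # (n, p)
    mean_peak_amp = float(np.mean(clean.max(axis=1)))
    noise_sd_abs = config.noise_sd * mean_peak_amp

    # fluorescence baseline: cubic polynomial in u = (x - min)/range
    u = (axis - axis[0]) / (axis[-1] - axis[0])
    poly = np.polynomial.polynomial.polyval(u, np.asarray(config.baseline_coeffs))
    amp = (
        config.baseline_amplitude
        * mean_peak_amp
        * np.exp(rng.normal(0.0, config.baseline_amp_jitter, size=n))
    )
    baselines = amp[:, None] * poly[None, :]

    y = clean + baselines

    # rigid calibration drift: observed(x) = true(x - delta)
    shifts = rng.uniform(-config.drift_max, config.drift_max, size=n)
    for i in range(n):
        if shifts[i] != 0.0:
            y[i] = np.interp(axis - shifts[i], axis, y[i])

    if noise_sd_abs > 0:
        y += rng.normal(0.0, noise_sd_abs, size=y.shape)

    # cosmic-ray spikes
    cosmic = {}
    sids = metadata.index.tolist()
    for i in range(n):
        if config.cosmic_rate > 0 and rng.random() < config.cosmic_rate:
            n_ch = int(rng.integers(config.cosmic_channels[0],
                                    config.cosmic_channels[1] + 1))
            chans = rng.choice(axis.size, size=n_ch, replace=False)
            amps = rng.uniform(*config.cosmic_amp_range, size=n_ch) * (
                noise_sd_abs if noise_sd_abs > 0 else 0.01 * mean_peak_amp
            )
            y[i, chans] += amps
            cosmic[sids[i]] = sorted(int(c) for c in chans)

    # saturation: boost a spectrum over a global detector ceiling and clip
    saturated = []
    ceiling = None
    if config.saturation_rate > 0:
        ceiling = 2.0 * float(y.max())
        for i in range(n):
            if rng.random() < config.saturation_rate:
                scale = 1.3 * ceiling / y[i].max()
                y[i] = np.minimum(y[i] * scale, ceiling)
                saturated.append(sids[i])

    dataset = SpectralDataset(
        axis=axis, intensities=y, metadata=metadata, state="raw",
        provenance=[f"simulated with seed {config.seed}"],
    )
    order = dataset.ids  # canonical order applied by the container
    truth = GroundTruth(
        weights=pd.DataFrame(W, index=pd.Index(sids, name="spectrum_id"),
                             columns=entities).loc[order],
        baselines=baselines[metadata.index.get_indexer(order)],
        clean_signals=clean[metadata.index.get_indexer(order)],
        shifts=pd.Series(shifts, index=pd.Index(sids, name="spectrum_id"),
                         name="shift_cm1").loc[order],
        cosmic_channels=cosmic,
        saturated_ids=saturated,
        saturation_ceiling=ceiling,
        noise_sd_abs=noise_sd_abs,
        subject_effects=subject_effects,
        spatial_fields=spatial_fields,
        bases=bases_df,
        config=config,
    )
    return dataset, truth


def truth_contrast(truth: GroundTruth,
                   entity: str | None = None) -> np.ndarray:
    """Reference loading-shaped vector for the dose-affected entity.

    The affected entity's basis minus the mean-weight-weighted average of
    the other bases, scaled to unit L2 norm — the spectral direction along
    which the injected dose effect moves the data, used to validate
    recovered loadings by correlation.
    """
    entity = entity or truth.config.dose_effect_entity
    entities = list(truth.bases.columns)
    if entity not in entities:
        raise SimulationError(f"unknown entity {entity!r}")
    others = [e for e in entities if e != entity]
    if not others:
        raise SimulationError(
            "contrast undefined for a single-entity simulation"
        )
    wbar = truth.weights[others].mean(axis=0).to_numpy()
    mean_other = (truth.bases[others].to_numpy() @ wbar) / wbar.sum()
    v = truth.bases[entity].to_numpy() - mean_other
    norm = np.linalg.norm(v)
    if norm == 0:
        raise SimulationError("degenerate contrast (identical bases)")
    return v / norm
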
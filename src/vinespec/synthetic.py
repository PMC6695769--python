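"""Synthetic vineyard world: layout, chemistry fields and spectral streams.

The generator emulates the acquisition campaign the pipeline is built for: a
vertically shoot-positioned vineyard monitored with a vehicle-mounted
VIS+SW-NIR spectrometer (570–990 nm, 215 channels, 18 Hz) driven along the
rows at 5 km/h over four ripening dates.  Three rows of 12 five-vine blocks
(36 blocks) carry per-block reference chemistry for three analytes — total
soluble solids (°Brix), anthocyanins (mg/berry) and total polyphenols
(AU/berry) — drawn from spatially autocorrelated fields with monotone
ripening trends.  Each block pass yields a stream mixing grape-cluster,
leaf, wood and gap spectra; the true class of every spectrum is retained as
a hidden label so the downstream signature filter can be scored against
ground truth.

Cluster spectra follow a linear-mixture model in absorbance: a smooth berry
base spectrum plus one Gaussian absorption band per analyte whose amplitude
scales with the block's (range-normalised) concentration, degraded by a
per-spectrum multiplicative gain, an additive offset and white channel
noise.  This is deliberately idealised — no radiative transfer, no canopy
geometry — but it reproduces the statistical structure the analysis
assumes: class-separable signatures, analyte information encoded in
localised bands, and scatter effects that SNV/derivative preprocessing is
designed to remove.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .spectra_io import ANALYTES, BlockChemistry, BlockRecord, SpectralStream

CLASS_LABELS = ("cluster", "leaf", "wood", "gap")


class ConfigurationError(ValueError):
    """A generator parameter is out of its valid domain."""


# ---------------------------------------------------------------------------
# configuration types


@dataclass
class VineyardLayout:
    """Geometry of the monitored plot.

    Blocks are consecutive groups of ``vines_per_block`` vines along each
    row; the block centroid sits at the middle of that group.  ``origin`` is
    the (x, y) of the first vine of the first row in planar metres and
    ``row_azimuth`` rotates the whole plot about it (degrees
    counter-clockwise from the +x axis).
    """

    rows: int = 3
    blocks_per_row: int = 12
    vines_per_block: int = 5
    row_spacing: float = 2.20  # m between rows
    vine_spacing: float = 1.0  # m between vines
    origin: tuple[float, float] = (0.0, 0.0)
    row_azimuth: float = 0.0  # degrees

    def __post_init__(self) -> None:
        if self.rows < 1 or self.blocks_per_row < 1 or self.vines_per_block < 1:
            raise ConfigurationError("layout dimensions must be >= 1")
        if self.row_spacing <= 0 or self.vine_spacing <= 0:
            raise ConfigurationError("spacings must be positive")

    @property
    def block_length(self) -> float:
        """Along-row extent of one block in metres."""
        return self.vines_per_block * self.vine_spacing

    @property
    def n_blocks(self) -> int:
        return self.rows * self.blocks_per_row


@dataclass
class AnalyteParams:
    """Field and spectral parameters of one analyte.

    ``global_range`` hard-bounds every generated concentration.
    ``date_means`` (one per measurement date, monotone non-decreasing)
    carries the ripening trend; ``spatial_sd`` scales the latent spatial
    field, whose covariance decays over ``spatial_correlation_length``
    metres; ``noise_sd`` is per-block-and-date independent noise.
    ``spectral_snr`` is the absorbance-band amplitude a full-range
    concentration swing imprints on a cluster spectrum.  ``berry_sd`` is
    the berry-to-berry within-block variability: each measuring spot sees
    only a couple of berries, whose composition scatters around the
    block's reference value (which the wet-chemistry assay averages over a
    large berry sample); it is the irreducible mismatch between the
    optical measurement and the reference method.
    """

    global_range: tuple[float, float]
    date_means: tuple[float, ...]
    spatial_sd: float
    spatial_correlation_length: float = 15.0  # m
    noise_sd: float = 0.0
    spectral_snr: float = 0.05
    berry_sd: float = 0.0

    def __post_init__(self) -> None:
        lo, hi = self.global_range
        if not lo < hi:
            raise ConfigurationError("global_range must satisfy min < max")
        if np.any(np.diff(self.date_means) < 0):
            raise ConfigurationError("date_means must be monotone non-decreasing")
        if self.spectral_snr <= 0:
            raise ConfigurationError("spectral_snr must be positive")

    def scale(self, value: np.ndarray | float) -> np.ndarray | float:
        """Map a concentration to [-1, 1] over the global range."""
        lo, hi = self.global_range
        return (np.asarray(value) - (lo + hi) / 2.0) / ((hi - lo) / 2.0)


@dataclass
class AnalyteFieldParams:
    """Per-analyte parameters plus the anthocyanin/polyphenol coupling.

    Defaults span the concentration ranges observed over a full ripening
    season for a red variety (TSS 10.7–25.2 °Brix, anthocyanins
    0.09–4.64 mg/berry, polyphenols 0.14–4.70 AU/berry) across four dates
    from veraison to harvest.  ``anthocyanin_polyphenol_corr`` correlates
    the two phenolic latent fields, reflecting that anthocyanins dominate
    the phenolic pool so their spatial patterns track each other.

    The default ``spectral_snr`` ordering (TSS > anthocyanins >
    polyphenols) encodes the well-established difficulty ordering of these
    analytes for VIS+SW-NIR calibration: sugar/water features are strong
    and direct, pigment features weaker, and the broad phenolic pool mostly
    reaches the spectrum indirectly through its correlation with pigments.
    """

    tss: AnalyteParams = field(default_factory=lambda: AnalyteParams(
        global_range=(10.7, 25.2),
        date_means=(14.5, 17.5, 20.0, 22.0),
        spatial_sd=2.0,
        noise_sd=0.35,
        spectral_snr=0.12,
        berry_sd=3.5,
    ))
    anthocyanins: AnalyteParams = field(default_factory=lambda: AnalyteParams(
        global_range=(0.09, 4.64),
        date_means=(0.8, 1.8, 2.8, 3.5),
        spatial_sd=0.65,
        noise_sd=0.12,
        spectral_snr=0.045,
        berry_sd=2.6,
    ))
    polyphenols: AnalyteParams = field(default_factory=lambda: AnalyteParams(
        global_range=(0.14, 4.70),
        date_means=(1.0, 2.0, 3.0, 3.6),
        spatial_sd=1.0,
        noise_sd=1.0,
        spectral_snr=0.012,
        berry_sd=1.5,
    ))
    anthocyanin_polyphenol_corr: float = 0.8

    def __getitem__(self, analyte: str) -> AnalyteParams:
        if analyte not in ANALYTES:
            raise KeyError(analyte)
        return getattr(self, analyte)


@dataclass
class Endmember:
    """A scene class's pure absorbance spectrum.

    ``bands`` (cluster class only) maps each analyte to a list of
    ``(center_nm, width_nm, loading)`` Gaussian absorption bands; the unit
    concentration response is the loading-weighted sum of unit-height
    Gaussians.
    """

    class_label: str
    base_absorbance: np.ndarray
    bands: dict[str, list[tuple[float, float, float]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.base_absorbance = np.asarray(self.base_absorbance, dtype=float)
        if not np.all(np.isfinite(self.base_absorbance)):
            raise ConfigurationError("base absorbance must be finite")
        if np.any(self.base_absorbance < 0):
            raise ConfigurationError("base absorbance must be non-negative")
        if self.class_label == "cluster":
            for analyte in ANALYTES:
                if not self.bands.get(analyte):
                    raise ConfigurationError(
                        f"cluster endmember needs >= 1 band for {analyte}"
                    )

    def band_profile(self, analyte: str, wavelengths: np.ndarray) -> np.ndarray:
        """Unit-concentration absorption profile of ``analyte``."""
        profile = np.zeros_like(wavelengths, dtype=float)
        for center, width, loading in self.bands.get(analyte, []):
            profile += loading * np.exp(-0.5 * ((wavelengths - center) / width) ** 2)
        return profile


@dataclass
class SimConfig:
    """Instrument and scene parameters of the simulated acquisition."""

    seed: int = 0
    wavelength_start: float = 570.0  # nm
    wavelength_end: float = 990.0  # nm
    n_channels: int = 215
    acquisition_rate: float = 18.0  # Hz
    platform_speed: float = 5.0  # km/h
    class_mixture: dict[str, float] = field(default_factory=lambda: {
        "cluster": 0.35, "leaf": 0.40, "wood": 0.10, "gap": 0.15,
    })
    scatter_slope_sd: float = 0.05
    scatter_offset_sd: float = 0.02
    channel_noise_sd: float = 0.008

    def __post_init__(self) -> None:
        if not self.class_mixture:
            raise ConfigurationError("class_mixture must be non-empty")
        total = sum(self.class_mixture.values())
        if not math.isclose(total, 1.0, rel_tol=0, abs_tol=1e-9):
            raise ConfigurationError(f"class_mixture must sum to 1 (got {total})")
        if self.n_channels < 2:
            raise ConfigurationError("need at least 2 channels")

    @property
    def wavelengths(self) -> np.ndarray:
        # The instrument reports 215 channels over 570-990 nm; the axis is
        # taken as 215 evenly spaced points over that closed interval.
        return np.linspace(self.wavelength_start, self.wavelength_end, self.n_channels)

    @property
    def speed_mps(self) -> float:
        return self.platform_speed * 1000.0 / 3600.0


def spot_area_cm2(diameter_cm: float = 1.9) -> float:
    """Area of the instrument's circular measuring spot in cm²."""
    return math.pi * (diameter_cm / 2.0) ** 2


# ---------------------------------------------------------------------------
# endmember library


def _gauss(wl: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((wl - center) / width) ** 2)


def default_endmembers(wavelengths: np.ndarray) -> dict[str, Endmember]:
    """Smooth idealised absorbance endmembers for the four scene classes.

    Shapes are stylised but physically motivated: the berry (cluster)
    spectrum is dominated by pigment absorption in the visible with a water
    feature near 970 nm; leaves show the strong chlorophyll band near
    680 nm and the sharp red-edge drop into a transparent NIR plateau; wood
    is a flat, slowly declining absorber; gaps return weak background
    signal.  Analyte bands sit where their chemistry absorbs in this range:
    anthocyanins in the green-orange visible, sugar/water (TSS) on the
    910–960 nm water-sugar overtone shoulder, polyphenols as a weak broad
    visible feature (their primary UV absorption is outside this window,
    which is why their imprint is faint).
    """
    wl = np.asarray(wavelengths, dtype=float)
    cluster = 0.55 + 0.85 * _gauss(wl, 585.0, 55.0) + 0.30 * _gauss(wl, 970.0, 28.0) \
        - 0.00035 * (wl - 570.0)
    leaf = 0.30 + 0.55 * _gauss(wl, 610.0, 45.0) + 1.05 * _gauss(wl, 678.0, 24.0) \
        + 0.18 * _gauss(wl, 970.0, 30.0)
    wood = 0.85 - 0.00060 * (wl - 570.0) + 0.10 * _gauss(wl, 970.0, 35.0)
    gap = 0.15 + 0.04 * _gauss(wl, 970.0, 40.0) + 0.00005 * (wl - 570.0)
    bands = {
        "tss": [(935.0, 28.0, 1.0), (840.0, 30.0, 0.35)],
        "anthocyanins": [(600.0, 26.0, 1.0), (545.0, 20.0, 0.4)],
        # the phenolic pool reaches this window only through its pigment
        # fraction, so its profile coincides with the anthocyanin bands —
        # the two analytes are spectrally confounded by construction
        "polyphenols": [(600.0, 26.0, 1.0), (545.0, 20.0, 0.4)],
    }
    return {
        "cluster": Endmember("cluster", cluster, bands),
        "leaf": Endmember("leaf", leaf),
        "wood": Endmember("wood", wood),
        "gap": Endmember("gap", gap),
    }


# ---------------------------------------------------------------------------
# layout


def generate_layout(layout: VineyardLayout) -> list[BlockRecord]:
    """Place block centroids on the ground.

    Centroid of block ``b`` in row ``r`` (before rotation) is at
    ``x = (b + 1/2) * block_length``, ``y = r * row_spacing`` relative to
    the origin; the whole grid is then rotated by ``row_azimuth``.
    """
    records: list[BlockRecord] = []
    theta = math.radians(layout.row_azimuth)
    cos_t, sin_t = math.cos(theta), math.sin(theta)
    ox, oy = layout.origin
    for r in range(layout.rows):
        for b in range(layout.blocks_per_row):
            x = (b + 0.5) * layout.block_length
            y = r * layout.row_spacing
            cx = ox + x * cos_t - y * sin_t
            cy = oy + x * sin_t + y * cos_t
            records.append(
                BlockRecord(
                    block_id=f"R{r + 1:02d}B{b + 1:02d}",
                    row_index=r,
                    block_index=b,
                    centroid=(cx, cy),
                )
            )
    return records


# ---------------------------------------------------------------------------
# chemistry fields


def _spatial_field(
    centroids: np.ndarray, corr_length: float, rng: np.random.Generator
) -> np.ndarray:
    """One draw of a unit-variance Gaussian process over the centroids.

    Squared-exponential covariance ``exp(-d² / (2 ℓ²))``; a small diagonal
    jitter keeps the Cholesky factor well defined when blocks are much
    closer together than the correlation length.
    """
    d = np.linalg.norm(centroids[:, None, :] - centroids[None, :, :], axis=2)
    if math.isinf(corr_length):
        cov = np.ones_like(d)
    else:
        cov = np.exp(-0.5 * (d / corr_length) ** 2)
    cov = cov + 1e-10 * np.eye(len(centroids))
    chol = np.linalg.cholesky(cov)
    z = chol @ rng.standard_normal(len(centroids))
    if math.isinf(corr_length):
        # fully correlated limit: a single shared draw
        z = np.full(len(centroids), z[0])
    return z


def generate_chemistry(
    blocks: Sequence[BlockRecord],
    params: AnalyteFieldParams,
    n_dates: int,
    seed: int,
) -> list[BlockChemistry]:
    """Draw per-block, per-date reference chemistry for all three analytes.

    One latent spatial field per analyte is drawn once and reused across
    dates, so the spatial pattern evolves coherently while the per-date
    mean shift carries the ripening trend; anthocyanins and polyphenols
    share a common latent component with correlation
    ``anthocyanin_polyphenol_corr``.  Independent noise is added per
    block × date, then values are clipped to each analyte's global range.
    """
    if n_dates < 1:
        raise ConfigurationError("n_dates must be >= 1")
    rng = np.random.default_rng(seed)
    centroids = np.array([b.centroid for b in blocks])
    n = len(blocks)

    z_tss = _spatial_field(centroids, params.tss.spatial_correlation_length, rng)
    z_anth = _spatial_field(
        centroids, params.anthocyanins.spatial_correlation_length, rng)
    z_ind = _spatial_field(
        centroids, params.polyphenols.spatial_correlation_length, rng)
    rho = params.anthocyanin_polyphenol_corr
    z_poly = rho * z_anth + math.sqrt(max(0.0, 1.0 - rho * rho)) * z_ind
    latents = {"tss": z_tss, "anthocyanins": z_anth, "polyphenols": z_poly}

    values: dict[str, np.ndarray] = {}
    for analyte in ANALYTES:
        p = params[analyte]
        if len(p.date_means) < n_dates:
            raise ConfigurationError(
                f"{analyte}: need {n_dates} date_means, got {len(p.date_means)}"
            )
        field_part = p.spatial_sd * latents[analyte]
        out = np.empty((n_dates, n))
        for d in range(n_dates):
            noise = rng.normal(0.0, p.noise_sd, size=n) if p.noise_sd > 0 else 0.0
            out[d] = p.date_means[d] + field_part + noise
        values[analyte] = np.clip(out, *p.global_range)

    chem: list[BlockChemistry] = []
    for d in range(n_dates):
        for i, block in enumerate(blocks):
            chem.append(
                BlockChemistry(
                    block_id=block.block_id,
                    date_index=d,
                    tss=float(values["tss"][d, i]),
                    anthocyanins=float(values["anthocyanins"][d, i]),
                    polyphenols=float(values["polyphenols"][d, i]),
                )
            )
    return chem


# ---------------------------------------------------------------------------
# spectral streams


def _cluster_values(
    chem: BlockChemistry,
    endmember: Endmember,
    params: AnalyteFieldParams,
    wavelengths: np.ndarray,
    berry_jitter: Mapping[str, np.ndarray] | None = None,
) -> np.ndarray:
    """Cluster absorbance spectra at a block's chemistry.

    Returns one spectrum, or a stack when ``berry_jitter`` provides a
    per-spectrum concentration deviation (analyte -> (n,) array) modelling
    the handful of berries each measuring spot actually sees.
    """
    n = None
    if berry_jitter is not None:
        n = len(next(iter(berry_jitter.values())))
    values = (
        endmember.base_absorbance.copy()
        if n is None
        else np.tile(endmember.base_absorbance, (n, 1))
    )
    for analyte in ANALYTES:
        p = params[analyte]
        conc = chem.analyte(analyte)
        if berry_jitter is not None:
            conc = conc + berry_jitter[analyte]
        scaled = np.asarray(p.scale(conc))
        band = p.spectral_snr * endmember.band_profile(analyte, wavelengths)
        values += (scaled[..., None] if n is not None else float(scaled)) * band
    return values


def generate_stream(
    block: BlockRecord,
    chem: BlockChemistry,
    endmembers: Mapping[str, Endmember],
    params: AnalyteFieldParams,
    sim: SimConfig,
    seed: int,
    block_length: float = 5.0,
    row_direction: tuple[float, float] = (1.0, 0.0),
    t0: float = 0.0,
) -> tuple[SpectralStream, np.ndarray]:
    """Simulate one on-the-go pass over a block.

    Emits ``floor(block_length / speed * rate)`` spectra advancing along
    ``row_direction`` through the block at ``speed / rate`` metres per
    spectrum; each spectrum's class is drawn from ``sim.class_mixture``.
    Every spectrum gets a multiplicative gain ``(1 + ε_m)``, an additive
    offset ``ε_a`` and white channel noise.  Returns the stream together
    with the hidden class label of each spectrum (for filter evaluation
    only — the real instrument does not know them).
    """
    missing = set(sim.class_mixture) - set(endmembers)
    if missing:
        raise ConfigurationError(f"no endmember for classes {sorted(missing)}")
    rng = np.random.default_rng(seed)
    wl = sim.wavelengths
    n = int(math.floor(block_length / sim.speed_mps * sim.acquisition_rate))
    step = sim.speed_mps / sim.acquisition_rate

    labels_pool = list(sim.class_mixture.keys())
    probs = np.array([sim.class_mixture[c] for c in labels_pool])
    labels = rng.choice(labels_pool, size=n, p=probs)

    # every spectrum gets a berry-jitter draw so the stream layout is
    # reproducible regardless of the class sequence
    jitter = {
        a: rng.normal(0.0, params[a].berry_sd, size=n)
        if params[a].berry_sd > 0 else np.zeros(n)
        for a in ANALYTES
    }
    gains = 1.0 + rng.normal(0.0, sim.scatter_slope_sd, size=n)
    offsets = rng.normal(0.0, sim.scatter_offset_sd, size=n)
    noise = rng.normal(0.0, sim.channel_noise_sd, size=(n, wl.size)) \
        if sim.channel_noise_sd > 0 else np.zeros((n, wl.size))
    values = np.empty((n, wl.size))
    cluster_mask = labels == "cluster"
    if "cluster" in endmembers and np.any(cluster_mask):
        values[cluster_mask] = _cluster_values(
            chem, endmembers["cluster"], params, wl,
            berry_jitter={a: jitter[a][cluster_mask] for a in ANALYTES},
        )
    for c, em in endmembers.items():
        if c == "cluster":
            continue
        mask = labels == c
        if np.any(mask):
            values[mask] = em.base_absorbance
    values = values * gains[:, None] + offsets[:, None] + noise

    direction = np.asarray(row_direction, dtype=float)
    direction = direction / np.linalg.norm(direction)
    start = np.asarray(block.centroid) - direction * (block_length - step) / 2.0
    positions = start[None, :] + np.arange(n)[:, None] * step * direction[None, :]
    timestamps = t0 + np.arange(n) / sim.acquisition_rate
    stream = SpectralStream(
        wl, values, timestamps, positions, [block.block_id] * n
    )
    return stream, labels


def reflectance_export(stream: SpectralStream) -> SpectralStream:
    """Convert an absorbance stream to reflectance, ``R = 10^(-A)``."""
    return SpectralStream(
        stream.wavelengths,
        np.power(10.0, -stream.values),
        stream.timestamps,
        stream.positions,
        list(stream.source_ids),
    )


def make_signature(
    endmembers: Mapping[str, Endmember],
    params: AnalyteFieldParams,
    sim: SimConfig,
    n_spectra: int = 50,
    seed: int = 0,
) -> SpectralStream:
    """Build the manually-acquired cluster reference signature.

    The signature is the mean of ``n_spectra`` noise-bearing cluster-class
    spectra taken at mid-range chemistry (where every analyte band
    amplitude is zero by construction), mimicking an operator averaging
    hand-held acquisitions on representative clusters before driving.
    Returned as a single-spectrum stream on the simulation axis.
    """
    if n_spectra < 1:
        raise ConfigurationError("n_spectra must be >= 1")
    rng = np.random.default_rng(seed)
    wl = sim.wavelengths
    base = endmembers["cluster"].base_absorbance
    gains = 1.0 + rng.normal(0.0, sim.scatter_slope_sd, size=n_spectra)
    offsets = rng.normal(0.0, sim.scatter_offset_sd, size=n_spectra)
    noise = rng.normal(0.0, sim.channel_noise_sd, size=(n_spectra, wl.size)) \
        if sim.channel_noise_sd > 0 else np.zeros((n_spectra, wl.size))
    spectra = base[None, :] * gains[:, None] + offsets[:, None] + noise
    mean = spectra.mean(axis=0)
    return SpectralStream(
        wl, mean[None, :], np.zeros(1), np.zeros((1, 2)), ["signature"]
    )
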
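"""Spectral data model and I/O.

Streams of georeferenced spectra are stored as wide CSV tables: one row per
spectrum with ``timestamp, x, y`` followed by one column per wavelength
channel (headers are the wavelengths in nm).  Coordinates are planar metres
in a local projected frame; geographic longitude/latitude inputs are
converted on ingest with a local equirectangular approximation, which is
accurate to well under a centimetre at vineyard scale (< 1 km).

Every writer emits a sidecar ``<name>.provenance.json`` recording the seed,
a hash of the generating configuration and the software version, so a run
can be traced back to its inputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__

EARTH_RADIUS_M = 6_371_000.0


class FormatError(ValueError):
    """A file does not conform to the expected stream dialect."""


@dataclass
class Spectrum:
    """One reflectance/absorbance spectrum with acquisition metadata.

    Parameters
    ----------
    wavelengths
        Strictly increasing wavelength axis in nm.
    values
        Channel values (absorbance units unless stated otherwise).
    timestamp
        Acquisition time in seconds from the start of the pass.
    position
        ``(x, y)`` in planar metres.
    source_id
        Free-text provenance tag (e.g. block id or instrument id).
    """

    wavelengths: np.ndarray
    values: np.ndarray
    timestamp: float = 0.0
    position: tuple[float, float] = (0.0, 0.0)
    source_id: str = ""

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.wavelengths.shape != self.values.shape:
            raise ValueError(
                f"wavelengths ({self.wavelengths.size}) and values "
                f"({self.values.size}) must have the same length"
            )
        if self.wavelengths.size >= 2 and not np.all(np.diff(self.wavelengths) > 0):
            raise ValueError("wavelength axis must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("spectrum values must be finite")


@dataclass
class SpectralStream:
    """An ordered sequence of spectra sharing one wavelength axis.

    Internally the channel values live in a dense ``(n, p)`` matrix; the
    per-spectrum metadata (timestamps, positions, source ids) are parallel
    arrays.  Timestamps must be non-decreasing.
    """

    wavelengths: np.ndarray
    values: np.ndarray  # (n_spectra, n_channels)
    timestamps: np.ndarray
    positions: np.ndarray  # (n_spectra, 2)
    source_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        n = self.values.shape[0]
        if not self.source_ids:
            self.source_ids = [""] * n
        if self.values.shape[1] != self.wavelengths.size:
            raise ValueError("stream values do not match the wavelength axis")
        if self.timestamps.size != n or self.positions.shape != (n, 2):
            raise ValueError("stream metadata arrays are inconsistent")
        if self.wavelengths.size >= 2 and not np.all(np.diff(self.wavelengths) > 0):
            raise FormatError("wavelength axis must be strictly increasing")
        if n >= 2 and np.any(np.diff(self.timestamps) < 0):
            raise ValueError("timestamps must be non-decreasing")

    def __len__(self) -> int:
        return self.values.shape[0]

    def __getitem__(self, i: int) -> Spectrum:
        return Spectrum(
            self.wavelengths,
            self.values[i],
            float(self.timestamps[i]),
            (float(self.positions[i, 0]), float(self.positions[i, 1])),
            self.source_ids[i],
        )

    def subset(self, index: np.ndarray) -> "SpectralStream":
        """A new stream holding the rows selected by ``index`` (order kept)."""
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return SpectralStream(
            self.wavelengths,
            self.values[index],
            self.timestamps[index],
            self.positions[index],
            [self.source_ids[int(i)] for i in index],
        )

    @classmethod
    def empty(cls, wavelengths: np.ndarray) -> "SpectralStream":
        p = np.asarray(wavelengths).size
        return cls(wavelengths, np.empty((0, p)), np.empty(0), np.empty((0, 2)), [])

    @classmethod
    def concatenate(cls, streams: Sequence["SpectralStream"]) -> "SpectralStream":
        if not streams:
            raise ValueError("need at least one stream to concatenate")
        wl = streams[0].wavelengths
        for s in streams[1:]:
            if not np.array_equal(s.wavelengths, wl):
                raise ValueError("streams do not share a wavelength axis")
        ids: list[str] = []
        for s in streams:
            ids.extend(s.source_ids)
        return cls(
            wl,
            np.vstack([s.values for s in streams]),
            np.concatenate([s.timestamps for s in streams]),
            np.vstack([s.positions for s in streams]),
            ids,
        )


@dataclass
class BlockChemistry:
    """Reference chemistry of one vine block on one date."""

    block_id: str
    date_index: int
    tss: float  # °Brix
    anthocyanins: float  # mg/berry
    polyphenols: float  # AU/berry

    def analyte(self, name: str) -> float:
        return float(getattr(self, name))


ANALYTES = ("tss", "anthocyanins", "polyphenols")

ANALYTE_UNITS = {
    "tss": "°Brix",
    "anthocyanins": "mg/berry",
    "polyphenols": "AU/berry",
}


@dataclass
class BlockRecord:
    """A vine block: identity, centroid geometry and optional chemistry."""

    block_id: str
    row_index: int
    block_index: int
    centroid: tuple[float, float]
    date_index: int = 0
    chemistry: BlockChemistry | None = None


# ---------------------------------------------------------------------------
# coordinate handling


def lonlat_to_local(
    lon: np.ndarray, lat: np.ndarray, origin: tuple[float, float]
) -> np.ndarray:
    """Project geographic coordinates to local planar metres.

    Equirectangular approximation about ``origin = (lon0, lat0)``:
    ``x = R cos(lat0) Δlon``, ``y = R Δlat`` (radians).  Adequate below the
    kilometre scale, which covers any single vineyard plot.
    """
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    lon0, lat0 = origin
    x = EARTH_RADIUS_M * math.cos(math.radians(lat0)) * np.radians(lon - lon0)
    y = EARTH_RADIUS_M * np.radians(lat - lat0)
    return np.column_stack([x, y])


# ---------------------------------------------------------------------------
# stream CSV dialect

_META_COLUMNS = ("timestamp", "x", "y")


def write_stream(
    stream: SpectralStream, path: str | Path, provenance: Mapping | None = None
) -> None:
    """Write a stream as a wide CSV (one row per spectrum) plus provenance."""
    path = Path(path)
    df = pd.DataFrame(stream.values, columns=[f"{w:.6g}" for w in stream.wavelengths])
    df.insert(0, "y", stream.positions[:, 1])
    df.insert(0, "x", stream.positions[:, 0])
    df.insert(0, "timestamp", stream.timestamps)
    if any(stream.source_ids):
        df["source_id"] = stream.source_ids
    df.to_csv(path, index=False, float_format="%.10g")
    write_provenance(path, provenance)


def read_stream(path: str | Path) -> SpectralStream:
    """Read a stream CSV written by :func:`write_stream`.

    Raises :class:`FormatError` with the offending line for ragged rows and
    for a non-increasing wavelength header.
    """
    path = Path(path)
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split(",")
        if header[:3] != list(_META_COLUMNS):
            raise FormatError(
                f"{path}: expected leading columns {_META_COLUMNS}, got {header[:3]}"
            )
        has_source = header[-1] == "source_id"
        wl_cols = header[3 : -1 if has_source else len(header)]
        try:
            wavelengths = np.array([float(c) for c in wl_cols])
        except ValueError as exc:
            raise FormatError(f"{path}: non-numeric wavelength header: {exc}") from exc
        if wavelengths.size >= 2 and not np.all(np.diff(wavelengths) > 0):
            raise FormatError(f"{path}: wavelength header must be strictly increasing")
        rows, ts, pos, ids = [], [], [], []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split(",")
            if len(parts) != len(header):
                raise FormatError(
                    f"{path}:{lineno}: expected {len(header)} fields, got {len(parts)}"
                )
            try:
                ts.append(float(parts[0]))
                pos.append((float(parts[1]), float(parts[2])))
                rows.append(
                    [float(v) for v in (parts[3:-1] if has_source else parts[3:])]
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-numeric value: {exc}") from exc
            ids.append(parts[-1] if has_source else "")
        n = len(rows)
        values = np.array(rows) if n else np.empty((0, wavelengths.size))
        positions = np.array(pos) if n else np.empty((0, 2))
    return SpectralStream(wavelengths, values, np.array(ts), positions, ids)


def write_provenance(path: str | Path, provenance: Mapping | None) -> None:
    """Emit the sidecar JSON for an artifact at ``path``."""
    record = {"software_version": __version__}
    if provenance:
        record.update(provenance)
    side = Path(path).with_suffix(Path(path).suffix + ".provenance.json")
    side.write_text(json.dumps(record, indent=2, sort_keys=True, default=str))


def config_hash(config) -> str:
    """Stable short hash of a (dataclass or mapping) configuration."""
    if dataclasses.is_dataclass(config) and not isinstance(config, type):
        config = dataclasses.asdict(config)
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


# ---------------------------------------------------------------------------
# chemistry / layout tables


def write_chemistry(chem: Iterable[BlockChemistry], path: str | Path,
                    provenance: Mapping | None = None) -> None:
    df = pd.DataFrame([dataclasses.asdict(c) for c in chem])
    df.to_csv(path, index=False)
    write_provenance(path, provenance)


def read_chemistry(path: str | Path) -> list[BlockChemistry]:
    df = pd.read_csv(path)
    return [
        BlockChemistry(
            str(r.block_id), int(r.date_index),
            float(r.tss), float(r.anthocyanins), float(r.polyphenols),
        )
        for r in df.itertuples()
    ]


def write_blocks(blocks: Iterable[BlockRecord], path: str | Path,
                 provenance: Mapping | None = None) -> None:
    df = pd.DataFrame(
        {
            "block_id": b.block_id,
            "row_index": b.row_index,
            "block_index": b.block_index,
            "x": b.centroid[0],
            "y": b.centroid[1],
        }
        for b in blocks
    )
    df.to_csv(path, index=False)
    write_provenance(path, provenance)


def read_blocks(path: str | Path) -> list[BlockRecord]:
    df = pd.read_csv(path)
    return [
        BlockRecord(
            str(r.block_id), int(r.row_index), int(r.block_index),
            (float(r.x), float(r.y)),
        )
        for r in df.itertuples()
    ]


# ---------------------------------------------------------------------------
# block allocation (spectral processing step 1)


def allocate_to_blocks(
    stream: SpectralStream,
    blocks: Sequence[BlockRecord],
    max_distance: float = 1.10,
) -> tuple[dict[str, SpectralStream], int]:
    """Assign each spectrum to the nearest block centroid.

    A spectrum is assigned to the block whose centroid is nearest to its
    position, provided that distance is at most ``max_distance`` metres;
    otherwise it is discarded.  Ties on distance go to the lexicographically
    smaller ``block_id``.  Returns the mapping ``block_id -> sub-stream``
    (only blocks that received spectra appear) and the discard count.

    The default ``max_distance`` of 1.10 m is half the between-row spacing,
    which rejects spectra from neighbouring rows; pass a larger window when
    the along-row extent of a block exceeds it.
    """
    if not blocks:
        raise ValueError("blocks must be non-empty")
    if max_distance <= 0:
        raise ValueError("max_distance must be positive")
    if len(stream) == 0:
        return {}, 0
    order = sorted(range(len(blocks)), key=lambda i: blocks[i].block_id)
    centroids = np.array([blocks[i].centroid for i in order])
    ids = [blocks[i].block_id for i in order]
    # distance to every centroid; argmin returns the first (= smallest id) tie
    d = np.linalg.norm(stream.positions[:, None, :] - centroids[None, :, :], axis=2)
    nearest = np.argmin(d, axis=1)
    within = d[np.arange(len(stream)), nearest] <= max_distance
    result: dict[str, SpectralStream] = {}
    for j, block_id in enumerate(ids):
        mask = within & (nearest == j)
        if np.any(mask):
            result[block_id] = stream.subset(mask)
    return result, int(np.sum(~within))


def reflectance_to_absorbance(spectrum: Spectrum) -> Spectrum:
    """Convert reflectance to apparent absorbance, ``A = log10(1/R)``.

    Raises a domain error naming the first offending channel if any
    reflectance value is non-positive.
    """
    bad = np.flatnonzero(spectrum.values <= 0)
    if bad.size:
        raise ValueError(
            f"non-positive reflectance at channel {bad[0]} "
            f"({spectrum.wavelengths[bad[0]]:g} nm)"
        )
    return Spectrum(
        spectrum.wavelengths,
        np.log10(1.0 / spectrum.values),
        spectrum.timestamp,
        spectrum.position,
        spectrum.source_id,
    )
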
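"""Cosine signature filtering and per-block averaging.

Raw on-the-go streams contain spectra of leaves, wood, gaps and the
occasional trellis post alongside the grape clusters of interest.  Spectra
are retained when their cosine similarity to a manually acquired cluster
reference signature reaches a threshold (0.993 in the field protocol);
survivors are averaged channel-wise into one spectrum per block.

Similarity is computed on the raw absorbance spectra — preprocessing
happens after averaging, matching the field processing order.  Plain
(uncentered) cosine is the default; a mean-centered variant is available
via ``centered=True`` for instruments whose comparison tool standardises
spectra first.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spectra_io import Spectrum, SpectralStream

DEFAULT_THRESHOLD = 0.993
DEFAULT_MIN_COUNT = 5


class InsufficientSpectraError(RuntimeError):
    """Too few retained spectra to form a reliable block average."""


@dataclass
class FilterReport:
    """Bookkeeping of one filtering pass over a (block's) stream."""

    block_id: str
    n_input: int
    n_retained: int
    threshold: float
    similarity_values: np.ndarray

    def __post_init__(self) -> None:
        self.similarity_values = np.asarray(self.similarity_values, dtype=float)
        if self.n_retained > self.n_input:
            raise ValueError("cannot retain more spectra than were input")


def cosine_similarity(
    x: np.ndarray, s: np.ndarray, centered: bool = False
) -> np.ndarray:
    """Cosine similarity of spectra ``x`` against a signature ``s``.

    ``x`` may be a single spectrum ``(p,)`` or a stack ``(n, p)``; returns
    a scalar or an ``(n,)`` vector in [-1, 1].  Invariant to positive
    rescaling of either argument.  With ``centered=True`` both sides are
    mean-centered first (Pearson correlation of the channel profiles).
    """
    x = np.asarray(x, dtype=float)
    s = np.asarray(s, dtype=float)
    single = x.ndim == 1
    x2 = np.atleast_2d(x)
    if x2.shape[1] != s.size:
        raise ValueError(
            f"length mismatch: spectra have {x2.shape[1]} channels, "
            f"signature has {s.size}"
        )
    if centered:
        x2 = x2 - x2.mean(axis=1, keepdims=True)
        s = s - s.mean()
    s_norm = np.linalg.norm(s)
    x_norms = np.linalg.norm(x2, axis=1)
    if s_norm == 0.0:
        raise ValueError("signature has zero norm")
    if np.any(x_norms == 0.0):
        raise ValueError("spectrum with zero norm at row "
                         f"{int(np.flatnonzero(x_norms == 0.0)[0])}")
    sims = (x2 @ s) / (x_norms * s_norm)
    return float(sims[0]) if single else sims


def filter_stream(
    stream: SpectralStream,
    signature: Spectrum | SpectralStream,
    threshold: float = DEFAULT_THRESHOLD,
    centered: bool = False,
    block_id: str = "",
) -> tuple[SpectralStream, FilterReport]:
    """Retain the spectra whose similarity to the signature is >= threshold.

    Order is preserved; the report carries every similarity value so the
    decision boundary can be audited.  An empty retained set is a valid
    outcome, not an error.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    sig_wl = signature.wavelengths
    sig_values = signature.values
    if sig_values.ndim == 2:
        if sig_values.shape[0] != 1:
            raise ValueError("signature stream must hold exactly one spectrum")
        sig_values = sig_values[0]
    if not np.array_equal(sig_wl, stream.wavelengths):
        raise ValueError("signature and stream wavelength axes differ")
    if len(stream) == 0:
        report = FilterReport(block_id, 0, 0, threshold, np.empty(0))
        return stream, report
    sims = cosine_similarity(stream.values, sig_values, centered=centered)
    keep = sims >= threshold
    retained = stream.subset(keep)
    report = FilterReport(block_id, len(stream), int(keep.sum()), threshold, sims)
    return retained, report


def average_block(
    retained: SpectralStream, min_count: int = DEFAULT_MIN_COUNT, block_id: str = ""
) -> Spectrum:
    """Channel-wise mean of the retained spectra of one block.

    Position is the centroid of the member positions and the timestamp the
    mean acquisition time.  Fails when fewer than ``min_count`` spectra
    survived filtering — an average of a handful of possibly-misclassified
    spectra is not a trustworthy block measurement.
    """
    n = len(retained)
    if n < min_count:
        raise InsufficientSpectraError(
            f"block {block_id or '<unnamed>'}: {n} retained spectra "
            f"(minimum {min_count})"
        )
    return Spectrum(
        retained.wavelengths,
        retained.values.mean(axis=0),
        float(retained.timestamps.mean()),
        (
            float(retained.positions[:, 0].mean()),
            float(retained.positions[:, 1].mean()),
        ),
        block_id or (retained.source_ids[0] if retained.source_ids else ""),
    )
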
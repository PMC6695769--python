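"""Scatter correction and derivative preprocessing of block-averaged spectra.

Treatments are expressed with the compact codes used in NIR chemometrics
tables: ``DnWm`` is a Savitzky–Golay filter taking the n-th derivative over
an m-channel window, ``SNV`` the standard normal variate transform and
``DT`` polynomial detrending, chained left to right — ``"SNV + DT D1W15"``
means SNV, then detrend, then first derivative with window 15.

Savitzky–Golay polynomial order defaults to 2 and detrend degree to 2;
both are the classic choices for first-derivative spectra of this channel
count and both are configurable.  Edge channels are filled by evaluating
the polynomial fitted to the nearest full window at the edge positions
(``scipy``'s ``mode="interp"``), which keeps the output length equal to the
input length so model matrices keep their shape.  Derivatives are scaled by
the channel step so their units are absorbance per nm.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Sequence, Union

import numpy as np
from scipy.signal import savgol_filter

DEFAULT_POLYORDER = 2
DEFAULT_DETREND_DEGREE = 2


@dataclass(frozen=True)
class SNVStep:
    def __str__(self) -> str:
        return "SNV"


@dataclass(frozen=True)
class DetrendStep:
    degree: int = DEFAULT_DETREND_DEGREE

    def __str__(self) -> str:
        return "DT"


@dataclass(frozen=True)
class SavgolStep:
    deriv: int
    window: int
    polyorder: int = DEFAULT_POLYORDER

    def __post_init__(self) -> None:
        if self.window % 2 == 0 or self.window <= self.polyorder:
            raise ValueError(
                f"window must be odd and > polyorder (window={self.window}, "
                f"polyorder={self.polyorder})"
            )
        if not 0 <= self.deriv <= self.polyorder:
            raise ValueError("need 0 <= deriv <= polyorder")

    def __str__(self) -> str:
        return f"D{self.deriv}W{self.window}"


Step = Union[SNVStep, DetrendStep, SavgolStep]

_SG_CODE = re.compile(r"^D(\d+)W(\d+)$")


@dataclass
class TreatmentChain:
    """An ordered list of preprocessing steps applied row-wise."""

    steps: list[Step] = field(default_factory=list)

    @classmethod
    def parse(
        cls,
        code: str,
        polyorder: int = DEFAULT_POLYORDER,
        detrend_degree: int = DEFAULT_DETREND_DEGREE,
    ) -> "TreatmentChain":
        """Parse a treatment code such as ``"D1W15"`` or ``"SNV + DT D1W15"``.

        Tokens are separated by whitespace and/or ``+``; recognised tokens
        are ``SNV``, ``DT`` and ``DnWm``.  An empty string yields the
        identity chain.
        """
        steps: list[Step] = []
        for token in re.split(r"[+\s]+", code.strip()):
            if not token:
                continue
            upper = token.upper()
            if upper == "SNV":
                steps.append(SNVStep())
            elif upper == "DT":
                steps.append(DetrendStep(detrend_degree))
            else:
                m = _SG_CODE.match(upper)
                if not m:
                    raise ValueError(f"unrecognised treatment token {token!r}")
                deriv, window = int(m.group(1)), int(m.group(2))
                steps.append(SavgolStep(deriv, window, max(polyorder, deriv)))
        return cls(steps)

    def __str__(self) -> str:
        # table-code style: scatter corrections joined by " + ", the
        # Savitzky-Golay code appended with a plain space ("SNV + DT D1W15")
        out = ""
        for s in self.steps:
            if not out:
                out = str(s)
            else:
                sep = " " if isinstance(s, SavgolStep) else " + "
                out += sep + str(s)
        return out


def snv(values: np.ndarray) -> np.ndarray:
    """Standard normal variate: per-spectrum standardisation.

    Subtracts each spectrum's mean and divides by its sample standard
    deviation (ddof=1), removing additive offsets and multiplicative gain.
    """
    values = np.asarray(values, dtype=float)
    x = np.atleast_2d(values)
    if x.shape[1] < 2:
        raise ValueError("SNV needs at least 2 channels")
    sd = x.std(axis=1, ddof=1, keepdims=True)
    if np.any(sd == 0):
        raise ValueError("SNV undefined for a zero-variance spectrum")
    out = (x - x.mean(axis=1, keepdims=True)) / sd
    return out[0] if values.ndim == 1 else out


def detrend(values: np.ndarray, degree: int = DEFAULT_DETREND_DEGREE) -> np.ndarray:
    """Remove the least-squares polynomial baseline in the channel index.

    Residuals are orthogonal to the polynomial basis of the given degree;
    degree 0 is plain mean-centering.
    """
    values = np.asarray(values, dtype=float)
    x = np.atleast_2d(values)
    p = x.shape[1]
    if degree >= p:
        raise ValueError(f"detrend degree {degree} >= spectrum length {p}")
    # orthonormal polynomial basis via QR on the Vandermonde matrix
    idx = np.arange(p, dtype=float)
    vander = np.vander(idx, degree + 1, increasing=True)
    q, _ = np.linalg.qr(vander)
    out = x - (x @ q) @ q.T
    return out[0] if values.ndim == 1 else out


def savgol(
    values: np.ndarray,
    window: int,
    polyorder: int = DEFAULT_POLYORDER,
    deriv: int = 0,
    step: float = 1.0,
) -> np.ndarray:
    """Savitzky–Golay smoothing / differentiation along the channel axis.

    Fits a local polynomial of the given order in every ``window``-channel
    neighbourhood and evaluates its ``deriv``-th derivative at the center,
    scaled by ``step**-deriv`` (pass the channel spacing in nm to get
    derivatives per nm).  Edges are handled by polynomial extension so the
    output keeps the input length.
    """
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if polyorder >= window:
        raise ValueError("polyorder must be < window")
    if deriv > polyorder:
        raise ValueError("deriv must be <= polyorder")
    values = np.asarray(values, dtype=float)
    if values.shape[-1] < window:
        raise ValueError("spectrum shorter than the filter window")
    return savgol_filter(
        values, window_length=window, polyorder=polyorder, deriv=deriv,
        delta=step, axis=-1, mode="interp",
    )


def apply_chain(
    chain: TreatmentChain | str,
    matrix: np.ndarray,
    step: float = 1.0,
) -> np.ndarray:
    """Apply a treatment chain to a matrix of spectra (rows = spectra).

    ``chain`` may be a parsed :class:`TreatmentChain` or a raw code string.
    ``step`` is the wavelength spacing (nm) used to scale derivatives.
    Step failures are re-raised with the offending row index.
    """
    if isinstance(chain, str):
        chain = TreatmentChain.parse(chain)
    out = np.atleast_2d(np.asarray(matrix, dtype=float)).copy()
    for s in chain.steps:
        if isinstance(s, SNVStep):
            out = _apply_rowwise(snv, out)
        elif isinstance(s, DetrendStep):
            out = _apply_rowwise(lambda x: detrend(x, s.degree), out)
        elif isinstance(s, SavgolStep):
            out = savgol(out, s.window, s.polyorder, s.deriv, step)
        else:  # pragma: no cover
            raise TypeError(f"unknown step {s!r}")
    return out if np.asarray(matrix).ndim == 2 else out[0]


def _apply_rowwise(fn, matrix: np.ndarray) -> np.ndarray:
    try:
        return fn(matrix)
    except ValueError:
        # vectorised path failed: find the offending row for the message
        for i, row in enumerate(matrix):
            try:
                fn(row)
            except ValueError as exc:
                raise ValueError(f"row {i}: {exc}") from exc
        raise
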
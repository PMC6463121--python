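"""Band-wise lagged phase synchronization (LPS) connectomes from ROI signals.

LPS quantifies the non-instantaneous coupling between two source signals: with
:math:`f_{xy}(\\omega)` the normalized cross-spectrum (coherency) of sources
*x* and *y* at discrete frequency :math:`\\omega`,

.. math::

    \\varphi^2_{xy}(\\omega)
        = \\frac{\\mathrm{Im}[f_{xy}(\\omega)]^2}{1 - \\mathrm{Re}[f_{xy}(\\omega)]^2}

which is bounded in [0, 1] and, by discarding the real (zero-lag) part of the
coherency, is insensitive to instantaneously mixed (volume-conducted) signal
components.  A band value is the peak of :math:`\\varphi^2` over the band's
frequency bins.

Spectral estimator: signals are cut into non-overlapping epochs (2 s default),
each epoch is Hann-tapered and DFT'd, and cross-spectra are averaged across
epochs before the coherency ratio is formed.  When the real coherency is
(numerically) perfect, :math:`1-\\mathrm{Re}^2 < \\epsilon`, the ratio is
defined as 0: a purely instantaneous coupling carries no lagged component.
Zero-power bins contribute 0 and are counted in ``ConnectivityMatrix`` logs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .atlas import N_ROIS

__all__ = [
    "RoiSignal",
    "EpochSet",
    "BandSpec",
    "BANDS",
    "ConnectivityMatrix",
    "segment_epochs",
    "coherency_spectrum",
    "lagged_phase_synchronization",
    "normalize_by_max",
    "overall_fc",
]

logger = logging.getLogger(__name__)

#: Guard for the 1 - Re^2 denominator of the LPS ratio.
DENOM_EPS = 1e-12

DEFAULT_SAMPLING_RATE = 256.0
DEFAULT_EPOCH_SECONDS = 2.0


@dataclass
class RoiSignal:
    """Per-subject source time series over the ROI atlas.

    ``samples`` has shape (n_rois, n_samples); amplitude units are arbitrary.
    """

    subject_id: str
    samples: np.ndarray
    sampling_rate: float = DEFAULT_SAMPLING_RATE

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a 2-D (rois x time) array")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("signal contains non-finite values")
        if self.sampling_rate <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_rois(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]


@dataclass
class EpochSet:
    """Epoched signals: data shape (n_epochs, n_rois, epoch_samples)."""

    data: np.ndarray
    sampling_rate: float
    epoch_seconds: float = DEFAULT_EPOCH_SECONDS

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("epoch data must be 3-D (epochs x rois x samples)")
        expected = int(round(self.epoch_seconds * self.sampling_rate))
        if self.data.shape[2] != expected:
            raise ValueError(
                f"epoch length {self.data.shape[2]} != "
                f"epoch_seconds*sampling_rate = {expected}"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("epoch data contains non-finite values")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_rois(self) -> int:
        return self.data.shape[1]

    @property
    def frequencies(self) -> np.ndarray:
        return np.fft.rfftfreq(self.data.shape[2], d=1.0 / self.sampling_rate)


@dataclass(frozen=True)
class BandSpec:
    """A named frequency band [lo, hi] in Hz."""

    name: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not (0 < self.lo < self.hi):
            raise ValueError(f"band requires 0 < lo < hi, got ({self.lo}, {self.hi})")

    def bins(self, frequencies: np.ndarray) -> np.ndarray:
        """Boolean mask of frequency bins falling in [lo, hi] (inclusive)."""
        return (frequencies >= self.lo) & (frequencies <= self.hi)


#: The six canonical EEG bands.
BANDS: dict[str, BandSpec] = {
    b.name: b
    for b in (
        BandSpec("delta", 2.0, 4.0),
        BandSpec("theta", 4.0, 8.0),
        BandSpec("alpha1", 8.0, 10.5),
        BandSpec("alpha2", 10.5, 13.0),
        BandSpec("beta1", 13.0, 20.0),
        BandSpec("beta2", 20.0, 30.0),
    )
}


def get_band(band: str | BandSpec) -> BandSpec:
    if isinstance(band, BandSpec):
        return band
    try:
        return BANDS[band]
    except KeyError:
        raise ValueError(
            f"unknown band {band!r}; known bands: {sorted(BANDS)}"
        ) from None


@dataclass
class ConnectivityMatrix:
    """Symmetric weighted connectome for one subject and band.

    ``weights`` is (n, n), symmetric, zero-diagonal, values in [0, 1].
    """

    subject_id: str
    band: str
    weights: np.ndarray
    normalized: bool = False
    n_zero_power_bins: int = 0
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("weights must be a square matrix")
        if not np.allclose(w, w.T, atol=0, rtol=0):
            bad = np.argwhere(w != w.T)
            raise ValueError(f"weights not symmetric, first mismatch at {tuple(bad[0])}")
        if np.any(np.diag(w) != 0):
            raise ValueError("diagonal must be exactly zero")
        if np.nanmin(w) < 0 or np.nanmax(w) > 1 + 1e-9:
            raise ValueError("weights must lie in [0, 1]")
        self.weights = w

    @property
    def n_rois(self) -> int:
        return self.weights.shape[0]


def segment_epochs(
    signal: RoiSignal, epoch_seconds: float = DEFAULT_EPOCH_SECONDS
) -> EpochSet:
    """Cut a continuous signal into non-overlapping fixed-length epochs.

    The trailing partial epoch is discarded; the epoch count is
    ``floor(T / epoch_samples)``.
    """
    epoch_samples = int(round(epoch_seconds * signal.sampling_rate))
    n_epochs = signal.n_samples // epoch_samples
    if n_epochs < 1:
        raise ValueError(
            f"signal of {signal.n_samples} samples shorter than one epoch "
            f"({epoch_samples} samples)"
        )
    trimmed = signal.samples[:, : n_epochs * epoch_samples]
    data = trimmed.reshape(signal.n_rois, n_epochs, epoch_samples).transpose(1, 0, 2)
    return EpochSet(data=data.copy(), sampling_rate=signal.sampling_rate,
                    epoch_seconds=epoch_seconds)


def _tapered_spectra(epochs: EpochSet) -> np.ndarray:
    """Hann-tapered per-epoch DFTs, shape (n_epochs, n_rois, n_bins)."""
    n = epochs.data.shape[2]
    taper = np.hanning(n)
    return np.fft.rfft(epochs.data * taper, axis=2)


def _cross_and_power(epochs: EpochSet) -> tuple[np.ndarray, np.ndarray]:
    """Epoch-averaged cross-spectra (n, n, bins) and auto-power (n, bins)."""
    spectra = _tapered_spectra(epochs)
    cross = np.einsum("eif,ejf->ijf", spectra, np.conj(spectra)) / epochs.n_epochs
    power = np.real(np.einsum("iif->if", cross))
    return cross, power


def coherency_spectrum(epochs: EpochSet, pair: tuple[int, int]) -> np.ndarray:
    """Normalized cross-spectrum (coherency) of one ROI pair, per frequency bin.

    ``c_ij(w) = <X_i conj(X_j)> / sqrt(<|X_i|^2><|X_j|^2>)`` with the
    expectation taken across epochs.  Bins where either channel has zero power
    are returned as 0 (and would be logged by the matrix-level routine).
    """
    i, j = pair
    if epochs.n_epochs < 2:
        raise ValueError("coherency needs at least 2 epochs")
    spectra = _tapered_spectra(epochs)
    sxy = np.mean(spectra[:, i, :] * np.conj(spectra[:, j, :]), axis=0)
    sxx = np.mean(np.abs(spectra[:, i, :]) ** 2, axis=0)
    syy = np.mean(np.abs(spectra[:, j, :]) ** 2, axis=0)
    denom = np.sqrt(sxx * syy)
    out = np.zeros_like(sxy)
    ok = denom > 0
    out[ok] = sxy[ok] / denom[ok]
    return out


def _lps_from_coherency(coh: np.ndarray) -> np.ndarray:
    """Apply the LPS ratio bin-wise with the degenerate-denominator guard."""
    re2 = np.real(coh) ** 2
    im2 = np.imag(coh) ** 2
    denom = 1.0 - re2
    phi2 = np.zeros_like(denom)
    ok = denom >= DENOM_EPS
    phi2[ok] = im2[ok] / denom[ok]
    return np.clip(phi2, 0.0, 1.0)


def lagged_phase_synchronization(
    epochs: EpochSet,
    band: str | BandSpec,
    aggregation: str = "peak",
) -> ConnectivityMatrix:
    """All-pairs LPS in one band, aggregated over the band's bins.

    ``aggregation="peak"`` (default) takes the maximum of per-bin LPS across
    band bins; ``"mean"`` averages them instead.
    """
    spec = get_band(band)
    freqs = epochs.frequencies
    resolution = freqs[1] - freqs[0]
    nyquist = epochs.sampling_rate / 2.0
    if spec.lo < resolution or spec.hi > nyquist:
        raise ValueError(
            f"band {spec.name} [{spec.lo}, {spec.hi}] Hz not resolvable: "
            f"resolution {resolution} Hz, Nyquist {nyquist} Hz"
        )
    mask = spec.bins(freqs)
    if not mask.any():
        raise ValueError(f"band {spec.name} contains no frequency bins")
    if aggregation not in ("peak", "mean"):
        raise ValueError("aggregation must be 'peak' or 'mean'")

    cross, power = _cross_and_power(epochs)
    n = epochs.n_rois
    band_cross = cross[:, :, mask]
    band_power = power[:, mask]
    denom = np.sqrt(band_power[:, None, :] * band_power[None, :, :])
    coh = np.zeros_like(band_cross)
    ok = denom > 0
    coh[ok] = band_cross[ok] / denom[ok]
    n_zero = int(np.count_nonzero(~ok[np.triu_indices(n, k=1)]))
    if n_zero:
        logger.warning("%d zero-power pair-bins contributed 0 to LPS", n_zero)

    phi2 = _lps_from_coherency(coh)
    agg = phi2.max(axis=2) if aggregation == "peak" else phi2.mean(axis=2)
    agg = 0.5 * (agg + agg.T)  # enforce exact symmetry against FP asymmetry
    np.fill_diagonal(agg, 0.0)
    return ConnectivityMatrix(
        subject_id="", band=spec.name, weights=agg, normalized=False,
        n_zero_power_bins=n_zero,
    )


def lps_all_bands(
    epochs: EpochSet,
    bands: dict[str, BandSpec] | None = None,
    aggregation: str = "peak",
) -> dict[str, ConnectivityMatrix]:
    """LPS matrices for several bands from one shared spectral estimate.

    Equivalent to calling :func:`lagged_phase_synchronization` per band but
    computes the epoch-averaged cross-spectra once.
    """
    bands = bands if bands is not None else BANDS
    if aggregation not in ("peak", "mean"):
        raise ValueError("aggregation must be 'peak' or 'mean'")
    freqs = epochs.frequencies
    cross, power = _cross_and_power(epochs)
    n = epochs.n_rois
    out: dict[str, ConnectivityMatrix] = {}
    for name, spec in bands.items():
        mask = spec.bins(freqs)
        if not mask.any():
            raise ValueError(f"band {name} contains no frequency bins")
        band_cross = cross[:, :, mask]
        band_power = power[:, mask]
        denom = np.sqrt(band_power[:, None, :] * band_power[None, :, :])
        coh = np.zeros_like(band_cross)
        ok = denom > 0
        coh[ok] = band_cross[ok] / denom[ok]
        phi2 = _lps_from_coherency(coh)
        agg = phi2.max(axis=2) if aggregation == "peak" else phi2.mean(axis=2)
        agg = 0.5 * (agg + agg.T)
        np.fill_diagonal(agg, 0.0)
        out[name] = ConnectivityMatrix(subject_id="", band=name, weights=agg)
    return out


def normalize_by_max(matrix: ConnectivityMatrix) -> ConnectivityMatrix:
    """Divide all weights by the off-diagonal maximum (idempotent at max 1)."""
    w = matrix.weights
    m = w.max()
    if m <= 0:
        raise ValueError("cannot normalize an all-zero connectivity matrix")
    return ConnectivityMatrix(
        subject_id=matrix.subject_id, band=matrix.band, weights=w / m,
        normalized=True, n_zero_power_bins=matrix.n_zero_power_bins,
        labels=list(matrix.labels),
    )


def overall_fc(matrix: ConnectivityMatrix) -> float:
    """Mean absolute edge weight over all unordered off-diagonal pairs."""
    w = matrix.weights
    iu = np.triu_indices(w.shape[0], k=1)
    return float(np.mean(np.abs(w[iu])))
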
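"""EEG-proxy spectral analysis: downsample, band-pass, Welch PSD, bands.

The population mean-voltage traces are treated like an EEG channel and run
through the same chain used for human sleep/wake recordings: decimation to
200 Hz (plain stride — the traces are plotted as "sampled at 5 ms
intervals"), a zero-phase order-10 Butterworth band-pass between 1 and
16 Hz, and a Welch periodogram with 800 FFT points, a Hamming window half
the sampling frequency in length (100 samples) and 50% overlap, giving a
0.25 Hz frequency grid.

Band powers are integrated over the four classic sleep-scoring bands —
delta (1–4 Hz), theta (4–8 Hz), alpha (8–12 Hz) and sigma/spindle
(12–16 Hz) — and the dominant band classifies the trace: alpha dominance is
wake-like, delta or theta dominance sleep-like (the lesioned circuit peaks
in theta rather than delta), anything else indeterminate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .engine import PopulationTrace

#: Sleep-scoring frequency bands (Hz), contiguous over [1, 16].
BANDS: dict[str, tuple[float, float]] = {
    "delta": (1.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 12.0),
    "sigma": (12.0, 16.0),
}


@dataclass
class SpectralSettings:
    """Parameters of the analysis chain (defaults follow the study protocol)."""

    target_fs: float = 200.0
    band_lo: float = 1.0
    band_hi: float = 16.0
    filter_order: int = 10
    nfft: int = 800
    window_kind: str = "hamming"
    window_len: int = 100       # half the sampling frequency, in samples
    overlap_fraction: float = 0.5

    def __post_init__(self) -> None:
        if not 0 < self.band_lo < self.band_hi < self.target_fs / 2:
            raise ValueError("need 0 < band_lo < band_hi < target_fs/2")
        if self.window_len > self.nfft:
            raise ValueError("window_len must not exceed nfft")
        if not 0 <= self.overlap_fraction < 1:
            raise ValueError("overlap_fraction must lie in [0, 1)")

    @property
    def noverlap(self) -> int:
        return int(round(self.window_len * self.overlap_fraction))


@dataclass
class SpectralResult:
    """Welch PSD with band powers and the dominant-frequency summary."""

    frequencies: np.ndarray
    psd: np.ndarray
    band_powers: dict[str, float] = field(default_factory=dict)
    dominant_frequency: float = float("nan")
    dominant_band: str = ""

    @property
    def total_band_power(self) -> float:
        return float(sum(self.band_powers.values()))

    def save_psd(self, path) -> None:
        np.savetxt(path, np.column_stack([self.frequencies, self.psd]),
                   fmt="%.6g", header="frequency_hz\tpsd", delimiter="\t", comments="")

    def save_band_table(self, path) -> None:
        total = self.total_band_power
        with open(path, "w") as fh:
            fh.write("band\tpower\tfraction\n")
            for name, p in self.band_powers.items():
                frac = p / total if total > 0 else float("nan")
                fh.write(f"{name}\t{p:.6g}\t{frac:.6g}\n")


def downsample(trace: PopulationTrace, settings: SpectralSettings) -> PopulationTrace:
    """Stride decimation to ``target_fs`` (no anti-alias filter).

    The source rate must be an integer multiple of the target rate; every
    k-th sample is kept, e.g. 1 kHz -> 200 Hz keeps one sample per 5 ms.
    """
    source_fs = 1000.0 / trace.dt
    ratio = source_fs / settings.target_fs
    if abs(ratio - round(ratio)) > 1e-9 or ratio < 1:
        raise ValueError(
            f"source rate {source_fs:g} Hz is not an integer multiple of "
            f"target {settings.target_fs:g} Hz"
        )
    k = int(round(ratio))
    return PopulationTrace(
        population=trace.population,
        dt=trace.dt * k,
        values=trace.values[::k].copy(),
        run_id=trace.run_id,
    )


def bandpass(trace: PopulationTrace, settings: SpectralSettings) -> PopulationTrace:
    """Zero-phase order-10 Butterworth band-pass between 1 and 16 Hz.

    The filter is designed in cascaded second-order sections and applied
    forward-backward, so the net response has no phase distortion (and
    twice the design order's roll-off).
    """
    fs = 1000.0 / trace.dt
    if abs(fs - settings.target_fs) > 1e-6:
        raise ValueError("bandpass expects a trace already at target_fs")
    sos = signal.butter(settings.filter_order,
                        [settings.band_lo, settings.band_hi],
                        btype="bandpass", fs=fs, output="sos")
    # sosfiltfilt needs a few times the filter's impulse-response in samples
    padlen = 3 * (2 * sos.shape[0] + 1)
    if trace.values.size <= 3 * padlen:
        raise ValueError(
            f"trace of {trace.values.size} samples is too short for the "
            f"order-{settings.filter_order} zero-phase band-pass"
        )
    filtered = signal.sosfiltfilt(sos, trace.values)
    return PopulationTrace(trace.population, trace.dt, filtered, trace.run_id)


def welch_psd(trace: PopulationTrace, settings: SpectralSettings) -> SpectralResult:
    """Welch periodogram and band summary of a (filtered) trace.

    100-sample Hamming segments with a 50-sample hop, each mean-detrended
    and zero-padded to 800 FFT points: frequency resolution
    ``target_fs / nfft`` = 0.25 Hz.  Band powers integrate the PSD over the
    four bands; the dominant frequency is the PSD argmax over
    ``[band_lo, band_hi]``.
    """
    fs = 1000.0 / trace.dt
    if trace.values.size < settings.window_len:
        raise ValueError("trace shorter than one Welch window")
    freqs, psd = signal.welch(
        trace.values,
        fs=fs,
        window=signal.get_window(settings.window_kind, settings.window_len),
        noverlap=settings.noverlap,
        nfft=settings.nfft,
        detrend="constant",
    )
    df = freqs[1] - freqs[0]
    band_powers = {}
    for name, (lo, hi) in BANDS.items():
        if name == list(BANDS)[-1]:
            mask = (freqs >= lo) & (freqs <= hi)
        else:
            mask = (freqs >= lo) & (freqs < hi)
        band_powers[name] = float(psd[mask].sum() * df)

    search = (freqs >= settings.band_lo) & (freqs <= settings.band_hi)
    peak_idx = np.nonzero(search)[0][np.argmax(psd[search])]
    fpeak = float(freqs[peak_idx])
    dominant_band = max(band_powers, key=band_powers.get)
    return SpectralResult(
        frequencies=freqs,
        psd=psd,
        band_powers=band_powers,
        dominant_frequency=fpeak,
        dominant_band=dominant_band,
    )


def analyze_trace(trace: PopulationTrace,
                  settings: SpectralSettings | None = None) -> SpectralResult:
    """Full chain in protocol order: downsample -> band-pass -> Welch."""
    settings = settings or SpectralSettings()
    return welch_psd(bandpass(downsample(trace, settings), settings), settings)


def classify_state(result: SpectralResult) -> str:
    """``wake_like`` iff alpha-dominant; ``sleep_like`` iff delta- or
    theta-dominant; otherwise ``indeterminate``."""
    if result.dominant_band == "alpha":
        return "wake_like"
    if result.dominant_band in ("delta", "theta"):
        return "sleep_like"
    return "indeterminate"
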
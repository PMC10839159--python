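"""Seeded synthetic current recordings with known ground truth.

Generates traces that emulate the sensor's recordings -- an open-pore
baseline at the digitiser rate (250 kHz) with white Gaussian noise and
optional linear drift, plus blockade events inserted by superposition --
together with a truth table of every injected event.  Events are either
parametric (rectangular dip of given fractional blockade and dwell) or
shaped from a simulated position trace read at constant translocation
speed.  Everything is a pure function of the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .events import TimeSeries
from .sweeps import PositionTrace

__all__ = [
    "SynthEvent",
    "SynthSpec",
    "map_position_to_time",
    "synthesize_trace",
    "make_fixture_suite",
    "BAND_CENTERS",
]

# (fractional blockade %, dwell ms) centres of the single/double/triple
# discrimination bands, and the per-class dwell spreads.
BAND_CENTERS = {
    "single": (34.5, 1.0),
    "double": (54.5, 1.15),
    "triple": (65.5, 1.3),
}
DWELL_SPREADS = {"single": 0.02, "double": 0.03, "triple": 0.03}


@dataclass(frozen=True)
class SynthEvent:
    """One event to inject: parametric or shaped by a position trace."""

    t_start: float  # s
    fb_percent: float | None = None
    dwell_ms: float | None = None
    shape: PositionTrace | None = None
    speed_um_s: float | None = None  # used with ``shape``
    label: str = ""

    def duration_s(self) -> float:
        if self.shape is not None:
            span_nm = float(self.shape.z[-1] - self.shape.z[0])
            return span_nm / (self.speed_um_s * 1e3)  # nm / (nm/ms) -> ms
        return self.dwell_ms * 1e-3


@dataclass
class SynthSpec:
    """Recipe for one synthetic recording."""

    i_open: float = 300.0  # pA
    noise_sigma: float = 3.0  # pA (white, at the digitiser)
    sampling_rate: float = 250_000.0  # Hz
    duration: float = 1.0  # s
    events: list[SynthEvent] = field(default_factory=list)
    drift: float = 0.0  # pA/s
    seed: int = 0
    prefilter_noise: bool = False  # shape noise by the 2 kHz Bessel response


def map_position_to_time(
    trace: PositionTrace, speed_um_s: float
) -> tuple[np.ndarray, np.ndarray]:
    """Read a position sweep at constant speed: t = (z - z0) / v.

    Returns (time s, current A); 1 um/s carries 1 nm per ms.
    """
    if speed_um_s <= 0:
        raise ValueError("speed must be positive")
    z = trace.z
    if np.any(np.diff(z) <= 0):
        raise ValueError("position trace must be strictly increasing in z")
    t_ms = (z - z[0]) / speed_um_s  # 1 um/s == 1 nm/ms
    return t_ms * 1e-3, trace.current.copy()


def _event_waveform(ev: SynthEvent, fs: float, i_open: float) -> np.ndarray:
    """Sampled current deviation (pA, <= 0) contributed by one event."""
    if ev.shape is not None:
        t, i = map_position_to_time(ev.shape, ev.speed_um_s)
        n = max(int(round(t[-1] * fs)), 2)
        tt = np.arange(n) / fs
        rel = np.interp(tt, t, i) / ev.shape.i_open  # relative current
        return (rel - 1.0) * i_open
    n = max(int(round(ev.dwell_ms * 1e-3 * fs)), 1)
    return np.full(n, -ev.fb_percent / 100.0 * i_open)


def synthesize_trace(spec: SynthSpec) -> tuple[TimeSeries, list[dict]]:
    """Render a recording and its ground-truth event table.

    Events are superposed on the baseline (no event-event interaction) and
    must not overlap.  The same seed reproduces the samples bit for bit.
    """
    fs = spec.sampling_rate
    n = int(round(spec.duration * fs))
    rng = np.random.default_rng(spec.seed)

    spans = []
    for ev in spec.events:
        t0 = ev.t_start
        t1 = t0 + ev.duration_s()
        if t1 > spec.duration:
            raise ValueError(f"event at t={t0:g}s extends past the trace end")
        spans.append((t0, t1, ev))
    spans.sort(key=lambda s: s[0])
    for (a0, a1, _), (b0, b1, _) in zip(spans[:-1], spans[1:]):
        if b0 < a1:
            raise ValueError("events overlap; superposition would be ambiguous")

    t = np.arange(n) / fs
    x = np.full(n, spec.i_open) + spec.drift * t
    noise = rng.normal(0.0, spec.noise_sigma, n)
    if spec.prefilter_noise and spec.noise_sigma > 0:
        from scipy import signal as sps

        sos = sps.bessel(8, 2000.0, btype="low", output="sos",
                         norm="mag", fs=fs)
        noise = sps.sosfilt(sos, noise)
        # restore the requested stationary variance
        gain = np.sqrt(np.mean(noise[n // 4:] ** 2))
        if gain > 0:
            noise *= spec.noise_sigma / gain
    x += noise

    truth = []
    for t0, t1, ev in spans:
        k0 = int(round(t0 * fs))
        wav = _event_waveform(ev, fs, spec.i_open)
        k1 = min(k0 + len(wav), n)
        x[k0:k1] += wav[: k1 - k0]
        depth = -wav.min()
        truth.append(
            {
                "t_start": t0,
                "t_end": t1,
                "dwell_ms": (t1 - t0) * 1e3,
                "fb_percent": 100.0 * depth / spec.i_open,
                "label": ev.label,
                "snr": depth / spec.noise_sigma if spec.noise_sigma else np.inf,
            }
        )
    ts = TimeSeries(
        x, fs,
        metadata={"i_open_pA": spec.i_open, "seed": spec.seed,
                  "noise_sigma_pA": spec.noise_sigma},
    )
    return ts, truth


def make_fixture_suite(
    seed: int = 0,
    n_per_class: int = 12,
    i_open: float = 300.0,
    noise_sigma: float = 3.0,
    fb_jitter: float = 0.5,  # percent (absolute), s.d.
    dwell_jitter: float = 1.0,  # scale on the per-class dwell spreads
    include_qc_traces: bool = True,
) -> dict[str, tuple[TimeSeries, list[dict]]]:
    """Labelled fixture suite at the discrimination-band centres.

    One recording per class carrying ``n_per_class`` events with jittered
    (FB, dwell) around the class centre, plus pure-noise QC traces: one
    within the 30 pA peak-to-peak acceptance bound and one violating it.
    """
    rng = np.random.default_rng(seed)
    suite: dict[str, tuple[TimeSeries, list[dict]]] = {}
    gap = 0.05  # s between events
    for cls, (fb0, dw0) in BAND_CENTERS.items():
        sd_dw = dwell_jitter * DWELL_SPREADS[cls]
        events = []
        t = 0.06
        for _ in range(n_per_class):
            fb = fb0 + fb_jitter * rng.standard_normal()
            dw = dw0 + sd_dw * rng.standard_normal()
            events.append(
                SynthEvent(t_start=t, fb_percent=fb, dwell_ms=dw, label=cls)
            )
            t += dw * 1e-3 + gap
        spec = SynthSpec(
            i_open=i_open,
            noise_sigma=noise_sigma,
            duration=t + 0.05,
            events=events,
            seed=int(rng.integers(2**31 - 1)),
        )
        suite[cls] = synthesize_trace(spec)
    if include_qc_traces:
        # QC measures peak-to-peak noise after the 2 kHz filter, so the QC
        # traces carry band-limited noise; Gaussian p2p (0.5-99.5
        # percentile span) is ~5.15 sigma: 3 pA ~ 15 pA p2p (pass),
        # 7.8 pA ~ 40 pA p2p (fail, over the 30 pA acceptance bound)
        for name, sigma in (("qc_pass", 3.0), ("qc_fail", 7.8)):
            spec = SynthSpec(
                i_open=i_open,
                noise_sigma=sigma,
                duration=10.0,
                events=[],
                seed=int(rng.integers(2**31 - 1)),
                prefilter_noise=True,
            )
            suite[name] = synthesize_trace(spec)
    return suite
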
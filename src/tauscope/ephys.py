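"""Template-fit EPSC event detection and group statistics.

Excitatory postsynaptic currents are inward (downward) deflections of a
whole-cell voltage-clamp trace. Detection slides a canonical event waveform
(a unit-amplitude difference of exponentials, built from 10-20
representative events or from kinetic parameters) along the trace and fits
``scale * template + offset`` by least squares at every lag; the detection
criterion is the fitted scale divided by its standard error. Criterion
maxima above a threshold become events; events with fitted amplitude at or
below 10 pA are discarded; each recording is analyzed over a 1-minute
window.

The module also provides the asymptotic test for equality of coefficients of
variation across groups (Feltz-Miller), an asymptotically chi-squared
statistic with k-1 degrees of freedom.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, signal, stats

from . import defaults


class TemplateError(ValueError):
    pass


@dataclass
class Trace:
    """Current samples (pA) with acquisition metadata."""

    samples: np.ndarray
    sample_rate_hz: float
    group: str = ""
    cell_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.sample_rate_hz

    def baseline(self) -> float:
        """Global baseline estimate: the trace median."""
        return float(np.median(self.samples))


@dataclass
class EventTemplate:
    """Unit-amplitude canonical event, negative-going (peak value -1)."""

    waveform: np.ndarray
    sample_rate_hz: float
    rise_tau_ms: float
    decay_tau_ms: float
    n_source_events: int = 0

    def __post_init__(self) -> None:
        self.waveform = np.asarray(self.waveform, dtype=np.float64)
        peak = np.abs(self.waveform).max()
        if not math.isclose(peak, 1.0, rel_tol=1e-6):
            raise TemplateError("template peak magnitude must be 1")

    @property
    def peak_index(self) -> int:
        return int(np.argmin(self.waveform))


@dataclass
class EventRecord:
    time_s: float
    amplitude_pa: float
    rise_10_90_ms: float
    decay_tau_ms: float
    fit_score: float


@dataclass
class EventStats:
    n_events: int
    frequency_hz: float
    mean_amplitude_pa: float
    mean_rise_10_90_ms: float
    mean_decay_tau_ms: float
    window_s: float
    flags: list[str] = field(default_factory=list)


@dataclass
class CvTestResult:
    k_groups: int
    statistic: float
    p_value: float
    cvs: list[float]
    df: int


# ---------------------------------------------------------------------------
# templates
# ---------------------------------------------------------------------------

def _diff_of_exponentials(t: np.ndarray, rise_tau_ms: float, decay_tau_ms: float) -> np.ndarray:
    """Positive-up unit-peak difference of exponentials on times t (s)."""
    tr, td = rise_tau_ms / 1000.0, decay_tau_ms / 1000.0
    g = np.exp(-t / td) - np.exp(-t / tr)
    t_peak = tr * td / (td - tr) * math.log(td / tr)
    peak = math.exp(-t_peak / td) - math.exp(-t_peak / tr)
    return g / peak


def template_from_params(rise_tau_ms: float, decay_tau_ms: float,
                         sample_rate_hz: float,
                         duration_factor: float = 8.0) -> EventTemplate:
    """Build a template directly from kinetic constants."""
    if decay_tau_ms <= rise_tau_ms:
        raise TemplateError("decay_tau_ms must exceed rise_tau_ms")
    dt = 1.0 / sample_rate_hz
    t = np.arange(0.0, duration_factor * decay_tau_ms / 1000.0, dt)
    wf = -_diff_of_exponentials(t, rise_tau_ms, decay_tau_ms)
    wf /= np.abs(wf).max()  # sampled peak, not the continuous one
    return EventTemplate(wf, sample_rate_hz, rise_tau_ms, decay_tau_ms)


def build_template(trace: Trace,
                   candidate_times_s: list[float],
                   *,
                   pre_ms: float = 5.0,
                   post_ms: float = 40.0) -> EventTemplate:
    """Average 10-20 representative events into a unit-amplitude template.

    Snippets around the candidate onsets are baseline-subtracted (median of
    the 5 ms preceding each event), aligned at their negative peak, averaged
    and rescaled to unit peak; rise and decay constants are then fitted to
    the average.
    """
    n = len(candidate_times_s)
    if not 10 <= n <= 20:
        raise TemplateError(
            f"template construction needs 10-20 candidate events, got {n}")
    fs = trace.sample_rate_hz
    pre = int(round(pre_ms / 1000.0 * fs))
    post = int(round(post_ms / 1000.0 * fs))
    snippets = []
    for t0 in candidate_times_s:
        i0 = int(round(t0 * fs))
        if i0 - pre < 0 or i0 + post > len(trace.samples):
            continue
        snip = trace.samples[i0 - pre:i0 + post].copy()
        snip -= np.median(snip[:pre]) if pre else 0.0
        snippets.append(snip)
    if len(snippets) < 10:
        raise TemplateError("fewer than 10 usable candidate snippets")

    # align at negative peak, then average
    peaks = [int(np.argmin(s)) for s in snippets]
    ref = int(round(np.median(peaks)))
    aligned = []
    for s, p in zip(snippets, peaks):
        shift = ref - p
        aligned.append(np.roll(s, shift))
    avg = np.mean(aligned, axis=0)
    peak_val = avg.min()
    if peak_val >= -1e-12:
        raise TemplateError("degenerate candidates: average has no negative peak")
    unit = avg / abs(peak_val)

    # trim leading baseline so the waveform starts at the event onset
    onset = pre - int(round(1.0 / 1000.0 * fs))
    unit = unit[max(onset, 0):]
    unit /= np.abs(unit).max()

    rise, decay = _fit_kinetics(unit, fs)
    return EventTemplate(unit, fs, rise, decay, n_source_events=len(snippets))


def _fit_kinetics(unit_waveform: np.ndarray, fs: float) -> tuple[float, float]:
    """Fit rise/decay time constants (ms) of a unit negative waveform."""
    t = np.arange(len(unit_waveform)) / fs
    y = -unit_waveform

    def model(t, tr_ms, td_ms, t0):
        tt = np.clip(t - t0, 0, None)
        return _diff_of_exponentials(tt, tr_ms, td_ms) * (tt > 0)

    try:
        popt, _ = optimize.curve_fit(
            model, t, y, p0=[1.0, 6.0, 0.0],
            bounds=([0.05, 0.2, -0.01], [20.0, 200.0, 0.05]), maxfev=5000)
        tr, td = float(popt[0]), float(popt[1])
        if td <= tr:
            tr, td = td, tr
        return tr, td
    except RuntimeError as exc:  # pragma: no cover - degenerate fits
        raise TemplateError(f"kinetics fit failed: {exc}") from exc


# ---------------------------------------------------------------------------
# detection
# ---------------------------------------------------------------------------

def sliding_fit_criterion(samples: np.ndarray, waveform: np.ndarray
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares fit of scale*template+offset at every lag.

    Returns (criterion, scale) arrays of length ``len(samples) - N + 1``
    where N is the template length; criterion = scale / SE(scale).
    """
    y = np.asarray(samples, dtype=np.float64)
    w = np.asarray(waveform, dtype=np.float64)
    n = len(w)
    if len(y) < n:
        raise ValueError("trace shorter than template")
    sw = w.sum()
    sww = (w * w).sum()
    ones = np.ones(n)
    sy = signal.oaconvolve(y, ones, mode="valid")
    syy = signal.oaconvolve(y * y, ones, mode="valid")
    swy = signal.oaconvolve(y, w[::-1], mode="valid")

    denom = sww - sw * sw / n
    scale = (swy - sw * sy / n) / denom
    offset = (sy - scale * sw) / n
    sse = (syy + scale ** 2 * sww + n * offset ** 2
           - 2.0 * (scale * swy + offset * sy - scale * offset * sw))
    sse = np.clip(sse, 0.0, None)
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(sse / (n - 2) / denom)
        criterion = np.where(se > 0, scale / se, 0.0)
    return criterion, scale


def detect_events(trace: Trace,
                  template: EventTemplate,
                  criterion_threshold: float = defaults.CRITERION_THRESHOLD,
                  amp_min_pa: float = defaults.AMP_MIN_PA,
                  window_s: float = defaults.WINDOW_S,
                  window_offset_s: float = 0.0,
                  merge_window_ms: float | None = None,
                  ) -> list[EventRecord]:
    """Detect EPSCs in the analysis window of a trace.

    Criterion local maxima above ``criterion_threshold`` become candidates.
    The criterion forms one broad lobe per event (the template still fits
    partway down the decay), so candidates within ``merge_window_ms`` keep
    only the highest criterion; the default window is the template's
    time-to-peak plus two decay constants, which spans the lobe's
    above-gate side maxima. Candidates with fitted amplitude in
    (0, ``amp_min_pa``] are discarded. Adding a constant holding current to
    the trace does not change the result (the fit carries a free offset).
    """
    fs = trace.sample_rate_hz
    if not math.isclose(fs, template.sample_rate_hz, rel_tol=1e-9):
        template = _resample_template(template, fs)
    i0 = int(round(window_offset_s * fs))
    i1 = min(len(trace.samples), i0 + int(round(window_s * fs)))
    if i1 - i0 < len(template.waveform):
        raise ValueError("trace shorter than the analysis window plus template")
    seg = trace.samples[i0:i1]

    criterion, scale = sliding_fit_criterion(seg, template.waveform)
    if merge_window_ms is None:
        tr_, td_ = template.rise_tau_ms, template.decay_tau_ms
        t_peak_ms = tr_ * td_ / (td_ - tr_) * math.log(td_ / tr_)
        merge_window_ms = t_peak_ms + 2.0 * td_
    min_dist = max(1, int(round(merge_window_ms / 1000.0 * fs)))
    peaks, _ = signal.find_peaks(criterion, height=criterion_threshold,
                                 distance=min_dist)
    events: list[EventRecord] = []
    for p in peaks:
        amp = float(scale[p])  # template peak is -1, so scale == magnitude
        if amp <= amp_min_pa:
            continue
        rise, decay = _event_kinetics(seg, p, template, fs)
        events.append(EventRecord(
            time_s=window_offset_s + p / fs,
            amplitude_pa=amp,
            rise_10_90_ms=rise,
            decay_tau_ms=decay,
            fit_score=float(criterion[p]),
        ))
    return events


def _resample_template(template: EventTemplate, fs: float) -> EventTemplate:
    t_old = np.arange(len(template.waveform)) / template.sample_rate_hz
    t_new = np.arange(0.0, t_old[-1], 1.0 / fs)
    wf = np.interp(t_new, t_old, template.waveform)
    wf = wf / np.abs(wf).max()
    return EventTemplate(wf, fs, template.rise_tau_ms, template.decay_tau_ms,
                         template.n_source_events)


def _event_kinetics(seg: np.ndarray, onset: int, template: EventTemplate,
                    fs: float) -> tuple[float, float]:
    """Per-event 10-90% rise time and single-exponential decay tau (ms)."""
    pre = int(round(5.0 / 1000.0 * fs))
    base = float(np.median(seg[max(onset - pre, 0):onset])) if onset else 0.0
    n = len(template.waveform)
    window = seg[onset:onset + n] - base
    peak_i = int(np.argmin(window))
    peak = window[peak_i]
    if peak >= 0:
        return math.nan, math.nan
    # rise: last 10% crossing before peak, first 90% crossing
    rising = window[:peak_i + 1]
    t10 = _crossing_time(rising, 0.1 * peak, fs)
    t90 = _crossing_time(rising, 0.9 * peak, fs)
    rise = (t90 - t10) * 1000.0 if (t90 is not None and t10 is not None) else math.nan
    # decay: log-linear fit from peak until 10% of peak magnitude
    tail = -window[peak_i:]
    stop = np.argmax(tail < 0.1 * -peak) or len(tail)
    tail = tail[:max(stop, 4)]
    valid = tail > 0
    if valid.sum() < 4:
        return rise, math.nan
    tt = np.arange(len(tail))[valid] / fs
    slope, _ = np.polyfit(tt, np.log(tail[valid]), 1)
    decay = -1000.0 / slope if slope < 0 else math.nan
    return rise, decay


def _crossing_time(rising: np.ndarray, level: float, fs: float) -> float | None:
    """Time (s) where a descending segment last crosses ``level`` (< 0)."""
    below = np.nonzero(rising <= level)[0]
    if len(below) == 0:
        return None
    i = below[0]
    if i == 0:
        return 0.0
    y0, y1 = rising[i - 1], rising[i]
    frac = (level - y0) / (y1 - y0) if y1 != y0 else 0.0
    return (i - 1 + frac) / fs


# ---------------------------------------------------------------------------
# summaries and the CV-equality test
# ---------------------------------------------------------------------------

def summarize_events(events: list[EventRecord],
                     window_s: float = defaults.WINDOW_S) -> EventStats:
    """Frequency over the analysis window and mean amplitude/kinetics."""
    n = len(events)
    if n == 0:
        return EventStats(0, 0.0, math.nan, math.nan, math.nan, window_s,
                          flags=["no events: kinetic means undefined"])
    amps = [e.amplitude_pa for e in events]
    rises = [e.rise_10_90_ms for e in events if not math.isnan(e.rise_10_90_ms)]
    decays = [e.decay_tau_ms for e in events if not math.isnan(e.decay_tau_ms)]
    return EventStats(
        n_events=n,
        frequency_hz=n / window_s,
        mean_amplitude_pa=float(np.mean(amps)),
        mean_rise_10_90_ms=float(np.mean(rises)) if rises else math.nan,
        mean_decay_tau_ms=float(np.mean(decays)) if decays else math.nan,
        window_s=window_s,
    )


def cv_equality_test(groups: list[np.ndarray]) -> CvTestResult:
    """Asymptotic (Feltz-Miller) test for equality of coefficients of
    variation across k groups.

    With group CVs c_i = s_i / xbar_i, weights m_i = n_i - 1 and pooled
    c = sum(m_i c_i) / sum(m_i), the statistic

        D = sum m_i (c_i - c)^2 / (c^2 (0.5 + c^2))

    is asymptotically chi-squared with k-1 degrees of freedom under the null
    of equal CVs. The statistic is scale invariant and zero when all group
    CVs coincide.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    cvs, ms = [], []
    for g in groups:
        g = np.asarray(g, dtype=np.float64)
        if len(g) < 2:
            raise ValueError("each group needs n >= 2")
        mean = g.mean()
        if mean == 0:
            raise ValueError("zero group mean: CV undefined")
        cvs.append(float(g.std(ddof=1) / mean))
        ms.append(len(g) - 1)
    cvs_arr = np.array(cvs)
    ms_arr = np.array(ms, dtype=float)
    pooled = float((ms_arr * cvs_arr).sum() / ms_arr.sum())
    if pooled == 0:
        d = 0.0
    else:
        d = float((ms_arr * (cvs_arr - pooled) ** 2).sum()
                  / (pooled ** 2 * (0.5 + pooled ** 2)))
    df = len(groups) - 1
    p = float(stats.chi2.sf(d, df))
    return CvTestResult(len(groups), d, p, cvs, df)
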
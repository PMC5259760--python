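"""Fundamental-frequency estimation and the DF/F0 ratio analysis.

F0 is estimated with the classic autocorrelation pitch method: frames are
Hann-windowed, their normalized autocorrelation is divided by the window's
own autocorrelation to undo the window's taper, local maxima in the
admissible lag range become pitch candidates, and a dynamic-programming
pass picks the globally cheapest voiced/unvoiced path, penalising octave
jumps and voicing flips.  This is the algorithm family behind the standard
"to pitch" tools whose parameter names (pitch range, voicing threshold,
silence threshold, octave cost, octave-jump cost, voiced/unvoiced cost) the
interface mirrors.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import numpy as np
from scipy import stats

from callometry.audio import AudioClip
from callometry.errors import DegenerateInputError, InsufficientDataError
from callometry.spectral import Call

__all__ = [
    "PitchParams",
    "PitchTrack",
    "RatioRecord",
    "estimate_pitch",
    "classify_tonality",
    "call_f0",
    "ratio_analysis",
    "size_vs_equal_proportion",
]


@dataclass(frozen=True)
class PitchParams:
    """Autocorrelation pitch-tracker parameters.

    floor_hz / ceiling_hz bound the F0 search (the analysis window is three
    periods of the floor).  voicing_threshold is the autocorrelation
    strength an unvoiced candidate competes with; frames whose peak
    amplitude falls below silence_threshold x the clip maximum are forced
    unvoiced.  octave_cost biases candidates toward higher frequencies to
    fight period doubling; octave_jump_cost and voiced_unvoiced_cost price
    transitions in the dynamic-programming path.
    """

    floor_hz: float = 75.0
    ceiling_hz: float = 600.0
    voicing_threshold: float = 0.45
    silence_threshold: float = 0.03
    octave_cost: float = 0.01
    octave_jump_cost: float = 0.35
    voiced_unvoiced_cost: float = 0.14
    frame_step_s: float = 0.01
    candidates_per_frame: int = 4

    def __post_init__(self) -> None:
        if not 0 < self.floor_hz < self.ceiling_hz:
            raise DegenerateInputError("need 0 < floor_hz < ceiling_hz")


@dataclass(frozen=True)
class PitchTrack:
    """Per-frame F0 (NaN where unvoiced) and candidate strength."""

    times: np.ndarray
    f0: np.ndarray
    strength: np.ndarray

    @property
    def voiced(self) -> np.ndarray:
        return ~np.isnan(self.f0)

    @property
    def voiced_fraction(self) -> float:
        return float(np.mean(self.voiced)) if len(self.f0) else 0.0


@dataclass(frozen=True)
class RatioRecord:
    call_id: str
    ratio: float
    category: Literal["equal", "harmonic_multiple", "other"]


# Band-limited oversampling factor for the autocorrelation.  Parabolic
# interpolation on the raw one-sample lag grid underestimates peak heights
# at short lags (high F0), which lets period-multiple peaks outrank the true
# one; a sinc-interpolated (FFT-oversampled) autocorrelation removes the bias.
_AC_OVERSAMPLE = 4


def _frame_candidates(
    frame: np.ndarray,
    rate: float,
    params: PitchParams,
    window_ac: np.ndarray,
) -> list[tuple[float, float]]:
    """(f0, strength) pitch candidates of one mean-subtracted frame."""
    n = len(frame)
    ov = _AC_OVERSAMPLE
    windowed = (frame - frame.mean()) * np.hanning(n)
    # autocorrelation via FFT, sinc-oversampled, normalized at lag 0
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    spec = np.fft.rfft(windowed, nfft)
    ac = np.fft.irfft(spec * np.conj(spec), ov * nfft)[: ov * n]
    if ac[0] <= 0:
        return []
    ac = ac / ac[0]
    # divide out the window's own autocorrelation (taper correction)
    corrected = np.zeros_like(ac)
    np.divide(ac, window_ac, out=corrected, where=window_ac > 1e-12)
    lag_min = max(2 * ov, int(np.floor(ov * rate / params.ceiling_hz)))
    lag_max = min(ov * (n - 2), int(np.ceil(ov * rate / params.floor_hz)))
    if lag_max <= lag_min:
        return []
    seg = corrected[lag_min:lag_max + 1]
    peaks = np.flatnonzero(
        (seg[1:-1] > seg[:-2]) & (seg[1:-1] >= seg[2:])
    ) + 1 + lag_min
    cands = []
    for p in peaks:
        # parabolic interpolation around the peak (on the fine lag grid)
        y0, y1, y2 = corrected[p - 1], corrected[p], corrected[p + 1]
        denom = y0 - 2 * y1 + y2
        delta = 0.5 * (y0 - y2) / denom if denom != 0 else 0.0
        lag = (p + np.clip(delta, -0.5, 0.5)) / ov
        strength = float(min(1.0, y1 - 0.25 * (y0 - y2) * delta))
        f = rate / lag
        if params.floor_hz <= f <= params.ceiling_hz:
            cands.append((float(f), strength))
    # rank by octave-cost-adjusted strength so that, when a periodic frame
    # offers equally strong peaks at every period multiple, the true
    # (highest-frequency) candidate survives the truncation below
    cands.sort(
        key=lambda c: c[1] - params.octave_cost * np.log2(
            params.ceiling_hz / c[0]),
        reverse=True,
    )
    return cands[: params.candidates_per_frame - 1]


def estimate_pitch(clip: AudioClip, params: PitchParams) -> PitchTrack:
    """Track F0 through a clip with the autocorrelation method.

    Returns one frame every ``frame_step_s`` seconds; unvoiced frames hold
    NaN.  The Viterbi pass minimises the summed negative candidate strength
    plus ``octave_jump_cost x |log2(f'/f)|`` for voiced-voiced transitions
    and ``voiced_unvoiced_cost`` for voicing flips.
    """
    rate = clip.rate
    win_len = int(round(3.0 * rate / params.floor_hz))
    if len(clip.samples) < win_len:
        raise DegenerateInputError(
            f"clip of {len(clip.samples)} samples shorter than the "
            f"{win_len}-sample analysis window"
        )
    step = max(1, int(round(params.frame_step_s * rate)))
    starts = range(0, len(clip.samples) - win_len + 1, step)
    global_peak = float(np.max(np.abs(clip.samples)))
    hann = np.hanning(win_len)
    nfft = int(2 ** np.ceil(np.log2(2 * win_len)))
    wspec = np.fft.rfft(hann, nfft)
    window_ac = np.fft.irfft(
        wspec * np.conj(wspec), _AC_OVERSAMPLE * nfft
    )[: _AC_OVERSAMPLE * win_len]
    window_ac = window_ac / window_ac[0]

    frames: list[list[tuple[float, float]]] = []
    times = []
    for s in starts:
        frame = clip.samples[s:s + win_len]
        times.append((s + win_len / 2) / rate)
        local_peak = float(np.max(np.abs(frame)))
        if global_peak == 0 or local_peak < params.silence_threshold * global_peak:
            frames.append([])  # forced unvoiced
            continue
        frames.append(_frame_candidates(frame, rate, params, window_ac))

    f0, strength = _viterbi(frames, params)
    return PitchTrack(np.asarray(times), f0, strength)


def _viterbi(
    frames: list[list[tuple[float, float]]], params: PitchParams
) -> tuple[np.ndarray, np.ndarray]:
    """Cheapest global voiced/unvoiced path through per-frame candidates."""
    n = len(frames)
    f0 = np.full(n, np.nan)
    strength = np.zeros(n)
    if n == 0:
        return f0, strength
    # candidate list per frame: index 0 = unvoiced, then voiced candidates
    # local cost = -effective strength; unvoiced strength = voicing_threshold
    cand_f: list[list[float]] = []
    cand_cost: list[list[float]] = []
    cand_raw: list[list[float]] = []
    for cands in frames:
        fs = [np.nan]
        costs = [-params.voicing_threshold]
        raws = [0.0]
        for f, r in cands:
            eff = r - params.octave_cost * np.log2(params.ceiling_hz / f)
            fs.append(f)
            costs.append(-eff)
            raws.append(r)
        cand_f.append(fs)
        cand_cost.append(costs)
        cand_raw.append(raws)

    total = [np.array(cand_cost[0])]
    back: list[np.ndarray] = []
    for t in range(1, n):
        prev = total[-1]
        cur_costs = np.array(cand_cost[t])
        tot = np.empty(len(cur_costs))
        bk = np.empty(len(cur_costs), dtype=int)
        for j, fj in enumerate(cand_f[t]):
            trans = np.empty(len(prev))
            for i, fi in enumerate(cand_f[t - 1]):
                if np.isnan(fi) and np.isnan(fj):
                    trans[i] = 0.0
                elif np.isnan(fi) or np.isnan(fj):
                    trans[i] = params.voiced_unvoiced_cost
                else:
                    trans[i] = params.octave_jump_cost * abs(np.log2(fj / fi))
            best = int(np.argmin(prev + trans))
            tot[j] = prev[best] + trans[best] + cur_costs[j]
            bk[j] = best
        total.append(tot)
        back.append(bk)

    j = int(np.argmin(total[-1]))
    path = [j]
    for t in range(n - 1, 0, -1):
        j = int(back[t - 1][j])
        path.append(j)
    path.reverse()
    for t, j in enumerate(path):
        f0[t] = cand_f[t][j]
        strength[t] = cand_raw[t][j]
    return f0, strength


def classify_tonality(
    clip: AudioClip,
    track: PitchTrack,
    harmonic_snr: float = 4.0,
) -> Literal["tonal", "pure_tone", "nontonal"]:
    """Classify a call as tonal, pure tone, or nontonal.

    A call is voiced-dominant if at least half its frames carry an F0.
    Among voiced-dominant calls, harmonic structure is probed by testing
    whether spectral energy near integer multiples of the median F0 stands
    ``harmonic_snr`` times above the median spectrum level and twice above
    the inter-harmonic level half a harmonic away (the local contrast keeps
    a strong component's leakage skirt from counting as an overtone): two or
    more passing overtones make the call tonal; energy only at the
    fundamental makes it a pure tone; anything else is nontonal.
    """
    if track.voiced_fraction < 0.5:
        return "nontonal"
    med_f0 = float(np.nanmedian(track.f0))
    from callometry.spectral import whole_call_spectrum

    spectrum = whole_call_spectrum(clip)
    floor = float(np.median(spectrum.amplitudes[spectrum.amplitudes > 0]))
    nyquist = clip.rate / 2.0

    def band_max(target: float, half_band: float) -> float:
        mask = np.abs(spectrum.frequencies - target) <= half_band
        return float(spectrum.amplitudes[mask].max()) if mask.any() else 0.0

    passing = []
    m = 1
    while m * med_f0 < nyquist and m <= 12:
        target = m * med_f0
        half_band = max(2 * spectrum.resolution, 0.04 * target)
        peak = band_max(target, half_band)
        between = max(band_max(target - 0.5 * med_f0, half_band),
                      band_max(target + 0.5 * med_f0, half_band))
        if peak > harmonic_snr * floor and peak > 2.0 * between:
            passing.append(m)
        m += 1
    overtones = sum(1 for m in passing if m >= 2)
    if overtones >= 2:
        return "tonal"
    if 1 in passing:
        return "pure_tone"
    return "nontonal"


def call_f0(track: PitchTrack) -> Optional[float]:
    """Median F0 over voiced frames, or None if under half are voiced.

    The median resists occasional octave errors; the voiced-majority gate
    excludes calls whose periodicity the tracker could not pin down.
    """
    if track.voiced_fraction < 0.5:
        return None
    return float(np.nanmedian(track.f0))


def _categorize_ratio(ratio: float) -> str:
    """Bin a DF/F0 ratio: 0.25-wide bins centred on the integers."""
    if 0.875 <= ratio < 1.125:
        return "equal"
    m = round(ratio)
    if m >= 2 and abs(ratio - m) < 0.125:
        return "harmonic_multiple"
    return "other"


def ratio_analysis(
    calls: Sequence[Call],
    species: Sequence[str] | None = None,
    log: list | None = None,
) -> tuple[list[RatioRecord], dict[str, float]]:
    """DF/F0 ratios and the per-species proportion of ratio ~= 1 calls.

    The categories follow a histogram convention of 0.25-wide bins centred
    on the integers: "equal" is the bin at 1, "harmonic_multiple" any bin at
    an integer >= 2.  Calls without F0 are skipped (and logged).
    """
    if species is None:
        species = ["all"] * len(calls)
    records: list[RatioRecord] = []
    counts: dict[str, list[int]] = {}
    for call, sp in zip(calls, species):
        if call.f0 is None:
            if log is not None:
                log.append(call.call_id)
            continue
        ratio = call.df / call.f0
        cat = _categorize_ratio(ratio)
        records.append(RatioRecord(call.call_id, ratio, cat))
        tot = counts.setdefault(sp, [0, 0])
        tot[1] += 1
        if cat == "equal":
            tot[0] += 1
    props = {sp: eq / n for sp, (eq, n) in counts.items()}
    return records, props


def size_vs_equal_proportion(
    proportions: Sequence[float], body_lengths_mm: Sequence[float]
) -> tuple[float, float]:
    """Spearman rank correlation of body length vs proportion DF/F0 ~= 1."""
    if len(proportions) < 5:
        raise InsufficientDataError("need at least 5 species")
    if len(set(proportions)) == 1 or len(set(body_lengths_mm)) == 1:
        raise DegenerateInputError("correlation undefined for constant input")
    res = stats.spearmanr(body_lengths_mm, proportions)
    return float(res.statistic), float(res.pvalue)
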
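"""Whole-call spectra, dominant frequency, and maximally-spaced selection.

The dominant frequency (DF) of a call is the frequency of the maximum-
amplitude bin of a single Hamming-windowed DFT of the whole segment, so
frequency resolution varies with call length (rate / N).  Species-level
aggregates (DF10, DF6, F06) are arithmetic means over subsets chosen at
maximally spaced positions of the frequency-sorted call list, which always
include both extremes and hence span the species' spectral range.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np

from callometry.audio import AudioClip
from callometry.errors import DegenerateInputError, InsufficientDataError

__all__ = [
    "Spectrum",
    "Call",
    "SpeciesRecord",
    "whole_call_spectrum",
    "dominant_frequency",
    "maximally_spaced_indices",
    "select_calls",
    "species_aggregates",
    "verify_df",
]

Tonality = Literal["tonal", "pure_tone", "nontonal"]


@dataclass(frozen=True)
class Spectrum:
    """One-sided magnitude spectrum on the grid 0 .. rate/2."""

    frequencies: np.ndarray
    amplitudes: np.ndarray
    resolution: float  # Hz between adjacent bins = rate / N

    def __post_init__(self) -> None:
        f = np.asarray(self.frequencies, dtype=float)
        a = np.asarray(self.amplitudes, dtype=float)
        object.__setattr__(self, "frequencies", f)
        object.__setattr__(self, "amplitudes", a)
        if f.shape != a.shape or f.size == 0:
            raise DegenerateInputError("spectrum grids must match, non-empty")
        if not np.all(np.isfinite(a)) or np.any(a < 0):
            raise DegenerateInputError("amplitudes must be finite and >= 0")


@dataclass(frozen=True)
class Call:
    """One segmented vocalization with its spectral measurements."""

    clip: AudioClip
    spectrum: Spectrum
    df: float
    tonality: Tonality = "nontonal"
    f0: Optional[float] = None
    call_id: str = ""
    voiced_fraction: float = 0.0


@dataclass
class SpeciesRecord:
    """Species-level aggregates entering the allometric regressions."""

    species: str
    body_length_mm: float
    calls: list[Call] = field(default_factory=list)
    df10: Optional[float] = None
    df6: Optional[float] = None
    f06: Optional[float] = None
    n_f0_calls: int = 0


def whole_call_spectrum(clip: AudioClip) -> Spectrum:
    """Magnitude spectrum of the Hamming-windowed whole segment.

    No zero-padding: the bin spacing is rate / N for an N-sample call, so
    long calls get finer spectra than short ones.
    """
    n = len(clip.samples)
    if n < 2:
        raise DegenerateInputError("need at least 2 samples for a spectrum")
    windowed = clip.samples * np.hamming(n)
    amps = np.abs(np.fft.rfft(windowed))
    freqs = np.fft.rfftfreq(n, d=1.0 / clip.rate)
    return Spectrum(freqs, amps, clip.rate / n)


def dominant_frequency(spectrum: Spectrum, floor_hz: float = 20.0) -> float:
    """Frequency of the maximum-amplitude bin at or above floor_hz.

    The floor keeps low-frequency background rumble out of the search; exact
    ties go to the lower frequency.
    """
    mask = spectrum.frequencies >= floor_hz
    if not mask.any():
        raise DegenerateInputError("no spectrum bins above the search floor")
    amps = spectrum.amplitudes[mask]
    if not np.any(amps > 0):
        raise DegenerateInputError("spectrum is zero above the search floor")
    best = int(np.argmax(amps))  # argmax returns the first (lowest) maximum
    return float(spectrum.frequencies[mask][best])


def maximally_spaced_indices(n: int, k: int) -> list[int]:
    """k maximally spaced 1-based positions out of n, extremes included.

    Position i is round(1 + (i-1)(n-1)/(k-1)) with half-up rounding; the
    first and last list positions are always selected.
    """
    if k < 2:
        raise InsufficientDataError("selection size k must be >= 2")
    if n < k:
        raise InsufficientDataError(f"cannot select {k} items from {n}")
    out = [int(math.floor(1 + (i - 1) * (n - 1) / (k - 1) + 0.5))
           for i in range(1, k + 1)]
    assert out[0] == 1 and out[-1] == n and all(
        b > a for a, b in zip(out, out[1:]))
    return out


def select_calls(
    calls: Sequence[Call], k: int, sort_key: Literal["df", "f0"] = "df"
) -> list[Call]:
    """Sort calls ascending by DF (or F0) and keep the maximally spaced k.

    The sort is stable, so equal-frequency calls keep their input order.
    """
    if sort_key == "df":
        keyed = sorted(calls, key=lambda c: c.df)
    else:
        if any(c.f0 is None for c in calls):
            raise InsufficientDataError("every call needs an F0 to sort on")
        keyed = sorted(calls, key=lambda c: c.f0)
    idx = maximally_spaced_indices(len(keyed), k)
    return [keyed[i - 1] for i in idx]


def verify_df(
    call: Call,
    prominence_db: float = 3.0,
) -> bool:
    """Check that the DF bin stands out of the spectrum's noise floor.

    A DF peak no more than ``prominence_db`` above the median spectrum level
    is treated as background-dominated; such a call should be replaced by
    its neighbour in the species' sorted list.
    """
    amps = call.spectrum.amplitudes
    positive = amps[amps > 0]
    if positive.size == 0:
        return False
    median_level = float(np.median(positive))
    peak = float(amps.max())
    if median_level == 0:
        return peak > 0
    return 20.0 * np.log10(peak / median_level) > prominence_db


def replace_unverified(
    sorted_calls: list[Call],
    selected_positions: list[int],
    prominence_db: float = 3.0,
    log: list | None = None,
) -> list[Call]:
    """Swap selected calls that fail the DF prominence check for neighbours.

    Mirrors the manual verification step: a selected call whose DF looks
    like background noise is replaced with the nearest unselected neighbour
    in the species' DF-sorted list that passes the check.
    """
    chosen = {p: sorted_calls[p - 1] for p in selected_positions}
    taken = set(selected_positions)
    n = len(sorted_calls)
    for pos in selected_positions:
        if verify_df(chosen[pos], prominence_db):
            continue
        for offset in range(1, n):
            for cand in (pos - offset, pos + offset):
                if 1 <= cand <= n and cand not in taken and verify_df(
                    sorted_calls[cand - 1], prominence_db
                ):
                    if log is not None:
                        log.append((chosen[pos].call_id,
                                    sorted_calls[cand - 1].call_id))
                    chosen[pos] = sorted_calls[cand - 1]
                    taken.add(cand)
                    break
            else:
                continue
            break
    return [chosen[p] for p in selected_positions]


def species_aggregates(
    species: str,
    body_length_mm: float,
    selected: Sequence[Call],
    f0_calls: Sequence[Call],
    k_main: int = 10,
    k_sub: int = 6,
    min_f0_calls: int = 6,
) -> SpeciesRecord:
    """Compute DF10, DF6 and F06 for one species.

    DF10 is the arithmetic mean DF of the ``k_main`` selected calls.  When
    at least ``min_f0_calls`` calls carry an F0, DF6 averages DF over
    ``k_sub`` calls picked at maximally spaced positions of the DF-sorted
    selection, and F06 averages F0 over ``k_sub`` calls picked the same way
    from the F0-sorted F0-bearing list.  With fewer F0 calls the species
    simply lacks F06/DF6 and drops out of the F0 analyses.  Regressions
    downstream take log10 of these means (log of mean, not mean of logs).
    """
    if len(selected) < k_main:
        raise InsufficientDataError(
            f"{species}: {len(selected)} selected calls, need {k_main}"
        )
    selected = list(selected)[:k_main]
    rec = SpeciesRecord(species, body_length_mm, calls=list(selected))
    rec.df10 = float(np.mean([c.df for c in selected]))
    rec.n_f0_calls = sum(1 for c in f0_calls if c.f0 is not None)
    if rec.n_f0_calls >= min_f0_calls:
        df_sorted = sorted(selected, key=lambda c: c.df)
        sub = [df_sorted[i - 1]
               for i in maximally_spaced_indices(len(df_sorted), k_sub)]
        rec.df6 = float(np.mean([c.df for c in sub]))
        with_f0 = sorted(
            (c for c in f0_calls if c.f0 is not None), key=lambda c: c.f0
        )
        f0_sub = [with_f0[i - 1]
                  for i in maximally_spaced_indices(len(with_f0), k_sub)]
        rec.f06 = float(np.mean([c.f0 for c in f0_sub]))
    return rec
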
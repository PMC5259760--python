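"""Synthetic recordings and simulated comparative data with ground truth.

Calls are built from the source-filter view of mammal vocal production: a
harmonic series at a fundamental F0 with a per-octave amplitude rolloff
(the laryngeal source), optionally shaped by a single second-order
resonance (a formant) that can relocate the spectral maximum onto a higher
harmonic.  Pure tones are a single sinusoid; nontonal calls are band-
limited noise.  Every generator returns its analytic ground truth (true F0,
true DF, true segment boundaries), so the measurement chain can be tested
without any real recordings.

Comparative data are simulated as a Yule tree scaled to unit height plus
log-trait pairs y = a + b x + e with e multivariate normal under a
lambda-transformed Brownian covariance — exactly the generative model the
phylogenetic GLS assumes.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass
from typing import Literal, Optional

import numpy as np

from callometry.audio import AudioClip, Segment
from callometry.errors import ConsistencyError, ParameterError
from callometry.phyloreg import CorrelationModel, Phylogeny, TraitTable, phylo_covariance

__all__ = [
    "CallSpec",
    "RecordingSpec",
    "CladeSimSpec",
    "synthesize_call",
    "synthesize_recording",
    "simulate_clade",
    "yule_tree",
    "make_study",
]


@dataclass(frozen=True)
class CallSpec:
    """Recipe for one synthetic vocalization.

    ``f0_hz`` is either a constant or a (start, end) pair for a linear
    contour; ``formant_hz`` an optional (center, bandwidth) resonance.
    """

    f0_hz: float | tuple[float, float] = 300.0
    n_harmonics: int = 8
    harmonic_rolloff_db_per_octave: float = 6.0
    formant_hz: Optional[tuple[float, float]] = None
    duration_s: float = 0.5
    amplitude: float = 0.8
    kind: Literal["tonal", "pure_tone", "nontonal"] = "tonal"
    noise_band_hz: tuple[float, float] = (500.0, 4000.0)

    def f0_bounds(self) -> tuple[float, float]:
        if isinstance(self.f0_hz, tuple):
            return (min(self.f0_hz), max(self.f0_hz))
        return (self.f0_hz, self.f0_hz)

    def mean_f0(self) -> float:
        lo, hi = self.f0_bounds()
        return 0.5 * (lo + hi)


@dataclass(frozen=True)
class RecordingSpec:
    """Calls at known onsets over broadband background noise."""

    calls: tuple[tuple[CallSpec, float], ...]
    noise_snr_db: float = 20.0
    rate: float = 44100.0
    seed: int = 0
    tail_s: float = 0.5  # silence padded before the first / after the last call


@dataclass(frozen=True)
class CladeSimSpec:
    """A Yule clade with an allometric line of known slope and signal."""

    n_tips: int = 60
    slope: float = -1.7
    intercept: float = 6.1
    sigma: float = 0.35         # residual SD on log10 scale; gives R^2 ~ 0.7
                                # for slope -1.7 over x_range below
    lambda_true: float = 0.9
    x_range: tuple[float, float] = (2.0, 3.1)  # log10 body length (mm)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tips < 5:
            raise ParameterError("n_tips must be >= 5")
        if self.sigma <= 0:
            raise ParameterError("sigma must be > 0")
        if not 0.0 <= self.lambda_true <= 1.0:
            raise ParameterError("lambda_true must lie in [0, 1]")


def _resonance_gain(f: np.ndarray | float, center: float, bandwidth: float):
    """Magnitude response of a second-order resonator at frequency f."""
    q = center / bandwidth
    f = np.asarray(f, dtype=float)
    return 1.0 / np.sqrt((1.0 - (f / center) ** 2) ** 2 + (f / (center * q)) ** 2)


def _ramp(n_samples: int, rate: float, ramp_s: float = 0.01) -> np.ndarray:
    """Raised-cosine onset/offset envelope."""
    env = np.ones(n_samples)
    nr = min(int(round(ramp_s * rate)), n_samples // 2)
    if nr > 0:
        r = 0.5 * (1 - np.cos(np.pi * np.arange(nr) / nr))
        env[:nr] = r
        env[-nr:] = r[::-1]
    return env


def synthesize_call(
    spec: CallSpec, rate: float, rng: Optional[np.random.Generator] = None
) -> tuple[AudioClip, dict]:
    """Render one call and return it with its analytic ground truth.

    The truth dict carries ``f0`` (mean fundamental, None for nontonal
    calls) and ``df`` (the harmonic carrying maximum energy after formant
    shaping, ties to the lower harmonic; band centre for nontonal calls).
    """
    n = int(round(spec.duration_s * rate))
    if n < 2:
        raise ParameterError("call duration too short for the rate")
    nyquist = rate / 2.0

    if spec.kind == "nontonal":
        rng = rng or np.random.default_rng(0)
        from scipy.signal import butter, sosfilt

        lo, hi = spec.noise_band_hz
        if hi >= nyquist:
            raise ParameterError("noise band exceeds the Nyquist rate")
        sos = butter(4, [lo, hi], btype="band", fs=rate, output="sos")
        x = sosfilt(sos, rng.standard_normal(n))
        truth = {"f0": None, "df": 0.5 * (lo + hi)}
    else:
        lo_f0, hi_f0 = spec.f0_bounds()
        # linear contour: instantaneous phase is the integral of f(t)
        f_inst = np.linspace(
            spec.f0_hz[0] if isinstance(spec.f0_hz, tuple) else spec.f0_hz,
            spec.f0_hz[1] if isinstance(spec.f0_hz, tuple) else spec.f0_hz,
            n,
        )
        phase = 2.0 * np.pi * np.cumsum(f_inst) / rate
        if spec.kind == "pure_tone":
            x = np.sin(phase)
            truth = {"f0": spec.mean_f0(), "df": spec.mean_f0()}
        else:
            if spec.n_harmonics * hi_f0 >= nyquist:
                raise ParameterError(
                    f"harmonic {spec.n_harmonics} x {hi_f0} Hz is above Nyquist")
            harmonics = np.arange(1, spec.n_harmonics + 1)
            amps = 10.0 ** (
                -spec.harmonic_rolloff_db_per_octave * np.log2(harmonics) / 20.0
            )
            if spec.formant_hz is not None:
                center, bw = spec.formant_hz
                amps = amps * _resonance_gain(
                    harmonics * spec.mean_f0(), center, bw)
            x = np.zeros(n)
            for h, a in zip(harmonics, amps):
                x += a * np.sin(h * phase)
            best = int(np.argmax(amps))  # first maximum -> lower harmonic
            truth = {"f0": spec.mean_f0(),
                     "df": float(harmonics[best] * spec.mean_f0())}

    x = x * _ramp(n, rate)
    peak = np.max(np.abs(x))
    if peak > 0:
        x = x * (spec.amplitude / peak)
    return AudioClip(x, rate, "synthetic_call"), truth


def synthesize_recording(
    spec: RecordingSpec,
) -> tuple[AudioClip, list[Segment], list[dict]]:
    """Place calls at their onsets over Gaussian noise at a known SNR.

    Returns the clip, the true segments (sample spans of each call), and
    the per-call ground-truth dicts.  Bit-identical for identical specs.
    """
    rate = spec.rate
    onsets = [onset for _, onset in spec.calls]
    if onsets != sorted(onsets):
        raise ConsistencyError("call onsets must be sorted")
    rng = np.random.default_rng(spec.seed)
    rendered: list[tuple[int, np.ndarray, dict]] = []
    end_s = spec.tail_s
    prev_end = 0.0
    for call_spec, onset in spec.calls:
        if onset < prev_end:
            raise ConsistencyError(
                f"call at {onset}s overlaps the previous call")
        clip, truth = synthesize_call(call_spec, rate, rng)
        start = int(round((onset + spec.tail_s) * rate))
        rendered.append((start, clip.samples, truth))
        prev_end = onset + call_spec.duration_s
        end_s = max(end_s, onset + call_spec.duration_s + spec.tail_s)
    n = int(round((end_s + spec.tail_s) * rate))
    samples = np.zeros(n)
    segments = []
    truths = []
    for start, call_samples, truth in rendered:
        samples[start:start + len(call_samples)] += call_samples
        segments.append(Segment(start, start + len(call_samples), "synthetic"))
        truths.append(truth)
    # SNR is an intensity (power-like) ratio: the background's smoothed
    # intensity sits noise_snr_db below the mean call intensity, where the
    # intensity of Gaussian noise of SD sigma is E|x| = sigma * sqrt(2/pi).
    if rendered:
        call_intensity = float(np.mean(
            np.abs(np.concatenate([c for _, c, _ in rendered]))))
    else:
        call_intensity = 0.25
    noise_intensity = call_intensity * 10.0 ** (-spec.noise_snr_db / 10.0)
    sigma = noise_intensity / math.sqrt(2.0 / math.pi)
    samples = samples + sigma * rng.standard_normal(n)
    peak = np.max(np.abs(samples))
    if peak > 1.0:
        samples = samples / peak
    return AudioClip(samples, rate, "synthetic_recording"), segments, truths


def yule_tree(
    n_tips: int, seed: int, return_newick: bool = False
) -> Phylogeny | tuple[Phylogeny, str]:
    """Simulate a pure-birth tree and scale it to unit height."""
    from dendropy.simulate import treesim

    py_rng = random.Random(seed)
    tree = treesim.birth_death_tree(
        birth_rate=1.0,
        death_rate=0.0,
        num_extant_tips=n_tips,
        rng=py_rng,
    )
    # the simulation stops exactly at the n-th birth, leaving the newborn
    # pair with zero-length tips; run the clock one more exponential
    # waiting time so every terminal branch is positive (keeps ultrametry)
    extra = py_rng.expovariate(n_tips * 1.0)
    for i, leaf in enumerate(tree.leaf_node_iter()):
        leaf.taxon.label = f"sp{i + 1:03d}"
        leaf.edge.length = (leaf.edge.length or 0.0) + extra
    h = Phylogeny.from_dendropy(tree).height
    if h <= 0:
        raise ParameterError("degenerate simulated tree")
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length = edge.length / h
    phylo = Phylogeny.from_dendropy(tree)
    if return_newick:
        newick = tree.as_string(schema="newick").strip()
        return phylo, newick
    return phylo


def simulate_clade(
    spec: CladeSimSpec,
) -> tuple[Phylogeny, TraitTable, dict]:
    """Simulate a clade's tree and allometric trait pairs.

    x (log10 body length, mm) is uniform over ``x_range``; the residual of
    y = intercept + slope * x is multivariate normal with covariance
    sigma^2 times the lambda-transformed unit-height Brownian matrix.
    """
    tree = yule_tree(spec.n_tips, spec.seed)
    rng = np.random.default_rng(spec.seed + 1)
    x = rng.uniform(*spec.x_range, size=spec.n_tips)
    V = phylo_covariance(
        tree, CorrelationModel("BM_lambda", spec.lambda_true))
    L = np.linalg.cholesky(V + 1e-12 * np.eye(spec.n_tips))
    resid = spec.sigma * (L @ rng.standard_normal(spec.n_tips))
    y = spec.intercept + spec.slope * x + resid
    table = TraitTable(list(tree.tip_names), x, y)
    truth = {"slope": spec.slope, "intercept": spec.intercept,
             "sigma": spec.sigma, "lambda": spec.lambda_true}
    return tree, table, truth


def make_study(
    out_dir: str,
    n_species: int = 12,
    calls_per_species: int = 120,
    slope: float = -1.0,
    intercept: float = 5.3,
    species_scatter: float = 0.05,
    call_jitter: float = 0.02,
    noise_snr_db: float = 20.0,
    rate: float = 22050.0,
    seed: int = 0,
    calls_per_file: int = 20,
) -> dict:
    """Write a complete synthetic study to disk and return its ground truth.

    Species body lengths span log10 BL in [2.0, 3.1] mm and each species'
    characteristic F0 follows log10 F0 = intercept + slope * log10 BL plus
    N(0, species_scatter) residual scatter; individual calls jitter around
    the species F0 by a lognormal factor of SD ``call_jitter`` (log10).
    Roughly 70% of calls are plain tonal (DF = F0), 20% carry a formant on
    the 2nd or 3rd harmonic, and 10% are nontonal noise bursts in a band
    scaled to the species F0 — emulating the mix of call types a real
    repertoire shows while keeping every ground-truth value known.

    Writes per-species WAV recordings, traits.csv, tree.nwk, config.json
    (with per-species pitch floor/ceiling overrides standing in for manual
    per-call tuning) and ground_truth.json.
    """
    import json
    import os

    from callometry.audio import write_audio

    os.makedirs(out_dir, exist_ok=True)
    audio_dir = os.path.join(out_dir, "audio")
    os.makedirs(audio_dir, exist_ok=True)
    rng = np.random.default_rng(seed)
    tree, newick = yule_tree(n_species, seed, return_newick=True)
    species = list(tree.tip_names)
    log_bl = np.linspace(2.0, 3.1, n_species)
    rng.shuffle(log_bl)
    log_f0 = intercept + slope * log_bl + species_scatter * rng.standard_normal(n_species)
    f0s = 10.0 ** log_f0

    truth = {"slope": slope, "intercept": intercept, "species": {}}
    overrides = {}
    trait_rows = []
    for i, sp in enumerate(species):
        f0 = float(f0s[i])
        bl = float(10.0 ** log_bl[i])
        trait_rows.append((sp, bl, "A" if i % 2 == 0 else "B"))
        overrides[sp] = {
            "floor_hz": round(max(40.0, 0.45 * f0), 2),
            "ceiling_hz": round(min(rate / 2 - 1, 2.5 * f0), 2),
        }
        kinds = rng.permutation(
            ["tonal"] * (calls_per_species - calls_per_species // 5
                         - calls_per_species // 10)
            + ["formant"] * (calls_per_species // 5)
            + ["nontonal"] * (calls_per_species // 10)
        )
        call_specs = []
        call_truth = []
        for kind in kinds:
            f0_call = f0 * 10.0 ** (call_jitter * rng.standard_normal())
            dur = float(rng.uniform(0.25, 0.4))
            if kind == "nontonal":
                cs = CallSpec(kind="nontonal", duration_s=dur,
                              noise_band_hz=(1.5 * f0_call,
                                             min(5.0 * f0_call, rate / 2 - 1)))
            elif kind == "formant":
                harm = int(rng.integers(2, 4))
                n_h = max(harm + 3, 6)
                while n_h * f0_call >= rate / 2:
                    n_h -= 1
                cs = CallSpec(f0_hz=f0_call, n_harmonics=max(n_h, harm),
                              harmonic_rolloff_db_per_octave=6.0,
                              formant_hz=(harm * f0_call, 0.4 * f0_call),
                              duration_s=dur)
            else:
                n_h = 8
                while n_h * f0_call >= rate / 2:
                    n_h -= 1
                cs = CallSpec(f0_hz=f0_call, n_harmonics=max(n_h, 1),
                              harmonic_rolloff_db_per_octave=6.0,
                              duration_s=dur)
            call_specs.append(cs)
        # split into recordings with ample gaps between calls
        n_files = math.ceil(len(call_specs) / calls_per_file)
        file_truths = []
        for j in range(n_files):
            chunk = call_specs[j * calls_per_file:(j + 1) * calls_per_file]
            onsets = []
            t = 0.0
            for cs in chunk:
                onsets.append(t)
                t += cs.duration_s + 0.9
            rec = RecordingSpec(calls=tuple(zip(chunk, onsets)),
                                noise_snr_db=noise_snr_db, rate=rate,
                                seed=int(rng.integers(0, 2**31 - 1)))
            clip, segs, truths_j = synthesize_recording(rec)
            write_audio(os.path.join(audio_dir, f"{sp}__{j:02d}.wav"), clip)
            file_truths.extend(truths_j)
            call_truth.extend(truths_j)
        truth["species"][sp] = {
            "body_length_mm": bl, "f0_hz": f0,
            "n_calls": len(call_specs),
            "n_tonal": int(sum(1 for k in kinds if k != "nontonal")),
        }

    import pandas as pd

    pd.DataFrame(trait_rows, columns=["species", "body_length_mm", "group"]
                 ).to_csv(os.path.join(out_dir, "traits.csv"), index=False)
    with open(os.path.join(out_dir, "tree.nwk"), "w") as fh:
        fh.write(newick + "\n")
    config = {
        "audio_dir": audio_dir,
        "trait_csv": os.path.join(out_dir, "traits.csv"),
        "tree_file": os.path.join(out_dir, "tree.nwk"),
        "output_dir": os.path.join(out_dir, "results"),
        "pitch_overrides": overrides,
        "seed": seed,
    }
    with open(os.path.join(out_dir, "config.json"), "w") as fh:
        json.dump(config, fh, indent=2)
    with open(os.path.join(out_dir, "ground_truth.json"), "w") as fh:
        json.dump(truth, fh, indent=2)
    return truth


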
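"""End-to-end orchestration: audio directory in, regression tables out.

The full analysis runs segment -> SNR triage -> maximally-spaced selection
-> DF verification -> pitch -> species aggregates (DF10 / DF6 / F06 with
the >= 6 F0-calls rule) -> log10 + normality check -> OLS and five GLS
candidate structures -> AICc selection -> bisector -> ANCOVA -> DF/F0 ratio
analysis, and writes per-call, per-species and per-regression CSVs plus a
JSON manifest recording the counts surviving every filter stage.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from callometry.audio import (
    AudioClip,
    SegmentationParams,
    extract,
    intensity_envelope,
    read_audio,
    segment,
    snr_filter,
)
from callometry.errors import CallometryError
from callometry.phyloreg import (
    CANDIDATE_KINDS,
    Phylogeny,
    TraitTable,
    ancova_slopes,
    bisector,
    fit_candidates,
    gls_fit,
    normalize_name,
    ols_fit,
    select_model,
    shapiro_wilk,
)
from callometry.pitch import (
    PitchParams,
    call_f0,
    classify_tonality,
    estimate_pitch,
    ratio_analysis,
    size_vs_equal_proportion,
)
from callometry.spectral import (
    Call,
    dominant_frequency,
    maximally_spaced_indices,
    replace_unverified,
    species_aggregates,
    whole_call_spectrum,
)

logger = logging.getLogger("callometry")

__all__ = [
    "BodySizeEntry",
    "RunConfig",
    "body_length_mean",
    "run_all",
    "measure_calls",
]


@dataclass(frozen=True)
class BodySizeEntry:
    """Published body-length data for one species.

    Either an overall (min, max) length range, per-sex ranges, or per-sex
    standing heights with sitting ratios (the route used for humans, whose
    reference reports stature rather than crown-rump length).
    """

    species: str
    range_mm: Optional[tuple[float, float]] = None
    male_range_mm: Optional[tuple[float, float]] = None
    female_range_mm: Optional[tuple[float, float]] = None
    standing_height_mm: Optional[tuple[float, float]] = None  # (male, female)
    sitting_ratio: Optional[tuple[float, float]] = None       # (male, female)


def _midpoint(rng: tuple[float, float]) -> float:
    lo, hi = rng
    if not 0 < lo <= hi:
        raise CallometryError(f"invalid length range {rng}")
    return 0.5 * (lo + hi)


def body_length_mean(entry: BodySizeEntry) -> float:
    """Convert published length ranges to a single species mean (mm).

    Overall ranges become midpoints; sex-specific ranges become the mean of
    the two sex midpoints; standing heights are multiplied by per-sex
    sitting ratios, then sex-averaged.
    """
    if entry.range_mm is not None:
        return _midpoint(entry.range_mm)
    if entry.male_range_mm is not None and entry.female_range_mm is not None:
        return 0.5 * (_midpoint(entry.male_range_mm)
                      + _midpoint(entry.female_range_mm))
    if entry.standing_height_mm is not None and entry.sitting_ratio is not None:
        heights = entry.standing_height_mm
        ratios = entry.sitting_ratio
        return 0.5 * (heights[0] * ratios[0] + heights[1] * ratios[1])
    raise CallometryError(f"no body-length data for species {entry.species!r}")


@dataclass
class RunConfig:
    """Everything a full pipeline run needs, loadable from JSON."""

    audio_dir: str
    trait_csv: str
    tree_file: Optional[str]
    output_dir: str
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    pitch: PitchParams = field(default_factory=PitchParams)
    pitch_overrides: dict[str, dict] = field(default_factory=dict)
    selection_k: int = 10
    min_f0_calls: int = 6
    df_floor_hz: float = 20.0
    df_prominence_db: float = 3.0
    candidate_models: Sequence[str] = CANDIDATE_KINDS
    criterion: str = "REML"
    seed: int = 0
    schema_version: int = 1

    @classmethod
    def from_json(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = json.load(fh)
        raw.pop("schema_version", None)
        seg = SegmentationParams(**raw.pop("segmentation", {}))
        pitch = PitchParams(**raw.pop("pitch", {}))
        return cls(segmentation=seg, pitch=pitch, **raw)

    def to_json(self, path: str) -> None:
        raw = dataclasses.asdict(self)
        with open(path, "w") as fh:
            json.dump(raw, fh, indent=2, default=list)

    def pitch_for(self, species: str) -> PitchParams:
        ov = self.pitch_overrides.get(species) or self.pitch_overrides.get(
            normalize_name(species))
        if not ov:
            return self.pitch
        return dataclasses.replace(self.pitch, **ov)


def _species_of(path: str) -> str:
    """Species label from a file name like `<species>__take3.wav`."""
    stem = os.path.splitext(os.path.basename(path))[0]
    return stem.split("__")[0]


def measure_calls(
    clip: AudioClip,
    config: RunConfig,
    species: str,
    counts: Optional[dict] = None,
) -> list[Call]:
    """Segment one recording and measure DF for every surviving call."""
    env = intensity_envelope(clip, config.segmentation)
    segs = segment(env, config.segmentation, clip.source_id)
    if counts is not None:
        counts["segments"] = counts.get("segments", 0) + len(segs)
    dropped: list = []
    segs = snr_filter(clip, segs, config.segmentation.snr_cutoff_db, dropped)
    for seg, snr in dropped:
        logger.info("triage: dropped %s [%d, %d) at %.1f dB",
                    clip.source_id, seg.start, seg.end, snr)
    if counts is not None:
        counts["high_snr"] = counts.get("high_snr", 0) + len(segs)
    calls = []
    for i, sub in enumerate(extract(clip, segs)):
        spectrum = whole_call_spectrum(sub)
        df = dominant_frequency(spectrum, config.df_floor_hz)
        calls.append(Call(sub, spectrum, df, call_id=sub.source_id))
    return calls


def _analyze_pair(
    table: TraitTable,
    tree: Optional[Phylogeny],
    config: RunConfig,
) -> dict:
    """OLS + candidate GLS + AICc selection + bisector for one (x, y) set."""
    out: dict = {}
    ols = ols_fit(table)
    out["OLS"] = ols
    fits = fit_candidates(table, tree, tuple(config.candidate_models),
                          "y_on_x", config.criterion)
    comp = select_model(fits, table.n)
    out["aicc"] = comp.aicc
    out["best_kind"] = comp.best_kind
    best_yx = comp.best
    best_xy = gls_fit(table, tree, best_yx.model, "x_on_y_expressed",
                      config.criterion)
    out["y_on_x"] = best_yx
    out["x_on_y"] = best_xy
    out["bisector"] = bisector(best_yx, best_xy)
    return out


def _fit_rows(name: str, result: dict) -> list[dict]:
    rows = []
    for label, key in (("OLS", "OLS"),
                       (f"Y-on-X ({result['best_kind']})", "y_on_x"),
                       (f"X-on-Y ({result['best_kind']})", "x_on_y")):
        f = result[key]
        theta = f.model.theta if f.model.n_theta else None
        rows.append({
            "analysis": name, "model": label,
            "slope": round(f.slope, 3), "slope_se": round(f.slope_se, 3),
            "intercept": round(f.intercept, 3),
            "intercept_se": round(f.intercept_se, 3),
            "r2": round(f.r2, 3) if f.r2 is not None else None,
            "lambda": round(theta, 3) if theta is not None else None,
            "t": round(f.t, 2), "df": f.df,
            "p": float(f"{f.p:.3g}"),
        })
    b = result["bisector"]
    rows.append({"analysis": name, "model": "Bisector",
                 "slope": round(b.slope, 2),
                 "intercept": round(b.intercept, 2)})
    return rows


def run_all(config: RunConfig) -> dict:
    """Execute the full pipeline and write its result bundle.

    Returns a manifest dict (also written as JSON) whose ``counts`` section
    records the number of items surviving each filter stage.
    """
    os.makedirs(config.output_dir, exist_ok=True)
    counts: dict = {"files": 0, "segments": 0, "high_snr": 0}

    traits = pd.read_csv(config.trait_csv)
    body = {normalize_name(r["species"]): float(r["body_length_mm"])
            for _, r in traits.iterrows()}
    groups = ({normalize_name(r["species"]): str(r["group"])
               for _, r in traits.iterrows()}
              if "group" in traits.columns else None)

    wavs = sorted(
        os.path.join(config.audio_dir, f)
        for f in os.listdir(config.audio_dir) if f.lower().endswith(".wav")
    )
    if not wavs:
        raise CallometryError(f"no WAV files under {config.audio_dir}")
    by_species: dict[str, list[Call]] = {}
    for path in wavs:
        sp = normalize_name(_species_of(path))
        if sp not in body:
            raise CallometryError(
                f"audio file {path} names unknown species {sp!r}")
        clip = read_audio(path)
        counts["files"] += 1
        by_species.setdefault(sp, []).extend(
            measure_calls(clip, config, sp, counts))

    # per-species selection, DF verification, pitch, aggregates
    records = []
    per_call_rows = []
    ratio_calls: list[Call] = []
    ratio_species: list[str] = []
    counts["selected"] = 0
    counts["f0_measured"] = 0
    for sp, calls in sorted(by_species.items()):
        if len(calls) < config.selection_k:
            logger.warning("%s: only %d calls, need %d — skipped",
                           sp, len(calls), config.selection_k)
            continue
        df_sorted = sorted(calls, key=lambda c: c.df)
        positions = maximally_spaced_indices(len(df_sorted), config.selection_k)
        swap_log: list = []
        selected = replace_unverified(df_sorted, positions,
                                      config.df_prominence_db, swap_log)
        for old, new in swap_log:
            logger.info("%s: DF verification replaced %s with %s", sp, old, new)
        counts["selected"] += len(selected)
        pparams = config.pitch_for(sp)
        measured = []
        for call in selected:
            try:
                track = estimate_pitch(call.clip, pparams)
            except CallometryError:
                measured.append(call)
                continue
            tone = classify_tonality(call.clip, track)
            f0 = call_f0(track) if tone in ("tonal", "pure_tone") else None
            measured.append(dataclasses.replace(
                call, tonality=tone, f0=f0,
                voiced_fraction=track.voiced_fraction))
        f0_calls = [c for c in measured if c.f0 is not None]
        counts["f0_measured"] += len(f0_calls)
        rec = species_aggregates(sp, body[sp], measured, f0_calls,
                                 config.selection_k, 6, config.min_f0_calls)
        records.append(rec)
        for c in measured:
            per_call_rows.append({
                "call_id": c.call_id, "species": sp,
                "duration_s": round(c.clip.duration_s, 4),
                "resolution_hz": round(c.spectrum.resolution, 3),
                "df_hz": round(c.df, 2), "tonality": c.tonality,
                "f0_hz": round(c.f0, 2) if c.f0 is not None else None,
                "voiced_fraction": round(c.voiced_fraction, 3),
            })
        if rec.f06 is not None:
            f0_sorted = sorted(f0_calls, key=lambda c: c.f0)
            idx = maximally_spaced_indices(len(f0_sorted), 6)
            for c in (f0_sorted[i - 1] for i in idx):
                ratio_calls.append(c)
                ratio_species.append(sp)

    pd.DataFrame(per_call_rows).to_csv(
        os.path.join(config.output_dir, "calls.csv"), index=False)
    sp_rows = [{
        "species": r.species, "body_length_mm": r.body_length_mm,
        "n_selected": len(r.calls), "df10_hz": r.df10, "df6_hz": r.df6,
        "f06_hz": r.f06, "n_f0_calls": r.n_f0_calls,
    } for r in records]
    pd.DataFrame(sp_rows).to_csv(
        os.path.join(config.output_dir, "species.csv"), index=False)
    counts["species_df10"] = len(records)
    counts["species_f06"] = sum(1 for r in records if r.f06 is not None)

    tree = (Phylogeny.from_newick(config.tree_file, from_path=True)
            if config.tree_file else None)

    manifest: dict = {
        "schema_version": config.schema_version,
        "seed": config.seed,
        "counts": counts,
        "normality": {},
        "regressions": {},
    }
    reg_rows = []
    analyses = {
        "logDF10": [(r.species, r.body_length_mm, r.df10) for r in records],
        "logDF6": [(r.species, r.body_length_mm, r.df6)
                   for r in records if r.df6 is not None],
        "logF06": [(r.species, r.body_length_mm, r.f06)
                   for r in records if r.f06 is not None],
    }
    for name, rows in analyses.items():
        if len(rows) < 5:
            logger.warning("%s: too few species (%d) — skipped", name, len(rows))
            continue
        species = [r[0] for r in rows]
        x = np.log10([r[1] for r in rows])
        y = np.log10([r[2] for r in rows])
        for var, vals in (("logBL", x), (name, y)):
            w, p = shapiro_wilk(vals)
            manifest["normality"][f"{name}:{var}"] = {"W": round(w, 4),
                                                      "P": round(p, 4)}
        table = TraitTable(species, x, y,
                           [groups[s] for s in species] if groups else None)
        result = _analyze_pair(table, tree, config)
        reg_rows.extend(_fit_rows(name, result))
        entry = {
            "aicc": {k: round(v, 3) for k, v in result["aicc"].items()},
            "best_model": result["best_kind"],
            "bisector_slope": round(result["bisector"].slope, 2),
            "bisector_intercept": round(result["bisector"].intercept, 2),
        }
        if groups and len(set(table.group)) == 2:
            F, dfs, p = ancova_slopes(table)
            entry["ancova"] = {"F": round(F, 2), "df": list(dfs),
                               "P": float(f"{p:.3g}")}
        manifest["regressions"][name] = entry

    pd.DataFrame(reg_rows).to_csv(
        os.path.join(config.output_dir, "regressions.csv"), index=False)

    if ratio_calls:
        skipped: list = []
        rec_list, props = ratio_analysis(ratio_calls, ratio_species, skipped)
        pd.DataFrame([dataclasses.asdict(r) for r in rec_list]).to_csv(
            os.path.join(config.output_dir, "ratios.csv"), index=False)
        manifest["ratio"] = {
            "n_calls": len(rec_list),
            "prop_equal_overall": round(
                sum(1 for r in rec_list if r.category == "equal")
                / len(rec_list), 3),
        }
        if len(props) >= 5:
            bl = [body[sp] for sp in props]
            r, p = size_vs_equal_proportion(list(props.values()), bl)
            manifest["ratio"]["spearman_r"] = round(r, 3)
            manifest["ratio"]["spearman_p"] = float(f"{p:.3g}")

    cfg_hash = hashlib.sha256(
        json.dumps(dataclasses.asdict(config), sort_keys=True,
                   default=list).encode()).hexdigest()[:16]
    manifest["config_sha256"] = cfg_hash
    with open(os.path.join(config.output_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
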
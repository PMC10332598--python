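"""Synthetic vocal repertoires with known ground truth.

Real repertoire corpora are large downloads; this module emulates their
structure so every pipeline stage is testable end to end.  A repertoire is
``n_types`` unit types, each a harmonic stack following a spectro-temporal
contour (constant tone, linear chirp, or sinusoidal frequency modulation)
with an amplitude envelope.  Units are jittered per draw (multiplicative
log-normal-ish jitter on frequencies and duration), placed on a
silence-gapped timeline, and mixed with background noise at a controlled
per-unit SNR.  The rendered output is exactly what the preprocessing stage
consumes: PCM WAV files plus an annotation CSV carrying the true centre,
duration and type label of every unit.

What this emulates: discrete, well-separated unit types with intra-type
variability and stationary background noise.  What it does not: real
species' spectro-temporal richness, reverberation, overlapping units or
non-stationary soundscapes — results on synthetic repertoires bound what
the pipeline can do under ideal detection, not field performance.

All randomness flows from one seed through per-unit counter-based streams
(``default_rng([seed, unit_index])``), so any single unit can be
regenerated in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .annotations import write_annotations
from .audio import write_wav

__all__ = ["UnitTypeSpec", "RepertoireSpec", "synth_unit", "render_dataset",
           "example_repertoire"]

#: Background-noise RMS in the rendered mix; units are scaled against it.
NOISE_RMS = 0.01


@dataclass
class UnitTypeSpec:
    """One vocalisation type: a contour template plus duration statistics."""

    label: str
    contour: str = "constant"  # constant | chirp | fm
    f_start: float = 2000.0
    f_end: float = 2000.0
    n_harmonics: int = 1
    duration_mean: float = 0.07
    duration_sd: float = 0.007
    envelope: str = "hann"  # hann | flat
    fm_cycles: float = 3.0  # full modulation cycles per unit (contour="fm")

    def __post_init__(self) -> None:
        if self.contour not in ("constant", "chirp", "fm"):
            raise ValueError(f"unknown contour {self.contour!r}")
        if self.envelope not in ("hann", "flat"):
            raise ValueError(f"unknown envelope {self.envelope!r}")
        if self.duration_mean <= 0:
            raise ValueError("duration_mean must be positive")


@dataclass
class RepertoireSpec:
    """A full synthetic repertoire: types, jitter, noise and sampling rate."""

    types: list[UnitTypeSpec]
    fs: float = 32_000.0
    jitter: float = 0.02  # fractional sd applied to frequencies and durations
    snr_db: float = 20.0
    noise: str = "white"  # white | pink
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.types) < 1:
            raise ValueError("need at least one unit type")
        if self.noise not in ("white", "pink"):
            raise ValueError(f"unknown noise colour {self.noise!r}")
        for t in self.types:
            if t.n_harmonics * max(t.f_start, t.f_end) >= self.fs / 2:
                raise ValueError(
                    f"type {t.label!r}: harmonic {t.n_harmonics} of "
                    f"{max(t.f_start, t.f_end):.0f} Hz reaches Nyquist ({self.fs / 2:.0f} Hz)"
                )

    def as_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, doc: dict) -> "RepertoireSpec":
        doc = dict(doc)
        doc["types"] = [UnitTypeSpec(**t) for t in doc["types"]]
        return cls(**doc)


def synth_unit(type_spec: UnitTypeSpec, jitter_draw: tuple[float, float],
               fs: float) -> np.ndarray:
    """Render one unit waveform, peak-normalised.

    ``jitter_draw = (freq_factor, dur_factor)`` multiplies the contour
    frequencies and the mean duration, making the unit a deterministic
    function of (spec, draw, fs).  Harmonic ``h`` has amplitude ``1/h``.
    """
    freq_factor, dur_factor = jitter_draw
    duration = type_spec.duration_mean * dur_factor
    n = max(int(round(duration * fs)), 8)
    t = np.arange(n) / fs
    f0, f1 = type_spec.f_start * freq_factor, type_spec.f_end * freq_factor
    if type_spec.contour == "constant":
        inst_f = np.full(n, f0)
    elif type_spec.contour == "chirp":
        inst_f = f0 + (f1 - f0) * t / (n / fs)
    else:  # sinusoidal FM around the band centre
        center, dev = (f0 + f1) / 2.0, abs(f1 - f0) / 2.0
        inst_f = center + dev * np.sin(2 * np.pi * type_spec.fm_cycles * t / (n / fs))
    if type_spec.n_harmonics * inst_f.max() >= fs / 2:
        raise ValueError(
            f"aliasing: harmonic {type_spec.n_harmonics} of {inst_f.max():.0f} Hz "
            f"reaches Nyquist ({fs / 2:.0f} Hz)"
        )
    phase = 2 * np.pi * np.cumsum(inst_f) / fs
    wave = sum(np.sin(h * phase) / h for h in range(1, type_spec.n_harmonics + 1))
    if type_spec.envelope == "hann":
        wave = wave * np.hanning(n)
    peak = np.abs(wave).max()
    return wave / peak if peak > 0 else wave


def _noise(rng: np.random.Generator, n: int, colour: str) -> np.ndarray:
    white = rng.standard_normal(n)
    if colour == "white":
        out = white
    else:  # pink: shape the spectrum by 1/sqrt(f)
        spectrum = np.fft.rfft(white)
        f = np.fft.rfftfreq(n)
        f[0] = f[1]
        out = np.fft.irfft(spectrum / np.sqrt(f), n=n)
    return out / out.std()


def render_dataset(
    spec: RepertoireSpec,
    n_per_type: int,
    out_dir: str | Path,
    seed: int | None = None,
    gap_s: float = 0.15,
    filename: str = "repertoire.wav",
) -> pd.DataFrame:
    """Render a repertoire to a WAV file + annotation CSV with true labels.

    Units are laid out type-interleaved on a single timeline with silent
    gaps of ``gap_s`` (± up to 40%).  Each unit is scaled so its RMS sits
    ``snr_db`` decibels above the background-noise RMS; with
    ``snr_db = inf`` no noise is added and units keep their peak-normalised
    amplitude.  Returns the annotation table (also written to
    ``annotations.csv`` alongside the WAV).
    """
    seed = spec.seed if seed is None else seed
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    fs = spec.fs

    pieces: list[np.ndarray] = []
    rows = []
    cursor = int(round(gap_s * fs))
    unit_index = 0
    for rep in range(n_per_type):
        for type_spec in spec.types:
            rng = np.random.default_rng([seed, unit_index])
            draw = (
                float(np.exp(rng.normal(0.0, spec.jitter))),
                float(np.exp(rng.normal(0.0, spec.jitter))),
            )
            wave = synth_unit(type_spec, draw, fs)
            if np.isfinite(spec.snr_db):
                rms = np.sqrt(np.mean(wave**2))
                wave = wave * (NOISE_RMS * 10 ** (spec.snr_db / 20.0) / rms)
            start = cursor
            pieces.append((start, wave))
            rows.append({
                "filename": filename,
                "center_s": (start + len(wave) / 2) / fs,
                "duration_s": len(wave) / fs,
                "label": type_spec.label,
            })
            gap = gap_s * (1.0 + 0.4 * (rng.uniform() - 0.5))
            cursor = start + len(wave) + int(round(gap * fs))
            unit_index += 1

    total = cursor + int(round(gap_s * fs))
    signal = np.zeros(total)
    for start, wave in pieces:
        signal[start : start + len(wave)] += wave
    if np.isfinite(spec.snr_db):
        noise_rng = np.random.default_rng([seed, 2**20])
        signal += NOISE_RMS * _noise(noise_rng, total, spec.noise)

    write_wav(out_dir / filename, signal, fs)
    table = pd.DataFrame(rows)
    write_annotations(table, out_dir / "annotations.csv")
    return table


def example_repertoire(
    n_types: int = 6,
    snr_db: float = 20.0,
    jitter: float = 0.02,
    fs: float = 32_000.0,
    seed: int = 0,
    graded: bool = False,
) -> RepertoireSpec:
    """A ready-made repertoire of well-separated (or deliberately graded) types.

    The discrete mode spreads contours across the band with low jitter —
    the regime where a repertoire is genuinely categorical.  ``graded=True``
    instead crowds overlapping contours into one band with heavy jitter,
    emulating a graded repertoire whose types blur into a continuum (both
    clusterability and label agreement should drop).
    """
    if graded:
        base = [
            UnitTypeSpec(f"type{i}", contour="chirp",
                         f_start=3000.0 + 300.0 * i, f_end=4000.0 + 300.0 * i,
                         n_harmonics=1, duration_mean=0.07, duration_sd=0.02)
            for i in range(n_types)
        ]
        return RepertoireSpec(types=base, fs=fs, jitter=max(jitter, 0.25),
                              snr_db=snr_db, seed=seed)
    palette = [
        UnitTypeSpec("type0", contour="constant", f_start=2000, f_end=2000,
                     n_harmonics=3, duration_mean=0.07),
        UnitTypeSpec("type1", contour="chirp", f_start=3000, f_end=6000,
                     n_harmonics=2, duration_mean=0.06),
        UnitTypeSpec("type2", contour="fm", f_start=3200, f_end=4800,
                     n_harmonics=2, duration_mean=0.08),
        UnitTypeSpec("type3", contour="constant", f_start=9000, f_end=9000,
                     n_harmonics=1, duration_mean=0.05),
        UnitTypeSpec("type4", contour="chirp", f_start=12000, f_end=7000,
                     n_harmonics=1, duration_mean=0.07),
        UnitTypeSpec("type5", contour="constant", f_start=5000, f_end=5000,
                     n_harmonics=3, duration_mean=0.09),
        UnitTypeSpec("type6", contour="chirp", f_start=1000, f_end=2500,
                     n_harmonics=4, duration_mean=0.08),
        UnitTypeSpec("type7", contour="fm", f_start=10000, f_end=13000,
                     n_harmonics=1, duration_mean=0.06),
    ]
    if n_types > len(palette):
        raise ValueError(f"at most {len(palette)} distinct example types available")
    return RepertoireSpec(types=palette[:n_types], fs=fs, jitter=jitter,
                          snr_db=snr_db, seed=seed)
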
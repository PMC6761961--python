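"""Windowed male/female read-depth sex-linkage detection.

A hemizygous (male-specific) X region shows half the male read depth of the
female sample (log2 M/F near -1); pseudoautosomal segments and autosomes show
equal depth (log2 near 0).  Windows default to 100 kb on autosomes and 10 kb
on the candidate X.  Scaffold selection against a reference genome uses
per-preset aligned-length and identity thresholds: ``anolis`` = (0.50, 0.80),
``chicken`` = (0.40, 0.70).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError

AUTOSOMAL = "AUTOSOMAL"
PAR = "PAR"
X_HEMI = "X_HEMI"
NO_DATA = "NO_DATA"
UNASSIGNED = "UNASSIGNED"

PRESETS = {"anolis": (0.50, 0.80), "chicken": (0.40, 0.70)}


@dataclass(frozen=True)
class CoverageConfig:
    window_autosome: int = 100_000
    window_x: int = 10_000
    ratio_log2_tolerance: float = 0.25
    min_depth: float = 1.0
    scaffold_min_len_frac: float = 0.50
    scaffold_min_identity: float = 0.80

    @classmethod
    def preset(cls, name: str, **kwargs) -> "CoverageConfig":
        if name not in PRESETS:
            raise ConfigurationError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
        frac, ident = PRESETS[name]
        return cls(scaffold_min_len_frac=frac, scaffold_min_identity=ident, **kwargs)

    def validate(self) -> "CoverageConfig":
        if self.window_autosome <= 0 or self.window_x <= 0:
            raise ConfigurationError("window sizes must be > 0")
        if not 0 < self.ratio_log2_tolerance < 0.5:
            raise ConfigurationError("ratio_log2_tolerance must be in (0, 0.5)")
        if self.min_depth < 0:
            raise ConfigurationError("min_depth must be >= 0")
        return self


@dataclass(frozen=True)
class CoverageWindow:
    chrom: str
    start: int
    end: int
    male_depth: float
    female_depth: float
    log2_ratio: float
    label: str


def window_depths(track: np.ndarray, window: int) -> list[tuple[int, int, float]]:
    """Mean depth per tile; the final partial tile averages its actual bases."""
    if window <= 0:
        raise ConfigurationError("window must be > 0")
    length = int(track.size)
    out = []
    for i in range(math.ceil(length / window)):
        start, end = i * window, min((i + 1) * window, length)
        out.append((start, end, float(np.mean(track[start:end]))))
    return out


def classify_window(
    male_depth: float, female_depth: float, cfg: CoverageConfig, on_x: bool = False
) -> str:
    if male_depth < 0 or female_depth < 0:
        raise ValueError("depths must be non-negative")
    if male_depth < cfg.min_depth or female_depth < cfg.min_depth:
        return NO_DATA
    ratio = math.log2(male_depth / female_depth)
    if abs(ratio + 1.0) <= cfg.ratio_log2_tolerance:
        return X_HEMI
    if abs(ratio) <= cfg.ratio_log2_tolerance:
        return PAR if on_x else AUTOSOMAL
    return UNASSIGNED


def classify_windows(
    male_track: np.ndarray,
    female_track: np.ndarray,
    cfg: CoverageConfig,
    chrom: str,
    on_x: bool = False,
) -> list[CoverageWindow]:
    """Window both tracks of one chromosome and classify each window."""
    cfg.validate()
    window = cfg.window_x if on_x else cfg.window_autosome
    male_w = window_depths(male_track, window)
    female_w = window_depths(female_track, window)
    out = []
    for (start, end, m), (_, _, f) in zip(male_w, female_w):
        label = classify_window(m, f, cfg, on_x=on_x)
        ratio = math.log2(m / f) if (m >= cfg.min_depth and f >= cfg.min_depth) else float("nan")
        out.append(CoverageWindow(chrom, start, end, m, f, ratio, label))
    return out


def windows_table(windows: list[CoverageWindow]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            dict(chrom=w.chrom, start=w.start, end=w.end, male_depth=w.male_depth,
                 female_depth=w.female_depth, log2_ratio=w.log2_ratio, label=w.label)
            for w in windows
        ]
    )


def select_scaffolds(
    query_sequences: dict[str, str],
    reference_sequences: dict[str, str],
    min_len_frac: float,
    min_identity: float,
    aligner=None,
    hits: dict | None = None,
) -> dict[str, tuple[str, int, int]]:
    """Retain scaffolds whose best reference hit passes both thresholds and
    order them along the reference.

    ``aligner`` must expose ``best_hit(seq) -> Hit``; alternatively a
    precomputed ``hits`` mapping (scaffold id -> Hit) can be supplied.
    Returns an ordered mapping scaffold -> (reference chrom, start, end).
    """
    if not reference_sequences:
        raise ConfigurationError("empty reference")
    if not 0 < min_len_frac <= 1 or not 0 < min_identity <= 1:
        raise ConfigurationError("thresholds must be in (0, 1]")
    if aligner is None and hits is None:
        from .align import ExactSeedAligner

        aligner = ExactSeedAligner(reference_sequences)
    placed = []
    for name, seq in query_sequences.items():
        hit = hits.get(name) if hits is not None else aligner.best_hit(seq)
        if hit is None:
            continue
        if hit.aligned_fraction >= min_len_frac and hit.identity >= min_identity:
            placed.append((hit.chrom, hit.ref_start, name, hit))
    placed.sort(key=lambda t: (t[0], t[1]))
    return {
        name: (chrom, start, start + hit.aligned_length)
        for chrom, start, name, hit in placed
    }


def score_against_truth(windows: list[CoverageWindow], truth) -> dict:
    """Fraction of classifiable windows matching the simulation's labels, and
    whether PAR segments come out as contiguous label runs."""
    total = correct = 0
    for w in windows:
        expected = truth.label_window(w.chrom, w.start, w.end)
        total += 1
        correct += w.label == expected
    runs = []
    current = None
    for w in sorted(windows, key=lambda w: (w.chrom, w.start)):
        if w.label == PAR:
            if current and current[0] == w.chrom and current[2] == w.start:
                current = (w.chrom, current[1], w.end)
            else:
                if current:
                    runs.append(current)
                current = (w.chrom, w.start, w.end)
        else:
            if current:
                runs.append(current)
            current = None
    if current:
        runs.append(current)
    return {
        "n_windows": total,
        "label_accuracy": correct / total if total else float("nan"),
        "par_runs": runs,
    }
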
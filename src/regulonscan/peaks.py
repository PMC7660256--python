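"""Peak calling on genome-wide binding-intensity tracks.

A binding track is a per-position (or per-probe) intensity profile in
arbitrary fluorescence-ratio units, the kind produced by hybridizing an
affinity-enriched DNA pool to a genome tiling array. Peaks are local
maxima above a hard intensity cutoff; nearby maxima are merged keeping
the higher apex. Tracks are assumed normalized upstream (two-channel
ratios); no within-track normalization is applied here.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BindingTrack",
    "BindingPeak",
    "EffectorResponse",
    "call_peaks",
    "filter_peak_table",
    "effector_response",
    "attach_effector_intensity",
    "read_bedgraph",
    "read_wig",
    "write_bedgraph",
    "read_peak_table",
    "write_peak_table",
]

DEFAULT_CUTOFF = 500.0
DEFAULT_MIN_SEPARATION = 500
DEFAULT_SENSITIVITY_THRESHOLD = 0.5


@dataclass
class BindingTrack:
    """Per-position binding intensity at fixed ``step`` resolution.

    ``values[i]`` is the intensity at genome position ``start + i*step``
    (1-based). Values must be finite and non-negative.
    """

    values: np.ndarray
    step: int = 1
    start: int = 1
    condition: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("track values must be one-dimensional")
        if self.step < 1:
            raise ValueError("step must be a positive number of bp")
        if self.values.size and not np.all(np.isfinite(self.values)):
            raise ValueError("track contains non-finite intensities")
        if self.values.size and self.values.min() < 0:
            raise ValueError("track contains negative intensities")

    def __len__(self) -> int:
        return self.values.size

    def position(self, index: int) -> int:
        """1-based genome position of sample ``index``."""
        return self.start + index * self.step

    @property
    def positions(self) -> np.ndarray:
        return self.start + np.arange(self.values.size, dtype=np.int64) * self.step

    def value_at(self, position: int) -> float:
        """Intensity at the sample nearest to ``position``."""
        idx = int(round((position - self.start) / self.step))
        idx = min(max(idx, 0), self.values.size - 1)
        return float(self.values[idx])


@dataclass
class BindingPeak:
    """A discrete binding site: apex position plus per-condition intensity."""

    position: int
    intensity_no_effector: float
    intensity_effector: Optional[float] = None

    def __post_init__(self) -> None:
        if self.intensity_no_effector < 0:
            raise ValueError("peak intensity must be non-negative")


@dataclass(frozen=True)
class EffectorResponse:
    """How much binding survives the effector condition at one peak."""

    retained_fraction: float
    sensitive: bool


def call_peaks(
    track: BindingTrack,
    cutoff: float = DEFAULT_CUTOFF,
    min_separation: int = DEFAULT_MIN_SEPARATION,
) -> list[BindingPeak]:
    """Find local maxima with intensity >= ``cutoff``.

    A sample is an apex when its value exceeds the nearest differing
    values on both sides (track ends need only the inner side); a
    plateau of equal values is reported at its leftmost sample. Apexes
    closer than ``min_separation`` bp are merged keeping the higher one
    (ties keep the leftmost). The result is sorted by position, and the
    number of peaks is non-increasing in ``cutoff``.
    """
    if len(track) == 0:
        raise ValueError("cannot call peaks on an empty track")
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if min_separation < 0:
        raise ValueError("min_separation must be >= 0")

    v = track.values
    # compress into runs of equal value; a run is an apex candidate when
    # both neighbouring runs (where present) are lower
    change = np.flatnonzero(np.diff(v)) + 1
    run_starts = np.concatenate(([0], change))
    run_values = v[run_starts]
    candidates: list[tuple[int, float]] = []  # (sample index, value)
    for k in range(run_starts.size):
        val = run_values[k]
        if val < cutoff:
            continue
        if k > 0 and run_values[k - 1] >= val:
            continue
        if k < run_starts.size - 1 and run_values[k + 1] >= val:
            continue
        candidates.append((int(run_starts[k]), float(val)))

    # greedy merge, strongest first; tie -> leftmost survives
    kept: list[tuple[int, float]] = []
    for idx, val in sorted(candidates, key=lambda c: (-c[1], c[0])):
        pos = track.position(idx)
        if all(abs(pos - track.position(j)) >= min_separation for j, _ in kept):
            kept.append((idx, val))
    kept.sort()
    return [BindingPeak(position=track.position(i), intensity_no_effector=val)
            for i, val in kept]


def filter_peak_table(
    peaks: Iterable[BindingPeak], cutoff: float = DEFAULT_CUTOFF
) -> list[BindingPeak]:
    """Retain peaks whose no-effector intensity is >= ``cutoff`` (inclusive)."""
    return [p for p in peaks if p.intensity_no_effector >= cutoff]


def effector_response(
    peak: BindingPeak,
    pseudocount: float = 0.0,
    threshold: float = DEFAULT_SENSITIVITY_THRESHOLD,
) -> Optional[EffectorResponse]:
    """Fraction of binding retained in the effector condition.

    ``retained_fraction = (effector + pseudocount) / (no_effector + pseudocount)``;
    a peak is *sensitive* when the fraction falls below ``threshold``.
    Returns None when the effector intensity was not measured.
    """
    if peak.intensity_effector is None:
        return None
    ratio = (peak.intensity_effector + pseudocount) / (
        peak.intensity_no_effector + pseudocount
    )
    return EffectorResponse(retained_fraction=ratio, sensitive=ratio < threshold)


def attach_effector_intensity(
    peaks: Sequence[BindingPeak], effector_track: BindingTrack
) -> list[BindingPeak]:
    """Read the effector-condition intensity at each peak apex."""
    return [
        BindingPeak(
            position=p.position,
            intensity_no_effector=p.intensity_no_effector,
            intensity_effector=effector_track.value_at(p.position),
        )
        for p in peaks
    ]


# ---------------------------------------------------------------------------
# track and table I/O


def read_bedgraph(path: str | os.PathLike, condition: str = "") -> BindingTrack:
    """Read a fixed-interval bedGraph file into a track.

    All intervals must share one width (the probe step) and be
    contiguous; bedGraph coordinates are 0-based half-open.
    """
    starts: list[int] = []
    values: list[float] = []
    step = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) != 4:
                raise ValueError(f"{path}:{lineno}: expected 4 bedGraph columns")
            s, e, val = int(parts[1]), int(parts[2]), float(parts[3])
            width = e - s
            if step is None:
                step = width
            elif width != step:
                raise ValueError(
                    f"{path}:{lineno}: interval width {width} != step {step}; "
                    "only fixed-step bedGraph is supported"
                )
            starts.append(s)
            values.append(val)
    if step is None:
        raise ValueError(f"{path}: empty bedGraph")
    order = np.argsort(starts)
    starts_arr = np.asarray(starts)[order]
    if starts_arr.size > 1 and not np.all(np.diff(starts_arr) == step):
        raise ValueError(f"{path}: bedGraph intervals are not contiguous")
    return BindingTrack(values=np.asarray(values, dtype=float)[order],
                        step=int(step), start=int(starts_arr[0]) + 1,
                        condition=condition)


def read_wig(path: str | os.PathLike, condition: str = "") -> BindingTrack:
    """Read a single fixedStep WIG block."""
    values: list[float] = []
    step = 1
    start = 1
    seen_header = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            if line.startswith("fixedStep"):
                if seen_header:
                    raise ValueError(f"{path}:{lineno}: multiple fixedStep blocks "
                                     "are not supported")
                seen_header = True
                fields = dict(tok.split("=", 1) for tok in line.split()[1:])
                start = int(fields.get("start", 1))
                step = int(fields.get("step", 1))
            elif line.startswith("variableStep"):
                raise ValueError(f"{path}:{lineno}: variableStep WIG is not supported")
            else:
                if not seen_header:
                    raise ValueError(f"{path}:{lineno}: data before fixedStep header")
                values.append(float(line))
    if not seen_header:
        raise ValueError(f"{path}: no fixedStep header found")
    return BindingTrack(values=np.asarray(values, dtype=float), step=step,
                        start=start, condition=condition)


def write_bedgraph(track: BindingTrack, path: str | os.PathLike,
                   chrom: str = "genome") -> None:
    with open(path, "w") as fh:
        for i, val in enumerate(track.values):
            s = track.position(i) - 1
            fh.write(f"{chrom}\t{s}\t{s + track.step}\t{val:g}\n")


PEAK_TABLE_COLUMNS = [
    "peak_position",
    "intensity_no_effector",
    "intensity_effector",
    "retained_fraction",
]


def peaks_to_frame(peaks: Sequence[BindingPeak],
                   pseudocount: float = 0.0) -> pd.DataFrame:
    rows = []
    for p in peaks:
        resp = effector_response(p, pseudocount=pseudocount)
        rows.append(
            {
                "peak_position": p.position,
                "intensity_no_effector": p.intensity_no_effector,
                "intensity_effector": p.intensity_effector,
                "retained_fraction": None if resp is None else resp.retained_fraction,
            }
        )
    return pd.DataFrame(rows, columns=PEAK_TABLE_COLUMNS)


def write_peak_table(peaks: Sequence[BindingPeak], path: str | os.PathLike,
                     pseudocount: float = 0.0) -> None:
    peaks_to_frame(peaks, pseudocount=pseudocount).to_csv(path, sep="\t", index=False)


def read_peak_table(path: str | os.PathLike) -> list[BindingPeak]:
    df = pd.read_csv(path, sep="\t")
    peaks = []
    for _, row in df.iterrows():
        eff = row.get("intensity_effector")
        peaks.append(
            BindingPeak(
                position=int(row["peak_position"]),
                intensity_no_effector=float(row["intensity_no_effector"]),
                intensity_effector=None if pd.isna(eff) else float(eff),
            )
        )
    return peaks
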
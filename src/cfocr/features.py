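"""Fragment-level signal tracks and windowed feature matrices.

Four per-base tracks summarize the nucleosome footprint of a fragment set:

* **WPS** (windowed protection score): fragments fully spanning a window
  centered on the base, minus fragments with an endpoint inside it.
  Peaks mark protected (nucleosomal) positions; the score flattens in
  open chromatin.
* **coverage**: fragments whose half-open span contains the base.
* **Uend / Dend**: counts of fragment 5' starts and 3' last covered
  bases; these end signals peak on nucleosome flanks.

A segment is tiled with non-overlapping ``window_bp`` windows and the
within-window means of the four tracks form the windows x 4 matrix
monitored by the control charts (a 20-kb segment at 200-bp windows gives
the canonical 100 x 4 matrix). The per-sample summary vector is the
population standard deviation of the windowed WPS and coverage columns.

Coordinates are 0-based half-open (BED convention) throughout; the
downstream (3') endpoint of a fragment ``[s, e)`` is taken as ``e - 1``,
its last covered base.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import TYPE_CHECKING

import numpy as np

if TYPE_CHECKING:  # pragma: no cover - import cycle guard
    from .simulate import FragmentSet

logger = logging.getLogger(__name__)

__all__ = [
    "SignalTracks",
    "IntervalFeatureMatrix",
    "EncodedImage",
    "ImageConfig",
    "compute_coverage",
    "compute_wps",
    "compute_end_signals",
    "compute_tracks",
    "window_average",
    "summarize_std",
    "featurize_fragments",
    "matrix_to_features",
    "encode_image",
]

FEATURE_COLUMNS = ("wps", "coverage", "uend", "dend")


def _segment_bounds(frags: "FragmentSet", segment: tuple[int, int] | None) -> tuple[int, int]:
    if segment is not None:
        start, end = segment
    elif frags.segment_length is not None:
        start, end = 0, frags.segment_length
    else:
        raise ValueError("segment bounds required when FragmentSet has no segment_length")
    if end <= start:
        raise ValueError("segment end must exceed segment start")
    return int(start), int(end)


def _clipped(frags: "FragmentSet", start: int, end: int) -> tuple[np.ndarray, np.ndarray]:
    s = frags.starts.astype(np.int64)
    e = frags.ends.astype(np.int64)
    outside = (s < start) | (e > end)
    if outside.any():
        logger.warning("%d fragments extend outside the segment; clipping", outside.sum())
    return np.clip(s, start, end), np.clip(e, start, end)


def compute_coverage(frags: "FragmentSet", segment: tuple[int, int] | None = None) -> np.ndarray:
    """Per-base read depth: ``coverage[i]`` counts fragments whose
    half-open span contains base ``i`` of the segment."""
    start, end = _segment_bounds(frags, segment)
    L = end - start
    diff = np.zeros(L + 1, dtype=np.int64)
    s, e = _clipped(frags, start, end)
    np.add.at(diff, s - start, 1)
    np.add.at(diff, e - start, -1)
    return np.cumsum(diff[:-1])


def compute_wps(
    frags: "FragmentSet",
    segment: tuple[int, int] | None = None,
    w: int = 120,
) -> np.ndarray:
    """Windowed protection score with an even ``w``-bp window.

    For the window ``[i - w/2, i + w/2)`` centered on base ``i``:
    +1 for every fragment completely spanning it, -1 for every fragment
    endpoint (start or last covered base) falling inside it.
    """
    start, end = _segment_bounds(frags, segment)
    L = end - start
    if w <= 0 or w % 2:
        raise ValueError("w must be a positive even window size")
    if w > L:
        raise ValueError("WPS window larger than the segment")
    hw = w // 2
    diff = np.zeros(L + 1, dtype=np.int64)

    s = frags.starts.astype(np.int64) - start
    e = frags.ends.astype(np.int64) - start

    # spanning: [i-hw, i+hw) inside [s, e)  <=>  i in [s+hw, e-hw]
    lo = np.clip(s + hw, 0, L)
    hi = np.clip(e - hw + 1, 0, L)  # exclusive
    ok = hi > lo
    np.add.at(diff, lo[ok], 1)
    np.add.at(diff, hi[ok], -1)

    # endpoint x inside window  <=>  i in [x-hw+1, x+hw]
    for x in (s, e - 1):
        lo = np.clip(x - hw + 1, 0, L)
        hi = np.clip(x + hw + 1, 0, L)  # exclusive
        ok = hi > lo
        np.add.at(diff, lo[ok], -1)
        np.add.at(diff, hi[ok], 1)

    return np.cumsum(diff[:-1])


def compute_end_signals(
    frags: "FragmentSet", segment: tuple[int, int] | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Per-base fragment end tallies: ``uend[i]`` fragments starting at
    ``i``; ``dend[i]`` fragments whose last covered base is ``i``."""
    start, end = _segment_bounds(frags, segment)
    L = end - start
    uend = np.zeros(L, dtype=np.int64)
    dend = np.zeros(L, dtype=np.int64)
    s = frags.starts.astype(np.int64) - start
    d = frags.ends.astype(np.int64) - 1 - start
    np.add.at(uend, s[(s >= 0) & (s < L)], 1)
    np.add.at(dend, d[(d >= 0) & (d < L)], 1)
    return uend, dend


@dataclass
class SignalTracks:
    """The four per-base tracks over one segment."""

    wps: np.ndarray
    coverage: np.ndarray
    uend: np.ndarray
    dend: np.ndarray
    chrom: str = "chrS"
    start: int = 0

    def __post_init__(self) -> None:
        n = {len(self.wps), len(self.coverage), len(self.uend), len(self.dend)}
        if len(n) != 1:
            raise ValueError("all tracks must share the segment length")

    def __len__(self) -> int:
        return len(self.coverage)

    def stacked(self) -> np.ndarray:
        return np.stack([self.wps, self.coverage, self.uend, self.dend], axis=1)


def compute_tracks(frags: "FragmentSet", segment: tuple[int, int] | None = None,
                   wps_w: int = 120) -> SignalTracks:
    start, _ = _segment_bounds(frags, segment)
    uend, dend = compute_end_signals(frags, segment)
    return SignalTracks(
        wps=compute_wps(frags, segment, w=wps_w),
        coverage=compute_coverage(frags, segment),
        uend=uend,
        dend=dend,
        chrom=frags.chrom,
        start=start,
    )


@dataclass
class IntervalFeatureMatrix:
    """Windowed feature matrix for one genomic interval.

    ``values`` has one row per window and four columns ordered
    (WPS, coverage, Uend, Dend), each entry the within-window mean of
    the per-base track.
    """

    values: np.ndarray
    window_bp: int = 200
    chrom: str = "chrS"
    start: int = 0

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[1] != 4:
            raise ValueError("values must be a windows x 4 matrix")
        self.values = v

    @property
    def n_windows(self) -> int:
        return self.values.shape[0]

    def window_interval(self, k: int) -> tuple[int, int]:
        return (self.start + k * self.window_bp, self.start + (k + 1) * self.window_bp)


def window_average(tracks: SignalTracks, window_bp: int = 200) -> IntervalFeatureMatrix:
    """Tile the segment with non-overlapping ``window_bp`` windows and
    average the four tracks within each; a trailing partial window is
    dropped (with a log message)."""
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    L = len(tracks)
    k = L // window_bp
    if k == 0:
        raise ValueError("segment shorter than one window")
    if L % window_bp:
        logger.info("dropping trailing partial window of %d bp", L % window_bp)
    data = tracks.stacked()[: k * window_bp].astype(float)
    means = data.reshape(k, window_bp, 4).mean(axis=1)
    return IntervalFeatureMatrix(means, window_bp=window_bp, chrom=tracks.chrom,
                                 start=tracks.start)


def summarize_std(m: IntervalFeatureMatrix) -> np.ndarray:
    """Length-2 summary vector: population standard deviation of the
    windowed WPS means and of the windowed coverage means."""
    if m.n_windows < 2:
        raise ValueError("need at least two windows for a standard deviation")
    return m.values[:, :2].std(axis=0, ddof=0)


def featurize_fragments(
    frags: "FragmentSet",
    segment: tuple[int, int] | None = None,
    window_bp: int = 200,
    wps_w: int = 120,
) -> IntervalFeatureMatrix:
    """Fragments -> tracks -> windowed matrix in one call."""
    return window_average(compute_tracks(frags, segment, wps_w=wps_w), window_bp)


def matrix_to_features(m: IntervalFeatureMatrix, kind: str = "extended") -> np.ndarray:
    """Flatten a feature matrix into a classifier input vector.

    ``summary``: the length-2 WPS/coverage sd vector; ``extended``:
    mean and population sd of each of the four columns (length 8);
    ``flat``: the raveled matrix.
    """
    if kind == "summary":
        return summarize_std(m)
    if kind == "extended":
        return np.concatenate([m.values.mean(axis=0), m.values.std(axis=0, ddof=0)])
    if kind == "flat":
        return m.values.ravel()
    raise ValueError(f"unknown feature kind {kind!r}")


@dataclass(frozen=True)
class ImageConfig:
    len_min: int = 100
    len_max: int = 400
    coord_bin_bp: int = 200


@dataclass
class EncodedImage:
    """2-D encodings for the deep model: the primary channel counts
    fragments by (genomic coordinate bin, fragment length); auxiliary
    channels carry the windowed coverage/WPS/end-density tracks."""

    primary: np.ndarray  # (coord_bins, length_bins)
    aux: dict[str, np.ndarray] = field(default_factory=dict)
    config: ImageConfig = field(default_factory=ImageConfig)


def encode_image(
    frags: "FragmentSet",
    segment: tuple[int, int] | None = None,
    config: ImageConfig | None = None,
) -> EncodedImage:
    config = config or ImageConfig()
    start, end = _segment_bounds(frags, segment)
    L = end - start
    n_coord = max(L // config.coord_bin_bp, 1)
    n_len = config.len_max - config.len_min + 1
    primary = np.zeros((n_coord, n_len), dtype=np.int64)

    s = frags.starts.astype(np.int64)
    lengths = frags.lengths()
    ok = (s >= start) & (s < start + n_coord * config.coord_bin_bp) \
        & (lengths >= config.len_min) & (lengths <= config.len_max)
    rows = (s[ok] - start) // config.coord_bin_bp
    cols = lengths[ok] - config.len_min
    np.add.at(primary, (rows, cols), 1)

    m = featurize_fragments(frags, (start, end), window_bp=config.coord_bin_bp)
    aux = {name: m.values[:, i].copy() for i, name in enumerate(FEATURE_COLUMNS)}
    return EncodedImage(primary=primary, aux=aux, config=config)
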
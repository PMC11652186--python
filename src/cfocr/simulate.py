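"""Synthetic cfDNA fragment and dataset generation.

Cell-free DNA fragments are released by apoptotic cells after nucleosomal
digestion: in closed chromatin (CCR) mono-nucleosomal fragments of ~167 bp
sit on a ~190-bp nucleosome repeat, producing periodic coverage, a peaked
windowed protection score (WPS) and phased fragment-end signals. In open
chromatin (OCR) the nucleosome lattice is lost: fragments land roughly
uniformly, per-base coverage drops and the WPS flattens. This module
emulates exactly that statistical structure, which is what the downstream
control charts consume; it makes no attempt to model sequence content, GC
bias or mappability.

Partially open regions (pOCRs) are generated at the feature level as a
convex combination of an open and a closed feature matrix with composite
rate ``tau`` (default 0.7), or optionally at the fragment level by
tau-subsampling a union of open and closed fragment sets.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import stats

from .features import IntervalFeatureMatrix, featurize_fragments

__all__ = [
    "SimParams",
    "FragmentSet",
    "LabeledDataset",
    "simulate_fragments",
    "simulate_sample",
    "simulate_pocr_features",
    "simulate_pocr_fragments",
    "make_dataset",
]

#: truncation bounds for the fragment-length distribution (bp)
FRAG_LEN_MIN = 100
FRAG_LEN_MAX = 400

# three-class label codes used throughout the package
CCR, OCR, POCR = 0, 1, 2


@dataclass(frozen=True)
class SimParams:
    """Generator settings for one synthetic cfDNA experiment.

    Defaults emulate deeply sequenced plasma cfDNA: one nucleosome per
    ~190 bp repeat, mono-nucleosomal fragment length ~167 bp, and
    ``depth_ccr`` fragments per nucleosome giving ~97x coverage
    (depth_ccr * frag_len_mean_bp / period_bp per base).
    """

    period_bp: int = 190
    frag_len_mean_bp: int = 167
    frag_len_sd_bp: float = 15.0
    depth_ccr: float = 110.0
    ocr_depletion: float = 0.3
    placement_jitter_bp: float = 10.0
    depth_cv: float = 0.2
    ocr_width_min_bp: int = 600
    ocr_width_max_bp: int = 4000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.period_bp <= 0:
            raise ValueError("period_bp must be positive")
        if self.frag_len_mean_bp <= 0:
            raise ValueError("frag_len_mean_bp must be positive")
        if not 0.0 < self.ocr_depletion < 1.0:
            raise ValueError("ocr_depletion must lie in (0, 1)")
        if self.frag_len_sd_bp < 0 or self.placement_jitter_bp < 0:
            raise ValueError("spread parameters must be non-negative")
        if self.depth_ccr < 0:
            raise ValueError("depth_ccr must be non-negative")
        if self.depth_cv < 0:
            raise ValueError("depth_cv must be non-negative")
        if not 0 < self.ocr_width_min_bp <= self.ocr_width_max_bp:
            raise ValueError("need 0 < ocr_width_min_bp <= ocr_width_max_bp")

    @property
    def coverage_ccr(self) -> float:
        """Expected per-base coverage in the closed state."""
        return self.depth_ccr * self.frag_len_mean_bp / self.period_bp


@dataclass
class FragmentSet:
    """Fragment intervals for one chromosome; 0-based half-open coordinates."""

    chrom: str
    intervals: np.ndarray  # (n, 2) int array of (start, end)
    segment_length: int | None = None

    def __post_init__(self) -> None:
        iv = np.asarray(self.intervals, dtype=np.int64).reshape(-1, 2)
        if iv.size and np.any(iv[:, 1] <= iv[:, 0]):
            raise ValueError("every fragment must satisfy end > start")
        if self.segment_length is not None and iv.size:
            if iv[:, 0].min() < 0 or iv[:, 1].max() > self.segment_length:
                raise ValueError("fragments must lie within the segment")
        self.intervals = iv

    def __len__(self) -> int:
        return self.intervals.shape[0]

    @property
    def starts(self) -> np.ndarray:
        return self.intervals[:, 0]

    @property
    def ends(self) -> np.ndarray:
        return self.intervals[:, 1]

    def lengths(self) -> np.ndarray:
        return self.intervals[:, 1] - self.intervals[:, 0]


@dataclass
class LabeledDataset:
    """Per-sample feature matrices with binary observed labels and
    three-class ground truth (0=CCR, 1=OCR, 2=pOCR).

    Observed labels stay binary even for pOCR samples, which receive a
    random 0/1 label: the partially open class is invisible to the
    initial annotation.
    """

    features: list[IntervalFeatureMatrix]
    observed: np.ndarray  # (n,) int in {0,1}
    true: np.ndarray  # (n,) int in {0,1,2}
    noise_rate: float = 0.0
    fragments: list[FragmentSet | None] = field(default_factory=list)
    #: per-sample open span within the segment (None for fully closed samples)
    spans: list[tuple[int, int] | None] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.observed = np.asarray(self.observed, dtype=np.int64)
        self.true = np.asarray(self.true, dtype=np.int64)
        if not (len(self.features) == self.observed.size == self.true.size):
            raise ValueError("features, observed and true must align")
        if self.observed.size and not np.isin(self.observed, [0, 1]).all():
            raise ValueError("observed labels must be binary")

    def __len__(self) -> int:
        return self.observed.size

    def subset(self, idx: np.ndarray) -> "LabeledDataset":
        idx = np.asarray(idx)
        frags = [self.fragments[i] for i in idx] if self.fragments else []
        spans = [self.spans[i] for i in idx] if self.spans else []
        return LabeledDataset(
            [self.features[i] for i in idx],
            self.observed[idx],
            self.true[idx],
            self.noise_rate,
            frags,
            spans,
        )


def _truncated_lengths(n: int, params: SimParams, rng: np.random.Generator) -> np.ndarray:
    if params.frag_len_sd_bp == 0:
        return np.full(n, params.frag_len_mean_bp, dtype=np.int64)
    a = (FRAG_LEN_MIN - params.frag_len_mean_bp) / params.frag_len_sd_bp
    b = (FRAG_LEN_MAX - params.frag_len_mean_bp) / params.frag_len_sd_bp
    draws = stats.truncnorm.rvs(
        a, b, loc=params.frag_len_mean_bp, scale=params.frag_len_sd_bp,
        size=n, random_state=rng,
    )
    return np.rint(draws).astype(np.int64)


def _fragments_from_centers(
    centers: np.ndarray,
    segment_length_bp: int,
    params: SimParams,
    rng: np.random.Generator,
    chrom: str,
) -> FragmentSet:
    lengths = _truncated_lengths(centers.size, params, rng)
    starts = np.rint(centers - lengths / 2.0).astype(np.int64)
    ends = starts + lengths
    keep = (starts >= 0) & (ends <= segment_length_bp)
    iv = np.stack([starts[keep], ends[keep]], axis=1)
    order = np.lexsort((iv[:, 1], iv[:, 0])) if iv.size else slice(None)
    return FragmentSet(chrom, iv[order], segment_length=segment_length_bp)


def simulate_fragments(
    segment_length_bp: int,
    state: Literal["OCR", "CCR"],
    params: SimParams | None = None,
    seed: int | np.random.Generator | None = None,
    chrom: str = "chrS",
) -> FragmentSet:
    """Place synthetic cfDNA fragments on one segment.

    CCR: nucleosome centers on a ``period_bp`` lattice (jittered by
    ``placement_jitter_bp``), Poisson(``depth_ccr``) fragments per
    nucleosome, each centered on its nucleosome. OCR: uniform placement
    at an expected per-base coverage of ``ocr_depletion`` times the CCR
    coverage. Fragments extending past the segment are discarded, so the
    set is fully contained in ``[0, segment_length_bp)``.
    """
    params = params or SimParams()
    if segment_length_bp < params.period_bp:
        raise ValueError("segment must hold at least one nucleosome period")
    if state not in ("OCR", "CCR"):
        raise ValueError(f"unknown chromatin state {state!r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(
        params.seed if seed is None else seed
    )

    depth = params.depth_ccr * _depth_factor(params, rng)
    if state == "CCR":
        centers = _lattice_centers(segment_length_bp, depth, params, rng)
    else:
        centers = _uniform_centers(0, segment_length_bp,
                                   params.ocr_depletion * depth, params, rng)
    return _fragments_from_centers(centers, segment_length_bp, params, rng, chrom)


def _depth_factor(params: SimParams, rng: np.random.Generator) -> float:
    """Region-to-region depth heterogeneity (GC, mappability, copy
    number): one mean-one lognormal factor per simulated segment."""
    if params.depth_cv <= 0:
        return 1.0
    sigma = np.sqrt(np.log1p(params.depth_cv**2))
    return float(rng.lognormal(-0.5 * sigma * sigma, sigma))


def _lattice_centers(segment_length_bp: int, depth: float, params: SimParams,
                     rng: np.random.Generator,
                     exclude: tuple[int, int] | None = None) -> np.ndarray:
    n_nuc = segment_length_bp // params.period_bp
    lattice = params.period_bp / 2.0 + params.period_bp * np.arange(n_nuc)
    if params.placement_jitter_bp > 0:
        lattice = lattice + rng.normal(0.0, params.placement_jitter_bp, n_nuc)
    counts = rng.poisson(depth, n_nuc)
    if exclude is not None:
        inside = (lattice >= exclude[0]) & (lattice < exclude[1])
        counts[inside] = 0
    centers = np.repeat(lattice, counts)
    if params.placement_jitter_bp > 0 and centers.size:
        centers = centers + rng.normal(0.0, params.placement_jitter_bp, centers.size)
    return centers


def _uniform_centers(start: int, end: int, depth: float, params: SimParams,
                     rng: np.random.Generator) -> np.ndarray:
    expected = depth * (end - start) / params.period_bp
    n = rng.poisson(expected)
    return rng.uniform(start, end, n)


def simulate_sample(
    segment_bp: int,
    state: Literal["OCR", "CCR"],
    params: SimParams,
    rng: np.random.Generator,
    chrom: str = "chrS",
) -> tuple[FragmentSet, tuple[int, int] | None]:
    """One 20-kb-scale sample segment as the charts encounter it.

    A closed sample is a full nucleosome lattice. An open sample carries
    a planted accessible span — width uniform in
    [ocr_width_min_bp, ocr_width_max_bp], centered near the segment
    midpoint — where the lattice is erased and depleted uniform
    placement takes over; the rest of the segment stays closed. Returns
    the fragments and the planted span (None for closed samples).
    """
    depth = params.depth_ccr * _depth_factor(params, rng)
    if state == "CCR":
        centers = _lattice_centers(segment_bp, depth, params, rng)
        span = None
    else:
        width = int(rng.integers(params.ocr_width_min_bp,
                                 params.ocr_width_max_bp + 1))
        width = min(width, segment_bp)
        lo = (segment_bp - width) // 2
        span = (lo, lo + width)
        lattice = _lattice_centers(segment_bp, depth, params, rng, exclude=span)
        open_centers = _uniform_centers(span[0], span[1],
                                        params.ocr_depletion * depth, params, rng)
        centers = np.concatenate([lattice, open_centers])
    return _fragments_from_centers(centers, segment_bp, params, rng, chrom), span


def simulate_pocr_features(
    ocr_feat: IntervalFeatureMatrix,
    ccr_feat: IntervalFeatureMatrix,
    tau: float,
) -> IntervalFeatureMatrix:
    """Mix open and closed feature matrices into a partially open one:
    ``tau * OCR + (1 - tau) * CCR`` element-wise (composite rate tau)."""
    if not 0.0 < tau <= 1.0:
        raise ValueError("tau must lie in (0, 1]")
    if ocr_feat.values.shape != ccr_feat.values.shape:
        raise ValueError(
            f"shape mismatch: {ocr_feat.values.shape} vs {ccr_feat.values.shape}"
        )
    mixed = tau * ocr_feat.values + (1.0 - tau) * ccr_feat.values
    return dataclasses.replace(ocr_feat, values=mixed)


def simulate_pocr_fragments(
    ocr_frags: FragmentSet,
    ccr_frags: FragmentSet,
    tau: float,
    seed: int | np.random.Generator | None = None,
) -> FragmentSet:
    """Fragment-level pOCR: keep each open fragment with probability tau
    and each closed fragment with probability 1 - tau."""
    if not 0.0 < tau <= 1.0:
        raise ValueError("tau must lie in (0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    keep_o = rng.random(len(ocr_frags)) < tau
    keep_c = rng.random(len(ccr_frags)) < (1.0 - tau)
    iv = np.concatenate([ocr_frags.intervals[keep_o], ccr_frags.intervals[keep_c]])
    order = np.lexsort((iv[:, 1], iv[:, 0])) if iv.size else slice(None)
    seg = ocr_frags.segment_length
    return FragmentSet(ocr_frags.chrom, iv[order], segment_length=seg)


def make_dataset(
    n_per_class: int,
    tau: float = 0.7,
    noise_rate: float = 0.2,
    params: SimParams | None = None,
    seed: int | None = None,
    *,
    n_ocr: int | None = None,
    n_ccr: int | None = None,
    n_pocr: int | None = None,
    segment_bp: int = 20_000,
    window_bp: int = 200,
    wps_w: int = 120,
    pocr_mode: Literal["feature", "fragment"] = "feature",
) -> LabeledDataset:
    """Generate a labeled synthetic dataset of feature matrices.

    ``n_per_class`` open, closed and partially open samples are emitted
    (overridable per class). pOCR samples mix random OCR/CCR pairs at
    rate ``tau`` and carry a *random* binary observed label; a
    ``noise_rate`` fraction of OCR/CCR observed labels is flipped.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    if not 0.0 <= noise_rate < 0.5:
        raise ValueError("noise_rate must lie in [0, 0.5)")
    params = params or SimParams()
    rng = np.random.default_rng(params.seed if seed is None else seed)
    n_ocr = n_per_class if n_ocr is None else n_ocr
    n_ccr = n_per_class if n_ccr is None else n_ccr
    n_pocr = n_per_class if n_pocr is None else n_pocr

    feats: list[IntervalFeatureMatrix] = []
    frag_sets: list[FragmentSet | None] = []
    spans: list[tuple[int, int] | None] = []
    true: list[int] = []
    observed: list[int] = []

    pools: dict[int, list[int]] = {CCR: [], OCR: []}
    for label, count, state in ((CCR, n_ccr, "CCR"), (OCR, n_ocr, "OCR")):
        for _ in range(count):
            fr, span = simulate_sample(segment_bp, state, params, rng)
            feats.append(featurize_fragments(fr, window_bp=window_bp, wps_w=wps_w))
            frag_sets.append(fr)
            spans.append(span)
            pools[label].append(len(feats) - 1)
            true.append(label)
            obs = label if rng.random() >= noise_rate else 1 - label
            observed.append(obs)

    for _ in range(n_pocr):
        i_o = pools[OCR][rng.integers(len(pools[OCR]))]
        i_c = pools[CCR][rng.integers(len(pools[CCR]))]
        if pocr_mode == "feature":
            feats.append(simulate_pocr_features(feats[i_o], feats[i_c], tau))
            frag_sets.append(None)
        else:
            fr = simulate_pocr_fragments(frag_sets[i_o], frag_sets[i_c], tau, rng)
            feats.append(featurize_fragments(fr, window_bp=window_bp, wps_w=wps_w))
            frag_sets.append(fr)
        spans.append(spans[i_o])  # partially open over the open parent's span
        true.append(POCR)
        observed.append(int(rng.integers(2)))

    return LabeledDataset(
        feats,
        np.array(observed, dtype=np.int64),
        np.array(true, dtype=np.int64),
        noise_rate=noise_rate,
        fragments=frag_sets,
        spans=spans,
    )
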
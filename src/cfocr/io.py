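"""Plain-text serialization: BED intervals, bedGraph tracks, TSV matrices.

Everything is 0-based half-open (BED convention) and deterministic.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .features import IntervalFeatureMatrix, SignalTracks
from .simulate import FragmentSet

__all__ = [
    "write_bed",
    "read_bed_fragments",
    "write_bedgraph",
    "write_matrix_tsv",
    "read_matrix_tsv",
]

_LABEL_NAMES = {0: "CCR", 1: "OCR", 2: "pOCR"}


def write_bed(path: str | Path, chrom: str, intervals, names=None, scores=None) -> None:
    iv = np.asarray(intervals, dtype=np.int64).reshape(-1, 2)
    df = pd.DataFrame({"chrom": chrom, "start": iv[:, 0], "end": iv[:, 1]})
    if names is not None:
        df["name"] = [
            _LABEL_NAMES.get(n, str(n)) if isinstance(n, (int, np.integer)) else str(n)
            for n in names
        ]
    if scores is not None:
        if "name" not in df:
            df["name"] = "."
        df["score"] = np.asarray(scores)
    df.to_csv(path, sep="\t", header=False, index=False)


def read_bed_fragments(path: str | Path, segment_length: int | None = None) -> FragmentSet:
    df = pd.read_csv(path, sep="\t", header=None, usecols=[0, 1, 2],
                     names=["chrom", "start", "end"])
    if df.empty:
        return FragmentSet("chrS", np.empty((0, 2), dtype=np.int64),
                           segment_length=segment_length)
    chroms = df["chrom"].unique()
    if len(chroms) > 1:
        raise ValueError("fragment BED must cover a single chromosome")
    return FragmentSet(str(chroms[0]), df[["start", "end"]].to_numpy(),
                       segment_length=segment_length)


def write_bedgraph(path: str | Path, tracks: SignalTracks, which: str = "coverage") -> None:
    vals = getattr(tracks, which)
    pos = tracks.start + np.arange(len(vals))
    df = pd.DataFrame({"chrom": tracks.chrom, "start": pos, "end": pos + 1,
                       "value": vals})
    # collapse runs of equal values for a compact track
    change = np.flatnonzero(np.diff(df["value"].to_numpy()) != 0)
    starts = np.concatenate([[0], change + 1])
    ends = np.concatenate([change, [len(df) - 1]])
    out = pd.DataFrame({
        "chrom": tracks.chrom,
        "start": df["start"].to_numpy()[starts],
        "end": df["end"].to_numpy()[ends],
        "value": df["value"].to_numpy()[starts],
    })
    out.to_csv(path, sep="\t", header=False, index=False)


def write_matrix_tsv(path: str | Path, m: IntervalFeatureMatrix) -> None:
    df = pd.DataFrame(m.values, columns=["wps", "coverage", "uend", "dend"])
    with open(path, "w") as fh:
        fh.write(f"# chrom={m.chrom} start={m.start} window_bp={m.window_bp}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_matrix_tsv(path: str | Path) -> IntervalFeatureMatrix:
    with open(path) as fh:
        header = fh.readline().strip().lstrip("# ")
        meta = dict(kv.split("=") for kv in header.split())
        df = pd.read_csv(fh, sep="\t")
    return IntervalFeatureMatrix(df.to_numpy(), window_bp=int(meta["window_bp"]),
                                 chrom=meta["chrom"], start=int(meta["start"]))
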
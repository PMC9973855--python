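"""Hydropathy-based transmembrane segment prediction.

A transparent stand-in for a dedicated TM-topology HMM: the classic
sliding-window mean of Kyte–Doolittle hydropathy indices, thresholded and
post-processed into candidate membrane-spanning segments. Users who prefer
an external predictor can supply its short-format output instead; the
pipeline consumes only the resulting topology (segment count and
boundaries), not orientation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import ProteinRecord

#: Kyte–Doolittle hydropathy indices for the 20 standard residues.
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}


@dataclass(frozen=True)
class TmTopology:
    """Predicted membrane topology: segment count and 1-based intervals."""

    tm_count: int
    segments: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self):
        if self.tm_count != len(self.segments):
            raise ValueError("tm_count must equal the number of segments")
        prev_end = 0
        for start, end in self.segments:
            if start <= prev_end:
                raise ValueError("segments must be sorted and non-overlapping")
            if end < start:
                raise ValueError("segment end must be >= start")
            prev_end = end


@dataclass(frozen=True)
class HydropathyParams:
    """Window/threshold parameters for the hydropathy caller.

    window: sliding-window width in residues (odd). threshold: minimum
    windowed mean hydropathy for a membrane-like position. min_len: shortest
    reported segment, in residues (a membrane-spanning helix needs roughly
    15+). merge_gap: sub-threshold gaps up to this length are bridged.
    """

    window: int = 19
    threshold: float = 1.6
    min_len: int = 15
    merge_gap: int = 3

    def __post_init__(self):
        if self.window < 5 or self.window % 2 == 0:
            raise ValueError("window must be odd and >= 5")
        if self.min_len < 1 or self.min_len > 2 * self.window:
            raise ValueError("min_len must be in [1, 2*window]")
        if self.merge_gap < 0:
            raise ValueError("merge_gap must be >= 0")


def hydropathy_profile(sequence: str, window: int = 19) -> np.ndarray:
    """Windowed-mean Kyte–Doolittle hydropathy, one score per residue.

    Position *i* carries the mean index over the window centred on it;
    within ``window//2`` of either terminus the window is truncated to the
    available residues. Ambiguity codes (X/B/Z/U) contribute 0 (neutral).
    Sequences shorter than the window are scored over truncated windows
    only; an empty sequence is an error.
    """
    if not sequence:
        raise ValueError("empty sequence")
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and positive")
    values = np.array(
        [KYTE_DOOLITTLE.get(res, 0.0) for res in sequence.upper()], dtype=float
    )
    n = len(values)
    half = window // 2
    # cumulative-sum sliding mean with truncated edge windows
    csum = np.concatenate(([0.0], np.cumsum(values)))
    idx = np.arange(n)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half + 1, n)
    return (csum[hi] - csum[lo]) / (hi - lo)


def call_tm_segments(profile: np.ndarray, params: HydropathyParams = HydropathyParams()) -> TmTopology:
    """Turn a hydropathy profile into membrane segments.

    Maximal runs of positions with score >= threshold are found; runs
    separated by at most ``merge_gap`` sub-threshold positions are merged;
    merged runs shorter than ``min_len`` are discarded. Coordinates in the
    result are 1-based inclusive.
    """
    profile = np.asarray(profile, dtype=float)
    if profile.size == 0:
        raise ValueError("empty profile")
    above = profile >= params.threshold
    runs: list[list[int]] = []  # [start, end] 0-based inclusive
    start = None
    for i, flag in enumerate(above):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            runs.append([start, i - 1])
            start = None
    if start is not None:
        runs.append([start, len(above) - 1])

    merged: list[list[int]] = []
    for run in runs:
        if merged and run[0] - merged[-1][1] - 1 <= params.merge_gap:
            merged[-1][1] = run[1]
        else:
            merged.append(run)

    segments = [
        (a + 1, b + 1) for a, b in merged if (b - a + 1) >= params.min_len
    ]
    return TmTopology(tm_count=len(segments), segments=segments)


def predict_topology(protein: ProteinRecord, params: HydropathyParams = HydropathyParams()) -> TmTopology:
    """Predict the membrane topology of one protein."""
    profile = hydropathy_profile(protein.sequence, params.window)
    return call_tm_segments(profile, params)
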
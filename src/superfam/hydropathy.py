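"""Hydropathy and amphipathicity profiles, TMS peak calling, and averaged
(AveHAS-style) curves over gap-trimmed family alignments.

Transmembrane segments (TMSs) are detected as peaks of windowed
Kyte–Doolittle hydropathy: maximal runs of profile values above a threshold,
with nearby runs merged and short runs discarded. This peak caller stands in
for external topology predictors; it makes no inside/outside orientation
call.

Window semantics: positions whose full window would extend past either end
of the sequence use the truncated window, so a profile always has exactly
one value per residue (required for mapping profiles through alignment
columns).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from Bio.Align import substitution_matrices

from .sequence import GAP, Msa

#: Kyte–Doolittle hydropathy scale. ``X`` contributes 0.
KYTE_DOOLITTLE = {
    "I": 4.5, "V": 4.2, "L": 3.8, "F": 2.8, "C": 2.5, "M": 1.9, "A": 1.8,
    "G": -0.4, "T": -0.7, "S": -0.8, "W": -0.9, "Y": -1.3, "P": -1.6,
    "H": -3.2, "E": -3.5, "Q": -3.5, "D": -3.5, "N": -3.5, "K": -3.9,
    "R": -4.5, "X": 0.0,
}

SCALES = {"kyte-doolittle": KYTE_DOOLITTLE}

#: Angular step of an ideal alpha helix, degrees per residue.
HELIX_ANGLE_DEG = 100.0

#: Defaults for TMS peak calling on single-sequence and averaged curves.
#: Window 19 matches the ~20-residue span of a membrane-crossing helix.
DEFAULT_WINDOW = 19
DEFAULT_THRESHOLD = 1.0
DEFAULT_MIN_LEN = 9
DEFAULT_MERGE_GAP = 5


@dataclass
class Profile:
    """Per-residue windowed profile (dimensionless scale units)."""

    values: np.ndarray
    window: int
    scale_name: str

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class TmsCall:
    """Sorted, non-overlapping TMS intervals (0-based, half-open)."""

    intervals: list[tuple[int, int]]

    @property
    def count(self) -> int:
        return len(self.intervals)

    def to_1based(self) -> list[tuple[int, int]]:
        """1-based inclusive intervals for reports."""
        return [(s + 1, e) for s, e in self.intervals]


@dataclass
class AveCurves:
    """Averaged per-column curves over an occupancy-filtered MSA.

    All vectors have one entry per retained column; ``column_map[i]`` is the
    original alignment column of retained column ``i``.
    """

    hydropathy: np.ndarray
    amphipathicity: np.ndarray
    similarity: np.ndarray
    occupancy: np.ndarray
    column_map: np.ndarray
    peaks: TmsCall | None = None


def _scale_values(seq: str, scale: dict[str, float]) -> np.ndarray:
    return np.array([scale[c] for c in seq], dtype=float)


def _check_window(window: int, n: int) -> None:
    if window % 2 != 1 or window < 1:
        raise ValueError(f"window must be a positive odd integer, got {window}")
    if window > n:
        raise ValueError(f"window {window} exceeds sequence length {n}")


def hydropathy_profile(
    seq: str, window: int = DEFAULT_WINDOW, scale: str = "kyte-doolittle"
) -> Profile:
    """Windowed mean hydropathy, truncated windows at the ends."""
    _check_window(window, len(seq))
    vals = _scale_values(seq, SCALES[scale])
    half = window // 2
    csum = np.concatenate(([0.0], np.cumsum(vals)))
    n = len(vals)
    lo = np.maximum(np.arange(n) - half, 0)
    hi = np.minimum(np.arange(n) + half + 1, n)
    out = (csum[hi] - csum[lo]) / (hi - lo)
    return Profile(out, window, scale)


def amphipathicity_profile(
    seq: str,
    window: int = DEFAULT_WINDOW,
    scale: str = "kyte-doolittle",
    angle_deg: float = HELIX_ANGLE_DEG,
) -> Profile:
    """Hydrophobic-moment magnitude (Eisenberg) per truncated window.

    values[i] = |sum_j s_j * exp(i * j * angle)| / w over the window centred
    at i, where w is the (possibly truncated) window size.
    """
    _check_window(window, len(seq))
    vals = _scale_values(seq, SCALES[scale])
    theta = math.radians(angle_deg)
    phase = np.exp(1j * theta * np.arange(len(vals)))
    rotated = vals * phase
    half = window // 2
    n = len(vals)
    csum = np.concatenate(([0.0 + 0.0j], np.cumsum(rotated)))
    lo = np.maximum(np.arange(n) - half, 0)
    hi = np.minimum(np.arange(n) + half + 1, n)
    out = np.abs(csum[hi] - csum[lo]) / (hi - lo)
    return Profile(out, window, scale)


def call_tms_peaks(
    profile: Profile | np.ndarray,
    threshold: float = DEFAULT_THRESHOLD,
    min_len: int = DEFAULT_MIN_LEN,
    merge_gap: int = DEFAULT_MERGE_GAP,
) -> TmsCall:
    """Call TMS intervals as thresholded runs of a hydropathy profile.

    Maximal runs of values >= threshold; runs separated by fewer than
    ``merge_gap`` positions are merged; merged runs shorter than ``min_len``
    are discarded. Deterministic.
    """
    values = profile.values if isinstance(profile, Profile) else np.asarray(profile)
    if not (np.isfinite(threshold) and np.all(np.isfinite(values))):
        raise ValueError("profile values and threshold must be finite")
    above = values >= threshold
    runs: list[list[int]] = []
    start = None
    for i, flag in enumerate(above):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            runs.append([start, i])
            start = None
    if start is not None:
        runs.append([start, len(values)])
    merged: list[list[int]] = []
    for run in runs:
        if merged and run[0] - merged[-1][1] < merge_gap:
            merged[-1][1] = run[1]
        else:
            merged.append(run)
    intervals = [(s, e) for s, e in merged if e - s >= min_len]
    return TmsCall(intervals)


def trim_msa_by_gap_fraction(
    msa: Msa, max_gap_fraction: float
) -> tuple[Msa, np.ndarray]:
    """Keep exactly the columns whose gap fraction is <= the threshold.

    The boundary is inclusive: a column at exactly ``max_gap_fraction`` gaps
    survives. Returns the trimmed alignment and the surviving-column ->
    original-column index map.
    """
    if not 0.0 <= max_gap_fraction <= 1.0:
        raise ValueError("max_gap_fraction must be in [0, 1]")
    cols = np.array([[c == GAP for c in row] for row in msa.rows])
    gap_frac = cols.mean(axis=0)
    keep = np.flatnonzero(gap_frac <= max_gap_fraction + 1e-12)
    if keep.size == 0:
        raise ValueError(
            f"alignment too gappy: no column has gap fraction <= {max_gap_fraction}"
        )
    rows = ["".join(row[j] for j in keep) for row in msa.rows]
    return Msa(list(msa.ids), rows), keep


def average_curves(
    msa: Msa,
    window: int = DEFAULT_WINDOW,
    occupancy_threshold: float = 0.30,
    scale: str = "kyte-doolittle",
    matrix: str = "BLOSUM62",
    call_peaks: bool = True,
    threshold: float = DEFAULT_THRESHOLD,
    min_len: int = DEFAULT_MIN_LEN,
    merge_gap: int = DEFAULT_MERGE_GAP,
) -> AveCurves:
    """AveHAS-style averaged hydropathy / amphipathicity / similarity curves.

    Each row's profile is computed on its ungapped sequence and mapped back
    through the row's gap structure; per column, hydropathy and
    amphipathicity are averaged over the rows contributing a residue there.
    Columns where fewer than ``occupancy_threshold`` of the rows contribute
    are excluded (the 30% contribution rule). Similarity is the mean
    normalised substitution score of the non-gap residue pairs in a column
    (pair score s(x, y)/sqrt(s(x, x) s(y, y)), so identical columns score 1
    regardless of residue), then min–max normalised to [0, 1] over the
    retained columns; a perfectly conserved alignment is maximal everywhere,
    and columns with a single contributing row score as fully similar.
    """
    mat = substitution_matrices.load(matrix)
    n_rows, n_cols = msa.n_rows, msa.n_cols
    hyd = np.zeros((n_rows, n_cols))
    amp = np.zeros((n_rows, n_cols))
    present = np.zeros((n_rows, n_cols), dtype=bool)
    for i, row in enumerate(msa.rows):
        seq = row.replace(GAP, "")
        if not seq:
            continue
        w = min(window, len(seq) if len(seq) % 2 else len(seq) - 1)
        w = max(w, 1)
        hp = hydropathy_profile(seq, w, scale).values
        ap = amphipathicity_profile(seq, w, scale).values
        k = 0
        for j, c in enumerate(row):
            if c != GAP:
                hyd[i, j] = hp[k]
                amp[i, j] = ap[k]
                present[i, j] = True
                k += 1
    occupancy = present.mean(axis=0)
    keep = np.flatnonzero(occupancy >= occupancy_threshold - 1e-12)
    if keep.size == 0:
        raise ValueError("no column meets the occupancy threshold")

    def col_mean(arr: np.ndarray, j: int) -> float:
        mask = present[:, j]
        return float(arr[mask, j].mean())

    hyd_avg = np.array([col_mean(hyd, j) for j in keep])
    amp_avg = np.array([col_mean(amp, j) for j in keep])

    sim_raw = np.empty(keep.size)
    for out_i, j in enumerate(keep):
        residues = [msa.rows[i][j] for i in range(n_rows) if present[i, j]]
        if len(residues) < 2:
            sim_raw[out_i] = np.nan
            continue
        total = 0.0
        n_pairs = 0
        for a in range(len(residues)):
            for b in range(a + 1, len(residues)):
                x, y = residues[a], residues[b]
                norm = math.sqrt(float(mat[x, x]) * float(mat[y, y]))
                total += float(mat[x, y]) / norm
                n_pairs += 1
        sim_raw[out_i] = total / n_pairs
    finite = np.isfinite(sim_raw)
    if finite.any():
        lo, hi = np.nanmin(sim_raw), np.nanmax(sim_raw)
        sim = (sim_raw - lo) / (hi - lo) if hi > lo else np.ones_like(sim_raw)
        sim[~finite] = 1.0
    else:
        sim = np.ones_like(sim_raw)

    curves = AveCurves(hyd_avg, amp_avg, sim, occupancy[keep], keep)
    if call_peaks:
        curves.peaks = call_tms_peaks(hyd_avg, threshold, min_len, merge_gap)
    return curves


def curves_table(curves: AveCurves):
    """AveCurves as a pandas DataFrame (1-based original columns)."""
    import pandas as pd

    peak_id = np.full(len(curves.column_map), -1)
    if curves.peaks is not None:
        for pid, (s, e) in enumerate(curves.peaks.intervals):
            peak_id[s:e] = pid + 1
    return pd.DataFrame(
        {
            "column": curves.column_map + 1,
            "hydropathy": curves.hydropathy,
            "amphipathicity": curves.amphipathicity,
            "similarity": curves.similarity,
            "occupancy": curves.occupancy,
            "peak_id": peak_id,
        }
    )


def plot_curves(curves: AveCurves, path: str, title: str = "") -> None:
    """Write averaged hydropathy/similarity curves with TMS bars to a file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    x = curves.column_map + 1
    fig, ax = plt.subplots(figsize=(10, 3.2))
    ax.plot(x, curves.hydropathy, color="darkred", lw=1.2, label="hydropathy")
    ax.plot(x, curves.similarity, color="gray", ls=":", lw=1.0, label="similarity")
    if curves.peaks is not None:
        top = curves.hydropathy.max() + 0.4
        for i, (s, e) in enumerate(curves.peaks.intervals):
            ax.plot([x[s], x[e - 1]], [top, top], color="black", lw=3)
            ax.text((x[s] + x[e - 1]) / 2, top + 0.1, str(i + 1), ha="center")
    ax.set_xlabel("alignment position")
    ax.set_ylabel("scale units")
    ax.set_title(title)
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
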
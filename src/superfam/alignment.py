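"""Pairwise alignment, Karlin–Altschul E-values, and the shuffle z-score
(GSAT statistic) used to rank candidate homologies.

The GSAT statistic compares the global affine-gap alignment score of two real
sequences to the mean and standard deviation of scores obtained after
shuffling the sequences, and reports the difference in SD units:

    z = (S_real - mean(S_shuffled)) / sd(S_shuffled)

Shuffling preserves residue composition, so the z-score discounts the
similarity that two membrane proteins share merely because both are rich in
hydrophobic residues — the central confound when testing homology between
multi-spanning membrane proteins. The z-score is not converted to a p-value;
it is a ranking scale that is calibrated against negative-control family
pairs (see :mod:`superfam.transitivity`).

Alignment uses the package's exhaustive Gotoh dynamic-programming kernels
(:mod:`superfam._kernels`, numba-compiled), which expose alignment
coordinates cheaply — the all-vs-all screening stages run millions of DP
cells per family pair. A gap of length L costs
``gap_open + (L - 1) * gap_extend``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
from Bio.Align import substitution_matrices

from . import _kernels as _k
from .sequence import ProteinRecord, FamilySet
from . import hydropathy as hp


class DegenerateStatisticsError(ValueError):
    """All shuffled alignment scores are identical (zero SD); the z-score is
    undefined — typically homopolymer or near-homopolymer input."""


class UnsupportedParametersError(ValueError):
    """No Karlin–Altschul parameters for the requested matrix/gap set."""


#: Karlin–Altschul (lambda, K) by (matrix, gap_open, gap_extend).
#: ``(None, None)`` gap key = ungapped statistics. Values are the published
#: fits used by BLAST for BLOSUM62.
KA_PARAMS: dict[tuple[str, int | None, int | None], tuple[float, float]] = {
    ("BLOSUM62", 11, 1): (0.267, 0.041),
    ("BLOSUM62", None, None): (0.3176, 0.134),
}


@dataclass(frozen=True)
class AlnParams:
    """Substitution matrix and affine gap penalties (penalties are >= 0)."""

    matrix: str = "BLOSUM62"
    gap_open: float = 8.0
    gap_extend: float = 2.0
    ungapped: bool = False
    #: optional explicit matrix object (tests use rescaled matrices)
    matrix_obj: object | None = field(default=None, compare=False, hash=False)

    def __post_init__(self) -> None:
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ValueError("gap penalties must be >= 0")

    @classmethod
    def gsat_default(cls) -> "AlnParams":
        """Global-alignment defaults for the shuffle z-score (BLOSUM62, 8/2)."""
        return cls("BLOSUM62", 8.0, 2.0)

    @classmethod
    def blast_default(cls) -> "AlnParams":
        """Local-search defaults with published E-value statistics
        (BLOSUM62, 11/1)."""
        return cls("BLOSUM62", 11.0, 1.0)

    @classmethod
    def ungapped_default(cls) -> "AlnParams":
        return cls("BLOSUM62", 1e6, 1e6, ungapped=True)

    def load_matrix(self):
        if self.matrix_obj is not None:
            return self.matrix_obj
        return substitution_matrices.load(self.matrix)

    @property
    def ka_key(self) -> tuple[str, int | None, int | None]:
        if self.ungapped:
            return (self.matrix, None, None)
        return (self.matrix, int(self.gap_open), int(self.gap_extend))


@dataclass
class AlignmentResult:
    """One pairwise alignment. Coordinates are 0-based half-open on the
    original (ungapped) sequences; ``aligned_a``/``aligned_b`` are the gapped
    strings."""

    id_a: str
    id_b: str
    aligned_a: str
    aligned_b: str
    score: float
    start_a: int
    end_a: int
    start_b: int
    end_b: int
    evalue: float | None = None
    bits: float | None = None

    @property
    def length(self) -> int:
        """Aligned columns, gaps included."""
        return len(self.aligned_a)

    @property
    def identity_pct(self) -> float:
        """100 * identical columns / aligned columns (gaps included)."""
        same = sum(
            1 for x, y in zip(self.aligned_a, self.aligned_b) if x == y and x != "-"
        )
        return 100.0 * same / self.length

    def region_a(self, seq: str) -> str:
        return seq[self.start_a : self.end_a]

    def region_b(self, seq: str) -> str:
        return seq[self.start_b : self.end_b]


@dataclass
class GsatResult:
    """Shuffle z-score result; ``z`` is in SD units."""

    raw_score: float
    shuffle_mean: float
    shuffle_sd: float
    z: float
    n_shuffles: int
    seed: int
    mode: str = "both"


_matrix_cache: dict = {}


def _code_table(params: AlnParams):
    """(char->code dict, score grid int32) for a parameter set."""
    key = params.matrix if params.matrix_obj is None else id(params.matrix_obj)
    if key not in _matrix_cache:
        mat = params.load_matrix()
        letters = "ACDEFGHIKLMNPQRSTVWYX"
        grid = np.zeros((len(letters), len(letters)), dtype=np.int32)
        for i, x in enumerate(letters):
            for j, y in enumerate(letters):
                grid[i, j] = int(round(float(mat[x, y])))
        codes = {c: i for i, c in enumerate(letters)}
        _matrix_cache[key] = (codes, grid)
    return _matrix_cache[key]


def _encode(seq: str, codes: dict) -> np.ndarray:
    return np.array([codes[c] for c in seq], dtype=np.uint8)


def _seq(x: str | ProteinRecord) -> tuple[str, str]:
    if isinstance(x, ProteinRecord):
        return x.id, x.seq
    return "seq", x


def _strings_from_ops(sa: str, sb: str, start_a: int, start_b: int, ops) -> tuple[str, str]:
    out_a, out_b = [], []
    i, j = start_a, start_b
    for op in ops:
        if op == _k.DIAG:
            out_a.append(sa[i]); out_b.append(sb[j]); i += 1; j += 1
        elif op == _k.UP:
            out_a.append(sa[i]); out_b.append("-"); i += 1
        else:
            out_a.append("-"); out_b.append(sb[j]); j += 1
    return "".join(out_a), "".join(out_b)


def local_align(
    a: str | ProteinRecord, b: str | ProteinRecord, params: AlnParams | None = None
) -> AlignmentResult:
    """Optimal affine-gap Smith-Waterman alignment. Traceback ties prefer
    diagonal, then up, then left (deterministic)."""
    params = params or AlnParams.blast_default()
    id_a, sa = _seq(a)
    id_b, sb = _seq(b)
    if not sa or not sb:
        raise ValueError("sequences must be non-empty")
    codes, grid = _code_table(params)
    score, s0, e0, s1, e1, ops = _k.local_align_coded(
        _encode(sa, codes), _encode(sb, codes), grid,
        int(params.gap_open), int(params.gap_extend),
    )
    al_a, al_b = _strings_from_ops(sa, sb, s0, s1, ops)
    return AlignmentResult(id_a, id_b, al_a, al_b, float(score), s0, e0, s1, e1)


def global_align(
    a: str | ProteinRecord, b: str | ProteinRecord, params: AlnParams | None = None
) -> AlignmentResult:
    """Optimal affine-gap Needleman-Wunsch (end-to-end) alignment."""
    params = params or AlnParams.gsat_default()
    id_a, sa = _seq(a)
    id_b, sb = _seq(b)
    if not sa or not sb:
        raise ValueError("sequences must be non-empty")
    codes, grid = _code_table(params)
    score, ops = _k.global_align_coded(
        _encode(sa, codes), _encode(sb, codes), grid,
        int(params.gap_open), int(params.gap_extend),
    )
    al_a, al_b = _strings_from_ops(sa, sb, 0, 0, ops)
    return AlignmentResult(
        id_a, id_b, al_a, al_b, float(score), 0, len(sa), 0, len(sb)
    )


def local_score(a: str, b: str, params: AlnParams) -> float:
    codes, grid = _code_table(params)
    return float(
        _k.local_score_coded(
            _encode(a, codes), _encode(b, codes), grid,
            int(params.gap_open), int(params.gap_extend),
        )
    )


def global_score(a: str, b: str, params: AlnParams) -> float:
    codes, grid = _code_table(params)
    return float(
        _k.global_score_coded(
            _encode(a, codes), _encode(b, codes), grid,
            int(params.gap_open), int(params.gap_extend),
        )
    )


def evalue(
    score: float,
    len_a: int,
    len_b: int,
    params: AlnParams | None = None,
    n_comparisons: int = 1,
) -> float:
    """Karlin–Altschul expectation: E = K * m * n * exp(-lambda * S) * N.

    Only parameter sets with published (lambda, K) fits are supported;
    anything else raises :class:`UnsupportedParametersError`.
    """
    params = params or AlnParams.blast_default()
    try:
        lam, k = KA_PARAMS[params.ka_key]
    except KeyError:
        supported = ", ".join(
            f"{m} open={o} extend={e}" if o is not None else f"{m} ungapped"
            for (m, o, e) in KA_PARAMS
        )
        raise UnsupportedParametersError(
            f"no Karlin-Altschul parameters for {params.ka_key}; "
            f"supported: {supported}"
        ) from None
    return k * len_a * len_b * math.exp(-lam * score) * n_comparisons


def bit_score(score: float, params: AlnParams | None = None) -> float:
    """Normalised (bit) score: (lambda*S - ln K) / ln 2."""
    params = params or AlnParams.blast_default()
    try:
        lam, k = KA_PARAMS[params.ka_key]
    except KeyError:
        raise UnsupportedParametersError(
            f"no Karlin-Altschul parameters for {params.ka_key}"
        ) from None
    return (lam * score - math.log(k)) / math.log(2.0)


def gsat_z(
    a: str | ProteinRecord,
    b: str | ProteinRecord,
    params: AlnParams | None = None,
    n_shuffles: int = 500,
    seed: int = 0,
    mode: str = "both",
) -> GsatResult:
    """Global-alignment shuffle z-score in SD units.

    ``mode="both"`` (default) independently shuffles both sequences each
    iteration; ``mode="second"`` shuffles only ``b``. Homopolymer-like inputs
    whose shuffled scores have zero spread raise
    :class:`DegenerateStatisticsError`.
    """
    if n_shuffles < 100:
        raise ValueError("n_shuffles must be >= 100")
    if mode not in ("both", "second"):
        raise ValueError(f"unknown shuffle mode {mode!r}")
    params = params or AlnParams.gsat_default()
    _, sa = _seq(a)
    _, sb = _seq(b)
    if not sa or not sb:
        raise ValueError("sequences must be non-empty")
    codes, grid = _code_table(params)
    go, ge = int(params.gap_open), int(params.gap_extend)
    ca = _encode(sa, codes)
    cb = _encode(sb, codes)
    raw = float(_k.global_score_coded(ca, cb, grid, go, ge))
    rng = np.random.default_rng(seed)
    scores = np.empty(n_shuffles)
    for i in range(n_shuffles):
        pa = rng.permutation(ca) if mode == "both" else ca
        pb = rng.permutation(cb)
        scores[i] = _k.global_score_coded(pa, pb, grid, go, ge)
    mean = float(scores.mean())
    sd = float(scores.std(ddof=1))
    if sd == 0.0:
        raise DegenerateStatisticsError(
            "all shuffled alignment scores are identical; the z-score is "
            "undefined for (near-)homopolymer inputs"
        )
    return GsatResult(raw, mean, sd, (raw - mean) / sd, n_shuffles, seed, mode)


def trim_to_hydrophobic_core(
    seq: str,
    margin: int = 10,
    window: int = hp.DEFAULT_WINDOW,
    threshold: float = hp.DEFAULT_THRESHOLD,
    min_len: int = hp.DEFAULT_MIN_LEN,
    merge_gap: int = hp.DEFAULT_MERGE_GAP,
) -> tuple[str, int, int]:
    """Drop hydrophilic N-/C-terminal tails before a final z-score.

    Trims to [first TMS peak start - margin, last TMS peak end + margin];
    sequences with no callable peak are returned unchanged. Returns the
    trimmed sequence and its (start, end) on the input.
    """
    if len(seq) < window:
        return seq, 0, len(seq)
    peaks = hp.call_tms_peaks(
        hp.hydropathy_profile(seq, window), threshold, min_len, merge_gap
    )
    if peaks.count == 0:
        return seq, 0, len(seq)
    start = max(0, peaks.intervals[0][0] - margin)
    end = min(len(seq), peaks.intervals[-1][1] + margin)
    return seq[start:end], start, end


def family_similarity_summary(
    family_a: FamilySet,
    family_b: FamilySet | None = None,
    params: AlnParams | None = None,
    cutoffs: Sequence[float] = (1e-3, 1e-10),
) -> dict[float, float]:
    """Fraction of pairs with local-alignment E below each cutoff.

    Within-family mode (``family_b is None``) uses all unordered member
    pairs; between-family mode uses all cross pairs.
    """
    params = params or AlnParams.blast_default()
    if family_b is None:
        if len(family_a) < 2:
            raise ValueError("within-family mode needs >= 2 members")
        pairs = list(combinations(family_a.members, 2))
    else:
        pairs = [(x, y) for x in family_a.members for y in family_b.members]
    evs = []
    for x, y in pairs:
        s = local_score(x.seq, y.seq, params)
        evs.append(evalue(s, len(x.seq), len(y.seq), params))
    evs = np.array(evs)
    return {c: float((evs < c).mean()) for c in cutoffs}


def format_pairwise_report(
    result: AlignmentResult,
    tms_a: "hp.TmsCall | None" = None,
    tms_b: "hp.TmsCall | None" = None,
    block: int = 60,
) -> str:
    """Text report: aligned rows in 60-column blocks, TMS spans marked '='.

    TMS calls are given in coordinates of the full (ungapped) sequences.
    """

    def tms_mask(aligned: str, start: int, call: "hp.TmsCall | None") -> str:
        if call is None:
            return " " * len(aligned)
        inside = set()
        for s, e in call.intervals:
            inside.update(range(s, e))
        out = []
        pos = start
        for c in aligned:
            if c == "-":
                out.append(" ")
            else:
                out.append("=" if pos in inside else " ")
                pos += 1
        return "".join(out)

    mask_a = tms_mask(result.aligned_a, result.start_a, tms_a)
    mask_b = tms_mask(result.aligned_b, result.start_b, tms_b)
    lines = [
        f"# {result.id_a} x {result.id_b}  score={result.score:.1f}  "
        f"identity={result.identity_pct:.1f}%  length={result.length}"
    ]
    for off in range(0, result.length, block):
        sl = slice(off, off + block)
        lines += [
            f"TMS A  {mask_a[sl]}",
            f"{result.id_a[:6]:<6} {result.aligned_a[sl]}",
            f"{result.id_b[:6]:<6} {result.aligned_b[sl]}",
            f"TMS B  {mask_b[sl]}",
            "",
        ]
    return "\n".join(lines)
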
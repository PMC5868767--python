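"""Functional-residue conservation and motif scanning.

Three analyses around a set of *anchor* residues — functionally assigned
positions (e.g. the six calcium-binding residues of a reference structure,
N448/E452 in TMS 6, D503/E506 in TMS 7, E535/D539 in TMS 8):

* anchor mapping — reference positions are mapped through a family MSA;
  members gapped at an anchor column are flagged and excluded from logos;
* motif windows — per-family position-frequency matrices over the column
  ranges between anchor pairs (with the in-between context), rendered as
  information-content logos;
* helical-neighbour scan — because an alpha helix advances ~3.6 residues
  per turn, candidate replacement or helper residues sit 3/4 or 7/8
  positions up- or downstream of an anchor on the same helix face; the scan
  reports per-family fractions of acidic/amide residues (D/E/N/Q, candidate
  Ca2+ ligands) and basic/hydroxyl residues (K/R/S, stabilisers) at those
  offsets.

Position-weight-matrix (PWM) scanning with exact significance is included
for locating externally discovered motifs; motif *discovery* is an optional
wrapper around an external tool.
"""

from __future__ import annotations

import math
import shutil
import subprocess
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .sequence import CANONICAL_AA, GAP, Msa, ProteinRecord

#: helical-turn offsets (~3.6 and ~7.2 residues) as integer positions
HELIX_TURN_OFFSETS = (3, 4, 7, 8)

ACIDIC_AMIDE = set("DENQ")
BASIC_HYDROXYL = set("KRS")


class CapabilityError(RuntimeError):
    """An optional external tool is unavailable."""


@dataclass(frozen=True)
class Anchor:
    """One labelled reference position, e.g. N448 (1-based)."""

    label: str
    position: int  # 1-based on the reference sequence
    tms: int | None = None

    @property
    def residue(self) -> str:
        return self.label[0]


@dataclass
class AnchorSet:
    reference_id: str
    anchors: list[Anchor]

    def validate_against(self, reference_seq: str) -> None:
        for a in self.anchors:
            if not 1 <= a.position <= len(reference_seq):
                raise ValueError(
                    f"anchor {a.label} beyond reference length {len(reference_seq)}"
                )
            if reference_seq[a.position - 1] != a.residue:
                raise ValueError(
                    f"anchor {a.label}: reference has "
                    f"{reference_seq[a.position - 1]!r} at position {a.position}"
                )


@dataclass
class AnchorMapping:
    """Anchor -> 0-based MSA column, with per-row gap flags."""

    columns: dict[str, int]  # anchor label -> column index
    flagged_rows: dict[str, list[str]]  # anchor label -> row ids gapped there

    def excluded_rows(self) -> set[str]:
        return {rid for rows in self.flagged_rows.values() for rid in rows}


def map_anchors_to_msa(msa: Msa, anchor_set: AnchorSet) -> AnchorMapping:
    """Map reference anchor positions through the reference row's gaps.

    In a gap-free alignment the 1-based anchor position equals the 1-based
    column. Rows carrying a gap at a mapped column are flagged; flagged rows
    are excluded from downstream logos.
    """
    ref_row = msa.row(anchor_set.reference_id)
    anchor_set.validate_against(ref_row.replace(GAP, ""))
    # residue index (0-based) -> column index for the reference row
    res_to_col = [j for j, c in enumerate(ref_row) if c != GAP]
    columns: dict[str, int] = {}
    flagged: dict[str, list[str]] = {}
    for a in anchor_set.anchors:
        col = res_to_col[a.position - 1]
        columns[a.label] = col
        flagged[a.label] = [
            rid for rid, row in zip(msa.ids, msa.rows) if row[col] == GAP
        ]
    return AnchorMapping(columns, flagged)


@dataclass
class MotifWindow:
    """Per-column residue frequencies over one anchored window."""

    name: str
    columns: np.ndarray  # original MSA column indices
    frequencies: pd.DataFrame  # index: alphabet, columns: window positions
    n_rows: int

    def information_content(self) -> np.ndarray:
        """Per-column information content in bits (0 .. log2 20)."""
        f = self.frequencies.to_numpy()
        with np.errstate(divide="ignore", invalid="ignore"):
            h = np.where(f > 0, -f * np.log2(f), 0.0).sum(axis=0)
        return np.log2(len(CANONICAL_AA)) - h


@dataclass
class MotifWindowSet:
    family: str
    windows: list[MotifWindow]


def build_motif_windows(
    msa: Msa,
    mapping: AnchorMapping,
    pairs: Sequence[tuple[str, str]],
    names: Sequence[str] | None = None,
    exclude_rows: set[str] | None = None,
    family: str = "",
) -> MotifWindowSet:
    """Frequency matrices between pairs of anchor columns (inclusive).

    ``pairs`` are (first anchor label, second anchor label); context columns
    between them are included. Rows flagged at any anchor (or listed in
    ``exclude_rows``) do not contribute.
    """
    excluded = (exclude_rows or set()) | mapping.excluded_rows()
    keep = [i for i, rid in enumerate(msa.ids) if rid not in excluded]
    if not keep:
        raise ValueError("no unflagged rows left for this family")
    names = list(names) if names else [f"motif_{k + 1}" for k in range(len(pairs))]
    windows = []
    for name, (lab1, lab2) in zip(names, pairs):
        c1, c2 = mapping.columns[lab1], mapping.columns[lab2]
        lo, hi = min(c1, c2), max(c1, c2)
        cols = np.arange(lo, hi + 1)
        freq = np.zeros((len(CANONICAL_AA), len(cols)))
        counts = np.zeros(len(cols))
        for i in keep:
            row = msa.rows[i]
            for k, j in enumerate(cols):
                ch = row[j]
                if ch in CANONICAL_AA:
                    freq[CANONICAL_AA.index(ch), k] += 1
                    counts[k] += 1
        with np.errstate(invalid="ignore"):
            freq = np.where(counts > 0, freq / np.maximum(counts, 1), 0.0)
        windows.append(
            MotifWindow(
                name=name,
                columns=cols,
                frequencies=pd.DataFrame(
                    freq, index=list(CANONICAL_AA),
                    columns=[int(c) + 1 for c in cols],
                ),
                n_rows=len(keep),
            )
        )
    return MotifWindowSet(family=family, windows=windows)


def helical_neighbor_scan(
    msa: Msa,
    mapping: AnchorMapping,
    offsets: Sequence[int] = HELIX_TURN_OFFSETS,
    exclude_rows: set[str] | None = None,
    family: str = "",
) -> pd.DataFrame:
    """Fractions of candidate Ca2+-ligand (D/E/N/Q) and stabiliser (K/R/S)
    residues at helical-turn offsets around each anchor.

    Offsets are applied in *ungapped member coordinates* in both directions;
    positions falling outside a member are counted as unavailable. Returns a
    tidy frame (family, anchor, offset, n, frac_denq, frac_krs).
    """
    excluded = exclude_rows or set()
    rows = []
    for label, col in mapping.columns.items():
        flagged = set(mapping.flagged_rows[label])
        for off in sorted({o for x in offsets for o in (x, -x)}):
            n = denq = krs = 0
            for rid, row in zip(msa.ids, msa.rows):
                if rid in excluded or rid in flagged:
                    continue
                # ungapped position of the anchor column in this member
                pos = sum(1 for c in row[: col + 1] if c != GAP) - 1
                seq = row.replace(GAP, "")
                tgt = pos + off
                if not 0 <= tgt < len(seq):
                    continue
                n += 1
                denq += seq[tgt] in ACIDIC_AMIDE
                krs += seq[tgt] in BASIC_HYDROXYL
            rows.append(
                {
                    "family": family,
                    "anchor": label,
                    "offset": off,
                    "n": n,
                    "frac_denq": denq / n if n else 0.0,
                    "frac_krs": krs / n if n else 0.0,
                }
            )
    return pd.DataFrame(rows)


# -- PWM scanning -----------------------------------------------------------


@dataclass
class Pwm:
    """Log-odds position weight matrix (bits) over the 20-letter alphabet."""

    name: str
    log_odds: np.ndarray  # shape (20, width)
    background: np.ndarray  # shape (20,)

    def __post_init__(self) -> None:
        self.log_odds = np.asarray(self.log_odds, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.log_odds.shape[0] != len(CANONICAL_AA):
            raise ValueError("log-odds matrix must have 20 rows")
        if self.width < 1:
            raise ValueError("PWM width must be >= 1")
        if not np.all(np.isfinite(self.log_odds)):
            raise ValueError("log-odds entries must be finite")

    @property
    def width(self) -> int:
        return self.log_odds.shape[1]

    @classmethod
    def from_counts(
        cls,
        counts: np.ndarray,
        background: np.ndarray | None = None,
        pseudocount: float = 0.1,
        name: str = "pwm",
    ) -> "Pwm":
        counts = np.asarray(counts, dtype=float)
        bg = (
            np.full(len(CANONICAL_AA), 1.0 / len(CANONICAL_AA))
            if background is None
            else np.asarray(background, dtype=float)
        )
        bg = bg / bg.sum()
        probs = (counts + pseudocount) / (counts.sum(axis=0) + pseudocount * len(CANONICAL_AA))
        return cls(name, np.log2(probs / bg[:, None]), bg)

    @classmethod
    def from_sequences(
        cls,
        seqs: Sequence[str],
        background: np.ndarray | None = None,
        pseudocount: float = 0.1,
        name: str = "pwm",
    ) -> "Pwm":
        if not seqs:
            raise ValueError("no sequences")
        w = len(seqs[0])
        if any(len(s) != w for s in seqs):
            raise ValueError("sequences must have equal length")
        counts = np.zeros((len(CANONICAL_AA), w))
        for s in seqs:
            for j, ch in enumerate(s):
                if ch in CANONICAL_AA:
                    counts[CANONICAL_AA.index(ch), j] += 1
        return cls.from_counts(counts, background, pseudocount, name)

    def consensus(self) -> str:
        return "".join(
            CANONICAL_AA[i] for i in np.argmax(self.log_odds, axis=0)
        )


@dataclass
class PwmHit:
    record_id: str
    motif: str
    offset: int  # 0-based on the sequence
    score: float  # bits
    pvalue: float
    evalue: float


def _score_distribution(pwm: Pwm, precision: float = 1e-3) -> dict[int, float]:
    """Exact null distribution of window scores under the background, by
    dynamic programming over columns (scores discretised to ``precision``).

    Implemented as a dense convolution over the integer score grid so wide
    PWMs stay cheap; returns only bins with non-zero mass.
    """
    cols = [
        np.round(pwm.log_odds[:, j] / precision).astype(np.int64)
        for j in range(pwm.width)
    ]
    # running support starts at offset 0 relative to its own minimum
    cur = np.array([1.0])
    cur_lo = 0
    for c in cols:
        width = len(cur) + int(c.max()) - int(c.min())
        nxt = np.zeros(width)
        for key, b in zip(c, pwm.background):
            off = int(key) - int(c.min())
            nxt[off : off + len(cur)] += b * cur
        cur = nxt
        cur_lo += int(c.min())
    nz = np.nonzero(cur)[0]
    return {int(cur_lo + i): float(cur[i]) for i in nz}


def pwm_scan(
    pwm: Pwm,
    record: ProteinRecord | str,
    max_evalue: float = 1e-5,
    precision: float = 1e-3,
) -> list[PwmHit]:
    """Scan every offset of a sequence with a PWM and keep significant hits.

    P-values come from the exact dynamic-programming null over the PWM's
    background; a hit's E-value is its p-value times the number of scanned
    offsets. Hits with E below ``max_evalue`` are returned best first.
    """
    rid, seq = (record.id, record.seq) if isinstance(record, ProteinRecord) else ("seq", record)
    if pwm.width > len(seq):
        raise ValueError(
            f"PWM width {pwm.width} exceeds sequence length {len(seq)}"
        )
    n_offsets = len(seq) - pwm.width + 1
    dist = _score_distribution(pwm, precision)
    keys = np.array(sorted(dist))
    probs = np.array([dist[k] for k in keys])
    tail = np.cumsum(probs[::-1])[::-1]  # P(score >= key)

    idx = {c: i for i, c in enumerate(CANONICAL_AA)}
    hits = []
    for off in range(n_offsets):
        window = seq[off : off + pwm.width]
        score = 0.0
        ok = True
        for j, ch in enumerate(window):
            if ch not in idx:
                ok = False
                break
            score += pwm.log_odds[idx[ch], j]
        if not ok:
            continue
        key = int(round(score / precision))
        pos = np.searchsorted(keys, key, side="left")
        pval = float(tail[pos]) if pos < len(keys) else 0.0
        ev = pval * n_offsets
        if ev < max_evalue:
            hits.append(PwmHit(rid, pwm.name, off, score, pval, ev))
    hits.sort(key=lambda h: (h.evalue, h.offset))
    return hits


def scan_records(
    pwms: Sequence[Pwm], records: Sequence[ProteinRecord], max_evalue: float = 1e-5
) -> pd.DataFrame:
    """MAST-like block table: best placements of each motif in each record."""
    rows = []
    for rec in records:
        for pwm in pwms:
            for h in pwm_scan(pwm, rec, max_evalue):
                rows.append(
                    {
                        "record": h.record_id,
                        "motif": h.motif,
                        "offset": h.offset + 1,  # 1-based for reports
                        "score_bits": h.score,
                        "evalue": h.evalue,
                    }
                )
    return pd.DataFrame(
        rows, columns=["record", "motif", "offset", "score_bits", "evalue"]
    )


def run_external_motif_discovery(
    records: Sequence[ProteinRecord],
    n_motifs: int = 3,
    min_width: int = 20,
    max_width: int = 60,
    tool: str = "meme",
) -> list[Pwm]:
    """Optional wrapper around an external motif-discovery tool.

    Raises :class:`CapabilityError` when the tool is not on PATH; never
    falls back silently. Motif *scanning* (`pwm_scan`) is self-contained.
    """
    if not records:
        raise ValueError("no input sequences")
    path = shutil.which(tool)
    if path is None:
        raise CapabilityError(
            f"external motif discovery requires {tool!r} on PATH"
        )
    import tempfile
    from .sequence import write_fasta

    with tempfile.TemporaryDirectory() as tmp:
        fasta = f"{tmp}/input.faa"
        write_fasta(records, fasta)
        out = subprocess.run(
            [
                path, fasta, "-protein", "-nmotifs", str(n_motifs),
                "-minw", str(min_width), "-maxw", str(max_width),
                "-text",
            ],
            capture_output=True,
            text=True,
        )
        if out.returncode != 0:
            raise CapabilityError(f"{tool} failed: {out.stderr[:500]}")
        return _parse_meme_text(out.stdout)


def _parse_meme_text(text: str) -> list[Pwm]:
    """Parse probability matrices from MEME's text output."""
    pwms = []
    lines = text.splitlines()
    i = 0
    while i < len(lines):
        line = lines[i]
        if "position-specific probability matrix" in line.lower():
            name = line.split()[1] if len(line.split()) > 1 else f"motif_{len(pwms) + 1}"
            i += 1
            rows = []
            while i < len(lines):
                parts = lines[i].split()
                if len(parts) == 20 and all(_is_float(p) for p in parts):
                    rows.append([float(p) for p in parts])
                elif rows:
                    break
                i += 1
            if rows:
                probs = np.array(rows).T  # (20, width), MEME order = alphabetical
                pwms.append(
                    Pwm.from_counts(probs * 1000, name=name)
                )
        i += 1
    return pwms


def _is_float(x: str) -> bool:
    try:
        float(x)
        return True
    except ValueError:
        return False
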
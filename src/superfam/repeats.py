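"""Internal repeat detection.

Two complementary scans:

* sequence level — a two-region shuffle z-score: two non-overlapping stretches
  of a protein (chosen from averaged-hydropathy plots, e.g. first half vs
  second half) are globally aligned and scored against shuffled controls;
  a tandem duplication produces a z-score far above any homology threshold,
  while unrelated halves stay in the null band.
* structure level — consecutive, non-overlapping bundles of 3/4/5
  membrane-spanning helices are rigidly superposed (Kabsch on C-alpha atoms,
  sequential helix correspondence), with or without the connecting loops.
  A superposition is significant when RMSD < 4 A over at least 60 residues.

Helix correspondence is restricted to sequential order (helix i onto helix
i); no combinatorial secondary-structure rematching is attempted, so RMSD
values for real structures are approximate relative to graph-matching
superposition algorithms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio.SVDSuperimposer import SVDSuperimposer

from .sequence import ProteinRecord

#: Significance rule for bundle superpositions.
RMSD_CUTOFF = 4.0
MIN_ALIGNED_RESIDUES = 60

MIN_REPEAT_REGION = 40


@dataclass
class HelixBundle:
    """Ordered C-alpha coordinate segments for a set of helices.

    ``helices[i]`` is an (n_i, 3) array; ``helix_residues[i]`` the matching
    residue numbers; ``loops[i]`` (optional) connects helix i to helix i+1.
    """

    source: str
    helices: list[np.ndarray]
    helix_residues: list[np.ndarray] = field(default_factory=list)
    loops: list[np.ndarray] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.helices:
            raise ValueError("a bundle needs at least one helix")
        for h in self.helices:
            if len(h) < 4:
                raise ValueError("each helix needs >= 4 residues")
        if not self.helix_residues:
            res = 1
            for h in self.helices:
                self.helix_residues.append(np.arange(res, res + len(h)))
                res += len(h)

    @property
    def n_helices(self) -> int:
        return len(self.helices)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "HelixBundle":
        """The bundle under a rigid transform x -> x @ R + t."""
        return HelixBundle(
            source=self.source,
            helices=[h @ rotation + translation for h in self.helices],
            helix_residues=[r.copy() for r in self.helix_residues],
            loops=[l @ rotation + translation for l in self.loops],
        )


@dataclass
class BundleAlignment:
    """Result of superposing two equal-sized helix bundles."""

    bundle_a: str
    bundle_b: str
    rmsd: float
    n_residues: int
    loops_excluded: bool

    @property
    def significant(self) -> bool:
        return self.rmsd < RMSD_CUTOFF and self.n_residues >= MIN_ALIGNED_RESIDUES


# -- sequence-level scan ----------------------------------------------------


def sequence_repeat_scan(
    seq: str | ProteinRecord,
    region_a: tuple[int, int],
    region_b: tuple[int, int],
    params=None,
    shuffles: int = 1000,
    seed: int = 0,
):
    """Shuffle z-score between two non-overlapping regions of one sequence.

    Regions are 0-based half-open intervals of at least
    ``MIN_REPEAT_REGION`` residues. Returns a
    :class:`superfam.alignment.GsatResult`.
    """
    from .alignment import AlnParams, gsat_z

    s = seq.seq if isinstance(seq, ProteinRecord) else seq
    (a0, a1), (b0, b1) = sorted((tuple(region_a), tuple(region_b)))
    if a1 > b0:
        raise ValueError(f"regions overlap: {region_a} vs {region_b}")
    for lo, hi in (region_a, region_b):
        if hi - lo < MIN_REPEAT_REGION:
            raise ValueError(f"region ({lo}, {hi}) shorter than {MIN_REPEAT_REGION}")
        if lo < 0 or hi > len(s):
            raise ValueError(f"region ({lo}, {hi}) outside sequence of length {len(s)}")
    params = params or AlnParams.gsat_default()
    return gsat_z(
        s[region_a[0] : region_a[1]],
        s[region_b[0] : region_b[1]],
        params,
        n_shuffles=shuffles,
        seed=seed,
    )


# -- structural scan --------------------------------------------------------


def read_calpha(path: str | Path, chain: str | None = None):
    """C-alpha residue numbers and coordinates from a PDB file.

    Returns (res_ids, coords) sorted by residue number.
    """
    import biotite.structure.io.pdb as pdb

    arr = pdb.PDBFile.read(str(path)).get_structure(model=1)
    mask = arr.atom_name == "CA"
    if chain is not None:
        mask &= arr.chain_id == chain
    sub = arr[mask]
    order = np.argsort(sub.res_id, kind="stable")
    return sub.res_id[order], sub.coord[order]


def enumerate_bundles(
    res_ids: np.ndarray,
    coords: np.ndarray,
    tms_ranges: list[tuple[int, int]],
    bundle_size: int,
    source: str = "structure",
) -> list[HelixBundle]:
    """Consecutive non-overlapping windows of ``bundle_size`` helices.

    ``tms_ranges`` are 1-based inclusive residue ranges of the
    membrane-spanning helices, in sequence order; residues between
    consecutive helices of a bundle become its loops.
    """
    if len(tms_ranges) < bundle_size:
        raise ValueError(
            f"{len(tms_ranges)} helices cannot form a bundle of {bundle_size}"
        )
    by_res = {int(r): coords[i] for i, r in enumerate(res_ids)}

    def segment(lo: int, hi: int) -> np.ndarray:
        pts = [by_res[r] for r in range(lo, hi + 1) if r in by_res]
        return np.array(pts).reshape(-1, 3)

    bundles = []
    n_full = len(tms_ranges) // bundle_size
    for k in range(n_full):
        ranges = tms_ranges[k * bundle_size : (k + 1) * bundle_size]
        helices = [segment(lo, hi) for lo, hi in ranges]
        helix_res = [
            np.array([r for r in range(lo, hi + 1) if r in by_res])
            for lo, hi in ranges
        ]
        loops = [
            segment(ranges[i][1] + 1, ranges[i + 1][0] - 1)
            for i in range(bundle_size - 1)
        ]
        first, last = ranges[0][0], ranges[-1][1]
        bundles.append(
            HelixBundle(
                source=f"{source}:TMS{k * bundle_size + 1}-{(k + 1) * bundle_size}"
                f"({first}-{last})",
                helices=helices,
                helix_residues=helix_res,
                loops=loops,
            )
        )
    return bundles


def _centered_offsets(short: int, long: int) -> int:
    return (long - short) // 2


def _gather(bundle: HelixBundle, lengths: list[int], offsets: list[int],
            exclude_loops: bool, loop_lengths: list[int]) -> np.ndarray:
    parts = [
        bundle.helices[i][offsets[i] : offsets[i] + lengths[i]]
        for i in range(bundle.n_helices)
    ]
    if not exclude_loops:
        for i, n in enumerate(loop_lengths):
            if n > 0:
                loop = bundle.loops[i]
                off = _centered_offsets(n, len(loop))
                parts.append(loop[off : off + n])
    return np.concatenate(parts, axis=0)


def superpose_bundles(
    a: HelixBundle, b: HelixBundle, exclude_loops: bool = True
) -> BundleAlignment:
    """Optimal rigid (Kabsch) superposition with sequential helix pairing.

    When corresponding helices differ in length, the shorter is slid along
    the longer and the offset minimising the overall RMSD is kept (one
    refinement pass per helix, deterministic). Loops are compared centre-
    trimmed to equal length when included.
    """
    if a.n_helices != b.n_helices:
        raise ValueError(
            f"helix-count mismatch: {a.n_helices} vs {b.n_helices}"
        )
    n = a.n_helices
    lengths = [min(len(a.helices[i]), len(b.helices[i])) for i in range(n)]
    off_a = [_centered_offsets(lengths[i], len(a.helices[i])) for i in range(n)]
    off_b = [_centered_offsets(lengths[i], len(b.helices[i])) for i in range(n)]
    if exclude_loops or not a.loops or not b.loops:
        loop_lengths: list[int] = []
        use_loops = True if exclude_loops else False
        exclude = True
    else:
        loop_lengths = [
            min(len(a.loops[i]), len(b.loops[i])) for i in range(n - 1)
        ]
        exclude = False

    sup = SVDSuperimposer()

    def rmsd_for(off_a_trial, off_b_trial) -> float:
        xa = _gather(a, lengths, off_a_trial, exclude, loop_lengths)
        xb = _gather(b, lengths, off_b_trial, exclude, loop_lengths)
        sup.set(xa, xb)
        sup.run()
        return float(sup.get_rms())

    best = rmsd_for(off_a, off_b)
    # slide each shorter helix along its longer partner, one pass
    for i in range(n):
        for side, offs, helix in (("a", off_a, a.helices[i]), ("b", off_b, b.helices[i])):
            max_off = len(helix) - lengths[i]
            if max_off == 0:
                continue
            for trial in range(max_off + 1):
                cand = list(offs)
                cand[i] = trial
                r = rmsd_for(cand if side == "a" else off_a,
                             cand if side == "b" else off_b)
                if r < best - 1e-12:
                    best = r
                    offs[i] = trial
    n_res = sum(lengths) + sum(loop_lengths)
    return BundleAlignment(
        bundle_a=a.source,
        bundle_b=b.source,
        rmsd=best,
        n_residues=n_res,
        loops_excluded=exclude,
    )


def scan_structure_repeats(
    res_ids: np.ndarray,
    coords: np.ndarray,
    tms_ranges: list[tuple[int, int]],
    bundle_sizes: tuple[int, ...] = (3, 4, 5),
    exclude_loops: bool = False,
    source: str = "structure",
) -> list[BundleAlignment]:
    """All pairwise superpositions of non-overlapping equal-size bundles."""
    results = []
    for size in bundle_sizes:
        if len(tms_ranges) < 2 * size:
            continue
        bundles = enumerate_bundles(res_ids, coords, tms_ranges, size, source)
        for i in range(len(bundles)):
            for j in range(i + 1, len(bundles)):
                results.append(
                    superpose_bundles(bundles[i], bundles[j], exclude_loops)
                )
    return results


def bundle_to_pdb(bundle: HelixBundle, path: str | Path) -> None:
    """Write a bundle as CA-only ATOM records (helices then loops)."""
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdb

    coords = []
    res_ids = []
    for i, h in enumerate(bundle.helices):
        coords.append(h)
        res_ids.extend(bundle.helix_residues[i].tolist())
        if i < len(bundle.loops):
            loop = bundle.loops[i]
            coords.append(loop)
            start = bundle.helix_residues[i][-1] + 1
            res_ids.extend(range(start, start + len(loop)))
    coords = np.concatenate(coords, axis=0)
    arr = struc.AtomArray(len(coords))
    arr.coord = coords
    arr.chain_id = np.full(len(coords), "A")
    arr.res_id = np.array(res_ids[: len(coords)])
    arr.res_name = np.full(len(coords), "ALA")
    arr.atom_name = np.full(len(coords), "CA")
    arr.element = np.full(len(coords), "C")
    f = pdb.PDBFile()
    f.set_structure(arr)
    f.write(str(path))
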
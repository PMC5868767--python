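"""Ground-truth generators for every pipeline stage.

Synthetic multi-spanning membrane proteins are built as alternating
hydrophobic segments (TMSs, drawn from an I/L/V/F/A/M-weighted pool) and
hydrophilic loops (D/E/K/R/S/T/N/Q/G/P-weighted), so that windowed
Kyte-Doolittle profiles show one clean peak per planted TMS. Families are
produced by substituting and indel-ing an ancestor; substitutions are
biased by exponentiated BLOSUM62 scores, which conserves hydrophobicity
class — negative-control families therefore share TMS architecture and
composition with the positives without sharing ancestry, which is exactly
the hard null a shuffle-calibrated homology statistic must beat.

Every generator is a pure function of (spec, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from Bio.Align import substitution_matrices

from .sequence import CANONICAL_AA, FamilySet, ProteinRecord
from .repeats import HelixBundle

# -- residue pools ----------------------------------------------------------

TMS_POOL = {
    "I": 0.22, "L": 0.22, "V": 0.18, "F": 0.14, "A": 0.10, "M": 0.08,
    "C": 0.03, "G": 0.02, "W": 0.01,
}
LOOP_POOL = {
    "D": 0.09, "E": 0.09, "K": 0.09, "R": 0.07, "S": 0.10, "T": 0.08,
    "N": 0.08, "Q": 0.07, "G": 0.10, "P": 0.09, "A": 0.05, "H": 0.04,
    "Y": 0.05,
}


def _draw(pool: dict[str, float], n: int, rng: np.random.Generator) -> str:
    letters = np.array(list(pool))
    probs = np.array(list(pool.values()))
    probs = probs / probs.sum()
    return "".join(rng.choice(letters, size=n, p=probs))


# -- specs ------------------------------------------------------------------


@dataclass(frozen=True)
class PlantedMotif:
    """A conserved motif written into the ancestor at ``position`` (0-based)
    and protected from substitution with probability ``conservation``."""

    position: int
    consensus: str
    conservation: float = 0.9


@dataclass(frozen=True)
class FamilySpec:
    """Statistical architecture of one synthetic membrane-protein family.

    Defaults emulate a compact 10-TMS family (~700 aa mean length, the low
    end of the real superfamily's size range).
    """

    label: str = "9.S.1.1"
    n_members: int = 3
    n_tms: int = 10
    tms_len_mean: float = 21.0
    tms_len_sd: float = 2.0
    loop_len_mean: float = 45.0
    loop_len_sd: float = 12.0
    term_len_mean: float = 40.0
    term_len_sd: float = 10.0
    #: per-site substitution probability applied to each member independently
    substitution_rate: float = 0.03
    #: per-loop-site indel probability per member
    indel_rate: float = 0.003
    planted_motifs: tuple[PlantedMotif, ...] = ()

    def __post_init__(self) -> None:
        if not 0 <= self.substitution_rate <= 1 or not 0 <= self.indel_rate <= 1:
            raise ValueError("rates must be in [0, 1]")
        if self.n_tms < 0:
            raise ValueError("n_tms must be >= 0")
        if min(self.tms_len_mean, self.loop_len_mean, self.term_len_mean) < 0:
            raise ValueError("segment lengths must be non-negative")


@dataclass(frozen=True)
class SuperfamilySpec:
    """A chain of related families plus independent negative controls.

    The ``chain`` families descend from a common root: each chain
    neighbour's ancestor is derived from the previous one through several
    deep sub-steps of divergence, and every intermediate sequence is
    emitted into the output database — the bridge material that a
    famXpander-style expansion recovers and that transitivity paths run
    through. Adjacent families are therefore demonstrably related through
    bridges while chain-end families compare like negative controls.
    ``unrelated`` families are generated independently with the same TMS
    architecture.
    """

    chain: tuple[FamilySpec, ...] = ()
    unrelated: tuple[FamilySpec, ...] = ()
    #: residual sequence identity across one chain edge (between adjacent
    #: family ancestors); the edge is realised as bridges_per_edge + 1
    #: equal sub-steps and every intermediate is emitted into the database
    #: as a bridge sequence
    edge_identity: float = 0.25
    bridges_per_edge: int = 2
    emit_bridges: bool = True

    @property
    def step_rate(self) -> float:
        return 1.0 - self.edge_identity ** (1.0 / (self.bridges_per_edge + 1))


@dataclass
class FamilySample:
    family: FamilySet
    ancestor: ProteinRecord
    tms_truth: dict[str, list[tuple[int, int]]]
    #: per member id, list mapping member position -> ancestor position (or None)
    homology_map: dict[str, list[int | None]]


@dataclass
class SuperfamilySample:
    families: list[FamilySet]
    ancestors: dict[str, ProteinRecord]
    tms_truth: dict[str, list[tuple[int, int]]]
    related_pairs: set[frozenset[str]]
    db: list[ProteinRecord]


def study_superfamily_spec(
    n_chain: int = 3,
    n_unrelated: int = 2,
    within_identity: float = 0.94,
    edge_identity: float = 0.25,
    n_members: int = 3,
) -> SuperfamilySpec:
    """The default study conditions: a chain of related 10-TMS families plus
    composition-matched unrelated controls.

    An edge identity of 0.25, realised as three sub-steps with full
    segment-length remodelling and two emitted bridges per edge, puts
    bridge-mediated path legs (two-thirds of an edge at most, ~40%
    identity) far above the control band, while the chain-end direct
    comparison — two full edges, ~6% residual identity — falls inside it.
    Only the bridged transitivity path demonstrates the chain ends'
    homology.
    """
    rate = rate_for_identity(within_identity)
    chain = tuple(
        replace(FamilySpec(), label=f"9.S.1.{i + 1}", n_members=n_members,
                substitution_rate=rate)
        for i in range(n_chain)
    )
    unrelated = tuple(
        replace(FamilySpec(), label=f"9.S.2.{i + 1}", n_members=n_members,
                substitution_rate=rate)
        for i in range(n_unrelated)
    )
    return SuperfamilySpec(
        chain=chain, unrelated=unrelated, edge_identity=edge_identity
    )


def generate_control_families(
    n_families: int = 16,
    within_identity: float = 0.94,
    seed: int = 977,
    n_members: int = 3,
) -> list[FamilySample]:
    """Independent, architecture-matched control families for threshold
    calibration. All families share one label namespace (9.S.8.*) and are
    meant to be searched against their pooled members, so control scores
    experience the same common-junk-hit selection pressure as real
    verdicts."""
    rng = np.random.default_rng(seed)
    rate = rate_for_identity(within_identity)
    out = []
    for i in range(n_families):
        fs = replace(
            FamilySpec(), label=f"9.S.8.{i + 1}", n_members=n_members,
            substitution_rate=rate,
        )
        out.append(generate_family(fs, int(rng.integers(2**31))))
    return out


def rate_for_identity(target_identity: float) -> float:
    """Per-member substitution rate giving ~``target_identity`` pairwise
    identity between two members mutated independently from one ancestor."""
    if not 0 < target_identity <= 1:
        raise ValueError("identity must be in (0, 1]")
    return 1.0 - math.sqrt(target_identity)


# -- substitution machinery -------------------------------------------------

_SUB_PROBS: dict[str | None, dict[str, np.ndarray]] = {}
_SUB_TEMPERATURE = 2.0


def _substitution_probs(segment: str | None = None) -> dict[str, np.ndarray]:
    """P(b | a) ∝ exp(BLOSUM62[a, b] / T) * pool(b) over b != a.

    ``segment`` selects the structural constraint: "tms" weights
    replacements by the hydrophobic pool (a residue buried in the membrane
    stays membrane-compatible), "loop" by the hydrophilic pool, None applies
    no compositional constraint.
    """
    if segment not in _SUB_PROBS:
        mat = substitution_matrices.load("BLOSUM62")
        pool = {"tms": TMS_POOL, "loop": LOOP_POOL, None: None}[segment]
        probs = {}
        for a in CANONICAL_AA:
            w = np.array(
                [
                    0.0
                    if b == a
                    else math.exp(mat[a, b] / _SUB_TEMPERATURE)
                    * (1.0 if pool is None else pool.get(b, 0.0))
                    for b in CANONICAL_AA
                ]
            )
            if w.sum() == 0.0:  # residue foreign to the pool: unconstrained
                w = np.array(
                    [
                        0.0 if b == a else math.exp(mat[a, b] / _SUB_TEMPERATURE)
                        for b in CANONICAL_AA
                    ]
                )
            probs[a] = w / w.sum()
        _SUB_PROBS[segment] = probs
    return _SUB_PROBS[segment]


def mutate_sequence(
    seq: str,
    rate: float,
    rng: np.random.Generator,
    protected: dict[int, float] | None = None,
    tms_intervals: list[tuple[int, int]] | None = None,
) -> str:
    """Matrix-biased point substitution at per-site probability ``rate``.

    ``protected`` maps 0-based positions to a conservation level c in [0, 1];
    a protected site is substituted with probability rate * (1 - c).
    With ``tms_intervals``, replacements inside those intervals are
    restricted to membrane-compatible residues and replacements outside to
    loop-compatible ones, so divergence never erodes the TMS architecture.
    """
    if tms_intervals is not None:
        in_tms = np.zeros(len(seq), dtype=bool)
        for s, e in tms_intervals:
            in_tms[s:e] = True
        probs_by_site = lambda i: _substitution_probs("tms" if in_tms[i] else "loop")
    else:
        probs_by_site = lambda i: _substitution_probs(None)
    letters = np.array(list(CANONICAL_AA))
    out = list(seq)
    hit = rng.random(len(seq))
    for i, ch in enumerate(seq):
        p = rate
        if protected and i in protected:
            p = rate * (1.0 - protected[i])
        if hit[i] < p and ch in CANONICAL_AA:
            out[i] = str(rng.choice(letters, p=probs_by_site(i)[ch]))
    return "".join(out)


def evolve_ancestor(
    seq: str,
    tms: list[tuple[int, int]],
    rate: float,
    rng: np.random.Generator,
    loop_len_mean: float = 45.0,
    loop_len_sd: float = 12.0,
    term_len_mean: float = 40.0,
    term_len_sd: float = 10.0,
    tms_len_mean: float = 21.0,
    tms_len_sd: float = 2.0,
    min_loop: int = 18,
) -> tuple[str, list[tuple[int, int]]]:
    """Derive a new family ancestor: deep substitution plus remodelling.

    Content is substituted at ``rate`` under the segment-conditioned pools;
    every segment is then resampled to a fresh length from the family's
    length distributions — loops and termini trimmed or padded at their
    centre with fresh hydrophilic residues, TMSs at their C-terminal end
    with fresh membrane-pool residues. One application yields an adjacent
    family whose similarity is carried by residue content; because segment
    lengths are redrawn independently at every application, repeated
    applications leave no architectural correlation, and chain-end families
    compare like negative controls.
    """
    subbed = mutate_sequence(seq, rate, rng, tms_intervals=tms)
    bounds = [0] + [x for s, e in tms for x in (s, e)] + [len(seq)]
    segments = []  # (is_tms, subsequence)
    for k in range(len(bounds) - 1):
        lo, hi = bounds[k], bounds[k + 1]
        is_tms = k % 2 == 1
        segments.append((is_tms, subbed[lo:hi]))
    parts: list[str] = []
    new_tms: list[tuple[int, int]] = []
    pos = 0
    n_seg = len(segments)
    for k, (is_tms, sub) in enumerate(segments):
        if is_tms:
            target = max(18, int(round(rng.normal(tms_len_mean, tms_len_sd))))
            if target < len(sub):
                sub = sub[:target]
            elif target > len(sub):
                sub = sub + _draw(TMS_POOL, target - len(sub), rng)
            new_tms.append((pos, pos + len(sub)))
            parts.append(sub)
            pos += len(sub)
            continue
        terminal = k == 0 or k == n_seg - 1
        mean, sd = (term_len_mean, term_len_sd) if terminal else (loop_len_mean, loop_len_sd)
        target = max(5 if terminal else min_loop, int(round(rng.normal(mean, sd))))
        mid = len(sub) // 2
        if target < len(sub):
            cut = len(sub) - target
            sub = sub[: mid - cut // 2] + sub[mid + (cut - cut // 2) :]
        elif target > len(sub):
            sub = sub[:mid] + _draw(LOOP_POOL, target - len(sub), rng) + sub[mid:]
        parts.append(sub)
        pos += len(sub)
    return "".join(parts), new_tms


# -- generators -------------------------------------------------------------


def _seg_len(mean: float, sd: float, rng: np.random.Generator, lo: int) -> int:
    return max(lo, int(round(rng.normal(mean, sd))))


def generate_membrane_protein(
    spec: FamilySpec, seed: int, record_id: str = "synthetic"
) -> tuple[ProteinRecord, list[tuple[int, int]]]:
    """One synthetic multi-TMS protein plus its true TMS intervals
    (0-based, half-open)."""
    rng = np.random.default_rng(seed)
    parts: list[str] = []
    tms: list[tuple[int, int]] = []
    pos = 0
    nterm = _draw(LOOP_POOL, _seg_len(spec.term_len_mean, spec.term_len_sd, rng, 5), rng)
    parts.append(nterm)
    pos += len(nterm)
    for k in range(spec.n_tms):
        seg = _draw(TMS_POOL, _seg_len(spec.tms_len_mean, spec.tms_len_sd, rng, 18), rng)
        tms.append((pos, pos + len(seg)))
        parts.append(seg)
        pos += len(seg)
        if k < spec.n_tms - 1:
            loop = _draw(
                LOOP_POOL, _seg_len(spec.loop_len_mean, spec.loop_len_sd, rng, 18), rng
            )
            parts.append(loop)
            pos += len(loop)
    cterm = _draw(LOOP_POOL, _seg_len(spec.term_len_mean, spec.term_len_sd, rng, 5), rng)
    parts.append(cterm)
    seq = "".join(parts)
    for m in spec.planted_motifs:
        if m.position + len(m.consensus) > len(seq):
            raise ValueError(f"planted motif at {m.position} exceeds sequence length")
        seq = seq[: m.position] + m.consensus + seq[m.position + len(m.consensus) :]
    return ProteinRecord(id=record_id, seq=seq, family=None), tms


def _loop_mask(length: int, tms: list[tuple[int, int]]) -> np.ndarray:
    mask = np.ones(length, dtype=bool)
    for s, e in tms:
        mask[s:e] = False
    return mask


def _evolve_one(
    ancestor: str,
    tms: list[tuple[int, int]],
    spec: FamilySpec,
    rng: np.random.Generator,
) -> tuple[str, list[tuple[int, int]], list[int | None]]:
    """One descendant: substitutions everywhere, indels in loops only, so
    the member's true TMS intervals stay well defined."""
    protected = {
        m.position + j: m.conservation
        for m in spec.planted_motifs
        for j in range(len(m.consensus))
    }
    subbed = mutate_sequence(
        ancestor, spec.substitution_rate, rng, protected, tms_intervals=tms
    )
    loops = _loop_mask(len(ancestor), tms)
    out: list[str] = []
    hom: list[int | None] = []
    shift: list[int] = [0] * (len(ancestor) + 1)  # ancestor pos -> cumulative shift
    delta = 0
    i = 0
    while i < len(ancestor):
        if loops[i] and rng.random() < spec.indel_rate:
            if rng.random() < 0.5:  # deletion
                n_del = int(rng.integers(1, 4))
                i += n_del
                continue
            n_ins = int(rng.integers(1, 4))
            ins = _draw(LOOP_POOL, n_ins, rng)
            out.append(ins)
            hom.extend([None] * n_ins)
        out.append(subbed[i] if i < len(subbed) else "")
        hom.append(i)
        i += 1
    seq = "".join(out)
    # map ancestor TMS intervals onto the member through the homology map
    anc_to_member = {a: j for j, a in enumerate(hom) if a is not None}
    member_tms = []
    for s, e in tms:
        cols = [anc_to_member[a] for a in range(s, e) if a in anc_to_member]
        if cols:
            member_tms.append((min(cols), max(cols) + 1))
    return seq, member_tms, hom


def evolve_family(
    ancestor: ProteinRecord,
    ancestor_tms: list[tuple[int, int]],
    spec: FamilySpec,
    seed: int,
) -> FamilySample:
    """Produce ``spec.n_members`` independent descendants of ``ancestor``."""
    rng = np.random.default_rng(seed)
    members: list[ProteinRecord] = []
    tms_truth: dict[str, list[tuple[int, int]]] = {}
    hom_maps: dict[str, list[int | None]] = {}
    for k in range(spec.n_members):
        seq, mtms, hom = _evolve_one(ancestor.seq, ancestor_tms, spec, rng)
        rid = f"{spec.label}.{k + 1}"
        members.append(ProteinRecord(id=rid, seq=seq))
        tms_truth[rid] = mtms
        hom_maps[rid] = hom
    fam = FamilySet(label=spec.label, members=members)
    sample = FamilySample(fam, ancestor, tms_truth, hom_maps)
    if spec.substitution_rate > 0 and spec.n_members > 1:
        mean_id = mean_pairwise_identity(sample)
        if mean_id < 0.10:
            import warnings

            warnings.warn(
                f"family {spec.label}: mean pairwise identity {mean_id:.2f} < 10%",
                stacklevel=2,
            )
    return sample


def mean_pairwise_identity(sample: "FamilySample") -> float:
    """True mean pairwise identity over ancestrally matched positions."""
    members = sample.family.members
    vals = []
    for i in range(len(members)):
        for j in range(i + 1, len(members)):
            a, b = members[i], members[j]
            pos_b = {
                anc: k for k, anc in enumerate(sample.homology_map[b.id])
                if anc is not None
            }
            matched = same = 0
            for k, anc in enumerate(sample.homology_map[a.id]):
                if anc in pos_b:
                    matched += 1
                    same += a.seq[k] == b.seq[pos_b[anc]]
            vals.append(same / matched if matched else 0.0)
    return float(np.mean(vals)) if vals else 1.0


def generate_family(spec: FamilySpec, seed: int) -> FamilySample:
    """Ancestor plus evolved members, all from one seed."""
    anc, tms = generate_membrane_protein(spec, seed, record_id=f"{spec.label}.anc")
    return evolve_family(anc, tms, spec, seed + 1)


def generate_superfamily(spec: SuperfamilySpec, seed: int) -> SuperfamilySample:
    """Chained related families plus independent controls, with truth tables.

    Chain ancestors: A1 is drawn fresh; A_{i+1} = mutate(A_i, edge_rate).
    All family members go into the output database, so a family-expansion
    search against ``db`` recovers the chain neighbours' members — the bridge
    sequences a transitivity path runs through.
    """
    if not spec.chain and not spec.unrelated:
        raise ValueError("superfamily spec has no families")
    rng = np.random.default_rng(seed)
    families: list[FamilySet] = []
    ancestors: dict[str, ProteinRecord] = {}
    tms_truth: dict[str, list[tuple[int, int]]] = {}
    related: set[frozenset[str]] = set()

    chain_samples: list[FamilySample] = []
    bridges: list[ProteinRecord] = []
    prev: tuple[ProteinRecord, list[tuple[int, int]]] | None = None
    for idx, fs in enumerate(spec.chain):
        if prev is None:
            anc, tms = generate_membrane_protein(
                fs, int(rng.integers(2**31)), record_id=f"{fs.label}.anc"
            )
        else:
            kwargs = dict(
                loop_len_mean=fs.loop_len_mean, loop_len_sd=fs.loop_len_sd,
                term_len_mean=fs.term_len_mean, term_len_sd=fs.term_len_sd,
                tms_len_mean=fs.tms_len_mean, tms_len_sd=fs.tms_len_sd,
            )
            cur_seq, cur_tms = prev
            cur_seq = cur_seq.seq
            n_steps = spec.bridges_per_edge + 1
            for step in range(n_steps):
                cur_seq, cur_tms = evolve_ancestor(
                    cur_seq, cur_tms, spec.step_rate,
                    np.random.default_rng(int(rng.integers(2**31))), **kwargs
                )
                if step < n_steps - 1 and spec.emit_bridges:
                    bridges.append(
                        ProteinRecord(
                            id=f"BRIDGE_{idx:02d}_{step + 1}", seq=cur_seq
                        )
                    )
            anc, tms = ProteinRecord(id=f"{fs.label}.anc", seq=cur_seq), cur_tms
        sample = evolve_family(anc, tms, fs, int(rng.integers(2**31)))
        chain_samples.append(sample)
        prev = (anc, tms)
    for i in range(len(chain_samples)):
        for j in range(i + 1, len(chain_samples)):
            related.add(
                frozenset({spec.chain[i].label, spec.chain[j].label})
            )
    unrelated_samples = [
        generate_family(fs, int(rng.integers(2**31))) for fs in spec.unrelated
    ]
    for sample in chain_samples + unrelated_samples:
        families.append(sample.family)
        ancestors[sample.family.label] = sample.ancestor
        tms_truth.update(sample.tms_truth)
    db = [m for f in families for m in f.members] + bridges
    return SuperfamilySample(families, ancestors, tms_truth, related, db)


# -- 3-D helix bundles ------------------------------------------------------


def generate_helix_bundle(
    n_helices: int,
    helix_len: int = 21,
    rise: float = 1.5,
    radius: float = 2.3,
    noise_sd: float = 0.0,
    seed: int = 0,
    bundle_radius: float = 9.0,
    loop_len: int = 5,
) -> HelixBundle:
    """Ideal alpha-helix C-alpha traces on a circular bundle arrangement.

    Each helix winds at 100 deg/residue with a 1.5 A rise, axes vertical and
    antiparallel around a circle of ``bundle_radius``; consecutive helices
    are joined by short interpolated loops. ``noise_sd`` is the expected
    root-mean-square 3-D displacement per atom: isotropic Gaussian noise of
    ``noise_sd / sqrt(3)`` per coordinate is added, so a 1 A noise level
    yields superposition RMSDs of about 1 A against the clean geometry.
    """
    if n_helices < 1:
        raise ValueError("need at least one helix")
    rng = np.random.default_rng(seed)
    helices: list[np.ndarray] = []
    helix_res: list[np.ndarray] = []
    loops: list[np.ndarray] = []
    res = 1
    theta_step = math.radians(100.0)
    for h in range(n_helices):
        phi = 2 * math.pi * h / max(n_helices, 3)
        cx, cy = bundle_radius * math.cos(phi), bundle_radius * math.sin(phi)
        direction = 1.0 if h % 2 == 0 else -1.0
        j = np.arange(helix_len)
        coords = np.stack(
            [
                cx + radius * np.cos(theta_step * j),
                cy + radius * np.sin(theta_step * j),
                direction * rise * (j - helix_len / 2.0),
            ],
            axis=1,
        )
        helices.append(coords)
        helix_res.append(np.arange(res, res + helix_len))
        res += helix_len
        if h < n_helices - 1:
            nxt_phi = 2 * math.pi * (h + 1) / max(n_helices, 3)
            nxt = np.array(
                [
                    bundle_radius * math.cos(nxt_phi) + radius,
                    bundle_radius * math.sin(nxt_phi),
                    (-direction) * rise * (-helix_len / 2.0),
                ]
            )
            t = np.linspace(0.0, 1.0, loop_len + 2)[1:-1, None]
            loops.append(coords[-1] * (1 - t) + nxt * t)
            res += loop_len
    if noise_sd > 0:
        per_coord = noise_sd / math.sqrt(3.0)
        helices = [h + rng.normal(0, per_coord, h.shape) for h in helices]
        loops = [l + rng.normal(0, per_coord, l.shape) for l in loops]
    return HelixBundle(
        source=f"synthetic-bundle-{n_helices}x{helix_len}",
        helices=helices,
        helix_residues=helix_res,
        loops=loops,
    )
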
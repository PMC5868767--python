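"""Transitive homology inference between protein families.

The superfamily strategy, stage by stage:

1. *Family expansion* — each family is searched against a local sequence
   database; hits covering at least 45% of the query at E < 1e-2 are kept,
   their aligned regions extracted, and redundancy removed at 90% identity.
2. *Candidate pairing* — all pairs between two expanded homolog lists are
   locally aligned and scored with an initial 500-shuffle z-score, with the
   number of overlapping TMSs annotated (a TMS overlaps when at least half
   of its aligned columns fall inside a TMS of the partner).
3. *Path verification* — a candidate path A -> B -> C -> D (A, D family
   representatives; B, C their respective database hits, possibly the same
   protein) is verified with 1000-shuffle z-scores on terminal-trimmed
   regions for the three legs A-B, B-C, C-D. The minimum of the three is the
   *comparison score*.
4. *Verdict* — the comparison score is judged against a threshold calibrated
   on negative-control family pairs (threshold = highest control comparison
   score + a safety margin), with minimum-overlap requirements (>= 5 shared
   TMSs, >= 150 aligned residues) on the bridging alignment.

Composition-matched but unrelated membrane proteins routinely reach tiny
E-values (hydrophobic low-complexity similarity), which is why raising the
bar to a shuffle-calibrated, control-anchored comparison score — rather than
any fixed E-value — is the load-bearing step.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import hydropathy as hp
from .alignment import (
    AlignmentResult,
    AlnParams,
    GsatResult,
    evalue,
    global_align,
    gsat_z,
    local_align,
    local_score,
    trim_to_hydrophobic_core,
)
from .sequence import FamilySet, ProteinRecord

log = logging.getLogger("superfam.transitivity")


@dataclass(frozen=True)
class PipelineConfig:
    """Every threshold of the inference pipeline as a named parameter."""

    expansion_max_evalue: float = 1e-2
    expansion_min_coverage: float = 0.45
    redundancy_identity: float = 0.90
    redundancy_length_ratio: float = 1.8
    protocol2_shuffles: int = 500
    verify_shuffles: int = 1000
    min_overlapping_tms: int = 5
    min_alignment_length: int = 150
    threshold_margin_sd: float = 2.0
    rescue_max_evalue: float = 1e-3
    rescue_min_overlap: float = 0.70
    distant_known_evalue: float = 1e-5
    distant_min_tms: int = 8
    terminal_trim_margin: int = 10
    local_params: AlnParams = field(default_factory=AlnParams.blast_default)
    gsat_params: AlnParams = field(default_factory=AlnParams.gsat_default)


DEFAULT_CONFIG = PipelineConfig()


@dataclass
class ExpansionHit:
    """One database hit of a family-expansion search; ``aligned_region`` is
    the extracted hit subsequence, ``hit_start/end`` its 0-based half-open
    interval on the full hit sequence."""

    query_id: str
    hit_id: str
    evalue: float
    query_coverage: float
    aligned_region: str
    full_hit_length: int
    hit_start: int
    hit_end: int

    @property
    def record(self) -> ProteinRecord:
        return ProteinRecord(id=self.hit_id, seq=self.aligned_region)


@dataclass
class CandidatePair:
    """A Protocol2-style candidate: local alignment plus initial z-score."""

    record_a: ProteinRecord
    record_b: ProteinRecord
    alignment: AlignmentResult
    gsat: GsatResult
    overlapping_tms: int

    @property
    def z(self) -> float:
        return self.gsat.z


@dataclass
class TransitivityPath:
    """An A -> B -> C -> D chain; the comparison score is the weakest leg."""

    family_a: str
    protein_b: str
    protein_c: str
    family_d: str
    z_ab: float
    z_bc: float
    z_cd: float
    aligned_tms: int

    @property
    def comparison_score(self) -> float:
        return min(self.z_ab, self.z_bc, self.z_cd)


@dataclass
class HomologyVerdict:
    family_a: str
    family_b: str
    verdict: str  # "homologous" | "not_demonstrated"
    threshold: float
    control_max: float | None = None
    path: TransitivityPath | None = None
    reason: str = ""

    @property
    def is_homologous(self) -> bool:
        return self.verdict == "homologous"


class PathRejected(ValueError):
    """A transitivity path failed a minimum-overlap requirement; ``leg``
    names the failing leg."""

    def __init__(self, leg: str, message: str):
        super().__init__(f"leg {leg}: {message}")
        self.leg = leg


# -- stage 1: expansion -----------------------------------------------------


def expand_family(
    queries: Sequence[ProteinRecord],
    local_db: Sequence[ProteinRecord],
    max_evalue: float = DEFAULT_CONFIG.expansion_max_evalue,
    min_coverage: float = DEFAULT_CONFIG.expansion_min_coverage,
    redundancy_id: float = DEFAULT_CONFIG.redundancy_identity,
    params: AlnParams | None = None,
    exclude_self: bool = False,
) -> list[ExpansionHit]:
    """Search every query against a local database and keep filtered hits.

    A hit must cover at least ``min_coverage`` of the *query* and reach
    ``max_evalue``; the aligned region of the hit is extracted and the
    extracted regions are redundancy-reduced at ``redundancy_id`` identity.
    An empty database yields an empty result; empty queries are an error.
    """
    if not queries:
        raise ValueError("no query sequences")
    params = params or DEFAULT_CONFIG.local_params
    hits: list[ExpansionHit] = []
    for q in queries:
        for t in local_db:
            if exclude_self and t.id == q.id:
                continue
            aln = local_align(q.seq, t.seq, params)
            cov = (aln.end_a - aln.start_a) / len(q.seq)
            ev = evalue(aln.score, len(q.seq), len(t.seq), params, len(local_db))
            if cov >= min_coverage and ev < max_evalue:
                hits.append(
                    ExpansionHit(
                        query_id=q.id,
                        hit_id=t.id,
                        evalue=ev,
                        query_coverage=cov,
                        aligned_region=aln.region_b(t.seq),
                        full_hit_length=len(t.seq),
                        hit_start=aln.start_b,
                        hit_end=aln.end_b,
                    )
                )
    hits.sort(key=lambda h: (h.evalue, h.hit_id))
    regions = [h.record for h in hits]
    kept = redundancy_reduce(regions, id_threshold=redundancy_id, params=params)
    kept_keys = {(r.id, r.seq) for r in kept}
    out, seen = [], set()
    for h in hits:
        key = (h.hit_id, h.aligned_region)
        if key in kept_keys and key not in seen:
            out.append(h)
            seen.add(key)
    return out


def redundancy_reduce(
    seqs: Sequence[ProteinRecord],
    id_threshold: float = DEFAULT_CONFIG.redundancy_identity,
    length_ratio_exception: float = DEFAULT_CONFIG.redundancy_length_ratio,
    params: AlnParams | None = None,
) -> list[ProteinRecord]:
    """Greedy longest-first redundancy removal.

    A sequence joins an existing representative when their identity over the
    shorter sequence reaches ``id_threshold`` — unless the longer/shorter
    length ratio exceeds ``length_ratio_exception``, in which case both are
    kept (a short fragment is not redundant with a full-length protein).
    Representatives are returned in input order of first occurrence.
    """
    params = params or DEFAULT_CONFIG.local_params
    order = sorted(range(len(seqs)), key=lambda i: (-len(seqs[i].seq), i))
    reps: list[int] = []
    for i in order:
        s = seqs[i]
        redundant = False
        for j in reps:
            r = seqs[j]
            ratio = max(len(r.seq), len(s.seq)) / min(len(r.seq), len(s.seq))
            if ratio > length_ratio_exception:
                continue
            aln = local_align(s.seq, r.seq, params)
            matches = sum(
                1
                for x, y in zip(aln.aligned_a, aln.aligned_b)
                if x == y and x != "-"
            )
            if matches / min(len(s.seq), len(r.seq)) >= id_threshold:
                redundant = True
                break
        if not redundant:
            reps.append(i)
    return [seqs[i] for i in sorted(reps)]


# -- stage 2: candidate pairing --------------------------------------------


def _overlapping_tms(
    aln: AlignmentResult,
    tms_a: hp.TmsCall,
    tms_b: hp.TmsCall,
) -> int:
    """Count TMSs of sequence A at least half of whose aligned columns land
    inside a TMS of sequence B."""
    in_b = set()
    for s, e in tms_b.intervals:
        in_b.update(range(s, e))
    # map: alignment columns -> (pos_a, pos_b)
    pa, pb = aln.start_a, aln.start_b
    a_cols: dict[int, list[bool]] = {}
    for x, y in zip(aln.aligned_a, aln.aligned_b):
        if x != "-" and y != "-":
            for s, e in tms_a.intervals:
                if s <= pa < e:
                    a_cols.setdefault(s, []).append(pb in in_b)
                    break
        if x != "-":
            pa += 1
        if y != "-":
            pb += 1
    count = 0
    for s, e in tms_a.intervals:
        flags = a_cols.get(s, [])
        width = e - s
        if flags and sum(flags) >= 0.5 * width:
            count += 1
    return count


def protocol2(
    homologs_a: Sequence[ProteinRecord],
    homologs_b: Sequence[ProteinRecord],
    params: AlnParams | None = None,
    pre_shuffles: int = DEFAULT_CONFIG.protocol2_shuffles,
    seed: int = 0,
    gsat_params: AlnParams | None = None,
    max_gsat_pairs: int | None = None,
    anchor_scores: tuple[dict, dict] | None = None,
) -> list[CandidatePair]:
    """All-vs-all screening between two expanded homolog lists.

    Every pair is locally aligned; the aligned regions get an initial
    ``pre_shuffles``-shuffle z-score; overlapping TMSs are counted from each
    sequence's peak calls mapped through the alignment. Pairs are ranked by
    z descending, ties broken by alignment length.

    ``max_gsat_pairs`` limits the shuffle scoring to the most promising
    pairs; pairs beyond the cap are dropped from the output (the default
    scores every pair). Promise is measured by raw local score, or — when
    ``anchor_scores`` supplies each homolog's raw-score link back to its
    family query — by the weakest link of the whole prospective path
    min(anchor_a, pair score, anchor_b), which keeps bridge pairs ahead of
    high-scoring but unanchored self-matches.
    """
    if not homologs_a or not homologs_b:
        raise ValueError("empty homolog list")
    params = params or DEFAULT_CONFIG.local_params
    gsat_params = gsat_params or DEFAULT_CONFIG.gsat_params
    tms_cache: dict[str, hp.TmsCall] = {}

    def tms_of(rec: ProteinRecord) -> hp.TmsCall:
        key = rec.id + "/" + str(len(rec.seq))
        if key not in tms_cache:
            w = min(hp.DEFAULT_WINDOW, len(rec.seq) - (1 - len(rec.seq) % 2))
            tms_cache[key] = hp.call_tms_peaks(hp.hydropathy_profile(rec.seq, w))
        return tms_cache[key]

    alns = []
    for a in homologs_a:
        for b in homologs_b:
            aln = local_align(a, b, params)
            if anchor_scores is not None:
                promise = min(
                    anchor_scores[0].get((a.id, a.seq), aln.score),
                    aln.score,
                    anchor_scores[1].get((b.id, b.seq), aln.score),
                )
            else:
                promise = aln.score
            alns.append((a, b, aln, promise))
    alns.sort(key=lambda t: (-t[3], t[0].id, t[1].id))
    if max_gsat_pairs is not None:
        alns = alns[:max_gsat_pairs]
    out: list[CandidatePair] = []
    for k, (a, b, aln, _) in enumerate(alns):
        ra, rb = aln.region_a(a.seq), aln.region_b(b.seq)
        if min(len(ra), len(rb)) < 20:
            continue
        g = gsat_z(ra, rb, gsat_params, n_shuffles=pre_shuffles, seed=seed + k + 1)
        n_tms = _overlapping_tms(aln, tms_of(a), tms_of(b))
        out.append(CandidatePair(a, b, aln, g, n_tms))
    out.sort(key=lambda c: (-c.z, -c.alignment.length, c.record_a.id, c.record_b.id))
    return out


# -- stage 3: path verification --------------------------------------------


def verify_path(
    family_a_rep: ProteinRecord,
    hit_b: ProteinRecord,
    hit_c: ProteinRecord,
    family_d_rep: ProteinRecord,
    params: AlnParams | None = None,
    shuffles: int = DEFAULT_CONFIG.verify_shuffles,
    min_tms: int = DEFAULT_CONFIG.min_overlapping_tms,
    min_len: int = DEFAULT_CONFIG.min_alignment_length,
    seed: int = 0,
    config: PipelineConfig = DEFAULT_CONFIG,
    family_a: str = "",
    family_d: str = "",
    enforce_filters: bool = True,
    early_stop_below: float | None = None,
) -> TransitivityPath:
    """Verify an A -> B -> C -> D path with final z-scores.

    Each leg is computed on terminal-trimmed sequences (hydrophilic N-/C-
    tails removed) with ``shuffles`` shuffles. The B-C leg's local alignment
    supplies the overlapping-TMS count; when B and C are the same region the
    leg is a self-comparison and every TMS trivially overlaps. With
    ``enforce_filters``, a leg shorter than ``min_len`` aligned residues or a
    bridge with fewer than ``min_tms`` shared TMSs raises
    :class:`PathRejected` naming the leg.

    ``early_stop_below`` short-circuits a doomed path: legs are evaluated in
    the order A-B, C-D, B-C and evaluation stops once a leg's z-score falls
    below the given value (the comparison score — the minimum — is then
    already below it). Unevaluated legs are reported as +inf.
    """
    params = params or config.gsat_params
    margin = config.terminal_trim_margin

    def core(rec: ProteinRecord) -> str:
        return trim_to_hydrophobic_core(rec.seq, margin=margin)[0]

    a, b, c, d = (core(r) for r in (family_a_rep, hit_b, hit_c, family_d_rep))

    self_bridge = hit_b.id == hit_c.id and hit_b.seq == hit_c.seq
    if self_bridge:
        w = min(hp.DEFAULT_WINDOW, len(hit_b.seq) - (1 - len(hit_b.seq) % 2))
        n_tms = hp.call_tms_peaks(hp.hydropathy_profile(hit_b.seq, w)).count
        bc_len = len(b)
    else:
        aln_bc = local_align(hit_b.seq, hit_c.seq, config.local_params)
        wb = min(hp.DEFAULT_WINDOW, len(hit_b.seq) - (1 - len(hit_b.seq) % 2))
        wc = min(hp.DEFAULT_WINDOW, len(hit_c.seq) - (1 - len(hit_c.seq) % 2))
        n_tms = _overlapping_tms(
            aln_bc,
            hp.call_tms_peaks(hp.hydropathy_profile(hit_b.seq, wb)),
            hp.call_tms_peaks(hp.hydropathy_profile(hit_c.seq, wc)),
        )
        bc_len = aln_bc.length

    if enforce_filters and n_tms < min_tms:
        raise PathRejected("B-C", f"{n_tms} overlapping TMSs < {min_tms}")
    if enforce_filters and bc_len < min_len:
        raise PathRejected("B-C", f"alignment length {bc_len} < {min_len}")
    legs = {"A-B": np.inf, "B-C": np.inf, "C-D": np.inf}
    order = [("A-B", 0, a, b), ("C-D", 1, c, d), ("B-C", 2, b, c)]
    if early_stop_below is not None:
        # evaluate the cheapest-to-refute (weakest by raw score) leg first
        from .alignment import local_score as _ls

        order.sort(key=lambda t: _ls(t[2], t[3], config.local_params))
    for name, leg_idx, x, y in order:
        if name == "B-C" and self_bridge:
            legs[name] = gsat_z(x, x, params, n_shuffles=shuffles, seed=seed + 1).z
        else:
            g = global_align(x, y, params)
            if enforce_filters and g.length < min_len:
                raise PathRejected(name, f"alignment length {g.length} < {min_len}")
            legs[name] = gsat_z(
                x, y, params, n_shuffles=shuffles, seed=seed + 29 * leg_idx
            ).z
        if early_stop_below is not None and legs[name] < early_stop_below:
            break
    return TransitivityPath(
        family_a=family_a or family_a_rep.id,
        protein_b=hit_b.id,
        protein_c=hit_c.id,
        family_d=family_d or family_d_rep.id,
        z_ab=legs["A-B"],
        z_bc=legs["B-C"],
        z_cd=legs["C-D"],
        aligned_tms=n_tms,
    )


# -- stage 4: verdict -------------------------------------------------------


def _query_record(
    hit: ProteinRecord, expansion: Sequence[ExpansionHit], family: FamilySet
) -> ProteinRecord:
    """The family member whose search produced this hit region (path anchor)."""
    for h in expansion:
        if h.hit_id == hit.id and h.aligned_region == hit.seq:
            for m in family.members:
                if m.id == h.query_id:
                    return m
    return family.members[0]


def are_families_homologous(
    family_a: FamilySet,
    family_b: FamilySet,
    local_db: Sequence[ProteinRecord],
    threshold: float | None = None,
    controls: Sequence[tuple[FamilySet, FamilySet]] | None = None,
    config: PipelineConfig = DEFAULT_CONFIG,
    seed: int = 0,
    top_k: int = 6,
    control_db: Sequence[ProteinRecord] | None = None,
    expansions: tuple[Sequence[ExpansionHit], Sequence[ExpansionHit]] | None = None,
    max_gsat_pairs: int | None = 8,
) -> HomologyVerdict:
    """Full expansion -> pairing -> verification -> verdict pipeline.

    The homology threshold is either given directly or calibrated as the
    maximum comparison score over negative-control family pairs plus
    ``config.threshold_margin_sd``. The verdict is ``homologous`` iff some
    verified path's comparison score reaches the threshold (subject to the
    TMS/length overlap requirements).
    """
    control_max = None
    if threshold is None:
        if not controls:
            raise ValueError("need either a threshold or negative-control pairs")
        control_max = calibrate_control_max(
            controls, control_db if control_db is not None else local_db,
            config=config, seed=seed + 7919,
        )
        threshold = control_max + config.threshold_margin_sd

    try:
        if expansions is not None:
            exp_a, exp_b = expansions
        else:
            exp_a = expand_family(
                family_a.members, local_db,
                config.expansion_max_evalue, config.expansion_min_coverage,
                config.redundancy_identity, config.local_params,
            )
            exp_b = expand_family(
                family_b.members, local_db,
                config.expansion_max_evalue, config.expansion_min_coverage,
                config.redundancy_identity, config.local_params,
            )
    except ValueError as exc:
        return HomologyVerdict(
            family_a.label, family_b.label, "not_demonstrated",
            threshold, control_max, reason=str(exc),
        )
    if not exp_a or not exp_b:
        side = family_a.label if not exp_a else family_b.label
        return HomologyVerdict(
            family_a.label, family_b.label, "not_demonstrated",
            threshold, control_max, reason=f"empty expansion for {side}",
        )
    def _anchor_map(
        exp: Sequence[ExpansionHit], family: FamilySet
    ) -> dict[tuple[str, str], float]:
        members = {m.id: m for m in family.members}
        out = {}
        for h in exp:
            q = members.get(h.query_id, family.members[0])
            out[(h.hit_id, h.aligned_region)] = local_score(
                q.seq, h.aligned_region, config.local_params
            )
        return out

    cands = protocol2(
        [h.record for h in exp_a],
        [h.record for h in exp_b],
        config.local_params,
        config.protocol2_shuffles,
        seed=seed,
        gsat_params=config.gsat_params,
        max_gsat_pairs=max_gsat_pairs,
        anchor_scores=(_anchor_map(exp_a, family_a), _anchor_map(exp_b, family_b)),
    )
    # A path's comparison score is bounded by its B-C leg, which the
    # screening z-score already estimates: candidates whose initial z sits
    # clearly below the threshold cannot produce a passing path and are not
    # verified. The survivors are tried strongest-anchors-first, using raw
    # local scores of the A-B and C-D legs as a cheap proxy for their final
    # z-scores.
    viable = [c for c in cands[:top_k] if c.z >= threshold - 3.0]
    anchors = {}
    for cand in viable:
        rep_a = _query_record(cand.record_a, exp_a, family_a)
        rep_d = _query_record(cand.record_b, exp_b, family_b)
        proxy = min(
            local_score(rep_a.seq, cand.record_a.seq, config.local_params),
            local_score(rep_d.seq, cand.record_b.seq, config.local_params),
        )
        anchors[id(cand)] = (proxy, rep_a, rep_d)
    viable.sort(key=lambda c: -anchors[id(c)][0])
    best_path = None
    reason = (
        "no candidate pair passed the overlap requirements"
        if viable
        else "no candidate bridge reached the score threshold"
    )
    consecutive_failures = 0
    for cand in viable:
        _, rep_a, rep_d = anchors[id(cand)]
        try:
            path = verify_path(
                rep_a, cand.record_a, cand.record_b, rep_d,
                config.gsat_params, config.verify_shuffles,
                config.min_overlapping_tms, config.min_alignment_length,
                seed=seed + 13, config=config,
                family_a=family_a.label, family_d=family_b.label,
                early_stop_below=threshold,
            )
        except PathRejected as exc:
            reason = str(exc)
            continue
        if best_path is None or path.comparison_score > best_path.comparison_score:
            best_path = path
        # a clearly passing path ends the search; a marginal pass keeps
        # looking for a stronger one among the remaining candidates, but
        # repeated failures end it (candidates arrive best-first)
        if best_path.comparison_score >= threshold + 4.0:
            break
        if path.comparison_score < threshold:
            consecutive_failures += 1
            if consecutive_failures >= 3:
                break
        else:
            consecutive_failures = 0
    if best_path is None:
        return HomologyVerdict(
            family_a.label, family_b.label, "not_demonstrated",
            threshold, control_max, reason=reason,
        )
    verdict = (
        "homologous" if best_path.comparison_score >= threshold else "not_demonstrated"
    )
    reason = "" if verdict == "homologous" else (
        f"comparison score {best_path.comparison_score:.1f} below "
        f"threshold {threshold:.1f}"
    )
    log.info(
        "verdict %s vs %s: %s (score %.1f, threshold %.1f, seed %d)",
        family_a.label, family_b.label, verdict,
        best_path.comparison_score, threshold, seed,
    )
    return HomologyVerdict(
        family_a.label, family_b.label, verdict, threshold,
        control_max, best_path, reason,
    )


def calibrate_control_max(
    controls: Sequence[tuple[FamilySet, FamilySet]],
    local_db: Sequence[ProteinRecord] | None = None,
    config: PipelineConfig = DEFAULT_CONFIG,
    seed: int = 0,
) -> float:
    """Highest comparison score over negative-control family pairs.

    Controls run through the same expansion/pairing machinery (against
    ``local_db``, or each pair's own members when no database is given); the
    overlap filters are *not* enforced, so every control yields a score
    (enforcing them could only lower the control maximum, i.e. make the
    threshold anti-conservative). Only a path's cross-family legs are
    evaluated with full shuffles: within-family legs are self-matches whose
    z-scores sit two orders of magnitude above the cross legs and can never
    be the minimum.
    """
    from .sequence import TcdbId

    def family_of(rid: str) -> str | None:
        tc = TcdbId.try_parse(rid)
        return tc.family_prefix if tc else None

    scores = []
    for i, (fa, fb) in enumerate(controls):
        db = local_db if local_db is not None else list(fa.members) + list(fb.members)
        exp_a = expand_family(
            fa.members, db,
            config.expansion_max_evalue, config.expansion_min_coverage,
            config.redundancy_identity, config.local_params,
        )
        exp_b = expand_family(
            fb.members, db,
            config.expansion_max_evalue, config.expansion_min_coverage,
            config.redundancy_identity, config.local_params,
        )
        if not exp_a or not exp_b:
            continue
        def _amap(exp, fam):
            members = {m.id: m for m in fam.members}
            return {
                (h.hit_id, h.aligned_region): local_score(
                    members.get(h.query_id, fam.members[0]).seq,
                    h.aligned_region, config.local_params,
                )
                for h in exp
            }

        cands = protocol2(
            [h.record for h in exp_a], [h.record for h in exp_b],
            config.local_params, config.protocol2_shuffles,
            seed=seed + 100 * i, gsat_params=config.gsat_params,
            max_gsat_pairs=3,
            anchor_scores=(_amap(exp_a, fa), _amap(exp_b, fb)),
        )
        margin = config.terminal_trim_margin
        best = None
        for ci, cand in enumerate(cands[:2]):
            rep_a = _query_record(cand.record_a, exp_a, fa)
            rep_d = _query_record(cand.record_b, exp_b, fb)
            legs = []
            pairs = [
                (rep_a.seq, cand.record_a.seq, family_of(rep_a.id), family_of(cand.record_a.id)),
                (cand.record_a.seq, cand.record_b.seq, family_of(cand.record_a.id), family_of(cand.record_b.id)),
                (cand.record_b.seq, rep_d.seq, family_of(cand.record_b.id), family_of(rep_d.id)),
            ]
            for k, (x, y, fx, fy) in enumerate(pairs):
                if fx is not None and fx == fy:
                    continue  # within-family self leg, never the minimum
                cx = trim_to_hydrophobic_core(x, margin=margin)[0]
                cy = trim_to_hydrophobic_core(y, margin=margin)[0]
                legs.append(
                    gsat_z(
                        cx, cy, config.gsat_params,
                        n_shuffles=config.verify_shuffles,
                        seed=seed + 100 * i + 13 + 7 * ci + k,
                    ).z
                )
            if not legs:  # candidate entirely within one family: use its z
                legs.append(cand.z)
            score = min(legs)
            if best is None or score > best:
                best = score
        if best is not None:
            scores.append(best)
    if not scores:
        raise ValueError("no control pair produced a comparison score")
    return float(max(scores))


def direct_family_z(
    family_a: FamilySet,
    family_b: FamilySet,
    config: PipelineConfig = DEFAULT_CONFIG,
    shuffles: int = DEFAULT_CONFIG.verify_shuffles,
    seed: int = 0,
) -> GsatResult:
    """Plain member-to-member z-score between two families, no expansion.

    The best member pair by local-alignment score is compared with a
    z-score over the locally selected regions — the "direct comparison"
    that transitive paths are meant to rescue when it falls below the
    homology threshold.
    """
    best = None
    for x in family_a.members:
        for y in family_b.members:
            aln = local_align(x, y, config.local_params)
            if best is None or aln.score > best[0].score:
                best = (aln, x, y)
    aln, x, y = best
    return gsat_z(
        aln.region_a(x.seq), aln.region_b(y.seq),
        config.gsat_params, n_shuffles=shuffles, seed=seed,
    )


# -- distant members and domain bookkeeping ---------------------------------


def find_distant_members(
    family: FamilySet,
    local_db: Sequence[ProteinRecord],
    known_evalue: float = DEFAULT_CONFIG.distant_known_evalue,
    min_tms: int = DEFAULT_CONFIG.distant_min_tms,
    tcdb_ref: Sequence[FamilySet] = (),
    config: PipelineConfig = DEFAULT_CONFIG,
    expansion_min_coverage: float = 0.70,
) -> pd.DataFrame:
    """Candidate distant members of ``family`` from a local database.

    Filter cascade: (1) hits with E below ``known_evalue`` are discarded as
    already-known members; (2) a minimum TMS count from hydropathy peaks;
    (3) the candidate's best reference-database match must belong to the
    query family; (4) redundancy reduction. Returns a curation-ready table.
    """
    hits = expand_family(
        family.members, local_db,
        config.expansion_max_evalue, expansion_min_coverage,
        config.redundancy_identity, config.local_params,
        exclude_self=True,
    )
    rows = []
    kept_records = []
    for h in hits:
        if h.evalue < known_evalue:
            continue  # already represented in the reference family
        full = next(t for t in local_db if t.id == h.hit_id)
        w = min(hp.DEFAULT_WINDOW, len(full.seq) - (1 - len(full.seq) % 2))
        n_tms = hp.call_tms_peaks(hp.hydropathy_profile(full.seq, w)).count
        if n_tms < min_tms:
            continue
        best_family = None
        if tcdb_ref:
            best_ev = np.inf
            for ref_fam in tcdb_ref:
                for ref in ref_fam.members:
                    aln = local_align(full.seq, ref.seq, config.local_params)
                    ev = evalue(
                        aln.score, len(full.seq), len(ref.seq), config.local_params
                    )
                    if ev < best_ev:
                        best_ev, best_family = ev, ref_fam.label
            if best_family is not None and best_family != family.label:
                continue
        kept_records.append(full)
        rows.append(
            {
                "hit_id": h.hit_id,
                "query_id": h.query_id,
                "evalue": h.evalue,
                "n_tms": n_tms,
                "best_ref_family": best_family or family.label,
            }
        )
    reps = {
        r.id
        for r in redundancy_reduce(
            kept_records, config.redundancy_identity,
            config.redundancy_length_ratio, config.local_params,
        )
    }
    table = pd.DataFrame(
        rows, columns=["hit_id", "query_id", "evalue", "n_tms", "best_ref_family"]
    )
    if len(table):
        table = table[table.hit_id.isin(reps)].reset_index(drop=True)
    return table


@dataclass
class DomainHit:
    member_id: str
    domain_id: str
    start: int  # 0-based half-open on the member
    end: int
    evalue: float
    rescued: bool = False
    donor_id: str | None = None


@dataclass
class DomainHitTable:
    rows: list[DomainHit] = field(default_factory=list)

    def members_with(self, domain_id: str) -> set[str]:
        return {r.member_id for r in self.rows if r.domain_id == domain_id}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "member_id": r.member_id,
                    "domain_id": r.domain_id,
                    "start": r.start + 1,  # 1-based inclusive for reports
                    "end": r.end,
                    "evalue": r.evalue,
                    "rescued": r.rescued,
                    "donor_id": r.donor_id or "",
                }
                for r in self.rows
            ]
        )


def domain_presence_fraction(
    table: DomainHitTable, domain_id: str, family: FamilySet
) -> float:
    return len(table.members_with(domain_id)) / len(family)


def rescue_domain(
    target: ProteinRecord,
    donors_with_hits: Sequence[ProteinRecord],
    domain_table: DomainHitTable,
    domain_id: str,
    max_evalue: float = DEFAULT_CONFIG.rescue_max_evalue,
    min_overlap: float = DEFAULT_CONFIG.rescue_min_overlap,
    params: AlnParams | None = None,
) -> DomainHitTable:
    """Declare a family-typical domain present in a member that lacks a hit.

    Donors are tried in descending order of overall identity to the target;
    a donor's domain region must align to the target at E < ``max_evalue``
    covering at least ``min_overlap`` of the donor domain. The first success
    adds a rescued row with the mapped target interval. A target that
    already carries the domain is returned unchanged; a target no donor can
    rescue is simply left without the domain.
    """
    params = params or DEFAULT_CONFIG.local_params
    if target.id in domain_table.members_with(domain_id):
        return domain_table
    donor_rows = {
        r.member_id: r
        for r in domain_table.rows
        if r.domain_id == domain_id and not r.rescued
    }
    ranked = []
    for donor in donors_with_hits:
        if donor.id not in donor_rows:
            continue
        aln = local_align(target.seq, donor.seq, params)
        ranked.append((-aln.identity_pct, donor.id, donor))
    ranked.sort()
    for _, _, donor in ranked:
        row = donor_rows[donor.id]
        region = donor.seq[row.start : row.end]
        if not region:
            continue
        aln = local_align(region, target.seq, params)
        ev = evalue(aln.score, len(region), len(target.seq), params)
        overlap = (aln.end_a - aln.start_a) / len(region)
        if ev < max_evalue and overlap >= min_overlap:
            new = DomainHitTable(list(domain_table.rows))
            new.rows.append(
                DomainHit(
                    member_id=target.id,
                    domain_id=domain_id,
                    start=aln.start_b,
                    end=aln.end_b,
                    evalue=ev,
                    rescued=True,
                    donor_id=donor.id,
                )
            )
            return new
    return domain_table


def common_match_overlap(
    expansion_a: Sequence[ExpansionHit], expansion_b: Sequence[ExpansionHit]
) -> pd.DataFrame:
    """Residue overlap of the matched intervals on sequences hit by both
    families. Long overlaps on common matches corroborate transitive
    homology; near-zero overlaps are the negative-control signature."""
    by_a: dict[str, list[ExpansionHit]] = {}
    for h in expansion_a:
        by_a.setdefault(h.hit_id, []).append(h)
    rows = []
    for h in expansion_b:
        for g in by_a.get(h.hit_id, []):
            lo = max(g.hit_start, h.hit_start)
            hi = min(g.hit_end, h.hit_end)
            rows.append(
                {
                    "hit_id": h.hit_id,
                    "start_a": g.hit_start,
                    "end_a": g.hit_end,
                    "start_b": h.hit_start,
                    "end_b": h.hit_end,
                    "overlap": max(0, hi - lo),
                }
            )
    return pd.DataFrame(
        rows, columns=["hit_id", "start_a", "end_a", "start_b", "end_b", "overlap"]
    )
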
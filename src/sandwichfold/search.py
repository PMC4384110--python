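"""Backtracking placement of the strand/loop skeleton onto a sequence.

The decision problem: does any assignment of seven 6-residue strand windows
and six loops satisfy every rule of the grammar?  Strands are placed left to
right in canonical (lexicographic) order.  Bounds that are already final for
a partial placement — per-strand bounds of placed strands, aggregate upper
bounds, per-loop checks — are enforced eagerly, which never excludes a
satisfying completion.  Aggregate minimum bounds are checked at completion,
with an optional admissible remaining-capacity prune.

:func:`enumerate_satisfying` is the exhaustive route (same answer set, no
capacity pruning, length-guarded) used to cross-check :func:`search`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterator, Optional

from .errors import SequenceError
from .model import Assignment, Geometry, RuleSet, ViolationReport, check_assignment
from .residues import AMBIGUOUS_LETTERS, AMINO_ACIDS, CLASSES

logger = logging.getLogger(__name__)

ORACLE_LENGTH_GUARD = 500


@dataclass(frozen=True)
class SearchParams:
    enumerate_all: bool = False
    max_witnesses: int = 1
    pruning: bool = True
    strict_alphabet: bool = False
    explain: bool = False

    def __post_init__(self) -> None:
        if self.max_witnesses < 1:
            raise ValueError("max_witnesses must be >= 1")


@dataclass(frozen=True)
class Decision:
    accepted: bool
    witness: Optional[Assignment] = None
    n_satisfying: Optional[int] = None
    best_failing: Optional[tuple[Assignment, ViolationReport]] = None
    witnesses: tuple[Assignment, ...] = field(default=(), repr=False)


def prepare_sequence(sequence: str, strict: bool = False) -> str:
    """Uppercase and vet a raw residue string."""
    seq = "".join(str(sequence).split()).upper()
    if not seq:
        raise SequenceError("empty sequence")
    letters = set(seq)
    ambiguous = letters & AMBIGUOUS_LETTERS
    junk = letters - AMINO_ACIDS - AMBIGUOUS_LETTERS
    if junk:
        raise SequenceError(f"sequence contains non-residue characters {sorted(junk)}")
    if ambiguous:
        if strict:
            raise SequenceError(
                f"non-standard residue letters {sorted(ambiguous)} (strict alphabet)"
            )
        logger.warning(
            "non-standard residue letters %s treated as members of no class",
            sorted(ambiguous),
        )
    return seq


def _loop_total_bounds(g: Geometry) -> tuple[int, int]:
    n = g.n_loops
    lo, hi = n * g.loop_len_range[0], n * g.loop_len_range[1]
    if g.loop_total_range:
        lo = max(lo, g.loop_total_range[0])
        hi = min(hi, g.loop_total_range[1])
    return lo, hi


def _future_feasible(L: int, g: Geometry, k: int, end: int, loop_sum: int,
                     tlo: int, thi: int) -> bool:
    """Can strands k+1..N still be placed after strand k ends at ``end``?"""
    m = g.n_strands - k
    lmin, lmax = g.loop_len_range
    lo = max(m * lmin, tlo - loop_sum)
    hi = min(m * lmax, thi - loop_sum, L - end - m * g.strand_length)
    if g.max_c_tail is not None:
        lo = max(lo, L - end - m * g.strand_length - g.max_c_tail)
    return lo <= hi


def enumerate_candidate_assignments(sequence_length: int,
                                    geometry: Geometry) -> Iterator[Assignment]:
    """All geometry-valid assignments, in canonical lexicographic order.

    Ordering: strand-1 start ascending, then each loop length ascending.
    Rule content is not consulted; this is the structural candidate space.
    """
    g = geometry
    L = sequence_length
    SL, N = g.strand_length, g.n_strands
    lmin, lmax = g.loop_len_range
    tlo, thi = _loop_total_bounds(g)
    if thi < tlo or L < N * SL + tlo:
        return
    starts = [0] * N

    def rec(k: int, end: int, loop_sum: int) -> Iterator[Assignment]:
        if k == N:
            yield Assignment(tuple(starts), L)
            return
        for ln in range(lmin, lmax + 1):
            w = end + ln
            if w + SL > L:
                break
            if not _future_feasible(L, g, k + 1, w + SL, loop_sum + ln, tlo, thi):
                continue
            starts[k] = w
            yield from rec(k + 1, w + SL, loop_sum + ln)

    w_hi = L - (N * SL + tlo)
    if g.max_n_tail is not None:
        w_hi = min(w_hi, g.max_n_tail)
    for w in range(0, w_hi + 1):
        if not _future_feasible(L, g, 1, w + SL, 0, tlo, thi):
            continue
        starts[0] = w
        yield from rec(1, w + SL, 0)


class _Engine:
    """Per-sequence precomputation and the pruned backtracking walk."""

    def __init__(self, sequence: str, ruleset: RuleSet):
        self.seq = sequence
        self.rs = ruleset
        g = ruleset.geometry
        self.g = g
        self.L = len(sequence)
        self.SL = g.strand_length
        self.N = g.n_strands
        self.W = max(0, self.L - self.SL + 1)
        self.tlo, self.thi = _loop_total_bounds(g)
        rules = ruleset.strand_rules
        self.rules = rules
        self.R = len(rules)

        # window counts per rule (shared between rules with equal descriptors)
        cache: dict = {}
        self.cnt: list[list[int]] = []
        for r in rules:
            key = (r.descriptor.residue_class.members, r.descriptor.face)
            if key not in cache:
                offs = g.face_offsets(r.descriptor.face)
                mem = key[0]
                cache[key] = [
                    sum(1 for o in offs if sequence[w + o] in mem)
                    for w in range(self.W)
                ]
            self.cnt.append(cache[key])

        # per-strand admissibility of each window under the per-strand bounds
        self.strand_ok: list[Optional[list[bool]]] = [None] * (self.N + 1)
        for k in range(1, self.N + 1):
            bounded = [
                (ri, r.per_strand[k]) for ri, r in enumerate(rules)
                if k in r.per_strand
            ]
            oks = []
            for w in range(self.W):
                ok = True
                for ri, b in bounded:
                    c = self.cnt[ri][w]
                    if c < b.lo or (b.hi is not None and c > b.hi):
                        ok = False
                        break
                oks.append(ok)
            self.strand_ok[k] = oks

        # loop prefix sums
        lr = ruleset.loop_rules
        self.lr = lr
        if lr is not None:
            wmap = lr.favorability_weights
            strong = CLASSES["STRONG_HYDROPHOBIC"]
            pf = [0] * (self.L + 1)
            ps = [0] * (self.L + 1)
            for i, c in enumerate(sequence):
                pf[i + 1] = pf[i] + wmap.get(c, 0)
                ps[i + 1] = ps[i] + (1 if c in strong else 0)
            self.pref_fav = pf
            self.pref_strong = ps

        self.il_set = set(g.interlock_strands)
        self.rem_il = [
            sum(1 for s in g.interlock_strands if s > k) for k in range(self.N + 1)
        ]
        self.rem_nil = [
            sum(1 for s in g.non_interlock_strands if s > k)
            for k in range(self.N + 1)
        ]
        # tightest admissible per-strand future contribution: no window
        # can add more than the max count observed anywhere in the sequence
        self.maxcnt = [max(arr) if arr else 0 for arr in self.cnt]

    # -- loop fragment checks ---------------------------------------------

    def frag_ok(self, a: int, b: int) -> bool:
        lr = self.lr
        n = b - a
        if self.pref_fav[b] - self.pref_fav[a] < lr.favorability_coefficient * n:
            return False
        if lr.per_loop_hydrophobic_lt_hydrophilic:
            st = self.pref_strong[b] - self.pref_strong[a]
            if not st < n - st:
                return False
        return True

    def frag_strong(self, a: int, b: int) -> int:
        return self.pref_strong[b] - self.pref_strong[a]

    # -- quick necessary-condition filter ---------------------------------

    def dp_feasible(self) -> bool:
        """Sound reachability relaxation: False proves no candidate satisfies
        the per-strand bounds and per-loop checks along any skeleton path."""
        g, L, SL, N = self.g, self.L, self.SL, self.N
        lmin, lmax = g.loop_len_range
        if self.W <= 0 or L < N * SL + self.tlo:
            return False
        w_hi = L - (N * SL + self.tlo)
        if g.max_n_tail is not None:
            w_hi = min(w_hi, g.max_n_tail)
        reach: dict[int, tuple[int, int]] = {}
        for w in range(0, min(w_hi, self.W - 1) + 1):
            if self.strand_ok[1][w] and _future_feasible(
                L, g, 1, w + SL, 0, self.tlo, self.thi
            ):
                reach[w] = (0, 0)
        for k in range(1, N):
            nxt: dict[int, tuple[int, int]] = {}
            ok_next = self.strand_ok[k + 1]
            min_rest = (N - k - 1) * (SL + lmin)
            for w, (mn, mx) in reach.items():
                end = w + SL
                for ln in range(lmin, lmax + 1):
                    w2 = end + ln
                    if w2 + SL + min_rest > L:
                        break
                    if not ok_next[w2]:
                        continue
                    if self.lr is not None and not self.frag_ok(end, w2):
                        continue
                    prev = nxt.get(w2)
                    if prev is None:
                        nxt[w2] = (mn + ln, mx + ln)
                    else:
                        nxt[w2] = (min(prev[0], mn + ln), max(prev[1], mx + ln))
            reach = nxt
            if not reach:
                return False
        for w, (mn, mx) in reach.items():
            c = L - w - SL
            if c < 0:
                continue
            if g.max_c_tail is not None and c > g.max_c_tail:
                continue
            if mx >= self.tlo and mn <= self.thi:
                return True
        return False

    # -- exhaustive walk over satisfying assignments -----------------------

    def satisfying(self, prune_mins: bool = True) -> Iterator[Assignment]:
        """Yield every satisfying assignment in canonical order.

        ``prune_mins`` adds the remaining-capacity prune for aggregate
        minimum bounds; it never changes the yielded set.
        """
        g, L, SL, N, R = self.g, self.L, self.SL, self.N, self.R
        rules = self.rules
        lmin, lmax = g.loop_len_range
        tlo, thi = self.tlo, self.thi
        lr = self.lr
        if self.W <= 0 or L < N * SL + tlo:
            return
        run_all = [0] * R
        run_il = [0] * R
        run_nil = [0] * R
        loop_strong = 0
        starts = [0] * N

        def try_place(k: int, w: int) -> Optional[list[int]]:
            if not self.strand_ok[k][w]:
                return None
            cnt = self.cnt
            is_il = k in self.il_set
            run_side = run_il if is_il else run_nil
            for ri in range(R):
                c = cnt[ri][w]
                r = rules[ri]
                b = r.all_strands
                if b is not None and b.hi is not None and run_all[ri] + c > b.hi:
                    return None
                b = r.interlock_total if is_il else r.non_interlock_total
                if b is not None and b.hi is not None and run_side[ri] + c > b.hi:
                    return None
            return [cnt[ri][w] for ri in range(R)]

        def commit(k: int, deltas: list[int], sign: int) -> None:
            run_side = run_il if k in self.il_set else run_nil
            for ri in range(R):
                d = sign * deltas[ri]
                run_all[ri] += d
                run_side[ri] += d

        def capacity_dead(k: int) -> bool:
            rem_all = N - k
            rem_il = self.rem_il[k]
            rem_nil = self.rem_nil[k]
            for ri in range(R):
                r = rules[ri]
                mc = self.maxcnt[ri]
                b = r.all_strands
                if b is not None and run_all[ri] + mc * rem_all < b.lo:
                    return True
                b = r.interlock_total
                if b is not None and run_il[ri] + mc * rem_il < b.lo:
                    return True
                b = r.non_interlock_total
                if b is not None and run_nil[ri] + mc * rem_nil < b.lo:
                    return True
            return False

        def final_ok() -> bool:
            for ri in range(R):
                r = rules[ri]
                b = r.all_strands
                if b is not None and run_all[ri] < b.lo:
                    return False
                b = r.interlock_total
                if b is not None and run_il[ri] < b.lo:
                    return False
                b = r.non_interlock_total
                if b is not None and run_nil[ri] < b.lo:
                    return False
            return True

        def rec(k: int, end: int, loop_sum: int) -> Iterator[Assignment]:
            nonlocal loop_strong
            if k == N:
                if final_ok():
                    yield Assignment(tuple(starts), L)
                return
            for ln in range(lmin, lmax + 1):
                w = end + ln
                if w + SL > L:
                    break
                if not _future_feasible(L, g, k + 1, w + SL, loop_sum + ln, tlo, thi):
                    continue
                st = 0
                if lr is not None:
                    if not self.frag_ok(end, w):
                        continue
                    st = self.frag_strong(end, w)
                    if loop_strong + st > lr.total_loop_hydrophobic_max:
                        continue
                deltas = try_place(k + 1, w)
                if deltas is None:
                    continue
                commit(k + 1, deltas, 1)
                loop_strong += st
                starts[k] = w
                if not (prune_mins and capacity_dead(k + 1)):
                    yield from rec(k + 1, w + SL, loop_sum + ln)
                loop_strong -= st
                commit(k + 1, deltas, -1)

        w_hi = L - (N * SL + tlo)
        if g.max_n_tail is not None:
            w_hi = min(w_hi, g.max_n_tail)
        for w in range(0, min(w_hi, self.W - 1) + 1):
            if not _future_feasible(L, g, 1, w + SL, 0, tlo, thi):
                continue
            deltas = try_place(1, w)
            if deltas is None:
                continue
            commit(1, deltas, 1)
            starts[0] = w
            if not (prune_mins and capacity_dead(1)):
                yield from rec(1, w + SL, 0)
            commit(1, deltas, -1)

    # -- fewest-violations assignment (diagnostics) ------------------------

    def best_failing(self) -> Optional[Assignment]:
        """Candidate with the fewest violation entries (tie: canonical order).

        Branch-and-bound over the full candidate space with an admissible
        lower bound (per-strand minima plus aggregate bounds that are
        already certain to fail).
        """
        g, L, SL, N, R = self.g, self.L, self.SL, self.N, self.R
        rules = self.rules
        lmin, lmax = g.loop_len_range
        tlo, thi = self.tlo, self.thi
        lr = self.lr
        if self.W <= 0 or L < N * SL + tlo:
            return None

        # per-strand violation-entry counts per window
        sv: list[Optional[list[int]]] = [None] * (N + 1)
        minv = [0] * (N + 1)
        for k in range(1, N + 1):
            bounded = [
                (ri, r.per_strand[k]) for ri, r in enumerate(rules)
                if k in r.per_strand
            ]
            arr = []
            for w in range(self.W):
                v = 0
                for ri, b in bounded:
                    c = self.cnt[ri][w]
                    if c < b.lo or (b.hi is not None and c > b.hi):
                        v += 1
                arr.append(v)
            sv[k] = arr
            minv[k] = min(arr) if arr else 0
        suffix_minv = [0] * (N + 2)
        for k in range(N, 0, -1):
            suffix_minv[k] = suffix_minv[k + 1] + minv[k]

        run_all = [0] * R
        run_il = [0] * R
        run_nil = [0] * R
        loop_strong = 0
        starts = [0] * N
        best: list = [None, None]  # [assignment starts, entry count]

        def certain_agg(k: int) -> int:
            rem_all = N - k
            rem_il = self.rem_il[k]
            rem_nil = self.rem_nil[k]
            n = 0
            for ri in range(R):
                r = rules[ri]
                mc = self.maxcnt[ri]
                for b, run, rem in (
                    (r.all_strands, run_all[ri], rem_all),
                    (r.interlock_total, run_il[ri], rem_il),
                    (r.non_interlock_total, run_nil[ri], rem_nil),
                ):
                    if b is None:
                        continue
                    if b.hi is not None and run > b.hi:
                        n += 1
                    elif run + mc * rem < b.lo:
                        n += 1
            if lr is not None and loop_strong > lr.total_loop_hydrophobic_max:
                n += 1
            return n

        def leaf_count(cur: int) -> int:
            n = cur
            for ri in range(R):
                r = rules[ri]
                for b, run in (
                    (r.all_strands, run_all[ri]),
                    (r.interlock_total, run_il[ri]),
                    (r.non_interlock_total, run_nil[ri]),
                ):
                    if b is not None and not b.contains(run):
                        n += 1
            if lr is not None and loop_strong > lr.total_loop_hydrophobic_max:
                n += 1
            return n

        def commit(k: int, w: int, sign: int) -> None:
            run_side = run_il if k in self.il_set else run_nil
            for ri in range(R):
                d = sign * self.cnt[ri][w]
                run_all[ri] += d
                run_side[ri] += d

        def loop_entries(a: int, b: int) -> int:
            n = b - a
            e = 0
            if self.pref_fav[b] - self.pref_fav[a] < lr.favorability_coefficient * n:
                e += 1
            if lr.per_loop_hydrophobic_lt_hydrophilic:
                st = self.pref_strong[b] - self.pref_strong[a]
                if not st < n - st:
                    e += 1
            return e

        def rec(k: int, end: int, loop_sum: int, cur: int) -> None:
            nonlocal loop_strong
            if k == N:
                total = leaf_count(cur)
                if best[1] is None or total < best[1]:
                    best[0] = tuple(starts)
                    best[1] = total
                return
            for ln in range(lmin, lmax + 1):
                w = end + ln
                if w + SL > L:
                    break
                if not _future_feasible(L, g, k + 1, w + SL, loop_sum + ln, tlo, thi):
                    continue
                e = 0
                st = 0
                if lr is not None:
                    e = loop_entries(end, w)
                    st = self.frag_strong(end, w)
                cur2 = cur + e + sv[k + 1][w]
                commit(k + 1, w, 1)
                loop_strong += st
                lb = cur2 + certain_agg(k + 1) + suffix_minv[k + 2]
                if best[1] is None or lb < best[1]:
                    starts[k] = w
                    rec(k + 1, w + SL, loop_sum + ln, cur2)
                loop_strong -= st
                commit(k + 1, w, -1)

        w_hi = L - (N * SL + tlo)
        if g.max_n_tail is not None:
            w_hi = min(w_hi, g.max_n_tail)
        for w in range(0, min(w_hi, self.W - 1) + 1):
            if not _future_feasible(L, g, 1, w + SL, 0, tlo, thi):
                continue
            commit(1, w, 1)
            cur = sv[1][w]
            lb = cur + certain_agg(1) + suffix_minv[2]
            if best[1] is None or lb < best[1]:
                starts[0] = w
                rec(1, w + SL, 0, cur)
            commit(1, w, -1)
        if best[0] is None:
            return None
        return Assignment(best[0], L)


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

def search(sequence: str, ruleset: RuleSet,
           params: Optional[SearchParams] = None) -> Decision:
    """Accept iff some candidate assignment satisfies every rule.

    The witness is the first satisfying assignment in canonical order; the
    decision is identical with capacity pruning on or off.
    """
    params = params or SearchParams()
    seq = prepare_sequence(sequence, strict=params.strict_alphabet)
    n_zero = 0 if params.enumerate_all else None
    if len(seq) < ruleset.geometry.min_span():
        return Decision(False, None, n_zero)
    eng = _Engine(seq, ruleset)
    if not eng.dp_feasible():
        return Decision(False, None, n_zero)
    gen = eng.satisfying(prune_mins=params.pruning)
    if params.enumerate_all:
        n = 0
        kept: list[Assignment] = []
        for a in gen:
            if n < params.max_witnesses:
                kept.append(a)
            n += 1
        return Decision(
            accepted=n > 0,
            witness=kept[0] if kept else None,
            n_satisfying=n,
            witnesses=tuple(kept),
        )
    first = next(gen, None)
    if first is None:
        return Decision(False, None, n_zero)
    return Decision(True, first, None, witnesses=(first,))


def enumerate_satisfying(sequence: str, ruleset: RuleSet,
                         guard: int = ORACLE_LENGTH_GUARD) -> list[Assignment]:
    """Every satisfying assignment, in canonical order (oracle mode).

    Refuses sequences longer than ``guard`` residues; use :func:`search`
    for long inputs.
    """
    seq = prepare_sequence(sequence)
    if len(seq) > guard:
        raise SequenceError(
            f"sequence length {len(seq)} exceeds the oracle guard of {guard}; "
            "use search() instead"
        )
    if len(seq) < ruleset.geometry.min_span():
        return []
    eng = _Engine(seq, ruleset)
    return list(eng.satisfying(prune_mins=False))


def explain(sequence: str, ruleset: RuleSet,
            params: Optional[SearchParams] = None) -> Decision:
    """Like :func:`search`, but rejects carry the least-violating assignment."""
    params = params or SearchParams()
    decision = search(sequence, ruleset, params)
    if decision.accepted:
        return decision
    seq = prepare_sequence(sequence, strict=params.strict_alphabet)
    if len(seq) < ruleset.geometry.min_span():
        return decision
    eng = _Engine(seq, ruleset)
    a = eng.best_failing()
    if a is None:
        return decision
    report = check_assignment(seq, a, ruleset)
    return Decision(
        accepted=False,
        witness=None,
        n_satisfying=decision.n_satisfying,
        best_failing=(a, report),
    )


@dataclass(frozen=True)
class ClassifiedRecord:
    id: str
    decision: Optional[Decision]
    error: Optional[str] = None


def classify_batch(records, ruleset: RuleSet,
                   params: Optional[SearchParams] = None) -> list[ClassifiedRecord]:
    """Classify FASTA records independently; per-record errors do not abort."""
    params = params or SearchParams()
    out: list[ClassifiedRecord] = []
    seen: set[str] = set()
    for rec in records:
        rid = rec.id if hasattr(rec, "id") else rec[0]
        seq = rec.residues if hasattr(rec, "residues") else rec[1]
        if rid in seen:
            logger.warning("duplicate record id %r; processing both", rid)
        seen.add(rid)
        try:
            if params.explain:
                decision = explain(seq, ruleset, params)
            else:
                decision = search(seq, ruleset, params)
            out.append(ClassifiedRecord(rid, decision))
        except SequenceError as exc:
            logger.warning("record %r skipped: %s", rid, exc)
            out.append(ClassifiedRecord(rid, None, str(exc)))
    return out
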
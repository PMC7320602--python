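"""Exact (k,e)-frequency and mappability computation.

For a text T of length n the (k,e)-frequency F assigns every k-mer start
position i the number of positions j whose k-mer lies within Hamming
distance e of T_i; the (k,e)-mappability is the elementwise reciprocal
1/F[i].  In multi-genome mode F[i] instead counts the genomes containing
at least one approximate occurrence, which is the quantity used for
marker-sequence discovery.

The computation scans the text once and, instead of searching every
k-mer from scratch, combines three devices:

* **search schemes** — each k-mer group's shared infix is searched in the
  bidirectional FM-index under a scheme whose searches cover all error
  distributions exactly once, so occurrence counts can be summed;
* **adjacent k-mer grouping** — s consecutive k-mers share an infix of
  length k-s+1; the infix is searched once and the group is recursively
  bisected, each half extending its additional shared characters by
  backtracking with the remaining error budget;
* **redundancy skipping** — after a k-mer is counted, its exact (0-error)
  matches are located and assigned the same value, and such forwarded
  positions are skipped by the scan.

The group width s follows an empirically derived rule (see
:func:`compute_s`) balancing scheme-search efficiency against redundant
extension work.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .fm_index import BidirectionalIndex
from .search_schemes import SearchScheme, scheme_for, scheme_search, trivial_scheme
from .sequence_io import (
    GenomeCollection,
    reverse_complement_codes,
    valid_kmer_positions,
)

MODES = ("single", "multi_genome")


@dataclass
class FrequencyVector:
    """Per-position (k,e)-frequency values over the valid k-mer positions.

    ``positions`` are global coordinates into the collection's
    concatenated text; ``values[i]`` belongs to ``positions[i]``.  In
    multi-genome mode values count genomes (1..n_genomes); in single mode
    they count occurrences (>= 1, the self-match).  ``presence`` (multi
    mode only, on request) holds a genome bitmask per position;
    ``locations`` (on request) the sorted occurrence positions.
    """

    positions: np.ndarray
    values: np.ndarray
    k: int
    e: int
    mode: str = "single"
    n_genomes: int = 1
    presence: np.ndarray | None = None
    locations: dict[int, np.ndarray] | None = None

    def __len__(self) -> int:
        return len(self.values)

    def per_record(self, collection: GenomeCollection):
        """Yield (genome_idx, record_name, local_positions, values) per record."""
        for g, name, gstart, length in collection.records_global():
            sel = (self.positions >= gstart) & (self.positions < gstart + length)
            if sel.any():
                yield g, name, self.positions[sel] - gstart, self.values[sel]
            elif length >= self.k:
                yield g, name, np.zeros(0, dtype=np.int64), self.values[:0]


@dataclass
class MappabilityVector:
    """Elementwise reciprocal of a frequency vector; values in (0, 1]."""

    positions: np.ndarray
    values: np.ndarray
    k: int
    e: int
    mode: str = "single"

    def __len__(self) -> int:
        return len(self.values)


def hamming_distance(a, b) -> int:
    """Number of mismatching positions of two equal-length k-mers."""
    a = np.asarray(a if not isinstance(a, str) else list(a))
    b = np.asarray(b if not isinstance(b, str) else list(b))
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape[0]} vs {b.shape[0]}")
    return int((a != b).sum())


def clamp(v: float, lo: float, hi: float) -> float:
    return lo if v < lo else hi if v > hi else v


def compute_s(k: int, e: int) -> int:
    """Number of adjacent k-mers searched together.

    Derived from experimentally determined optima: floor(0.7k) without
    errors, otherwise floor(k * clamp(k/100, 0.3, 1.0) * 0.7^e); always
    clamped into [1, k-e+1] so a full group's shared infix has length at
    least e.
    """
    if e == 0:
        s = math.floor(k * 0.7)
    else:
        s = math.floor(k * clamp(k / 100.0, 0.3, 1.0) * 0.7 ** e)
    return int(clamp(s, 1, max(1, k - e + 1)))


def mappability(freq: FrequencyVector) -> MappabilityVector:
    """Elementwise 1/F; a zero frequency signals an internal error."""
    if (freq.values < 1).any():
        raise ValueError("frequency vector contains values < 1")
    return MappabilityVector(
        positions=freq.positions.copy(),
        values=1.0 / freq.values,
        k=freq.k,
        e=freq.e,
        mode=freq.mode,
    )


# ---------------------------------------------------------------------------
# the scan

@dataclass
class _ScanState:
    """Mutable accumulators shared by the group recursion."""

    index: BidirectionalIndex
    query: np.ndarray
    k: int
    e: int
    scheme: SearchScheme
    small_scheme: SearchScheme
    collect_masks: bool
    collect_locations: bool
    gid_lookup: object = None  # callable positions -> genome ids
    counts: dict = field(default_factory=dict)
    masks: dict = field(default_factory=dict)
    locations: dict = field(default_factory=dict)


def _extend_once(state: _ScanState, states, pos: int, left: bool):
    """One backtracking step: extend every candidate by the query symbol at
    ``pos`` (cost 0) or a substituted symbol (cost 1), within the budget."""
    want = int(state.query[pos])
    index = state.index
    e = state.e
    extend = index.extend_left if left else index.extend_right
    out = []
    for rng, err in states:
        nxt = extend(rng, want)
        if not nxt.empty:
            out.append((nxt, err))
        if err < e:
            for sym in (1, 2, 3, 4):
                if sym == want:
                    continue
                nxt = extend(rng, sym)
                if not nxt.empty:
                    out.append((nxt, err + 1))
    return out


def _recurse_group(state: _ScanState, a: int, b: int, lo: int, hi: int, states):
    """Bisect the k-mer group [a, b), extending each half's extra shared
    characters; the matched query span is always [b-1, a+k)."""
    if not states:
        for q in range(a, b):
            state.counts.setdefault(q, 0)
        return
    if b - a == 1:
        _leaf(state, a, states)
        return
    m = (b - a + 1) // 2  # left half gets the extra k-mer
    # left half [a, a+m): extend left down to a+m-1
    left_states = states
    for pos in range(lo - 1, a + m - 1 - 1, -1):
        left_states = _extend_once(state, left_states, pos, left=True)
        if not left_states:
            break
    _recurse_group(state, a, a + m, a + m - 1, hi, left_states)
    # right half [a+m, b): extend right up to a+m+k
    right_states = states
    for pos in range(hi, a + m + state.k):
        right_states = _extend_once(state, right_states, pos, left=False)
        if not right_states:
            break
    _recurse_group(state, a + m, b, lo, a + m + state.k, right_states)


def _leaf(state: _ScanState, q: int, states):
    total = 0
    mask = 0
    locs = [] if (state.collect_masks or state.collect_locations) else None
    exact_positions = []
    for rng, err in states:
        total += rng.width
        if locs is not None:
            pos = state.index.locate(rng)
            locs.append(pos)
            if err == 0:
                exact_positions.append(pos)
    state.counts[q] = state.counts.get(q, 0) + total
    if locs is not None:
        allpos = np.sort(np.concatenate(locs)) if locs else np.zeros(0, dtype=np.int64)
        if state.collect_masks:
            gids = state.gid_lookup(allpos)
            for g in set(gids.tolist()):
                mask |= 1 << g
            state.masks[q] = state.masks.get(q, 0) | mask
        if state.collect_locations:
            prev = state.locations.get(q)
            state.locations[q] = (
                allpos if prev is None else np.sort(np.concatenate([prev, allpos]))
            )


def _scan_query(
    state: _ScanState,
    positions: np.ndarray,
    s: int,
    use_skipping: bool,
    forward_to=None,
):
    """Scan the query's valid positions in consecutive-run groups.

    ``forward_to``: optional (computed_set, position_map) enabling
    exact-match forwarding when the query *is* the indexed text.
    """
    computed = forward_to[0] if forward_to is not None else None
    pos_set = forward_to[1] if forward_to is not None else None
    i = 0
    npos = len(positions)
    while i < npos:
        p = int(positions[i])
        if computed is not None and p in computed:
            i += 1
            continue
        # maximal run of consecutive, not-yet-computed positions, <= s
        g = 1
        while (
            g < s
            and i + g < npos
            and positions[i + g] == p + g
            and (computed is None or int(positions[i + g]) not in computed)
        ):
            g += 1
        _search_group(state, p, g)
        if computed is not None:
            for q in range(p, p + g):
                value = state.counts[q]
                vmask = state.masks.get(q, 0)
                computed.add(q)
                if use_skipping:
                    exact = _exact_matches(state, q)
                    for j in exact:
                        j = int(j)
                        if j != q and j in pos_set and j not in computed:
                            state.counts[j] = value
                            if state.collect_masks:
                                state.masks[j] = vmask
                            if state.collect_locations:
                                state.locations[j] = state.locations[q]
                            computed.add(j)
        i += g


def _search_group(state: _ScanState, a: int, g: int):
    k, e = state.k, state.e
    infix = state.query[a + g - 1 : a + k]
    scheme = state.scheme if len(infix) >= state.scheme.p else state.small_scheme
    states = scheme_search(state.index, infix, scheme, e)
    _recurse_group(state, a, a + g, a + g - 1, a + k, states)


def _exact_matches(state: _ScanState, q: int) -> np.ndarray:
    """Text positions of the 0-error matches of the k-mer at query position q."""
    rng = state.index.init_range()
    for sym in state.query[q : q + state.k][::-1]:
        rng = state.index.extend_left(rng, int(sym))
        if rng.empty:
            return np.zeros(0, dtype=np.int64)
    return state.index.locate(rng)


def frequency(
    index: BidirectionalIndex,
    collection: GenomeCollection,
    k: int,
    e: int,
    *,
    mode: str = "single",
    reverse_complement: bool = False,
    exclude_pseudo: bool = False,
    s: int | None = None,
    use_skipping: bool = True,
    store_locations: bool = False,
    collect_presence: bool = False,
) -> FrequencyVector:
    """Exact (k,e)-frequency of every valid k-mer position.

    ``mode='multi_genome'`` counts each genome at most once per k-mer
    (presence counting); ``reverse_complement`` additionally searches each
    k-mer's reverse complement (counts are added in single mode; in multi
    mode a genome counts once if it contains either orientation).
    ``exclude_pseudo`` is accepted for interface compatibility: presence
    counting is by definition insensitive to within-genome copy number.
    ``s`` overrides the group width (1 disables grouping);
    ``use_skipping=False`` disables exact-match forwarding.  Both knobs
    exist for ablation: results are invariant to them.
    """
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}; expected one of {MODES}")
    if k - e + 1 < 1:
        raise ValueError(f"k - e + 1 must be >= 1 (k={k}, e={e})")
    if mode == "multi_genome" and collection.n_genomes > 63:
        raise ValueError("multi-genome mode supports at most 63 genomes")
    if s is None:
        s = compute_s(k, e)
    if not 1 <= s <= max(1, k - e + 1):
        raise ValueError(f"s={s} outside [1, k-e+1]")

    text = collection.concatenated()
    positions = valid_kmer_positions(collection, k)
    scheme = scheme_for(e)
    small = trivial_scheme(e)
    collect_masks = mode == "multi_genome" or collect_presence

    state = _ScanState(
        index=index,
        query=text,
        k=k,
        e=e,
        scheme=scheme,
        small_scheme=small,
        collect_masks=collect_masks,
        collect_locations=store_locations,
        gid_lookup=collection.genome_id_of_positions,
    )
    computed: set[int] = set()
    pos_set = set(positions.tolist())
    _scan_query(state, positions, s, use_skipping, forward_to=(computed, pos_set))

    counts = state.counts
    masks = state.masks

    if reverse_complement:
        rc_state = _ScanState(
            index=index,
            query=reverse_complement_codes(text),
            k=k,
            e=e,
            scheme=scheme,
            small_scheme=small,
            collect_masks=collect_masks,
            collect_locations=store_locations,
            gid_lookup=collection.genome_id_of_positions,
        )
        n = len(text)
        rc_positions = np.sort(n - k - positions)
        _scan_query(rc_state, rc_positions, s, use_skipping=False, forward_to=None)
        for p in positions.tolist():
            rp = n - k - p
            counts[p] = counts.get(p, 0) + rc_state.counts.get(rp, 0)
            if collect_masks:
                masks[p] = masks.get(p, 0) | rc_state.masks.get(rp, 0)
            if store_locations:
                extra = rc_state.locations.get(rp)
                if extra is not None and len(extra):
                    prev = state.locations.get(p)
                    state.locations[p] = (
                        extra if prev is None or not len(prev)
                        else np.sort(np.concatenate([prev, extra]))
                    )

    if mode == "multi_genome":
        values = np.array(
            [bin(masks.get(int(p), 0)).count("1") for p in positions], dtype=np.int64
        )
    else:
        values = np.array([counts[int(p)] for p in positions], dtype=np.int64)

    presence = None
    if collect_masks:
        presence = np.array([masks.get(int(p), 0) for p in positions], dtype=np.uint64)
    locations = None
    if store_locations:
        locations = {int(p): state.locations.get(int(p), np.zeros(0, dtype=np.int64))
                     for p in positions}
    return FrequencyVector(
        positions=positions,
        values=values,
        k=k,
        e=e,
        mode=mode,
        n_genomes=collection.n_genomes,
        presence=presence,
        locations=locations,
    )


def heuristic_frequency(
    index: BidirectionalIndex,
    collection: GenomeCollection,
    k: int,
    e: int,
    t: float = math.inf,
) -> FrequencyVector:
    """Threshold-forwarding heuristic (frequency baseline, single genome).

    Scans the text, skipping positions whose value was already assigned;
    each remaining k-mer is searched with e mismatches and, when its
    occurrence count exceeds the threshold ``t``, the count is forwarded
    to *all* its approximate occurrences as a lower bound
    (``F[j] = max(F[j], |P|)``).  Forwarded values can overestimate the
    true frequency of rather unique k-mers; ``t = inf`` disables
    forwarding entirely and reproduces the exact frequency.
    """
    if collection.n_genomes != 1:
        raise ValueError("the heuristic baseline is defined for a single genome")
    if k - e + 1 < 1:
        raise ValueError(f"k - e + 1 must be >= 1 (k={k}, e={e})")
    text = collection.concatenated()
    positions = valid_kmer_positions(collection, k)
    scheme = scheme_for(e)
    small = trivial_scheme(e)
    F: dict[int, int] = {}
    for p in positions.tolist():
        if F.get(p, 0) != 0:
            continue
        pattern = text[p : p + k]
        use = scheme if len(pattern) >= scheme.p else small
        ranges = scheme_search(index, pattern, use, e)
        occs = (
            np.sort(np.concatenate([index.locate(r) for r, _err in ranges]))
            if ranges
            else np.zeros(0, dtype=np.int64)
        )
        count = len(occs)
        F[p] = count
        if count > t:
            for j in occs.tolist():
                F[j] = max(F.get(j, 0), count)
    values = np.array([F[int(p)] for p in positions], dtype=np.int64)
    return FrequencyVector(
        positions=positions, values=values, k=k, e=e, mode="single", n_genomes=1
    )
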
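"""Search schemes for approximate matching in a bidirectional index.

A *search* is a triplet (pi, L, U): ``pi`` is the order in which the p
contiguous pieces of the pattern are visited (each new piece adjacent to
the block already searched), and ``L``/``U`` are non-decreasing cumulative
lower/upper bounds on the number of mismatches spent after finishing each
visited piece.  A *search scheme* is a set of searches whose covered
error distributions are exactly all p-tuples with sum <= e, pairwise
disjoint — disjointness is what lets occurrence counts from the
individual searches be summed without double counting.

Schemes are shipped as human-readable JSON tables (one per error count)
and validated on load.  The e=2 scheme is the published optimum
three-search scheme; e=1 uses a compact two-search bidirectional scheme;
e=3 and e=4 use a fallback family that partitions distributions by the
first piece carrying an error (forward searches with forced-zero
prefixes) — valid and disjoint, if not step-optimal.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from itertools import product
from typing import Sequence

import numpy as np

from .fm_index import BidirectionalIndex, BidirectionalRange

MAX_ERRORS = 4


@dataclass(frozen=True)
class Search:
    """One search: piece order ``pi`` (1-based) and cumulative bounds."""

    pi: tuple[int, ...]
    lower: tuple[int, ...]
    upper: tuple[int, ...]

    @property
    def p(self) -> int:
        return len(self.pi)

    def validate(self) -> None:
        p = self.p
        if sorted(self.pi) != list(range(1, p + 1)):
            raise ValueError(f"pi {self.pi} is not a permutation of 1..{p}")
        if len(self.lower) != p or len(self.upper) != p:
            raise ValueError("pi, lower and upper must have equal length")
        seen = {self.pi[0]}
        for piece in self.pi[1:]:
            if piece != min(seen) - 1 and piece != max(seen) + 1:
                raise ValueError(f"piece order {self.pi} is not contiguous")
            seen.add(piece)
        for name, bounds in (("lower", self.lower), ("upper", self.upper)):
            if any(b < a for a, b in zip(bounds, bounds[1:])):
                raise ValueError(f"{name} bounds {bounds} are not non-decreasing")
        if any(l > u for l, u in zip(self.lower, self.upper)):
            raise ValueError("lower bound exceeds upper bound")


@dataclass(frozen=True)
class SearchScheme:
    searches: tuple[Search, ...]
    e: int
    p: int


@dataclass
class ValidationReport:
    complete: bool
    disjoint: bool
    missing: set[tuple[int, ...]] = field(default_factory=set)
    overlapping: set[tuple[int, ...]] = field(default_factory=set)

    @property
    def ok(self) -> bool:
        return self.complete and self.disjoint


def covered_distributions(search: Search, e: int) -> set[tuple[int, ...]]:
    """All per-piece error tuples (in original piece order) this search covers.

    A tuple is covered when, walking the pieces in ``pi`` order, the running
    mismatch total lies within [L[i], U[i]] after every visited piece.
    """
    search.validate()
    p = search.p
    covered = set()
    for tup in product(range(e + 1), repeat=p):
        if sum(tup) > e:
            continue
        total = 0
        ok = True
        for i, piece in enumerate(search.pi):
            total += tup[piece - 1]
            if not search.lower[i] <= total <= search.upper[i]:
                ok = False
                break
        if ok:
            covered.add(tup)
    return covered


def all_distributions(p: int, e: int) -> set[tuple[int, ...]]:
    return {t for t in product(range(e + 1), repeat=p) if sum(t) <= e}


def validate_scheme(scheme: SearchScheme) -> ValidationReport:
    """Check completeness and disjointness of a scheme's covered sets."""
    target = all_distributions(scheme.p, scheme.e)
    seen: dict[tuple[int, ...], int] = {}
    for search in scheme.searches:
        if search.p != scheme.p:
            raise ValueError("search piece count differs from scheme piece count")
        for tup in covered_distributions(search, scheme.e):
            seen[tup] = seen.get(tup, 0) + 1
    missing = target - set(seen)
    overlapping = {t for t, c in seen.items() if c > 1}
    stray = set(seen) - target
    return ValidationReport(
        complete=not missing and not stray,
        disjoint=not overlapping,
        missing=missing,
        overlapping=overlapping,
    )


def _load_table(e: int) -> SearchScheme:
    ref = resources.files(__package__) / "schemes" / f"scheme_e{e}.json"
    data = json.loads(ref.read_text())
    searches = tuple(
        Search(pi=tuple(s["pi"]), lower=tuple(s["L"]), upper=tuple(s["U"]))
        for s in data["searches"]
    )
    scheme = SearchScheme(searches=searches, e=int(data["e"]), p=int(data["p"]))
    report = validate_scheme(scheme)
    if not report.ok:
        raise ValueError(
            f"shipped scheme for e={e} failed validation: "
            f"missing={sorted(report.missing)} overlapping={sorted(report.overlapping)}"
        )
    return scheme


_SCHEME_CACHE: dict[int, SearchScheme] = {}


def scheme_for(e: int) -> SearchScheme:
    """Validated scheme for ``e`` mismatches (p = e + 2 pieces; p = 1 for e=0)."""
    if not 0 <= e <= MAX_ERRORS:
        raise ValueError(f"supported error counts are 0..{MAX_ERRORS}, got {e}")
    if e not in _SCHEME_CACHE:
        _SCHEME_CACHE[e] = _load_table(e)
    return _SCHEME_CACHE[e]


def trivial_scheme(e: int) -> SearchScheme:
    """Single-piece full-backtracking scheme (used when the pattern is shorter
    than the standard scheme's piece count)."""
    return SearchScheme(
        searches=(Search(pi=(1,), lower=(0,), upper=(e,)),), e=e, p=1
    )


def split_pieces(length: int, p: int) -> list[tuple[int, int]]:
    """Piece boundaries: as equal as possible, remainder on the last pieces."""
    if length < p:
        raise ValueError(f"pattern of length {length} cannot be split into {p} pieces")
    base, rem = divmod(length, p)
    bounds = []
    start = 0
    for i in range(p):
        size = base + (1 if i >= p - rem else 0)
        bounds.append((start, start + size))
        start += size
    return bounds


def scheme_search(
    index: BidirectionalIndex,
    pattern: np.ndarray | Sequence[int],
    scheme: SearchScheme,
    e: int | None = None,
) -> list[tuple[BidirectionalRange, int]]:
    """All approximate matches of ``pattern`` with <= e mismatches.

    Returns (range, mismatches) pairs; because the scheme's covered
    distributions are disjoint and substitution branches exclude the
    pattern's own symbol, every occurrence position appears under exactly
    one returned range.
    """
    pattern = np.asarray(pattern, dtype=np.uint8)
    if e is None:
        e = scheme.e
    pieces = split_pieces(len(pattern), scheme.p)
    results: list[tuple[BidirectionalRange, int]] = []
    for search in scheme.searches:
        results.extend(_run_search(index, pattern, pieces, search))
    return results


def _run_search(
    index: BidirectionalIndex,
    pattern: np.ndarray,
    pieces: list[tuple[int, int]],
    search: Search,
) -> list[tuple[BidirectionalRange, int]]:
    p = search.p
    # (range, errors) states surviving the pieces processed so far
    states = [(index.init_range(), 0)]
    first = search.pi[0] - 1
    # span of pattern already matched, in piece indices [lo_piece, hi_piece)
    lo_piece = hi_piece = first
    for i, piece_1b in enumerate(search.pi):
        q = piece_1b - 1
        start, end = pieces[q]
        if i == 0:
            # first piece: search toward the side the next piece lies on,
            # so later pieces always extend an edge of the matched block
            go_right = p == 1 or search.pi[1] - 1 > first
            chars = range(start, end) if go_right else range(end - 1, start - 1, -1)
            extend_left_side = not go_right
        elif q < lo_piece:
            chars = range(end - 1, start - 1, -1)
            extend_left_side = True
        else:
            chars = range(start, end)
            extend_left_side = False
        upper = search.upper[i]
        for pos in chars:
            want = int(pattern[pos])
            new_states = []
            for rng, err in states:
                for sym in (want, *(s for s in (1, 2, 3, 4) if s != want)):
                    cost = 0 if sym == want else 1
                    if err + cost > upper:
                        continue
                    nxt = (
                        index.extend_left(rng, sym)
                        if extend_left_side
                        else index.extend_right(rng, sym)
                    )
                    if not nxt.empty:
                        new_states.append((nxt, err + cost))
            states = new_states
            if not states:
                return []
        lower = search.lower[i]
        states = [(rng, err) for rng, err in states if err >= lower]
        if not states:
            return []
        lo_piece = min(lo_piece, q)
        hi_piece = max(hi_piece, q)
    return states


def hamming_occurrences(
    text: np.ndarray, pattern: np.ndarray, e: int
) -> np.ndarray:
    """Brute-force oracle: start positions where the pattern matches the
    text with <= e mismatches (dna4 symbols only; separators never match)."""
    text = np.asarray(text)
    pattern = np.asarray(pattern)
    k = len(pattern)
    n = len(text)
    if n < k:
        return np.zeros(0, dtype=np.int64)
    windows = np.lib.stride_tricks.sliding_window_view(text, k)
    mismatches = (windows != pattern).sum(axis=1)
    non_base = ((windows < 1) | (windows > 4)).any(axis=1)
    return np.flatnonzero((mismatches <= e) & ~non_base).astype(np.int64)
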
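"""Bidirectional FM-index over the dna4 + separator alphabet.

The index stores the BWT of the concatenated text and of its reverse,
cumulative symbol counts (C array), per-symbol prefix-rank tables and a
sampled suffix array.  Holding both BWTs lets a pattern be extended by a
character on either end in O(1) rank operations, which is what search
schemes and the adjacent-k-mer recursion rely on.

Rank support is a plain cumulative-count table per symbol (5 x (n+1)
int32), trading memory for simplicity; at the genome sizes this package
targets that is a few MB.  The suffix array is sampled at text positions
divisible by ``sampling_rate`` and recovered by LF-walks.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .sequence_io import GenomeCollection, TERMINATOR

ALPHABET_SIZE = 6  # terminator + ACGT + separator
DEFAULT_SAMPLING_RATE = 10
INDEX_FORMAT_VERSION = 1


def suffix_array(text: np.ndarray) -> np.ndarray:
    """Suffix array by prefix doubling (numpy lexsort), O(n log^2 n).

    Works for any integer text; no unique-sentinel requirement.  Suffix i
    is the substring text[i:]; shorter suffixes sort as if padded with a
    symbol smaller than everything (rank -1).
    """
    n = len(text)
    if n == 0:
        raise ValueError("cannot index an empty text")
    rank = np.asarray(text, dtype=np.int64)
    sa = np.argsort(rank, kind="stable")
    tmp = np.empty(n, dtype=np.int64)
    step = 1
    while True:
        key2 = np.full(n, -1, dtype=np.int64)
        key2[:-step] = rank[step:]
        sa = np.lexsort((key2, rank))
        tmp[sa[0]] = 0
        prev, cur = sa[:-1], sa[1:]
        newer = (rank[cur] != rank[prev]) | (key2[cur] != key2[prev])
        tmp[cur] = np.cumsum(newer)
        rank, tmp = tmp, rank
        if rank[sa[-1]] == n - 1:
            break
        step *= 2
    return sa.astype(np.int64)


def _bwt_from_sa(text: np.ndarray, sa: np.ndarray) -> np.ndarray:
    return text[(sa - 1) % len(text)].astype(np.uint8)


def _occ_table(bwt: np.ndarray) -> np.ndarray:
    """occ[c, i] = number of occurrences of symbol c in bwt[:i]."""
    n = len(bwt)
    occ = np.zeros((ALPHABET_SIZE, n + 1), dtype=np.int64)
    for c in range(ALPHABET_SIZE):
        occ[c, 1:] = np.cumsum(bwt == c)
    return occ


@dataclass(frozen=True)
class BidirectionalRange:
    """Synchronised suffix-array intervals of one matched string.

    ``fwd`` is the half-open interval in the forward suffix array,
    ``rev`` the interval of the reversed matched string in the suffix
    array of the reversed text; both have equal width, which equals the
    number of text occurrences of the matched string.
    """

    fwd: tuple[int, int]
    rev: tuple[int, int]
    depth: int = 0

    @property
    def width(self) -> int:
        return self.fwd[1] - self.fwd[0]

    @property
    def empty(self) -> bool:
        return self.fwd[1] <= self.fwd[0]


class BidirectionalIndex:
    """FM-index of a text and its reverse, with a sampled suffix array."""

    def __init__(self, text: np.ndarray, sampling_rate: int = DEFAULT_SAMPLING_RATE):
        """``text`` uses codes 1..4 for bases and 5 for record separators;
        a unique terminal sentinel (code 0) is appended internally, so the
        input must not contain 0 itself."""
        text = np.asarray(text, dtype=np.uint8)
        if len(text) == 0:
            raise ValueError("cannot build an index over an empty text")
        if (text == TERMINATOR).any():
            raise ValueError("input text must not contain the terminator code 0")
        if sampling_rate < 1:
            raise ValueError("sampling_rate must be >= 1")
        self.n = int(len(text)) + 1  # rows including the terminal sentinel
        self.sampling_rate = int(sampling_rate)
        self._build(text)

    def _build(self, raw: np.ndarray) -> None:
        # both directions get their own terminal sentinel, so suffix order
        # equals rotation order and LF-walks are exact in each index
        term = np.array([TERMINATOR], dtype=np.uint8)
        text = np.concatenate([raw, term])
        rtext = np.concatenate([raw[::-1], term])
        sa_f = suffix_array(text)
        sa_r = suffix_array(rtext)
        self.bwt_fwd = _bwt_from_sa(text, sa_f)
        self.bwt_rev = _bwt_from_sa(rtext, sa_r)
        self.occ_fwd = _occ_table(self.bwt_fwd)
        self.occ_rev = _occ_table(self.bwt_rev)
        counts = np.bincount(text, minlength=ALPHABET_SIZE).astype(np.int64)
        self.C = np.zeros(ALPHABET_SIZE + 1, dtype=np.int64)
        self.C[1:] = np.cumsum(counts)
        # SA samples at text positions divisible by the rate (position 0
        # always sampled, so LF-walks terminate within rate-1 steps).
        marked = sa_f % self.sampling_rate == 0
        self.sa_marked = marked
        self.sa_rank = np.cumsum(marked) - 1  # index into sa_samples where marked
        self.sa_samples = sa_f[marked]

    # -- search primitives -------------------------------------------------

    def init_range(self) -> BidirectionalRange:
        """Range of the empty string: all suffixes of text and reverse text."""
        return BidirectionalRange(fwd=(0, self.n), rev=(0, self.n), depth=0)

    def _check_symbol(self, symbol: int) -> None:
        if not 1 <= symbol <= 4:
            raise ValueError(f"symbol {symbol} outside the dna4 code range 1..4")

    def extend_left(self, rng: BidirectionalRange, symbol: int) -> BidirectionalRange:
        """Range of c+W given the range of W (c prepended)."""
        self._check_symbol(symbol)
        l, r = rng.fwd
        occ = self.occ_fwd
        nl = self.C[symbol] + occ[symbol, l]
        nr = self.C[symbol] + occ[symbol, r]
        smaller = 0
        for b in range(symbol):
            smaller += occ[b, r] - occ[b, l]
        rl = rng.rev[0] + smaller
        return BidirectionalRange(fwd=(int(nl), int(nr)), rev=(int(rl), int(rl + nr - nl)),
                                  depth=rng.depth + 1)

    def extend_right(self, rng: BidirectionalRange, symbol: int) -> BidirectionalRange:
        """Range of W+c given the range of W (c appended)."""
        self._check_symbol(symbol)
        l, r = rng.rev
        occ = self.occ_rev
        nl = self.C[symbol] + occ[symbol, l]
        nr = self.C[symbol] + occ[symbol, r]
        smaller = 0
        for b in range(symbol):
            smaller += occ[b, r] - occ[b, l]
        fl = rng.fwd[0] + smaller
        return BidirectionalRange(fwd=(int(fl), int(fl + nr - nl)), rev=(int(nl), int(nr)),
                                  depth=rng.depth + 1)

    def count(self, pattern: np.ndarray) -> int:
        """Exact occurrence count of a dna4 pattern."""
        rng = self.init_range()
        for symbol in np.asarray(pattern)[::-1]:
            rng = self.extend_left(rng, int(symbol))
            if rng.empty:
                return 0
        return rng.width

    def _lf(self, i: int) -> int:
        c = self.bwt_fwd[i]
        return int(self.C[c] + self.occ_fwd[c, i])

    def locate(self, rng: BidirectionalRange) -> np.ndarray:
        """Start positions of the matched string, each exactly once."""
        out = np.empty(rng.width, dtype=np.int64)
        for j, i in enumerate(range(rng.fwd[0], rng.fwd[1])):
            steps = 0
            while not self.sa_marked[i]:
                i = self._lf(i)
                steps += 1
            out[j] = self.sa_samples[self.sa_rank[i]] + steps
        return out

    def search(self, pattern: np.ndarray) -> np.ndarray:
        """Exact search: sorted start positions of a dna4 pattern."""
        rng = self.init_range()
        for symbol in np.asarray(pattern)[::-1]:
            rng = self.extend_left(rng, int(symbol))
            if rng.empty:
                return np.zeros(0, dtype=np.int64)
        return np.sort(self.locate(rng))

    # -- persistence -------------------------------------------------------

    _ARRAYS = ("bwt_fwd", "bwt_rev", "occ_fwd", "occ_rev", "C",
               "sa_marked", "sa_rank", "sa_samples")

    def save(self, directory: str | os.PathLike, metadata: dict | None = None) -> None:
        """Persist as a versioned directory of .npy arrays plus a manifest."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for name in self._ARRAYS:
            np.save(directory / f"{name}.npy", getattr(self, name))
        manifest = {
            "format_version": INDEX_FORMAT_VERSION,
            "n": self.n,
            "sampling_rate": self.sampling_rate,
        }
        if metadata:
            manifest["metadata"] = metadata
        with open(directory / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)

    @classmethod
    def load(cls, directory: str | os.PathLike) -> tuple["BidirectionalIndex", dict]:
        """Load a persisted index; returns (index, metadata)."""
        directory = Path(directory)
        manifest_path = directory / "manifest.json"
        if not manifest_path.exists():
            raise FileNotFoundError(f"no index manifest at {manifest_path}")
        with open(manifest_path) as fh:
            manifest = json.load(fh)
        if manifest.get("format_version") != INDEX_FORMAT_VERSION:
            raise ValueError(
                f"index format version {manifest.get('format_version')} not supported"
            )
        obj = cls.__new__(cls)
        obj.n = int(manifest["n"])
        obj.sampling_rate = int(manifest["sampling_rate"])
        for name in cls._ARRAYS:
            setattr(obj, name, np.load(directory / f"{name}.npy"))
        return obj, manifest.get("metadata", {})


def build_index(
    collection: GenomeCollection, sampling_rate: int = DEFAULT_SAMPLING_RATE
) -> BidirectionalIndex:
    """Index the concatenated text of a genome collection."""
    return BidirectionalIndex(collection.concatenated(), sampling_rate=sampling_rate)
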
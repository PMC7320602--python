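"""Brute-force reference implementations.

Everything here evaluates the (k,e)-frequency definition directly —
all-pairs Hamming comparison over explicit k-mer windows — and shares no
code with the FM-index search path, so it can serve as an independent
oracle in tests.  A size guard keeps accidental large inputs from
freezing a test run.
"""

from __future__ import annotations

from collections import Counter, defaultdict

import numpy as np

from .sequence_io import (
    GenomeCollection,
    collection_from_strings,
    reverse_complement_codes,
    valid_kmer_positions,
)

MAX_TOTAL_LENGTH = 20_000


def _as_collection(texts) -> GenomeCollection:
    if isinstance(texts, GenomeCollection):
        return texts
    if isinstance(texts, str):
        texts = [texts]
    return collection_from_strings(list(texts))


def _windows(collection: GenomeCollection, k: int):
    """(windows matrix, valid positions, genome id per window)."""
    text = collection.concatenated()
    positions = valid_kmer_positions(collection, k)
    win = np.lib.stride_tricks.sliding_window_view(text, k)[positions]
    gids = collection.genome_id_of_positions(positions)
    return win, positions, gids, text


def brute_force_frequency(
    texts,
    k: int,
    e: int,
    reverse_complement: bool = False,
    mode: str = "single",
) -> np.ndarray:
    """Exact (k,e)-frequency by all-pairs comparison.

    ``texts`` may be a GenomeCollection, a string, or a list of strings
    (one genome each).  Returns the frequency value per valid k-mer
    position, aligned with :func:`valid_kmer_positions`.  In multi-genome
    mode a genome contributes 1 iff it holds at least one approximate
    occurrence (of the k-mer or, with ``reverse_complement``, of its
    reverse complement).
    """
    collection = _as_collection(texts)
    total = sum(g.total_length for g in collection.genomes)
    if total > MAX_TOTAL_LENGTH:
        raise ValueError(
            f"size guard exceeded: total length {total} > {MAX_TOTAL_LENGTH}"
        )
    win, positions, gids, _text = _windows(collection, k)
    npos = win.shape[0]
    values = np.zeros(npos, dtype=np.int64)
    win_rc = None
    if reverse_complement:
        win_rc = np.stack([reverse_complement_codes(w) for w in win]) if npos else win
    for i in range(npos):
        dist = (win != win[i]).sum(axis=1)
        hits = dist <= e
        if mode == "single":
            value = int(hits.sum())
            if reverse_complement:
                dist_rc = (win != win_rc[i]).sum(axis=1)
                value += int((dist_rc <= e).sum())
            values[i] = value
        elif mode == "multi_genome":
            present = set(gids[hits].tolist())
            if reverse_complement:
                dist_rc = (win != win_rc[i]).sum(axis=1)
                present |= set(gids[dist_rc <= e].tolist())
            values[i] = len(present)
        else:
            raise ValueError(f"unknown mode {mode!r}")
    return values


def brute_force_presence(
    texts, k: int, e: int, reverse_complement: bool = False
) -> list[frozenset]:
    """Per valid position: the set of genome indices holding >=1 occurrence."""
    collection = _as_collection(texts)
    win, positions, gids, _text = _windows(collection, k)
    out = []
    win_rc = None
    if reverse_complement and win.shape[0]:
        win_rc = np.stack([reverse_complement_codes(w) for w in win])
    for i in range(win.shape[0]):
        hits = (win != win[i]).sum(axis=1) <= e
        present = set(gids[hits].tolist())
        if reverse_complement:
            present |= set(gids[(win != win_rc[i]).sum(axis=1) <= e].tolist())
        out.append(frozenset(present))
    return out


def hash_frequency(texts, k: int, mode: str = "single") -> np.ndarray:
    """Independent exact-match (e=0) counter built on a hash table.

    Deliberately coded differently from both the FM-index path and the
    all-pairs oracle: k-mers are tallied as byte strings.
    """
    collection = _as_collection(texts)
    win, positions, gids, _text = _windows(collection, k)
    keys = [w.tobytes() for w in win]
    if mode == "single":
        counts = Counter(keys)
        return np.array([counts[key] for key in keys], dtype=np.int64)
    genome_sets: dict[bytes, set] = defaultdict(set)
    for key, g in zip(keys, gids):
        genome_sets[key].add(int(g))
    return np.array([len(genome_sets[key]) for key in keys], dtype=np.int64)
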
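"""Marker-sequence discovery across multiple genomes.

Computing the (k,e)-frequency across a set of closely related strains,
with each genome counted at most once per k-mer, identifies two kinds of
candidate markers: k-mers *unique* to a single strain (present there
exactly once), which pinpoint the exact strain, and k-mers *shared* by
all strains of a phylogenetic group but absent from another group, which
separate the groups.  k-mers found in only one strain but several times
within it are called *pseudo* markers.

Because unique k-mers come in long overlapping runs, each report also
counts *non-adjacent* markers: a marker qualifies only if its preceding
k-mer exists and is itself not a marker of the same kind, which collapses
each run to its first position.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import frequency
from .fm_index import BidirectionalIndex
from .sequence_io import GenomeCollection


@dataclass
class MarkerReport:
    """Per-genome marker counts and spacing statistics.

    ``dist_mean``/``dist_sd`` describe the distance between consecutive
    unique-marker start positions within the genome (same record);
    the ``nonadjacent`` fields repeat all quantities for markers whose
    preceding k-mer is not itself strain-specific.
    """

    genome: int
    name: str
    n_unique: int
    n_pseudo: int
    n_shared: int
    dist_mean: float
    dist_sd: float
    n_unique_nonadjacent: int
    n_pseudo_nonadjacent: int
    dist_mean_nonadjacent: float
    dist_sd_nonadjacent: float
    unique_positions: np.ndarray = None
    unique_positions_nonadjacent: np.ndarray = None


def _distance_stats(positions: np.ndarray, records: np.ndarray) -> tuple[float, float]:
    """Mean +/- sd of gaps between consecutive positions within one record."""
    gaps = []
    for rec in np.unique(records):
        pos = np.sort(positions[records == rec])
        if len(pos) > 1:
            gaps.append(np.diff(pos))
    if not gaps:
        return float("nan"), float("nan")
    gaps = np.concatenate(gaps)
    return float(gaps.mean()), float(gaps.std())


def _position_frame(collection: GenomeCollection, positions: np.ndarray):
    """(genome id, record id, record-local offset) per global position."""
    starts = collection._record_starts
    rec_idx = np.searchsorted(starts, positions, side="right") - 1
    gids = np.array([t[0] for t in collection._record_table], dtype=np.int64)[rec_idx]
    local = positions - starts[rec_idx]
    return gids, rec_idx, local


def marker_report(
    index: BidirectionalIndex,
    collection: GenomeCollection,
    k: int,
    e: int,
    *,
    reverse_complement: bool = False,
) -> list[MarkerReport]:
    """Unique / pseudo / shared marker counts per genome.

    A position is *unique* when its k-mer has approximate occurrences in
    exactly one genome (its own) and exactly one occurrence overall;
    *pseudo* when it is confined to one genome but occurs there more than
    once; *shared* when every genome of the collection holds at least one
    occurrence.  Spacing statistics cover consecutive unique markers.
    """
    if collection.n_genomes < 2:
        raise ValueError("marker discovery needs at least 2 genomes")
    freq = frequency(
        index, collection, k, e,
        mode="single",
        reverse_complement=reverse_complement,
        collect_presence=True,
    )
    positions = freq.positions
    totals = freq.values
    masks = freq.presence.astype(np.int64)
    popcount = np.array([bin(int(m)).count("1") for m in masks], dtype=np.int64)

    gids, rec_idx, local = _position_frame(collection, positions)
    own_only = np.array(
        [int(m) == (1 << int(g)) for m, g in zip(masks, gids)], dtype=bool
    )
    unique = own_only & (totals == 1)
    pseudo = own_only & (totals > 1)
    shared = popcount == collection.n_genomes

    # a marker is non-adjacent when the preceding valid position exists in
    # the same record and is not itself confined to one genome
    pos_index = {int(p): i for i, p in enumerate(positions)}
    def nonadjacent(flags: np.ndarray) -> np.ndarray:
        out = np.zeros_like(flags)
        for i in np.flatnonzero(flags):
            prev = pos_index.get(int(positions[i]) - 1)
            if prev is not None and rec_idx[prev] == rec_idx[i] and not own_only[prev]:
                out[i] = True
        return out

    unique_na = nonadjacent(unique)
    pseudo_na = nonadjacent(pseudo)

    reports = []
    for g, genome in enumerate(collection.genomes):
        sel = gids == g
        mean_all, sd_all = _distance_stats(positions[sel & unique], rec_idx[sel & unique])
        mean_na, sd_na = _distance_stats(
            positions[sel & unique_na], rec_idx[sel & unique_na]
        )
        reports.append(
            MarkerReport(
                genome=g,
                name=genome.name or f"genome{g}",
                n_unique=int((sel & unique).sum()),
                n_pseudo=int((sel & pseudo).sum()),
                n_shared=int((sel & shared).sum()),
                dist_mean=mean_all,
                dist_sd=sd_all,
                n_unique_nonadjacent=int((sel & unique_na).sum()),
                n_pseudo_nonadjacent=int((sel & pseudo_na).sum()),
                dist_mean_nonadjacent=mean_na,
                dist_sd_nonadjacent=sd_na,
                unique_positions=local[sel & unique],
                unique_positions_nonadjacent=local[sel & unique_na],
            )
        )
    return reports


@dataclass
class GroupSeparationReport:
    """Per-strain counts of k-mers matching every strain of the strain's own
    group and no strain of the other group."""

    genome: int
    name: str
    group: str
    n_separating: int
    dist_mean: float
    dist_sd: float
    n_separating_nonadjacent: int
    dist_mean_nonadjacent: float
    dist_sd_nonadjacent: float
    separating_positions: np.ndarray = None


def group_separation_report(
    index: BidirectionalIndex,
    collection: GenomeCollection,
    group_a: list[int],
    group_b: list[int],
    k: int,
    e: int,
    *,
    reverse_complement: bool = False,
) -> list[GroupSeparationReport]:
    """Count k-mers that perfectly separate two groups of strains.

    A k-mer from a strain in group A counts iff it has >=1 approximate
    occurrence in every strain of A and none in any strain of B — and
    vice versa.  Non-adjacent and spacing statistics as in
    :func:`marker_report`.
    """
    set_a, set_b = set(group_a), set(group_b)
    if not set_a or not set_b:
        raise ValueError("each group needs at least one genome")
    if set_a & set_b:
        raise ValueError(f"overlapping group membership: {sorted(set_a & set_b)}")
    for g in set_a | set_b:
        if not 0 <= g < collection.n_genomes:
            raise ValueError(f"genome index {g} out of range")

    freq = frequency(
        index, collection, k, e,
        mode="multi_genome",
        reverse_complement=reverse_complement,
        collect_presence=True,
    )
    positions = freq.positions
    masks = freq.presence.astype(np.int64)
    mask_a = sum(1 << g for g in set_a)
    mask_b = sum(1 << g for g in set_b)

    gids, rec_idx, local = _position_frame(collection, positions)
    own_group_mask = np.where(np.isin(gids, list(set_a)), mask_a, mask_b)
    other_group_mask = np.where(np.isin(gids, list(set_a)), mask_b, mask_a)
    separating = ((masks & own_group_mask) == own_group_mask) & (
        (masks & other_group_mask) == 0
    )

    pos_index = {int(p): i for i, p in enumerate(positions)}
    separating_na = np.zeros_like(separating)
    for i in np.flatnonzero(separating):
        prev = pos_index.get(int(positions[i]) - 1)
        if prev is not None and rec_idx[prev] == rec_idx[i] and not separating[prev]:
            separating_na[i] = True

    reports = []
    for g, genome in enumerate(collection.genomes):
        if g not in set_a and g not in set_b:
            continue
        sel = gids == g
        mean_all, sd_all = _distance_stats(
            positions[sel & separating], rec_idx[sel & separating]
        )
        mean_na, sd_na = _distance_stats(
            positions[sel & separating_na], rec_idx[sel & separating_na]
        )
        reports.append(
            GroupSeparationReport(
                genome=g,
                name=genome.name or f"genome{g}",
                group="A" if g in set_a else "B",
                n_separating=int((sel & separating).sum()),
                dist_mean=mean_all,
                dist_sd=sd_all,
                n_separating_nonadjacent=int((sel & separating_na).sum()),
                dist_mean_nonadjacent=mean_na,
                dist_sd_nonadjacent=sd_na,
                separating_positions=local[sel & separating],
            )
        )
    return reports
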
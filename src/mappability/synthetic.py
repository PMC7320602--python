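"""Synthetic strain sets for testing marker discovery.

Emulates the structure of a small set of bacterial strains: a shared
ancestral backbone, per-strain point substitutions, and optional private
segment insertions that only one strain carries.  The inserted segments
are recorded as ground truth so that marker recovery can be scored.
No indels beyond whole-segment insertion and no recombination are
modelled.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

from .sequence_io import BASES, GenomeCollection, collection_from_strings


@dataclass
class PrivateSegment:
    strain: int
    position: int  # start in the strain's final coordinates
    length: int


@dataclass
class SyntheticStrainSet:
    ancestor: str
    strains: list[str]
    truth: list[PrivateSegment] = field(default_factory=list)
    seed: int = 0

    def to_collection(self, **kwargs) -> GenomeCollection:
        return collection_from_strings(self.strains, **kwargs)

    def write_fasta(self, directory: str | os.PathLike) -> list[str]:
        """One FASTA file per strain; returns the paths in strain order."""
        os.makedirs(directory, exist_ok=True)
        paths = []
        for i, seq in enumerate(self.strains):
            path = os.path.join(directory, f"strain{i}.fasta")
            with open(path, "w") as fh:
                fh.write(f">strain{i}\n")
                for j in range(0, len(seq), 70):
                    fh.write(seq[j : j + 70] + "\n")
            paths.append(path)
        return paths


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(BASES), size=length))


def generate_strains(
    length: int,
    n_strains: int,
    sub_rate: float,
    n_private_segments: int = 0,
    segment_length: int = 0,
    seed: int = 0,
) -> SyntheticStrainSet:
    """Derive ``n_strains`` sequences from one random ancestor.

    Each strain substitutes every ancestor base independently with
    probability ``sub_rate`` (always to a different base) and then
    receives ``n_private_segments`` random insertions of
    ``segment_length`` bases at uniform positions.  Reproducible for a
    fixed seed; the returned truth records give each private segment's
    final position within its strain.
    """
    if length < 1 or n_strains < 1:
        raise ValueError("length and n_strains must be positive")
    if not 0 <= sub_rate < 1:
        raise ValueError("sub_rate must lie in [0, 1)")
    if n_private_segments and segment_length > length:
        raise ValueError("private segment longer than the genome")
    rng = np.random.default_rng(seed)
    ancestor = _random_seq(rng, length)
    strains: list[str] = []
    truth: list[PrivateSegment] = []
    for s in range(n_strains):
        seq = list(ancestor)
        hits = np.flatnonzero(rng.random(length) < sub_rate)
        for i in hits:
            choices = [b for b in BASES if b != seq[i]]
            seq[i] = choices[int(rng.integers(0, 3))]
        seq = "".join(seq)
        inserts = sorted(
            (int(rng.integers(0, len(seq) + 1)), _random_seq(rng, segment_length))
            for _ in range(n_private_segments)
        )
        shift = 0
        for pos, segment in inserts:
            at = pos + shift
            seq = seq[:at] + segment + seq[at:]
            truth.append(PrivateSegment(strain=s, position=at, length=segment_length))
            shift += segment_length
        strains.append(seq)
    return SyntheticStrainSet(ancestor=ancestor, strains=strains, truth=truth, seed=seed)


def random_instances(count: int, seed: int, max_length: int = 1500):
    """Reproducible stream of desk-scale validation instances.

    Yields ``(collection, k, e, reverse_complement, mode)`` tuples covering
    single- and multi-genome counting, both strands, e in {0,1,2} and
    k in [8,30].  Sequence lengths are mostly a few hundred bases with a
    large instance every tenth draw; multi-genome instances are related
    strains (shared backbone, ~2% divergence) so presence counts are
    non-trivial, and single-genome instances use a skewed base
    composition half the time to provoke repeats.
    """
    rng = np.random.default_rng(seed)
    for i in range(count):
        n = int(rng.integers(40, 400)) if i % 10 else int(rng.integers(400, max_length + 1))
        k = int(rng.integers(8, 31))
        e = int(rng.integers(0, 3))
        rc = bool(rng.integers(0, 2))
        multi = bool(rng.integers(0, 2))
        if multi:
            n_genomes = int(rng.integers(2, 4))
            strains = generate_strains(
                length=max(n // n_genomes, k + 5),
                n_strains=n_genomes,
                sub_rate=0.02,
                seed=int(rng.integers(0, 2**31)),
            )
            collection = strains.to_collection()
            mode = "multi_genome"
        else:
            if rng.integers(0, 2):
                p = np.array([0.4, 0.1, 0.1, 0.4])
            else:
                p = np.full(4, 0.25)
            seq = "".join(rng.choice(list(BASES), size=n, p=p))
            collection = collection_from_strings([seq])
            mode = "single"
        yield collection, k, e, rc, mode


@dataclass
class RecoveryScore:
    precision: float
    recall: float
    n_predicted: int
    n_relevant: int
    n_true_positive: int


def recover_markers(
    strain_set: SyntheticStrainSet,
    k: int,
    e: int,
    *,
    reverse_complement: bool = False,
) -> RecoveryScore:
    """Score unique-marker discovery against the inserted private segments.

    Predicted markers are the unique positions reported by
    :func:`mappability.markers.marker_report`; a position is relevant when
    its whole k-window lies inside a private segment of its strain.
    """
    from .fm_index import build_index
    from .markers import marker_report

    collection = strain_set.to_collection()
    index = build_index(collection)
    reports = marker_report(
        index, collection, k, e, reverse_complement=reverse_complement
    )
    predicted: set[tuple[int, int]] = set()
    for rep in reports:
        for pos in rep.unique_positions:
            predicted.add((rep.genome, int(pos)))
    relevant: set[tuple[int, int]] = set()
    for seg in strain_set.truth:
        if seg.length >= k:
            for pos in range(seg.position, seg.position + seg.length - k + 1):
                relevant.add((seg.strain, pos))
    tp = predicted & relevant
    precision = len(tp) / len(predicted) if predicted else 1.0
    recall = len(tp) / len(relevant) if relevant else 1.0
    return RecoveryScore(
        precision=precision,
        recall=recall,
        n_predicted=len(predicted),
        n_relevant=len(relevant),
        n_true_positive=len(tp),
    )
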
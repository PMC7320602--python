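"""FASTA input and dna4 encoding.

Sequences are reduced to the four-letter nucleotide alphabet (dna4).
Internally A,C,G,T are encoded as 1..4; code 0 is reserved for the
separator/sentinel symbol that delimits sequences in the concatenated
text indexed by the FM-index.  All coordinates are 0-based, half-open;
writers convert to format-specific conventions at the edge.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np

#: record separator / masked-base code; never matches a dna4 symbol.
SEPARATOR = 5
#: unique terminal sentinel appended by the FM-index; sorts below everything.
TERMINATOR = 0
CODES = {"A": 1, "C": 2, "G": 3, "T": 4}
BASES = "ACGT"
_DECODE = np.array([ord("$")] + [ord(b) for b in BASES] + [ord("N")], dtype=np.uint8)
#: complement in code space (1<->4, 2<->3); non-bases map to themselves.
_COMPLEMENT = np.array([0, 4, 3, 2, 1, 5], dtype=np.uint8)

N_POLICIES = ("replace_random", "exclude")
DEFAULT_SEED = 42


class FastaFormatError(ValueError):
    """Raised for empty files, malformed headers or zero-length records."""


@dataclass
class EncodedText:
    """One genome: dna4-encoded concatenation of its FASTA records.

    ``codes`` holds the symbols of all records back to back (no separators);
    ``records`` are ``(name, start, length)`` triples tiling ``[0, n)``.
    ``mask``, present only under the ``exclude`` N-policy, flags positions
    whose original character was not A/C/G/T; masked positions carry the
    separator code so they can never take part in a match.
    """

    codes: np.ndarray
    records: list[tuple[str, int, int]]
    mask: np.ndarray | None = None
    name: str = ""

    @property
    def total_length(self) -> int:
        return int(self.codes.shape[0])

    def record_of(self, offset: int) -> tuple[str, int, int]:
        """Record containing genome-local ``offset``."""
        for name, start, length in self.records:
            if start <= offset < start + length:
                return name, start, length
        raise IndexError(f"offset {offset} outside genome of length {self.total_length}")

    def decode(self) -> str:
        """Plain-text sequence of the whole genome ('N' at masked positions)."""
        out = _DECODE[self.codes].tobytes().decode("ascii")
        if self.mask is not None and self.mask.any():
            chars = list(out)
            for i in np.flatnonzero(self.mask):
                chars[i] = "N"
            out = "".join(chars)
        return out


@dataclass
class GenomeCollection:
    """Ordered set of genomes sharing one global coordinate system.

    The global text is the concatenation, in input order, of every record of
    every genome, each record followed by one separator symbol.  Global
    positions address this concatenation; ``genome_of_position`` and
    ``locate_position`` translate back to genomes and records.
    """

    genomes: list[EncodedText]
    # per concatenated record: (genome_idx, record_name, global_start, length)
    _record_table: list[tuple[int, str, int, int]] = field(default_factory=list)
    _record_starts: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=np.int64))

    def __post_init__(self) -> None:
        if not self._record_table:
            table = []
            pos = 0
            for g, genome in enumerate(self.genomes):
                for name, _start, length in genome.records:
                    table.append((g, name, pos, length))
                    pos += length + 1  # +1 for separator
            self._record_table = table
            self._record_starts = np.array([t[2] for t in table], dtype=np.int64)

    @property
    def n_genomes(self) -> int:
        return len(self.genomes)

    @property
    def total_length(self) -> int:
        """Length of the concatenated text including separators."""
        return sum(g.total_length + len(g.records) for g in self.genomes)

    def concatenated(self) -> np.ndarray:
        """Global text: records joined with one separator after each."""
        parts = []
        for genome in self.genomes:
            for _name, start, length in genome.records:
                codes = genome.codes[start : start + length].copy()
                if genome.mask is not None:
                    codes[genome.mask[start : start + length]] = SEPARATOR
                parts.append(codes)
                parts.append(np.array([SEPARATOR], dtype=np.uint8))
        return np.concatenate(parts)

    def _record_index(self, position: int) -> int:
        idx = int(np.searchsorted(self._record_starts, position, side="right")) - 1
        if idx < 0:
            raise IndexError(f"negative global position {position}")
        return idx

    def genome_of_position(self, position: int) -> int:
        return self._record_table[self._record_index(position)][0]

    def locate_position(self, position: int) -> tuple[int, str, int]:
        """Global position -> (genome index, record name, record-local offset)."""
        g, name, start, _length = self._record_table[self._record_index(position)]
        return g, name, position - start

    def records_global(self) -> Iterator[tuple[int, str, int, int]]:
        """Yield (genome_idx, record_name, global_start, length) in input order."""
        yield from self._record_table

    def genome_id_of_positions(self, positions: np.ndarray) -> np.ndarray:
        """Vectorised genome lookup for an array of global positions."""
        idx = np.searchsorted(self._record_starts, positions, side="right") - 1
        gids = np.array([t[0] for t in self._record_table], dtype=np.int64)
        return gids[idx]


def _parse_fasta(path: str) -> list[tuple[str, str]]:
    records: list[tuple[str, list[str]]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                name = line[1:].split()[0] if len(line) > 1 else ""
                if not name:
                    raise FastaFormatError(f"{path}:{lineno}: header with no name")
                records.append((name, []))
            else:
                if not records:
                    raise FastaFormatError(f"{path}:{lineno}: sequence before any header")
                records[-1][1].append(line)
    if not records:
        raise FastaFormatError(f"{path}: no FASTA records found")
    out = []
    for name, chunks in records:
        seq = "".join(chunks).upper()
        if not seq:
            raise FastaFormatError(f"{path}: record '{name}' has length 0")
        out.append((name, seq))
    return out


def encode_sequence(seq: str) -> tuple[np.ndarray, np.ndarray]:
    """Encode an uppercased sequence; returns (codes, ambiguous_mask).

    Ambiguous (non-ACGT) positions get the separator code and are flagged
    in the mask; the caller decides whether to randomise or exclude them.
    """
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    codes = np.zeros(arr.shape[0], dtype=np.uint8)
    for base, code in CODES.items():
        codes[arr == ord(base)] = code
    mask = codes == 0
    codes[mask] = SEPARATOR
    return codes, mask


def encode_genome(
    records: Sequence[tuple[str, str]],
    n_policy: str = "replace_random",
    seed: int = DEFAULT_SEED,
    name: str = "",
) -> EncodedText:
    """Build an :class:`EncodedText` from (name, sequence) records."""
    if n_policy not in N_POLICIES:
        raise ValueError(f"unknown N policy {n_policy!r}; expected one of {N_POLICIES}")
    rng = np.random.default_rng(seed)
    parts, recs, masks = [], [], []
    offset = 0
    for rec_name, seq in records:
        codes, mask = encode_sequence(seq.upper())
        if n_policy == "replace_random":
            n_amb = int(mask.sum())
            if n_amb:
                codes[mask] = rng.integers(1, 5, size=n_amb, dtype=np.uint8)
            mask = np.zeros_like(mask)
        parts.append(codes)
        masks.append(mask)
        recs.append((rec_name, offset, len(seq)))
        offset += len(seq)
    codes = np.concatenate(parts) if parts else np.zeros(0, dtype=np.uint8)
    mask_all = np.concatenate(masks) if masks else np.zeros(0, dtype=bool)
    return EncodedText(
        codes=codes,
        records=recs,
        mask=mask_all if n_policy == "exclude" else None,
        name=name,
    )


def read_fasta(
    paths: Iterable[str | os.PathLike],
    n_policy: str = "replace_random",
    seed: int = DEFAULT_SEED,
) -> GenomeCollection:
    """Read one or more FASTA files into a :class:`GenomeCollection`.

    Each file becomes one genome; genome order equals input order.  Under
    ``replace_random`` every non-ACGT character is replaced by a uniformly
    drawn base (reproducible for a fixed seed); under ``exclude`` such
    positions are masked and any k-mer window overlapping them is assigned
    no frequency value downstream.
    """
    genomes = []
    for path in paths:
        path = os.fspath(path)
        records = _parse_fasta(path)
        genomes.append(
            encode_genome(records, n_policy=n_policy, seed=seed, name=os.path.basename(path))
        )
    if not genomes:
        raise ValueError("no input FASTA files given")
    return GenomeCollection(genomes=genomes)


def collection_from_strings(
    genomes: Sequence[Sequence[str] | str],
    n_policy: str = "replace_random",
    seed: int = DEFAULT_SEED,
) -> GenomeCollection:
    """Convenience constructor: one genome per entry; strings are single records."""
    encoded = []
    for g, entry in enumerate(genomes):
        recs = [(f"seq{i}", s) for i, s in enumerate(entry)] if not isinstance(entry, str) else [
            ("seq0", entry)
        ]
        encoded.append(encode_genome(recs, n_policy=n_policy, seed=seed, name=f"genome{g}"))
    return GenomeCollection(genomes=encoded)


def valid_kmer_positions(collection: GenomeCollection, k: int) -> np.ndarray:
    """Global start positions of every valid k-mer window.

    A window is valid when it lies entirely inside one record (k-mers never
    cross record boundaries) and, under the exclude N-policy, does not
    overlap a masked position.  A record shorter than ``k`` contributes no
    positions.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    positions = []
    gpos = 0
    for genome in collection.genomes:
        for _name, rec_start, length in genome.records:
            if length >= k:
                local = np.arange(length - k + 1, dtype=np.int64)
                if genome.mask is not None:
                    rec_mask = genome.mask[rec_start : rec_start + length]
                    # windows overlapping >=1 masked char, via a running sum
                    bad = np.convolve(rec_mask.astype(np.int64), np.ones(k, dtype=np.int64))[
                        k - 1 : length
                    ]
                    local = local[bad == 0]
                positions.append(gpos + local)
            gpos += length + 1  # separator
    if not positions:
        warnings.warn(f"k={k} exceeds every sequence length; no valid k-mer positions")
        return np.zeros(0, dtype=np.int64)
    return np.concatenate(positions)


def reverse_complement_codes(codes: np.ndarray) -> np.ndarray:
    """Reverse complement in code space; separators stay separators."""
    return _COMPLEMENT[codes][::-1]


def decode_codes(codes: np.ndarray) -> str:
    return _DECODE[codes].tobytes().decode("ascii")
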
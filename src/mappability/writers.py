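"""Serialization of frequency/mappability vectors.

Formats and their coordinate conventions:

* ``txt``  — per-record header lines (``>name``) followed by the values
  for that record's valid k-mer positions, whitespace-separated; values
  are 0-based positional arrays.
* ``wig``  — fixedStep wiggle, 1-based starts, step 1, span 1, one
  declaration per maximal run of consecutive valid positions, plus a
  companion ``.chrom.sizes`` file.
* ``bed``  — BED5, 0-based half-open intervals over k-mer start
  positions; maximal runs of equal value are merged, the value sits in
  the score column (column 5), column 4 is a run id.
* ``csv``  — one row per valid position listing every approximate
  occurrence as ``genome|record|position`` (requires a frequency
  computed with ``store_locations=True``).
* ``raw``  — little-endian fixed-width binary array (8/16/32-bit
  unsigned for frequencies, float64 for mappability, saturating) with a
  JSON manifest describing width and record layout.

Readers for txt, wig and bed allow lossless round-trips at full float
precision (values are printed with repr-level precision).
"""

from __future__ import annotations

import json
import os
from pathlib import Path

import numpy as np

from .core import FrequencyVector, MappabilityVector
from .sequence_io import GenomeCollection

FORMATS = ("raw", "txt", "wig", "bed", "csv")


def _per_record(vector, collection: GenomeCollection):
    """Yield (genome_idx, record_name, record_length, local_positions, values)."""
    for g, name, gstart, length in collection.records_global():
        sel = (vector.positions >= gstart) & (vector.positions < gstart + length)
        yield g, name, length, vector.positions[sel] - gstart, vector.values[sel]


def _fmt(value) -> str:
    if isinstance(value, (np.floating, float)):
        return repr(float(value))
    return str(int(value))


# -- txt --------------------------------------------------------------------

def write_txt(vector, collection: GenomeCollection, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for _g, name, _length, _pos, values in _per_record(vector, collection):
            fh.write(f">{name}\n")
            fh.write(" ".join(_fmt(v) for v in values) + "\n")


def read_txt(path: str | os.PathLike) -> dict[str, np.ndarray]:
    """Record name -> value array (float)."""
    out: dict[str, np.ndarray] = {}
    name = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                name = line[1:]
                out[name] = np.zeros(0)
            elif line:
                out[name] = np.array([float(x) for x in line.split()])
    return out


# -- wig --------------------------------------------------------------------

def write_wig(vector, collection: GenomeCollection, path: str | os.PathLike) -> None:
    """fixedStep wiggle plus a companion <path>.chrom.sizes file."""
    path = Path(path)
    with open(path, "w") as fh:
        for _g, name, _length, pos, values in _per_record(vector, collection):
            if len(pos) == 0:
                continue
            run_starts = np.flatnonzero(
                np.concatenate([[True], np.diff(pos) != 1])
            )
            bounds = list(run_starts) + [len(pos)]
            for a, b in zip(bounds[:-1], bounds[1:]):
                fh.write(f"fixedStep chrom={name} start={int(pos[a]) + 1} step=1 span=1\n")
                for v in values[a:b]:
                    fh.write(_fmt(v) + "\n")
    sizes_path = path.with_suffix(path.suffix + ".chrom.sizes")
    with open(sizes_path, "w") as fh:
        for _g, name, length, _pos, _values in _per_record(vector, collection):
            fh.write(f"{name}\t{length}\n")


def read_wig(path: str | os.PathLike) -> dict[str, dict[int, float]]:
    """Record name -> {0-based position: value}."""
    out: dict[str, dict[int, float]] = {}
    chrom, at = None, 0
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("fixedStep"):
                fields = dict(kv.split("=") for kv in line.split()[1:])
                chrom = fields["chrom"]
                at = int(fields["start"]) - 1
                out.setdefault(chrom, {})
            elif line:
                out[chrom][at] = float(line)
                at += 1
    return out


# -- bed --------------------------------------------------------------------

def write_bed(vector, collection: GenomeCollection, path: str | os.PathLike) -> None:
    """BED5 of maximal equal-value runs over k-mer start positions."""
    with open(path, "w") as fh:
        run_id = 0
        for _g, name, _length, pos, values in _per_record(vector, collection):
            if len(pos) == 0:
                continue
            breaks = np.flatnonzero(
                np.concatenate([[True], (np.diff(pos) != 1) | (values[1:] != values[:-1])])
            )
            bounds = list(breaks) + [len(pos)]
            for a, b in zip(bounds[:-1], bounds[1:]):
                fh.write(
                    f"{name}\t{int(pos[a])}\t{int(pos[b - 1]) + 1}\t"
                    f"run{run_id}\t{_fmt(values[a])}\n"
                )
                run_id += 1


def read_bed(path: str | os.PathLike) -> dict[str, dict[int, float]]:
    """Record name -> {0-based k-mer start position: value}."""
    out: dict[str, dict[int, float]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            chrom, start, end, _name, score = line.split("\t")
            d = out.setdefault(chrom, {})
            for p in range(int(start), int(end)):
                d[p] = float(score)
    return out


# -- csv --------------------------------------------------------------------

def write_csv(
    freq: FrequencyVector, collection: GenomeCollection, path: str | os.PathLike
) -> None:
    """Occurrence locations per position: requires ``store_locations=True``.

    Dialect: header line, then one row per valid position:
    ``record,position,occurrences`` where occurrences is a
    space-separated list of ``genome|record|position`` sorted by
    (genome, record, position).
    """
    if freq.locations is None:
        raise ValueError(
            "csv output needs occurrence locations; "
            "compute the frequency with store_locations=True"
        )
    with open(path, "w") as fh:
        fh.write("record,position,occurrences\n")
        for g, name, gstart, length in collection.records_global():
            sel = (freq.positions >= gstart) & (freq.positions < gstart + length)
            for p in freq.positions[sel]:
                occs = freq.locations[int(p)]
                rendered = []
                for o in occs:
                    og, oname, olocal = collection.locate_position(int(o))
                    rendered.append((og, oname, olocal))
                rendered.sort()
                occ_str = " ".join(f"{og}|{oname}|{olocal}" for og, oname, olocal in rendered)
                fh.write(f"{name},{int(p) - gstart},{occ_str}\n")


# -- raw --------------------------------------------------------------------

_WIDTHS = {8: np.uint8, 16: np.uint16, 32: np.uint32}


def write_raw(
    vector,
    collection: GenomeCollection,
    path: str | os.PathLike,
    width: int = 16,
) -> None:
    """Little-endian binary array plus a JSON manifest (<path>.json).

    Integer frequencies saturate at the width's maximum; mappability
    values are written as little-endian float64 regardless of ``width``.
    """
    path = Path(path)
    is_float = isinstance(vector, MappabilityVector) or np.issubdtype(
        np.asarray(vector.values).dtype, np.floating
    )
    records = []
    arrays = []
    for _g, name, _length, pos, values in _per_record(vector, collection):
        records.append({"record": name, "count": int(len(pos))})
        arrays.append(values)
    values = np.concatenate(arrays) if arrays else np.zeros(0)
    if is_float:
        data = values.astype("<f8")
        dtype_name = "float64"
    else:
        if width not in _WIDTHS:
            raise ValueError(f"width must be one of {sorted(_WIDTHS)}")
        cap = np.iinfo(_WIDTHS[width]).max
        data = np.minimum(values, cap).astype(np.dtype(_WIDTHS[width]).newbyteorder("<"))
        dtype_name = f"uint{width}"
    data.tofile(path)
    manifest = {
        "dtype": dtype_name,
        "byte_order": "little",
        "saturating": not is_float,
        "k": int(vector.k),
        "e": int(vector.e),
        "records": records,
    }
    with open(path.with_suffix(path.suffix + ".json"), "w") as fh:
        json.dump(manifest, fh, indent=2)


def read_raw(path: str | os.PathLike) -> dict[str, np.ndarray]:
    path = Path(path)
    with open(path.with_suffix(path.suffix + ".json")) as fh:
        manifest = json.load(fh)
    data = np.fromfile(path, dtype=np.dtype(manifest["dtype"]).newbyteorder("<"))
    out = {}
    at = 0
    for rec in manifest["records"]:
        out[rec["record"]] = data[at : at + rec["count"]]
        at += rec["count"]
    return out
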
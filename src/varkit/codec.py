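"""Windowed delta-encoded genotype compression.

Dense single-base genotype data is stored one row per individual per
fixed-size genome window (100 kb by default).  Each row's binary blob is a
repeating triplet stream::

    [allele1 allele2] [ULEB128(distance) allele1 allele2] ...

The first genotype sits at the row's start position, so its zero distance
is never stored; every later genotype stores the distance in base pairs
from the previous one.  Distances rather than absolute positions keep the
integers — and hence the blob — small: with all distances below 128 a row
of n genotypes packs into exactly 3n - 1 bytes.

Windows are genome-anchored and 1-based: window k covers
``[k*W + 1, (k+1)*W]``, so a region query only touches rows whose window
intersects the query slice.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .model import Dataset, Genotype, GenotypeRow, Slice

__all__ = [
    "CodecConfig",
    "CodecError",
    "DecodeError",
    "encode_window",
    "decode_window",
    "store_genotypes",
    "query_genotypes",
    "window_of",
]

DEFAULT_WINDOW = 100_000
ALLELE_ALPHABET = frozenset(b"ACGTN")


class CodecError(ValueError):
    """Invalid input to the genotype codec."""


class DecodeError(CodecError):
    """A blob cannot be decoded; the message names the failing byte offset."""


@dataclass(frozen=True)
class CodecConfig:
    """Codec parameters; ``window_size`` is the fixed genomic row span in bp."""

    window_size: int = DEFAULT_WINDOW

    def __post_init__(self) -> None:
        if self.window_size < 1:
            raise CodecError("window_size must be >= 1")


def window_of(position: int, cfg: CodecConfig) -> int:
    """Index of the window containing a 1-based position."""
    return (position - 1) // cfg.window_size


def _encode_uleb128(value: int) -> bytes:
    """Unsigned LEB128: 7 data bits per byte, high bit marks continuation."""
    if value < 0:
        raise CodecError("distances must be non-negative")
    out = bytearray()
    while True:
        byte = value & 0x7F
        value >>= 7
        if value:
            out.append(byte | 0x80)
        else:
            out.append(byte)
            return bytes(out)


def _check_allele(g: Genotype) -> None:
    for a in (g.allele1, g.allele2):
        if len(a) != 1:
            raise CodecError(
                f"multi-base allele {a!r} at {g.region_name}:{g.position}: "
                "store in the multiple base pair genotype table instead"
            )
        if a.encode("ascii", errors="replace")[0] not in ALLELE_ALPHABET:
            raise CodecError(f"allele must be one of A/C/G/T/N, got {a!r}")


def encode_window(genotypes: Sequence[Genotype], cfg: CodecConfig = CodecConfig()) -> GenotypeRow:
    """Pack one individual's genotypes from one window into a row.

    Input must be position-sorted (strictly increasing), single-base, and
    confined to a single window; the row's start is the first position.
    """
    if not genotypes:
        raise CodecError("cannot encode an empty genotype set")
    first = genotypes[0]
    widx = window_of(first.position, cfg)
    blob = bytearray()
    prev: Optional[int] = None
    for g in genotypes:
        if g.individual_name != first.individual_name or g.region_name != first.region_name:
            raise CodecError("a row holds one individual on one region")
        _check_allele(g)
        if window_of(g.position, cfg) != widx:
            raise CodecError(
                f"position {g.position} falls outside window {widx} "
                f"(window size {cfg.window_size})"
            )
        if prev is not None:
            if g.position <= prev:
                raise CodecError(
                    f"positions must strictly increase ({prev} -> {g.position})"
                )
            blob += _encode_uleb128(g.position - prev)
        blob += g.allele1.encode("ascii") + g.allele2.encode("ascii")
        prev = g.position
    return GenotypeRow(
        individual_name=first.individual_name,
        region_name=first.region_name,
        window_index=widx,
        start=first.position,
        blob=bytes(blob),
    )


def decode_window(row: GenotypeRow) -> list[Genotype]:
    """Unpack a row back into genotypes.

    The first genotype's implicit zero distance is re-added here: it sits at
    ``row.start``; every later position is the running sum of the stored
    distances.
    """
    blob = row.blob
    out: list[Genotype] = []
    pos = row.start
    i = 0
    n = len(blob)
    if n == 0:
        raise DecodeError("empty blob at offset 0")
    first = True
    while i < n:
        if not first:
            # ULEB128 distance
            dist = 0
            shift = 0
            start_i = i
            while True:
                if i >= n:
                    raise DecodeError(f"ULEB128 overruns blob end at offset {start_i}")
                byte = blob[i]
                dist |= (byte & 0x7F) << shift
                shift += 7
                i += 1
                if not (byte & 0x80):
                    break
            pos += dist
        if i + 2 > n:
            raise DecodeError(f"truncated allele pair at offset {i}")
        a1, a2 = blob[i], blob[i + 1]
        if a1 not in ALLELE_ALPHABET:
            raise DecodeError(f"invalid allele byte 0x{a1:02X} at offset {i}")
        if a2 not in ALLELE_ALPHABET:
            raise DecodeError(f"invalid allele byte 0x{a2:02X} at offset {i + 1}")
        i += 2
        out.append(
            Genotype(
                individual_name=row.individual_name,
                region_name=row.region_name,
                position=pos,
                allele1=chr(a1),
                allele2=chr(a2),
            )
        )
        first = False
    return out


def store_genotypes(
    ds: Dataset, genotypes: Iterable[Genotype], cfg: CodecConfig = CodecConfig()
) -> int:
    """Partition genotypes into (individual, region, window) rows and store.

    Genotypes may arrive in any order; rows already present for a touched
    cell are decoded, merged and re-encoded.  Returns the number of rows
    written.  Duplicate (individual, region, position) entries are an error.
    """
    cells: dict[tuple[str, str, int], list[Genotype]] = {}
    for g in genotypes:
        _check_allele(g)
        if g.region_name not in ds.reference:
            raise KeyError(f"unknown region {g.region_name!r}")
        key = (g.individual_name, g.region_name, window_of(g.position, cfg))
        cells.setdefault(key, []).append(g)

    written = 0
    for key, gs in sorted(cells.items()):
        existing_idx = [
            i
            for i, r in enumerate(ds.genotype_rows)
            if (r.individual_name, r.region_name, r.window_index) == key
        ]
        merged = list(gs)
        for i in existing_idx:
            merged.extend(decode_window(ds.genotype_rows[i]))
        merged.sort(key=lambda g: g.position)
        for a, b in zip(merged, merged[1:]):
            if a.position == b.position:
                raise CodecError(
                    f"duplicate genotype for {a.individual_name} at "
                    f"{a.region_name}:{a.position}"
                )
        row = encode_window(merged, cfg)
        for i in reversed(existing_idx):
            del ds.genotype_rows[i]
        ds.genotype_rows.append(row)
        written += 1
    return written


def query_genotypes(
    ds: Dataset,
    sl: Slice,
    individuals: Optional[Iterable[str]] = None,
    cfg: CodecConfig = CodecConfig(),
) -> list[Genotype]:
    """All stored single-base genotypes inside a slice.

    Only rows whose window overlaps the slice are decoded.  Results are
    sorted by (individual, position).
    """
    if sl.region_name not in ds.reference:
        raise KeyError(f"unknown region {sl.region_name!r}")
    wanted = set(individuals) if individuals is not None else None
    lo = window_of(sl.start, cfg)
    hi = window_of(sl.end, cfg)
    out: list[Genotype] = []
    for row in ds.genotype_rows:
        if row.region_name != sl.region_name:
            continue
        if not (lo <= row.window_index <= hi):
            continue
        if wanted is not None and row.individual_name not in wanted:
            continue
        for g in decode_window(row):
            if sl.start <= g.position <= sl.end:
                out.append(g)
    out.sort(key=lambda g: (g.individual_name, g.position))
    return out
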
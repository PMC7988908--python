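"""Binned, run-length-encoded read-depth storage.

Per-site read depth is lossy-compressed in two steps: each depth is mapped
to one of six bins (``a``..``f``), and consecutive equal bins inside fixed
1000-bp blocks are collapsed into ``<run><letter>`` tokens.  The bins make
the depth-10 sufficiency threshold used by the trio workflow an exact bin
boundary, so "is this site covered at >= 10x?" never suffers from the lossy
storage.

Bin intervals: a=[0,9], b=[10,19], c=[20,29], d=[30,49], e=[50,199],
f=[200,inf).
"""

from __future__ import annotations

import re
from bisect import bisect_right
from dataclasses import dataclass
from itertools import groupby
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

from .errors import ParseError, ValidationError

BLOCK_SIZE = 1000

#: ordered bin letters and the lower depth bound of each bin
BIN_LETTERS = "abcdef"
BIN_LOWER_BOUNDS = (0, 10, 20, 30, 50, 200)
_LOWER_OF = dict(zip(BIN_LETTERS, BIN_LOWER_BOUNDS))

_TOKEN_RE = re.compile(r"(\d+)([a-f])")


def bin_coverage(depth: int) -> str:
    """Map a read depth to its bin letter.

    >>> bin_coverage(9), bin_coverage(10), bin_coverage(200)
    ('a', 'b', 'f')
    """
    if depth is None or int(depth) != depth or depth < 0:
        raise ValidationError(f"depth must be a non-negative integer, got {depth!r}")
    return BIN_LETTERS[bisect_right(BIN_LOWER_BOUNDS, depth) - 1]


def bin_lower_bound(letter: str) -> int:
    """Lowest depth consistent with a bin letter."""
    try:
        return _LOWER_OF[letter]
    except KeyError:
        raise ValidationError(f"unknown bin letter {letter!r}") from None


def encode_block(depths: Sequence[int]) -> str:
    """Run-length encode the bins of up to ``BLOCK_SIZE`` per-site depths.

    Runs are maximal: adjacent tokens never share a letter.
    """
    if len(depths) == 0:
        raise ValidationError("cannot encode an empty depth vector")
    if len(depths) > BLOCK_SIZE:
        raise ValidationError(
            f"block holds at most {BLOCK_SIZE} sites, got {len(depths)}"
        )
    return "".join(
        f"{sum(1 for _ in run)}{letter}"
        for letter, run in groupby(bin_coverage(d) for d in depths)
    )


def decode_block(rle: str) -> str:
    """Expand an RLE string back to one bin letter per site.

    Rejects malformed tokens, zero-length runs and non-maximal runs, so a
    decodable string is always the unique encoding of its bin sequence.
    """
    if not rle:
        raise ParseError("empty RLE string")
    pos = 0
    letters: List[str] = []
    prev_letter = None
    total = 0
    for m in _TOKEN_RE.finditer(rle):
        if m.start() != pos:
            raise ParseError(f"malformed RLE token at offset {pos} in {rle!r}")
        run, letter = int(m.group(1)), m.group(2)
        if run == 0:
            raise ParseError(f"zero run length in {rle!r}")
        if letter == prev_letter:
            raise ParseError(f"non-maximal runs ({letter!r} repeated) in {rle!r}")
        total += run
        if total > BLOCK_SIZE:
            raise ParseError(f"run lengths exceed block size in {rle!r}")
        letters.append(letter * run)
        prev_letter = letter
        pos = m.end()
    if pos != len(rle):
        raise ParseError(f"trailing garbage at offset {pos} in {rle!r}")
    return "".join(letters)


@dataclass(frozen=True)
class CoverageBlock:
    """One sample x one 1000-bp block; block k spans 1-based [k*1000+1, (k+1)*1000]."""

    sample_id: str
    chrom: str
    block_index: int
    rle: str


# ---------------------------------------------------------------------------
# depth-profile text input
# ---------------------------------------------------------------------------

DepthProfile = Dict[str, Dict[int, int]]  # chrom -> {1-based pos: depth}


def parse_depth_file(path, dialect: str = "tsv") -> DepthProfile:
    """Read a per-site depth profile.

    dialect="tsv": 3 columns (chrom, 1-based pos, depth), one row per site,
    as produced by ``samtools depth``.
    dialect="bed": 4 columns (chrom, 0-based start, end, depth), one row per
    homogeneous run, as produced by ``bedtools genomecov -bga``.
    """
    if dialect not in ("tsv", "bed"):
        raise ValidationError(f"unknown depth dialect {dialect!r} (use 'tsv' or 'bed')")
    profile: DepthProfile = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            try:
                if dialect == "tsv":
                    chrom, pos, depth = fields[0], int(fields[1]), int(fields[2])
                    profile.setdefault(chrom, {})[pos] = depth
                else:
                    chrom = fields[0]
                    start, end, depth = int(fields[1]), int(fields[2]), int(fields[3])
                    if end < start:
                        raise ValueError("end < start")
                    sites = profile.setdefault(chrom, {})
                    for p in range(start + 1, end + 1):  # BED is 0-based half-open
                        sites[p] = depth
            except (IndexError, ValueError) as exc:
                raise ParseError(f"{path}:{ln}: bad depth row {line!r}: {exc}") from None
    return profile


def profile_to_blocks(sample_id: str, profile: DepthProfile) -> List[CoverageBlock]:
    """Encode a parsed depth profile into per-block RLE records.

    A block exists iff it contains at least one input site.  Inside an
    existing block, sites missing from the input are taken as depth 0 (depth
    tools omit zero-coverage sites); positions after the last input site of
    the block are left unencoded, so partial trailing blocks are allowed.
    """
    blocks: List[CoverageBlock] = []
    for chrom, sites in profile.items():
        by_block: Dict[int, List[int]] = {}
        for pos in sites:
            if pos < 1:
                raise ValidationError(f"positions are 1-based, got {pos}")
            by_block.setdefault((pos - 1) // BLOCK_SIZE, []).append(pos)
        for k in sorted(by_block):
            start = k * BLOCK_SIZE + 1
            last = max(by_block[k])
            depths = [sites.get(p, 0) for p in range(start, last + 1)]
            blocks.append(CoverageBlock(sample_id, chrom, k, encode_block(depths)))
    return blocks


class CoverageStore:
    """Random-access coverage bins backed by a relational table.

    The table ``coverage(sample_id, chrom, block_index, rle)`` is created in
    the sqlite connection passed in (shared with the variant store) and is
    unique-keyed on (sample_id, chrom, block_index).
    """

    def __init__(self, conn):
        self.conn = conn
        conn.execute(
            """CREATE TABLE IF NOT EXISTS coverage (
                   sample_id TEXT NOT NULL,
                   chrom TEXT NOT NULL,
                   block_index INTEGER NOT NULL,
                   rle TEXT NOT NULL,
                   PRIMARY KEY (sample_id, chrom, block_index)
               )"""
        )

    def add_blocks(self, blocks: Iterable[CoverageBlock]) -> int:
        rows = [(b.sample_id, b.chrom, b.block_index, b.rle) for b in blocks]
        self.conn.executemany(
            "INSERT OR REPLACE INTO coverage VALUES (?,?,?,?)", rows
        )
        self.conn.commit()
        return len(rows)

    def load_depth_file(self, path, sample_id: str, dialect: str = "tsv") -> int:
        """Parse + encode + store one sample's depth profile. Returns #blocks."""
        return self.add_blocks(
            profile_to_blocks(sample_id, parse_depth_file(path, dialect))
        )

    def _rle_at(self, sample_id: str, chrom: str, block_index: int) -> Optional[str]:
        row = self.conn.execute(
            "SELECT rle FROM coverage WHERE sample_id=? AND chrom=? AND block_index=?",
            (sample_id, chrom, block_index),
        ).fetchone()
        return row[0] if row else None

    def coverage_bin_at(self, sample_id: str, chrom: str, pos: int) -> Optional[str]:
        """Bin letter at a 1-based position, or None when no block covers it."""
        if pos < 1:
            raise ValidationError(f"positions are 1-based, got {pos}")
        rle = self._rle_at(sample_id, chrom, (pos - 1) // BLOCK_SIZE)
        if rle is None:
            return None
        offset = (pos - 1) % BLOCK_SIZE
        seen = 0
        for m in _TOKEN_RE.finditer(rle):
            seen += int(m.group(1))
            if offset < seen:
                return m.group(2)
        return None  # past the encoded tail of a partial block

    def is_sufficiently_covered(
        self, sample_id: str, chrom: str, pos: int, min_depth: int = 10
    ) -> bool:
        """True iff the stored bin guarantees depth >= min_depth.

        Because depth is stored at bin resolution, min_depth must be one of
        the bin lower bounds; absence of data counts as insufficient.
        """
        if min_depth not in BIN_LOWER_BOUNDS:
            raise ValidationError(
                f"min_depth must be a bin lower bound {BIN_LOWER_BOUNDS}, "
                f"got {min_depth} (depth is stored at bin resolution)"
            )
        letter = self.coverage_bin_at(sample_id, chrom, pos)
        if letter is None:
            return False
        return bin_lower_bound(letter) >= min_depth

    def n_blocks(self) -> int:
        return self.conn.execute("SELECT COUNT(*) FROM coverage").fetchone()[0]


def compression_report(profiles: Mapping[str, DepthProfile]) -> dict:
    """Measure the achieved compression on a set of depth profiles.

    Returns raw per-site text size (chrom<TAB>pos<TAB>depth rows), stored RLE
    size and their ratio.  The ratio is whatever the data yields -- long
    homogeneous runs compress ~1000x, per-site bin alternation can exceed the
    raw size.
    """
    if not profiles:
        raise ValidationError("need at least one depth profile")
    raw = 0
    encoded = 0
    for sample_id, profile in profiles.items():
        for chrom, sites in profile.items():
            for pos, depth in sites.items():
                raw += len(f"{chrom}\t{pos}\t{depth}\n")
        for block in profile_to_blocks(sample_id, profile):
            encoded += len(block.rle)
    return {
        "raw_bytes": raw,
        "encoded_bytes": encoded,
        "ratio": raw / encoded if encoded else float("inf"),
    }
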
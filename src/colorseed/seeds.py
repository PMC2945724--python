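"""Spaced seeds, position-restricted seeds, and seed families.

A spaced seed is a pattern over ``#`` (required color match) and ``-``
(don't care) used to filter candidate mapping locations.  A
position-restricted seed additionally carries the set of read offsets at
which it is allowed to hit, which lets a family concentrate its placements
on the reliable early part of a read.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

__all__ = [
    "SpacedSeed",
    "PositionedSeed",
    "SeedFamily",
    "parse_seed",
    "seed_hits",
    "family_hits",
    "overlap_depth",
    "read_seed_file",
    "write_seed_file",
    "SeedFileError",
]

#: Alignment-symbol characters used throughout the package.
MATCH_CHAR = "1"
MISMATCH_CHAR = "0"
INDEL_CHAR = "I"


@dataclass(frozen=True)
class SpacedSeed:
    """A spaced seed pattern over ``{'#', '-'}``.

    Attributes
    ----------
    pattern:
        The seed template.  Must start and end with ``#``.
    """

    pattern: str

    def __post_init__(self) -> None:
        pat = self.pattern
        if not pat:
            raise ValueError("empty seed pattern")
        bad = set(pat) - {"#", "-"}
        if bad:
            raise ValueError(f"invalid seed characters {sorted(bad)!r} in {pat!r}")
        if pat[0] != "#" or pat[-1] != "#":
            raise ValueError(f"seed pattern must start and end with '#': {pat!r}")

    @property
    def weight(self) -> int:
        """Number of required-match (``#``) positions."""
        return self.pattern.count("#")

    @property
    def span(self) -> int:
        """Total pattern length."""
        return len(self.pattern)

    def __str__(self) -> str:  # serialization = the pattern itself
        return self.pattern


@dataclass(frozen=True)
class PositionedSeed:
    """A spaced seed together with its allowed 0-based start offsets."""

    seed: SpacedSeed
    positions: tuple[int, ...]

    def __post_init__(self) -> None:
        pos = tuple(sorted(set(int(p) for p in self.positions)))
        if any(p < 0 for p in pos):
            raise ValueError(f"negative seed start position in {pos}")
        object.__setattr__(self, "positions", pos)

    def validate_for(self, read_length: int) -> None:
        s = self.seed.span
        for p in self.positions:
            if p + s > read_length:
                raise ValueError(
                    f"position {p} of seed {self.seed} does not fit a read of "
                    f"length {read_length} (needs {p + s})"
                )


@dataclass(frozen=True)
class SeedFamily:
    """Several position-restricted seeds used simultaneously on reads of
    fixed length ``read_length``.  A read alignment is *hit* when at least
    one member hits at one of its allowed positions.

    A member with an empty position set is legal but can never hit.
    """

    members: tuple[PositionedSeed, ...]
    read_length: int

    def __post_init__(self) -> None:
        members = tuple(self.members)
        if not members:
            raise ValueError("a seed family needs at least one member")
        object.__setattr__(self, "members", members)
        for mem in members:
            mem.validate_for(self.read_length)

    @property
    def total_positions(self) -> int:
        return sum(len(m.positions) for m in self.members)

    @property
    def weights(self) -> tuple[int, ...]:
        return tuple(m.seed.weight for m in self.members)


def parse_seed(text: str) -> SpacedSeed:
    """Parse a seed pattern, ignoring any whitespace inside it.

    Printed seed tables often typeset gaps as ``- - -``; whitespace is
    deleted before validation.
    """
    cleaned = re.sub(r"\s+", "", text)
    if not cleaned:
        raise ValueError("empty seed pattern")
    bad = [(i, ch) for i, ch in enumerate(cleaned) if ch not in "#-"]
    if bad:
        i, ch = bad[0]
        raise ValueError(f"invalid character {ch!r} at index {i} in seed {cleaned!r}")
    return SpacedSeed(cleaned)


def seed_hits(seed: SpacedSeed, alignment: str, offset: int) -> bool:
    """Does ``seed`` hit ``alignment`` when placed at ``offset``?

    The alignment string uses ``'1'`` for a color match, ``'0'`` for a
    color mismatch and ``'I'`` for a color indel.  A window containing an
    indel symbol anywhere (even under a ``-``) never hits: seeds must be
    placed between indels.
    """
    s = seed.span
    if offset < 0 or offset + s > len(alignment):
        raise ValueError(
            f"offset {offset} out of range for span {s} on alignment of "
            f"length {len(alignment)}"
        )
    window = alignment[offset : offset + s]
    if INDEL_CHAR in window:
        return False
    for pat_ch, al_ch in zip(seed.pattern, window):
        if pat_ch == "#" and al_ch != MATCH_CHAR:
            return False
    return True


def family_hits(family: SeedFamily, alignment: str) -> bool:
    """Direct scan: does any member hit at any of its allowed positions?

    Allowed positions index the *read colors*: an indel column carries no
    read color, so the alignment column where a placement at read
    position ``p`` starts is the column of the ``p``-th non-indel symbol
    (and the window itself must be indel-free, which :func:`seed_hits`
    enforces).  On indel-free alignments read positions and columns
    coincide.
    """
    n = len(alignment)
    # column index of each read position
    read_cols = [j for j, ch in enumerate(alignment) if ch != INDEL_CHAR]
    for mem in family.members:
        s = mem.seed.span
        for p in mem.positions:
            if p >= len(read_cols):
                continue
            col = read_cols[p]
            if col + s <= n and seed_hits(mem.seed, alignment, col):
                return True
    return False


def overlap_depth(family: SeedFamily) -> int:
    """Chromatic number of the interval graph of all seed placements.

    Each placement of a member at position ``p`` covers the read interval
    ``[p, p + span - 1]``.  For interval graphs the chromatic number equals
    the maximum clique size, i.e. the maximum number of placements covering
    any single read position, which a sweep over the read computes directly.
    """
    events: list[tuple[int, int]] = []
    for mem in family.members:
        s = mem.seed.span
        for p in mem.positions:
            events.append((p, +1))
            events.append((p + s, -1))
    if not events:
        return 0
    events.sort()
    depth = best = 0
    for _, delta in events:
        depth += delta
        best = max(best, depth)
    return best


class SeedFileError(ValueError):
    """Malformed seed file; carries a line/column diagnostic."""

    def __init__(self, message: str, line: int, column: int = 0):
        super().__init__(f"line {line}, column {column}: {message}")
        self.line = line
        self.column = column


def read_seed_file(path, read_length: int) -> SeedFamily:
    """Read one seed family from a seed file.

    Format: one member per line, ``PATTERN<TAB>p1,p2,...`` where ``*``
    stands for all valid start positions for the given read length.
    Lines starting with ``;`` are comments.
    """
    members: list[PositionedSeed] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith(";"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise SeedFileError(
                    "expected 'PATTERN<TAB>positions'", lineno, len(line)
                )
            try:
                seed = parse_seed(parts[0])
            except ValueError as exc:
                raise SeedFileError(str(exc), lineno, 1) from exc
            pos_field = parts[1].strip()
            if pos_field == "*":
                positions = tuple(range(read_length - seed.span + 1))
                if not positions:
                    raise SeedFileError(
                        f"seed span {seed.span} exceeds read length {read_length}",
                        lineno,
                        len(parts[0]) + 2,
                    )
            else:
                try:
                    positions = tuple(int(p) for p in pos_field.split(",") if p != "")
                except ValueError as exc:
                    raise SeedFileError(
                        f"bad position list {pos_field!r}", lineno, len(parts[0]) + 2
                    ) from exc
                if not positions:
                    raise SeedFileError(
                        "empty position list (use '*' for all positions)",
                        lineno,
                        len(parts[0]) + 2,
                    )
            try:
                ps = PositionedSeed(seed, positions)
                ps.validate_for(read_length)
                members.append(ps)
            except ValueError as exc:
                raise SeedFileError(str(exc), lineno, len(parts[0]) + 2) from exc
    if not members:
        raise SeedFileError("no seeds found in file", 1, 0)
    return SeedFamily(tuple(members), read_length)


def write_seed_file(path, family: SeedFamily, comment: str | None = None) -> None:
    with open(path, "w") as fh:
        if comment:
            for line in comment.splitlines():
                fh.write(f"; {line}\n")
        for mem in family.members:
            all_pos = tuple(range(family.read_length - mem.seed.span + 1))
            if mem.positions == all_pos:
                fh.write(f"{mem.seed.pattern}\t*\n")
            else:
                fh.write(
                    f"{mem.seed.pattern}\t{','.join(str(p) for p in mem.positions)}\n"
                )
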
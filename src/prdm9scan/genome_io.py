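"""Genome and interval I/O: FASTA, BED3+ and chrom.sizes, plus the coordinate model.

All coordinates are 0-based half-open (BED convention). Touching intervals do
not overlap. A "breakpoint position" derived from a BED interval is the
interval midpoint ``floor((start + end) / 2)``.

Genome sequences are stored uppercased over the alphabet {A, C, G, T, N}:
``U`` is mapped to ``T`` and any other character (including IUPAC ambiguity
codes) is masked to ``N``, so that degenerate genome positions never count as
motif matches. ``gap_mask`` records the maximal N-runs per chromosome; motif
scanning and region randomization both honor it.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

from Bio import SeqIO

logger = logging.getLogger("prdm9scan")

_VALID_BASES = frozenset("ACGTN")
_N_RUN = re.compile("N+")


class Interval(NamedTuple):
    """0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass
class GenomeAssembly:
    """Ordered chromosomes with lengths, optional sequence and N-gap mask.

    This is the sampling space for region randomization. Chromosome order is
    input order (never lexicographic); all downstream sorting respects it.
    """

    chroms: list[tuple[str, int]]
    sequence: dict[str, str] | None = None
    gap_mask: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = [name for name, _ in self.chroms]
        if not names:
            raise ValueError("assembly has no chromosomes")
        if len(set(names)) != len(names):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate chromosome name(s): {', '.join(dup)}")
        for name, length in self.chroms:
            if length < 1:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")
        if self.sequence is not None:
            for name, length in self.chroms:
                seq = self.sequence.get(name)
                if seq is None or len(seq) != length:
                    raise ValueError(
                        f"sequence for {name!r} missing or length mismatch "
                        f"({'absent' if seq is None else len(seq)} vs declared {length})"
                    )
        for name, gaps in self.gap_mask.items():
            length = dict(self.chroms).get(name)
            if length is None:
                raise ValueError(f"gap_mask references unknown chromosome {name!r}")
            prev_end = -1
            for start, end in gaps:
                if not (0 <= start < end <= length):
                    raise ValueError(f"gap {name}:{start}-{end} out of bounds")
                if start <= prev_end:
                    raise ValueError(f"gap_mask for {name!r} not sorted/disjoint")
                prev_end = end
        self._order = {name: i for i, (name, _) in enumerate(self.chroms)}
        self._lengths = dict(self.chroms)

    @property
    def names(self) -> list[str]:
        return [name for name, _ in self.chroms]

    def length_of(self, chrom: str) -> int:
        try:
            return self._lengths[chrom]
        except KeyError:
            raise KeyError(f"unknown chromosome {chrom!r}") from None

    def chrom_index(self, chrom: str) -> int:
        try:
            return self._order[chrom]
        except KeyError:
            raise KeyError(f"unknown chromosome {chrom!r}") from None

    def has_sequence(self) -> bool:
        return self.sequence is not None

    def sort_key(self, iv: Interval) -> tuple[int, int, int]:
        return (self.chrom_index(iv.chrom), iv.start, iv.end)

    def validate_interval(self, iv: Interval, context: str = "") -> None:
        where = f" {context}" if context else ""
        if iv.chrom not in self._lengths:
            raise ValueError(f"unknown chromosome {iv.chrom!r}{where}")
        if iv.start < 0 or iv.start >= iv.end:
            raise ValueError(f"start >= end or negative start{where}: {iv}")
        if iv.end > self._lengths[iv.chrom]:
            raise ValueError(
                f"end {iv.end} > length of {iv.chrom} ({self._lengths[iv.chrom]}){where}"
            )


@dataclass
class RegionSet:
    """A named list of intervals; duplicates permitted, order significant.

    ``extras`` holds any BED columns beyond the first three, aligned with
    ``intervals`` (opaque annotations, preserved on round-trip).
    """

    label: str
    intervals: list[Interval]
    is_sorted: bool = False
    extras: list[tuple[str, ...]] | None = None
    assembly: GenomeAssembly | None = field(default=None, compare=False, repr=False)

    def __len__(self) -> int:
        return len(self.intervals)

    def sort(self, assembly: GenomeAssembly) -> "RegionSet":
        """Return a copy sorted by (assembly chrom order, start, end)."""
        keyed = sorted(
            range(len(self.intervals)),
            key=lambda i: assembly.sort_key(self.intervals[i]),
        )
        return RegionSet(
            label=self.label,
            intervals=[self.intervals[i] for i in keyed],
            is_sorted=True,
            extras=[self.extras[i] for i in keyed] if self.extras is not None else None,
            assembly=assembly,
        )


def _clean_sequence(raw: str) -> str:
    seq = raw.upper().replace("U", "T")
    return "".join(c if c in _VALID_BASES else "N" for c in seq)


def _n_gaps(seq: str) -> list[tuple[int, int]]:
    return [(m.start(), m.end()) for m in _N_RUN.finditer(seq)]


def read_fasta(path: str | Path) -> GenomeAssembly:
    """Read a (possibly line-wrapped) multi-record FASTA into a GenomeAssembly.

    Sequences are uppercased, U→T, anything outside {A,C,G,T} masked to N and
    covered by the gap mask. Chromosome order is file order.
    """
    path = Path(path)
    chroms: list[tuple[str, int]] = []
    sequence: dict[str, str] = {}
    gap_mask: dict[str, list[tuple[int, int]]] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        name = record.id
        if name in sequence:
            raise ValueError(f"duplicate FASTA record {name!r} in {path}")
        seq = _clean_sequence(str(record.seq))
        if not seq:
            raise ValueError(f"zero-length FASTA record {name!r} in {path}")
        chroms.append((name, len(seq)))
        sequence[name] = seq
        gaps = _n_gaps(seq)
        if gaps:
            gap_mask[name] = gaps
    if not chroms:
        raise ValueError(f"no FASTA records found in {path}")
    return GenomeAssembly(chroms=chroms, sequence=sequence, gap_mask=gap_mask)


def write_fasta(assembly: GenomeAssembly, path: str | Path, line_width: int = 60) -> None:
    """Write an assembly's sequence as wrapped FASTA (record order = chrom order)."""
    if not assembly.has_sequence():
        raise ValueError("assembly has no sequence to write")
    path = Path(path)
    with path.open("w") as fh:
        for name, _ in assembly.chroms:
            fh.write(f">{name}\n")
            seq = assembly.sequence[name]
            for i in range(0, len(seq), line_width):
                fh.write(seq[i : i + line_width] + "\n")


def read_chrom_sizes(path: str | Path) -> GenomeAssembly:
    """Read a two-column UCSC-style chrom.sizes table into a sequence-free assembly."""
    path = Path(path)
    chroms: list[tuple[str, int]] = []
    seen: set[str] = set()
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected two columns, got {line!r}")
            name = fields[0]
            try:
                length = int(fields[1])
            except ValueError:
                raise ValueError(
                    f"{path}:{lineno}: non-integer length {fields[1]!r} for {name!r}"
                ) from None
            if length < 1:
                raise ValueError(f"{path}:{lineno}: non-positive length {length} for {name!r}")
            if name in seen:
                raise ValueError(f"{path}:{lineno}: duplicate chromosome {name!r}")
            seen.add(name)
            chroms.append((name, length))
    if not chroms:
        raise ValueError(f"empty chrom.sizes file {path}")
    return GenomeAssembly(chroms=chroms)


_BED_SKIP = ("track", "browser", "#")


def read_bed(path: str | Path, assembly: GenomeAssembly, label: str | None = None) -> RegionSet:
    """Read a BED3+ file, validating every interval against *assembly*.

    Extra columns are preserved as opaque annotations. Output is sorted by
    assembly chromosome order. Header/track lines are skipped with a warning.
    """
    path = Path(path)
    intervals: list[Interval] = []
    extras: list[tuple[str, ...]] = []
    any_extras = False
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(_BED_SKIP):
                logger.warning("%s:%d: skipping header/track line", path, lineno)
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 tab-separated columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from None
            iv = Interval(chrom, start, end)
            try:
                assembly.validate_interval(iv)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
            intervals.append(iv)
            extra = tuple(fields[3:])
            extras.append(extra)
            any_extras = any_extras or bool(extra)
    rs = RegionSet(
        label=label if label is not None else path.stem,
        intervals=intervals,
        extras=extras if any_extras else None,
        assembly=assembly,
    )
    return rs.sort(assembly)


def write_bed(regions: RegionSet, path: str | Path) -> None:
    """Write a RegionSet as tab-separated BED (no header; empty set → empty file)."""
    path = Path(path)
    with path.open("w") as fh:
        for i, iv in enumerate(regions.intervals):
            cols = [iv.chrom, str(iv.start), str(iv.end)]
            if regions.extras is not None and regions.extras[i]:
                cols.extend(regions.extras[i])
            fh.write("\t".join(cols) + "\n")
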
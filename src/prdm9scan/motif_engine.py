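"""Degenerate IUPAC motif expansion and exhaustive genome scanning.

The PRDM9 zinc-finger array recognizes the degenerate 13-bp motif
CCNCCNTNNCCNC; its five N positions expand to 4^5 = 1024 concrete variants.
Every concrete variant can be located exhaustively in a genome by plain
string scanning — occurrences may overlap each other, and no occurrence ever
spans a masked (N) position because concrete variants contain no N.

Scanning defaults to the forward strand only; ``strand_mode="both"`` also
reports reverse-complement occurrences on forward coordinates, deduplicated
against identical forward intervals.
"""

from __future__ import annotations

import itertools
import re
import warnings
from dataclasses import dataclass, field

from .genome_io import GenomeAssembly, Interval, RegionSet

IUPAC_BASES: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
# minimal IUPAC code for a non-empty subset of {A,C,G,T}
IUPAC_CODE: dict[frozenset, str] = {frozenset(v): k for k, v in IUPAC_BASES.items()}

DEFAULT_MOTIF_PATTERN = "CCNCCNTNNCCNC"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class DegenerateMotif:
    """A sequence pattern over the IUPAC alphabet."""

    pattern: str

    def __post_init__(self) -> None:
        if not self.pattern:
            raise ValueError("empty motif pattern")
        for i, c in enumerate(self.pattern):
            if c not in IUPAC_BASES:
                raise ValueError(f"invalid IUPAC character {c!r} at position {i}")

    def __len__(self) -> int:
        return len(self.pattern)

    @property
    def cardinality(self) -> int:
        """Number of concrete ACGT expansions (product of per-position set sizes)."""
        n = 1
        for c in self.pattern:
            n *= len(IUPAC_BASES[c])
        return n

    def matches(self, sequence: str) -> bool:
        """Position-wise membership of a concrete sequence in this pattern."""
        return len(sequence) == len(self.pattern) and all(
            b in IUPAC_BASES[c] for b, c in zip(sequence, self.pattern)
        )

    def to_regex(self) -> str:
        parts = []
        for c in self.pattern:
            bases = IUPAC_BASES[c]
            parts.append(bases if len(bases) == 1 else f"[{bases}]")
        return "".join(parts)


@dataclass(frozen=True)
class MotifVariant:
    """One concrete ACGT expansion; ``variant_id`` is its index in the
    lexicographic (A<C<G<T) expansion order of the parent pattern, stable
    across runs."""

    sequence: str
    variant_id: int


def expand_degenerate(motif: DegenerateMotif) -> list[MotifVariant]:
    """All distinct concrete expansions in lexicographic order.

    Per-position base sets are iterated in A<C<G<T order, so ``itertools.product``
    yields the overall lexicographic order directly.
    """
    per_position = ["".join(sorted(IUPAC_BASES[c])) for c in motif.pattern]
    return [
        MotifVariant(sequence="".join(combo), variant_id=i)
        for i, combo in enumerate(itertools.product(*per_position))
    ]


def _find_all(haystack: str, needle: str) -> list[int]:
    """All (possibly overlapping) occurrence starts of a literal string."""
    hits = []
    i = haystack.find(needle)
    while i != -1:
        hits.append(i)
        i = haystack.find(needle, i + 1)
    return hits


def scan_motif(
    assembly: GenomeAssembly,
    variant: MotifVariant,
    strand_mode: str = "forward",
) -> RegionSet:
    """Every occurrence of a concrete variant in the genome, as sorted intervals.

    Occurrences may overlap; reverse-complement matches (``strand_mode="both"``)
    are reported on forward coordinates and deduplicated against forward hits.
    """
    if strand_mode not in ("forward", "both"):
        raise ValueError(f"strand_mode must be 'forward' or 'both', got {strand_mode!r}")
    if not assembly.has_sequence():
        raise ValueError("assembly has no sequence; scanning requires one")
    m = len(variant.sequence)
    if all(length < m for _, length in assembly.chroms):
        warnings.warn(f"variant length {m} exceeds every chromosome; no hits possible")
        return RegionSet(label=variant.sequence, intervals=[], is_sorted=True, assembly=assembly)
    rc = reverse_complement(variant.sequence)
    intervals: list[Interval] = []
    for name, _ in assembly.chroms:
        seq = assembly.sequence[name]
        starts = set(_find_all(seq, variant.sequence))
        if strand_mode == "both" and rc != variant.sequence:
            starts.update(_find_all(seq, rc))
        intervals.extend(Interval(name, s, s + m) for s in sorted(starts))
    return RegionSet(label=variant.sequence, intervals=intervals, is_sorted=True, assembly=assembly)


@dataclass
class ScanResult:
    """Per-variant hit sets plus their union (= hits of the degenerate pattern)."""

    motif: DegenerateMotif
    per_variant: dict[int, RegionSet]
    union: RegionSet
    variants: list[MotifVariant] = field(default_factory=list)

    def n_hits(self, variant_id: int) -> int:
        return len(self.per_variant[variant_id])


def scan_all_variants(
    assembly: GenomeAssembly,
    motif: DegenerateMotif,
    strand_mode: str = "forward",
) -> ScanResult:
    """Scan every expansion of a degenerate motif in one pass.

    A single regex scan of the degenerate pattern (overlapping matches via a
    lookahead capture) finds the union; each matched substring is assigned to
    its variant. This is exactly equivalent to running :func:`scan_motif` per
    variant, because per-variant hit sets are disjoint as sequences.
    """
    if strand_mode not in ("forward", "both"):
        raise ValueError(f"strand_mode must be 'forward' or 'both', got {strand_mode!r}")
    if not assembly.has_sequence():
        raise ValueError("assembly has no sequence; scanning requires one")
    variants = expand_degenerate(motif)
    id_of = {v.sequence: v.variant_id for v in variants}
    m = len(motif)
    fwd = re.compile(f"(?=({motif.to_regex()}))")
    rc_pattern = DegenerateMotif(reverse_complement_pattern(motif.pattern))
    rev = re.compile(f"(?=({rc_pattern.to_regex()}))")

    per_variant_hits: dict[int, list[Interval]] = {v.variant_id: [] for v in variants}
    union_intervals: list[Interval] = []
    for name, _ in assembly.chroms:
        seq = assembly.sequence[name]
        # start -> set of matching variant ids (a position may carry a forward
        # match of one variant and a reverse match of another)
        found: dict[int, set[int]] = {}
        for mo in fwd.finditer(seq):
            found.setdefault(mo.start(), set()).add(id_of[mo.group(1)])
        if strand_mode == "both":
            for mo in rev.finditer(seq):
                found.setdefault(mo.start(), set()).add(
                    id_of[reverse_complement(mo.group(1))]
                )
        for start in sorted(found):
            iv = Interval(name, start, start + m)
            union_intervals.append(iv)
            for vid in found[start]:
                per_variant_hits[vid].append(iv)

    per_variant = {
        vid: RegionSet(
            label=variants[vid].sequence, intervals=hits, is_sorted=True, assembly=assembly
        )
        for vid, hits in per_variant_hits.items()
    }
    union = RegionSet(
        label=f"{motif.pattern}.union", intervals=union_intervals, is_sorted=True, assembly=assembly
    )
    return ScanResult(motif=motif, per_variant=per_variant, union=union, variants=variants)


def reverse_complement_pattern(pattern: str) -> str:
    """Reverse complement of an IUPAC pattern (complementing each base set)."""
    out = []
    for c in reversed(pattern):
        comp = frozenset(b.translate(_COMPLEMENT) for b in IUPAC_BASES[c])
        out.append(IUPAC_CODE[comp])
    return "".join(out)
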
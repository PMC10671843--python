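"""Synthetic genomes with planted motif sites and breakpoint sets with
controlled enrichment.

The generator emulates the shape of a real study — a multi-chromosome
genome, a degenerate motif whose chosen expansion is planted at known
("truth") positions, and per-cancer-type breakpoint sets in which a fraction
``f`` of breakpoints falls within ``d`` bp of a planted site while the rest
land uniformly — so every pipeline stage and statistical property can be
tested without any download. Background chance occurrences of the motif are
deliberately NOT scrubbed: a real genome has them, and the permutation test
must stay powerful despite them; truth labels let tests condition on planted
sites only.

Default geometry: a 5-Mb assembly (2 chromosomes x 2.5 Mb), 300 planted
sites, 60 breakpoints — small enough for desk-scale simulation, large
enough that window/hit overlap is rare under the null.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .genome_io import (
    GenomeAssembly,
    Interval,
    RegionSet,
    write_bed,
    write_fasta,
)
from .motif_engine import DegenerateMotif, MotifVariant, expand_degenerate
from .region_ops import BreakpointSet

DEFAULT_PLANTED_SEQUENCE = "CCACCATCACCAC"

_MAX_PLACEMENT_ATTEMPTS = 100_000


@dataclass
class SyntheticConfig:
    """Parameters of one synthetic study condition."""

    n_chroms: int = 2
    chrom_length: int = 2_500_000
    gc_content: float = 0.5
    motif: DegenerateMotif = field(default_factory=lambda: DegenerateMotif("CCNCCNTNNCCNC"))
    n_planted_sites: int = 300
    n_breakpoints: int = 60
    enrichment_fraction: float = 0.0
    proximity_distance: int = 50
    planted_variant: MotifVariant | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.gc_content < 1.0):
            raise ValueError("gc_content must be in (0, 1)")
        if not (0.0 <= self.enrichment_fraction <= 1.0):
            raise ValueError("enrichment_fraction must be in [0, 1]")
        if self.proximity_distance < 0:
            raise ValueError("proximity_distance must be >= 0")
        if min(self.n_chroms, self.chrom_length) < 1:
            raise ValueError("need >= 1 chromosome of positive length")
        if self.n_planted_sites < 0 or self.n_breakpoints < 0:
            raise ValueError("counts must be >= 0")
        genome = self.n_chroms * self.chrom_length
        if self.n_planted_sites * len(self.motif) * 5 > genome:
            raise ValueError("planted sites would occupy too much of the genome")
        if self.planted_variant is None:
            if self.motif.matches(DEFAULT_PLANTED_SEQUENCE):
                seq = DEFAULT_PLANTED_SEQUENCE
            else:
                seq = expand_degenerate(self.motif)[0].sequence
            object.__setattr__(self, "planted_variant", _variant_of(self.motif, seq))
        elif not self.motif.matches(self.planted_variant.sequence):
            raise ValueError(
                f"planted variant {self.planted_variant.sequence!r} does not match "
                f"motif {self.motif.pattern!r}"
            )

    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chroms)]

    def bare_assembly(self) -> GenomeAssembly:
        """The assembly geometry without sequence (for region-only workflows)."""
        return GenomeAssembly(chroms=[(n, self.chrom_length) for n in self.chrom_names()])


def _variant_of(motif: DegenerateMotif, sequence: str) -> MotifVariant:
    for v in expand_degenerate(motif):
        if v.sequence == sequence:
            return v
    raise ValueError(f"{sequence!r} is not an expansion of {motif.pattern!r}")


def _rng_for(config: SyntheticConfig, stream: str) -> np.random.Generator:
    """Independent substream per artifact, derived from the one global seed."""
    digest = hashlib.blake2b(stream.encode(), digest_size=4).digest()
    return np.random.default_rng(
        np.random.SeedSequence([config.seed, int.from_bytes(digest, "big")])
    )


def plant_sites(config: SyntheticConfig) -> RegionSet:
    """Uniform non-overlapping placements of the planted variant (truth sites).

    Sequence-free: returns only the positions. The same positions, under the
    same seed, are what :func:`generate_genome` writes into the sequence.
    """
    rng = _rng_for(config, "sites")
    m = len(config.motif)
    names = config.chrom_names()
    occupied: dict[str, list[tuple[int, int]]] = {n: [] for n in names}
    intervals: list[Interval] = []
    attempts = 0
    while len(intervals) < config.n_planted_sites:
        if attempts >= _MAX_PLACEMENT_ATTEMPTS:
            raise RuntimeError(
                f"could not place {config.n_planted_sites} non-overlapping sites in "
                f"{_MAX_PLACEMENT_ATTEMPTS} attempts; use a larger genome"
            )
        attempts += 1
        chrom = names[int(rng.integers(config.n_chroms))]
        start = int(rng.integers(config.chrom_length - m + 1))
        end = start + m
        if any(s < end and start < e for s, e in occupied[chrom]):
            continue
        occupied[chrom].append((start, end))
        intervals.append(Interval(chrom, start, end))
    rs = RegionSet(label="truth_sites", intervals=intervals)
    bare = config.bare_assembly()
    return rs.sort(bare)


def generate_genome(config: SyntheticConfig) -> tuple[GenomeAssembly, RegionSet]:
    """I.i.d. background sequence with the planted variant written at truth sites.

    Bases are drawn with P(G) = P(C) = gc/2 and P(A) = P(T) = (1-gc)/2.
    Background chance occurrences of the motif are left in place (documented
    generator property). Deterministic given the config seed.
    """
    truth = plant_sites(config)
    rng = _rng_for(config, "genome")
    p = np.array([
        (1 - config.gc_content) / 2,  # A
        config.gc_content / 2,        # C
        config.gc_content / 2,        # G
        (1 - config.gc_content) / 2,  # T
    ])
    alphabet = np.frombuffer(b"ACGT", dtype=np.uint8)
    sequence: dict[str, str] = {}
    planted = config.planted_variant.sequence.encode()
    by_chrom: dict[str, list[Interval]] = {}
    for iv in truth.intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    for name in config.chrom_names():
        draw = rng.choice(4, size=config.chrom_length, p=p)
        buf = bytearray(alphabet[draw].tobytes())
        for iv in by_chrom.get(name, ()):
            buf[iv.start : iv.end] = planted
        sequence[name] = buf.decode("ascii")
    assembly = GenomeAssembly(
        chroms=[(n, config.chrom_length) for n in config.chrom_names()],
        sequence=sequence,
    )
    truth.assembly = assembly
    return assembly, truth


def generate_breakpoints(
    config: SyntheticConfig, truth_sites: RegionSet, label: str = "synthetic"
) -> BreakpointSet:
    """Breakpoints: each one is enriched (within +-d of a uniformly chosen
    planted site center) with probability f, otherwise uniform on the genome."""
    if config.enrichment_fraction > 0 and len(truth_sites) == 0:
        raise ValueError("enrichment_fraction > 0 requires planted sites")
    rng = _rng_for(config, f"breakpoints:{label}")
    centers = [(iv.chrom, iv.midpoint) for iv in truth_sites.intervals]
    d = config.proximity_distance
    names = config.chrom_names()
    positions: list[tuple[str, int]] = []
    enriched: list[bool] = []
    for _ in range(config.n_breakpoints):
        if centers and rng.random() < config.enrichment_fraction:
            chrom, center = centers[int(rng.integers(len(centers)))]
            lo = max(0, center - d)
            hi = min(config.chrom_length - 1, center + d)
            positions.append((chrom, int(rng.integers(lo, hi + 1))))
            enriched.append(True)
        else:
            chrom = names[int(rng.integers(config.n_chroms))]
            positions.append((chrom, int(rng.integers(config.chrom_length))))
            enriched.append(False)
    return BreakpointSet(label=label, positions=positions, enriched=enriched)


@dataclass
class StudyProfile:
    """Shape of a multi-cancer-type fixture: one genome, several labeled
    breakpoint sets of unequal sizes (echoing a four-cancer study design)."""

    labels: dict[str, tuple[int, float]] = field(
        default_factory=lambda: {
            # label -> (n_breakpoints, enrichment_fraction); sizes echo the
            # relative proportions of a four-cancer breakpoint catalog
            "BRC": (150, 0.5),
            "LUAD": (170, 0.5),
            "OV": (230, 0.5),
            "HN": (170, 0.5),
        }
    )
    n_chroms: int = 3
    chrom_length: int = 2_000_000
    n_planted_sites: int = 300
    proximity_distance: int = 50
    seed: int = 0


def make_study_fixture(profile: StudyProfile, outdir: str | Path) -> dict:
    """Write a full fixture bundle: FASTA, chrom.sizes, per-label breakpoint
    BEDs, truth BEDs and a manifest TSV recording all parameters and seeds."""
    if not profile.labels:
        raise ValueError("profile needs at least one label")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    base = SyntheticConfig(
        n_chroms=profile.n_chroms,
        chrom_length=profile.chrom_length,
        n_planted_sites=profile.n_planted_sites,
        proximity_distance=profile.proximity_distance,
        seed=profile.seed,
    )
    assembly, truth = generate_genome(base)
    fasta = outdir / "genome.fa"
    write_fasta(assembly, fasta)
    sizes = outdir / "genome.chrom.sizes"
    with sizes.open("w") as fh:
        for name, length in assembly.chroms:
            fh.write(f"{name}\t{length}\n")
    truth_bed = outdir / "truth_sites.bed"
    write_bed(truth, truth_bed)

    bed_paths: dict[str, Path] = {}
    manifest_rows = [
        ("seed", profile.seed),
        ("n_chroms", profile.n_chroms),
        ("chrom_length", profile.chrom_length),
        ("n_planted_sites", profile.n_planted_sites),
        ("proximity_distance", profile.proximity_distance),
        ("planted_variant", base.planted_variant.sequence),
        ("motif", base.motif.pattern),
    ]
    for label, (n_bp, f) in profile.labels.items():
        cfg = replace(base, n_breakpoints=n_bp, enrichment_fraction=f)
        bset = generate_breakpoints(cfg, truth, label=label)
        regions = RegionSet(
            label=label,
            intervals=[Interval(c, p, p + 1) for c, p in bset.positions],
            extras=[("enriched" if e else "background",) for e in bset.enriched],
        ).sort(assembly)
        path = outdir / f"breakpoints_{label}.bed"
        write_bed(regions, path)
        bed_paths[label] = path
        manifest_rows.append((f"n_breakpoints[{label}]", n_bp))
        manifest_rows.append((f"enrichment_fraction[{label}]", f))
    manifest = outdir / "manifest.tsv"
    with manifest.open("w") as fh:
        fh.write("parameter\tvalue\n")
        for k, v in manifest_rows:
            fh.write(f"{k}\t{v}\n")
    return {
        "fasta": fasta,
        "chrom_sizes": sizes,
        "truth_bed": truth_bed,
        "breakpoint_beds": bed_paths,
        "manifest": manifest,
        "assembly": assembly,
        "truth": truth,
    }
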
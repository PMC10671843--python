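"""Region-randomization permutation inference for motif/breakpoint association.

The test asks whether breakpoint-centered windows overlap motif occurrences
more often than expected if the windows were placed uniformly at random on
the genome. The null is built by re-placing every window independently and
uniformly over all valid starts (chromosome drawn with probability
proportional to the number of valid starts it offers, gap-masked positions
excluded), holding motif hits fixed, and recomputing the count-once overlap
statistic.

For an observed statistic ``obs`` and permuted values ``perm_1..perm_n``:

    p  = (1 + #{perm_i >= obs}) / (n + 1)          (alternative = "greater")
    z  = (obs - mean(perm)) / sd(perm)             (sample sd, ddof = 1)

``alternative="auto"`` resolves to "greater" when obs >= mean(perm), else
"less". The +1 smoothing keeps p in (0, 1]; the smallest attainable p is
1/(n_perm + 1) — with the default n_perm = 1000, 1/1001 ~ 0.001.

The positional control (`local_zscore`) shifts the windows by signed offsets
and re-expresses the shifted observed counts as z-scores against the
*unshifted* null; a sharp peak at shift 0 indicates that the association is
position-specific rather than a broad regional effect.

A screen applies the test to every (motif variant x breakpoint set x window
width) combination and flags rows by the rule p < 0.05 and |z| > 3. No
multiple-testing correction enters that flag (the screen reproduces the raw
rule); Benjamini-Hochberg q-values are reported alongside for honest reading.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .genome_io import GenomeAssembly, Interval, RegionSet
from .motif_engine import (
    IUPAC_CODE,
    DegenerateMotif,
    MotifVariant,
    scan_all_variants,
)
from .region_ops import (
    BreakpointSet,
    WindowSet,
    make_windows,
    merge_intervals,
    overlaps_any,
    regions_to_arrays,
)

SIGNIFICANCE_P = 0.05
SIGNIFICANCE_Z = 3.0

SCREEN_COLUMNS = [
    "variant_id", "variant_seq", "cancer_label", "window_width",
    "n_windows", "n_hits", "observed", "perm_mean", "perm_sd",
    "z_score", "p_value", "q_value", "significant", "n_perm", "seed", "status",
]


def is_significant(p_value: float, z_score: float) -> bool:
    """The screening rule: p < 0.05 and z < -3 or z > 3 (NaN z never passes)."""
    return bool(p_value < SIGNIFICANCE_P and abs(z_score) > SIGNIFICANCE_Z)


# ---------------------------------------------------------------------------
# Uniform placement machinery
# ---------------------------------------------------------------------------

class PlacementSampler:
    """Uniform sampler over all valid (chromosome, start) placements of a
    fixed-length region, excluding starts whose region would overlap the
    assembly gap mask. Chromosomes are implicitly weighted by the number of
    valid starts they offer."""

    def __init__(self, assembly: GenomeAssembly, length: int):
        if length < 1:
            raise ValueError("region length must be >= 1")
        self.length = length
        seg_chrom: list[int] = []
        seg_start: list[int] = []
        seg_count: list[int] = []
        for ci, (name, clen) in enumerate(assembly.chroms):
            pos = 0
            runs = []
            for gs, ge in assembly.gap_mask.get(name, ()):  # ungapped runs
                if gs > pos:
                    runs.append((pos, gs))
                pos = ge
            if pos < clen:
                runs.append((pos, clen))
            for a, b in runs:
                if b - a >= length:
                    seg_chrom.append(ci)
                    seg_start.append(a)
                    seg_count.append(b - a - length + 1)
        if not seg_count:
            raise ValueError(
                f"no chromosome has an un-masked stretch of length >= {length}"
            )
        self.seg_chrom = np.array(seg_chrom, np.int64)
        self.seg_start = np.array(seg_start, np.int64)
        counts = np.array(seg_count, np.int64)
        self.cum = np.cumsum(counts)
        self.offsets = self.cum - counts  # first flat index of each segment
        self.total = int(self.cum[-1])

    def sample(self, rng: np.random.Generator, k: int) -> tuple[np.ndarray, np.ndarray]:
        """k independent uniform placements -> (chrom_index, start) arrays."""
        u = rng.integers(0, self.total, size=k)
        seg = np.searchsorted(self.cum, u, side="right")
        return self.seg_chrom[seg], self.seg_start[seg] + (u - self.offsets[seg])


def randomize_regions(
    regions: RegionSet,
    assembly: GenomeAssembly,
    rng: np.random.Generator,
) -> RegionSet:
    """Re-place every interval independently and uniformly on the genome.

    Lengths are preserved; a region may move between chromosomes; placed
    regions may overlap each other; placements never intersect the gap mask.
    Deterministic given the generator state.
    """
    lengths = [iv.length for iv in regions.intervals]
    samplers = {L: PlacementSampler(assembly, L) for L in sorted(set(lengths))}
    names = assembly.names
    intervals: list[Interval] = []
    by_len: dict[int, list[int]] = {}
    for i, L in enumerate(lengths):
        by_len.setdefault(L, []).append(i)
    placed: list[Interval | None] = [None] * len(lengths)
    for L in sorted(by_len):
        idxs = by_len[L]
        ci, st = samplers[L].sample(rng, len(idxs))
        for j, i in enumerate(idxs):
            placed[i] = Interval(names[int(ci[j])], int(st[j]), int(st[j]) + L)
    intervals = [iv for iv in placed if iv is not None]
    return RegionSet(label=f"{regions.label}.randomized", intervals=intervals, assembly=assembly)


# ---------------------------------------------------------------------------
# Permutation test
# ---------------------------------------------------------------------------

@dataclass
class PermTestResult:
    """Observed overlap, permutation-null summary and derived statistics."""

    observed: int
    perm_mean: float
    perm_sd: float
    z_score: float  # NaN when perm_sd == 0
    p_value: float
    alternative: str  # resolved: "greater" or "less"
    n_perm: int
    seed: int
    n_windows: int
    n_hits: int
    window_width: int = 0
    variant_id: int | None = None
    variant_seq: str | None = None
    label: str | None = None
    null_counts: np.ndarray | None = field(default=None, repr=False, compare=False)

    @property
    def z_defined(self) -> bool:
        return np.isfinite(self.z_score)


def _regions_as_indexed_arrays(
    regions: RegionSet, assembly: GenomeAssembly
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(chrom_index, start, end) arrays in interval order."""
    ci = np.array([assembly.chrom_index(iv.chrom) for iv in regions.intervals], np.int64)
    st = np.array([iv.start for iv in regions.intervals], np.int64)
    en = np.array([iv.end for iv in regions.intervals], np.int64)
    return ci, st, en


def _merged_by_chrom_index(
    regions: RegionSet, assembly: GenomeAssembly
) -> dict[int, tuple[np.ndarray, np.ndarray]]:
    return {
        assembly.chrom_index(chrom): merge_intervals(arr)
        for chrom, arr in regions_to_arrays(regions).items()
    }


def _count_once(
    ci: np.ndarray,
    st: np.ndarray,
    en: np.ndarray,
    merged: dict[int, tuple[np.ndarray, np.ndarray]],
) -> int:
    return int(_overlap_flags(ci, st, en, merged).sum())


def _overlap_flags(
    ci: np.ndarray,
    st: np.ndarray,
    en: np.ndarray,
    merged: dict[int, tuple[np.ndarray, np.ndarray]],
) -> np.ndarray:
    flags = np.zeros(len(st), dtype=bool)
    for c, m in merged.items():
        sel = ci == c
        if sel.any():
            flags[sel] = overlaps_any(st[sel], en[sel], m)
    return flags


def perm_test(
    windows: WindowSet,
    hits: RegionSet,
    assembly: GenomeAssembly,
    n_perm: int = 1000,
    seed: int = 0,
    alternative: str = "auto",
    randomize: str = "windows",
    keep_null: bool = False,
) -> PermTestResult:
    """Permutation test of window/hit overlap against the uniform-placement null.

    By default the window set is randomized and the motif hits held fixed
    (``randomize="hits"`` swaps the roles; the observed statistic is
    unchanged). The statistic is count-once over windows: the number of
    windows containing >= 1 motif hit.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if len(windows) == 0:
        raise ValueError("window set is empty")
    if alternative not in ("auto", "greater", "less"):
        raise ValueError(f"invalid alternative {alternative!r}")
    if randomize not in ("windows", "hits"):
        raise ValueError(f"randomize must be 'windows' or 'hits', got {randomize!r}")

    rng = np.random.default_rng(seed)
    w_ci, w_st, w_en = _regions_as_indexed_arrays(windows, assembly)
    merged_hits = _merged_by_chrom_index(hits, assembly)
    observed = _count_once(w_ci, w_st, w_en, merged_hits)

    if randomize == "windows":
        null = _null_randomizing_queries(
            w_en - w_st, merged_hits, assembly, n_perm, rng
        )
    else:
        null = _null_randomizing_subjects(
            w_ci, w_st, w_en, hits, assembly, n_perm, rng
        )

    perm_mean = float(null.mean())
    perm_sd = float(null.std(ddof=1)) if n_perm > 1 else 0.0
    resolved = alternative
    if alternative == "auto":
        resolved = "greater" if observed >= perm_mean else "less"
    if resolved == "greater":
        exceed = int((null >= observed).sum())
    else:
        exceed = int((null <= observed).sum())
    p_value = (1 + exceed) / (n_perm + 1)
    if perm_sd > 0:
        z = (observed - perm_mean) / perm_sd
    else:
        warnings.warn("permutation null has zero spread; z-score undefined")
        z = float("nan")
    return PermTestResult(
        observed=observed,
        perm_mean=perm_mean,
        perm_sd=perm_sd,
        z_score=z,
        p_value=p_value,
        alternative=resolved,
        n_perm=n_perm,
        seed=seed,
        n_windows=len(windows),
        n_hits=len(hits),
        window_width=getattr(windows, "window_width", 0),
        label=getattr(windows, "source_label", None) or windows.label,
        null_counts=null if keep_null else None,
    )


def _null_randomizing_queries(
    lengths: np.ndarray,
    merged_hits: dict[int, tuple[np.ndarray, np.ndarray]],
    assembly: GenomeAssembly,
    n_perm: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Null counts when the query (window) set is re-placed each permutation.

    All n_perm x n_windows placements of each unique window length are drawn
    in one vectorized batch; per-permutation counts fall out of a reshape.
    """
    null = np.zeros(n_perm, dtype=np.int64)
    for L in np.unique(lengths):
        idx = np.flatnonzero(lengths == L)
        sampler = PlacementSampler(assembly, int(L))
        k = n_perm * len(idx)
        ci, st = sampler.sample(rng, k)
        flags = _overlap_flags(ci, st, st + int(L), merged_hits)
        null += flags.reshape(n_perm, len(idx)).sum(axis=1)
    return null


def _null_randomizing_subjects(
    w_ci: np.ndarray,
    w_st: np.ndarray,
    w_en: np.ndarray,
    hits: RegionSet,
    assembly: GenomeAssembly,
    n_perm: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Null counts when the subject (hit) set is re-placed each permutation."""
    null = np.empty(n_perm, dtype=np.int64)
    for i in range(n_perm):
        placed = randomize_regions(hits, assembly, rng)
        null[i] = _count_once(w_ci, w_st, w_en, _merged_by_chrom_index(placed, assembly))
    return null


# ---------------------------------------------------------------------------
# Local (displacement) z-score profile
# ---------------------------------------------------------------------------

@dataclass
class LocalZProfile:
    """z-scores of the shifted observed statistic against the unshifted null."""

    shifts: np.ndarray  # signed bp offsets, symmetric around 0
    z_at_shift: np.ndarray
    observed_at_shift: np.ndarray
    parent: PermTestResult

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"shift_bp": self.shifts, "observed": self.observed_at_shift, "z": self.z_at_shift}
        )


def local_zscore(
    parent: PermTestResult,
    windows: WindowSet,
    hits: RegionSet,
    assembly: GenomeAssembly,
    max_shift: int | None = None,
    step: int | None = None,
) -> LocalZProfile:
    """Shift all windows by each offset d in [-max_shift, +max_shift] (step bp),
    clip at chromosome bounds, recompute the observed count and express it as a
    z-score with the parent's perm_mean/perm_sd (the null is not re-simulated).

    Defaults: max_shift = 5 x window width, step = window width / 2.
    """
    if not parent.z_defined:
        raise ValueError("parent result has undefined z (zero-spread null)")
    width = windows.window_width or 0
    if max_shift is None:
        if not width:
            raise ValueError("max_shift required when window width is unknown")
        max_shift = 5 * width
    if step is None:
        step = max(1, (width // 2) if width else max_shift // 10)
    if max_shift % step:
        raise ValueError(f"max_shift {max_shift} must be a multiple of step {step}")

    w_ci, w_st, w_en = _regions_as_indexed_arrays(windows, assembly)
    chrom_len = np.array(
        [assembly.length_of(assembly.names[int(c)]) for c in w_ci], np.int64
    )
    merged_hits = _merged_by_chrom_index(hits, assembly)
    shifts = np.arange(-max_shift, max_shift + 1, step, dtype=np.int64)
    observed = np.empty(len(shifts), np.int64)
    for i, d in enumerate(shifts):
        st = np.clip(w_st + d, 0, chrom_len)
        en = np.clip(w_en + d, 0, chrom_len)
        nonempty = en > st
        observed[i] = _count_once(
            w_ci[nonempty], st[nonempty], en[nonempty], merged_hits
        )
    z = (observed - parent.perm_mean) / parent.perm_sd
    # shift 0 must reproduce the parent z bit-for-bit
    zero = int(np.flatnonzero(shifts == 0)[0])
    observed[zero] = parent.observed
    z[zero] = parent.z_score
    return LocalZProfile(shifts=shifts, z_at_shift=z, observed_at_shift=observed, parent=parent)


# ---------------------------------------------------------------------------
# All-variant screen
# ---------------------------------------------------------------------------

def combination_seed(base_seed: int, variant_id: int, label: str, width: int) -> int:
    """Stable per-combination seed (< 2^31) so single combinations re-run in
    isolation match the full screen."""
    key = f"{base_seed}|{variant_id}|{label}|{width}".encode()
    return int.from_bytes(hashlib.blake2b(key, digest_size=4).digest(), "big") % (2**31)


@dataclass
class ScreenTable:
    """One permutation-test row per (variant x breakpoint set x window width)."""

    table: pd.DataFrame
    motif: DegenerateMotif | None = None

    def significant_variants(self, mode: str = "any") -> list[int]:
        """Variant ids significant in >= 1 combination ("any") or in every
        (label x width) combination ("all")."""
        ok = self.table[self.table["status"] == "ok"]
        sig = ok.groupby("variant_id")["significant"]
        if mode == "any":
            flagged = sig.any()
        elif mode == "all":
            n_combo = ok.groupby("variant_id").size()
            flagged = sig.all() & (n_combo == n_combo.max())
        else:
            raise ValueError(f"mode must be 'any' or 'all', got {mode!r}")
        return sorted(int(v) for v in flagged[flagged].index)

    def to_tsv(self, path) -> None:
        write_screen_tsv(self.table, path)


def write_screen_tsv(table: pd.DataFrame, path) -> None:
    """Deterministic TSV serialization (fixed float formatting)."""
    out = table.copy()
    for col in ("perm_mean", "perm_sd", "z_score", "p_value", "q_value"):
        out[col] = out[col].map(lambda x: "NA" if pd.isna(x) else format(float(x), ".10g"))
    out.to_csv(path, sep="\t", index=False)


def screen_all(
    variants: list[MotifVariant],
    breakpoint_sets: list[BreakpointSet],
    widths: list[int],
    assembly: GenomeAssembly,
    n_perm: int = 1000,
    base_seed: int = 0,
    alternative: str = "auto",
    randomize: str = "windows",
    strand_mode: str = "forward",
    hits_by_variant: dict[int, RegionSet] | None = None,
    motif: DegenerateMotif | None = None,
) -> ScreenTable:
    """Run the permutation test for every (variant, breakpoint set, width).

    Motif hits per variant are scanned from the assembly sequence unless a
    precomputed ``hits_by_variant`` map is given. A failed combination becomes
    a row with an error status rather than being dropped. Rows are sorted by
    (p, |z| descending) with a deterministic tiebreak; BH q-values are computed
    within each (label x width) stratum.
    """
    if not variants or not breakpoint_sets or not widths:
        raise ValueError("variants, breakpoint_sets and widths must all be non-empty")
    if hits_by_variant is None:
        if motif is None:
            raise ValueError("either hits_by_variant or motif must be provided")
        scan = scan_all_variants(assembly, motif, strand_mode=strand_mode)
        hits_by_variant = {v.variant_id: scan.per_variant[v.variant_id] for v in variants}

    rows = []
    for bset in breakpoint_sets:
        for width in widths:
            windows = make_windows(bset, width, assembly)
            for v in variants:
                seed = combination_seed(base_seed, v.variant_id, bset.label, width)
                hits = hits_by_variant[v.variant_id]
                try:
                    r = perm_test(
                        windows, hits, assembly,
                        n_perm=n_perm, seed=seed, alternative=alternative,
                        randomize=randomize,
                    )
                    rows.append({
                        "variant_id": v.variant_id,
                        "variant_seq": v.sequence,
                        "cancer_label": bset.label,
                        "window_width": width,
                        "n_windows": r.n_windows,
                        "n_hits": r.n_hits,
                        "observed": r.observed,
                        "perm_mean": r.perm_mean,
                        "perm_sd": r.perm_sd,
                        "z_score": r.z_score,
                        "p_value": r.p_value,
                        "q_value": np.nan,
                        "significant": is_significant(r.p_value, r.z_score)
                        if r.z_defined
                        else False,
                        "n_perm": n_perm,
                        "seed": seed,
                        "status": "ok",
                    })
                except Exception as exc:  # pragma: no cover - defensive
                    rows.append({
                        "variant_id": v.variant_id,
                        "variant_seq": v.sequence,
                        "cancer_label": bset.label,
                        "window_width": width,
                        "n_windows": len(windows),
                        "n_hits": len(hits),
                        "observed": np.nan,
                        "perm_mean": np.nan,
                        "perm_sd": np.nan,
                        "z_score": np.nan,
                        "p_value": np.nan,
                        "q_value": np.nan,
                        "significant": False,
                        "n_perm": n_perm,
                        "seed": seed,
                        "status": f"error: {exc}",
                    })
    table = pd.DataFrame(rows, columns=SCREEN_COLUMNS)
    for (_, _), idx in table[table["status"] == "ok"].groupby(
        ["cancer_label", "window_width"]
    ).groups.items():
        p = table.loc[idx, "p_value"].to_numpy(float)
        if len(p):
            table.loc[idx, "q_value"] = multipletests(p, method="fdr_bh")[1]
    table["abs_z"] = table["z_score"].abs()
    table = table.sort_values(
        by=["p_value", "abs_z", "cancer_label", "window_width", "variant_id"],
        ascending=[True, False, True, True, True],
        kind="mergesort",
    ).drop(columns="abs_z").reset_index(drop=True)
    return ScreenTable(table=table, motif=motif)


# ---------------------------------------------------------------------------
# Consensus motif
# ---------------------------------------------------------------------------

BASES = "ACGT"


@dataclass
class ConsensusMatrix:
    """Position x base count matrix over a set of equal-length sequences, with
    the minimal-IUPAC consensus string (code covering bases with count > 0)."""

    counts: np.ndarray  # shape (L, 4), columns A,C,G,T
    consensus: str
    n_sequences: int

    def as_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, columns=list(BASES))
        df.insert(0, "position", np.arange(1, len(df) + 1))
        return df


def consensus_motif(significant_variants: list[MotifVariant]) -> ConsensusMatrix:
    """Unweighted per-position base counts and the IUPAC consensus."""
    if not significant_variants:
        raise ValueError("no variants supplied")
    seqs = [v.sequence for v in significant_variants]
    L = len(seqs[0])
    if any(len(s) != L for s in seqs):
        raise ValueError("variants have mixed lengths")
    counts = np.zeros((L, 4), dtype=np.int64)
    base_idx = {b: i for i, b in enumerate(BASES)}
    for s in seqs:
        for j, b in enumerate(s):
            counts[j, base_idx[b]] += 1
    consensus = "".join(
        IUPAC_CODE[frozenset(BASES[i] for i in np.flatnonzero(counts[j] > 0))]
        for j in range(L)
    )
    return ConsensusMatrix(counts=counts, consensus=consensus, n_sequences=len(seqs))


# ---------------------------------------------------------------------------
# Plots (Fig 2/3 analogues); optional, headless-safe
# ---------------------------------------------------------------------------

def plot_null_histogram(result: PermTestResult, path) -> None:
    """Null histogram with observed (green) and expected (red) markers."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if result.null_counts is None:
        raise ValueError("result carries no null counts (rerun with keep_null=True)")
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.hist(result.null_counts, bins=30, color="0.6")
    ax.axvline(result.observed, color="green", lw=2, label="observed (Ev_obs)")
    ax.axvline(result.perm_mean, color="red", lw=2, label="expected (Ev_exp)")
    ax.set_xlabel("count-once overlap")
    ax.set_ylabel("permutations")
    ax.set_title(
        f"{result.label or ''} w={result.window_width} "
        f"p={result.p_value:.4g} z={result.z_score:.3f}"
    )
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_local_z(profile: LocalZProfile, path) -> None:
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(profile.shifts, profile.z_at_shift, marker="o", ms=3)
    ax.axvline(0, color="0.7", lw=1)
    ax.set_xlabel("window shift (bp)")
    ax.set_ylabel("local z-score")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
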
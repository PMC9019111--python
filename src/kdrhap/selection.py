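"""Selection scans: core haplotypes, EHH decay, windowed haplotype
homozygosity, shared-haplotype lengths and the first-detection-year test.

A recent selective sweep leaves carriers of the favoured allele on long,
nearly identical haplotypes.  Extended haplotype homozygosity (EHH)
measures this directly: starting from a short "core" region that
distinguishes the genetic backgrounds of interest, EHH at a position x is
the probability that two randomly drawn carriers of a core are identical
at every included site from the core edge out to x.  Recombination breaks
carriers onto other backgrounds, so EHH decays with distance; slow decay
relative to wild-type haplotypes is the signature of positive selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .hapmatrix import HaplotypeMatrix

__all__ = [
    "CoreHaplotypeSet",
    "define_core_haplotypes",
    "EHHCurve",
    "ehh_decay",
    "window_homozygosity",
    "haplotype_homozygosity",
    "divergence_region_scan",
    "GeneticMap",
    "SharedLengthResult",
    "shared_haplotype_lengths",
    "detection_year_correlation",
]


# --------------------------------------------------------- core haplotypes


@dataclass
class CoreHaplotypeSet:
    """Distinct haplotypes over the core interval, with frequencies.

    ``interval`` is (start, end), 1-based, end-exclusive, so its length is
    simply ``end - start``.  Cores at or below ``min_frequency`` are
    dropped ("above 1%" is a strict comparison).  ``labels`` maps core id
    -> group label derived from focal-allele content.
    """

    interval: tuple[int, int]
    cores: list[tuple]  # distinct haplotype strings over core sites
    frequencies: list[float]
    carriers: list[np.ndarray]  # haplotype columns per core
    labels: list[str]
    min_frequency: float
    site_rows: np.ndarray  # matrix rows of the core sites

    @property
    def length(self) -> int:
        return self.interval[1] - self.interval[0]

    def core_by_label(self, label: str) -> int:
        return self.labels.index(label)


def define_core_haplotypes(
    haps: HaplotypeMatrix,
    core: tuple[int, int],
    min_frequency: float = 0.01,
    focal_carriage: dict[str, np.ndarray] | None = None,
) -> CoreHaplotypeSet:
    """Enumerate distinct haplotypes over the core interval.

    Cores are sorted by decreasing frequency; those at a cohort frequency
    not strictly above ``min_frequency`` are dropped.  When
    ``focal_carriage`` is given (label base -> boolean carrier vector),
    each retained core is labelled by the focal allele its carriers hold:
    single-letter bases are numbered by decreasing core frequency, longer
    bases name the largest core directly, and cores with no focal allele
    are ``wt`` (numbered wt1, wt2, ... beyond the first).
    """
    start, end = core
    if end <= start:
        raise ValueError("empty core interval")
    rows = haps.site_index_in(start, end)
    if rows.size == 0:
        raise ValueError("core interval contains no variant sites")
    sub = haps.codes[rows]
    n = haps.n_haplotypes
    groups: dict[tuple, list[int]] = {}
    for h in range(n):
        key = tuple(int(x) for x in sub[:, h])
        groups.setdefault(key, []).append(h)
    ordered = sorted(groups.items(), key=lambda kv: (-len(kv[1]), kv[0]))
    cores, freqs, carriers = [], [], []
    for key, members in ordered:
        f = len(members) / n
        if f > min_frequency:
            cores.append(key)
            freqs.append(f)
            carriers.append(np.array(members))

    labels: list[str] = []
    if focal_carriage is None:
        labels = [f"core{i + 1}" for i in range(len(cores))]
    else:
        counters: dict[str, int] = {}
        wt_count = 0
        for members in carriers:
            base = ""
            for b, carr in focal_carriage.items():
                frac = np.count_nonzero(np.asarray(carr)[members]) / len(members)
                if frac > 0.5:
                    base = b
                    break
            if not base:
                wt_count += 1
                labels.append("wt" if wt_count == 1 else f"wt{wt_count}")
            elif len(base) == 1:
                counters[base] = counters.get(base, 0) + 1
                labels.append(f"{base}{counters[base]}")
            else:
                counters[base] = counters.get(base, 0) + 1
                labels.append(base if counters[base] == 1 else f"{base}.{counters[base]}")

    return CoreHaplotypeSet(
        interval=core,
        cores=cores,
        frequencies=freqs,
        carriers=carriers,
        labels=labels,
        min_frequency=min_frequency,
        site_rows=rows,
    )


# ------------------------------------------------------------------- EHH


@dataclass
class EHHCurve:
    """EHH values at successive site positions away from the core."""

    core_id: int
    direction: str  # upstream | downstream
    positions: np.ndarray
    ehh: np.ndarray
    n_carriers: int

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "core_id": self.core_id,
                "direction": self.direction,
                "position": self.positions,
                "ehh": self.ehh,
            }
        )


def _included_site_mask(
    haps: HaplotypeMatrix,
    exclude_nonsynonymous: dict[int, object] | None,
    exclude_singletons: bool,
) -> np.ndarray:
    """Sites retained for EHH/shared-length scans.

    Non-synonymous sites are excluded so the decay reflects the genetic
    background, not the resistance alleles themselves; cohort-wide
    singletons are excluded as phasing/sequencing noise.
    """
    mask = np.ones(haps.n_sites, dtype=bool)
    if exclude_nonsynonymous:
        for row, eff in exclude_nonsynonymous.items():
            cls = getattr(eff, "effect_class", None)
            if cls in ("missense", "nonsense"):
                mask[row] = False
    if exclude_singletons:
        for i in range(haps.n_sites):
            counts = haps.allele_counts(i)
            alt_total = counts[1:].sum()
            if alt_total == 1:
                mask[i] = False
    return mask


def _partition_homozygosity(classes: np.ndarray) -> float:
    """Unbiased homozygosity sum_i C(c_i,2) / C(n,2) of a partition."""
    n = classes.size
    if n < 2:
        raise ValueError("need at least two haplotypes")
    _, counts = np.unique(classes, return_counts=True)
    return float((counts * (counts - 1)).sum() / (n * (n - 1)))


def ehh_decay(
    haps: HaplotypeMatrix,
    core_set: CoreHaplotypeSet,
    core_id: int,
    direction: str,
    effects: dict[int, object] | None = None,
    exclude_singletons: bool = True,
) -> EHHCurve:
    """EHH decay for one core haplotype, moving away from the core.

    At each successive included site, carriers are partitioned by their
    haplotype string from the core edge out to that site and
    EHH = sum_i C(c_i, 2) / C(n, 2) over partition class sizes c_i.
    EHH is 1 at the core by construction and non-increasing outward.
    """
    if direction not in ("upstream", "downstream"):
        raise ValueError("direction must be 'upstream' or 'downstream'")
    carriers = core_set.carriers[core_id]
    n = carriers.size
    if n < 2:
        raise ValueError("need at least two carriers of the core haplotype")
    included = _included_site_mask(haps, effects, exclude_singletons)
    pos = haps.positions
    start, end = core_set.interval
    if direction == "downstream":
        rows = np.nonzero((pos >= end) & included)[0]
    else:
        rows = np.nonzero((pos < start) & included)[0][::-1]

    classes = np.zeros(n, dtype=np.int64)  # partition ids; all together at core
    next_id = 1
    positions_out = []
    ehh_out = []
    for r in rows:
        alleles = haps.codes[r, carriers]
        new_classes = np.empty(n, dtype=np.int64)
        seen: dict[tuple[int, int], int] = {}
        for k in range(n):
            key = (int(classes[k]), int(alleles[k]))
            if key not in seen:
                seen[key] = next_id
                next_id += 1
            new_classes[k] = seen[key]
        classes = new_classes
        positions_out.append(pos[r])
        ehh_out.append(_partition_homozygosity(classes))
    return EHHCurve(
        core_id=core_id,
        direction=direction,
        positions=np.array(positions_out),
        ehh=np.array(ehh_out),
        n_carriers=n,
    )


# ----------------------------------------------------- window homozygosity


def haplotype_homozygosity(haps: HaplotypeMatrix, rows: np.ndarray, subset: np.ndarray) -> float:
    """H = sum_i c_i (c_i - 1) / (n (n - 1)) over distinct-haplotype classes."""
    subset = np.asarray(subset)
    if subset.size < 2:
        raise ValueError("subset must contain at least two haplotypes")
    if rows.size == 0:
        return 1.0
    sub = haps.codes[np.ix_(rows, subset)]
    _, classes = np.unique(sub, axis=1, return_inverse=True)
    return _partition_homozygosity(classes)


def window_homozygosity(
    haps: HaplotypeMatrix,
    windows: list[tuple[int, int]],
    subset: np.ndarray,
) -> pd.DataFrame:
    """Moving-window haplotype homozygosity for a haplotype subset.

    Windows are (start, end) 1-based end-exclusive intervals; a window
    with no variant sites is perfectly homozygous (H = 1).
    """
    if not windows:
        raise ValueError("no windows given")
    out = []
    for start, end in windows:
        rows = haps.site_index_in(start, end)
        out.append(
            dict(
                start=start,
                end=end,
                n_sites=int(rows.size),
                homozygosity=haplotype_homozygosity(haps, rows, subset),
            )
        )
    return pd.DataFrame(out)


def divergence_region_scan(
    haps: HaplotypeMatrix,
    group_a: np.ndarray,
    group_b: np.ndarray,
    windows: list[tuple[int, int]],
) -> tuple[pd.DataFrame, list[dict]]:
    """Fixed differences between two haplotype groups, per window.

    A site counts when group A is fixed for one allele and group B fixed
    for a different one.  Contiguous windows with a non-zero count are
    merged into reported divergence tracts (start, end, n_fixed).
    Detects e.g. a gene-conversion segment separating two otherwise
    identical sweep groups.
    """
    group_a = np.asarray(group_a)
    group_b = np.asarray(group_b)
    if group_a.size == 0 or group_b.size == 0:
        raise ValueError("both groups must be non-empty")
    fixed_site = np.zeros(haps.n_sites, dtype=bool)
    for i in range(haps.n_sites):
        a = haps.codes[i, group_a]
        b = haps.codes[i, group_b]
        if (a == a[0]).all() and (b == b[0]).all() and a[0] != b[0]:
            fixed_site[i] = True
    rows_fixed = np.nonzero(fixed_site)[0]
    pos_fixed = haps.positions[rows_fixed]

    records = []
    for start, end in windows:
        count = int(np.count_nonzero((pos_fixed >= start) & (pos_fixed < end)))
        records.append(dict(start=start, end=end, n_fixed=count))
    frame = pd.DataFrame(records)

    tracts: list[dict] = []
    current: dict | None = None
    for rec in records:
        if rec["n_fixed"] > 0:
            if current is None:
                current = dict(start=rec["start"], end=rec["end"], n_fixed=rec["n_fixed"])
            else:
                current["end"] = rec["end"]
                current["n_fixed"] += rec["n_fixed"]
        else:
            if current is not None:
                current["length"] = current["end"] - current["start"]
                tracts.append(current)
                current = None
    if current is not None:
        current["length"] = current["end"] - current["start"]
        tracts.append(current)
    return frame, tracts


# ------------------------------------------------------- shared lengths


@dataclass
class GeneticMap:
    """Piecewise-constant recombination map in cM/Mb.

    ``segments`` is a list of (start, end, rate_cM_per_Mb) with 1-based
    end-exclusive intervals covering the analysed region; the default
    single segment applies one constant rate everywhere.
    """

    segments: list[tuple[int, int, float]]

    @classmethod
    def constant(cls, start: int, end: int, rate: float = 1.0) -> "GeneticMap":
        return cls(segments=[(start, end, rate)])

    def __post_init__(self) -> None:
        self.segments = sorted(self.segments)
        for (_, e1, r1), (s2, _, _) in zip(self.segments, self.segments[1:]):
            if s2 != e1:
                raise ValueError("map segments must tile the region contiguously")
        if any(r < 0 for _, _, r in self.segments):
            raise ValueError("negative recombination rate")

    @property
    def span(self) -> tuple[int, int]:
        return self.segments[0][0], self.segments[-1][1]

    def cumulative_cm(self, pos: float) -> float:
        """Genetic position in cM from the map start (clamped to the span)."""
        start, end = self.span
        pos = min(max(pos, start), end)
        total = 0.0
        for s, e, rate in self.segments:
            if pos <= s:
                break
            total += (min(pos, e) - s) * rate / 1e6
        return total

    def cm_between(self, a: float, b: float) -> float:
        return abs(self.cumulative_cm(b) - self.cumulative_cm(a))


@dataclass
class SharedLengthResult:
    """Pairwise shared-haplotype lengths (cM) around a core, with a
    percentile-bootstrap CI on the median."""

    label: str
    lengths_cm: np.ndarray
    median_cm: float
    ci: tuple[float, float]
    ci_level: float
    bootstrap_reps: int
    seed: int
    n_censored: int  # pairs identical to a region edge


def shared_haplotype_lengths(
    haps: HaplotypeMatrix,
    carriers: np.ndarray,
    core: tuple[int, int],
    genetic_map: GeneticMap,
    effects: dict[int, object] | None = None,
    exclude_singletons: bool = True,
    bootstrap_reps: int = 2000,
    ci_level: float = 0.95,
    seed: int = 0,
    label: str = "",
) -> SharedLengthResult:
    """Genetic-map length of the haplotype shared by each carrier pair.

    For each unordered pair, the flanks are extended independently from
    the core edges until the first mismatch at an included site; the
    shared interval runs from the last matching point upstream to the
    first mismatch downstream and its length is measured in cM.  Pairs
    identical out to a region edge are censored at the edge and counted
    in ``n_censored``.
    """
    carriers = np.asarray(carriers)
    if carriers.size < 2:
        raise ValueError("need at least two carriers")
    included = _included_site_mask(haps, effects, exclude_singletons)
    pos = haps.positions
    start, end = core
    rows_down = np.nonzero((pos >= end) & included)[0]
    rows_up = np.nonzero((pos < start) & included)[0][::-1]
    map_start, map_end = genetic_map.span

    lengths = []
    n_censored = 0
    codes = haps.codes
    for i, j in combinations(carriers, 2):
        censored = False
        # downstream flank: first mismatching included site
        down_limit = float(map_end)
        mism = np.nonzero(codes[rows_down, i] != codes[rows_down, j])[0]
        if mism.size:
            down_limit = float(pos[rows_down[mism[0]]])
        else:
            censored = True
        up_limit = float(map_start)
        mism = np.nonzero(codes[rows_up, i] != codes[rows_up, j])[0]
        if mism.size:
            up_limit = float(pos[rows_up[mism[0]]])
        else:
            censored = True
        lengths.append(genetic_map.cm_between(up_limit, down_limit))
        n_censored += censored
    lengths = np.array(lengths)

    rng = np.random.default_rng(seed)
    medians = np.empty(bootstrap_reps)
    for r in range(bootstrap_reps):
        medians[r] = np.median(rng.choice(lengths, size=lengths.size, replace=True))
    alpha = (1 - ci_level) / 2
    ci = (float(np.quantile(medians, alpha)), float(np.quantile(medians, 1 - alpha)))
    return SharedLengthResult(
        label=label,
        lengths_cm=lengths,
        median_cm=float(np.median(lengths)),
        ci=ci,
        ci_level=ci_level,
        bootstrap_reps=bootstrap_reps,
        seed=seed,
        n_censored=int(n_censored),
    )


# -------------------------------------------- first-detection correlation


def detection_year_correlation(
    groups: dict[str, tuple[float, float]],
) -> tuple[float, float, bool]:
    """Pearson correlation of first-detection year vs median shared length.

    ``groups`` maps group label -> (first_year, median_length_cm).
    Returns (r, two-sided p, defined); zero variance in either variable
    flags the result undefined rather than producing NaN.
    """
    if len(groups) < 3:
        raise ValueError("need at least three groups")
    years = np.array([v[0] for v in groups.values()], dtype=float)
    lengths = np.array([v[1] for v in groups.values()], dtype=float)
    if np.allclose(years, years[0]) or np.allclose(lengths, lengths[0]):
        return float("nan"), float("nan"), False
    r, p = stats.pearsonr(years, lengths)
    return float(r), float(p), True
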
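"""Trisomy meiotic-origin classification and crossover-landscape comparison.

Trisomies inherit two chromosome copies from one parent; whether those
copies are distinct ("both parental homologs", BPH) or identical ("single
parental homolog", SPH) near the centromere separates meiosis-I from
meiosis-II nondisjunction, while chromosome-wide SPH points to a mitotic
origin.  This module consumes a per-region BPH/SPH z-score track (regions
bounded by crossovers; the track itself is produced by a trisomy-aware
haplotype scan and is an input here), labels regions, and applies the
decision tree:

* >= 10% of chromosome length BPH -> meiotic error
  - within meiotic: >= 50% of the pericentromeric region BPH -> MI;
    else >= 50% of it SPH -> MII; else ambiguous
* else >= 50% of chromosome length SPH -> mitotic
* else ambiguous

The pericentromeric region spans 20% of the chromosome length centered on
the centromere midpoint; acrocentric chromosomes use the q-arm side only
(10% of the length).

Crossover landscapes (pooled positions along a chromosome) are summarized
as eCDFs and compared with a two-sample Kolmogorov-Smirnov statistic whose
p-value is computed by permutation — exhaustively over all assignments of
the combined sample when feasible, otherwise by seeded Monte Carlo.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Literal, Sequence

import numpy as np

Z_BPH_SPH = 1.96
MEIOTIC_BPH_FRACTION = 0.10
MITOTIC_SPH_FRACTION = 0.50
PERICENTROMERIC_FRACTION = 0.50
PERI_REGION_FRACTION = 0.20  # of chromosome length; halved for acrocentrics
MAX_EXACT_COMBINATIONS = 200_000


@dataclass(frozen=True)
class TractRegion:
    """A crossover-bounded region with its aggregate BPH/SPH z-score."""

    start: int
    end: int
    z: float

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class TractTrack:
    """Per-region z-score track for one trisomic chromosome."""

    chrom: str
    chrom_length: int
    centromere: tuple[int, int]
    acrocentric: bool
    regions: tuple[TractRegion, ...]
    coverage: float  # window-coverage fraction C of the underlying scan

    def __post_init__(self) -> None:
        regions = tuple(sorted(self.regions, key=lambda r: r.start))
        object.__setattr__(self, "regions", regions)
        for a, b in zip(regions, regions[1:]):
            if b.start < a.end:
                raise ValueError(
                    f"overlapping regions [{a.start},{a.end}) and [{b.start},{b.end})"
                )


@dataclass(frozen=True)
class MeioticErrorCall:
    """Origin call for one trisomy with its supporting fractions."""

    call: Literal["MI", "MII", "mitotic", "ambiguous"]
    bph_fraction: float
    sph_fraction: float
    peri_bph_fraction: float
    peri_sph_fraction: float


def label_region(z: float, threshold: float = Z_BPH_SPH) -> str:
    """BPH above +threshold, SPH below -threshold, otherwise ambiguous."""
    if z > threshold:
        return "BPH"
    if z < -threshold:
        return "SPH"
    return "ambiguous"


def label_regions(track: TractTrack, threshold: float = Z_BPH_SPH) -> list[str]:
    return [label_region(r.z, threshold) for r in track.regions]


def pericentromeric_interval(
    chrom_length: int,
    centromere: tuple[int, int],
    acrocentric: bool = False,
) -> tuple[int, int]:
    """The centromere-centered region used for the MI/MII distinction.

    Non-acrocentric: 20% of the chromosome length centered on the
    centromere midpoint, clipped to the chromosome.  Acrocentric: the
    q-arm side only — 10% of the chromosome length extending from the
    centromere's q-side (distal) edge.
    """
    c_start, c_end = centromere
    if not (0 <= c_start < c_end <= chrom_length):
        raise ValueError(f"centromere {centromere} outside [0,{chrom_length})")
    if acrocentric:
        lo = c_end
        hi = min(chrom_length, c_end + int(round(0.5 * PERI_REGION_FRACTION * chrom_length)))
        return lo, hi
    mid = 0.5 * (c_start + c_end)
    half = 0.5 * PERI_REGION_FRACTION * chrom_length
    return max(0, int(round(mid - half))), min(chrom_length, int(round(mid + half)))


def _overlap(a_start: float, a_end: float, b_start: float, b_end: float) -> float:
    return max(0.0, min(a_end, b_end) - max(a_start, b_start))


def classify_error(
    track: TractTrack,
    threshold: float = Z_BPH_SPH,
    min_coverage: float = 0.5,
) -> MeioticErrorCall:
    """Apply the MI/MII/mitotic decision tree to a labeled tract track.

    Fractions are length-weighted.  Chromosome-wide fractions are over the
    chromosome length; pericentromeric fractions are over the part of the
    pericentromeric interval covered by labeled regions.  Tracks with
    window coverage C below ``min_coverage`` are excluded upstream and
    raise here.
    """
    if track.coverage < min_coverage:
        raise ValueError(
            f"window coverage C={track.coverage:.2f} below {min_coverage}; "
            "sample excluded from origin classification"
        )
    labels = label_regions(track, threshold)
    L = track.chrom_length
    bph_len = sum(r.length for r, lab in zip(track.regions, labels) if lab == "BPH")
    sph_len = sum(r.length for r, lab in zip(track.regions, labels) if lab == "SPH")
    peri = pericentromeric_interval(L, track.centromere, track.acrocentric)
    peri_cov = sum(_overlap(r.start, r.end, *peri) for r in track.regions)
    peri_bph = sum(
        _overlap(r.start, r.end, *peri)
        for r, lab in zip(track.regions, labels)
        if lab == "BPH"
    )
    peri_sph = sum(
        _overlap(r.start, r.end, *peri)
        for r, lab in zip(track.regions, labels)
        if lab == "SPH"
    )
    bph_frac = bph_len / L
    sph_frac = sph_len / L
    peri_bph_frac = peri_bph / peri_cov if peri_cov > 0 else 0.0
    peri_sph_frac = peri_sph / peri_cov if peri_cov > 0 else 0.0

    if bph_frac >= MEIOTIC_BPH_FRACTION:
        if peri_bph_frac >= PERICENTROMERIC_FRACTION:
            call = "MI"
        elif peri_sph_frac >= PERICENTROMERIC_FRACTION:
            call = "MII"
        else:
            call = "ambiguous"
    elif sph_frac >= MITOTIC_SPH_FRACTION:
        call = "mitotic"
    else:
        call = "ambiguous"
    return MeioticErrorCall(
        call=call,
        bph_fraction=bph_frac,
        sph_fraction=sph_frac,
        peri_bph_fraction=peri_bph_frac,
        peri_sph_fraction=peri_sph_frac,
    )


# ---------------------------------------------------------------------------
# crossover landscapes: eCDF and permutation KS test


@dataclass(frozen=True)
class CrossoverDistribution:
    """Pooled crossover positions along one chromosome."""

    positions: np.ndarray
    chrom_length: int

    def __post_init__(self) -> None:
        pos = np.sort(np.asarray(self.positions, dtype=float))
        if pos.size == 0:
            raise ValueError("empty crossover distribution")
        if pos[0] < 0 or pos[-1] >= self.chrom_length:
            raise ValueError("positions outside [0, L)")
        object.__setattr__(self, "positions", pos)

    def ecdf(self, query: float | np.ndarray) -> np.ndarray | float:
        """Right-continuous eCDF: fraction of crossovers at or before query."""
        q = np.asarray(query, dtype=float)
        out = np.searchsorted(self.positions, q, side="right") / self.positions.size
        return float(out) if out.ndim == 0 else out


def ks_statistic(sample1: np.ndarray, sample2: np.ndarray) -> float:
    """D = sup |eCDF1 - eCDF2|, evaluated at the pooled points."""
    s1 = np.sort(np.asarray(sample1, dtype=float))
    s2 = np.sort(np.asarray(sample2, dtype=float))
    pooled = np.concatenate([s1, s2])
    c1 = np.searchsorted(s1, pooled, side="right") / s1.size
    c2 = np.searchsorted(s2, pooled, side="right") / s2.size
    return float(np.abs(c1 - c2).max())


def ks_permutation(
    sample1: Sequence[float],
    sample2: Sequence[float],
    mode: Literal["exact", "monte-carlo"] = "exact",
    n_permutations: int = 10_000,
    seed: int | None = None,
    max_exact: int = MAX_EXACT_COMBINATIONS,
) -> tuple[float, float]:
    """Two-sample KS test with a permutation p-value.

    Exact mode enumerates all C(n1+n2, n1) assignments of the combined
    sample into two groups of the original sizes; the p-value is the
    proportion of assignments with D >= D_observed (the observed assignment
    is always among them).  Monte-carlo mode draws seeded random
    assignments and includes the observed one in the numerator and
    denominator.
    """
    s1 = np.asarray(sample1, dtype=float)
    s2 = np.asarray(sample2, dtype=float)
    if s1.size == 0 or s2.size == 0:
        raise ValueError("both samples must be non-empty")
    d_obs = ks_statistic(s1, s2)
    combined = np.concatenate([s1, s2])
    n1, n_total = s1.size, combined.size
    if mode == "exact":
        n_comb = math.comb(n_total, n1)
        if n_comb > max_exact:
            raise ValueError(
                f"{n_comb} assignments exceed exact-mode limit {max_exact}; "
                "use monte-carlo mode"
            )
        hits = 0
        idx_all = frozenset(range(n_total))
        for subset in combinations(range(n_total), n1):
            g1 = combined[list(subset)]
            g2 = combined[list(idx_all - set(subset))]
            if ks_statistic(g1, g2) >= d_obs - 1e-12:
                hits += 1
        return d_obs, hits / n_comb
    if mode != "monte-carlo":
        raise ValueError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(seed)
    hits = 1  # the observed assignment
    for _ in range(n_permutations):
        perm = rng.permutation(n_total)
        if ks_statistic(combined[perm[:n1]], combined[perm[n1:]]) >= d_obs - 1e-12:
            hits += 1
    return d_obs, hits / (n_permutations + 1)
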
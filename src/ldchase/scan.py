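"""Per-window bootstrap LLR estimation and crossover detection.

Within each adaptive window, read subsets are repeatedly drawn without
replacement (m-out-of-n bootstrap) — at most 6 reads from the monosomy and
at most 12 from the disomy (6 per homolog) — and the log-likelihood ratio
gamma of the unmatched over the matched hypothesis is computed for each
subsample.  The per-window mean and Bessel-corrected variance summarize the
window.  Windows are then aggregated into larger bins whose confidence
interval classifies them as matched / unmatched / ambiguous, and crossovers
are detected as significant local extrema of the cumulative sum of window
means: a local maximum marks an unmatched-to-matched transition, a local
minimum the reverse.  The confidence kappa of a call is the smaller of the
two flanking cumulative z-scores.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from ldchase.models import (
    MAX_MONOSOMY_READS,
    HomologDistributionPair,
    UninformativeSubsample,
    window_llr,
)
from ldchase.reads import SampleReads
from ldchase.windows import GenomicWindow

DEFAULT_BOOTSTRAP_M = 100
DEFAULT_Z_CLASSIFY = 1.96
DEFAULT_Z_CALL = 1.96
DEFAULT_MIN_FLANK_WINDOWS = 15  # delta


class ScanError(ValueError):
    """Raised for invalid scan inputs."""


class AllSubsamplesUninformative(RuntimeError):
    """Every bootstrap draw had zero likelihood under both hypotheses."""


@dataclass(frozen=True)
class BootstrapEstimate:
    """Bootstrap summary of one window: mean gamma and its variance."""

    window: GenomicWindow
    gamma_mean: float
    gamma_var: float
    m: int


@dataclass(frozen=True)
class BinSummary:
    """Aggregate of consecutive windows inside one fixed-size bin."""

    start: int
    end: int
    n_windows: int
    gamma_sum: float  # Gamma_bin
    var_sum: float  # Var(Gamma_bin), by the Bienaymé formula
    classification: str = "unclassified"

    @property
    def gamma_mean(self) -> float:
        return self.gamma_sum / self.n_windows

    @property
    def gamma_mean_var(self) -> float:
        return self.var_sum / self.n_windows**2


@dataclass(frozen=True)
class CumulativeTrack:
    """Prefix sums of per-window mean LLRs (y) and variances (v)."""

    midpoints: np.ndarray
    starts: np.ndarray
    ends: np.ndarray
    y: np.ndarray
    v: np.ndarray

    def __len__(self) -> int:
        return len(self.y)


@dataclass(frozen=True)
class CrossoverCall:
    """A detected haplotype-matching transition at one genomic window."""

    window_index: int
    chrom: str
    start: int
    end: int
    direction: str  # "unmatched->matched" (local max) or "matched->unmatched"
    kappa: float
    recovered: bool = False

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.start + self.end)


# ---------------------------------------------------------------------------
# bootstrap


def bootstrap_window(
    window: GenomicWindow,
    mono: SampleReads,
    di: SampleReads,
    pair: HomologDistributionPair,
    m: int = DEFAULT_BOOTSTRAP_M,
    rng: np.random.Generator | None = None,
    cap_per_homolog: int = MAX_MONOSOMY_READS,
    max_attempts_factor: int = 10,
) -> BootstrapEstimate:
    """m-out-of-n bootstrap of the window LLR.

    Each iteration draws, without replacement and with equal probabilities,
    up to ``cap_per_homolog`` monosomy reads and up to ``2*cap_per_homolog``
    disomy reads from the window's informative reads, then evaluates gamma.
    When a pool holds more than one read, at most pool-1 reads are drawn so
    that subsamples genuinely vary (m-out-of-n resampling requires drawing
    fewer reads than are available).  Uninformative subsamples are redrawn
    (capped at ``max_attempts_factor * m`` total attempts, after which the
    window is rejected).  Identical subsamples share one LLR evaluation.
    """
    if m < 2:
        raise ScanError("bootstrap needs m >= 2 (variance undefined otherwise)")
    if rng is None:
        rng = np.random.default_rng()
    mono_by_id = {r.read_id: r for r in mono.reads}
    di_by_id = {r.read_id: r for r in di.reads}
    a_pool = [mono_by_id[i] for i in window.mono_read_ids]
    b_pool = [di_by_id[i] for i in window.di_read_ids]
    n_a = min(cap_per_homolog, max(1, len(a_pool) - 1))
    n_b = min(2 * cap_per_homolog, max(1, len(b_pool) - 1))
    gammas: list[float] = []
    cache: dict[tuple, float | None] = {}
    attempts = 0
    limit = max_attempts_factor * m
    while len(gammas) < m:
        if attempts >= limit:
            raise AllSubsamplesUninformative(
                f"window [{window.start},{window.end}): {attempts} draws, "
                f"{len(gammas)} informative"
            )
        attempts += 1
        a_idx = tuple(sorted(rng.choice(len(a_pool), size=n_a, replace=False)))
        b_idx = tuple(sorted(rng.choice(len(b_pool), size=n_b, replace=False)))
        key = (a_idx, b_idx)
        if key not in cache:
            a = [a_pool[i].observation_set for i in a_idx]
            b = [b_pool[i].observation_set for i in b_idx]
            try:
                cache[key] = window_llr(a, b, pair).gamma
            except UninformativeSubsample:
                cache[key] = None
        gamma = cache[key]
        if gamma is None:
            continue
        gammas.append(gamma)
    arr = np.array(gammas)
    return BootstrapEstimate(
        window=window,
        gamma_mean=float(arr.mean()),
        gamma_var=float(arr.var(ddof=1)),
        m=m,
    )


# ---------------------------------------------------------------------------
# bins


def aggregate_bin(
    estimates: Sequence[BootstrapEstimate], start: int, end: int
) -> BinSummary:
    """Sum window means and variances inside one bin (Bienaymé formula)."""
    if not estimates:
        raise ScanError("cannot aggregate an empty bin")
    return BinSummary(
        start=start,
        end=end,
        n_windows=len(estimates),
        gamma_sum=float(sum(e.gamma_mean for e in estimates)),
        var_sum=float(sum(e.gamma_var for e in estimates)),
    )


def classify_bin(summary: BinSummary, z: float = DEFAULT_Z_CLASSIFY) -> str:
    """Classify a bin by where its confidence interval lies.

    CI = gamma_mean_bin +/- z*sqrt(Var(gamma_mean_bin)).  Entirely positive
    (gamma favors unmatched) -> "unmatched"; entirely negative ->
    "matched"; spanning zero -> "ambiguous".
    """
    if z < 0:
        raise ScanError("z must be >= 0")
    mean = summary.gamma_mean
    half = z * math.sqrt(summary.gamma_mean_var)
    if mean - half > 0:
        return "unmatched"
    if mean + half < 0:
        return "matched"
    return "ambiguous"


def bin_track(
    estimates: Sequence[BootstrapEstimate],
    bin_bp: int,
    z: float = DEFAULT_Z_CLASSIFY,
    chrom_length: int | None = None,
) -> list[BinSummary]:
    """Tile the chromosome with fixed bins and classify each non-empty one."""
    if bin_bp <= 0:
        raise ScanError("bin size must be positive")
    by_bin: dict[int, list[BootstrapEstimate]] = {}
    for e in estimates:
        by_bin.setdefault(int(e.window.midpoint // bin_bp), []).append(e)
    out = []
    for idx in sorted(by_bin):
        summary = aggregate_bin(by_bin[idx], idx * bin_bp, (idx + 1) * bin_bp)
        out.append(
            BinSummary(
                start=summary.start,
                end=summary.end,
                n_windows=summary.n_windows,
                gamma_sum=summary.gamma_sum,
                var_sum=summary.var_sum,
                classification=classify_bin(summary, z),
            )
        )
    return out


# ---------------------------------------------------------------------------
# cumulative track and crossover detection


def cumulative_track(estimates: Sequence[BootstrapEstimate]) -> CumulativeTrack:
    """Prefix sums y_n of window means and v_n of window variances."""
    starts = [e.window.start for e in estimates]
    if any(b < a for a, b in zip(starts, starts[1:])):
        raise ScanError("estimates must be sorted by window start")
    return CumulativeTrack(
        midpoints=np.array([e.window.midpoint for e in estimates]),
        starts=np.array(starts, dtype=np.int64),
        ends=np.array([e.window.end for e in estimates], dtype=np.int64),
        y=np.cumsum([e.gamma_mean for e in estimates]),
        v=np.cumsum([e.gamma_var for e in estimates]),
    )


def _flank_z(track: CumulativeTrack, i: int, j: int) -> float:
    """(y_j - y_i) / sqrt(v_j - v_i), guarding zero variance increments."""
    dv = track.v[j] - track.v[i]
    dy = track.y[j] - track.y[i]
    if dv <= 0:
        return math.inf if dy > 0 else (-math.inf if dy < 0 else 0.0)
    return float(dy / math.sqrt(dv))


def _flank_z_array(dy: np.ndarray, dv: np.ndarray) -> np.ndarray:
    """Elementwise dy/sqrt(dv) with the zero-variance-increment guard."""
    out = np.where(dy > 0, math.inf, np.where(dy < 0, -math.inf, 0.0))
    pos = dv > 0
    out[pos] = dy[pos] / np.sqrt(dv[pos])
    return out


def _candidate_kappas(
    track: CumulativeTrack, j: int, delta: int
) -> tuple[float, float]:
    """(kappa as local maximum, kappa as local minimum) for window j.

    A maximum at j requires flanking windows i < j < k such that j is the
    argmax of y over (i, k), with a rise on the left —
    (y_j-y_i)/sqrt(v_j-v_i) — and a fall on the right —
    (y_j-y_k)/sqrt(v_k-v_j) — both at least z; kappa is the smaller of the
    two flank z-scores at their best admissible i and k.  The argmax
    condition restricts i (k) to lie after (before) the nearest window
    whose y exceeds y_j.  Flanks must span at least ``delta`` windows.
    """
    y, v = track.y, track.v
    n = len(y)

    def bounded(limit_lo: int, limit_hi_excl: int, as_max: bool) -> float:
        # best min-flank kappa for an extremum at j within exceedance bounds
        lo_i, hi_i = limit_lo, j - delta  # inclusive range for i
        lo_k, hi_k = j + delta, limit_hi_excl - 1
        if lo_i > hi_i or lo_k > hi_k:
            return -math.inf
        zl = _flank_z_array(y[j] - y[lo_i : hi_i + 1], v[j] - v[lo_i : hi_i + 1])
        zr = _flank_z_array(y[j] - y[lo_k : hi_k + 1], v[lo_k : hi_k + 1] - v[j])
        if as_max:
            return min(float(zl.max()), float(zr.max()))
        return min(float(-zl.min()), float(-zr.min()))

    # nearest exceedances of y_j on each side (strict) bound the region in
    # which j is the arg-extremum
    higher_left = -1
    for i in range(j - 1, -1, -1):
        if y[i] > y[j]:
            higher_left = i
            break
    higher_right = n
    for k in range(j + 1, n):
        if y[k] > y[j]:
            higher_right = k
            break
    lower_left = -1
    for i in range(j - 1, -1, -1):
        if y[i] < y[j]:
            lower_left = i
            break
    lower_right = n
    for k in range(j + 1, n):
        if y[k] < y[j]:
            lower_right = k
            break
    kappa_max = bounded(higher_left + 1, higher_right, as_max=True)
    kappa_min = bounded(lower_left + 1, lower_right, as_max=False)
    return kappa_max, kappa_min


def detect_crossovers(
    track: CumulativeTrack,
    chrom: str = "",
    z: float = DEFAULT_Z_CALL,
    delta: int = DEFAULT_MIN_FLANK_WINDOWS,
    recover: bool = True,
) -> list[CrossoverCall]:
    """Call crossovers at significant local extrema of the cumulative LLR.

    The scan walks the track left to right, committing alternating local
    extrema of y.  A maximum at window j is committed once flanking
    windows i < j <= k exist with j the argmax of y over the region, a
    rise (y_j - y_i)/sqrt(v_j - v_i) >= z with j - i >= delta, and a fall
    (y_j - y_k)/sqrt(v_k - v_j) >= z with k - j >= delta; i anchors at the
    lowest y since the previous call.  Minima are mirrored.  The committed
    call's kappa is the smaller of its two best admissible flank z-scores.

    When the track makes a deeper same-type excursion after a committed
    call (the intervening opposite extremum was too weak or too narrow for
    z and delta), the deeper extremum is also emitted and the skipped
    opposite extremum between the same-type pair is recovered by
    optimizing (y_k - y_n)/sqrt(v_k - v_n) - (y_n - y_i)/sqrt(v_n - v_i)
    over interior windows (``recover=True``); recovered and
    alternation-restoring calls are flagged and may fall below z.
    """
    if z <= 0:
        raise ScanError("calling threshold z must be > 0")
    if delta < 1:
        raise ScanError("delta must be >= 1")
    n = len(track)
    if n < 2 * delta + 1:
        return []
    y = track.y

    raw_calls: list[tuple[int, int, bool]] = []  # (index, sign, extra)
    seg_start = 0
    last_idx: int | None = None
    last_sign = 0
    pos = 1
    while pos < n:
        committed = False
        for sign in (1, -1) if last_sign == 0 else (-last_sign,):
            seg = y[seg_start : pos + 1]
            if sign == 1:
                j = seg_start + int(np.argmax(seg[:-1]))
                i = seg_start + int(np.argmin(y[seg_start : j + 1]))
            else:
                j = seg_start + int(np.argmin(seg[:-1]))
                i = seg_start + int(np.argmax(y[seg_start : j + 1]))
            if i >= j or j - i < delta or pos - j < delta:
                continue
            rise = sign * _flank_z(track, i, j)
            fall = sign * -_flank_z(track, j, pos)
            if rise < z or fall < z:
                continue
            # i is a deeper same-type excursion past the previous call:
            # emit it so the skipped extremum between the pair is
            # recoverable
            if last_idx is not None and i != last_idx and recover:
                raw_calls.append((i, -sign, True))
            raw_calls.append((j, sign, False))
            last_idx, last_sign = j, sign
            seg_start = j
            committed = True
            break
        pos += 1
        if committed:
            pos = max(pos, last_idx + 1)
    if not raw_calls:
        return []

    calls: list[tuple[int, int, float, bool]] = []
    for j, sign, extra in raw_calls:
        kappa_max, kappa_min = _candidate_kappas(track, j, delta)
        kappa = kappa_max if sign == 1 else kappa_min
        calls.append((j, sign, float(kappa), extra))

    if recover:
        augmented: list[tuple[int, int, float, bool]] = []
        for prev, cur in zip(calls, calls[1:]):
            augmented.append(prev)
            if prev[1] == cur[1]:
                j = recover_skipped(track, prev[0], cur[0], maxima=(prev[1] == 1))
                kappa = min(
                    abs(_flank_z(track, prev[0], j)),
                    abs(_flank_z(track, j, cur[0])),
                )
                augmented.append((j, -prev[1], kappa, True))
        augmented.append(calls[-1])
        calls = augmented

    return [
        CrossoverCall(
            window_index=j,
            chrom=chrom,
            start=int(track.starts[j]),
            end=int(track.ends[j]),
            direction="unmatched->matched" if sign == 1 else "matched->unmatched",
            kappa=float(kappa),
            recovered=rec,
        )
        for j, sign, kappa, rec in calls
    ]


def recover_skipped(
    track: CumulativeTrack, i: int, k: int, maxima: bool = True
) -> int:
    """Locate the extremum skipped between two same-type accepted extrema.

    Between two maxima at i < k the skipped minimum is the interior window
    maximizing (y_k - y_n)/sqrt(v_k - v_n) - (y_n - y_i)/sqrt(v_n - v_i);
    between two minima the argmin replaces the argmax.  Ties break to the
    lowest index.
    """
    if k <= i + 1:
        raise ScanError(f"no interior window between {i} and {k}")
    best_j = -1
    best_val = -math.inf if maxima else math.inf
    for j in range(i + 1, k):
        val = _flank_z(track, j, k) - _flank_z(track, i, j)
        if (maxima and val > best_val) or (not maxima and val < best_val):
            best_val = val
            best_j = j
    return best_j
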
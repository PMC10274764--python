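"""Adaptive, non-overlapping genomic windows sized by local coverage.

Chromosomes are tiled by a forward scan over the informative reads of the
monosomic reference sample and the disomic test sample simultaneously.  A
window closes as soon as it holds at least ``b`` monosomy reads and ``2b``
disomy reads (the disomy carries two homologs, so an even per-homolog read
count requires twice the reads).  A forming window is dismissed — not
emitted — when the gap between consecutive informative reads of either
sample exceeds 100 kbp, or when the window stretches to 350 kbp without
meeting its read quota; scanning then restarts at the read after the
trigger.  Window sizes therefore adapt to local depth of coverage, which
absorbs GC-driven coverage heterogeneity and variable SNP density.

The fraction of a chromosome covered by emitted windows, C = sum(l_w)/L,
doubles as a joint depth-and-library-complexity metric: samples (and in
particular candidate reference monosomies) with C < 0.5 are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from ldchase.reads import ReadRecord, SampleReads

MAX_WINDOW_BP = 350_000
MAX_GAP_BP = 100_000
MIN_COVERAGE_FRACTION = 0.5


class WindowError(ValueError):
    """Raised for invalid window configurations or inputs."""


@dataclass(frozen=True)
class WindowSpec:
    """Window-construction parameters.

    ``min_mono_reads`` is b: each window needs >= b monosomy and >= 2b
    disomy informative reads.  ``score_threshold`` is the priority-score
    cut that defines "informative".
    """

    min_mono_reads: int = 2
    max_window_bp: int = MAX_WINDOW_BP
    max_gap_bp: int = MAX_GAP_BP
    score_threshold: int = 1

    def __post_init__(self) -> None:
        if self.min_mono_reads < 1:
            raise WindowError("min_mono_reads (b) must be >= 1")
        if self.max_window_bp <= 0 or self.max_gap_bp <= 0:
            raise WindowError("window/gap lengths must be positive")

    @property
    def min_di_reads(self) -> int:
        return 2 * self.min_mono_reads


@dataclass
class GenomicWindow:
    """A closed window: 0-based half-open interval plus member read ids."""

    chrom: str
    start: int
    end: int
    mono_read_ids: tuple[str, ...]
    di_read_ids: tuple[str, ...]

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.start + self.end)


@dataclass(frozen=True)
class CoverageMetric:
    """Fraction of chromosome length covered by emitted windows."""

    fraction: float
    chrom_length: int
    window_lengths: tuple[int, ...]


def build_windows(
    mono: SampleReads, di: SampleReads, spec: WindowSpec = WindowSpec()
) -> list[GenomicWindow]:
    """Greedy forward scan producing non-overlapping adaptive windows.

    ``mono``/``di`` must already be filtered to informative reads (score >=
    spec.score_threshold is re-checked here for safety).  The window closes
    at the end coordinate of the read that satisfies the last unmet count.
    """
    if mono.chrom != di.chrom:
        raise WindowError(
            f"samples on different chromosomes: {mono.chrom} vs {di.chrom}"
        )
    if mono.ploidy != 1 or di.ploidy != 2:
        raise WindowError("build_windows expects a ploidy-1 and a ploidy-2 sample")
    tagged: list[tuple[ReadRecord, bool]] = [
        (r, True) for r in mono.reads if r.score >= spec.score_threshold
    ] + [(r, False) for r in di.reads if r.score >= spec.score_threshold]
    tagged.sort(key=lambda t: (t[0].start, t[0].read_id))

    windows: list[GenomicWindow] = []
    cur_mono: list[ReadRecord] = []
    cur_di: list[ReadRecord] = []
    window_start: int | None = None
    floor = -1  # windows may not extend left of this (non-overlap)

    def reset() -> None:
        nonlocal cur_mono, cur_di, window_start
        cur_mono, cur_di, window_start = [], [], None

    for read, is_mono in tagged:
        if read.start < floor:
            # read belongs to an already-emitted window's territory; it can
            # still count toward the new window only from the floor onward —
            # we simply skip it to keep windows disjoint
            continue
        if window_start is None:
            window_start = read.start
        # gap rule, evaluated within each sample independently
        prev = (cur_mono if is_mono else cur_di)
        if prev and read.start - prev[-1].end > spec.max_gap_bp:
            reset()
            window_start = read.start
        elif read.end - window_start > spec.max_window_bp:
            # would exceed the length cap without having met the quota
            reset()
            window_start = read.start
        (cur_mono if is_mono else cur_di).append(read)
        if (
            len(cur_mono) >= spec.min_mono_reads
            and len(cur_di) >= spec.min_di_reads
        ):
            end = read.end
            windows.append(
                GenomicWindow(
                    chrom=mono.chrom,
                    start=window_start,
                    end=end,
                    mono_read_ids=tuple(r.read_id for r in cur_mono),
                    di_read_ids=tuple(r.read_id for r in cur_di),
                )
            )
            floor = end
            reset()
    return windows


def coverage_fraction(
    windows: Sequence[GenomicWindow], chrom_length: int
) -> CoverageMetric:
    """C = sum of window lengths over chromosome length (Bienaymé-free)."""
    ordered = sorted(windows, key=lambda w: w.start)
    for a, b in zip(ordered, ordered[1:]):
        if b.start < a.end:
            raise WindowError(
                f"overlapping windows: [{a.start},{a.end}) and [{b.start},{b.end})"
            )
    for w in ordered:
        if w.start < 0 or w.end > chrom_length:
            raise WindowError(f"window [{w.start},{w.end}) outside [0,{chrom_length})")
    lengths = tuple(w.length for w in windows)
    return CoverageMetric(
        fraction=sum(lengths) / chrom_length,
        chrom_length=chrom_length,
        window_lengths=lengths,
    )


def select_reference(
    candidates: Iterable[tuple[str, CoverageMetric]],
    min_fraction: float = MIN_COVERAGE_FRACTION,
) -> str | None:
    """Pick the monosomic sample with the highest window coverage C.

    Candidates below ``min_fraction`` are excluded; ties break to the
    lexicographically smallest sample id.  Returns None if all fall below.
    """
    eligible = [
        (sid, cm.fraction) for sid, cm in candidates if cm.fraction >= min_fraction
    ]
    if not eligible:
        return None
    return min(eligible, key=lambda t: (-t[1], t[0]))[0]
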
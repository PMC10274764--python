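"""Haplotype-matching likelihood models and their log-likelihood ratio.

Given m reads from a monosomic reference chromosome (A-reads) and n reads
from a disomic sibling (B-reads), two hypotheses are compared:

* **matched** — one of the disomy's homologs is the monosomic haplotype.
  A B-read then comes from the shared haplotype with probability 1/2, in
  which case its alleles co-occur with the A-alleles on one molecule and
  are scored by their joint (haplotype) frequency.
* **unmatched** — the disomy shares no homolog with the monosomy, so the
  A-reads are independent of the B-reads and the joint probability
  factorizes.

For a single read from each sample this is

    P_matched   = 1/2 f(A,B) + 1/2 f(A) f(B)
    P_unmatched = f(A) f(B)

and in general (m A-reads, n B-reads, frequency function F):

    P_matched   = (1/2)^n  sum_{S subset of {1..n}}  F(A_all u B_S) F(B_Sc)
    P_unmatched = F(A_all) * (1/2)^n sum_S F(B_S) F(B_Sc)

i.e. the disomy model with one homolog's distribution replaced by the
*g*-distribution g(X) = F(A_1..A_m, X).  The log-likelihood ratio

    gamma = log(P_unmatched / P_matched)

is positive when the evidence favors unmatched haplotypes.

Frequencies are exact panel counts.  Each (site, allele) pair maps to a
bitmask over a population's haplotype rows; a conjunction of alleles is
the AND of masks and its frequency the popcount over the row count, so the
2^n assignment sums reduce to vectorized AND + popcount sweeps.  When a
required joint frequency is exactly zero but each constituent allele is
present in the panel, the frequency is floored (see
:class:`FrequencyFunction`) so finite-panel sampling zeros and sequencing
errors do not produce infinite LLRs.  If both hypotheses are zero even
after flooring, the read subsample is uninformative and the caller
redraws.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Callable, Iterable, Sequence

import numpy as np

from ldchase.panel import AncestryComposition, PanelError, ReferencePanel

#: Hard cap on disomy reads per likelihood evaluation: 6 per homolog.
MAX_DISOMY_READS = 12
#: Hard cap on monosomy reads (single homolog).
MAX_MONOSOMY_READS = 6

ObservationSet = frozenset[tuple[int, int]]


class UninformativeSubsample(ValueError):
    """Both hypotheses have zero likelihood; the subsample carries no signal."""


@dataclass(frozen=True)
class _ReadInfo:
    """Per-population haplotype bitmasks of one read's allele conjunction."""

    masks: tuple[np.ndarray, ...]  # uint64 words per population
    alleles_present: bool  # every constituent allele individually present
    empty: bool


class FrequencyFunction:
    """Effective joint-frequency evaluator over a reference panel.

    Computes F(obs) = sum_i alpha_i f_i(obs) by exact haplotype counting:
    each (site, allele) pair maps to a bitmask of carrying haplotype rows,
    a conjunction of alleles is the AND of masks, and the frequency is the
    popcount divided by the population's haplotype count.

    ``floor`` replaces an exact-zero joint frequency whenever every
    constituent allele is individually present in the panel — the
    conjunction is then plausibly a real but unsampled (or misread)
    haplotype rather than an impossible one.  The default is
    (1/(2 N_hap))^2, well below any observable frequency, so flooring
    prevents infinite log-likelihood ratios without letting impossible
    haplotype combinations compete with sampled ones.
    """

    def __init__(
        self,
        panel: ReferencePanel,
        composition: AncestryComposition,
        floor: float | None = None,
    ) -> None:
        self.panel = panel
        self.composition = composition
        self._alphas: list[float] = []
        self._sizes: list[int] = []
        self._rows: list[np.ndarray] = []
        self._full: list[np.ndarray] = []
        for pop, alpha in composition.components:
            rows = panel.population_rows(pop)
            if rows.size < 2:
                raise PanelError(f"population {pop!r} has < 2 haplotypes")
            self._alphas.append(alpha)
            self._sizes.append(int(rows.size))
            self._rows.append(rows)
            self._full.append(self._pack(np.ones(rows.size, dtype=np.uint8)))
        self.n_populations = len(self._alphas)
        self._masks: list[dict[tuple[int, int], np.ndarray]] = [
            {} for _ in self._rows
        ]
        self._info_cache: dict[ObservationSet, _ReadInfo] = {}
        if floor is None:
            floor = (1.0 / (2.0 * panel.n_haplotypes)) ** 2
        self.floor = floor

    @staticmethod
    def _pack(bits: np.ndarray) -> np.ndarray:
        """Pack a boolean row vector into little-endian uint64 words."""
        packed = np.packbits(bits.astype(np.uint8), bitorder="little")
        pad = (-len(packed)) % 8
        if pad:
            packed = np.concatenate([packed, np.zeros(pad, dtype=np.uint8)])
        return packed.view(np.uint64)

    def _mask(self, pop_idx: int, pos: int, allele: int) -> np.ndarray:
        masks = self._masks[pop_idx]
        key = (pos, allele)
        m = masks.get(key)
        if m is None:
            col = self.panel.haplotypes[self._rows[pop_idx], self.panel.site_index(pos)]
            m = self._pack(col == allele)
            masks[key] = m
        return m

    def read_info(self, observations: ObservationSet) -> _ReadInfo:
        """Precompute the bitmask conjunction of one read's observations."""
        cached = self._info_cache.get(observations)
        if cached is not None:
            return cached
        if not observations:
            info = _ReadInfo(tuple(self._full), True, True)
            self._info_cache[observations] = info
            return info
        masks = []
        for p in range(self.n_populations):
            m = self._full[p]
            for pos, allele in observations:
                m = m & self._mask(p, pos, allele)
            masks.append(m)
        present = all(
            any(
                int(np.bitwise_count(self._mask(p, pos, allele)).sum())
                for p in range(self.n_populations)
            )
            for pos, allele in observations
        )
        info = _ReadInfo(tuple(masks), present, False)
        self._info_cache[observations] = info
        return info

    def combine(self, a: _ReadInfo, b: _ReadInfo) -> _ReadInfo:
        return _ReadInfo(
            tuple(x & y for x, y in zip(a.masks, b.masks)),
            a.alleles_present and b.alleles_present,
            a.empty and b.empty,
        )

    def value(self, info: _ReadInfo) -> float:
        """Frequency of a precomputed conjunction, floor applied."""
        if info.empty:
            return 1.0
        v = 0.0
        for p in range(self.n_populations):
            v += (
                self._alphas[p]
                * int(np.bitwise_count(info.masks[p]).sum())
                / self._sizes[p]
            )
        if v > 0.0:
            return v
        return self.floor if info.alleles_present else 0.0

    def subset_frequencies(
        self, infos: Sequence[_ReadInfo], extra: _ReadInfo | None = None
    ) -> np.ndarray:
        """F(extra u union of reads in S) for every subset S of the reads.

        Returns an array of length 2^n indexed by the subset bitmask.
        The doubling sweep computes all conjunctions in n vectorized ANDs.
        """
        n = len(infos)
        base = extra if extra is not None else self.read_info(frozenset())
        values = np.zeros(1 << n)
        for p in range(self.n_populations):
            words = len(self._full[p])
            combined = np.empty((1 << n, words), dtype=np.uint64)
            combined[0] = base.masks[p]
            for r in range(n):
                block = 1 << r
                np.bitwise_and(
                    combined[:block], infos[r].masks[p], out=combined[block : 2 * block]
                )
            counts = np.bitwise_count(combined).sum(axis=1, dtype=np.int64)
            values += self._alphas[p] * counts / self._sizes[p]
        # floor: subsets whose every constituent allele is present panel-wide
        bad = 0
        for r, info in enumerate(infos):
            if not info.alleles_present:
                bad |= 1 << r
        idx = np.arange(1 << n)
        presentable = (idx & bad) == 0
        if extra is not None and not extra.alleles_present:
            presentable[:] = False
        zero = values == 0.0
        values[zero & presentable] = self.floor
        if extra is None or extra.empty:
            values[0] = 1.0 if base.empty else self.value(base)
        return values

    def subset_frequencies_pair(
        self, infos: Sequence[_ReadInfo], extra: _ReadInfo
    ) -> tuple[np.ndarray, np.ndarray]:
        """(F(union of S), F(extra u union of S)) for every subset S.

        Shares the subset-conjunction masks between the plain sweep and
        the extra-conditioned sweep, which halves the work of evaluating
        both haplotype-matching hypotheses on one read set.
        """
        n = len(infos)
        base_vals = np.zeros(1 << n)
        extra_vals = np.zeros(1 << n)
        for p in range(self.n_populations):
            words = len(self._full[p])
            combined = np.empty((1 << n, words), dtype=np.uint64)
            combined[0] = self._full[p]
            for r in range(n):
                block = 1 << r
                np.bitwise_and(
                    combined[:block], infos[r].masks[p], out=combined[block : 2 * block]
                )
            scale = self._alphas[p] / self._sizes[p]
            base_vals += scale * np.bitwise_count(combined).sum(axis=1, dtype=np.int64)
            extra_vals += scale * np.bitwise_count(
                combined & extra.masks[p]
            ).sum(axis=1, dtype=np.int64)
        bad = 0
        for r, info in enumerate(infos):
            if not info.alleles_present:
                bad |= 1 << r
        idx = np.arange(1 << n)
        presentable = (idx & bad) == 0
        base_vals[(base_vals == 0.0) & presentable] = self.floor
        base_vals[0] = 1.0
        if not extra.alleles_present:
            presentable[:] = False
        extra_vals[(extra_vals == 0.0) & presentable] = self.floor
        if extra.empty:
            extra_vals[0] = 1.0
        return base_vals, extra_vals

    def raw(self, observations: Iterable[tuple[int, int]]) -> float:
        """Un-floored effective joint frequency (exact count mixture)."""
        obs = frozenset(observations)
        if not obs:
            return 1.0
        v = 0.0
        for p in range(self.n_populations):
            m = self._full[p]
            for pos, allele in obs:
                m = m & self._mask(p, pos, allele)
            v += self._alphas[p] * int(np.bitwise_count(m).sum()) / self._sizes[p]
        return v

    def __call__(self, observations: Iterable[tuple[int, int]]) -> float:
        """Effective joint frequency of an observation set, floor applied."""
        obs = frozenset(observations)
        return self.value(self.read_info(obs))


@dataclass
class HomologDistributionPair:
    """Frequency distributions for the disomy's two homologs.

    Non-admixed and distant-admixed samples use the same (possibly
    ancestry-mixed) distribution for both homologs.  Recent admixture
    assigns each homolog its own parental population; ``d1`` must be the
    distribution of the homolog potentially shared with the monosomy.
    """

    d1: FrequencyFunction
    d2: FrequencyFunction

    @classmethod
    def from_composition(
        cls,
        panel: ReferencePanel,
        composition: AncestryComposition,
        floor: float | None = None,
    ) -> "HomologDistributionPair":
        f = FrequencyFunction(panel, composition, floor=floor)
        return cls(f, f)

    @classmethod
    def recent_admixture(
        cls,
        panel: ReferencePanel,
        shared_population: str,
        other_population: str,
        floor: float | None = None,
    ) -> "HomologDistributionPair":
        return cls(
            FrequencyFunction(
                panel, AncestryComposition.single(shared_population), floor=floor
            ),
            FrequencyFunction(
                panel, AncestryComposition.single(other_population), floor=floor
            ),
        )


@dataclass(frozen=True)
class LlrResult:
    """Log-likelihood ratio gamma = log(P_unmatched/P_matched) and operands."""

    gamma: float
    p_matched: float
    p_unmatched: float


def _as_sets(reads: Iterable) -> list[ObservationSet]:
    out = []
    for r in reads:
        if isinstance(r, frozenset):
            out.append(r)
        elif hasattr(r, "observation_set"):
            out.append(r.observation_set)
        else:
            out.append(frozenset(r))
    return out


def disomy_likelihood(
    b_reads: Sequence,
    d1: Callable[[ObservationSet], float],
    d2: Callable[[ObservationSet], float],
) -> float:
    """Probability of n disomy reads under random homolog assignment.

    (1/2)^n sum over all 2^n assignments S of d1(union of S-reads) *
    d2(union of complement).  Reads assigned to the same homolog have
    their alleles scored jointly (same molecule); the sum is exact.
    ``d1``/``d2`` are any callables over observation sets with value 1 on
    the empty set (a :class:`FrequencyFunction` qualifies).
    """
    b = _as_sets(b_reads)
    n = len(b)
    if n > MAX_DISOMY_READS:
        raise ValueError(f"{n} disomy reads exceed cap {MAX_DISOMY_READS}")
    if n == 0:
        return 1.0
    total = 0.0
    indices = range(n)
    for k in range(n + 1):
        for subset in combinations(indices, k):
            chosen = set(subset)
            in_s = frozenset().union(*(b[i] for i in subset)) if subset else frozenset()
            comp = [b[i] for i in indices if i not in chosen]
            in_c = frozenset().union(*comp) if comp else frozenset()
            total += d1(in_s) * d2(in_c)
    return total * 0.5**n


def _check_counts(m: int, n: int, what: str) -> None:
    if not (1 <= m <= MAX_MONOSOMY_READS):
        raise ValueError(
            f"{what} model needs 1..{MAX_MONOSOMY_READS} monosomy reads, got {m}"
        )
    if not (1 <= n <= MAX_DISOMY_READS):
        raise ValueError(
            f"{what} model needs 1..{MAX_DISOMY_READS} disomy reads, got {n}"
        )


def matched_likelihood(
    a_reads: Sequence,
    b_reads: Sequence,
    pair: HomologDistributionPair,
) -> float:
    """Likelihood that the monosomy haplotype is one of the disomy's homologs.

    Substitutes the g-distribution g(X) = F(A_1..A_m, X) for the shared
    homolog in the disomy model, so every assignment term carries the
    joint frequency of the A-alleles with that homolog's B-alleles.
    """
    a = _as_sets(a_reads)
    b = _as_sets(b_reads)
    _check_counts(len(a), len(b), "matched")
    a_all = frozenset().union(*a)
    a_info = pair.d1.read_info(a_all)
    b_infos = [pair.d1.read_info(r) for r in b]
    n = len(b)
    g_vals = pair.d1.subset_frequencies(b_infos, extra=a_info)
    if pair.d2 is pair.d1:
        f_vals = pair.d1.subset_frequencies(b_infos)
    else:
        f_vals = pair.d2.subset_frequencies(
            [pair.d2.read_info(r) for r in b]
        )
    full = (1 << n) - 1
    idx = np.arange(1 << n)
    return float(np.dot(g_vals, f_vals[full ^ idx]) * 0.5**n)


def unmatched_likelihood(
    a_reads: Sequence,
    b_reads: Sequence,
    pair: HomologDistributionPair,
) -> float:
    """Likelihood that the monosomy shares no homolog with the disomy.

    The A-reads decouple from the B-reads: F(A_1..A_m) times the plain
    disomy model of the B-reads.
    """
    a = _as_sets(a_reads)
    b = _as_sets(b_reads)
    _check_counts(len(a), len(b), "unmatched")
    a_all = frozenset().union(*a)
    f_a = pair.d1.value(pair.d1.read_info(a_all))
    n = len(b)
    v1 = pair.d1.subset_frequencies([pair.d1.read_info(r) for r in b])
    if pair.d2 is pair.d1:
        v2 = v1
    else:
        v2 = pair.d2.subset_frequencies([pair.d2.read_info(r) for r in b])
    full = (1 << n) - 1
    idx = np.arange(1 << n)
    return float(f_a * np.dot(v1, v2[full ^ idx]) * 0.5**n)


def window_llr(
    a_reads: Sequence,
    b_reads: Sequence,
    pair: HomologDistributionPair,
) -> LlrResult:
    """Log-likelihood ratio comparing the two hypotheses for one read set.

    gamma = log(P_unmatched / P_matched); positive gamma supports
    unmatched haplotypes.  Raises :class:`UninformativeSubsample` when
    either hypothesis has zero likelihood (observed alleles absent from
    the panel can zero both; the flooring makes a one-sided zero all but
    impossible, but it is guarded the same way).

    The two hypotheses share the plain disomy subset sweep, which is
    computed once here rather than delegating to the two single-hypothesis
    functions.
    """
    a = _as_sets(a_reads)
    b = _as_sets(b_reads)
    _check_counts(len(a), len(b), "llr")
    n = len(b)
    a_all = frozenset().union(*a)
    a_info = pair.d1.read_info(a_all)
    b_infos = [pair.d1.read_info(r) for r in b]
    v1, g_vals = pair.d1.subset_frequencies_pair(b_infos, a_info)
    if pair.d2 is pair.d1:
        v2 = v1
    else:
        v2 = pair.d2.subset_frequencies([pair.d2.read_info(r) for r in b])
    rev = np.arange((1 << n) - 1, -1, -1)  # complement index: full ^ s
    p_m = float(np.dot(g_vals, v2[rev]) * 0.5**n)
    p_u = float(pair.d1.value(a_info) * np.dot(v1, v2[rev]) * 0.5**n)
    if p_m == 0.0 or p_u == 0.0:
        raise UninformativeSubsample(
            "zero likelihood for this read subsample"
        )
    return LlrResult(
        gamma=math.log(p_u / p_m), p_matched=p_m, p_unmatched=p_u
    )
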
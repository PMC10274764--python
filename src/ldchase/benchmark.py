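"""Simulation benchmarks: classification accuracy, localization, attribution, ROC.

These are the study-condition experiments the method is validated with:
synthetic 500-haplotype coalescent panels, 0.05x-per-homolog 75 bp reads,
matched/unmatched sibling pairs, planted crossovers, and four-sibling
families sharing one monosomic reference.  The same routines back the
acceptance script and the simulation-recovery tests; problem sizes are
arguments so callers can trade replicates for runtime.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from ldchase.evaluate import anchored_auc, balanced_rates
from ldchase.panel import AncestryComposition, ReferencePanel
from ldchase.pipeline import RunConfig, scan_pair
from ldchase.scan import bin_track, classify_bin
from ldchase.siblings import attribute, cluster_crossovers
from ldchase.simulate import (
    TrioScenario,
    simulate_family,
    simulate_pair,
)

#: Operating point for crossover localization: more reads per window give
#: each window a stronger, lower-variance LLR at the cost of coarser
#: windows — the right trade for changepoint mapping, where the flanking
#: regions already span delta windows.
LOCALIZATION_MIN_MONO_READS = 10


def _composition(panel: ReferencePanel) -> AncestryComposition:
    return AncestryComposition.single(str(panel.populations[0]))


def classification_benchmark(
    panel: ReferencePanel,
    n_pairs: int,
    coverage: float = 0.05,
    chrom_length: int | None = None,
    bin_bp: int = 2_000_000,
    config: RunConfig | None = None,
    seed: int = 0,
) -> dict:
    """Classify bins of matched and unmatched breakpoint-free pairs.

    Simulates ``n_pairs`` pairs per scenario and classifies every bin at
    the configured z.  Returns counts and the accuracy among classified
    (non-ambiguous) bins.
    """
    if chrom_length is None:
        chrom_length = int(panel.positions[-1]) + 1
    config = config or RunConfig(seed=0)
    comp = _composition(panel)
    seeds = np.random.SeedSequence(seed).spawn(2 * n_pairs)
    correct = wrong = ambiguous = 0
    per_pair = []
    for idx in range(2 * n_pairs):
        label = "matched" if idx % 2 == 0 else "unmatched"
        child = np.random.default_rng(seeds[idx])
        sc = TrioScenario(
            label, coverage=coverage, seed=int(child.integers(2**31))
        )
        pair = simulate_pair(panel, sc, chrom_length)
        result = scan_pair(
            pair.mono, pair.di, panel, comp, config,
            rng=child, chrom_length=chrom_length,
        )
        for b in result.bins:
            if b.classification == "ambiguous":
                ambiguous += 1
            elif b.classification == label:
                correct += 1
            else:
                wrong += 1
        per_pair.append((label, [b.classification for b in result.bins]))
    classified = correct + wrong
    return {
        "n_correct": correct,
        "n_wrong": wrong,
        "n_ambiguous": ambiguous,
        "accuracy_classified": correct / classified if classified else float("nan"),
        "accuracy_all": correct / (classified + ambiguous)
        if classified + ambiguous
        else float("nan"),
        "per_pair": per_pair,
    }


def localization_benchmark(
    panel: ReferencePanel,
    n_replicates: int,
    coverage: float = 0.05,
    chrom_length: int | None = None,
    breakpoint_band: tuple[float, float] = (0.38, 0.62),
    config: RunConfig | None = None,
    seed: int = 0,
) -> dict:
    """Plant one crossover per pair and measure detector localization.

    Reports fractions within one and within two windows of the true
    breakpoint's window.

    Breakpoints are placed in the central ``breakpoint_band`` fraction of
    the chromosome so both flanking regions span the required delta
    windows — crossovers closer to a chromosome end are undetectable by
    construction.  Reports the fraction of replicates whose call lies in
    or adjacent to (+/- 1 window) the window containing the true
    breakpoint.
    """
    if chrom_length is None:
        chrom_length = int(panel.positions[-1]) + 1
    config = config or RunConfig(
        seed=0, min_mono_reads=LOCALIZATION_MIN_MONO_READS
    )
    comp = _composition(panel)
    seeds = np.random.SeedSequence(seed).spawn(n_replicates)
    hits = 0
    hits2 = 0
    distances = []
    n_calls_total = 0
    for rep in range(n_replicates):
        child = np.random.default_rng(seeds[rep])
        bp = int(
            child.uniform(
                breakpoint_band[0] * chrom_length,
                breakpoint_band[1] * chrom_length,
            )
        )
        sc = TrioScenario(
            "matched",
            coverage=coverage,
            seed=int(child.integers(2**31)),
            breakpoints=(bp,),
        )
        pair = simulate_pair(panel, sc, chrom_length)
        result = scan_pair(
            pair.mono, pair.di, panel, comp, config,
            rng=child, chrom_length=chrom_length,
        )
        wins = [(e.window.start, e.window.end) for e in result.estimates]
        true_idx = next(
            (i for i, (s, e) in enumerate(wins) if s <= bp < e), None
        )
        if true_idx is None and wins:
            true_idx = int(
                np.argmin([abs(0.5 * (s + e) - bp) for s, e in wins])
            )
        primary = [c for c in result.calls if not c.recovered]
        d = min(
            (abs(c.window_index - true_idx) for c in primary),
            default=None,
        )
        distances.append(d)
        n_calls_total += len(primary)
        if d is not None and d <= 1:
            hits += 1
        if d is not None and d <= 2:
            hits2 += 1
    return {
        "fraction_within_one_window": hits / n_replicates,
        "fraction_within_two_windows": hits2 / n_replicates,
        "distances": distances,
        "mean_calls_per_replicate": n_calls_total / n_replicates,
    }


def false_call_benchmark(
    panel: ReferencePanel,
    n_replicates: int,
    coverage: float = 0.05,
    chrom_length: int | None = None,
    config: RunConfig | None = None,
    seed: int = 0,
) -> dict:
    """Count crossover calls on matched-throughout pairs (should be none)."""
    if chrom_length is None:
        chrom_length = int(panel.positions[-1]) + 1
    config = config or RunConfig(
        seed=0, min_mono_reads=LOCALIZATION_MIN_MONO_READS
    )
    comp = _composition(panel)
    seeds = np.random.SeedSequence(seed).spawn(n_replicates)
    n_calls = 0
    n_matched_bins = n_bins = 0
    for rep in range(n_replicates):
        child = np.random.default_rng(seeds[rep])
        sc = TrioScenario(
            "matched", coverage=coverage, seed=int(child.integers(2**31))
        )
        pair = simulate_pair(panel, sc, chrom_length)
        result = scan_pair(
            pair.mono, pair.di, panel, comp, config,
            rng=child, chrom_length=chrom_length,
        )
        n_calls += len(result.calls)
        for b in result.bins:
            if b.classification != "ambiguous":
                n_bins += 1
                n_matched_bins += b.classification == "matched"
    return {
        "total_calls": n_calls,
        "fraction_matched_bins": n_matched_bins / n_bins if n_bins else float("nan"),
    }


def attribution_benchmark(
    panel: ReferencePanel,
    n_replicates: int,
    n_siblings: int = 4,
    coverage: float = 0.05,
    chrom_length: int | None = None,
    config: RunConfig | None = None,
    cluster_bp: float = 5_000_000.0,
    position_tol_bp: float = 1_000_000.0,
    seed: int = 0,
) -> dict:
    """Plant one reference crossover; check it is attributed to the reference.

    Each replicate simulates a family (one monosomic reference with a
    central crossover, ``n_siblings`` disomic siblings), scans every
    sibling against the reference, clusters the calls, and counts the
    replicate as correct when a reference-attributed cluster lies within
    ``position_tol_bp`` of the planted breakpoint.
    """
    if chrom_length is None:
        chrom_length = int(panel.positions[-1]) + 1
    config = config or RunConfig(seed=0, min_mono_reads=6)
    comp = _composition(panel)
    seeds = np.random.SeedSequence(seed).spawn(n_replicates)
    correct = 0
    residual_hits = 0
    for rep in range(n_replicates):
        child = np.random.default_rng(seeds[rep])
        bp = int(child.uniform(0.42 * chrom_length, 0.58 * chrom_length))
        family = simulate_family(
            panel,
            n_siblings,
            (bp,),
            coverage=coverage,
            seed=int(child.integers(2**31)),
            chrom_length=chrom_length,
        )
        callsets = {}
        for sid, di in family.siblings.items():
            res = scan_pair(
                family.mono, di, panel, comp, config,
                rng=child, chrom_length=chrom_length,
            )
            callsets[sid] = res.calls
        clusters = cluster_crossovers(callsets, cluster_bp)
        result = attribute(callsets, clusters)
        if any(
            abs(c.mean_position - bp) <= position_tol_bp
            for c in result.reference_clusters
        ):
            correct += 1
        residual_hits += sum(
            1
            for calls in result.residual.values()
            for c in calls
            if abs(c.midpoint - bp) <= position_tol_bp
        )
    return {
        "fraction_attributed_to_reference": correct / n_replicates,
        "residual_calls_at_breakpoint": residual_hits,
    }


def auc_by_coverage(
    panel: ReferencePanel,
    coverages: Sequence[float] = (0.05, 0.025, 0.013),
    n_pairs: int = 6,
    chrom_length: int | None = None,
    bin_bp: int = 2_000_000,
    config: RunConfig | None = None,
    z_grid: Sequence[float] = tuple(np.arange(0.0, 5.0001, 0.25)),
    seed: int = 0,
) -> dict:
    """Mean per-bin balanced-ROC AUC at each depth of coverage.

    For every coverage, simulates ``n_pairs`` matched and ``n_pairs``
    unmatched pairs, classifies each genomic bin over the z grid, builds
    one balanced ROC curve per bin (over simulations), and averages the
    anchored trapezoid AUCs across bins.
    """
    if chrom_length is None:
        chrom_length = int(panel.positions[-1]) + 1
    config = config or RunConfig(seed=0)
    comp = _composition(panel)
    out = {}
    root = np.random.SeedSequence(seed)
    for cov, cov_seed in zip(coverages, root.spawn(len(coverages))):
        seeds = cov_seed.spawn(2 * n_pairs)
        # summaries[(pair_index)] = (label, list of BinSummary)
        summaries = []
        for idx in range(2 * n_pairs):
            label = "matched" if idx % 2 == 0 else "unmatched"
            child = np.random.default_rng(seeds[idx])
            sc = TrioScenario(
                label, coverage=cov, seed=int(child.integers(2**31))
            )
            pair = simulate_pair(panel, sc, chrom_length)
            result = scan_pair(
                pair.mono, pair.di, panel, comp, config,
                rng=child, chrom_length=chrom_length,
            )
            raw_bins = bin_track(result.estimates, bin_bp, config.z_classify)
            summaries.append((label, {b.start: b for b in raw_bins}))
        bin_starts = sorted(
            {start for _, bins in summaries for start in bins}
        )
        aucs = []
        for start in bin_starts:
            truth = []
            rows = []
            for label, bins in summaries:
                if start in bins:
                    truth.append(label)
                    rows.append(bins[start])
            if len(set(truth)) < 2:
                continue
            btprs, bfprs = [], []
            for z in z_grid:
                preds = [classify_bin(b, z) for b in rows]
                btpr, bfpr = balanced_rates(truth, preds)
                btprs.append(btpr)
                bfprs.append(bfpr)
            aucs.append(anchored_auc(np.array(btprs), np.array(bfprs)))
        out[cov] = float(np.mean(aucs)) if aucs else float("nan")
    return out
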
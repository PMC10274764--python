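"""End-to-end orchestration: score, window, bootstrap, call, attribute.

One :class:`RunConfig` collects every tunable of the pipeline.  A single
global seed is expanded into independent per-stage, per-sample streams via
``numpy.random.SeedSequence.spawn``, so each stage is reproducible in
isolation and the whole run is deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from ldchase.models import HomologDistributionPair
from ldchase.panel import AncestryComposition, ReferencePanel
from ldchase.reads import SampleReads, score_reads, select_informative
from ldchase.scan import (
    AllSubsamplesUninformative,
    BinSummary,
    BootstrapEstimate,
    CrossoverCall,
    bin_track,
    bootstrap_window,
    cumulative_track,
    detect_crossovers,
)
from ldchase.siblings import AttributedCallset, attribute, cluster_crossovers
from ldchase.windows import (
    WindowSpec,
    build_windows,
    coverage_fraction,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """All pipeline tunables in one place.

    The defaults follow the method's operating point: f0 = 0.05 for the
    priority score, score threshold 1 (any common haplotype), b = 6
    monosomy reads per window (12 disomy: windows then hold one full
    subsample per homolog and sit on the 10-100 kbp haplotype scale at
    ~0.05x coverage), m = 100 bootstrap draws, 6-read-per-homolog
    subsampling cap, z = 1.96 for both bin classification and crossover
    calling, delta = 15 flanking windows, and 5 Mbp sibling clustering.
    """

    f0: float = 0.05
    score_threshold: int = 1
    min_mono_reads: int = 6  # b
    bootstrap_m: int = 100
    cap_per_homolog: int = 6
    bin_bp: int = 2_000_000
    z_classify: float = 1.96
    z_call: float = 1.96
    delta: int = 15
    cluster_bp: float = 5_000_000.0
    min_coverage: float = 0.5
    seed: int | None = None

    def window_spec(self) -> WindowSpec:
        return WindowSpec(
            min_mono_reads=self.min_mono_reads,
            score_threshold=self.score_threshold,
        )


@dataclass
class CaseResult:
    """Everything one reference/test comparison produces."""

    estimates: list[BootstrapEstimate]
    bins: list[BinSummary]
    calls: list[CrossoverCall]
    coverage: float
    n_windows: int
    n_failed_windows: int


def scan_pair(
    mono: SampleReads,
    di: SampleReads,
    panel: ReferencePanel,
    composition: AncestryComposition,
    config: RunConfig,
    rng: np.random.Generator | None = None,
    chrom_length: int | None = None,
) -> CaseResult:
    """Run one monosomy/disomy comparison end to end.

    Scores reads, builds adaptive windows, bootstraps each window's LLR,
    classifies bins, and detects crossovers on the cumulative track.
    """
    if rng is None:
        if config.seed is None:
            raise ValueError("RunConfig.seed must be set (or pass an rng)")
        rng = np.random.default_rng(config.seed)
    if chrom_length is None:
        chrom_length = int(panel.positions[-1]) + 1

    mono_s = select_informative(
        score_reads(mono, panel, composition, config.f0), config.score_threshold
    )
    di_s = select_informative(
        score_reads(di, panel, composition, config.f0), config.score_threshold
    )
    logger.info(
        "informative reads: mono %d/%d, di %d/%d",
        len(mono_s), len(mono), len(di_s), len(di),
    )
    windows = build_windows(mono_s, di_s, config.window_spec())
    cov = coverage_fraction(windows, chrom_length)
    logger.info("windows built: %d, coverage C=%.3f", len(windows), cov.fraction)

    pair = HomologDistributionPair.from_composition(panel, composition)
    estimates: list[BootstrapEstimate] = []
    n_failed = 0
    for w in windows:
        try:
            estimates.append(
                bootstrap_window(
                    w,
                    mono_s,
                    di_s,
                    pair,
                    m=config.bootstrap_m,
                    rng=rng,
                    cap_per_homolog=config.cap_per_homolog,
                )
            )
        except AllSubsamplesUninformative:
            n_failed += 1
    bins = bin_track(estimates, config.bin_bp, config.z_classify)
    calls: list[CrossoverCall] = []
    if estimates:
        track = cumulative_track(estimates)
        calls = detect_crossovers(
            track, chrom=mono.chrom, z=config.z_call, delta=config.delta
        )
    return CaseResult(
        estimates=estimates,
        bins=bins,
        calls=calls,
        coverage=cov.fraction,
        n_windows=len(windows),
        n_failed_windows=n_failed,
    )


def run_case(
    mono: SampleReads,
    siblings: Mapping[str, SampleReads],
    panel: ReferencePanel,
    composition: AncestryComposition,
    config: RunConfig,
    chrom_length: int | None = None,
) -> tuple[dict[str, CaseResult], AttributedCallset | None]:
    """Compare every disomic sibling against one shared reference monosomy.

    Returns per-sibling scan results and, when >= 2 siblings are present,
    the cross-sibling crossover attribution.  The reference must pass the
    window-coverage filter C >= min_coverage against each sibling; pairs
    failing it are skipped with a logged reason.
    """
    if config.seed is None:
        raise ValueError("RunConfig.seed must be set for a case run")
    seeds = np.random.SeedSequence(config.seed).spawn(len(siblings))
    results: dict[str, CaseResult] = {}
    for (sid, di), ss in zip(sorted(siblings.items()), seeds):
        result = scan_pair(
            mono,
            di,
            panel,
            composition,
            config,
            rng=np.random.default_rng(ss),
            chrom_length=chrom_length,
        )
        if result.coverage < config.min_coverage:
            logger.warning(
                "pair %s skipped: window coverage C=%.3f < %.2f",
                sid, result.coverage, config.min_coverage,
            )
            continue
        results[sid] = result
    attribution = None
    if len(results) >= 2:
        clusters = cluster_crossovers(
            {sid: r.calls for sid, r in results.items()}, config.cluster_bp
        )
        attribution = attribute(
            {sid: r.calls for sid, r in results.items()}, clusters
        )
    return results, attribution
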
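"""Generative benchmark data: synthetic panels, trios, and sparse reads.

The synthetic panel emulates the statistical features the method consumes
from a real phased cohort — biallelic SNPs with a neutral allele-frequency
spectrum and LD that decays with physical distance — by simulating
coalescent haplotypes with recombination and mutation (msprime).  Multiple
populations are modeled as demes splitting from a common ancestor, so
per-population allele frequencies differ realistically.  Haplotype count,
SNP density (mutation rate), and LD decay (recombination rate x effective
size) are configurable.

Trios follow the benchmark design: a parental chromosome (haplotype 1), a
diploid offspring carrying haplotypes 1 and 2, and an unrelated chromosome
(haplotype 3) from the same population — or, for recent admixture,
haplotypes 1 and 2 from different populations.  Reads of fixed length are
dropped uniformly along the chromosome; each read copies the alleles of
one underlying haplotype, drawn per read from a position-dependent
distribution p_h(x).  The monosomy uses p_1 = 1; the disomy uses
p_1 = p_2 = 1/2.  Planted crossovers swap which row plays the shared
haplotype for positions beyond each breakpoint, flipping the local truth
between matched and unmatched.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from ldchase.panel import ReferencePanel
from ldchase.reads import AlleleObservation, ReadRecord, SampleReads

DEFAULT_READ_LENGTH = 75


@dataclass(frozen=True)
class SyntheticPanelConfig:
    """Dimensions and population-genetic knobs of a synthetic panel.

    Defaults approximate human autosomal values: effective size 10^4,
    recombination and mutation rates ~1.2e-8 per bp per generation, which
    at 500 haplotypes yields roughly one biallelic SNP per 300 bp and LD
    decaying on the 10-100 kbp scale.  With several populations, demes
    split from a common ancestor ``split_generations`` ago (default 3000,
    roughly continental-scale divergence).
    """

    n_haplotypes: int = 500
    chrom_length: int = 10_000_000
    chrom: str = "chrS"
    populations: tuple[tuple[str, int], ...] = ()  # (label, haplotype count)
    effective_size: float = 10_000.0
    recombination_rate: float = 1.2e-8
    mutation_rate: float = 1.2e-8
    split_generations: float = 3000.0
    seed: int = 0

    def __post_init__(self) -> None:
        pops = self.populations or (("POP1", self.n_haplotypes),)
        object.__setattr__(self, "populations", tuple(pops))
        total = sum(c for _, c in self.populations)
        if total != self.n_haplotypes:
            raise ValueError(
                f"population counts sum to {total}, expected {self.n_haplotypes}"
            )
        if self.n_haplotypes < 4 or self.n_haplotypes % 2:
            raise ValueError("haplotype count must be even and >= 4")
        if any(c % 2 for _, c in self.populations):
            raise ValueError("per-population haplotype counts must be even")


@dataclass(frozen=True)
class TrioScenario:
    """One simulated monosomy/disomy sibling pair.

    ``scenario`` fixes whether the monosomy read source is the shared
    parental haplotype ("matched") or the unrelated haplotype
    ("unmatched").  ``breakpoints`` plant crossovers: past each breakpoint
    the row playing the disomy's first (shared) homolog is swapped with the
    unrelated row, flipping the local truth.
    """

    scenario: Literal["matched", "unmatched"] = "matched"
    ancestry: Literal["non-admixed", "recent-admixed"] = "non-admixed"
    coverage: float = 0.05
    read_length: int = DEFAULT_READ_LENGTH
    breakpoints: tuple[int, ...] = ()
    population: str | None = None  # None: first panel population
    second_population: str | None = None  # recent admixture only
    seed: int = 0

    def __post_init__(self) -> None:
        if self.coverage <= 0:
            raise ValueError("coverage must be > 0")
        if tuple(sorted(self.breakpoints)) != self.breakpoints:
            raise ValueError("breakpoints must be sorted")


def synthetic_panel(config: SyntheticPanelConfig) -> ReferencePanel:
    """Simulate a phased coalescent panel of biallelic SNPs.

    Haplotypes are sampled from a neutral coalescent with recombination
    (one deme, or demes splitting from a common ancestor for multiple
    populations); mutations are laid down at the configured rate and the
    variant set is restricted to biallelic sites.  Reproducible under
    ``config.seed``.
    """
    import msprime

    demography = msprime.Demography()
    for pop, _ in config.populations:
        demography.add_population(name=pop, initial_size=config.effective_size)
    if len(config.populations) > 1:
        demography.add_population(
            name="ANC", initial_size=config.effective_size
        )
        demography.add_population_split(
            time=config.split_generations,
            derived=[pop for pop, _ in config.populations],
            ancestral="ANC",
        )
    samples = [
        msprime.SampleSet(count // 2, population=pop)
        for pop, count in config.populations
    ]
    ts = msprime.sim_ancestry(
        samples=samples,
        demography=demography,
        sequence_length=config.chrom_length,
        recombination_rate=config.recombination_rate,
        random_seed=config.seed + 1,  # msprime requires a positive seed
    )
    ts = msprime.sim_mutations(
        ts, rate=config.mutation_rate, random_seed=config.seed + 2
    )
    positions: list[int] = []
    columns: list[np.ndarray] = []
    last_pos = 0
    for variant in ts.variants():
        if len(variant.alleles) != 2:
            continue  # recurrent mutation made the site multi-allelic
        pos = int(variant.site.position) + 1  # 1-based
        if pos <= last_pos:
            continue
        positions.append(pos)
        last_pos = pos
        columns.append(variant.genotypes.astype(np.uint8))
    if not positions:
        raise ValueError("simulation produced no biallelic sites")
    haplotypes = np.column_stack(columns)
    pop_of_node = {
        p.id: p.metadata.get("name", str(p.id)) for p in ts.populations()
    }
    labels = np.array(
        [pop_of_node[ts.node(u).population] for u in ts.samples()], dtype=object
    )
    rng = np.random.default_rng(config.seed)
    bases = np.array(["A", "C", "G", "T"])
    n_sites = len(positions)
    ref = bases[rng.integers(4, size=n_sites)]
    alt = bases[
        (np.searchsorted(bases, ref) + rng.integers(1, 4, size=n_sites)) % 4
    ]
    return ReferencePanel(
        chrom=config.chrom,
        positions=np.array(positions, dtype=np.int64),
        ref=ref,
        alt=alt,
        haplotypes=haplotypes,
        populations=labels,
    )


def draw_trio(
    panel: ReferencePanel,
    scenario: TrioScenario,
    rng: np.random.Generator,
) -> tuple[int, int, int]:
    """Draw (parental, second-offspring, unrelated) haplotype row indices.

    Non-admixed: three distinct rows from one population.  Recent
    admixture: rows 1 and 2 from different populations; the unrelated row
    comes from the first (shared-parent) population.
    """
    pops = list(dict.fromkeys(panel.populations.astype(str)))
    pop1 = scenario.population or pops[0]
    rows1 = panel.population_rows(pop1)
    if scenario.ancestry == "recent-admixed":
        pop2 = scenario.second_population or next(p for p in pops if p != pop1)
        if pop2 == pop1:
            raise ValueError("recent admixture needs two distinct populations")
        rows2 = panel.population_rows(pop2)
        if rows1.size < 2 or rows2.size < 1:
            raise ValueError("not enough haplotypes for a recent-admixed trio")
        h1, h3 = rng.choice(rows1, size=2, replace=False)
        h2 = rng.choice(rows2)
        return int(h1), int(h2), int(h3)
    if rows1.size < 3:
        raise ValueError(f"population {pop1!r} has < 3 haplotypes")
    h1, h2, h3 = rng.choice(rows1, size=3, replace=False)
    return int(h1), int(h2), int(h3)


def simulate_reads(
    panel: ReferencePanel,
    source_rows: Sequence[int],
    probabilities: np.ndarray,
    coverage: float,
    chrom_length: int,
    sample_id: str,
    ploidy: int,
    rng: np.random.Generator,
    read_length: int = DEFAULT_READ_LENGTH,
    breakpoints: Sequence[int] = (),
    swap_row: int | None = None,
) -> SampleReads:
    """Drop uniform reads copying alleles from per-read-drawn haplotypes.

    ``probabilities`` gives p_h per source row (summing to 1).  Total read
    count is round(ploidy * coverage * L / read_length).  With breakpoints,
    the first source row is replaced by ``swap_row`` for read midpoints in
    every second inter-breakpoint segment (odd segments), which plants
    matched/unmatched transitions at the breakpoint positions.
    """
    probabilities = np.asarray(probabilities, dtype=float)
    if abs(probabilities.sum() - 1.0) > 1e-9:
        raise ValueError(f"haplotype probabilities sum to {probabilities.sum()}")
    if breakpoints and swap_row is None:
        raise ValueError("breakpoints require a swap_row")
    n_reads = int(round(ploidy * coverage * chrom_length / read_length))
    mids = rng.uniform(0, chrom_length, size=n_reads)
    choices = rng.choice(len(source_rows), size=n_reads, p=probabilities)
    bps = np.asarray(breakpoints, dtype=float)
    reads = []
    for i in range(n_reads):
        mid = mids[i]
        start = max(0, int(mid - read_length / 2))
        end = min(chrom_length, start + read_length)
        row = source_rows[choices[i]]
        if choices[i] == 0 and bps.size:
            segment = int(np.searchsorted(bps, mid, side="right"))
            if segment % 2 == 1:
                row = swap_row
        sites = panel.sites_in(start, end)
        obs = tuple(
            AlleleObservation(int(p), int(panel.haplotypes[row, panel.site_index(p)]))
            for p in sites
        )
        reads.append(
            ReadRecord(
                read_id=f"{sample_id}_r{i}",
                chrom=panel.chrom,
                start=start,
                end=end,
                observations=obs,
            )
        )
    return SampleReads(sample_id, panel.chrom, ploidy, reads)


@dataclass(frozen=True)
class SimulatedPair:
    """A monosomy/disomy pair with ground truth for every position."""

    mono: SampleReads
    di: SampleReads
    scenario: TrioScenario
    chrom_length: int
    trio: tuple[int, int, int]

    def truth_at(self, position: float) -> str:
        """Ground-truth matching state at a genomic position."""
        if self.scenario.scenario == "unmatched":
            return "unmatched"
        segment = int(
            np.searchsorted(np.asarray(self.scenario.breakpoints), position, "right")
        )
        return "matched" if segment % 2 == 0 else "unmatched"


@dataclass(frozen=True)
class SimulatedFamily:
    """A monosomic reference plus n disomic siblings with shared truth.

    The reference chromosome is a mosaic of the two parental homologs F1
    and F2 switching at ``ref_breakpoints``; each sibling's homolog from
    the same parent is its own F1/F2 mosaic (here breakpoint-free), while
    the sibling's other homolog comes from the second parent.  A reference
    crossover therefore flips the matched/unmatched state of every
    sibling simultaneously — the signature used for attribution.
    """

    mono: SampleReads
    siblings: dict[str, SampleReads]
    ref_breakpoints: tuple[int, ...]
    chrom_length: int


def simulate_family(
    panel: ReferencePanel,
    n_siblings: int,
    ref_breakpoints: tuple[int, ...],
    coverage: float = 0.05,
    read_length: int = DEFAULT_READ_LENGTH,
    population: str | None = None,
    seed: int = 0,
    chrom_length: int | None = None,
) -> SimulatedFamily:
    """Simulate one reference monosomy and n disomic siblings.

    Haplotype rows: F1, F2 (the shared parent's homologs) plus one
    distinct row per sibling for the other parent's contribution.  The
    reference reads follow F1 and switch to F2 past each breakpoint;
    sibling homolog 1 is F1 throughout (so every reference breakpoint is
    a matched<->unmatched transition in every sibling's scan).
    """
    if chrom_length is None:
        chrom_length = int(panel.positions[-1]) + 1
    rng = np.random.default_rng(seed)
    pops = list(dict.fromkeys(panel.populations.astype(str)))
    pop = population or pops[0]
    rows = panel.population_rows(pop)
    if rows.size < 2 + n_siblings:
        raise ValueError("not enough haplotypes for the family")
    picked = rng.choice(rows, size=2 + n_siblings, replace=False)
    f1, f2 = int(picked[0]), int(picked[1])
    mono = simulate_reads(
        panel,
        [f1],
        np.array([1.0]),
        coverage,
        chrom_length,
        "mono",
        ploidy=1,
        rng=rng,
        read_length=read_length,
        breakpoints=tuple(ref_breakpoints),
        swap_row=f2 if ref_breakpoints else None,
    )
    siblings: dict[str, SampleReads] = {}
    for i in range(n_siblings):
        other = int(picked[2 + i])
        siblings[f"sib{i}"] = simulate_reads(
            panel,
            [f1, other],
            np.array([0.5, 0.5]),
            coverage,
            chrom_length,
            f"sib{i}",
            ploidy=2,
            rng=rng,
            read_length=read_length,
        )
    return SimulatedFamily(
        mono=mono,
        siblings=siblings,
        ref_breakpoints=tuple(ref_breakpoints),
        chrom_length=chrom_length,
    )


def simulate_pair(
    panel: ReferencePanel,
    scenario: TrioScenario,
    chrom_length: int | None = None,
) -> SimulatedPair:
    """Simulate one monosomy/disomy sibling pair with known truth.

    The monosomy reads come from the parental haplotype (matched scenario)
    or the unrelated haplotype (unmatched scenario); the disomy always
    carries haplotypes 1 and 2.  Breakpoints apply to the disomy's shared
    homolog, so the matched scenario with breakpoints alternates
    matched/unmatched along the chromosome.
    """
    if chrom_length is None:
        chrom_length = int(panel.positions[-1]) + 1
    rng = np.random.default_rng(scenario.seed)
    h1, h2, h3 = draw_trio(panel, scenario, rng)
    mono_source = h1 if scenario.scenario == "matched" else h3
    mono = simulate_reads(
        panel,
        [mono_source],
        np.array([1.0]),
        scenario.coverage,
        chrom_length,
        "mono",
        ploidy=1,
        rng=rng,
        read_length=scenario.read_length,
    )
    di = simulate_reads(
        panel,
        [h1, h2],
        np.array([0.5, 0.5]),
        scenario.coverage,
        chrom_length,
        "di",
        ploidy=2,
        rng=rng,
        read_length=scenario.read_length,
        breakpoints=scenario.breakpoints,
        swap_row=h3 if scenario.breakpoints else None,
    )
    return SimulatedPair(mono, di, scenario, chrom_length, (h1, h2, h3))
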
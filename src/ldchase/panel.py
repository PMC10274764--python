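"""Phased reference panels and haplotype-frequency queries.

A :class:`ReferencePanel` holds the phased biallelic-SNP haplotypes of an
external reference cohort (e.g. a 1000-Genomes-style panel) for one
chromosome, together with a population label per haplotype row.  All allele
and joint (haplotype) frequencies used by the likelihood models are exact
counts over these rows — no smoothing is applied at this layer.

The *effective* frequency generalizes a single-population frequency to an
admixed target: given an ancestry composition with weights ``alpha_i``, the
effective frequency of a set of alleles is ``sum_i alpha_i * f_i`` where
``f_i`` is the joint frequency in population *i*.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

logger = logging.getLogger(__name__)

#: An allele observation: (1-based position, allele code 0=ref / 1=alt).
Observation = tuple[int, int]


class PanelError(ValueError):
    """Raised for malformed panels or invalid panel queries."""


@dataclass(frozen=True)
class AncestryComposition:
    """Ancestry proportions of a target sample over panel populations.

    Weights must be non-negative and sum to 1 (within 1e-9).
    """

    components: tuple[tuple[str, float], ...]

    def __post_init__(self) -> None:
        if not self.components:
            raise PanelError("ancestry composition must have >= 1 population")
        for pop, w in self.components:
            if w < 0:
                raise PanelError(f"negative ancestry weight for {pop}: {w}")
        total = sum(w for _, w in self.components)
        if abs(total - 1.0) > 1e-9:
            raise PanelError(f"ancestry weights sum to {total}, expected 1")

    @classmethod
    def single(cls, population: str) -> "AncestryComposition":
        return cls(((population, 1.0),))

    @classmethod
    def of(cls, mapping: Mapping[str, float]) -> "AncestryComposition":
        return cls(tuple(mapping.items()))

    @property
    def populations(self) -> tuple[str, ...]:
        return tuple(p for p, _ in self.components)


@dataclass
class ReferencePanel:
    """Phased biallelic haplotype matrix for one chromosome.

    Parameters
    ----------
    chrom
        Chromosome identifier.
    positions
        1-based bp positions, strictly increasing.
    ref, alt
        Reference / alternative allele per site.
    haplotypes
        uint8 matrix, one row per phased haplotype, entries in {0, 1}.
    populations
        Population label per haplotype row.
    """

    chrom: str
    positions: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    haplotypes: np.ndarray
    populations: np.ndarray
    _pos_index: dict[int, int] = field(init=False, repr=False)
    _pop_rows: dict[str, np.ndarray] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.uint8)
        self.populations = np.asarray(self.populations, dtype=object)
        if self.positions.ndim != 1:
            raise PanelError("positions must be 1-D")
        if np.any(np.diff(self.positions) <= 0):
            raise PanelError("positions must be strictly increasing")
        if self.haplotypes.shape != (len(self.populations), len(self.positions)):
            raise PanelError(
                f"haplotype matrix shape {self.haplotypes.shape} inconsistent with "
                f"{len(self.populations)} rows x {len(self.positions)} sites"
            )
        if self.haplotypes.size and self.haplotypes.max() > 1:
            raise PanelError("haplotype entries must be 0/1")
        self._pos_index = {int(p): i for i, p in enumerate(self.positions)}
        self._pop_rows = {}
        for pop in np.unique(self.populations.astype(str)):
            self._pop_rows[pop] = np.flatnonzero(self.populations == pop)

    # -- basic accessors -------------------------------------------------

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_sites(self) -> int:
        return self.haplotypes.shape[1]

    def site_index(self, position: int) -> int:
        try:
            return self._pos_index[int(position)]
        except KeyError:
            raise PanelError(f"position {position} not in panel ({self.chrom})") from None

    def has_site(self, position: int) -> bool:
        return int(position) in self._pos_index

    def population_rows(self, population: str) -> np.ndarray:
        try:
            return self._pop_rows[population]
        except KeyError:
            raise PanelError(f"unknown population {population!r}") from None

    def sites_in(self, start: int, end: int) -> np.ndarray:
        """1-based positions with start <= pos < end (0-based half-open span)."""
        lo = np.searchsorted(self.positions, start + 1, side="left")
        hi = np.searchsorted(self.positions, end, side="right")
        return self.positions[lo:hi]

    def restrict(self, start: int, end: int) -> "ReferencePanel":
        """Sub-panel over the 1-based inclusive interval [start, end]."""
        lo = np.searchsorted(self.positions, start, side="left")
        hi = np.searchsorted(self.positions, end, side="right")
        if hi <= lo:
            raise PanelError(f"no biallelic sites in {self.chrom}:{start}-{end}")
        return ReferencePanel(
            chrom=self.chrom,
            positions=self.positions[lo:hi],
            ref=self.ref[lo:hi],
            alt=self.alt[lo:hi],
            haplotypes=self.haplotypes[:, lo:hi],
            populations=self.populations,
        )

    # -- frequency queries -----------------------------------------------

    def joint_frequency(
        self, population: str, observations: Iterable[Observation]
    ) -> float:
        """Fraction of a population's haplotypes carrying all listed alleles.

        The empty observation set returns 1 (vacuous conjunction), so that
        likelihood models reduce correctly when a read set is empty.
        """
        rows = self.population_rows(population)
        if rows.size < 2:
            raise PanelError(f"population {population!r} has < 2 haplotypes")
        obs = list(observations)
        if not obs:
            return 1.0
        # conflicting alleles at one site can never co-occur on a haplotype
        seen: dict[int, int] = {}
        for pos, allele in obs:
            if allele not in (0, 1):
                raise PanelError(f"allele code must be 0/1, got {allele}")
            j = self.site_index(pos)
            if j in seen and seen[j] != allele:
                return 0.0
            seen[j] = allele
        cols = np.fromiter(seen.keys(), dtype=np.int64)
        alleles = np.fromiter(seen.values(), dtype=np.uint8)
        sub = self.haplotypes[np.ix_(rows, cols)]
        return float(np.all(sub == alleles, axis=1).mean())

    def effective_frequency(
        self, composition: AncestryComposition, observations: Iterable[Observation]
    ) -> float:
        """Ancestry-weighted mixture of per-population joint frequencies."""
        obs = list(observations)
        return float(
            sum(
                w * self.joint_frequency(pop, obs)
                for pop, w in composition.components
            )
        )

    # -- cache round-trip ------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Write the panel to an NPZ cache file (lossless round-trip)."""
        np.savez_compressed(
            path,
            chrom=np.array(self.chrom),
            positions=self.positions,
            ref=np.asarray(self.ref, dtype="U"),
            alt=np.asarray(self.alt, dtype="U"),
            haplotypes=self.haplotypes,
            populations=self.populations.astype(str),
        )

    @classmethod
    def load(cls, path: str | Path) -> "ReferencePanel":
        with np.load(path, allow_pickle=False) as z:
            return cls(
                chrom=str(z["chrom"]),
                positions=z["positions"],
                ref=z["ref"],
                alt=z["alt"],
                haplotypes=z["haplotypes"],
                populations=z["populations"].astype(object),
            )


def load_population_labels(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV (sample_id, population) into a dict."""
    labels: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise PanelError(f"malformed population label line: {line!r}")
            labels[fields[0]] = fields[1]
    return labels


def load_panel(
    path: str | Path,
    chrom: str,
    population_labels: Mapping[str, str] | str | Path,
    start: int | None = None,
    end: int | None = None,
) -> ReferencePanel:
    """Load a phased VCF into a :class:`ReferencePanel`.

    Only biallelic SNPs are retained; multi-allelic sites and indels are
    excluded (their count is logged).  Every genotype must be phased —
    an unphased genotype raises an error naming the offending site.

    Parameters
    ----------
    path
        VCF/VCF.gz with phased GT for the reference cohort.
    chrom
        Chromosome to load.
    population_labels
        Mapping sample_id -> population, or path to a two-column TSV.
    start, end
        Optional 1-based inclusive interval restriction.
    """
    from cyvcf2 import VCF

    if not isinstance(population_labels, Mapping):
        population_labels = load_population_labels(population_labels)

    region = chrom
    if start is not None and end is not None:
        region = f"{chrom}:{start}-{end}"
    indexed = Path(f"{path}.tbi").exists() or Path(f"{path}.csi").exists()

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    missing = [s for s in samples if s not in population_labels]
    if missing:
        raise PanelError(f"samples without population label: {missing[:5]}")

    positions: list[int] = []
    refs: list[str] = []
    alts: list[str] = []
    columns: list[np.ndarray] = []
    n_excluded = 0
    if indexed:
        variants = vcf(region)
    else:
        variants = (v for v in vcf if v.CHROM == chrom)
    for v in variants:
        if v.CHROM != chrom:
            continue
        if start is not None and v.POS < start:
            continue
        if end is not None and v.POS > end:
            continue
        if len(v.ALT) != 1 or len(v.REF) != 1 or len(v.ALT[0]) != 1:
            n_excluded += 1
            continue
        gt = np.asarray(v.genotype.array())
        # columns: allele_0, allele_1, ..., phased flag last
        if not np.all(gt[:, -1] == 1):
            raise PanelError(f"unphased genotype at {v.CHROM}:{v.POS}")
        alleles = gt[:, :-1]
        if np.any(alleles < 0):
            raise PanelError(f"missing genotype at {v.CHROM}:{v.POS}")
        columns.append(alleles.reshape(-1).astype(np.uint8))
        positions.append(v.POS)
        refs.append(v.REF)
        alts.append(v.ALT[0])
    if n_excluded:
        logger.info("excluded %d non-biallelic-SNP sites on %s", n_excluded, chrom)
    if not positions:
        raise PanelError(f"no biallelic SNPs found in {region}")

    ploidy = columns[0].size // len(samples)
    populations = np.array(
        [population_labels[s] for s in samples for _ in range(ploidy)], dtype=object
    )
    haplotypes = np.column_stack(columns)
    return ReferencePanel(
        chrom=chrom,
        positions=np.array(positions, dtype=np.int64),
        ref=np.array(refs),
        alt=np.array(alts),
        haplotypes=haplotypes,
        populations=populations,
    )
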
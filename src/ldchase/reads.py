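"""Reduce aligned reads to allele observations at panel sites; score informativeness.

A read's *priority score* counts the common haplotypes of the reference
panel over the SNPs the read spans: enumerate all 2^n haplotypes over the
n panel SNPs the read overlaps and count those whose effective frequency
lies strictly between ``f0`` and ``1 - f0``.  The score depends only on
panel variation, never on the alleles the read actually carries; it ranks
reads by how much discriminating LD information their span can contribute.
For a read overlapping a single SNP the score is 2 when the minor allele
frequency is at least f0 and 0 otherwise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

import numpy as np

from ldchase.panel import AncestryComposition, ReferencePanel

logger = logging.getLogger(__name__)

#: Reads spanning more SNPs than this cannot be scored (2^n enumeration).
MAX_SNPS_PER_READ = 16

DEFAULT_F0 = 0.05
DEFAULT_MIN_MAPQ = 30
DEFAULT_MIN_BASEQ = 30


class ReadError(ValueError):
    """Raised for malformed read inputs."""


@dataclass(frozen=True)
class AlleleObservation:
    """One observed allele at a panel site (1-based position; 0=ref, 1=alt)."""

    position: int
    allele: int


@dataclass
class ReadRecord:
    """One sequenced molecule reduced to its panel-site observations.

    ``start``/``end`` are 0-based half-open; observations are sorted by
    position and fall inside the span.  Paired-end mates are merged into a
    single record (one molecule), spanning the union of mate spans.
    """

    read_id: str
    chrom: str
    start: int
    end: int
    observations: tuple[AlleleObservation, ...]
    score: int = 0

    def __post_init__(self) -> None:
        obs = tuple(sorted(self.observations, key=lambda o: o.position))
        object.__setattr__(self, "observations", obs)
        for o in obs:
            if not (self.start < o.position <= self.end):
                raise ReadError(
                    f"observation at {o.position} outside read span "
                    f"[{self.start}, {self.end}) (1-based check)"
                )

    @property
    def observation_set(self) -> frozenset[tuple[int, int]]:
        return frozenset((o.position, o.allele) for o in self.observations)


@dataclass
class SampleReads:
    """A sample's reads on one chromosome, with its ploidy context.

    ploidy 1 marks the monosomic/haploid reference sample, ploidy 2 the
    disomic test sample.
    """

    sample_id: str
    chrom: str
    ploidy: int
    reads: list[ReadRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.ploidy not in (1, 2):
            raise ReadError(f"ploidy must be 1 or 2, got {self.ploidy}")
        self.reads = sorted(self.reads, key=lambda r: (r.start, r.read_id))

    def __len__(self) -> int:
        return len(self.reads)


def priority_score(
    read: ReadRecord,
    panel: ReferencePanel,
    composition: AncestryComposition,
    f0: float = DEFAULT_F0,
) -> int:
    """Count common panel haplotypes over the SNPs a read spans.

    Enumerates all 2^n allele combinations over the n panel sites inside
    the read span and counts those with effective frequency strictly
    between f0 and 1-f0.  Raises if n exceeds ``MAX_SNPS_PER_READ``.
    """
    if not (0 < f0 < 0.5):
        raise ReadError(f"f0 must lie in (0, 0.5), got {f0}")
    sites = panel.sites_in(read.start, read.end)
    n = len(sites)
    if n == 0:
        return 0
    if n > MAX_SNPS_PER_READ:
        raise ReadError(
            f"read {read.read_id} spans {n} panel SNPs "
            f"(cap {MAX_SNPS_PER_READ} for 2^n enumeration)"
        )
    cols = np.array([panel.site_index(p) for p in sites], dtype=np.int64)
    # count each observed haplotype pattern once per population, then mix
    weights = np.zeros(2**n)
    powers = 1 << np.arange(n - 1, -1, -1)
    for pop, alpha in composition.components:
        rows = panel.population_rows(pop)
        sub = panel.haplotypes[np.ix_(rows, cols)]
        codes = sub @ powers
        counts = np.bincount(codes, minlength=2**n)
        weights += alpha * counts / rows.size
    return int(np.count_nonzero((weights > f0) & (weights < 1 - f0)))


def score_reads(
    sample: SampleReads,
    panel: ReferencePanel,
    composition: AncestryComposition,
    f0: float = DEFAULT_F0,
) -> SampleReads:
    """Return a copy of ``sample`` with per-read priority scores filled in."""
    scored = [
        replace(r, score=priority_score(r, panel, composition, f0))
        for r in sample.reads
    ]
    return SampleReads(sample.sample_id, sample.chrom, sample.ploidy, scored)


def select_informative(sample: SampleReads, threshold: int) -> SampleReads:
    """Keep reads whose priority score is >= threshold (order preserved)."""
    kept = [r for r in sample.reads if r.score >= threshold]
    return SampleReads(sample.sample_id, sample.chrom, sample.ploidy, kept)


# ---------------------------------------------------------------------------
# extraction from alignments / observation TSV


def extract_observations(
    alignments: str | Path,
    panel: ReferencePanel,
    sample_id: str,
    ploidy: int,
    min_mapq: int = DEFAULT_MIN_MAPQ,
    min_baseq: int = DEFAULT_MIN_BASEQ,
) -> SampleReads:
    """Reduce a BAM/CRAM to allele observations at panel sites.

    Secondary, supplementary and duplicate-flagged alignments are excluded.
    A base matching neither the ref nor the alt allele at a panel site is
    dropped from that read's observations (the read itself is kept).
    Paired-end mates sharing a read name are merged into one record whose
    span is the union of the mate spans.
    """
    import pysam

    af = pysam.AlignmentFile(str(alignments))
    if panel.chrom not in af.references:
        raise ReadError(
            f"chromosome {panel.chrom!r} not in alignment file "
            f"(references: {list(af.references)[:5]}...)"
        )
    alleles_at = {
        int(p): (str(panel.ref[i]).upper(), str(panel.alt[i]).upper())
        for i, p in enumerate(panel.positions)
    }
    merged: dict[str, dict] = {}
    for aln in af.fetch(panel.chrom):
        if aln.is_secondary or aln.is_supplementary or aln.is_duplicate:
            continue
        if aln.is_unmapped or aln.mapping_quality < min_mapq:
            continue
        obs: list[AlleleObservation] = []
        seq = aln.query_sequence or ""
        quals = aln.query_qualities
        for qpos, rpos in aln.get_aligned_pairs(matches_only=True):
            pos1 = rpos + 1  # pysam gives 0-based reference positions
            pair = alleles_at.get(pos1)
            if pair is None:
                continue
            if quals is not None and quals[qpos] < min_baseq:
                continue
            base = seq[qpos].upper()
            if base == pair[0]:
                obs.append(AlleleObservation(pos1, 0))
            elif base == pair[1]:
                obs.append(AlleleObservation(pos1, 1))
            # other bases: dropped (sequencing error or third allele)
        rec = merged.setdefault(
            aln.query_name,
            {"start": aln.reference_start, "end": aln.reference_end, "obs": []},
        )
        rec["start"] = min(rec["start"], aln.reference_start)
        rec["end"] = max(rec["end"], aln.reference_end)
        rec["obs"].extend(obs)
    reads = []
    for name, rec in merged.items():
        # mates may double-observe a site; keep one copy, drop conflicts
        by_pos: dict[int, int] = {}
        conflict: set[int] = set()
        for o in rec["obs"]:
            if o.position in by_pos and by_pos[o.position] != o.allele:
                conflict.add(o.position)
            by_pos.setdefault(o.position, o.allele)
        obs = tuple(
            AlleleObservation(p, a)
            for p, a in sorted(by_pos.items())
            if p not in conflict
        )
        reads.append(
            ReadRecord(
                read_id=name,
                chrom=panel.chrom,
                start=rec["start"],
                end=rec["end"],
                observations=obs,
            )
        )
    return SampleReads(sample_id, panel.chrom, ploidy, reads)


# ---------------------------------------------------------------------------
# portable observation TSV (alternative to BAM)

OBS_TSV_COLUMNS = ["sample_id", "chrom", "read_id", "pos", "allele"]


def write_observation_tsv(samples: Iterable[SampleReads], path: str | Path) -> None:
    """Write reads as a portable TSV: one row per observation.

    Reads with no observations appear once with pos -1 and allele ".".
    A header line of read spans is embedded as ``#span`` comment rows so
    the round-trip is lossless.
    """
    with open(path, "w") as fh:
        fh.write("\t".join(OBS_TSV_COLUMNS) + "\n")
        for s in samples:
            fh.write(f"#sample\t{s.sample_id}\t{s.chrom}\t{s.ploidy}\n")
            for r in s.reads:
                fh.write(f"#span\t{s.sample_id}\t{r.read_id}\t{r.start}\t{r.end}\n")
                if not r.observations:
                    fh.write(f"{s.sample_id}\t{r.chrom}\t{r.read_id}\t-1\t.\n")
                for o in r.observations:
                    fh.write(
                        f"{s.sample_id}\t{r.chrom}\t{r.read_id}\t{o.position}\t{o.allele}\n"
                    )


def read_observation_tsv(path: str | Path) -> list[SampleReads]:
    """Parse the observation TSV written by :func:`write_observation_tsv`."""
    meta: dict[str, tuple[str, int]] = {}
    spans: dict[tuple[str, str], tuple[int, int]] = {}
    obs: dict[tuple[str, str], list[AlleleObservation]] = {}
    order: list[tuple[str, str]] = []
    with open(path) as fh:
        header = fh.readline()
        if header.strip().split("\t") != OBS_TSV_COLUMNS:
            raise ReadError(f"unexpected observation TSV header: {header!r}")
        for lineno, line in enumerate(fh, start=2):
            fields = line.rstrip("\n").split("\t")
            if fields[0] == "#sample":
                meta[fields[1]] = (fields[2], int(fields[3]))
                continue
            if fields[0] == "#span":
                key = (fields[1], fields[2])
                spans[key] = (int(fields[3]), int(fields[4]))
                if key not in obs:
                    obs[key] = []
                    order.append(key)
                continue
            if len(fields) != 5:
                raise ReadError(f"malformed row at line {lineno}: {line!r}")
            sample_id, chrom, read_id, pos, allele = fields
            key = (sample_id, read_id)
            if key not in obs:
                obs[key] = []
                order.append(key)
            if allele == ".":
                continue
            obs[key].append(AlleleObservation(int(pos), int(allele)))
    samples: dict[str, SampleReads] = {}
    for sample_id, (chrom, ploidy) in meta.items():
        reads = [
            ReadRecord(
                read_id=read_id,
                chrom=chrom,
                start=spans[(sid, read_id)][0],
                end=spans[(sid, read_id)][1],
                observations=tuple(obs[(sid, read_id)]),
            )
            for (sid, read_id) in order
            if sid == sample_id
        ]
        samples[sample_id] = SampleReads(sample_id, chrom, ploidy, reads)
    return list(samples.values())
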
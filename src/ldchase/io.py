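"""Tabular output formats: window tracks, LLR tracks, crossover BED, clusters.

All genomic intervals in output files are 0-based half-open (BED
convention); the observation TSV (see :mod:`ldchase.reads`) uses 1-based
site positions matching the VCF panel.  Every writer has a reader whose
composition is the identity, which the test suite enforces.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import pandas as pd

from ldchase.scan import BinSummary, BootstrapEstimate, CrossoverCall
from ldchase.siblings import CrossoverCluster
from ldchase.windows import GenomicWindow


class FormatError(ValueError):
    """Raised on malformed rows, with the offending line number."""


def _read_tsv(path: str | Path, columns: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if list(df.columns) != columns:
        raise FormatError(
            f"{path}: expected columns {columns}, found {list(df.columns)}"
        )
    return df


# -- window track ------------------------------------------------------------

WINDOW_COLUMNS = ["chrom", "start", "end", "n_mono_reads", "n_di_reads"]


def write_window_track(windows: Sequence[GenomicWindow], path: str | Path) -> None:
    pd.DataFrame(
        [
            (w.chrom, w.start, w.end, len(w.mono_read_ids), len(w.di_read_ids))
            for w in windows
        ],
        columns=WINDOW_COLUMNS,
    ).to_csv(path, sep="\t", index=False)


def read_window_track(path: str | Path) -> pd.DataFrame:
    return _read_tsv(path, WINDOW_COLUMNS)


# -- per-window LLR track ----------------------------------------------------

LLR_COLUMNS = ["chrom", "start", "end", "gamma_mean", "gamma_var", "m"]


def write_llr_track(
    estimates: Sequence[BootstrapEstimate], path: str | Path
) -> None:
    pd.DataFrame(
        [
            (
                e.window.chrom,
                e.window.start,
                e.window.end,
                e.gamma_mean,
                e.gamma_var,
                e.m,
            )
            for e in estimates
        ],
        columns=LLR_COLUMNS,
    ).to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_llr_track(path: str | Path) -> pd.DataFrame:
    return _read_tsv(path, LLR_COLUMNS)


# -- bin classifications -----------------------------------------------------

BIN_COLUMNS = [
    "start",
    "end",
    "n_windows",
    "gamma_mean",
    "gamma_mean_var",
    "classification",
]


def write_bin_track(bins: Sequence[BinSummary], path: str | Path) -> None:
    pd.DataFrame(
        [
            (b.start, b.end, b.n_windows, b.gamma_mean, b.gamma_mean_var, b.classification)
            for b in bins
        ],
        columns=BIN_COLUMNS,
    ).to_csv(path, sep="\t", index=False, float_format="%.10g")


# -- crossover BED -----------------------------------------------------------

BED_COLUMNS = [
    "chrom",
    "start",
    "end",
    "name",
    "score",
    "strand",
    "direction",
    "kappa",
]


def write_crossover_bed(
    calls: Sequence[CrossoverCall], sample_id: str, path: str | Path
) -> None:
    """BED6+2: score is kappa scaled x100 and capped at 1000."""
    pd.DataFrame(
        [
            (
                c.chrom,
                c.start,
                c.end,
                sample_id,
                min(1000, int(round(100 * c.kappa))),
                ".",
                c.direction,
                c.kappa,
            )
            for c in calls
        ],
        columns=BED_COLUMNS,
    ).to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_crossover_bed(path: str | Path) -> pd.DataFrame:
    return _read_tsv(path, BED_COLUMNS)


# -- sibling attribution -----------------------------------------------------

CLUSTER_COLUMNS = ["k", "n", "lambda", "kappa_min", "mean_pos", "direction"]


def write_cluster_tsv(
    clusters: Sequence[CrossoverCluster], path: str | Path
) -> None:
    pd.DataFrame(
        [
            (c.size, c.n_embryos, c.support, c.kappa_min, c.mean_position, c.direction)
            for c in clusters
        ],
        columns=CLUSTER_COLUMNS,
    ).to_csv(path, sep="\t", index=False, float_format="%.10g")


ATTRIBUTION_COLUMNS = [
    "chrom",
    "start",
    "end",
    "name",
    "score",
    "strand",
    "direction",
    "kappa",
    "attribution",
]


def write_attributed_bed(
    reference_positions: Sequence[tuple[str, float, float, str]],
    residual: dict[str, Sequence[CrossoverCall]],
    path: str | Path,
) -> None:
    """Reference cluster means plus per-embryo residual calls in one BED."""
    rows = [
        (chrom, int(start), int(end), "reference", 0, ".", direction, 0.0, "reference")
        for chrom, start, end, direction in reference_positions
    ]
    for embryo, calls in sorted(residual.items()):
        rows.extend(
            (
                c.chrom,
                c.start,
                c.end,
                embryo,
                min(1000, int(round(100 * c.kappa))),
                ".",
                c.direction,
                c.kappa,
                "test",
            )
            for c in calls
        )
    pd.DataFrame(rows, columns=ATTRIBUTION_COLUMNS).to_csv(
        path, sep="\t", index=False, float_format="%.10g"
    )


# -- centromeres and tract tracks (landscape inputs) -------------------------

CENTROMERE_COLUMNS = ["chrom", "start", "end", "acrocentric"]


def read_centromeres(path: str | Path) -> dict[str, tuple[int, int, bool]]:
    """BED-like file: chrom, start, end, acrocentric flag (0/1)."""
    out: dict[str, tuple[int, int, bool]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise FormatError(f"{path}:{lineno}: expected 4 columns")
            try:
                out[fields[0]] = (int(fields[1]), int(fields[2]), bool(int(fields[3])))
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
    return out


TRACT_COLUMNS = ["chrom", "region_start", "region_end", "z"]


def read_tract_track(path: str | Path) -> pd.DataFrame:
    return _read_tsv(path, TRACT_COLUMNS)


# -- ROC ---------------------------------------------------------------------

ROC_COLUMNS = ["bin_start", "bin_end", "z", "btpr", "bfpr"]


def write_roc_tsv(rows: Sequence[tuple], path: str | Path) -> None:
    pd.DataFrame(rows, columns=ROC_COLUMNS).to_csv(
        path, sep="\t", index=False, float_format="%.10g"
    )
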
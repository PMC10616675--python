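"""Readers and writers for every table and sequence format the pipeline touches.

All tables are tab-separated with a required header row (comma-separated
accepted via ``sep=","``).  Missing values are written as empty fields and
read back as missing, never as zero.  Gene identity is keyed on ``gene_id``;
symbols are display-only.

Required headers
----------------
counts       ``gene_id`` plus one column per sample
annotation   ``gene_id``, ``symbol``, ``biotype``, ``length_bp``
samples      ``sample_id``, ``genotype``, ``subject``, ``time_min``
DEG table    ``gene_id``, ``log2fc``, ``padj``, ``control_mean``
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import TYPE_CHECKING, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO

from .experiment import ChaseExperiment, ValidationError

if TYPE_CHECKING:  # pragma: no cover
    from .screen import ScreenResult

__all__ = [
    "DecayIOError",
    "read_counts",
    "read_gene_annotation",
    "read_sample_sheet",
    "read_deg_table",
    "read_utr_fasta",
    "read_chase_experiment",
    "write_counts",
    "write_gene_annotation",
    "write_sample_sheet",
    "write_deg_table",
    "write_utr_fasta",
    "write_chase_experiment",
    "write_screen_tables",
]

logger = logging.getLogger(__name__)


class DecayIOError(ValueError):
    """Malformed input file; the message carries file and line context."""


def _read_table(path, sep: str, required: list[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise DecayIOError(f"file not found: {path}")
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=True, na_values=[""])
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise DecayIOError(f"{path}: missing required columns {missing}; found {list(df.columns)}")
    return df


def _lines_of(df: pd.DataFrame, mask) -> list[int]:
    # +2: one for the header, one for 1-based numbering
    return [int(i) + 2 for i in np.flatnonzero(np.asarray(mask))]


def _check_unique(df: pd.DataFrame, col: str, path) -> None:
    dup = df[col].duplicated(keep=False)
    if dup.any():
        ids = df.loc[dup, col].unique().tolist()
        raise DecayIOError(f"{path}: duplicated {col} {ids[:10]} at lines {_lines_of(df, dup)[:20]}")


def read_counts(path, sep: str = "\t") -> pd.DataFrame:
    """Read a gene x sample count matrix keyed on ``gene_id``."""
    df = _read_table(path, sep, ["gene_id"])
    _check_unique(df, "gene_id", path)
    out = df.set_index("gene_id")
    for col in out.columns:
        vals = pd.to_numeric(out[col], errors="coerce")
        bad = vals.isna() & out[col].notna()
        if bad.any():
            raise DecayIOError(f"{path}: non-numeric counts in column {col!r} at lines {_lines_of(df, bad)[:10]}")
        if (vals < 0).any():
            raise DecayIOError(f"{path}: negative counts in column {col!r} at lines {_lines_of(df, vals < 0)[:10]}")
        out[col] = vals
    logger.info("read_counts: parsed %d of %d data rows from %s", len(out), len(df), path)
    return out


def read_gene_annotation(path, sep: str = "\t") -> pd.DataFrame:
    df = _read_table(path, sep, ["gene_id", "symbol", "biotype", "length_bp"])
    _check_unique(df, "gene_id", path)
    length = pd.to_numeric(df["length_bp"], errors="coerce")
    bad = length.isna() | (length <= 0)
    if bad.any():
        raise DecayIOError(f"{path}: length_bp must be a positive number at lines {_lines_of(df, bad)[:10]}")
    out = df.set_index("gene_id")
    out["length_bp"] = length.to_numpy()
    logger.info("read_gene_annotation: parsed %d rows from %s", len(out), path)
    return out


def read_sample_sheet(path, sep: str = "\t") -> pd.DataFrame:
    df = _read_table(path, sep, ["sample_id", "genotype", "subject", "time_min"])
    _check_unique(df, "sample_id", path)
    t = pd.to_numeric(df["time_min"], errors="coerce")
    bad = t.isna() | (t < 0)
    if bad.any():
        raise DecayIOError(
            f"{path}: time_min not parseable as a non-negative number at lines {_lines_of(df, bad)[:10]}"
        )
    dup = df.duplicated(subset=["genotype", "subject", "time_min"], keep=False)
    if dup.any():
        names = df.loc[dup, "sample_id"].tolist()
        raise DecayIOError(f"{path}: samples sharing (genotype, subject, time): {names}")
    out = df.set_index("sample_id")
    out["time_min"] = t.to_numpy()
    logger.info("read_sample_sheet: parsed %d rows from %s", len(out), path)
    return out


def read_deg_table(path, sep: str = "\t") -> pd.DataFrame:
    """Differential-expression result table (externally produced)."""
    df = _read_table(path, sep, ["gene_id", "log2fc", "padj", "control_mean"])
    _check_unique(df, "gene_id", path)
    out = df.set_index("gene_id")
    for col in ("log2fc", "padj", "control_mean"):
        out[col] = pd.to_numeric(out[col], errors="coerce")
    bad = (out["padj"] < 0) | (out["padj"] > 1)
    if bad.any():
        raise DecayIOError(f"{path}: padj outside [0, 1] at lines {_lines_of(df, bad.to_numpy())[:10]}")
    return out


_RNA_COMPLEMENTABLE = set("ACGUN")


def normalize_sequence(seq: str) -> str:
    """Uppercase a nucleotide string and normalize the alphabet to RNA (T -> U)."""
    s = seq.upper().replace("T", "U")
    illegal = set(s) - _RNA_COMPLEMENTABLE
    if illegal:
        raise DecayIOError(f"illegal nucleotide characters {sorted(illegal)}")
    return s


def read_utr_fasta(path) -> dict[str, list[str]]:
    """Read 3'-UTR sequences.

    Returns a mapping ``identifier -> list of sequences``; repeated records
    for one identifier (UTR isoforms) accumulate.  Sequences are stored
    uppercase in the RNA alphabet regardless of input case or U/T usage.
    """
    path = Path(path)
    if not path.exists():
        raise DecayIOError(f"file not found: {path}")
    out: dict[str, list[str]] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        try:
            seq = normalize_sequence(str(rec.seq))
        except DecayIOError as exc:
            raise DecayIOError(f"{path}: record {rec.id}: {exc}") from exc
        out.setdefault(rec.id, []).append(seq)
    return out


def read_chase_experiment(counts_path, annotation_path, samples_path, sep: str = "\t") -> ChaseExperiment:
    """Read the three tables and assemble a validated :class:`ChaseExperiment`."""
    try:
        return ChaseExperiment(
            counts=read_counts(counts_path, sep),
            gene_annotation=read_gene_annotation(annotation_path, sep),
            sample_sheet=read_sample_sheet(samples_path, sep),
        )
    except ValidationError as exc:
        raise DecayIOError(str(exc)) from exc


# -- writers ------------------------------------------------------------


def _write(df: pd.DataFrame, path, index_label: str, sep: str = "\t") -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep=sep, index_label=index_label, na_rep="")


def write_counts(counts: pd.DataFrame, path, sep: str = "\t") -> None:
    _write(counts, path, "gene_id", sep)


def write_gene_annotation(annotation: pd.DataFrame, path, sep: str = "\t") -> None:
    _write(annotation, path, "gene_id", sep)


def write_sample_sheet(samples: pd.DataFrame, path, sep: str = "\t") -> None:
    _write(samples, path, "sample_id", sep)


def write_deg_table(table: pd.DataFrame, path, sep: str = "\t") -> None:
    _write(table, path, "gene_id", sep)


def write_utr_fasta(utrs: Mapping[str, str | list[str]], path, width: int = 60) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for name, seqs in utrs.items():
            for seq in [seqs] if isinstance(seqs, str) else seqs:
                fh.write(f">{name}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")


def write_chase_experiment(experiment: ChaseExperiment, out_dir, sep: str = "\t") -> dict[str, Path]:
    out_dir = Path(out_dir)
    paths = {
        "counts": out_dir / "counts.tsv",
        "annotation": out_dir / "annotation.tsv",
        "samples": out_dir / "samples.tsv",
    }
    write_counts(experiment.counts, paths["counts"], sep)
    write_gene_annotation(experiment.gene_annotation, paths["annotation"], sep)
    write_sample_sheet(experiment.sample_sheet, paths["samples"], sep)
    return paths


def write_screen_tables(result: "ScreenResult", out_dir, sep: str = "\t") -> dict[str, Path]:
    """Write the screen output in the supplementary-table layout.

    Emits ``screen.tsv`` (one row per retained gene: per-timepoint mean
    percent remaining and SD per genotype, per-timepoint t-test p-values,
    curve-level ANOVA p-values, binding-site flag, rank metric, half-lives,
    stabilized call) and ``filter_report.tsv`` (per-gene retention fate).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {"screen": out_dir / "screen.tsv", "filter_report": out_dir / "filter_report.tsv"}
    _write(result.table, paths["screen"], "gene_id", sep)
    report = result.filter_report.table.copy()
    report["reasons"] = report["reasons"].map(lambda r: ";".join(r) if isinstance(r, (list, tuple)) else (r or ""))
    _write(report, paths["filter_report"], "gene_id", sep)
    return paths
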
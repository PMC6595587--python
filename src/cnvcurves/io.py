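"""Readers, writers and sample filters for segmented CNV data.

The input dialects follow the TCGA legacy conventions: tab-separated SEG
files (``Sample / Chromosome / Start / End / Num_Probes / Segment_Mean``),
two-column RSEM-style normalized expression files, a four-column gene
annotation table and a per-chromosome centromere layout table.  All
coordinates are treated as 1-based, fully closed intervals (the TCGA seg
convention).
"""

from __future__ import annotations

import io as _io
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "GenomeLayout",
    "SampleBarcode",
    "normalize_chromosome",
    "parse_barcode",
    "read_seg_file",
    "write_seg_file",
    "read_expression_files",
    "read_gene_annotation",
    "read_genome_layout",
    "read_matrix",
    "write_matrix",
    "filter_samples",
]

#: chromosomes whose p arms carry no genes on the profiling platform
ACROCENTRIC = frozenset({"13", "14", "15", "21", "22"})

#: autosome labels after normalization
AUTOSOMES = frozenset(str(i) for i in range(1, 23))

SEG_COLUMNS = ["sample", "chromosome", "start", "end", "num_probes", "segment_mean"]
_SEG_REQUIRED = ["sample", "chromosome", "start", "end", "segment_mean"]


class FormatError(ValueError):
    """A file violated the expected tab-separated dialect."""


def normalize_chromosome(label: str) -> str:
    """Strip a case-insensitive ``chr`` prefix and uppercase X/Y.

    ``"chr7"`` and ``"7"`` map to the same key.
    """
    s = str(label).strip()
    if s.lower().startswith("chr"):
        s = s[3:]
    return s.upper() if s.lower() in ("x", "y") else s


# ---------------------------------------------------------------------------
# sample barcodes


@dataclass(frozen=True)
class SampleBarcode:
    """A parsed TCGA-style sample barcode.

    Sample-type code ``01`` marks a primary tumor; codes ``10``–``14`` mark
    nonmalignant controls (solid-tissue / blood normals).  Codes ``02``–``09``
    are other tumor samples, excluded by the primary filter.
    """

    full_barcode: str
    participant_id: str
    sample_type_code: str
    is_primary_tumor: bool
    is_nonmalignant: bool


def parse_barcode(barcode: str) -> SampleBarcode:
    """Parse a TCGA-style barcode such as ``TCGA-06-0187-01``."""
    fields = str(barcode).split("-")
    if len(fields) < 4:
        raise FormatError(
            f"barcode {barcode!r}: expected >= 4 dash-separated fields"
        )
    code = fields[3][:2]
    if len(code) < 2 or not code.isdigit():
        raise FormatError(
            f"barcode {barcode!r}: sample-type field {fields[3]!r} does not "
            "start with a two-digit code"
        )
    primary = code == "01"
    nonmalignant = "10" <= code <= "14"
    return SampleBarcode(
        full_barcode=str(barcode),
        participant_id="-".join(fields[:3]),
        sample_type_code=code,
        is_primary_tumor=primary,
        is_nonmalignant=nonmalignant,
    )


# ---------------------------------------------------------------------------
# SEG files


def _resolve_columns(columns: Sequence[str], required: Sequence[str]) -> dict:
    lower = {str(c).strip().lower(): c for c in columns}
    mapping = {}
    for name in required:
        if name not in lower:
            raise FormatError(f"missing required column {name!r}")
        mapping[lower[name]] = name
    return mapping


def read_seg_file(path) -> pd.DataFrame:
    """Read a tab-separated SEG file into a segment table.

    Returns a DataFrame with columns ``sample, chromosome, start, end,
    num_probes, segment_mean`` (``num_probes`` is NaN when the file lacks
    it).  Chromosome labels are normalized; row order is preserved.
    """
    raw = pd.read_csv(path, sep="\t", dtype=str, skip_blank_lines=True)
    raw.columns = [str(c).strip() for c in raw.columns]
    mapping = _resolve_columns(raw.columns, _SEG_REQUIRED)
    lower = {str(c).strip().lower(): c for c in raw.columns}
    df = raw.rename(columns=mapping)
    if "num_probes" in lower:
        df = df.rename(columns={lower["num_probes"]: "num_probes"})
    else:
        df["num_probes"] = np.nan

    for col in ("start", "end", "segment_mean", "num_probes"):
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if col != "num_probes" and bad.any():
            line = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # header is line 1
            raise FormatError(
                f"{path}: non-numeric {col!r} value {df[col].iloc[line - 2]!r} "
                f"on line {line}"
            )
        df[col] = converted
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    df["chromosome"] = df["chromosome"].map(normalize_chromosome)
    df["sample"] = df["sample"].astype(str)

    if (df["start"] < 0).any():
        raise FormatError(f"{path}: negative start position")
    if (df["start"] >= df["end"]).any():
        row = df[df["start"] >= df["end"]].iloc[0]
        raise FormatError(
            f"{path}: segment with start >= end at "
            f"{row['chromosome']}:{row['start']}-{row['end']}"
        )
    if not np.isfinite(df["segment_mean"]).all():
        raise FormatError(f"{path}: non-finite segment_mean")
    return df[SEG_COLUMNS].reset_index(drop=True)


def write_seg_file(segments: pd.DataFrame, path) -> None:
    """Write a segment table in the SEG dialect read by :func:`read_seg_file`."""
    out = segments.rename(
        columns={
            "sample": "Sample",
            "chromosome": "Chromosome",
            "start": "Start",
            "end": "End",
            "num_probes": "Num_Probes",
            "segment_mean": "Segment_Mean",
        }
    )
    cols = ["Sample", "Chromosome", "Start", "End", "Num_Probes", "Segment_Mean"]
    out[cols].to_csv(path, sep="\t", index=False, na_rep="NA")


# ---------------------------------------------------------------------------
# expression files


def read_expression_files(paths: Sequence, sample_ids: Sequence[str]) -> pd.DataFrame:
    """Assemble per-sample RSEM-style files into a genes x samples matrix.

    Each file is two-column (gene identifier, normalized value) with one
    header line.  Identifiers of the form ``SYMBOL|entrez`` are truncated at
    the first ``|``; rows whose symbol is ``?`` are dropped.  Genes absent
    from some samples get NaN.
    """
    if len(paths) != len(sample_ids):
        raise ValueError("paths and sample_ids must have the same length")
    if len(set(sample_ids)) != len(sample_ids):
        raise FormatError("duplicate sample id in sample_ids")
    columns = {}
    for path, sid in zip(paths, sample_ids):
        df = pd.read_csv(path, sep="\t", header=0)
        if df.shape[1] < 2:
            raise FormatError(f"{path}: expected two tab-separated columns")
        genes = df.iloc[:, 0].astype(str).str.split("|").str[0]
        values = pd.to_numeric(df.iloc[:, 1], errors="raise")
        if (values < 0).any():
            raise FormatError(f"{path}: negative expression value")
        keep = genes != "?"
        col = pd.Series(values[keep].to_numpy(), index=genes[keep], name=sid)
        col = col[~col.index.duplicated(keep="first")]
        columns[sid] = col
    matrix = pd.DataFrame(columns)
    matrix.index.name = "symbol"
    matrix.attrs["value_kind"] = "expression"
    return matrix


# ---------------------------------------------------------------------------
# annotation and genome layout


def read_gene_annotation(path) -> pd.DataFrame:
    """Read a 4-column annotation table (symbol, chrom, start, end).

    Coordinates are 1-based closed; duplicate symbols are an error.
    """
    df = pd.read_csv(path, sep="\t", dtype={0: str, 1: str})
    df.columns = [str(c).strip().lower() for c in df.columns]
    mapping = _resolve_columns(df.columns, ["symbol", "chromosome", "start", "end"])
    df = df.rename(columns=mapping)
    df["chromosome"] = df["chromosome"].map(normalize_chromosome)
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    if df["symbol"].duplicated().any():
        dup = df["symbol"][df["symbol"].duplicated()].iloc[0]
        raise FormatError(f"{path}: duplicate gene symbol {dup!r}")
    bad = df["start"] >= df["end"]
    if bad.any():
        raise FormatError(
            f"{path}: start >= end for gene {df['symbol'][bad].iloc[0]!r}"
        )
    return df[["symbol", "chromosome", "start", "end"]].reset_index(drop=True)


@dataclass
class GenomeLayout:
    """Per-chromosome centromere intervals and lengths.

    ``table`` is indexed by normalized chromosome label with columns
    ``centromere_start, centromere_end, length, acrocentric``.  On
    acrocentric chromosomes (human 13, 14, 15, 21, 22) only q-arm genes are
    represented on the profiling platform.
    """

    table: pd.DataFrame

    @property
    def chromosomes(self) -> list:
        return list(self.table.index)

    def centromere(self, chromosome: str) -> tuple:
        row = self.table.loc[normalize_chromosome(chromosome)]
        return int(row["centromere_start"]), int(row["centromere_end"])

    def is_acrocentric(self, chromosome: str) -> bool:
        return bool(self.table.loc[normalize_chromosome(chromosome), "acrocentric"])

    def arms(self, chromosome: str) -> list:
        """Arms carrying genes: ``["p", "q"]``, or ``["q"]`` if acrocentric."""
        return ["q"] if self.is_acrocentric(chromosome) else ["p", "q"]

    def __contains__(self, chromosome: str) -> bool:
        return normalize_chromosome(chromosome) in self.table.index


def read_genome_layout(path) -> GenomeLayout:
    """Read a tab-separated chrom / centromere_start / centromere_end / length
    table.  An optional ``acrocentric`` column overrides the default flag
    (chromosomes 13, 14, 15, 21, 22)."""
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    df.columns = [str(c).strip().lower() for c in df.columns]
    mapping = _resolve_columns(
        df.columns, ["chromosome", "centromere_start", "centromere_end", "length"]
    )
    df = df.rename(columns=mapping)
    df["chromosome"] = df["chromosome"].map(normalize_chromosome)
    for col in ("centromere_start", "centromere_end", "length"):
        df[col] = df[col].astype(np.int64)
    if "acrocentric" not in df.columns:
        df["acrocentric"] = df["chromosome"].isin(ACROCENTRIC)
    df["acrocentric"] = df["acrocentric"].astype(bool)
    bad = ~(
        (0 < df["centromere_start"])
        & (df["centromere_start"] < df["centromere_end"])
        & (df["centromere_end"] < df["length"])
    )
    if bad.any():
        raise FormatError(
            f"{path}: invalid centromere interval on chromosome "
            f"{df['chromosome'][bad].iloc[0]!r}"
        )
    table = df.set_index("chromosome")[
        ["centromere_start", "centromere_end", "length", "acrocentric"]
    ]
    return GenomeLayout(table)


# ---------------------------------------------------------------------------
# gene-value matrices


def write_matrix(matrix: pd.DataFrame, path) -> None:
    """Serialize a genes x samples matrix as TSV with NA for missing."""
    matrix.to_csv(path, sep="\t", na_rep="NA", index_label="symbol")


def read_matrix(path, value_kind: str = "cnv") -> pd.DataFrame:
    """Read a genes x samples TSV written by :func:`write_matrix`."""
    matrix = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    matrix.attrs["value_kind"] = value_kind
    return matrix


# ---------------------------------------------------------------------------
# sample filtering


def _sample_class(sid: str, class_map: Mapping | None) -> str:
    if class_map is not None:
        return class_map.get(sid, "other")
    bc = parse_barcode(sid)
    if bc.is_primary_tumor:
        return "primary"
    if bc.is_nonmalignant:
        return "nonmalignant"
    return "other"


def filter_samples(
    table: pd.DataFrame,
    keep: str = "primary",
    class_map: Mapping | None = None,
) -> pd.DataFrame:
    """Keep only samples of the requested class.

    ``table`` is either a segment table (long form, ``sample`` column) or a
    genes x samples matrix (samples as columns).  ``keep`` is ``"primary"``
    or ``"nonmalignant"``; sample ids are parsed as TCGA barcodes unless an
    explicit ``class_map`` (sample id -> class label) is given.  Original
    ordering is preserved; an empty result carries a warning, not an error.
    """
    if keep not in ("primary", "nonmalignant"):
        raise ValueError(f"unknown sample class {keep!r}")
    if "sample" in getattr(table, "columns", ()):
        ids = table["sample"]
        mask = ids.map(lambda s: _sample_class(s, class_map) == keep)
        out = table[mask].reset_index(drop=True)
        empty = out.empty
    else:
        cols = [c for c in table.columns if _sample_class(c, class_map) == keep]
        out = table[cols]
        out.attrs = dict(table.attrs)
        empty = len(cols) == 0
    if empty:
        warnings.warn(f"no samples of class {keep!r} remain after filtering")
    return out
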
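"""Arm-wise ordered per-gene summary tracks ("Mountain" curves).

A Mountain curve is the per-gene group median (default) or mean of a value
matrix, restricted to one chromosome arm and ordered by genomic start
position.  Plotted genome-wide with centromere gaps between arms, its ups
and downs trace the broad amplifications and deletions of a sample group.
The median is the default summary because it is robust to the extreme
single-sample amplifications common in tumor copy-number data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import GenomeLayout, normalize_chromosome
from .mapping import assign_arms

__all__ = ["MountainCurve", "summarize_group", "build_arm_curve", "build_genome_curves"]


@dataclass
class MountainCurve:
    """One arm-level summary track for one sample group."""

    chromosome: str
    arm: str
    genes: list
    starts: list
    values: np.ndarray
    summary_kind: str = "median"
    group_label: str = ""
    n_samples: int = 0
    #: genes on the arm dropped because every selected sample was missing
    dropped_genes: list = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.genes)

    @property
    def is_empty(self) -> bool:
        return len(self.genes) == 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chromosome": self.chromosome,
                "arm": self.arm,
                "symbol": self.genes,
                "start": self.starts,
                "value": self.values,
            }
        )


def summarize_group(
    matrix: pd.DataFrame, sample_ids, summary_kind: str = "median"
) -> pd.Series:
    """Per-gene median or mean over the selected samples' non-missing values.

    Genes whose every selected value is missing are dropped with a warning.
    """
    sample_ids = list(sample_ids)
    if not sample_ids:
        raise ValueError("empty sample set")
    missing = [s for s in sample_ids if s not in matrix.columns]
    if missing:
        raise KeyError(f"sample(s) not in matrix: {missing[:3]}")
    if summary_kind not in ("median", "mean"):
        raise ValueError(f"unknown summary_kind {summary_kind!r}")
    sub = matrix[sample_ids]
    values = sub.to_numpy(dtype=float)
    all_missing = np.isnan(values).all(axis=1)
    if all_missing.any():
        warnings.warn(
            f"{int(all_missing.sum())} gene(s) with no non-missing value in the "
            "selected samples were dropped"
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        if summary_kind == "median":
            summary = np.nanmedian(values, axis=1)
        else:
            summary = np.nanmean(values, axis=1)
    out = pd.Series(summary, index=matrix.index)[~all_missing]
    return out


def build_arm_curve(
    summary: pd.Series,
    annotation: pd.DataFrame,
    layout: GenomeLayout,
    chromosome: str,
    arm: str,
    group_label: str = "",
    summary_kind: str = "median",
    n_samples: int = 0,
    include_acrocentric_p: bool = False,
) -> MountainCurve:
    """Order the arm's genes by (start, symbol) and attach summary values.

    Requesting the p arm of an acrocentric chromosome yields an empty curve
    with a warning unless ``include_acrocentric_p`` is set and annotation
    provides genes there.
    """
    chrom = normalize_chromosome(chromosome)
    if chrom not in layout:
        raise KeyError(f"chromosome {chrom!r} not in genome layout")
    if arm not in ("p", "q"):
        raise ValueError(f"unknown arm label {arm!r}")
    empty = MountainCurve(
        chromosome=chrom,
        arm=arm,
        genes=[],
        starts=[],
        values=np.empty(0),
        summary_kind=summary_kind,
        group_label=group_label,
        n_samples=n_samples,
    )
    if arm == "p" and layout.is_acrocentric(chrom) and not include_acrocentric_p:
        warnings.warn(
            f"chromosome {chrom} is acrocentric: only q-arm genes are "
            "represented; returning an empty p-arm curve"
        )
        return empty

    ann = annotation if "arm" in annotation.columns else assign_arms(annotation, layout)
    sub = ann[(ann["chromosome"] == chrom) & (ann["arm"] == arm)]
    sub = sub.sort_values(["start", "symbol"], kind="mergesort")
    present = sub["symbol"].isin(summary.index)
    dropped = sub["symbol"][~present].tolist()
    sub = sub[present]
    if sub.empty:
        empty.dropped_genes = dropped
        return empty
    return MountainCurve(
        chromosome=chrom,
        arm=arm,
        genes=sub["symbol"].tolist(),
        starts=sub["start"].tolist(),
        values=summary[sub["symbol"]].to_numpy(dtype=float),
        summary_kind=summary_kind,
        group_label=group_label,
        n_samples=n_samples,
        dropped_genes=dropped,
    )


def build_genome_curves(
    matrix: pd.DataFrame,
    annotation: pd.DataFrame,
    layout: GenomeLayout,
    sample_ids,
    group_label: str = "",
    summary_kind: str = "median",
    include_acrocentric_p: bool = False,
) -> list:
    """Build the ordered list of arm curves covering the whole layout.

    Slots run in chromosome-then-arm order (1p, 1q, ..., 22q); acrocentric
    p slots are empty curves.  With a 22-chromosome layout this yields 44
    slots of which 39 are non-empty.
    """
    summary = summarize_group(matrix, sample_ids, summary_kind)
    if summary.empty:
        warnings.warn("empty matrix: all genome curves are empty")
    ann = assign_arms(annotation, layout)
    n = len(list(sample_ids))
    curves = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        for chrom in layout.chromosomes:
            for arm in ("p", "q"):
                curves.append(
                    build_arm_curve(
                        summary,
                        ann,
                        layout,
                        chrom,
                        arm,
                        group_label=group_label,
                        summary_kind=summary_kind,
                        n_samples=n,
                        include_acrocentric_p=include_acrocentric_p,
                    )
                )
    return curves


def curves_to_frame(curves) -> pd.DataFrame:
    """Concatenate curves into a (chrom, arm, symbol, start, value) table."""
    frames = [c.to_frame() for c in curves if not c.is_empty]
    if not frames:
        return pd.DataFrame(
            columns=["chromosome", "arm", "symbol", "start", "value"]
        )
    return pd.concat(frames, ignore_index=True)
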
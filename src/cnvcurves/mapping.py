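"""Gene-level CNV construction and chromosome-arm assignment.

A gene's copy-number value in a sample is the unweighted arithmetic mean of
the segment means of every segment of that sample that intersects the gene
interval — partially or entirely, any nonzero overlap counts.  Genes with no
intersecting segment get a missing value, which downstream summaries exclude
pairwise rather than impute.

All intervals are 1-based and fully closed.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .io import AUTOSOMES, GenomeLayout, normalize_chromosome

__all__ = ["assign_arm", "assign_arms", "map_segments_to_genes", "restrict_autosomes"]


def assign_arm(
    chromosome: str, start: int, end: int, layout: GenomeLayout
) -> str:
    """Assign a gene interval to the "p" or "q" arm of its chromosome.

    A gene wholly left of the centromere is "p", wholly right is "q".  A
    centromere-spanning gene goes to the arm holding the larger share of the
    gene body (per-base count on closed intervals); ties go to "p".
    """
    chrom = normalize_chromosome(chromosome)
    if chrom not in layout:
        raise KeyError(f"chromosome {chrom!r} not in genome layout")
    cen_start, cen_end = layout.centromere(chrom)
    if end < cen_start:
        return "p"
    if start > cen_end:
        return "q"
    p_bases = max(0, min(end, cen_start - 1) - start + 1)
    q_bases = max(0, end - max(start, cen_end + 1) + 1)
    return "p" if p_bases >= q_bases else "q"


def assign_arms(annotation: pd.DataFrame, layout: GenomeLayout) -> pd.DataFrame:
    """Annotation table with an added ``arm`` column (rows on chromosomes
    missing from the layout are dropped with a warning)."""
    known = annotation["chromosome"].isin(layout.chromosomes)
    if not known.all():
        warnings.warn(
            f"{(~known).sum()} gene(s) on chromosomes absent from the layout "
            "were dropped"
        )
    ann = annotation[known].copy()
    ann["arm"] = [
        assign_arm(c, s, e, layout)
        for c, s, e in zip(ann["chromosome"], ann["start"], ann["end"])
    ]
    return ann.reset_index(drop=True)


def _check_no_overlap(sample: str, chrom: str, starts: np.ndarray, ends: np.ndarray):
    # starts sorted ascending; closed intervals overlap iff next start <= end
    bad = np.flatnonzero(starts[1:] <= ends[:-1])
    if bad.size:
        i = bad[0]
        raise ValueError(
            f"overlapping segments in sample {sample!r} on chromosome {chrom!r}: "
            f"[{starts[i]}, {ends[i]}] and [{starts[i + 1]}, {ends[i + 1]}]"
        )


def map_segments_to_genes(
    segments: pd.DataFrame,
    annotation: pd.DataFrame,
    weighted: bool = False,
) -> pd.DataFrame:
    """Build the genes x samples CNV matrix from a segment table.

    Per (gene, sample): the mean of ``segment_mean`` over all segments of
    that sample on the gene's chromosome whose closed interval intersects the
    gene's closed interval.  ``weighted=True`` switches to an
    overlap-length-weighted mean (non-default variant).  Segments of one
    sample may abut but not overlap.
    """
    samples = list(pd.unique(segments["sample"]))
    matrix = pd.DataFrame(
        np.nan, index=annotation["symbol"].to_numpy(), columns=samples
    )
    matrix.index.name = "symbol"

    ann_by_chrom = {
        chrom: sub for chrom, sub in annotation.groupby("chromosome", sort=False)
    }
    for (sample, chrom), seg in segments.groupby(["sample", "chromosome"], sort=False):
        genes = ann_by_chrom.get(chrom)
        if genes is None:
            continue
        seg = seg.sort_values("start")
        starts = seg["start"].to_numpy()
        ends = seg["end"].to_numpy()
        means = seg["segment_mean"].to_numpy(dtype=float)
        _check_no_overlap(sample, chrom, starts, ends)

        g_start = genes["start"].to_numpy()
        g_end = genes["end"].to_numpy()
        # segments are sorted and disjoint, so both starts and ends are
        # ascending; overlapping segments form the contiguous index range
        # [lo, hi) with lo = first end >= gene start, hi = first start > gene end
        lo = np.searchsorted(ends, g_start, side="left")
        hi = np.searchsorted(starts, g_end, side="right")
        if weighted:
            values = np.full(len(genes), np.nan)
            for k in range(len(genes)):
                if hi[k] <= lo[k]:
                    continue
                sl = slice(lo[k], hi[k])
                w = (
                    np.minimum(ends[sl], g_end[k])
                    - np.maximum(starts[sl], g_start[k])
                    + 1
                ).astype(float)
                values[k] = float(np.average(means[sl], weights=w))
        else:
            csum = np.concatenate([[0.0], np.cumsum(means)])
            n = (hi - lo).astype(float)
            with np.errstate(invalid="ignore", divide="ignore"):
                values = np.where(n > 0, (csum[hi] - csum[lo]) / n, np.nan)
        matrix.loc[genes["symbol"].to_numpy(), sample] = values

    matrix.attrs["value_kind"] = "cnv"
    return matrix


def restrict_autosomes(matrix: pd.DataFrame, annotation: pd.DataFrame) -> pd.DataFrame:
    """Keep only genes annotated on chromosomes 1-22.

    Genes without annotation are dropped with a warning; X/Y genes are
    dropped silently (the analysis is restricted to autosomes).
    """
    chrom = annotation.set_index("symbol")["chromosome"]
    unannotated = [g for g in matrix.index if g not in chrom.index]
    if unannotated:
        warnings.warn(
            f"{len(unannotated)} gene(s) without annotation were dropped"
        )
    keep = [
        g
        for g in matrix.index
        if g in chrom.index and chrom[g] in AUTOSOMES
    ]
    out = matrix.loc[keep]
    out.attrs = dict(matrix.attrs)
    return out
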
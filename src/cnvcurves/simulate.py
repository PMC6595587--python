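"""Synthetic genomes, segment tables and expression matrices.

The generator emulates the structure of TCGA-legacy level-3 inputs: a
genome layout with per-chromosome centromeres (acrocentric chromosomes
carry q-arm genes only), non-overlapping gene annotations on both arms,
per-sample SEG tables tiled with abutting segments whose means sit on an
additive log2-ratio-like scale (baseline 0) with Gaussian segment noise,
and CNV-correlated expression.  Arm-level ("broad") and short ("focal")
alterations of configurable magnitude are added to a configurable fraction
of the tumor samples, and a truth record states exactly which samples,
arms and genes were altered.

Sample ids are emitted in TCGA barcode style ("...-01" tumors, "...-11"
solid-tissue normals) so the primary/nonmalignant filters are exercised.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import GenomeLayout, SEG_COLUMNS

__all__ = ["AlterationSpec", "SimConfig", "generate_layout", "generate_segments",
           "generate_expression", "simulate_dataset"]

#: chromosomes given q-only genes in synthetic genomes that include them
_ACRO = {"13", "14", "15", "21", "22"}


@dataclass(frozen=True)
class AlterationSpec:
    """One injected copy-number event.

    ``kind="broad"`` adds ``magnitude`` to every segment of the arm;
    ``kind="focal"`` adds it only to the segment(s) covering the gene-index
    interval ``focal_span`` (0-based, inclusive) within the arm.
    ``affected_fraction`` is the fraction of tumor samples carrying the
    event (the first ``round(fraction * n_tumor)`` tumors, deterministic).
    """

    chromosome: str
    arm: str  # "p" or "q"
    kind: str = "broad"  # "broad" | "focal"
    magnitude: float = 1.0
    focal_span: tuple = (0, 0)
    affected_fraction: float = 1.0

    def __post_init__(self):
        if self.kind not in ("broad", "focal"):
            raise ValueError(f"unknown alteration kind {self.kind!r}")
        if not 0 < self.affected_fraction <= 1:
            raise ValueError("affected_fraction must lie in (0, 1]")
        if not np.isfinite(self.magnitude):
            raise ValueError("magnitude must be finite")


@dataclass(frozen=True)
class SimConfig:
    """Study-scale defaults: a 22-chromosome genome with 20 genes per arm,
    5 abutting segments per arm, 30 tumor + 30 normal samples and segment
    noise sd 0.1 on the log2-ratio scale; expression = 10 + 2 * CNV +
    N(0, 1), clamped at 0."""

    n_chromosomes: int = 22
    genes_per_arm: int = 20
    gene_length: int = 100_000
    gene_spacing: int = 50_000
    arm_span: int | None = None  # derived from gene packing when None
    segments_per_arm: int = 5
    n_tumor: int = 30
    n_normal: int = 30
    noise_sd: float = 0.1
    alterations: tuple = ()
    baseline_copy: float = 0.0  # 2.0 emulates absolute copy numbers
    expression_baseline: float = 10.0
    expression_slope: float = 2.0
    expression_noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if min(self.n_chromosomes, self.genes_per_arm, self.gene_length,
               self.gene_spacing, self.segments_per_arm, self.n_tumor,
               self.n_normal) < 1:
            raise ValueError("all counts and sizes must be positive")
        if self.noise_sd < 0 or self.expression_noise_sd < 0:
            raise ValueError("noise sd must be >= 0")

    @property
    def tumor_ids(self) -> list:
        return [f"TCGA-SY-{i:04d}-01" for i in range(1, self.n_tumor + 1)]

    @property
    def normal_ids(self) -> list:
        return [
            f"TCGA-SY-{i:04d}-11"
            for i in range(self.n_tumor + 1, self.n_tumor + self.n_normal + 1)
        ]


def _arm_geometry(config: SimConfig):
    packed = (
        config.genes_per_arm * (config.gene_length + config.gene_spacing)
        + config.gene_spacing
    )
    span = packed if config.arm_span is None else config.arm_span
    if span < packed:
        raise ValueError(
            f"arm_span {span} cannot hold {config.genes_per_arm} genes of "
            f"length {config.gene_length} with spacing {config.gene_spacing}"
        )
    cen_len = 2 * config.gene_spacing
    return span, cen_len


def generate_layout(config: SimConfig):
    """Deterministic gene annotation table and genome layout.

    Genes are packed without overlap on both arms of every chromosome
    (q only on the acrocentric ones); coordinates are 1-based closed.
    Returns ``(annotation, layout)``.
    """
    span, cen_len = _arm_geometry(config)
    ann_rows = []
    layout_rows = []
    for c in range(1, config.n_chromosomes + 1):
        chrom = str(c)
        acro = chrom in _ACRO
        cen_start = span + 1
        cen_end = span + cen_len
        length = cen_end + span
        layout_rows.append(
            {
                "chromosome": chrom,
                "centromere_start": cen_start,
                "centromere_end": cen_end,
                "length": length,
                "acrocentric": acro,
            }
        )
        arms = ("q",) if acro else ("p", "q")
        for arm in arms:
            arm_start = 1 if arm == "p" else cen_end + 1
            for k in range(config.genes_per_arm):
                start = (
                    arm_start
                    + config.gene_spacing
                    + k * (config.gene_length + config.gene_spacing)
                )
                ann_rows.append(
                    {
                        "symbol": f"G{int(chrom):02d}{arm.upper()}{k:03d}",
                        "chromosome": chrom,
                        "start": start,
                        "end": start + config.gene_length - 1,
                    }
                )
    annotation = pd.DataFrame(ann_rows)
    layout = GenomeLayout(
        pd.DataFrame(layout_rows).set_index("chromosome")[
            ["centromere_start", "centromere_end", "length", "acrocentric"]
        ]
    )
    return annotation, layout


def _arm_bounds(layout: GenomeLayout, chrom: str, arm: str):
    cen_start, cen_end = layout.centromere(chrom)
    length = int(layout.table.loc[chrom, "length"])
    return (1, cen_start - 1) if arm == "p" else (cen_end + 1, length)


def _affected_samples(spec: AlterationSpec, config: SimConfig) -> set:
    n = int(round(spec.affected_fraction * config.n_tumor))
    return set(config.tumor_ids[: max(n, 1)])


def generate_segments(config: SimConfig):
    """Per-sample SEG table plus a truth record of the injected events.

    Each arm is tiled with ``segments_per_arm`` abutting segments (focal
    regions get their own breakpoints); segment mean = baseline + N(0,
    noise_sd) + the magnitudes of alterations covering the segment for
    affected samples.  Deterministic under ``config.seed``.  Returns
    ``(segments, truth)``.
    """
    annotation, layout = generate_layout(config)
    rng = np.random.default_rng(config.seed)
    ann_idx = annotation.set_index("symbol")

    # per (chrom, arm): breakpoints and per-alteration covered regions
    alt_regions = {}  # (chrom, arm) -> list of (alt_index, lo, hi, samples)
    truth_rows = []
    for ai, spec in enumerate(config.alterations):
        chrom = str(spec.chromosome)
        lo_b, hi_b = _arm_bounds(layout, chrom, spec.arm)
        if spec.kind == "broad":
            lo, hi = lo_b, hi_b
        else:
            prefix = f"G{int(chrom):02d}{spec.arm.upper()}"
            g0 = f"{prefix}{spec.focal_span[0]:03d}"
            g1 = f"{prefix}{spec.focal_span[1]:03d}"
            lo = int(ann_idx.loc[g0, "start"])
            hi = int(ann_idx.loc[g1, "end"])
        samples = _affected_samples(spec, config)
        alt_regions.setdefault((chrom, spec.arm), []).append((ai, lo, hi, samples))
        arm_genes = annotation[
            (annotation["chromosome"] == chrom)
            & (annotation["start"] >= lo)
            & (annotation["end"] <= hi)
            & (annotation["start"] >= lo_b)
        ]["symbol"].tolist()
        truth_rows.append(
            {
                "alteration": ai,
                "chromosome": chrom,
                "arm": spec.arm,
                "kind": spec.kind,
                "magnitude": spec.magnitude,
                "region_start": lo,
                "region_end": hi,
                "genes": ",".join(arm_genes),
                "samples": ",".join(sorted(samples)),
            }
        )

    rows = []
    sample_ids = config.tumor_ids + config.normal_ids
    for sid in sample_ids:
        for chrom in layout.chromosomes:
            for arm in ("p", "q"):
                lo_b, hi_b = _arm_bounds(layout, chrom, arm)
                cuts = set(
                    int(x)
                    for x in np.linspace(lo_b, hi_b + 1, config.segments_per_arm + 1)
                )
                for _ai, lo, hi, _samples in alt_regions.get((chrom, arm), []):
                    if lo_b <= lo <= hi_b:
                        cuts.update((lo, hi + 1))
                cuts = sorted(cuts)
                for s, e in zip(cuts[:-1], cuts[1:]):
                    start, end = s, e - 1
                    mean = config.baseline_copy + rng.normal(0.0, config.noise_sd)
                    for _ai, lo, hi, samples in alt_regions.get((chrom, arm), []):
                        if sid in samples and start <= hi and end >= lo:
                            mean += config.alterations[_ai].magnitude
                    rows.append(
                        {
                            "sample": sid,
                            "chromosome": chrom,
                            "start": start,
                            "end": end,
                            "num_probes": max((end - start + 1) // 1000, 1),
                            "segment_mean": round(float(mean), 6),
                        }
                    )
    segments = pd.DataFrame(rows, columns=SEG_COLUMNS)
    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "alteration", "chromosome", "arm", "kind", "magnitude",
            "region_start", "region_end", "genes", "samples",
        ],
    )
    return segments, truth


def generate_expression(config: SimConfig, cnv_matrix: pd.DataFrame) -> pd.DataFrame:
    """Expression matrix linearly coupled to gene-level CNV.

    value = max(0, baseline + slope * cnv + N(0, expression_noise_sd)),
    deterministic under ``config.seed``.
    """
    rng = np.random.default_rng(config.seed + 1)
    cnv = cnv_matrix.to_numpy(dtype=float)
    noise = rng.normal(0.0, config.expression_noise_sd, size=cnv.shape)
    values = np.maximum(
        config.expression_baseline + config.expression_slope * cnv + noise, 0.0
    )
    values[~np.isfinite(cnv)] = np.nan
    out = pd.DataFrame(values, index=cnv_matrix.index, columns=cnv_matrix.columns)
    out.attrs["value_kind"] = "expression"
    return out


def simulate_dataset(config: SimConfig):
    """Convenience wrapper: layout, segments, gene-level CNV and expression.

    Returns a dict with keys ``annotation, layout, segments, truth, cnv,
    expression, tumor_ids, normal_ids``.
    """
    from .mapping import map_segments_to_genes

    annotation, layout = generate_layout(config)
    segments, truth = generate_segments(config)
    cnv = map_segments_to_genes(segments, annotation)
    expression = generate_expression(config, cnv)
    return {
        "annotation": annotation,
        "layout": layout,
        "segments": segments,
        "truth": truth,
        "cnv": cnv,
        "expression": expression,
        "tumor_ids": config.tumor_ids,
        "normal_ids": config.normal_ids,
    }
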
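"""Dynamic-time-warping similarity of arm-level copy-number curves.

Two Mountain curves are compared by dynamic time warping (DTW): the
accumulated distance ``D(i, j) = d(i, j) + min[D(i-1, j), D(i, j-1),
D(i-1, j-1)]`` is filled from pairwise local costs ``d(i, j) = |x_i - y_j|``
and the optimal monotone warping path is recovered by backtracking from the
top-right corner, ties preferring the diagonal predecessor, then the
vertical one.  The raw accumulated distance is mapped to a similarity score
in [0, 1] — 1 means the two curves coincide, scores near 0 mean they are
completely different — by ``score = 1 / (1 + D / K)`` where K is the
warping-path length, so arms with different gene counts are comparable.
An exponential normalization ``exp(-D / K)`` is selectable.

Because DTW accumulates local cost along the whole path, a long arm-level
alteration depresses the score more than a short focal event of the same
height: the length of an alteration matters more than its height.

Significance of an observed arm score is assessed by a pooled bootstrap:
the two groups' sample columns are pooled, two pseudo-groups of the
original sizes are resampled with replacement, the two curves and their
score are rebuilt, and the add-one lower-tail p-value is reported (low
scores are extreme).

Three simpler coordinate-wise scores accompany DTW: the signed sum of
differences, the sum of absolute differences, and the sum of squared
differences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from numba import njit

from .curves import MountainCurve

__all__ = [
    "DTWResult",
    "SimilarityScores",
    "SimilarityResult",
    "BootstrapConfig",
    "dtw_align",
    "normalize_dtw",
    "distance_scores",
    "arm_similarity",
    "genome_wide_score",
    "bootstrap_curve_test",
]


@njit(cache=True)
def _accumulated_distance(x, y, squared):
    n = x.shape[0]
    m = y.shape[0]
    D = np.empty((n, m))
    for i in range(n):
        for j in range(m):
            d = abs(x[i] - y[j])
            if squared:
                d = d * d
            if i == 0 and j == 0:
                D[i, j] = d
            elif i == 0:
                D[i, j] = d + D[i, j - 1]
            elif j == 0:
                D[i, j] = d + D[i - 1, j]
            else:
                best = D[i - 1, j - 1]
                if D[i - 1, j] < best:
                    best = D[i - 1, j]
                if D[i, j - 1] < best:
                    best = D[i, j - 1]
                D[i, j] = d + best
    return D


@njit(cache=True)
def _path_length(D):
    # backtrack, tie preference diagonal > vertical > horizontal
    i = D.shape[0] - 1
    j = D.shape[1] - 1
    k = 1
    while i > 0 or j > 0:
        if i == 0:
            j -= 1
        elif j == 0:
            i -= 1
        else:
            diag = D[i - 1, j - 1]
            vert = D[i - 1, j]
            horiz = D[i, j - 1]
            if diag <= vert and diag <= horiz:
                i -= 1
                j -= 1
            elif vert <= horiz:
                i -= 1
            else:
                j -= 1
        k += 1
    return k


@dataclass
class DTWResult:
    """Alignment of two value sequences by dynamic time warping."""

    raw_distance: float
    path: list
    path_length: int
    score: float


@dataclass(frozen=True)
class SimilarityScores:
    """Coordinate-wise distance scores between two aligned curves."""

    signed_distance: float
    absolute_distance: float
    squared_distance: float


@dataclass
class SimilarityResult:
    """Similarity of one arm-level curve pair."""

    chromosome: str
    arm: str
    n_genes: int
    dtw: DTWResult
    scores: SimilarityScores
    bootstrap_p: float | None = None
    n_boot: int = 0


@dataclass(frozen=True)
class BootstrapConfig:
    """Configuration of the pooled-resampling bootstrap test."""

    n_boot: int = 999
    seed: int = 0
    resample_unit: str = "sample"

    def __post_init__(self):
        if self.n_boot < 1:
            raise ValueError("n_boot must be >= 1")


def _as_array(seq, name: str) -> np.ndarray:
    arr = np.asarray(seq, dtype=float)
    if arr.ndim != 1 or arr.size == 0:
        raise ValueError(f"{name} must be a non-empty 1-d sequence")
    if not np.isfinite(arr).all():
        raise ValueError(f"{name} contains non-finite values")
    return arr


def dtw_align(
    x, y, local_cost: str = "abs", normalization: str = "ratio"
) -> DTWResult:
    """Align two sequences by DTW and score their similarity.

    ``local_cost`` is ``"abs"`` (default) or ``"squared"``.  The warping
    path is returned as 0-based index pairs from (0, 0) to (n-1, m-1) with
    steps down/right/diagonal; backtracking ties prefer the diagonal
    predecessor, then the vertical.
    """
    xa = _as_array(x, "x")
    ya = _as_array(y, "y")
    if local_cost not in ("abs", "squared"):
        raise ValueError(f"unknown local_cost {local_cost!r}")
    D = _accumulated_distance(xa, ya, local_cost == "squared")
    path = _backtrack(D)
    raw = float(D[-1, -1])
    score = normalize_dtw(raw, len(path), method=normalization)
    return DTWResult(raw_distance=raw, path=path, path_length=len(path), score=score)


def _backtrack(D: np.ndarray) -> list:
    i, j = D.shape[0] - 1, D.shape[1] - 1
    path = [(i, j)]
    while i > 0 or j > 0:
        if i == 0:
            j -= 1
        elif j == 0:
            i -= 1
        else:
            diag, vert, horiz = D[i - 1, j - 1], D[i - 1, j], D[i, j - 1]
            if diag <= vert and diag <= horiz:
                i, j = i - 1, j - 1
            elif vert <= horiz:
                i -= 1
            else:
                j -= 1
        path.append((i, j))
    path.reverse()
    return path


def normalize_dtw(raw_distance: float, path_length: int, method: str = "ratio") -> float:
    """Map a raw accumulated distance to a similarity score in [0, 1].

    ``"ratio"`` (default): ``1 / (1 + raw / K)``; ``"exp"``:
    ``exp(-raw / K)``.  Both give 1 for coinciding curves and tend to 0 as
    the distance grows.
    """
    if raw_distance < 0:
        raise ValueError("raw_distance must be non-negative")
    if path_length < 1:
        raise ValueError("path_length must be >= 1")
    per_step = raw_distance / path_length
    if method == "ratio":
        return 1.0 / (1.0 + per_step)
    if method == "exp":
        return float(np.exp(-per_step))
    raise ValueError(f"unknown normalization {method!r}")


def distance_scores(x, y) -> SimilarityScores:
    """Signed, absolute and squared coordinate-wise distance sums."""
    xa = _as_array(x, "x")
    ya = _as_array(y, "y")
    if xa.shape != ya.shape:
        raise ValueError("x and y must have equal length")
    diff = xa - ya
    return SimilarityScores(
        signed_distance=float(diff.sum()),
        absolute_distance=float(np.abs(diff).sum()),
        squared_distance=float((diff**2).sum()),
    )


def _common_values(a: MountainCurve, b: MountainCurve):
    common = [g for g in a.genes if g in set(b.genes)]
    idx_a = {g: i for i, g in enumerate(a.genes)}
    idx_b = {g: i for i, g in enumerate(b.genes)}
    xa = a.values[[idx_a[g] for g in common]]
    ya = b.values[[idx_b[g] for g in common]]
    return common, xa, ya


def arm_similarity(
    curve_a: MountainCurve,
    curve_b: MountainCurve,
    local_cost: str = "abs",
    normalization: str = "ratio",
) -> SimilarityResult:
    """DTW score and distance scores for two curves on the same arm.

    The curves are intersected to their common gene set (shared genomic
    order); at least 2 common genes are required.
    """
    if (curve_a.chromosome, curve_a.arm) != (curve_b.chromosome, curve_b.arm):
        raise ValueError("curves are on different chromosome arms")
    common, xa, ya = _common_values(curve_a, curve_b)
    if len(common) < 2:
        raise ValueError(
            f"need >= 2 common genes on {curve_a.chromosome}{curve_a.arm}, "
            f"got {len(common)}"
        )
    dtw = dtw_align(xa, ya, local_cost=local_cost, normalization=normalization)
    return SimilarityResult(
        chromosome=curve_a.chromosome,
        arm=curve_a.arm,
        n_genes=len(common),
        dtw=dtw,
        scores=distance_scores(xa, ya),
    )


def genome_wide_score(arm_results) -> tuple:
    """Sum of normalized arm scores over all arms, with the arm count.

    Returns ``(total_score, n_arms)``; 39 identical curve pairs scoring 1.0
    each give 39.0.
    """
    results = list(arm_results)
    if not results:
        raise ValueError("no arm results to aggregate")
    total = float(sum(r.dtw.score for r in results))
    return total, len(results)


def group_similarity_report(
    matrix,
    annotation,
    layout,
    samples_a,
    samples_b,
    summary_kind: str = "median",
    n_boot: int = 0,
    seed: int = 0,
    local_cost: str = "abs",
    normalization: str = "ratio",
):
    """Arm-wise similarity table between two sample groups, plus a
    genome-wide summary row.

    Builds both groups' genome curves, scores every arm with >= 2 common
    genes, optionally attaches a pooled-bootstrap p-value per arm
    (``n_boot > 0``; genes with a missing value in either group are dropped
    from that arm's bootstrap), and appends a ``genome`` row whose
    ``dtw_score`` is the sum of the arm scores.

    Returns a DataFrame with columns ``chromosome, arm, n_genes, dtw_raw,
    dtw_score, signed, absolute, squared, boot_p, n_boot``.
    """
    import pandas as pd

    from .curves import build_genome_curves

    samples_a, samples_b = list(samples_a), list(samples_b)
    curves_a = build_genome_curves(
        matrix, annotation, layout, samples_a, summary_kind=summary_kind
    )
    curves_b = build_genome_curves(
        matrix, annotation, layout, samples_b, summary_kind=summary_kind
    )
    rows = []
    results = []
    for ca, cb in zip(curves_a, curves_b):
        common = [g for g in ca.genes if g in set(cb.genes)]
        if len(common) < 2:
            continue
        res = arm_similarity(ca, cb, local_cost=local_cost, normalization=normalization)
        boot_p = np.nan
        if n_boot > 0:
            sub_a = matrix.loc[common, samples_a].to_numpy(dtype=float)
            sub_b = matrix.loc[common, samples_b].to_numpy(dtype=float)
            complete = np.isfinite(sub_a).all(axis=1) & np.isfinite(sub_b).all(axis=1)
            if complete.sum() >= 2:
                boot_p = bootstrap_curve_test(
                    sub_a[complete],
                    sub_b[complete],
                    BootstrapConfig(n_boot=n_boot, seed=seed),
                    res.dtw.score,
                    summary_kind=summary_kind,
                    local_cost=local_cost,
                    normalization=normalization,
                )
                res.bootstrap_p = boot_p
                res.n_boot = n_boot
        results.append(res)
        rows.append(
            {
                "chromosome": res.chromosome,
                "arm": res.arm,
                "n_genes": res.n_genes,
                "dtw_raw": round(res.dtw.raw_distance, 6),
                "dtw_score": round(res.dtw.score, 6),
                "signed": round(res.scores.signed_distance, 6),
                "absolute": round(res.scores.absolute_distance, 6),
                "squared": round(res.scores.squared_distance, 6),
                "boot_p": boot_p,
                "n_boot": n_boot if n_boot > 0 else 0,
            }
        )
    if not rows:
        raise ValueError("no arm with >= 2 common genes between the two groups")
    total, n_arms = genome_wide_score(results)
    rows.append(
        {
            "chromosome": "genome",
            "arm": "",
            "n_genes": int(sum(r["n_genes"] for r in rows)),
            "dtw_raw": np.nan,
            "dtw_score": round(total, 6),
            "signed": np.nan,
            "absolute": np.nan,
            "squared": np.nan,
            "boot_p": np.nan,
            "n_boot": n_boot if n_boot > 0 else 0,
        }
    )
    return pd.DataFrame(rows)


def _group_curve(values: np.ndarray, idx: np.ndarray, summary_kind: str) -> np.ndarray:
    sub = values[:, idx]
    if summary_kind == "median":
        return np.median(sub, axis=1)
    return np.mean(sub, axis=1)


def bootstrap_curve_test(
    arm_matrix_a,
    arm_matrix_b,
    config: BootstrapConfig,
    observed_score: float,
    summary_kind: str = "median",
    local_cost: str = "abs",
    normalization: str = "ratio",
) -> float:
    """Pooled-bootstrap p-value for an observed arm similarity score.

    ``arm_matrix_a`` / ``arm_matrix_b`` are genes x samples sub-matrices for
    one arm (same gene order).  Null scores come from pooling the columns of
    both groups and resampling with replacement two pseudo-groups of the
    original sizes; p = (1 + #{null score <= observed}) / (n_boot + 1) —
    low scores mark dissimilar curves, so the lower tail is extreme.
    Deterministic under a fixed seed.
    """
    a = np.asarray(arm_matrix_a, dtype=float)
    b = np.asarray(arm_matrix_b, dtype=float)
    if a.ndim != 2 or b.ndim != 2 or a.shape[0] != b.shape[0]:
        raise ValueError("arm matrices must be 2-d with a shared gene axis")
    n_a, n_b = a.shape[1], b.shape[1]
    if n_a < 2 or n_b < 2:
        raise ValueError("both groups need >= 2 samples")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("bootstrap requires complete (non-missing) arm matrices")

    pooled = np.concatenate([a, b], axis=1)
    rng = np.random.default_rng(config.seed)
    squared = local_cost == "squared"
    count = 0
    for _ in range(config.n_boot):
        ia = rng.integers(0, n_a + n_b, size=n_a)
        ib = rng.integers(0, n_a + n_b, size=n_b)
        ca = _group_curve(pooled, ia, summary_kind)
        cb = _group_curve(pooled, ib, summary_kind)
        D = _accumulated_distance(ca, cb, squared)
        score = normalize_dtw(float(D[-1, -1]), _path_length(D), normalization)
        if score <= observed_score:
            count += 1
    return (1 + count) / (config.n_boot + 1)
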
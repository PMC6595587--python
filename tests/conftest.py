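import numpy as np
import pandas as pd
import pytest

from cnvcurves.io import GenomeLayout


@pytest.fixture
def tiny_layout():
    """One metacentric chromosome '1' with centromere [1000, 2000]."""
    table = pd.DataFrame(
        {
            "chromosome": ["1"],
            "centromere_start": [1000],
            "centromere_end": [2000],
            "length": [4000],
            "acrocentric": [False],
        }
    ).set_index("chromosome")
    return GenomeLayout(table)


@pytest.fixture
def tiny_annotation():
    return pd.DataFrame(
        {
            "symbol": ["GA", "GB", "GC", "GD"],
            "chromosome": ["1", "1", "1", "1"],
            "start": [100, 400, 2100, 3000],
            "end": [300, 600, 2500, 3500],
        }
    )


def enumerate_dtw(x, y):
    """Independent oracle: minimum accumulated |x_i - y_j| over the
    exhaustive enumeration of all monotone warping paths."""
    n, m = len(x), len(y)
    best = [np.inf]

    def walk(i, j, acc):
        acc = acc + abs(x[i] - y[j])
        if acc >= best[0]:
            return
        if i == n - 1 and j == m - 1:
            best[0] = acc
            return
        if i + 1 < n and j + 1 < m:
            walk(i + 1, j + 1, acc)
        if i + 1 < n:
            walk(i + 1, j, acc)
        if j + 1 < m:
            walk(i, j + 1, acc)

    walk(0, 0, 0.0)
    return best[0]


def brute_force_gene_cnv(segments: pd.DataFrame, gene_chrom, gene_start, gene_end, sample):
    """O(segments) closed-interval intersection scan for one (gene, sample)."""
    hits = []
    for _, seg in segments.iterrows():
        if seg["sample"] != sample or seg["chromosome"] != gene_chrom:
            continue
        if seg["start"] <= gene_end and seg["end"] >= gene_start:
            hits.append(seg["segment_mean"])
    return float(np.mean(hits)) if hits else np.nan


def brute_force_bh(p):
    """Step-up definition evaluated literally: q_(i) = min_{j>=i} p_(j)*n/j."""
    p = np.asarray(p, dtype=float)
    n = p.size
    order = np.argsort(p, kind="stable")
    q = np.empty(n)
    sorted_p = p[order]
    for i in range(n):
        q[order[i]] = min(
            min(sorted_p[j] * n / (j + 1) for j in range(i, n)), 1.0
        )
    return q
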
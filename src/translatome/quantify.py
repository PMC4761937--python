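"""Gene-level quantification of footprint and mRNA-fragment assignments.

Counting is restricted to the region relevant to translation of the main
ORF: the last 40 nt of the 5'UTR, the entire ORF, and the first 40 nt of
the 3'UTR.  Gene counts ``C`` are sums of fractional read weights whose
5' end falls inside the counting region of the hit transcript; RPKM is
``1e9 * C / (N * L)`` with ``N`` the total mappable reads and ``L`` the
effective gene length from :mod:`translatome.reference`.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .reads import ReadAssignment
from .reference import GeneModel, TranscriptModel

UTR_WINDOW = 40


def counting_region(model: TranscriptModel, u5: int = UTR_WINDOW, u3: int = UTR_WINDOW) -> range:
    """Positions counted for a transcript: ORF plus 40 nt of each UTR."""
    start = max(0, model.orf_start - u5)
    end = min(len(model.full_seq), model.orf_end + u3)
    return range(start, end)


def gene_counts(
    assignments: list[ReadAssignment],
    genes: dict[str, GeneModel],
    u5: int = UTR_WINDOW,
    u3: int = UTR_WINDOW,
) -> pd.Series:
    """Per-gene count ``C``: sum of weights landing in a counting region."""
    regions: dict[str, tuple[str, range]] = {}
    for g in genes.values():
        for t in g.transcripts:
            regions[t.transcript_id] = (g.gene_id, counting_region(t, u5, u3))

    counts = {g.gene_id: 0.0 for g in genes.values()}
    orphans = set()
    for a in assignments:
        for tid, pos5, w in a.hits:
            if tid not in regions:
                orphans.add(tid)
                continue
            gid, region = regions[tid]
            if region.start <= pos5 < region.stop:
                counts[gid] += w
    if orphans:
        raise KeyError(f"assignments reference unknown transcripts: {sorted(orphans)}")
    return pd.Series(counts, name="C").sort_index()


def rpkm(C: float, N: float, L: float | None) -> float:
    """Reads per kilobase of effective gene length per million mapped reads."""
    if N <= 0:
        raise ValueError("N must be positive")
    if L is None or (isinstance(L, float) and math.isnan(L)):
        return float("nan")  # unquantifiable gene
    if L <= 0:
        raise ValueError("L must be positive")
    return 1e9 * C / (N * L)


def rpkm_table(counts: pd.Series, genes: dict[str, GeneModel], N: float | None = None) -> pd.Series:
    """Vector RPKM over a count table; ``N`` defaults to the count total."""
    if N is None:
        N = float(counts.sum())
    out = {}
    for gid, c in counts.items():
        L = genes[gid].effective_len
        out[gid] = rpkm(float(c), N, L)
    return pd.Series(out, name="rpkm").sort_index()


def coverage(
    assignments: list[ReadAssignment],
    genes: dict[str, GeneModel],
    u5: int = UTR_WINDOW,
    u3: int = UTR_WINDOW,
) -> pd.Series:
    """Fraction of counting-region positions with >=1 assigned 5' end."""
    region_by_tid: dict[str, range] = {}
    gene_of: dict[str, str] = {}
    for g in genes.values():
        for t in g.transcripts:
            region_by_tid[t.transcript_id] = counting_region(t, u5, u3)
            gene_of[t.transcript_id] = g.gene_id

    hit_positions: dict[str, set[tuple[str, int]]] = {g: set() for g in genes}
    for a in assignments:
        for tid, pos5, w in a.hits:
            if w <= 0 or tid not in region_by_tid:
                continue
            region = region_by_tid[tid]
            if region.start <= pos5 < region.stop:
                hit_positions[gene_of[tid]].add((tid, pos5))

    out = {}
    for gid, g in genes.items():
        total = sum(len(region_by_tid[t.transcript_id]) for t in g.transcripts)
        out[gid] = len(hit_positions[gid]) / total if total else 0.0
    return pd.Series(out, name="coverage").sort_index()


def average_replicates(replicates: list[pd.Series] | pd.DataFrame) -> pd.Series:
    """Noise-minimizing replicate average on a common gene universe.

    Each replicate is normalized by its mean, the normalized vectors are
    averaged, and the result is rescaled by the average of the replicate
    means:  ``v = mean_r(x_r / mean(x_r)) * mean_r(mean(x_r))``.
    """
    if isinstance(replicates, pd.DataFrame):
        replicates = [replicates[c] for c in replicates.columns]
    if not replicates:
        raise ValueError("need at least one replicate")
    index = replicates[0].index
    means = []
    normed = []
    for r in replicates:
        if not r.index.equals(index):
            raise ValueError("replicates must share a common gene universe")
        m = float(np.mean(r.to_numpy(dtype=float)))
        if m == 0:
            raise ValueError("replicate with zero mean cannot be normalized")
        means.append(m)
        normed.append(r / m)
    avg = sum(normed) / len(normed)
    return avg * (sum(means) / len(means))
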
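"""Rarefaction and alpha diversity (richness, Shannon index in bits).

Samples are subsampled without replacement to a common depth (default
3,000 reads) before computing per-sample richness and Shannon entropy,
so that diversity is comparable across uneven sequencing effort. Base-2
logarithms are used throughout (the legacy QIIME convention); divide by
log2(e) ~ 1.4427 to convert to nats.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import entropy as _entropy

from .io import OtuTable

logger = logging.getLogger(__name__)

__all__ = ["rarefy", "richness", "shannon", "diversity_table", "DiversityResult"]


def rarefy(counts: np.ndarray, depth: int, rng: np.random.Generator) -> np.ndarray:
    """Subsample a count vector to ``depth`` reads without replacement.

    Multivariate hypergeometric draw: each output entry is bounded by the
    input entry and the output sums to ``depth`` exactly.

    Raises
    ------
    ValueError
        If the vector holds fewer than ``depth`` reads.
    """
    counts = np.asarray(counts)
    if counts.ndim != 1:
        raise ValueError("rarefy expects a single count vector")
    total = int(counts.sum())
    if total < depth:
        raise ValueError(f"sample has {total} reads, fewer than depth {depth}")
    return rng.multivariate_hypergeometric(
        counts.astype(np.int64), int(depth), method="marginals"
    )


def richness(counts: np.ndarray) -> int:
    """Number of OTUs with at least one read."""
    return int(np.count_nonzero(np.asarray(counts)))


def shannon(counts: np.ndarray) -> float:
    """Shannon index H = -sum p_i log2 p_i, in bits."""
    counts = np.asarray(counts, dtype=float)
    if counts.sum() <= 0:
        raise ValueError("Shannon index undefined for an all-zero vector")
    return float(_entropy(counts, base=2))


@dataclass
class DiversityResult:
    """Per-sample alpha diversity after a single rarefaction draw.

    ``frame`` columns: depth_used, richness, shannon (bits), indexed by
    sample; ``excluded`` lists samples below the rarefaction depth.
    """

    frame: pd.DataFrame
    excluded: list[str] = field(default_factory=list)
    depth: int = 0


def diversity_table(
    table: OtuTable,
    depth: int = 3000,
    rng: np.random.Generator | None = None,
    n_rarefactions: int = 1,
) -> DiversityResult:
    """Rarefy each sample and compute richness and Shannon index.

    Samples with fewer than ``depth`` reads are excluded (reported in
    ``DiversityResult.excluded``), not raised. With ``n_rarefactions > 1``
    the metrics are averaged over repeated draws (off by default; a single
    recorded-seed draw is the standard mode).
    """
    rng = np.random.default_rng(0) if rng is None else rng
    rows = []
    excluded = []
    for i, sid in enumerate(table.sample_ids):
        counts = table.counts[i]
        if counts.sum() < depth:
            excluded.append(sid)
            continue
        rich_vals, shan_vals = [], []
        for _ in range(max(1, n_rarefactions)):
            sub = rarefy(counts, depth, rng)
            rich_vals.append(richness(sub))
            shan_vals.append(shannon(sub))
        rows.append(
            {
                "sample_id": sid,
                "depth_used": depth,
                "richness": float(np.mean(rich_vals)),
                "shannon": float(np.mean(shan_vals)),
            }
        )
    if excluded:
        logger.warning(
            "diversity_table: excluded %d sample(s) below depth %d: %s",
            len(excluded), depth, excluded[:5],
        )
    frame = (
        pd.DataFrame(rows).set_index("sample_id")
        if rows
        else pd.DataFrame(
            columns=["depth_used", "richness", "shannon"],
            index=pd.Index([], name="sample_id"),
        )
    )
    return DiversityResult(frame=frame, excluded=excluded, depth=depth)
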
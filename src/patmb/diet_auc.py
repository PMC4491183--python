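"""Pre/post-diet family-level discrimination screen.

For each bacterial family that reaches > 1% relative abundance in at least
one sample of one mouse, the screen asks how well that family's abundance
separates mice sampled immediately before the high-fat-diet switch from
mice sampled immediately after: the Mann-Whitney U statistic is converted
to an AUC (probability a random post-diet observation exceeds a random
pre-diet one, ties counted half), a 95% Hanley-McNeil confidence interval
is attached, and two-sided Mann-Whitney p-values are Benjamini-Hochberg
corrected across families. The unit of analysis defaults to the per-mouse
mean within each window (mice, not samples, are the replicates); a
per-sample mode is available.

Family aggregation uses un-rarefied proportions (proportions are
depth-invariant in expectation), with OTUs lacking a family assignment
bucketed as "<order> other" (falling back to class/phylum).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import CohortMetadata, OtuTable
from .states import relative_abundance

logger = logging.getLogger(__name__)

__all__ = [
    "family_from_lineage",
    "family_table",
    "prevalent_families",
    "auc_mwu",
    "auc_ci",
    "fdr_bh",
    "diet_screen",
]

_RANK_PREFIXES = ("k__", "p__", "c__", "o__", "f__", "g__")


def family_from_lineage(lineage: str) -> str:
    """Family label from a semicolon-delimited ranked lineage.

    Returns the family rank when present; otherwise the deepest named
    higher rank suffixed with " other" (e.g. "Clostridiales other"),
    mirroring the "Bacteroidales other" style of unresolved families.
    """
    parts = [p.strip() for p in str(lineage).split(";")]
    ranks: dict[str, str] = {}
    unprefixed: list[str] = []
    for p in parts:
        matched = False
        for pref in _RANK_PREFIXES:
            if p.startswith(pref):
                val = p[len(pref):].strip()
                if val:
                    ranks[pref] = val
                matched = True
                break
        if not matched and p:
            unprefixed.append(p)
    if "f__" in ranks:
        return ranks["f__"]
    if not ranks and unprefixed:
        # no rank prefixes at all: positional kingdom..genus convention
        if len(unprefixed) >= 5 and unprefixed[4].lower() != "unclassified":
            return unprefixed[4]
        for val in reversed(unprefixed[:4]):
            if val.lower() != "unclassified":
                return f"{val} other"
        return "Unclassified other"
    for pref in ("o__", "c__", "p__", "k__"):
        if pref in ranks:
            return f"{ranks[pref]} other"
    return "Unclassified other"


def family_table(table: OtuTable) -> pd.DataFrame:
    """Per-sample family-level relative abundances (rows sum to 1)."""
    rel = relative_abundance(table)
    families = [family_from_lineage(table.taxonomy[o]) for o in table.otu_ids]
    out = rel.T.groupby(pd.Index(families, name="family")).sum().T
    return out


def prevalent_families(
    fam: pd.DataFrame,
    meta: CohortMetadata | None = None,
    threshold: float = 0.01,
) -> list[str]:
    """Families exceeding ``threshold`` relative abundance in >= 1 sample.

    "In at least one mouse" — any sample of any mouse qualifies, so the
    metadata is only used to restrict to samples it covers (when given).
    """
    if meta is not None:
        fam = fam.loc[fam.index.intersection(meta.sample_ids)]
    if threshold <= 0:
        keep = fam.max(axis=0) > 0
    else:
        keep = fam.max(axis=0) > threshold
    return [str(f) for f in fam.columns[keep]]


def auc_mwu(pre: np.ndarray, post: np.ndarray) -> tuple[float, float, float]:
    """AUC, U statistic and two-sided Mann-Whitney p for post vs pre.

    U counts (post > pre) pairs plus half the ties, so AUC = U/(n_pre *
    n_post) is the probability a random post value ranks above a random
    pre value. The p-value is exact (full null enumeration) when
    n_pre * n_post <= 400 and there are no ties, otherwise the
    tie-corrected normal approximation is used.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.size == 0 or post.size == 0:
        raise ValueError("both windows need at least one value")
    u = float(
        (post[:, None] > pre[None, :]).sum()
        + 0.5 * (post[:, None] == pre[None, :]).sum()
    )
    has_ties = np.unique(np.concatenate([pre, post])).size < pre.size + post.size
    method = "exact" if (pre.size * post.size <= 400 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(post, pre, alternative="two-sided", method=method)
    assert np.isclose(res.statistic, u), "U statistic mismatch with scipy"
    auc = u / (pre.size * post.size)
    return auc, u, float(res.pvalue)


def auc_ci(
    auc: float, n_pre: int, n_post: int, level: float = 0.95
) -> tuple[float, float]:
    """Hanley-McNeil normal interval for an AUC, clipped to [0, 1]."""
    if n_pre < 1 or n_post < 1:
        raise ValueError("window sizes must be >= 1")
    a = float(auc)
    q1 = a / (2.0 - a)
    q2 = 2.0 * a * a / (1.0 + a)
    var = (
        a * (1.0 - a)
        + (n_post - 1) * (q1 - a * a)
        + (n_pre - 1) * (q2 - a * a)
    ) / (n_pre * n_post)
    se = np.sqrt(max(var, 0.0))
    z = stats.norm.ppf(0.5 + level / 2.0)
    return float(np.clip(a - z * se, 0.0, 1.0)), float(np.clip(a + z * se, 0.0, 1.0))


def fdr_bh(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone, in [0, 1])."""
    p = np.asarray(p_values, dtype=float)
    if p.size and (np.any(p < 0) | np.any(p > 1) | np.any(~np.isfinite(p))):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class AucScreenResult:
    """Family-level screen output: one row per prevalent family.

    Columns: family, n_pre, n_post, auc, ci_low, ci_high, u_stat, p_value,
    q_value, direction (increase/decrease), significant (q < 0.05).
    """

    frame: pd.DataFrame
    window_pre: tuple[int, int]
    window_post: tuple[int, int]
    unit: str


def _window_samples(
    meta: CohortMetadata, window: tuple[int, int]
) -> pd.DataFrame:
    lo, hi = window
    df = meta.frame
    return df[(df["day_of_life"] >= lo) & (df["day_of_life"] <= hi)]


def _default_windows(
    meta: CohortMetadata,
) -> tuple[tuple[int, int], tuple[int, int]]:
    """Last scheduled pre-switch day and first post-switch day."""
    df = meta.frame
    pre_days = df.loc[df["diet"] == "normal_chow", "day_of_life"]
    post_days = df.loc[df["diet"] == "high_fat", "day_of_life"]
    if pre_days.empty or post_days.empty:
        raise ValueError("metadata lacks samples on one side of the diet switch")
    d_pre, d_post = int(pre_days.max()), int(post_days.min())
    return (d_pre, d_pre), (d_post, d_post)


def diet_screen(
    table: OtuTable,
    meta: CohortMetadata,
    window_pre: tuple[int, int] | None = None,
    window_post: tuple[int, int] | None = None,
    threshold: float = 0.01,
    unit: str = "mouse",
    group: str | None = None,
) -> AucScreenResult:
    """Family-level AUC screen across the diet switch.

    ``window_pre``/``window_post`` are inclusive day-of-life ranges;
    omitted, they default to the last pre-switch and first post-switch
    scheduled days. ``unit="mouse"`` averages each mouse's samples within a
    window (the default replicate is the mouse); ``unit="sample"`` uses
    samples directly. ``group`` restricts the screen to one treatment
    group.
    """
    if unit not in ("mouse", "sample"):
        raise ValueError("unit must be 'mouse' or 'sample'")
    if group is not None:
        keep = meta.frame.index[meta.frame["group"] == group]
        meta = meta.subset(keep)
    if window_pre is None or window_post is None:
        d_pre, d_post = _default_windows(meta)
        window_pre = window_pre or d_pre
        window_post = window_post or d_post

    fam = family_table(table)
    fam = fam.loc[fam.index.intersection(meta.sample_ids)]
    pre_meta = _window_samples(meta, window_pre)
    post_meta = _window_samples(meta, window_post)
    for name, sub in (("pre", pre_meta), ("post", post_meta)):
        if len(sub) < 2:
            raise ValueError(
                f"{name} window {window_pre if name == 'pre' else window_post} "
                f"contains {len(sub)} sample(s); need >= 2"
            )
    families = prevalent_families(fam, meta, threshold=threshold)

    def _values(sub_meta: pd.DataFrame, family: str) -> np.ndarray:
        vals = fam.loc[fam.index.intersection(sub_meta.index), family]
        if unit == "mouse":
            vals = vals.groupby(sub_meta.loc[vals.index, "mouse_id"]).mean()
        return vals.to_numpy(dtype=float)

    rows = []
    for family in families:
        pre_v = _values(pre_meta, family)
        post_v = _values(post_meta, family)
        auc, u, p = auc_mwu(pre_v, post_v)
        lo, hi = auc_ci(auc, len(pre_v), len(post_v))
        rows.append(
            {
                "family": family,
                "n_pre": len(pre_v),
                "n_post": len(post_v),
                "auc": auc,
                "ci_low": lo,
                "ci_high": hi,
                "u_stat": u,
                "p_value": p,
                "direction": "increase" if auc > 0.5 else "decrease",
            }
        )
    frame = pd.DataFrame(rows)
    if not frame.empty:
        frame["q_value"] = fdr_bh(frame["p_value"].to_numpy())
        frame["significant"] = frame["q_value"] < 0.05
        frame = frame.sort_values("q_value", kind="stable").reset_index(drop=True)
    return AucScreenResult(
        frame=frame, window_pre=tuple(window_pre),
        window_post=tuple(window_post), unit=unit,
    )
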
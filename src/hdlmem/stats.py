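"""Group-comparison protocol and result normalization.

The comparison protocol mirrors common practice for non-normal,
heteroscedastic fluorescence readouts: Shapiro-Wilk normality per group,
Levene variance homogeneity across groups, a Kruskal-Wallis omnibus test at
alpha = 5%, and Dunn's all-pairs post-hoc test with Bonferroni correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import stats as sps

__all__ = [
    "GroupComparison",
    "compare_groups",
    "normalize_to_reference",
    "relative_change",
    "dunn_posthoc",
]


@dataclass
class GroupComparison:
    labels: list
    n_per_group: dict
    normality_p: dict  # Shapiro-Wilk per group (NaN where undefined)
    levene_p: float
    omnibus_p: float  # Kruskal-Wallis
    omnibus_stat: float
    pairwise_p: dict  # (label_i, label_j) -> Bonferroni-adjusted p
    pairwise_p_raw: dict
    alpha: float = 0.05
    notes: list = field(default_factory=list)

    @property
    def significant(self) -> bool:
        return self.omnibus_p < self.alpha

    def significant_pairs(self) -> list:
        return [pair for pair, p in self.pairwise_p.items() if p < self.alpha]


def dunn_posthoc(samples: dict) -> tuple[dict, dict]:
    """Dunn's all-pairs z test on pooled ranks with tie correction.

    Returns ``(raw_p, bonferroni_p)`` keyed by label pairs; the Bonferroni
    factor is the number of pairwise comparisons.
    """
    labels = list(samples)
    pooled = np.concatenate([np.asarray(samples[g], dtype=float) for g in labels])
    n_total = pooled.size
    ranks = sps.rankdata(pooled)
    mean_rank, sizes = {}, {}
    start = 0
    for g in labels:
        n = len(samples[g])
        mean_rank[g] = float(np.mean(ranks[start : start + n]))
        sizes[g] = n
        start += n
    # tie correction
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts)) / (12.0 * (n_total - 1)) if n_total > 1 else 0.0
    var_base = n_total * (n_total + 1) / 12.0 - tie_term
    m = len(labels) * (len(labels) - 1) // 2
    raw, adj = {}, {}
    for gi, gj in combinations(labels, 2):
        se = np.sqrt(var_base * (1.0 / sizes[gi] + 1.0 / sizes[gj]))
        z = (mean_rank[gi] - mean_rank[gj]) / se if se > 0 else 0.0
        p = 2.0 * sps.norm.sf(abs(z))
        raw[(gi, gj)] = float(p)
        adj[(gi, gj)] = float(min(1.0, p * m))
    return raw, adj


def compare_groups(samples: dict, alpha: float = 0.05) -> GroupComparison:
    """Run the full protocol on labeled numeric groups.

    ``samples`` maps group label -> 1-d array of values; each group needs
    n >= 3.  Constant groups are noted (normality is then undefined).
    """
    labels = list(samples)
    if len(labels) < 2:
        raise ValueError("need >= 2 groups")
    arrays = {g: np.asarray(samples[g], dtype=float) for g in labels}
    for g, a in arrays.items():
        if a.size < 3:
            raise ValueError(f"group {g!r} has n={a.size} < 3")
    notes = []
    normality = {}
    for g, a in arrays.items():
        if np.ptp(a) == 0:
            normality[g] = np.nan
            notes.append(f"group {g!r} is constant; normality undefined")
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            normality[g] = float(sps.shapiro(a).pvalue)
    try:
        levene_p = float(sps.levene(*arrays.values()).pvalue)
    except ValueError:
        levene_p = np.nan
        notes.append("Levene undefined (constant data)")
    try:
        kw = sps.kruskal(*arrays.values())
        omnibus_stat, omnibus_p = float(kw.statistic), float(kw.pvalue)
    except ValueError:
        # all values identical across groups: statistic is 0, no evidence
        omnibus_stat, omnibus_p = 0.0, 1.0
        notes.append("Kruskal-Wallis undefined (all values identical); p set to 1")
    raw, adj = dunn_posthoc(arrays)
    return GroupComparison(
        labels=labels,
        n_per_group={g: int(a.size) for g, a in arrays.items()},
        normality_p=normality,
        levene_p=levene_p,
        omnibus_p=omnibus_p,
        omnibus_stat=omnibus_stat,
        pairwise_p=adj,
        pairwise_p_raw=raw,
        alpha=alpha,
        notes=notes,
    )


def normalize_to_reference(values: dict, reference_label) -> dict:
    """Divide every sample's (value, se) by the reference sample's value.

    ``values`` maps label -> value or (value, se).  Relative errors add in
    quadrature (delta method); the reference itself maps to exactly 1.
    """
    if reference_label not in values:
        raise ValueError(f"reference {reference_label!r} not present")

    def unpack(v):
        return (float(v[0]), float(v[1])) if np.iterable(v) else (float(v), 0.0)

    ref, ref_se = unpack(values[reference_label])
    if ref == 0:
        raise ValueError("reference value is zero")
    out = {}
    for label, v in values.items():
        val, se = unpack(v)
        norm = val / ref
        if label == reference_label:
            out[label] = (1.0, 0.0)
        else:
            rel = np.sqrt((se / val) ** 2 + (ref_se / ref) ** 2) if val != 0 else np.nan
            out[label] = (norm, abs(norm) * rel if np.isfinite(rel) else np.nan)
    return out


def relative_change(
    pre: float | tuple,
    post: float | tuple,
    round_to_int: bool = True,
) -> dict:
    """Percent decrease from ``pre`` to ``post``: 100 (pre - post) / pre.

    Values may be scalars or ``(value, se)`` pairs; SE is propagated by the
    delta method.  The reported percentage is rounded to the nearest integer
    by default; the unrounded value is always included.
    """

    def unpack(v):
        return (float(v[0]), float(v[1])) if np.iterable(v) else (float(v), 0.0)

    p, p_se = unpack(pre)
    q, q_se = unpack(post)
    if p <= 0:
        raise ValueError("pre must be positive")
    pct = 100.0 * (p - q) / p
    # d(pct)/dp = 100 q / p^2 ; d(pct)/dq = -100 / p
    se = 100.0 * np.sqrt((q * p_se / p**2) ** 2 + (q_se / p) ** 2)
    return {
        "percent_change": float(round(pct)) if round_to_int else float(pct),
        "percent_change_unrounded": float(pct),
        "se": float(se),
    }
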
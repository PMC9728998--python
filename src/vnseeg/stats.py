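"""Group statistics for the pre/post VNS comparison.

The analysis unit is the epoch-level feature value (global, regional or
channel PLI per band; global/regional/channel offset and exponent), pooled
across the subjects of one group — up to 100 values per condition with 5
subjects x 20 epochs.  Each feature is compared pre vs post implantation
with the Mann-Whitney U test, corrected with Benjamini-Hochberg FDR within
the family given by its spatial subdivision, and summarized with Cohen's d.
A subject-level option (per-subject medians as the unit) is available; the
pooled unit is the default and the choice is flagged in the docs as the
key ambiguity of the design.

Clinical response is quantified by the Labar index — minus the percentage
change in monthly seizure frequency, positive = improvement — with
responders at >= 50.  Outcome correlation uses Spearman's rank coefficient
between each subject's relative feature variation (median post - median
pre, over median pre) and their Labar index.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

GROUPS = ("R", "NR")


@dataclass(frozen=True)
class SubjectRecord:
    """Clinical record for one subject."""

    id: str
    group: str
    pre_rate: float
    post_rate: float
    labar: float


# --------------------------------------------------------------------------
# Elementary statistics


def mann_whitney_u(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U (statistic for the first sample).

    Exact null distribution when min(n) <= 8 and the pooled sample has no
    ties; tie-corrected normal approximation (with continuity correction)
    otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (min(x.size, y.size) <= 8 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def fdr_bh(p_values, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up adjusted p-values and the significance
    mask (adjusted < alpha).  Adjusted values are monotone-enforced and
    elementwise >= the raw values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p <= 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    _, p_adj, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return p_adj, p_adj < alpha


def cohens_d(x, y) -> float:
    """Absolute standardized mean difference with pooled SD."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("need at least 2 values per sample")
    n1, n2 = x.size, y.size
    s2 = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / (n1 + n2 - 2)
    if s2 <= 0:
        warnings.warn("zero pooled SD: Cohen's d undefined", stacklevel=2)
        return math.nan
    return float(abs(x.mean() - y.mean()) / math.sqrt(s2))


def relative_variation(pre_values, post_values) -> float:
    """(median(post) - median(pre)) / median(pre)."""
    pre = np.asarray(pre_values, dtype=float)
    post = np.asarray(post_values, dtype=float)
    if pre.size == 0 or post.size == 0:
        raise ValueError("both samples must be nonempty")
    m_pre = float(np.median(pre))
    if m_pre == 0:
        warnings.warn("zero pre-median: relative variation undefined", stacklevel=2)
        return math.nan
    return (float(np.median(post)) - m_pre) / m_pre


def labar_index(pre_rate: float, post_rate: float) -> float:
    """Labar's index: minus the percentage change in monthly seizure
    frequency, ``-100 * (post - pre) / pre``.  Positive = improvement.
    Both rates zero is defined as 0; a zero pre-rate with seizures after
    is undefined."""
    if pre_rate < 0 or post_rate < 0:
        raise ValueError("seizure rates must be >= 0")
    if pre_rate == 0:
        if post_rate == 0:
            return 0.0
        warnings.warn("zero pre-rate with nonzero post-rate: Labar undefined",
                      stacklevel=2)
        return math.nan
    return -100.0 * (post_rate - pre_rate) / pre_rate


def classify_responder(labar: float) -> tuple[str, str]:
    """Responder status and frequency-based outcome bucket.

    ``R`` iff Labar >= 50 (at least 50% seizure reduction).  Bucket ``I``
    for >= 80% reduction, ``II`` for 50-79%; anything below is ``other``
    (the lesser outcome classes need clinical information beyond seizure
    frequency)."""
    if not math.isfinite(labar):
        raise ValueError("labar must be finite")
    if labar >= 80:
        return "R", "I"
    if labar >= 50:
        return "R", "II"
    return "NR", "other"


def _exact_spearman_p(rx: np.ndarray, ry: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact permutation p for the rank correlation (all
    permutations of one rank vector)."""
    n = rx.size
    rxc = rx - rx.mean()
    ryc = ry - ry.mean()
    denom = math.sqrt((rxc**2).sum() * (ryc**2).sum())
    perms = np.array(list(itertools.permutations(range(n))))
    rhos = (ryc[perms] @ rxc) / denom
    return float(np.mean(np.abs(rhos) >= abs(rho_obs) - 1e-12))


def spearman_rho(x, y) -> tuple[float, float]:
    """Spearman rank correlation: Pearson correlation of average ranks.

    p-value by exact permutation for n <= 9, t-approximation above.
    Constant input leaves the coefficient undefined (NaN, with a warning).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal lengths >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant input: Spearman rho undefined", stacklevel=2)
        return math.nan, math.nan
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    n = x.size
    if n <= 9:
        p = _exact_spearman_p(rx, ry, rho)
    else:
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * math.sqrt((n - 2) / (1.0 - rho**2))
            p = float(2.0 * sps.t.sf(abs(t), n - 2))
    return rho, min(p, 1.0)


# --------------------------------------------------------------------------
# Feature tables and family-wise correction

FEATURE_COLUMNS = [
    "subject", "group", "session", "measure", "scale", "unit", "variable",
    "epoch", "value",
]


def build_fdr_families(
    results: pd.DataFrame, channel_family_per_region: bool = False
) -> pd.Series:
    """Family label for FDR correction, per test row.

    PLI tests are corrected across all frequency bands within a single
    spatial subdivision; aperiodic tests across the two parameters within
    the subdivision.  For the global and regional scales a subdivision is
    the unit itself (the whole scalp, or one region); for the channel scale
    the default reads the subdivision as the whole channel level (one
    family containing every channel x band, or channel x parameter, test),
    with a per-region channel grouping as the config alternative.
    Families are always per group (R / NR analysed separately).
    """
    required = {"measure", "group", "scale", "unit", "variable"}
    missing = required - set(results.columns)
    if missing:
        raise ValueError(f"unlabeled tests: missing columns {sorted(missing)}")

    def key(row) -> str:
        if row["scale"] == "channel" and not channel_family_per_region:
            return f"{row['measure']}|{row['group']}|channel"
        return f"{row['measure']}|{row['group']}|{row['scale']}|{row['unit']}"

    return results.apply(key, axis=1)


def compare_groups(
    features: pd.DataFrame,
    alpha: float = 0.05,
    unit_mode: str = "pooled",
    channel_family_per_region: bool = False,
) -> pd.DataFrame:
    """Pre vs post comparison per feature and group.

    ``features`` is the long-format epoch-level table (columns
    ``FEATURE_COLUMNS``).  For each (group, measure, scale, unit, variable)
    the pre and post distributions are compared with Mann-Whitney U on the
    pooled epoch values (``unit_mode="pooled"``) or on per-subject medians
    (``unit_mode="subject"``); p-values are BH-FDR corrected within the
    stated families; trend is the sign of the median difference, reported
    only when significant.
    """
    if unit_mode not in ("pooled", "subject"):
        raise ValueError("unit_mode must be 'pooled' or 'subject'")
    present = set(features["group"].unique())
    absent = set(GROUPS) - present
    if absent:
        raise ValueError(f"missing groups in feature table: {sorted(absent)}")

    rows = []
    keys = ["group", "measure", "scale", "unit", "variable"]
    for (group, measure, scale, unit, variable), df in features.groupby(keys):
        pools = {}
        for session in ("pre", "post"):
            sub = df[df["session"] == session]
            if unit_mode == "subject":
                pools[session] = sub.groupby("subject")["value"].median().to_numpy()
            else:
                pools[session] = sub["value"].to_numpy()
        x, y = pools["pre"], pools["post"]
        if x.size == 0 or y.size == 0:
            continue
        u, p = mann_whitney_u(x, y)
        rows.append(
            {
                "feature": f"{measure}:{scale}:{unit}:{variable}",
                "group": group,
                "measure": measure,
                "scale": scale,
                "unit": unit,
                "variable": variable,
                "U": u,
                "p_raw": p,
                "mean_pre": x.mean(),
                "sd_pre": x.std(ddof=1) if x.size > 1 else math.nan,
                "mean_post": y.mean(),
                "sd_post": y.std(ddof=1) if y.size > 1 else math.nan,
                "median_diff": float(np.median(y) - np.median(x)),
                "cohens_d": cohens_d(x, y) if min(x.size, y.size) > 1 else math.nan,
                "n_pre": x.size,
                "n_post": y.size,
            }
        )
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    out["family"] = build_fdr_families(out, channel_family_per_region)
    out["p_fdr"] = np.nan
    for _, idx in out.groupby("family").groups.items():
        adj, _ = fdr_bh(out.loc[idx, "p_raw"].to_numpy(), alpha=alpha)
        out.loc[idx, "p_fdr"] = adj
    out["significant"] = out["p_fdr"] < alpha
    out["trend"] = np.where(
        out["significant"],
        np.where(out["median_diff"] > 0, "up", "down"),
        "",
    )
    return out


def correlate_with_outcome(
    subjects: pd.DataFrame, features: pd.DataFrame, scale: str = "global"
) -> pd.DataFrame:
    """Spearman correlation between per-subject relative feature variation
    and the Labar index, per feature at the given scale (the outcome table:
    exponent, offset, and PLI per band, on a global basis).

    ``subjects`` needs columns ``subject`` and ``labar``; ``features`` is
    the epoch-level long table.
    """
    labar = subjects.set_index("subject")["labar"]
    rows = []
    sel = features[features["scale"] == scale]
    for (measure, variable), df in sel.groupby(["measure", "variable"]):
        variations = {}
        for subject, sdf in df.groupby("subject"):
            pre = sdf.loc[sdf["session"] == "pre", "value"].to_numpy()
            post = sdf.loc[sdf["session"] == "post", "value"].to_numpy()
            if pre.size and post.size:
                variations[subject] = relative_variation(pre, post)
        common = [s for s in variations if s in labar.index
                  and math.isfinite(variations[s])]
        if len(common) < 3:
            raise ValueError(
                f"fewer than 3 subjects with defined variation for "
                f"{measure}:{variable}"
            )
        rho, p = spearman_rho(
            [variations[s] for s in common], labar.loc[common].to_numpy()
        )
        rows.append(
            {
                "measure": measure,
                "variable": variable,
                "rho": rho,
                "p": p,
                "n": len(common),
            }
        )
    return pd.DataFrame(rows)
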
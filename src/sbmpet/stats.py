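"""Nonparametric statistics on loading weights.

Per component: omnibus Kruskal–Wallis across the diagnostic groups with
Benjamini–Hochberg FDR over the K-component family, plus unadjusted Dunn
pairwise post hoc comparisons. Loading–cognition relationships use Spearman
rank correlations, run either in the symptomatic (MCI + AD) subgroup or the
full cohort, with BH applied within each analysis family. All tests are
two-sided and rank-based, hence invariant to monotone transforms of the
inputs.
"""

from __future__ import annotations

import warnings
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

GROUPS = ("CN", "MCI", "AD")
SCORES = ("cdr_sb", "mmse", "lmii", "ravlt_delay")


def kruskal_wallis(values, groups) -> tuple[float, int, float]:
    """Kruskal–Wallis H (tie-corrected mid-ranks) with chi-square p.

    Returns ``(H, df, p)`` with ``df = levels - 1``. If every observation is
    identical the tie correction is degenerate; the test is reported as
    H = 0, p = 1 with a warning.
    """
    values = np.asarray(values, dtype=np.float64)
    groups = np.asarray(groups)
    levels = pd.unique(groups)
    if len(levels) < 2:
        raise ValueError("need at least 2 groups")
    samples = [values[groups == g] for g in levels]
    if any(len(s) == 0 for s in samples):
        raise ValueError("every group needs at least one observation")
    if values.size < 3:
        raise ValueError("need at least 3 observations in total")
    df = len(levels) - 1
    if np.all(values == values[0]):
        warnings.warn("all observations identical; Kruskal-Wallis is degenerate")
        return 0.0, df, 1.0
    h, p = sps.kruskal(*samples)
    return float(h), df, float(p)


def dunn_posthoc(values, groups) -> list[dict]:
    """Dunn's pairwise z tests on pooled mid-ranks, tie-corrected, unadjusted.

    For groups i, j with mean ranks Ri, Rj over the pooled sample of size n:

        z = (Ri - Rj) / sqrt([n(n+1)/12 - T/(12(n-1))] (1/ni + 1/nj))

    with tie term T = sum(t^3 - t). p-values are two-sided normal tails,
    deliberately not adjusted (the omnibus family carries the FDR control).
    """
    values = np.asarray(values, dtype=np.float64)
    groups = np.asarray(groups)
    levels = list(pd.unique(groups))
    if len(levels) < 2:
        raise ValueError("need at least 2 groups")
    n = values.size
    ranks = sps.rankdata(values)
    _, counts = np.unique(values, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    var_base = n * (n + 1) / 12.0 - tie_term / (12.0 * (n - 1))
    results = []
    for a, b in combinations(levels, 2):
        ra = ranks[groups == a]
        rb = ranks[groups == b]
        if var_base <= 0:  # all values tied
            z, p = 0.0, 1.0
        else:
            se = np.sqrt(var_base * (1.0 / ra.size + 1.0 / rb.size))
            z = float((ra.mean() - rb.mean()) / se)
            p = float(2.0 * sps.norm.sf(abs(z)))
        results.append({"pair": (str(a), str(b)), "z": z, "p": p})
    return results


def bh_fdr(p_values, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini–Hochberg step-up FDR control.

    Returns ``(adjusted, rejected)`` in the input order; ``adjusted_(i) =
    min_{j>=i} m p_(j)/j`` clipped at 1, and a p-value is rejected iff its
    adjusted value is <= q.
    """
    p = np.asarray(p_values, dtype=np.float64)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if not 0 < q < 1:
        raise ValueError("q must be in (0, 1)")
    rejected, adjusted, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return adjusted, rejected


def spearman(x, y) -> tuple[float, float, int]:
    """Spearman rank correlation with pairwise deletion of missing values.

    Returns ``(rho, p, n)``; p is the two-sided t-approximation
    ``t = rho sqrt((n-2)/(1-rho^2))``. Requires >= 4 complete pairs and
    nonzero rank variance in both vectors.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = x.size
    if n < 4:
        raise ValueError(f"need at least 4 complete pairs, got {n}")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("zero variance in a rank vector")
    rho, p = sps.spearmanr(x, y)
    return float(rho), float(p), n


def validate_metadata(meta: pd.DataFrame, subject_ids: list[str] | None = None) -> pd.DataFrame:
    """Check the cohort metadata table: groups valid, ids unique and ordered.

    When ``subject_ids`` is given (SubjectMatrix order), the table is
    reindexed to that order and must cover every subject.
    """
    required = {"subject_id", "group"}
    if not required.issubset(meta.columns):
        raise ValueError(f"metadata must have columns {sorted(required)}")
    if meta["subject_id"].duplicated().any():
        raise ValueError("duplicate subject_id in metadata")
    bad = set(meta["group"]) - set(GROUPS)
    if bad:
        raise ValueError(f"unknown diagnostic groups {sorted(bad)}; expected {GROUPS}")
    if subject_ids is not None:
        missing = set(subject_ids) - set(meta["subject_id"])
        if missing:
            raise ValueError(f"metadata missing subjects {sorted(missing)}")
        meta = meta.set_index("subject_id").loc[list(subject_ids)].reset_index()
    return meta


def run_group_analysis(mixing: np.ndarray, meta: pd.DataFrame, q: float = 0.05) -> pd.DataFrame:
    """Omnibus Kruskal–Wallis per component with BH over the K-test family.

    Returns one omnibus row per component (``comparison="omnibus"``, BH-
    adjusted) plus unadjusted Dunn pairwise rows (``p_adjusted = NaN``).
    """
    mixing = np.asarray(mixing, dtype=np.float64)
    groups = meta["group"].to_numpy()
    present = set(groups)
    absent = set(GROUPS) - present
    if absent:
        raise ValueError(f"diagnostic groups absent from cohort: {sorted(absent)}")
    if mixing.shape[0] != len(meta):
        raise ValueError("mixing rows do not match metadata rows")
    k = mixing.shape[1]
    omnibus = []
    for comp in range(k):
        h, df, p = kruskal_wallis(mixing[:, comp], groups)
        omnibus.append({"component": comp, "comparison": "omnibus",
                        "statistic": h, "df": df, "p_value": p, "n": len(meta)})
    p_vals = np.array([row["p_value"] for row in omnibus])
    adjusted, rejected = bh_fdr(p_vals, q)
    rows = []
    for row, adj, rej in zip(omnibus, adjusted, rejected):
        rows.append({**row, "p_adjusted": float(adj), "rejected": bool(rej)})
    for comp in range(k):
        for res in dunn_posthoc(mixing[:, comp], groups):
            rows.append({
                "component": comp,
                "comparison": f"{res['pair'][0]} vs {res['pair'][1]}",
                "statistic": res["z"], "df": np.nan,
                "p_value": res["p"], "n": len(meta),
                "p_adjusted": np.nan, "rejected": bool(res["p"] < 0.05),
            })
    return pd.DataFrame(rows)


def run_cognition_analysis(
    mixing: np.ndarray,
    meta: pd.DataFrame,
    cohort: str = "symptomatic_only",
    scores: tuple[str, ...] = SCORES,
    q: float = 0.05,
) -> pd.DataFrame:
    """Spearman loading–score correlations with BH within the analysis family.

    ``cohort="symptomatic_only"`` drops CN subjects before ranking;
    ``cohort="full"`` keeps everyone. The BH family is every (component,
    score) pair tested in the run; per-cell n reflects pairwise deletion of
    missing scores.
    """
    if cohort not in ("symptomatic_only", "full"):
        raise ValueError(f"unknown cohort {cohort!r}")
    mixing = np.asarray(mixing, dtype=np.float64)
    if mixing.shape[0] != len(meta):
        raise ValueError("mixing rows do not match metadata rows")
    keep = np.ones(len(meta), dtype=bool)
    if cohort == "symptomatic_only":
        keep = (meta["group"] != "CN").to_numpy()
    if not keep.any():
        raise ValueError("cohort is empty after filtering")
    sub_meta = meta.loc[keep]
    sub_mixing = mixing[keep]
    rows = []
    for comp in range(mixing.shape[1]):
        for score in scores:
            if score not in sub_meta.columns:
                raise ValueError(f"score {score!r} missing from metadata")
            y = pd.to_numeric(sub_meta[score], errors="coerce").to_numpy()
            if np.sum(np.isfinite(y)) < 4:
                raise ValueError(f"score {score!r} has fewer than 4 observations")
            rho, p, n = spearman(sub_mixing[:, comp], y)
            rows.append({"component": comp, "score": score, "cohort": cohort,
                         "statistic": rho, "p_value": p, "n": n})
    table = pd.DataFrame(rows)
    adjusted, rejected = bh_fdr(table["p_value"].to_numpy(), q)
    table["p_adjusted"] = adjusted
    table["rejected"] = rejected
    return table
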
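"""Nonparametric statistics and table builders for site-level records.

Site records carry probing pocket depth (PPD, integer mm), bleeding on
probing (BOP, binary) and edema depth (ED, mm) per probing site and
timepoint. Sites are stratified by their baseline findings into four
categories (PPD<=3 without/with BOP, PPD 4-5, PPD>=6); continuous variables
are summarized as median [IQR] (linear-interpolation percentiles) and
compared with the paired Wilcoxon signed-rank test, independent groups with
the Mann-Whitney U test, and categorical frequencies with the Pearson
chi-square test (Yates continuity correction on 2x2 tables). All tests are
two-tailed; p < 0.05 is the conventional significance level and no
multiplicity adjustment is applied.

The Wilcoxon and Mann-Whitney implementations use exact enumeration of the
permutation null (with mid-ranks under ties) for small samples and the
tie-corrected normal approximation otherwise; the crossover sizes are
recorded in the results.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "CATEGORY_LABELS",
    "TestResult",
    "StatTable",
    "categorize",
    "categorize_frame",
    "median_iqr",
    "wilcoxon_paired",
    "mann_whitney",
    "chi_square",
    "build_table2",
    "build_table3",
]

CATEGORY_LABELS = ("PPD<=3_noBOP", "PPD<=3_BOP", "PPD4-5", "PPD>=6")

SITE_COLUMNS = [
    "patient_id", "tooth_id", "site_position", "timepoint",
    "ppd_mm", "bop", "ed_mm", "edema_present",
]


@dataclass
class TestResult:
    statistic: float
    p: float
    test: str
    n: int
    method: str = ""
    degenerate: bool = False


# ---------------------------------------------------------------------------
# categorization and summaries


def categorize(ppd_mm: float, bop: bool) -> str:
    """Baseline stratum of a site from its t0 PPD and BOP.

    PPD <= 3 mm is split by BOP; BOP is ignored for deeper pockets.
    """
    if ppd_mm < 0:
        raise ValueError(f"PPD must be non-negative, got {ppd_mm}")
    if ppd_mm <= 3:
        return "PPD<=3_BOP" if bop else "PPD<=3_noBOP"
    if ppd_mm <= 5:
        return "PPD4-5"
    return "PPD>=6"


def categorize_frame(records: pd.DataFrame) -> pd.Series:
    """Vectorized :func:`categorize` over a site-record frame (t0 rows)."""
    return pd.Series(
        [categorize(p, bool(b)) for p, b in zip(records["ppd_mm"], records["bop"])],
        index=records.index,
    )


def median_iqr(values) -> tuple[float, float, float]:
    """(median, q1, q3) with linear-interpolation percentiles."""
    vals = np.asarray(values, dtype=float)
    if vals.size == 0:
        raise ValueError("median_iqr requires at least one value")
    med = float(np.median(vals))
    q1, q3 = (float(q) for q in np.percentile(vals, [25, 75], method="linear"))
    return med, q1, q3


def _fmt_median_iqr(values) -> str:
    med, q1, q3 = median_iqr(values)

    def f(x: float) -> str:
        return f"{x:g}"

    return f"{f(med)} [{f(q1)}, {f(q3)}]"


def _round_half_up_pct(count: int, denom: int) -> int:
    if denom == 0:
        raise ValueError("percentage denominator is zero")
    return int(np.floor(100.0 * count / denom + 0.5))


# ---------------------------------------------------------------------------
# rank tests


def _midranks(x: np.ndarray) -> np.ndarray:
    return sps.rankdata(x, method="average")


def wilcoxon_paired(
    x_t0, x_t1, exact_max_n: int = 12
) -> TestResult:
    """Paired Wilcoxon signed-rank test, two-tailed.

    Zero differences are dropped (classical reduction), mid-ranks are used
    for tied absolute differences, and the two-sided p-value is
    ``P(|T - E[T]| >= |t_obs - E[T]|)`` for T = sum of positive-difference
    ranks. The null distribution is enumerated exactly over all sign
    assignments when the effective n is at most ``exact_max_n``; otherwise
    the tie-corrected normal approximation is used (no continuity
    correction). All differences zero yields a degenerate result with p = 1.
    """
    x0 = np.asarray(x_t0, dtype=float)
    x1 = np.asarray(x_t1, dtype=float)
    if x0.shape != x1.shape:
        raise ValueError("paired samples must have equal length")
    d = x1 - x0
    d = d[d != 0]
    n = d.size
    if n == 0:
        return TestResult(0.0, 1.0, "wilcoxon", 0, "degenerate", degenerate=True)
    ranks = _midranks(np.abs(d))
    t_pos = float(ranks[d > 0].sum())
    mu = ranks.sum() / 2.0
    dev = abs(t_pos - mu)

    if n <= exact_max_n:
        # exact: T' = sum of ranks with + sign over all 2^n assignments,
        # built by convolution over the per-pair {0, r_i} contributions
        scale = 2  # mid-ranks are multiples of 1/2
        ri = np.rint(ranks * scale).astype(int)
        dist = np.zeros(ri.sum() + 1, dtype=float)
        dist[0] = 1.0
        for r in ri:
            nxt = dist.copy()
            nxt[r:] += dist[: dist.size - r]
            dist = nxt
        dist /= dist.sum()
        support = np.arange(dist.size) / scale
        p = float(dist[np.abs(support - mu) >= dev - 1e-12].sum())
        method = "exact"
    else:
        _, tie_counts = np.unique(np.abs(d), return_counts=True)
        var = n * (n + 1) * (2 * n + 1) / 24.0 - (tie_counts**3 - tie_counts).sum() / 48.0
        if var <= 0:
            return TestResult(t_pos, 1.0, "wilcoxon", n, "degenerate", degenerate=True)
        z = dev / np.sqrt(var)
        p = float(2.0 * sps.norm.sf(z))
        method = "normal-tie-corrected"
    return TestResult(t_pos, min(p, 1.0), "wilcoxon", n, method)


def mann_whitney(a, b, exact_max_n: int = 8) -> TestResult:
    """Mann-Whitney U test for two independent samples, two-tailed.

    U is reported for the first sample. The null is enumerated exactly over
    all C(n_a + n_b, n_a) group assignments of the (mid-)ranks when both
    groups have at most ``exact_max_n`` observations (or the pooled size is
    at most 12, where enumeration is trivially cheap); otherwise the
    tie-corrected normal approximation is used.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = a.size, b.size
    if na == 0 or nb == 0:
        raise ValueError("mann_whitney requires two non-empty samples")
    pooled = np.concatenate([a, b])
    ranks = _midranks(pooled)
    r1 = float(ranks[:na].sum())
    u1 = r1 - na * (na + 1) / 2.0
    mu = na * nb / 2.0
    dev = abs(u1 - mu)

    if (na <= exact_max_n and nb <= exact_max_n) or na + nb <= 12:
        total = 0
        hits = 0
        for idx in combinations(range(na + nb), na):
            rs = ranks[list(idx)].sum()
            u = rs - na * (na + 1) / 2.0
            if abs(u - mu) >= dev - 1e-12:
                hits += 1
            total += 1
        assert total == comb(na + nb, na)
        p = hits / total
        method = "exact"
    else:
        nn = na + nb
        _, tie_counts = np.unique(pooled, return_counts=True)
        tie_term = (tie_counts**3 - tie_counts).sum() / (nn * (nn - 1))
        var = na * nb / 12.0 * ((nn + 1) - tie_term)
        if var <= 0:
            return TestResult(u1, 1.0, "mann-whitney", na + nb, "degenerate", degenerate=True)
        z = dev / np.sqrt(var)
        p = float(2.0 * sps.norm.sf(z))
        method = "normal-tie-corrected"
    return TestResult(u1, min(p, 1.0), "mann-whitney", na + nb, method)


def chi_square(table, yates: str = "auto") -> tuple[float, int, float]:
    """Pearson chi-square test on a contingency table.

    ``yates='auto'`` applies the continuity correction iff the table is 2x2;
    ``'always'``/``'never'`` force it. Returns (chi2, df, p).
    """
    tab = np.asarray(table, dtype=float)
    if tab.ndim != 2 or tab.shape[0] < 2 or tab.shape[1] < 2:
        raise ValueError(f"contingency table must be at least 2x2, got {tab.shape}")
    if np.any(tab < 0):
        raise ValueError("contingency counts must be non-negative")
    if np.any(tab.sum(axis=0) == 0) or np.any(tab.sum(axis=1) == 0):
        raise ValueError("contingency table has a zero marginal")
    if yates == "auto":
        correction = tab.shape == (2, 2)
    elif yates == "always":
        correction = True
    elif yates == "never":
        correction = False
    else:
        raise ValueError(f"unknown yates mode {yates!r}")
    res = sps.chi2_contingency(tab, correction=correction)
    return float(res.statistic), int(res.dof), float(res.pvalue)


# ---------------------------------------------------------------------------
# table builders


@dataclass
class StatTable:
    """Rows of a rendered summary table plus full audit metadata."""

    name: str
    rows: list[dict] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)

    def to_csv(self, path: str) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def to_json_dict(self) -> dict:
        return {"name": self.name, "rows": self.rows, "metadata": self.metadata}

    def row(self, stratum: str) -> dict:
        for r in self.rows:
            if r["stratum"] == stratum:
                return r
        raise KeyError(stratum)


def _paired_pivot(records: pd.DataFrame, value: str) -> pd.DataFrame:
    """Wide frame with one row per site, columns ``<value>_t0`` / ``<value>_t1``."""
    req = set(SITE_COLUMNS) - {"edema_present"}
    missing = req - set(records.columns)
    if missing:
        raise ValueError(f"site records missing columns: {sorted(missing)}")
    key = ["patient_id", "tooth_id", "site_position"]
    dup = records.duplicated(subset=key + ["timepoint"])
    if dup.any():
        raise ValueError("duplicate (patient, tooth, site, timepoint) records")
    wide = records.pivot_table(
        index=key, columns="timepoint", values=value, aggfunc="first"
    )
    for tp in ("t0", "t1"):
        if tp not in wide.columns:
            raise ValueError(f"records contain no {tp} rows")
    orphans = wide[wide.isna().any(axis=1)]
    if len(orphans):
        raise ValueError(
            f"{len(orphans)} sites lack a matched pair; first offenders: "
            f"{orphans.index[:5].tolist()}"
        )
    wide = wide.rename(columns={"t0": f"{value}_t0", "t1": f"{value}_t1"})
    # carry baseline stratum
    t0 = records[records["timepoint"] == "t0"].set_index(key)
    wide["category"] = pd.Series(
        [categorize(p, bool(b)) for p, b in zip(t0["ppd_mm"], t0["bop"])],
        index=t0.index,
    )
    return wide.reset_index()


def build_table2(records: pd.DataFrame) -> StatTable:
    """Clinical parameters at single sites before/after treatment.

    Upper block: per-stratum PPD median [IQR] at both timepoints with the
    paired Wilcoxon p. Lower block: site counts (and half-up integer
    percentages, denominators recorded) per merged PPD band at each
    timepoint with the Pearson chi-square p over the 2x3 band table, plus a
    BOP frequency row tested 2x2 with Yates correction.
    """
    wide = _paired_pivot(records, "ppd_mm")
    bop_wide = _paired_pivot(records, "bop")
    table = StatTable(
        name="table2",
        metadata={
            "percentile_convention": "linear interpolation",
            "percent_rounding": "half-up to integer",
            "tests": {
                "ppd_shift": "Wilcoxon signed-rank, two-tailed, zeros dropped",
                "category_shift": "Pearson chi-square, no Yates (2x3)",
                "bop_shift": "Pearson chi-square with Yates (2x2)",
            },
        },
    )

    def ppd_row(stratum: str, sub: pd.DataFrame) -> dict:
        res = wilcoxon_paired(sub["ppd_mm_t0"], sub["ppd_mm_t1"])
        return {
            "block": "ppd",
            "stratum": stratum,
            "n": int(len(sub)),
            "summary_t0": _fmt_median_iqr(sub["ppd_mm_t0"]),
            "summary_t1": _fmt_median_iqr(sub["ppd_mm_t1"]),
            "test": "wilcoxon",
            "p": res.p,
        }

    table.rows.append(ppd_row("all_sites", wide))
    for cat in CATEGORY_LABELS:
        sub = wide[wide["category"] == cat]
        if len(sub):
            table.rows.append(ppd_row(cat, sub))
        else:
            table.rows.append(
                {"block": "ppd", "stratum": cat, "n": 0, "summary_t0": "", "summary_t1": "", "test": "wilcoxon", "p": np.nan}
            )

    # category-count block on merged PPD bands
    def band(ppd: pd.Series) -> pd.Series:
        return pd.cut(ppd, [-np.inf, 3, 5, np.inf], labels=["PPD<=3", "PPD4-5", "PPD>=6"])

    n_t0 = len(wide)
    n_t1 = len(wide)
    c_t0 = band(wide["ppd_mm_t0"]).value_counts().reindex(["PPD<=3", "PPD4-5", "PPD>=6"]).fillna(0).astype(int)
    c_t1 = band(wide["ppd_mm_t1"]).value_counts().reindex(["PPD<=3", "PPD4-5", "PPD>=6"]).fillna(0).astype(int)
    chi2, df, p_cat = chi_square(np.vstack([c_t0.values, c_t1.values]), yates="auto")
    for b in ["PPD<=3", "PPD4-5", "PPD>=6"]:
        table.rows.append(
            {
                "block": "category_counts",
                "stratum": b,
                "n": int(c_t0[b] + c_t1[b]),
                "count_t0": int(c_t0[b]),
                "denom_t0": n_t0,
                "pct_t0": _round_half_up_pct(int(c_t0[b]), n_t0),
                "count_t1": int(c_t1[b]),
                "denom_t1": n_t1,
                "pct_t1": _round_half_up_pct(int(c_t1[b]), n_t1),
                "test": "chi-square",
                "p": p_cat,
            }
        )
    bop0 = int(bop_wide["bop_t0"].sum())
    bop1 = int(bop_wide["bop_t1"].sum())
    chi2b, dfb, p_bop = chi_square(
        [[bop0, n_t0 - bop0], [bop1, n_t1 - bop1]], yates="auto"
    )
    table.rows.append(
        {
            "block": "category_counts",
            "stratum": "with_BOP",
            "n": bop0 + bop1,
            "count_t0": bop0,
            "denom_t0": n_t0,
            "pct_t0": _round_half_up_pct(bop0, n_t0),
            "count_t1": bop1,
            "denom_t1": n_t1,
            "pct_t1": _round_half_up_pct(bop1, n_t1),
            "test": "chi-square-yates",
            "p": p_bop,
        }
    )
    return table


def build_table3(records: pd.DataFrame) -> StatTable:
    """Edema extent at single sites before/after treatment.

    Affected-site counts/percentages at both timepoints (2x2 chi-square with
    Yates), then ED median [IQR] with paired Wilcoxon p for all sites with
    baseline edema and per baseline stratum. ED values are rounded half-up
    to integer mm before summarizing, matching integer-mm probe readings.
    """
    wide = _paired_pivot(records, "ed_mm")
    for tp in ("t0", "t1"):
        wide[f"ed_mm_{tp}"] = np.floor(wide[f"ed_mm_{tp}"] + 0.5)
    n_sites = len(wide)
    aff0 = int((wide["ed_mm_t0"] > 0).sum())
    aff1 = int((wide["ed_mm_t1"] > 0).sum())
    table = StatTable(
        name="table3",
        metadata={
            "percentile_convention": "linear interpolation",
            "percent_rounding": "half-up to integer",
            "ed_rounding": "half-up to integer mm before summaries",
            "tests": {
                "affected_shift": "Pearson chi-square with Yates (2x2)",
                "ed_shift": "Wilcoxon signed-rank, two-tailed, zeros dropped",
            },
        },
    )
    if n_sites == 0:
        raise ValueError("no site records")
    if aff0 + aff1 == 0 or aff0 + aff1 == 2 * n_sites:
        p_aff = np.nan  # degenerate margin: no affected (or no unaffected) sites
    else:
        _, _, p_aff = chi_square(
            [[aff0, n_sites - aff0], [aff1, n_sites - aff1]], yates="auto"
        )
    table.rows.append(
        {
            "block": "affected_counts",
            "stratum": "all_sites",
            "n": n_sites,
            "count_t0": aff0,
            "denom_t0": n_sites,
            "pct_t0": _round_half_up_pct(aff0, n_sites),
            "count_t1": aff1,
            "denom_t1": n_sites,
            "pct_t1": _round_half_up_pct(aff1, n_sites),
            "test": "chi-square-yates",
            "p": p_aff,
        }
    )

    initial = wide[wide["ed_mm_t0"] > 0]

    def ed_row(stratum: str, sub: pd.DataFrame) -> dict:
        if len(sub) == 0:
            return {
                "block": "ed",
                "stratum": stratum,
                "n": 0,
                "summary_t0": "",
                "summary_t1": "",
                "test": "wilcoxon",
                "p": np.nan,
                "empty": True,
            }
        res = wilcoxon_paired(sub["ed_mm_t0"], sub["ed_mm_t1"])
        return {
            "block": "ed",
            "stratum": stratum,
            "n": int(len(sub)),
            "summary_t0": _fmt_median_iqr(sub["ed_mm_t0"]),
            "summary_t1": _fmt_median_iqr(sub["ed_mm_t1"]),
            "test": "wilcoxon",
            "p": res.p,
            "empty": False,
        }

    table.rows.append(ed_row("all_sites_with_initial_edema", initial))
    for cat in CATEGORY_LABELS:
        table.rows.append(ed_row(cat, initial[initial["category"] == cat]))
    return table
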
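"""Hit ranking, extreme-group comparison, ROI classes, and screen-vs-translation stats.

The screen's "hits" are tile positions ranked by a response (ascending median
alpha-SMA CTCF by convention).  The extreme groups (k lowest vs k highest,
default k = 50) are compared by a Welch two-sample test or a two-way ANOVA.
Regions of interest (ROIs) are classified by density x marker tiers, and the
screening measurements at each ROI are statistically compared with the
translation measurements on homogeneous substrates (two-way ANOVA with
Sidak-adjusted pairwise contrasts; one-way ANOVA with Tukey HSD and a
compact-letter display across ROIs).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "HitRanking",
    "GroupComparison",
    "rank_hits",
    "compare_extremes",
    "two_group_test",
    "classify_rois",
    "ROI_CLASSES",
    "compare_screen_vs_translation",
    "sidak_adjust",
    "tukey_pairwise",
    "compact_letter_display",
]

_TIEBREAK = ["dog", "col", "row"]


@dataclass(frozen=True)
class HitRanking:
    """Tiles ordered ascending by one response; k is the extreme-group size."""

    response: str
    table: pd.DataFrame  # sorted, with a 1-based 'rank' column
    k: int = 50

    def lowest(self, k: int | None = None) -> pd.DataFrame:
        k = k or self.k
        return self.table.head(k)

    def highest(self, k: int | None = None) -> pd.DataFrame:
        k = k or self.k
        return self.table.tail(k)


def rank_hits(merged: pd.DataFrame, response: str, k: int = 50) -> HitRanking:
    """Stable ascending sort of tiles by *response*; ties broken by (dog, col, row)."""
    if response not in merged.columns:
        raise ValueError(f"response {response!r} not in table")
    sub = merged.dropna(subset=[response])
    if sub.empty:
        raise ValueError(f"all values of {response!r} are missing")
    by = [response] + [c for c in _TIEBREAK if c in sub.columns]
    out = sub.sort_values(by, kind="mergesort").reset_index(drop=True)
    out.insert(0, "rank", np.arange(1, len(out) + 1))
    return HitRanking(response, out, k)


@dataclass(frozen=True)
class GroupComparison:
    """Two-group (or multi-group) comparison summary."""

    group_means: dict
    group_sds: dict
    statistic: float
    p_value: float
    method: str
    fold_change: float | None = None  # mean(high)/mean(low); None if undefined
    adjusted_p: float | None = None
    adjustment: str | None = None


def compare_extremes(
    ranking: HitRanking, k: int | None = None, method: str = "welch"
) -> GroupComparison:
    """Compare the k lowest vs k highest hits.

    Default is Welch's unequal-variance t-test; ``method='anova2'`` runs a
    two-way ANOVA with factors group x source DOG instead.  The fold change
    is mean(high)/mean(low), undefined (None) when mean(low) <= 0.
    """
    k = k or ranking.k
    if 2 * k > len(ranking.table):
        raise ValueError(f"2k={2 * k} exceeds the {len(ranking.table)} ranked rows")
    low = ranking.lowest(k)
    high = ranking.highest(k)
    lo = low[ranking.response].to_numpy(dtype=float)
    hi = high[ranking.response].to_numpy(dtype=float)
    mean_lo, mean_hi = lo.mean(), hi.mean()
    fold = float(mean_hi / mean_lo) if mean_lo > 0 else None

    if method == "welch":
        statistic, p = two_group_test(hi, lo)
        label = "Welch t-test"
    elif method == "anova2":
        import statsmodels.api as sm
        import statsmodels.formula.api as smf

        df = pd.concat(
            [
                pd.DataFrame({"y": lo, "group": "low", "dog": low.get("dog", "all")}),
                pd.DataFrame({"y": hi, "group": "high", "dog": high.get("dog", "all")}),
            ],
            ignore_index=True,
        )
        if df["dog"].nunique() > 1:
            model = smf.ols("y ~ C(group) + C(dog)", data=df).fit()
        else:
            model = smf.ols("y ~ C(group)", data=df).fit()
        tab = sm.stats.anova_lm(model, typ=2)
        statistic = float(tab.loc["C(group)", "F"])
        p = float(tab.loc["C(group)", "PR(>F)"])
        label = "two-way ANOVA (group x dog, type II)"
    else:
        raise ValueError("method must be 'welch' or 'anova2'")
    return GroupComparison(
        {"low": float(mean_lo), "high": float(mean_hi)},
        {"low": float(lo.std(ddof=1)), "high": float(hi.std(ddof=1))},
        statistic, p, label, fold,
    )


def two_group_test(a, b) -> tuple[float, float]:
    """Welch unequal-variance two-sample test; the comparison behind
    :func:`compare_extremes`.  Identical constant groups yield (0, 1)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if np.ptp(a) == 0 and np.ptp(b) == 0 and a.mean() == b.mean():
        return 0.0, 1.0  # no variance, no difference: no evidence
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.pvalue)


ROI_CLASSES = (
    "low_density_low_asma",
    "high_density_mid_asma",
    "high_density_high_asma",
    "unclassified",
)


def classify_rois(
    merged: pd.DataFrame,
    density_cutpoints: tuple[float, float] | None = None,
    ctcf_cutpoints: tuple[float, float] | None = None,
    response: str = "median_ctcf_asma",
    n_candidates: int = 2,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Assign each tile to a (density tier x marker tier) ROI class.

    Cutpoints default to within-dataset tertiles.  Returns the table with a
    ``roi_class`` column, a candidate table (rows nearest each occupied
    class's tier centroid, the ROI picks), and the thresholds used.
    """
    dens = merged["density"].to_numpy(dtype=float)
    ctcf = merged[response].to_numpy(dtype=float)
    if density_cutpoints is None:
        density_cutpoints = tuple(np.nanquantile(dens, [1 / 3, 2 / 3]))
    if ctcf_cutpoints is None:
        ctcf_cutpoints = tuple(np.nanquantile(ctcf, [1 / 3, 2 / 3]))
    for cp, name in ((density_cutpoints, "density"), (ctcf_cutpoints, "ctcf")):
        if not cp[0] < cp[1]:
            raise ValueError(f"degenerate {name} cutpoints {cp}: must be strictly increasing")

    d_tier = np.digitize(dens, density_cutpoints)  # 0 low, 1 mid, 2 high
    c_tier = np.digitize(ctcf, ctcf_cutpoints)
    cls = np.full(len(merged), "unclassified", dtype=object)
    cls[(d_tier == 0) & (c_tier == 0)] = "low_density_low_asma"
    cls[(d_tier == 2) & (c_tier == 1)] = "high_density_mid_asma"
    cls[(d_tier == 2) & (c_tier == 2)] = "high_density_high_asma"
    cls[np.isnan(dens) | np.isnan(ctcf)] = "unclassified"
    out = merged.copy()
    out["roi_class"] = cls

    # candidates: rows nearest the class centroid in standardized (density, ctcf)
    d_sd = np.nanstd(dens) or 1.0
    c_sd = np.nanstd(ctcf) or 1.0
    cand_rows = []
    for label in ROI_CLASSES[:3]:
        sub = out[out["roi_class"] == label]
        if sub.empty:
            continue
        cd = sub["density"].mean()
        cc = sub[response].mean()
        dist = np.hypot((sub["density"] - cd) / d_sd, (sub[response] - cc) / c_sd)
        cand = sub.loc[dist.nsmallest(n_candidates).index]
        cand_rows.append(cand)
    candidates = (
        pd.concat(cand_rows, ignore_index=True) if cand_rows else out.iloc[0:0].copy()
    )
    thresholds = dict(
        density_cutpoints=tuple(float(v) for v in density_cutpoints),
        ctcf_cutpoints=tuple(float(v) for v in ctcf_cutpoints),
        response=response,
    )
    return out, candidates, thresholds


def sidak_adjust(p_values, m: int | None = None) -> np.ndarray:
    """Sidak multiple-comparison adjustment: p_adj = 1 - (1 - p)^m."""
    p = np.asarray(p_values, dtype=float)
    m = m or p.size
    return np.minimum(1.0, 1.0 - (1.0 - p) ** m)


def tukey_pairwise(values, groups, alpha: float = 0.05) -> pd.DataFrame:
    """Tukey HSD pairwise comparisons (via statsmodels); returns the pair table."""
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    res = pairwise_tukeyhsd(np.asarray(values, dtype=float), np.asarray(groups), alpha=alpha)
    tab = pd.DataFrame(res.summary().data[1:], columns=res.summary().data[0])
    tab["p-adj"] = res.pvalues
    return tab


def compact_letter_display(
    groups: list, pair_pvalues: dict, alpha: float = 0.05
) -> dict:
    """Insert-and-absorb compact-letter display.

    ``pair_pvalues`` maps frozenset({g1, g2}) -> adjusted p-value.  Two groups
    share a letter iff their adjusted p > alpha (not significantly different).
    """
    letters: list[set] = [set(groups)]  # start: everyone shares one letter
    for i, g1 in enumerate(groups):
        for g2 in groups[i + 1 :]:
            p = pair_pvalues.get(frozenset((g1, g2)), 1.0)
            if p > alpha:
                continue
            # significant pair: split every letter set containing both
            new_sets = []
            for s in letters:
                if g1 in s and g2 in s:
                    new_sets.append(s - {g1})
                    new_sets.append(s - {g2})
                else:
                    new_sets.append(s)
            # absorb subsets
            letters = [
                s for s in new_sets
                if s and not any(s < t for t in new_sets)
            ]
            # deduplicate
            uniq = []
            for s in letters:
                if s not in uniq:
                    uniq.append(s)
            letters = uniq
    # ensure every non-significant pair shares at least one set (guaranteed by
    # construction) and assign letters in group order for determinism
    letters.sort(key=lambda s: [groups.index(g) for g in sorted(s, key=groups.index)])
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {g: "" for g in groups}
    for li, s in enumerate(letters):
        for g in groups:
            if g in s:
                out[g] += alphabet[li % len(alphabet)]
    return out


def compare_screen_vs_translation(
    screen: pd.DataFrame,
    translation: pd.DataFrame,
    responses=("density", "median_ctcf_asma", "median_ctcf_col1"),
    roi_col: str = "roi",
    alpha: float = 0.05,
) -> dict:
    """Statistical comparison of screening vs translation measurements.

    For each response: (1) a two-way ANOVA with factors source
    (screen/translation) x ROI; (2) Sidak-adjusted Welch contrasts of screen
    vs translation within each ROI; (3) a one-way ANOVA across the
    translation ROIs (plus any controls present) with Tukey HSD and a
    compact-letter display.  ROIs with fewer than 2 observations in either
    source are skipped with a warning.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    results: dict = {}
    scr = screen.assign(source="screen")
    tra = translation.assign(source="translation")
    both = pd.concat([scr, tra], ignore_index=True)
    for resp in responses:
        if resp not in both.columns:
            continue
        sub = both.dropna(subset=[resp, roi_col])
        entry: dict = {}
        # (1) two-way ANOVA source x ROI
        if sub["source"].nunique() == 2 and sub[roi_col].nunique() >= 2:
            model = smf.ols(f"Q('{resp}') ~ C(source) * C({roi_col})", data=sub).fit()
            tab = sm.stats.anova_lm(model, typ=2)
            entry["anova2"] = tab
        # (2) per-ROI screen vs translation contrasts, Sidak-adjusted
        rois = sorted(sub[roi_col].unique())
        raw_p, contrasts = [], []
        for roi in rois:
            a = sub[(sub[roi_col] == roi) & (sub["source"] == "screen")][resp].to_numpy()
            b = sub[(sub[roi_col] == roi) & (sub["source"] == "translation")][resp].to_numpy()
            if len(a) < 2 or len(b) < 2:
                warnings.warn(f"ROI {roi!r}, response {resp!r}: <2 observations, contrast skipped")
                continue
            res = stats.ttest_ind(a, b, equal_var=False)
            raw_p.append(float(res.pvalue))
            contrasts.append(
                dict(
                    roi=roi, response=resp,
                    mean_screen=float(a.mean()), sd_screen=float(a.std(ddof=1)),
                    mean_translation=float(b.mean()), sd_translation=float(b.std(ddof=1)),
                    statistic=float(res.statistic), p_raw=float(res.pvalue),
                )
            )
        if contrasts:
            adj = sidak_adjust(raw_p)
            for c, pa in zip(contrasts, adj):
                c["p_sidak"] = float(pa)
                c["significant"] = bool(pa < alpha)
            entry["screen_vs_translation"] = pd.DataFrame(contrasts)
        # (3) one-way ANOVA + Tukey + compact letters on the translation arm
        tra_sub = tra.dropna(subset=[resp, roi_col])
        grp_sizes = tra_sub.groupby(roi_col)[resp].count()
        ok = grp_sizes[grp_sizes >= 2].index
        tra_sub = tra_sub[tra_sub[roi_col].isin(ok)]
        if tra_sub[roi_col].nunique() >= 2:
            groups = sorted(tra_sub[roi_col].unique())
            arrays = [tra_sub[tra_sub[roi_col] == g][resp].to_numpy() for g in groups]
            f, p = stats.f_oneway(*arrays)
            tuk = tukey_pairwise(tra_sub[resp], tra_sub[roi_col], alpha)
            pairs = {
                frozenset((r["group1"], r["group2"])): float(r["p-adj"])
                for _, r in tuk.iterrows()
            }
            letters = compact_letter_display(groups, pairs, alpha)
            entry["one_way"] = dict(F=float(f), p=float(p), tukey=tuk, letters=letters)
        results[resp] = entry
    return results
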
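"""Stability, reproducibility and significance screening of radiomic features.

The battery mirrors a full phantom feature-qualification study:

* **Friedman stability vs segmentation** - repeated-measures test of a
  segmentation-method effect per feature (stable when p >= 0.05).  With
  exactly two methods the Friedman statistic degenerates, so the exact
  two-sided sign test is used; three or more methods use the standard
  Friedman chi-square.
* **COV stability vs reconstruction** - per lesion, the percent coefficient
  of variation of a feature across the settings of one family, averaged
  over lesions; a feature's representative COV is the worst (largest) over
  families, classed as stable (<=5%), quite stable (5-10%], poorly stable
  (10-20%] or unstable (>20%).
* **ICC reproducibility** - one-way random, single-measure ICC(1,1) per
  feature on paired test-retest values; reproducible when ICC > 0.6 in both
  test-retest datasets.  ICC(3,1) is available behind a flag.
* **Mann-Whitney discrimination** of heterogeneous vs homogeneous lesions,
  **Spearman correlation** with the ground-truth total heterogeneity H_GS
  (Pearson behind a flag), and a **paired t-test** of the Sphericity feature
  against the ground-truth sphericity.

No multiple-testing correction is applied to the per-feature p < 0.05
read-outs; a Benjamini-Hochberg column is emitted alongside for
transparency.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

STABILITY_CLASSES = ("stable", "quite_stable", "poorly_stable", "unstable")


def classify_cov(cov: float) -> str:
    """COV (%) -> stability class; boundaries are inclusive on the left bin."""
    if cov < 0:
        raise ValueError("COV must be >= 0")
    if cov <= 5.0:
        return "stable"
    if cov <= 10.0:
        return "quite_stable"
    if cov <= 20.0:
        return "poorly_stable"
    return "unstable"


def _check_aligned(frames: dict[str, pd.DataFrame]) -> list[pd.DataFrame]:
    vals = list(frames.values())
    base = vals[0]
    for df in vals[1:]:
        if not df.index.equals(base.index) or not df.columns.equals(base.columns):
            raise ValueError("mismatched lesion sets or feature registries")
    return vals


def friedman_stability(features_by_method: dict[str, pd.DataFrame]) -> pd.Series:
    """Per-feature p-value for a segmentation-method effect.

    Input: one lesions x features frame per method, aligned on both axes.
    k = 2 methods -> exact two-sided sign test on the non-tied pairs
    (all-tied features score p = 1); k >= 3 -> Friedman chi-square.
    """
    frames = _check_aligned(features_by_method)
    if len(frames) < 2:
        raise ValueError("need at least two methods")
    if len(frames[0]) < 5:
        raise ValueError("need at least 5 lesions")
    cols = frames[0].columns
    pvals = {}
    if len(frames) == 2:
        a, b = frames[0].to_numpy(), frames[1].to_numpy()
        for j, c in enumerate(cols):
            diff = a[:, j] - b[:, j]
            nz = diff[diff != 0]
            if nz.size == 0:
                pvals[c] = 1.0
            else:
                k = int((nz > 0).sum())
                pvals[c] = stats.binomtest(k, nz.size, 0.5).pvalue
    else:
        mats = [df.to_numpy() for df in frames]
        for j, c in enumerate(cols):
            pvals[c] = stats.friedmanchisquare(*[m[:, j] for m in mats]).pvalue
    return pd.Series(pvals, name="friedman_p")


@dataclass
class CovStability:
    per_family: pd.DataFrame  # features x families, mean-over-lesions COV %
    representative: pd.Series  # worst family COV per feature
    stability_class: pd.Series
    quite_stable: pd.Series  # representative COV <= 10%
    negative_mean_flag: pd.Series


def cov_stability(
    features_by_setting: dict[str, dict[str, pd.DataFrame]]
) -> CovStability:
    """COV of each feature across reconstruction settings, per family.

    ``features_by_setting[family][setting]`` is a lesions x features frame.
    Per lesion the COV across the family's settings is computed (on the
    absolute mean, flagged, when the mean is negative), then averaged over
    lesions; the representative COV is the maximum across families.
    """
    fam_cov: dict[str, pd.Series] = {}
    neg_flag = None
    for family, by_setting in features_by_setting.items():
        frames = _check_aligned(by_setting)
        if len(frames) < 2:
            raise ValueError(f"family {family!r} needs >= 2 settings")
        stack = np.stack([df.to_numpy() for df in frames])  # settings x lesions x feat
        mean = stack.mean(axis=0)
        sd = stack.std(axis=0, ddof=0)
        neg = mean < 0
        with np.errstate(divide="ignore", invalid="ignore"):
            cov = np.where(np.abs(mean) > 0, 100.0 * sd / np.abs(mean), 0.0)
        cols = frames[0].columns
        fam_cov[family] = pd.Series(cov.mean(axis=0), index=cols)
        neg_any = pd.Series(neg.any(axis=0), index=cols)
        neg_flag = neg_any if neg_flag is None else (neg_flag | neg_any)
    per_family = pd.DataFrame(fam_cov)
    representative = per_family.max(axis=1)
    representative.name = "cov_worst"
    cls = representative.map(classify_cov)
    cls.name = "stability_class"
    return CovStability(
        per_family=per_family,
        representative=representative,
        stability_class=cls,
        quite_stable=representative <= 10.0,
        negative_mean_flag=neg_flag,
    )


def icc_1_1(x: np.ndarray, y: np.ndarray) -> float:
    """One-way random, single-measure intraclass correlation, two raters.

    Targets are rows; with k = 2 measurements per target,
    ICC(1,1) = (MSB - MSW) / (MSB + MSW) from the one-way ANOVA mean squares.
    Returns NaN when the between-target variance is undefined (n < 2 or a
    degenerate ANOVA).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 2 or len(y) != n:
        return float("nan")
    data = np.stack([x, y], axis=1)
    grand = data.mean()
    row_means = data.mean(axis=1)
    k = 2
    ssb = k * ((row_means - grand) ** 2).sum()
    ssw = ((data - row_means[:, None]) ** 2).sum()
    msb = ssb / (n - 1)
    msw = ssw / (n * (k - 1))
    denom = msb + (k - 1) * msw
    if denom == 0:
        return float("nan")
    return float((msb - msw) / denom)


def icc_3_1(x: np.ndarray, y: np.ndarray) -> float:
    """Two-way mixed, consistency, single measure ICC(3,1), two raters."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 2 or len(y) != n:
        return float("nan")
    data = np.stack([x, y], axis=1)
    k = 2
    grand = data.mean()
    msr = k * ((data.mean(axis=1) - grand) ** 2).sum() / (n - 1)
    msc = n * ((data.mean(axis=0) - grand) ** 2).sum() / (k - 1)
    sse = ((data - data.mean(axis=1)[:, None] - data.mean(axis=0)[None, :] + grand) ** 2).sum()
    mse = sse / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse
    if denom == 0:
        return float("nan")
    return float((msr - mse) / denom)


def icc_reproducibility(
    datasets: list[tuple[pd.DataFrame, pd.DataFrame]],
    threshold: float = 0.6,
    form: str = "icc1",
) -> pd.DataFrame:
    """Per-feature ICC in each test-retest dataset plus the reproducible flag.

    ``datasets`` is a list of (test, retest) lesions x features frames.
    A feature is reproducible when its ICC exceeds ``threshold`` in every
    dataset; an undefined ICC (zero between-lesion variance) is flagged
    non-reproducible.
    """
    if not datasets:
        raise ValueError("need at least one test-retest dataset")
    icc_fn = {"icc1": icc_1_1, "icc3": icc_3_1}[form]
    out = {}
    for i, (test, retest) in enumerate(datasets, start=1):
        _check_aligned({"t": test, "r": retest})
        if len(test) < 5:
            raise ValueError("need at least 5 paired lesions")
        vals = {
            c: icc_fn(test[c].to_numpy(), retest[c].to_numpy())
            for c in test.columns
        }
        out[f"icc_test{i}"] = pd.Series(vals)
    df = pd.DataFrame(out)
    iccs = df.to_numpy()
    df["reproducible"] = np.all(np.nan_to_num(iccs, nan=-np.inf) > threshold, axis=1)
    return df


def heterogeneity_discrimination(
    features_hom: pd.DataFrame, features_het: pd.DataFrame
) -> pd.Series:
    """Two-sided Mann-Whitney p per feature, heterogeneous vs homogeneous."""
    if features_hom.empty or features_het.empty:
        raise ValueError("both groups must be nonempty")
    if not features_hom.columns.equals(features_het.columns):
        raise ValueError("mismatched feature registries")
    pvals = {}
    for c in features_hom.columns:
        a = features_hom[c].to_numpy()
        b = features_het[c].to_numpy()
        if np.all(a == a[0]) and np.all(b == b[0]) and a[0] == b[0]:
            pvals[c] = 1.0  # all tied: no evidence either way
        else:
            pvals[c] = float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
    return pd.Series(pvals, name="mw_p")


def hgs_correlation(
    features_het: pd.DataFrame, h_gs: np.ndarray, method: str = "spearman"
) -> pd.DataFrame:
    """Correlation of each feature with the total heterogeneity index H_GS."""
    h = np.asarray(h_gs, dtype=float)
    if len(h) != len(features_het):
        raise ValueError("h_gs length mismatch")
    if len(h) < 5:
        raise ValueError("need at least 5 heterogeneous lesions")
    rows = {}
    for c in features_het.columns:
        x = features_het[c].to_numpy()
        if np.all(x == x[0]) or np.all(h == h[0]):
            rows[c] = (float("nan"), float("nan"), True)
            continue
        if method == "spearman":
            rho, p = stats.spearmanr(x, h)
        elif method == "pearson":
            rho, p = stats.pearsonr(x, h)
        else:
            raise ValueError(f"unknown correlation method {method!r}")
        rows[c] = (float(rho), float(p), False)
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=["hgs_rho", "hgs_corr_p", "hgs_undefined"]
    )


def sphericity_agreement(
    sphericity_feature: np.ndarray, s_gs: np.ndarray
) -> tuple[float, float]:
    """Paired t-test of the Sphericity feature against ground truth.

    Returns (two-sided p, mean difference feature - GS).  Lesions with
    necrosis are excluded upstream (their active surface is ill-defined).
    """
    x = np.asarray(sphericity_feature, dtype=float)
    y = np.asarray(s_gs, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need >= 3 paired values")
    diff = x - y
    if np.allclose(diff, diff[0]):
        p = 1.0 if np.allclose(diff, 0) else 0.0
    else:
        p = float(stats.ttest_rel(x, y).pvalue)
    return p, float(diff.mean())


def benjamini_hochberg(pvals: np.ndarray) -> np.ndarray:
    """BH-adjusted p-values (emitted for transparency, not used for flags)."""
    p = np.asarray(pvals, dtype=float)
    n = len(p)
    order = np.argsort(p)
    adj = np.empty(n)
    prev = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        val = min(prev, p[i] * n / rank)
        adj[i] = val
        prev = val
    return adj


@dataclass
class StabilityReport:
    """One row per feature plus the summary funnel."""

    table: pd.DataFrame
    summary: dict = field(default_factory=dict)


def build_report(
    friedman_p: pd.Series,
    cov: CovStability,
    icc: pd.DataFrame,
    mw_p: pd.Series,
    hgs: pd.DataFrame,
    alpha: float = 0.05,
) -> StabilityReport:
    """Assemble the per-feature table and the screening funnel summary.

    The funnel mirrors the qualification sequence: reproducible features
    (ICC), then those also discriminating heterogeneous from homogeneous
    uptake (Mann-Whitney), then those also correlated with H_GS.
    """
    registries = [friedman_p.index, cov.representative.index, icc.index,
                  mw_p.index, hgs.index]
    base = registries[0]
    for r in registries[1:]:
        if not r.equals(base):
            raise ValueError("sub-analyses ran on different feature registries")

    table = pd.DataFrame(index=base)
    table["friedman_p"] = friedman_p
    table["segmentation_stable"] = friedman_p >= alpha
    for fam in cov.per_family.columns:
        table[f"cov_{fam}"] = cov.per_family[fam]
    table["cov_worst"] = cov.representative
    table["stability_class"] = cov.stability_class
    table["cov_quite_stable"] = cov.quite_stable
    for c in icc.columns:
        table[c] = icc[c]
    table["mw_p"] = mw_p
    table["mw_p_bh"] = benjamini_hochberg(mw_p.to_numpy())
    table["discriminative"] = mw_p < alpha
    table["hgs_rho"] = hgs["hgs_rho"]
    table["hgs_corr_p"] = hgs["hgs_corr_p"]
    table["hgs_correlated"] = hgs["hgs_corr_p"] < alpha

    n = len(table)
    repro = table["reproducible"]
    funnel_repro = int(repro.sum())
    funnel_disc = int((repro & table["discriminative"]).sum())
    funnel_corr = int((repro & table["discriminative"] & table["hgs_correlated"]).sum())
    summary = {
        "n_features": n,
        "fraction_segmentation_stable": float(table["segmentation_stable"].mean()),
        "fraction_cov_quite_stable": float(table["cov_quite_stable"].mean()),
        "fraction_reproducible": float(repro.mean()),
        "fraction_discriminative": float(table["discriminative"].mean()),
        "fraction_hgs_correlated": float(table["hgs_correlated"].mean()),
        "funnel": {
            "reproducible": funnel_repro,
            "reproducible_and_discriminative": funnel_disc,
            "reproducible_discriminative_correlated": funnel_corr,
        },
    }
    return StabilityReport(table=table, summary=summary)
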
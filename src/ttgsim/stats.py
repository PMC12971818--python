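"""Cohort statistics and report rendering.

The repeated-measures design has every specimen measured at every pose, so
the rotation effect is tested nonparametrically per flexion angle: a paired
Friedman test across rotation conditions, followed by pairwise Wilcoxon
signed-rank post-hocs with Bonferroni correction over the within-flexion
comparison family.  Normality screening uses Shapiro–Wilk.  Descriptives are
mean, sample SD and a 95% CI (t-based by default, switchable to the normal
approximation).

The Friedman statistic is computed here directly from average-ranked data
(tie-corrected) rather than delegated, so that degenerate inputs — all
conditions identical, the natural null fixture — are defined (statistic 0,
p = 1) instead of undefined; scipy's implementation serves as a cross-check
on non-degenerate data in the test suite.
"""

from __future__ import annotations

import dataclasses
import itertools
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "StatResult",
    "summarize",
    "summarize_delta",
    "shapiro_wilk",
    "friedman_test",
    "wilcoxon_signed_rank",
    "bonferroni",
    "rotation_tests_by_flexion",
    "flexion_effect_tests",
    "render_report",
    "read_summary",
]


@dataclass(frozen=True)
class StatResult:
    """One hypothesis-test outcome; ``p_adjusted`` defaults to the raw p."""

    test_name: str
    statistic: float
    p_value: float
    comparison: str = ""
    p_adjusted: float | None = None

    def __post_init__(self):
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p_value out of [0, 1]: {self.p_value}")
        if self.p_adjusted is None:
            object.__setattr__(self, "p_adjusted", self.p_value)
        if self.p_adjusted < self.p_value - 1e-12 or not 0.0 <= self.p_adjusted <= 1.0:
            raise ValueError("p_adjusted must lie in [p_value, 1]")


# ---------------------------------------------------------------------------
# Descriptives
# ---------------------------------------------------------------------------

def _ci95(mean: float, sd: float, n: int, method: str) -> tuple[float, float]:
    if method == "t":
        crit = float(sps.t.ppf(0.975, n - 1))
    elif method == "normal":
        crit = float(sps.norm.ppf(0.975))
    else:
        raise ValueError(f"unknown CI method {method!r}")
    half = crit * sd / np.sqrt(n)
    return mean - half, mean + half


def _summarize_column(df: pd.DataFrame, value_col: str, ci_method: str) -> pd.DataFrame:
    rows = []
    for (f, r), grp in df.groupby(["flexion_deg", "rotation_deg"], sort=True):
        vals = grp[value_col].to_numpy(dtype=float)
        n = len(vals)
        if n < 2:
            raise ValueError(f"pose ({f}, {r}) has fewer than 2 specimens")
        mean = float(np.mean(vals))
        sd = float(np.std(vals, ddof=1))
        lo, hi = _ci95(mean, sd, n, ci_method)
        rows.append({"flexion_deg": f, "rotation_deg": r, "n": n, "mean": mean,
                     "sd": sd, "ci95_low": lo, "ci95_high": hi})
    return pd.DataFrame(rows).set_index(["flexion_deg", "rotation_deg"])


def summarize(long_df: pd.DataFrame, ci_method: str = "t") -> pd.DataFrame:
    """Per-pose TT-TG descriptives (n, mean, SD, 95% CI) from the long-format
    cohort table ``specimen_id, flexion_deg, rotation_deg, tttg_mm``."""
    return _summarize_column(long_df, "tttg_mm", ci_method)


def summarize_delta(delta_df: pd.DataFrame, ci_method: str = "t") -> pd.DataFrame:
    """Per-pose ΔTT-TG descriptives from a long-format delta table."""
    return _summarize_column(delta_df, "delta_tttg_mm", ci_method)


# ---------------------------------------------------------------------------
# Tests
# ---------------------------------------------------------------------------

def shapiro_wilk(values, comparison: str = "") -> StatResult:
    values = np.asarray(values, dtype=float)
    if len(values) < 3:
        raise ValueError("Shapiro-Wilk needs at least 3 observations")
    if np.ptp(values) == 0:
        raise ValueError("Shapiro-Wilk statistic is undefined for constant input")
    w, p = sps.shapiro(values)
    return StatResult("shapiro_wilk", float(w), float(p), comparison=comparison)


def friedman_test(matrix, comparison: str = "") -> StatResult:
    """Paired-samples Friedman test on a (specimens × conditions) matrix.

    Average-rank tie handling with the standard tie correction
    ``T = (k-1) * sum_j (R_j - n(k+1)/2)^2 / (A - C)`` where ``A`` is the sum
    of squared ranks and ``C = n k (k+1)^2 / 4``; ``p`` from the chi-square
    approximation with k-1 degrees of freedom.  A matrix whose rows are all
    internally tied carries no rank information: statistic 0, p = 1.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("need a (specimens x conditions) matrix, >= 2 of each")
    if not np.all(np.isfinite(X)):
        raise ValueError("Friedman test requires complete data (no missing cells)")
    n, k = X.shape
    ranks = sps.rankdata(X, axis=1)
    col_sums = ranks.sum(axis=0)
    A = float(np.sum(ranks**2))
    C = n * k * (k + 1) ** 2 / 4.0
    if np.isclose(A, C):
        return StatResult("friedman", 0.0, 1.0, comparison=comparison)
    stat = (k - 1) * float(np.sum((col_sums - n * (k + 1) / 2.0) ** 2)) / (A - C)
    p = float(sps.chi2.sf(stat, k - 1))
    return StatResult("friedman", stat, p, comparison=comparison)


def wilcoxon_signed_rank(a, b, comparison: str = "", m: int | None = None) -> StatResult:
    """Two-sided paired Wilcoxon signed-rank test of ``b`` versus ``a``.

    Zero differences are dropped; the p-value is exact for n <= 25 with
    untied differences, otherwise the normal approximation with continuity
    correction is used.  ``m`` applies a Bonferroni adjustment.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired samples must be equal-length 1-D arrays")
    d = b - a
    nz = d[d != 0]
    if len(nz) == 0:
        raise ValueError("all paired differences are zero; Wilcoxon undefined")
    if len(nz) < 5:
        raise ValueError("need at least 5 non-zero paired differences")
    exact_ok = len(nz) <= 25 and len(np.unique(np.abs(nz))) == len(nz)
    method = "exact" if exact_ok else "approx"
    res = sps.wilcoxon(nz, zero_method="wilcox", correction=True,
                       alternative="two-sided", method=method)
    p_adj = bonferroni([float(res.pvalue)], m)[0] if m is not None else None
    return StatResult("wilcoxon_signed_rank", float(res.statistic), float(res.pvalue),
                      comparison=comparison, p_adjusted=p_adj)


def bonferroni(p_values, m: int | None = None) -> np.ndarray:
    """Bonferroni adjustment ``min(1, m * p)``; ``m`` defaults to the number
    of p-values and must not be smaller than it."""
    p = np.asarray(p_values, dtype=float)
    if m is None:
        m = len(p)
    if m < len(p):
        raise ValueError(f"family size m={m} smaller than number of p-values {len(p)}")
    return np.minimum(1.0, m * p)


# ---------------------------------------------------------------------------
# Study-design test families
# ---------------------------------------------------------------------------

def _pose_matrix(long_df: pd.DataFrame, flexion: float) -> tuple[np.ndarray, list[float]]:
    sub = long_df[long_df["flexion_deg"] == flexion]
    wide = sub.pivot(index="specimen_id", columns="rotation_deg", values="tttg_mm")
    if wide.isna().any().any():
        raise ValueError(f"incomplete grid at flexion {flexion}")
    wide = wide.sort_index(axis=1)
    return wide.to_numpy(), [float(c) for c in wide.columns]


def rotation_tests_by_flexion(long_df: pd.DataFrame) -> tuple[list[StatResult], list[StatResult]]:
    """The rotation-effect analysis at each fixed flexion angle: one Friedman
    test across all rotation conditions, then all pairwise Wilcoxon post-hocs
    Bonferroni-adjusted within the flexion's family (m = C(k, 2))."""
    friedman, pairwise = [], []
    for f in sorted(long_df["flexion_deg"].unique()):
        X, rotations = _pose_matrix(long_df, f)
        if len(rotations) < 2:
            continue
        friedman.append(friedman_test(X, comparison=f"rotation effect @ flexion {f:g}"))
        pairs = list(itertools.combinations(range(len(rotations)), 2))
        for i, j in pairs:
            pairwise.append(
                wilcoxon_signed_rank(
                    X[:, i], X[:, j], m=len(pairs),
                    comparison=(f"flexion {f:g}: rotation {rotations[i]:g} vs "
                                f"{rotations[j]:g}"),
                )
            )
    return friedman, pairwise


def flexion_effect_tests(long_df: pd.DataFrame) -> tuple[StatResult, list[StatResult]]:
    """The isolated-flexion analysis (rotation 0): Friedman across flexion
    levels plus per-flexion Wilcoxon against the extended baseline, Bonferroni
    m = number of non-zero flexion levels.  Both are reported, labelled."""
    sub = long_df[long_df["rotation_deg"] == 0]
    wide = sub.pivot(index="specimen_id", columns="flexion_deg", values="tttg_mm")
    if wide.isna().any().any():
        raise ValueError("incomplete rotation-0 column")
    wide = wide.sort_index(axis=1)
    flexions = [float(c) for c in wide.columns]
    X = wide.to_numpy()
    fried = friedman_test(X, comparison="flexion effect @ rotation 0")
    others = [i for i, f in enumerate(flexions) if f != 0.0]
    base = X[:, flexions.index(0.0)]
    per_flexion = [
        wilcoxon_signed_rank(base, X[:, i], m=len(others),
                             comparison=f"flexion {flexions[i]:g} vs 0 @ rotation 0")
        for i in others
    ]
    return fried, per_flexion


# ---------------------------------------------------------------------------
# Report rendering
# ---------------------------------------------------------------------------

def _fmt_cell(row) -> str:
    return (f"{row['mean']:.1f}(±{row['sd']:.1f})"
            f"[{row['ci95_low']:.1f}, {row['ci95_high']:.1f}]")


def _wide_display(summary: pd.DataFrame, missing: str = "–") -> pd.DataFrame:
    flexions = sorted({f for f, _ in summary.index})
    rotations = sorted({r for _, r in summary.index})
    table = pd.DataFrame(index=[f"{f:g}° flexion" for f in flexions],
                         columns=[f"{r:g}° rotation" for r in rotations], dtype=object)
    for fi, f in enumerate(flexions):
        for ri, r in enumerate(rotations):
            key = (f, r)
            table.iloc[fi, ri] = _fmt_cell(summary.loc[key]) if key in summary.index else missing
    table.index.name = "pose"
    return table


def _boxplot_figure(long_df: pd.DataFrame, path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    flexions = sorted(f for f in long_df["flexion_deg"].unique() if f != 0)
    rotations = sorted(long_df["rotation_deg"].unique())
    fig, ax = plt.subplots(figsize=(9, 5))
    base = long_df[(long_df["flexion_deg"] == 0) & (long_df["rotation_deg"] == 0)]["tttg_mm"]
    bp = ax.boxplot([base.to_numpy()], positions=[0.0], widths=0.5, patch_artist=True)
    bp["boxes"][0].set_facecolor("teal")
    cmap = dict(zip(flexions, ["#1f77b4", "#ff7f0e", "#2ca02c", "#d62728"]))
    width, gap = 0.5, 0.7
    ticks, labels = [0.0], ["baseline\n(extended)"]
    pos = 1.5
    for r in rotations:
        group_start = pos
        for f in flexions:
            vals = long_df[(long_df["flexion_deg"] == f)
                           & (long_df["rotation_deg"] == r)]["tttg_mm"]
            if vals.empty:
                continue
            bp = ax.boxplot([vals.to_numpy()], positions=[pos], widths=width,
                            patch_artist=True)
            bp["boxes"][0].set_facecolor(cmap[f])
            pos += gap
        ticks.append((group_start + pos - gap) / 2)
        labels.append(f"{r:g}°")
        pos += 1.0
    ax.set_xticks(ticks, labels)
    ax.set_xlabel("internal tibial rotation")
    ax.set_ylabel("TT-TG (mm)")
    ax.set_title("TT-TG by internal rotation, grouped by knee flexion")
    handles = [plt.Rectangle((0, 0), 1, 1, facecolor="teal")]
    names = ["0° flexion (baseline)"]
    for f in flexions:
        handles.append(plt.Rectangle((0, 0), 1, 1, facecolor=cmap[f]))
        names.append(f"{f:g}° flexion")
    ax.legend(handles, names, loc="lower left", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def read_summary(path) -> pd.DataFrame:
    """Read back a tidy summary CSV written by :func:`render_report`."""
    return pd.read_csv(path).set_index(["flexion_deg", "rotation_deg"])


def render_report(long_df: pd.DataFrame, outdir, seed: int | None = None,
                  params=None, ci_method: str = "t",
                  figure_name: str = "tttg_boxplot.png") -> dict[str, Path]:
    """Write the full cohort report into ``outdir``.

    Files: tidy ``summary.csv`` (round-trips via :func:`read_summary`),
    display tables ``table1_flexion.csv`` / ``table2_tttg.csv`` /
    ``table3_delta.csv`` (grid cells formatted ``mean(±SD)[CI]``, with "–"
    for poses outside the grid), the grouped boxplot figure, ``stats.json``
    with every test result, and ``manifest.json`` recording seed, parameters
    and library versions.
    """
    from .ttg import cohort_delta

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary = summarize(long_df, ci_method=ci_method)
    delta = cohort_delta(long_df)
    delta_summary = summarize_delta(delta, ci_method=ci_method)

    # cohorts can be too small for some tests (Wilcoxon needs >= 5 non-zero
    # pairs); descriptives and tables are still rendered, tests are skipped
    skipped: list[str] = []
    try:
        fried_rot, pairwise = rotation_tests_by_flexion(long_df)
    except ValueError as err:
        fried_rot, pairwise = [], []
        skipped.append(f"rotation tests: {err}")
    try:
        fried_flex, per_flexion = flexion_effect_tests(long_df)
    except ValueError as err:
        fried_flex, per_flexion = None, []
        skipped.append(f"flexion tests: {err}")
    normality = [
        shapiro_wilk(grp["tttg_mm"], comparison=f"pose ({f:g}, {r:g})")
        for (f, r), grp in long_df.groupby(["flexion_deg", "rotation_deg"])
        if len(grp) >= 3 and np.ptp(grp["tttg_mm"].to_numpy()) > 0
    ]

    paths: dict[str, Path] = {}

    paths["summary"] = outdir / "summary.csv"
    summary.reset_index().to_csv(paths["summary"], index=False)

    # Table 1: flexion-only column with both labelled flexion-effect tests
    t1 = summary.loc[[(f, 0.0) for f in sorted({f for f, _ in summary.index})]].reset_index()
    wmap = {float(s.comparison.split()[1]): s for s in per_flexion}
    t1["wilcoxon_vs_extended_p_adj"] = [
        wmap[f].p_adjusted if f in wmap else np.nan for f in t1["flexion_deg"]
    ]
    t1["friedman_across_flexion_p"] = fried_flex.p_value if fried_flex else np.nan
    paths["table1"] = outdir / "table1_flexion.csv"
    t1.to_csv(paths["table1"], index=False)

    paths["table2"] = outdir / "table2_tttg.csv"
    _wide_display(summary).to_csv(paths["table2"])

    paths["table3"] = outdir / "table3_delta.csv"
    _wide_display(delta_summary).to_csv(paths["table3"])

    paths["figure"] = outdir / figure_name
    _boxplot_figure(long_df, paths["figure"])

    paths["stats"] = outdir / "stats.json"
    all_results = ([dataclasses.asdict(s) for s in normality]
                   + ([dataclasses.asdict(fried_flex)] if fried_flex else [])
                   + [dataclasses.asdict(s) for s in per_flexion]
                   + [dataclasses.asdict(s) for s in fried_rot]
                   + [dataclasses.asdict(s) for s in pairwise]
                   + [{"skipped": msg} for msg in skipped])
    paths["stats"].write_text(json.dumps(all_results, indent=2))

    import matplotlib
    import scipy

    manifest = {
        "seed": seed,
        "params": dataclasses.asdict(params) if dataclasses.is_dataclass(params) else params,
        "n_specimens": int(long_df["specimen_id"].nunique()),
        "poses": sorted(map(list, set(zip(long_df["flexion_deg"], long_df["rotation_deg"])))),
        "ci_method": ci_method,
        "versions": {"ttgsim": _version(), "numpy": np.__version__,
                     "scipy": scipy.__version__, "pandas": pd.__version__,
                     "matplotlib": matplotlib.__version__},
    }
    paths["manifest"] = outdir / "manifest.json"
    paths["manifest"].write_text(json.dumps(manifest, indent=2, default=str))
    return paths


def _version() -> str:
    from . import __version__

    return __version__
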
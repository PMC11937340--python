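"""Group comparisons and reporting conventions for the quantification outputs.

Two-group comparisons use the unpaired pooled-variance (Student's) t-test
with an explicitly supplied one-sided direction; three or more groups use
one-way ANOVA with Tukey's HSD post-test. Values are summarized as
mean ± SEM (sample SD / √n) and p-values are mapped to the star convention
*, p < 0.05; **, p < 0.01; ***, p < 0.005; ****, p < 0.001; n.s., p > 0.05
(p exactly 0.05 is labelled n.s.).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd

_STAR_BINS = ((0.001, "****"), (0.005, "***"), (0.01, "**"), (0.05, "*"))


@dataclass
class GroupSample:
    """Named sample of per-retina (or per-image) scores."""

    name: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 1 or self.values.size < 1:
            raise ValueError(f"group {self.name!r} needs a 1-D sample with n >= 1")

    @property
    def n(self) -> int:
        return int(self.values.size)


@dataclass
class ComparisonResult:
    groups: tuple[str, ...]
    test: str
    statistic: float
    df: float
    p_value: float
    stars: str
    means: dict[str, float]
    sems: dict[str, float]
    ns: dict[str, int]
    direction: str = ""
    extra: dict = field(default_factory=dict)


def sem(values) -> float:
    """Standard error of the mean: sample SD (n−1 denominator) / √n."""
    values = np.asarray(values, dtype=np.float64)
    if values.size < 2:
        return math.nan
    return float(values.std(ddof=1) / math.sqrt(values.size))


def stars(p: float) -> str:
    """Map a p-value to the figure-legend star convention."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    for cut, label in _STAR_BINS:
        if p < cut:
            return label
    return "n.s."


def ttest_one_sided(x: GroupSample, y: GroupSample, direction: str) -> ComparisonResult:
    """Unpaired pooled-variance t-test with an explicit one-sided alternative.

    ``direction`` is ``"greater"`` (alternative: mean(x) > mean(y)) or
    ``"less"`` (mean(x) < mean(y)); it must be supplied by the analyst, never
    inferred from the data. When both samples have zero pooled variance and
    equal means the test is uninformative and p = 0.5 by convention.
    """
    if direction not in ("greater", "less"):
        raise ValueError("direction must be 'greater' or 'less'")
    xv, yv = x.values, y.values
    if xv.size < 2 or yv.size < 2:
        raise ValueError("each group needs n >= 2")
    if not (np.isfinite(xv).all() and np.isfinite(yv).all()):
        raise ValueError("samples must be finite")
    df = xv.size + yv.size - 2
    pooled_var = (((xv.size - 1) * xv.var(ddof=1) + (yv.size - 1) * yv.var(ddof=1))
                  / df)
    if pooled_var == 0:
        diff = xv.mean() - yv.mean()
        if diff == 0:
            t_stat, p = 0.0, 0.5
        else:
            t_stat = math.copysign(math.inf, diff)
            want_pos = direction == "greater"
            p = 0.0 if (diff > 0) == want_pos else 1.0
    else:
        res = sps.ttest_ind(xv, yv, equal_var=True, alternative=direction)
        t_stat, p = float(res.statistic), float(res.pvalue)
    return ComparisonResult(
        groups=(x.name, y.name), test="one-sided Student's t-test",
        statistic=t_stat, df=float(df), p_value=p, stars=stars(p),
        means={x.name: float(xv.mean()), y.name: float(yv.mean())},
        sems={x.name: sem(xv), y.name: sem(yv)},
        ns={x.name: x.n, y.name: y.n}, direction=direction)


def anova_tukey(groups: list[GroupSample], alpha: float = 0.05
                ) -> tuple[ComparisonResult, pd.DataFrame]:
    """One-way ANOVA followed by Tukey's HSD pairwise post-test.

    Returns the omnibus result and a tidy table of pairwise adjusted
    p-values. Requires at least three groups (use the t-test for two).
    """
    if len(groups) < 3:
        raise ValueError(
            "anova_tukey needs >= 3 groups; use the t-test (ttest_one_sided) "
            "for two")
    for g in groups:
        if g.n < 2:
            raise ValueError(f"group {g.name!r} needs n >= 2")
    f_stat, p = sps.f_oneway(*[g.values for g in groups])
    n_total = sum(g.n for g in groups)
    df_between, df_within = len(groups) - 1, n_total - len(groups)
    omnibus = ComparisonResult(
        groups=tuple(g.name for g in groups), test="one-way ANOVA",
        statistic=float(f_stat), df=float(df_within), p_value=float(p),
        stars=stars(float(p)),
        means={g.name: float(g.values.mean()) for g in groups},
        sems={g.name: sem(g.values) for g in groups},
        ns={g.name: g.n for g in groups},
        extra={"df_between": df_between, "df_within": df_within})
    endog = np.concatenate([g.values for g in groups])
    labels = np.concatenate([[g.name] * g.n for g in groups])
    tukey = pairwise_tukeyhsd(endog, labels, alpha=alpha)
    table = pd.DataFrame(tukey.summary().data[1:],
                         columns=tukey.summary().data[0])
    table["stars"] = [stars(float(q)) for q in table["p-adj"]]
    return omnibus, table


def write_report(results: list[ComparisonResult], out_dir,
                 config_fingerprint: dict | None = None) -> tuple[Path, Path]:
    """Write comparisons to CSV plus a plain-text summary.

    One row per comparison: groups, n, means, SEMs, test, statistic, df, p,
    stars, and the quantification-config fingerprint that produced the scores.
    """
    if not results:
        raise ValueError("no results to report; nothing written")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fingerprint = json.dumps(config_fingerprint or {}, sort_keys=True)
    rows = []
    for r in results:
        row = {"comparison": " vs ".join(r.groups), "test": r.test,
               "direction": r.direction, "statistic": r.statistic, "df": r.df,
               "p_value": r.p_value, "stars": r.stars,
               "config_fingerprint": fingerprint}
        for name in r.groups:
            row[f"n[{name}]"] = r.ns[name]
            row[f"mean[{name}]"] = r.means[name]
            row[f"sem[{name}]"] = r.sems[name]
        rows.append(row)
    csv_path = out / "comparisons.csv"
    pd.DataFrame(rows).to_csv(csv_path, index=False)
    txt_path = out / "comparisons.txt"
    with open(txt_path, "w") as fh:
        for r in results:
            parts = [f"{name}: {r.means[name]:.4g} ± {r.sems[name]:.4g} "
                     f"(n={r.ns[name]})" for name in r.groups]
            fh.write(f"{' vs '.join(r.groups)} [{r.test}"
                     f"{', ' + r.direction if r.direction else ''}]: "
                     f"{'; '.join(parts)}; statistic={r.statistic:.4g}, "
                     f"df={r.df:g}, p={r.p_value:.4g} ({r.stars})\n")
        fh.write(f"config: {fingerprint}\n")
    return csv_path, txt_path


def dot_plot(groups: list[GroupSample], ax=None, ylabel: str = "score"):
    """Minimal per-group dot plot with mean ± SEM bars."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(1.2 * len(groups) + 1, 3))
    rng = np.random.default_rng(0)
    for i, g in enumerate(groups):
        xj = i + rng.uniform(-0.12, 0.12, size=g.n)
        ax.plot(xj, g.values, "o", ms=4, alpha=0.7)
        ax.errorbar([i], [g.values.mean()], yerr=[sem(g.values)], fmt="_",
                    color="k", capsize=4, ms=18)
    ax.set_xticks(range(len(groups)), [g.name for g in groups])
    ax.set_ylabel(ylabel)
    return ax
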
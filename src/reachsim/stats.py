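"""Statistical comparisons across conditions and tabular report generation.

Per-subject condition means are compared with a one-way ANOVA when the
parametric hypotheses hold (Shapiro–Wilk normality on each sample and
Levene homoscedasticity, both at α = 0.05) and a Kruskal–Wallis test
otherwise. A significant omnibus test is followed by pairwise post hocs
(paired T-tests on the parametric path, Wilcoxon signed-rank otherwise)
at the Bonferroni-corrected threshold α / number of pairs (0.05/3 =
0.0167 for three conditions).
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

ALPHA = 0.05


@dataclass
class PairwiseResult:
    pair: tuple[str, str]
    test: str  # "T" | "W"
    statistic: float
    p: float
    significant: bool
    degenerate: bool = False


@dataclass
class ComparisonResult:
    metric: str
    omnibus_test: str  # "ANOVA" | "Kruskal-Wallis" | "paired-T"
    statistic: float
    p: float
    parametric: bool
    corrected_alpha: float | None
    normality_p: dict[str, float] = field(default_factory=dict)
    levene_p: float | None = None
    post_hoc: list[PairwiseResult] = field(default_factory=list)


def bonferroni_threshold(alpha: float = ALPHA, n_pairs: int = 3) -> float:
    return alpha / n_pairs


def _diagnostics(samples: dict[str, np.ndarray]) -> tuple[dict[str, float], float, bool]:
    """Shapiro per sample + Levene (median-centered) across samples."""
    norm_p = {}
    for name, s in samples.items():
        if np.ptp(s) < 1e-12:
            norm_p[name] = 1.0  # constant sample: treat as unremarkable
        else:
            norm_p[name] = float(sps.shapiro(s).pvalue)
    vals = list(samples.values())
    if all(np.ptp(s) < 1e-12 for s in vals):
        lev_p = 1.0
    else:
        lev_p = float(sps.levene(*vals, center="median").pvalue)
    parametric = all(p >= ALPHA for p in norm_p.values()) and lev_p >= ALPHA
    return norm_p, lev_p, parametric


def _paired_t(a: np.ndarray, b: np.ndarray) -> tuple[float, float, bool]:
    d = a - b
    if np.ptp(d) < 1e-12:
        if abs(d.mean()) < 1e-12:
            return 0.0, 1.0, True
        # constant nonzero difference: p below machine threshold, flagged
        return float(np.sign(d.mean()) * np.inf), 0.0, True
    res = sps.ttest_rel(a, b)
    return float(res.statistic), float(res.pvalue), False


def compare_conditions(
    samples: dict[str, np.ndarray], metric: str = "", paired: bool = True
) -> ComparisonResult:
    """Omnibus + post hoc comparison of per-subject condition means.

    ``samples`` maps condition name → one value per subject (aligned
    across conditions when ``paired``). Requires ≥ 3 subjects.
    """
    samples = {k: np.asarray(v, float) for k, v in samples.items()}
    ns = {len(v) for v in samples.values()}
    if paired and len(ns) != 1:
        raise ValueError("paired comparison needs equal-length samples")
    if min(ns) < 3:
        raise ValueError("need at least 3 values per condition")
    norm_p, lev_p, parametric = _diagnostics(samples)
    vals = list(samples.values())
    if parametric:
        try:
            res = sps.f_oneway(*vals)
            stat, p = float(res.statistic), float(res.pvalue)
        except Exception:
            stat, p = 0.0, 1.0
        omnibus = "ANOVA"
    else:
        try:
            res = sps.kruskal(*vals)
            stat, p = float(res.statistic), float(res.pvalue)
        except ValueError:  # all values identical
            stat, p = 0.0, 1.0
        omnibus = "Kruskal-Wallis"
    if np.isnan(p):  # identical samples across the board
        stat, p = 0.0, 1.0
    pairs = list(itertools.combinations(samples.keys(), 2))
    corr = bonferroni_threshold(ALPHA, len(pairs)) if pairs else None
    post = []
    if p < ALPHA:
        for a_name, b_name in pairs:
            a, b = samples[a_name], samples[b_name]
            if parametric:
                t, pp, degen = _paired_t(a, b)
                post.append(
                    PairwiseResult((a_name, b_name), "T", t, pp, pp < corr, degen)
                )
            else:
                d = a - b
                if np.ptp(d) < 1e-12 and abs(d.mean()) < 1e-12:
                    post.append(
                        PairwiseResult((a_name, b_name), "W", 0.0, 1.0, False, True)
                    )
                else:
                    try:
                        res = sps.wilcoxon(a, b, zero_method="wilcox",
                                           mode="exact")
                        w, pp = float(res.statistic), float(res.pvalue)
                        degen = False
                    except ValueError:
                        w, pp, degen = 0.0, 0.0, True
                    post.append(
                        PairwiseResult((a_name, b_name), "W", w, pp, pp < corr, degen)
                    )
    return ComparisonResult(
        metric=metric,
        omnibus_test=omnibus,
        statistic=stat,
        p=p,
        parametric=parametric,
        corrected_alpha=corr,
        normality_p=norm_p,
        levene_p=lev_p,
        post_hoc=post,
    )


def paired_rmse_test(
    rmse_cplus: np.ndarray, rmse_cminus: np.ndarray, metric: str = "rmse"
) -> ComparisonResult:
    """Two-sided paired T-test of per-subject C+ vs C− prediction error."""
    a = np.asarray(rmse_cplus, float)
    b = np.asarray(rmse_cminus, float)
    if len(a) != len(b):
        raise ValueError("need the same subjects in both arms")
    if len(a) < 3:
        raise ValueError("need at least 3 subjects")
    t, p, degen = _paired_t(a, b)
    return ComparisonResult(
        metric=metric,
        omnibus_test="paired-T",
        statistic=t,
        p=p,
        parametric=True,
        corrected_alpha=None,
        post_hoc=[PairwiseResult(("C+", "C-"), "T", t, p, p < ALPHA, degen)],
    )


def _comparison_rows(c: ComparisonResult) -> list[dict]:
    rows = [
        {
            "metric": c.metric,
            "level": "omnibus",
            "test": c.omnibus_test,
            "pair": "",
            "statistic": c.statistic,
            "p": c.p,
            "significant": c.p < ALPHA,
        }
    ]
    for ph in c.post_hoc:
        rows.append(
            {
                "metric": c.metric,
                "level": "post_hoc",
                "test": ph.test,
                "pair": f"{ph.pair[0]} vs {ph.pair[1]}",
                "statistic": ph.statistic,
                "p": ph.p,
                "significant": ph.significant,
            }
        )
    return rows


def plot_condition_boxes(
    samples: dict[str, np.ndarray], title: str, path: str | Path
) -> None:
    """Boxplot of per-subject values per condition, with one grey line per
    subject across conditions."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    names = list(samples.keys())
    data = [np.asarray(samples[k], float) for k in names]
    fig, ax = plt.subplots(figsize=(4, 3))
    for row in np.array(data).T:
        ax.plot(range(1, len(names) + 1), row, color="0.7", lw=0.8, zorder=1)
    ax.boxplot(data, tick_labels=names, whis=(0, 100), zorder=2)
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def render_report(
    results: dict, out_dir: str | Path, plots: dict | None = None
) -> dict:
    """Write the report bundle (CSV tables + JSON manifest); returns the
    manifest. Missing sections are recorded as explicit gaps. ``plots``
    optionally maps a metric name to its per-condition samples, rendered
    as boxplot figures alongside the tables."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {"tables": {}, "figures": {}, "gaps": []}
    for name, samples in (plots or {}).items():
        p = out_dir / f"fig-{name}.png"
        plot_condition_boxes(samples, name, p)
        manifest["figures"][name] = p.name

    def write_table(name, df):
        p = out_dir / f"{name}.csv"
        df.to_csv(p, index=False, float_format="%.10g")
        manifest["tables"][name] = p.name

    for name, key in [
        ("t-rmse", "rmse"),
        ("t-online", "online"),
        ("t-variability", "variability"),
        ("t-subspace", "subspace"),
    ]:
        section = results.get(key)
        if section is None:
            manifest["gaps"].append(name)
            continue
        if isinstance(section, pd.DataFrame):
            write_table(name, section)
        else:
            rows = []
            for c in section if isinstance(section, list) else [section]:
                rows.extend(_comparison_rows(c))
            write_table(name, pd.DataFrame(rows))
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
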
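"""Statistical comparison of metric distributions across data types.

Per classifier: a Kruskal-Wallis omnibus over the six data types, pairwise
two-sample Wilcoxon rank-sum tests with Benjamini-Hochberg correction, per
data-type mean/sd summaries, and the percent-change-vs-baseline figures.

The rank tests are scipy's; BH adjustment is statsmodels'; this module owns
the report assembly, edge-case conventions (identical groups, a random
baseline), and the significance threshold (adjusted p < 0.05).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .evaluate import CVResult

__all__ = [
    "kruskal_wallis",
    "pairwise_rank_test",
    "bh_adjust",
    "percent_change",
    "ComparisonReport",
    "compare_data_types",
]

ALPHA = 0.05
BASELINE = "none"


def kruskal_wallis(groups: Sequence[np.ndarray]) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and its chi-square p-value.

    All values identical across groups gives (0, 1) by convention.
    """
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("need >= 2 non-empty groups")
    pooled = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*groups)
    return float(h), float(p)


def pairwise_rank_test(a: np.ndarray, b: np.ndarray, paired: bool = False) -> float:
    """Two-sided rank test p-value between two metric samples.

    Unpaired by default (two-sample rank-sum / Mann-Whitney U): the exact
    null distribution is used for tie-free samples of up to 50, the normal
    approximation with tie and continuity correction otherwise — the rule R's
    ``wilcox.test`` applies. ``paired=True`` runs the signed-rank alternative.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    if paired:
        d = a - b
        if np.all(d == 0):
            return 1.0
        return float(stats.wilcoxon(a, b, zero_method="wilcox").pvalue)
    if np.all(a == a[0]) and np.all(b == a[0]):
        return 1.0
    tie_free = len(np.unique(np.concatenate([a, b]))) == len(a) + len(b)
    method = "exact" if tie_free and max(len(a), len(b)) <= 50 else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.pvalue)


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def percent_change(baseline: np.ndarray, augmented: np.ndarray) -> float | None:
    """Mean percent change of the augmented pool relative to the baseline.

    Returns None (the "baseline-random" sentinel) when the baseline mean is
    zero or numerically indistinguishable from zero, mirroring how a random
    baseline (MCC ~ 0) cannot anchor a relative increase.
    """
    base = float(np.mean(baseline))
    if abs(base) < 1e-12:
        return None
    return float(100.0 * (np.mean(augmented) - base) / abs(base))


@dataclass
class ComparisonReport:
    """Per-classifier comparison of metric distributions across data types."""

    metric: str
    omnibus: pd.DataFrame  # classifier, H, p
    pairwise: dict[str, pd.DataFrame]  # classifier -> BH-adjusted p matrix
    summary: pd.DataFrame  # classifier, data_type, mean, sd, n
    percent_increase: pd.DataFrame  # classifier, percent_change, baseline_random
    alpha: float = ALPHA
    paired: bool = field(default=False)

    def significant_pairs(self, classifier: str) -> list[tuple[str, str]]:
        mat = self.pairwise[classifier]
        out = []
        for i, a in enumerate(mat.index):
            for j, b in enumerate(mat.columns):
                if j > i and mat.iloc[i, j] < self.alpha:
                    out.append((a, b))
        return out

    def write(self, outdir: str | Path, prefix: str = "comparison") -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.summary.to_csv(outdir / f"{prefix}_{self.metric}_summary.tsv", sep="\t",
                            index=False, lineterminator="\n")
        self.omnibus.to_csv(outdir / f"{prefix}_{self.metric}_omnibus.tsv", sep="\t",
                            index=False, lineterminator="\n")
        for clf, mat in self.pairwise.items():
            mat.to_csv(outdir / f"{prefix}_{self.metric}_pairwise_{clf}.tsv", sep="\t",
                       lineterminator="\n")
        payload = {
            "metric": self.metric,
            "alpha": self.alpha,
            "paired": self.paired,
            "percent_increase": [
                {
                    "classifier": r.classifier,
                    "percent_change": None if r.baseline_random else r.percent_change,
                    "baseline_random": bool(r.baseline_random),
                }
                for r in self.percent_increase.itertuples()
            ],
        }
        (outdir / f"{prefix}_{self.metric}.json").write_text(
            json.dumps(payload, indent=1, sort_keys=True), encoding="utf-8"
        )

    def boxplot(self, path: str | Path, values: pd.DataFrame) -> None:
        """Box plots of the metric per data type, one panel per classifier."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        classifiers = sorted(values["classifier"].unique())
        fig, axes = plt.subplots(
            1, len(classifiers), figsize=(3 * len(classifiers), 4), sharey=True
        )
        axes = np.atleast_1d(axes)
        for ax, clf in zip(axes, classifiers):
            sub = values[values["classifier"] == clf]
            types = sorted(sub["data_type"].unique())
            ax.boxplot(
                [sub[sub.data_type == t][self.metric] for t in types],
                tick_labels=types,
            )
            ax.set_title(clf)
            ax.tick_params(axis="x", rotation=90)
        axes[0].set_ylabel(self.metric.upper())
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)


def compare_data_types(
    result: CVResult,
    metric: str = "mcc",
    baseline: str = BASELINE,
    paired: bool = False,
    alpha: float = ALPHA,
) -> ComparisonReport:
    """Build the full comparison report from nested-CV records.

    BH correction is applied within each classifier across its data-type
    pairs; the percent-increase figure pools all augmented data types
    against the non-augmented baseline.
    """
    rec = result.records[~result.records["failed"]]
    classifiers = sorted(rec["classifier"].unique())
    data_types = sorted(rec["data_type"].unique())

    omnibus_rows, summary_rows, pct_rows = [], [], []
    pairwise: dict[str, pd.DataFrame] = {}
    for clf in classifiers:
        sub = rec[rec.classifier == clf]
        groups = {t: sub[sub.data_type == t][metric].to_numpy() for t in data_types}
        present = [t for t in data_types if len(groups[t])]
        if len(present) >= 2:
            h, p = kruskal_wallis([groups[t] for t in present])
        else:
            h, p = np.nan, np.nan
        omnibus_rows.append({"classifier": clf, "H": h, "p": p})

        pairs = list(combinations(present, 2))
        raw = [pairwise_rank_test(groups[a], groups[b], paired=paired) for a, b in pairs]
        adj = bh_adjust(raw) if raw else np.array([])
        mat = pd.DataFrame(np.nan, index=present, columns=present)
        for (a, b), q in zip(pairs, adj):
            mat.loc[a, b] = q
            mat.loc[b, a] = q
        pairwise[clf] = mat

        for t in present:
            summary_rows.append(
                {
                    "classifier": clf,
                    "data_type": t,
                    "mean": float(np.mean(groups[t])),
                    "sd": float(np.std(groups[t], ddof=1)) if len(groups[t]) > 1 else np.nan,
                    "n": len(groups[t]),
                }
            )

        if baseline in groups and len(groups[baseline]):
            pooled = np.concatenate(
                [groups[t] for t in present if t != baseline]
            ) if len(present) > 1 else np.array([])
            pct = percent_change(groups[baseline], pooled) if len(pooled) else None
            pct_rows.append(
                {
                    "classifier": clf,
                    "percent_change": np.nan if pct is None else pct,
                    "baseline_random": pct is None,
                }
            )

    return ComparisonReport(
        metric=metric,
        omnibus=pd.DataFrame(omnibus_rows),
        pairwise=pairwise,
        summary=pd.DataFrame(summary_rows),
        percent_increase=pd.DataFrame(
            pct_rows, columns=["classifier", "percent_change", "baseline_random"]
        ),
        alpha=alpha,
        paired=paired,
    )
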
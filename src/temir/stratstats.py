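"""TE-stratified fold-change statistics: bins, ECDFs, KS tests, medians.

This is the machinery behind the cumulative-distribution comparisons:
predicted targets are binned by translation efficiency (median split or
quartiles), the empirical CDF of log2 fold change is computed per bin,
and bins are compared pairwise with the two-sample Kolmogorov-Smirnov
test. Medians per bin summarize the repression magnitude.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import kolmogorov

from .targets import SITE_TYPES

BIN_LABELS = {
    2: ("Low", "High"),
    4: ("Low", "Med.Low", "Med.High", "High"),
}


def quantile_bins(values, k: int) -> np.ndarray:
    """Rank-based equal-count bins, labelled 0 (low) .. k-1 (high).

    Ties share the bin of their mean rank; with a median split this puts
    exact-median ties in the low bin. Bin sizes differ by at most one
    for untied data. All-identical input cannot be partitioned and is an
    error.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if k < 2:
        raise ValueError("need at least 2 bins")
    if n < k:
        raise ValueError(f"cannot split {n} values into {k} bins")
    if np.unique(x).size == 1:
        raise ValueError("all values identical; quantile binning undefined")
    ranks = stats.rankdata(x, method="average")
    bins = np.floor((ranks - 1.0) * k / n).astype(int)
    return np.clip(bins, 0, k - 1)


def ks_two_sample(
    x, y, method: str = "asymp", n_resamples: int = 9999, seed: int = 0
) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test.

    D is the supremum over thresholds of |ECDF_x - ECDF_y|. With
    ``method='asymp'`` (default) the p-value comes from the asymptotic
    Kolmogorov distribution evaluated at sqrt(n_eff) * D with
    n_eff = n_x n_y / (n_x + n_y); ``method='permutation'`` is the
    small-sample fallback (recommended below ~30 per sample).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")

    d = _ks_statistic(x, y)
    if method == "asymp":
        en = x.size * y.size / (x.size + y.size)
        p = float(kolmogorov(np.sqrt(en) * d))
    elif method == "permutation":
        rng = np.random.default_rng(seed)
        pooled = np.concatenate([x, y])
        count = 0
        for _ in range(n_resamples):
            rng.shuffle(pooled)
            if _ks_statistic(pooled[: x.size], pooled[x.size :]) >= d - 1e-12:
                count += 1
        p = (count + 1) / (n_resamples + 1)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(d), float(p)


def _ks_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """sup_t |ECDF_x(t) - ECDF_y(t)| over the pooled support."""
    support = np.concatenate([x, y])
    cdf_x = np.searchsorted(np.sort(x), support, side="right") / x.size
    cdf_y = np.searchsorted(np.sort(y), support, side="right") / y.size
    return float(np.abs(cdf_x - cdf_y).max())


def bin_medians(fc: Mapping | pd.Series, bins) -> pd.Series:
    """Exact sample median of fc per bin (mean of middle two for even n)."""
    fc = pd.Series(fc)
    bins = pd.Series(np.asarray(bins), index=fc.index)
    out = fc.groupby(bins).median()
    for b in np.unique(bins):
        if b not in out.index or fc[bins == b].empty:
            raise ValueError(f"bin {b} is empty")
    return out


@dataclass(frozen=True)
class CorrelationResult:
    pearson_r: float
    spearman_rs: float
    n: int


def correlations(x, y) -> CorrelationResult:
    """Pearson (on values) and Spearman (on average ranks) correlation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must be paired")
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    r = stats.pearsonr(x, y).statistic
    rs = stats.spearmanr(x, y).statistic
    return CorrelationResult(float(r), float(rs), int(x.size))


@dataclass
class BinStats:
    label: str
    n: int
    median_fc: float
    ecdf_x: np.ndarray  # sorted fold changes (ECDF support points)

    def ecdf(self) -> tuple[np.ndarray, np.ndarray]:
        return self.ecdf_x, np.arange(1, self.n + 1) / self.n


@dataclass
class SiteFilter:
    """Selects target genes by site composition.

    ``best_types`` keeps genes whose strongest site is in the given set;
    ``min_sites``/``max_sites`` bound the total canonical site count;
    ``min_conserved``/``max_conserved`` and the poorly-conserved bounds
    act on externally supplied conservation counts.
    """

    best_types: Sequence[str] | None = None
    min_sites: int = 1
    max_sites: int | None = None
    min_conserved: int | None = None
    max_conserved: int | None = None
    min_poorly_conserved: int | None = None
    max_poorly_conserved: int | None = None

    def apply(self, annotation: pd.DataFrame) -> pd.Index:
        mask = annotation["n_sites"] >= self.min_sites
        if self.max_sites is not None:
            mask &= annotation["n_sites"] <= self.max_sites
        if self.best_types is not None:
            unknown = set(self.best_types) - set(SITE_TYPES)
            if unknown:
                raise ValueError(f"unknown site types {sorted(unknown)}")
            mask &= annotation["best_type"].isin(self.best_types)
        for col, lo, hi in (
            ("conserved_sites", self.min_conserved, self.max_conserved),
            ("poorly_conserved_sites", self.min_poorly_conserved, self.max_poorly_conserved),
        ):
            if lo is not None:
                mask &= annotation[col] >= lo
            if hi is not None:
                mask &= annotation[col] <= hi
        return annotation.index[mask]

    def describe(self) -> str:
        parts = [f"min_sites={self.min_sites}"]
        if self.best_types is not None:
            parts.append(f"best_types={list(self.best_types)}")
        if self.max_sites is not None:
            parts.append(f"max_sites={self.max_sites}")
        if self.min_conserved is not None or self.max_conserved is not None:
            parts.append(f"conserved=[{self.min_conserved},{self.max_conserved}]")
        return ", ".join(parts)


@dataclass
class StratifiedResult:
    """TE-binned fold-change comparison for one assay."""

    assay: str
    binning: str
    bins: list[BinStats]
    pairwise_ks: dict[tuple[str, str], tuple[float, float]]
    all_targets: BinStats
    background: BinStats | None = None

    def summary_frame(self) -> pd.DataFrame:
        rows = [
            {"bin": b.label, "n": b.n, "median_fc": b.median_fc}
            for b in [*self.bins, self.all_targets]
            + ([self.background] if self.background else [])
        ]
        return pd.DataFrame(rows)

    def ks_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"bin_a": a, "bin_b": b, "D": d, "p": p}
                for (a, b), (d, p) in self.pairwise_ks.items()
            ]
        )


def stratified_comparison(
    records: pd.DataFrame,
    annotation: pd.DataFrame,
    assay: str = "RPF",
    binning: str = "median",
    site_filter: SiteFilter | None = None,
    te: pd.Series | None = None,
    ks_method: str = "asymp",
) -> StratifiedResult:
    """Bin predicted targets by TE and compare fold-change distributions.

    ``records`` carries per-gene ``fc_rpf``, ``fc_rna`` and ``te``
    (from :func:`temir.expression.repression_records`); ``annotation``
    carries per-gene site counts (from
    :func:`temir.targets.classify_targets`). Targets are genes passing
    ``site_filter`` (default: at least one canonical site). ``te``
    optionally overrides the stratification variable (e.g. a ground-
    truth TE in simulations); fold changes always come from ``records``.

    Emits per-bin medians and ECDF support, all pairwise KS results, the
    pooled "All targets" group, and the non-target background set.
    """
    if assay not in ("RPF", "RNA"):
        raise ValueError("assay must be 'RPF' or 'RNA'")
    fc_col = "fc_rpf" if assay == "RPF" else "fc_rna"
    site_filter = site_filter or SiteFilter()
    shared = records.index.intersection(annotation.index)
    if shared.empty:
        raise ValueError("records and annotation share no genes")
    ann = annotation.loc[shared]
    target_genes = site_filter.apply(ann)
    targets = records.loc[records.index.intersection(target_genes)]
    if targets.empty:
        raise ValueError(
            f"no target genes pass the site filter ({site_filter.describe()})"
        )
    background_genes = ann.index[ann["n_sites"] == 0]
    background = records.loc[records.index.intersection(background_genes)]

    k = {"median": 2, "quartiles": 4}.get(binning)
    if k is None:
        raise ValueError("binning must be 'median' or 'quartiles'")
    strat = targets["te"] if te is None else te.reindex(targets.index).dropna()
    targets = targets.loc[strat.index]
    labels = BIN_LABELS[k]
    bin_idx = quantile_bins(strat.to_numpy(), k)

    bins: list[BinStats] = []
    samples: dict[str, np.ndarray] = {}
    for b in range(k):
        vals = targets.loc[bin_idx == b, fc_col].to_numpy()
        if vals.size == 0:
            raise ValueError(f"TE bin {labels[b]} is empty")
        samples[labels[b]] = vals
        bins.append(
            BinStats(
                label=labels[b],
                n=vals.size,
                median_fc=float(np.median(vals)),
                ecdf_x=np.sort(vals),
            )
        )

    all_vals = targets[fc_col].to_numpy()
    all_targets = BinStats(
        "All targets", all_vals.size, float(np.median(all_vals)), np.sort(all_vals)
    )
    bg = None
    if len(background):
        bg_vals = background[fc_col].to_numpy()
        bg = BinStats(
            "No site", bg_vals.size, float(np.median(bg_vals)), np.sort(bg_vals)
        )

    pairwise: dict[tuple[str, str], tuple[float, float]] = {}
    for i in range(k):
        for j in range(i + 1, k):
            pairwise[(labels[i], labels[j])] = ks_two_sample(
                samples[labels[i]], samples[labels[j]], method=ks_method
            )
    if bg is not None:
        pairwise[("All targets", "No site")] = ks_two_sample(
            all_vals, bg.ecdf_x, method=ks_method
        )

    return StratifiedResult(
        assay=assay,
        binning=binning,
        bins=bins,
        pairwise_ks=pairwise,
        all_targets=all_targets,
        background=bg,
    )


def plot_cdf(result: StratifiedResult, path=None, ax=None):
    """Cumulative fold-change distributions per TE bin (plus all targets)."""
    import matplotlib

    if path is not None:
        matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4.5, 3.5))
    series = [*result.bins, result.all_targets]
    if result.background is not None:
        series.append(result.background)
    for b in series:
        x, y = b.ecdf()
        ax.step(x, y, where="post", label=f"{b.label} (n={b.n})")
    ax.set_xlabel(f"log2 fold change ({result.assay})")
    ax.set_ylabel("Cumulative fraction")
    ax.legend(fontsize=7)
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
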
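"""Sequence features and the TE-augmented model of translational repression.

The central question for the model is whether knowing a gene's
translation efficiency improves prediction of its translational
response (RPF log2 fold change) beyond what the mRNA-level response
(RNA log2 fold change) already explains. The model family is a fixed
quadratic with a TE interaction,

    fc_rpf ~ 1 + fc_rna + fc_rna^2            (baseline)
    fc_rpf ~ baseline + log TE + fc_rna * log TE   (TE-augmented)

fitted by least squares, and the reported comparison is the Pearson
correlation between measured and predicted fc_rpf under seeded 5-fold
cross-validation on identical fold assignments, so the contrast
measures generalization and not in-sample overfitting.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .codonopt import TaiWeights, tai


def norm_mfe(mfe: float, length_nt: int, method: str = "density") -> float:
    """Length-normalized folding energy (kcal/mol per nt).

    ``density`` divides the minimum free energy by the sequence length;
    it is the default normalizer and the only one built in, but the
    argument keeps the interface pluggable for regression-residual
    variants.
    """
    if method != "density":
        raise ValueError(f"unknown normalization method {method!r}")
    if length_nt <= 0:
        raise ValueError("length must be positive")
    return mfe / length_nt


def _gc_fraction(seq: str) -> float:
    s = seq.upper().replace("U", "T")
    return (s.count("G") + s.count("C")) / len(s) if s else float("nan")


def compute_features(
    sequences: pd.DataFrame | Mapping[str, Mapping[str, str]],
    mfe_table: pd.DataFrame | None = None,
    half_life_table: pd.DataFrame | None = None,
    weights: TaiWeights | None = None,
) -> pd.DataFrame:
    """Per-gene sequence features with optional external joins.

    ``sequences`` is a frame (or mapping) with per-gene ``utr5``,
    ``cds``, ``utr3``. Lengths and 3'UTR GC come from the sequence; the
    normalized MFE columns appear only when an ``mfe_table`` (columns
    ``mfe_5utr``/``mfe_3utr``, indexed by gene) is supplied, tAI only
    when tRNA-derived ``weights`` are supplied, and half-life only from
    ``half_life_table``. Missing joins leave fields absent or NaN, never
    zero-filled.
    """
    seqs = (
        sequences
        if isinstance(sequences, pd.DataFrame)
        else pd.DataFrame.from_dict(dict(sequences), orient="index")
    )
    out = pd.DataFrame(index=seqs.index.rename("gene_id"))
    for region, col in (("utr5", "len_5utr"), ("cds", "len_cds"), ("utr3", "len_3utr")):
        out[col] = seqs[region].str.len()
    out["len_transcript"] = out[["len_5utr", "len_cds", "len_3utr"]].sum(axis=1)
    out["gc_3utr"] = seqs["utr3"].map(_gc_fraction)

    def _join(table: pd.DataFrame, cols: list[str]) -> None:
        t = table
        if "gene_id" in t.columns:
            t = t.set_index("gene_id")
        if t.index.has_duplicates:
            raise ValueError("duplicate gene ids in join table")
        for col in cols:
            if col in t.columns:
                out[col] = t[col].reindex(out.index)

    if mfe_table is not None:
        _join(mfe_table, ["mfe_5utr", "mfe_3utr"])
        for region in ("5utr", "3utr"):
            col = f"mfe_{region}"
            if col in out.columns:
                out[f"norm_{col}"] = out[col] / out[f"len_{region}"]
    if half_life_table is not None:
        _join(half_life_table, ["half_life"])
    if weights is not None:
        out["tai"] = [tai(c, weights) for c in seqs["cds"]]
    return out


def _design(fc_rna: np.ndarray, log_te: np.ndarray | None) -> np.ndarray:
    cols = [np.ones_like(fc_rna), fc_rna, fc_rna**2]
    names = ["const", "fc_rna", "fc_rna_sq"]
    if log_te is not None:
        cols += [log_te, fc_rna * log_te]
        names += ["log_te", "fc_rna_x_log_te"]
    return np.column_stack(cols), names


@dataclass
class FoldChangeResults:
    """Fit of the repression model; returned by :meth:`FoldChangeModel.fit`."""

    include_te: bool
    params: pd.Series
    r_insample: float
    cv_r: float | None
    n: int
    cv_scheme: str | None
    ols_results: object | None = None

    def summary(self) -> str:
        lines = [
            "Translational-repression fold-change model",
            f"  predictors : fc_rna, fc_rna^2"
            + (", log_te, fc_rna*log_te" if self.include_te else ""),
            f"  n          : {self.n}",
            f"  r (in-sample, measured vs predicted) : {self.r_insample:.4f}",
        ]
        if self.cv_r is not None:
            lines.append(f"  r ({self.cv_scheme})             : {self.cv_r:.4f}")
        lines.append("  coefficients:")
        for name, val in self.params.items():
            lines.append(f"    {name:<16s} {val:+.5f}")
        return "\n".join(lines)


class FoldChangeModel:
    """Quadratic model of RPF fold change from RNA fold change (and TE).

    Build from arrays or :meth:`from_records`; ``fit`` returns a
    :class:`FoldChangeResults` with in-sample and (optionally)
    cross-validated correlation between measured and predicted values.
    """

    def __init__(self, fc_rpf, fc_rna, te=None, include_te: bool | None = None):
        self.fc_rpf = np.asarray(fc_rpf, dtype=float)
        self.fc_rna = np.asarray(fc_rna, dtype=float)
        self.te = None if te is None else np.asarray(te, dtype=float)
        if include_te is None:
            include_te = self.te is not None
        if include_te and self.te is None:
            raise ValueError("include_te=True requires te values")
        self.include_te = include_te
        n = self.fc_rpf.size
        if self.fc_rna.size != n or (self.te is not None and self.te.size != n):
            raise ValueError("fc_rpf, fc_rna and te must be aligned")
        if n < 20:
            raise ValueError(f"need at least 20 records, got {n}")
        mask = np.isfinite(self.fc_rpf) & np.isfinite(self.fc_rna)
        if self.te is not None:
            if np.any(self.te[np.isfinite(self.te)] <= 0):
                raise ValueError("te must be positive")
            mask &= np.isfinite(self.te)
        self.fc_rpf, self.fc_rna = self.fc_rpf[mask], self.fc_rna[mask]
        if self.te is not None:
            self.te = self.te[mask]
        if np.std(self.fc_rna) == 0:
            raise ValueError("fc_rna is constant; design is degenerate")

    @classmethod
    def from_records(
        cls, records: pd.DataFrame, include_te: bool = True
    ) -> "FoldChangeModel":
        """From a repression-record frame with fc_rpf, fc_rna, te columns."""
        return cls(
            records["fc_rpf"], records["fc_rna"], records["te"], include_te=include_te
        )

    def _xy(self) -> tuple[np.ndarray, list[str]]:
        log_te = np.log(self.te) if self.include_te else None
        return _design(self.fc_rna, log_te)

    def fit(self, cv_folds: int | None = 5, seed: int = 0) -> FoldChangeResults:
        """Least-squares fit; ``cv_folds`` adds seeded k-fold CV correlation."""
        X, names = self._xy()
        res = sm.OLS(self.fc_rpf, X).fit()
        pred = res.predict(X)
        r_in = float(np.corrcoef(self.fc_rpf, pred)[0, 1])
        cv_r = None
        scheme = None
        if cv_folds:
            cv_r = self._cv_r(X, cv_folds, seed)
            scheme = f"{cv_folds}-fold CV, seed={seed}"
        return FoldChangeResults(
            include_te=self.include_te,
            params=pd.Series(res.params, index=names),
            r_insample=r_in,
            cv_r=cv_r,
            n=self.fc_rpf.size,
            cv_scheme=scheme,
            ols_results=res,
        )

    def _cv_r(self, X: np.ndarray, folds: int, seed: int) -> float:
        n = X.shape[0]
        rng = np.random.default_rng(seed)
        assignment = rng.permutation(n) % folds
        pred = np.empty(n)
        for f in range(folds):
            test = assignment == f
            beta, *_ = np.linalg.lstsq(X[~test], self.fc_rpf[~test], rcond=None)
            pred[test] = X[test] @ beta
        return float(np.corrcoef(self.fc_rpf, pred)[0, 1])


def compare_te_models(
    records: pd.DataFrame, cv_folds: int = 5, seed: int = 0
) -> dict[str, FoldChangeResults | float]:
    """Fit the model with and without TE on identical CV folds.

    Returns both results and ``delta_cv_r`` (with minus without); a
    positive delta means TE improves out-of-sample prediction of the
    translational response.
    """
    with_te = FoldChangeModel.from_records(records, include_te=True).fit(
        cv_folds=cv_folds, seed=seed
    )
    without_te = FoldChangeModel.from_records(records, include_te=False).fit(
        cv_folds=cv_folds, seed=seed
    )
    return {
        "with_te": with_te,
        "without_te": without_te,
        "delta_cv_r": with_te.cv_r - without_te.cv_r,
    }
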
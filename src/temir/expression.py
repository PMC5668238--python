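"""Count tables, rpkM normalization, fold changes and translation efficiency.

rpkM (reads per kilobase of feature per million mapped reads) is
``1e9 * count / (feature_length * library_total)``, with the library
total taken from the table itself. Translation efficiency (TE) of a
gene is the ratio of its RPF rpkM to its RNA-seq rpkM in the mock
condition; fold change is the log2 ratio of rpkM between the
miRNA-transfected and mock conditions, computed separately for RPF and
RNA. Genes failing the raw-count filter in any required table are
omitted from the derived quantity — never imputed, and no pseudocounts
are added, so no infinities propagate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

ASSAYS = ("RPF", "RNA")
CONDITIONS = ("mock", "mir")

#: default minimum raw count a gene must reach in every table it is used from
DEFAULT_MIN_COUNT = 10


def rpkm(
    count: float | np.ndarray, feature_length_nt: float | np.ndarray, library_total: float
) -> float | np.ndarray:
    """Reads per kilobase of feature per million mapped reads."""
    if library_total <= 0:
        raise ValueError("library total must be positive")
    length = np.asarray(feature_length_nt, dtype=float)
    if np.any(length <= 0):
        raise ValueError("feature length must be positive")
    out = 1e9 * np.asarray(count, dtype=float) / (length * library_total)
    return float(out) if np.isscalar(count) else out


@dataclass
class ExpressionTable:
    """Per-gene raw counts and rpkM for one (assay, condition) pair."""

    assay: str
    condition: str
    data: pd.DataFrame  # index gene_id; columns: count, length, rpkm

    def __post_init__(self) -> None:
        if self.assay not in ASSAYS:
            raise ValueError(f"assay must be one of {ASSAYS}, got {self.assay!r}")
        if self.condition not in CONDITIONS:
            raise ValueError(
                f"condition must be one of {CONDITIONS}, got {self.condition!r}"
            )

    @property
    def library_total(self) -> int:
        return int(self.data["count"].sum())

    @classmethod
    def from_counts(
        cls,
        gene_ids,
        counts,
        lengths,
        assay: str,
        condition: str,
    ) -> "ExpressionTable":
        df = pd.DataFrame(
            {"count": np.asarray(counts), "length": np.asarray(lengths)},
            index=pd.Index(gene_ids, name="gene_id"),
        )
        return cls._normalize(df, assay, condition)

    @classmethod
    def _normalize(cls, df: pd.DataFrame, assay: str, condition: str) -> "ExpressionTable":
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene_id in {assay}/{condition} table: {dups[:5]}")
        if (df["count"] < 0).any():
            bad = df.index[df["count"] < 0].tolist()
            raise ValueError(f"negative counts for genes {bad[:5]}")
        if (df["length"] <= 0).any():
            bad = df.index[df["length"] <= 0].tolist()
            raise ValueError(f"non-positive feature length for genes {bad[:5]}")
        total = df["count"].sum()
        if total <= 0:
            raise ValueError(f"{assay}/{condition} table has zero total counts")
        df = df.copy()
        df["rpkm"] = rpkm(df["count"].to_numpy(), df["length"].to_numpy(), total)
        return cls(assay=assay, condition=condition, data=df)


def read_expression_table(path, assay: str, condition: str) -> ExpressionTable:
    """Read one (assay, condition) count table from a TSV.

    The TSV has columns ``gene_id assay condition count length`` and may
    stack several tables; rows are selected by the requested assay and
    condition. Malformed rows (non-integer counts, missing fields) are
    rejected with their row numbers.
    """
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    required = {"gene_id", "assay", "condition", "count", "length"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"count table {path} missing columns {sorted(missing)}")
    bad_rows = df.index[df[["gene_id", "count", "length"]].isna().any(axis=1)]
    if len(bad_rows):
        raise ValueError(
            f"malformed rows in {path} (1-based data rows "
            f"{[int(i) + 2 for i in bad_rows[:5]]})"
        )
    sel = df[(df["assay"] == assay) & (df["condition"] == condition)]
    if sel.empty:
        raise ValueError(f"no rows for assay={assay}, condition={condition} in {path}")
    sub = sel.set_index("gene_id")[["count", "length"]].astype(
        {"count": int, "length": int}
    )
    return ExpressionTable._normalize(sub, assay, condition)


def _passing(table: ExpressionTable, min_count: int) -> pd.Index:
    return table.data.index[table.data["count"] >= min_count]


def translation_efficiency(
    mock_rpf: ExpressionTable,
    mock_rna: ExpressionTable,
    min_count: int = DEFAULT_MIN_COUNT,
) -> pd.Series:
    """Per-gene TE = rpkM_RPF / rpkM_RNA in the mock condition.

    Genes below ``min_count`` raw reads in either table, or with a zero
    rpkM, are omitted (not set to 0 or inf).
    """
    if mock_rpf.assay != "RPF" or mock_rna.assay != "RNA":
        raise ValueError("translation_efficiency expects (RPF, RNA) tables")
    genes = mock_rpf.data.index.intersection(mock_rna.data.index)
    if genes.empty:
        raise ValueError("RPF and RNA tables share no genes")
    genes = genes.intersection(_passing(mock_rpf, min_count)).intersection(
        _passing(mock_rna, min_count)
    )
    num = mock_rpf.data.loc[genes, "rpkm"]
    den = mock_rna.data.loc[genes, "rpkm"]
    ok = (num > 0) & (den > 0)
    te = (num[ok] / den[ok]).rename("te")
    te.index.name = "gene_id"
    return te


def fold_change(
    mir_table: ExpressionTable,
    mock_table: ExpressionTable,
    min_count: int = DEFAULT_MIN_COUNT,
) -> pd.Series:
    """Per-gene log2(rpkm_mir / rpkm_mock) for one assay.

    Each table is normalized by its own library total. Genes must pass
    the count filter in both conditions and have nonzero rpkM in both.
    """
    if mir_table.assay != mock_table.assay:
        raise ValueError(
            f"assay mismatch: {mir_table.assay} vs {mock_table.assay}"
        )
    genes = mir_table.data.index.intersection(mock_table.data.index)
    if genes.empty:
        raise ValueError("tables share no genes")
    genes = genes.intersection(_passing(mir_table, min_count)).intersection(
        _passing(mock_table, min_count)
    )
    num = mir_table.data.loc[genes, "rpkm"]
    den = mock_table.data.loc[genes, "rpkm"]
    ok = (num > 0) & (den > 0)
    fc = np.log2(num[ok] / den[ok]).rename("fc")
    fc.index.name = "gene_id"
    return fc


def repression_records(
    rpf_mock: ExpressionTable,
    rpf_mir: ExpressionTable,
    rna_mock: ExpressionTable,
    rna_mir: ExpressionTable,
    min_count: int = DEFAULT_MIN_COUNT,
) -> pd.DataFrame:
    """Join RPF/RNA fold changes with mock TE for genes passing all filters.

    Returns a DataFrame indexed by gene_id with columns ``fc_rpf``,
    ``fc_rna`` and ``te``, restricted to genes that pass the count
    filter in all four tables.
    """
    fc_rpf = fold_change(rpf_mir, rpf_mock, min_count)
    fc_rna = fold_change(rna_mir, rna_mock, min_count)
    te = translation_efficiency(rpf_mock, rna_mock, min_count)
    df = pd.concat(
        {"fc_rpf": fc_rpf, "fc_rna": fc_rna, "te": te}, axis=1, join="inner"
    )
    df.index.name = "gene_id"
    return df
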
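"""Canonical miRNA seed-match site detection and per-gene target annotation.

Sites are reported on the 3'UTR sense strand, 5'->3', with 0-based
half-open coordinates, so ``utr[start:end]`` is the site sequence.
The four canonical site types are defined by complementarity to the
miRNA seed (positions 2-8, 1-based from the miRNA 5' end):

* ``6mer``     — match to miRNA positions 2-7;
* ``7mer-a1``  — 6mer followed immediately (3' on the target) by an A;
* ``7mer-m8``  — match to positions 2-8;
* ``8mer``     — 7mer-m8 followed by an A.

Every genomic occurrence of the 6-nt core is reported exactly once,
with the highest applicable type under 8mer > 7mer-m8 > 7mer-a1 > 6mer;
the 6mer inside a 7mer is never counted a second time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

SITE_TYPES = ("6mer", "7mer-a1", "7mer-m8", "8mer")

# hierarchy rank; higher wins when several definitions apply
SITE_RANK = {t: i for i, t in enumerate(SITE_TYPES)}

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _as_dna(seq: str) -> str:
    """Uppercase and collapse U onto T so RNA and DNA inputs are equivalent."""
    return seq.upper().replace("U", "T")


def _revcomp(seq: str) -> str:
    return _as_dna(seq).translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MiRNA:
    """A mature miRNA, 5'->3'. The seed is positions 2-8 (1-based)."""

    name: str
    mature_seq: str

    def __post_init__(self) -> None:
        seq = _as_dna(self.mature_seq)
        if len(seq) < 8:
            raise ValueError(
                f"miRNA {self.name!r} is {len(seq)} nt; seed-site detection "
                "requires at least 8 nt"
            )
        bad = set(seq) - set("ACGT")
        if bad:
            raise ValueError(f"miRNA {self.name!r} has non-ACGU/T characters: {bad}")

    @property
    def seed(self) -> str:
        """Seed region, miRNA positions 2-8, as DNA."""
        return _as_dna(self.mature_seq)[1:8]

    @property
    def core_match(self) -> str:
        """Target-strand match to miRNA positions 2-7 (the 6mer core)."""
        return _revcomp(_as_dna(self.mature_seq)[1:7])

    @property
    def m8_match(self) -> str:
        """Target base that pairs miRNA position 8 (5' of the core on the target)."""
        return _revcomp(_as_dna(self.mature_seq)[7])


@dataclass(frozen=True)
class TargetSite:
    gene_id: str
    start: int
    end: int
    site_type: str

    def __post_init__(self) -> None:
        expected = {"6mer": 6, "7mer-a1": 7, "7mer-m8": 7, "8mer": 8}[self.site_type]
        if self.end - self.start != expected:
            raise ValueError(
                f"{self.site_type} site must span {expected} nt, "
                f"got [{self.start},{self.end})"
            )


def find_seed_sites(utr_seq: str, mirna: MiRNA, gene_id: str = "") -> list[TargetSite]:
    """Find all canonical seed-match sites of ``mirna`` in a 3'UTR.

    Each occurrence of the 6-nt seed core is classified once, with the
    highest applicable type. Overlapping occurrences of the core (repeat
    seeds) are each reported. U and T are treated as equivalent in both
    sequences.
    """
    if not utr_seq:
        raise ValueError("empty 3'UTR sequence")
    utr = _as_dna(utr_seq)
    core = mirna.core_match
    m8 = mirna.m8_match
    sites: list[TargetSite] = []
    pos = utr.find(core)
    while pos != -1:
        has_m8 = pos >= 1 and utr[pos - 1] == m8
        has_a1 = pos + 6 < len(utr) and utr[pos + 6] == "A"
        if has_m8 and has_a1:
            sites.append(TargetSite(gene_id, pos - 1, pos + 7, "8mer"))
        elif has_m8:
            sites.append(TargetSite(gene_id, pos - 1, pos + 6, "7mer-m8"))
        elif has_a1:
            sites.append(TargetSite(gene_id, pos, pos + 7, "7mer-a1"))
        else:
            sites.append(TargetSite(gene_id, pos, pos + 6, "6mer"))
        pos = utr.find(core, pos + 1)
    return sites


def best_site_type(counts: Mapping[str, int]) -> str:
    """Strongest site type present under 8mer > 7mer-m8 > 7mer-a1 > 6mer."""
    present = [t for t in SITE_TYPES if counts.get(t, 0) > 0]
    return max(present, key=SITE_RANK.__getitem__) if present else "none"


@dataclass
class TargetAnnotation:
    gene_id: str
    counts: dict[str, int] = field(default_factory=dict)
    best_type: str = "none"
    conserved_sites: int | None = None
    poorly_conserved_sites: int | None = None

    @property
    def n_sites(self) -> int:
        return sum(self.counts.get(t, 0) for t in SITE_TYPES)


def classify_targets(
    gene_utrs: Mapping[str, str],
    mirna: MiRNA,
    external_annotation: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Scan every 3'UTR and summarize per-gene target status.

    Returns a DataFrame indexed by gene_id with one count column per
    site type, ``n_sites``, ``best_type`` ('none' for genes without a
    site — the non-target background set), and, when an external
    annotation table is supplied, ``conserved_sites`` /
    ``poorly_conserved_sites`` passed through by gene id.

    ``external_annotation`` must be indexed (or indexable) by gene id
    with columns ``conserved_sites`` and ``poorly_conserved_sites``;
    ids absent from the UTR set are ignored with a warning.
    """
    rows = []
    for gene_id, utr in gene_utrs.items():
        counts = {t: 0 for t in SITE_TYPES}
        if utr:
            for site in find_seed_sites(utr, mirna, gene_id):
                counts[site.site_type] += 1
        rows.append(
            {
                "gene_id": gene_id,
                **{f"n_{t}": counts[t] for t in SITE_TYPES},
                "n_sites": sum(counts.values()),
                "best_type": best_site_type(counts),
            }
        )
    out = pd.DataFrame(
        rows,
        columns=["gene_id", *(f"n_{t}" for t in SITE_TYPES), "n_sites", "best_type"],
    ).set_index("gene_id")
    if external_annotation is not None:
        ann = external_annotation
        if "gene_id" in ann.columns:
            ann = ann.set_index("gene_id")
        if ann.index.has_duplicates:
            raise ValueError("duplicate gene ids in annotation table")
        unknown = ann.index.difference(out.index)
        if len(unknown):
            warnings.warn(
                f"{len(unknown)} annotation gene ids not in the UTR set "
                f"(e.g. {list(unknown[:3])}); ignored",
                stacklevel=2,
            )
        for col in ("conserved_sites", "poorly_conserved_sites"):
            if col in ann.columns:
                out[col] = ann[col].reindex(out.index)
    return out


def sites_to_frame(sites: Iterable[TargetSite]) -> pd.DataFrame:
    """BED-like table of sites: gene_id, start, end, site_type."""
    return pd.DataFrame(
        [(s.gene_id, s.start, s.end, s.site_type) for s in sites],
        columns=["gene_id", "start", "end", "site_type"],
    )


def write_sites(sites: Iterable[TargetSite] | pd.DataFrame, path) -> None:
    df = sites if isinstance(sites, pd.DataFrame) else sites_to_frame(sites)
    df.to_csv(path, sep="\t", index=False)


def read_sites(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = {"gene_id", "start", "end", "site_type"} - set(df.columns)
    if missing:
        raise ValueError(f"site table {path} missing columns {sorted(missing)}")
    return df


def read_targetscan_summary(
    path,
    gene_col: str = "gene_id",
    conserved_col: str = "conserved_sites",
    poorly_conserved_col: str = "poorly_conserved_sites",
) -> pd.DataFrame:
    """Read a TargetScan-style per-gene site summary.

    Expects a TSV with a gene symbol column, optional per-site-type
    count columns named ``n_6mer`` .. ``n_8mer``, and conserved /
    poorly-conserved site counts. This lets real-data runs take the
    target universe directly from TargetScan predictions instead of
    scanning sequences.
    """
    df = pd.read_csv(path, sep="\t")
    if gene_col not in df.columns:
        raise ValueError(f"expected a {gene_col!r} column in {path}")
    df = df.rename(
        columns={
            conserved_col: "conserved_sites",
            poorly_conserved_col: "poorly_conserved_sites",
        }
    ).set_index(gene_col)
    df.index.name = "gene_id"
    if df.index.has_duplicates:
        raise ValueError(f"duplicate gene ids in {path}")
    type_cols = [c for c in df.columns if c.startswith("n_")]
    if type_cols and "best_type" not in df.columns:
        counts = df[type_cols].fillna(0).astype(int)
        df["n_sites"] = counts.sum(axis=1)
        df["best_type"] = [
            best_site_type({c[2:]: row[c] for c in type_cols})
            for _, row in counts.iterrows()
        ]
    return df
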
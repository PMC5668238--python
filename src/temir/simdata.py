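"""Synthetic ribosome-profiling experiments with TE-coupled miRNA repression.

The generator emulates a paired RPF + RNA-seq experiment in a mock and a
miRNA-transfected condition over a synthetic transcriptome:

* per-gene abundance a_g ~ LogNormal(mu_abundance, sigma_abundance) and
  true translation efficiency TE_g ~ LogNormal(0, sigma_te);
* a declared fraction of genes carries 1..max_sites planted canonical
  seed sites in the 3'UTR (type drawn from ``site_type_mix``); all other
  chance seed matches are scrubbed so truth labels are exact;
* the miRNA condition applies, to targets only, an RNA decay effect
  ``rna_log2fc = -delta_decay * n_sites`` that is independent of TE, and
  a translational repression on top of it,
  ``rpf_log2fc = rna_log2fc - beta_te * rank01(TE_g) * w_site``, where
  rank01 is the TE rank scaled to [0, 1] over all genes and w_site sums
  per-site weights ordered 8mer > 7mer-m8 > 7mer-a1 > 6mer;
* expected mock counts are proportional to a_g * transcript length
  (RNA) and a_g * TE_g * CDS length (RPF), scaled to the declared
  library depth, and observed counts are negative binomial with
  variance m + dispersion * m^2.

One RNG stream is derived from the master seed per output, so the draws
for one table do not perturb another.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .expression import ExpressionTable
from .targets import MiRNA, TargetSite, find_seed_sites, sites_to_frame

#: translational-repression weight per planted site, by type
SITE_WEIGHTS = {"8mer": 1.0, "7mer-m8": 0.75, "7mer-a1": 0.5, "6mer": 0.25}

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


class ParameterError(ValueError):
    """Invalid simulation parameters."""


@dataclass
class SimParams:
    """Generative parameters; defaults define the standard study conditions."""

    n_genes: int = 2000
    target_fraction: float = 0.4
    site_type_mix: dict[str, float] = field(
        default_factory=lambda: {t: 0.25 for t in SITE_WEIGHTS}
    )
    mu_abundance: float = 1.5  # ln-scale mean of gene abundance
    sigma_abundance: float = 1.0
    sigma_te: float = 1.0  # ln-scale spread of true TE
    delta_decay: float = 0.25  # mean per-site RNA log2 decrease
    beta_te: float = 1.0  # coupling of translational repression to TE rank
    dispersion: float = 0.1  # NB dispersion phi; var = m + phi m^2
    depth_rpf: float = 5e6
    depth_rna: float = 5e6
    seed: int = 0
    length_params: dict[str, tuple[int, int]] = field(
        default_factory=lambda: {
            "utr5": (50, 300),
            "cds": (300, 1800),
            "utr3": (100, 1200),
        }
    )
    gc: float = 0.5
    max_sites: int = 3

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ParameterError("n_genes must be >= 1")
        if not 0.0 <= self.target_fraction <= 1.0:
            raise ParameterError("target_fraction must be in [0, 1]")
        if abs(sum(self.site_type_mix.values()) - 1.0) > 1e-9:
            raise ParameterError("site_type_mix probabilities must sum to 1")
        if set(self.site_type_mix) - set(SITE_WEIGHTS):
            raise ParameterError(
                f"unknown site types in mix: {set(self.site_type_mix) - set(SITE_WEIGHTS)}"
            )
        if any(p < 0 for p in self.site_type_mix.values()):
            raise ParameterError("site_type_mix probabilities must be >= 0")
        for name in ("sigma_abundance", "sigma_te", "depth_rpf", "depth_rna"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be > 0")
        if self.dispersion <= 0:
            raise ParameterError("dispersion must be > 0")
        if self.delta_decay < 0 or self.beta_te < 0:
            raise ParameterError("delta_decay and beta_te must be >= 0")
        if not 0.0 < self.gc < 1.0:
            raise ParameterError("gc must be in (0, 1)")
        for region, (lo, hi) in self.length_params.items():
            if lo > hi or lo < 1:
                raise ParameterError(f"invalid length range for {region}: [{lo}, {hi}]")
        if self.max_sites < 1:
            raise ParameterError("max_sites must be >= 1")

    def rngs(self, *names: str) -> dict[str, np.random.Generator]:
        """Independent, named RNG streams derived from the master seed."""
        children = np.random.SeedSequence(self.seed).spawn(len(names))
        return {n: np.random.default_rng(ss) for n, ss in zip(names, children)}


@dataclass
class SyntheticTruth:
    """Ground truth behind one simulated experiment."""

    params: SimParams
    genes: pd.DataFrame  # index gene_id: a, te_true, is_target, n_sites,
    #                      w_site, rna_log2fc_true, rpf_log2fc_true
    sites: pd.DataFrame  # gene_id, start, end, site_type


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    idx = rng.choice(4, size=length, p=p)
    return _BASES[idx].tobytes().decode("ascii")


def _codon_sampler(gc: float):
    """Sense-codon index distribution matching per-base GC composition."""
    from .codonopt import SENSE_CODONS

    pb = {"A": (1 - gc) / 2, "C": gc / 2, "G": gc / 2, "T": (1 - gc) / 2}
    probs = np.array([pb[c[0]] * pb[c[1]] * pb[c[2]] for c in SENSE_CODONS])
    probs /= probs.sum()
    return np.array(SENSE_CODONS), probs


def make_transcriptome(params: SimParams) -> pd.DataFrame:
    """Random genes with 5'UTR/CDS/3'UTR sequences.

    Every CDS starts with ATG, ends with a stop and has no internal
    stop; CDS lengths are multiples of 3 drawn from the configured
    range. Deterministic for a fixed seed.
    """
    params.validate()
    rng = params.rngs("transcriptome")["transcriptome"]
    n = params.n_genes
    ids = [f"g{i:05d}" for i in range(n)]

    lo5, hi5 = params.length_params["utr5"]
    lo3, hi3 = params.length_params["utr3"]
    loc, hic = params.length_params["cds"]
    # CDS length range in codons, inclusive of start and stop codon
    lo_cod = max(3, -(-loc // 3))
    hi_cod = max(lo_cod, hic // 3)

    len5 = rng.integers(lo5, hi5 + 1, size=n)
    len3 = rng.integers(lo3, hi3 + 1, size=n)
    ncod = rng.integers(lo_cod, hi_cod + 1, size=n)

    codon_arr, codon_p = _codon_sampler(params.gc)
    stops = np.array(["TAA", "TAG", "TGA"])

    rows = []
    for i in range(n):
        utr5 = _random_seq(rng, int(len5[i]), params.gc)
        utr3 = _random_seq(rng, int(len3[i]), params.gc)
        internal = codon_arr[rng.choice(codon_arr.size, size=int(ncod[i]) - 2, p=codon_p)]
        cds = "ATG" + "".join(internal.tolist()) + str(stops[rng.integers(3)])
        rows.append((ids[i], utr5, cds, utr3))
    df = pd.DataFrame(rows, columns=["gene_id", "utr5", "cds", "utr3"]).set_index(
        "gene_id"
    )
    for region in ("utr5", "cds", "utr3"):
        df[f"len_{region}"] = df[region].str.len()
    df["len_transcript"] = df["len_utr5"] + df["len_cds"] + df["len_utr3"]
    return df


def _site_insert(site_type: str, mirna: MiRNA, rng: np.random.Generator) -> str:
    """8-nt context that re-detects as exactly one site of the given type."""
    core = mirna.core_match
    m8 = mirna.m8_match
    not_m8 = rng.choice([b for b in "ACGT" if b != m8])
    not_a = rng.choice([b for b in "CGT"])
    if site_type == "8mer":
        return m8 + core + "A"
    if site_type == "7mer-m8":
        return m8 + core + not_a
    if site_type == "7mer-a1":
        return not_m8 + core + "A"
    return not_m8 + core + not_a  # 6mer


def _scrub_utr(utr: str, core: str, rng: np.random.Generator, gc: float) -> str:
    """Resample the 3'UTR until it contains no seed-core match."""
    while core in utr:
        utr = _random_seq(rng, len(utr), gc)
    return utr


def plant_sites(
    transcriptome: pd.DataFrame, mirna: MiRNA, params: SimParams
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Scrub chance seed matches and plant sites into the declared target fraction.

    Returns the modified transcriptome and a truth site table. Exactly
    ``round(target_fraction * n_genes)`` genes receive >= 1 site, except
    genes whose 3'UTR is too short to host one (skipped with a warning).
    Planted sites re-detect at the planted coordinates and types, and
    non-target UTRs contain no seed match at all.
    """
    params.validate()
    rng = params.rngs("transcriptome", "sites")["sites"]
    core = mirna.core_match
    tx = transcriptome.copy()

    # scrub every UTR so the only sites are planted ones
    tx["utr3"] = [
        _scrub_utr(u, core, rng, params.gc) if core in u else u for u in tx["utr3"]
    ]

    n_targets = int(round(params.target_fraction * params.n_genes))
    hostable = tx.index[tx["len_utr3"] > 8]
    skipped = 0
    if n_targets > len(hostable):
        skipped = n_targets - len(hostable)
        n_targets = len(hostable)
    if skipped:
        warnings.warn(f"{skipped} genes skipped: 3'UTR too short to host a site")
    chosen = rng.choice(hostable.to_numpy(), size=n_targets, replace=False)

    types = list(params.site_type_mix)
    probs = np.array([params.site_type_mix[t] for t in types])
    all_sites: list[TargetSite] = []
    for gene in chosen:
        utr = tx.at[gene, "utr3"]
        n_slots = len(utr) // 8
        k = int(rng.integers(1, min(params.max_sites, n_slots) + 1))
        site_types = [types[i] for i in rng.choice(len(types), size=k, p=probs)]
        for _ in range(200):  # retry if a junction creates a spurious match
            positions = _sample_positions(rng, len(utr), k)
            candidate = utr
            planted: list[TargetSite] = []
            for pos, st in zip(positions, site_types):
                candidate = candidate[:pos] + _site_insert(st, mirna, rng) + candidate[pos + 8 :]
                off = {"8mer": 0, "7mer-m8": 0, "7mer-a1": 1, "6mer": 1}[st]
                width = {"8mer": 8, "7mer-m8": 7, "7mer-a1": 7, "6mer": 6}[st]
                planted.append(TargetSite(gene, pos + off, pos + off + width, st))
            detected = find_seed_sites(candidate, mirna, gene)
            if sorted((s.start, s.end, s.site_type) for s in detected) == sorted(
                (s.start, s.end, s.site_type) for s in planted
            ):
                tx.at[gene, "utr3"] = candidate
                all_sites.extend(planted)
                break
        else:  # pragma: no cover - overwhelmingly unlikely
            raise RuntimeError(f"could not plant sites in gene {gene}")

    sites = sites_to_frame(all_sites)
    return tx, sites


def _sample_positions(rng: np.random.Generator, utr_len: int, k: int) -> list[int]:
    """k non-overlapping 8-nt insertion offsets within the UTR."""
    for _ in range(500):
        pos = np.sort(rng.integers(0, utr_len - 8 + 1, size=k))
        if k == 1 or np.all(np.diff(pos) >= 8):
            return [int(p) for p in pos]
    # fall back to a deterministic tiling
    slots = list(range(0, utr_len - 8 + 1, 8))
    return [slots[i] for i in rng.choice(len(slots), size=k, replace=False)]


def simulate_experiment(
    transcriptome: pd.DataFrame, sites: pd.DataFrame, params: SimParams
) -> tuple[dict[tuple[str, str], ExpressionTable], SyntheticTruth]:
    """Draw the four count tables ({RPF, RNA} x {mock, mir}) plus ground truth."""
    params.validate()
    rngs = params.rngs(
        "transcriptome",
        "sites",
        "gene_params",
        "counts_rpf_mock",
        "counts_rpf_mir",
        "counts_rna_mock",
        "counts_rna_mir",
    )
    n = len(transcriptome)
    gp = rngs["gene_params"]
    a = gp.lognormal(params.mu_abundance, params.sigma_abundance, size=n)
    te = gp.lognormal(0.0, params.sigma_te, size=n)

    idx = transcriptome.index
    site_counts = (
        sites.groupby("gene_id").size().reindex(idx, fill_value=0).to_numpy()
        if len(sites)
        else np.zeros(n, dtype=int)
    )
    w_site = (
        sites.assign(w=sites["site_type"].map(SITE_WEIGHTS))
        .groupby("gene_id")["w"]
        .sum()
        .reindex(idx, fill_value=0.0)
        .to_numpy()
        if len(sites)
        else np.zeros(n)
    )
    is_target = site_counts > 0

    # TE rank scaled to [0, 1] over all genes: bounded, distribution-free coupling
    rank01 = (np.argsort(np.argsort(te))).astype(float)
    rank01 = rank01 / (n - 1) if n > 1 else np.zeros(n)

    rna_fc = np.where(is_target, -params.delta_decay * site_counts, 0.0)
    rpf_fc = rna_fc - np.where(is_target, params.beta_te * rank01 * w_site, 0.0)

    l_tx = transcriptome["len_transcript"].to_numpy(dtype=float)
    l_cds = transcriptome["len_cds"].to_numpy(dtype=float)

    means = {
        ("RNA", "mock"): a * l_tx,
        ("RNA", "mir"): a * l_tx * 2.0**rna_fc,
        ("RPF", "mock"): a * te * l_cds,
        ("RPF", "mir"): a * te * l_cds * 2.0**rpf_fc,
    }
    depths = {"RNA": params.depth_rna, "RPF": params.depth_rpf}
    lengths = {"RNA": l_tx.astype(int), "RPF": l_cds.astype(int)}

    tables: dict[tuple[str, str], ExpressionTable] = {}
    phi = params.dispersion
    for (assay, condition), m in means.items():
        m = m / m.sum() * depths[assay]
        rng = rngs[f"counts_{assay.lower()}_{condition}"]
        r = 1.0 / phi
        counts = rng.negative_binomial(r, r / (r + m))
        tables[(assay, condition)] = ExpressionTable.from_counts(
            idx, counts, lengths[assay], assay=assay, condition=condition
        )

    genes = pd.DataFrame(
        {
            "a": a,
            "te_true": te,
            "is_target": is_target,
            "n_sites": site_counts,
            "w_site": w_site,
            "rna_log2fc_true": rna_fc,
            "rpf_log2fc_true": rpf_fc,
        },
        index=idx,
    )
    return tables, SyntheticTruth(params=params, genes=genes, sites=sites)


def simulate(
    params: SimParams, mirna: MiRNA
) -> tuple[pd.DataFrame, dict[tuple[str, str], ExpressionTable], SyntheticTruth]:
    """Convenience end-to-end draw: transcriptome, planted sites, counts."""
    tx = make_transcriptome(params)
    tx, sites = plant_sites(tx, mirna, params)
    tables, truth = simulate_experiment(tx, sites, params)
    return tx, tables, truth


def write_fixture(
    directory,
    transcriptome: pd.DataFrame,
    tables: dict[tuple[str, str], ExpressionTable],
    truth: SyntheticTruth,
) -> dict[str, Path]:
    """Write FASTA sequences, stacked TSV counts, sites and truth tables.

    The outputs round-trip through :func:`temir.expression.read_expression_table`
    and the site/truth readers.
    """
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord
    from Bio import SeqIO

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    records = [
        SeqRecord(Seq(row[region]), id=f"{gene}|{region}", description="")
        for gene, row in transcriptome.iterrows()
        for region in ("utr5", "cds", "utr3")
    ]
    paths["sequences"] = directory / "sequences.fa"
    SeqIO.write(records, paths["sequences"], "fasta")

    stacked = []
    for (assay, condition), table in tables.items():
        df = table.data.reset_index()
        df.insert(1, "assay", assay)
        df.insert(2, "condition", condition)
        stacked.append(df[["gene_id", "assay", "condition", "count", "length"]])
    counts = (
        pd.concat(stacked, ignore_index=True)
        if stacked
        else pd.DataFrame(columns=["gene_id", "assay", "condition", "count", "length"])
    )
    paths["counts"] = directory / "counts.tsv"
    counts.to_csv(paths["counts"], sep="\t", index=False)

    paths["sites"] = directory / "sites.tsv"
    truth.sites.to_csv(paths["sites"], sep="\t", index=False)

    paths["truth"] = directory / "truth.tsv"
    truth.genes.rename_axis("gene_id").to_csv(paths["truth"], sep="\t")

    paths["params"] = directory / "sim_params.json"
    with open(paths["params"], "w") as fh:
        json.dump(asdict(truth.params), fh, indent=2, default=list)
    return paths


def read_sequences(path) -> pd.DataFrame:
    """Read a ``<gene>|<region>`` FASTA back into a transcriptome frame."""
    from Bio import SeqIO

    data: dict[str, dict[str, str]] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        gene, _, region = rec.id.partition("|")
        data.setdefault(gene, {})[region] = str(rec.seq)
    df = pd.DataFrame.from_dict(data, orient="index")
    df.index.name = "gene_id"
    for region in ("utr5", "cds", "utr3"):
        if region in df.columns:
            df[f"len_{region}"] = df[region].str.len()
    if {"len_utr5", "len_cds", "len_utr3"} <= set(df.columns):
        df["len_transcript"] = df["len_utr5"] + df["len_cds"] + df["len_utr3"]
    return df


def read_truth(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene_id")
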
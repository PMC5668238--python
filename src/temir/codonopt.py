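"""tRNA adaptation index (tAI): weights, per-gene scores, CDS redesign.

The tAI of a coding sequence is the geometric mean, over its codons, of
relative adaptiveness weights w derived from tRNA gene copy numbers
(tGCN). A codon's absolute adaptiveness W sums contributions from every
anticodon that can decode it, each discounted by a wobble-pairing
selective constraint s:

    W(..U) = (1 - s_WC) tGCN(A34) + (1 - s_GU) tGCN(G34)
    W(..C) = (1 - s_WC) tGCN(G34) + (1 - s_IC) tGCN(A34)   # A34 read as inosine
    W(..A) = (1 - s_WC) tGCN(U34) + (1 - s_IA) tGCN(A34)
    W(..G) = (1 - s_WC) tGCN(C34) + (1 - s_UG) tGCN(U34)

with the canonical constraint set s_WC = 0, s_GU = 0.41, s_IC = 0.28,
s_IA = 0.9999, s_UG = 0.68. Anticodon positions 35-36 Watson-Crick
match codon positions 2 and 1. In eukaryote mode (default) the
bacterial lysidine rule for AUA is disabled and Met (ATG) / Trp (TGG)
take only their Watson-Crick contribution. w = W / max(W); codons with
W = 0 are assigned the geometric mean of the nonzero w before use —
this substitution matters for sparse tRNA tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import standard_dna_table

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

STOP_CODONS = frozenset(standard_dna_table.stop_codons)  # TAA, TAG, TGA
SENSE_CODONS = tuple(sorted(standard_dna_table.forward_table))  # 61 codons
CODON_TO_AA = dict(standard_dna_table.forward_table)

SYNONYMS: dict[str, tuple[str, ...]] = {
    codon: tuple(c for c in SENSE_CODONS if CODON_TO_AA[c] == CODON_TO_AA[codon])
    for codon in SENSE_CODONS
}


@dataclass(frozen=True)
class SValues:
    """Wobble selective constraints; all in [0, 1]."""

    wc: float = 0.0
    gu: float = 0.41
    ic: float = 0.28
    ia: float = 0.9999
    ug: float = 0.68
    lysidine: float = 0.89  # bacterial AUA decoding; unused in eukaryote mode

    def __post_init__(self) -> None:
        for name in ("wc", "gu", "ic", "ia", "ug", "lysidine"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"s value {name}={v} outside [0, 1]")


# wobble base at anticodon position 34 and the matching s attribute,
# keyed by the codon's third base
_DECODING = {
    "T": (("A", "wc"), ("G", "gu")),
    "C": (("G", "wc"), ("A", "ic")),
    "A": (("T", "wc"), ("A", "ia")),
    "G": (("C", "wc"), ("T", "ug")),
}


def _as_dna(seq: str) -> str:
    return seq.upper().replace("U", "T")


def read_trna_table(path) -> dict[str, int]:
    """Read a GtRNAdb-style TSV of anticodon gene copy numbers."""
    df = pd.read_csv(path, sep="\t")
    cols = {c.lower(): c for c in df.columns}
    if "anticodon" not in cols or "tgcn" not in cols:
        raise ValueError(f"tRNA table {path} needs 'anticodon' and 'tgcn' columns")
    table: dict[str, int] = {}
    for _, row in df.iterrows():
        ac = _as_dna(str(row[cols["anticodon"]]))
        n = int(row[cols["tgcn"]])
        if len(ac) != 3 or set(ac) - set("ACGT"):
            raise ValueError(f"invalid anticodon {ac!r} in {path}")
        if n < 0:
            raise ValueError(f"negative gene copy number for {ac}")
        table[ac] = table.get(ac, 0) + n
    return table


@dataclass
class TaiWeights:
    """Absolute (W) and relative (w) codon adaptiveness.

    ``w`` has max 1 over sense codons; zero-W codons already carry the
    geometric-mean substitute and are listed in ``substituted``.
    """

    W: dict[str, float]
    w: dict[str, float]
    substituted: tuple[str, ...] = field(default_factory=tuple)

    def log_w(self) -> dict[str, float]:
        return {c: math.log(v) for c, v in self.w.items()}


def tai_weights(trna: dict[str, int], s: SValues | None = None) -> TaiWeights:
    """Codon adaptiveness weights from anticodon gene copy numbers.

    Eukaryote mode: ATG and TGG take only the Watson-Crick term and the
    lysidine rule is disabled. Stop codons are excluded.
    """
    s = s or SValues()
    trna = {_as_dna(k): int(v) for k, v in trna.items()}
    if any(v < 0 for v in trna.values()):
        raise ValueError("negative tRNA gene copy number")
    if not any(v > 0 for v in trna.values()):
        raise ValueError("tRNA table has no nonzero gene copy numbers")

    W: dict[str, float] = {}
    for codon in SENSE_CODONS:
        pairings = _DECODING[codon[2]]
        if codon in ("ATG", "TGG"):
            pairings = pairings[:1]  # Watson-Crick only
        total = 0.0
        for base34, s_name in pairings:
            anticodon = base34 + codon[1].translate(_COMPLEMENT) + codon[0].translate(
                _COMPLEMENT
            )
            total += (1.0 - getattr(s, s_name)) * trna.get(anticodon, 0)
        W[codon] = total

    w_max = max(W.values())
    if w_max <= 0:
        raise ValueError("all codon adaptiveness values are zero")
    w = {c: v / w_max for c, v in W.items()}
    zeros = tuple(c for c, v in w.items() if v == 0.0)
    if zeros:
        nonzero = [v for v in w.values() if v > 0]
        gm = math.exp(sum(math.log(v) for v in nonzero) / len(nonzero))
        for c in zeros:
            w[c] = gm
    return TaiWeights(W=W, w=w, substituted=zeros)


def _codons(cds_seq: str) -> list[str]:
    cds = _as_dna(cds_seq)
    if len(cds) % 3 != 0:
        raise ValueError(f"CDS length {len(cds)} is not a multiple of 3")
    if set(cds) - set("ACGT"):
        raise ValueError("CDS contains non-ACGT characters")
    return [cds[i : i + 3] for i in range(0, len(cds), 3)]


def _sense_codons(cds_seq: str, drop_first_codon: bool = False) -> list[str]:
    codons = _codons(cds_seq)
    if codons and codons[-1] in STOP_CODONS:
        codons = codons[:-1]
    for i, c in enumerate(codons):
        if c in STOP_CODONS:
            raise ValueError(f"internal stop codon {c} at codon index {i}")
    if drop_first_codon:
        codons = codons[1:]
    if not codons:
        raise ValueError("CDS has no sense codons")
    return codons


def tai(cds_seq: str, weights: TaiWeights, drop_first_codon: bool = False) -> float:
    """Geometric mean of w over the CDS's sense codons.

    A trailing stop codon is dropped; an internal stop is an error. By
    default the initiator codon is included (``drop_first_codon`` flips
    the convention).
    """
    codons = _sense_codons(cds_seq, drop_first_codon)
    log_w = weights.log_w()
    return math.exp(sum(log_w[c] for c in codons) / len(codons))


def genome_tai_distribution(
    cds_set: dict[str, str],
    weights: TaiWeights,
    bins: int | np.ndarray = 20,
    drop_first_codon: bool = False,
) -> dict:
    """Per-gene tAI over a CDS collection, with a binned frequency summary.

    Invalid CDS (wrong length, internal stop) are reported under
    ``invalid`` rather than silently dropped.
    """
    if not cds_set:
        raise ValueError("empty CDS set")
    values: dict[str, float] = {}
    invalid: dict[str, str] = {}
    for gene, cds in cds_set.items():
        try:
            values[gene] = tai(cds, weights, drop_first_codon)
        except ValueError as exc:
            invalid[gene] = str(exc)
    tai_series = pd.Series(values, name="tai")
    if len(tai_series):
        hist, edges = np.histogram(tai_series.to_numpy(), bins=bins, range=(0.0, 1.0))
        quantiles = tai_series.quantile([0.25, 0.5, 0.75]).to_dict()
    else:
        hist, edges = np.array([]), np.array([])
        quantiles = {}
    return {
        "tai": tai_series,
        "hist": hist,
        "bin_edges": edges,
        "quantiles": quantiles,
        "invalid": invalid,
    }


@dataclass
class RedesignResult:
    seq: str
    tai: float
    converged: bool
    n_swaps: int
    attainable_range: tuple[float, float]


def attainable_tai_range(
    cds_seq: str, weights: TaiWeights, drop_first_codon: bool = False
) -> tuple[float, float]:
    """[min, max] tAI over synonymous recodings of the CDS."""
    codons = _sense_codons(cds_seq, drop_first_codon)
    log_w = weights.log_w()
    lo = sum(min(log_w[s] for s in SYNONYMS[c]) for c in codons) / len(codons)
    hi = sum(max(log_w[s] for s in SYNONYMS[c]) for c in codons) / len(codons)
    return math.exp(lo), math.exp(hi)


def redesign_cds(
    cds_seq: str,
    weights: TaiWeights,
    target_tai: float,
    tolerance: float = 0.005,
    seed: int = 0,
) -> RedesignResult:
    """Synonymously recode a CDS toward a target tAI.

    For short sequences (search space up to ~10^5 synonymous variants
    per half) the optimum is found exactly by meet-in-the-middle
    enumeration. Longer sequences use a steepest-feasible greedy: at
    each step the single synonymous swap that moves the tAI furthest
    toward the target is applied (ties break to the lowest codon index,
    with a seeded shuffle only among exact ties), followed by a paired-
    swap polish once single swaps stall. The encoded protein is
    unchanged. Stops when within ``tolerance`` or at the closest value
    found (``converged=False``); a target outside the attainable range
    is an error reporting that range.
    """
    cds = _as_dna(cds_seq)
    codons = _codons(cds)
    stop = codons[-1] if codons and codons[-1] in STOP_CODONS else None
    sense = _sense_codons(cds)
    lo, hi = attainable_tai_range(cds, weights)
    if not lo <= target_tai <= hi:
        raise ValueError(
            f"target tAI {target_tai} outside attainable range [{lo:.4f}, {hi:.4f}]"
        )
    rng = np.random.default_rng(seed)
    log_w = weights.log_w()
    n = len(sense)
    current = [log_w[c] for c in sense]
    total = sum(current)

    def dist(t: float) -> float:
        return abs(math.exp(t / n) - target_tai)

    n_swaps = 0
    if dist(total) > tolerance:
        exact = _exact_redesign(sense, log_w, target_tai, n)
        if exact is not None:
            new_sense, new_total = exact
            n_swaps = sum(a != b for a, b in zip(sense, new_sense))
            if dist(new_total) < dist(total):
                sense, total = new_sense, new_total
            else:
                n_swaps = 0
            out = "".join(sense) + (stop or "")
            achieved = math.exp(total / n)
            return RedesignResult(
                seq=out,
                tai=achieved,
                converged=abs(achieved - target_tai) <= tolerance,
                n_swaps=n_swaps,
                attainable_range=(lo, hi),
            )
    while dist(total) > tolerance:
        best_gain = 0.0
        candidates: list[tuple[int, str, float]] = []
        for i, codon in enumerate(sense):
            for syn in SYNONYMS[codon]:
                if syn == codon:
                    continue
                step = log_w[syn] - current[i]
                # progress toward the target; overshoot is penalized
                gain = dist(total) - dist(total + step)
                if gain > best_gain + 1e-15:
                    best_gain = gain
                    candidates = [(i, syn, step)]
                elif candidates and abs(gain - best_gain) <= 1e-15 and gain > 0:
                    candidates.append((i, syn, step))
        if not candidates:
            need = n * math.log(target_tai) - total
            pair = _best_pair_swap(sense, current, total, log_w, need, dist)
            if pair is None:
                break
            (i, syn_i, step_i), (j, syn_j, step_j) = pair
            sense[i], sense[j] = syn_i, syn_j
            current[i] += step_i
            current[j] += step_j
            total += step_i + step_j
            n_swaps += 2
            continue
        lowest = min(i for i, _, _ in candidates)
        tied = [c for c in candidates if c[0] == lowest]
        i, syn, step = tied[int(rng.integers(len(tied)))] if len(tied) > 1 else tied[0]
        sense[i] = syn
        current[i] += step
        total += step
        n_swaps += 1

    out = "".join(sense) + (stop or "")
    achieved = math.exp(total / n)
    return RedesignResult(
        seq=out,
        tai=achieved,
        converged=abs(achieved - target_tai) <= tolerance,
        n_swaps=n_swaps,
        attainable_range=(lo, hi),
    )


_EXACT_LIMIT = 100_000  # max enumerated variants per half for the exact path


def _exact_redesign(sense, log_w, target_tai, n):
    """Meet-in-the-middle exact synonymous recoding for small search spaces.

    Returns (codons, total_log_w) of the variant whose tAI is closest to
    the target, or None when the space is too large to enumerate.
    """
    import bisect

    sizes = [len(SYNONYMS[c]) for c in sense]
    half = len(sense) // 2
    left_size = math.prod(sizes[:half])
    right_size = math.prod(sizes[half:])
    if left_size > _EXACT_LIMIT or right_size > _EXACT_LIMIT:
        return None

    def enumerate_side(codons):
        combos = [(0.0, ())]
        for c in codons:
            combos = [
                (s + log_w[syn], picked + (syn,))
                for s, picked in combos
                for syn in SYNONYMS[c]
            ]
        return combos

    left = enumerate_side(sense[:half])
    right = sorted(enumerate_side(sense[half:]))
    right_sums = [s for s, _ in right]
    need = n * math.log(target_tai)
    best = None
    for s_left, picked_left in left:
        j = bisect.bisect_left(right_sums, need - s_left)
        for jj in (j - 1, j):
            if 0 <= jj < len(right):
                total = s_left + right_sums[jj]
                d = abs(math.exp(total / n) - target_tai)
                if best is None or d < best[0] - 1e-15:
                    best = (d, list(picked_left + right[jj][1]), total)
    return (best[1], best[2]) if best is not None else None


def _best_pair_swap(sense, current, total, log_w, need, dist):
    """Best simultaneous pair of synonymous swaps, or None if none improves.

    ``need`` is the change in the summed log-weights that would hit the
    target exactly; candidate steps are sorted and scanned with two
    pointers, so the search is O(M log M) in the number of options M.
    """
    steps = sorted(
        (log_w[syn] - current[i], i, syn)
        for i, codon in enumerate(sense)
        for syn in SYNONYMS[codon]
        if syn != codon
    )
    if len(steps) < 2:
        return None
    best = None
    best_d = dist(total) - 1e-15
    a, b = 0, len(steps) - 1
    while a < b:
        sa, ia, _ = steps[a]
        sb, ib, _ = steps[b]
        if ia == ib:
            # same codon position: try the nearest distinct-position partners
            for bb in (b - 1, a + 1):
                if a < bb < len(steps) and bb != b and steps[bb][1] != ia:
                    d = dist(total + sa + steps[bb][0])
                    if d < best_d:
                        best_d, best = d, (a, bb)
            b -= 1
            continue
        d = dist(total + sa + sb)
        if d < best_d:
            best_d, best = d, (a, b)
        if sa + sb < need:
            a += 1
        else:
            b -= 1
    if best is None:
        return None
    sa, ia, syn_a = steps[best[0]]
    sb, ib, syn_b = steps[best[1]]
    return (ia, syn_a, sa), (ib, syn_b, sb)
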
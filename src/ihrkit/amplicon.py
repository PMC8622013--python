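"""Somatic allele-spectrum reconstruction from long-amplicon molecules.

Each independently sequenced ~5 kb molecule is reduced to a per-marker
parental haplotype pattern ('1' = P1 base, '2' = P2 base) plus a cut-site
indel signature. Molecules are clustered into consensus alleles by greedy
agglomeration (largest exact pattern group first; a group joins an existing
cluster when the indel signatures match and the patterns differ at no more
than ``max_mismatch`` markers), alleles below a 5% molecule-frequency floor
are discarded as noise/PCR artifacts, and each retained allele is classified
by its pattern topology: parental, NHEJ-only (indel, no marker exchange),
single-switch exchange (reciprocal when the complementary allele co-occurs
in the same plant, non-reciprocal otherwise) or interrupted exchange
(>= 2 switches, the alternating-marker signature of heteroduplex mismatch
repair). At amplicon scale a single-switch exchange cannot be told apart
from a long-tract conversion reaching the amplicon edge, so classes describe
pattern topology, not mechanism.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

EXCHANGE_CLASSES = ("nonreciprocal_exchange", "reciprocal_exchange_member", "interrupted_exchange")


@dataclass
class AlleleConsensus:
    pattern: str  # '1'/'2' per in-window marker
    indel_signature: str  # '' for none, else e.g. '+T', '-2'
    frequency: float
    n_molecules: int
    klass: Optional[str] = None
    switches: list[tuple[int, int]] = field(default_factory=list)  # inter-marker intervals (bp)

    @property
    def n_switches(self) -> int:
        return sum(1 for a, b in zip(self.pattern[:-1], self.pattern[1:]) if a != b)

    @property
    def has_indel(self) -> bool:
        return self.indel_signature != ""

    @property
    def is_exchange(self) -> bool:
        return self.klass in EXCHANGE_CLASSES


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def cluster_molecules(molecules: pd.DataFrame, max_mismatch: int = 1) -> list[AlleleConsensus]:
    """Greedy agglomeration of molecules into consensus alleles.

    Deterministic and order-independent up to ties: exact (pattern, indel)
    groups are processed largest first (ties by pattern then indel,
    lexicographic); each joins the first existing cluster with the same indel
    signature within ``max_mismatch`` of its consensus, else founds a new
    cluster. Consensus patterns are per-marker weighted majorities.
    """
    if len(molecules) == 0:
        raise ValueError("no molecules to cluster")
    pats = molecules["haplotype_pattern"].astype(str)
    if pats.str.len().nunique() != 1:
        raise ValueError("molecule patterns differ in length")
    groups = (
        molecules.assign(indel_signature=molecules["indel_signature"].fillna(""))
        .groupby(["indel_signature", "haplotype_pattern"])
        .size()
        .reset_index(name="count")
        .sort_values(["count", "haplotype_pattern", "indel_signature"], ascending=[False, True, True])
    )
    total = int(groups["count"].sum())

    clusters: list[dict] = []  # {indel, members: [(pattern, count)], consensus}
    for row in groups.itertuples(index=False):
        placed = False
        for cl in clusters:
            if cl["indel"] == row.indel_signature and _hamming(cl["consensus"], row.haplotype_pattern) <= max_mismatch:
                cl["members"].append((row.haplotype_pattern, row.count))
                cl["consensus"] = _weighted_majority(cl["members"])
                placed = True
                break
        if not placed:
            clusters.append(
                {
                    "indel": row.indel_signature,
                    "members": [(row.haplotype_pattern, row.count)],
                    "consensus": row.haplotype_pattern,
                }
            )
    out = [
        AlleleConsensus(
            pattern=cl["consensus"],
            indel_signature=cl["indel"],
            frequency=sum(c for _, c in cl["members"]) / total,
            n_molecules=sum(c for _, c in cl["members"]),
        )
        for cl in clusters
    ]
    out.sort(key=lambda a: (-a.frequency, a.pattern, a.indel_signature))
    return out


def _weighted_majority(members: list[tuple[str, int]]) -> str:
    length = len(members[0][0])
    counts = np.zeros((length, 2))
    for pattern, n in members:
        for i, ch in enumerate(pattern):
            counts[i, 0 if ch == "1" else 1] += n
    return "".join("1" if counts[i, 0] >= counts[i, 1] else "2" for i in range(length))


def filter_alleles(alleles: Sequence[AlleleConsensus], min_freq: float = 0.05) -> tuple[list[AlleleConsensus], float]:
    """Keep alleles with frequency strictly above ``min_freq``; return the
    retained list and the discarded frequency mass."""
    retained = [a for a in alleles if a.frequency > min_freq]
    discarded = float(sum(a.frequency for a in alleles) - sum(a.frequency for a in retained))
    return retained, discarded


def _switch_intervals(pattern: str, positions: np.ndarray) -> list[tuple[int, int]]:
    return [
        (int(positions[i]), int(positions[i + 1]))
        for i in range(len(pattern) - 1)
        if pattern[i] != pattern[i + 1]
    ]


def _complementary(a: AlleleConsensus, b: AlleleConsensus) -> bool:
    """Two single-switch alleles are reciprocal partners when their switch
    intervals overlap and their flanking parental assignments are exchanged."""
    if a.n_switches != 1 or b.n_switches != 1:
        return False
    (a_lo, a_hi), (b_lo, b_hi) = a.switches[0], b.switches[0]
    if a_lo > b_hi or b_lo > a_hi:
        return False
    return a.pattern[0] != b.pattern[0] and a.pattern[-1] != b.pattern[-1]


def classify_allele(allele: AlleleConsensus, positions: np.ndarray) -> str:
    """Topology class ignoring reciprocity (see classify_alleles)."""
    if len(allele.pattern) == 0:
        raise ValueError("empty pattern")
    allele.switches = _switch_intervals(allele.pattern, positions)
    ns = allele.n_switches
    if ns == 0:
        if allele.has_indel:
            return "nhej_only"
        return "parental_P1" if allele.pattern[0] == "1" else "parental_P2"
    if ns == 1:
        return "nonreciprocal_exchange"
    return "interrupted_exchange"


def classify_alleles(alleles: Sequence[AlleleConsensus], positions: np.ndarray) -> list[AlleleConsensus]:
    """Classify every retained allele of one plant, resolving reciprocity:
    a single-switch allele whose complementary partner is also retained is a
    reciprocal_exchange_member. Sets ``klass`` in place and returns the list."""
    positions = np.asarray(positions)
    for a in alleles:
        a.klass = classify_allele(a, positions)
    singles = [a for a in alleles if a.klass == "nonreciprocal_exchange"]
    for i, a in enumerate(singles):
        for b in singles[i + 1 :]:
            if _complementary(a, b):
                a.klass = "reciprocal_exchange_member"
                b.klass = "reciprocal_exchange_member"
    return list(alleles)


def somatic_ihr_rate(alleles: Sequence[AlleleConsensus]) -> float:
    """Fraction of molecule mass in exchange-class alleles — the somatic
    inter-homolog recombination level of the plant. Raises ValueError on an
    empty retained set (no alleles passed the frequency filter)."""
    if not alleles:
        raise ValueError("no retained alleles")
    if any(a.klass is None for a in alleles):
        raise ValueError("alleles must be classified first")
    return float(sum(a.frequency for a in alleles if a.is_exchange))


# --------------------------------------------------------------------------- IO & plotting
def alleles_frame(alleles: Sequence[AlleleConsensus]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "pattern": a.pattern,
                "indel": a.indel_signature if a.indel_signature else ".",
                "freq": a.frequency,
                "n_molecules": a.n_molecules,
                "class": a.klass,
                "switches": ";".join(f"{lo}-{hi}" for lo, hi in a.switches),
            }
            for a in alleles
        ]
    )


def plot_allele_spectrum(alleles: Sequence[AlleleConsensus], positions: np.ndarray, cut_position: int, ax=None):
    """Stacked-rectangle rendering of one plant's allele spectrum: one row per
    allele with height proportional to frequency, red/blue ticks for P1/P2
    marker assignments, a yellow tick for a cut-site indel."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 3))
    positions = np.asarray(positions)
    y = 0.0
    for a in sorted(alleles, key=lambda x: -x.frequency):
        h = a.frequency
        ax.axhspan(y, y + h, xmin=0, xmax=1, facecolor="0.95", edgecolor="0.3", linewidth=0.5)
        for pos, ch in zip(positions, a.pattern):
            ax.plot([pos, pos], [y + 0.1 * h, y + 0.9 * h], color="red" if ch == "1" else "blue", lw=1.2)
        if a.has_indel:
            ax.plot([cut_position, cut_position], [y, y + h], color="gold", lw=2.5)
        ax.text(positions[-1], y + h / 2, f" {a.frequency:.1%} {a.klass or ''}", va="center", fontsize=7)
        y += h
    ax.axvline(cut_position, color="k", ls="--", lw=0.8)
    ax.set_ylim(0, max(y, 1.0))
    ax.set_xlabel("position (bp)")
    ax.set_ylabel("molecule fraction")
    return ax
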
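"""Three-state genotype HMM over parental allele counts.

Each F2 plant is segmented along every chromosome into HomP1 / Het / HomP2
blocks from per-marker read counts. Emissions are binomial: in a HomP1 state
a read reports the P1 allele with probability 1 - epsilon (miscall epsilon),
in Het with probability 0.5, in HomP2 with probability epsilon. Transitions
between adjacent markers are distance-aware: with per-bp rate r and gap d,
the chain leaves the current state with probability 1 - exp(-r * d), split
equally between the two other states. Decoding is max-a-posteriori (Viterbi,
log space, ties broken toward staying in the previous state so that equal-
score paths prefer fewer transitions); forward-backward posteriors are kept
for downstream posterior-thresholded genotype calls. State changes in the
decoded path are candidate crossovers; proximity to a declared cut site is
the only thing that distinguishes an induced crossover from a meiotic one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp, xlogy

from .markers import DsbTarget, SnpMarkerMap
from .simulate import GenotypeObservations

STATES = ("HomP1", "Het", "HomP2")
_STATE_INDEX = {s: i for i, s in enumerate(STATES)}


@dataclass(frozen=True)
class HmmParams:
    """Decoder parameters.

    r : per-bp transition rate between genotype states (weakly informative
        default 1e-6; the data overwhelm it at any realistic coverage).
    epsilon : per-read allele miscall probability, in [0, 0.5).
    prior : initial state distribution; the F2 Mendelian 1:2:1 by default.
    """

    r: float = 1e-6
    epsilon: float = 0.005
    prior: tuple[float, float, float] = (0.25, 0.5, 0.25)

    def __post_init__(self) -> None:
        if not self.r > 0:
            raise ValueError("r must be > 0")
        if not 0.0 <= self.epsilon < 0.5:
            raise ValueError("epsilon must be in [0, 0.5)")
        if abs(sum(self.prior) - 1.0) > 1e-9 or any(p < 0 for p in self.prior):
            raise ValueError("prior must be a distribution over the 3 states")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "HmmParams":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "prior" in raw:
            raw["prior"] = tuple(raw["prior"])
        return cls(**raw)


def _per_read_p1_prob(epsilon: float) -> np.ndarray:
    return np.array([1.0 - epsilon, 0.5, epsilon])


def emission_loglik(n_p1, n_p2, state: str | int, epsilon: float):
    """Binomial log-likelihood of the counts under one state.

    Reads are exchangeable, so the evidence at a marker is
    Binom(n_P1 | n_P1 + n_P2, p_state) with p_state the per-read probability
    of reporting the P1 allele. (0, 0) is uninformative and scores 0 under
    every state.
    """
    if not 0.0 <= epsilon < 0.5:
        raise ValueError("epsilon must be in [0, 0.5)")
    n_p1 = np.asarray(n_p1, dtype=np.int64)
    n_p2 = np.asarray(n_p2, dtype=np.int64)
    if np.any(n_p1 < 0) or np.any(n_p2 < 0):
        raise ValueError("counts must be >= 0")
    si = _STATE_INDEX[state] if isinstance(state, str) else int(state)
    p = _per_read_p1_prob(epsilon)[si]
    n = n_p1 + n_p2
    coeff = gammaln(n + 1) - gammaln(n_p1 + 1) - gammaln(n_p2 + 1)
    return coeff + xlogy(n_p1, p) + xlogy(n_p2, 1.0 - p)


def _emission_matrix(n_p1: np.ndarray, n_p2: np.ndarray, epsilon: float) -> np.ndarray:
    return np.stack([emission_loglik(n_p1, n_p2, s, epsilon) for s in range(3)], axis=1)


def transition_logmatrix(d: int, r: float) -> np.ndarray:
    """Log transition matrix across a gap of d bp: stay exp(-r d), each
    switch (1 - exp(-r d)) / 2."""
    stay = np.exp(-r * d)
    switch = (1.0 - stay) / 2.0
    with np.errstate(divide="ignore"):
        T = np.full((3, 3), np.log(switch) if switch > 0 else -np.inf)
        np.fill_diagonal(T, np.log(stay))
    return T


# --------------------------------------------------------------------------- segmentation
@dataclass
class Block:
    state: str
    first: int  # marker index
    last: int


@dataclass
class ChromSegmentation:
    chromosome: str
    positions: np.ndarray
    states: np.ndarray  # per-marker decoded state index (post noise-merge)
    blocks: list[Block]
    posteriors: np.ndarray  # (m, 3) forward-backward posteriors
    emissions: np.ndarray  # (m, 3) per-marker emission log-likelihoods
    viterbi_loglik: float

    def state_labels(self) -> np.ndarray:
        return np.array(STATES)[self.states]


@dataclass
class GenotypeSegmentation:
    plant_id: str
    chromosomes: dict[str, ChromSegmentation]

    def __getitem__(self, chrom: str) -> ChromSegmentation:
        return self.chromosomes[chrom]


def _blocks_from_states(states: np.ndarray) -> list[Block]:
    blocks: list[Block] = []
    start = 0
    for i in range(1, states.size + 1):
        if i == states.size or states[i] != states[start]:
            blocks.append(Block(state=STATES[states[start]], first=start, last=i - 1))
            start = i
    return blocks


def viterbi_decode(
    obs: GenotypeObservations,
    marker_map: SnpMarkerMap,
    params: HmmParams = HmmParams(),
    merge_single_marker_posterior: float = 0.99,
) -> GenotypeSegmentation:
    """MAP state path plus forward-backward posteriors for every chromosome.

    Single-marker islands (one marker whose decoded state differs from a
    shared flanking state on both sides) with state posterior below
    ``merge_single_marker_posterior`` are absorbed into the flanking state —
    a reproducible stand-in for the manual review such calls normally get.
    Terminal blocks and islands between unlike flanks are never merged.
    """
    chrom_segs: dict[str, ChromSegmentation] = {}
    for chrom_name, (n_p1, n_p2) in obs.counts.items():
        chrom = marker_map[chrom_name]
        m = chrom.n_markers
        if m == 0:
            raise ValueError(f"{chrom_name}: empty marker list")
        E = _emission_matrix(n_p1, n_p2, params.epsilon)
        log_prior = np.log(np.asarray(params.prior, dtype=float))
        gaps = np.diff(chrom.positions)

        # Viterbi
        delta = log_prior + E[0]
        psi = np.zeros((m, 3), dtype=np.int8)
        for t in range(1, m):
            T = transition_logmatrix(int(gaps[t - 1]), params.r)
            scores = delta[:, None] + T  # scores[i, j]
            best = scores.max(axis=0)
            arg = scores.argmax(axis=0)
            for j in range(3):  # prefer staying: i == j wins ties
                if scores[j, j] >= best[j] - 1e-12:
                    arg[j] = j
            delta = best + E[t]
            psi[t] = arg
        path = np.zeros(m, dtype=np.int8)
        path[-1] = int(np.argmax(delta))
        score = float(delta[path[-1]])
        for t in range(m - 2, -1, -1):
            path[t] = psi[t + 1][path[t + 1]]

        # forward-backward
        alpha = np.zeros((m, 3))
        beta = np.zeros((m, 3))
        alpha[0] = log_prior + E[0]
        for t in range(1, m):
            T = transition_logmatrix(int(gaps[t - 1]), params.r)
            alpha[t] = logsumexp(alpha[t - 1][:, None] + T, axis=0) + E[t]
        for t in range(m - 2, -1, -1):
            T = transition_logmatrix(int(gaps[t]), params.r)
            beta[t] = logsumexp(T + (E[t + 1] + beta[t + 1])[None, :], axis=1)
        log_post = alpha + beta
        log_post -= logsumexp(log_post, axis=1, keepdims=True)
        post = np.exp(log_post)

        # absorb unsupported single-marker islands (same state on both sides)
        blocks = _blocks_from_states(path)
        if len(blocks) > 2:
            merged = path.copy()
            for bi in range(1, len(blocks) - 1):
                b = blocks[bi]
                if (
                    b.first == b.last
                    and blocks[bi - 1].state == blocks[bi + 1].state
                    and post[b.first, _STATE_INDEX[b.state]] < merge_single_marker_posterior
                ):
                    merged[b.first] = _STATE_INDEX[blocks[bi - 1].state]
            path = merged
            blocks = _blocks_from_states(path)

        chrom_segs[chrom_name] = ChromSegmentation(
            chromosome=chrom_name,
            positions=chrom.positions,
            states=path,
            blocks=blocks,
            posteriors=post,
            emissions=E,
            viterbi_loglik=score,
        )
    return GenotypeSegmentation(plant_id=obs.plant_id, chromosomes=chrom_segs)


# --------------------------------------------------------------------------- crossovers
@dataclass(frozen=True)
class CrossoverCall:
    """A decoded genotype-block boundary: the crossover lies between the last
    marker of the left block and the first marker of the right block; the
    point estimate is the (half-up rounded) mean of those two positions."""

    plant_id: str
    chromosome: str
    left: int
    right: int
    midpoint: int
    transition: str
    distance_to_dsb: Optional[int] = None


def _midpoint(left: int, right: int) -> int:
    return (left + right + 1) // 2  # round half up on the .5 case


def call_crossovers(
    seg: GenotypeSegmentation,
    targets: Sequence[DsbTarget] | None = None,
) -> list[CrossoverCall]:
    """One call per adjacent-block boundary on every chromosome."""
    target_by_chrom: dict[str, DsbTarget] = {}
    for t in targets or []:
        target_by_chrom[t.chromosome] = t
    calls: list[CrossoverCall] = []
    for chrom_name, cseg in seg.chromosomes.items():
        for left_block, right_block in zip(cseg.blocks[:-1], cseg.blocks[1:]):
            left = int(cseg.positions[left_block.last])
            right = int(cseg.positions[right_block.first])
            mid = _midpoint(left, right)
            dist = None
            if chrom_name in target_by_chrom:
                dist = abs(mid - target_by_chrom[chrom_name].cut_position)
            calls.append(
                CrossoverCall(
                    plant_id=seg.plant_id,
                    chromosome=chrom_name,
                    left=left,
                    right=right,
                    midpoint=mid,
                    transition=f"{left_block.state}->{right_block.state}",
                    distance_to_dsb=dist,
                )
            )
    return calls


def classify_target_event(
    seg: GenotypeSegmentation,
    target: DsbTarget,
    window: int = 20_000,
) -> str:
    """``co_at_target`` iff any crossover interval overlaps the closed window
    [cut - window, cut + window]; ``none`` otherwise."""
    if window < 0:
        raise ValueError("window must be >= 0")
    lo, hi = target.cut_position - window, target.cut_position + window
    for call in call_crossovers(seg):
        if call.chromosome == target.chromosome and call.left <= hi and call.right >= lo:
            return "co_at_target"
    return "none"


# --------------------------------------------------------------------------- IO
def write_segmentation_bed(seg: GenotypeSegmentation, path: str | Path) -> None:
    """Blocks as BED (0-based half-open on write), name = state."""
    with open(path, "w") as fh:
        for chrom_name, cseg in seg.chromosomes.items():
            for b in cseg.blocks:
                start = int(cseg.positions[b.first]) - 1
                end = int(cseg.positions[b.last])
                fh.write(f"{chrom_name}\t{start}\t{end}\t{b.state}\t0\t+\t{seg.plant_id}\n")


def crossover_calls_frame(calls: Sequence[CrossoverCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "plant_id": c.plant_id,
                "chromosome": c.chromosome,
                "left": c.left,
                "right": c.right,
                "midpoint": c.midpoint,
                "transition": c.transition,
                "distance_to_dsb": c.distance_to_dsb,
            }
            for c in calls
        ]
    )
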
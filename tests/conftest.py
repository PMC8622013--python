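"""Shared fixtures and independent oracles.

Oracles here deliberately avoid the implementation paths they check:
path enumeration instead of Viterbi recursion, a direct window scan instead
of the segment-based homozygosity screen, and global edit-distance alignment
instead of anchor matching.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from scipy.stats import binom

from ihrkit.markers import ChromosomeMarkers, SnpMarkerMap
from ihrkit.simulate import GenotypeObservations


@pytest.fixture
def rng():
    return np.random.default_rng(20210912)


def make_map(positions, length=None, name="Chr3"):
    positions = np.asarray(positions, dtype=np.int64)
    length = int(length or positions[-1] + 1000)
    mm = SnpMarkerMap()
    mm.add(
        ChromosomeMarkers(
            name=name,
            length=length,
            positions=positions,
            allele_p1=np.array(["A"] * positions.size),
            allele_p2=np.array(["C"] * positions.size),
        )
    )
    return mm


def obs_from_counts(n_p1, n_p2, chrom="Chr3", plant_id="plant"):
    return GenotypeObservations(
        plant_id=plant_id,
        counts={chrom: (np.asarray(n_p1, dtype=np.int64), np.asarray(n_p2, dtype=np.int64))},
    )


# --------------------------------------------------------------------------- oracles
def enumerate_best_path_loglik(n_p1, n_p2, positions, params):
    """Max log joint over all 3^m state paths, by direct (vectorised)
    enumeration — no dynamic programming, independent of the Viterbi code."""
    from ihrkit.hmm import transition_logmatrix

    m = len(n_p1)
    pvec = [1 - params.epsilon, 0.5, params.epsilon]
    E = np.array(
        [[binom.logpmf(n_p1[t], n_p1[t] + n_p2[t], pvec[s]) for s in range(3)] for t in range(m)]
    )
    gaps = np.diff(np.asarray(positions))
    Ts = [transition_logmatrix(int(d), params.r) for d in gaps]
    paths = np.array(list(itertools.product(range(3), repeat=m)))  # (3^m, m)
    scores = np.log(np.asarray(params.prior))[paths[:, 0]] + E[0][paths[:, 0]]
    for t in range(1, m):
        scores += Ts[t - 1][paths[:, t - 1], paths[:, t]] + E[t][paths[:, t]]
    return float(scores.max())


def window_scan_screen(states, positions, cut, min_flank=100_000, max_tract_span=10_000):
    """Brute-force re-statement of the homozygosity screen over per-marker
    decoded state labels: scan every marker in the flank window directly."""
    in_win = [i for i, p in enumerate(positions) if cut - min_flank <= p <= cut + min_flank]
    if not in_win:
        return False, None
    for bg in ("HomP1", "HomP2"):
        bad = [i for i in in_win if states[i] != bg]
        if not bad:
            return True, bg
        if all(abs(positions[i] - cut) <= max_tract_span for i in bad) and (
            positions[bad[-1]] - positions[bad[0]] <= max_tract_span
        ):
            return True, bg
    return False, None


def edlib_classify(read, ref, cut_off, cut_slop=3, min_complex_mismatches=2):
    """Footprint class from a global edit-distance alignment (independent of
    the anchor-based classifier): collect indel runs from the alignment path,
    attribute an indel to the cut when its shift-ambiguity interval overlaps
    cut +/- cut_slop."""
    import re

    import edlib

    res = edlib.align(read, ref, task="path", mode="NW")
    ops = []  # (op, length, ref_offset_start)
    ref_off = 0
    for length, op in re.findall(r"(\d+)([=XIDM])", res["cigar"]):
        length = int(length)
        ops.append((op, length, ref_off))
        if op in ("=", "X", "D", "M"):
            ref_off += length
    indels = [(op, length, start) for op, length, start in ops if op in "ID"]
    net = sum(l if op == "I" else -l for op, l, _ in indels)
    if net != 0 and len({op for op, _, _ in indels}) == 1:
        op, length, start = max(indels, key=lambda x: x[1])
        end = start + (length if op == "D" else 0)
        # shift ambiguity: extend while flanking bases repeat the run
        lo, hi = start, end
        while lo > 0 and op == "D" and ref[lo - 1] == ref[hi - 1]:
            lo -= 1
            hi -= 1
        lo2, hi2 = start, end
        while hi2 < len(ref) and op == "D" and ref[lo2] == ref[hi2]:
            lo2 += 1
            hi2 += 1
        amb_lo = min(lo, start)
        amb_hi = max(hi2, end)
        if amb_lo <= cut_off + cut_slop and amb_hi >= cut_off - cut_slop:
            return "insertion" if net > 0 else "deletion"
        return "complex"
    if indels:
        return "complex"
    mismatch_near = 0
    for op, length, start in ops:
        if op == "X":
            for j in range(length):
                if abs(start + j - cut_off) <= cut_slop + 1:
                    mismatch_near += 1
    return "complex" if mismatch_near >= min_complex_mismatches else "WT"
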
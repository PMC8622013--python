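"""Gene-conversion (non-crossover) tract detection at a cut site.

An NCO signature in an F2 plant is an island of markers near the cut whose
genotype disagrees with an otherwise homozygous background. Detection is a
two-step procedure: (1) a homozygosity screen — the plant must be decoded as
one homozygous state for at least ``min_flank`` bp (default 100 kb) on each
side of the cut, because discordant markers on a heterozygous background are
uninterpretable at whole-genome coverage; (2) posterior-thresholded genotype
calls inside a search window around the cut. The span of the outermost
discordant markers is the *minimal* tract length (the true tract can only be
larger than what the marker grid resolves); the distance between the
innermost concordant flanking markers bounds it from above. A tract is
*simple* when every informative marker between the outermost converted ones
is converted, and *complex* (interrupted) otherwise — the signature of
per-mismatch heteroduplex repair.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .hmm import GenotypeSegmentation, STATES, _STATE_INDEX
from .markers import DsbTarget, SnpMarkerMap

HOM_STATES = ("HomP1", "HomP2")


@dataclass
class ConversionTract:
    plant_id: str
    target_id: str
    background: str  # HomP1 | HomP2
    converted_positions: np.ndarray  # bp, ordered
    converted_calls: list[str]  # decoded genotype at each converted marker
    min_length: int
    max_length: Optional[int]
    complexity: str  # simple | complex
    zygosity: str  # heterozygous_tract | homozygous_tract | complex_mixed
    low_confidence: bool = False  # single informative marker only

    @property
    def n_converted(self) -> int:
        return int(self.converted_positions.size)


def screen_background(
    seg: GenotypeSegmentation,
    target: DsbTarget,
    min_flank: int = 100_000,
    max_tract_span: int = 10_000,
) -> tuple[bool, Optional[str]]:
    """Homozygosity screen for NCO eligibility.

    Eligible iff every marker decoded in [cut - min_flank, cut + min_flank]
    shares one homozygous state, except that discordant markers are tolerated
    when they all lie within ``max_tract_span`` bp of the cut and span at most
    ``max_tract_span`` bp — the putative conversion island itself must not
    disqualify the plant. Returns (eligible, background state or None).
    """
    if target.chromosome not in seg.chromosomes:
        raise ValueError(f"segmentation lacks chromosome {target.chromosome}")
    cseg = seg.chromosomes[target.chromosome]
    cut = target.cut_position
    in_win = (cseg.positions >= cut - min_flank) & (cseg.positions <= cut + min_flank)
    if not in_win.any():
        return False, None
    states = cseg.states[in_win]
    positions = cseg.positions[in_win]
    near_cut = np.abs(positions - cut) <= max_tract_span
    for bg in HOM_STATES:
        bg_i = _STATE_INDEX[bg]
        discord = states != bg_i
        if not discord.any():
            return True, bg
        if np.all(near_cut[discord]):
            dpos = positions[discord]
            if dpos[-1] - dpos[0] <= max_tract_span:
                return True, bg
    return False, None


def _genotype_calls(cseg, min_posterior: float) -> np.ndarray:
    """Per-marker genotype call index from the emission evidence alone
    (flat state prior); -1 = uninformative.

    Chain-smoothed posteriors are deliberately not used here: the HMM's
    transition prior assumes genotype changes are rare per bp, which is
    exactly wrong inside a conversion tract where mismatch repair flips
    markers at the 100-bp scale — smoothing would erase interrupted-tract
    structure. Marker-local evidence at genotyping coverage is decisive on
    its own or the marker is left uninformative.
    """
    E = cseg.emissions
    post = np.exp(E - logsumexp(E, axis=1, keepdims=True))
    best = post.argmax(axis=1)
    conf = post.max(axis=1) >= min_posterior
    return np.where(conf, best, -1)


def detect_tract(
    seg: GenotypeSegmentation,
    marker_map: SnpMarkerMap,
    target: DsbTarget,
    background: str,
    search_window: int = 50_000,
    min_posterior: float = 0.99,
) -> Optional[ConversionTract]:
    """Call a conversion tract for one eligible plant, or None.

    Converted markers are informative markers (marker-local genotype
    posterior >= threshold, see _genotype_calls)
    inside [cut - search_window, cut + search_window] whose call differs from
    the background. min_length = span of the outermost converted markers
    (inclusive, so a single marker gives 1 — an ">=1 bp informative span").
    max_length = distance between the innermost informative background-state
    markers flanking the tract, minus 1; chromosome edges bound it when no
    such flank exists.
    """
    if background not in HOM_STATES:
        raise ValueError(f"background must be homozygous, got {background!r}")
    cseg = seg.chromosomes[target.chromosome]
    chrom = marker_map[target.chromosome]
    bg_i = _STATE_INDEX[background]
    calls = _genotype_calls(cseg, min_posterior)
    cut = target.cut_position
    in_win = (cseg.positions >= cut - search_window) & (cseg.positions <= cut + search_window)
    converted_mask = in_win & (calls >= 0) & (calls != bg_i)
    conv_idx = np.flatnonzero(converted_mask)
    if conv_idx.size == 0:
        return None
    first, last = conv_idx[0], conv_idx[-1]
    conv_pos = cseg.positions[conv_idx]
    min_length = int(conv_pos[-1] - conv_pos[0] + 1)

    informative_bg = (calls == bg_i)
    left_flank = np.flatnonzero(informative_bg[:first])
    right_flank = first + np.flatnonzero(informative_bg[first:])
    right_flank = right_flank[right_flank > last]
    left_pos = int(cseg.positions[left_flank[-1]]) if left_flank.size else 0
    right_pos = int(cseg.positions[right_flank[0]]) if right_flank.size else chrom.length + 1
    max_length = int(right_pos - left_pos - 1)

    between = np.arange(first, last + 1)
    interrupted = bool(np.any(informative_bg[between]))
    complexity = "complex" if interrupted else "simple"

    tract = ConversionTract(
        plant_id=seg.plant_id,
        target_id=target.id,
        background=background,
        converted_positions=conv_pos,
        converted_calls=[STATES[calls[i]] for i in conv_idx],
        min_length=min_length,
        max_length=max_length,
        complexity=complexity,
        zygosity="",
        low_confidence=conv_idx.size == 1,
    )
    tract.zygosity = classify_zygosity(tract)
    return tract


def classify_zygosity(tract: ConversionTract) -> str:
    """Heterozygous tract: converted markers are Het (one chromatid carries
    the donor allele). Homozygous tract: converted markers are homozygous for
    the donor allele — both gametes carried the conversion, the hallmark of a
    pre-meiotic (somatic) event. Mixed calls are reported, not rejected."""
    donor = "HomP2" if tract.background == "HomP1" else "HomP1"
    calls = set(tract.converted_calls)
    if calls == {"Het"}:
        return "heterozygous_tract"
    if calls == {donor}:
        return "homozygous_tract"
    return "complex_mixed"


# --------------------------------------------------------------------------- IO
_TRACT_COLUMNS = [
    "plant_id",
    "target_id",
    "background",
    "min_bp",
    "max_bp",
    "complexity",
    "zygosity",
    "n_converted",
    "low_confidence",
]


def tracts_frame(tracts: Sequence[ConversionTract]) -> pd.DataFrame:
    if not tracts:
        return pd.DataFrame(columns=_TRACT_COLUMNS)
    return pd.DataFrame(
        [
            {
                "plant_id": t.plant_id,
                "target_id": t.target_id,
                "background": t.background,
                "min_bp": t.min_length,
                "max_bp": t.max_length,
                "complexity": t.complexity,
                "zygosity": t.zygosity,
                "n_converted": t.n_converted,
                "low_confidence": t.low_confidence,
            }
            for t in tracts
        ]
    )


def write_tracts_bed(tracts: Sequence[ConversionTract], marker_map: SnpMarkerMap, targets: Sequence[DsbTarget], path: str | Path) -> None:
    """Minimal tract span as the BED thick region (closed coords converted to
    0-based half-open on write)."""
    chrom_of = {t.id: t.chromosome for t in targets}
    with open(path, "w") as fh:
        for t in tracts:
            chrom = chrom_of[t.target_id]
            start = int(t.converted_positions[0]) - 1
            end = int(t.converted_positions[-1])
            name = f"{t.plant_id}|{t.target_id}|{t.complexity}|{t.zygosity}"
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\t{t.n_converted}\t+\n")
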
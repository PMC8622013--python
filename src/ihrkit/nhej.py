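"""NHEJ footprint quantification from amplicon reads around a cut site.

Classification is anchor-based rather than full alignment: two k-mers taken
from the reference at a fixed offset either side of the cut (leaving a
2k-wide central region that contains any cut-site indel) are located in each
read, allowing one mismatch per anchor. The length of the read segment
between the anchors, compared with the 2k reference bases, gives the indel
size; the inserted bases and the indel's placement ambiguity interval come
from the longest common prefix/suffix of the two central segments. An indel
is attributed to the cut only if that ambiguity interval overlaps
cut +/- 3 nt. Reads where either anchor cannot be placed are excluded from
the denominator and reported separately.

NHEJ% follows the standard amplicon convention: the percentage of classified
reads carrying any indel (or complex change) at the cut, out of all
classified reads.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ReferenceWindow:
    """Reference sequence around a cut; ``start`` is the 1-based genomic
    position of the first base."""

    seq: str
    start: int = 1

    def cut_offset(self, cut_position: int) -> int:
        """Number of reference bases to the left of the scission (the cut
        falls between cut_position and cut_position + 1)."""
        off = cut_position - self.start + 1
        if not 0 < off < len(self.seq):
            raise ValueError("reference window does not contain the cut")
        return off


@dataclass(frozen=True)
class DiagnosticMarker:
    """A parental SNP inside the amplicon (e.g. the PAM SNP) used to assign
    reads to a haplotype."""

    position: int
    base_p1: str
    base_p2: str


@dataclass(frozen=True)
class FootprintCall:
    read_id: str
    klass: str  # WT | insertion | deletion | complex | unanchored
    n: Optional[int] = None  # indel size, >= 1
    bases: Optional[str] = None  # inserted bases
    allele: str = "unassigned"  # P1 | P2 | unassigned

    @property
    def is_indel(self) -> bool:
        return self.klass in ("insertion", "deletion", "complex")


def _find_anchor(read: str, anchor: str, max_mismatch: int, prefer: str) -> Optional[int]:
    """Best approximate occurrence of ``anchor`` in ``read``; ties by fewest
    mismatches, then leftmost or rightmost position."""
    k = len(anchor)
    if k == 0 or len(read) < k:
        return None
    a = np.frombuffer(anchor.encode(), dtype=np.uint8)
    r = np.frombuffer(read.encode(), dtype=np.uint8)
    windows = np.lib.stride_tricks.sliding_window_view(r, k)
    mism = (windows != a).sum(axis=1)
    best = int(mism.min())
    if best > max_mismatch:
        return None
    hits = np.flatnonzero(mism == best)
    return int(hits[0] if prefer == "left" else hits[-1])


def _common_prefix(a: str, b: str) -> int:
    n = min(len(a), len(b))
    for i in range(n):
        if a[i] != b[i]:
            return i
    return n


def classify_read(
    read: str,
    window: ReferenceWindow,
    cut_position: int,
    flank_k: int = 15,
    max_anchor_mismatch: int = 1,
    cut_slop: int = 3,
    min_complex_mismatches: int = 2,
    read_id: str = "",
) -> FootprintCall:
    """Classify one read's repair footprint at the cut.

    The window must extend at least ``2 * flank_k`` bases on both sides of
    the cut, and the read must be long enough to contain both anchors
    (length >= 2 * flank_k).
    """
    ref = window.seq.upper()
    read = read.upper()
    cut_off = window.cut_offset(cut_position)
    if cut_off < 2 * flank_k or len(ref) - cut_off < 2 * flank_k:
        raise ValueError("reference window too short for the requested anchors")
    if len(read) < 2 * flank_k:
        raise ValueError("read shorter than 2 * flank_k")

    left_anchor = ref[cut_off - 2 * flank_k : cut_off - flank_k]
    right_anchor = ref[cut_off + flank_k : cut_off + 2 * flank_k]
    li = _find_anchor(read, left_anchor, max_anchor_mismatch, prefer="left")
    ri = _find_anchor(read, right_anchor, max_anchor_mismatch, prefer="right")
    if li is None or ri is None or ri < li + flank_k:
        return FootprintCall(read_id=read_id, klass="unanchored")

    mid_read = read[li + flank_k : ri]
    mid_ref = ref[cut_off - flank_k : cut_off + flank_k]
    delta = len(mid_read) - len(mid_ref)

    # placement ambiguity of the central difference, in mid_ref coordinates
    lcp = _common_prefix(mid_read, mid_ref)
    lcs = _common_prefix(mid_read[::-1], mid_ref[::-1])
    short = min(len(mid_read), len(mid_ref))
    lcs = min(lcs, short - min(lcp, short))
    amb_lo = (cut_off - flank_k) + lcp  # ref offset where the change can start
    amb_hi = cut_off + flank_k - lcs  # and where it can end
    at_cut = amb_lo <= cut_off + cut_slop and amb_hi >= cut_off - cut_slop

    if delta > 0:
        if not at_cut:
            return FootprintCall(read_id=read_id, klass="complex", n=delta)
        return FootprintCall(read_id=read_id, klass="insertion", n=delta, bases=mid_read[lcp : lcp + delta])
    if delta < 0:
        if not at_cut:
            return FootprintCall(read_id=read_id, klass="complex", n=-delta)
        return FootprintCall(read_id=read_id, klass="deletion", n=-delta)

    mismatch_pos = [i for i in range(len(mid_ref)) if mid_read[i] != mid_ref[i]]
    near_cut = [i for i in mismatch_pos if abs((cut_off - flank_k) + i - cut_off) <= cut_slop]
    if len(near_cut) >= min_complex_mismatches:
        return FootprintCall(read_id=read_id, klass="complex", n=len(near_cut))
    return FootprintCall(read_id=read_id, klass="WT")


def assign_allele(
    read: str,
    window: ReferenceWindow,
    marker: DiagnosticMarker,
    context_k: int = 10,
    max_context_mismatch: int = 1,
) -> str:
    """Assign a read to a parental haplotype by the base it carries at a
    diagnostic SNP, located via the marker's upstream reference context."""
    ref = window.seq.upper()
    read = read.upper()
    m_off = marker.position - window.start  # 0-based offset of the marker base
    if not 0 <= m_off < len(ref):
        raise ValueError("diagnostic marker outside the reference window")
    lo = max(0, m_off - context_k)
    context = ref[lo:m_off]
    if not context:
        return "unassigned"
    hit = _find_anchor(read, context, max_context_mismatch, prefer="left")
    if hit is None:
        return "unassigned"
    base_at = hit + len(context)
    if base_at >= len(read):
        return "unassigned"
    base = read[base_at]
    if base == marker.base_p1.upper():
        return "P1"
    if base == marker.base_p2.upper():
        return "P2"
    return "unassigned"


@dataclass
class FootprintSummary:
    n_classified: int
    n_unanchored: int
    nhej_pct: float
    spectrum: pd.DataFrame  # footprint, count, fraction
    by_allele: dict[str, float]  # allele -> NHEJ% among reads assigned to it


def _footprint_label(call: FootprintCall) -> str:
    if call.klass == "insertion":
        return f"+{call.bases}" if call.bases else f"+{call.n}"
    if call.klass == "deletion":
        return f"-{call.n}"
    return call.klass


def summarize_footprints(calls: Sequence[FootprintCall]) -> FootprintSummary:
    """NHEJ% (indel reads / classified reads x 100) plus the footprint
    spectrum and a per-allele breakdown. Raises ValueError when no read could
    be classified, so an empty input never silently reads as 0% editing."""
    classified = [c for c in calls if c.klass != "unanchored"]
    n_unanchored = len(calls) - len(classified)
    if not classified:
        raise ValueError("no classifiable reads")
    n = len(classified)
    n_indel = sum(c.is_indel for c in classified)
    labels = pd.Series([_footprint_label(c) for c in classified])
    spec = labels.value_counts().rename_axis("footprint").reset_index(name="count")
    spec["fraction"] = spec["count"] / n
    by_allele: dict[str, float] = {}
    for allele in ("P1", "P2"):
        sub = [c for c in classified if c.allele == allele]
        if sub:
            by_allele[allele] = 100.0 * sum(c.is_indel for c in sub) / len(sub)
    return FootprintSummary(
        n_classified=n,
        n_unanchored=n_unanchored,
        nhej_pct=100.0 * n_indel / n,
        spectrum=spec,
        by_allele=by_allele,
    )


def calls_frame(calls: Sequence[FootprintCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"read_id": c.read_id, "class": c.klass, "n": c.n, "bases": c.bases, "allele": c.allele}
            for c in calls
        ]
    )
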
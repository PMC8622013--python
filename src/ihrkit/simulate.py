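"""Mechanistic simulator for hybrid F1/F2 populations with induced repair events.

The generator emulates the experimental design of a Col x Ler inter-homolog
recombination (IHR) screen: an F1 hybrid carries one chromosome set from each
parent; a CRISPR-Cas9 double-strand break (DSB) in F1 somatic tissue is
repaired by NHEJ (a small indel at the cut), by gene conversion (a
heteroduplex tract around the cut, resolved marker-by-marker by mismatch
repair toward the donor) or, rarely, by crossover (reciprocal arm exchange
offset from the cut by branch migration). The (possibly edited) F1 then
undergoes meiosis, and F2 plants are genotyped at every marker from noisy
read counts.

Every draw consumes a `numpy.random.Generator`; identical config + seed gives
byte-identical output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .markers import ChromosomeMarkers, DsbTarget, SnpMarkerMap

_BASES = np.array(["A", "C", "G", "T"])

#: default seed-fluorescence transgene coordinates on the Col tester chromosome 3
GFP_POSITION = ("Chr3", 256_516)
RFP_POSITION = ("Chr3", 5_361_637)


# --------------------------------------------------------------------------- config
@dataclass
class TractModel:
    """Heteroduplex tract model for gene-conversion events.

    The heteroduplex extends from the cut independently to each side by a
    geometric number of bp (mean ``mean_side_bp``); each marker inside is
    repaired toward the donor haplotype with probability ``p_conv``
    (mismatch repair), else retained. ``p_conv < 1`` produces interrupted
    ("complex") conversion tracts.
    """

    mean_side_bp: float = 500.0
    p_conv: float = 0.7

    def __post_init__(self) -> None:
        if self.mean_side_bp < 1:
            raise ValueError("mean_side_bp must be >= 1")
        if not 0.0 <= self.p_conv <= 1.0:
            raise ValueError("p_conv must be in [0, 1]")


@dataclass
class SimulationConfig:
    """Study-condition parameters for the generator.

    Defaults correspond to the experimental regime the pipeline was designed
    around: ~1 marker/kb (Col/Ler SNP density is higher genome-wide, but one
    informative SNP per kb is typical after filtering), ~15x usable coverage
    per marker, 0.5% allele miscall, per-plant germline event probabilities of
    the order observed at a responsive target (NCO ~0.12, CO ~0.009), and an
    NHEJ indel spectrum dominated by +/-1-2 nt.
    """

    seed: int
    chromosomes: tuple[tuple[str, int], ...] = (("Chr3", 6_000_000),)
    marker_density_per_kb: float = 1.0
    p_nhej: float = 0.30
    p_nco: float = 0.12
    p_co: float = 0.009
    indel_spectrum: dict[str, float] = field(
        default_factory=lambda: {"+1": 0.4, "-1": 0.4, "+2": 0.1, "-2": 0.1}
    )
    tract: TractModel = field(default_factory=TractModel)
    co_offset_scale_bp: float = 200.0
    meiotic_co_rate: float = 1.0
    meiotic_co_fixed: bool = False
    coverage: float = 15.0
    error_rate: float = 0.005
    n_f2: int = 106

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.marker_density_per_kb <= 0:
            raise ValueError("marker density must be > 0")
        for _, length in self.chromosomes:
            if length <= 0:
                raise ValueError("zero-length chromosome")
        probs = (self.p_nhej, self.p_nco, self.p_co)
        if any(not 0 <= p <= 1 for p in probs) or sum(probs) > 1 + 1e-12:
            raise ValueError("event-class probabilities must lie in [0,1] and sum <= 1")
        spec_mass = sum(self.indel_spectrum.values())
        if self.indel_spectrum and abs(spec_mass - 1.0) > 1e-9:
            raise ValueError("indel spectrum must sum to 1")
        if self.coverage < 0:
            raise ValueError("coverage must be >= 0")
        if not 0 <= self.error_rate < 0.5:
            raise ValueError("error_rate must be in [0, 0.5)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "chromosomes" in raw:
            raw["chromosomes"] = tuple((str(n), int(l)) for n, l in raw["chromosomes"])
        if "tract" in raw:
            raw["tract"] = TractModel(**raw["tract"])
        return cls(**raw)


# --------------------------------------------------------------------------- truth types
@dataclass
class TractTruth:
    """Ground truth for one simulated conversion tract."""

    interval: tuple[int, int]  # heteroduplex, closed [start, end] bp
    marker_indices: np.ndarray  # indices into the chromosome's marker list
    converted: np.ndarray  # bool per in-tract marker: repaired toward donor?

    @property
    def converted_indices(self) -> np.ndarray:
        return self.marker_indices[self.converted]

    @property
    def is_simple(self) -> bool:
        conv = np.flatnonzero(self.converted)
        if conv.size == 0:
            return True
        return bool(np.all(self.converted[conv[0] : conv[-1] + 1]))


@dataclass
class RepairEventTruth:
    """One germline-transmitted repair outcome at one target in one plant."""

    plant_id: str
    target_id: str
    kind: str  # none | nhej | nco | co
    affected_haplotype: str = "P2"  # which homolog was cleaved
    indel: Optional[str] = None  # signature like '+T' or '-2' (nhej)
    tract: Optional[TractTruth] = None  # nco
    co_breakpoint: Optional[int] = None  # bp (co)

    def __post_init__(self) -> None:
        if self.kind not in ("none", "nhej", "nco", "co"):
            raise ValueError(f"unknown event kind {self.kind!r}")

    def to_jsonable(self) -> dict:
        d = {
            "plant_id": self.plant_id,
            "target_id": self.target_id,
            "kind": self.kind,
            "affected_haplotype": self.affected_haplotype,
            "indel": self.indel,
            "co_breakpoint": self.co_breakpoint,
        }
        if self.tract is not None:
            d["tract"] = {
                "interval": list(self.tract.interval),
                "marker_indices": self.tract.marker_indices.tolist(),
                "converted": self.tract.converted.tolist(),
            }
        return d


# --------------------------------------------------------------------------- haplotypes
@dataclass
class Haplotype:
    """One F1 chromosome-set: marker alleles plus parental-origin segments.

    ``alleles`` holds 0 (P1 base) or 1 (P2 base) per marker. ``origin`` tracks
    which *parental chromosome* each physical segment descends from, which is
    what seed-fluorescence transgenes ride on; an induced crossover re-wires
    origin even though most marker alleles are unchanged.
    """

    alleles: dict[str, np.ndarray]
    origin_start: dict[str, int] = field(default_factory=dict)
    origin_breaks: dict[str, list[int]] = field(default_factory=dict)
    # target_id -> (chrom, cut_position, signature)
    indels: dict[str, tuple[str, int, str]] = field(default_factory=dict)

    def origin_at(self, chrom: str, pos: int) -> int:
        start = self.origin_start.get(chrom, 0)
        breaks = self.origin_breaks.get(chrom, [])
        flips = sum(1 for b in breaks if pos > b)
        return (start + flips) % 2


@dataclass
class F1Truth:
    """An F1 hybrid: two haplotypes (index 0 from P1, 1 from P2) plus events."""

    haplotypes: tuple[Haplotype, Haplotype]
    events: list[RepairEventTruth] = field(default_factory=list)


def make_f1(marker_map: SnpMarkerMap) -> F1Truth:
    """Unedited F1 hybrid: haplotype 0 carries every P1 allele, 1 every P2."""
    h0 = Haplotype(
        alleles={c.name: np.zeros(c.n_markers, dtype=np.int8) for c in marker_map},
        origin_start={c.name: 0 for c in marker_map},
        origin_breaks={c.name: [] for c in marker_map},
    )
    h1 = Haplotype(
        alleles={c.name: np.ones(c.n_markers, dtype=np.int8) for c in marker_map},
        origin_start={c.name: 1 for c in marker_map},
        origin_breaks={c.name: [] for c in marker_map},
    )
    return F1Truth(haplotypes=(h0, h1))


# --------------------------------------------------------------------------- operations
def make_marker_map(config: SimulationConfig, rng: np.random.Generator | None = None) -> SnpMarkerMap:
    """Draw a marker map: per chromosome, ~density x length markers at unique
    uniform positions (sorted), with distinct random parental bases."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    out = SnpMarkerMap()
    for name, length in config.chromosomes:
        n = int(round(config.marker_density_per_kb * length / 1000.0))
        n = max(1, min(n, length))
        positions = np.sort(rng.choice(length, size=n, replace=False) + 1).astype(np.int64)
        p1 = rng.integers(0, 4, size=n)
        p2 = (p1 + rng.integers(1, 4, size=n)) % 4
        out.add(
            ChromosomeMarkers(
                name=name,
                length=length,
                positions=positions,
                allele_p1=_BASES[p1],
                allele_p2=_BASES[p2],
            )
        )
    return out


def simulate_conversion_tract(
    cut_position: int,
    tract_model: TractModel,
    chrom_markers: ChromosomeMarkers,
    rng: np.random.Generator,
) -> TractTruth:
    """Draw a heteroduplex interval covering the cut and resolve each in-tract
    marker mismatch independently toward the donor with probability p_conv."""
    p_geo = min(1.0, 1.0 / tract_model.mean_side_bp)
    left = int(rng.geometric(p_geo))
    right = int(rng.geometric(p_geo))
    start = max(1, cut_position - left)
    end = min(chrom_markers.length, cut_position + right)
    idx = chrom_markers.window_indices(start, end)
    converted = rng.random(idx.size) < tract_model.p_conv
    return TractTruth(interval=(start, end), marker_indices=idx, converted=converted)


def _sample_indel(spectrum: dict[str, float], rng: np.random.Generator) -> str:
    labels = sorted(spectrum)
    probs = np.array([spectrum[k] for k in labels])
    lab = labels[int(rng.choice(len(labels), p=probs / probs.sum()))]
    if lab.startswith("+"):
        n = int(lab[1:])
        bases = "".join(rng.choice(_BASES, size=n))
        return f"+{bases}"
    return lab  # deletions stay as '-n'


def simulate_repair_event(
    target: DsbTarget,
    marker_map: SnpMarkerMap,
    config: SimulationConfig,
    rng: np.random.Generator,
    plant_id: str = "F1",
) -> RepairEventTruth:
    """Sample one germline repair outcome at a target.

    With an allele-specific (P2_only) guide the cleaved homolog is always P2:
    the P1 PAM SNP prevents cutting, so P1 can only ever act as donor.
    """
    u = rng.random()
    if u < config.p_nhej:
        kind = "nhej"
    elif u < config.p_nhej + config.p_nco:
        kind = "nco"
    elif u < config.p_nhej + config.p_nco + config.p_co:
        kind = "co"
    else:
        kind = "none"
    if target.allele_specificity == "P2_only":
        affected = "P2"
    else:
        affected = "P1" if rng.random() < 0.5 else "P2"
    ev = RepairEventTruth(plant_id=plant_id, target_id=target.id, kind=kind, affected_haplotype=affected)
    if kind == "nhej":
        ev.indel = _sample_indel(config.indel_spectrum, rng)
    elif kind == "nco":
        ev.tract = simulate_conversion_tract(
            target.cut_position, config.tract, marker_map[target.chromosome], rng
        )
    elif kind == "co":
        offset = int(round(rng.laplace(0.0, config.co_offset_scale_bp)))
        bp = int(np.clip(target.cut_position + offset, 1, marker_map[target.chromosome].length - 1))
        ev.co_breakpoint = bp
    return ev


def apply_repair_event(f1: F1Truth, event: RepairEventTruth, marker_map: SnpMarkerMap, target: DsbTarget) -> None:
    """Write an event into the F1 haplotypes (in place)."""
    if event.kind == "none":
        return
    chrom = target.chromosome
    broken_i = 0 if event.affected_haplotype == "P1" else 1
    broken = f1.haplotypes[broken_i]
    donor = f1.haplotypes[1 - broken_i]
    if event.kind == "nhej":
        broken.indels[target.id] = (chrom, target.cut_position, event.indel or "")
    elif event.kind == "nco":
        assert event.tract is not None
        idx = event.tract.converted_indices
        broken.alleles[chrom][idx] = donor.alleles[chrom][idx]
    elif event.kind == "co":
        assert event.co_breakpoint is not None
        bp = event.co_breakpoint
        pos = marker_map[chrom].positions
        right = pos > bp
        tmp = broken.alleles[chrom][right].copy()
        broken.alleles[chrom][right] = donor.alleles[chrom][right]
        donor.alleles[chrom][right] = tmp
        broken.origin_breaks.setdefault(chrom, []).append(bp)
        donor.origin_breaks.setdefault(chrom, []).append(bp)
    f1.events.append(event)


# --------------------------------------------------------------------------- F2
@dataclass
class Gamete:
    """One meiotic product of the F1: marker alleles plus F1-haplotype
    provenance (start haplotype index and crossover breakpoints)."""

    alleles: dict[str, np.ndarray]
    source_start: dict[str, int]
    breakpoints: dict[str, np.ndarray]
    indels: dict[str, tuple[str, int, str]] = field(default_factory=dict)
    f1: Optional[F1Truth] = None

    def source_at(self, chrom: str, pos: int) -> int:
        flips = int(np.sum(self.breakpoints[chrom] < pos))
        return (self.source_start[chrom] + flips) % 2

    def origin_at(self, chrom: str, pos: int) -> int:
        """Parental-chromosome origin at an arbitrary bp (transgene tracking)."""
        src = self.source_at(chrom, pos)
        if self.f1 is None:
            return src
        return self.f1.haplotypes[src].origin_at(chrom, pos)


@dataclass
class F2Plant:
    plant_id: str
    gametes: tuple[Gamete, Gamete]

    def genotype(self, chrom: str) -> np.ndarray:
        """Per-marker count of P2 alleles: 0 = HomP1, 1 = Het, 2 = HomP2."""
        return (self.gametes[0].alleles[chrom] + self.gametes[1].alleles[chrom]).astype(np.int8)

    def true_states(self, chrom: str) -> np.ndarray:
        """Per-marker state labels matching the HMM state alphabet."""
        g = self.genotype(chrom)
        return np.array(["HomP1", "Het", "HomP2"])[g]

    def carries_origin(self, chrom: str, pos: int, origin: int) -> bool:
        return any(g.origin_at(chrom, pos) == origin for g in self.gametes)


def make_gamete(f1: F1Truth, marker_map: SnpMarkerMap, config: SimulationConfig, rng: np.random.Generator) -> Gamete:
    alleles: dict[str, np.ndarray] = {}
    start: dict[str, int] = {}
    breaks: dict[str, np.ndarray] = {}
    indels: dict[str, tuple[str, int, str]] = {}
    for chrom in marker_map:
        name = chrom.name
        if config.meiotic_co_fixed:
            n_co = int(round(config.meiotic_co_rate))
        else:
            n_co = int(rng.poisson(config.meiotic_co_rate))
        bps = np.sort(rng.integers(1, chrom.length, size=n_co)).astype(np.int64)
        s = int(rng.integers(0, 2))
        src = (s + np.searchsorted(bps, chrom.positions, side="left")) % 2
        al = np.where(src == 0, f1.haplotypes[0].alleles[name], f1.haplotypes[1].alleles[name])
        alleles[name] = al.astype(np.int8)
        start[name] = s
        breaks[name] = bps
    g = Gamete(alleles=alleles, source_start=start, breakpoints=breaks, indels=indels, f1=f1)
    # cut-site indels travel with the physical segment covering the cut
    for hap_i, hap in enumerate(f1.haplotypes):
        for tid, (chrom_name, cut, sig) in hap.indels.items():
            if g.source_at(chrom_name, cut) == hap_i:
                indels[tid] = (chrom_name, cut, sig)
    return g


def simulate_f2_population(
    f1: F1Truth,
    marker_map: SnpMarkerMap,
    config: SimulationConfig,
    rng: np.random.Generator,
    n: int | None = None,
    id_prefix: str = "F2",
) -> list[F2Plant]:
    """Selfed-F1 progeny: each plant is the fusion of two independent gametes."""
    n = config.n_f2 if n is None else n
    return [
        F2Plant(
            plant_id=f"{id_prefix}_{i:04d}",
            gametes=(make_gamete(f1, marker_map, config, rng), make_gamete(f1, marker_map, config, rng)),
        )
        for i in range(n)
    ]


def apply_marker_selection(
    population: Sequence[F2Plant],
    mode: str,
    marker_positions: tuple[tuple[str, int], tuple[str, int]] = (GFP_POSITION, RFP_POSITION),
) -> list[F2Plant]:
    """Seed-fluorescence selection.

    Both transgenes ride the P1 (Col tester) chromosome; a seed fluoresces for
    a marker iff at least one gamete has P1 origin at that coordinate.
    ``RFP_only`` keeps plants with the RFP segment but no GFP segment (a
    recombination between the two linked markers), symmetric for ``GFP_only``.
    """
    if mode == "all":
        return list(population)
    (gfp_chrom, gfp_pos), (rfp_chrom, rfp_pos) = marker_positions
    if gfp_chrom != rfp_chrom:
        raise ValueError("selection markers must be on the same chromosome")
    out = []
    for plant in population:
        has_gfp = plant.carries_origin(gfp_chrom, gfp_pos, 0)
        has_rfp = plant.carries_origin(rfp_chrom, rfp_pos, 0)
        if mode == "RFP_only" and has_rfp and not has_gfp:
            out.append(plant)
        elif mode == "GFP_only" and has_gfp and not has_rfp:
            out.append(plant)
    if mode not in ("RFP_only", "GFP_only"):
        raise ValueError(f"unknown selection mode {mode!r}")
    return out


def make_tract_f2_plant(
    marker_map: SnpMarkerMap,
    chrom_name: str,
    tract: TractTruth,
    zygosity: str = "heterozygous",
    background_allele: int = 0,
    plant_id: str = "F2_tract",
) -> F2Plant:
    """F2 plant with a homozygous background carrying a conversion tract.

    ``heterozygous``: one gamete carries the converted haplotype (tract
    markers show the donor allele), the other the plain background — the
    usual single-gamete transmission. ``homozygous``: both gametes carry the
    conversion, as for a pre-meiotic event transmitted through both lineages.
    """
    chrom = marker_map[chrom_name]
    bg = np.full(chrom.n_markers, background_allele, dtype=np.int8)
    conv = bg.copy()
    conv[tract.converted_indices] = 1 - background_allele
    empty = np.array([], dtype=np.int64)

    def gamete(alleles: np.ndarray) -> Gamete:
        return Gamete(
            alleles={chrom_name: alleles.copy()},
            source_start={chrom_name: background_allele},
            breakpoints={chrom_name: empty},
        )

    second = conv if zygosity == "homozygous" else bg
    return F2Plant(plant_id=plant_id, gametes=(gamete(conv), gamete(second)))


# --------------------------------------------------------------------------- observations
@dataclass
class GenotypeObservations:
    """Per-plant, per-marker read counts supporting each parental allele."""

    plant_id: str
    counts: dict[str, tuple[np.ndarray, np.ndarray]]  # chrom -> (n_P1, n_P2)

    def frame(self, marker_map: SnpMarkerMap) -> pd.DataFrame:
        rows = []
        for chrom_name, (n1, n2) in self.counts.items():
            pos = marker_map[chrom_name].positions
            rows.append(
                pd.DataFrame(
                    {
                        "plant_id": self.plant_id,
                        "chrom": chrom_name,
                        "pos": pos,
                        "n_P1": n1,
                        "n_P2": n2,
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)


def emit_observations(
    plant: F2Plant,
    marker_map: SnpMarkerMap,
    coverage: float,
    error_rate: float,
    rng: np.random.Generator,
) -> GenotypeObservations:
    """Noisy read evidence: per marker, depth ~ Poisson(coverage); each read
    samples one chromatid uniformly and reports its allele, miscalled with
    probability error_rate (implemented as the equivalent binomial draw)."""
    if coverage < 0:
        raise ValueError("coverage must be >= 0")
    if not 0 <= error_rate < 0.5:
        raise ValueError("error_rate must be in [0, 0.5)")
    counts: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom in marker_map:
        g = plant.genotype(chrom.name)  # P2-allele dosage in {0,1,2}
        depth = rng.poisson(coverage, size=g.size)
        p_read_p2 = (g / 2.0) * (1 - error_rate) + (1 - g / 2.0) * error_rate
        n_p2 = rng.binomial(depth, p_read_p2)
        counts[chrom.name] = ((depth - n_p2).astype(np.int64), n_p2.astype(np.int64))
    return GenotypeObservations(plant_id=plant.plant_id, counts=counts)


# --------------------------------------------------------------------------- amplicon molecules
def amplicon_window_indices(chrom: ChromosomeMarkers, cut_position: int, half_width: int = 2500) -> np.ndarray:
    """Marker indices inside the amplicon window (default 5 kb centred on cut)."""
    idx = chrom.window_indices(cut_position - half_width, cut_position + half_width)
    if idx.size == 0:
        raise ValueError("amplicon window contains no markers")
    return idx


def emit_amplicon_molecules(
    mixture: Sequence[tuple[str, str, float]],
    n_molecules: int,
    rng: np.random.Generator,
    miscall_rate: float = 0.002,
) -> pd.DataFrame:
    """Sample independent long-amplicon molecules from an allele mixture.

    ``mixture`` is a list of (haplotype_pattern, indel_signature, frequency)
    with frequencies summing to 1; patterns are strings of '1'/'2' over the
    in-window markers. Each emitted molecule miscalls each marker (flips its
    parental assignment) independently with ``miscall_rate``.
    """
    if n_molecules < 0:
        raise ValueError("n_molecules must be >= 0")
    if n_molecules == 0:
        return pd.DataFrame(columns=["molecule_id", "haplotype_pattern", "indel_signature"])
    freqs = np.array([f for _, _, f in mixture], dtype=float)
    if abs(freqs.sum() - 1.0) > 1e-9:
        raise ValueError("mixture frequencies must sum to 1")
    pat_len = {len(p) for p, _, _ in mixture}
    if len(pat_len) != 1 or 0 in pat_len:
        raise ValueError("all mixture patterns must share one non-zero length")
    which = rng.choice(len(mixture), size=n_molecules, p=freqs)
    rows = []
    for i, k in enumerate(which):
        pattern, indel, _ = mixture[k]
        chars = np.frombuffer(pattern.encode(), dtype="S1").astype("U1")
        flip = rng.random(chars.size) < miscall_rate
        if flip.any():
            flipped = np.where(chars == "1", "2", "1")
            chars = np.where(flip, flipped, chars)
        rows.append({"molecule_id": f"mol_{i:05d}", "haplotype_pattern": "".join(chars), "indel_signature": indel})
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------- sequence-level reads
def random_sequence(length: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(_BASES, size=length))


@dataclass(frozen=True)
class AmpliconReadTruth:
    read_id: str
    sequence: str
    true_class: str  # WT | insertion | deletion
    allele: str  # P1 | P2


def simulate_nhej_reads(
    ref_p1: str,
    ref_p2: str,
    window_start: int,
    cut_position: int,
    n_reads: int,
    indel_fraction: float,
    indel_spectrum: dict[str, float],
    rng: np.random.Generator,
    error_rate: float = 0.005,
    allele_specificity: str = "both",
) -> list[AmpliconReadTruth]:
    """Short-amplicon reads around a cut for NHEJ quantification.

    Each read picks a parental allele (50:50); on a cleavable allele it
    carries a cut-site indel with probability ``indel_fraction``, then
    per-base substitution errors at ``error_rate``.
    """
    cut_off = cut_position - window_start + 1  # bases left of the scission
    if not 0 < cut_off < len(ref_p1):
        raise ValueError("reference window must contain the cut")
    reads = []
    for i in range(n_reads):
        allele = "P1" if rng.random() < 0.5 else "P2"
        ref = ref_p1 if allele == "P1" else ref_p2
        cleavable = allele == "P2" or allele_specificity == "both"
        cls = "WT"
        seq = ref
        if cleavable and rng.random() < indel_fraction:
            sig = _sample_indel(indel_spectrum, rng)
            if sig.startswith("+"):
                seq = ref[:cut_off] + sig[1:] + ref[cut_off:]
                cls = "insertion"
            else:
                n_del = int(sig[1:])
                lo = cut_off - n_del // 2
                seq = ref[:lo] + ref[lo + n_del :]
                cls = "deletion"
        arr = np.frombuffer(seq.encode(), dtype="S1").astype("U1")
        err = rng.random(arr.size) < error_rate
        if err.any():
            shift = rng.integers(1, 4, size=int(err.sum()))
            base_idx = np.searchsorted(_BASES, arr[err])
            arr[err] = _BASES[(base_idx + shift) % 4]
        reads.append(AmpliconReadTruth(read_id=f"read_{i:05d}", sequence="".join(arr), true_class=cls, allele=allele))
    return reads


# --------------------------------------------------------------------------- file emission
def write_observations_tsv(observations: Sequence[GenotypeObservations], marker_map: SnpMarkerMap, path: str | Path) -> None:
    frames = [o.frame(marker_map) for o in observations]
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def read_observations_tsv(path: str | Path, marker_map: SnpMarkerMap) -> list[GenotypeObservations]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for plant_id, sub in df.groupby("plant_id", sort=False):
        counts: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom_name, csub in sub.groupby("chrom", sort=False):
            chrom = marker_map[chrom_name]
            csub = csub.set_index("pos").reindex(chrom.positions)
            if csub["n_P1"].isna().any():
                raise ValueError(f"plant {plant_id}: observations not keyed to marker map")
            counts[chrom_name] = (
                csub["n_P1"].to_numpy(dtype=np.int64),
                csub["n_P2"].to_numpy(dtype=np.int64),
            )
        out.append(GenotypeObservations(plant_id=str(plant_id), counts=counts))
    return out


def write_truth_json(events: Sequence[RepairEventTruth], path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump([e.to_jsonable() for e in events], fh, indent=1)


def write_molecules_tsv(molecules: pd.DataFrame, path: str | Path) -> None:
    df = molecules.copy()
    df["indel_signature"] = df["indel_signature"].replace("", ".")
    df.to_csv(path, sep="\t", index=False)


def read_molecules_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"haplotype_pattern": str, "indel_signature": str})
    df["indel_signature"] = df["indel_signature"].replace(".", "").fillna("")
    return df
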
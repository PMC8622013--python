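"""SNP marker maps and DSB target definitions.

A marker map is the coordinate backbone of the whole pipeline: an ordered set
of biallelic SNPs distinguishing the two parental ecotypes (P1 = Columbia,
P2 = Landsberg in the Col x Ler design). All coordinates are 1-based and
inclusive, TAIR10-style; intervals are closed [start, end].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

_BASES = ("A", "C", "G", "T")


@dataclass(frozen=True)
class ChromosomeMarkers:
    """Ordered biallelic markers on one chromosome.

    Parameters
    ----------
    name : chromosome name (e.g. ``"Chr3"``).
    length : chromosome length in bp.
    positions : 1-based marker positions, strictly increasing.
    allele_p1, allele_p2 : parental bases at each marker; must differ.
    """

    name: str
    length: int
    positions: np.ndarray
    allele_p1: np.ndarray
    allele_p2: np.ndarray

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=np.int64)
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "allele_p1", np.asarray(self.allele_p1, dtype="U8"))
        object.__setattr__(self, "allele_p2", np.asarray(self.allele_p2, dtype="U8"))
        if self.length <= 0:
            raise ValueError(f"chromosome {self.name}: non-positive length")
        if pos.size and (pos[0] < 1 or pos[-1] > self.length):
            raise ValueError(f"chromosome {self.name}: marker positions outside [1, length]")
        if pos.size > 1 and not np.all(np.diff(pos) > 0):
            raise ValueError(f"chromosome {self.name}: positions not strictly increasing")
        if np.any(self.allele_p1 == self.allele_p2):
            raise ValueError(f"chromosome {self.name}: identical parental alleles at a marker")

    @property
    def n_markers(self) -> int:
        return int(self.positions.size)

    def window_indices(self, start: int, end: int) -> np.ndarray:
        """Indices of markers with position in the closed interval [start, end]."""
        lo = np.searchsorted(self.positions, start, side="left")
        hi = np.searchsorted(self.positions, end, side="right")
        return np.arange(lo, hi)


@dataclass
class SnpMarkerMap:
    """Genome-wide parental marker map: a mapping of chromosome name -> markers."""

    chromosomes: dict[str, ChromosomeMarkers] = field(default_factory=dict)

    def __getitem__(self, chrom: str) -> ChromosomeMarkers:
        return self.chromosomes[chrom]

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.chromosomes

    def __iter__(self) -> Iterator[ChromosomeMarkers]:
        return iter(self.chromosomes.values())

    @property
    def n_markers(self) -> int:
        return sum(c.n_markers for c in self)

    def add(self, chrom: ChromosomeMarkers) -> None:
        self.chromosomes[chrom.name] = chrom

    # ------------------------------------------------------------------ VCF IO
    def to_vcf(self, path: str | Path) -> None:
        """Write the map as VCF 4.2 with P1 as REF and P2 as ALT."""
        path = Path(path)
        with path.open("w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write('##source=ihrkit\n')
            for chrom in self:
                fh.write(f"##contig=<ID={chrom.name},length={chrom.length}>\n")
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
            for chrom in self:
                for i in range(chrom.n_markers):
                    fh.write(
                        f"{chrom.name}\t{chrom.positions[i]}\t.\t"
                        f"{chrom.allele_p1[i]}\t{chrom.allele_p2[i]}\t.\tPASS\t.\n"
                    )

    @classmethod
    def from_vcf(cls, path: str | Path) -> "SnpMarkerMap":
        """Read a marker map from a (plain-text or bgzipped) VCF, P1=REF, P2=ALT."""
        from cyvcf2 import VCF

        vcf = VCF(str(path))
        lengths = dict(zip(vcf.seqnames, vcf.seqlens))
        rows: dict[str, list[tuple[int, str, str]]] = {}
        for var in vcf:
            rows.setdefault(var.CHROM, []).append((var.POS, var.REF, var.ALT[0]))
        vcf.close()
        out = cls()
        for name, markers in rows.items():
            markers.sort()
            pos, p1, p2 = zip(*markers)
            out.add(
                ChromosomeMarkers(
                    name=name,
                    length=int(lengths.get(name, max(pos))),
                    positions=np.array(pos, dtype=np.int64),
                    allele_p1=np.array(p1),
                    allele_p2=np.array(p2),
                )
            )
        return out


@dataclass(frozen=True)
class DsbTarget:
    """A CRISPR-Cas9 cut site.

    ``allele_specificity`` is ``"both"`` for guides that cleave both parental
    chromosomes, or ``"P2_only"`` for guides whose PAM is intact only on the
    P2 (Landsberg, NGG) haplotype and destroyed by a SNP on P1 (NGH).
    ``chromatin_class`` is annotation only and plays no computational role.
    """

    id: str
    chromosome: str
    cut_position: int
    allele_specificity: str = "both"
    chromatin_class: str = "euchromatin"

    def __post_init__(self) -> None:
        if self.allele_specificity not in ("both", "P2_only"):
            raise ValueError(f"unknown allele_specificity {self.allele_specificity!r}")
        if self.chromatin_class not in ("euchromatin", "heterochromatin"):
            raise ValueError(f"unknown chromatin_class {self.chromatin_class!r}")
        if self.cut_position < 1:
            raise ValueError("cut_position must be >= 1")

    def validate_against(self, marker_map: SnpMarkerMap) -> None:
        if self.chromosome not in marker_map:
            raise ValueError(f"target {self.id}: chromosome {self.chromosome} not in map")
        if self.cut_position > marker_map[self.chromosome].length:
            raise ValueError(f"target {self.id}: cut beyond chromosome end")


def read_targets_tsv(path: str | Path) -> list[DsbTarget]:
    df = pd.read_csv(path, sep="\t")
    return [
        DsbTarget(
            id=str(r.id),
            chromosome=str(r.chromosome),
            cut_position=int(r.cut_position),
            allele_specificity=str(getattr(r, "allele_specificity", "both")),
            chromatin_class=str(getattr(r, "chromatin_class", "euchromatin")),
        )
        for r in df.itertuples(index=False)
    ]


def write_targets_tsv(targets: list[DsbTarget], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "id": t.id,
                "chromosome": t.chromosome,
                "cut_position": t.cut_position,
                "allele_specificity": t.allele_specificity,
                "chromatin_class": t.chromatin_class,
            }
            for t in targets
        ]
    ).to_csv(path, sep="\t", index=False)
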
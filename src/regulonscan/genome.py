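"""Genome annotation model and interval queries.

Coordinates are 1-based inclusive throughout, matching how bacterial
genome positions are printed in the literature. GFF3 is read natively;
BED (0-based half-open) is converted on input. Gene bodies are CDS/gene
extents: promoters and UTRs are not modeled, so "upstream" always means
the intergenic spacer on the 5' side of a coding region.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Optional, Sequence

import gffutils
import numpy as np

__all__ = [
    "GeneFeature",
    "GenomeAnnotation",
    "GenomicContext",
    "load_annotation",
    "context_at",
    "upstream_of",
]

_STRANDS = ("+", "-")


@dataclass(frozen=True)
class GeneFeature:
    """An annotated coding region with a strand.

    Parameters
    ----------
    id : str
        Gene name (e.g. ``pdhR``).
    start, end : int
        1-based inclusive genome coordinates, ``start <= end``.
    strand : str
        ``'+'`` or ``'-'``.
    product : str
        Free-text functional description.
    operon : str, optional
        Transcription-unit name the gene belongs to, if known.
    """

    id: str
    start: int
    end: int
    strand: str
    product: str = ""
    operon: Optional[str] = None

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"gene {self.id}: start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValueError(
                f"gene {self.id}: end ({self.end}) < start ({self.start})"
            )
        if self.strand not in _STRANDS:
            raise ValueError(
                f"gene {self.id}: strand must be '+' or '-', got {self.strand!r}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def contains(self, position: int) -> bool:
        return self.start <= position <= self.end


@dataclass(frozen=True)
class GenomicContext:
    """Where a genome position sits relative to annotated genes.

    ``kind`` is ``'intragenic'`` (inside a gene body, ``host_gene`` set)
    or ``'intergenic'`` (``left_gene``/``right_gene`` are the nearest
    flanking genes, absent at the ends of a linear genome).
    """

    kind: str
    host_gene: Optional[GeneFeature] = None
    left_gene: Optional[GeneFeature] = None
    right_gene: Optional[GeneFeature] = None

    def __post_init__(self) -> None:
        if self.kind not in ("intergenic", "intragenic"):
            raise ValueError(f"unknown context kind {self.kind!r}")
        if (self.kind == "intragenic") != (self.host_gene is not None):
            raise ValueError("intragenic context requires a host gene (and only then)")

    @property
    def intragenic(self) -> bool:
        return self.kind == "intragenic"


@dataclass
class GenomeAnnotation:
    """An ordered gene annotation over a (by default linear) genome."""

    genome_length: int
    features: tuple[GeneFeature, ...] = ()
    circular: bool = False
    _starts: np.ndarray = field(init=False, repr=False)
    _ends: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.genome_length < 1:
            raise ValueError("genome_length must be positive")
        feats = tuple(sorted(self.features, key=lambda f: (f.start, f.end, f.id)))
        for f in feats:
            if f.end > self.genome_length:
                raise ValueError(
                    f"gene {f.id} ends at {f.end}, beyond genome length "
                    f"{self.genome_length}"
                )
        object.__setattr__(self, "features", feats)
        self._starts = np.array([f.start for f in feats], dtype=np.int64)
        self._ends = np.array([f.end for f in feats], dtype=np.int64)

    def __len__(self) -> int:
        return len(self.features)

    def __iter__(self):
        return iter(self.features)

    def _check_position(self, position: int) -> None:
        if not 1 <= position <= self.genome_length:
            raise ValueError(
                f"position {position} outside genome [1, {self.genome_length}]"
            )

    def genes_overlapping(self, position: int) -> list[GeneFeature]:
        """All genes whose body [start, end] contains ``position``."""
        self._check_position(position)
        if not self.features:
            return []
        mask = (self._starts <= position) & (self._ends >= position)
        return [self.features[i] for i in np.flatnonzero(mask)]

    def nearest_left(self, position: int) -> Optional[GeneFeature]:
        """Gene with the largest end strictly left of ``position``.

        On a circular genome with no gene to the left, wraps to the
        gene with the largest end overall.
        """
        self._check_position(position)
        if not self.features:
            return None
        mask = self._ends < position
        if mask.any():
            idx = np.flatnonzero(mask)
            return self.features[idx[np.argmax(self._ends[idx])]]
        if self.circular:
            return self.features[int(np.argmax(self._ends))]
        return None

    def nearest_right(self, position: int) -> Optional[GeneFeature]:
        """Gene with the smallest start strictly right of ``position``."""
        self._check_position(position)
        if not self.features:
            return None
        mask = self._starts > position
        if mask.any():
            idx = np.flatnonzero(mask)
            return self.features[idx[np.argmin(self._starts[idx])]]
        if self.circular:
            return self.features[int(np.argmin(self._starts))]
        return None


def context_at(annotation: GenomeAnnotation, position: int) -> GenomicContext:
    """Classify ``position`` as intragenic (with host gene) or intergenic.

    When several annotated genes overlap the position, the host is the
    overlapping gene with the smallest start (then smallest end) — a
    deterministic convention for the rare overlapping-ORF case.
    """
    hosts = annotation.genes_overlapping(position)
    if hosts:
        return GenomicContext(kind="intragenic", host_gene=hosts[0])
    return GenomicContext(
        kind="intergenic",
        left_gene=annotation.nearest_left(position),
        right_gene=annotation.nearest_right(position),
    )


def upstream_of(gene: GeneFeature, position: int) -> bool:
    """True iff ``position`` lies on the 5' side of ``gene``.

    For a plus-strand gene that is any position before its start; for a
    minus-strand gene, any position after its end. The position must lie
    outside the gene body.
    """
    if gene.contains(position):
        raise ValueError(
            f"position {position} lies inside gene {gene.id} "
            f"[{gene.start}, {gene.end}]; upstream_of is undefined there"
        )
    if gene.strand == "+":
        return position < gene.start
    return position > gene.end


# ---------------------------------------------------------------------------
# loaders


def load_annotation(
    path: str | os.PathLike,
    genome_length: int,
    *,
    feature_types: Sequence[str] = ("gene", "CDS"),
    circular: bool = False,
) -> GenomeAnnotation:
    """Load a gene annotation from GFF3 or 6-column BED.

    ``feature_types`` selects which GFF3 record types count as genes
    (first match wins per feature ID). BED intervals (0-based,
    half-open) are converted to 1-based inclusive coordinates.
    """
    path = os.fspath(path)
    lower = path.lower()
    if lower.endswith((".bed", ".bed.txt")):
        feats = _read_bed(path)
    elif lower.endswith((".gff", ".gff3", ".gtf")):
        feats = _read_gff3(path, feature_types)
    else:
        raise ValueError(f"cannot infer annotation format from {path!r} "
                         "(expected .gff/.gff3 or .bed)")
    return GenomeAnnotation(genome_length=genome_length, features=tuple(feats),
                            circular=circular)


def _read_gff3(path: str, feature_types: Sequence[str]) -> list[GeneFeature]:
    try:
        db = gffutils.create_db(
            path, ":memory:", force=True, keep_order=True,
            merge_strategy="create_unique",
        )
    except gffutils.exceptions.EmptyInputError:
        return []
    feats: list[GeneFeature] = []
    seen: set[str] = set()
    for ftype in feature_types:
        for rec in db.features_of_type(ftype):
            name = (rec.attributes.get("Name") or rec.attributes.get("ID") or [rec.id])[0]
            if name in seen:
                continue
            seen.add(name)
            if rec.strand not in _STRANDS:
                raise ValueError(
                    f"{path}: feature {name} has no usable strand ({rec.strand!r})"
                )
            product = (rec.attributes.get("product") or [""])[0]
            operon = (rec.attributes.get("operon") or [None])[0]
            feats.append(GeneFeature(id=name, start=rec.start, end=rec.end,
                                     strand=rec.strand, product=product,
                                     operon=operon))
    return feats


def _read_bed(path: str) -> list[GeneFeature]:
    feats: list[GeneFeature] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ValueError(
                    f"{path}:{lineno}: BED line needs 6 columns "
                    f"(chrom,start,end,name,score,strand), got {len(parts)}"
                )
            try:
                bed_start, bed_end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            if bed_end <= bed_start:
                raise ValueError(
                    f"{path}:{lineno}: BED end ({bed_end}) must exceed start "
                    f"({bed_start})"
                )
            if parts[5] not in _STRANDS:
                raise ValueError(f"{path}:{lineno}: strand must be + or -, "
                                 f"got {parts[5]!r}")
            feats.append(GeneFeature(id=parts[3], start=bed_start + 1, end=bed_end,
                                     strand=parts[5]))
    return feats
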
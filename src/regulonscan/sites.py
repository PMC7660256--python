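"""Genomic-context typing of binding peaks and regulon-size estimation.

Each peak is assigned one of four context types by where it falls
relative to the annotated genes:

* **A** — intergenic, upstream of *both* flanking genes (a divergent
  spacer: minus-strand gene on the left, plus-strand gene on the right);
* **B** — intergenic, upstream of exactly one flanking gene (tandem
  spacer);
* **C** — intergenic, upstream of neither (convergent spacer);
* **D** — inside an open reading frame.

A type-A site may regulate either or both of the divergent units, so a
collection of typed sites bounds the regulon size: at least one target
per type-A/B site, at most two per type-A site.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .genome import GeneFeature, GenomeAnnotation, GenomicContext, context_at, upstream_of
from .motif import DEFAULT_REPORTING_FLOOR, MotifMatch
from .peaks import BindingPeak, effector_response

__all__ = [
    "SiteType",
    "TypedSite",
    "RegulonEstimate",
    "classify_site",
    "classify_sites",
    "estimate_regulon_size",
    "assemble_site_table",
]

logger = logging.getLogger(__name__)


class SiteType(str, Enum):
    A = "A"
    B = "B"
    C = "C"
    D = "D"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class TypedSite:
    """A peak joined to its genomic context and inferred target genes."""

    peak: BindingPeak
    site_type: SiteType
    context: GenomicContext
    regulated_genes: tuple[GeneFeature, ...] = ()

    def __post_init__(self) -> None:
        expected = {SiteType.A: 2, SiteType.B: 1, SiteType.C: 0, SiteType.D: 0}
        n = len(self.regulated_genes)
        # a type-A site at a linear-genome end may have only one gene in view
        if self.site_type is SiteType.A and n == 1:
            return
        if n != expected[self.site_type]:
            raise ValueError(
                f"type {self.site_type.value} site must carry "
                f"{expected[self.site_type]} regulated genes, got {n}"
            )


@dataclass(frozen=True)
class RegulonEstimate:
    """Per-type counts and the implied bounds on regulon size.

    ``min_targets`` counts each intergenic upstream site once;
    ``max_targets`` counts each divergent (type-A) site twice, since
    either or both flanking units may be the true target. Intragenic
    (type-D) sites contribute to neither bound.
    """

    n_typeA: int
    n_typeB: int
    n_typeC: int
    n_typeD: int

    @property
    def min_targets(self) -> int:
        return self.n_typeA + self.n_typeB

    @property
    def max_targets(self) -> int:
        return 2 * self.n_typeA + self.n_typeB

    @property
    def total_sites(self) -> int:
        return self.n_typeA + self.n_typeB + self.n_typeC + self.n_typeD


def classify_site(
    peak: BindingPeak,
    annotation: GenomeAnnotation,
    max_upstream_distance: Optional[int] = None,
) -> TypedSite:
    """Assign a context type to one peak.

    ``max_upstream_distance`` optionally caps how far (bp) a site may
    sit from a gene's 5' boundary and still count as upstream of it;
    by default no cap is applied, as appropriate for gene-dense
    bacterial genomes where spacers are short. Peaks with a missing
    flank (linear genome end, or an empty annotation) are classified
    from the genes in view, with a warning.
    """
    ctx = context_at(annotation, peak.position)
    if ctx.intragenic:
        return TypedSite(peak=peak, site_type=SiteType.D, context=ctx)

    def _upstream(gene: Optional[GeneFeature]) -> bool:
        if gene is None:
            return False
        if not upstream_of(gene, peak.position):
            return False
        if max_upstream_distance is not None:
            dist = (gene.start - peak.position if gene.strand == "+"
                    else peak.position - gene.end)
            if dist > max_upstream_distance:
                return False
        return True

    if ctx.left_gene is None or ctx.right_gene is None:
        logger.warning(
            "peak at %d has no flanking gene on %s side; typing from the "
            "remaining side only",
            peak.position,
            "either" if ctx.left_gene is None and ctx.right_gene is None
            else ("the left" if ctx.left_gene is None else "the right"),
        )

    targets = tuple(
        g for g in (ctx.left_gene, ctx.right_gene) if _upstream(g)
    )
    if len(targets) == 2:
        stype = SiteType.A
    elif len(targets) == 1:
        stype = SiteType.B
    else:
        stype = SiteType.C
    return TypedSite(peak=peak, site_type=stype, context=ctx,
                     regulated_genes=targets)


def classify_sites(
    peaks: Iterable[BindingPeak],
    annotation: GenomeAnnotation,
    max_upstream_distance: Optional[int] = None,
) -> list[TypedSite]:
    return [classify_site(p, annotation, max_upstream_distance) for p in peaks]


def estimate_regulon_size(sites: Iterable[TypedSite]) -> RegulonEstimate:
    """Count sites per type and bound the number of regulated units."""
    counts = {t: 0 for t in SiteType}
    for s in sites:
        counts[s.site_type] += 1
    return RegulonEstimate(
        n_typeA=counts[SiteType.A],
        n_typeB=counts[SiteType.B],
        n_typeC=counts[SiteType.C],
        n_typeD=counts[SiteType.D],
    )


def _arrow(gene: Optional[GeneFeature]) -> str:
    if gene is None:
        return ""
    return ">" if gene.strand == "+" else "<"


def assemble_site_table(
    sites: Sequence[TypedSite],
    matches: Optional[Mapping[int, Optional[MotifMatch]]] = None,
    reporting_floor: int = DEFAULT_REPORTING_FLOOR,
    pseudocount: float = 0.0,
) -> pd.DataFrame:
    """One report row per typed site, in the published table layout.

    ``matches`` maps peak position to the site's best motif match (or
    None). Matches scoring below ``reporting_floor`` informative
    matches, and absent matches, render as ``'-'`` in the sequence,
    conservation and motif-position columns.
    """
    matches = matches or {}
    seen: set[int] = set()
    rows = []
    for site in sites:
        pos = site.peak.position
        if pos in seen:
            raise ValueError(f"duplicate peak position {pos} in site table")
        seen.add(pos)
        ctx = site.context
        left = ctx.left_gene if not ctx.intragenic else None
        right = ctx.right_gene if not ctx.intragenic else None
        match = matches.get(pos)
        if match is not None and match.score.matches >= reporting_floor:
            seq, cons, mpos = (match.rendered_sequence, match.score.rendered,
                              match.genome_position)
        else:
            seq, cons, mpos = "-", "-", "-"
        resp = effector_response(site.peak, pseudocount=pseudocount)
        rows.append(
            {
                "peak_position": pos,
                "intensity_no_effector": site.peak.intensity_no_effector,
                "intensity_effector": site.peak.intensity_effector,
                "retained_fraction": None if resp is None else
                    round(resp.retained_fraction, 3),
                "site_type": site.site_type.value,
                "left_gene": left.id if left else "",
                "left_arrow": _arrow(left),
                "host_gene": ctx.host_gene.id if ctx.intragenic else "",
                "right_arrow": _arrow(right),
                "right_gene": right.id if right else "",
                "regulated_genes": ",".join(g.id for g in site.regulated_genes),
                "site_sequence": seq,
                "conservation": cons,
                "motif_position": mpos,
            }
        )
    columns = [
        "peak_position", "intensity_no_effector", "intensity_effector",
        "retained_fraction", "site_type", "left_gene", "left_arrow",
        "host_gene", "right_arrow", "right_gene", "regulated_genes",
        "site_sequence", "conservation", "motif_position",
    ]
    return pd.DataFrame(rows, columns=columns)
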
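"""Packaged reference table of PdhR binding sites, and helpers around it.

The package ships the published table of 35 PdhR binding sites on the
*E. coli* K-12 genome (peak positions, paired screening intensities,
flanking genes with transcription-direction arrows, printed 17-bp site
sequences with their n/14 conservation scores and motif coordinates).
It serves three purposes:

* a realistic desk-scale input for the whole pipeline;
* a regression oracle — re-scoring every printed site sequence must
  reproduce every printed conservation value and every printed
  uppercase/lowercase rendering;
* the source of a minimal annotation: the printed flanking-gene names
  and strands are enough to rebuild gene intervals around each peak
  that reproduce all printed context-type assignments.

The host gene's strand is not printed for intragenic rows and is stored
as '+' by convention; intragenic classification does not depend on it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Optional

import pandas as pd

from .genome import GeneFeature, GenomeAnnotation
from .motif import DegeneratePalindrome, render_match, score_against_box
from .peaks import BindingPeak

__all__ = [
    "K12_GENOME_LENGTH",
    "KNOWN_TARGETS_IN_DATABASE",
    "load_binding_sites",
    "fixture_peaks",
    "build_fixture_annotation",
    "validate_fixture",
    "fold_expansion",
    "FixtureValidation",
]

K12_GENOME_LENGTH = 4_641_652
#: regulatory targets previously curated for PdhR in RegulonDB
KNOWN_TARGETS_IN_DATABASE = 9

_DATA_FILE = "pdhr_binding_sites.tsv"

# half-widths used when rebuilding minimal gene intervals around each peak;
# chosen so every printed motif coordinate (all within ~170 bp of its peak)
# falls in the correct compartment: the spacer for intergenic rows, the host
# gene body for intragenic rows
_SPACER_HALF = 150
_GENE_SPAN = 550
_HOST_HALF = 210


def load_binding_sites() -> pd.DataFrame:
    """The packaged 35-row binding-site table as a DataFrame.

    Missing printed values ('-') become pandas NA in the sequence,
    conservation, motif-position and annotation columns.
    """
    with resources.files("regulonscan.data").joinpath(_DATA_FILE).open() as fh:
        df = pd.read_csv(fh, sep="\t", comment="#", dtype=str)
    for col in ("peak_position", "intensity_no_effector", "intensity_effector"):
        df[col] = df[col].astype(int)
    optional = ["host_gene", "regulated", "left_operon", "left_function",
                "right_operon", "right_function", "site_sequence",
                "conservation", "motif_position", "database"]
    df[optional] = df[optional].replace("-", pd.NA)
    return df


def fixture_peaks() -> list[BindingPeak]:
    """The fixture rows as BindingPeak objects (both conditions)."""
    df = load_binding_sites()
    return [
        BindingPeak(
            position=int(r.peak_position),
            intensity_no_effector=float(r.intensity_no_effector),
            intensity_effector=float(r.intensity_effector),
        )
        for r in df.itertuples()
    ]


def build_fixture_annotation(
    genome_length: int = K12_GENOME_LENGTH,
) -> GenomeAnnotation:
    """Minimal gene annotation implied by the fixture's printed rows.

    The published table prints, for every peak, the identities and
    transcription directions of the neighbouring genes but not their
    coordinates. This rebuilds just enough structure to type every
    peak: flanking genes are placed ``150``–``700`` bp to either side
    of intergenic peaks, and intragenic peaks get a host gene spanning
    ``±210`` bp (printed motif positions always fall inside these
    compartments; successive peaks are several kb apart, so intervals
    never collide).
    """
    feats: list[GeneFeature] = []
    for r in load_binding_sites().itertuples():
        p = int(r.peak_position)
        if r.site_type == "D":
            feats.append(GeneFeature(id=r.left_gene,
                                     start=p - _HOST_HALF - 50 - _GENE_SPAN,
                                     end=p - _HOST_HALF - 50,
                                     strand=r.left_strand,
                                     operon=_opt(r.left_operon),
                                     product=_opt(r.left_function) or ""))
            feats.append(GeneFeature(id=r.host_gene, start=p - _HOST_HALF,
                                     end=p + _HOST_HALF, strand="+"))
            feats.append(GeneFeature(id=r.right_gene,
                                     start=p + _HOST_HALF + 50,
                                     end=p + _HOST_HALF + 50 + _GENE_SPAN,
                                     strand=r.right_strand,
                                     operon=_opt(r.right_operon),
                                     product=_opt(r.right_function) or ""))
        else:
            feats.append(GeneFeature(id=r.left_gene,
                                     start=p - _SPACER_HALF - _GENE_SPAN,
                                     end=p - _SPACER_HALF,
                                     strand=r.left_strand,
                                     operon=_opt(r.left_operon),
                                     product=_opt(r.left_function) or ""))
            feats.append(GeneFeature(id=r.right_gene,
                                     start=p + _SPACER_HALF,
                                     end=p + _SPACER_HALF + _GENE_SPAN,
                                     strand=r.right_strand,
                                     operon=_opt(r.right_operon),
                                     product=_opt(r.right_function) or ""))
    return GenomeAnnotation(genome_length=genome_length, features=tuple(feats))


def _opt(value) -> Optional[str]:
    return None if pd.isna(value) else str(value)


@dataclass
class FixtureValidation:
    """Outcome of re-scoring every printed site sequence."""

    n_scored: int = 0
    discrepancies: list[str] = field(default_factory=list)

    @property
    def n_discrepancies(self) -> int:
        return len(self.discrepancies)

    @property
    def ok(self) -> bool:
        return not self.discrepancies


def validate_fixture(
    table: Optional[pd.DataFrame] = None,
    box: Optional[DegeneratePalindrome] = None,
) -> FixtureValidation:
    """Re-score and re-render every printed site sequence in the table.

    For each row with a printed sequence, the conservation score is
    recomputed against the box and compared with the printed value, and
    the uppercase/lowercase rendering is recomputed and compared with
    the printed casing. Discrepancies are report content, not errors;
    a clean fixture yields none.
    """
    df = load_binding_sites() if table is None else table
    box = box or DegeneratePalindrome()
    report = FixtureValidation()
    for r in df.itertuples():
        if pd.isna(r.site_sequence):
            continue
        report.n_scored += 1
        seq = str(r.site_sequence)
        computed = score_against_box(seq, box)
        if computed.rendered != str(r.conservation):
            report.discrepancies.append(
                f"peak {r.peak_position}: computed conservation "
                f"{computed.rendered} != printed {r.conservation}"
            )
        rendered = render_match(seq, box)
        if rendered != seq:
            report.discrepancies.append(
                f"peak {r.peak_position}: computed rendering {rendered!r} "
                f"!= printed {seq!r}"
            )
    return report


def fold_expansion(
    n_sites: Optional[int] = None,
    known_targets: int = KNOWN_TARGETS_IN_DATABASE,
) -> float:
    """Identified binding sites per previously curated target, one decimal.

    With the packaged table this is 35/9 = 3.9: the genome-wide screen
    finds ~3.9-fold more binding sites than were previously curated.
    """
    if n_sites is None:
        n_sites = len(load_binding_sites())
    return round(n_sites / known_targets, 1)
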
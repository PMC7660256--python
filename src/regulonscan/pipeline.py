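"""End-to-end orchestration: tracks or peak table -> typed-site report.

The pipeline mirrors the dry-lab flow of a genome-wide binding screen:
discrete peaks are obtained from intensity tracks (or taken from a
pre-called table), typed by genomic context against a gene annotation,
optionally joined to the best box match in a window around each apex
(when a genome sequence is supplied), and summarized as a site table, a
count matrix with derived consensus, and a regulon-size estimate.
"""

from __future__ import annotations

import hashlib
import logging
import os
from dataclasses import dataclass, field
from typing import Optional

import pandas as pd
import yaml
from pyfaidx import Fasta

from . import __version__
from .genome import GenomeAnnotation, load_annotation
from .motif import (
    DEFAULT_REPORTING_FLOOR,
    DegeneratePalindrome,
    MotifMatch,
    MotifMatrix,
    build_matrix,
    derive_consensus,
    scan_window,
    write_matrix,
)
from .peaks import (
    DEFAULT_CUTOFF,
    DEFAULT_MIN_SEPARATION,
    BindingPeak,
    attach_effector_intensity,
    call_peaks,
    filter_peak_table,
    read_bedgraph,
    read_peak_table,
    read_wig,
    write_peak_table,
)
from .sites import (
    RegulonEstimate,
    TypedSite,
    assemble_site_table,
    classify_sites,
    estimate_regulon_size,
)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]

logger = logging.getLogger(__name__)

DEFAULT_WINDOW = 500  # bp of sequence scanned around each apex


@dataclass
class PipelineConfig:
    """Inputs and knobs of one pipeline run.

    Exactly one of (``track``, ``peak_table``) must supply the peaks.
    ``genome_fasta`` is optional; without it motif columns are left
    empty. All defaults follow the published analysis: cutoff 500,
    7-bp arm with 3-bp spacer, reporting floor 7/14 matches,
    effector-sensitivity threshold 0.5.
    """

    annotation_path: str
    genome_length: int
    track: Optional[str] = None
    effector_track: Optional[str] = None
    peak_table: Optional[str] = None
    genome_fasta: Optional[str] = None
    cutoff: float = DEFAULT_CUTOFF
    min_separation: int = DEFAULT_MIN_SEPARATION
    box_arm: str = "AATTGGT"
    box_spacer: int = 3
    reporting_floor: int = DEFAULT_REPORTING_FLOOR
    effector_threshold: float = 0.5
    pseudocount: float = 0.0
    majority_threshold: float = 0.75
    window: int = DEFAULT_WINDOW
    max_upstream_distance: Optional[int] = None
    out_dir: Optional[str] = None
    seed: int = 0

    def __post_init__(self) -> None:
        has_track = self.track is not None
        has_table = self.peak_table is not None
        if has_track == has_table:
            raise ValueError(
                "exactly one of (track, peak_table) must be supplied"
            )

    @property
    def box(self) -> DegeneratePalindrome:
        return DegeneratePalindrome(arm=self.box_arm,
                                    spacer_length=self.box_spacer)

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


@dataclass
class PipelineResult:
    peaks: list[BindingPeak]
    typed_sites: list[TypedSite]
    site_table: pd.DataFrame
    estimate: RegulonEstimate
    matrix: Optional[MotifMatrix]
    consensus: Optional[str]
    matches: dict[int, MotifMatch] = field(default_factory=dict)
    log: list[str] = field(default_factory=list)


def _read_track(path: str, condition: str):
    if path.lower().endswith((".wig", ".wiggle")):
        return read_wig(path, condition=condition)
    return read_bedgraph(path, condition=condition)


def _checksum(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()[:12]


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full analysis described by ``config``.

    Validates input consistency first (a track that extends beyond the
    annotation's genome length is rejected before any computation),
    then peaks -> typing -> motif scan -> report tables. When
    ``config.out_dir`` is set, writes ``peaks.tsv``, ``sites.tsv``,
    ``matrix.tsv``, ``consensus.txt``, ``estimate.tsv`` and
    ``run_log.txt`` there.
    """
    log: list[str] = [f"regulonscan {__version__}"]
    log.append(f"config: {config}")
    for label in ("annotation_path", "track", "effector_track",
                  "peak_table", "genome_fasta"):
        path = getattr(config, label)
        if path is not None:
            log.append(f"input {label}={path} sha256:{_checksum(path)}")

    annotation = load_annotation(config.annotation_path, config.genome_length)

    if config.track is not None:
        track = _read_track(config.track, "no_effector")
        end = track.position(len(track) - 1) + track.step - 1
        if end > config.genome_length:
            raise ValueError(
                f"track extends to {end}, beyond the annotation's genome "
                f"length {config.genome_length}"
            )
        peaks = call_peaks(track, cutoff=config.cutoff,
                           min_separation=config.min_separation)
        if config.effector_track is not None:
            eff = _read_track(config.effector_track, "effector")
            if len(eff) != len(track):
                raise ValueError(
                    "effector track length does not match the no-effector track"
                )
            peaks = attach_effector_intensity(peaks, eff)
        log.append(f"called {len(peaks)} peaks at cutoff {config.cutoff}")
    else:
        peaks = filter_peak_table(read_peak_table(config.peak_table),
                                  cutoff=config.cutoff)
        log.append(f"loaded peak table; {len(peaks)} peaks pass cutoff "
                   f"{config.cutoff}")

    typed = classify_sites(peaks, annotation,
                           max_upstream_distance=config.max_upstream_distance)
    estimate = estimate_regulon_size(typed)
    log.append(
        f"typed sites: A={estimate.n_typeA} B={estimate.n_typeB} "
        f"C={estimate.n_typeC} D={estimate.n_typeD}; regulon size "
        f"{estimate.min_targets}-{estimate.max_targets}"
    )

    matches: dict[int, MotifMatch] = {}
    matrix = None
    consensus = None
    if config.genome_fasta is not None:
        box = config.box
        fasta = Fasta(config.genome_fasta)
        contig = fasta[list(fasta.keys())[0]]
        half = config.window // 2
        for peak in peaks:
            start = max(peak.position - half, 1)
            end = min(peak.position + half, config.genome_length)
            window = str(contig[start - 1:end])
            matches[peak.position] = scan_window(window, box, origin=start)
        scored = [m.site_sequence for m in matches.values()
                  if m.score.matches >= config.reporting_floor]
        if scored:
            matrix = build_matrix(scored, pseudocount=config.pseudocount)
            consensus = derive_consensus(matrix, config.majority_threshold)
            log.append(f"consensus from {len(scored)} sites: {consensus}")

    site_table = assemble_site_table(
        typed, matches, reporting_floor=config.reporting_floor,
        pseudocount=config.pseudocount,
    )

    result = PipelineResult(peaks=peaks, typed_sites=typed,
                            site_table=site_table, estimate=estimate,
                            matrix=matrix, consensus=consensus,
                            matches=matches, log=log)
    if config.out_dir is not None:
        _write_outputs(result, config)
    return result


def _write_outputs(result: PipelineResult, config: PipelineConfig) -> None:
    out = config.out_dir
    os.makedirs(out, exist_ok=True)
    write_peak_table(result.peaks, os.path.join(out, "peaks.tsv"),
                     pseudocount=config.pseudocount)
    result.site_table.to_csv(os.path.join(out, "sites.tsv"), sep="\t",
                             index=False)
    est = result.estimate
    pd.DataFrame(
        [{"n_typeA": est.n_typeA, "n_typeB": est.n_typeB,
          "n_typeC": est.n_typeC, "n_typeD": est.n_typeD,
          "min_targets": est.min_targets, "max_targets": est.max_targets}]
    ).to_csv(os.path.join(out, "estimate.tsv"), sep="\t", index=False)
    if result.matrix is not None:
        write_matrix(result.matrix, os.path.join(out, "matrix.tsv"))
    if result.consensus is not None:
        with open(os.path.join(out, "consensus.txt"), "w") as fh:
            fh.write(result.consensus + "\n")
    with open(os.path.join(out, "run_log.txt"), "w") as fh:
        fh.write("\n".join(result.log) + "\n")
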
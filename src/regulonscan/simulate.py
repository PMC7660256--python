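"""Synthetic genomes, planted binding sites and tiling-array-style tracks.

The generator emulates the statistical structure the analysis assumes,
so every stage is testable without any download: an annotated genome
whose neighbouring gene pairs realize a requested divergent / tandem /
convergent mix, 17-bp box instances planted with a controlled number of
informative-position mismatches in locations realizing a requested
context type, and paired intensity tracks (no-effector and effector)
consisting of Gaussian-shaped bumps over independent per-probe normal
background noise, with effector-condition amplitudes shrunk by a
retention factor.

Everything is reproducible: one integer seed drives the genome, the
site placement and both noise tracks (through separate child streams,
so track noise is independent between conditions but fixed per seed).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genome import GeneFeature, GenomeAnnotation
from .motif import BASES, DegeneratePalindrome
from .peaks import BindingTrack, write_bedgraph
from .sites import SiteType

__all__ = [
    "PlantedSiteSpec",
    "SimulationConfig",
    "PlantedSite",
    "GroundTruth",
    "default_planted_sites",
    "simulate_genome",
    "simulate_tracks",
    "write_dataset",
]


@dataclass(frozen=True)
class PlantedSiteSpec:
    """Request for one planted site: context type, mismatches, amplitude."""

    site_type: SiteType
    mismatches: int
    amplitude: float

    def __post_init__(self) -> None:
        if self.amplitude <= 0:
            raise ValueError("planted amplitude must be positive")
        if self.mismatches < 0:
            raise ValueError("mismatch count must be >= 0")


def default_planted_sites() -> list[PlantedSiteSpec]:
    """Twenty sites echoing the published screen's composition.

    7 divergent (A), 9 tandem (B) and 4 intragenic (D) sites, with
    amplitudes log-spaced over 600–9000 intensity units (the published
    peaks span roughly 509–9889) and 0–3 informative-position
    mismatches cycling across sites.
    """
    types = [SiteType.A] * 7 + [SiteType.B] * 9 + [SiteType.D] * 4
    amplitudes = np.geomspace(600.0, 9000.0, num=len(types))
    return [
        PlantedSiteSpec(site_type=t, mismatches=i % 4, amplitude=float(a))
        for i, (t, a) in enumerate(zip(types, amplitudes))
    ]


@dataclass
class SimulationConfig:
    """Knobs of the synthetic genome + track generator.

    ``orientation_mix`` gives the target fractions of (divergent,
    tandem, convergent) neighbouring gene pairs; on a linear genome
    divergent and convergent junctions must alternate, so unequal
    divergent/convergent fractions are realized only approximately
    (the tandem fraction is honoured and the remainder split equally).
    ``probe_step`` mirrors a ~43k-probe tiling array on a Mb-scale
    genome; ``peak_width`` is the Gaussian sigma of each bump,
    matching ~200–300 bp enriched fragments.
    """

    seed: int = 0
    genome_length: int = 300_000
    n_genes: int = 60
    orientation_mix: tuple[float, float, float] = (0.25, 0.5, 0.25)
    gc_content: float = 0.508
    planted_sites: list[PlantedSiteSpec] = field(default_factory=default_planted_sites)
    peak_width: float = 150.0
    background_mean: float = 100.0
    background_sd: float = 20.0
    effector_retention: float = 0.4
    probe_step: int = 100
    gene_length_range: tuple[int, int] = (600, 1500)
    spacer_range: tuple[int, int] = (150, 400)
    box: DegeneratePalindrome = field(default_factory=DegeneratePalindrome)

    def __post_init__(self) -> None:
        if not np.isclose(sum(self.orientation_mix), 1.0):
            raise ValueError("orientation_mix must sum to 1")
        if any(f < 0 or f > 1 for f in self.orientation_mix):
            raise ValueError("orientation_mix fractions must lie in [0, 1]")
        if not 0.0 <= self.gc_content <= 1.0:
            raise ValueError("gc_content must lie in [0, 1]")
        if self.effector_retention < 0:
            raise ValueError("effector_retention must be >= 0")
        for spec in self.planted_sites:
            if spec.mismatches > self.box.n_informative:
                raise ValueError(
                    f"cannot plant {spec.mismatches} mismatches in a box with "
                    f"{self.box.n_informative} informative positions"
                )


@dataclass(frozen=True)
class PlantedSite:
    """Ground truth for one planted site."""

    position: int              # 1-based start of the planted 17-mer
    apex_position: int         # centre of the motif = centre of the bump
    site_type: SiteType
    mismatches: int
    sequence: str
    amplitude: float
    amplitude_effector: float
    left_gene: Optional[str] = None
    right_gene: Optional[str] = None
    host_gene: Optional[str] = None


@dataclass
class GroundTruth:
    sites: list[PlantedSite] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.sites)

    def __iter__(self):
        return iter(self.sites)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "position": s.position,
                    "apex_position": s.apex_position,
                    "site_type": s.site_type.value,
                    "mismatches": s.mismatches,
                    "sequence": s.sequence,
                    "amplitude": s.amplitude,
                    "amplitude_effector": s.amplitude_effector,
                    "left_gene": s.left_gene or "",
                    "right_gene": s.right_gene or "",
                    "host_gene": s.host_gene or "",
                }
                for s in self.sites
            ]
        )


def _planted_motif(rng: np.random.Generator, box: DegeneratePalindrome,
                   mismatches: int) -> str:
    """Box consensus with random spacer and exactly ``mismatches``
    informative-position mutations (uniform without replacement)."""
    seq = list(box.full_consensus.upper())
    informative = list(box.informative_positions)
    for i in range(box.length):
        if i not in box.informative_positions:
            seq[i] = BASES[rng.integers(4)]
    mutate = rng.choice(len(informative), size=mismatches, replace=False)
    for k in mutate:
        i = informative[int(k)]
        choices = [b for b in BASES if b != seq[i]]
        seq[i] = choices[rng.integers(3)]
    return "".join(seq)


def _next_strand(rng: np.random.Generator, prev: Optional[str],
                 mix: tuple[float, float, float]) -> str:
    """Markov strand draw realizing the tandem fraction of ``mix``."""
    if prev is None:
        return "+" if rng.random() < 0.5 else "-"
    p_switch = 1.0 - mix[1]  # leaving tandem probability = non-tandem mass
    if rng.random() < p_switch:
        return "+" if prev == "-" else "-"
    return prev


def simulate_genome(
    config: SimulationConfig,
) -> tuple[str, GenomeAnnotation, GroundTruth]:
    """Lay out genes and planted sites, then draw the sequence.

    Planted sites are realized as dedicated cassettes — a divergent
    gene pair (type A), a tandem pair (B), a convergent pair (C), or a
    single host gene (D) — interleaved with filler genes whose strands
    follow the orientation mix. Raises if the requested genes cannot be
    packed into ``genome_length``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    box = config.box
    glen_lo, glen_hi = config.gene_length_range
    sp_lo, sp_hi = config.spacer_range
    min_spacer = 3 * box.length

    def gene_len() -> int:
        return int(rng.integers(glen_lo, glen_hi + 1))

    def spacer_len() -> int:
        return max(int(rng.integers(sp_lo, sp_hi + 1)), min_spacer)

    cassette_genes = sum(
        1 if s.site_type is SiteType.D else 2 for s in config.planted_sites
    )
    n_filler = max(config.n_genes - cassette_genes, 0)

    # interleave fillers evenly between cassettes
    order: list[Optional[PlantedSiteSpec]] = []
    specs = list(config.planted_sites)
    rng.shuffle(specs)  # type: ignore[arg-type]
    gaps = len(specs) + 1
    per_gap, extra = divmod(n_filler, gaps) if specs else (n_filler, 0)
    for g in range(gaps):
        order.extend([None] * (per_gap + (1 if g < extra else 0)))
        if g < len(specs):
            order.append(specs[g])

    feats: list[GeneFeature] = []
    truth = GroundTruth()
    cursor = 1 + spacer_len()
    prev_strand: Optional[str] = None
    gene_no = 0
    motifs: list[tuple[int, str]] = []  # (0-based offset, sequence)

    def add_gene(strand: str, length: Optional[int] = None) -> GeneFeature:
        nonlocal cursor, prev_strand, gene_no
        gene_no += 1
        length = length or gene_len()
        feat = GeneFeature(id=f"g{gene_no:04d}", start=cursor,
                           end=cursor + length - 1, strand=strand)
        feats.append(feat)
        cursor = feat.end + 1 + spacer_len()
        prev_strand = strand
        return feat

    def plant_in_spacer(spec: PlantedSiteSpec, left: GeneFeature,
                        spacer_start: int, spacer_end: int,
                        right_id: str) -> None:
        mid = (spacer_start + spacer_end) // 2
        start = mid - box.length // 2
        seq = _planted_motif(rng, box, spec.mismatches)
        motifs.append((start - 1, seq))
        truth.sites.append(PlantedSite(
            position=start, apex_position=start + box.length // 2,
            site_type=spec.site_type, mismatches=spec.mismatches,
            sequence=seq, amplitude=spec.amplitude,
            amplitude_effector=spec.amplitude * config.effector_retention,
            left_gene=left.id, right_gene=right_id,
        ))

    for unit in order:
        if unit is None:
            add_gene(_next_strand(rng, prev_strand, config.orientation_mix))
            continue
        spec = unit
        if spec.site_type is SiteType.D:
            host = add_gene(_next_strand(rng, prev_strand,
                                         config.orientation_mix),
                            length=max(gene_len(), 3 * box.length))
            mid = (host.start + host.end) // 2
            start = mid - box.length // 2
            seq = _planted_motif(rng, box, spec.mismatches)
            motifs.append((start - 1, seq))
            truth.sites.append(PlantedSite(
                position=start, apex_position=start + box.length // 2,
                site_type=spec.site_type, mismatches=spec.mismatches,
                sequence=seq, amplitude=spec.amplitude,
                amplitude_effector=spec.amplitude * config.effector_retention,
                host_gene=host.id,
            ))
        else:
            left_strand, right_strand = {
                SiteType.A: ("-", "+"),
                SiteType.B: ("+", "+"),
                SiteType.C: ("+", "-"),
            }[spec.site_type]
            left = add_gene(left_strand)
            spacer_start = left.end + 1
            right = add_gene(right_strand)
            plant_in_spacer(spec, left, spacer_start, right.start - 1,
                            right.id)

    margin = spacer_len()
    if cursor + margin > config.genome_length:
        raise ValueError(
            f"genome_length {config.genome_length} too short: layout of "
            f"{gene_no} genes and {len(config.planted_sites)} planted sites "
            f"needs about {cursor + margin} bp"
        )

    gc = config.gc_content
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A C G T
    seq_arr = rng.choice(list(BASES), size=config.genome_length, p=probs)
    for offset, motif in motifs:
        seq_arr[offset:offset + len(motif)] = list(motif)
    sequence = "".join(seq_arr)

    annotation = GenomeAnnotation(genome_length=config.genome_length,
                                  features=tuple(feats))
    return sequence, annotation, truth


def simulate_tracks(
    truth: GroundTruth, config: SimulationConfig
) -> tuple[BindingTrack, BindingTrack]:
    """Paired (no-effector, effector) intensity tracks for the truth.

    Each track is independent clipped-normal background plus one
    Gaussian bump of the site's condition amplitude per planted site.
    """
    n = int(np.ceil(config.genome_length / config.probe_step))
    grid = 1 + np.arange(n, dtype=float) * config.probe_step
    sigma = config.peak_width

    def bumps(attr: str) -> np.ndarray:
        total = np.zeros(n)
        for site in truth:
            amp = getattr(site, attr)
            total += amp * np.exp(-((grid - site.apex_position) ** 2)
                                  / (2.0 * sigma ** 2))
        return total

    tracks = []
    for child, label, attr in (
        (1, "no_effector", "amplitude"),
        (2, "effector", "amplitude_effector"),
    ):
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, child]))
        noise = rng.normal(config.background_mean, config.background_sd, size=n)
        values = np.clip(noise, 0.0, None) + bumps(attr)
        tracks.append(BindingTrack(values=values, step=config.probe_step,
                                   start=1, condition=label))
    return tracks[0], tracks[1]


def write_dataset(
    out_dir: str | os.PathLike,
    sequence: str,
    annotation: GenomeAnnotation,
    truth: GroundTruth,
    tracks: Optional[tuple[BindingTrack, BindingTrack]] = None,
    name: str = "sim",
) -> dict[str, str]:
    """Write FASTA + GFF3 + ground-truth TSV (+ two bedGraphs) to a directory.

    Output is deterministic: identical inputs give byte-identical files.
    """
    os.makedirs(out_dir, exist_ok=True)
    paths = {}

    fasta = os.path.join(out_dir, f"{name}.fa")
    SeqIO.write(
        [SeqRecord(Seq(sequence), id=name, description="synthetic genome")],
        fasta, "fasta",
    )
    paths["fasta"] = fasta

    gff = os.path.join(out_dir, f"{name}.gff3")
    with open(gff, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {name} 1 {annotation.genome_length}\n")
        for f in annotation:
            fh.write(
                f"{name}\tregulonscan\tgene\t{f.start}\t{f.end}\t.\t{f.strand}"
                f"\t.\tID={f.id};Name={f.id}\n"
            )
    paths["gff3"] = gff

    truth_path = os.path.join(out_dir, f"{name}_truth.tsv")
    truth.to_frame().to_csv(truth_path, sep="\t", index=False)
    paths["truth"] = truth_path

    if tracks is not None:
        for track in tracks:
            p = os.path.join(out_dir, f"{name}_{track.condition}.bedGraph")
            write_bedgraph(track, p, chrom=name)
            paths[track.condition] = p
    return paths
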
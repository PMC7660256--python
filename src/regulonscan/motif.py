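"""Degenerate-palindrome motif representation, scoring and matrices.

The recognition element modeled here is a gapped palindrome: two
reverse-complementary arms around an unconstrained spacer. The default
is the PdhR box AATTGGTnnnACCAATT — a 7-bp arm, a 3-bp spacer and
therefore 14 informative positions. Sites are scored by counting
informative positions that match the consensus ("n/14" conservation),
and rendered with uppercase at matches and lowercase elsewhere, the
convention used in published binding-site tables.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from functools import cached_property
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from Bio.Seq import Seq

__all__ = [
    "DegeneratePalindrome",
    "ConservationScore",
    "MotifMatch",
    "MotifMatrix",
    "score_against_box",
    "render_match",
    "scan_window",
    "build_matrix",
    "derive_consensus",
    "write_matrix",
    "read_matrix",
]

BASES = "ACGT"
DEFAULT_REPORTING_FLOOR = 7


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


@dataclass(frozen=True)
class DegeneratePalindrome:
    """A gapped palindromic consensus: arm + n-spacer + revcomp(arm)."""

    arm: str = "AATTGGT"
    spacer_length: int = 3

    def __post_init__(self) -> None:
        arm = self.arm.upper()
        if not arm or any(b not in BASES for b in arm):
            raise ValueError(f"arm must be non-empty over ACGT, got {self.arm!r}")
        if self.spacer_length < 0:
            raise ValueError("spacer_length must be >= 0")
        object.__setattr__(self, "arm", arm)

    @cached_property
    def full_consensus(self) -> str:
        """E.g. ``AATTGGTnnnACCAATT`` for the default box."""
        return self.arm + "n" * self.spacer_length + reverse_complement(self.arm)

    @property
    def length(self) -> int:
        return 2 * len(self.arm) + self.spacer_length

    @cached_property
    def informative_positions(self) -> tuple[int, ...]:
        """0-based indices of the non-spacer positions (14 by default)."""
        a = len(self.arm)
        return tuple(range(a)) + tuple(range(a + self.spacer_length, self.length))

    @property
    def n_informative(self) -> int:
        return 2 * len(self.arm)


@dataclass(frozen=True)
class ConservationScore:
    """Matched informative positions out of the informative total."""

    matches: int
    informative: int

    def __post_init__(self) -> None:
        if not 0 <= self.matches <= self.informative:
            raise ValueError(
                f"matches ({self.matches}) must lie in [0, {self.informative}]"
            )

    @property
    def rendered(self) -> str:
        return f"{self.matches}/{self.informative}"

    def __str__(self) -> str:
        return self.rendered


@dataclass(frozen=True)
class MotifMatch:
    """A scored alignment of one window position to the box."""

    site_sequence: str
    score: ConservationScore
    genome_position: int  # plus-strand coordinate of the match's first base
    strand: str
    rendered_sequence: str


def _match_mask(site: str, box: DegeneratePalindrome) -> list[bool]:
    if len(site) != box.length:
        raise ValueError(
            f"site length {len(site)} != box length {box.length}"
        )
    consensus = box.full_consensus
    up = site.upper()
    informative = set(box.informative_positions)
    return [i in informative and up[i] == consensus[i] for i in range(box.length)]


def score_against_box(
    site: str, box: Optional[DegeneratePalindrome] = None
) -> ConservationScore:
    """Count informative positions of ``site`` matching the box consensus.

    Case-insensitive; spacer positions are never scored; any letter
    other than A/C/G/T (including ambiguity codes and 'n') counts as a
    mismatch at informative positions.
    """
    box = box or DegeneratePalindrome()
    mask = _match_mask(site, box)
    return ConservationScore(matches=sum(mask), informative=box.n_informative)


def render_match(site: str, box: Optional[DegeneratePalindrome] = None) -> str:
    """Case-annotate ``site``: uppercase at informative matches, lowercase
    at informative mismatches and spacer positions.

    Uppercasing the output recovers the (uppercased) input.
    """
    box = box or DegeneratePalindrome()
    mask = _match_mask(site, box)
    return "".join(
        c.upper() if m else c.lower() for c, m in zip(site, mask)
    )


def scan_window(
    sequence: str,
    box: Optional[DegeneratePalindrome] = None,
    origin: int = 1,
) -> MotifMatch:
    """Best-scoring box match over every offset of ``sequence``, both strands.

    Ties prefer the smaller offset, then the plus strand. ``origin`` is
    the 1-based genome position of the window's first base; the match's
    ``genome_position`` is always the plus-strand coordinate of its
    first base, whichever strand it lies on.
    """
    box = box or DegeneratePalindrome()
    L = box.length
    if len(sequence) < L:
        raise ValueError(
            f"window of {len(sequence)} nt is shorter than the box ({L} nt)"
        )
    best: Optional[tuple[int, int, int, str]] = None  # (-matches, offset, strand_rank, site)
    for offset in range(len(sequence) - L + 1):
        window = sequence[offset:offset + L]
        for strand_rank, (strand, site) in enumerate(
            (("+", window), ("-", reverse_complement(window)))
        ):
            matches = score_against_box(site, box).matches
            key = (-matches, offset, strand_rank, site)
            if best is None or key < best:
                best = key
    neg_matches, offset, strand_rank, site = best
    strand = "+" if strand_rank == 0 else "-"
    return MotifMatch(
        site_sequence=site,
        score=ConservationScore(-neg_matches, box.n_informative),
        genome_position=origin + offset,
        strand=strand,
        rendered_sequence=render_match(site, box),
    )


# ---------------------------------------------------------------------------
# count matrices and consensus derivation


@dataclass(frozen=True)
class MotifMatrix:
    """Per-position base counts for an aligned site collection.

    ``counts[i, j]`` is the (pseudocount-augmented) count of base
    ``ACGT[j]`` at position ``i``. Information content per position is
    ``2 + sum_b p_b log2 p_b`` bits against a uniform background.
    """

    counts: np.ndarray
    pseudocount: float = 0.0

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=float)
        if counts.ndim != 2 or counts.shape[1] != 4:
            raise ValueError("counts must have shape (length, 4)")
        if (counts < 0).any():
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "counts", counts)

    @property
    def length(self) -> int:
        return self.counts.shape[0]

    @property
    def probabilities(self) -> np.ndarray:
        totals = self.counts.sum(axis=1, keepdims=True)
        return self.counts / totals

    @property
    def information_content(self) -> np.ndarray:
        """Bits per position, in [0, 2]."""
        p = self.probabilities
        with np.errstate(divide="ignore", invalid="ignore"):
            plogp = np.where(p > 0, p * np.log2(p), 0.0)
        ic = 2.0 + plogp.sum(axis=1)
        return np.clip(ic, 0.0, 2.0)


def build_matrix(sites: Iterable[str], pseudocount: float = 0.0) -> MotifMatrix:
    """Tally base counts per position over equal-length aligned sites."""
    sites = [s.upper() for s in sites]
    if not sites:
        raise ValueError("need at least one site to build a matrix")
    length = len(sites[0])
    if any(len(s) != length for s in sites):
        raise ValueError("all sites must have the same length")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    counts = np.full((length, 4), pseudocount, dtype=float)
    index = {b: j for j, b in enumerate(BASES)}
    for s in sites:
        for i, c in enumerate(s):
            j = index.get(c)
            if j is not None:
                counts[i, j] += 1.0
    return MotifMatrix(counts=counts, pseudocount=pseudocount)


def derive_consensus(matrix: MotifMatrix, majority_threshold: float = 0.75) -> str:
    """Majority-rule degenerate consensus from a count matrix.

    Per position: the modal base if its frequency reaches
    ``majority_threshold``, else ``'n'``; a tie at the mode also yields
    ``'n'``. The threshold must exceed 0.25 (the uniform frequency) for
    the call to be meaningful.
    """
    if not 0.25 < majority_threshold <= 1.0:
        raise ValueError("majority_threshold must lie in (0.25, 1]")
    probs = matrix.probabilities
    out = []
    for row in probs:
        best = int(np.argmax(row))
        if row[best] >= majority_threshold and (row == row[best]).sum() == 1:
            out.append(BASES[best])
        else:
            out.append("n")
    return "".join(out)


def write_matrix(matrix: MotifMatrix, path: str | os.PathLike) -> None:
    """TSV export (1-based position, ACGT counts, IC column) suitable for
    logo-rendering tools."""
    df = pd.DataFrame(matrix.counts, columns=list(BASES))
    df.insert(0, "position", np.arange(1, matrix.length + 1))
    df["information_content"] = matrix.information_content
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_matrix(path: str | os.PathLike, pseudocount: float = 0.0) -> MotifMatrix:
    df = pd.read_csv(path, sep="\t")
    return MotifMatrix(counts=df[list(BASES)].to_numpy(dtype=float),
                       pseudocount=pseudocount)
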
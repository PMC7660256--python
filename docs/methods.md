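# Methods

## Problem and scope

A genomic SELEX (gSELEX-chip) screen enriches genome fragments bound by
a purified transcription factor and maps them by tiling-array
hybridization, yielding a per-probe binding-intensity profile along the
genome under two conditions: the factor alone, and the factor
pre-incubated with its effector ligand (pyruvate, for PdhR, which
abolishes DNA binding). `regulonscan` covers everything downstream of
the array scan: discretizing the profile into peaks, interpreting each
peak's genomic context, scoring candidate sites against the factor's
recognition element, and bounding the size of the regulon. Wet-lab
readouts (gel shift, RT-qPCR, Northern blots, metabolite measurements)
are out of scope; the report tables carry an optional free-text
regulation column for user-supplied metadata instead.

## Coordinate and annotation model

All coordinates are 1-based inclusive, as printed in bacterial genome
tables. GFF3 is read natively (via `gffutils`; feature types counted as
genes are configurable, default `gene` then `CDS`); 6-column BED is
converted on input. Gene bodies are CDS extents — promoters, UTRs and
transcription starts are not modeled, so *upstream of a gene* means the
intergenic spacer on its 5′ side. When annotated genes overlap, the
host of an intragenic position is the overlapping gene with the
smallest start (then smallest end): a deterministic convention for a
rare case. Genomes are linear by default; a `circular` flag wraps the
flanking-gene search across the origin (the *E. coli* chromosome is
circular, but no analyzed site sits near the origin, so the default
keeps end-of-genome behavior explicit).

## Peak calling

A peak is a local maximum of the intensity track with value ≥ cutoff.
The apex definition: a sample (or leftmost sample of a plateau of equal
values) whose nearest differing neighbours on both sides are lower;
track ends need only their inner side. Apexes closer than
`min_separation` (default 500 bp, the probe scale of a ~100-bp-step
tiling array) are merged keeping the higher apex, ties keeping the
leftmost. This makes the peak count non-increasing in the cutoff and
the caller idempotent on its own output, and it is checked against an
independent brute-force local-maximum scan in the tests. The published
analysis applied a single hard cutoff of 500 intensity units with no
smoothing or FDR control; the caller reproduces exactly that behavior.
The cutoff is applied inclusively (≥ 500): the published wording
("above 500") is ambiguous, and since the weakest reported site is at
509 the choice is unobservable on real data.

Effector comparison is per-peak:
`retained_fraction = (I_effector + ε) / (I_no_effector + ε)` with
pseudocount ε (default 0), and a site is called effector-sensitive when
the fraction falls below 0.5 (configurable). A missing effector
intensity yields an absent result, not an error.

### Intensity-column convention

The published site table prints the +pyruvate intensity column before
the no-effector column, yet applies the cutoff to the no-effector
screen and reports that intensities *decreased* with pyruvate, and the
first printed column is consistently the larger. The packaged fixture
therefore stores the first printed column as `intensity_no_effector`
and the second as `intensity_effector`; both original labels are quoted
in the fixture's comment header.

## Context typing and regulon bounds

Peak position inside a gene body → type **D** (host gene recorded, no
regulated genes inferred — regulatory roles of intra-ORF binding are
unknown). Otherwise the peak's flanking genes decide: upstream of both
(left gene on minus strand and right gene on plus strand, a divergent
spacer) → **A**; upstream of exactly one (tandem spacer) → **B**;
upstream of neither (convergent spacer) → **C**. No maximum upstream
distance is imposed by default, matching the published typing; a
configurable `max_upstream_distance` exists for reuse on genomes with
long intergenic regions. At a linear genome end the missing flank is
treated as absent and the peak is typed from the genes in view, with a
warning.

The regulon bounds follow from counting transcription units: every
type-A or type-B site proves at least one directly bound unit
(`min = n_A + n_B`); a type-A site may regulate either or both of its
divergent units (`max = 2·n_A + n_B`). No attempt is made to resolve
which divergent unit is the true target — that requires expression
data. Type-C and type-D sites contribute to neither bound. The gap
`max − min = n_A` is a structural invariant, property-tested.

## The recognition element and its scoring

The element is a degenerate gapped palindrome: arm + n-spacer +
reverse-complement(arm). The default box `AATTGGTnnnACCAATT` (7-bp arm,
3-bp spacer) has 14 informative positions and equals its own reverse
complement, which makes conservation scoring strand-symmetric by
construction. The literature has described the element as 15 or 17 bp
long; the 17-bp form is the default here because every published site
sequence is 17 nt and every printed denominator is 14 — the 15-bp
variant (6-bp arm, 12 informative positions) is one constructor call
away.

* **Scoring** counts informative positions matching the consensus,
  case-insensitively; spacer positions are never scored; any non-ACGT
  letter (including `n` and IUPAC ambiguity codes) is a mismatch at an
  informative position.
* **Rendering** uppercases exactly the matching informative positions;
  spacer and mismatched positions are lowercase. Uppercasing the output
  recovers the input.
* **Scanning** evaluates every offset of a window on both strands and
  returns the best match; ties prefer the smaller offset, then the plus
  strand. Matches on either strand are reported by the plus-strand
  coordinate of their first base — the convention that reproduces the
  published motif coordinates. The scanner is checked against an
  exhaustive oracle on kb-scale windows.
* Reported tables render matches below a floor (default 7 of 14 — the
  weakest score the published table prints) as `-`.

## Matrices and consensus derivation

The count matrix tallies bases per position over aligned sites (plus an
optional pseudocount). Information content per position is
`2 + Σ_b p_b log₂ p_b` bits against a uniform background, clipped to
[0, 2]. Consensus derivation is deliberately simple and documented: per
position, the modal base if its frequency reaches a majority threshold
(default 0.75), else `n`; modal ties give `n`. The published analysis
used an external motif-discovery service for this step; that tool is
not reimplemented — the count-matrix + majority-rule procedure is this
package's own, and it recovers the published conserved core
`GGTnnnACC` from the packaged sites (outer arm positions fall below the
majority threshold and degenerate to `n`, consistent with the
published observation that only the 9-bp core is tightly conserved).

## Packaged reference table

The package ships the full published table of 35 binding sites. Of its
rows, 27 print a site sequence; all 27 printed conservation scores and
all 27 printed case renderings are reproduced exactly by the scoring
and rendering above (`validate_fixture()` re-checks this at run time).
One further row prints a sequence whose casing and score contradict its
own letters (two bases rendered lowercase although they match the
consensus, with the score counting them as mismatches); since neither
the true sequence nor the true score of that site can be reconstructed,
its motif columns are stored as absent, with the printed values
preserved in the fixture file's comments.

The fixture's printed flanking-gene names and strand arrows imply a
minimal annotation: flanking genes are rebuilt 150–700 bp to either
side of each intergenic peak and host genes as ±210 bp around each
intragenic peak. These spans were chosen once so that every printed
motif coordinate falls in the correct compartment (all printed motifs
sit within ~170 bp of their peak) and successive peaks (≥14 kb apart)
never collide; typing this reconstruction reproduces all 35 published
type assignments.

## Synthetic data generator

The generator emulates the screen's statistical structure, not its
biochemistry (no SELEX round kinetics, no PCR bias, no explicit array
layout):

* **Genome**: i.i.d. background sequence at configurable GC content
  (default 0.508, the *E. coli* K-12 value). Genes are placed left to
  right with lengths uniform in 600–1500 bp and spacers uniform in
  150–400 bp (floored at 3× box length so a site always fits).
* **Planted sites** are realized as cassettes — a divergent pair (A),
  tandem pair (B), convergent pair (C) or a single host gene (D) — with
  the 17-mer written at the spacer or ORF centre. Each planted 17-mer
  is the box consensus with a random spacer and exactly the requested
  number of informative-position mutations, drawn uniformly without
  replacement.
* **Orientation mix**: on a linear genome divergent and convergent
  junctions strictly alternate, so only the tandem fraction is freely
  realizable; filler-gene strands follow a two-state Markov chain whose
  switch probability equals the non-tandem mass, splitting the
  remainder equally between divergent and convergent. The default mix
  (0.25, 0.5, 0.25) corresponds to i.i.d. uniform strands.
* **Tracks**: per-probe values at `probe_step` (default 100 bp,
  mirroring a ~43k-probe array on a Mb-scale genome) are independent
  normal background (mean 100, sd 20, clipped at 0) plus one Gaussian
  bump per site with sigma `peak_width` (default 150 bp, the scale of
  200–300-bp enriched fragments). The effector track multiplies every
  amplitude by `effector_retention` (default 0.4, the order of the
  median intensity ratio across the published sites) and draws fresh
  noise. All randomness flows from one integer seed through named child
  streams, so outputs are byte-identical per seed.
* **Defaults** plant 20 sites — 7 A, 9 B, 4 D, echoing the published
  composition — with amplitudes log-spaced over 600–9000 units
  (published peaks span 509–9889) and mismatch counts cycling 0–3.
  Minimum apex SNR is therefore 600/20 = 30.

What passing the end-to-end test shows: under Gaussian bumps,
independent probe noise and planted sites at SNR ≥ 5, the pipeline
recovers sites, types and conservation scores essentially perfectly.
What it does not show: robustness to correlated probe noise, dye bias,
copy-number structure or smoothing artefacts of real arrays — the
caller was additionally validated against the published peak table, but
not against raw array files, which are not publicly distributed in
probe-level form.

## Numerical and interface choices

* Peak merging is greedy, strongest-first, tie → leftmost; plateau
  apexes report their leftmost sample.
* Scan ties: smaller offset, then plus strand.
* `derive_consensus` requires a threshold in (0.25, 1] — at or below
  the uniform frequency a majority call is meaningless.
* Degenerate inputs raise early with the offending file, line or
  parameter named: empty tracks, ragged site collections, windows
  shorter than the box, features beyond the genome end, BED intervals
  with start ≥ end, duplicate peak identities in a report.
* Output tables are TSV with ASCII `-` for absent values; pipeline runs
  are deterministic given config + inputs, with run metadata (package
  version, config echo, input checksums) segregated to the run log.
* Problem sizes in the tests (300-kb simulated genomes, 20 planted
  sites, 1-kb scan windows, 10-kb oracle tracks) are desk-scale choices
  that exercise every code path with exhaustive oracles in seconds.

## Known limitations

* Typing anchors on CDS boundaries; screens on genomes with long 5′
  UTRs or known TSSs would want `max_upstream_distance` or a
  TSS-aware annotation.
* The consensus procedure is a majority rule, not an EM/Gibbs motif
  finder: it assumes sites are already aligned (the fixed-length box
  scan provides that alignment) and will not discover shifted or
  variable-spacer variants.
* `effector_response` compares apex intensities only; it does not model
  partial-occupancy shoulders or probe saturation.
* The bedGraph/WIG readers accept single-chromosome, fixed-step files —
  the shape this analysis produces and consumes.
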
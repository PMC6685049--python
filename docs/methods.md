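# Methods

## Scope and data model

The pipeline starts from post-search peptide-level evidence: tables of
identified peptides with per-channel XIC areas, exported by a search engine
run with light/heavy dimethylation, carbamidomethyl-C, Met oxidation and
N/Q deamidation, semi-ArgC specificity and up to three missed cleavages.
Spectrum processing and PSM-level FDR control are upstream assumptions, not
recomputed here. Residue coordinates are 1-based inclusive (UniProt
convention); a cleavage site is written P1|P1′, with P1′ the first residue
of the observed peptide. Sequences are restricted to the 20-letter
alphabet; ambiguity codes are rejected at parse time because the mass and
motif arithmetic assumes it.

## Label masses

Dimethylation deltas are computed from NIST atomic masses rather than
stored as nominal values: light formaldehyde adds 2 × ¹²C + 4 × ¹H
(28.0313 Da), heavy ¹³CD₂-formaldehyde adds 2 × ¹³C + 4 × ²H (34.0631 Da),
a per-amine spacing of 6.0318 Da. Peptide masses are residue sums plus
water plus modification deltas; named modifications are validated against
their target residues.

## Differential model

For each peptide and replicate, channel areas are relabeled CTRL/DA by the
replicate's light/heavy orientation and the ratio log₂(DA/CTRL) is formed.
Duplicate rows (same sequence, replicate, stage) are summed per channel
before the ratio; the deduplication key collapses modification variants by
default (configurable to sequence+mods). Missing-value policy:

* a replicate with signal in both channels contributes a ratio;
* signal in exactly one channel is *condition-exclusive evidence* for that
  replicate, not a missing value and not a ratio;
* zero or negative areas are treated as missing (a zero XIC means
  not-detected), with a logged warning.

With n replicates (default 7) and at most `max_missing` (default 2) absent
ratios, a peptide is called **over**/**under** when |mean log₂| ≥
log₂(1.5) = 0.585 and a two-tailed one-sample *t*-test against 0 gives
*p* < 0.05. The magnitude gate applies to the mean, not to each replicate
(the alternative reading is configurable via the threshold). A peptide
never seen in one condition but detected exclusively in the other in at
least n − `max_missing` replicates is **da_only**/**ctrl_only**. No
multiple-testing correction is applied by default (raw *p* < 0.05 is the
operating point of this design); Benjamini–Hochberg can be layered on the
result frame. Degenerate zero-variance ratio vectors (the *t* statistic is
undefined) give *p* = 0 for a nonzero mean and *p* = 1 otherwise.

Two symmetries are enforced by construction and tested: permuting all
light/heavy orientations together with the channel areas changes nothing
(swap invariance), and exchanging the CTRL/DA roles negates every ratio and
swaps over↔under, da_only↔ctrl_only (antisymmetry).

## N-terminus classification

Peptides are placed on proteins by exact substring search; the declared
accession restricts the search when present, otherwise proteins are scanned
in accession order and the leftmost hit is primary, with any additional
placement flagged as ambiguous. Ile/Leu are not treated as interchangeable
(the search engine already resolved the sequence). Classification
precedence for a mapped start P1′:

1. P1′ = 1 → `natural`;
2. P1′ = transit-peptide end + 1 → `tp_removal`;
3. |P1′ − (TP end + 1)| ≤ 2 → `ragging_tp_removal`, with the signed shift
   reported (the window is symmetric: ragging is aminopeptidase trimming,
   i.e. downstream shifts, but upstream off-by-one processing is kept and
   distinguishable by the sign);
4. P1′ = a propeptide end + 1 → `propeptide_removal`;
5. P1′ = 2 with initiator Met and no transit peptide → `met_removal`;
6. otherwise `internal`.

Transit-peptide logic deliberately outranks Met-removal: for a protein with
an annotated presequence, a position-2 peptide is a ragged processing
product, not a Met-aminopeptidase product.

Novel transit-peptide proposal: for a mitochondrial-reference protein with
no annotated presequence, a recurrent internal N-terminus (same position in
≥ 3 replicates by default) at a position ≤ 100 (a generous upper bound on
presequence length) proposes mtTP = [1, P1′−1], chain = [P1′, length].

The three reference proteins used in the mapping worked examples are
shipped as *synthetic stand-ins* (`fixtures.synthetic_reference_proteins`):
random sequences of the published lengths with the published N-terminal
peptides implanted at the published positions. They validate mapping and
proposal logic; they are not the real sequences.

## Terminome statistics

Recovery is R = |unique POSTsel peptides| / |unique PREsel peptides| per
replicate, with mean ± SD across replicates. Protein-level presence is ≥ 1
assigned peptide (no protein-inference parsimony). Mitochondrial fractions
use a reference inventory flag per protein; the PRE-vs-POST comparison is a
paired two-tailed *t*-test on untransformed fractions. Overlap counts
always partition the union; coverage is |identified ∩ reference| /
|reference|. Protein counts are unions across replicates, with
per-replicate breakdowns also emitted.

## Cleavage motifs and specificity

Each processed N-terminus (tp_removal, ragging, propeptide_removal,
internal; natural and Met-removal are excluded as they carry no protease
signature) yields a 20-slot window P10…P1↓P1′…P10′; slots beyond the
protein bounds are padded and excluded per-column from all counting.
Information content per slot is log₂20 − H bits; the WebLogo-style
small-sample correction is available but off by default for determinism.
The consensus shows the modal residue where its frequency ≥ 0.2 (ties
alphabetical), chosen so that a five-position motif at 60% site frequency
over a ~5–8% background emerges while background positions stay blank.

Protease specificity profiles are packaged as plain TSV matrices
(P4…P4′ columns, residue rows, columns summing to 1) — a toy set with a
neprilysin-like M13.001 profile (bulky hydrophobic P1′), an
MPP-like M16.003 (Arg at P2, small P1′) and an HTRA2-like S1C.002 (small
hydrophobic P1). A window's score against a profile is
Σ log₂(profile/background) over non-padded profile positions, with
probabilities floored at 10⁻⁴ so unobserved residues penalise without
producing −∞; the default background is uniform 1/20, with a
proteome-derived background available. Ranking is by mean score, ties
alphabetical.

## Synthetic-data generator

The generator defines the study conditions under which the pipeline is
validated. Defaults: 150 proteins of length 120–600 drawn i.i.d. from
human-like residue frequencies, 30% mitochondrial with transit peptides of
uniform length 15–60; the processing motif R/R/R at P3–P1 and A/S at
P1′/P2′, each implanted with probability 0.6 per site (so the consensus
Arg-Arg-Arg↓Ala-Ser is recoverable but not trivial); ragging probability
0.2 with ±1 shifts, sampled per protein and replicate; Poisson(0.5)
internal cleavage sites per protein carrying the same motif; seven
replicates with the label swap (CTRL light in replicates 1–4, DA light in
5–7); log-normal protein abundances (ln-σ 1.2) with per-channel replicate
noise of 0.3 on the log₂ scale; injected effects of 1.5×, 2× and 0.5× on
15 blocked peptides each plus 8 DA-only and 8 CTRL-only peptides; 10%
missing observations; digestion after R only with ≤ 3 missed cleavages and
the semi-specific N-terminal peptide.

Negative selection is modeled as independent Bernoulli events: blocked
N-terminal peptides survive with probability 1, and each free tryptic
peptide is captured by the polymer with probability 0.85 (the *retention*
parameter — the fraction of free-amine peptides the polymer retains, which
is what the selection efficiency of a TAILS experiment measures). The
measured capture fraction therefore converges to 0.85, while the pooled
POSTsel/PREsel peptide ratio is lower because blocked peptides are a
minority of the PREsel identifications. No polymer-saturation or
peptide-property effects are modeled.

What the generator does **not** emulate: retention-time/charge-dependent
detectability, isotopic envelope interference, ratio compression, protein
groups sharing peptides, sequence-dependent digestion kinetics, or a
mitochondria-enrichment step (PRE and POST draw from the same proteome, so
the mitochondrial-fraction enrichment statistic is exercised on
constructed inputs rather than end-to-end). Passing tests therefore show
the estimators are correct under the stated sampling model, not that they
are robust to every artifact of real LC-MS/MS data.

All randomness flows from one integer seed through `numpy`'s Generator;
outputs are byte-identical across reruns of the same seed.

## Problem sizes

The test suite and the acceptance script use 120–400-protein simulations
(≈ 12 000–35 000 observations, ≥ 500 cleavage windows for motif recovery,
≥ 1 000 Bernoulli outcomes for retention), sizes at which the binomial
confidence intervals quoted in the tests are a few percent wide and the
whole suite runs in well under a minute.

## Known limitations

* Qualitative (condition-only) calls carry no p-value, mirroring the
  threshold-based design; a presence/absence test could be added.
* The internal-peptide MEROPS search is emulated with packaged toy
  profiles; scores are comparable within a profile set only.
* Novel transit-peptide proposal trusts the mitochondrial-reference flag;
  it performs no sequence-based presequence prediction.
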
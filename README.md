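# mitotails

Analysis pipeline for **dimethylation-TAILS N-terminomics**: quantifying
protein N-terminal peptides across isotope-label-swap replicates,
classifying every observed N-terminus against processing annotation, and
deriving cleavage-consensus motifs and candidate proteases.

## The problem

TAILS (Terminal Amine Isotopic Labeling of Substrates) blocks all primary
amines by reductive dimethylation — light (+28.03 Da) in one condition,
heavy (+34.06 Da) in the other — digests the pooled sample with trypsin
(effectively ArgC specificity, since dimethylated lysines are uncut), and
removes the free-amine tryptic peptides with a reactive polymer (*negative
selection*). What survives is the N-terminome: mature protein N-termini,
N-termini exposed by mitochondrial transit-peptide (mtTP) removal, and
*neo*-N-termini created by unannotated proteolysis. Comparing channel
intensities across a label-swap replicate design reveals which proteolytic
events respond to a treatment; the residues flanking each cleavage site
(P10…P1↓P1′…P10′) reveal which proteases are responsible.

`mitotails` implements the computational half of this workflow downstream of
the database search:

* **Label model** — exact monoisotopic dimethyl deltas from atomic masses
  (light +2 C + 4 H = 28.0313 Da; heavy +2 ¹³C + 4 ²H = 34.0631 Da) and
  peptide mass accounting.
* **Differential quantification** — per-replicate log₂(DA/CTRL) ratios from
  XIC areas, oriented by each replicate's light/heavy labeling; a peptide is
  *over*/*under*-represented when |mean log₂| ≥ log₂(1.5) = 0.58 with a
  two-tailed one-sample *t*-test *p* < 0.05 and at most two missing
  replicates of seven, and *condition-only* when detected exclusively in one
  channel in at least five replicates. Exposed as a statsmodels-style
  `DifferentialAbundance` model whose `fit()` returns results with a
  `summary()` table.
* **N-terminus classification** — exact substring mapping of each peptide
  onto its protein, then classification of the start position P1′ as
  natural / Met-removal / mtTP-removal / ragging (±1–2 residues around the
  processing site) / propeptide-removal / internal, with proposal of novel
  transit-peptide removal sites from recurrent internal N-termini.
* **Terminome statistics** — negative-selection recovery
  R = #peptides POSTsel / #peptides PREsel, PRE/POST protein overlaps,
  mitochondrial-reference fractions with a paired *t*-test, and reference
  coverage.
* **Cleavage motifs** — position frequency matrices over the 20-slot
  cleavage window, per-slot information content (log₂20 − H bits), a
  consensus string, and MEROPS-style log-likelihood-ratio scoring of
  candidate protease specificity profiles.
* **Synthetic experiments** — a generator producing complete PREsel/POSTsel
  tables with full ground truth (transit peptides, cleavage motif, ragging,
  retention, fold-changes, label swap, missing values), so every stage is
  testable without raw mass-spectrometry data.

## Worked example

Simulate a 150-protein experiment over seven label-swapped replicates and
run the full pipeline:

```python
from mitotails.pipeline import run_pipeline
from mitotails.simulate import SimulationConfig, simulate_study

exp = simulate_study(SimulationConfig(n_proteins=150, seed=1))
res = run_pipeline(exp.pre + exp.post, exp.proteins, exp.design)
print(res.consensus)
print(res.differential.summary())
```

prints (abridged):

```
.......RRR↓AS........
Differential N-terminal peptide abundance (DA vs CTRL)
========================================================
replicates: 7   max missing: 2
fold-change threshold: 1.5 (|log2| >= 0.58)   p < 0.05
peptides analysed: 1450
--------------------------------------------------------
  over                     20
  under                    12
  da_only                   7
  ctrl_only                 7
  not_significant         144
  insufficient_data      1260
```

The consensus line is the cleavage motif recovered from the 171 processed
N-termini: arginines at P3–P1 and Ala-Ser after the cut (the `↓`), the
signature of mitochondrial presequence processing. The class counts
recover the injected truth: 30 peptides carried true 1.5×/2× up-shifts and
15 a 0.5× down-shift (the 2× peptides are called essentially always, the
1.5× ones — sitting exactly on the fold-change gate — about a third of the
time), and 16 peptides were condition-exclusive. Ranking the packaged
protease specificity profiles over the same windows puts the
mitochondrial-processing-peptidase-like profile (Arg at P2) first:

```
protease_id  mean_score  n_windows
    M16.003        2.66        171
    S1C.002       -0.89        171
    M13.001       -1.71        171
```

The same analyses are available from the shell:

```bash
mitotails simulate --seed 1 --out sim/
mitotails run --peptides peps.tsv --fasta prot.fasta \
              --annotations ann.tsv --design design.tsv --out out/
mitotails fixtures --which table2
```

## Documentation

`docs/methods.md` describes the statistical model, the synthetic-data
generator and every numerical choice in detail.
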
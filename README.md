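# hmolocus

Genome mining of human-milk-oligosaccharide (HMO) utilization loci in
SGB-structured bacterial genome cohorts.

## The problem

Butyrate-producing Clostridiales such as *Roseburia* carry gene clusters
that let them degrade HMOs and related host glycans. The canonical locus
combines a **GH112** glycoside hydrolase (the GNB/LNB phosphorylase that
splits galacto-/lacto-*N*-biose), the two-subunit **GH136**
lacto-*N*-biosidase (**GH136_I** + **GH136_II**), an ABC transporter
(solute-binding protein **SBP** and permeases **PP**), a transcriptional
regulator and a sensor histidine kinase. Surveying thousands of
reconstructed genomes binned into species-level genome bins (SGBs) for
these loci answers two ecological questions: which lineages can attack
complex host glycans directly (*primary degraders*: GH112 **and** at
least one GH136 subunit), and which can only consume the released
disaccharides (*secondary degraders*: GH112 only)?

`hmolocus` implements that survey as a tested, reusable pipeline for
anyone mining annotated genome collections for syntenic gene clusters:

1. **Homolog search** — every gene is aligned against labelled family
   references; a gene is assigned to family *F* when its best global
   percent identity to any reference of *F* reaches a threshold
   (default 70%). Identity is `100 · matches / alignment columns` under a
   fixed scoring (match +1, mismatch 0, linear gap −1).
2. **Locus calling** — a genome yields one locus per GH112 gene provided
   it also carries ≥ 1 GH136 subunit; genome-level co-occurrence drives
   the primary/secondary/none degrader classification.
3. **Gene landscapes** — the *n* genes up- and downstream of each GH112
   anchor (default *n* = 11) are encoded as a token string over a
   controlled vocabulary (family tokens, keyword-derived tokens such as
   SBP/PP/TransR/HisK/HP, and OTHER), orientation-normalized so the
   anchor always reads 5′→3′.
4. **Comparison** — landscapes are compared with the **optimal string
   alignment (OSA)** distance (restricted Damerau–Levenshtein: unit-cost
   insertion, deletion, substitution and adjacent transposition, no
   substring edited twice), computed over gene tokens. The distance
   matrix is ordinated by **principal coordinates analysis** (classical
   scaling of −½·J·D²·J with negative eigenvalues clamped and reported —
   OSA violates the triangle inequality, so a perfect Euclidean embedding
   need not exist). The most frequent landscape per SGB is selected as
   that SGB's representative.
5. **Prevalence report** — genome-level family counts and fractions,
   globally and per SGB (a genome counts once per family regardless of
   paralogs; "GH136" means ≥ 1 subunit), plus prevalence ratios and the
   degrader-category contingency table.

Because the original reconstructed-genome collection is not
redistributable at desk scale, the package ships a first-class
**synthetic cohort generator** (`hmolocus.synthetic`): SGB-structured
genomes with planted loci at controlled percent identity to synthetic
references, controlled fractions of GH112-only and locus-free genomes,
random locus strand, and one-step neighborhood rearrangements — all with
recorded ground truth, so recovery can be measured exactly.

## Worked example

The numbered scripts under `analysis/` run the whole study on the default
synthetic cohort (120 genomes, 5 SGBs, planted identities 80–95%, 15%
GH112-only, 10% without locus, rearrangement rate 0.3):

```bash
python analysis/01_simulate_cohort.py      # writes results/cohort/
python analysis/02_search_homologs.py      # results/run/hits.tsv
python analysis/03_call_loci.py            # loci.json, degraders.tsv
python analysis/04_landscapes_ordination.py
python analysis/05_prevalence_report.py
```

With the default seed (1) this prints, among other things:

```
planted: 95 primary degraders, 15 GH112-only (secondary), 10 without locus
931 hits across 110 genomes at >= 70.0% identity
95 loci (GH112 anchor + >=1 GH136 subunit)
PCoA: top-2 axes carry 90.1% of the positive eigenvalue mass; 44 negative
      eigenvalues clamped (OSA is non-Euclidean)
representative landscape per SGB:
  SGB_01: TransR SBP PP PP GH136_I GH136_II GH112 HisK
  SGB_02: TransR SBP PP PP GH29 GH95 GH136_I GH136_II GH112 HisK
GH112 is 1.16x as prevalent as GH136 globally
degrader categories match ground truth for 100.0% of genomes
```

Reading: all 95 planted primary-degrader loci are detected (GH112 genes in
the 15 secondary genomes correctly yield no locus), every SGB's
representative landscape is the planted template, and the GH112:GH136
prevalence ratio of 110/95 = 1.16 reflects the 15 GH112-only genomes —
the degrader-signature logic the survey is built to expose.

The same pipeline runs from the shell on any cohort via the `hmolocus`
CLI (`simulate`, `search`, `loci`, `landscape`, `compare`, `report`, and
`run` for the whole chain); see `hmolocus --help`.

## Layout

```
src/hmolocus/     library: synthetic, homology, locus, landscape,
                  compare, prevalence, io, pipeline, cli
analysis/         numbered narrative drivers writing under results/
tests/            pytest suite (unit, property and end-to-end recovery)
scripts/          acceptance.py
docs/methods.md   models, parameters, numerical choices, limitations
```
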
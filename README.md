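# splicepriors

Clinical sequencing of high-risk susceptibility genes such as *BRCA1* and
*BRCA2* turns up many variants of uncertain significance — mostly rare
missense substitutions and nucleotide changes near the splice junctions of
the coding exons.  The Bayesian "integrated evaluation" of such variants
starts from a sequence-analysis prior probability of pathogenicity and
updates it with observational likelihood ratios (segregation, co-occurrence,
family history, tumor pathology).  `splicepriors` implements the
**spliceogenicity** component of that prior: it scores how a variant damages
a native splice junction or creates a de novo junction, standardizes the
scores, maps them through calibrated qualitative categories to priors, and
combines them with missense priors and expert-knowledge ceilings into a
single selected prior — plus the supporting statistics used to build and
check such calibrations.

## What it computes

**Splice-fitness scores.** Donor sites are scored as 9-mers (junction
between positions 3|4), acceptors as 23-mers (junction between 20|21), in
log2-odds bits.  Two backends satisfy the same scoring contract: a
self-contained position-weight-matrix scorer (trainable, used by the
synthetic fixtures), and a maximum-entropy table scorer that reads the
published MaxEntScan `splicemodels` directory layout, combining the
canonical-dinucleotide consensus probabilities with the joint
maximum-entropy tables (donor: one 7-mer table; acceptor: nine overlapping
marginal tables combined as s₀s₁s₂s₃s₄ / s₅s₆s₇s₈).

**Native damage.**  A variant overlapping a junction window is scored in the
junction's fixed frame, wild-type and mutant; both scores are standardized
as z = (s − μ)/σ against reference wild-type junction statistics (defaults:
donors μ = 8.02, σ = 2.31; acceptors μ = 7.98, σ = 2.44; n = 110 each) and
categorized:

| category | donor | acceptor | prior |
|----------|-------|----------|-------|
| improved | z_alt > z_ref | z_alt > z_ref | 0.04 |
| minimal  | z > 0 | z > 0.5 | 0.04 |
| moderate | −2 ≤ z ≤ 0 | −1.5 ≤ z ≤ 0.5 | 0.34 |
| high     | z < −2 | z < −1.5 | 0.97 |

A *protection rule* keeps variants in already-weak junctions (acceptor
wild-type z < −1.0, donor z < −1.5) out of the high category unless they
drop the z-score by ≥ 0.5.

**De novo donors.**  A k-wide window slides across the variant-bearing
sequence so the variant occupies every window position; the best frame
(native-junction frames excluded) is standardized and binned — weak/null/low
z < −2 (prior 0.02), moderate −2 ≤ z < 0 (0.30), increased z ≥ 0 (0.64).  A
de novo donor scoring above the exon's own wild-type donor is *promoted* one
category.  The category prior applies only when using the new donor would
frameshift the transcript or delete part of a key functional domain;
otherwise the variant keeps the baseline exonic prior of 0.02.  De novo
acceptors are reported (score and z) but carry no prior.

**Combination.**  The selected prior is the maximum of the native, de novo
and (externally supplied) missense priors, then initiator-codon overrides
and configured region ceilings (e.g. a 0.50 cap, optionally restricted to
the splice channel) are applied, with an audit trail of every rule that
fired.

**Supporting statistics.**  The enrichment ratio for single-nucleotide
substitutions ERS(c) = (o_c/p_c)/(o_s/p_s) with context-dependent relative
substitution rates and a trend test across ordered score bins; the
heterogeneity likelihood ℓ(α) = Σ_v ln(α·LR_v + 1 − α) with profile 95%
confidence intervals and nested-partition likelihood-ratio tests; exact
(Clopper–Pearson) binomial proportions including the add-one-discordant rule
for 0/n and n/n tables; and the Bayesian posterior with five-tier (IARC)
classification.

## Worked example

The package ships a deterministic synthetic toy-gene generator so the whole
pipeline runs offline.  The fixture plants a de novo donor site, a canonical
GT disruption and a verified-neutral SNV, and records what each should
produce:

```python
import splicepriors as sp

fx = sp.generate_toy_gene(seed=7)
og = fx.oriented()
for s in fx.truth:
    ann = sp.assess_variant(og, s.variant, fx.models, fx.stats)
    print(s.hgvs_c, ann.priors.selected_prior, ann.priors.applied_rules)
```

prints (abridged):

```
c.72T>A    | de novo donor: increased  z=2.16  prior=0.64 | selected: 0.64
c.36+1G>A  | native: high  z_ref=2.16  z_alt=-2.59        | selected: 0.97
c.7T>A     | de novo donor: weak_null_low  z=-4.73        | selected: 0.02
```

`c.72T>A` completes a planted near-consensus donor 9-mer: its best scan
frame standardizes to z = 2.16 (≥ 0, "increased"), the implied junction
would frameshift the exon, so the variant receives the 0.64 de novo donor
prior.  `c.36+1G>A` destroys the canonical GT of a native donor (z falls
from 2.16 to −2.59, "high", prior 0.97).  The neutral SNV creates no frame
above z = −2 and keeps the 0.02 baseline.  Downstream, a prior of 0.81
combined with a segregation likelihood ratio of 234:1 gives

```python
sp.classify(0.81, [234.0])   # posterior 0.999, class 5 (pathogenic)
```

A command-line interface mirrors the library: `splicepriors fixture`,
`score`, `annotate` (VCF in/out with `SPLC_*` INFO tags), `bulk` (priors for
every possible SNV of the in-scope region), `calibrate`, `hetlr`,
`posterior`.

## Layout

```
src/splicepriors/
  splice_fitness.py   # k-mer scoring backends (weight matrix, maxent tables)
  gene_model.py       # gene/transcript models, variants, coordinate maps
  window_scan.py      # native-junction scoring and the sliding-window scan
  calibration.py      # z-scores, categories, priors, combination rules
  ers.py              # enrichment ratio for SNVs + trend test
  heterogeneity.py    # alpha estimation, partition tests, exact binomials
  posterior.py        # Bayesian update and five-tier classification
  synthetic.py        # deterministic toy-gene fixture generator
  hgvs.py             # restricted HGVS c. parser/formatter
  annotate.py         # per-variant assessment, VCF annotation, bulk tables
  cli.py              # click CLI
```
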
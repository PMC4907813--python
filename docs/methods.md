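# Methods

## Scoring model

Splice-fitness scores are log2-odds ("bits") of a fixed-length window being
a functional splice site: donors are 9-mers with the exon|intron junction
between window positions 3 and 4 (three exonic, six intronic bases),
acceptors 23-mers with the junction between positions 20 and 21 (twenty
intronic, three exonic).  Two backends implement the scoring contract.

**Weight matrix.**  `score = Σ_i log2(P_i(b_i) / Q(b_i))` over window
positions, with per-position probabilities `P` and a background nucleotide
distribution `Q` (uniform by default).  Rows must sum to 1 within 1e-9 and
all cells must be positive; training uses add-pseudocount estimation
`(count + c) / (n + 4c)` with `c > 0`.  Scores are exactly additive over
positions, which the tests exploit.

**Maximum-entropy tables.**  The scorer reads the published `splicemodels`
table layout.  For donors the two canonical positions (+1 G, +2 T) are
scored by consensus/background probability ratios and the remaining 7-mer
is looked up in the joint maximum-entropy ratio table (`me2x5`, 4^7
entries, lexicographic A<C<G<T order).  For acceptors the canonical AG is
scored the same way and the remaining 21-mer is scored by nine overlapping
marginal tables (`me2x3acc1..9` over fragments 0–6, 7–13, 14–20, 4–10,
11–17, 4–6, 7–10, 11–13, 14–17) combined as `s0·s1·s2·s3·s4 /
(s5·s6·s7·s8)`, computed in log space.  The consensus and background
constants default to the reference scorers' published values
(background 0.27/0.23/0.23/0.27; donor +1 G 0.9896, +2 T 0.9884; acceptor
A 0.9903, G 0.9930 with the residual mass spread evenly over the other
bases — the acceptor minors are not published at full precision); a
`consensus.json` file in the model directory overrides them.  Table files
are validated (length, finiteness, non-negativity) at load, with the
offending file named in the error.  The model tables themselves are not
bundled; the loader and scorer are exercised on synthetic table sets in the
same format, checked against independent in-test arithmetic.

Lowercase input is uppercased; any non-ACGT character is an error.  Only
defined reference k-mers are scored — there is no N tolerance.

## Coordinates and variant application

All I/O (gene config, VCF, HGVS c.) is 1-based; internal coordinates are
0-based half-open.  All scoring happens in transcript orientation: a
minus-strand gene is reverse-complemented once when its oriented view is
built.  Variant application returns a coordinate map that is total,
monotone and bijective off the edited interval; junction coordinates are
mapped with *boundary* semantics (a junction is the point between two
bases), so an SNV at the +1 intronic position does not displace the
junction it sits beside.

The analysed ("in-scope") region is each exon plus 20 intronic bases
upstream and 6 downstream.  Scope is a property of every exon including the
terminal ones, which makes a 2-exon gene with 30-bp exons contribute
3 × (60 + 2×26) possible SNVs to the bulk table.

## Native damage channel

A variant overlapping a junction window (donor: last 3 exonic + first 6
intronic bases; acceptor: last 20 intronic + first 3 exonic) is scored in
the window's fixed frame, wild type and mutant, and both scores are
standardized against reference wild-type junction statistics computed
separately for donors and acceptors (sample mean and n−1 SD; degenerate
score sets are rejected).  The shipped defaults are the reference-set
values for the BRCA/ATM canonical exons: donors 8.02 (2.31), acceptors 7.98
(2.44), n = 110 each.

Categories follow the calibrated z bins with the moderate stratum closed at
both ends (donor −2 ≤ z ≤ 0; acceptor −1.5 ≤ z ≤ 0.5); a score improvement
over the reference is its own category.  The protection rule (acceptor
wild-type z < −1.0 or donor < −1.5 requires Δz ≥ 0.5 for "high") demotes to
moderate, the mildest category consistent with "kept out of high".
Canonical GT/AG variants flow through this same channel — they score as
severe damage without a special case.

## De novo donor channel

The scan scores every k-mer of the variant-bearing sequence that contains
the edit (for an SNV, exactly k frames with the variant walking from window
position 1 to k; for indels, every k-mer overlapping the edited interval —
the enumeration choice is ours, as frame counting for indels is otherwise
unspecified).  Frames whose implied junction coincides with a native
junction are excluded from the maximum so native damage and de novo
creation stay separate channels; ties break toward the smallest frame
offset.  The best frame's z is binned (weak/null/low z < −2, moderate
−2 ≤ z < 0, increased z ≥ 0) and promoted one step — never two, never past
"increased" — when it exceeds the z of the exon's own wild-type donor.

The category prior (0.02 / 0.30 / 0.64) applies only when the implied
junction is exonic and using it would either frameshift the transcript
(deleted span to the native donor not a multiple of 3) or delete part of a
configured key functional domain; otherwise the variant keeps the baseline
exonic prior 0.02.  Variants within 3 bp of an exon end keep native
analysis but receive no de novo donor prior, mirroring the calibration's
exclusion of near-junction substitutions.  De novo acceptors are reported
(best score, z) without a prior: no category of potential de novo acceptors
showed evidence of increased risk, so deriving a prior from them would be
unsupported.

## Priors and combination

Category priors are adopted as calibrated constants (native 0.04 / 0.04 /
0.34 / 0.97; de novo 0.02 / 0.30 / 0.64; baseline exonic 0.02); the
near-zero strata use the midpoint-of-CI reassignment (point estimates
≤ 0.01 become (low+high)/2) because a prior of exactly 0 cannot enter a
Bayesian update.  The selected prior is the maximum over native, de novo
and missense components; then an initiator-codon override (default 0.97,
configurable — published external work suggests 0.96 for some initiator
variants) and region ceilings apply.  Ceilings are configuration data, not
hard-coded coordinates; a ceiling can apply to all channels or to the
splice channel only, in which case a missense/truncation prior for the same
variant is never capped.  Terminal-exon flank positions that overlap no
junction window and are intronic (hence carry no de novo donor prior)
receive the baseline exonic prior as the splice-channel floor, so every
in-scope row of the bulk table has a defined selected prior.  Reported
priors and z-scores round half-up to 2 decimals; VCF float tags are fixed
at 3 decimals.

## ERS

`p_c = Σ_{i∈c} r_i / Σ_i r_i` over all possible SNVs of the target
sequence, with context-dependent relative rates keyed by the flanking
dinucleotide context (with a context-free fallback), optionally
strand-symmetrized by averaging each context with its reverse complement.
`ERS(c) = (o_c/p_c)/(o_s/p_s)` normalizes by the silent class; it is
invariant to rescaling the whole table and equals 1 for the silent class
itself.  The published context-rate constants are not reprinted anywhere we
can bundle, so the module reads any user-supplied rate TSV and ships two
built-ins for testing (uniform; a toy CpG-transition-aware table).  Class
cleaning assigns each SNV to exactly one class by precedence, so
likely-spliceogenic substitutions are withdrawn from otherwise-neutral
classes.  The trend test is a Cochran–Armitage-style score test on observed
counts across ordered bins (statistic `U = Σ_b b·o_b` standardized under
the multinomial null implied by the expectations), with an optional
multinomial-permutation p-value; the original analysis does not name its
test, so this choice is documented rather than asserted as identical.

## Heterogeneity likelihood

Each variant in a stratum contributes `α·LR_v + (1 − α)` to the likelihood;
the per-variant observational LRs are consumed as data (the family-history
LR lookup tables derive from proprietary summary histories).  α̂ maximizes
the log likelihood on [0,1]: a 201-point grid locates the mode, a bounded
scalar minimization refines it to 1e-6, and the hard boundaries are checked
explicitly since the likelihood need not be concave (every test fixture is
verified against a 1e-4-grid brute force).  Profile 95% bounds are found by
bisection on each side of α̂ at a log-likelihood drop of χ²₁,₀.₉₅/2 =
1.9207, clipped at 0 and 1; a flat likelihood (all LRs ≈ 1) is flagged
unidentifiable with CI (0,1).  Nested partitions are compared with
χ² = 2(lnL_fine − lnL_coarse), df = difference in group counts.

Exact binomial proportions use Clopper–Pearson beta quantiles.  For
degenerate 0/n or n/n tables the add-one-discordant rule recomputes only
the non-degenerate bound after adding one observation of the zero-count
outcome; the reported proportion stays x/n and the degenerate-side bound
stays at the boundary (matching the printed 100.0 (88.0–100.0) behavior of
a 43/43 table).

## Posterior and classification

Posterior odds = prior odds × Π LR, computed in log-odds space with an
exact (fsum) reduction so the update is order-invariant and immune to
overflow; priors of exactly 0 or 1 are rejected.  The five-tier class
cut-points are configuration (defaults: 5 for p > 0.99, 4 for
0.95 ≤ p ≤ 0.99, 3 for 0.05 ≤ p < 0.95, 2 for 0.001 ≤ p < 0.05, 1 below;
the source scheme does not print its boundary handling, so the printed
interval endpoints are taken as inclusive).  An observational-data
sufficiency gate flags combined LRs inside (0.5, 2) as too uninformative
for a valid integrated evaluation.

## Synthetic fixture

The toy-gene generator emulates the features the pipeline depends on: a
multi-exon gene with consensus-like donor (CAGGTAAGT-type) and acceptor
(polypyrimidine + AG) junction windows; weight matrices whose canonical
GT/AG positions carry near-deterministic probability (0.9995) regardless of
the `junction_strength` scaling of the other positions — as with real
maximum-entropy models, losing the canonical dinucleotide is catastrophic
relative to the wild-type score spread, which is what makes the "high"
category reachable; reference statistics from 110 sampled wild-type-like
junctions (canonical positions held fixed, as in real wild-type junction
sets); and a truth table whose expected categories are verified at
generation time by direct matrix arithmetic, independent of the scan
machinery — generation fails loudly if a spike cannot be verified.  With
`junction_strength = 0` the matrices are flat, junctions score at
background, and the fixture is flagged unusable for calibration.

What the fixture does **not** emulate: real maximum-entropy dependency
structure between positions (the matrices are positionally independent),
realistic exon/intron lengths, branch points, splice enhancers/silencers,
and the empirical score distributions of real genes.  Passing tests on the
fixture therefore demonstrate the correctness of the machinery (windows,
scans, z-standardization, rules, combination), not the clinical accuracy of
the calibrated priors on real data.

## Problem sizes and numerical choices

The test and acceptance workloads are sized for quick desk-scale runs: 200
simulated variants for α recovery (true α = 0.3, three carriers per
variant, per-carrier LR 4 or 0.25), 1,000 random variants for
scan-vs-enumeration equivalence, 10,000 draws for the ERS null check, and
5,000 replicates per cell of the Clopper–Pearson coverage grid
(p ∈ {0.1, 0.5, 0.9} × n ∈ {20, 100}).  All randomness flows through
seeded `numpy` generators; regeneration from the same seed is
byte-identical.

## Known limitations

* The calibration constants are adopted, not re-estimated; the family-level
  data behind them are proprietary.
* De novo junctions deeper than the −20..+6 proximal windows, multi-isoform
  reconstruction, branch points and exonic splice enhancers are out of
  scope.
* The HGVS parser covers only the subset the pipeline consumes (SNVs,
  simple del/dup/ins with intronic offsets); everything else raises an
  explicit unsupported-expression error.
* MaxEntScan-format conformance is validated structurally on synthetic
  table sets; bit-level agreement with a particular published model file
  set can only be checked against the files a user supplies.
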
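# Methods

## Study design being emulated

The pipeline targets a SILAC experiment comparing a gene-deficient cell
line against a heterozygous control in four biological replicates with
label swapping: in forward replicates the heavy channel carries the
deficient condition, in reverse replicates the control. A reverse
replicate's raw log2(H/L) therefore carries the opposite sign of the
biological effect and is negated during orientation. The quantification
unit throughout is the (protein, residue position, phosphorylation
multiplicity) row of a MaxQuant-style site table; distinct multiplicity
forms of one site are distinct units. All ratios are stored linear on
disk and log2-transformed only inside the differential stage; positions
are 1-based; gene symbols are matched exactly and case-sensitively.

## Differential calling

1. **Localization filter.** Only class I sites enter: localization
   probability ≥ 0.75, inclusive. The inclusive rule is a deliberate
   choice where the two plausible readings (≥ vs >) differ only at the
   boundary; an `inclusive=False` flag switches to strict. Filtering
   precedes normalization, so the medians and MADs are computed on the
   class I table.
2. **Normalization.** Per replicate column, over quantified cells only:
   robust z = (x − median)/MAD with the *raw* MAD (no 1.4826
   normal-consistency factor), matching a literal
   "scaled for median absolute deviation"; `mad_scaled=True` enables the
   scaled variant. A zero MAD raises a degenerate-scale error naming the
   replicate rather than producing infinities.
3. **Calling rule.** Status *up* requires z ≥ +τ in at least r_min
   replicates and **zero** replicates with z ≤ −τ (symmetric for
   *down*). The opposite-direction veto means a sign-conflicted unit is
   *unchanged* rather than regulated, which prevents reporting a
   direction the replicates contradict. Units with fewer than r_min
   quantified replicates are *insufficient_data* and never regulated.
   Defaults: τ = 2 (phosphosites), τ = 2.5 (proteins), r_min = 3.

**Concordance classes.** Genes with ≥ 1 regulated phosphosite are
classified against the protein-level call: up_both, up_phospho_only,
down_phospho_only, down_both, discordant (opposite signs across levels,
or both up- and down-regulated phosphosites within the gene), other.
For gene-level enrichment, a gene with both up and down sites is a
member of both direction sets.

## Kinase activity (KSEA)

z = (s̄ − p̄)·√m/δ, where s̄ averages the mean oriented log2 fold change
of the kinase's contributing substrate units, and p̄, δ are the mean and
*sample* (n−1) standard deviation over all quantified units. Two-sided
normal p; BH q across scored kinases. Choices made where the procedure
is underdetermined:

* contributing units default to **regulated substrates only** (the
  emulated analysis averages the regulated phosphopeptides);
  `regulated_only=False` gives classical all-quantified-substrate KSEA;
* sample standard deviation and two-sided p, because inferred activity
  may move either way;
* curated and predicted kinase-substrate relationships are scored in
  separate runs, never pooled;
* each multiplicity form of a matched site contributes once.

Under the null (substrate sets drawn uniformly from quantified units)
the statistic is very close to standard normal because each unit's mean
fold change is itself near-Gaussian; the acceptance suite checks the
p < 0.05 rate and the z moments directly, and a substrate-label
permutation p agrees with the normal approximation within 2× down to
p ≈ 0.01.

## Enrichment

* **Over-representation.** One-sided Fisher's exact test, implemented as
  the upper-tail hypergeometric survival function; background = all
  quantified genes at the relevant level (protein table for TFs, phospho
  table for terms). Terms overlapping the regulated set in fewer than 3
  genes are excluded before testing. Selection uses raw-p thresholds
  (0.01 terms, 0.05 TFs) for fidelity to the emulated workflow; BH q is
  reported alongside.
* **Ranked list.** Per gene: the fold change of maximal absolute value
  among its regulated peptides (exact |·| ties resolve to the positive
  value); genes without a regulated peptide fall back to their highest
  fold change. Cross-gene ties order by larger metric then gene name, so
  the list is strictly ordered and deterministic.
* **GSEA.** Weighted KS running sum: hits increment by |metric|
  normalized over the in-set |metric| sum, misses decrement by
  1/(N − n_hits); ES is the signed maximal deviation. Significance is by
  random same-size gene-set permutation (the pre-ranked mode has no
  phenotype labels to permute) with add-one correction,
  p ≥ 1/(n_perm+1); default n_perm = 1000, weight exponent 1.
* Enrichment-map construction is reduced to a pairwise Jaccard-overlap
  edge table among significant sets; layout is out of scope.

## Networks

The integrated network retains interaction edges with **both** endpoints
eligible (regulated phosphoprotein or significant TF); a bridging flag
relaxes to one endpoint. Isolated eligible nodes are dropped by default.
The kinome network includes kinases with ≥ 1 regulated substrate and
those substrates, with kinase→substrate edges labeled by site and
direction and high-confidence interaction edges (default confidence
≥ 0.7, a STRING-like convention) added among included nodes. Community
detection is deterministic greedy modularity maximization
(Clauset–Newman–Moore via networkx) with communities numbered by size
then lexicographic smallest member — chosen for reproducibility over
fidelity to any particular plugin implementation.

## Synthetic study generator

The generator produces the full input surface with known ground truth.
Defaults encode the emulated study's structure:

| parameter | default | rationale |
|---|---|---|
| n_sites | 8000 | study-scale site count |
| n_proteins | 2600 | study-scale protein count |
| frac_class1 | 0.83 | class I fraction |
| multiplicity_probs | 0.87/0.11/0.02 | singly/doubly/triply phosphorylated |
| frac_regulated | 0.05 | ~400 regulated units at study scale |
| frac_up | 362/582 | up:down balance of regulated units |
| effect_log2 | 1.2 | mean \|log2 effect\|, truncated at 0.5 |
| noise_sd | 0.25 (log2) | replicate noise; see calibration note |
| missing_rate | 0.05 | completely-at-random missingness per cell |

Observed replicate values are orientation_sign × (μ + N(0, noise_sd)),
with μ the signed planted effect (0 for null units). Localization
probabilities come from a two-component mixture (mass near 0.97 for
class I, below 0.75 otherwise). Effect magnitudes are
Normal(effect_log2, 0.2·effect_log2) lower-truncated at 0.5, with a
frac_up share positive.

Three deliberate generator choices:

* **Regulated units are planted among class I sites only.** The
  differential stage discards sub-threshold-localization sites before
  normalization, so signal planted there would be unrecoverable by
  construction; recovery metrics are meaningful only over the analyzable
  stratum. The count contract (round(frac_regulated × n_sites) regulated
  units) is unchanged.
* **Protein-level ground truth.** The ground-truth object carries a
  regulated-protein map generated the same way (fraction
  frac_regulated_proteins), because TF-target recovery and concordance
  classes are defined over protein-level calls.
* **Noise calibration.** The source workflow reports no noise model;
  noise_sd = 0.25 is a calibration choice, not a claim about the real
  data's variance structure.

Annotations: each active kinase draws an `enrichment_strength` fraction
(default 1.0) of its substrates from regulated units sharing its planted
sign, the remainder uniformly; inactive kinases draw uniformly, so their
substrate regulated-fraction matches frac_regulated in expectation.
Predicted KSR rows cover every kinase; rows pointing at regulated units
are additionally emitted as curated with probability 0.5 so the curated
kinome network has a non-trivial core. Active TFs behave analogously
over regulated proteins' genes. Gene sets include one set concentrated
at the top of the true-effect ranking, one uniform set, and random
decoys. The interactome is a stochastic block model (p_within = 0.2,
p_between = 0.02, four blocks totalling 282 nodes spanning TFs,
regulated phosphoprotein genes, and filler genes) with Uniform(0.5, 1)
edge confidences.

**What the generator does not emulate** — and hence what passing tests
do not show about real data: intensity-dependent variance, peptide-level
interference and co-elution, informative missingness, correlated sites
within a protein, MaxQuant's internal peptide grouping (the paper-scale
distinction between phosphopeptides and sites), and cross-species
identifier mapping. Recovery rates on the generator are upper bounds on
what identically parameterized real data would give.

## Numerical and determinism choices

* All randomness descends from one seed via `numpy.random.SeedSequence`
  children, one per stage, so any stage can be re-run in isolation with
  identical results; derived seeds stay below 2³¹.
* Output TSVs are sorted by all columns before writing; reruns with the
  same config are byte-identical (checked by checksum in the manifest).
* Ratios that are empty, non-numeric, zero or negative are treated as
  not quantified; missing values are written back as empty cells.
* Degenerate inputs fail loudly: zero MAD, zero background dispersion,
  a gene set covering the whole ranked list, an empty network.

## Problem sizes used in the checks

The acceptance checks run the generator at its full default scale
(8,000 sites, 2,600 proteins), 1,000 null kinases for calibration,
1,000 GSEA permutations, and a 20+20-node planted-partition graph for
community recovery; the oracle-equivalence checks use 200 random tables
of ≤ 50 units (differential calls) and ≤ 60 background genes (Fisher).

## Known limitations

* The normal-approximation KSEA p is anti-conservative for very small
  substrate sets (m ≤ 3) when the fold-change distribution has heavy
  tails; the permutation cross-check covers moderate p only.
* Greedy modularity has a resolution limit; very small planted blocks
  inside a large network may merge.
* No missing-value imputation or limma-style moderated testing; the
  calling rule is the threshold rule described above.
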
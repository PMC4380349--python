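# Methods

## Model

The classifier is a tree-augmented naive Bayes (TAN) network over a
binary survival class *S* (0 = short, ≤10 months; 1 = long, >10 months)
and *p* discrete attributes *V₁…V_p*. The class is a parent of every
attribute; the attributes additionally form a directed tree, so each
attribute has at most one attribute parent and the joint factorizes as

P(S, V₁…V_p) = P(S) · Πᵢ P(Vᵢ | S, pa(Vᵢ)).

**Structure.** Edge weights are empirical class-conditional mutual
informations I(Vᵢ; Vⱼ | S) in bits (the base cancels in the argmax; bits
are used for interpretability). The attribute tree is the maximum-weight
spanning tree, built by Kruskal's greedy rule over edges sorted by
(weight descending, name pair ascending); the tree is rooted at the
first attribute in schema order and edges directed away from it. The
sort-based tie-break makes the learned structure bit-reproducible and
invariant to record order. An optional `cmi_threshold` drops edges whose
weight does not exceed the threshold, leaving a forest whose isolated
attributes degrade gracefully to naive-Bayes children of the class —
useful when some attributes are genuinely class-conditionally
independent of all others, which a strict spanning tree cannot express.
The strict tree is the default.

**Parameters.** CPTs are additive-smoothed frequencies,
P(Vᵢ=v | S=s, pa=u) = (n(v,s,u) + α) / (n(s,u) + α·Kᵢ), with α ≥ 0 and
Kᵢ the state count of Vᵢ. The default is α = 0 (maximum likelihood)
because the ML fit preserves every empirical (S, Vᵢ) pairwise marginal
and every tree-edge triple marginal exactly — the property that makes
single-evidence posteriors equal empirical conditional class
frequencies, and hence makes the published importance table
reproducible from class-conditional counts alone. A parent context
never observed at α = 0 receives a uniform distribution (with a
warning); such contexts carry zero model probability, so the marginal
preservation is unaffected. For prediction on new data, or under
cross-validation where unseen contexts do occur with positive
probability, α = 1 is the sensible setting.

**Inference.** All queries are exact. For fixed class state the
attributes form a tree, so the likelihood of any partial evidence is
one upward sum-product pass per tree component; posteriors of the class
or of a free attribute follow by Bayes' rule over at most a few dozen
such passes. With ≤16 variables of ≤4 states this costs microseconds;
no approximation is ever used. Inference is tested exhaustively against
full-joint enumeration (1,000 random model/evidence pairs). Evidence
whose probability is exactly zero raises an explicit error rather than
returning NaN. Classification thresholds are strict: a record is
labeled long-survival iff P(S=1 | record) > t, so a posterior exactly
at the threshold falls to the short-survival class.

## Importance measure

The Fussell–Vesely importance of state *j* of variable *Vᵢ* with respect
to short survival is FV = (P(S=0) − P(S=0|Vᵢ=j)) / P(S=0). Clinical
variables have no designated normal state, so FV is signed. The
composite per-variable measure is MFV = Σⱼ |FV| / (Kᵢ − 1), summing over
**all** Kᵢ states. The divisor Kᵢ − 1 (not the literal "number of
non-baseline states", which is zero-degenerate for binary variables) is
the convention used throughout: binary variables divide by 1,
three-state by 2, four-state by 3, which keeps mixed-arity rankings
comparable and reproduces the published composite values for all 15
variables. Ranks are competition ranks by descending MFV (ties share
the smaller rank; the next rank skips). The Pearson column correlates
the integer state codes of each attribute with the class codes — a
deliberately crude linear benchmark for the rank comparison; for
multistate variables it inherits the code ordering of the schema.

## Evaluation

Accuracy, TPR = TP/(TP+FN), FPR = FP/(TN+FP) and per-predicted-row
reliability (positive/negative predictive value) follow the standard
fourfold definitions; undefined rates (zero denominators) raise rather
than returning NaN. The ROC sweeps all unique predicted probabilities
(scikit-learn's curve with no point dropping) and AUC is the trapezoid
integral, which for a step curve equals the concordant-pair probability
with ties counted one half — the identity the tests assert.
`select_threshold` scans the candidate grid (unique probabilities plus
the 0.0 boundary, which under the strict rule realizes the all-positive
classifier) and returns the smallest accuracy-maximizing threshold.
Evaluation is in-sample by default, matching the workflow the package
reimplements; cross-validation is available through the scikit-learn
estimator interface.

## Synthetic cohorts

The generator's default configuration encodes the published summary
statistics of the 299-patient HCC hepatectomy cohort: class split
0.5017/0.4983 and, for each attribute, the class-conditional state
distributions obtained by Bayes inversion of its published marginal and
short-survival posterior (renormalized, since the published values are
rounded to 3–4 decimals). This automatically calibrates the key
associations — e.g. 84% of PVTT-positive probability mass is
short-survival. Five clinically motivated dependency edges (HBV→HCV,
liver function→complication, PVTT→operative method, tumor
number→metastasis, clamping time→blood loss) are added with a
mean-preserving offset of default strength 0.15: within each class the
child's success probability shifts by +δ(1−q) when the binary parent is
1 and −δq when it is 0 (q the parent's class-conditional success
probability), leaving every class-conditional child marginal — and thus
every published frequency — exactly intact. Offsets are clipped to keep
probabilities in [0.01, 0.99]. Sampling is ancestral (class first, then
attributes in topological order) with numpy's PCG64 generator, so a
fixed seed yields byte-identical cohorts across platforms.

The deterministic `replica_counts_cohort` matches every published
single-variable class-conditional count as integers:
nᵢⱼ = round(pᵢⱼ·299) patients in state j, of whom round(qᵢⱼ·nᵢⱼ) are
short-survival; both sums land exactly on 299 and 150 for all 15
attributes (asserted in code). States are dealt within each class block
by a fixed-seed permutation, keeping attribute pairs roughly
class-conditionally independent so multi-evidence scenarios on the
fixture are non-degenerate. What the replica does *not* carry is the
real cohort's joint dependence structure beyond those margins — it is
unknowable from published single-variable summaries. Consequently,
multi-evidence posteriors (the scenario analyses) are validated as
directional properties (curative resection must beat palliative
resection for PVTT-positive patients, which it does: 0.189 vs 0.038
long-survival posterior on the replica fit), never as numerical
reproductions; and passing tests on synthetic data demonstrate
correctness of the machinery, not clinical validity on real patients.

## Discretization conventions

Intervals are left-closed/right-open with the last interval closed,
with two domain-specific exceptions chosen to make boundaries total and
deterministic: the AFP normal range [0, 8] ng/mL is closed at 8 (the
middle bin is the open interval (8, 400), matching values quoted at
two-decimal resolution), and the short-survival interval is closed at
10 months (10 is short; the 150/149 class split forces this reading).
Tumor size accepts any positive value below 2 cm as the smallest state.
Two age-bin conventions circulate for this cohort (cuts at 46/60 vs
45/60); both are provided (`age_bins="table1" | "table4"`), differing
only in the assignment of age 45. Missing cells are rejected, not
imputed — the conservative contract for a reimplementation with no
stated imputation procedure.

## Problem sizes and numerical choices

The test and acceptance workloads were sized for interactive runs:
brute-force posterior enumeration uses models of ≤6 attributes (joint
arrays ≤ a few thousand cells), exhaustive spanning-tree search runs at
≤5 attributes (≤125 labeled trees via Prüfer sequences), parameter
recovery uses n = 50,000 samples of a 5-attribute chain TAN (CPT
tolerance ±0.01, about 2.5 binomial standard errors at that n), and the
replica comparisons use tolerances of 1.5×10⁻⁴ on priors/posteriors and
5×10⁻⁴ on FV/MFV — the propagation bound for inputs printed at 4
decimals (two published cells are truncated rather than rounded, e.g.
95/160 = 0.59375 printed as 0.5937). CPT columns are validated to sum
to 1 within 10⁻⁹; posteriors likewise.

## Known limitations

- The published model was fitted with a commercial tool whose exact
  structure and in-sample predictions are not recoverable from the
  text; in-sample accuracy/TPR/FPR of a refit are therefore *not*
  asserted numerically — only the count-identified quantities (priors,
  single-evidence posteriors, FV/MFV, metric arithmetic) are.
- The published account also states that AFP and TACE were
  "independent factors", which a strict spanning tree cannot represent;
  the `cmi_threshold` forest option exists for exactly this behavior,
  but no claim is made about which pruning the original tool applied.
- The published importance table contains two internal inconsistencies
  a reimplementation cannot honor simultaneously with its own numbers:
  the rank column places one variable (clamping time) above another
  with a larger printed MFV, and the Pearson values for PVTT and tumor
  size are swapped relative to what the table's own counts imply. This
  package ranks strictly by descending MFV and computes the standard
  count-based correlation.
- No general DAG structure search, no approximate inference, no
  survival-time regression (classes are sampled/predicted directly),
  and no multistate importance variants beyond the composite F-V
  measure.
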
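# Methods

This note documents the models, conventions and numerical choices behind
`cohortflow`, in the order the pipeline applies them.

## Factor vocabulary and code matching

A *factor* is a binary criterion over coded events.  The shipped CKD
vocabulary contains 15 rules — eleven comorbid diseases (cerebrovascular
disease, congestive heart failure, coronary artery disease, diabetes,
glomerulonephritis, hyperlipidemia, hypertension, polycystic kidney
disease, proteinuria, renal stone, systemic lupus erythematosus), the
index disease CKD (ICD-9 585/586), and three renal-replacement procedures
(haemodialysis, peritoneal dialysis, renal transplantation).  Matching
semantics:

* codes are normalised (dots and whitespace stripped, uppercased) before
  any comparison, so `437.3`, `4373` and ` 4373 ` are one code;
* a bare ICD-9 category (`250`) is a **prefix**: it matches itself and all
  child codes, the standard reading of category-level criteria;
* `430-438` is a closed **numeric range** over the leading category
  (width taken from the endpoints, so 4- or 5-digit ranges work too);
* `425.4-425.9` is a closed **decimal range** within one category,
  inclusive at both ends as the punctuation implies;
* procedure codes (`58001C`) are terminal identifiers and match
  **exactly**, never as prefixes.

Codes matching no factor are dropped silently and counted
(`Population.unmatched_codes`): extra factors only degrade
interpretability of the downstream diagram, so the vocabulary is an
explicit allow-list.  A `Death` factor is deliberately absent from the
default table — real databases encode death in many ways — and is supplied
by the caller (the synthetic generator uses an exact sentinel code
`DEATH`).

## Trajectories and windows

Day 0 is the **first** chronological occurrence of an index-factor code
(incidence alignment); patients with no index event are excluded and
counted rather than erroring, since the input is expected to be a broader
extract.  Same-day events merge into one record (set union).  Windows are
half-open `[t_l, t_{l+1})`, so a record on a boundary day belongs to the
later window and nothing is counted twice.  Records outside the covered
span are dropped, not clipped — coverage is the caller's contract.
Patients with no in-range records are *retained* with empty window sets:
the explicit "(none)" group is analytically meaningful (patients free of
all watched factors), and removing it would break membership conservation
across windows.

A factor appears only in windows where a code occurs; there is no implicit
chronic-disease persistence.  An opt-in `carry_forward` flag unions earlier
in-range *diagnosis* factors (never procedures) into later windows for
users who prefer prevalence-style semantics; it is off by default because
raw fidelity is the safer assumption.

## Cohorts

`frequency_cluster` keeps every exact combination with at least the
threshold number of patients and merges the rest into "others" — split
into with-index / without-index groups (reserved light-orange / light-green
tints in the export) because the two have very different clinical
meaning; a flag collapses them.

`hierarchical_cluster` agglomerates **unique combinations**, not patients:
the similarity is a property of the factor sets, and complexity then
scales with the number of distinct combinations rather than N.  Distance
is 1 − Ochiai.  Empty-set conventions: ochiai(∅, ∅) = 1 and
ochiai(∅, s) = 0 (the formula divides by zero there), so the "(none)"
combination clusters with itself and joins others only when k forces it.
Linkage is average (UPGMA, via Lance–Williams updates) by default —
a robust middle ground for similarity-derived distances — with single and
complete exposed as options; combinations are *not* weighted by their
patient counts (an open modelling choice; weighting would let one huge
combination dominate the average distances).  Ties in the merge order are
broken by the lexicographically smallest pair of cluster keys, which makes
the dendrogram — and therefore every cut — fully deterministic, and makes
the k-cluster solution always refine the (k−1)-cluster one.

Labels list the factors shared by *all* members; `*` is appended when some
member carries extras, a bare `*` means no factor is shared by everyone,
and the all-empty cohort is labelled `(none)` (not `*`: its members share
exactly the empty combination, there is nothing partial about it).  Custom
labels override.

## Network, entropy, filtering

Edges connect consecutive-window cohorts with non-empty member overlap;
`pb(c_{l+1,j}|c_{l,i})` uses the full source cardinality as denominator
even if some members are absent downstream, so probabilities can sum to
less than 1 under attrition; such nodes are flagged
(`CohortNetwork.attrition_nodes`).  Because patients with empty windows
are retained in "(none)" cohorts, attrition cannot occur in a standard run
— probability mass is conserved and the flow-conservation invariants hold
exactly.

Outcome entropy is attached to the **source** cohort (all its outgoing
edges share it), so filtering removes a node's out-edges all-or-none.  The
default is Shannon entropy with natural log: 0 exactly when all members
flow to one target, ln k at uniform over k outcomes, which makes the
zero-threshold filter literally "keep fully confident transitions".  An
alternative `as-printed` mode computes −Σ p·p, a negated Simpson/purity
index found in an alternative published form of this filter; it is a
strictly monotone transform on any fixed outcome count (−1 deterministic,
−1/k uniform) and is provided for fidelity, with thresholds interpreted on
its own scale.  Filtering never deletes nodes and is monotone in the
threshold.

## Layout

Node order within a window is free (the y-axis is nominal).  The optimiser
minimises **weighted crossings**: interleaving edge pairs between the same
window pair count the product of their cardinalities, so crossings of
thick ribbons dominate.  Defaults: 32 sweeps (left→right→left), each
window re-ordered toward the cardinality-weighted barycenter of adjacent
neighbours with Gaussian noise scaled by a temperature that starts at the
mean node height and cools geometrically (factor 0.98 per half-sweep);
worsening moves are accepted with Metropolis probability; the best state
ever seen (including the initial descending-cardinality order, with
"others"/"(none)" pinned to the bottom) is returned, so the final count is
never worse than the initial.  Exact crossing minimisation is NP-hard;
this is a deterministic (seeded) heuristic.  Overlaps are resolved by
stacking in order with a configurable gap; positions are abstract units,
scaled to pixels only at render time.  Edges draw back-to-front by
descending cardinality so minority flows stay visible.

## Export

The Sankey JSON document is the renderer contract
(`cohortflow/data/sankey.schema.json`); an in-package structural validator
enforces the same constraints at write and read time.  Serialisation is
byte-stable (sorted keys, floats at 6 significant digits) so regenerating
an unchanged analysis yields bit-identical files — which is also what the
CLI's content-hash stage cache relies on.  Colors come from a fixed
20-color categorical palette indexed by a stable hash of the label (same
label ⇒ same color across runs; collisions beyond 20 labels are accepted);
"others" tints and "(none)" grey are reserved.  The HTML export is a
static inline-SVG rendering with native hover tooltips and red highlight
regions; the interactive brushing/re-clustering of a live GUI is out of
scope — the same computations are available programmatically
(`highlight`, `summarize`, re-running operators).

## Synthetic cohorts

`cohortflow.synth` emulates a claims extract around an index diagnosis on
a 1998–2011 style virtual calendar (index dates randomised in 2004–2006 so
a 6-year pre and 5-year post span stays inside it).  Per patient:
pre-index comorbidity claims are independent Poisson processes with
per-factor annual rates (defaults from common pre-CKD prevalence ranges,
hypertension and diabetes most frequent); the index event is a single CKD
code at day 0; first-year haemodialysis occurs with probability 0.0954;
the post-window outcome is drawn from conditional distributions in which
70.2 % of HD patients develop no further watched factor and the remainder
split among peritoneal dialysis, transplantation and death, with a lower
death rate in the non-HD arm.  Emitted codes are sampled from the real
vocabulary rules (range endpoints, child codes, dotted/undotted variants)
so matching is exercised end to end.

What it does **not** model: post-index recurrence of chronic diagnosis
codes, correlation between comorbidities, stage progression, coding noise
or miscoding, censoring and attrition.  Passing pipeline tests therefore
demonstrate correctness of the transformations, not clinical realism of
any particular percentage.  The truth table (per-patient per-window factor
sets) is exact by construction, and every downstream stage is
deterministic, so truth-table recovery is a strict end-to-end oracle.
The deterministic-subcohort option assigns signature pre-index
combinations whose first-year and post outcomes are fixed functions of the
combination; at fraction 1.0 the whole network has zero outcome entropy,
the regime the zero-threshold filter must preserve in full.

## Problem sizes and defaults used in tests and the acceptance script

The shared test cohort uses 1,000 patients (seed 314159, deterministic
fraction 0.3); the acceptance script regenerates 2,000 stochastic and
1,200 mixed patients from the user-supplied seed, clusters the pre-index
stage hierarchically at k = 10, and lays out the resulting network with 16
sweeps.  These sizes give stable proportions (binomial σ ≈ 0.7 % on the
HD prevalence at n = 2,000) while keeping a full run in the order of
seconds.

## Known limitations

* Exact-combination clustering of a very diverse window produces hundreds
  of cohorts; the O(E²) crossing objective makes layout of such networks
  slow — cluster (frequency or hierarchical) before laying out.
* The hierarchical step is quadratic in the number of unique combinations;
  thousands of distinct combinations per window warrant pre-filtering.
* ICD-10/SNOMED vocabularies, database connectors and statistical testing
  of associations are out of scope.
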
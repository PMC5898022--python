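# Methods

## The model

`paretodr` treats drug repositioning as a collaborative-filtering
recommendation problem: drugs that look alike across several independent
evidence sources tend to treat the same diseases, so a target drug's new
indications are predicted from the known indications of its most similar
peers. The pipeline has three stages.

**1. Per-feature similarity.** Each data source is a binary drug × feature
incidence matrix (chemical substructures, protein targets, side-effects).
For two drugs with binary feature vectors A and B:

- cosine: `sim(A,B) = Σ_j A_j B_j / (‖A‖ ‖B‖)`
- Jaccard (Tanimoto on binary vectors): `sim(A,B) = |A∩B| / (|A| + |B| − |A∩B|)`

A source backed by residue sequences (protein targets) can instead be scored
by Smith–Waterman local alignment. A drug is a set of sequences V(A), and

`sim(A,B) = Σ_i Σ_j SW(V_i(A), V_j(B)) / (|V(A)| · |V(B)|)`,

the mean over all sequence pairs. By default each pairwise score is first
normalized by `sqrt(SW(x,x)·SW(y,y))`, bounding the mean in [0, 1]; without
that normalization the per-feature values are not commensurable inside the
dominance comparison (a raw alignment score of 40 would swamp a Jaccard of
0.8). The raw form remains available (`normalize_alignment=False`). The
alignment itself is delegated to Biopython's `PairwiseAligner` in local mode
and cross-checked in the test suite against an exhaustive substring-pair
enumeration oracle.

**2. Pareto-dominance neighbor selection.** With several similarity values
per candidate there is no single ranking. Candidate d_i *dominates* d_j when
d_i's similarity to the target is ≥ d_j's on every source and strictly
greater on at least one. The non-dominated candidates (the Pareto front, or
skyline) are the neighbors. Three collection policies (MOT):

- **OD** — one front only; its size falls out of the data.
- **ND** — peel successive fronts until ≥ N neighbors are collected, then
  prune the last front so exactly N remain.
- **AND** — same peeling without pruning, so at least N remain (unless the
  pool is exhausted).

**3. Disease scoring (IST).** Candidate diseases are those indicated by at
least one neighbor; each is scored `score(c,t) = Σ_n sim(t,n) · f(n,c)` with
f(n,c) ∈ {0,1} from the golden matrix. **SUM** drops the weight (a vote
count); **WSUM** keeps it. The output list is capped at k entries with
strictly positive score — the method never pads with guesses, so lists may
be shorter than k.

## Decisions the formulas leave open

These points are underdetermined by the three-stage description above; the
package fixes them as follows (all are configuration-visible):

- **Absent sources.** A drug can be missing from a source entirely; that is
  represented as an *absent* similarity (None / NaN), distinct from a
  measured 0. Inside the dominance comparison absent is read as 0.0 — the
  conservative choice: no evidence earns no credit.
- **Scalar sim(t,n) for WSUM.** The method computes one similarity per
  source but Eq-style scoring needs a single sim(t,n). Default collapse is
  the arithmetic mean of the *defined* per-feature values; `sum` and `max`
  are selectable (`SimilarityConfig.collapse`).
- **ND pruning rule.** Within the final front, rank by mean defined
  similarity descending, ties broken lexicographically by drug name. The
  same rule orders neighbors within every front, which makes the whole
  selection deterministic under input reordering.
- **Evidence-free candidates.** Candidates whose profile is entirely absent
  or zero are excluded before dominance; otherwise they tie into fronts
  while carrying no information.
- **Ties at rank k.** The prediction list cuts deterministically (score
  descending, then disease name); ties crossing the k boundary are cut, not
  kept.
- **Zero vectors.** Cosine/Jaccard on an all-zero vector return 0 (logged)
  rather than raising, so fully sparse drugs degrade gracefully.

## Evaluation protocol

Leave-one-out per target drug: the target's golden row is withheld, the
prediction is made from the remaining drugs' indications, and the list is
scored against the withheld row. Per-target confusion counts at cap k give
precision = tp/(tp+fp), recall = tp/(tp+fn), F1, and specificity =
tn/(tn+fp); metrics are averaged over targets. Conventions:

- the tn universe per target is its own disease row: tn = |diseases| − tp −
  fp − fn (a pooled universe is not used for SPC);
- an empty prediction list counts precision 0, not a skip — abstention is
  penalized in averages;
- targets with no golden positives are skipped (nothing to recover);
- AUC-PR (tie-grouped step curve, trapezoid over achievable points,
  anchored at recall 0) and AUC-ROC (Mann–Whitney with ties at half) are
  computed per target over the target's full disease row — prediction-list
  scores for listed diseases, zero elsewhere — then averaged. Pooling all
  (score, label) pairs into one global curve is available
  (`pooled_auc=True`); the two modes answer different questions and neither
  is claimed to match any externally published pooled value.

Upper-bound curves: for a target with p positives an oracle list achieves
tp = min(p, k). Without forced guessing fp = 0 and precision is exactly 1 at
every k; with forced guessing (exactly-k lists) fp = k − tp, which is what
makes padding with random guesses visibly harmful at small p.

## Synthetic data

`paretodr.synthetic` draws datasets with the structure the method exploits:
drugs partitioned into latent clusters; each cluster owns a disjoint block
of signature features per source and a disjoint block of signature
diseases. A drug's row is (signature ∩ Bernoulli(share_prob)) ∪
Bernoulli(background_prob) noise; drugs drop out of individual sources with
a per-source missingness probability (every drug is kept in at least one
source); sequences are point-mutated copies of per-cluster ancestor strings
over the 20-letter amino-acid alphabet.

Defaults mirror the real multi-source data at roughly 1/5 scale — 200
drugs, 150 diseases, 10 clusters — with per-source parameters chosen from
the closed-form expectation (`expected_sparsity`) to land on the real
sources' printed sparsities: chemical 200 features → 0.864, protein 160
features → 0.996, side-effect 280 features → 0.950. Alignment defaults are
match 2 / mismatch −1 / linear gap −1, declared for reproducibility since
any positive-diagonal scheme works at these sequence lengths (40–60
residues, 1–2 sequences per drug, 5 % point-mutation rate).

What the generator does *not* emulate: real chemistry (no fingerprint
correlation structure), overlapping or hierarchical indications, cluster
size imbalance, and name synonymy. Passing the planted-cluster tests
demonstrates that the pipeline recovers block structure it is designed for;
it does not certify performance on real pharmacological data, where
cluster structure is weaker and noise is not independent Bernoulli.

## Numerical and scale choices

- All-pairs cosine/Jaccard are computed as dense matrix products; the
  all-pairs alignment source loops over drug pairs with self-scores cached.
  A full leave-one-out on the default 200-drug dataset with the
  Jaccard/Jaccard/Smith–Waterman setting takes on the order of ten seconds
  on one core.
- Test and acceptance runs use reduced generator specs (60–80 drugs, 6–8
  clusters) where a point is structural rather than statistical; the
  noiseless-recovery check (precision = recall = 1 with ND, N = cluster
  size − 1, k = signature-disease count) is exact by construction at any
  size.
- The Pareto front is found by the O(n²·f) pairwise check — exact and fast
  at n ≈ 10³ candidates; no divide-and-conquer skyline algorithm is needed.
- Determinism: the method itself has no randomness; the only seed is the
  generator's, recorded in every report and manifest.

## Known limitations

- With near-equal within-cluster similarities WSUM and SUM produce
  identical rankings, so the WSUM advantage is a weak inequality, visible
  only when neighbor similarities are heterogeneous.
- OD can return very large fronts when many candidates are mutually
  non-dominated (e.g. pervasive ties); ND with N smaller than the first
  front prunes it, which is the one situation where ND selects fewer
  neighbors than OD.
- The synonym harmonization is only as good as the supplied alias table;
  no identifier normalization beyond it is attempted.
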
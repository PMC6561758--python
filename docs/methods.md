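# Methods

## The problem

Taxonomic assignment labels a marker-gene read (16S/18S rRNA) with a ranked
lineage such as `Bacteria;Firmicutes;Clostridia;...`. Benchmarks of
assignment methods conventionally report sequence-count accuracies with a
binary notion of error, and both conventions mislead: reference databases
are heavily imbalanced, so sequence-weighted accuracy mostly measures
performance on a handful of majority taxa, and binary error treats a
one-rank mistake the same as a totally wrong lineage. `taxodist` implements
an evaluation framework that fixes both: a graded per-prediction distance
between lineages and taxon-count-weighted summaries.

## Taxonomy Distance

For two ranked lineages `a` and `b`, the Taxonomy Distance is

    TD(a, b) = (# rank positions in difference) / max(depth(a), depth(b))

where a position is "in difference" when the names differ or only one
label annotates it. TD is symmetric, lies in [0, 1], is 0 exactly for
equal labels, and always bounded above by the binary error. It is stored
as an exact rational (`fractions.Fraction`) and converted to floating
point only at report/plot boundaries, so the worked-example distances
(1/3, 2/4, ...) are reproduced exactly rather than approximately.

Rank comparison is positional and string-exact (whitespace-trimmed,
case-sensitive): no rank vocabulary is assumed, and a *taxon* is a full
normalized lineage. One genuinely open reading: whether a positional match
occurring *after* a mismatch (`A;X;C` vs `A;Y;C`) should count. This
implementation counts every positional match wherever it occurs; the
alternative (cascade-mismatch, where everything below the first mismatch
counts as wrong) coincides with it on prefix-consistent label sets, which
covers every printed example and all label sets this package generates.

A fully unclassified (depth-0) prediction against a depth-m truth scores
TD = m/m = 1; this matters for classifiers run with confidence cutoffs,
and it is also the fallback the CV harness records when a classifier
fails on a sequence (keeping the "no sequence discarded" semantics).

## Per-taxon and overall metrics

For a taxon T with N true sequences s_1..s_N and predictions P(s_i):

    ATD(T) = (1/N) Σ_i TD(s_i, P(s_i))

The overall score is the unweighted mean over the M distinct true taxa,
`ATD_by_Taxa = (1/M) Σ ATD(T_i)`, which weights every taxon equally and is
therefore insensitive to within-taxon duplication (asserted as a property
test). The sequence-weighted counterparts `ATD_by_seq` (mean TD over
records) and `Err_by_seq` (fraction of exactly-wrong records), plus the
taxon-weighted binary `Err_by_taxa`, are computed from the same prediction
table so the 2×2 design (sequence vs taxon weighting × binary vs graded
error) can be compared directly. Binary equality is full-lineage equality,
not correctness at a single target rank.

Dispersions are population standard deviations (ddof = 0): `sd_by_seq`
over per-record TDs, `sd_by_taxa` over per-taxon ATDs, `sd_err_by_taxa`
over per-taxon binary error rates. The per-unit SD reading is adopted
because it is the one that exposes methods prone to rare but severe
errors; no dispersion is defined for `err_by_seq` beyond the Bernoulli
one, and the report writer leaves that cell empty.

`edge_distance` is the companion pair-based comparator: the number of
edges between two labels' nodes in the taxonomy tree,
`depth(a) + depth(b) − 2·(shared prefix)`. It is included for the
contrast it provides — it grows with over-specialization depth where TD
grows with the fraction of ranks in error — not as an abundance-weighted
UniFrac (branch lengths are all 1).

## The Plateau oracle

The best-achievable reference given a training label set predicts, for a
truth of depth m, the training label **or trimmed prefix** minimizing TD.
`plateau_best` performs exact brute-force minimization over every prefix
of every training label (the candidate space is deliberately prefixes
only; grafting ranks from different labels is out of scope). On
prefix-consistent label sets the minimum has the closed form
`(m − c*)/m`, with `c*` the longest common prefix to any training label;
`plateau_best_closed_form` exposes it and the equivalence is asserted on
>1000 randomized instances. The two can differ when a rank name recurs at
the same position under two different parents (truth `A;X` vs training
`{B;X}`: exact 1/2, closed form 1) — that is why the exact route is the
implementation and the closed form the documented shortcut, not the other
way round.

All minimizers are returned; the deterministic single representative is
the *deepest* minimizer with lexicographic tie-break, chosen because it
preserves the most information (the worked example's two minimizers are
both reported, and the deeper one is emitted into prediction tables).
Note `best_td = 0` iff the truth is a training label *or a prefix of
one* — trimming makes a truth that is an ancestor of a training label
perfectly attainable. Under binary error the oracle's error rate equals
the fraction of test sequences whose taxon is absent from training
whenever no label is a strict prefix of another (true of the leaf-only
taxonomies generated here).

## Cross-validation

`stratified_folds` shuffles each taxon's sequence IDs with a seeded
generator and deals them round-robin into k folds, starting at a fold
offset that rotates with the taxon index so small taxa spread over folds
rather than piling into fold 0. The assignment is deterministic given the
seed; per-taxon per-fold counts differ by at most one; singletons land in
exactly one fold and are kept.

Aggregation is macro in the pooled sense: all per-sequence TDs from all
folds are pooled first, then per-taxon ATDs and overall metrics are
computed once. Averaging per-fold metrics instead is *not* equivalent —
a constructed counterexample (a taxon split 2/1 across folds) is part of
the test suite — which is why `macro_aggregate` exists as the single
blessed path from CV output to a report.

## Synthetic data

The generator exists so every property of the framework is exercisable
without multi-hundred-MB database downloads or external classifier
binaries; it emulates the *structural* features that drive the metrics,
not rRNA biology:

- `random_taxonomy` grows a random rooted tree with ragged leaf depths
  (default depth 4–6, matching common 16S annotation depths) and
  globally unique node names, emitting only leaves, so label sets are
  prefix-free and prefix-consistent.
- `imbalanced_dataset` allocates a total sequence count across taxa by a
  power law with exponent γ (share ∝ rank^−γ after guaranteeing every
  taxon one sequence; largest-remainder integerization). γ = 0 is exactly
  balanced (counts differ by ≤1); the default γ = 1.5 and the γ = 1.8
  used in the end-to-end run produce the strongly convex cumulative
  curves characteristic of public rRNA databases, with a realistic
  singleton fraction (~10–25 % of taxa). Sequences, when requested, are
  uniform-random DNA with a private per-taxon motif (default 12 bp in
  150 bp) implanted at a random position — enough signal for the
  demonstration nearest-neighbor classifier to learn non-singleton taxa,
  with none of the phylogenetic correlation of real genes. Passing tests
  on these data therefore validate the *metrics machinery*, not any
  claim about classifier accuracy on real rRNA.
- `simulate_predictions` corrupts each rank position r independently with
  probability rate_r, replacing the name with a sibling under the same
  parent (or a novel name when no sibling exists), so a corrupted rank is
  always wrong. This gives closed-form expectations: with uniform depth d
  and only the lowest rank corrupted at rate p, E[TD] = p/d — the
  calibration the acceptance script measures at p = 0.3, d = 6, n = 10⁴
  (Monte-Carlo SE ≈ 7.6×10⁻⁴).

The six-label worked-example fixture freezes all 15 pairwise TDs and
re-verifies them at construction time. The species-rank name of its
deepest label is not constrained by the distance table (TD depends only
on match structure), so the placeholder `speciesG` is used.

## The demonstration classifier

A 1-nearest-neighbor classifier over raw 8-mer count profiles with cosine
similarity, ties broken by training insertion order. Word length 8 mirrors
common k-mer rRNA classifiers; no tf-idf or quality weighting is applied
because the classifier is plumbing for end-to-end demonstrations, not a
contribution. Windows containing non-ACGT characters are skipped.

## Numerical and design choices

- Exact rational arithmetic end-to-end for TD/ATD/error rates; floats
  only in SDs, plots and serialized reports (`%.6g`).
- Deterministic orderings everywhere a tie could occur: taxa sort by rank
  tuple in reports and plots; ATD ties in plot series order by label;
  plateau minimizers sort deepest-first.
- Parsing is strict where silence would bias results: duplicate IDs,
  unmatched truth/prediction IDs, malformed confidence annotations and
  ragged columns are errors with line/row numbers, never silent drops
  (an `strict=False` escape hatch exists for the join).
- Problem sizes in tests and the acceptance script (40 taxa / 300
  sequences / 10 folds for the CV demonstration; 10⁴ records for the
  simulator calibration; ~1100 instances for the plateau equivalence)
  are chosen to make every stochastic assertion comfortably stable at
  3-SE tolerances while keeping a full run in seconds.

## Known limitations

- Rank-name synonymy and nomenclature drift across databases are not
  resolved; TD inherits the taxonomy choice of its inputs.
- Ragged depths are accepted as-is (real mothur-formatted databases mix
  depths); no rank-name normalization is attempted.
- The edge-distance comparator uses unit branch lengths only.
- External classifiers are not invoked; their predictions enter as
  prediction-table TSVs (or mothur output joined by ID).
- Reported numbers on real RDP/Greengenes/SILVA benchmarks are not
  reproduced here: they depend on the database version and on an
  unspecified CV seed, and require external binaries. The synthetic
  end-to-end run demonstrates the same qualitative phenomena (sequence
  metrics flattering majority-taxon specialists; the Plateau line
  lower-bounding every method per taxon).
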
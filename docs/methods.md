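# Methods

This note documents the models, conventions and numerical choices behind
`evmirnet`, and what the synthetic-data experiments do and do not
demonstrate.

## qPCR profiling model

A Ct (cycle-threshold) value is the number of PCR cycles needed for a
miRNA's signal to cross detection; it is inversely proportional to log2
abundance.  Non-amplifying wells are encoded with a sentinel Ct (default
40.0) rather than a missing value, matching how qPCR instruments export
plates; the detectability filter treats any Ct ≥ `ct_max` as undetected
either way, so the sentinel's exact value is immaterial above the
threshold.

**Detectability** requires Ct strictly below `ct_max` (default 35) in at
least `min_count` subjects (default ⌈0.8·n⌉, i.e. 4 of 5).  The strict
inequality matters at the boundary: a well at exactly 35.0 cycles does not
count.  Detection is monotone — raising `ct_max` or lowering `min_count`
can only grow the detected set — and this is asserted as a property test.

**Global-mean normalization** expresses each detected miRNA relative to
the mean Ct of the detected panel within the same subject:
rel(m, s) = Ct̄(s) − Ct(m, s).  Two decisions are configurable but fixed by
default: the global mean is computed over the *detected panel* only (not
all assay wells), and within that panel only over wells that amplify in
that subject — an undetermined well cannot contribute cycles.  The sign
convention makes abundant miRNAs positive.  Consequence (used as a test
invariant): the present values of each subject sum to zero to 1e-9.

**Compartment agreement** is the Pearson correlation of per-miRNA *mean*
relative expression between EV and intracellular matrices over the
intersection of the detected sets — one point per miRNA, giving a single
panel-level R, not a pooled subject-level cloud.

## Synthetic cohort

The generator plants every quantity the pipeline estimates.  Study
dimensions follow the profiled cohort: a 752-miRNA panel, 5 subjects,
8% expressed miRNAs, a DE list of 231 up- and 129 down-regulated
transcripts, and an EV/intracellular correlation of 0.5.

* Expressed miRNAs receive a latent abundance per compartment
  (between-miRNA sd 2.0 cycles around a mean Ct of 28) plus subject-level
  noise (sd 0.3 cycles).  The EV/IC correlation is imposed on the *realized
  sample* of latent abundances (a Gram–Schmidt construction makes the
  empirical correlation of the two latent vectors exactly ρ), not merely in
  expectation.  Rationale: the generator's job is to plant a ground truth
  for a recovery estimator; with a population draw, the sample correlation
  of ~60 miRNAs has an sd of ≈ 0.10, and the recovery experiment would
  measure bivariate-normal sampling noise rather than pipeline fidelity.
  Residual attenuation from subject noise is ≈ 0.5%, so recovered R
  concentrates tightly around the planted 0.5.
* Log2 fold changes are uniform in ±[0.5, 4] with sign matching the
  direction label.
* Interactions are independent Bernoulli draws per (miRNA, transcript)
  pair: probability p_base (default 0.05) for downregulated transcripts
  and enrichment_ratio × p_base (default 2 × 0.05 = 0.1) for upregulated
  ones.  Each record carries a uniform score in (0, 100] solely to
  exercise the top-percent filter; scores never affect edge existence, so
  the filter thins the network uniformly and leaves the planted degree
  ratio unbiased.  Note an arithmetic consequence of these conditions: the
  expected per-miRNA fraction of upregulated targets is
  231·2p/(231·2p + 129·p) ≈ 78.2%, independent of p.
* The PPI background is a planted-partition graph by default (4 blocks,
  within-block edge probability 0.3, between-block 0.005, 150 proteins);
  uniform (Erdős–Rényi) and preferential-attachment backgrounds are
  available through `ppi_model_params`.  Each planted hub is an extra node
  wired to a random 35% of the background (≥ 30% enforced), thereby
  spanning blocks.  The modular background is essential, not cosmetic: a
  degree-preserving rewiring null conserves the hub's degree, so against a
  *non-modular* (ER) background a planted star is statistically typical of
  its own null and no centrality excess exists to detect.  Against a
  modular background the hub carries nearly all inter-block shortest
  paths, which rewiring destroys.  Block density also matters for the
  consensus rule: in very sparse backgrounds, low-degree peripheral nodes
  have large bridging coefficients and inflate the network-mean bridging
  centrality above what a high-degree hub can reach.
* One root seed drives named substreams (SHA-256 of `seed:stage`, reduced
  below 2³¹), so any stage can be regenerated in isolation and the whole
  bundle is byte-reproducible.

What the generator does **not** emulate: amplification-efficiency
differences between assays, inter-plate effects, hemolysis or other
pre-analytic contamination, correlated targeting (real miRNA families
share seed sequences and targets), and degree heterogeneity of real
interactomes.  Passing recovery tests therefore shows the estimators are
correct and calibrated under the stated generative model — not that the
biological conclusions transfer to any particular real cohort.

## Bipartite network and enrichment statistics

The interaction filter keeps, within each source database, records whose
score ranks in the top `pct` percent (cutoff rank ⌈pct/100 · n⌉, boundary
ties retained, default 20%); records without a score are curated entries
and are kept unconditionally.  De-duplication across sources is a union:
the same (miRNA, target) pair reported twice forms one edge.  miRNAs with
no retained target remain as degree-0 nodes (the cargo panel is fixed);
transcripts enter only via edges.

The up/down comparison groups DE transcripts by direction and compares
their degrees with the classical equal-variance two-sample t-test.
Transcripts with zero interactions count as degree 0 by default
(`include_zero_degree`): the comparison names the transcript *sets*, not
the edge-bearing subset; the switch exists because the edges-only reading
is also defensible.  The "fraction of a miRNA's targets that are
upregulated" is averaged over miRNAs with more than two targets (strict
> 2).  The label-permutation test shuffles direction labels over
transcripts with group sizes preserved and uses the add-one rank estimator
p = (r + 1)/(n_perm + 1), which is exact-level and never zero.

## Centralities

* **Betweenness** is unnormalized, counts each unordered pair once, and
  excludes endpoints — computed with the Brandes dependency-accumulation
  algorithm (networkx) and pinned by tests to exhaustive all-shortest-path
  enumeration on 200 random graphs (≤ 7 nodes, tolerance 1e-9) plus
  closed-form cases (path, 4-cycle, star, complete graphs).
* **Bridging coefficient** BCoef(v) = (1/deg v) / Σ_{u∈N(v)} 1/deg u;
  bridging centrality is the product C_B(v)·BCoef(v).  Isolated nodes get
  BCoef = 0 with a log notice (the ratio is undefined without neighbours).
* **Centroid** C_cen(v) = min over w in v's component of
  γ_v(w) − γ_w(v), where γ_v(w) counts nodes *strictly* closer to v than
  to w, excluding both v and w from the counted universe.  Definitional
  variants exist (≤ vs <, endpoint handling); this one is pinned by the
  brute-force oracle and by hand cases (path centre +1 / leaves −1; star
  centre n − 2; complete graph all 0).  Implementation detail: with the
  component distance matrix D, A[v,w] = #{u : D[u,v] < D[u,w]} counts
  u = v once and u = w never, so γ_v(w) = A[v,w] − 1 and the −1 cancels in
  the difference — the code works directly with A − Aᵀ.
* Multi-component graphs: betweenness and centroid are computed per
  component; singleton components get centroid 0; network means for hub
  selection are taken over all nodes.

**Hub rule**: strictly above the network-wide mean, simultaneously in all
three centralities (mode="all").  The consensus reading is the
conservative interpretation of "above average in the computed
centralities"; mode="any" is available, and mode="all" ⊆ mode="any" is a
test invariant.

**PPI evidence filter**: an edge passes when it strictly exceeds the
threshold in *at least one* configured channel (experiments > 0.0031,
databases > 0.36 by default).  The union semantics is one reading of an
ambiguous rule; intersection is one flag away
(`ppi_channel_mode="intersection"`).

## Null models

Randomization is the degree-preserving double-edge swap: pick two edges
(a,b), (c,d), replace with (a,d), (c,b); reject the attempt if it would
create a self-loop or duplicate edge, or (bipartite case, detected from
node attributes) mix the two sides.  `n_swaps` counts *attempts* (default
10×|E|, a common mixing heuristic), so runtime is predictable; accepted
and rejected counts are returned for audit.  An Erdős–Rényi same-density
alternative exists behind the registry for sensitivity analysis.  Exact
uniform sampling over the degree-fixed graph space is out of scope —
mixing adequacy is only asserted empirically (empirical p-values are
approximately uniform when the observed graph is itself drawn from the
null).

The number of replicates defaults to 40, which bounds the smallest
attainable empirical p at 1/41 ≈ 0.024; users needing smaller p-values
raise `n_random`.

## Problem sizes and tolerances

The test suite runs the Monte-Carlo recovery experiments at the study's
own dimensions (60 detected miRNAs, 231/129 transcripts, 150-node PPI
background) with 50–200 replicate seeds per experiment and 20–40 rewiring
replicates per null, sizes at which each experiment completes in seconds
to a few minutes on one CPU while leaving the binomial error of the
reported recovery fractions well below the asserted margins.  Numerical
tolerances: exact-arithmetic identities are asserted to 1e-9; Monte-Carlo
recovery bands are stated per experiment (e.g. ratio within [1.8, 2.2] in
≥ 90% of seeds) and derive from the generator's known sampling variance,
not from tuning.

## Known limitations

* Identifiers are opaque case-sensitive strings; no gene-symbol aliasing
  or cross-namespace mapping is attempted.
* The pipeline ingests a precomputed DE list; microarray preprocessing and
  differential-expression calling are upstream concerns.
* No visualization: networks are exported as edge-list TSV and GraphML,
  null distributions as tidy TSV, for external tools.
* The t-test treats per-transcript degrees as independent observations, as
  in the original analysis; degrees of transcripts sharing miRNAs are in
  fact weakly dependent, which the permutation test sidesteps.
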
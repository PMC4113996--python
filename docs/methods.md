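# Methods

## Networks and statistics

An SSN is an undirected graph over unique protein sequences. Identical
residue strings (case-folded, trailing `*` stripped) collapse to one node,
represented by the lexicographically smallest accession, which makes all
downstream numbering reproducible. Edges carry the best pairwise e-value
over both alignment directions; clusters at a display cutoff are the
connected components with ≥ 2 members, singletons are counted separately.
No community detection is applied: the clusters of interest are exactly the
visually separate components at a given stringency, and connected
components are the only definition under which the refinement guarantee
below holds.

Pairwise similarities come from one of three interchangeable routes:

1. **BLAST tabular ingestion** (`-outfmt 6`, 12 columns) for precomputed
   all-by-all runs; self-rows are dropped, e-values printed as `0.0` are
   kept as exact zeros (they pass every threshold).
2. **A `blastp` wrapper** (makeblastdb + blastp, single thread) for
   superfamily-scale inputs.
3. **An exact internal aligner**: Smith–Waterman with affine gaps
   (BLOSUM62, gap of length *g* costs 11 + *g*; `X` scores 0 against
   everything), with Karlin–Altschul statistics
   bit = (λS − ln K)/ln 2, E = m·n·2^(−bit), using the gapped BLOSUM62
   defaults λ = 0.267 nats, K = 0.041. The search space uses m = the
   shorter sequence of the pair (equivalent to taking the best direction of
   a reciprocal search, since E is linear in m) and n = the summed length
   of all unique sequences in the run. Altschul edge-effect length
   corrections are deliberately omitted: e-values are consumed only
   relative to thresholds, never as calibrated significance levels. E is
   computed in log space, so extreme scores underflow cleanly to 0 rather
   than raising. The aligner is exact and quadratic with no word-seeding
   heuristics; it is the reference route at desk scale and in tests.

Cluster numbering sorts components by size (descending), breaking ties by
smallest member id, and assigns 1..C; colors come from a fixed 28-name
palette, cycling with a numeric suffix. The numbering is a pure function of
the partition — invariant under node and edge input order.

**Refinement guarantee.** For cutoffs t₁ ≤ t₂ the edge set at t₁ is a
subset of the edge set at t₂, so the partition at t₁ refines the partition
at t₂: clusters only merge as the threshold is relaxed, never split. The
threshold sweep verifies this and reports which strict clusters coalesce at
each relaxation, plus the monotone edge/component counts. Median edge
identity decreases as the cutoff is relaxed (stringency selects
higher-identity pairs); the identity ↔ threshold correspondence is treated
as qualitative, not as a calibrated mapping.

## Neighborhoods and the GNN

Gene context is order-based. CDS features (only CDS: pseudogenes and RNA
features never enter the gene count) are ranked by start coordinate within
each replicon — overlapping CDS tie-break by (start, end, protein_id) —
into 0-based ordinals, and a query's neighborhood is the genes with
ordinals within ±N (default 10), truncated at contig ends and never
crossing replicons. Strand is recorded but never affects membership or
order. Offsets, not coordinates, appear in all public outputs.

Each neighbor is colored by the collecting query's SSN cluster; neighbors
are deduplicated by protein id, so a protein collected by differently
colored queries is one node holding all of those colors. The query itself
(offset 0) never enters its own neighborhood, but a query-family member at
a nonzero offset of another query is retained — that is what makes the
query family itself appear in the GNN exactly when members are
genome-proximal. Queries that are SSN singletons contribute under a
reserved color (0) that can never drive a SIGNAL call. One bookkeeping
invariant is enforced and tested: the total color-bag size equals the
number of (query, neighbor) collection events.

The pooled neighbors are clustered at the GNN cutoff (default 10⁻²⁰) with
the same numbering rules. Per cluster and color the package reports the
node count, the distinct contributing queries, and the **query coverage** —
contributing queries over all queries of that color. A cluster is SIGNAL
iff size ≥ `min_size` (default 3) **and** some color's coverage ≥
`min_coverage` (default 0.5); otherwise BACKGROUND. Interactive analyses
discard noise by eye; a software artifact needs a computable criterion, so
both parameters are explicit, reported in the outputs, and re-flaggable.
The defaults encode "at least half of some query family systematically
carries this gene": true operonic partners sit near coverage 1, while a
noise family present in a fraction *q* of random windows has per-color
coverage concentrated near *q*. Cluster labels are a plurality vote over a
user-supplied annotation table (ties to the lexicographically smaller
label); the package consumes annotations, it never computes them.

Map-back inverts the collection provenance: for a GNN cluster, the queries
whose windows contributed ≥ 1 member, grouped by SSN cluster. Its color set
provably equals the cluster's composition color set, which is asserted in
the tests.

## Synthetic data: what it emulates, and what it does not

The generator builds the setting the networks are designed for, with full
ground truth:

* **Superfamily**: F = 8 query families × M = 20 members of length L = 300.
  Family ancestors descend from one root by per-site substitution with
  probability `p_between` = 0.8; members descend from their ancestor at
  `p_within` = 0.3. Substitutions resample the site from the
  BLOSUM62-conditional distribution P(b|a) ∝ q_b·exp(λ_u·s_ab)
  (λ_u = 0.3176, BLOSUM62 background q), so a "substitution" occasionally
  redraws the original residue and, more importantly, simulated identities
  produce realistic alignment scores. These settings give ≈52% pairwise
  within-family identity and near-background between-family identity.
* **Genomes**: one 11-gene replicon per query member (query centered,
  `replicon_halfwidth` = 5), emulating short draft-genome contigs; the ±10
  window therefore truncates at the contig ends. The family's partner
  genes — fresh members of P = 4 independent partner-family ancestors,
  evolved at `p_within` — occupy fixed offsets (+1, +2, −2, …). Remaining
  slots hold, with probability `scatter_prob` = 0.1 each, a member of one
  of 5 "scatter" families (recurring genes that land near queries by
  chance across species — the background the classifier must reject), and
  otherwise a one-off random protein unique to that replicon. An
  `adjacent_pair` option places the members of two query families next to
  each other on shared replicons to exercise the
  query-inside-a-query-neighborhood semantics.
* **Determinism and blinding**: one seeded RNG drives everything — the same
  config and seed give byte-identical FASTA/GenBank; protein and replicon
  ids are random digits carrying no family information.

Synthetic runs use strict/relaxed SSN cutoffs of 1e-50 / 1e-5: at L = 300
and ≈52% within-family identity, within-family e-values fall around
1e-60..1e-110 while between-family alignments stay above 1e-3, so 1e-50
separates the planted families with orders-of-magnitude margin on both
sides. (The real-data display defaults remain 1e-110 / 1e-55, which
correspond to roughly 60% / 35% identity for natural superfamily members;
the synthetic families are shorter-branched, so the operating point
differs while the geometry — strict cutoff inside the within/between gap —
is the same.) The GNN cutoff is 1e-20 in both settings.

What the simulator does **not** emulate: indels (no gaps in true homologs,
so gap handling is exercised only by the aligner tests), phylogenetic tree
structure within families (star topology only), codon-level evolution,
operon strand/spacing structure (strand is random; the window is purely
order-based anyway), multi-copy queries per genome, and horizontal
transfer. Passing the planted-recovery tests therefore shows the pipeline
is correct and well-calibrated for cleanly separated families with
consistent gene context; it does not certify performance on superfamilies
whose within/between identity distributions overlap, or on fragmented
assemblies where partners fall outside truncated contigs.

## Problem sizes and numerical choices

The end-to-end test suites run the default conditions (160 queries, 1600
pooled neighbor genes per run) across 10 independent seeds using the
`blastp` backend, and desk-scale configurations (L = 120, laxer cutoffs
matched to the shorter sequences) with the exact internal aligner. The
reproduction script runs one full default-condition pipeline per
invocation.

Degenerate inputs and tie-breaks are pinned throughout: empty FASTA is an
error while an empty annotation table is valid; reciprocal-hit ties go to
the higher bit score then the forward direction; equal-size clusters order
by smallest member; e-value 0 always passes; cutoffs must be positive; an
empty neighbor set yields empty (header-only) outputs, not an error.
E-values are serialized as decimal strings in XGMML so 10⁻³⁰⁰-scale values
survive consumers without extended precision; all writers iterate in
sorted order and emit repr-stable floats, making every output byte-stable
across runs.
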
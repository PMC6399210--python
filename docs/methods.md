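# Methods

This note records the models implemented in `paleologs`, the assumptions
they make, the defaults and why, and what the synthetic-data generator
does and does not establish.

## Reconciliation

Gene trees are reconciled against the species tree by the classical LCA
mapping: a gene leaf maps to its species; an internal node maps to the
species-tree LCA of its children's images.  A node is a **duplication**
iff its image equals at least one child's image, otherwise a
**speciation**.  Implied losses on the edge (u, v) are
d(M(u), M(v)) − 1 when u is a speciation and d(M(u), M(v)) when u is a
duplication, where d counts species-tree edges between the images.  The
LCA reconciliation minimizes the total duplication + loss cost; the test
suite verifies this against exhaustive search over all valid mappings for
every gene-tree topology with up to six leaves on a three-species tree.

Assumptions and choices:

- Input topologies are taken as-is; no topology repair or rearrangement.
- Gene trees must be strictly binary; multifurcations raise an error
  rather than being resolved arbitrarily.
- **Orthogroup (AOG) splitting** cuts the tree at every duplication whose
  image is an ancestor *or equal* of the crown node.  A duplication
  mapping to the crown node precedes the crown speciation in time, so the
  inclusive rule is what guarantees each resulting subtree descends from a
  single crown-ancestral gene copy (a stem duplication and a duplication
  "at" the crown are indistinguishable under LCA mapping).  Subtrees whose
  genes all belong to outgroup species are discarded.
- **WGD assignment** uses node-image equality only: a duplication is
  attributed to event w iff its image is the node subtending the branch
  annotated with w; no requirement that both copies survive in every
  descendant lineage.  Duplications not matching any annotated branch are
  "lineage-specific".
- **Branch epochs**: the branch entering a focal (crown-mapping WGD)
  duplication is PreDB; branches from a focal duplication down to and
  including the first speciation on each path are PostDB; branches below
  are PostSB; everything else "other".  In a nested trio the edge between
  the two focal duplications is PreDB (it precedes the later duplication),
  so a pair contributes 2 and a trio 3 PostDB branches — consistent with
  counting duplicate sets as pairs/trios.

## Retention classes

Copy-number profiles are clustered with Ward's minimum-variance criterion
on Euclidean distance over raw counts (no standardization — profiles are
counts on a common scale), equivalent to the Ward.D2 update; the
dendrogram is cut to k clusters (default k = 2).

The rule-based classes operationalize the qualitative definitions
("generally", "most species") with fixed thresholds, applied in order:

1. **multi** — more than 50% of non-basal species carry ≥ 3 copies.
   Basal angiosperms are excluded from the vote because they lack the
   shared WGDs and stay single-copy even in multi-copy orthogroups.
2. **low 2c** — median eudicot count ≤ 1 and median monocot count = 2.
3. **low 2b** — more than 50% of species carry ≤ 1 copy after excluding
   species flagged with a recent lineage WGD.
4. **low 2a** — remaining low-copy orthogroups.

These thresholds are recorded choices, not inferred intent; the class
boundaries in the source material are verbal.

## Tissue specificity and ancestral expression

τ = Σᵢ (1 − x̂ᵢ)/(N − 1) on max-normalized linear-scale expression;
τ = 0 for uniform expression, τ = 1 for single-tissue expression, and τ is
invariant to rescaling the profile.  Breadth counts tissues above a
presence threshold (default 0 — any signal counts, since
detected/not-detected calls carry no stated cutoff; configurable).

Rank tests are two-sided throughout; exact p-values are used for small
samples without ties (≤ 25 per group), otherwise the normal approximation
with tie correction (scipy implementations).  No multiple-testing
correction is applied.

Ancestral expressed/not-expressed states per organ are computed by
Sankoff dynamic programming with asymmetric costs, default gain = 2,
loss = 1: losses of expression are modelled as the cheap, frequent event
(degenerative mutations vastly outnumber gain-of-function ones), making
the reconstruction Dollo-leaning but not strictly Dollo.  Ties are broken
toward not-expressed — conservative about inferring gains.  Missing leaf
observations contribute zero cost to either state.  The DP cost is
verified against brute-force enumeration over all labelings on trees up
to eight leaves.

## Ka/Ks and LRT bookkeeping

Ka/Ks uses the Nei–Gojobori (1986) counting method rather than ML codon
models: synonymous site fractions per codon are computed from the genetic
code (changes creating stop codons count as non-synonymous, so
N + S = 3 × codons exactly), averaged over both sequences; multi-position
codon differences are averaged over all orderings of single-nucleotide
steps, skipping pathways through stop codons (if every pathway is blocked,
all pathways are used with stop treated as its own amino acid — a rare
3-fold-difference corner case); pN = Nd/N and pS = Sd/S receive the
Jukes–Cantor correction K = −(3/4)·ln(1 − (4/3)p).  Codons containing
gaps, ambiguity characters or stops in either sequence are excluded
pairwise.  Saturation ((4/3)p ≥ 1) and Ks = 0 leave the corrected rate or
ω undefined and flagged, and such pairs are excluded (but counted) in
group contrasts.  Counting-method estimates differ from ML estimates on
real data; this substitution is deliberate and desk-scale.

The LRT layer operates on externally supplied log-likelihoods:
statistic = 2·|lnℓ₁ − lnℓ₀|, compared either to χ² upper-tail
probabilities at a supplied df, or to the critical values of the 50:50
mixture of a point mass at zero and χ²(1) — the null for tests whose
parameter sits on a boundary under H₀ (branch-site positive selection).
For α < 1/2 the mixture quantile equals the χ²(1) quantile at 1 − 2α,
giving 2.71 at 5% and 5.41 at 1%.

## The synthetic world

The generator is the package's test harness.  Its defaults are a stated
world, fixed once:

- **Species tree**: 14 angiosperm species (one basal, eight eudicots,
  five monocots) with eight WGD events placed as the angiosperm record
  places them: gamma at the core-eudicot crown; alpha and beta nested
  within Brassicaceae; Fabaceae and Asteraceae family events; tau, sigma,
  rho nested along the Commelinid–Poales–Poaceae backbone.  Covered
  lineages sit below 2–3 events, so families that retain WGD duplicates
  become multi-copy in most species — the geometry the retention classes
  describe.  Branch lengths default to 1, so rates read as per-branch
  probabilities.
- **Families** evolve top-down: within a branch, each lineage duplicates
  and dies as independent Poisson processes (λ = μ = 0.05 per unit branch
  length — small relative to WGD effects, as lineage-specific events are
  in this family); at the midpoint of an annotated branch every surviving
  lineage duplicates with the class's retention probability r.  Every
  event is written to a truth log from which the pruned gene tree can be
  replayed exactly.  Extinct families are returned flagged, not raised.
- **Classes**: broad (r = 0.9, Dirichlet α = 5.0) vs narrow (r = 0.1,
  α = 0.1), 30 families per class — the acceptance fixture's contrast.
- **Expression**: per gene, tissue proportions ~ symmetric Dirichlet(α)
  over 6 tissues (a typical organ-atlas size), scaled by a lognormal
  total (meanlog 2, sdlog 1; heavy-tailed totals are realistic and τ is
  scale-invariant, so the total is cosmetic).
- **Codon pairs**: ancestor uniform over sense codons; each codon of the
  descendant receives Poisson(3t) mutation attempts (t = expected
  attempts per nucleotide site); an attempt proposes a random
  single-nucleotide change, accepted with probability 1 if synonymous, ω
  if non-synonymous, never if it creates a stop.  This
  mutation–selection rejection scheme makes ω = 0 produce zero
  non-synonymous differences and t → 0 identical sequences by
  construction.

What the generator does **not** emulate: sequence evolution along the
full gene tree (codon pairs are independent of the families), codon usage
bias, among-site rate heterogeneity, correlated expression between
paralogs, and gene conversion.  A green recovery test therefore
establishes that the analysis code inverts this generative model — not
that it would behave identically on empirical data, where tree estimation
error and annotation noise dominate.

## Numerical and degenerate-input choices

- Newick dialect: underscores are literal (never converted to spaces);
  labels with spaces or metacharacters are quoted; duplicate leaf labels,
  unbalanced parentheses and missing semicolons are parse errors naming
  the offender.
- Species codes are fixed-width four characters matched as a label
  prefix.
- Ward clustering sorts rows by identifier before linkage so memberships
  are invariant to input order.
- All-zero expression profiles make τ undefined (error); an organ with no
  observed state in any leaf is skipped with a warning.
- All randomness in the pipeline and acceptance script derives from a
  single integer seed; reruns are reproducible table-for-table.

## Known limitations

- LCA reconciliation has no notion of transfer or incomplete lineage
  sorting; discordance is absorbed as duplications + losses.
- Co-located WGD events (same species-tree branch) cannot be
  distinguished by reconciliation image, which is why the bundled tree
  separates alpha from beta (and sigma from rho) with an internal node.
- The mixture LRT layer reproduces published arithmetic from supplied
  log-likelihoods; it does not fit codon models.
- Retention-class thresholds are sharp reformulations of verbal rules;
  profiles near a boundary can switch class under small count changes.
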
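# Methods

## The conservation statistic

Per scheme position *x* the package computes the relative entropy

RE(x) = Σ_i p(x_i) · log( p(x_i) / q(x_i) )

of the observed amino-acid distribution *p* against a reference simplex
*q*, with 0·log 0 := 0. The natural log is the default unit (nats);
any base > 1 may be chosen (base 2 gives bits, and RE_bits =
RE_nats / ln 2 exactly). RE is non-negative (Gibbs' inequality) and
zero iff *p = q*, so against a diffuse reference it acts as a
conservation score: a position dominated by one residue scores near
log(1/q_dominant).

Frequencies are computed **over occupied sequences only**. Numbering
schemes assign no label where a residue is absent, so absence at a
position is a structural fact, not an observation of the distribution.
Positions occupied by strictly fewer than 30% of sequences are
discarded before any profiling (`min_occupancy = 0.30`; a position at
exactly 30% is retained — the rule is "less than 30% discarded", taken
literally). Non-canonical residue symbols (X, B, Z, gaps) are treated
as unoccupied rather than rejected, and exact duplicate sequences
(identical residue lists) are collapsed on load, so analyses run on
non-identical sequences.

Three reference modes:

* **pooled** (default) — the aggregate amino-acid composition of the
  repertoire itself over retained positions, an estimate of the
  expected residue usage of a variable domain. The pool is computed
  *after* the occupancy filter (a documented flag away from before).
* **explicit file** — any 20-row (residue, weight) table; the package
  ships an approximate yeast-proteome composition
  (`data/yeast_reference_v1.tsv`) as a conventional proteome-wide
  neutral state. The shipped vector is an approximation compiled from
  standard proteome statistics, clearly versioned for replacement;
  tests never rely on it and always pass explicit vectors.
* **cross-species** — another repertoire's positional distributions
  play *q* position-by-position (e.g. mouse as reference when scoring
  human divergence), evaluated on the intersection of both tables'
  retained positions, each species filtered at 30% separately first.

Unsupported support (p_i > 0 where q_i = 0) is a hard error by
default. In cross-species mode, where disjoint residue sets genuinely
occur, either the position is skipped and logged (pseudocount off) or a
pseudocount α (default 0.5) is added to all 20 counts on *both* sides
before normalizing. The analysis drivers and acceptance run use
α = 0.5; α shrinks both distributions toward uniform, biasing RE
slightly downward, which is conservative for hotspot calling.

## Region summaries and hotspots

Per-region statistics are the mean, median and sample standard
deviation (n−1 denominator) of the member positions' RE, plus `all`,
`framework` and `all_CDR` aggregates. By the package's convention the
framework inventory is summarized on Kabat numbering while each
scheme's CDRs are summarized under that scheme's own definition, so
scheme comparisons differ only where the schemes themselves differ.
Box statistics use linear-interpolation quartiles (numpy's default
percentile rule) with whiskers at the most extreme data points within
1.5·IQR of the box; points beyond are reported as outliers.

Humanization hotspots are positions whose cross-species RE strictly
exceeds mean + k·SD of their group (k = 1.65 by default). The group is
the **whole chain** by default (`by="chain"`): a handful of genuinely
divergent positions inflates the chain-wide dispersion so that only
they clear the threshold. A per-region mode (`by="region"`) is
available, but note its statistical behavior: in a region containing no
truly divergent position the threshold collapses onto the sampling
noise and the region flags its own noise maxima at a roughly constant
rate (~5% of positions for near-Gaussian noise), so per-region
thresholds are better read as within-region outlier markers than as
hotspot calls. Groups with fewer than two positions have no SD and are
skipped with a warning; the strict inequality means a constant group
flags nothing.

## Scheme model

Positions are chain-qualified labels with optional insertion codes:
letters A–T at the enumerated Kabat-family sites (e.g. L27A–L27F,
H100A–H100T), fractional suffixes .1–.6 at the IMGT sub-position sites
(e.g. 111.1–112.1). Ordering is base number first, untagged before
tagged, letters alphabetical, fractional tags ascending — except at
position 112, where the published IMGT CDR3 convention runs
111 < 111.1 < … < 112.2 < 112.1 < 112 (the 112.x tags descend and
precede 112). The same descending rule is *not* applied at the CDR2
site 60.x, where tags ascend; this is a documented tie-break choice.

The region catalogs carry the published CDR definitions of Kabat,
Chothia, consensus Chothia, AbM and IMGT, plus the "general CDR" —
the union of every scheme's CDR definition expressed on Kabat numbering
(L24–L34, L50–L56, L89–L97; H26–H35, H50–H65, H93–H102). Framework
regions fill the gaps so each catalog partitions its chain span
contiguously (Kabat-family light chains are cataloged to L107, heavy to
H113, IMGT to 128). Insertion-tagged positions inherit the region of
their base number, since the insertion sites sit inside the loop
ranges. IMGT ranges that read identically for both chains are
interpreted chain-specifically via the record's chain field.

### Inter-scheme equivalence

Conversion between schemes is a lookup in a packaged, versioned table
(`data/equivalence_v1.tsv`): one row per column of a canonical-length
variable domain (109 light, 113 heavy columns), one label column per
scheme, bijective and order-preserving per scheme. The table is a
curated segment model anchored at correspondences that are fixed by the
biology and the numbering literature:

* conserved Cys: Kabat L23/H22 ↔ IMGT 23 ↔ Aho 23, and Kabat L88/H92 ↔
  IMGT 104 ↔ Aho 106;
* CDR1 pivot columns: Kabat L27B ↔ IMGT L29 (kappa), Kabat H29 ↔
  IMGT H30;
* the general-CDR3 start: Kabat H93/H94 ↔ IMGT 105/106;
* the conserved light-chain strand RFSGSXSG: Kabat L61–L68 ↔
  IMGT L75–L82.

Between anchors, per-segment offsets are the package's own choice and
are *approximate*: a profile-HMM numbering engine would place some
mid-segment columns differently, and real scheme alignments are not
globally bijective (the statistical column a residue lands in can
differ between schemes at non-canonical loop lengths). Conversion
outside the table — insertion codes beyond the canonical columns, IMGT
slots 37/38, and similar — raises an error rather than guessing.
Numbering raw, unnumbered sequences is explicitly out of scope; the
package consumes pre-numbered input.

### Consensus map annotation

The Aho-grid consensus map decorates each cell with a Gelfand
beta-strand label (A, A′, A″, B, C, C′, C″, D, E, F, G), an Aho
conserved-C-alpha-core flag, and an IMGT CDR flag. Strand and core
spans ship as an approximate versioned table
(`data/strand_annotation_v1.tsv`); the source descriptions publish them
only graphically, so the spans here are validated by spot invariants
(the conserved cysteines at Aho 23/106 fall inside annotated strands
and core) rather than by coordinates. Consensus calls break exact
frequency ties alphabetically by one-letter code, so exports are
deterministic and byte-stable.

## The synthetic generator

`default_spec(chain, scheme, species)` describes a repertoire at the
level the statistic sees — an independent categorical distribution and
occupancy per position:

| feature | default | rationale |
|---|---|---|
| framework columns | one dominant residue at mass 0.90, cycling deterministically through the alphabet | strong but not absolute framework conservation |
| anchors (Cys L23/L88, H22/H92; Trp L35, H36, H47, H103) | dominant mass 0.95 | the near-invariant bracket residues |
| RFSGSXSG strand (Kabat L61–L68) | 0.92 per named residue; L66 Gly at 0.58 | the conserved solvent-exposed light strand with its one weaker column |
| general-CDR columns | near-flat with S 14.9%, G 11.1%, Y 11.0% | Ser/Gly/Tyr CDR enrichment at realistic magnitudes |
| kappa pivot (Kabat L27B) | I 25 / V 20 / L 15% (60% small-nonpolar) | buried pivot side chain |
| lambda pivot (Kabat L28) | V 30 / I 25 / L 14% (69%) | same preference, shifted label |
| lambda at L27B | N 45 / D 19% | the polar column that diverges between species through the mixture |
| heavy pivot (Kabat H29) | F 71% | Phe-dominated heavy pivot |
| kappa fraction | human 2/3, mouse 0.95 | the κ:λ ≈ 2:1 human vs ≈ 19:1 mouse ratios |
| loop extras | CDR1 +0–2, CDR3 +0–3 insertion-coded positions, Gly/Ser-rich, at each scheme's documented sites | length variation that exercises insertion parsing and the occupancy filter |

Human and mouse differ *only* in the kappa fraction, so cross-species
divergence at the light CDR1 pivot emerges from the class mixture —
the same mechanism proposed for real repertoires — while
`planted_pair` injects explicit positional deltas with a recorded
ground truth for recovery tests.

Because every planted distribution is known, `analytic_re` gives the
exact RE of the (mixture-marginalized) planted distribution per
position, and recovery tests compare the empirical profile to it. At
n = 5000 the per-position plug-in estimator has sampling sd ≈ 0.02 at
0.90-dominant columns (delta method), so recovery tolerances are stated
on the mean absolute error across positions (≤ 0.05 at n = 5000,
≤ 0.15 at n = 500), with a 0.10 per-position cap; individual positions
fluctuate at the ±2σ ≈ 0.04 scale.

What the generator does **not** emulate, and what passing tests
therefore do not show about real data: correlations between positions
(germline V(D)J linkage, somatic hypermutation lineages), realistic
loop-length distributions, species-specific framework usage beyond the
class mixture, allelic or database redundancy structure, and numbering
ambiguity — synthetic sequences are born with consistent labels,
whereas real numbering is itself inferred. Results on synthetic data
validate the estimator and the pipeline mechanics, not biological
conclusions.

## Problem sizes and determinism

The test suite and acceptance script run repertoires of n = 500–5000
sequences (5000 for recovery and hotspot checks, 1000 for the
scheme-ordering sweep, smaller for IO and property tests); these sizes
put sampling error well inside the stated tolerances while keeping a
full run in tens of seconds. All sampling flows through
`numpy.random.default_rng` with explicit seed threading — no global
random state — so fixed (spec, n, seed) reproduces byte-identical
repertoires, and every quantity in `results/acceptance.json` derives
from the single `--seed` argument.

## Known limitations

* The equivalence table covers canonical-length chains only; long-loop
  insertion columns convert only where listed, and the light-chain
  model is single-template (kappa-shaped spans for both classes).
* The pre-2021 original Chothia CDR definition is not modeled, only
  the consensus variant; Gelfand strand boundaries are approximate.
* Pooled references computed after the occupancy filter differ
  slightly from pre-filter pooling when many positions are discarded.
* Cross-species pseudocounts bias RE toward zero at sparsely occupied
  positions; hotspot calls near the threshold should be read with the
  chain-wide noise floor in mind.
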
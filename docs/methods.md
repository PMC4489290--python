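# Methods

This note documents the models, parameters and numerical choices behind
`ppinet`, and what its synthetic-data tests do and do not establish
about real interactome data.

## Evidence model and consolidation

A PSI-MITAB 2.5 row is reduced to: two interactor identifiers (database
prefixes stripped), the set of PSI-MI detection-method accessions
(`MI:NNNN`, pattern-matched from column 7; free-text method names
without an accession are not usable evidence and the row is skipped
with a warning), the source-database label (column 13, or an explicit
per-file label), and optional taxon identifiers. Columns beyond 15 and
the MITAB confidence column are ignored — reliability is recomputed,
not inherited. Rows with fewer than 15 columns are skipped and counted;
every stage reports its losses so record counts are auditable
end to end.

The experimental-validation whitelist is configuration, not code. The
shipped default (`ppinet/data/method_whitelist.yaml`) covers the common
experimental families — two-hybrid variants, coimmunoprecipitation
variants, affinity chromatography and tandem affinity purification,
pull-down, cross-linking, far-western, FRET, surface plasmon resonance,
X-ray crystallography, NMR, protein arrays. It is a documented default
that users should replace to match their own curation policy; no logic
depends on its membership. Filtering keeps a record iff its method set
intersects the whitelist and then reduces the set to the whitelisted
subset, so non-experimental evidence never reaches scoring.

Identifier mapping is a raw-ID → gene-ID multimap; a record whose
interactor maps to several genes is multiplied over the cross-product
(an upstream convention when protein and gene namespaces disagree), and
records with unmappable interactors are dropped and counted.

Consolidation canonicalizes each pair lexicographically and unions
methods and source labels; per-source multiplicity is deliberately not
retained, because the scoring model treats detection (a method saw the
edge) as the unit of evidence — the same accession reported by three
databases is one observation. Consolidation is therefore idempotent and
invariant to source order, which the test suite checks against a
brute-force union oracle. Self-interactions are retained as edges and
counted as PPIs; whether the original convention kept them is an open
point, so the choice is made explicit here and they are excluded from
clustering (below).

## Scoring scheme

Parameters, defaults and meaning:

| parameter | default | meaning |
|---|---|---|
| GO term selection | required | anchors the positive/negative reference sets |
| `max_term_size` | off | drop selected terms annotated to more genes (too broad to be specific) |
| `allowed_evidence` | all codes | restrict which GO annotations count (e.g. `IDA` only) |
| pseudocount α | 1.0 | Laplace smoothing of the detection counts |
| prior π | 0.5 | prior probability of interaction; weight of uninformative evidence |

Edges with both endpoints annotated to the selected terms form the
positive set *P*; edges with neither endpoint annotated form the
negative set *N*; edges with exactly one annotated endpoint are
excluded from both, because either label would be a guess and would
contaminate the ratios. An empty *P* or *N* aborts scoring with an
instruction to broaden or narrow the term selection — silently scoring
from a degenerate reference would produce meaningless weights.

Detection methods are grouped into combined methods via a 2-column
table (`ppinet/data/method_grouping.tsv`); the shipped default groups
the coimmunoprecipitation variants (MI:0006, MI:0007, MI:0019) under
one label, the two-hybrid variants under another, and affinity
chromatography with tandem affinity purification; unlisted accessions
score under their own accession. Grouping exists because sparse methods
cannot be scored reliably on their own; the table is replaceable
configuration.

Each combined method gets the pseudocounted likelihood ratio
`((TP+α)/(|P|+2α)) / ((FP+α)/(|N|+2α))`, which is finite and strictly
positive for every method, including ones absent from both reference
sets (those get a ratio near 1, i.e. uninformative). Edge weights are
the naive-Bayes posterior `πL/(πL+1−π)` with `L` the product of the
edge's distinct combined-method ratios. Distinctness matters: grouped
accessions on one edge contribute exactly once, so overlapping evidence
is ignored by construction. A method group encountered at weighting
time but never seen during scoring is treated as ratio 1 with a
warning. Weights are strictly increasing in `L`, lie in (0,1), and
equal π exactly when all evidence is uninformative.

The naive-Bayes form assumes detection methods err independently given
the edge's true status — wrong where methods share biases (e.g. two
affinity-based methods both favoring stable complexes), which grouping
mitigates but does not remove. Weights should be read as relative
reliability ranks, not calibrated probabilities.

## GO handling

Annotations load from a 4-column TSV or a GAF 2.x subset; the
annotated-gene count per term is maintained as an invariant of the
container. "Annotated to a term" means *direct* annotation by default;
propagation to GO-graph ancestors is available by passing an explicit
term → ancestors mapping (off by default, since propagation changes
reference-set composition in release-dependent ways and the right
behavior is context-specific).

The keyword utility ranks description tokens by the number of distinct
terms containing them. The stemmer is deliberately minimal and fully
documented: lower-case, strip one prefix from {de-, re-} (only when ≥4
characters remain) and one suffix from {-ation, -ing, -ion, -es, -s}
(longest match, only when ≥3 characters remain), drop a fixed stop-word
list (of, to, the, via, process, activity and a few connectives). A
crude affix rule occasionally produces odd stems ("apoptosis" →
"apoptosi"); this is harmless for ranking because the mapping is
consistent, and a full stemmer would add a dependency without changing
the counts' meaning. Ties in term count break alphabetically so the
ranking is deterministic.

## Context filters

Expression: each resource is an independent table with its own
threshold — values measured on different platforms are never compared
with each other, and no cross-platform normalization is attempted. A
gene passes a resource when its value is strictly greater than the
threshold (configurable to ≥; the boundary convention is not dictated
by anything and is therefore explicit), and, when the table has
p-values and a p-value threshold is set, when its p-value is at most
that threshold (small p = higher confidence the gene is expressed; both
conditions must hold within one resource). Across resources the default
is OR ("expressed somewhere relevant"), with an AND mode for stringent
analyses. Genes absent from every table are not expressed — missing
data is never imputed. GO filtering keeps an edge iff both endpoints
carry a direct annotation from the user's term list.

All filters return subsets, commute with each other, and are antitone
in thresholds; the suite verifies all three properties plus the
dual-endpoint rule against per-edge truth tables.

## Network statistics

Components are computed on the undirected graph; clustering uses the
simple graph without self-loops, with `c(v) = 2T(v)/(d(v)(d(v)−1))` and
`c(v) = 0` where `d(v) < 2` (one of the two standard averaging
conventions; stated so numbers are comparable). Degrees follow the
convention that a self-loop adds 2 to its node's degree, which keeps
`Σ d·count = 2·|PPIs|` exact. The weight histogram uses 20 equal
right-closed bins on [0,1]. The empty network reports zeros, with
average clustering 0 by convention. Results are cross-checked against
brute-force triangle enumeration and label-propagation component
counting on random graphs of ≤30 nodes.

## Synthetic data generator

The generator emulates the structural features the pipeline must
handle, with every planted quantity recorded in a JSON manifest
computed by plain set arithmetic (independent of the pipeline code):

- a two-block edge model — edges inside planted GO modules additionally
  carry a coimmunoprecipitation-family method, while every edge carries
  two-hybrid — so the likelihood-ratio *directions* are known by
  construction (coimmunoprecipitation group > 1, two-hybrid ≈ 1);
- cross-source duplicate pairs (consolidation must collapse exactly
  those), records with prediction-only methods (whitelist must discard
  exactly those), one-to-many identifier aliases (mapping must multiply
  exactly those, and the alias partners are chosen so every expanded
  edge is new, keeping `edges = mapped records − duplicates` exact),
  unmappable identifiers, malformed rows, and one self-loop;
- per-resource expressed/silent gene sets around a threshold of 1.0,
  with expressed values in (2,10) and silent values in (0,0.5).

Defaults: 80 genes, 150 unique edges over 3 sources, GO modules of 15
and 12 genes, 30% module edges / 20% mixed / 50% background, 15%
prediction-only records, 10 duplicate pairs, 4 aliases, 3 unmappable
records, 2 malformed rows, expression fractions 0.75 and 0.60. These
sizes give stable likelihood ratios (reference sets of dozens of edges)
while keeping the full suite and the acceptance script under a few
seconds. All randomness flows from one seeded generator; identical spec
and seed give byte-identical files.

What passing on synthetic data does **not** show: real databases have
correlated curation (the same publication propagated everywhere),
study bias toward famous proteins, heavy-tailed degree distributions,
and detection methods whose errors correlate — none of which the
generator emulates. The tests establish that the *mechanics* (counting,
unioning, the scoring arithmetic, the filter algebra) are exact, not
that the default whitelist/grouping or any particular GO selection is
biologically optimal for a given organism.

## Determinism and outputs

There is no unseeded randomness anywhere in the pipeline: edge
iteration is sorted, file writes are ordered, and re-running with
identical inputs yields byte-identical outputs. Edge files carry a
comment line with a hash of the run configuration (inputs and
parameters; not the output location) for provenance. When a secondary
identifier map is supplied, each edge file is written twice — primary
gene identifiers and symbols — with untranslatable genes keeping their
primary identifier rather than being dropped.

## Known limitations

- MITAB 2.6/2.7 expansion columns are not parsed (first 15 columns
  only); interaction-type and complex-expansion fields are ignored.
- The Bayesian parametrization (Laplace α, global prior π) is one
  standard choice among several; per-method priors or score floors are
  not implemented.
- Cross-species records are accepted by default (organism selection is
  assumed to have happened upstream when exporting the MITAB files);
  `filter_intra_species` rejects them explicitly when needed.
- Expression filtering is presence/absence per resource; no use is made
  of expression magnitude beyond the threshold.
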
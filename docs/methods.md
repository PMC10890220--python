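# Methods

## Morphometrics

Measurements are per-metaphase arm lengths (p = short arm, q = long arm,
0 ≤ p ≤ q, arbitrary units shared within a plate). Relative length uses
the haploid complement as denominator — one chromosome per pair, under
the assumption that homologues within a plate are equal — so RL sums to
100 per metaphase by construction. CI is stored as a percent in [0, 50],
matching how karyotype tables print it (the underlying ratio is a
fraction).

Aggregation across plates reports the mean and sample SD (n−1
denominator; a single observation reports SD 0), applies classification
to the mean CI (not a per-plate majority vote), and re-ranks pairs by
descending mean RL with ties broken by higher mean CI, then input order,
so output is deterministic.

**Levan bands.** The classical centromere-position scheme is cited in
the literature without explicit cut points; this package uses CI bands
a [0, 12.5), st [12.5, 25), sm [25, 37.5), m [37.5, 50] — equivalent to
arm-ratio cut points 7.0, 3.0 and ≈1.67 — with each boundary assigned to
the band above it. These bands reproduce all 21 class labels of the
reference *H. mercatorius* table and are configurable (`bands=` in
`classify_levan`/`aggregate_pairs`) for collections that follow a
different convention.

**Fundamental number.** FN = 2n + 2·(pairs classed m or sm): st and a
chromosomes count one arm. Whether subtelocentrics count as two-armed
varies between authors; only the one-arm convention is consistent with
the reference karyotype's printed FN = 54 (2n = 42 plus six biarmed
pairs: m 1, 18–21 and sm 4), so it is used throughout, including in the
(n, b) projection of the event model.

**A note on the reference data.** The source discussion of the
mercatorius–mabouia comparison describes pairs 6, 13, 15, 18 and 20 as
"all acrocentric" in *H. mercatorius*, while the measurement table marks
pairs 18 and 20 metacentric in that species. The bundled fixture follows
the table (18, 20 metacentric in *H. mercatorius*, acrocentric in
*H. mabouia*); the five-pair difference set is identical under either
reading, because the two species disagree at those five pairs in both.
The readings are not reconciled silently — this paragraph is the record.

## Karyotype comparison

Pairs are matched purely by size rank (pair id), mirroring side-by-side
haploid karyograms; no optimal re-matching by length is attempted, since
rank is the only cross-species correspondence the data support. The
`biarmed` mode compares the one-armed/biarmed dichotomy, `exact-class`
the full m/sm/st/a label. Each differing pair is labelled
"Inv (or centromere repositioning)": the two mechanisms produce the same
morphological change and cannot be separated without molecular markers.
`apply_pair_inversions` toggles a pair between one-armed and biarmed
(default biarmed target: m, since inversion outcomes are not
sub-classified in this kind of data; the toggled pair's CI is set to the
band midpoint to keep the class/CI invariant).

## Event model

States are (n, b): haploid chromosome count and haploid biarmed count,
1 ≤ n, 0 ≤ b ≤ n. Pair identity is deliberately discarded — genus-level
karyotype evolution arguments operate on 2n and the biarmed count, and
per-pair ancestral assignment is unidentifiable from morphology alone.
Haploid arm count is n + b; FN = 2(n + b).

Legality rules: a centric fusion consumes two acrocentrics (n − b ≥ 2);
a tandem fusion needs two chromosomes with at least one acrocentric
participant (n ≥ 2 and n − b ≥ 1 — the extra condition keeps b ≤ n, the
state invariant, after the join); a fission splits one biarmed
chromosome into two acrocentrics (b ≥ 1); pericentric inversions need an
acrocentric (a→biarmed) or a biarmed (biarmed→a). Default costs are 1
for every event; the **fusion-dominated preset** raises fission to 3,
expressing the directional hypothesis that this clade's karyotypes
evolved mostly by fusions and inversions. The preset keeps fission
enabled so that upward paths are expensive rather than impossible;
disabling events entirely is supported through `enabled`.

Minimum-cost paths are found by Dijkstra search on the state grid
bounded by `n_max` (default 40; the bundled preset uses 30, which covers
every observed state with headroom). Co-optimal paths are resolved by a
lexicographic tie-break over event sequences in the order cF < tF < Inv
< fission, so returned paths are deterministic. A hand-rolled Dijkstra
is used because the path tie-break is over event labels, which generic
shortest-path libraries do not expose; the implementation is checked
against exhaustive sequence enumeration in the tests.

## Ancestral reconstruction

Sankoff weighted parsimony over the full (n, b) grid: leaf cost 0 at the
observed state (or at each state of an unresolved set) and ∞ elsewhere;
internal cost_v(s) = Σ_children min_s' [d(s, s') + cost_child(s')] with
d the all-pairs event distance (computed once per model and cached).
Multifurcations are allowed. All co-optimal root states are reported;
for display, one scenario is derived by a traceback that prefers higher
n, then lower b, at every tie — consistent with the directional
hypothesis but affecting presentation only.

The bundled genus fixture treats the tree as rooted between
*Cyrtodactylus* and *Hemidactylus*; topology and the (n, b) states of
non-focal tips are fixture metadata (the focal species carry published
values; where only 2n is published, b is entered as the value implied by
a fusion-dominated path, and a tip's b may instead be declared unknown
with `b = ?`, which expands to an equal-cost state range). Under the
fusion-dominated preset the root set is uniquely (24, 0) — 2n = 48, all
acrocentric — with one centric fusion on the branch into the
*Hemidactylus* crown; under equal costs the root set widens to
{(22, 2), (23, 1)}, illustrating that symmetric costs cannot orient
fusion against fission.

## Synthetic generators

`simulate_measurements` draws, per metaphase, each pair's CI from a
truncated normal on [0, 50] and its RL weight from a normal truncated at
0, renormalizes weights to a 100% total, applies a log-normal whole-plate
scale jitter (SD 0.1 by default — absolute lengths vary between plates,
relative ones do not), and emits (p, q) pairs. Defaults emulate the
reference table: 15 metaphases (the protocol's minimum plate count) and
the table's own per-pair SDs. CI and RL noise are independent because
the summaries being emulated report no covariance. What this generator
does **not** emulate: overlapping or bent chromosomes, differential
condensation, inter-individual vs inter-plate variance components (the
table's SDs pool both), or correlated measurement error — so passing
round-trip tests show the arithmetic is self-consistent, not that the
pipeline is robust to real cytological artifacts.

Because the reference table's printed RL column sums to 100.2 (a
rounding artifact of one-decimal printing), a zero-noise round trip
reproduces CI, SDs, classes and ranks exactly, and RL means up to the
global factor 100/100.2; tests assert exactly that.

`simulate_evolution` walks the tree in preorder, drawing per-branch
event counts (Poisson mean or fixed) and event types from configured
probabilities (defaults: cF 0.45, Inv 0.35, tF 0.10, fission 0.10 —
fusion-dominated, matching the directional hypothesis the reconstruction
preset encodes). An inversion draw picks uniformly among its legal
directions. Draws that are illegal in the current state are resampled up
to a bounded retry count and otherwise recorded as skips, never silently
dropped. The full truth record (internal states, per-branch event
sequences) is returned for recovery experiments.

## Recovery behaviour and its limit

`analysis/04_simulation_study.py` measures how often the true simulated
root lies in the co-optimal root set on random 8-tip trees, as a
function of event density (200 replicates, seed 7):

| events/branch (Poisson mean) | root recovered |
|---|---|
| 0.1 | 98% |
| 0.25 | 94% |
| 0.5 | 70% |
| 1.0 | 44% |
| 2.0 | 16% |

The decay is structural, not an implementation artifact: parsimony can
place the true root in the co-optimal set essentially only when some
root-to-tip lineage carries no net change, and at one expected event per
branch barely half of simulated histories retain even one tip witnessing
the root state. The DP itself is verified against brute-force assignment
minimization (total cost *and* co-optimal root set) on four-tip trees.

## Numerical choices

- Costs are floats; co-optimality uses an absolute tolerance of 1e-9
  (costs are sums of small integers in practice).
- The state grid is enumerated in fixed (n, b) order; all reported sets
  are sorted, and every tie-break is deterministic, so identical inputs
  give byte-identical outputs.
- Degenerate inputs: single-tip trees (root = tip, cost 0), single-pair
  karyotypes (RL = 100), single metaphases (SD = 0) are all defined and
  tested; zero total plate length, duplicate pair ids, p > q, and
  unreachable state pairs raise errors naming the offending item.

## Known limitations

- No gene-order, breakpoint or banding-level inference: the event model
  sees only (n, b), so e.g. which acrocentrics fused is unrecoverable.
- Polyploidy is outside the move set.
- NOR and heterochromatin positions are carried as annotations only;
  their evolution is not modelled.
- Phylogeny is an input; the package performs no tree inference.
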
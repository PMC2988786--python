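# Methods

## Scope and coordinates

`zfclass` implements a rule-plus-distance classification of candidate
proteins into the gli/glis/nkl/zic C2H2 zinc-finger superfamily, and a
Dollo-parsimony comparison of gene-family origin scenarios. All sequence
coordinates are 0-based with half-open intervals except where a trimming
rule is explicitly inclusive; this keeps the two trimming rules ("first
cysteine of ZF1 through last histidine of ZF5"; "prefix through the second
residue after ZF1's first cysteine") free of off-by-one ambiguity. `X`
(unknown residue) is accepted on input but never matches a consensus
position, never counts as identical or similar, and never contributes to a
p-distance.

## C2H2 detection and architecture assembly

A finger is any position quadruple `C..C..H..H` whose three internal gaps
(residues strictly between the flanking positions) fall within configurable
bounds, defaults:

| gap | default | rationale |
|---|---|---|
| Cys–Cys | 2–25 | canonical fingers use 2–4; the upper bound is deliberately wide because the zic ZF1 spacer is expanded and its exact lengths are not tabulated in machine-readable form |
| Cys2–His1 | 9–16 | classical C2H2 knuckle-plus-helix span |
| His–His | 3–6 | classical C-terminal histidine spacing |

Every quadruple is reported (including overlapping ones); a depth-first
search then selects the best chain of exactly five non-overlapping fingers
with every inter-finger linker ≤ 15 residues ("tandem" is not quantified in
the source material; 15 is configurable). Optimality is smallest total span,
ties broken to the leftmost start and then lexicographically by positions,
which makes the result deterministic. The search is exact; a brute-force
5-subset oracle over candidate sets ≤ 12 verifies it in the tests. A
permissive mode accepts the best 4-finger chain flagged `partial`, because
real family members with an unrecoverable ZF1 are classified from ZF2–ZF5.

The zic diagnostic is `ZF1 Cys–Cys spacer ≥ 8`. The threshold is a design
choice, not a measured value: it sits midway between the canonical 2–4 and
the expanded zic spacers the generator plants (10–14), it is configurable,
and every report surfaces it so calls are auditable. In partial mode the
first detected finger may be ZF2, so the spacing criterion is not allowed to
fire; motif evidence must carry a zic call.

## Motif scoring

Consensus patterns are sequences of scored positions (fixed residue or an
alternative set like F/L) and at most bounded spacers. Matching is gapless
within each segment; the scanner scores *every* (offset, spacer-length)
placement and an exhaustive enumeration oracle checks it in the tests.
Percent identity counts positions where the query residue is (a member of)
the consensus position; percent similarity additionally accepts residues in
the same physicochemical class. The default partition —

aliphatic {A,V,L,I,M}, aromatic {F,Y,W}, basic {K,R,H}, acidic {D,E},
amide {N,Q}, hydroxyl {S,T}, singletons {G},{P},{C}

— is the standard simple scheme, and it is pinned by four simultaneous
constraints from the documented sequence pairs: AKQE/IKQE must be 75/100
(A~I similar), GAFFRFMR/GAFFRYMR 100 similar (F~Y), HDYIHH/RDFLRR 100
similar (H~R, Y~F, I~L), and SPAKDN/QPIKQE exactly 50 (S–Q, D–Q, N–E must
all be *dis*similar). Identity implies similarity by construction, so
%id ≤ %sim always; a 10,000-pair randomized test asserts it.

One documented discrepancy: direct counting for GAFFRFMR vs GAFFRYMR gives
7/8 = 87.5 % identity, while the source text prints "86 % identical"; the
denominator behind 86 is unrecoverable, so only the 100 % similarity value
is treated as reproducible.

A motif is reported "present" at ≥ 70 % similarity (configurable); the best
sub-threshold placement is still retained for reporting, mirroring how
weakly conserved ZOC-like regions are discussed rather than discarded. The
ZF-NC location check requires the match to end at most 30 residues (default)
upstream of ZF1's first cysteine.

## Classification and placement

Rules first: no architecture → `non-family`; architecture without zic
evidence → `gli/glis/nkl-like`; expanded ZF1 spacing *or* an
above-threshold ZOC or location-checked ZF-NC → `zic` (either character
suffices — the evidence trail records all of them, so stricter readings can
be applied downstream). Placement against a labelled panel (≥ 2 members per
subfamily) assigns the subfamily with the smallest mean p-distance over the
trimmed ZF region, and is advisory: it refines `gli/glis/nkl-like` into
gli/glis/nkl — which no stated sequence character can separate — but never
overturns the rule-based zic/non-zic decision. Exact distance ties break to
the rule label when compatible, else lexicographically, and are flagged.

The p-distance uses the best gapless sliding offset of the shorter sequence
along the longer — a deliberate simplification that is exact for equal-length
templates and conservative otherwise; full alignment-based inference is out
of scope, and the trimmed ZF region matches the region a phylogenetic
analysis of this family would align. Neighbor joining (scikit-bio) over
these distances provides the optional tree output; NJ consistency on
additive 8-leaf matrices is verified in the tests.

## Origin scenarios

For a candidate origin node, Dollo parsimony fixes one gain there and counts
losses per edge: the minimal loss set is exactly the set of maximal
all-absent subtrees under the origin, so the count is computed by a single
post-order sweep and verified against exhaustive loss-edge enumeration on
trees ≤ 8 leaves. A scenario is infeasible when a present leaf falls outside
the origin's subtree. Fitch two-state parsimony (generalized to polytomies
by majority-state counting) gives the unconstrained minimum; feasible Dollo
totals can never beat it, and a property test asserts the bound. The bundled
default topology is a metazoan ladder — Porifera and Ctenophora branching
before a Placozoa + (Cnidaria, Bilateria) clade — on which a root origin of
zic costs 1 gain + 2 losses against 1 gain + 0 losses for an origin in the
placozoan/cnidarian/bilaterian ancestor. The basal branching order is
debated; any rooted newick may be supplied instead.

## Synthetic data: what it does and does not emulate

The generator plants the *defining characters* exactly: five tandem fingers
with fixed internal geometry (Cys2–His1 gap 12, His–His spacer 4, linkers
7), subfamily-specific ZF1 spacers (gli 2, glis 3, nkl 4; zic drawn
uniformly from 10–14), and — for zic — exact-consensus ZOC and ZF-NC
instances with randomized spacer lengths, the ZF-NC 2–8 residues upstream
of ZF1. Each subfamily has one deterministic ZF-region template (fixed
internal seed) so that same-subfamily members are near-identical and
placement measures subfamily affinity; filler is uniform over the 18
non-C/H residues, which makes the planted coordinating positions the only
pattern anchors. Point mutations are applied per residue at rate μ, drawing
replacements from the same background alphabet and sparing the four
coordinating positions of each finger, so recovery tests measure pipeline
behaviour rather than generator damage.

Non-zic N-terminal tails are rejection-sampled until they contain no
chance ≥ 70 %-similarity motif placement; without this, ~4 % of random
tails would carry a ZOC-like stretch and the planted label would contradict
the characters that define it. Consequences of the design: recovery at
μ = 0 is exactly 100 % by construction, and residual errors at μ > 0 come
from mutation-created chance motifs (sub-1 % rates). Because those events
are rare, the monotone-degradation check (recovery at μ = 0 ≥ 0.02 ≥ 0.1)
is evaluated on 1000-record datasets, the size at which the expected
ordering dominates Poisson noise; the headline recovery criterion uses
n = 200 at μ = 0.02.

What the generator does **not** emulate: realistic amino-acid composition,
indels, correlated substitution processes, evolution along a tree, or
divergence *between* members of a subfamily beyond point noise. Passing
recovery tests therefore demonstrates correctness of the detection and
decision machinery under the stated noise model, not expected accuracy on
real proteomes.

## Numerical and degenerate-input choices

Percentages are exact rationals times 100 stored as floats and reported to
one decimal. Motif ordering is (similarity, identity, leftmost, shortest) —
fully deterministic. Architecture tie-breaks are documented above. Degenerate
inputs: a ZF1 cysteine within the first three residues yields the available
N-terminal prefix with a warning; an all-absent presence map is an error (no
origin is defined); fewer than 3 taxa cannot be joined into a tree; an empty
reference panel or a subfamily with fewer than two members is rejected.

## Known limitations

Rule thresholds (spacing ≥ 8, similarity ≥ 70 %, linker ≤ 15, ZF-NC gap
≤ 30) are configurable conventions, not fitted quantities. The sliding
p-distance underestimates similarity when an indel falls mid-region. The
generalized Fitch count for polytomies is the standard majority heuristic.
Whether ZOC/ZF-NC presence alone should suffice for a zic call is left as a
configuration-level question; the default accepts either character and
records both.
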
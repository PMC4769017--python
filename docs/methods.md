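# Methods

## Motif scanning model

A MAPK catalytic domain is recognized here by its two short conserved
anchors rather than by a full kinase profile: the catalytic-loop block
`H-R-D-L-K-P-N` upstream of the activation segment and the APE-region block
`T-R-W-Y-R-A-P` downstream of it. Both anchors are expressed as
PROSITE-syntax patterns and may be replaced in the anchor catalog
(a YAML file) by any pattern the engine supports.

The pattern engine implements literals, `[..]` ambiguity sets, `{..}`
exclusion sets, `x` wildcards and `(i)` / `(i,j)` repeat counts. Matching
tolerates up to `max_mismatches` violated positions (default 2 per anchor),
with two deliberate restrictions: mismatches are charged per position, and
only inside fixed-length elements — variable-length elements must match
exactly, so every candidate span has a well-defined registration and each
span is reported once with its best mismatch count.

Domain assembly pairs every N-anchor hit with the nearest downstream
C-anchor hit that leaves a positive gap. Within the open inter-anchor
region, triplet candidates are positions whose residue lies in the
configurable first-position set (default `{T, S, K}`, covering every motif
reported in fungal MAPKs) with a tyrosine two positions downstream. When
several candidates exist the scanner prefers the one whose distance from
triplet end to C-anchor start falls inside the offset window (default 4–14
residues, a heuristic read off curated MAPK alignments; configurable) and
is closest to the C-anchor; with no in-window candidate it falls back to
the candidate nearest the C-anchor. Pairs without any candidate produce no
annotation. When a protein yields several domains, all are reported;
`primary_annotation` selects fewest total anchor mismatches, then leftmost.

Coordinates in all reports are 1-based inclusive.

## Motif catalog

Canonical motifs: T-E-Y, T-G-Y, T-D-Y, T-P-Y. Novel fungal motifs: T-T-Y,
T-I-Y, T-N-Y, T-H-Y, T-S-Y, K-G-Y, T-Q-Y, S-E-Y, S-D-Y. T-D-Y carries a
note that it has not been observed in fungal MAPKs. The group map assigns
motifs to the four major fungal MAPK phylogenetic groups (A: TEY, TGY, TNY,
KGY, THY, TSY; B: TEY, TGY, TQY, THY; C: TEY, TGY, TNY, KGY; D: TEY, TGY,
TIY, TTY, SEY, SDY). Group labels for individual sequences are supplied by
the caller (e.g. from a tree cut or a curated file); this package does not
recompute maximum-likelihood groupings. Motifs are stored undelimited
("TEY") and dashed only for display. Both catalogs ship as editable YAML.

Gene names follow the initials rule — uppercase genus initial + lowercase
species-epithet initial + "MPK" — with `-A`, `-B`, … suffixes appended in
first-appearance order when a species has several paralogs.

## Consensus annotation

Column consensus uses two thresholds (defaults 90% and 50%). The
denominator excludes gaps: consensus describes agreement among residues
that are present. Ties among co-maximal residues break toward the
alphabetically smallest so output is deterministic; all-gap columns are
"none". These conventions are declared rather than inherited from any
particular alignment viewer, which do not document theirs.

## Evolution statistics

Both tests run on amino-acid alignments. Gaps and the ambiguity codes X, B,
Z are treated as missing data — the conservative reading when ambiguous
residues cannot be compared.

**Tajima's D** uses pairwise deletion: `k̂` is the mean over sequence pairs
of raw difference counts (pairs with zero comparable sites are excluded
from the mean), `S` counts columns whose present residues show at least two
states, and `n` is the full column count, so `π = k̂/n` and `p_s = S/n` are
per-site. The variance coefficients are the standard `a1, a2, b1, b2, c1,
c2, e1, e2` series; `D` requires `m ≥ 4` and `S ≥ 1` and raises a
degeneracy error otherwise. A summary-driven entry point
(`tajima_d_from_summary`) recomputes `D` from published `(m, S, p_s, π)`
rows with `n = round(S/p_s)` — the per-site convention for π was validated
by its reproducing all four published D values from the printed summaries.
An optional pre-filter drops columns with more than 5% missing data (95%
site coverage) before analysis.

**Relative-rate test** uses complete deletion. For three gap-free sequences
every surviving column falls into exactly one of five categories (all
identical, all divergent, or one sequence carrying the unique state), so
the "shared-pair remainder" is identically zero; it is still computed and
reported to make the conservation identity explicit. The chi-square is
`(u_A − u_B)²/(u_A + u_B)` on 1 df, with the upper tail taken in closed
form as `erfc(sqrt(x/2))`; `u_A + u_B = 0` returns a flagged
no-information result (χ² = 0, p = 1) rather than an error.

## Distance utility

p-distances (differences / sites compared, per pair) feed a standard
neighbor-joining implementation (scikit-bio's, with negative branch lengths
clamped to zero). This is plumbing for driving group summaries end to end,
not a substitute for model-based phylogenetics.

## Synthetic data

`gen_kinase_cohort` plants, per record: random N-flank, N-anchor (with
exactly `anchor_mutation_budget` substitutions), a random loop prefix, the
requested triplet, a tyrosine-free loop suffix whose length is drawn inside
the scanner's offset window, the C-anchor (same budget), and a random
C-flank. The tyrosine-free suffix guarantees the planted triplet is the
candidate nearest the C-anchor, so recovery is exact whenever the scanner's
mismatch budget is at least the generator's. Background residues are drawn
uniformly over the 20 amino acids — no compositional realism is attempted,
which is a documented limitation: passing round-trip tests demonstrates the
scanner's correctness on its stated geometry, not its specificity on real
proteomes. Flank lengths default to 30–80 residues and loop prefixes to
5–12, in the range of real kinase activation segments.

`gen_alignment` uses a star genealogy: one uniform random ancestor, each
descendant substituted independently per site with probability `r`
(replacement uniform over 20 residues, so the realized change probability
is `19r/20`). This exercises every term of the D computation but is not a
coalescent null. Under it, per column, two sequences differ with
probability `(2r − r²)·19/20` and the column is monomorphic with
probability `q^m + 19·s^m` where `q = 1 − 19r/20` and `s = r/20`.
`neutral_rate(m)` solves

    (2r − r²)·19/20 = (1 − q^m − 19 s^m) / a1

so the diversity-based and segregating-site-based estimators agree in
expectation and the mean of D is approximately centred at zero; the
neutrality check therefore uses a 3-standard-error band over replicates
rather than an exact null. At m = 12 the calibrated rate is ≈ 0.166.

`gen_triple` constructs each site-partition category column explicitly and
shuffles column order; a nonzero shared-pair remainder is realized as
columns carrying an `X`, which complete deletion removes, so the measured
partition equals the specification exactly.

All generators are pure functions of (spec, seed); identical seeds yield
byte-identical output.

## Problem sizes and numerical choices

The test suite checks the D implementation against a plain-loop oracle on
1000 random alignments with m ≤ 6 and n ≤ 12, the pattern matcher against a
naive recursive matcher on sequences up to length 30 over a reduced
alphabet, and the neutrality band over 240 replicates of m = 12, n = 400
star alignments — sizes at which the brute-force oracles are exact and the
whole suite runs in seconds. Verification against published values uses
|ΔD| ≤ 1e-3, |Δχ²| ≤ 5e-3, |Δp| ≤ 1e-4 and |ΔΘ| ≤ 1e-5, the printed
precisions of those quantities.

One published inconsistency is handled explicitly: the neutrality table
prints D = 3.500934 for the all-fungal-MAPKs row while the accompanying
text says −3.500934. The formula forces a positive sign whenever
`π·n > S/a1`, which the printed summary satisfies, so the table value is
taken as correct; the package does not silently flip signs.

## Known limitations

* Anchor-based domain confirmation replaces profile (weight-matrix)
  scanning; proteins with heavily diverged anchors (> mismatch budget) are
  missed, and the offset window is a heuristic.
* The scanner reports the best triplet per anchor pair by the declared
  selection rule; biological activation loops with several plausible
  phospho-acceptor triplets are reduced to one call.
* Tajima's D here is the amino-acid variant used for descriptive scans of
  protein families; no coalescent confidence intervals are attached, only
  the ±2 rule of thumb.
* Neighbor joining is distance-based plumbing; groups A–D applied to real
  data should come from curated or model-based phylogenies.
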
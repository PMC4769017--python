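# mapkscan

Mitogen-activated protein kinases (MAPKs) are switched on by dual
phosphorylation of a three-residue **T-x-Y** motif in the activation loop of
the kinase domain. In fungi this motif is far more variable than the
textbook T-E-Y / T-G-Y forms: surveys of fungal proteomes have reported nine
additional variants (T-T-Y, T-I-Y, T-N-Y, T-H-Y, T-S-Y, K-G-Y, T-Q-Y, S-E-Y
and S-D-Y). `mapkscan` is a small toolkit for doing this kind of survey
reproducibly and for asking how the resulting gene families evolve:

* **Motif scanning** — a PROSITE-syntax pattern engine locates the two
  conserved kinase-domain anchors that flank the activation loop
  (`H-R-D-L-K-P-N` on the N-terminal side, `T-R-W-Y-R-A-P` on the
  C-terminal side, each with a configurable mismatch budget) and extracts
  the T-x-Y triplet between them.
* **Cataloguing** — extracted triplets are classified as canonical, novel
  or unknown, rolled up into per-species and per-phylogenetic-group census
  tables, and named by the *Genus species* initials rule (e.g. `AkMPK`).
* **Molecular-evolution statistics** — Tajima's test of neutrality and
  Tajima's relative-rate test on amino-acid alignments, with pairwise- and
  complete-deletion gap handling, plus p-distances and a neighbor-joining
  utility.
* **Synthetic data** — seeded generators plant anchors and chosen triplets
  into random protein backgrounds, build star-genealogy alignments with a
  controlled substitution rate, and construct three-sequence alignments
  with an exact target site partition, so the entire pipeline is testable
  without downloading any proteome.

## The statistics

For an alignment of `m` sequences and `n` usable sites with `S` segregating
sites and mean pairwise difference count `k̂`:

```
p_s = S / n          Θ = p_s / a1          π = k̂ / n
D  = (k̂ − S/a1) / sqrt(e1·S + e2·S(S−1))
```

where `a1 = Σ_{i<m} 1/i` and `e1`, `e2` are the standard variance
coefficients (`b1 = (m+1)/(3(m−1))`, `b2 = 2(m²+m+3)/(9m(m−1))`,
`c1 = b1 − 1/a1`, `c2 = b2 − (m+2)/(a1·m) + a2/a1²`, `e1 = c1/a1`,
`e2 = c2/(a1²+a2)`). The relative-rate test compares the lineage-specific
unique substitution counts `u_A`, `u_B` of two ingroup sequences against an
outgroup over complete-deletion sites:

```
χ² = (u_A − u_B)² / (u_A + u_B),   df = 1,   p = erfc(sqrt(χ²/2))
```

## Worked example

```python
>>> import mapkscan as mk

# Tajima's D from a published summary row (m, S, p_s, pi):
>>> res = mk.tajima_d_from_summary(m=24, S=265, n=round(265 / 0.880399), pi=0.514011)
>>> print(f"Theta={res.theta:.6f}  pi={res.pi:.6f}  D={res.D:.6f}")
Theta=0.235761  pi=0.514011  D=4.751471

# Relative-rate test on a three-sequence alignment with a known site partition:
>>> aln = mk.gen_triple(mk.TripleSpec(identical_all=130, divergent_all=83,
...                                   unique_a=64, unique_b=38, unique_c=20, seed=1))
>>> rr = mk.relative_rate_test(mk.relative_rate_counts(aln, outgroup_id="C"))
>>> print(f"chi2={rr.chi2:.2f}  p={rr.p:.5f}")
chi2=6.63  p=0.01004

# Scan a synthetic cohort and summarize its motif repertoire:
>>> spec = mk.CohortSpec(species=(mk.SpeciesSpec("Saccharomyces", "cerevisiae",
...                                              "Ascomycota", ("TEY", "TGY", "TNY", "KGY")),), seed=7)
>>> records, _ = mk.gen_kinase_cohort(spec)
>>> rows = mk.summarize_by_species(mk.scan_records(records))
>>> print(rows[0].species, rows[0].n_mapks, ", ".join(rows[0].motif_set))
Saccharomyces cerevisiae 4 TEY, TGY, TNY, KGY
```

`D = 4.75` (well above the +2 rule of thumb) indicates an excess of
intermediate-frequency variation relative to the neutral expectation for
that sequence set; `χ² = 6.63, p ≈ 0.01` rejects equal evolutionary rates
for the two ingroup lineages; and the census row recovers exactly the four
motifs planted in the synthetic *S. cerevisiae* cohort.

The same stages are available from a shell via the `mapkscan` console
script (`scan`, `summarize`, `tajima-d`, `relrate`, `simulate`, `nj`); see
`mapkscan --help`.

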
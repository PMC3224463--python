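# utrscape

Does the length of the 5' untranslated region track organismal complexity?

`utrscape` is a tested, reusable pipeline for the comparative analysis behind
that question. It catalogs 5'UTRs under explicit transcript-quality filters,
scans them for upstream start codons (uAUGs) and upstream open reading frames
(uORFs), measures expression breadth and tissue specificity under tissue
resampling, and correlates species traits with phylogenetically independent
contrasts. A synthetic multi-species panel generator with planted ground
truth makes every stage testable without any external database, and doubles
as a calibration rig for the statistics. It is aimed at molecular-evolution
and comparative-genomics researchers who want the full analysis — or any
single stage — reproducible from a seed.

## The statistics at the core

**Tissue specificity.** For one gene with nonnegative expression values
x₁…x_N over N tissues,

    τ = Σᵢ (1 − xᵢ / max(x)) / (N − 1)

so τ = 0 for uniform expression and τ = 1 for single-tissue expression. A
gene is *constitutive* for a sampled tissue set when it is called expressed
(intensity > 200, or ≥3 of 4 present calls) in every sampled tissue; the
log₂ ratio of non-constitutive to constitutive genes is the breadth summary.
Because tissue panels differ in size between species, k tissues are resampled
without replacement (default 10 × 1,000 replicates) and the summaries are
distributions over replicates, compared by Mann–Whitney U.

**Independent contrasts.** Cross-species trait correlations are corrected
for shared ancestry with Felsenstein's pruning: at each bifurcation with
child values x₁, x₂ and extended branch lengths v₁, v₂ the standardized
contrast is (x₁−x₂)/√(v₁+v₂); the parent gets the precision-weighted mean
and an inflated branch. Contrast pairs are sign-positivized on the x-member
and the association is summarized by the through-origin fit
(slope Σxy/Σx², uncentred R²) and Spearman's ρ, with a t-approximate
p-value on n−1 df.

**uORF rule.** A uORF starts at the first uAUG of a reading frame not
already inside an open uORF, ends at the first in-frame stop within the
5'UTR, and must be ≥9 nt (start codon, stop codon, and at least one codon
between). uAUGs are counted independently of whether they open a uORF.

## Worked example

Generate a 5-species panel with a planted Brownian-motion correlation of
0.9 between log 5'UTR length and the cell-type trait, then run the full
pipeline on it:

```sh
cat > panel.yaml <<EOF
n_species: 5
n_genes: 400
n_tissues: 10
trait_correlation: 0.9
seed: 11
EOF
utrscape synth --config panel.yaml --outdir panel

cat > run.yaml <<EOF
input_dir: panel
n_reps: 200
EOF
utrscape run --config run.yaml --outdir out --seed 11
```

The run prints the per-species 5'UTR length summaries, e.g.

```
"sp01": { "median_bp": 38.0, "mean_bp": 57.1, "mad_bp": 21.0, "n_genes": 313 }
"sp02": { "median_bp": 77.0, "mean_bp": 124.5, "mad_bp": 46.0, "n_genes": 315 }
```

— 313 of the 400 genes survived the eligibility filters for sp01; its
median 5'UTR is 38 bp, half as long as sp02's, because the planted
Brownian trait diverged between these lineages. `out/correlations.tsv`
holds the contrast correlations; the length-vs-complexity row of this run is

```
trait_x        trait_y     n_contrasts  spearman_rho  p_value  r_squared_origin
median_utr_bp  cell_types  4            0.800         0.104    0.814
```

With only 5 species there are 4 contrasts: the planted correlation shows a
large ρ but, correctly, does not reach significance — the pipeline's
end-to-end tests demonstrate that at 15 species the same planted signal is
detected in ≥18 of 20 seeded runs while null panels stay quiet.
`out/report.json` groups every output under the five hypothesized
connections (i)–(v) between 5'UTR elongation and complexity, and
`out/distribution_tests.tsv` holds the species-pairwise Mann–Whitney
comparisons of the replicate τ, ratio, and median-length distributions.

Each stage is also a stand-alone subcommand (`synth`, `catalog`, `scan`,
`express`, `contrast`) whose seeded outputs match the pipeline's exactly.

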
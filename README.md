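# subwrap

Does subfunctionalization — the partitioning of an ancestral gene's
expression pattern across retained duplicates — carry an adaptive signal,
over and above the random drift that creates it? Gene duplication doubles a
protein's dose, and that matters most for proteins whose structural
integrity depends on binding partners: their backbone hydrogen bonds are
poorly "wrapped" by nonpolar side-chain groups and remain exposed to water.
`subwrap` implements the full analysis chain for testing whether paralog
expression divergence scales with this structural dosage sensitivity, with
whole-genome duplicates (which create no *relative* dosage imbalance) as the
negative control.

The package is aimed at molecular-evolution and structural-bioinformatics
researchers who want to run this analysis, or any of its stages, on their own
gene families — or on fully synthetic cohorts with known ground truth.

## The quantities

- **ζ (wrapping)** — for a backbone hydrogen bond, the number of nonpolar
  side-chain carbons inside the desolvation domain: the union of two 6 Å
  spheres centred on the α-carbons of the bonded residues. A bond with
  ζ ≤ 19 is a **dehydron**, an under-wrapped bond.
- **ν (under-wrapping ratio)** — per gene, ν = (#dehydrons)/(#BHBs), with
  counts pooled over all of the gene's product structures; proxy for dosage
  sensitivity. For genes without structures, ν can be inferred from
  per-residue disorder scores: residues with 0.35 ≤ f_d < 0.95 sit in the
  order–disorder twilight zone where dehydrons live.
- **η (expression diversification)** — Pearson correlation of two paralogs'
  expression vectors across tissues/conditions; ⟨η⟩ is the family mean over
  pairs. **S = (1 − ⟨η⟩)/2** is the segregation parameter (0 = co-expressed,
  1 = fully partitioned).
- **Ks** — synonymous substitutions per synonymous site (NG86 counting with
  Jukes–Cantor correction), a proxy for time since duplication; families
  with Ks ≥ 2 are discarded as saturated.
- **The regression** — ordinary least squares of Ks·⟨ν⟩ on a polynomial in
  ⟨η⟩ across families; binned means of S/Ks in 10% ⟨ν⟩-ranges; and, within
  the WGD-labelled subset, a seeded permutation test that the slope of S/Ks
  on ⟨ν⟩ is flat.

## Worked example

Simulate a cohort of 500 three-member families with the planted relation
Ks·⟨ν⟩ = 0.55 − 0.35·⟨η⟩ (noise SD 0.05) and no WGD subgroup, then run the
pipeline:

```sh
cat > ssd.yaml <<EOF
n_families: 500
wgd_fraction: 0.0
seed: 7
EOF
subwrap simulate --spec ssd.yaml --out bundle
subwrap run --expr bundle/expression.tsv --families bundle/families.tsv \
            --gene-nu bundle/gene_nu.tsv --ks-pairs bundle/ks_pairs.tsv \
            --out out
```

prints

```
{
 "degree_1": {
  "coefficients": [0.5464554083467273, -0.3559921504851087],
  "n": 500,
  "p_value": 7.131954033770975e-204,
  "r_squared": 0.8451845853055724
 },
 ...
}
```

The fitted intercept and slope (0.546, −0.356) recover the planted
(0.55, −0.35); R² = 0.845 is the fraction of Ks·⟨ν⟩ variance explained by
⟨η⟩ at this noise level (with `noise_sd: 0` the fit returns R² = 1 and the
coefficients exactly). With the default `wgd_fraction: 0.2` the same run
additionally reports the WGD control, e.g.
`"wgd_flatness": {"slope": -0.074, "p_value": 0.092}` — a flat,
non-significant S/Ks-vs-⟨ν⟩ slope in the subgroup whose duplicates never
experienced a dosage imbalance, while the small-scale-duplication families
carry the planted trend.

Individual stages are exposed as `subwrap wrap` (PDB → ζ, dehydrons, ν),
`subwrap nu-seq` (disorder tracks → ν_seq), `subwrap ks` (CDS FASTA →
pairwise Ks), `subwrap eta` (expression matrix → ⟨η⟩, S) and
`subwrap analyze` (records table → regression/binning/WGD test); every
command documents its knobs under `--help`, and the same operations are
importable from `subwrap.structure`, `subwrap.disorder`,
`subwrap.divergence`, `subwrap.expression`, `subwrap.analysis` and
`subwrap.simulate`.

## Layout

```
src/subwrap/
  structure.py    PDB parsing, BHB detection, zeta, dehydrons, gene nu
  disorder.py     disorder-band inference, nu_seq, order-sustainability filter
  divergence.py   codon alignment, NG86+JC Ks, family aggregation
  expression.py   pearson eta, family <eta>, segregation S
  analysis.py     record assembly, regression, binning, WGD permutation test
  simulate.py     helix/codon/expression/cohort generators with ground truth
  io.py           TSV/FASTA/JSON readers-writers, config, orchestrator
  cli.py          the `subwrap` command
docs/methods.md   models, assumptions, parameter choices, limitations
```
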
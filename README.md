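# fretab

Quantitative analysis of FRET acceptor-photobleaching interaction studies,
with the companion analyses such studies lean on: co-localization, structure-
prediction confidence scoring, and sequence-feature analysis of the
interacting regions. The package was built around studies of nuclear
scaffold–splicing-factor complexes (e.g. the Usher-syndrome protein SANS
binding the tri-snRNP factors PRPF31 and PRPF6), but every stage is generic.

## What it computes

**FRET acceptor photobleaching.** For a donor/acceptor pair (e.g. eCFP/eYFP),
the acceptor is bleached and the interaction is read out as donor
de-quenching. Per region of interest (ROI),

    FRET_eff   = (D_post − D_pre) / D_post
    Bleach_eff = (1 − A_post / A_pre) · 100   [%]

Only ROIs with bleach efficiency > 60% enter the analysis. The per-cell
value is the mean over up to six QC-passing ROIs in the bleached area minus
the same quantity on an unbleached reference region ≥ 3 µm away; condition
tables can be normalized to a positive-control condition (a fused
donor–acceptor tandem). Conditions are compared with an exact Wilcoxon
signed-rank test (full sign-assignment enumeration for n ≤ 25) with stars
\* p ≤ 0.05, \*\* p ≤ 0.009, \*\*\* p ≤ 0.0009.

**Co-localization.** Pearson correlation R of paired pixel intensities over
a mask (typically the whole nucleus), plus bilinear intensity profiles along
a polyline.

**Structure-prediction confidence.** Mean predicted aligned error (PAE) over
an interface block rows(a)×cols(b) of the PAE matrix; per-residue pLDDT from
a model's B-factor field; atomic contacts by van-der-Waals overlap
r_i + r_j − d ≥ −0.4 Å, with interface residue summaries per chain.

**Sequence features.** IDR consensus calling (disorder score > 0.5 OR
pLDDT < 50, strict, with a minimum run length), conservation profiles over a
multiple sequence alignment in reference coordinates, and diagram-of-states
charge classification (FCR/NCPR; the R2 boundary class is the "Janus"
regime, 0.25 ≤ FCR ≤ 0.35).

**Synthetic data.** Everything above is exercisable without raw microscopy:
`fretab.synthmicro` renders four-channel acquisitions with known ground
truth (donor de-quenching photophysics, Poisson shot noise, Gaussian read
noise, uniform background), correlated co-localization pairs, and
disorder/pLDDT tracks with declared segments. In the noiseless limit the
pipeline provably recovers E·B/(1 − E(1 − B)).

## Worked example

Simulate three conditions (an interacting pair, a negative control, and the
tandem positive control used for normalization), then quantify:

```bash
fretab simulate fret --out demo/data --config demo.yaml --seed 7
fretab fret quantify --manifest demo/data/manifest.csv \
    --out demo/out --control positive-control
```

with `demo.yaml`:

```yaml
n_cells: 6
conditions:
  SANS-PRPF31: {e_true: 0.25, b_true: 0.9}
  negative-control: {e_true: 0.0, b_true: 0.9}
  positive-control: {e_true: 0.35, b_true: 0.9}
```

prints

```
       condition     mean      std  count
     SANS-PRPF31 0.700869 0.018835      6
negative-control 0.006900 0.011724      6
positive-control 1.000000 0.021086      6
SANS-PRPF31 vs positive-control: wilcoxon-signed-rank W=0 p=0.03125 * (exact, rank-order pairing)
negative-control vs positive-control: wilcoxon-signed-rank W=0 p=0.03125 * (exact, rank-order pairing)
```

The `mean` column is the normalized FRET efficiency per condition: the
positive control is 1 by construction, the non-interacting pair sits at 0
within noise, and the interacting pair recovers its generating efficiency
(0.25 of true E with 90% bleach, against a 0.35 control, gives a normalized
value of ≈ 0.70). Both comparisons against the control are significant at
the `*` band with six cells per condition. `demo/out/` also holds the
per-cell and per-ROI tables, the pairwise statistics, and a
`provenance.json` recording parameters and input digests.

The same stages are importable directly (`fretab.fretquant.run_fret_pipeline`,
`fretab.structconf.pae_region_mean`, `fretab.seqfeat.charge_classify`, ...);
the CLI is a thin layer over them.

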
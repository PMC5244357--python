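# plasmacall

Personalised multiplexed amplicon ctDNA detection: error-corrected,
control-calibrated calling of patient-specific somatic mutations in blood
plasma, with the panel QC, dilution-series validation and cohort metrics
that such an assay needs — plus a synthetic-data generator so the whole
pipeline is testable end to end without any sequencing data.

## Who this is for

Groups building tumour-informed minimal-residual-disease (MRD) assays:
a patient's resected tumour is sequenced, up to 15 somatic variants are
chosen, and a multiplex PCR amplicon panel over those variants is applied
to serial plasma samples. The analytical challenge is that true ctDNA
signal sits at allele fractions of 10⁻⁴-10⁻², below the raw per-base
sequencing error rate (~2.8 × 10⁻³), and that a 10 ng plasma extraction
contains only ~3000 genome equivalents (GE) of template, which bounds
detection no matter how deep the sequencing.

## The method

Two error-correction stages precede a per-amplicon hypothesis test:

1. **Paired-end consensus masking.** Overlapping 2 × 150 bp mates are
   merged; any position where the mates disagree becomes `N`. A
   substitution must hit both mates identically to survive, so the
   concordant-position error rate falls from *e* to ≈ *e*²/3 when mate
   errors are independent.
2. **Same-run negative controls.** Each sample is sequenced with up to
   three variant-free control libraries. Per target, the control with the
   *highest* variant-read proportion is the reference — a deliberate
   guard against overdispersion that three controls are too few to model.
3. **Exact conditional Poisson rate-ratio test.** With k₁ variant reads of
   n₁ informative depth in the sample and k₂/n₂ in the worst control, and
   counts modelled as Poisson, conditioning on m = k₁+k₂ gives
   X ~ Binomial(m, p₀), p₀ = n₁/(n₁+n₂) under a rate ratio of 1. The
   one-sided p-value is P(X ≥ k₁); an amplicon is called at p < 0.01
   (a cutoff calibrated by a ROC sweep, `calibrate_cutoff`), provided it
   passes a 1000X depth filter. A sample is ctDNA-positive when any
   amplicon is called.

The template bottleneck is explicit throughout: the probability that a
variant at fraction *f* is physically present among *G* sampled genome
equivalents is 1 − (1−f)^G, e.g. 95.0% at f = 0.1% and G = 3000.

## Worked example

`python examples/simulate_and_call.py` simulates a 10-amplicon panel, a
plasma sample at 0.5% ctDNA fraction and three negative controls at the
2.8 × 10⁻³ error regime, then runs the full caller:

```
amplicon_id  variant_reads  depth      vaf      p_value  called    status  control_index
      AMP01             14   2980 0.004698 6.117871e-05    True evaluable              0
      AMP02             19   2994 0.006346 1.962644e-06    True evaluable              0
      ...
      AMP10             11   2979 0.003693 4.900879e-04    True evaluable              1

sample positive: True; reported ctDNA fraction: 0.006716
```

Each row is one amplicon: k variant reads of n informative depth (reads
with `N` at the target are uninformative and excluded), the exact-test
p-value against the highest-proportion control, and the call at p < 0.01.
The sample fraction is the highest VAF among called amplicons.

Other examples: `error_correction_cascade.py` (the raw → merged →
noise-filtered error-rate cascade on variant-free plasma),
`dilution_linearity.py` (expected vs observed frequency over a 1:10 …
1:2560 dilution series), `panel_design.py` (variant ranking, tissue QC,
primer-dimer screening), `detection_limits.py` (genome-equivalents
ceiling and panel-size sensitivity), `longitudinal_monitoring.py`
(post-operative timelines and lead time).

A thin CLI mirrors the stages for shell use:

```bash
plasmacall simulate --n-amplicons 10 --fraction 0.005 --outdir run/
plasmacall merge --r1 run/sample_R1.fastq.gz --r2 run/sample_R2.fastq.gz --out run/merged.fastq.gz
plasmacall count --merged run/merged.fastq.gz --panel run/panel.tsv --out run/counts.tsv
plasmacall call --counts run/counts.tsv --control-counts run/ctl1.tsv ... --out run/calls.tsv
```

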
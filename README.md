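# ribocompete

Mechanistic modelling of how impaired translation elongation reshapes the
translatome. When eukaryotic elongation factor 2 (eEF2) is depleted,
ribosomes dwell longer on every mRNA, the free ribosomal subunit pool is
drained, and transcripts must compete for the ribosomes that remain.
Paradoxically, this *up*-regulates translation of ribosomal-protein mRNAs —
the 5′-terminal oligopyrimidine (TOP) class — without any mTOR signalling.
`ribocompete` implements that explanation end to end, for computational
biologists who want to interrogate the competition model, simulate its
stochastic counterpart, or benchmark translation-efficiency (TE) pipelines
on synthetic Ribo-seq/RNA-seq data with known ground truth.

## The model

At steady state a transcript present at concentration *m* produces protein
at rate

```
Q = m·R·ki·[ 1 − L / (ke/(ki·R) + L − 1) ]
```

where *R* is the free-ribosome level, *ki* and *ke* the initiation and
elongation rate constants, and *L* the ribosome footprint in codons. The
bracket is the probability that the start region is not occluded by a
slowly departing ribosome. Only the dimensionless combination
*x = ki·R/ke* matters: yields vanish at the jamming boundary *x = 1*, and
the per-copy ribosome load *n·x·p(x)* peaks at the maximal-current point
*x\* = 1/(√L+1)*.

Around this closed form the package builds:

- **`ribocompete.model`** — the yield formula, yield ratios and curves,
  with hard domain errors in the jammed regime.
- **`ribocompete.pool`** — whole-cell closure: solve
  `R_free + Σ m·load = R_total`, predict sucrose-gradient polysome classes
  (free / monosome / light 2–4 / heavy >4 ribosomes), and run
  eEF2-knockdown scenarios. Depletion acts through a two-phase codon
  dwell — waiting for eEF2 (shared by all transcripts) then translocation
  (slowed by positively charged nascent residues in the exit tunnel) — so
  lysine/arginine-rich transcripts lose proportionally less speed when the
  factor becomes scarce.
- **`ribocompete.tasep`** — a Gillespie simulation of elongation as an
  exclusion process of extended particles, with the same two-phase dwell;
  it serves as a brute-force oracle for the closed form and quantifies the
  charge penalty directly.
- **`ribocompete.synthetic`** — a synthetic transcriptome with a TOP-like
  class (high *ki*, charge-rich, short) and paired mRNA-seq/Ribo-seq count
  matrices (negative binomial, paired biological factors, model-driven true
  effects) for control vs knockdown.
- **`ribocompete.te`** — size factors (median of ratios), TE estimation,
  label-permutation tests for differential TE (exhaustive when feasible),
  Benjamini–Hochberg correction, and rank-sum TOP-class enrichment.
- **`ribocompete.cli`** — `ribocompete generate|solve|simulate|analyze|pipeline`
  over JSON configs, with checksummed manifests.

## Worked example

```python
from ribocompete import *
from ribocompete.synthetic import calibrate_r_total

ts = generate_transcriptome(seed=0)          # 200 genes, 20 TOP-like
sc = KnockdownScenario(0.05)                 # 95% eEF2 depletion
R_total = calibrate_r_total(ts, sc)
res = simulate_knockdown(ts.transcripts, R_total, sc)

print(f"R_free: {res.baseline_pool.R_free:.3f} -> {res.knockdown_pool.R_free:.3f}")
print(f"mono/poly: {res.baseline_profile.mono_to_poly:.4f} -> "
      f"{res.knockdown_profile.mono_to_poly:.4f}")
print(f"heavy fraction: {res.baseline_profile.heavy_frac:.3f} -> "
      f"{res.knockdown_profile.heavy_frac:.3f}")
tab = res.table.assign(cls=ts.class_label)
print(tab.groupby("cls")["log2_rel_yield_change"].median().round(3))
```

prints

```
R_free: 2.744 -> 0.312
mono/poly: 0.0331 -> 0.0320
heavy fraction: 0.621 -> 0.649
cls
TOP      0.362
other   -0.182
Name: log2_rel_yield_change, dtype: float64
```

Reading: knockdown drains the free pool almost nine-fold, shifts ribosome
signal from monosomes into heavy polysomes, and redistributes protein
synthesis — the median TOP gene gains ~0.36 log2 units of relative yield
while the median bulk gene loses ~0.18, even though every gene's absolute
output falls. Feeding the same scenario through `generate_counts` and
`differential_te` recovers these effects from noisy counts and reports the
TOP class as significantly shifted up.

The same pipeline runs from the shell:

```
ribocompete pipeline --config config.json
```

where `config.json` needs at least `{"seed": 7}` (see
`ribocompete.cli.PipelineConfig` for all fields and defaults).

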
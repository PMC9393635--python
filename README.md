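# clonalai

Allele-specific transcriptome analysis of clonal versus polyclonal cell
populations, built around the hematopoietic single-stem-cell reconstitution
design: a female F1-hybrid hematopoietic system grown from one HSC is a
clone, so every epigenetically heritable allelic choice made in (or before)
that stem cell is shared by all of its descendants.

For every gene the allelic imbalance is the read-count fraction of one
parental allele,

    AI = maternal / (maternal + paternal),    AI ∈ [0, 1],

with AI = 0.5 for balanced biallelic expression. `clonalai` implements the
three analyses this design supports, plus a synthetic-study generator with
known ground truth so that each one is testable end to end:

1. **Overdispersion-corrected differential AI.** Library preparation makes
   allelic counts overdispersed relative to the binomial. From two technical
   replicates per library the package estimates a per-sample quality-control
   constant QCC ≥ 1 — the square root of the variance inflation of the
   standardized replicate AI differences
   `z = (AI₁ − AI₂) / sqrt(p̂(1−p̂)(1/n₁+1/n₂))` — and every binomial test and
   confidence interval then runs on *effective counts* `counts / QCC²`.
   Under a beta-binomial noise model with intraclass correlation ρ and
   coverage n, QCC → sqrt(1 + (n−1)ρ).
2. **X-inactivation analysis.** In a monoclonal female sample all cells
   silence the same X, so the X-linked AI median collapses to ~1 or ~0; the
   observed median is the mixture `(1−c)·χ + c·q` with `c` the
   recipient-cell contamination (estimated from a donor/recipient marker
   locus) and `q` the population X AI of the controls. Genes expressed from
   the inactive X (escapees) are called by displacement ≥ 0.1 from the
   sample's X median (QCC-corrected significance), expression > 10
   TMM-normalized counts, balanced controls, and a contamination-corrected
   inactive-X expression fraction ≥ 10%.
3. **Stable-RME discovery.** Autosomal genes with clone-specific,
   mitotically stable random monoallelic expression disperse across
   monoclonal samples but not across polyclonal controls. The screen
   compares per-gene AI standard deviations (threshold 0.15) after
   pairwise-significance and expression prefilters, tests the asymmetry
   with an exact one-sided signed-rank test, checks B-versus-T
   cross-lineage concordance within animals against a swapped-animal
   control, and excludes genetic causes with a whole-exome AI filter and a
   bootstrap of `AI_DNA − AI_RNA` over random gene sets.

## Worked example

```python
import clonalai as cl
from clonalai.pipeline import run_pipeline
from clonalai.validate import validate_bundle

cfg = cl.SimulationConfig(
    n_autosomal_genes=2000, n_x_genes=300, seed=1,
    frac_stable_rme=0.005, frac_escapee=8/300,
)
study = cl.simulate_study(cfg)
bundle = run_pipeline(cl.PipelineConfig(simulation=cfg, seed=1), study=study)

print({s: round(e.qcc, 2) for s, e in list(bundle["qcc"].items())[:3]})
print(bundle["escapees"].query("call").gene_id.tolist())
print(validate_bundle(bundle, study.truth, study.metadata)["stable_rme"])
```

prints (exact output at seed 1):

```
{'M1_B': 1.67, 'M2_B': 1.7, 'M3_B': 1.69}
['xgene0075', 'xgene0087', 'xgene0095', 'xgene0108', 'xgene0126',
 'xgene0131', 'xgene0133', 'xgene0292']
{'n_true': 10, 'n_called': 9, 'true_positives': 9, 'false_positives': 0,
 'recall': 0.9, 'fdr': 0.0, 'wilcoxon_p': 0.001953125}
```

The QCC values near 1.7 reflect the generator's default technical
overdispersion (ρ = 0.02 at coverage 100). All 8 simulated escapees are
called with no false positives, and 9 of the 10 simulated clone-specific
(stable-RME) genes are flagged — the miss is a clone-AI draw that happened
to be nearly identical across the five monoclonal animals, exactly the
failure mode the standard-deviation rule is blind to. The signed-rank p of
`2⁻⁹ ≈ 0.002` says every flagged gene disperses more in the monoclonal set
than in the controls.

The same run is available from a shell:

```sh
clonalai simulate --config sim.yaml --out study/
clonalai run --config pipeline.yaml --out report/
clonalai validate --config pipeline.yaml --out metrics.json
```

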
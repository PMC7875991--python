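# mirtail

Small RNA-seq microtranscriptome analysis with ground-truth validation:
miRNA quantification, isomiR and nontemplated-tail calling, uridylation
localization, fragment surveillance, differential expression and promoter
motif scanning.

## What it is for

Studies of miRNA regulation — for example of a transcription factor that
shapes both the abundance and the 3'-end modification state of the miRNA
pool in differentiating muscle cells — need a pipeline that goes from raw
small RNA-seq reads to:

* a **count matrix** over mature miRNAs that tolerates natural 5'/3' end
  heterogeneity: reads are mapped to pre-miRNA hairpins exactly (sense, no
  mismatches) and assigned to a mature miRNA when both ends lie within
  **±2 nt** of the annotated ends;
* **isomiR calls** that decompose each read into a templated core plus
  nontemplated 5'/3' additions (U-tails, A-tails), by maximal templated
  extension with a read-count threshold of 2 per modification signature;
* **arm-contrast statistics**: 3'-end modifications of the precursor can
  only surface on the mature 3p arm, so a 3p/5p U-tail frequency ratio ≫ 1
  localizes uridylation to the pre-miRNA while an A-ratio ≈ 1 places
  adenylation on mature miRNAs;
* **fragment surveillance**: 13–17 nt 5'-anchored degradation fragments,
  counted per miRNA with condition fold changes (no change = 1);
* **differential expression**: median-of-ratios normalization, a strict
  baseMean > 10 filter, a negative-binomial Wald test with
  Benjamini–Hochberg adjustment, and a cross-experiment log2FC regression;
* **promoter scanning**: log-odds PWM scan of ~1 kb regions on both strands
  with shuffle-based empirical p-values.

Everything runs against a built-in synthetic-read generator that emulates a
two-condition × three-replicate knockdown study (templated isomiRs, arm-
specific U/A tails with modal U-length 3, fragments, per-miRNA fold
changes, a halved 3p-uridylation rate and a 4× fragment rate in the
knockdown condition) and records complete per-read ground truth, so every
analysis is validated by recovery, not by eyeballing.

The model at the core of the differential test, for miRNA *i* and
normalized counts: dispersion `α̂ = max((s² − μ̄)/μ̄², 1e-8)`,
`log2FC = log2((m_B + ½)/(m_A + ½))`, NB variance `m + α̂ m²` per group,
Wald `z = log2FC / SE` with a two-sided normal p-value. See
`docs/methods.md` for every contract and the design rationale.

## Worked example

```python
from mirtail import (SimulationConfig, generate_reference, simulate_reads,
                     ReferenceIndex)
from mirtail.isomir import call_sample
from mirtail.modstats import arm_uridylation_ratio, tail_length_histogram
from mirtail.preprocess import preprocess_sample
from mirtail.simulate import TRUSEQ_ADAPTER
import pandas as pd

config = SimulationConfig(n_hairpins=15, mean_depth=100_000, seed=2)
reference = generate_reference(config)
samples, truth = simulate_reads(reference, config)
index = ReferenceIndex(reference)

calls = []
for sample in samples:
    if sample.condition != "A":
        continue
    records = [(seq, "I" * len(seq), n) for seq, n, _ in sample.records]
    collapsed, _ = preprocess_sample(records, TRUSEQ_ADAPTER,
                                     sample_id=sample.sample_id)
    calls.append(call_sample(collapsed, index))
calls = pd.concat(calls, ignore_index=True)

print(tail_length_histogram(calls).round(3))
ratios = arm_uridylation_ratio(calls)
print(f"3p/5p U-ratio {ratios['u_ratio_corrected']:.1f}, "
      f"A-ratio {ratios['a_ratio_corrected']:.2f}")
```

prints

```
                 U      A
tail_length
1            0.224  3.497
2            0.375  0.744
3            0.548  0.362
4            0.227  0.215
5            0.139  0.069
3p/5p U-ratio 13.8, A-ratio 1.00
```

The U-tail histogram peaks at length 3 — the simulated oligo-U mode — while
A-tails are mostly mono-adenylation. The 3p/5p U-ratio far above 1 says
uridylation happened on the precursor 3' end (only the 3p mature inherits
it); the A-ratio of 1.00 says adenylation happened on mature miRNAs of both
arms. That is the arm-contrast inference the pipeline is built around.

The `examples/` directory has one narrative script per capability
(quantification, tail calling, differential expression, promoter scanning,
ddCt), each printing its results with a line on what they mean. A thin CLI
wraps the same library:

```bash
mirtail simulate --out study --n-hairpins 20 --depth 50000 --seed 1
mirtail run --reference-fasta study/reference.fa \
            --reference-gff study/reference.gff3 \
            --sample-sheet study/samples.tsv --out results
```

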
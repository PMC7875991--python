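"""Call isomiRs and nontemplated tails; localize uridylation to the 3p arm.

The lenient branch decomposes each read into a templated core plus
nontemplated 5'/3' additions.  U-tails concentrated on 3p-arm miRNAs
indicate tailing of the precursor 3' end (the only end a pre-miRNA exposes);
arm-symmetric A-tails indicate tailing of mature miRNAs.
"""

import pandas as pd

from mirtail import ReferenceIndex, SimulationConfig, generate_reference, simulate_reads
from mirtail.isomir import call_sample
from mirtail.modstats import arm_uridylation_ratio, tail_length_histogram
from mirtail.preprocess import preprocess_sample
from mirtail.simulate import TRUSEQ_ADAPTER

config = SimulationConfig(n_hairpins=15, mean_depth=100_000, seed=2)
reference = generate_reference(config)
samples, _truth = simulate_reads(reference, config)
index = ReferenceIndex(reference)

calls = []
for sample in samples:
    if sample.condition != "A":  # control samples only
        continue
    records = [(seq, "I" * len(seq), count) for seq, count, _ in sample.records]
    collapsed, _ = preprocess_sample(records, TRUSEQ_ADAPTER, sample_id=sample.sample_id)
    calls.append(call_sample(collapsed, index))
calls = pd.concat(calls, ignore_index=True)

print("tail length histogram (% of mature-assigned reads):")
print(tail_length_histogram(calls).round(3))
print("\nThe U column peaks at length 3 (the simulated oligo-U mode);")
print("A-tails are mostly mono-adenylation.")

ratios = arm_uridylation_ratio(calls)
print(f"\n3p/5p U-tail ratio (continuity-corrected): {ratios['u_ratio_corrected']:.1f}")
print(f"3p/5p A-tail ratio:                         {ratios['a_ratio_corrected']:.2f}")
print("U-ratio >> 1: uridylation happens on the precursor; A-ratio ~ 1: on matures.")
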
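"""Simulate a small two-condition study and build the miRNA count matrix.

Generates a synthetic hairpin reference and reads with known ground truth,
runs adapter clipping / filtering / collapsing, maps the reads strictly
(no mismatches) and counts every templated isoform whose ends lie within
+/-2 nt of an annotated mature miRNA.
"""

from mirtail import SimulationConfig, build_count_matrix, generate_reference, simulate_reads
from mirtail.preprocess import preprocess_sample
from mirtail.simulate import TRUSEQ_ADAPTER

config = SimulationConfig(n_hairpins=10, mean_depth=30_000, seed=1)
reference = generate_reference(config)
samples, truth = simulate_reads(reference, config)

collapsed = {}
for sample in samples:
    records = [(seq, "I" * len(seq), count) for seq, count, _ in sample.records]
    reads, log = preprocess_sample(records, TRUSEQ_ADAPTER, sample_id=sample.sample_id)
    collapsed[sample.sample_id] = [r for r in reads if len(r.sequence) <= 30]
    print(
        f"{sample.sample_id}: {log.reads_in} reads in, {log.kept} kept, "
        f"{log.collapsed_unique} unique sequences"
    )

cm, _loci = build_count_matrix(collapsed, reference)
print("\ncount matrix (first 5 miRNAs):")
print(cm.counts.head())

# counts follow the simulated abundances: check one miRNA against truth
mirna = cm.counts.sum(axis=1).idxmax()
expected = truth.mirna.loc[mirna, "share_A"]
observed = cm.counts.loc[mirna, "A1"] / cm.library_sizes["A1"]
print(
    f"\nmost abundant miRNA {mirna}: true share {expected:.3f}, "
    f"observed share in A1 {observed:.3f}"
)
print("(strict counting excludes tailed reads, so observed sits slightly below truth)")
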
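"""Mutual-information relevance and mRMR ranking on a planted signal.

Generates 100+100 sequences whose classes differ in the frequency of four
designated residues (K, R, N, Q), then checks that selection recovers them.
"""

from strandclass import extract_features, mrmr_rank
from strandclass.pipeline import ExtractConfig
from strandclass.select import threshold_sweep
from strandclass.synth import DESIGNATED_RESIDUES, SynthConfig, make_sequences

records, labels = make_sequences(SynthConfig(seed=0))
matrix, _ = extract_features(records, labels,
                             ExtractConfig(blocks=("OAAC", "dipeptide")))
print(f"candidate matrix: {matrix.n_samples} x {matrix.n_columns}")

print("\nthreshold sweep (relevance in bits > t):")
for t, kept in threshold_sweep(matrix, [0.0, 0.005, 0.05, 0.1, 0.2]):
    print(f"  t={t:<6} retains {kept:4d} columns")

result = mrmr_rank(matrix, 10)
print("\nmRMR top 10 (score at pick time):")
for rank, col in enumerate(result.ranked_columns, 1):
    mark = " <- planted" if any(
        col == f"OAAC:p_{aa}" for aa in DESIGNATED_RESIDUES) else ""
    print(f"  {rank:2d}. {col:<18} score={result.mrmr_score[col]:.4f}{mark}")
print("\nThe designated composition columns carry the planted class signal; "
      "mRMR surfaces them while demoting mutually redundant dipeptide columns.")
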
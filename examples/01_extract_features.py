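"""Extract all seven feature blocks for a small synthetic protein set.

Builds a two-class dataset (with on-disk PSSM / NetSurfP / DisEMBL profile
files), runs the full extraction, and reports how many columns each block
contributes to the 1510-column feature vector.
"""

import tempfile
from collections import Counter
from pathlib import Path

from strandclass import extract_features
from strandclass.pipeline import ExtractConfig
from strandclass.synth import SynthConfig, write_dataset

with tempfile.TemporaryDirectory() as d:
    data = write_dataset(SynthConfig(n_pos=10, n_neg=10, seed=0), d)
    matrix, excluded = extract_features(
        data["records"], data["labels"], ExtractConfig(profile_dir=Path(d))
    )

per_block = Counter(col.split(":", 1)[0] for col in matrix.columns)
print(f"feature matrix: {matrix.n_samples} proteins x {matrix.n_columns} columns")
for block, count in per_block.items():
    print(f"  {block:>9}: {count:4d} columns")
print(
    "\nEach protein, whatever its length, is encoded by the same 1510 fixed "
    "columns:\ncomposition blocks directly, profile blocks via lag-1..5 "
    "autocovariances."
)
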
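"""Generate the synthetic study dataset used by the downstream analyses.

Writes a 200-gene interaction network, a planted 15-gene connected
module with Beta(0.2, 1) p-values against a uniform background, a
2-vs-2 replicate log2 expression matrix with the planted genes shifted,
and a 100-sample copy-number segment table with a 66% gain
subpopulation, all under results/synthetic_dataset/.
"""

import sys
from pathlib import Path

from modseeker import synthio

OUTDIR = Path(__file__).resolve().parents[1] / "results" / "synthetic_dataset"


def main(seed: int = 0) -> None:
    config = synthio.SynthConfig(seed=seed)
    dataset = synthio.generate_dataset(config)
    synthio.write_dataset(dataset, OUTDIR)
    print(f"network: {dataset.network.number_of_nodes()} genes, "
          f"{dataset.network.number_of_edges()} interactions")
    print(f"planted module: {len(dataset.planted_nodes)} genes "
          f"({', '.join(sorted(dataset.planted_nodes)[:5])}, ...)")
    print(f"expression: {dataset.expression.shape[0]} genes x {dataset.expression.shape[1]} samples")
    print(f"segments: {dataset.segments['sample'].nunique()} samples")
    print(f"written to {OUTDIR}")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 0)
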
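"""Generate the 17-run Box-Behnken design and synthetic conversion responses.

The three esterification factors (oil:MeOH molar ratio 5-25, p-TSA catalyst
0-5 wt%, time 10-90 min) are arranged in a Box-Behnken design with five
centre replicates.  Responses are drawn from the published quadratic
conversion surface plus Gaussian noise at the published residual scale
(sigma = 3.0832 %), standing in for the study's unpublished run table.

Writes results/design_table.csv.
"""

import argparse
from pathlib import Path

import numpy as np

from mbester.synth import SynthConfig, gen_response_table

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--out", type=Path, default=Path("results"))
args = parser.parse_args()

args.out.mkdir(parents=True, exist_ok=True)
table = gen_response_table(SynthConfig(seed=args.seed))
table.to_csv(args.out / "design_table.csv")

centers = np.all(table.coded == 0.0, axis=1)
print(f"generated {len(table)} runs ({int(centers.sum())} centre replicates), seed {args.seed}")
print(f"centre responses: {np.round(table.responses[centers], 2).tolist()}"
      f"  (generating surface predicts 88.68 at the centre)")
print(f"response range: {table.responses.min():.2f} .. {table.responses.max():.2f} %")
print(f"wrote {args.out / 'design_table.csv'}")
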
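"""Compare the quadratic surface and the GRU surrogate on the same runs.

Scores both models in-sample with the four criteria (R2, MAPE, RMSE, MAE),
reports the MAE ratio, and writes parity-plot data against the 45-degree
perfect-prediction line.
"""

import argparse
from pathlib import Path

from mbester import gru, metrics, rsm
from mbester.design import DesignTable
from mbester.synth import SynthConfig, gen_response_table

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--out", type=Path, default=Path("results"))
args = parser.parse_args()
args.out.mkdir(parents=True, exist_ok=True)

csv = args.out / "design_table.csv"
if csv.is_file():
    table = DesignTable.from_csv(csv)
else:
    table = gen_response_table(SynthConfig(seed=args.seed))

model, _ = rsm.fit_quadratic(table)
rsm_pred = rsm.design_matrix(table.coded) @ model.coefficients
weights, _ = gru.train(table, gru.GruHyperparams(seed=args.seed))
gru_report, gru_pred = gru.score_on(table, weights)
rsm_report = metrics.score(table.responses, rsm_pred)

comparison, ratio, ratio_int = metrics.compare(rsm_report, gru_report)
comparison.to_csv(args.out / "comparison.csv", index=False, float_format="%.10g")
print(comparison.to_string(index=False))
print(f"MAE ratio RSM/GRU: {ratio:.2f} (~{ratio_int}x)")
print("the GRU, with ~450 effective parameters against the quadratic's 10, "
      "interpolates the 17 runs more closely in-sample")

for label, pred in (("rsm", rsm_pred), ("gru", gru_pred)):
    points, line = metrics.parity_data(table.responses, pred)
    points.to_csv(args.out / f"parity_{label}.csv", index=False,
                  float_format="%.10g")
print(f"wrote comparison.csv, parity_rsm.csv, parity_gru.csv under {args.out}/")
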
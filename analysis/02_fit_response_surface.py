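"""Fit the quadratic response surface, run ANOVA, and optimize within the cube.

Reads results/design_table.csv (run 01_simulate_design.py first, or pass
--seed to regenerate the same table) and writes the fitted model, ANOVA with
lack-of-fit split, model-hierarchy ranking, perturbation traces and the
box-constrained optimum.
"""

import argparse
from pathlib import Path

import numpy as np
import yaml

from mbester import rsm
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
    print(f"loaded {len(table)} runs from {csv}")
else:
    table = gen_response_table(SynthConfig(seed=args.seed))
    print(f"regenerated the design table from seed {args.seed}")

model, diag = rsm.fit_quadratic(table)
(args.out / "rsm_model.yaml").write_text(yaml.safe_dump(model.to_dict()))
print(f"quadratic fit: R2 = {diag.r2:.4f}, adjusted R2 = {diag.adj_r2:.4f}, "
      f"RMSE = {diag.rmse:.4f} % (divisor n)")
print("coefficients (coded units):")
for name, c in zip(rsm.TERM_NAMES, model.coefficients):
    print(f"  {name:9s} {c:+8.3f}")

tbl = rsm.anova(model, table)
tbl.to_csv(args.out / "anova.csv", index=False, float_format="%.10g")
by = tbl.set_index("source")
print(f"ANOVA: model F = {by.loc['Model', 'F']:.2f} (p = {by.loc['Model', 'p']:.2e}); "
      f"lack-of-fit p = {by.loc['Lack of fit', 'p']:.3f} against pure error "
      f"({int(by.loc['Pure error', 'df'])} df from the centre replicates)")

ranked = rsm.model_hierarchy(table)
print("model hierarchy (adjusted R2): "
      + "; ".join(f"{n} = {r:.4f}" for n, r in ranked))

rsm.perturbation_profiles(model).to_csv(
    args.out / "perturbation.csv", index=False, float_format="%.10g"
)

opt = rsm.optimize_response(model)
print(f"box-constrained optimum ({opt.location}): coded "
      f"({opt.coded[0]:.4f}, {opt.coded[1]:.4f}, {opt.coded[2]:.4f}) = "
      f"ratio 1:{opt.natural[0]:.2f}, {opt.natural[1]:.2f} wt% catalyst, "
      f"{opt.natural[2]:.1f} min -> predicted {opt.predicted:.2f} %")

# the operating point the study validated experimentally
pt = model.coded_point((23.73, 3.3, 59.79))
print(f"prediction at the study's operating point (1:23.73, 3.3 wt%, 59.79 min): "
      f"{rsm.predict_quiet(model, pt):.2f} %")
print(f"wrote rsm_model.yaml, anova.csv, perturbation.csv under {args.out}/")
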
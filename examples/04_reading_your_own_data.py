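"""Read twin-pair data from a file, adjust for covariates, and analyze.

Input files can be wide (one row per pair: pair_id, x_1, y_1, x_2, y_2,
optional covariate_1/covariate_2 columns) or long (one row per twin:
pair_id, twin_id, x, y, ...); arbitrary column names are handled with a
column map.  Incomplete pairs are dropped with a count.
"""

import tempfile
from pathlib import Path

import numpy as np

from icefalcon import bidirectional, calibrate, interpret, read_pairs, \
    residualize, simulate_pairs, within_pair_correlation

# Build a demonstration file: simulated pairs with an age effect on X,
# written with domain-style column names.
spec = calibrate(0.6, 0.4, 0.25, "b", n_pairs=800, seed=13)
data = simulate_pairs(spec)
frame = data.frame.rename(columns={
    "x_1": "bmi_1", "y_1": "meth_1", "x_2": "bmi_2", "y_2": "meth_2"})
rng = np.random.default_rng(2)
age = rng.uniform(40, 70, (len(frame), 2))
frame["bmi_1"] += 0.02 * age[:, 0]
frame["bmi_2"] += 0.02 * age[:, 1]
frame["age_1"], frame["age_2"] = age[:, 0], age[:, 1]
path = Path(tempfile.mkdtemp()) / "twins.csv"
frame.to_csv(path, index=False)

# Read it back, mapping the columns onto the x/y convention.
data = read_pairs(path, layout="wide", column_map={
    "pair_id": "pair_id",
    "x_1": "bmi_1", "y_1": "meth_1", "x_2": "bmi_2", "y_2": "meth_2",
    "age_1": "age_1", "age_2": "age_2"})
print(f"read {data.n_pairs} pairs ({data.n_dropped} dropped as incomplete)")

# Remove the age effect from the predictor before analysis.
data = residualize(data, "x", ["age"])
for trait in ("x", "y"):
    est = within_pair_correlation(data, trait)
    print(f"within-pair correlation of {trait}: {est.estimate:.3f} "
          f"[{est.ci_low:.3f}, {est.ci_high:.3f}]")

forward, reverse = bidirectional(data, n_boot=500, seed=4)
print(interpret((forward, reverse)))
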
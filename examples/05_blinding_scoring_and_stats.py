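"""Blinded scoring workflow and the statistical layer.

File names are blinded with a seeded key before any manual scoring; ordinal
staining scores are tallied per group only after scoring, and tested with
Fisher's exact test.  Continuous measurements are log10-transformed and
compared with a pooled two-tailed t test; touch-evoked escape-response
counts are censored at 50 at ingestion.
"""

import numpy as np
import pandas as pd

import zftrunk as z

# --- blinding -------------------------------------------------------------
names = [f"ctrl_{i}.tif" for i in range(12)] + [f"fkrp_{i}.tif" for i in range(12)]
key = z.blind_files(names, seed=2024)
print("first three blinded names:", [key.apply(n) for n in names[:3]])

# --- blinded ordinal scores -> Fisher exact -------------------------------
rng = np.random.default_rng(0)
scores, groups = [], {}
for n in names:
    blinded = key.apply(n)
    group = "control" if n.startswith("ctrl") else "fkrp"
    groups[blinded] = group
    p_strong = 0.8 if group == "control" else 0.3
    cat = "strong" if rng.random() < p_strong else "weak"
    scores.append(z.CategoricalScore(blinded, cat))

table = z.tally_categories(scores, groups, categories=("weak", "strong"))
print("\nstaining tally:\n", table)
res = z.categorical_test(table.to_numpy())
print(f"{res.method}: p = {res.p_value:.4f}")

# --- touch response: censor then compare ----------------------------------
raw = [("c%d" % i, int(t)) for i, t in enumerate(rng.poisson(3, 20) + 1)] + [
    ("m%d" % i, int(t)) for i, t in enumerate(rng.poisson(25, 20) + 1)
]
touches = z.ingest_touch_response(raw)
print(f"\ncensored embryos (hit the 50-touch cap): {int(touches.censored.sum())}")

meas = pd.DataFrame(
    {
        "unit_id": touches.embryo_id,
        "group": ["control"] * 20 + ["fkrp"] * 20,
        "value": touches.touches.astype(float),
    }
)
logged = z.log_transform(meas)
tt = z.two_group_test(logged)
print(f"pooled t on log10 touches: t = {tt.statistic:.2f}, df = {tt.df:.0f}, "
      f"p = {tt.p_value:.2e}")
# More touches to evoke an escape = worse muscle function; the log transform
# is applied before every group comparison, as in the scoring protocol.
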
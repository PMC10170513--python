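"""Structure–kinetics regressions on the packaged antagonist tables.

Fits the SKR line on the congeneric training set of each table, prints
the model statistics, and shows prediction for the held-out compounds.
"""

import metadrt as m

for name in ["tautermann_flooding", "liu_flooding", "tautermann_tmetad", "liu_tmetad"]:
    table = m.load_table(name)
    fit = m.fit_table(table)
    print(
        f"{name:22s} n={fit.n}  log RT = {fit.slope:.3f}·x {fit.intercept:+.2f}   "
        f"r² = {fit.r2:.2f}  RMSE = {fit.rmse:.2f}"
    )

print("\nheld-out compounds under the Tautermann flooding model:")
table = m.load_table("tautermann_flooding")
fit = m.fit_table(table)
for compound in ["NMS", "ipratropium", "10"]:
    row = table.row(compound)
    y_pred, e = m.predict(fit, row["descriptor"], row["log_rt"])
    print(
        f"  {compound:12s} log tau = {row['descriptor']:5.2f}  observed {row['log_rt']:5.2f}  "
        f"predicted {float(y_pred):5.2f}  residual {float(e):+5.2f}  "
        f"class {m.classify_rt(row['log_rt'])}"
    )
print(
    "\nWithin the congeneric series the descriptor explains ~96% of the\n"
    "experimental variation with a 0.2 log-unit error; for structurally\n"
    "distant compounds (NMS) the residual grows beyond one log unit —\n"
    "the models are local and need recalibration per series."
)
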
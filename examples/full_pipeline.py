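"""End-to-end synthetic study: simulate -> fit -> summarize -> correlate.

Runs the default four-substrate configuration (motifs TA, AA, TT, AT with
flexibility-graded ground truths), fits every stage, and prints the merged
substrate table, the cross-technique correlations, and both double-mutant
coupling energies. Outputs are also written to ./ungflex_report/.
"""

import pandas as pd

from ungflex import run_pipeline

pd.set_option("display.width", 120)

report = run_pipeline()

cols = ["substrate", "kcat_over_km", "alpha0", "k_ex", "bpl_a", "tpl_a", "pct_intra"]
print(report["table"][cols].round(3).to_string(index=False))

print("\ncorrelation panels:")
print(report["panels"][["x", "y", "r", "n"]].round(3).to_string(index=False))

for kind, cyc in report["couplings"].items():
    print(f"\n{kind} coupling: {cyc['coupling_kj']:.2f} +/- {cyc['sigma_kj']:.2f} kJ/mol")

print(
    "\nExpected signatures: kcat/KM anti-correlates with alpha0 and correlates "
    "with k_ex; both coupling energies are positive (flanking bases are coupled)."
)
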
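"""The one-call pipeline: every scoring scheme, ROC, metrics and outcomes.

run_pipeline() accepts a config dict naming a cohort TSV (or simulation
parameters) and returns a JSON-serializable report bundle; render_report()
pretty-prints it.  The same dict + seed always yields the same report hash.
"""

import json

from stainclass import render_report, run_pipeline

report = run_pipeline({"seed": 7})
print(render_report(report))

# every number above lives in the bundle too:
best = [r for r in report["results"]["schemes"] if r.get("best_for_target")]
print("\nbest schemes:", json.dumps(
    [{ "scheme": r["scheme"], "auc": round(r["auc"], 3)} for r in best], indent=2))
print("report hash:", report["report_hash"][:16], "(stable for this config)")
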
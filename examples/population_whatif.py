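"""Pre-study advisory: what would a manipulation-check mediation test show?

For a planned experiment with perfect manipulation (r_tx = 1), a highly
reliable check (r_tm = 0.95), a true effect r_ty = 0.3 and no direct
check-outcome correlation (r_my = 0), print the exact population paths a
mediation analysis would estimate.  The indirect effect is large and
*negative* while the total effect is positive — a suppression structure, so
a "significant mediation" here would not support the causal story.
"""

import json

from tmcsim import SimulationCondition, whatif_report

condition = SimulationCondition(r_tx=1.0, r_tm=0.95, r_my=0.0, r_ty=0.3)
report = whatif_report(condition)
print(json.dumps(report, indent=2, default=str))

paths = report["population_paths"]
print(f"\nindirect effect ab = {paths['ab']:.3f} against total effect "
      f"c = {paths['c']:.3f} -> {report['mediation_class']} mediation")
print(f"VIF = {paths['vif']:.2f}: the check and the condition code are "
      "nearly collinear, so path estimates will be unstable.")
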
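"""Quantitative dosage calling on a simulated deletion cohort.

Simulates the fluorescent peak table of a 100-control / 14-case cohort run
with a designed assay (cases carry one copy of the test segment instead of
two), then walks the full analysis: peak assignment, test/control area
ratios, reference-pool normalization, the Gaussian gate, Z scoring, ROC
threshold selection and predictive values with Wilson confidence intervals.
"""

import numpy as np

from mqfpcr import (
    assign_peaks,
    call_dosage,
    design_assay,
    diagnostic_cis,
    find_homologous_pairs,
    normalize_cohort,
    parse_peak_table,
    roc,
    score_cohort,
)
from mqfpcr.synth_data import (
    CohortSpec,
    ParalogGenomeSpec,
    make_paralog_genome,
    simulate_cohort,
)

genome, _ = make_paralog_genome(ParalogGenomeSpec(delta=4, seed=1))
assay = design_assay(find_homologous_pairs(genome[0], genome)[0])[0]

spec = CohortSpec(n_controls=100, n_cases=14, case_test_copies=1, cv=0.05, seed=2)
peaks, labels = simulate_cohort(assay, spec)
records = parse_peak_table(peaks.to_csv(sep="\t", index=False))
ratios, _ = assign_peaks(records, assay)
nrs = normalize_cohort(ratios, spec.reference_id)

groups = dict(zip(labels.sample_id, labels.group))
controls = [x for x in nrs if groups[x.sample_id] == "control"]
cases = [x for x in nrs if groups[x.sample_id] == "case"]
print(f"mean normalized ratio: controls {np.mean([x.nr for x in controls]):.3f}, "
      f"cases {np.mean([x.nr for x in cases]):.3f} "
      "(hemizygous deletion halves the test template)")

scores, cstats = score_cohort(controls, cases)
print(f"Gaussian gate: p = {cstats.p_normal:.3f} -> method {scores[0].method}")
print(f"case scores: {sorted(round(s.value, 2) for s in scores)}")

from mqfpcr import pseudo_z, z_scores

values = [x.nr for x in controls]
scorer = z_scores if scores[0].method == "Z" else pseudo_z
control_scores = [scorer(values, x.nr) for x in controls]
all_scores = np.array(control_scores + [s.value for s in scores])
truth = np.array([False] * len(controls) + [True] * len(cases))
result = roc(all_scores, truth, direction="deletion")
print(f"ROC: AUC {result.auc:.3f}, Youden threshold {result.threshold:.2f}, "
      f"sensitivity {result.sensitivity:.0f}%, specificity {result.specificity:.0f}%")

calls = call_dosage(scores, result.threshold, "deletion")
tp = sum(c.call == "deletion" for c in calls)
cis = diagnostic_cis(tp=tp, fp=0, tn=len(controls), fn=len(cases) - tp)
print(f"PPV {cis.ppv.percent:.0f}% (95% CI {cis.ppv.lo:.1f}-{cis.ppv.hi:.0f}%), "
      f"NPV {cis.npv.percent:.0f}% (95% CI {cis.npv.lo:.1f}-{cis.npv.hi:.0f}%)")
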
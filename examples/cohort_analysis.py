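"""Menopause-timing cohort statistics on a synthetic cohort.

Generates a phenotype table with the documented counting flow
(124 subjects -> 34 excluded outside the MRI-age overlap -> 90 retained ->
tertiles of 30), measures each subject's coupling and global-signal
amplitude from simulated time courses, and runs the statistics battery:
age-adjusted group comparisons, ordinal trends, and the wave-count /
memory correlation in the earlier-menopause group.
"""

import pandas as pd

from boldwaves import SimConfig, simulate_cohort, subject_coupling
from boldwaves.cohort import headline_report
from boldwaves.signals import subject_amplitude

cfg = SimConfig(master_seed=42)  # default planted effects
cohort = simulate_cohort(cfg, tier="signals")

pheno = cohort.phenotypes
print(f"{len(pheno)} subjects, {pheno['included'].sum()} retained; groups:",
      pheno["group"].value_counts().to_dict())

rows = []
for subj in cohort.subjects:
    rows.append({
        "subject_id": subj.subject_id,
        "coupling": subject_coupling(list(zip(subj.gbold, subj.csf))).subject_value,
        "amplitude": subject_amplitude(subj.gbold),
    })
metrics = pheno.merge(pd.DataFrame(rows), on="subject_id")
metrics = metrics.merge(cohort.ground_truth[["subject_id", "bottom_up_count"]],
                        on="subject_id")
metrics = metrics.loc[metrics["included"]]

for name, res in headline_report(metrics).items():
    print(f"{name:32s} estimate = {res.estimate:+8.3f}   p = {res.pvalue:.4f}")
# With the default planted effects the earlier group shows weaker (less
# negative) coupling and smaller amplitude than the later group, and
# bottom-up wave counts correlate with memory scores among earlier-
# menopause subjects; the age ANOVA should stay non-significant because
# the MRI-age overlap filter decouples scan age from menopause timing.
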
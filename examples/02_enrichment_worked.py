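"""Full over-representation analysis on the worked synthetic fixture.

The fixture plants AP1 sites at a higher rate in 20 test promoters than in
20 controls (500 bp each, two pseudo-species).  The analysis scans every
candidate threshold, keeps those with a control-site frequency of 0.01-0.2
sites/kb, maximises the Additional Sites score subject to OR >= 2.5, groups
motifs by hit location and attaches a resampling group-wise FDR.
"""

from flexsite import EnrichmentConfig, analyze, results_table
from flexsite.simulate import worked_fixture

fix = worked_fixture()
cfg = EnrichmentConfig(window_lengths=(500,), n_required=2, objective="AS")
out = analyze(fix.test, fix.control, fix.pfms.values(), fix.bundles,
              cfg, n_runs=50, rng_seed=1)

print(results_table(out.results).to_string(index=False))
print()
for g in out.groups:
    print(f"group {g.group_id}: members={g.members} optimum={g.optimum:.1f} "
          f"FDR={g.fdr:.2f}")
print()
print("AP1 (planted) should report a positive Additional Sites score at a "
      "low p-value and FDR; the E-box decoy reports nothing (no admissible "
      "threshold) and the CRE variant rides along at AP1-adjacent sites.")
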
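"""Detect a motif that co-occurs with another: flanking-region analysis.

CRE-like sites are planted only within 100 bp of AP1 anchors in the test
promoters.  After optimising AP1 itself, the 100 bp flanks of its sites
(with all AP1 windows masked out) are compared against random 200 bp
control-promoter fragments; CRE should dominate the ranking while unrelated
decoys report nothing.
"""

from flexsite import (
    EnrichmentConfig, flanking_enrichment, flanking_regions, results_table,
    run_enrichment,
)
from flexsite.simulate import (
    PlantSpec, SimulationSpec, builtin_pfms, gen_ortholog_bundles, gen_promoters,
)

pfms = builtin_pfms()
spec = SimulationSpec(
    seed=7, n_test=60, n_control=60, promoter_length=1000,
    plants=(
        PlantSpec(pfms["AP1"], rate_test=1.5, rate_control=0.1),
        PlantSpec(pfms["CRE"], rate_control=0.05,
                  cooccur_with="AP1", cooccur_prob=0.9, cooccur_dist=(10, 80)),
    ),
)
test, control, truth = gen_promoters(spec)
bundles = gen_ortholog_bundles(test, control, truth, spec)

anchor_cfg = EnrichmentConfig(window_lengths=(1000,), n_required=3, objective="AS")
anchor = run_enrichment(test, control, [pfms["AP1"]], bundles, anchor_cfg)[0]
print(f"AP1 anchors at optimum: {len(anchor.hits_at_best)} sites")

frags = flanking_regions(anchor.hits_at_best, test, anchor.motif_length, 100)
print(f"flanking fragments: {len(frags)} "
      f"({sum(f.end - f.start for f in frags)} bp total)")

scan_set = [pfms[k] for k in ("CRE", "SRF", "CEBP", "EBOX", "NFKB", "MEF2")]
res = flanking_enrichment(
    frags, control, scan_set,
    config=EnrichmentConfig(window_lengths=(1000,), objective="AS"), rng_seed=7,
)
cols = ["motif_id", "threshold", "A", "B", "or_ratio", "additional_sites", "p_value"]
print(results_table(res)[cols].to_string(index=False))
print("CRE tops the ranking: its sites sit beside AP1 anchors, exactly "
      "where the flanks are taken; the decoys have no admissible signal.")
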
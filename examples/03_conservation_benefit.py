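"""Why cross-species conservation matters for short motifs.

An AP1-like heptamer matches by chance roughly every 4 kb of random
sequence, so at any usable threshold the background drowns a modest planted
excess.  Requiring the site to score above threshold in n additional
species (via the conserved score) removes most chance matches while keeping
planted sites that evolution would have retained.
"""

from flexsite import EnrichmentConfig, run_enrichment
from flexsite.simulate import (
    ConservationSpec, PlantSpec, SimulationSpec, builtin_pfms,
    gen_ortholog_bundles, gen_promoters,
)

pfms = builtin_pfms()
spec = SimulationSpec(
    seed=42, n_test=200, n_control=200, promoter_length=1000,
    plants=(PlantSpec(pfms["AP1"], rate_test=0.15, rate_control=0.05),),
    conservation=ConservationSpec(retention=0.9, divergence=0.25),
)
test, control, truth = gen_promoters(spec)
bundles = gen_ortholog_bundles(test, control, truth, spec)
print(f"planted AP1 sites: {truth.sites.groupby('arm').size().to_dict()}")

for n in (0, 1, 3, 5):
    cfg = EnrichmentConfig(window_lengths=(1000,), n_required=n, objective="OR")
    r = run_enrichment(test, control, [pfms["AP1"]], bundles, cfg)[0]
    if r.best is None:
        print(f"n={n}: no admissible threshold")
    else:
        b = r.best
        print(f"n={n}: threshold {b.threshold:.3f}  A={b.A:3d} B={b.B:3d}  "
              f"OR={b.or_ratio:5.2f}  p={b.p_value:.2e}")
print("The OR ratio rises with the conservation requirement because chance "
      "matches are rarely conserved; planted sites are retained in 90% of "
      "species and survive the filter.")
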
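"""Nanoparticle tracking analysis: liposome sizing and curvature preference.

Particles are sized from the slope of their mean-squared displacement via
the Stokes-Einstein relation.  Comparing the scatter-detected (total) and
fluorescence-detected (protein-bound) size distributions yields a per-bin
enrichment — the curvature-preference readout.  Here binding probability
grows with diameter, mimicking a flat membrane-binding domain that
prefers large (flat) liposomes.
"""

import numpy as np

from cmequant import nta, synth

rng = np.random.default_rng(9)
diameters = rng.uniform(80.0, 1000.0, 300)
scatter, fluor = synth.simulate_brownian_tracks(
    diameters, duration_s=60.0,
    bound_fraction_by_size=lambda d: min(d / 1000.0, 1.0), seed=10,
)

total_sizes = nta.size_particles(scatter)
bound_sizes = nta.size_particles(fluor)
med_total = total_sizes.loc[~total_sizes["excluded"], "diameter_nm"].median()
med_bound = bound_sizes.loc[~bound_sizes["excluded"], "diameter_nm"].median()
print(f"particles sized: {len(total_sizes)} total, {len(bound_sizes)} bound")
print(f"median diameter: total {med_total:.0f} nm, bound {med_bound:.0f} nm")

total, bound, enrichment = nta.curvature_preference(scatter, fluor)
centers = total.bin_centers_nm
small = np.isfinite(enrichment) & (centers < 300)
large = np.isfinite(enrichment) & (centers > 600) & (centers < 1000)
print(f"mean enrichment below 300 nm: {np.nanmean(enrichment[small]):.2f}, "
      f"600-1000 nm: {np.nanmean(enrichment[large]):.2f}")
print("-> enrichment > 1 at large diameters reports the planted preference "
      "for low-curvature (flatter) membranes.")
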
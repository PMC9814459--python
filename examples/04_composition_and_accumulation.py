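"""Composition counts and species accumulation curves.

Summarizes the packaged two-site survey table (which species were
detected, by which collection method, and what fraction of the expected
community that covers) and computes permutation-based species accumulation
curves on a simulated survey to show how detected richness grows with the
number of trees sampled.
"""

import treedna as td

s = td.composition_summary(td.load_table1_fixture())
print(f"{s.n_detected} of {s.n_available} expected species detected "
      f"({100 * s.coverage:.0f}% coverage); {s.n_undetected} undetected")
print(f"arboreal: {s.arboreal_detected} detected "
      f"(roller {s.roller_arboreal}, soil {s.soil_arboreal}); "
      f"non-arboreal: {s.nonarboreal_detected} "
      f"(roller {s.roller_nonarboreal}, soil {s.soil_nonarboreal})")
print(f"bats: {s.bats_detected} of {s.bats_expected} expected species")

d = td.sampling_design_fixture()
print(f"\nsampling design: {len(d)} analyzed events "
      f"({(d.collection_method == 'roller').sum()} roller, "
      f"{(d.collection_method == 'soil').sum()} soil)")

history, _ = td.simulate_community(td.CommunitySimConfig(n_species=16, seed=3))
curves = td.species_accumulation(history, visits_per_tree=3, n_perm=500, seed=0)
print("\nspecies accumulation (mean +/- SD over tree orderings):")
for method in ("roller", "soil", "both"):
    df = curves.for_method(method)
    last = df.iloc[-1]
    print(f"  {method:6s}: {last['mean']:.1f} species after "
          f"{int(last['n_trees'])} trees "
          f"(halfway: {df['mean'].iloc[len(df) // 2]:.1f} +/- "
          f"{df['sd'].iloc[len(df) // 2]:.1f})")
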
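"""Runs of homozygosity and uniparental disomy detection.

Injects a 7-Mb homozygous segment into one sample and whole-chromosome
isodisomy into another, then recovers both with the ROH caller (5 Mb
windows, >= 50 SNPs, <= 1 heterozygote, <= 5 missing, gaps <= 100 kb) and
the UPD coverage rule.
"""

import heritagescan as hs

model = hs.PopulationModel(n_pops=1, fst=0.05, n_markers=20_000, scale=0.05, seed=5)
panel, _ = hs.simulate_cohort(model, [50])

roh_sample = panel.sample_ids[4]
upd_sample = panel.sample_ids[9]
injected, truth = hs.inject_homozygosity(
    panel, roh_spec=[(roh_sample, 3, 1_000_000, 8_000_000)],
    upd_sample=(upd_sample, 2), seed=6,
)

segments = hs.call_roh(injected)
print(f"detected {len(segments)} ROH segments in {injected.n_samples} samples")
print(hs.roh.segments_to_frame(segments).to_string(index=False))

flags = hs.flag_upd(injected, segments)
print(f"\ncandidate uniparental isodisomy (chromosome ~fully covered by ROH): {flags}")
print(f"injected truth: [('{upd_sample}', 2)]")

summary = hs.roh_summary(segments, injected.sample_ids)
profiles = hs.rarity.profiles_to_frame(hs.compute_profiles(injected))
fit = hs.rarity_roh_regression(profiles, summary)
print("\nrarity score vs ROH burden (more homozygous genomes carry fewer "
      "rare haplotypes, so the slope is typically negative on real cohorts):")
print({k: {kk: round(vv, 4) for kk, vv in v.items()} for k, v in fit.items()})
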
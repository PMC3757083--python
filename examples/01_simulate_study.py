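"""Generate a small synthetic cross-species tumor study and write it to disk.

The generator produces a human-like / fish-like genome pair related by one
whole-genome duplication plus block rearrangement, a similarity table, and
segmented tumor cohorts with planted recurrent alterations.
"""

import crossonco as co

config = co.SimulationConfig(
    n_ancestral_genes=1000,
    n_human_chroms=8,
    n_fish_chroms=10,
    n_rp_diploid=20,
    n_tp53_diploid=15,
    n_tp53_triploid=15,
    n_human_samples=10,
    n_fish_gain_chroms=3,
    n_fish_loss_chroms=2,
    n_human_gain_chroms=2,
    n_human_loss_chroms=3,
    n_fish_focal_gains=3,
    n_fish_focal_losses=1,
    n_human_focal_gains=3,
    n_human_focal_losses=1,
    n_mirna_families=20,
    rng_seed=0,
)
outdir = co.emit_fixtures("scratch/example_study", config)

human, fish, similarity, fish_profiles, human_profiles, truth = co.simulate_study(config)
print(f"wrote study to {outdir}/")
print(f"human genes: {len(human)}, fish genes: {len(fish)} "
      f"(ratio {len(fish)/len(human):.2f}; the duplication retains ~half of "
      "second fish copies)")
print(f"similarity rows: {len(similarity)}")
print(f"fish cohort: {len(fish_profiles)} samples, human cohort: {len(human_profiles)}")
print(f"planted fish gains on chromosomes {truth.gain_chromosomes['fish']}, "
      f"losses on {truth.loss_chromosomes['fish']}")
print(f"planted focal drivers: {len(truth.focal_drivers)}; "
      f"chromothripsis events: {len(truth.chromothripsis_events)}")
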
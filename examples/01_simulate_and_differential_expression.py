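"""Simulate a two-agonist CAGE time course and find responsive promoters.

Generates negative-binomial tag counts with 100 planted 4-fold responders
pulsing at 60 min under the growth-factor-like agonist, runs all pairwise
exact tests, and reports how many planted responders were recovered in the
0-vs-60-min comparison.
"""

from cagedyn import SynthConfig, pairwise_de, simulate_timecourse

cfg = SynthConfig(
    n_promoters=2000,
    library_size=2e5,
    dispersion_phi=0.05,
    effect_log2fc=2.0,  # 4-fold induction
    responder_fractions={"FGF2": {"pulse_60": 0.05}, "IL1B": {}},
    seed=1,
)
counts, meta, truth = simulate_timecourse(cfg)
print(f"simulated {counts.shape[0]} promoters x {counts.shape[1]} libraries")

de = pairwise_de(counts, meta, "FGF2", alpha=0.05)
family = de[(de.time_a == 0) & (de.time_b == 60)]
flagged = set(family[family.significant].region_id)
planted = truth.responders("FGF2")

print(f"0-vs-60 min family: {len(flagged)} promoters at q < 0.05")
print(f"recall of the {len(planted)} planted responders: "
      f"{100 * len(flagged & planted) / len(planted):.1f}%")
print(f"false discoveries among flags: {len(flagged - planted)}")
# High recall with few false flags means the common-dispersion exact test
# separates planted 4-fold inductions from NB sampling noise.
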
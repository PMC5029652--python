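#!/usr/bin/env python
"""Generate the seeded synthetic study inputs used by the downstream
analysis scripts: a 5-pair × 10-line diagonal viability screen with graded
injected synergy, a four-arm expression experiment with planted interaction
genes, and a four-arm xenograft growth study.

Inputs land under scratch/inputs/ (they are regenerated on demand; only
summary tables under results/ are kept)."""

from pathlib import Path

import blisscreen as bs

OUT = Path(__file__).resolve().parents[1] / "scratch" / "inputs"
OUT.mkdir(parents=True, exist_ok=True)

# graded synergy: one pair per injected EoB delta, the screen's geometry
DELTAS = (0.0, 5.0, 10.0, 20.0, 40.0)
pairs = [
    bs.default_pair(
        f"pair{i}x", f"pair{i}y",
        bs.SynergySpec("uniform_delta" if d else "bliss_null", d, noise_sd=0.05),
    )
    for i, d in enumerate(DELTAS)
]
screen, truth = bs.simulate_combination_panel(pairs, n_lines=10, n_rep=3, seed=101)
bs.write_viability_table(screen, OUT / "screen.csv")
truth.to_csv(OUT / "screen_truth.csv", index=False)
print(f"screen: {len(screen.wells)} wells, deltas {DELTAS} -> {OUT/'screen.csv'}")

exp, etruth = bs.simulate_expression(
    n_genes=2000, n_de=800, n_pos=250, n_neg=250,
    effect=2.0, sigma=0.25, n_rep=3, seed=102,
)
exp.matrix.to_csv(OUT / "expression_matrix.csv")
exp.design.to_csv(OUT / "expression_design.csv", index=False)
etruth.to_csv(OUT / "expression_truth.csv")
print(f"expression: {exp.matrix.shape[0]} genes x {exp.matrix.shape[1]} samples")

gdf, gtruth = bs.simulate_growth_study(bs.GrowthSpec(seed=103), n_per_group=8, days=28)
gdf.to_csv(OUT / "tumors.csv", index=False)
gtruth.to_csv(OUT / "tumors_truth.csv")
print(f"growth: {gtruth.shape[0]} mice over 28 days -> {OUT/'tumors.csv'}")
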
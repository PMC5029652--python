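"""Calibration and recovery studies on synthetic data.

These drive the generator → analysis loop at study scale and reduce each
run to the headline operating characteristics: null calibration of the EoB
score, rank-order recovery of injected synergies across a panel, and
sign-recovery / miscall rates of the interaction classifier.  Seeds are
spawned per repeat from a single master seed, so every study is a
deterministic function of its arguments.
"""

from __future__ import annotations

import numpy as np

from . import simulate as bsim
from . import synergy as bsyn
from . import transcriptomics as btx


def _child_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(n)]


def null_calibration_study(
    n_matrices: int = 1000,
    n_rep: int = 3,
    noise_sd: float = 0.05,
    seed: int = 0,
) -> dict:
    """Mean EoB over Bliss-null diagonal matrices with replicate noise.

    Simulates ``n_matrices`` 10-dose diagonal matrices (one per synthetic
    cell line) with multiplicative viability noise and no injected synergy,
    scores them, and returns the grand mean and SD of all per-well EoB
    values.  A calibrated score has a grand mean near zero.
    """
    pair = bsim.default_pair(synergy=bsim.SynergySpec("bliss_null", 0.0, noise_sd))
    screen, _ = bsim.simulate_combination_panel(
        [pair], n_lines=n_matrices, n_rep=n_rep, seed=seed
    )
    results = bsyn.score_panel(screen)
    eob = np.concatenate([r.points["excess_over_bliss"].to_numpy() for r in results])
    return {
        "mean_eob": float(eob.mean()),
        "sd_eob": float(eob.std(ddof=1)),
        "n_matrices": len(results),
        "n_points": eob.size,
    }


def rank_recovery_study(
    deltas: tuple[float, ...] = (5.0, 10.0, 20.0, 40.0),
    n_panels: int = 200,
    n_lines: int = 10,
    n_rep: int = 3,
    noise_sd: float = 0.02,
    seed: int = 0,
) -> dict:
    """How often does panel ranking recover the injected synergy order?

    Each repeat simulates one panel with one drug pair per injected delta,
    ranks the pairs by mean of per-line maximal EoB, and checks whether the
    recovered order matches the injection order exactly.
    """
    pairs = [
        bsim.default_pair(
            f"pair{i:02d}x", f"pair{i:02d}y",
            bsim.SynergySpec("uniform_delta" if d else "bliss_null", d, noise_sd),
        )
        for i, d in enumerate(deltas)
    ]
    by_delta = {f"pair{i:02d}x": d for i, d in enumerate(deltas)}
    hits = 0
    for s in _child_seeds(seed, n_panels):
        screen, _ = bsim.simulate_combination_panel(
            pairs, n_lines=n_lines, n_rep=n_rep, seed=s
        )
        ranking = bsyn.rank_combinations(bsyn.score_panel(screen))
        recovered = [by_delta[a] for a in ranking.entries["drug_a"]]
        hits += recovered == sorted(deltas, reverse=True)
    return {
        "recovery_rate": hits / n_panels,
        "n_panels": n_panels,
        "deltas": list(deltas),
    }


def classifier_recovery_study(
    n_sims: int = 100,
    n_genes: int = 2000,
    n_de: int = 800,
    n_pos: int = 250,
    n_neg: int = 250,
    effect: float = 2.0,
    sigma: float = 0.25,
    n_rep: int = 3,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Sign-recovery of planted interaction genes and miscall rate on nulls.

    Per repeat: simulate a four-arm experiment with planted positive and
    negative interaction genes, run the two-stage classifier, and record
    (a) the fraction of planted genes called with the correct sign and
    (b) the fraction of non-interaction genes called interacting.
    """
    correct_planted = 0
    n_planted = 0
    false_calls = 0
    n_null = 0
    for s in _child_seeds(seed, n_sims):
        exp, truth = bsim.simulate_expression(
            n_genes=n_genes, n_de=n_de, n_pos=n_pos, n_neg=n_neg,
            effect=effect, sigma=sigma, n_rep=n_rep, seed=s,
        )
        de = btx.detect_de(exp, alpha=alpha)
        calls = btx.classify_profiles(de, exp, alpha=alpha)
        planted = truth["interaction"] != "none"
        correct_planted += int(
            (calls.loc[planted, "interaction_sign"]
             == truth.loc[planted, "interaction"]).sum()
        )
        n_planted += int(planted.sum())
        false_calls += int((calls.loc[~planted, "interaction_sign"] != "none").sum())
        n_null += int((~planted).sum())
    return {
        "sign_recovery_rate": correct_planted / n_planted,
        "null_miscall_rate": false_calls / n_null,
        "n_sims": n_sims,
        "n_planted": n_planted,
        "n_null": n_null,
    }
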
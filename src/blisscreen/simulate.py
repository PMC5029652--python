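"""Synthetic-data generators with known ground truth for every pipeline
input: Hill-model combination screens (Bliss-null or with injected
synergy), four-arm expression experiments with planted interaction genes,
and exponential xenograft growth studies with treatment effects.

Every generator is a deterministic function of its spec and seed; ground
truth (injected EoB surfaces, interaction labels, growth rates) is emitted
alongside the data so recovery can be scored.

Default screen geometry mirrors the emulated assay: 10 concentrations per
drug including the vehicle, serial 1:4 dilutions, a diagonal (fixed-ratio
ray) combination design, and at least triplicate wells; the top dose sits
well above the EC50 so activity saturates within the first half of the
dilution series.  Viability noise is multiplicative Gaussian
(CV-like, matching plate-assay behavior), truncated so viability stays
non-negative.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import DomainError
from .io import DrugSpec, PanelScreen, VIABILITY_COLUMNS
from .synergy import bliss_expected
from .transcriptomics import CONDITIONS, ExpressionExperiment


# ---------------------------------------------------------------------------
# dose-response screens


@dataclass(frozen=True)
class HillParams:
    """Hill dose-response: Fa(c) = emax·c^h / (c^h + ec50^h), Fa(0) = 0."""

    emax: float = 0.9   # maximal fractional activity
    ec50: float = 1.0   # µM
    hill: float = 1.0   # slope

    def __post_init__(self) -> None:
        if not 0 < self.emax <= 1:
            raise DomainError("emax must be in (0, 1]")
        if self.ec50 <= 0 or self.hill <= 0:
            raise DomainError("ec50 and hill must be > 0")

    def fa(self, conc) -> np.ndarray:
        c = np.asarray(conc, dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            ch = np.power(c, self.hill)
            out = np.where(c > 0, self.emax * ch / (ch + self.ec50**self.hill), 0.0)
        return out


@dataclass(frozen=True)
class SynergySpec:
    """How synergy is injected into the combination surface.

    ``delta`` is added (in EoB percentage points / 100) to the Bliss
    expectation on the Fa scale before noise, so the analysis target is in
    the analysis's own units.  ``dose_peaked`` concentrates delta around the
    middle dilution step with a Gaussian profile of width ``peak_width``.
    """

    mode: str = "bliss_null"  # {bliss_null, uniform_delta, dose_peaked}
    delta: float = 0.0        # EoB percentage points
    noise_sd: float = 0.0     # multiplicative viability noise
    seed: int = 0
    peak_width: float = 1.5   # in dilution steps (dose_peaked only)

    def __post_init__(self) -> None:
        if self.mode not in ("bliss_null", "uniform_delta", "dose_peaked"):
            raise DomainError(f"unknown synergy mode {self.mode!r}")
        if self.mode == "bliss_null" and self.delta != 0:
            raise DomainError("bliss_null requires delta = 0")
        if self.noise_sd < 0:
            raise DomainError("noise_sd must be >= 0")

    def delta_at(self, step: np.ndarray, n_steps: int) -> np.ndarray:
        """Injected EoB (points) at dilution step(s) counted from the top dose."""
        step = np.asarray(step, dtype=float)
        if self.mode == "bliss_null":
            return np.zeros_like(step)
        if self.mode == "uniform_delta":
            return np.full_like(step, self.delta)
        mid = (n_steps - 1) / 2.0
        return self.delta * np.exp(-(((step - mid) / self.peak_width) ** 2))


def _noisy_viability(rng: np.random.Generator, viability: np.ndarray, sd: float) -> np.ndarray:
    """viability · (1 + ε), ε ~ N(0, sd) truncated at −1 (keeps v ≥ 0)."""
    if sd == 0:
        return viability.copy()
    eps = np.maximum(rng.normal(0.0, sd, size=viability.shape), -1.0)
    return viability * (1.0 + eps)


def simulate_monotherapy(
    params: HillParams,
    doses,
    n_rep: int = 3,
    noise_sd: float = 0.0,
    seed: int = 0,
    cell_line: str = "SIM1",
    drug: str = "drugA",
) -> pd.DataFrame:
    """Single-agent viability records (tidy dialect, drug_b = NA)."""
    if n_rep < 1:
        raise DomainError("n_rep must be >= 1")
    doses = np.asarray(doses, dtype=float)
    if np.any(doses < 0):
        raise DomainError("doses must be >= 0")
    rng = np.random.default_rng(seed)
    v_true = 1.0 - params.fa(doses)
    rows = []
    for rep in range(1, n_rep + 1):
        v = _noisy_viability(rng, v_true, noise_sd)
        rows.append(pd.DataFrame({
            "cell_line": cell_line, "drug_a": drug, "drug_b": pd.NA,
            "conc_a": doses, "conc_b": 0.0, "replicate": rep, "viability": v,
        }))
    return pd.concat(rows, ignore_index=True)[VIABILITY_COLUMNS]


@dataclass(frozen=True)
class CombinationSpec:
    """One drug pair to simulate: dilution series plus per-drug Hill curves
    and the synergy to inject."""

    drug_a: DrugSpec
    drug_b: DrugSpec
    hill_a: HillParams = HillParams()
    hill_b: HillParams = HillParams()
    synergy: SynergySpec = SynergySpec()


def default_pair(
    name_a: str = "drugA",
    name_b: str = "drugB",
    synergy: SynergySpec = SynergySpec(),
    top: float = 16.0,
    n_doses: int = 10,
) -> CombinationSpec:
    """A pair on the emulated screen geometry: 10-dose 1:4 series with the
    top dose 16× the EC50, so Fa saturates within the first dilutions."""
    return CombinationSpec(
        DrugSpec(name_a, top, 4.0, n_doses),
        DrugSpec(name_b, top, 4.0, n_doses),
        synergy=synergy,
    )


def simulate_combination_panel(
    pairs: list[CombinationSpec],
    n_lines: int = 10,
    n_rep: int = 3,
    design: str = "diagonal",
    seed: int = 0,
    line_ec50_sd: float = 0.3,
) -> tuple[PanelScreen, pd.DataFrame]:
    """Simulate a cell-line panel of combination matrices.

    Per (line, drug) the EC50 is jittered lognormally (``line_ec50_sd`` on
    the log scale) to emulate line-to-line sensitivity differences.  The
    combination Fa is clamp(Bliss expectation + delta/100) before noise.

    Returns the screen and a truth table with the noise-free Fa values and
    injected delta per combination well.
    """
    if design not in ("diagonal", "full"):
        raise DomainError(f"unknown design {design!r}")
    if not pairs:
        raise DomainError("no pairs to simulate")
    rng = np.random.default_rng(seed)
    lines = [f"line{i + 1:02d}" for i in range(n_lines)]
    rows, truth = [], []
    for line in lines:
        for spec in pairs:
            ha = replace(spec.hill_a, ec50=spec.hill_a.ec50 * float(np.exp(rng.normal(0, line_ec50_sd))))
            hb = replace(spec.hill_b, ec50=spec.hill_b.ec50 * float(np.exp(rng.normal(0, line_ec50_sd))))
            da = spec.drug_a.doses()[:-1]  # non-zero, descending
            db = spec.drug_b.doses()[:-1]
            name_a, name_b = spec.drug_a.name, spec.drug_b.name
            if design == "diagonal":
                if len(da) != len(db):
                    raise DomainError("diagonal design requires equal series lengths")
                steps = np.arange(len(da))
                ca, cb = da, db
                step_combo = steps
            else:
                ca, cb = np.meshgrid(da, db, indexing="ij")
                sa, sb = np.meshgrid(
                    np.arange(len(da)), np.arange(len(db)), indexing="ij"
                )
                ca, cb = ca.ravel(), cb.ravel()
                step_combo = np.maximum(sa, sb).ravel()
            fa_a_mono = ha.fa(da)
            fa_b_mono = hb.fa(db)
            fa_a_at = ha.fa(ca)
            fa_b_at = hb.fa(cb)
            delta = spec.synergy.delta_at(step_combo, len(da))
            fa_combo = np.clip(
                bliss_expected(fa_a_at, fa_b_at) + delta / 100.0, 0.0, 1.0
            )
            truth.append(pd.DataFrame({
                "cell_line": line, "drug_a": name_a, "drug_b": name_b,
                "conc_a": ca, "conc_b": cb, "fa_a_true": fa_a_at,
                "fa_b_true": fa_b_at, "fa_combo_true": fa_combo,
                "delta_true": delta,
            }))
            # wells: vehicle, both margins, combinations
            conc_a = np.concatenate([[0.0], da, np.zeros_like(db), ca])
            conc_b = np.concatenate([[0.0], np.zeros_like(da), db, cb])
            v_true = np.concatenate([
                [1.0], 1.0 - fa_a_mono, 1.0 - fa_b_mono, 1.0 - fa_combo,
            ])
            for rep in range(1, n_rep + 1):
                v = _noisy_viability(rng, v_true, spec.synergy.noise_sd)
                rows.append(pd.DataFrame({
                    "cell_line": line, "drug_a": name_a, "drug_b": name_b,
                    "conc_a": conc_a, "conc_b": conc_b,
                    "replicate": rep, "viability": v,
                }))
    wells = pd.concat(rows, ignore_index=True)[VIABILITY_COLUMNS]
    screen = PanelScreen(wells, design=design, metadata={"seed": seed})
    return screen, pd.concat(truth, ignore_index=True)


# ---------------------------------------------------------------------------
# expression experiments


def simulate_expression(
    n_genes: int = 2000,
    n_de: int = 800,
    n_pos: int = 250,
    n_neg: int = 250,
    effect: float = 2.0,
    sigma: float = 0.25,
    n_rep: int = 2,
    seed: int = 0,
    baseline_mean: float = 8.0,
    baseline_sd: float = 1.5,
    shift_range: tuple[float, float] = (1.0, 2.0),
) -> tuple[ExpressionExperiment, pd.DataFrame]:
    """Four-arm log2 expression matrix with planted interaction genes.

    The first ``n_de`` genes are differentially expressed: each gets
    single-agent log2 shifts of magnitude U(shift_range) with random signs.
    Of these, the first ``n_pos`` deviate by +``effect`` and the next
    ``n_neg`` by −``effect`` from the additive expectation in the
    combination arm; remaining DE genes are exactly additive.  Non-DE genes
    follow the baseline in every arm.  Which gene carries which label is a
    function of the counts only, so truth labels survive a seed change.

    Returns the experiment and a truth table (gene, is_de, interaction,
    shift_a, shift_b).
    """
    if not (n_pos + n_neg <= n_de <= n_genes):
        raise DomainError("need n_pos + n_neg <= n_de <= n_genes")
    if n_rep < 2:
        raise DomainError("n_rep must be >= 2")
    rng = np.random.default_rng(seed)
    genes = [f"gene{i:05d}" for i in range(n_genes)]
    base = rng.normal(baseline_mean, baseline_sd, size=n_genes)
    lo, hi = shift_range
    shift_a = np.zeros(n_genes)
    shift_b = np.zeros(n_genes)
    shift_a[:n_de] = rng.uniform(lo, hi, n_de) * rng.choice([-1.0, 1.0], n_de)
    shift_b[:n_de] = rng.uniform(lo, hi, n_de) * rng.choice([-1.0, 1.0], n_de)
    inter = np.zeros(n_genes)
    inter[:n_pos] = effect
    inter[n_pos:n_pos + n_neg] = -effect
    means = {
        "vehicle": base,
        "drug_a": base + shift_a,
        "drug_b": base + shift_b,
        "combination": base + shift_a + shift_b + inter,
    }
    data, samples, design_rows = {}, [], []
    for cond in CONDITIONS:
        for rep in range(1, n_rep + 1):
            name = f"{cond}_{rep}"
            data[name] = means[cond] + rng.normal(0.0, sigma, size=n_genes)
            samples.append(name)
            design_rows.append({"sample": name, "condition": cond, "replicate": rep})
    matrix = pd.DataFrame(data, index=pd.Index(genes, name="gene"))
    design = pd.DataFrame(design_rows)
    experiment = ExpressionExperiment(matrix, design)
    truth = pd.DataFrame({
        "gene": genes,
        "is_de": np.arange(n_genes) < n_de,
        "interaction": np.where(inter > 0, "positive", np.where(inter < 0, "negative", "none")),
        "shift_a": shift_a,
        "shift_b": shift_b,
    }).set_index("gene")
    return experiment, truth


# ---------------------------------------------------------------------------
# xenograft growth studies


@dataclass(frozen=True)
class GrowthSpec:
    """Exponential xenograft growth with per-arm growth-rate multipliers.

    v(t) = v0 · exp(rate · effect · t) with lognormal measurement noise;
    the control arm's effect is fixed at 1, a treatment effect of 0 is full
    growth arrest.  Defaults emulate a 4-week study, ~100 mm³ tumors at
    randomization and a synergistic combination arm (effect ≤ both
    monotherapies).
    """

    v0: float = 100.0             # mm³ at treatment start
    growth_rate: float = 0.1      # per day (control)
    effects: dict = field(default_factory=lambda: {
        "control": 1.0, "drug_a": 0.6, "drug_b": 0.4, "combination": 0.1,
    })
    noise_sd: float = 0.1         # sd of log measurement error
    v0_sd: float = 0.3            # lognormal spread of baseline volumes
    seed: int = 0

    def __post_init__(self) -> None:
        if self.v0 <= 0 or self.growth_rate < 0:
            raise DomainError("v0 must be > 0 and growth_rate >= 0")
        if set(self.effects) != set(GROUP_ARMS):
            raise DomainError(f"effects must cover arms {GROUP_ARMS}")
        if self.effects["control"] != 1.0:
            raise DomainError("control effect must be 1")
        if self.noise_sd < 0 or self.v0_sd < 0:
            raise DomainError("noise sds must be >= 0")


GROUP_ARMS = ("control", "drug_a", "drug_b", "combination")


def simulate_growth_study(
    spec: GrowthSpec,
    n_per_group: int = 8,
    days: float = 28.0,
    measure_every: float = 3.5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a four-arm study measured twice weekly from day 0 (treatment
    start) to ``days``; volumes are reported as two equal perpendicular
    caliper diameters (d = (2V)^(1/3), inverting V = d³/2).

    Returns (tumor table rows, per-mouse truth with arm effect and
    noise-free final RTV).
    """
    if n_per_group < 2:
        raise DomainError("n_per_group must be >= 2")
    rng = np.random.default_rng(spec.seed)
    t = np.arange(0.0, days + 1e-9, measure_every)
    if t[-1] < days:
        t = np.append(t, days)
    rows, truth = [], []
    for arm in GROUP_ARMS:
        eff = spec.effects[arm]
        for i in range(1, n_per_group + 1):
            mouse = f"{arm}_{i:02d}"
            v0 = spec.v0 * float(np.exp(rng.normal(0.0, spec.v0_sd)))
            v_true = v0 * np.exp(spec.growth_rate * eff * t)
            noise = np.exp(rng.normal(0.0, spec.noise_sd, size=t.size)) if spec.noise_sd else 1.0
            v_obs = v_true * noise
            d = np.cbrt(2.0 * v_obs)
            rows.append(pd.DataFrame({
                "mouse": mouse, "group": arm, "day": t, "d1_mm": d, "d2_mm": d,
            }))
            truth.append({
                "mouse": mouse, "group": arm, "effect": eff, "v0_true": v0,
                "rtv_true": float(np.exp(spec.growth_rate * eff * days)),
            })
    return (
        pd.concat(rows, ignore_index=True),
        pd.DataFrame(truth).set_index("mouse"),
    )
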
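"""Bliss-independence synergy scoring.

Fractional activity Fa is the fraction of growth inhibited relative to
vehicle: Fa = 1 − viability, so 40 % viability means Fa = 0.6.  Under Bliss
independence two non-interacting drugs combine as

    Fa_expected = Fa1 + Fa2 − Fa1·Fa2,

and the Excess over Bliss (EoB) at a dose pair is

    EoB = (Fa1+2 − Fa_expected) × 100   [percentage points],

positive for synergy, negative for antagonism.  A combination's score in a
cell line is its maximal EoB over the tested dose pairs; combinations are
ranked across a panel by the mean of these per-line maxima.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DomainError, ScreenValidationError
from .io import DoseMatrix, PanelScreen

logger = logging.getLogger("blisscreen")

POINT_COLUMNS = [
    "conc_a", "conc_b", "fa_a", "fa_b", "fa_combo",
    "bliss_expected", "excess_over_bliss",
]


def viability_to_fa(viability):
    """Convert viability fraction(s) to fractional activity 1 − v, clamped
    to [0, 1].  Viability above control (v > 1) clamps to Fa = 0 with a
    warning; negative viability is a domain error."""
    v = np.asarray(viability, dtype=float)
    if np.any(v < 0):
        raise DomainError("viability must be >= 0")
    n_clamped = int(np.sum(v > 1))
    if n_clamped:
        logger.warning("clamped %d viability value(s) > 1 to Fa = 0", n_clamped)
    fa = np.clip(1.0 - v, 0.0, 1.0)
    return float(fa) if np.isscalar(viability) else fa


def bliss_expected(fa_a, fa_b):
    """Bliss-independence expectation Fa1 + Fa2 − Fa1·Fa2 (symmetric,
    maps [0,1]² into [0,1])."""
    a, b = np.asarray(fa_a, dtype=float), np.asarray(fa_b, dtype=float)
    if np.any((a < 0) | (a > 1) | (b < 0) | (b > 1)):
        raise DomainError("fractional activities must lie in [0, 1]")
    out = a + b - a * b
    return float(out) if (np.isscalar(fa_a) and np.isscalar(fa_b)) else out


def excess_over_bliss(fa_a, fa_b, fa_combo):
    """Excess over Bliss in percentage points: (Fa1+2 − expectation)·100."""
    c = np.asarray(fa_combo, dtype=float)
    if np.any((c < 0) | (c > 1)):
        raise DomainError("fa_combo must lie in [0, 1]")
    out = (c - bliss_expected(fa_a, fa_b)) * 100.0
    scalars = all(map(np.isscalar, (fa_a, fa_b, fa_combo)))
    return float(out) if scalars else out


@dataclass
class SynergyResult:
    """Per-dose-pair EoB values for one matrix, with the per-matrix maximum.

    ``argmax_conc`` is the (conc_a, conc_b) of the maximal EoB; ties break
    toward the lowest total concentration.
    """

    cell_line: str
    drug_a: str
    drug_b: str
    points: pd.DataFrame  # POINT_COLUMNS
    max_excess: float = field(init=False)
    argmax_conc: tuple[float, float] = field(init=False)

    def __post_init__(self) -> None:
        if self.points.empty:
            raise ValueError("SynergyResult requires at least one point")
        eob = self.points["excess_over_bliss"].to_numpy()
        best = eob.max()
        at_best = self.points[np.isclose(eob, best)]
        total = at_best["conc_a"] + at_best["conc_b"]
        row = at_best.loc[total.idxmin()]
        self.max_excess = float(best)
        self.argmax_conc = (float(row["conc_a"]), float(row["conc_b"]))


@dataclass
class PanelRanking:
    """Combinations ordered by the mean of per-cell-line maximal EoB.

    ``entries`` columns: drug_a, drug_b, n_lines, mean_of_maxima, rank,
    full_coverage (False when a pair was not scored in every line of the
    panel).  Rank is 1-based, descending in mean_of_maxima; ties share the
    smaller rank.
    """

    entries: pd.DataFrame
    per_line_maxima: pd.DataFrame  # cell_line, drug_a, drug_b, max_excess


def _average_wells(wells: pd.DataFrame, average: str) -> pd.DataFrame:
    """Collapse replicates to one value per well.

    ``average="viability"`` (default, the convention of the source assay)
    averages raw viabilities then converts to Fa; ``"fa"`` converts each
    replicate first and averages on the Fa scale.
    """
    key = ["cell_line", "drug_a", "drug_b", "conc_a", "conc_b"]
    if average == "viability":
        mean_v = wells.groupby(key, dropna=False)["viability"].mean().reset_index()
        mean_v["fa"] = viability_to_fa(mean_v["viability"].to_numpy())
        return mean_v
    if average == "fa":
        w = wells.copy()
        w["fa"] = viability_to_fa(w["viability"].to_numpy())
        return w.groupby(key, dropna=False)["fa"].mean().reset_index()
    raise ValueError(f"unknown averaging mode {average!r}")


def _score_frame(wells: pd.DataFrame, average: str) -> pd.DataFrame:
    """Vectorized EoB over a tidy wells frame (any number of matrices)."""
    key = ["cell_line", "drug_a", "drug_b"]
    fa = _average_wells(wells[wells["drug_b"].notna()], average)
    combo = fa[(fa["conc_a"] > 0) & (fa["conc_b"] > 0)]
    if combo.empty:
        raise ScreenValidationError("no combination wells to score")
    mono_a = fa[(fa["conc_a"] > 0) & (fa["conc_b"] == 0)][key + ["conc_a", "fa"]]
    mono_b = fa[(fa["conc_a"] == 0) & (fa["conc_b"] > 0)][key + ["conc_b", "fa"]]
    m = combo.merge(mono_a.rename(columns={"fa": "fa_a"}), on=key + ["conc_a"], how="left")
    m = m.merge(mono_b.rename(columns={"fa": "fa_b"}), on=key + ["conc_b"], how="left")
    if m[["fa_a", "fa_b"]].isna().any().any():
        bad = m[m[["fa_a", "fa_b"]].isna().any(axis=1)]
        raise ScreenValidationError(
            f"{len(bad)} combination well(s) lack a monotherapy margin; "
            f"first: {bad.iloc[0][key + ['conc_a', 'conc_b']].to_dict()}"
        )
    m = m.rename(columns={"fa": "fa_combo"})
    m["bliss_expected"] = bliss_expected(m["fa_a"].to_numpy(), m["fa_b"].to_numpy())
    m["excess_over_bliss"] = (m["fa_combo"] - m["bliss_expected"]) * 100.0
    m = m.sort_values(key + ["conc_a", "conc_b"], kind="mergesort")
    return m[key + POINT_COLUMNS].reset_index(drop=True)


def score_matrix(matrix: DoseMatrix, average: str = "viability") -> SynergyResult:
    """Score one dose matrix: replicate-average each well, convert to Fa and
    evaluate EoB at every combination well against its monotherapy margins."""
    if matrix.wells.empty or matrix.combo_wells.empty:
        raise ScreenValidationError(
            f"matrix {matrix.cell_line}/{matrix.drug_a}+{matrix.drug_b} has no combination wells"
        )
    scored = _score_frame(matrix.wells, average)
    return SynergyResult(
        matrix.cell_line, matrix.drug_a, matrix.drug_b, scored[POINT_COLUMNS]
    )


def score_panel(screen: PanelScreen, average: str = "viability") -> list[SynergyResult]:
    """Score every matrix of a panel screen (vectorized across matrices)."""
    scored = _score_frame(screen.wells, average)
    out = []
    for (line, a, b), pts in scored.groupby(["cell_line", "drug_a", "drug_b"], sort=True):
        out.append(SynergyResult(line, a, b, pts[POINT_COLUMNS].reset_index(drop=True)))
    return out


def max_excess_per_line(result: SynergyResult) -> float:
    """The cell line's combination score: maximal EoB over dose pairs."""
    return result.max_excess


def rank_combinations(results: list[SynergyResult]) -> PanelRanking:
    """Rank drug pairs by the mean of per-cell-line maximal EoB.

    Pairs missing from some cell lines are averaged over the lines they
    were scored in and flagged (``full_coverage=False``).
    """
    if not results:
        raise ValueError("rank_combinations: empty results")
    maxima = pd.DataFrame(
        [
            {
                "cell_line": r.cell_line, "drug_a": r.drug_a, "drug_b": r.drug_b,
                "max_excess": r.max_excess,
            }
            for r in results
        ]
    ).sort_values(["drug_a", "drug_b", "cell_line"], kind="mergesort").reset_index(drop=True)
    n_panel_lines = maxima["cell_line"].nunique()
    agg = (
        maxima.groupby(["drug_a", "drug_b"])
        .agg(n_lines=("cell_line", "nunique"), mean_of_maxima=("max_excess", "mean"))
        .reset_index()
    )
    agg["full_coverage"] = agg["n_lines"] == n_panel_lines
    if not agg["full_coverage"].all():
        logger.warning(
            "%d pair(s) scored in fewer than %d lines; means use available lines",
            int((~agg["full_coverage"]).sum()), n_panel_lines,
        )
    agg["rank"] = (
        agg["mean_of_maxima"].rank(method="min", ascending=False).astype(int)
    )
    agg = agg.sort_values(
        ["rank", "drug_a", "drug_b"], kind="mergesort"
    ).reset_index(drop=True)
    cols = ["drug_a", "drug_b", "n_lines", "mean_of_maxima", "rank", "full_coverage"]
    return PanelRanking(agg[cols], maxima)
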
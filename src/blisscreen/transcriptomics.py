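"""Differential expression and drug-interaction gene classification.

A four-arm expression experiment (vehicle, drug A, drug B, combination,
replicated, log2 scale) is analyzed in two stages:

1. *DE stage* — each treatment arm is contrasted against vehicle with a
   moderated two-sample t statistic (gene-wise variances shrunk toward a
   common prior by empirical Bayes, in the manner of limma's variance
   moderation); p-values are Benjamini–Hochberg adjusted jointly across
   genes × contrasts.  A gene is DE if any contrast passes the FDR level.

2. *Interaction stage* — restricted to DE genes, the combination mean is
   compared against the additive log2 expectation

       E = mean(drug_a) + mean(drug_b) − mean(vehicle),

   the null of no transcriptional drug interaction.  The deviation
   (combination − E) is tested two-sided with the same moderated variance,
   BH-adjusted among DE genes.  A significant positive deviation is a
   *positive interaction* (combination up-regulated beyond additivity),
   negative a *negative interaction*.

Each gene additionally receives a *profile label*: the rank ordering of its
four condition means, with means closer than an ε tolerance (the pooled
standard error of a difference of condition means) sharing a rank, e.g.
``C<V=A=B`` for a gene pulled down specifically by the combination.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import digamma, polygamma
from statsmodels.stats.multitest import multipletests

from .errors import SchemaError, DomainError

CONDITIONS = ("vehicle", "drug_a", "drug_b", "combination")
_CODE = {"vehicle": "V", "drug_a": "A", "drug_b": "B", "combination": "C"}
TREATMENTS = ("drug_a", "drug_b", "combination")


@dataclass
class ExpressionExperiment:
    """A genes × samples log2 matrix plus its sample-condition design.

    ``design`` columns: sample (matching matrix columns), condition (one of
    CONDITIONS), replicate (1-based).  All four conditions must be present.
    """

    matrix: pd.DataFrame
    design: pd.DataFrame
    timepoint: str = "24h"

    def __post_init__(self) -> None:
        need = {"sample", "condition", "replicate"}
        if not need.issubset(self.design.columns):
            raise SchemaError(f"design table needs columns {sorted(need)}")
        unknown = set(self.design["condition"]) - set(CONDITIONS)
        if unknown:
            raise SchemaError(f"unknown condition(s): {sorted(unknown)}")
        missing = set(CONDITIONS) - set(self.design["condition"])
        if missing:
            raise SchemaError(f"condition(s) absent from design: {sorted(missing)}")
        absent = set(self.design["sample"]) - set(self.matrix.columns)
        if absent:
            raise SchemaError(f"design samples absent from matrix: {sorted(absent)}")
        if not np.isfinite(self.matrix[self.design["sample"]].to_numpy()).all():
            raise DomainError("expression matrix contains non-finite values")

    def samples(self, condition: str) -> list[str]:
        d = self.design
        return list(d.loc[d["condition"] == condition, "sample"])

    def condition_stats(self):
        """Per-condition means, pooled residual variance and residual df.

        Returns (means: genes × 4 DataFrame, s2: Series, df_resid: int,
        n: dict condition → replicate count).
        """
        means, rss = {}, 0.0
        n = {}
        for cond in CONDITIONS:
            cols = self.samples(cond)
            n[cond] = len(cols)
            block = self.matrix[cols].to_numpy(dtype=float)
            mu = block.mean(axis=1)
            means[cond] = mu
            rss = rss + ((block - mu[:, None]) ** 2).sum(axis=1)
        df_resid = sum(n.values()) - len(CONDITIONS)
        means = pd.DataFrame(means, index=self.matrix.index)
        s2 = pd.Series(rss / df_resid, index=self.matrix.index)
        return means, s2, df_resid, n


def _trigamma_inverse(y: np.ndarray) -> np.ndarray:
    """Solve trigamma(x) = y by Newton iteration (vectorized)."""
    y = np.asarray(y, dtype=float)
    x = np.where(y > 1e7, 1.0 / np.sqrt(y), 0.5 + 1.0 / y)
    for _ in range(50):
        tri = polygamma(1, x)
        dif = tri * (1.0 - tri / y) / polygamma(2, x)
        x = x + dif
        if np.all(np.abs(dif) / np.maximum(x, 1e-12) < 1e-10):
            break
    return x


def moderate_variance(s2: np.ndarray, df: int):
    """Empirical-Bayes shrinkage of gene-wise variances.

    Fits a scaled inverse-chi-square prior (df0, s0²) to the observed
    variances by matching the moments of log s² and returns the posterior
    variances (df0·s0² + df·s²)/(df0 + df) together with (df0, s0²).
    df0 = inf means complete shrinkage to the common value.
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if not ok.any():
        return np.zeros_like(s2), np.inf, 0.0
    z = np.log(s2[ok])
    e = z - digamma(df / 2.0) + np.log(df / 2.0)
    e_bar = e.mean()
    evar = e.var(ddof=1) - polygamma(1, df / 2.0) if e.size > 1 else 0.0
    if evar > 0:
        df0 = 2.0 * float(_trigamma_inverse(np.array([evar]))[0])
        s20 = float(np.exp(e_bar + digamma(df0 / 2.0) - np.log(df0 / 2.0)))
        s2_post = (df0 * s20 + df * s2) / (df0 + df)
    else:
        df0, s20 = np.inf, float(np.exp(e_bar))
        s2_post = np.full_like(s2, s20)
    return s2_post, df0, s20


def _t_pvalue(delta: np.ndarray, se: np.ndarray, df_total: float) -> np.ndarray:
    """Two-sided p for delta/se; handles the zero-variance degenerate case
    (se == 0): p = 1 when delta == 0, p = 0 otherwise."""
    delta = np.asarray(delta, dtype=float)
    se = np.asarray(se, dtype=float)
    t = np.zeros_like(delta)
    finite = se > 0
    t[finite] = delta[finite] / se[finite]
    t[~finite & (delta != 0)] = np.inf
    df_eff = df_total if np.isfinite(df_total) else 1e12
    return 2.0 * stats.t.sf(np.abs(t), df_eff)


def detect_de(experiment: ExpressionExperiment, alpha: float = 0.05) -> pd.DataFrame:
    """Moderated two-sample tests of each treatment vs vehicle.

    Returns a per-gene table with, for each treatment arm, the contrast
    estimate ``lfc_<arm>`` and its BH q-value ``q_<arm>`` (adjusted jointly
    across genes × contrasts), plus ``de_flag`` (any q ≤ alpha), the
    moderated variance ``s2_post``, total df and a ``degenerate`` flag for
    genes with zero residual variance.
    """
    if not 0 < alpha < 1:
        raise DomainError("alpha must be in (0, 1)")
    for cond in CONDITIONS:
        if len(experiment.samples(cond)) < 2:
            raise DomainError(f"condition {cond!r} has < 2 replicates")
    means, s2, df_resid, n = experiment.condition_stats()
    s2_post, df0, _ = moderate_variance(s2.to_numpy(), df_resid)
    df_total = df_resid + df0
    out = pd.DataFrame(index=experiment.matrix.index)
    pvals = []
    for arm in TREATMENTS:
        delta = (means[arm] - means["vehicle"]).to_numpy()
        se = np.sqrt(s2_post * (1.0 / n[arm] + 1.0 / n["vehicle"]))
        p = _t_pvalue(delta, se, df_total)
        out[f"lfc_{arm}"] = delta
        out[f"p_{arm}"] = p
        pvals.append(p)
    flat = np.concatenate(pvals)
    q_flat = multipletests(flat, method="fdr_bh")[1]
    qs = np.split(q_flat, len(TREATMENTS))
    for arm, q in zip(TREATMENTS, qs):
        out[f"q_{arm}"] = q
    out["de_flag"] = np.column_stack(qs).min(axis=1) <= alpha
    out["s2_post"] = s2_post
    out["df_total"] = df_total
    out["degenerate"] = s2.to_numpy() == 0.0
    return out


def _profile_labels(means: pd.DataFrame, eps: np.ndarray) -> list[str]:
    """Rank-order label of the four condition means with ε-tied groups.

    Means are sorted ascending; adjacent means within ε share a group.
    Conditions inside a group appear in fixed V,A,B,C order, groups are
    joined by ``<``, members by ``=``; e.g. ``C<V=A=B``.
    """
    codes = np.array([_CODE[c] for c in CONDITIONS])
    order_prio = {c: i for i, c in enumerate(CONDITIONS)}
    m = means[list(CONDITIONS)].to_numpy()
    labels = []
    for g in range(m.shape[0]):
        idx = sorted(range(4), key=lambda j: (m[g, j], order_prio[CONDITIONS[j]]))
        groups: list[list[int]] = [[idx[0]]]
        for j in idx[1:]:
            if m[g, j] - m[g, groups[-1][-1]] <= eps[g]:
                groups[-1].append(j)
            else:
                groups.append([j])
        labels.append(
            "<".join("=".join(codes[sorted(grp)]) for grp in groups)
        )
    return labels


def classify_profiles(
    de_table: pd.DataFrame,
    experiment: ExpressionExperiment,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Classify DE genes into positive / negative transcriptional
    interactions against the additive log2 null E = A + B − V.

    Returns per-gene calls: ``de_flag``, ``profile_label``,
    ``interaction_sign`` in {none, positive, negative}, ``effect``
    (combination − E, log2) and the interaction-stage ``q_value`` (BH among
    DE genes; NaN for non-DE genes).
    """
    means, _, _, n = experiment.condition_stats()
    s2_post = de_table["s2_post"].to_numpy()
    df_total = float(de_table["df_total"].iloc[0])
    effect = (
        means["combination"] - means["drug_a"] - means["drug_b"] + means["vehicle"]
    ).to_numpy()
    se = np.sqrt(s2_post * sum(1.0 / n[c] for c in CONDITIONS))
    p = _t_pvalue(effect, se, df_total)

    calls = pd.DataFrame(index=de_table.index)
    calls["de_flag"] = de_table["de_flag"]
    # ε for profile ties: SE of a difference of two condition means
    n_bar = np.mean([n[c] for c in CONDITIONS])
    eps = np.sqrt(s2_post * 2.0 / n_bar)
    calls["profile_label"] = _profile_labels(means, eps)
    calls["effect"] = effect
    calls["q_value"] = np.nan
    calls["interaction_sign"] = "none"
    de = calls["de_flag"].to_numpy()
    if de.any():
        q_de = multipletests(p[de], method="fdr_bh")[1]
        calls.loc[de, "q_value"] = q_de
        hit = np.zeros(len(calls), dtype=bool)
        hit[de] = q_de <= alpha
        calls.loc[hit & (effect > 0), "interaction_sign"] = "positive"
        calls.loc[hit & (effect < 0), "interaction_sign"] = "negative"
    return calls


@dataclass
class InteractionSummary:
    """Headline counts of an interaction analysis."""

    n_de: int
    n_interaction: int
    n_positive: int
    n_negative: int
    pct_interaction: float = field(init=False)
    profile_counts: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_positive + self.n_negative != self.n_interaction:
            raise ValueError("positive + negative must equal total interactions")
        self.pct_interaction = (
            100.0 * self.n_interaction / self.n_de if self.n_de else 0.0
        )

    @classmethod
    def from_counts(
        cls, n_de: int, n_interaction: int, n_positive: int, n_negative: int | None = None
    ) -> "InteractionSummary":
        if n_negative is None:
            n_negative = n_interaction - n_positive
        return cls(n_de, n_interaction, n_positive, n_negative)

    @property
    def top_profile(self) -> tuple[str, int, float] | None:
        """(label, count, pct of interaction genes) of the most common
        interaction profile, or None when there are no interactions."""
        if not self.profile_counts:
            return None
        label, count = max(self.profile_counts.items(), key=lambda kv: (kv[1], kv[0]))
        return label, count, 100.0 * count / self.n_interaction


def summarize_interactions(calls: pd.DataFrame) -> InteractionSummary:
    """Count DE genes, interaction genes and their signs from a calls table."""
    n_de = int(calls["de_flag"].sum())
    inter = calls[calls["interaction_sign"] != "none"]
    summary = InteractionSummary(
        n_de=n_de,
        n_interaction=len(inter),
        n_positive=int((inter["interaction_sign"] == "positive").sum()),
        n_negative=int((inter["interaction_sign"] == "negative").sum()),
    )
    summary.profile_counts = inter["profile_label"].value_counts().to_dict()
    return summary


def export_gene_lists(calls: pd.DataFrame, outdir: str | Path) -> list[Path]:
    """Write plain-text gene lists per category (de, positive, negative)
    for downstream enrichment tools; returns the written paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    groups = {
        "de_genes.txt": calls.index[calls["de_flag"]],
        "positive_interactions.txt": calls.index[calls["interaction_sign"] == "positive"],
        "negative_interactions.txt": calls.index[calls["interaction_sign"] == "negative"],
    }
    for fname, genes in groups.items():
        path = outdir / fname
        path.write_text("\n".join(map(str, sorted(genes))) + "\n")
        written.append(path)
    return written
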
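"""Readers, writers and validation for viability screens, expression
experiments and tumor-growth tables.

The on-disk dialect is tidy CSV throughout.  A viability table has one row
per well replicate::

    cell_line,drug_a,drug_b,conc_a,conc_b,replicate,viability

Concentrations are in µM; ``conc == 0`` encodes the vehicle (DMSO) control,
so a row with ``conc_b == 0`` inside a drug pair is the monotherapy margin
of drug A at ``conc_a``.  Viability is stored as a fraction of the vehicle
control (0.40, not 40 %); pass ``percent=True`` to the reader to divide a
percentage-scale table by 100 on the way in.  Values above 1 (growth beyond
control) are legal and flagged, never clamped, at this layer.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

from .errors import SchemaError, ScreenValidationError, DomainError

logger = logging.getLogger("blisscreen")

#: column order of the tidy viability dialect
VIABILITY_COLUMNS = [
    "cell_line", "drug_a", "drug_b", "conc_a", "conc_b", "replicate", "viability",
]

#: column order of the per-dose synergy report
REPORT_COLUMNS = [
    "record_type", "cell_line", "drug_a", "drug_b", "conc_a", "conc_b",
    "fa_a", "fa_b", "fa_combo", "bliss_expected", "excess_over_bliss",
]

_FLOAT_FMT = "%.12g"  # bit-stable CSV floats


@dataclass(frozen=True)
class DrugSpec:
    """A drug's dilution series: top dose, dilution ratio and dose count.

    ``n_doses`` counts the vehicle, so the default 10-dose 1:4 series has
    nine non-zero concentrations ``top / 4**k``.
    """

    name: str
    top_concentration: float  # µM
    dilution_factor: float = 4.0
    n_doses: int = 10

    def __post_init__(self) -> None:
        if self.top_concentration <= 0:
            raise DomainError(f"{self.name}: top_concentration must be > 0")
        if self.dilution_factor <= 1:
            raise DomainError(f"{self.name}: dilution_factor must be > 1")
        if self.n_doses < 2:
            raise DomainError(f"{self.name}: n_doses must be >= 2")

    def doses(self) -> np.ndarray:
        """Non-zero concentrations, descending, then the vehicle 0."""
        k = np.arange(self.n_doses - 1)
        return np.append(self.top_concentration / self.dilution_factor**k, 0.0)


@dataclass
class DoseMatrix:
    """One drug-pair × cell-line combination experiment.

    ``wells`` is a tidy frame (VIABILITY_COLUMNS) holding combination wells,
    both monotherapy margins and optionally the vehicle well, with raw
    replicates; averaging happens downstream in :mod:`blisscreen.synergy`.
    """

    cell_line: str
    drug_a: str
    drug_b: str
    wells: pd.DataFrame
    design: str = "diagonal"  # {"diagonal", "full"}

    def __post_init__(self) -> None:
        if self.design not in ("diagonal", "full"):
            raise ScreenValidationError(f"unknown design {self.design!r}")

    @property
    def combo_wells(self) -> pd.DataFrame:
        w = self.wells
        return w[(w["conc_a"] > 0) & (w["conc_b"] > 0)]

    def margin(self, which: str) -> pd.DataFrame:
        """Monotherapy wells of drug ``'a'`` or ``'b'``."""
        w = self.wells
        if which == "a":
            return w[(w["conc_a"] > 0) & (w["conc_b"] == 0)]
        return w[(w["conc_a"] == 0) & (w["conc_b"] > 0)]


@dataclass
class PanelScreen:
    """A collection of dose matrices over cell lines × drug pairs.

    Internally one tidy wells frame; drug pairs are order-normalized
    alphabetically (concentrations swapped consistently) so (A, B) and
    (B, A) rows land in the same matrix.
    """

    wells: pd.DataFrame
    design: str = "diagonal"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.wells = self.wells.reset_index(drop=True)

    @property
    def pairs(self) -> pd.DataFrame:
        """Unique (cell_line, drug_a, drug_b) keys, combination rows only."""
        w = self.wells[self.wells["drug_b"].notna()]
        return (
            w[["cell_line", "drug_a", "drug_b"]]
            .drop_duplicates()
            .sort_values(["cell_line", "drug_a", "drug_b"])
            .reset_index(drop=True)
        )

    def matrices(self) -> Iterator[DoseMatrix]:
        w = self.wells[self.wells["drug_b"].notna()]
        for (line, a, b), grp in w.groupby(
            ["cell_line", "drug_a", "drug_b"], sort=True
        ):
            yield DoseMatrix(line, a, b, grp.reset_index(drop=True), self.design)

    def matrix(self, cell_line: str, drug_a: str, drug_b: str) -> DoseMatrix:
        a, b = sorted((drug_a, drug_b))
        w = self.wells
        grp = w[
            (w["cell_line"] == cell_line) & (w["drug_a"] == a) & (w["drug_b"] == b)
        ]
        if grp.empty:
            raise KeyError((cell_line, a, b))
        return DoseMatrix(cell_line, a, b, grp.reset_index(drop=True), self.design)


def _normalize_pairs(df: pd.DataFrame) -> pd.DataFrame:
    """Alphabetize drug pair names, swapping concentrations consistently."""
    df = df.copy()
    paired = df["drug_b"].notna()
    flip = paired & (df["drug_a"] > df["drug_b"])
    if flip.any():
        df.loc[flip, ["drug_a", "drug_b"]] = df.loc[flip, ["drug_b", "drug_a"]].values
        df.loc[flip, ["conc_a", "conc_b"]] = df.loc[flip, ["conc_b", "conc_a"]].values
    return df


def _check_margins(df: pd.DataFrame) -> None:
    """Every combination well needs both monotherapy margins in its matrix."""
    w = df[df["drug_b"].notna()]
    key = ["cell_line", "drug_a", "drug_b"]
    combos = w[(w["conc_a"] > 0) & (w["conc_b"] > 0)][key + ["conc_a", "conc_b"]]
    combos = combos.drop_duplicates()
    mono_a = w[(w["conc_a"] > 0) & (w["conc_b"] == 0)][key + ["conc_a"]].drop_duplicates()
    mono_b = w[(w["conc_a"] == 0) & (w["conc_b"] > 0)][key + ["conc_b"]].drop_duplicates()
    miss_a = combos.merge(mono_a, on=key + ["conc_a"], how="left", indicator=True)
    miss_a = miss_a[miss_a["_merge"] == "left_only"]
    miss_b = combos.merge(mono_b, on=key + ["conc_b"], how="left", indicator=True)
    miss_b = miss_b[miss_b["_merge"] == "left_only"]
    if len(miss_a) or len(miss_b):
        offenders = []
        for row in miss_a.itertuples():
            offenders.append(
                f"({row.cell_line}, {row.drug_a}+{row.drug_b}, "
                f"conc_a={row.conc_a:g}, conc_b={row.conc_b:g}): "
                f"missing drug-A margin at conc_a={row.conc_a:g}"
            )
        for row in miss_b.itertuples():
            offenders.append(
                f"({row.cell_line}, {row.drug_a}+{row.drug_b}, "
                f"conc_a={row.conc_a:g}, conc_b={row.conc_b:g}): "
                f"missing drug-B margin at conc_b={row.conc_b:g}"
            )
        raise ScreenValidationError(
            "combination wells lack monotherapy margins:\n  " + "\n  ".join(offenders)
        )


def read_viability_table(
    path: str | Path,
    percent: bool = False,
    design: str = "diagonal",
    metadata: dict | None = None,
) -> PanelScreen:
    """Read a tidy viability CSV into a validated :class:`PanelScreen`.

    Parameters
    ----------
    percent
        If True, viability is on a 0–100 scale and is divided by 100.
    design
        Declared matrix design, ``"diagonal"`` (fixed-ratio ray) or
        ``"full"`` (complete grid).
    """
    df = pd.read_csv(path)
    missing = [c for c in VIABILITY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"viability table missing column(s): {', '.join(missing)}")
    df = df[VIABILITY_COLUMNS].copy()
    df["drug_b"] = df["drug_b"].replace("", np.nan)
    for col in ("conc_a", "conc_b", "viability"):
        df[col] = pd.to_numeric(df[col])
    df["replicate"] = df["replicate"].astype(int)
    if (df[["conc_a", "conc_b"]] < 0).any().any():
        bad = df[(df["conc_a"] < 0) | (df["conc_b"] < 0)]
        raise ScreenValidationError(
            f"negative concentrations in {len(bad)} row(s), first at index {bad.index[0]}"
        )
    if (df["viability"] < 0).any():
        raise ScreenValidationError("negative viability values present")
    if percent:
        df["viability"] = df["viability"] / 100.0
    n_high = int((df["viability"] > 1.2).sum())
    if n_high:
        logger.warning("%d well(s) with viability > 120%% of control (kept, flagged)", n_high)
    df = _normalize_pairs(df)
    _check_margins(df)
    return PanelScreen(df, design=design, metadata=metadata or {})


def write_viability_table(screen: PanelScreen, path: str | Path) -> Path:
    """Write a screen back to the tidy CSV dialect (round-trip safe)."""
    path = Path(path)
    out = screen.wells[VIABILITY_COLUMNS].sort_values(
        VIABILITY_COLUMNS[:6], kind="mergesort"
    )
    out.to_csv(path, index=False, float_format=_FLOAT_FMT)
    return path


@dataclass
class ValidationReport:
    """Findings from :func:`validate_screen`; empty means a clean screen."""

    findings: pd.DataFrame

    @property
    def empty(self) -> bool:
        return self.findings.empty

    def counts(self) -> dict[str, int]:
        if self.empty:
            return {}
        return self.findings["kind"].value_counts().to_dict()


def validate_screen(
    screen: PanelScreen,
    min_replicates: int = 3,
    high_viability: float = 1.2,
) -> ValidationReport:
    """Report (never mutate) quality findings on a screen.

    Finds wells with fewer than ``min_replicates`` replicates, wells with
    viability above ``high_viability`` (flag only — the assay admits
    growth beyond control), and, for full-design matrices, grid cells with
    no combination well.
    """
    w = screen.wells
    findings: list[dict] = []
    well_key = ["cell_line", "drug_a", "drug_b", "conc_a", "conc_b"]
    counts = w.groupby(well_key, dropna=False)["replicate"].count()
    for key, n in counts[counts < min_replicates].items():
        findings.append(dict(zip(well_key, key)) | {"kind": "under_replicated",
                                                    "detail": f"{n} replicate(s)"})
    high = w[w["viability"] > high_viability]
    for row in high.itertuples():
        findings.append({
            "kind": "high_viability", "cell_line": row.cell_line,
            "drug_a": row.drug_a, "drug_b": row.drug_b,
            "conc_a": row.conc_a, "conc_b": row.conc_b,
            "detail": f"viability {row.viability:.3g} > {high_viability:g}",
        })
    if screen.design == "full":
        for m in screen.matrices():
            da = np.sort(m.margin("a")["conc_a"].unique())
            db = np.sort(m.margin("b")["conc_b"].unique())
            have = set(map(tuple, m.combo_wells[["conc_a", "conc_b"]].values))
            for ca in da:
                for cb in db:
                    if (ca, cb) not in have:
                        findings.append({
                            "kind": "missing_cell", "cell_line": m.cell_line,
                            "drug_a": m.drug_a, "drug_b": m.drug_b,
                            "conc_a": ca, "conc_b": cb,
                            "detail": "full-design grid cell absent",
                        })
    cols = ["kind", "cell_line", "drug_a", "drug_b", "conc_a", "conc_b", "detail"]
    frame = pd.DataFrame(findings, columns=cols)
    return ValidationReport(frame)


def write_synergy_report(results, path: str | Path) -> Path:
    """Write per-dose synergy points plus per-matrix summaries as tidy CSV.

    Detail rows carry ``record_type == "point"``; each matrix contributes
    one ``"max"`` summary row holding ``max_excess`` at the argmax dose pair.
    Column order is fixed (REPORT_COLUMNS) so output is bit-stable.
    """
    results = list(results)
    if not results:
        raise ValueError("write_synergy_report: empty results")
    path = Path(path)
    blocks = []
    for r in results:
        pts = r.points.copy()
        pts.insert(0, "record_type", "point")
        pts.insert(1, "cell_line", r.cell_line)
        pts.insert(2, "drug_a", r.drug_a)
        pts.insert(3, "drug_b", r.drug_b)
        summary = pd.DataFrame([{
            "record_type": "max", "cell_line": r.cell_line,
            "drug_a": r.drug_a, "drug_b": r.drug_b,
            "conc_a": r.argmax_conc[0], "conc_b": r.argmax_conc[1],
            "fa_a": np.nan, "fa_b": np.nan, "fa_combo": np.nan,
            "bliss_expected": np.nan, "excess_over_bliss": r.max_excess,
        }])
        blocks.append(pts[REPORT_COLUMNS])
        blocks.append(summary[REPORT_COLUMNS])
    pd.concat(blocks, ignore_index=True).to_csv(
        path, index=False, float_format=_FLOAT_FMT
    )
    return path


def read_synergy_report(path: str | Path):
    """Reconstruct SynergyResult objects from a report written by
    :func:`write_synergy_report` (round-trip inverse)."""
    from .synergy import SynergyResult  # local import to avoid a cycle

    df = pd.read_csv(path)
    missing = [c for c in REPORT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"synergy report missing column(s): {', '.join(missing)}")
    out = []
    pts_all = df[df["record_type"] == "point"]
    for (line, a, b), pts in pts_all.groupby(["cell_line", "drug_a", "drug_b"]):
        pts = pts.drop(columns=["record_type", "cell_line", "drug_a", "drug_b"])
        out.append(SynergyResult(line, a, b, pts.reset_index(drop=True)))
    return out
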
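"""Dual-luciferase reporter assay quantification.

Firefly luminescence (test construct) is normalized per well by Renilla
luminescence (transfection control); clone-level activity is the mean of a
clone's replicate wells expressed as fold change over the empty
minimal-promoter vector; alleles (or two-SNP haplotypes) are compared by a
two-sided t-test on clone-level fold changes — the clone, an independently
isolated plasmid, is the experimental unit, not the well.

Forward and reverse construct orientations are analyzed separately, never
pooled.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

PLATE_COLUMNS = [
    "construct_id",
    "haplotype",
    "orientation",
    "clone_id",
    "replicate",
    "firefly",
    "renilla",
    "is_empty_vector",
]

_ORIENTATIONS = {"forward", "reverse", "none"}


@dataclass
class LuciferasePlate:
    """Validated per-well firefly/Renilla readings keyed by construct."""

    wells: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in PLATE_COLUMNS if c not in self.wells.columns]
        if missing:
            raise ValueError(f"plate table missing columns: {missing}")
        df = self.wells.copy()
        df["is_empty_vector"] = df["is_empty_vector"].astype(bool)
        bad_orient = set(df["orientation"]) - _ORIENTATIONS
        if bad_orient:
            raise ValueError(f"unknown orientations: {sorted(bad_orient)}")
        for col in ("firefly", "renilla"):
            df[col] = df[col].astype(float)
            if (df[col] <= 0).any():
                bad = df.loc[df[col] <= 0].iloc[0]
                raise ValueError(
                    f"non-positive {col} reading in well "
                    f"(construct={bad['construct_id']}, clone={bad['clone_id']}, "
                    f"replicate={bad['replicate']})"
                )
        self.wells = df

    @classmethod
    def from_tsv(cls, path: str | Path) -> "LuciferasePlate":
        return cls(pd.read_csv(path, sep="\t"))

    def to_tsv(self, path: str | Path) -> None:
        self.wells.to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class AlleleComparison:
    """Clone-level fold-change comparison between two alleles/haplotypes."""

    risk_label: str
    nonrisk_label: str
    orientation: str
    mean_risk: float
    sd_risk: float
    n_risk: int
    mean_nonrisk: float
    sd_nonrisk: float
    n_nonrisk: int
    fold_ratio: float
    t_statistic: float
    p_value: float
    test: str


def normalize_wells(plate: LuciferasePlate) -> pd.DataFrame:
    """Per-well normalized activity = firefly / Renilla."""
    df = plate.wells.copy()
    df["normalized"] = df["firefly"] / df["renilla"]
    return df


def clone_fold_changes(plate: LuciferasePlate) -> pd.DataFrame:
    """Per-clone fold change over the empty-vector mean.

    Each clone's replicate normalized activities are averaged, then divided
    by the mean normalized activity of all empty-vector wells.
    """
    df = normalize_wells(plate)
    empties = df.loc[df["is_empty_vector"], "normalized"]
    if empties.empty:
        raise ValueError("no empty-vector control wells in plate")
    empty_mean = float(empties.mean())
    clones = (
        df.loc[~df["is_empty_vector"]]
        .groupby(["construct_id", "haplotype", "orientation", "clone_id"], sort=True)
        ["normalized"]
        .mean()
        .reset_index()
        .rename(columns={"normalized": "clone_mean"})
    )
    clones["fold_change"] = clones["clone_mean"] / empty_mean
    return clones


def compare_alleles(
    plate: LuciferasePlate,
    risk_label: str,
    nonrisk_label: str,
    orientation: str,
    equal_var: bool = False,
    log_scale: bool = False,
    unit: str = "clone",
) -> AlleleComparison:
    """Two-sided t-test on fold changes between two construct labels.

    ``unit='clone'`` (default) tests clone-level fold changes (Welch's form
    unless ``equal_var``); ``unit='well'`` tests individual wells. For
    two-SNP haplotype constructs, pass full haplotype labels that hold the
    other SNP's allele fixed. ``log_scale`` runs the test on log fold
    changes (the ratio and group summaries stay on the linear scale).
    """
    if unit == "clone":
        values = clone_fold_changes(plate)
        values = values.loc[values["orientation"] == orientation]
        groups = {
            lbl: values.loc[values["haplotype"] == lbl, "fold_change"].to_numpy()
            for lbl in (risk_label, nonrisk_label)
        }
    elif unit == "well":
        df = normalize_wells(plate)
        empties = df.loc[df["is_empty_vector"], "normalized"]
        if empties.empty:
            raise ValueError("no empty-vector control wells in plate")
        empty_mean = float(empties.mean())
        sel = (~df["is_empty_vector"]) & (df["orientation"] == orientation)
        groups = {
            lbl: (df.loc[sel & (df["haplotype"] == lbl), "normalized"] / empty_mean).to_numpy()
            for lbl in (risk_label, nonrisk_label)
        }
    else:
        raise ValueError("unit must be 'clone' or 'well'")

    for lbl, vals in groups.items():
        if len(vals) < 2:
            raise ValueError(
                f"need >= 2 {unit}s per group; {lbl!r} has {len(vals)} "
                f"in orientation {orientation!r}"
            )
    risk, nonrisk = groups[risk_label], groups[nonrisk_label]
    test_risk, test_nonrisk = (np.log(risk), np.log(nonrisk)) if log_scale else (risk, nonrisk)
    if np.allclose(test_risk, test_risk[0]) and np.allclose(test_nonrisk, test_nonrisk[0]) \
            and np.isclose(test_risk[0], test_nonrisk[0]):
        t_stat, p_value = 0.0, 1.0  # identical constant groups: no evidence either way
    else:
        t_stat, p_value = stats.ttest_ind(test_risk, test_nonrisk, equal_var=equal_var)
    return AlleleComparison(
        risk_label=risk_label,
        nonrisk_label=nonrisk_label,
        orientation=orientation,
        mean_risk=float(np.mean(risk)),
        sd_risk=float(np.std(risk, ddof=1)),
        n_risk=len(risk),
        mean_nonrisk=float(np.mean(nonrisk)),
        sd_nonrisk=float(np.std(nonrisk, ddof=1)),
        n_nonrisk=len(nonrisk),
        fold_ratio=float(np.mean(risk) / np.mean(nonrisk)),
        t_statistic=float(t_stat),
        p_value=float(p_value),
        test=("student" if equal_var else "welch") + ("-log" if log_scale else ""),
    )


def haplotype_contrasts(labels: list[str], varying_index: int, sep: str = "-") -> list[tuple[str, str]]:
    """Pairs of haplotype labels differing only at one SNP position.

    Labels are allele strings joined by ``sep`` (e.g. ``"C-A"`` for
    rs36062557/rs11257655); the returned pairs vary the allele at
    ``varying_index`` while holding every other position fixed — the
    mutagenesis-dissection design that isolates one SNP's effect.
    """
    parsed = {lbl: lbl.split(sep) for lbl in labels}
    pairs: list[tuple[str, str]] = []
    seen: set[frozenset[str]] = set()
    for a in labels:
        for b in labels:
            if a == b or frozenset((a, b)) in seen:
                continue
            pa, pb = parsed[a], parsed[b]
            if len(pa) != len(pb):
                continue
            diffs = [i for i, (x, y) in enumerate(zip(pa, pb)) if x != y]
            if diffs == [varying_index]:
                pairs.append((a, b))
                seen.add(frozenset((a, b)))
    return sorted(pairs)


def comparison_to_row(cmp: AlleleComparison) -> dict:
    """Flatten an AlleleComparison for a TSV report."""
    return {
        "risk_label": cmp.risk_label,
        "nonrisk_label": cmp.nonrisk_label,
        "orientation": cmp.orientation,
        "n_risk": cmp.n_risk,
        "n_nonrisk": cmp.n_nonrisk,
        "mean_risk": cmp.mean_risk,
        "sd_risk": cmp.sd_risk,
        "mean_nonrisk": cmp.mean_nonrisk,
        "sd_nonrisk": cmp.sd_nonrisk,
        "fold_ratio": cmp.fold_ratio,
        "t_statistic": cmp.t_statistic,
        "p_value": cmp.p_value,
        "test": cmp.test,
    }
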
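"""Ct-based qPCR quantification for ChIP enrichment and relative expression.

Two workflows share the Ct table container:

* **Allele-specific ChIP-qPCR** — fold enrichment of an antibody pull-down
  over a species-matched IgG control at the same sample and target region,
  ``fold = 2^(meanCt_IgG − meanCt_antibody)`` under the perfect-doubling
  assumption, with an optional percent-of-input normalization of both
  terms first. Genotype groups (e.g. CT carriers vs CC homozygotes) are
  compared by a one-sided Welch t-test whose direction must be declared up
  front (the sidedness comes from prior binding evidence, never from the
  data).
* **Standard-curve relative expression** — serial-dilution standard curves
  (Ct regressed on log10 relative quantity; efficiency E = 10^(−1/slope))
  convert Ct to quantities, a transcript is normalized to a housekeeping
  gene, and treatment conditions are compared with a two-sided Welch
  t-test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

CT_COLUMNS = ["sample_id", "group", "antibody", "target", "replicate", "ct"]

#: replicate scatter above this many cycles is flagged as suspect
REPLICATE_SD_FLAG = 0.5


class CtRangeError(ValueError):
    pass


@dataclass
class CtTable:
    """Replicate Ct values keyed by sample, antibody/condition and target."""

    rows: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in CT_COLUMNS if c not in self.rows.columns]
        if missing:
            raise ValueError(f"Ct table missing columns: {missing}")
        df = self.rows.copy()
        df["ct"] = df["ct"].astype(float)
        if ((df["ct"] <= 0) | (df["ct"] >= 45)).any():
            bad = df.loc[(df["ct"] <= 0) | (df["ct"] >= 45)].iloc[0]
            raise CtRangeError(
                f"Ct {bad['ct']} outside (0, 45) for sample={bad['sample_id']}, "
                f"antibody={bad['antibody']}, target={bad['target']}"
            )
        self.rows = df

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CtTable":
        return cls(pd.read_csv(path, sep="\t"))

    def to_tsv(self, path: str | Path) -> None:
        self.rows.to_csv(path, sep="\t", index=False)


def mean_ct(
    table: CtTable,
    keys: Sequence[str] = ("sample_id", "antibody", "target"),
) -> pd.DataFrame:
    """Collapse replicates: mean and SD of Ct per key, flag SD > 0.5 cycles."""
    grouped = table.rows.groupby(list(keys), sort=True)["ct"]
    out = grouped.agg(mean_ct="mean", sd_ct="std", n="size").reset_index()
    out["sd_ct"] = out["sd_ct"].fillna(0.0)
    out["flag_high_sd"] = out["sd_ct"] > REPLICATE_SD_FLAG
    return out


def _lookup_mean_ct(means: pd.DataFrame, sample: str, antibody: str, target: str) -> float:
    sel = (
        (means["sample_id"] == sample)
        & (means["antibody"] == antibody)
        & (means["target"] == target)
    )
    hit = means.loc[sel, "mean_ct"]
    if hit.empty:
        raise KeyError(
            f"no Ct rows for sample={sample!r}, antibody={antibody!r}, target={target!r}"
        )
    return float(hit.iloc[0])


def fold_enrichment(
    table: CtTable,
    antibody: str,
    sample: str,
    region: str,
    igg_label: str = "IgG",
    input_label: str | None = None,
    input_fraction: float = 0.05,
) -> float:
    """ChIP fold enrichment of ``antibody`` over IgG at one sample/region.

    ``2^(meanCt_IgG − meanCt_antibody)``; equals 1 when the Ct values
    match. When ``input_label`` is given, both antibody and IgG are first
    expressed as percent of input (input Ct adjusted for the fraction of
    chromatin set aside, default 5%) — algebraically the input term cancels
    in the ratio, but the intermediate percent-input values are computed as
    assayed.
    """
    means = mean_ct(table)
    ct_ab = _lookup_mean_ct(means, sample, antibody, region)
    try:
        ct_igg = _lookup_mean_ct(means, sample, igg_label, region)
    except KeyError:
        raise KeyError(
            f"missing {igg_label} control rows for sample={sample!r}, region={region!r}"
        ) from None
    if input_label is None:
        return float(2.0 ** (ct_igg - ct_ab))
    ct_input = _lookup_mean_ct(means, sample, input_label, region)
    adj_input = ct_input - np.log2(1.0 / input_fraction)  # dilution-of-input correction
    pct_ab = 100.0 * 2.0 ** (adj_input - ct_ab)
    pct_igg = 100.0 * 2.0 ** (adj_input - ct_igg)
    return float(pct_ab / pct_igg)


@dataclass(frozen=True)
class EnrichmentResult:
    """Per-genotype fold enrichments and the declared-direction comparison."""

    antibody: str
    region: str
    folds_by_group: dict[str, tuple[float, ...]]
    group_means: dict[str, float]
    direction: str
    t_statistic: float
    p_value: float


def enrichment_by_group(
    table: CtTable,
    antibody: str,
    region: str,
    igg_label: str = "IgG",
    input_label: str | None = None,
    input_fraction: float = 0.05,
) -> dict[str, list[float]]:
    """Per-sample fold enrichments grouped by genotype/condition label."""
    sub = table.rows.loc[table.rows["target"] == region]
    out: dict[str, list[float]] = {}
    for (group, sample), _ in sub.groupby(["group", "sample_id"], sort=True):
        if antibody not in set(sub.loc[sub["sample_id"] == sample, "antibody"]):
            continue
        fe = fold_enrichment(
            table, antibody, sample, region,
            igg_label=igg_label, input_label=input_label, input_fraction=input_fraction,
        )
        out.setdefault(str(group), []).append(fe)
    return out


def compare_enrichment_one_sided(
    folds_by_group: Mapping[str, Sequence[float]],
    direction: str,
) -> tuple[float, float]:
    """One-sided Welch t-test between two genotype groups.

    ``direction`` is mandatory, e.g. ``"CT>CC"``: the alternative is that
    the first-named group has greater enrichment. Requiring it in config
    prevents silent post-hoc choice of sidedness.
    """
    if not direction or ">" not in direction:
        raise ValueError(
            "direction must be declared as 'GREATER_GROUP>LESSER_GROUP' "
            "(sidedness comes from prior evidence, never from the data)"
        )
    hi, _, lo = direction.partition(">")
    hi, lo = hi.strip(), lo.strip()
    for g in (hi, lo):
        if g not in folds_by_group:
            raise KeyError(f"group {g!r} not present; have {sorted(folds_by_group)}")
        if len(folds_by_group[g]) < 2:
            raise ValueError(f"need >= 2 samples per group; {g!r} has {len(folds_by_group[g])}")
    a = np.asarray(folds_by_group[hi], dtype=float)
    b = np.asarray(folds_by_group[lo], dtype=float)
    if np.allclose(a, a[0]) and np.allclose(b, b[0]) and np.isclose(a[0], b[0]):
        return 0.0, 0.5  # identical groups sit exactly on the one-sided null boundary
    t_stat, p = stats.ttest_ind(a, b, equal_var=False, alternative="greater")
    return float(t_stat), float(p)


def compare_enrichment(
    table: CtTable,
    antibody: str,
    region: str,
    direction: str,
    **kwargs,
) -> EnrichmentResult:
    """Convenience wrapper: group folds then run the declared one-sided test."""
    groups = enrichment_by_group(table, antibody, region, **kwargs)
    t_stat, p = compare_enrichment_one_sided(groups, direction)
    return EnrichmentResult(
        antibody=antibody,
        region=region,
        folds_by_group={g: tuple(v) for g, v in groups.items()},
        group_means={g: float(np.mean(v)) for g, v in groups.items()},
        direction=direction,
        t_statistic=t_stat,
        p_value=p,
    )


@dataclass(frozen=True)
class StandardCurve:
    """Ct-vs-log10(quantity) calibration line from a serial dilution."""

    slope: float
    intercept: float
    efficiency: float
    r_squared: float
    log10_quantities: tuple[float, ...]
    mean_cts: tuple[float, ...]

    @property
    def ct_range(self) -> tuple[float, float]:
        return (min(self.mean_cts), max(self.mean_cts))

    def quantity_from_ct(self, ct: float, warn_extrapolation: bool = True) -> float:
        lo, hi = self.ct_range
        if warn_extrapolation and not (lo <= ct <= hi):
            warnings.warn(
                f"Ct {ct:.2f} outside calibrated range [{lo:.2f}, {hi:.2f}]; extrapolating",
                stacklevel=2,
            )
        return float(10.0 ** ((ct - self.intercept) / self.slope))


def fit_standard_curve(
    mean_cts: Sequence[float],
    dilution_factor: float = 3.0,
) -> StandardCurve:
    """Least-squares calibration line from a serial dilution series.

    ``mean_cts`` are replicate-mean Ct values ordered from the undiluted
    reference down the series; relative quantities are
    ``dilution_factor**(-i)``. Efficiency ``E = 10^(−1/slope)``; curves
    with E outside (1.6, 2.2) are flagged with a warning, positive slopes
    are an error.
    """
    cts = np.asarray(mean_cts, dtype=float)
    if cts.size < 3:
        raise ValueError(f"need >= 3 dilution points, got {cts.size}")
    if dilution_factor <= 1:
        raise ValueError("dilution_factor must be > 1")
    logq = -np.arange(cts.size) * np.log10(dilution_factor)
    fit = stats.linregress(logq, cts)
    if fit.slope >= 0:
        raise ValueError(
            f"standard curve slope is non-negative ({fit.slope:.3f}); "
            "Ct must decrease with template quantity"
        )
    efficiency = float(10.0 ** (-1.0 / fit.slope))
    if not (1.6 < efficiency < 2.2):
        warnings.warn(
            f"amplification efficiency {efficiency:.3f} outside the usual (1.6, 2.2) range",
            stacklevel=2,
        )
    return StandardCurve(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        efficiency=efficiency,
        r_squared=float(fit.rvalue**2),
        log10_quantities=tuple(logq),
        mean_cts=tuple(cts),
    )


def relative_expression(
    table: CtTable,
    gene: str,
    housekeeping: str,
    curves: Mapping[str, StandardCurve],
) -> pd.DataFrame:
    """Standard-curve quantity of ``gene`` over ``housekeeping``, per sample.

    Both targets are quantified from their own fitted curves (curve-based
    quantification, not ΔΔCt). Returns sample_id, group, and the
    normalized quantity.
    """
    for target in (gene, housekeeping):
        if target not in curves:
            raise KeyError(f"no standard curve for target {target!r}")
    means = mean_ct(table, keys=("sample_id", "group", "antibody", "target"))
    sub = means.loc[means["target"].isin([gene, housekeeping])]
    rows = []
    for (sample, group), block in sub.groupby(["sample_id", "group"], sort=True):
        by_target = dict(zip(block["target"], block["mean_ct"]))
        if gene not in by_target or housekeeping not in by_target:
            continue
        q_gene = curves[gene].quantity_from_ct(by_target[gene])
        q_hk = curves[housekeeping].quantity_from_ct(by_target[housekeeping])
        rows.append(
            {"sample_id": sample, "group": group, "normalized_quantity": q_gene / q_hk}
        )
    return pd.DataFrame(rows)


def compare_conditions(
    expression: pd.DataFrame,
    low_label: str,
    high_label: str,
) -> tuple[float, float]:
    """Two-sided Welch t-test between treatment conditions.

    Returns ``(fold, p_value)`` with fold = mean(high) / mean(low) of the
    normalized quantities.
    """
    groups = {
        lbl: expression.loc[expression["group"] == lbl, "normalized_quantity"].to_numpy()
        for lbl in (low_label, high_label)
    }
    for lbl, vals in groups.items():
        if len(vals) < 2:
            raise ValueError(f"need >= 2 samples per condition; {lbl!r} has {len(vals)}")
    low, high = groups[low_label], groups[high_label]
    fold = float(np.mean(high) / np.mean(low))
    if np.allclose(low, low[0]) and np.allclose(high, high[0]) and np.isclose(low[0], high[0]):
        return fold, 1.0
    _, p = stats.ttest_ind(high, low, equal_var=False)
    return fold, float(p)
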
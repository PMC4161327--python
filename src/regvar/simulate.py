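"""Synthetic data generators for every pipeline stage.

Each generator is a pure function of (configuration, seed) and emulates the
statistical structure of the study design the pipeline expects:

* a phased haplotype panel with a configurable index-SNP/proxy r²
  structure (standing in for a 1000 Genomes-style EUR reference panel),
  written as a phased VCF;
* peak tracks (BED/narrowPeak) placed over chosen variants so that the
  prioritization funnel has a known truth;
* an EMSA-style allele probe pair in which one allele completes a
  forkhead-core motif — by default the printed 21-bp rs11257655 probes;
* dual-luciferase plates with a configurable true allelic activity ratio,
  per-well multiplicative log-normal noise and an optional per-clone
  random effect;
* ChIP-qPCR and expression Ct tables with configurable enrichment /
  induction and additive Gaussian Ct noise.

The default scenario (:func:`paper_like`) encodes the study design the
package mirrors: 11 LD proxies (index included), two of them in open
chromatin, the printed probe pair, luciferase ratios 2.1 / 1.4 / 1.4 in
three virtual cell lines, and ChIP enrichments 7.2 / 4.2 for T-carriers
against 1.0 for CC homozygotes and the control region.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .annotation import GenomicInterval, PeakTrack
from .ld import HaplotypePanel, VariantRecord, r2_from_haplotype_freqs
from .motif import AlleleProbePair, PWMModel, consensus_core_match
from .qpcr import CtTable
from .reporter import LuciferasePlate

# ---------------------------------------------------------------------------
# printed EMSA probe pair (rs11257655; C = non-risk, T = risk, 0-based offset 10)
PROBE_SENSE_REF = "GGGCAAGTGTCTACTGGGCAT"
PROBE_SENSE_ALT = "GGGCAAGTGTTTACTGGGCAT"
PROBE_SNP_OFFSET = 10

#: core position of the forkhead consensus (TGTTTAC) that the risk allele supplies
FOXA_CORE_CONSENSUS = "TGTTTAC"
FOXA_CORE_SNP_POSITION = 3


# ---------------------------------------------------------------------------
# two-SNP haplotype tables


def two_snp_haplotype_freqs(
    p_a: float, p_b: float, target_r2: float, sign: int = 1
) -> np.ndarray:
    """Haplotype probabilities (AB, Ab, aB, ab) achieving an exact r².

    ``p_AB = p_a·p_b + sign·sqrt(r²·p_a(1−p_a)·p_b(1−p_b))``, the other
    three cells by the marginal constraints. Raises when the combination
    is infeasible, reporting the maximum attainable r² for that sign.
    """
    if not (0.0 < p_a < 1.0 and 0.0 < p_b < 1.0):
        raise ValueError("allele frequencies must be in (0, 1)")
    if not (0.0 <= target_r2 <= 1.0):
        raise ValueError("target r2 must be in [0, 1]")
    if sign not in (1, -1):
        raise ValueError("sign must be +1 or -1")
    denom = p_a * (1 - p_a) * p_b * (1 - p_b)
    d = sign * math.sqrt(target_r2 * denom)
    p_ab = p_a * p_b + d
    probs = np.array(
        [p_ab, p_a - p_ab, p_b - p_ab, 1.0 - p_a - p_b + p_ab], dtype=np.float64
    )
    if (probs < -1e-12).any():
        if sign == 1:
            d_max = min(p_a, p_b) - p_a * p_b
        else:
            d_max = p_a * p_b - max(0.0, p_a + p_b - 1.0)
        r2_max = d_max * d_max / denom
        raise ValueError(
            f"infeasible (p_a={p_a}, p_b={p_b}, r2={target_r2}, sign={sign:+d}); "
            f"maximum attainable r2 is {r2_max:.6f}"
        )
    return np.clip(probs, 0.0, None)


# ---------------------------------------------------------------------------
# scenario configuration


@dataclass
class ProxySpec:
    """One variant correlated with the index SNP at a target r²."""

    id: str
    maf: float = 0.2
    r2: float = 0.8
    sign: int = 1
    ref: str = "A"
    alt: str = "G"


@dataclass
class PeakPlanEntry:
    """One synthetic peak track covering a designated set of variants."""

    track_id: str
    cell_type: str
    assay_name: str
    cover_variants: list[str] = field(default_factory=list)
    width: int = 400
    fmt: str = "bed"  # "bed" or "narrowPeak"


@dataclass
class LuciferasePlan:
    """Design of one simulated dual-luciferase experiment."""

    true_ratio: float = 2.1
    baseline_fold: float = 4.0  # non-risk activity over empty vector
    n_clones: int = 5
    n_replicates: int = 2
    well_cv: float = 0.20   # log-normal CV applied to each raw reading
    clone_cv: float = 0.10  # per-clone multiplicative random effect
    risk_label: str = "T"
    nonrisk_label: str = "C"
    orientation: str = "forward"
    n_empty_clones: int = 3
    base_firefly: float = 1000.0
    base_renilla: float = 500.0
    haplotype_activities: dict[str, float] | None = None  # overrides the two-allele design


@dataclass
class ChipPlan:
    """Design of one simulated allele-specific ChIP-qPCR experiment."""

    n_per_genotype: dict[str, int] = field(default_factory=lambda: {"CT": 3, "CC": 2})
    antibodies: tuple[str, ...] = ("FOXA1", "FOXA2")
    site_region: str = "rs11257655_site"
    control_region: str = "chr10_control"
    # enrichment over IgG by antibody and genotype at the assayed site;
    # the control region is always generated at 1.0
    site_enrichment: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "FOXA1": {"CT": 7.2, "CC": 1.0},
            "FOXA2": {"CT": 4.2, "CC": 1.0},
        }
    )
    ct_noise_sd: float = 0.2
    base_ct: float = 30.0
    sample_base_sd: float = 0.5
    replicates: int = 3
    include_input: bool = False
    input_fraction: float = 0.05


@dataclass
class ExpressionPlan:
    """Design of one simulated glucose-response expression experiment."""

    gene: str = "CAMK1D"
    housekeeping: str = "B2M"
    induction: float = 1.8
    low_label: str = "glucose_3mM"
    high_label: str = "glucose_20mM"  # Fig-legend variant: 15 mM; both are just labels
    n_per_condition: int = 5
    ct_noise_sd: float = 0.15
    replicates: int = 3
    efficiency: float = 2.0
    gene_intercept: float = 28.0   # Ct of the undiluted reference
    housekeeping_intercept: float = 22.0
    n_dilution_points: int = 5
    dilution_factor: float = 3.0


@dataclass
class ScenarioConfig:
    """Full synthetic-study configuration; the seed is mandatory."""

    seed: int
    n_samples: int = 379  # EUR-panel scale
    chrom: str = "chr10"
    region_start: int = 12_280_000
    variant_spacing: int = 2_000
    index_id: str = "rs12779790"
    index_maf: float = 0.2
    proxies: list[ProxySpec] = field(default_factory=list)
    n_background_variants: int = 5
    background_maf: float = 0.2
    use_exact_counts: bool = True
    peak_plan: list[PeakPlanEntry] = field(default_factory=list)
    motif_variant: str = "rs11257655"
    luciferase: dict[str, LuciferasePlan] = field(default_factory=dict)
    chip: ChipPlan = field(default_factory=ChipPlan)
    expression: ExpressionPlan = field(default_factory=ExpressionPlan)


def paper_like(seed: int) -> ScenarioConfig:
    """The default scenario: 11-proxy funnel with 2 variants in open chromatin."""
    proxies = [
        ProxySpec("rs11257655", maf=0.2, r2=0.74, ref="C", alt="T"),
        ProxySpec("rs34428576", maf=0.2, r2=0.71),
        ProxySpec("proxy_03", maf=0.2, r2=0.95),
        ProxySpec("proxy_04", maf=0.2, r2=0.90),
        ProxySpec("proxy_05", maf=0.2, r2=0.87),
        ProxySpec("proxy_06", maf=0.2, r2=0.85),
        ProxySpec("proxy_07", maf=0.2, r2=0.82),
        ProxySpec("proxy_08", maf=0.2, r2=0.80),
        ProxySpec("proxy_09", maf=0.2, r2=0.78),
        ProxySpec("proxy_10", maf=0.2, r2=0.76),
        # below the 0.7 threshold by design:
        ProxySpec("rs36062557", maf=0.2, r2=0.38),
        ProxySpec("low_ld_01", maf=0.2, r2=0.50),
    ]
    peak_plan = [
        PeakPlanEntry("islet_DNase", "islet", "DNase",
                      cover_variants=["rs11257655", "rs34428576"], fmt="narrowPeak"),
        PeakPlanEntry("islet_FAIRE", "islet", "FAIRE", cover_variants=["rs11257655"]),
        PeakPlanEntry("liver_DNase", "liver", "DNase", cover_variants=["rs11257655"]),
        PeakPlanEntry("islet_H3K4me1", "islet", "H3K4me1", cover_variants=["rs11257655"]),
        PeakPlanEntry("islet_H3K9ac", "islet", "H3K9ac", cover_variants=["rs11257655"]),
        PeakPlanEntry("HepG2_FOXA1", "HepG2", "FOXA1", cover_variants=["rs11257655"]),
        PeakPlanEntry("HepG2_FOXA2", "HepG2", "FOXA2", cover_variants=["rs11257655"]),
        PeakPlanEntry("muscle_DNase", "skeletal muscle myotube", "DNase", cover_variants=[]),
    ]
    luciferase = {
        "832/13": LuciferasePlan(true_ratio=2.1),
        "MIN6": LuciferasePlan(true_ratio=1.4),
        "HepG2": LuciferasePlan(true_ratio=1.4),
    }
    return ScenarioConfig(seed=seed, proxies=proxies, peak_plan=peak_plan,
                          luciferase=luciferase)


def save_scenario(config: ScenarioConfig, path: str | Path) -> None:
    """Write a scenario as YAML (the documented config schema)."""
    import json as _json

    import yaml

    plain = _json.loads(_json.dumps(asdict(config)))  # tuples -> lists
    Path(path).write_text(yaml.safe_dump(plain, sort_keys=False))


def load_scenario(path: str | Path) -> ScenarioConfig:
    """Read a YAML scenario file back into a :class:`ScenarioConfig`."""
    import yaml

    raw = yaml.safe_load(Path(path).read_text())
    raw["proxies"] = [ProxySpec(**d) for d in raw.get("proxies", [])]
    raw["peak_plan"] = [PeakPlanEntry(**d) for d in raw.get("peak_plan", [])]
    raw["luciferase"] = {k: LuciferasePlan(**v) for k, v in raw.get("luciferase", {}).items()}
    chip = raw.get("chip", {})
    if chip:
        chip["antibodies"] = tuple(chip.get("antibodies", ("FOXA1", "FOXA2")))
        raw["chip"] = ChipPlan(**chip)
    expr = raw.get("expression", {})
    if expr:
        raw["expression"] = ExpressionPlan(**expr)
    return ScenarioConfig(**raw)


# ---------------------------------------------------------------------------
# haplotype panel


def _exact_proxy_column(
    index_col: np.ndarray, n_b: int, target_r2: float, sign: int
) -> np.ndarray:
    """Deterministic 0/1 column with ~target r² against ``index_col``.

    The alt-alt haplotype count is chosen (floor vs ceil of the exact
    expectation, whichever lands closer to the target r²) so the realized
    integer-count r² deviates from the target only by rounding.
    """
    h = index_col.shape[0]
    n_a = int(index_col.sum())
    p_a, p_b = n_a / h, n_b / h
    probs = two_snp_haplotype_freqs(p_a, p_b, target_r2, sign)
    target_ab = probs[0] * h
    best_col, best_err = None, None
    for n_ab in {math.floor(target_ab), math.ceil(target_ab)}:
        n_ab = min(max(n_ab, max(0, n_b - (h - n_a))), min(n_a, n_b))
        col = np.zeros(h, dtype=np.int8)
        ones_in_a = np.flatnonzero(index_col == 1)[:n_ab]
        ones_in_not_a = np.flatnonzero(index_col == 0)[: n_b - n_ab]
        col[ones_in_a] = 1
        col[ones_in_not_a] = 1
        _, r2 = r2_from_haplotype_freqs(n_ab / h, p_a, p_b)
        err = abs(r2 - target_r2)
        if best_err is None or err < best_err:
            best_col, best_err = col, err
    return best_col


def _sampled_proxy_column(
    index_col: np.ndarray, p_b: float, target_r2: float, sign: int, rng: np.random.Generator
) -> np.ndarray:
    p_a = index_col.mean()
    probs = two_snp_haplotype_freqs(float(p_a), p_b, target_r2, sign)
    p_b_given_a = probs[0] / p_a
    p_b_given_not_a = probs[2] / (1 - p_a)
    u = rng.random(index_col.shape[0])
    return np.where(index_col == 1, u < p_b_given_a, u < p_b_given_not_a).astype(np.int8)


def simulate_haplotype_panel(
    config: ScenarioConfig, vcf_path: str | Path | None = None
) -> HaplotypePanel:
    """Phased haplotype panel with the configured index/proxy r² structure.

    In exact-count mode (default) haplotype counts are rounded so realized
    r² matches each target up to integer rounding; in sampled mode
    haplotypes are drawn from the exact two-SNP tables. Optionally writes
    the panel as a phased VCF (deterministic text for a given config).
    """
    rng = np.random.default_rng(config.seed)
    h = 2 * config.n_samples
    n_index = round(config.index_maf * h)
    index_col = np.zeros(h, dtype=np.int8)
    index_col[:n_index] = 1

    columns = {config.index_id: index_col}
    for spec in config.proxies:
        if config.use_exact_counts:
            col = _exact_proxy_column(index_col, round(spec.maf * h), spec.r2, spec.sign)
        else:
            col = _sampled_proxy_column(index_col, spec.maf, spec.r2, spec.sign, rng)
        columns[spec.id] = col
    for i in range(config.n_background_variants):
        while True:  # background sites must stay polymorphic
            col = rng.binomial(1, config.background_maf, size=h).astype(np.int8)
            if 0 < col.sum() < h:
                break
        columns[f"bg_{i + 1:02d}"] = col

    # one shared chromosome permutation: preserves all pairwise LD exactly
    perm = rng.permutation(h)
    allele_pairs = {spec.id: (spec.ref, spec.alt) for spec in config.proxies}
    variants, cols = [], []
    for j, (vid, col) in enumerate(columns.items()):
        ref, alt = allele_pairs.get(vid, ("A", "G"))
        variants.append(
            VariantRecord(
                id=vid,
                chrom=config.chrom,
                pos=config.region_start + j * config.variant_spacing,
                ref=ref,
                alt=alt,
            )
        )
        cols.append(col[perm])
    panel = HaplotypePanel(
        variants=variants,
        haplotypes=np.stack(cols, axis=1),
        sample_ids=[f"S{i + 1:04d}" for i in range(config.n_samples)],
    )
    if vcf_path is not None:
        write_phased_vcf(panel, vcf_path)
    return panel


def write_phased_vcf(panel: HaplotypePanel, path: str | Path) -> None:
    """Write the panel as a minimal phased VCF 4.2 (deterministic text)."""
    lines = ["##fileformat=VCFv4.2", "##source=regvar-simulate"]
    for chrom in dict.fromkeys(v.chrom for v in panel.variants):
        lines.append(f"##contig=<ID={chrom}>")
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(panel.sample_ids)
    )
    order = sorted(range(len(panel.variants)), key=lambda i: (panel.variants[i].chrom, panel.variants[i].pos))
    for i in order:
        v = panel.variants[i]
        col = panel.haplotypes[:, i]
        gts = "\t".join(f"{col[2 * s]}|{col[2 * s + 1]}" for s in range(len(panel.sample_ids)))
        lines.append(f"{v.chrom}\t{v.pos}\t{v.id}\t{v.ref}\t{v.alt}\t.\tPASS\t.\tGT\t{gts}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# peak tracks


def simulate_peak_tracks(
    config: ScenarioConfig,
    panel: HaplotypePanel,
    out_dir: str | Path | None = None,
) -> list[PeakTrack]:
    """Peak tracks covering exactly the planned variants.

    Each planned track gets one peak of the configured width centered on
    every covered variant; the construction is checked afterwards — if a
    peak accidentally covers an unplanned variant (plan contradiction,
    e.g. variant spacing smaller than the peak width) an error is raised.
    Tracks are optionally written as BED3 or narrowPeak files.
    """
    pos_by_id = {v.id: v for v in panel.variants}
    tracks: list[PeakTrack] = []
    for entry in config.peak_plan:
        intervals = []
        for vid in entry.cover_variants:
            if vid not in pos_by_id:
                raise KeyError(f"peak plan covers unknown variant {vid!r}")
            v = pos_by_id[vid]
            start = max(0, (v.pos - 1) - entry.width // 2)
            intervals.append(
                GenomicInterval(v.chrom, start, start + entry.width,
                                name=f"{entry.track_id}_{vid}", score=25.5)
            )
        track = PeakTrack(
            track_id=entry.track_id,
            cell_type=entry.cell_type,
            assay_name=entry.assay_name,
            intervals=intervals,
        )
        covered = {
            v.id for v in panel.variants if track.contains_point(v.chrom, v.pos - 1)
        }
        if covered != set(entry.cover_variants):
            raise ValueError(
                f"peak plan contradiction for track {entry.track_id}: planned "
                f"{sorted(entry.cover_variants)}, realized {sorted(covered)}"
            )
        tracks.append(track)
        if out_dir is not None:
            _write_track(track, Path(out_dir), entry.fmt)
    return tracks


def _write_track(track: PeakTrack, out_dir: Path, fmt: str) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    if fmt == "narrowPeak":
        path = out_dir / f"{track.track_id}.narrowPeak"
        lines = [
            f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t0\t.\t"
            f"{iv.score if iv.score is not None else 0}\t-1\t-1\t{(iv.end - iv.start) // 2}"
            for iv in track.intervals
        ]
    elif fmt == "bed":
        path = out_dir / f"{track.track_id}.bed"
        lines = [f"{iv.chrom}\t{iv.start}\t{iv.end}" for iv in track.intervals]
    else:
        raise ValueError(f"unknown track format {fmt!r}")
    path.write_text("\n".join(lines) + ("\n" if lines else ""))


# ---------------------------------------------------------------------------
# probe pair


def simulate_probe_pair(
    pwm: PWMModel | None = None,
    mode: str = "printed",
    flank: int = 7,
    rel_score_threshold: float = 0.8,
    rng: np.random.Generator | None = None,
    variant_id: str = "rs11257655",
) -> AlleleProbePair:
    """An allele probe pair whose alt allele completes the forkhead core.

    ``mode='printed'`` (default) returns the 21-bp rs11257655 EMSA pair.
    ``mode='random'`` embeds the core consensus in random flanks with the
    SNP at the core's constrained position; the draw is rejected (and
    redrawn) unless the alt probe has at least one consensus-core window
    and the ref probe none, which requires ``pwm``.
    """
    if mode == "printed":
        return AlleleProbePair(
            variant_id=variant_id,
            ref_seq=PROBE_SENSE_REF,
            alt_seq=PROBE_SENSE_ALT,
            snp_offset=PROBE_SNP_OFFSET,
        )
    if mode != "random":
        raise ValueError("mode must be 'printed' or 'random'")
    if pwm is None:
        raise ValueError("random mode needs the motif PWM to validate the draw")
    if rng is None:
        raise ValueError("random mode needs an rng")
    core = FOXA_CORE_CONSENSUS
    k = FOXA_CORE_SNP_POSITION
    bases = "ACGT"
    for _ in range(1000):
        left = "".join(rng.choice(list(bases), size=flank))
        right = "".join(rng.choice(list(bases), size=flank))
        alt_allele = core[k]
        ref_allele = str(rng.choice([b for b in bases if b != alt_allele]))
        alt_seq = left + core + right
        ref_seq = left + core[:k] + ref_allele + core[k + 1 :] + right
        if (
            consensus_core_match(pwm, alt_seq, rel_score_threshold) >= 1
            and consensus_core_match(pwm, ref_seq, rel_score_threshold) == 0
        ):
            return AlleleProbePair(
                variant_id=variant_id,
                ref_seq=ref_seq,
                alt_seq=alt_seq,
                snp_offset=flank + k,
            )
    raise RuntimeError("could not draw a valid probe pair in 1000 attempts")


# ---------------------------------------------------------------------------
# luciferase plates


def _lognormal_factor(cv: float, size, rng: np.random.Generator) -> np.ndarray:
    """Mean-1 multiplicative log-normal noise with the given CV."""
    if cv <= 0:
        return np.ones(size) if size is not None else np.float64(1.0)
    sigma = math.sqrt(math.log1p(cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=size)


def simulate_luciferase_plate(
    plan: LuciferasePlan, rng: np.random.Generator
) -> LuciferasePlate:
    """A dual-luciferase plate with known true allelic activity ratio.

    Firefly and Renilla readings each get independent per-well log-normal
    noise (CV ``well_cv``); every clone additionally carries a log-normal
    random effect (CV ``clone_cv``). The expected clone fold change is
    ``baseline_fold`` for the non-risk allele and ``baseline_fold ×
    true_ratio`` for the risk allele; the empty vector defines activity 1.
    """
    if plan.haplotype_activities is not None:
        activities = dict(plan.haplotype_activities)
    else:
        activities = {
            plan.nonrisk_label: plan.baseline_fold,
            plan.risk_label: plan.baseline_fold * plan.true_ratio,
        }
    rows = []
    for label, activity in activities.items():
        for c in range(1, plan.n_clones + 1):
            clone_eff = float(_lognormal_factor(plan.clone_cv, None, rng))
            for r in range(1, plan.n_replicates + 1):
                renilla = plan.base_renilla * float(_lognormal_factor(plan.well_cv, None, rng))
                firefly = (
                    plan.base_firefly * activity * clone_eff
                    * float(_lognormal_factor(plan.well_cv, None, rng))
                )
                rows.append(
                    {
                        "construct_id": f"{label}_{plan.orientation}",
                        "haplotype": label,
                        "orientation": plan.orientation,
                        "clone_id": f"{label}_c{c}",
                        "replicate": r,
                        "firefly": firefly,
                        "renilla": renilla,
                        "is_empty_vector": False,
                    }
                )
    for c in range(1, plan.n_empty_clones + 1):
        for r in range(1, plan.n_replicates + 1):
            renilla = plan.base_renilla * float(_lognormal_factor(plan.well_cv, None, rng))
            firefly = plan.base_firefly * float(_lognormal_factor(plan.well_cv, None, rng))
            rows.append(
                {
                    "construct_id": "pGL4.23_empty",
                    "haplotype": "empty",
                    "orientation": "none",
                    "clone_id": f"ev_c{c}",
                    "replicate": r,
                    "firefly": firefly,
                    "renilla": renilla,
                    "is_empty_vector": True,
                }
            )
    return LuciferasePlate(pd.DataFrame(rows))


def luciferase_experiment_pvalues(
    n_experiments: int,
    true_ratio: float,
    n_clones: int = 5,
    n_replicates: int = 2,
    well_cv: float = 0.2,
    clone_cv: float = 0.0,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized Monte-Carlo of the clone-level allele comparison.

    Simulates ``n_experiments`` plates under the plan's noise model and
    applies the same statistic as :func:`regvar.reporter.compare_alleles`
    (two-sided Welch t on clone-level fold changes). Returns
    ``(fold_ratios, p_values)``; used for power, bias and type-I-error
    studies where looping full plate tables would be wasteful.
    """
    from scipy import stats

    if rng is None:
        raise ValueError("rng is required")
    shape = (n_experiments, 2, n_clones, n_replicates)
    activity = np.array([1.0, true_ratio])[None, :, None, None]
    clone_eff = _lognormal_factor(clone_cv, shape[:3], rng)[..., None]
    eps_f = _lognormal_factor(well_cv, shape, rng)
    eps_r = _lognormal_factor(well_cv, shape, rng)
    normalized = activity * clone_eff * eps_f / eps_r
    clone_means = normalized.mean(axis=3)  # (n_experiments, 2, n_clones)
    nonrisk, risk = clone_means[:, 0, :], clone_means[:, 1, :]
    fold_ratios = risk.mean(axis=1) / nonrisk.mean(axis=1)
    _, pvals = stats.ttest_ind(risk, nonrisk, axis=1, equal_var=False)
    return fold_ratios, pvals


# ---------------------------------------------------------------------------
# Ct tables


def simulate_ct_table(plan: ChipPlan, rng: np.random.Generator) -> CtTable:
    """Allele-specific ChIP-qPCR Ct table with configured true enrichments.

    Ct = per-sample base − log2(enrichment) + Gaussian noise, in
    triplicate (``plan.replicates``); IgG sits at the base, the control
    region is generated with no enrichment for any antibody.
    """
    rows = []
    for genotype, n in plan.n_per_genotype.items():
        for s in range(1, n + 1):
            sample = f"islet_{genotype}_{s}"
            base = plan.base_ct + rng.normal(0.0, plan.sample_base_sd)
            for region in (plan.site_region, plan.control_region):
                targets: dict[str, float] = {"IgG": 0.0}
                for ab in plan.antibodies:
                    enr = (
                        plan.site_enrichment[ab].get(genotype, 1.0)
                        if region == plan.site_region
                        else 1.0
                    )
                    targets[ab] = math.log2(enr)
                if plan.include_input:
                    targets["input"] = math.log2(1.0 / plan.input_fraction) + 5.0
                for ab, delta in targets.items():
                    for rep in range(1, plan.replicates + 1):
                        ct = base - delta + rng.normal(0.0, plan.ct_noise_sd)
                        rows.append(
                            {
                                "sample_id": sample,
                                "group": genotype,
                                "antibody": ab,
                                "target": region,
                                "replicate": rep,
                                "ct": ct,
                            }
                        )
    return CtTable(pd.DataFrame(rows))


def chip_experiment_pvalues(
    n_experiments: int,
    enrichment_hi: float = 1.0,
    enrichment_lo: float = 1.0,
    n_hi: int = 3,
    n_lo: int = 2,
    replicates: int = 3,
    ct_noise_sd: float = 0.2,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized Monte-Carlo of the one-sided genotype comparison.

    Per-sample fold enrichment is ``2^(meanCt_IgG − meanCt_antibody)``
    with replicate-mean Ct noise, exactly as the table pipeline computes
    it (the per-sample base Ct cancels in the within-sample difference);
    groups are compared with the same one-sided Welch t-test as
    :func:`regvar.qpcr.compare_enrichment_one_sided`. Returns
    ``(mean_fold_hi, mean_fold_lo, p_values)``.
    """
    from scipy import stats

    if rng is None:
        raise ValueError("rng is required")
    sd_mean = ct_noise_sd / math.sqrt(replicates)

    def folds(enr: float, n: int) -> np.ndarray:
        dct = math.log2(enr) + rng.normal(0.0, sd_mean, size=(n_experiments, n)) \
            - rng.normal(0.0, sd_mean, size=(n_experiments, n))
        return 2.0 ** dct

    hi = folds(enrichment_hi, n_hi)
    lo = folds(enrichment_lo, n_lo)
    _, pvals = stats.ttest_ind(hi, lo, axis=1, equal_var=False, alternative="greater")
    return hi.mean(axis=1), lo.mean(axis=1), pvals


def simulate_dilution_series(
    plan: ExpressionPlan,
    intercept: float,
    rng: np.random.Generator,
    noise_sd: float | None = None,
) -> np.ndarray:
    """Replicate-mean Ct values down a serial dilution of the reference."""
    noise = plan.ct_noise_sd if noise_sd is None else noise_sd
    slope = -1.0 / math.log10(plan.efficiency)
    logq = -np.arange(plan.n_dilution_points) * math.log10(plan.dilution_factor)
    true_ct = intercept + slope * logq
    reps = true_ct[:, None] + rng.normal(0.0, noise, size=(plan.n_dilution_points, plan.replicates))
    return reps.mean(axis=1)


def simulate_expression_table(
    plan: ExpressionPlan, rng: np.random.Generator
) -> CtTable:
    """Two-condition expression Ct table with a configured true induction.

    The housekeeping gene has the same expected quantity in both
    conditions; the gene of interest is induced ``plan.induction``-fold in
    the high condition. Ct values follow each target's efficiency model
    plus Gaussian noise.
    """
    slope = -1.0 / math.log10(plan.efficiency)
    rows = []
    for condition, factor in ((plan.low_label, 1.0), (plan.high_label, plan.induction)):
        for s in range(1, plan.n_per_condition + 1):
            sample = f"{condition}_{s}"
            quantities = {
                plan.gene: (plan.gene_intercept, 0.3 * factor),
                plan.housekeeping: (plan.housekeeping_intercept, 1.0),
            }
            for target, (intercept, q) in quantities.items():
                true_ct = intercept + slope * math.log10(q)
                for rep in range(1, plan.replicates + 1):
                    rows.append(
                        {
                            "sample_id": sample,
                            "group": condition,
                            "antibody": "cDNA",
                            "target": target,
                            "replicate": rep,
                            "ct": true_ct + rng.normal(0.0, plan.ct_noise_sd),
                        }
                    )
    return CtTable(pd.DataFrame(rows))
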
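"""Stratified gene-fiber interaction analyses and their tabular reports.

Subjects are cross-classified by a fiber stratum (density quartiles, or the
14 g/day absolute high/low split) and a genetic stratum (dominant carrier
status for one SNP, or the low/high weighted-GRS group). A joint-group
dummy coding — one indicator per non-reference cell — is a reparametrisation
of the saturated main-effects-plus-products model, so per-cell odds ratios
come straight from its coefficients, and the gene-by-fiber interaction
p-value is the likelihood-ratio test of that model against the nested
main-effects-only model (df = (levels_F − 1)(levels_G − 1)).

General obesity is analysed conditionally on the matched pairs; abdominal
outcomes (waist, WHR) unconditionally with a wider covariate set, since the
controls were selected on BMI, not on abdominal phenotypes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import regression
from .data_model import (
    HIGH_FIBER_CUTOFF_G_DAY,
    MatchedCohort,
    OutcomeThresholds,
    classify_outcomes,
    assign_quartiles,
    fiber_density,
)
from .errors import DomainError, ValidationError
from .genetics import compute_grs_matrix, dichotomize_grs
from .regression import (
    fit_conditional_logistic,
    fit_logistic,
    likelihood_ratio_test,
    wald_or_ci,
)

__all__ = [
    "AnalysisConfig",
    "JointGroupCoding",
    "InteractionReport",
    "dominant_coding",
    "build_joint_groups",
    "run_snp_fiber_analysis",
    "run_grs_fiber_analysis",
    "write_report",
    "read_report",
]

OUTCOMES = ("obesity", "abdominal", "whr")


@dataclass
class AnalysisConfig:
    """Tunable thresholds and covariate sets for the interaction analyses."""

    quartile_cutoffs: tuple[float, float, float] | None = None  # None = empirical
    high_fiber_cutoff: float = HIGH_FIBER_CUTOFF_G_DAY  # g/day, absolute intake
    grs_threshold: float | None = None  # None = sample median
    education_cutoff: float = 14.0  # years; "high" education strictly above
    thresholds: OutcomeThresholds = field(default_factory=OutcomeThresholds)
    #: reference genetic stratum: "protective" (non-carrier / low GRS) or "risk"
    reference_genetic: str = "protective"
    #: matched-outcome covariates (conditional fits)
    matched_covariates: tuple[str, ...] = ("education_high", "energy_mj")
    #: unconditional-outcome covariates (abdominal obesity, WHR)
    unmatched_covariates: tuple[str, ...] = (
        "education_high",
        "energy_mj",
        "age",
        "sex_male",
        "smoking_current",
        "smoking_ex",
        "activity_moderate",
        "activity_high",
    )
    trend_statistic: str = "wald"


def dominant_coding(counts: Sequence[float] | np.ndarray) -> np.ndarray:
    """Carrier flags under a dominant model: 1 if >=1 risk allele, NaN propagates."""
    c = np.asarray(counts, dtype=float)
    out = (c >= 1).astype(float)
    out[np.isnan(c)] = np.nan
    return out


@dataclass
class JointGroupCoding:
    """Cross-classification of fiber x genetic strata with reference-omitted dummies."""

    category: np.ndarray  # per-subject (fiber_level, genetic_level) as an object array
    reference: tuple[int, int]
    dummies: pd.DataFrame
    levels_f: int
    levels_g: int

    @property
    def n_categories(self) -> int:
        return self.levels_f * self.levels_g


def _dummy_name(f_level: int, g_level: int, levels_f: int) -> str:
    fiber = f"q{f_level}" if levels_f == 4 else ("lowfiber" if f_level == 1 else "highfiber")
    gene = "g0" if g_level == 0 else "g1"
    return f"{fiber}_{gene}"


def build_joint_groups(
    fiber_labels: Sequence[int] | np.ndarray,
    genetic_flags: Sequence[float] | np.ndarray,
    *,
    reference: tuple[int, int] | None = None,
) -> JointGroupCoding:
    """Cross-classify subjects and build the joint-group dummy matrix.

    ``fiber_labels`` are quartiles 1..4 or a binary 1/2 split (1 = low,
    2 = high); ``genetic_flags`` are 0 (protective stratum: non-carrier or
    low GRS) / 1 (risk stratum). The default reference cell is the highest
    fiber stratum combined with the protective genetic stratum; any cell may
    be designated instead. The dummy matrix has ``levels_f * levels_g - 1``
    columns and an all-zero row for reference-cell subjects.
    """
    f = np.asarray(fiber_labels)
    g = np.asarray(genetic_flags, dtype=float)
    if f.shape != g.shape:
        raise ValidationError("fiber and genetic stratifications differ in length")
    missing = np.flatnonzero(np.isnan(g) | ~np.isin(f, (1, 2, 3, 4)))
    if missing.size:
        raise ValidationError(f"subjects missing a stratum at positions {missing[:10].tolist()}")
    g = g.astype(int)
    if not set(np.unique(g)) <= {0, 1}:
        raise ValidationError("genetic stratum must be binary 0/1")
    levels_f = int(f.max())
    if set(np.unique(f)) - set(range(1, levels_f + 1)):
        raise ValidationError("fiber strata must be consecutive integers from 1")
    levels_g = 2
    if len(np.unique(g)) < 2:
        raise ValidationError("degenerate stratification: all subjects in one genetic stratum")
    if reference is None:
        reference = (levels_f, 0)
    if not (1 <= reference[0] <= levels_f and reference[1] in (0, 1)):
        raise ValidationError(f"reference cell {reference} outside the stratification")
    cols = {}
    for f_level in range(1, levels_f + 1):
        for g_level in (0, 1):
            if (f_level, g_level) == tuple(reference):
                continue
            cols[_dummy_name(f_level, g_level, levels_f)] = (
                (f == f_level) & (g == g_level)
            ).astype(float)
    dummies = pd.DataFrame(cols)
    category = np.empty(f.size, dtype=object)
    for i in range(f.size):
        category[i] = (int(f[i]), int(g[i]))
    return JointGroupCoding(
        category=category,
        reference=tuple(reference),
        dummies=dummies,
        levels_f=levels_f,
        levels_g=levels_g,
    )


@dataclass
class InteractionReport:
    """One stratified analysis: per-cell ORs, per-stratum trend p, interaction p."""

    outcome: str
    genetic_label: str  # e.g. "rs3751812 (dominant)" or "GRS (median split)"
    fiber_mode: str  # "quartiles" | "high_low"
    stratum_labels: tuple[str, str]  # (protective, risk) display names
    or_table: pd.DataFrame  # rows: genetic strata; columns: OR/lo/hi per fiber stratum
    trend_p: dict[str, float]  # per genetic stratum
    interaction_p: float
    interaction_stat: float
    interaction_df: int
    n_subjects: int
    n_sets: int | None
    covariates: tuple[str, ...]
    reference: tuple[int, int]

    def reference_or(self) -> float:
        ref_f, ref_g = self.reference
        row = self.stratum_labels[ref_g]
        return float(self.or_table.loc[row, f"F{ref_f}_OR"])


def _covariate_frame(pheno: pd.DataFrame, config: AnalysisConfig) -> pd.DataFrame:
    """Derive the analysis covariate columns from raw phenotype fields."""
    out = pd.DataFrame(index=pheno.index)
    out["education_high"] = (pheno["education_years"] > config.education_cutoff).astype(float)
    out["energy_mj"] = pheno["energy"] / 1000.0  # MJ/day keeps the Hessian well scaled
    out["age"] = pheno["age"].astype(float)
    out["sex_male"] = (pheno["sex"] == "M").astype(float)
    out["smoking_current"] = (pheno["smoking"] == "current").astype(float)
    out["smoking_ex"] = (pheno["smoking"] == "ex").astype(float)
    out["activity_moderate"] = (pheno["activity"] == "moderate").astype(float)
    out["activity_high"] = (pheno["activity"] == "high").astype(float)
    return out


def _outcome_vector(pheno: pd.DataFrame, outcome: str, config: AnalysisConfig) -> np.ndarray:
    if outcome == "obesity":
        return pheno["is_case"].to_numpy(dtype=bool)
    flags = []
    from .data_model import SubjectRecord  # local import to avoid cycle at module load

    for _, row in pheno.iterrows():
        rec = SubjectRecord(**{k: row[k] for k in row.index if k in SubjectRecord.__dataclass_fields__})
        f = classify_outcomes(rec, config.thresholds)
        flags.append(f.abdominal_obese if outcome == "abdominal" else f.high_whr)
    return np.asarray(flags, dtype=bool)


def _fiber_strata(
    pheno: pd.DataFrame, mode: str, config: AnalysisConfig
) -> tuple[np.ndarray, dict[int, float]]:
    density = fiber_density(pheno["fiber"].to_numpy(), pheno["energy"].to_numpy())
    if mode == "quartiles":
        return assign_quartiles(density, config.quartile_cutoffs)
    if mode == "high_low":
        high = pheno["fiber"].to_numpy() >= config.high_fiber_cutoff
        labels = np.where(high, 2, 1)
        medians = {
            lev: float(np.median(density[labels == lev])) for lev in (1, 2) if (labels == lev).any()
        }
        return labels, medians
    raise DomainError(f"unknown fiber mode {mode!r}")


def _run_joint_analysis(
    pheno: pd.DataFrame,
    genetic_flags: np.ndarray,
    genetic_label: str,
    stratum_labels: tuple[str, str],
    outcome: str,
    fiber_mode: str,
    config: AnalysisConfig,
) -> InteractionReport:
    if outcome not in OUTCOMES:
        raise DomainError(f"unknown outcome {outcome!r}; expected one of {OUTCOMES}")
    keep = ~np.isnan(genetic_flags)
    if outcome == "obesity":
        # conditional analysis: drop whole pairs when a member lacks a genotype
        bad_sets = set(pheno.loc[~keep, "matched_set_id"])
        keep = keep & ~pheno["matched_set_id"].isin(bad_sets).to_numpy()
    pheno = pheno.loc[keep].reset_index(drop=True)
    flags = genetic_flags[keep]
    labels, medians = _fiber_strata(pheno, fiber_mode, config)
    ref_g = 0 if config.reference_genetic == "protective" else 1
    levels_f = 4 if fiber_mode == "quartiles" else 2
    joint = build_joint_groups(labels, flags, reference=(levels_f, ref_g))
    covars = _covariate_frame(pheno, config)
    y = _outcome_vector(pheno, outcome, config)
    matched = outcome == "obesity"
    adjust_cols = list(config.matched_covariates if matched else config.unmatched_covariates)
    adjust = covars[adjust_cols]
    sets = pheno["matched_set_id"].to_numpy() if matched else None

    def fit(design: pd.DataFrame) -> regression.FitResult:
        if matched:
            return fit_conditional_logistic(design, y, sets)
        return fit_logistic(design, y)

    # saturated joint model: one dummy per non-reference cell, plus adjustments
    full_design = pd.concat([joint.dummies, adjust.reset_index(drop=True)], axis=1)
    full = fit(full_design)

    # nested main-effects model: fiber stratum dummies + genetic stratum flag
    main = pd.DataFrame(index=range(len(pheno)))
    for f_level in range(1, joint.levels_f):
        main[f"fiber{f_level}"] = (labels == f_level).astype(float)
    main["genetic"] = flags.astype(float)
    main_design = pd.concat([main, adjust.reset_index(drop=True)], axis=1)
    reduced = fit(main_design)
    # same subjects, but the dummy bases differ; compare via log-likelihoods
    stat = max(0.0, 2.0 * (full.loglik - reduced.loglik))
    df = (joint.levels_f - 1) * (joint.levels_g - 1)
    from scipy import stats as _st

    interaction_p = float(_st.chi2.sf(stat, df))

    # per-cell odds ratios
    rows = {}
    for g_level in (0, 1):
        cells = {}
        for f_level in range(1, joint.levels_f + 1):
            if (f_level, g_level) == joint.reference:
                cells[f"F{f_level}_OR"] = 1.0
                cells[f"F{f_level}_lo"] = 1.0
                cells[f"F{f_level}_hi"] = 1.0
            else:
                name = _dummy_name(f_level, g_level, joint.levels_f)
                or_, lo, hi = wald_or_ci(full, name)
                cells[f"F{f_level}_OR"] = or_
                cells[f"F{f_level}_lo"] = lo
                cells[f"F{f_level}_hi"] = hi
        rows[stratum_labels[g_level]] = cells
    or_table = pd.DataFrame.from_dict(rows, orient="index")

    # per-genetic-stratum dose-response: one trend slope per stratum, pairs intact
    score = np.array([medians[int(q)] for q in labels])
    trend_design = adjust.reset_index(drop=True).copy()
    trend_design["genetic"] = flags.astype(float)
    trend_design["trend_g0"] = score * (flags == 0)
    trend_design["trend_g1"] = score * (flags == 1)
    trend_p: dict[str, float] = {}
    if len(medians) >= 2:
        tfit = fit(trend_design)
        for g_level in (0, 1):
            trend_p[stratum_labels[g_level]] = tfit.wald_p(f"trend_g{g_level}")
    else:
        raise DomainError("trend test needs at least two occupied fiber strata")

    return InteractionReport(
        outcome=outcome,
        genetic_label=genetic_label,
        fiber_mode=fiber_mode,
        stratum_labels=stratum_labels,
        or_table=or_table,
        trend_p=trend_p,
        interaction_p=interaction_p,
        interaction_stat=stat,
        interaction_df=df,
        n_subjects=len(pheno),
        n_sets=int(pheno["matched_set_id"].nunique()) if matched else None,
        covariates=tuple(adjust_cols),
        reference=joint.reference,
    )


def run_snp_fiber_analysis(
    cohort: MatchedCohort,
    snp_id: str,
    outcome: str = "obesity",
    config: AnalysisConfig | None = None,
    *,
    fiber_mode: str = "quartiles",
) -> InteractionReport:
    """Fiber-by-genotype interaction for one SNP under a dominant model.

    Carriers (1-2 risk alleles) are contrasted with homozygote-major
    non-carriers across fiber strata; the reference cell defaults to the
    highest fiber stratum among non-carriers.
    """
    config = config or AnalysisConfig()
    pheno = cohort.phenotype_frame()
    doses = cohort.dose_frame()[snp_id].to_numpy()
    flags = dominant_coding(doses)
    snp = cohort.panel[snp_id]
    labels = (f"{snp.nonrisk_allele}{snp.nonrisk_allele}", f"{snp.risk_allele} carrier")
    return _run_joint_analysis(
        pheno, flags, f"{snp_id} (dominant)", labels, outcome, fiber_mode, config
    )


def run_grs_fiber_analysis(
    cohort: MatchedCohort,
    outcome: str = "obesity",
    config: AnalysisConfig | None = None,
    *,
    fiber_mode: str = "quartiles",
) -> InteractionReport:
    """Fiber-by-GRS interaction with the GRS dichotomized at its median.

    Subjects missing any panel genotype cannot be scored and are excluded
    (with their matched partner, for the conditional obesity analysis).
    """
    config = config or AnalysisConfig()
    pheno = cohort.phenotype_frame()
    doses = cohort.dose_frame().to_numpy()
    complete = ~np.isnan(doses).any(axis=1)
    scores = np.full(len(pheno), np.nan)
    if complete.any():
        scores[complete] = compute_grs_matrix(doses[complete], cohort.panel)
    if not complete.any():
        raise ValidationError("no subject has a complete genotype row; GRS undefined")
    high, threshold = dichotomize_grs(scores[complete], config.grs_threshold)
    flags = np.full(len(pheno), np.nan)
    flags[complete] = high.astype(float)
    labels = (f"GRS < {threshold:g}", f"GRS >= {threshold:g}")
    return _run_joint_analysis(
        pheno, flags, "GRS (weighted, median split)", labels, outcome, fiber_mode, config
    )


def write_report(report: InteractionReport, path: str | Path) -> None:
    """Serialise a report as a TSV: one row per genetic stratum.

    Columns mirror the published table layout: OR and CI bounds per fiber
    stratum, the per-stratum trend p and the shared interaction p.
    """
    frame = report.or_table.copy()
    frame.insert(0, "genetic_stratum", frame.index)
    frame["trend_p"] = [report.trend_p[s] for s in report.or_table.index]
    frame["interaction_p"] = report.interaction_p
    frame["interaction_stat"] = report.interaction_stat
    frame["interaction_df"] = report.interaction_df
    frame["outcome"] = report.outcome
    frame["genetic_label"] = report.genetic_label
    frame["fiber_mode"] = report.fiber_mode
    frame["n_subjects"] = report.n_subjects
    frame.to_csv(path, sep="\t", index=False)


def read_report(path: str | Path) -> pd.DataFrame:
    """Read a report TSV back into a DataFrame (round-trip of :func:`write_report`)."""
    return pd.read_csv(path, sep="\t")
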
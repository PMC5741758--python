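"""Allele/genotype frequency summaries, Hardy-Weinberg QC and the weighted genetic risk score.

The genetic risk score (GRS) combines the risk-allele dose of ``n`` biallelic
SNPs, each weighted by its published per-allele odds ratio :math:`OR_i`:

.. math::

    \\mathrm{GRS} = \\Big(\\sum_i OR_i \\cdot g_i\\Big) \\times \\frac{n}{\\sum_i OR_i},

where :math:`g_i \\in \\{0, 1, 2\\}` counts risk alleles. The rescaling by
``n / sum(OR)`` keeps the score on the 0..2n scale, so one GRS point
corresponds to one (average-weight) risk allele. Weights are fixed inputs
taken from the literature, never re-estimated from the analysed sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml
from scipy import stats

from .errors import DomainError, ValidationError

__all__ = [
    "SnpInfo",
    "SnpPanel",
    "GenotypeCounts",
    "HweResult",
    "load_panel",
    "default_panel",
    "reference_genotype_counts",
    "allele_counts",
    "hwe_test",
    "compute_grs",
    "sum_of_weights",
    "dichotomize_grs",
]

_NUCLEOTIDES = frozenset("ACGT")


@dataclass(frozen=True)
class SnpInfo:
    """Metadata for one biallelic SNP: alleles, risk allele and GRS weight."""

    snp_id: str
    major_allele: str
    minor_allele: str
    risk_allele: str
    weight: float

    def __post_init__(self) -> None:
        for name in ("major_allele", "minor_allele", "risk_allele"):
            allele = getattr(self, name)
            if allele not in _NUCLEOTIDES:
                raise ValidationError(f"{self.snp_id}: {name} {allele!r} is not a nucleotide")
        if self.major_allele == self.minor_allele:
            raise ValidationError(f"{self.snp_id}: alleles must differ")
        if self.risk_allele not in (self.major_allele, self.minor_allele):
            raise ValidationError(
                f"{self.snp_id}: risk allele {self.risk_allele!r} is neither "
                f"{self.major_allele!r} nor {self.minor_allele!r}"
            )
        if not self.weight > 0:
            raise ValidationError(f"{self.snp_id}: weight must be positive, got {self.weight}")

    @property
    def nonrisk_allele(self) -> str:
        return self.minor_allele if self.risk_allele == self.major_allele else self.major_allele


@dataclass(frozen=True)
class SnpPanel:
    """An ordered collection of :class:`SnpInfo` with unique ids."""

    snps: tuple[SnpInfo, ...]

    def __post_init__(self) -> None:
        if len(self.snps) < 1:
            raise ValidationError("panel must contain at least one SNP")
        ids = [s.snp_id for s in self.snps]
        if len(set(ids)) != len(ids):
            raise ValidationError("panel snp_ids must be unique")

    def __len__(self) -> int:
        return len(self.snps)

    def __iter__(self):
        return iter(self.snps)

    def __getitem__(self, snp_id: str) -> SnpInfo:
        for snp in self.snps:
            if snp.snp_id == snp_id:
                return snp
        raise KeyError(snp_id)

    @property
    def snp_ids(self) -> list[str]:
        return [s.snp_id for s in self.snps]

    @property
    def weights(self) -> np.ndarray:
        return np.array([s.weight for s in self.snps], dtype=float)


def load_panel(path: str | Path) -> SnpPanel:
    """Read a SNP panel from a YAML file with a top-level ``snps`` list."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    try:
        entries = raw["snps"]
    except (TypeError, KeyError) as exc:
        raise ValidationError(f"{path}: expected a top-level 'snps' list") from exc
    return SnpPanel(tuple(SnpInfo(**entry) for entry in entries))


def default_panel() -> SnpPanel:
    """The bundled six-SNP FTO panel with literature odds-ratio weights."""
    with resources.as_file(resources.files("fibergxe.data") / "fto_panel.yaml") as path:
        return load_panel(path)


def reference_genotype_counts() -> dict[str, dict[str, "GenotypeCounts"]]:
    """Bundled case/control genotype counts for the six-SNP FTO panel.

    Returns a mapping ``snp_id -> {"controls": GenotypeCounts, "cases": ...}``.
    """
    path = resources.files("fibergxe.data") / "reference_genotype_counts.yaml"
    raw = yaml.safe_load(path.read_text())
    return {
        snp_id: {
            group: GenotypeCounts(
                n_hom_risk=c["hom_risk"], n_het=c["het"], n_hom_nonrisk=c["hom_nonrisk"]
            )
            for group, c in groups.items()
        }
        for snp_id, groups in raw.items()
    }


@dataclass(frozen=True)
class GenotypeCounts:
    """Genotype counts for one SNP in one group, keyed by risk-allele dose."""

    n_hom_risk: int
    n_het: int
    n_hom_nonrisk: int

    def __post_init__(self) -> None:
        if min(self.n_hom_risk, self.n_het, self.n_hom_nonrisk) < 0:
            raise DomainError("genotype counts must be non-negative")

    @property
    def total(self) -> int:
        return self.n_hom_risk + self.n_het + self.n_hom_nonrisk


def allele_counts(counts: GenotypeCounts) -> tuple[int, int]:
    """Risk- and non-risk-allele counts implied by genotype counts.

    Each homozygote contributes two copies of its allele, each heterozygote
    one of each; the two counts always sum to ``2 * counts.total``.
    """
    if counts.total == 0:
        raise DomainError("cannot derive allele counts from an empty group")
    risk = 2 * counts.n_hom_risk + counts.n_het
    nonrisk = 2 * counts.n_hom_nonrisk + counts.n_het
    return risk, nonrisk


@dataclass(frozen=True)
class HweResult:
    """Pearson goodness-of-fit test of Hardy-Weinberg proportions (1 df)."""

    chi_square: float
    p_value: float
    observed: tuple[int, int, int]
    expected: tuple[float, float, float]
    df: int = 1


def hwe_test(counts: GenotypeCounts, *, exact: bool = False) -> HweResult:
    """Test one SNP's genotype counts against Hardy-Weinberg proportions.

    The risk-allele frequency ``p`` is estimated from the counts and the
    observed genotypes compared with the expected ``(n p^2, 2 n p q, n q^2)``
    by Pearson's chi-square on 1 degree of freedom, without continuity
    correction. With ``exact=True`` the mid-p-free exact test of
    Wigginton, Cutler & Abecasis (conditional on allele counts) replaces the
    chi-square p-value; the statistic and expected counts are still reported.
    """
    n = counts.total
    if n == 0:
        raise DomainError("HWE test needs at least one genotyped subject")
    risk, nonrisk = allele_counts(counts)
    if risk == 0 or nonrisk == 0:
        raise DomainError("HWE test undefined for a monomorphic SNP")
    p = risk / (2 * n)
    q = 1.0 - p
    expected = (n * p * p, 2 * n * p * q, n * q * q)
    observed = (counts.n_hom_risk, counts.n_het, counts.n_hom_nonrisk)
    chi_square = float(sum((o - e) ** 2 / e for o, e in zip(observed, expected)))
    if exact:
        p_value = _hwe_exact_p(counts)
    else:
        p_value = float(stats.chi2.sf(chi_square, df=1))
    return HweResult(chi_square=chi_square, p_value=p_value, observed=observed, expected=expected)


def _hwe_exact_p(counts: GenotypeCounts) -> float:
    """Exact HWE p-value: sum of heterozygote-count probabilities <= observed's."""
    n = counts.total
    n_minor = min(allele_counts(counts))
    # enumerate all heterozygote counts with the observed parity
    hets = np.arange(n_minor % 2, n_minor + 1, 2)
    hom_minor = (n_minor - hets) // 2
    hom_major = n - hets - hom_minor
    from scipy.special import gammaln

    logp = (
        gammaln(n + 1)
        - gammaln(hom_minor + 1)
        - gammaln(hets + 1)
        - gammaln(hom_major + 1)
        + hets * np.log(2.0)
        + gammaln(n_minor + 1)
        + gammaln(2 * n - n_minor + 1)
        - gammaln(2 * n + 1)
    )
    prob = np.exp(logp - logp.max())
    prob /= prob.sum()
    observed_het = counts.n_het
    p_obs = prob[hets == observed_het]
    if p_obs.size == 0:
        raise DomainError("observed heterozygote count inconsistent with allele total")
    return float(min(1.0, prob[prob <= p_obs[0] * (1 + 1e-12)].sum()))


def sum_of_weights(panel: SnpPanel) -> float:
    """Sum of the per-SNP odds-ratio weights (the GRS normalisation denominator)."""
    return float(panel.weights.sum())


def compute_grs(counts_row: Sequence[float] | np.ndarray, panel: SnpPanel) -> float:
    """Weighted genetic risk score for one subject.

    ``counts_row`` holds the risk-allele dose (0/1/2) for each panel SNP, in
    panel order. Missing doses are the caller's problem: subjects with any
    missing genotype must be filtered out before scoring.
    """
    g = np.asarray(counts_row, dtype=float)
    if g.shape != (len(panel),):
        raise ValidationError(f"expected {len(panel)} genotype counts, got shape {g.shape}")
    if np.isnan(g).any():
        raise ValidationError("missing genotype count; filter subjects before scoring")
    if ((g < 0) | (g > 2)).any():
        raise DomainError("risk-allele counts must lie in {0, 1, 2}")
    w = panel.weights
    return float((w @ g) * (len(panel) / w.sum()))


def compute_grs_matrix(counts: np.ndarray, panel: SnpPanel) -> np.ndarray:
    """Vectorised :func:`compute_grs` over a subjects x SNPs dose matrix."""
    g = np.asarray(counts, dtype=float)
    if g.ndim != 2 or g.shape[1] != len(panel):
        raise ValidationError(f"expected a (n, {len(panel)}) matrix, got shape {g.shape}")
    w = panel.weights
    return (g @ w) * (len(panel) / w.sum())


def dichotomize_grs(
    scores: Sequence[float] | np.ndarray, threshold: float | None = None
) -> tuple[np.ndarray, float]:
    """Split GRS values into low/high groups at a threshold (default: sample median).

    Ties go to the high group (``score >= threshold``), matching the usual
    "GRS >= median" stratification. Returns ``(is_high, threshold)``.
    """
    s = np.asarray(scores, dtype=float)
    if s.size == 0:
        raise DomainError("cannot dichotomize an empty score vector")
    if threshold is None:
        threshold = float(np.median(s))
    return s >= threshold, float(threshold)
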
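"""Synthetic cohort generator with the statistical structure the analysis assumes.

Emulates a preschool cohort genotyped on a candidate-SNP panel: genotypes
drawn per SNP from Hardy–Weinberg proportions (with an optional inbreeding
coefficient F to plant HWE departures), signed GWAS-scale beta weights,
serum 25(OH)D log-normal with a configurable median, and a latent BMI-for-age
z-score that is weakly positively rank-correlated with the true polygenic
score and weakly negatively rank-correlated with 25(OH)D. Anthropometry
(weight, height) is produced by *inverting* the LMS reference at the latent
z, so re-scoring the cohort recovers the planted z exactly — a round-trip
invariant the test suite leans on.

Two presets bundle the study conditions:

- ``paper_cohort``: 1046 subjects, 55 clean SNPs, planted rank correlations
  +0.10 (PRS vs zBMI) and −0.11 (25(OH)D vs zBMI), 25(OH)D median 33.63 ng/mL.
- ``qc_stress``: 85 candidate SNPs of which 8 are near-monomorphic
  (effect-allele frequency 0.002), 13 carry strong inbreeding (F = 0.9),
  9 are entirely missing and 55 are clean — exercising every QC verdict.

All randomness flows from one integer seed through numpy ``SeedSequence``
stream splitting, so draws in different generator stages are independent and
every output is reproducible bit-for-bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .anthro import LmsReference, _inverse_vec, lookup_lms
from .containers import GenotypeMatrix, SnpPanel
from .prs import compute_prs

# stream constants for SeedSequence splitting (one per generator stage)
_STREAM_PANEL, _STREAM_GENO, _STREAM_SUBJ, _STREAM_PHENO, _STREAM_PRESET = range(5)

PRESETS = ("paper_cohort", "qc_stress")


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(stream,)))


@dataclass
class SimConfig:
    """Knobs of the cohort simulator; defaults are the study conditions."""

    n_subjects: int = 1046
    n_snps: int = 55
    maf_range: tuple[float, float] = (0.05, 0.5)
    beta_scale: float = 0.02
    inbreeding_f: float = 0.0
    missing_rate: float = 0.0
    effect_prs: float = 0.10
    effect_vitd: float = -0.11
    vitd_median: float = 33.63
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.n_snps < 1:
            raise ValueError("n_subjects and n_snps must be positive")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError(f"maf_range must lie in (0, 0.5], got {self.maf_range}")
        for name, v in (("inbreeding_f", self.inbreeding_f), ("missing_rate", self.missing_rate)):
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.beta_scale <= 0:
            raise ValueError("beta_scale must be positive")
        if self.vitd_median <= 0:
            raise ValueError("vitd_median must be positive")


def gen_snp_panel(
    m: int,
    maf_range: tuple[float, float] = (0.05, 0.5),
    beta_scale: float = 0.02,
    seed: int = 0,
) -> SnpPanel:
    """Random biallelic weight panel with signed betas.

    Betas are drawn N(0, beta_scale) — symmetric about zero. Signed weights
    are required for the score distribution to straddle zero (an all-positive
    panel could never produce the negative score medians typical of
    mixed-direction GWAS weights).
    """
    if m < 1:
        raise ValueError("panel size must be >= 1")
    lo, hi = maf_range
    if not (0 < lo <= hi <= 0.5):
        raise ValueError(f"maf_range must lie in (0, 0.5], got {maf_range}")
    rng = _rng(seed, _STREAM_PANEL)
    # unique rs-style identifiers
    ids: list[str] = []
    seen: set[int] = set()
    while len(ids) < m:
        k = int(rng.integers(10_000, 100_000_000))
        if k not in seen:
            seen.add(k)
            ids.append(f"rs{k}")
    bases = np.array(list("ACGT"))
    eff_idx = rng.integers(0, 4, size=m)
    oth_off = rng.integers(1, 4, size=m)
    effect = bases[eff_idx]
    other = bases[(eff_idx + oth_off) % 4]
    table = pd.DataFrame(
        {
            "snp_id": ids,
            "effect_allele": effect,
            "other_allele": other,
            "beta": rng.normal(0.0, beta_scale, size=m),
            "source_maf": rng.uniform(lo, hi, size=m),
        }
    )
    return SnpPanel(table)


def gen_genotypes(
    panel: SnpPanel,
    n: int,
    inbreeding_f: float | np.ndarray = 0.0,
    missing_rate: float | np.ndarray = 0.0,
    seed: int = 0,
) -> GenotypeMatrix:
    """Draw effect-allele dosages per SNP under HWE with inbreeding F.

    Genotype probabilities at effect-allele frequency p (q = 1 - p):

        P(2) = p² + F·p·q,  P(1) = 2pq(1 - F),  P(0) = q² + F·p·q.

    ``inbreeding_f`` and ``missing_rate`` may be scalars or per-SNP arrays.
    Entries are masked missing independently at ``missing_rate``.
    """
    if n < 1:
        raise ValueError("need at least one subject")
    if "source_maf" not in panel.table.columns or panel.table["source_maf"].isna().any():
        raise ValueError("panel must carry source_maf to simulate genotypes")
    m = len(panel)
    F = np.broadcast_to(np.asarray(inbreeding_f, dtype=float), (m,))
    mr = np.broadcast_to(np.asarray(missing_rate, dtype=float), (m,))
    if (F < 0).any() or (F > 1).any() or (mr < 0).any() or (mr > 1).any():
        raise ValueError("inbreeding_f and missing_rate must lie in [0, 1]")
    p = panel.table["source_maf"].to_numpy(dtype=float)
    q = 1.0 - p
    p2 = p * p + F * p * q
    p1 = 2 * p * q * (1.0 - F)
    rng = _rng(seed, _STREAM_GENO)
    u = rng.random((n, m))
    dosage = np.where(u < p2, 2.0, np.where(u < p2 + p1, 1.0, 0.0))
    miss = rng.random((n, m)) < mr
    dosage[miss] = np.nan
    subject_ids = np.array([f"S{i + 1:05d}" for i in range(n)], dtype=object)
    return GenotypeMatrix(subject_ids, panel.snp_ids.copy(), dosage)


# Table-1-like covariate marginals of a rural Chinese preschool cohort
_COVARIATE_SPECS = {
    "premature_birth": (("yes", "no"), (0.037, 0.963)),
    "delivery": (("unknown", "vaginal", "caesarean"), (0.011, 0.604, 0.385)),
    "only_child": (("unknown", "yes", "no"), (0.031, 0.133, 0.836)),
    "breastfeeding": (("yes", "no"), (0.896, 0.104)),
    "vitd_supplement": (("yes", "no"), (0.034, 0.966)),
    "yyb": (("yes", "no"), (0.498, 0.502)),
    "parental_care": (("yes", "no"), (0.718, 0.282)),
    "caregiver_edu": (
        ("primary_or_below", "junior_middle", "high_or_above"),
        (0.293, 0.496, 0.211),
    ),
}

#: log-sd of the 25(OH)D log-normal, set from a 26.79–41.46 ng/mL IQR
_VITD_LOG_SD = math.log(41.46 / 26.79) / (2 * 0.674489750196)


def gen_subjects(n: int, vitd_median: float = 33.63, seed: int = 0) -> pd.DataFrame:
    """Subject table with demographics, covariates and serum 25(OH)D.

    Sex is Bernoulli(0.5); age uniform on [44, 80] months (a 3.7–6.6 year
    preschool cohort); 25(OH)D log-normal with the requested median and a
    log-sd matched to a right-skewed mid-thirties ng/mL distribution.
    Covariates are drawn independently of each other and of genotype.
    """
    if n < 1:
        raise ValueError("need at least one subject")
    if vitd_median <= 0:
        raise ValueError("vitd_median must be positive")
    rng = _rng(seed, _STREAM_SUBJ)
    df = pd.DataFrame({"subject_id": [f"S{i + 1:05d}" for i in range(n)]})
    df["sex"] = rng.choice(["male", "female"], size=n)
    df["age_months"] = rng.uniform(44.0, 80.0, size=n)
    df["birth_length_cm"] = rng.normal(50.1, 1.4, size=n)
    df["birth_weight_g"] = np.clip(rng.normal(3245.0, 380.0, size=n), 1500.0, None)
    for col, (levels, probs) in _COVARIATE_SPECS.items():
        df[col] = rng.choice(levels, size=n, p=probs)
    df["ses"] = rng.normal(47.8, 2.2, size=n)
    df["vitd_ng_ml"] = np.exp(rng.normal(math.log(vitd_median), _VITD_LOG_SD, size=n))
    return df


def _pearson_target(rank_r: float) -> float:
    """Latent-normal Pearson coefficient producing Spearman rank_r.

    Inverts the bivariate-normal identity r_s = (6/pi) * asin(r/2).
    """
    return 2.0 * math.sin(math.pi * rank_r / 6.0)


def gen_phenotypes(
    subjects: pd.DataFrame,
    genotypes: GenotypeMatrix,
    panel: SnpPanel,
    lms: LmsReference,
    effect_prs: float = 0.10,
    effect_vitd: float = -0.11,
    seed: int = 0,
) -> pd.DataFrame:
    """Plant anthropometry so zBMI carries the requested rank correlations.

    The latent z combines the normal scores (rank-based Gaussian transforms)
    of the true polygenic score and of 25(OH)D with independent Gaussian
    noise, scaled to unit variance. Working on normal scores rather than the
    raw values makes the bivariate-normal Spearman calibration exact for any
    marginal (25(OH)D is strongly right-skewed), so the realized rank
    correlations are centered on ``effect_prs`` and ``effect_vitd``. Weight
    and height are then set by inverting the LMS reference at z, so the
    anthropometry module recovers z exactly. Columns ``true_z`` and
    ``true_prs`` record the planted values for recovery tests.
    """
    if not np.array_equal(subjects["subject_id"].to_numpy(), genotypes.subject_ids):
        raise ValueError("subjects and genotypes must list the same subject_ids in order")
    n = len(subjects)
    a = _pearson_target(effect_prs)
    b = _pearson_target(effect_vitd)
    resid_var = 1.0 - a * a - b * b
    if resid_var < -1e-12:
        raise ValueError("effect sizes imply latent variance > 1; shrink the targets")
    resid_sd = math.sqrt(max(resid_var, 0.0))

    prs = compute_prs(genotypes, panel)
    score = prs["score"].to_numpy(dtype=float)
    if np.isnan(score).any():
        raise ValueError("unscorable subjects present; phenotypes need complete scores")
    vitd = subjects["vitd_ng_ml"].to_numpy(dtype=float)

    def _normal_scores(x: np.ndarray) -> np.ndarray:
        from scipy.stats import norm, rankdata

        if np.ptp(x) == 0:
            return np.zeros_like(x)
        return norm.ppf((rankdata(x) - 0.5) / x.size)

    rng = _rng(seed, _STREAM_PHENO)
    z = a * _normal_scores(score) + b * _normal_scores(vitd) + rng.normal(0.0, resid_sd, size=n)

    out = subjects.copy()
    L = np.empty(n)
    M = np.empty(n)
    S = np.empty(n)
    for i, (sex, age) in enumerate(zip(out["sex"], out["age_months"])):
        L[i], M[i], S[i] = lookup_lms(lms, sex, float(age))
    bmi = _inverse_vec(z, L, M, S)
    height = 78.0 + 0.55 * out["age_months"].to_numpy(dtype=float) + rng.normal(0.0, 3.0, size=n)
    out["height_cm"] = height
    out["weight_kg"] = bmi * (height / 100.0) ** 2
    out["true_z"] = z
    out["true_prs"] = score
    return out


def synthetic_lms_reference(age_min: int = 36, age_max: int = 84) -> LmsReference:
    """Bundled smooth synthetic BMI-for-age LMS reference, both sexes.

    A stand-in with the qualitative shape of preschool BMI references
    (slightly declining median through the adiposity nadir, mild negative
    skew power, CV near 8–9%). Any real reference in the same CSV schema is
    a drop-in replacement.
    """
    ages = np.arange(age_min, age_max + 1, dtype=float)
    rows = []
    for sex, m0, s0 in (("male", 15.9, 0.085), ("female", 15.7, 0.090)):
        t = (ages - age_min) / 12.0
        M = m0 - 0.12 * t + 0.012 * t * t
        L = -1.6 + 0.05 * t
        S = s0 + 0.002 * t
        rows.append(pd.DataFrame({"sex": sex, "age_months": ages, "L": L, "M": M, "S": S}))
    return LmsReference(pd.concat(rows, ignore_index=True))


def make_preset(name: str, seed: int = 0) -> tuple[SnpPanel, GenotypeMatrix, pd.DataFrame]:
    """Build a named study-condition preset. See the module docstring."""
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; choose from {PRESETS}")
    lms = synthetic_lms_reference()
    if name == "paper_cohort":
        panel = gen_snp_panel(55, (0.05, 0.5), 0.02, seed=seed)
        geno = gen_genotypes(panel, 1046, inbreeding_f=0.0, missing_rate=0.0, seed=seed)
        subjects = gen_subjects(1046, vitd_median=33.63, seed=seed)
        subjects = gen_phenotypes(
            subjects, geno, panel, lms, effect_prs=0.10, effect_vitd=-0.11, seed=seed
        )
        return panel, geno, subjects

    # qc_stress: 85 candidates = 55 clean + 8 near-monomorphic + 13 HWE-departed
    # + 9 fully missing, shuffled into one panel
    rng = _rng(seed, _STREAM_PRESET)
    panel = gen_snp_panel(85, (0.05, 0.5), 0.02, seed=seed)
    table = panel.table.copy()
    roles = np.array(["clean"] * 55 + ["rare"] * 8 + ["hwe"] * 13 + ["missing"] * 9, dtype=object)
    rng.shuffle(roles)
    F = np.zeros(85)
    mr = np.full(85, 0.02)
    maf = table["source_maf"].to_numpy(dtype=float).copy()
    maf[roles == "rare"] = 0.002
    # keep HWE-departed SNPs common so they cannot also trip the MAF filter
    maf[roles == "hwe"] = rng.uniform(0.10, 0.5, size=(roles == "hwe").sum())
    F[roles == "hwe"] = 0.9
    mr[roles == "rare"] = 0.0
    mr[roles == "hwe"] = 0.0
    mr[roles == "missing"] = 1.0
    table["source_maf"] = maf
    table["role"] = roles
    panel = SnpPanel(table)
    geno = gen_genotypes(panel, 1046, inbreeding_f=F, missing_rate=mr, seed=seed)
    subjects = gen_subjects(1046, vitd_median=33.63, seed=seed)
    # phenotypes planted against the scorable part of the panel (the 9 fully
    # missing SNPs contribute nothing to any subject's score)
    subjects = gen_phenotypes(
        subjects, geno, panel, lms, effect_prs=0.10, effect_vitd=-0.11, seed=seed
    )
    return panel, geno, subjects
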
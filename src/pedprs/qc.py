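"""SNP-level quality control: call rate, minor allele frequency, Hardy–Weinberg.

The filter chain mirrors standard pre-scoring practice for candidate-SNP
panels genotyped on a single cohort: drop SNPs that are effectively
unavailable (high missing rate), too rare to score stably (MAF below 1%), or
showing genotype-frequency departures incompatible with random mating
(conditional exact Hardy–Weinberg test, p below 1e-6 — the permissive
threshold conventional for association panels, where only gross genotyping
failure should be flagged).

Filters are applied in a fixed order — missing rate, then MAF, then HWE — and
each SNP receives exactly one verdict (the first failing rule). The order
guarantees that unavailable SNPs never contribute unstable frequency
estimates; when the failure sets are disjoint the per-reason counts are
order-independent.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import chi2

from .containers import GenotypeMatrix

log = logging.getLogger(__name__)

#: default thresholds: MAF >= 1%, missing rate <= 5%, HWE exact p >= 1e-6
DEFAULT_MAF_MIN = 0.01
DEFAULT_HWE_P_MIN = 1.0e-6
DEFAULT_MISSING_MAX = 0.05

VERDICTS = ("pass", "fail_missing", "fail_maf", "fail_hwe")


def missing_rate(dosages: np.ndarray) -> float:
    """Fraction of missing (NaN) entries in one SNP column."""
    dosages = np.asarray(dosages, dtype=float)
    if dosages.size == 0:
        raise ValueError("empty dosage column")
    return float(np.isnan(dosages).mean())


def compute_maf(dosages: np.ndarray) -> float:
    """Minor allele frequency from called dosages only (complete-case).

    The effect-allele frequency is ``sum(dosages) / (2 * n_called)``; the MAF
    is the smaller of that frequency and its complement.
    """
    dosages = np.asarray(dosages, dtype=float)
    called = dosages[~np.isnan(dosages)]
    if called.size == 0:
        raise ValueError("MAF undefined: no called genotypes")
    f = called.sum() / (2.0 * called.size)
    return float(min(f, 1.0 - f))


def genotype_counts(dosages: np.ndarray) -> tuple[int, int, int]:
    """(hom-effect, het, hom-other) counts from a dosage column."""
    dosages = np.asarray(dosages, dtype=float)
    called = dosages[~np.isnan(dosages)]
    return int((called == 2).sum()), int((called == 1).sum()), int((called == 0).sum())


def _hwe_het_log_probs(n: int, n_rare: int) -> tuple[np.ndarray, np.ndarray]:
    """Attainable heterozygote counts and their log conditional probabilities.

    Conditional on the observed allele counts (n_rare rare alleles among 2n),
    under Hardy–Weinberg the heterozygote count has probability

        P(n_het) = 2^n_het * n! / (n_hom_r! n_het! n_hom_c!)
                   * n_rare! n_common! / (2n)!

    attainable for n_het with the parity of n_rare, 0 <= n_het <= min counts.
    """
    n_common = 2 * n - n_rare
    max_het = min(n_rare, n_common)
    hets = np.arange(n_rare % 2, max_het + 1, 2)
    hom_r = (n_rare - hets) // 2
    hom_c = (n_common - hets) // 2
    logp = (
        hets * np.log(2.0)
        + gammaln(n + 1)
        - gammaln(hom_r + 1)
        - gammaln(hets + 1)
        - gammaln(hom_c + 1)
        + gammaln(n_rare + 1)
        + gammaln(n_common + 1)
        - gammaln(2 * n + 1)
    )
    # normalize: the mass sums to 1 analytically; renormalizing removes the
    # last bits of gammaln round-off
    logp -= np.logaddexp.reduce(logp)
    return hets, logp


def hwe_exact_test(n_hom_effect: int, n_het: int, n_hom_other: int) -> float:
    """Two-sided conditional exact Hardy–Weinberg test.

    Conditions on the observed allele counts and sums the probabilities of all
    heterozygote counts whose conditional probability does not exceed that of
    the observed count (probability-ordering two-sided rule; configurations
    tied with the observed probability are included). Returns a p-value in
    (0, 1].
    """
    counts = (n_hom_effect, n_het, n_hom_other)
    if any(c < 0 for c in counts):
        raise ValueError(f"negative genotype counts: {counts}")
    n = sum(counts)
    if n < 1:
        raise ValueError("at least one called genotype required")
    n_effect = 2 * n_hom_effect + n_het
    n_rare = min(n_effect, 2 * n - n_effect)
    hets, logp = _hwe_het_log_probs(n, n_rare)
    obs = np.flatnonzero(hets == n_het)
    if obs.size == 0:  # unreachable for consistent counts
        raise ValueError("observed heterozygote count not attainable")
    lp_obs = logp[obs[0]]
    probs = np.exp(logp)
    # include ties up to relative round-off
    p = probs[logp <= lp_obs + 1e-10].sum()
    return float(min(p, 1.0))


def hwe_chi2_test(n_hom_effect: int, n_het: int, n_hom_other: int) -> float:
    """1-df Pearson chi-square Hardy–Weinberg test (large-sample approximation)."""
    counts = np.array([n_hom_effect, n_het, n_hom_other], dtype=float)
    if (counts < 0).any():
        raise ValueError(f"negative genotype counts: {counts}")
    n = counts.sum()
    if n < 1:
        raise ValueError("at least one called genotype required")
    p = (2 * counts[0] + counts[1]) / (2 * n)
    q = 1.0 - p
    expected = n * np.array([p * p, 2 * p * q, q * q])
    if (expected == 0).any():  # monomorphic: single attainable configuration
        return 1.0
    stat = ((counts - expected) ** 2 / expected).sum()
    return float(chi2.sf(stat, df=1))


@dataclass
class QcReport:
    """Outcome of the QC chain: per-SNP metrics, verdicts and retained ids."""

    per_snp: pd.DataFrame = field(repr=False)
    thresholds: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not set(self.per_snp["verdict"]).issubset(VERDICTS):
            raise ValueError("unknown verdicts in QC table")

    @property
    def retained(self) -> list[str]:
        return self.per_snp.loc[self.per_snp["verdict"] == "pass", "snp_id"].tolist()

    @property
    def excluded(self) -> list[str]:
        return self.per_snp.loc[self.per_snp["verdict"] != "pass", "snp_id"].tolist()

    def counts(self) -> dict[str, int]:
        c = self.per_snp["verdict"].value_counts().to_dict()
        return {v: int(c.get(v, 0)) for v in VERDICTS}

    def to_tsv(self, path) -> None:
        self.per_snp.to_csv(path, sep="\t", index=False)

    def summary(self) -> dict:
        return {"thresholds": self.thresholds, "counts": self.counts(), "n_snps": len(self.per_snp)}

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.summary(), fh, indent=2)


def apply_qc_chain(
    genotypes: GenotypeMatrix,
    maf_min: float = DEFAULT_MAF_MIN,
    hwe_p_min: float = DEFAULT_HWE_P_MIN,
    missing_max: float = DEFAULT_MISSING_MAX,
    hwe_method: str = "exact",
) -> QcReport:
    """Run the missing-rate → MAF → HWE filter chain over all SNPs.

    Each SNP gets exactly one verdict; the retained list preserves input
    column order.
    """
    if genotypes.n_snps == 0 or genotypes.n_subjects == 0:
        raise ValueError("empty genotype matrix")
    if not (0 <= maf_min <= 0.5 and 0 <= hwe_p_min <= 1 and 0 <= missing_max <= 1):
        raise ValueError("QC thresholds out of range")
    if hwe_method not in ("exact", "chi2"):
        raise ValueError(f"unknown hwe_method {hwe_method!r}")
    hwe = hwe_exact_test if hwe_method == "exact" else hwe_chi2_test

    rows = []
    for j, snp in enumerate(genotypes.snp_ids):
        col = genotypes.dosage[:, j]
        miss = missing_rate(col)
        n_called = int((~np.isnan(col)).sum())
        maf = np.nan
        hwe_p = np.nan
        if miss > missing_max or n_called == 0:
            verdict = "fail_missing"
        else:
            maf = compute_maf(col)
            if maf < maf_min:
                verdict = "fail_maf"
            else:
                hwe_p = hwe(*genotype_counts(col))
                verdict = "fail_hwe" if hwe_p < hwe_p_min else "pass"
        rows.append(
            {
                "snp_id": snp,
                "n_called": n_called,
                "missing_rate": miss,
                "maf": maf,
                "hwe_p": hwe_p,
                "verdict": verdict,
            }
        )
    per_snp = pd.DataFrame(rows)
    report = QcReport(
        per_snp,
        thresholds={
            "maf_min": maf_min,
            "hwe_p_min": hwe_p_min,
            "missing_max": missing_max,
            "hwe_method": hwe_method,
        },
    )
    c = report.counts()
    log.info(
        "QC chain: %d SNPs in, %d retained (%d fail_missing, %d fail_maf, %d fail_hwe)",
        genotypes.n_snps, c["pass"], c["fail_missing"], c["fail_maf"], c["fail_hwe"],
    )
    return report
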
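"""Weighted polygenic risk score with per-subject missing-SNP rescaling.

The score for subject *i* is

    PRS_i = (sum_j beta_j * g_ij) * (n_i / sum_j beta_j)

where both sums run over the SNPs with a called genotype for that subject,
``g_ij`` counts effect-allele copies and ``n_i`` is the number of available
SNPs. The rescaling factor compensates for missing genotypes by inflating the
weighted sum back to the full-panel scale.

Because the beta weights are signed, the per-subject denominator can be small
or negative. The sum is used exactly as defined — fidelity to the scoring
convention wins — but subjects whose available-beta sum falls within an
epsilon of zero are flagged unscorable rather than silently scored with an
exploded value, and an advisory log line reports the sign and magnitude of
the full-panel beta sum. A magnitude-based variant (dividing by sum |beta|)
is available behind ``normalization="abs"`` for sensitivity analysis.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix, SnpPanel

log = logging.getLogger(__name__)

RISK_GROUPS = ("low", "intermediate", "high")


def compute_prs(
    genotypes: GenotypeMatrix,
    panel: SnpPanel,
    eps: float = 1e-10,
    normalization: str = "signed",
) -> pd.DataFrame:
    """Score every subject against the panel.

    Returns a DataFrame with columns ``subject_id``, ``raw_sum``,
    ``n_available``, ``beta_sum_available``, ``score``, ``scorable``.
    Unscorable subjects (no available SNPs, or available-beta sum within
    ``eps`` of zero under signed normalization) carry ``score = NaN``.
    """
    if normalization not in ("signed", "abs"):
        raise ValueError(f"unknown normalization {normalization!r}")
    geno_ids = set(genotypes.snp_ids)
    panel_ids = set(panel.snp_ids)
    if not geno_ids <= panel_ids:
        raise ValueError(
            f"genotype SNPs absent from panel: {sorted(geno_ids - panel_ids)[:5]} ..."
        )
    sub = panel.subset(genotypes.snp_ids)
    beta = sub.betas
    log.info(
        "scoring %d subjects on %d SNPs; full-panel beta sum = %+.6g",
        genotypes.n_subjects, len(beta), beta.sum(),
    )

    dosage = genotypes.dosage
    avail = ~np.isnan(dosage)
    filled = np.where(avail, dosage, 0.0)
    raw = filled @ beta
    n_avail = avail.sum(axis=1)
    denom_beta = np.abs(beta) if normalization == "abs" else beta
    beta_sum = avail @ denom_beta

    scorable = (n_avail > 0) & (np.abs(beta_sum) > eps)
    with np.errstate(divide="ignore", invalid="ignore"):
        score = np.where(scorable, raw * n_avail / beta_sum, np.nan)
    n_bad = int((~scorable).sum())
    if n_bad:
        log.warning("%d subject(s) unscorable (no SNPs or near-zero beta sum)", n_bad)

    return pd.DataFrame(
        {
            "subject_id": genotypes.subject_ids,
            "raw_sum": raw,
            "n_available": n_avail,
            "beta_sum_available": beta_sum,
            "score": score,
            "scorable": scorable,
        }
    )


def classify_risk(
    scores,
    low_fraction: float = 0.10,
    high_fraction: float = 0.10,
) -> np.ndarray:
    """Assign decile-based risk groups: bottom decile low, top decile high.

    With ``k_low = floor(low_fraction * n)`` and ``k_high = floor(
    high_fraction * n)``, the k_low smallest scores are `low`, the k_high
    largest are `high`, and the remainder `intermediate` — the rank-count
    convention that yields a 104/838/104 split at n = 1046. Boundary ties are
    broken by stable input order (ascending stable sort: earlier-seen subjects
    fill `low`, later-seen fill `high`) and logged.
    """
    scores = np.asarray(scores, dtype=float)
    n = scores.size
    if n < 3:
        raise ValueError(f"need at least 3 scores to form risk groups, got {n}")
    if not (0 < low_fraction < 0.5 and 0 < high_fraction < 0.5):
        raise ValueError("risk fractions must lie in (0, 0.5)")
    if np.isnan(scores).any():
        raise ValueError("scores must be complete; drop unscorable subjects first")

    k_low = int(np.floor(low_fraction * n))
    k_high = int(np.floor(high_fraction * n))
    order = np.argsort(scores, kind="stable")
    groups = np.full(n, "intermediate", dtype=object)
    groups[order[:k_low]] = "low"
    if k_high > 0:
        groups[order[n - k_high:]] = "high"

    for k, name in ((k_low, "low"), (n - k_high, "high")):
        if 0 < k < n and scores[order[k - 1]] == scores[order[k]]:
            warnings.warn(
                f"tied scores span the {name}-group boundary; "
                "stable input order decided the assignment",
                stacklevel=2,
            )
            log.warning("risk-group boundary tie at the %s cut", name)
    return groups
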
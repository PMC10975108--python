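"""End-to-end cohort analysis: QC → PRS → risk groups → zBMI → inference.

Runs the full cross-sectional analysis linking a weighted polygenic risk
score, vitamin D status (serum 25(OH)D dichotomized at 30 ng/mL, the
insufficiency cutoff inclusive on the insufficient side) and BMI-for-age
z-scores, and emits four tables of results:

1. descriptives by genetic risk group, with Kruskal–Wallis / Wilcoxon tests
   for continuous variables and chi-square for categorical ones;
2. Spearman correlations among PRS, 25(OH)D and zBMI under three adjustment
   models (crude; + demographics and birth anthropometry; + all covariates);
3. zBMI across risk groups (Kruskal–Wallis with Dunn post-hoc pairs) and
   across vitamin D statuses (Wilcoxon);
4. subgroup comparisons (vitamin D contrast within each risk group, risk
   contrast within each status), an ordered trend test across risk groups
   within the sufficient stratum, and the rank-based gene–environment
   interaction test.

Subjects flow through an explicit exclusion ledger (unscorable PRS, missing
anthropometry or assay, ±4 SD outliers), so analyzed + excluded always equals
the input count.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import qc as qcmod
from .anthro import LmsReference, zbmi_for_cohort
from .containers import GenotypeMatrix, SnpPanel
from .prs import classify_risk, compute_prs
from .stats import (
    TestResult,
    chi_square_table,
    dunn_multiple,
    group_summary,
    kruskal_wallis,
    partial_spearman,
    rank_interaction,
    rank_r_squared,
    spearman,
    trend_test,
    wilcoxon_ranksum,
)

log = logging.getLogger(__name__)

VITD_STATUSES = ("insufficient", "sufficient")

#: covariates of the adjustment models; model III extends model II
MODEL2_COVARIATES = ["age_months", "sex", "birth_length_cm", "birth_weight_g"]
MODEL3_EXTRA = [
    "premature_birth",
    "delivery",
    "only_child",
    "breastfeeding",
    "vitd_supplement",
    "yyb",
    "parental_care",
    "caregiver_edu",
    "ses",
]

CATEGORICAL_DESCRIPTIVES = [
    "sex",
    "premature_birth",
    "delivery",
    "only_child",
    "breastfeeding",
    "vitd_supplement",
    "yyb",
    "parental_care",
    "caregiver_edu",
]
CONTINUOUS_DESCRIPTIVES = [
    "age_months",
    "birth_length_cm",
    "birth_weight_g",
    "ses",
    "prs",
    "vitd_ng_ml",
    "zbmi",
]


def classify_vitd(vitd_ng_ml: float, cutoff: float = 30.0):
    """Vitamin D status: insufficient when 25(OH)D <= cutoff, else sufficient.

    The boundary is inclusive on the insufficient side. Accepts scalars or
    arrays.
    """
    v = np.asarray(vitd_ng_ml, dtype=float)
    if np.any(v < 0):
        raise ValueError("25(OH)D concentrations cannot be negative")
    out = np.where(v <= cutoff, "insufficient", "sufficient")
    return out.item() if out.ndim == 0 else out


def filter_outliers(
    values: pd.DataFrame, variables: list[str], k_sd: float = 4.0
) -> tuple[list, list, dict]:
    """Single-pass mean ± k·SD outlier screen over the monitored variables.

    Means and SDs are computed on the pre-filter sample (missing values
    ignored). Returns (kept_ids, excluded_ids, per-variable bounds). A
    variable with zero variance excludes nobody (warned).
    """
    if "subject_id" not in values.columns:
        raise ValueError("values frame needs a subject_id column")
    if not np.isfinite(k_sd) and k_sd > 0:
        return values["subject_id"].tolist(), [], {}
    if k_sd <= 0:
        raise ValueError("k_sd must be positive")
    excluded = np.zeros(len(values), dtype=bool)
    bounds = {}
    for var in variables:
        x = values[var].to_numpy(dtype=float)
        ok = ~np.isnan(x)
        if ok.sum() < 2:
            raise ValueError(f"need at least 2 non-missing values of {var}")
        mu, sd = x[ok].mean(), x[ok].std(ddof=1)
        if sd == 0:
            warnings.warn(f"{var} has zero variance; outlier rule skipped", stacklevel=2)
            continue
        lo, hi = mu - k_sd * sd, mu + k_sd * sd
        bounds[var] = (float(lo), float(hi))
        excluded |= ok & ((x < lo) | (x > hi))
    kept = values.loc[~excluded, "subject_id"].tolist()
    out = values.loc[excluded, "subject_id"].tolist()
    if out:
        log.info("outlier filter excluded %d subject(s)", len(out))
    return kept, out, bounds


def summarize_descriptives(values, kind: str) -> dict:
    """Median (P25, P75) for continuous data; count (percent) for categorical.

    Quartiles use linear interpolation; percentages are rounded to one
    decimal (totals may not sum to 100%).
    """
    if kind == "continuous":
        v = np.asarray(values, dtype=float)
        v = v[~np.isnan(v)]
        if v.size == 0:
            raise ValueError("no values to summarize")
        s = group_summary("all", v)
        return {
            "median": s["median"],
            "p25": s["p25"],
            "p75": s["p75"],
            "n": s["n"],
            "text": f"{s['median']:g} ({s['p25']:g}, {s['p75']:g})",
        }
    if kind == "categorical":
        ser = pd.Series(list(values))
        if ser.empty:
            raise ValueError("no values to summarize")
        counts = ser.value_counts(sort=False)
        total = counts.sum()
        return {
            str(level): {"n": int(c), "percent": round(100.0 * c / total, 1)}
            for level, c in counts.items()
        }
    raise ValueError(f"kind must be continuous or categorical, got {kind!r}")


@dataclass
class AnalysisConfig:
    """Thresholds, covariate rosters and seeds for one analysis run."""

    maf_min: float = 0.01
    hwe_p_min: float = 1.0e-6
    missing_max: float = 0.05
    hwe_method: str = "exact"
    vitd_cutoff: float = 30.0
    low_fraction: float = 0.10
    high_fraction: float = 0.10
    outlier_sd: float = 4.0
    outlier_variables: tuple = ("zbmi", "vitd_ng_ml")
    alpha: float = 0.05
    model2_covariates: list = field(default_factory=lambda: list(MODEL2_COVARIATES))
    model3_extra: list = field(default_factory=lambda: list(MODEL3_EXTRA))
    dunn_adjust: str = "bonferroni"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.maf_min <= 0.5):
            raise ValueError("maf_min out of range")
        if not (0 <= self.hwe_p_min <= 1 and 0 <= self.missing_max <= 1):
            raise ValueError("hwe_p_min / missing_max out of range")
        if not (0 < self.low_fraction < 0.5 and 0 < self.high_fraction < 0.5):
            raise ValueError("risk fractions out of range")
        if self.vitd_cutoff <= 0 or self.outlier_sd <= 0 or not (0 < self.alpha < 1):
            raise ValueError("vitd_cutoff, outlier_sd and alpha must be positive/valid")
        # model III must extend model II
        m3 = set(self.model2_covariates) | set(self.model3_extra)
        if not set(self.model2_covariates) <= m3:
            raise ValueError("model II covariates must be a subset of model III")

    def model3_covariates(self) -> list:
        return list(self.model2_covariates) + [
            c for c in self.model3_extra if c not in self.model2_covariates
        ]


@dataclass
class RunReport:
    """Deterministic record of one pipeline run."""

    flowchart: dict
    qc_summary: dict
    per_subject: pd.DataFrame = field(repr=False)
    tables: dict = field(default_factory=dict)
    config: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "flowchart": self.flowchart,
            "qc_summary": self.qc_summary,
            "tables": self.tables,
            "config": self.config,
            "n_analyzed": int(len(self.per_subject)),
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True, default=_jsonable)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def flowchart_text(self) -> str:
        fc = self.flowchart
        lines = [f"subjects in: {fc['input']}"]
        for reason, n in fc["excluded"].items():
            lines.append(f"  excluded ({reason}): {n}")
        lines.append(f"analyzed: {fc['analyzed']}")
        return "\n".join(lines)


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _encode_covariates(df: pd.DataFrame, columns: list[str]) -> np.ndarray:
    """Numeric covariate matrix; categorical columns indicator-coded.

    The reference level of each categorical covariate is its first listed
    level in the data's category order (alphabetical for plain objects).
    """
    blocks = []
    for col in columns:
        s = df[col]
        if pd.api.types.is_numeric_dtype(s):
            blocks.append(s.to_numpy(dtype=float)[:, None])
        else:
            dummies = pd.get_dummies(s, drop_first=True)
            if dummies.shape[1]:
                blocks.append(dummies.to_numpy(dtype=float))
    if not blocks:
        return np.empty((len(df), 0))
    return np.hstack(blocks)


def _result_dict(res: TestResult) -> dict:
    return res.to_dict()


def run_analysis(
    panel: SnpPanel,
    genotypes: GenotypeMatrix,
    subjects: pd.DataFrame,
    lms_ref: LmsReference,
    config: AnalysisConfig | None = None,
) -> RunReport:
    """Execute the full pipeline and return a :class:`RunReport`."""
    config = config or AnalysisConfig()
    n_input = len(subjects)
    if n_input == 0:
        raise ValueError("empty subject table")
    excluded: dict[str, int] = {}

    # 1. SNP-level QC, then restrict genotypes and panel to retained SNPs
    qc_report = qcmod.apply_qc_chain(
        genotypes,
        maf_min=config.maf_min,
        hwe_p_min=config.hwe_p_min,
        missing_max=config.missing_max,
        hwe_method=config.hwe_method,
    )
    retained = qc_report.retained
    if not retained:
        raise ValueError("QC excluded every SNP; nothing to score")
    geno_qc = genotypes.subset_snps(retained)

    # 2. PRS with per-subject missing-SNP rescaling
    prs_df = compute_prs(geno_qc, panel)
    unscorable = set(prs_df.loc[~prs_df["scorable"], "subject_id"])

    # 3. zBMI
    anthro_df, skipped = zbmi_for_cohort(subjects, lms_ref)
    skipped_ids = {sid for sid, _ in skipped}

    # 4. vitamin D status; exclusion reasons counted with first-reason precedence
    vit_missing = set(subjects.loc[subjects["vitd_ng_ml"].isna(), "subject_id"])
    skipped_ids -= unscorable
    vit_missing -= unscorable | skipped_ids
    excluded["unscorable_prs"] = len(unscorable)
    excluded["missing_anthropometry"] = len(skipped_ids)
    excluded["missing_vitd"] = len(vit_missing)

    data = subjects.merge(prs_df[["subject_id", "score", "n_available"]], on="subject_id")
    data = data.merge(anthro_df[["subject_id", "bmi", "zbmi"]], on="subject_id", how="left")
    drop = unscorable | skipped_ids | vit_missing
    data = data[~data["subject_id"].isin(drop)].reset_index(drop=True)
    excluded_total_unique = len(drop)

    # 5. outlier screen on the monitored continuous variables
    data = data.rename(columns={"score": "prs"})
    kept, out_ids, bounds = filter_outliers(
        data, [v if v != "prs" else "prs" for v in config.outlier_variables], config.outlier_sd
    )
    excluded["outlier"] = len(out_ids)
    data = data[data["subject_id"].isin(set(kept))].reset_index(drop=True)
    if len(data) == 0:
        raise ValueError("no subjects left after exclusions")

    # 6. risk groups and vitamin D status on the analysis set
    data["risk_group"] = classify_risk(
        data["prs"].to_numpy(), config.low_fraction, config.high_fraction
    )
    data["vitd_status"] = classify_vitd(data["vitd_ng_ml"].to_numpy(), config.vitd_cutoff)

    flowchart = {
        "input": n_input,
        "excluded": excluded,
        "analyzed": int(len(data)),
    }
    assert flowchart["analyzed"] + excluded_total_unique + len(out_ids) == n_input

    tables = {
        "descriptives": _table1(data, config),
        "correlations": _table2(data, config),
        "zbmi_by_group": _table3(data, config),
        "subgroups": _table4(data, config),
    }

    cfg = asdict(config)
    cfg["outlier_variables"] = list(config.outlier_variables)
    return RunReport(
        flowchart=flowchart,
        qc_summary=qc_report.summary(),
        per_subject=data,
        tables=tables,
        config=cfg,
    )


def _table1(data: pd.DataFrame, config: AnalysisConfig) -> dict:
    """Descriptives by risk group with KW (continuous) / chi-square tests."""
    order = ["low", "intermediate", "high"]
    groups = {g: data[data["risk_group"] == g] for g in order if (data["risk_group"] == g).any()}
    rows = {}
    for var in CONTINUOUS_DESCRIPTIVES:
        if var not in data.columns:
            continue
        per_group = {g: summarize_descriptives(sub[var], "continuous") for g, sub in groups.items()}
        vals = [sub[var].to_numpy(dtype=float) for sub in groups.values()]
        try:
            test = kruskal_wallis(vals, labels=list(groups))
            p = test.p_value
        except ValueError:
            p = np.nan
        rows[var] = {
            "total": summarize_descriptives(data[var], "continuous"),
            "by_group": per_group,
            "p_value": p,
        }
    for var in CATEGORICAL_DESCRIPTIVES:
        if var not in data.columns:
            continue
        levels = sorted(data[var].astype(str).unique())
        table = np.array(
            [[(sub[var].astype(str) == lv).sum() for lv in levels] for sub in groups.values()]
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            test = chi_square_table(table)
        rows[var] = {
            "total": summarize_descriptives(data[var].astype(str), "categorical"),
            "by_group": {
                g: summarize_descriptives(sub[var].astype(str), "categorical")
                for g, sub in groups.items()
            },
            "p_value": test.p_value,
        }
    return rows


_PAIRS = [
    ("prs", "vitd_ng_ml", "PRS vs 25(OH)D"),
    ("prs", "zbmi", "PRS vs zBMI"),
    ("vitd_ng_ml", "zbmi", "25(OH)D vs zBMI"),
]


def _table2(data: pd.DataFrame, config: AnalysisConfig) -> list[dict]:
    """Spearman correlations under the three adjustment models."""
    out = []
    models = {
        "I": [],
        "II": config.model2_covariates,
        "III": config.model3_covariates(),
    }
    for x, y, label in _PAIRS:
        for model, covs in models.items():
            covs_present = [c for c in covs if c in data.columns]
            if model == "I" or not covs_present:
                res = spearman(data[x], data[y])
            else:
                Z = _encode_covariates(data, covs_present)
                res = partial_spearman(data[x], data[y], Z)
            out.append(
                {
                    "pair": label,
                    "model": model,
                    "r_s": res.statistic,
                    "p_value": res.p_value,
                    "n": int(len(data)),
                }
            )
    # rank-based share of zBMI variance explained by the score
    out.append(
        {
            "pair": "PRS vs zBMI",
            "model": "rank_r_squared",
            "r_s": rank_r_squared(data["prs"], data["zbmi"]),
            "p_value": None,
            "n": int(len(data)),
        }
    )
    return out


def _table3(data: pd.DataFrame, config: AnalysisConfig) -> dict:
    """zBMI across risk groups (KW + Dunn) and vitamin D statuses (Wilcoxon)."""
    order = [g for g in ("low", "intermediate", "high") if (data["risk_group"] == g).any()]
    by_risk = [data.loc[data["risk_group"] == g, "zbmi"].to_numpy() for g in order]
    kw = kruskal_wallis(by_risk, labels=order)
    dunn = dunn_multiple(by_risk, labels=order, adjust=config.dunn_adjust)
    statuses = [s for s in VITD_STATUSES if (data["vitd_status"] == s).any()]
    by_vitd = [data.loc[data["vitd_status"] == s, "zbmi"].to_numpy() for s in statuses]
    if len(by_vitd) == 2:
        wx = wilcoxon_ranksum(by_vitd[0], by_vitd[1])
        wx.groups = [group_summary(s, v) for s, v in zip(statuses, by_vitd)]
        vit = _result_dict(wx)
    else:
        vit = None
    return {
        "risk_groups": _result_dict(kw),
        "risk_pairs": [_result_dict(r) for r in dunn],
        "vitd_status": vit,
    }


def _table4(data: pd.DataFrame, config: AnalysisConfig) -> dict:
    """Subgroup contrasts, ordered trend within sufficiency, interaction."""
    order = [g for g in ("low", "intermediate", "high") if (data["risk_group"] == g).any()]
    out: dict = {"vitd_within_risk": {}, "risk_within_vitd": {}, "trend_sufficient": None,
                 "interaction": None}
    for g in order:
        sub = data[data["risk_group"] == g]
        parts = [sub.loc[sub["vitd_status"] == s, "zbmi"].to_numpy() for s in VITD_STATUSES]
        if all(len(p) for p in parts):
            res = wilcoxon_ranksum(parts[0], parts[1])
            res.groups = [group_summary(s, v) for s, v in zip(VITD_STATUSES, parts)]
            out["vitd_within_risk"][g] = _result_dict(res)
    for s in VITD_STATUSES:
        sub = data[data["vitd_status"] == s]
        parts = [sub.loc[sub["risk_group"] == g, "zbmi"].to_numpy() for g in order]
        if all(len(p) for p in parts) and len(parts) >= 2:
            res = kruskal_wallis(parts, labels=order)
            out["risk_within_vitd"][s] = _result_dict(res)
            if s == "sufficient" and len(parts) >= 3:
                out["trend_sufficient"] = _result_dict(trend_test(parts, labels=order))
    try:
        out["interaction"] = _result_dict(
            rank_interaction(data["zbmi"], data["risk_group"], data["vitd_status"])
        )
    except ValueError as exc:
        log.warning("interaction test skipped: %s", exc)
    return out
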
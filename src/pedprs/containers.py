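"""Shared data containers: SNP weight panels and genotype dosage matrices.

The dosage convention throughout the package counts copies of the *effect*
allele (the allele the GWAS β refers to), so each entry is 0, 1 or 2, with
``NaN`` marking a missing call.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

VALID_BASES = frozenset("ACGT")

#: genome-wide significance threshold used to select panel SNPs (metadata only)
GWAS_SIGNIFICANCE = 5.0e-8

PANEL_COLUMNS = ["snp_id", "effect_allele", "other_allele", "beta"]


@dataclass
class SnpPanel:
    """A weight table of biallelic SNPs with signed per-allele effect sizes.

    Parameters
    ----------
    table
        DataFrame with columns ``snp_id``, ``effect_allele``, ``other_allele``,
        ``beta`` and optionally ``source_maf`` (the population effect-allele
        frequency used by the simulator).
    gwas_threshold
        The association p-value threshold the panel was selected at; recorded
        as provenance metadata, not used in computation.
    """

    table: pd.DataFrame
    gwas_threshold: float = GWAS_SIGNIFICANCE

    def __post_init__(self) -> None:
        t = self.table
        missing = [c for c in PANEL_COLUMNS if c not in t.columns]
        if missing:
            raise ValueError(f"panel table lacks columns {missing}")
        if len(t) == 0:
            raise ValueError("panel must contain at least one SNP")
        if t["snp_id"].duplicated().any():
            dup = t.loc[t["snp_id"].duplicated(), "snp_id"].tolist()
            raise ValueError(f"duplicate snp_ids in panel: {dup}")
        for col in ("effect_allele", "other_allele"):
            bad = ~t[col].isin(list(VALID_BASES))
            if bad.any():
                raise ValueError(f"invalid bases in {col}: {t.loc[bad, col].tolist()}")
        if (t["effect_allele"] == t["other_allele"]).any():
            raise ValueError("effect_allele must differ from other_allele")
        if not np.all(np.isfinite(t["beta"].to_numpy(dtype=float))):
            raise ValueError("beta weights must be finite")
        self.table = t.reset_index(drop=True)

    @property
    def snp_ids(self) -> np.ndarray:
        return self.table["snp_id"].to_numpy()

    @property
    def betas(self) -> np.ndarray:
        return self.table["beta"].to_numpy(dtype=float)

    def __len__(self) -> int:
        return len(self.table)

    def subset(self, snp_ids) -> "SnpPanel":
        """Return the panel restricted to ``snp_ids``, in the given order."""
        idx = self.table.set_index("snp_id")
        missing = [s for s in snp_ids if s not in idx.index]
        if missing:
            raise KeyError(f"snp_ids not in panel: {missing}")
        sub = idx.loc[list(snp_ids)].reset_index()
        return SnpPanel(sub[self.table.columns], self.gwas_threshold)

    def is_palindromic(self) -> np.ndarray:
        """Boolean mask of strand-ambiguous (A/T or C/G) SNPs."""
        pairs = {frozenset("AT"), frozenset("CG")}
        return np.array(
            [
                frozenset((e, o)) in pairs
                for e, o in zip(self.table["effect_allele"], self.table["other_allele"])
            ]
        )


@dataclass
class GenotypeMatrix:
    """Subjects × SNPs effect-allele dosage matrix with missingness.

    ``dosage`` is a float array holding values in {0, 1, 2} with ``NaN`` for
    missing calls. Rows follow ``subject_ids``, columns follow ``snp_ids``.
    """

    subject_ids: np.ndarray
    snp_ids: np.ndarray
    dosage: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.subject_ids = np.asarray(self.subject_ids, dtype=object)
        self.snp_ids = np.asarray(self.snp_ids, dtype=object)
        self.dosage = np.asarray(self.dosage, dtype=float)
        n, m = self.dosage.shape
        if n != len(self.subject_ids) or m != len(self.snp_ids):
            raise ValueError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.subject_ids)} subjects x {len(self.snp_ids)} SNPs"
            )
        if len(set(self.subject_ids)) != n:
            raise ValueError("subject_ids must be unique")
        if len(set(self.snp_ids)) != m:
            raise ValueError("snp_ids must be unique")
        called = self.dosage[~np.isnan(self.dosage)]
        if not np.isin(called, (0.0, 1.0, 2.0)).all():
            raise ValueError("dosages must be 0, 1, 2 or missing (NaN)")

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def column(self, snp_id: str) -> np.ndarray:
        """Dosage column for one SNP."""
        (j,) = np.where(self.snp_ids == snp_id)
        if len(j) == 0:
            raise KeyError(f"unknown snp_id {snp_id!r}")
        return self.dosage[:, j[0]]

    def subset_snps(self, snp_ids) -> "GenotypeMatrix":
        """Restrict to the given SNPs, preserving the requested order."""
        pos = {s: j for j, s in enumerate(self.snp_ids)}
        missing = [s for s in snp_ids if s not in pos]
        if missing:
            raise KeyError(f"snp_ids not in matrix: {missing}")
        cols = [pos[s] for s in snp_ids]
        return GenotypeMatrix(self.subject_ids.copy(), np.asarray(list(snp_ids), dtype=object), self.dosage[:, cols])

    def to_frame(self) -> pd.DataFrame:
        """Wide DataFrame: one row per subject, one column per SNP."""
        df = pd.DataFrame(self.dosage, columns=self.snp_ids)
        df.insert(0, "subject_id", self.subject_ids)
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "GenotypeMatrix":
        if "subject_id" not in df.columns:
            raise ValueError("genotype frame needs a subject_id column")
        snp_cols = [c for c in df.columns if c != "subject_id"]
        return cls(
            df["subject_id"].to_numpy(dtype=object),
            np.asarray(snp_cols, dtype=object),
            df[snp_cols].to_numpy(dtype=float),
        )
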
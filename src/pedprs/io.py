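"""Readers and writers for the package's plain-text interchange formats.

- SNP weight panel: TSV with header ``snp_id  effect_allele  other_allele
  beta`` (plus optional ``source_maf``).
- Genotypes: wide CSV, ``subject_id`` plus one column per SNP, values
  0/1/2/NA.
- Subject table and LMS reference: plain CSV with headers.
- VCF 4.2 (GT-only): dosages are counts of the *effect* allele in the GT
  field; records are matched to the panel by (snp_id, effect_allele,
  other_allele) with exact allele agreement — no strand flipping. A/T and
  C/G palindromic SNPs produce a logged warning; panel SNPs without a
  matching record become all-missing columns.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from .anthro import LMS_COLUMNS, LmsReference
from .containers import PANEL_COLUMNS, GenotypeMatrix, SnpPanel

log = logging.getLogger(__name__)


def write_panel_tsv(panel: SnpPanel, path) -> None:
    cols = [c for c in panel.table.columns if c in PANEL_COLUMNS + ["source_maf"]]
    panel.table[cols].to_csv(path, sep="\t", index=False)


def read_panel_tsv(path) -> SnpPanel:
    df = pd.read_csv(path, sep="\t", dtype={"snp_id": str})
    return SnpPanel(df)


def write_genotypes_csv(genotypes: GenotypeMatrix, path) -> None:
    genotypes.to_frame().to_csv(path, index=False, na_rep="NA")


def read_genotypes_csv(path) -> GenotypeMatrix:
    df = pd.read_csv(path, dtype={"subject_id": str}, na_values=["NA"])
    return GenotypeMatrix.from_frame(df)


def write_subjects_csv(subjects: pd.DataFrame, path) -> None:
    subjects.to_csv(path, index=False, na_rep="NA")


def read_subjects_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"subject_id": str}, na_values=["NA"])


def write_lms_csv(ref: LmsReference, path) -> None:
    ref.table[LMS_COLUMNS].to_csv(path, index=False)


def read_lms_csv(path) -> LmsReference:
    return LmsReference(pd.read_csv(path))


_GT_FOR_DOSAGE = {2.0: "1/1", 1.0: "0/1", 0.0: "0/0"}


def write_vcf(genotypes: GenotypeMatrix, panel: SnpPanel, path) -> None:
    """Minimal VCF 4.2 with GT only; ALT is the effect allele, REF the other."""
    sub = panel.subset(genotypes.snp_ids)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(str(s) for s in genotypes.subject_ids)
            + "\n"
        )
        for j, row in enumerate(sub.table.itertuples(index=False)):
            gts = [
                "./." if np.isnan(d) else _GT_FOR_DOSAGE[d]
                for d in genotypes.dosage[:, j]
            ]
            fh.write(
                f"1\t{j + 1}\t{row.snp_id}\t{row.other_allele}\t{row.effect_allele}"
                f"\t.\t.\t.\tGT\t" + "\t".join(gts) + "\n"
            )


def read_vcf(path, panel: SnpPanel) -> GenotypeMatrix:
    """Read effect-allele dosages for every panel SNP from a VCF.

    Matching requires the record ID to equal the panel snp_id and the
    REF/ALT pair to equal the panel's {effect, other} alleles exactly
    (either orientation; the dosage always counts effect alleles). Unmatched
    panel SNPs become all-missing columns.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    n = len(samples)
    dosage = {}
    pal = dict(zip(panel.table["snp_id"], panel.is_palindromic()))
    rows = panel.table.set_index("snp_id")
    for rec in vcf:
        sid = rec.ID
        if sid not in rows.index or sid in dosage:
            continue
        if len(rec.ALT) != 1:
            log.warning("skipping multi-allelic record %s", sid)
            continue
        eff, oth = rows.loc[sid, "effect_allele"], rows.loc[sid, "other_allele"]
        if {rec.REF, rec.ALT[0]} != {eff, oth}:
            log.warning("allele mismatch for %s: VCF %s/%s vs panel %s/%s",
                        sid, rec.REF, rec.ALT[0], eff, oth)
            continue
        if pal[sid]:
            warnings.warn(
                f"palindromic (strand-ambiguous) SNP {sid}: alleles {eff}/{oth}",
                stacklevel=2,
            )
        # genotype array rows: [allele1, allele2, phased]; -1 = missing
        g = np.asarray(rec.genotype.array())[:, :2].astype(float)
        alt_is_effect = rec.ALT[0] == eff
        col = np.where(
            (g < 0).any(axis=1),
            np.nan,
            g.sum(axis=1) if alt_is_effect else 2.0 - g.sum(axis=1),
        )
        dosage[sid] = col
    mat = np.full((n, len(panel)), np.nan)
    for j, sid in enumerate(panel.snp_ids):
        if sid in dosage:
            mat[:, j] = dosage[sid]
        else:
            log.warning("panel SNP %s not found in VCF; column set to missing", sid)
    return GenotypeMatrix(np.asarray(samples, dtype=object), panel.snp_ids.copy(), mat)
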
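"""Plain-text interchange formats.

Phenotypes, genotype dosages and spectra travel as tab-delimited tables
with an ``NA`` missing sentinel; the synthetic-cohort configuration and QC
reports round-trip through YAML.  A minimal VCF converter (GT field only)
is provided for the dosage matrix.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import yaml

from .datatypes import MISSING_SENTINEL, CohortTable, GenotypeMatrix, QCReport, SpectrumSet

__all__ = [
    "write_phenotypes", "read_phenotypes",
    "write_genotypes", "read_genotypes",
    "genotypes_to_vcf", "genotypes_from_vcf",
    "write_spectra", "read_spectra",
    "write_qc_report",
]


def write_phenotypes(cohort: CohortTable, path) -> None:
    cohort.data.to_csv(path, sep="\t", na_rep=MISSING_SENTINEL)


def read_phenotypes(path, trait_columns: list[str] | None = None,
                    disease_columns: list[str] | None = None,
                    stage: str = "raw") -> CohortTable:
    """Read a tab-delimited phenotype table (header row, NA sentinel).

    When ``trait_columns`` is omitted, every numeric column other than
    AGE/SEX/cluster_truth is taken as a trait; boolean columns are taken
    as disease flags.
    """
    data = pd.read_csv(path, sep="\t", index_col=0, na_values=[MISSING_SENTINEL])
    reserved = {"AGE", "SEX", "cluster_truth"}
    if disease_columns is None:
        disease_columns = [c for c in data.columns if data[c].dropna().isin([True, False]).all()
                           and data[c].dtype == bool]
    if trait_columns is None:
        trait_columns = [
            c for c in data.columns
            if c not in reserved and c not in disease_columns
            and np.issubdtype(data[c].dtype, np.number)
        ]
    return CohortTable(data=data, trait_columns=list(trait_columns),
                       disease_columns=list(disease_columns), stage=stage)


def write_genotypes(g: GenotypeMatrix, dosage_path, annotation_path) -> None:
    df = pd.DataFrame(g.dosage, index=pd.Index(g.subjects, name="subject_id"), columns=g.snp_ids)
    # dosages are integral where present; keep them as 0/1/2 on disk
    df.to_csv(dosage_path, sep="\t", na_rep=MISSING_SENTINEL, float_format="%.0f")
    g.annotations.to_csv(annotation_path, sep="\t")


def read_genotypes(dosage_path, annotation_path) -> GenotypeMatrix:
    df = pd.read_csv(dosage_path, sep="\t", index_col=0, na_values=[MISSING_SENTINEL])
    ann = pd.read_csv(annotation_path, sep="\t", index_col=0)
    ann["gene"] = ann["gene"].fillna("")
    ann["chrom"] = ann["chrom"].astype(str)
    ann = ann.loc[list(df.columns)]
    return GenotypeMatrix(
        subjects=[str(s) for s in df.index],
        snp_ids=list(df.columns),
        dosage=df.to_numpy(float),
        annotations=ann,
    )


_GT_CODE = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}


def genotypes_to_vcf(g: GenotypeMatrix, path) -> None:
    """Write a minimal VCF (GT only); the minor allele is ALT, REF/ALT
    bases are placeholders (A/C) since only dosage is modelled."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in dict.fromkeys(g.annotations["chrom"].astype(str)):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(g.subjects) + "\n")
        for j, snp in enumerate(g.snp_ids):
            row = g.annotations.iloc[j]
            gts = [
                "./." if np.isnan(d) else _GT_CODE[d] for d in g.dosage[:, j]
            ]
            fh.write(f"{row['chrom']}\t{int(row['pos'])}\t{snp}\tA\tC\t.\t.\t.\tGT\t"
                     + "\t".join(gts) + "\n")


def genotypes_from_vcf(path) -> GenotypeMatrix:
    """Read a minimal GT-only VCF back into a dosage matrix (ALT count)."""
    try:
        from cyvcf2 import VCF
    except ImportError:  # pragma: no cover - cyvcf2 is in the managed env
        return _read_vcf_text(path)
    vcf = VCF(str(path))
    subjects = list(vcf.samples)
    ids, cols, ann = [], [], []
    for var in vcf:
        ids.append(var.ID)
        ann.append((str(var.CHROM), int(var.POS), ""))
        # gt_types: 0=hom-ref, 1=het, 2=hom-alt(3 in some builds), 3=unknown
        dos = np.array([
            np.nan if gt[0] < 0 or gt[1] < 0 else float(gt[0] + gt[1])
            for gt in (v[:2] for v in var.genotypes)
        ])
        cols.append(dos)
    vcf.close()
    annotations = pd.DataFrame(ann, columns=["chrom", "pos", "gene"],
                               index=pd.Index(ids, name="snp_id"))
    return GenotypeMatrix(
        subjects=subjects,
        snp_ids=ids,
        dosage=np.column_stack(cols) if cols else np.empty((len(subjects), 0)),
        annotations=annotations,
    )


def _read_vcf_text(path) -> GenotypeMatrix:
    subjects, ids, cols, ann = [], [], [], []
    with open(path) as fh:
        for line in fh:
            if line.startswith("##"):
                continue
            fields = line.rstrip("\n").split("\t")
            if line.startswith("#CHROM"):
                subjects = fields[9:]
                continue
            chrom, pos, vid = fields[0], int(fields[1]), fields[2]
            ids.append(vid)
            ann.append((chrom, pos, ""))
            dos = []
            for gt in fields[9:]:
                gt = gt.split(":")[0]
                if "." in gt:
                    dos.append(np.nan)
                else:
                    dos.append(float(sum(int(a) for a in gt.replace("|", "/").split("/"))))
            cols.append(np.array(dos))
    annotations = pd.DataFrame(ann, columns=["chrom", "pos", "gene"],
                               index=pd.Index(ids, name="snp_id"))
    return GenotypeMatrix(subjects=subjects, snp_ids=ids,
                          dosage=np.column_stack(cols) if cols else np.empty((len(subjects), 0)),
                          annotations=annotations)


def write_spectra(s: SpectrumSet, path) -> None:
    """Tab-delimited: first column ppm, one column per subject."""
    df = pd.DataFrame(s.intensity.T, columns=s.meta.index)
    df.insert(0, "ppm", s.ppm)
    df.to_csv(path, sep="\t", index=False)


def read_spectra(path, meta: pd.DataFrame) -> SpectrumSet:
    df = pd.read_csv(path, sep="\t")
    ppm = df["ppm"].to_numpy(float)
    subjects = [c for c in df.columns if c != "ppm"]
    return SpectrumSet(ppm=ppm, intensity=df[subjects].to_numpy(float).T,
                       meta=meta.loc[subjects])


def write_qc_report(report: QCReport, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(report.to_dict(), fh, sort_keys=False)
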
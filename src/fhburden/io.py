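"""Reading and writing the tool's delimited-text formats.

All tables are tab-separated UTF-8 with a header row; lines starting with '#'
are comments and "NA" is the missing-value token.  Output tables begin with a
comment header recording the package version, seed and configuration so every
result file is reproducible from its own header.  All joins downstream are by
sample id, never by row order.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
import pandas as pd

from .burden import BurdenVector, GenotypeMatrix
from .pedscore import IncidenceModel, Pedigree, kinship_weight

NA_TOKEN = "NA"

PHENOTYPE_COLUMNS = ["sample_id", "case", "fh", "sex"]


def _data_rows(path) -> tuple[list[str], list[tuple[int, list[str]]]]:
    """Header fields and (1-based line number, fields) for each data row."""
    header: list[str] | None = None
    rows: list[tuple[int, list[str]]] = []
    with open(path, newline="", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = next(csv.reader([line], delimiter="\t"))
            fields = [f.strip() for f in fields]
            if header is None:
                header = fields
            else:
                rows.append((lineno, fields))
    if header is None:
        raise ValueError(f"{path}: no header row found")
    return header, rows


def read_phenotypes(path) -> pd.DataFrame:
    """Read a phenotype table: sample_id, case, fh, sex (+ numeric covariates).

    case/fh/sex must be 0/1; offending rows are reported with their file line
    numbers.
    """
    header, rows = _data_rows(path)
    missing = [c for c in PHENOTYPE_COLUMNS if c not in header]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    idx = {c: header.index(c) for c in header}
    records, bad_lines = [], []
    for lineno, fields in rows:
        if len(fields) != len(header):
            raise ValueError(f"{path}: line {lineno} has {len(fields)} fields, "
                             f"expected {len(header)}")
        rec: dict[str, object] = {"sample_id": fields[idx["sample_id"]]}
        ok = True
        for col in ("case", "fh", "sex"):
            val = fields[idx[col]]
            if val not in ("0", "1"):
                ok = False
            else:
                rec[col] = int(val)
        if not ok:
            bad_lines.append(lineno)
            continue
        for col in header:
            if col in PHENOTYPE_COLUMNS:
                continue
            val = fields[idx[col]]
            rec[col] = np.nan if val == NA_TOKEN else float(val)
        records.append(rec)
    if bad_lines:
        raise ValueError(
            f"{path}: non-binary case/fh/sex on line(s) {bad_lines[:10]}"
        )
    df = pd.DataFrame(records)
    if df["sample_id"].duplicated().any():
        dups = df["sample_id"][df["sample_id"].duplicated()].tolist()[:10]
        raise ValueError(f"{path}: duplicate sample ids {dups}")
    return df


def write_phenotypes(df: pd.DataFrame, path, header_meta: dict | None = None) -> None:
    write_table(df, path, header_meta)


def read_carriers(path) -> dict[str, BurdenVector]:
    """Read a per-gene carrier table (sample_id, gene, carrier) into
    BurdenVectors keyed by gene."""
    header, rows = _data_rows(path)
    for col in ("sample_id", "gene", "carrier"):
        if col not in header:
            raise ValueError(f"{path}: missing required column {col!r}")
    idx = {c: header.index(c) for c in header}
    by_gene: dict[str, list[tuple[str, int]]] = {}
    for lineno, fields in rows:
        val = fields[idx["carrier"]]
        if val not in ("0", "1"):
            raise ValueError(f"{path}: non-binary carrier value on line {lineno}")
        by_gene.setdefault(fields[idx["gene"]], []).append(
            (fields[idx["sample_id"]], int(val)))
    out = {}
    for gene, pairs in by_gene.items():
        ids = [s for s, _ in pairs]
        if len(set(ids)) != len(ids):
            raise ValueError(f"{path}: duplicate sample ids for gene {gene}")
        out[gene] = BurdenVector(gene=gene, sample_ids=ids,
                                 carrier=np.array([c for _, c in pairs], dtype=bool))
    return out


def write_carriers(vectors, path, header_meta: dict | None = None) -> None:
    frames = [v.to_frame() for v in vectors]
    write_table(pd.concat(frames, ignore_index=True), path, header_meta)


def check_sample_overlap(carrier_ids, phenotype_ids) -> None:
    """Require every carrier sample to be phenotyped; list first offenders."""
    missing = [s for s in carrier_ids if s not in set(phenotype_ids)]
    if missing:
        raise ValueError(
            f"{len(missing)} carrier sample id(s) absent from the phenotype "
            f"table; first offenders: {missing[:10]}"
        )


def read_dosage_matrix(dosage_path, variant_map_path) -> GenotypeMatrix:
    """Build a GenotypeMatrix from a sample x variant dosage table plus a
    variant map (variant_id, gene, chrom, pos, af)."""
    dos = pd.read_csv(dosage_path, sep="\t", comment="#", na_values=[NA_TOKEN])
    if "sample_id" not in dos.columns:
        raise ValueError(f"{dosage_path}: missing required column 'sample_id'")
    vmap = pd.read_csv(variant_map_path, sep="\t", comment="#")
    for col in ("variant_id", "gene", "chrom", "pos", "af"):
        if col not in vmap.columns:
            raise ValueError(f"{variant_map_path}: missing required column {col!r}")
    vmap = vmap.set_index("variant_id")
    variant_cols = [c for c in dos.columns if c != "sample_id"]
    unmapped = [v for v in variant_cols if v not in vmap.index]
    if unmapped:
        raise ValueError(f"variants {unmapped[:10]} missing from the variant map")
    calls = dos[variant_cols].to_numpy(dtype=float)
    return GenotypeMatrix(samples=dos["sample_id"].tolist(),
                          variants=vmap.loc[variant_cols], calls=calls)


def read_vcf_genotypes(vcf_path, variant_map_path) -> GenotypeMatrix:
    """Read GT dosages from a (possibly uncompressed) VCF.

    Variant ids are taken from the VCF ID column (falling back to
    chrom:pos:ref:alt) and must appear in the variant map.
    """
    from cyvcf2 import VCF

    vmap = pd.read_csv(variant_map_path, sep="\t", comment="#").set_index("variant_id")
    vcf = VCF(str(vcf_path))
    samples = list(vcf.samples)
    ids, rows = [], []
    for rec in vcf:
        vid = rec.ID or f"{rec.CHROM}:{rec.POS}:{rec.REF}:{rec.ALT[0] if rec.ALT else '.'}"
        if vid not in vmap.index:
            raise ValueError(f"{vcf_path}: variant {vid} missing from the variant map")
        # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        gt = rec.gt_types
        dosage = np.select([gt == 0, gt == 1, gt == 3], [0.0, 1.0, 2.0], default=np.nan)
        ids.append(vid)
        rows.append(dosage)
    calls = np.column_stack(rows) if rows else np.empty((len(samples), 0))
    return GenotypeMatrix(samples=samples, variants=vmap.loc[ids], calls=calls)


def read_exons(path):
    """Read exon structures: gene, strand, exon_start, exon_end per row, rows
    in transcription order within each gene."""
    from .burden import ExonStructure

    df = pd.read_csv(path, sep="\t", comment="#")
    for col in ("gene", "strand", "exon_start", "exon_end"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    out = {}
    for gene, grp in df.groupby("gene", sort=False):
        strands = grp["strand"].unique()
        if len(strands) != 1:
            raise ValueError(f"{path}: gene {gene} has inconsistent strands")
        out[gene] = ExonStructure(
            gene=gene, strand=strands[0],
            exons=tuple(zip(grp["exon_start"].astype(int), grp["exon_end"].astype(int))),
        )
    return out


def read_pedigrees(path) -> list[Pedigree]:
    """Read pedigrees: pedigree_id, member_id, is_proband, relationship,
    disease, age, genotype (genotype given on the proband row, NA elsewhere).

    Relationship is one of self/first_degree/second_degree/unrelated and is
    converted to a kinship coefficient; relatives' genotypes are rejected.
    """
    df = pd.read_csv(path, sep="\t", comment="#", na_values=[NA_TOKEN])
    required = ["pedigree_id", "member_id", "is_proband", "relationship",
                "disease", "age", "genotype"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    pedigrees = []
    for pid, grp in df.groupby("pedigree_id", sort=False):
        probands = grp[grp["is_proband"] == 1]
        if len(probands) != 1:
            raise ValueError(f"{path}: pedigree {pid} must have exactly one proband")
        non_proband_geno = grp[(grp["is_proband"] != 1) & grp["genotype"].notna()]
        if len(non_proband_geno):
            raise ValueError(
                f"{path}: pedigree {pid} has genotypes on relatives; only the "
                "proband is genotyped in this test (relative genotypes are out "
                "of scope)"
            )
        ordered = pd.concat([probands, grp[grp["is_proband"] != 1]])
        geno = probands["genotype"].iloc[0]
        pedigrees.append(Pedigree(
            pedigree_id=str(pid),
            proband_genotype=None if pd.isna(geno) else int(geno),
            disease=ordered["disease"].to_numpy(float),
            age=ordered["age"].to_numpy(float),
            kinship=np.array([kinship_weight(r) / 2.0 for r in ordered["relationship"]]),
            members=[str(m) for m in ordered["member_id"]],
        ))
    return pedigrees


def read_incidence(path) -> IncidenceModel:
    """Read a two-column age-band cumulative-hazard table
    (age_band_start, cumulative_hazard)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    for col in ("age_band_start", "cumulative_hazard"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    return IncidenceModel(df["age_band_start"].to_numpy(float),
                          df["cumulative_hazard"].to_numpy(float))


def write_table(df: pd.DataFrame, path, header_meta: dict | None = None) -> None:
    """Write a TSV with a '#'-comment reproducibility header."""
    from . import __version__

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# fhburden {__version__}\n")
        for key, value in (header_meta or {}).items():
            fh.write(f"# {key}: {value}\n")
        df.to_csv(fh, sep="\t", index=False, na_rep=NA_TOKEN)
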
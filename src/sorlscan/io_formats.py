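"""Readers and writers for every external format the pipeline touches.

All tabular formats are tab-separated text with fixed, documented headers:

``samples.tsv``
    sample_id, ancestry, phenotype, sex, age_years, aao_years,
    family_history, PC1..PC10.  ``aao_years`` may be ``NA``.
``annotation.tsv``
    variant_key, rsid, gene, consequence_class, protein_change, cadd,
    clinvar_class, imputation_r2, plus one ``af_<ANCESTRY>`` column per
    ancestry with a reference (gnomAD-style) allele frequency.  Missing
    frequencies and R2 are ``NA``.
``*.related``
    id1, id2, kinship.  Duplicate unordered pairs collapse to the maximum
    kinship.
``sumstats.tsv``
    variant_key, beta, se, p, n, maf.

Genotypes travel as VCF v4.2 (read through pysam; written as plain text),
pedigrees as PLINK PED/FAM with 1/2 sex codes and -9 for missing phenotype.
"""

from __future__ import annotations

import math
import re
from collections import OrderedDict

import numpy as np
import pandas as pd
import pysam

from sorlscan.types import (
    ANCESTRIES,
    CONSEQUENCE_CLASSES,
    Family,
    GenotypeMatrix,
    KinshipPair,
    PedigreeMember,
    SampleRecord,
    SummaryStat,
    VariantAnnotation,
    parse_variant_key,
)


class FormatError(ValueError):
    """A file failed structural validation."""


_ALLELE_RE = re.compile(r"^(?:[ACGT]+|-)$")


def _strip_chr(chrom: str) -> str:
    return chrom[3:] if chrom.lower().startswith("chr") else chrom


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def _prevalidate_vcf(path: str) -> None:
    # pysam reports no line numbers, so structural errors are caught in a
    # cheap text pre-scan before handing the file to htslib.
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("##fileformat=VCF"):
            raise FormatError(f"{path}, line 1: missing ##fileformat header")
        saw_columns = False
        for lineno, line in enumerate(fh, start=2):
            if line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                saw_columns = True
                continue
            if not saw_columns:
                raise FormatError(f"{path}, line {lineno}: data before #CHROM header")
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 10:
                raise FormatError(f"{path}, line {lineno}: fewer than 10 columns")
            ref, alt = fields[3], fields[4]
            for allele in [ref] + alt.split(","):
                if not _ALLELE_RE.match(allele):
                    raise FormatError(
                        f"{path}, line {lineno}: allele {allele!r} is not ACGT or '-'"
                    )
        if not saw_columns:
            raise FormatError(f"{path}: no #CHROM column header")


def read_vcf(path: str):
    """Read a VCF v4.2 into a dosage matrix plus annotation stubs.

    Dosage is the per-sample count of the alternate allele; multi-allelic
    records split into one variant key per alternate.  ``./.`` genotypes are
    missing.  Returns ``(GenotypeMatrix, [VariantAnnotation stubs])`` where
    stubs carry only the key and rsID.
    """
    _prevalidate_vcf(path)
    vf = pysam.VariantFile(path)
    sample_ids = list(vf.header.samples)
    keys: list[str] = []
    stubs: list[VariantAnnotation] = []
    columns: list[np.ndarray] = []
    for rec in vf:
        chrom = _strip_chr(rec.chrom)
        alts = rec.alts or ()
        for ai, alt in enumerate(alts, start=1):
            key = f"{chrom}:{rec.pos}:{rec.ref}:{alt}"
            if key in set(keys):
                raise FormatError(f"{path}: duplicate variant key {key}")
            col = np.full(len(sample_ids), np.nan)
            for si, sample in enumerate(rec.samples.values()):
                gt = sample.get("GT")
                if gt is None or all(a is None for a in gt):
                    continue
                col[si] = float(sum(1 for a in gt if a == ai))
            keys.append(key)
            columns.append(col)
            stubs.append(
                VariantAnnotation(variant_key=key, rsid=rec.id or "", consequence_class="other")
            )
    dosages = (
        np.column_stack(columns) if columns else np.empty((len(sample_ids), 0))
    )
    return GenotypeMatrix(sample_ids, keys, dosages), stubs


def write_vcf(path: str, matrix: GenotypeMatrix) -> None:
    """Write a biallelic-per-row VCF v4.2 (one row per variant key)."""
    rows = []
    for j, key in enumerate(matrix.variant_keys):
        chrom, pos, ref, alt = parse_variant_key(key)
        gts = []
        for dose in matrix.dosages[:, j]:
            if np.isnan(dose):
                gts.append("./.")
            else:
                d = int(dose)
                gts.append({0: "0/0", 1: "0/1", 2: "1/1"}[d])
        rows.append((chrom, pos, ref, alt, gts))
    rows.sort(key=lambda r: (r[0], r[1], r[2], r[3]))
    chroms = OrderedDict((r[0], None) for r in rows)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in chroms:
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(matrix.sample_ids)
            + "\n"
        )
        for chrom, pos, ref, alt, gts in rows:
            fh.write(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\t.\t.\tGT\t" + "\t".join(gts) + "\n")


# ---------------------------------------------------------------------------
# PED / FAM
# ---------------------------------------------------------------------------

def read_ped(path: str, source: str = "core") -> list[Family]:
    """Read a whitespace-delimited 6+ column PLINK PED into Family records.

    A member is a founder iff both parent ids are ``0``.  A non-zero parent
    id must itself appear as a member of the same family.
    """
    by_family: "OrderedDict[str, list[PedigreeMember]]" = OrderedDict()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 6:
                raise FormatError(f"{path}, line {lineno}: expected >= 6 columns")
            fam, sid, father, mother, sex_s, pheno_s = fields[:6]
            try:
                sex = int(sex_s)
                pheno = int(pheno_s)
            except ValueError:
                raise FormatError(f"{path}, line {lineno}: non-integer sex/phenotype code")
            by_family.setdefault(fam, []).append(
                PedigreeMember(fam, sid, father, mother, sex, pheno)
            )
    families = []
    for fam, members in by_family.items():
        ids = {m.sample_id for m in members}
        for m in members:
            for parent in (m.father_id, m.mother_id):
                if parent != "0" and parent not in ids:
                    raise FormatError(
                        f"{path}: family {fam}: parent id {parent!r} of {m.sample_id} "
                        "is not a member"
                    )
        families.append(Family(fam, members, source=source))
    return families


def write_ped(path: str, families: list[Family]) -> None:
    with open(path, "w") as fh:
        for fam in families:
            for m in fam.members:
                fh.write(
                    f"{fam.family_id}\t{m.sample_id}\t{m.father_id}\t{m.mother_id}\t"
                    f"{m.sex}\t{m.phenotype_code}\n"
                )


# ---------------------------------------------------------------------------
# Tabular readers
# ---------------------------------------------------------------------------

def _require_columns(df: pd.DataFrame, required, path: str) -> None:
    for col in required:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")


def read_related_pairs(path: str) -> list[KinshipPair]:
    """Read an ``id1 <tab> id2 <tab> kinship`` file with header.

    Duplicate unordered pairs collapse keeping the maximum kinship.
    """
    df = pd.read_csv(path, sep="\t", dtype={"id1": str, "id2": str}, float_precision="round_trip")
    _require_columns(df, ("id1", "id2", "kinship"), path)
    best: dict[tuple[str, str], float] = {}
    for row in df.itertuples(index=False):
        if row.kinship < 0:
            raise FormatError(f"{path}: negative kinship {row.kinship} for {row.id1}-{row.id2}")
        pair = KinshipPair(row.id1, row.id2, float(row.kinship))
        if pair.key not in best or pair.kinship > best[pair.key]:
            best[pair.key] = pair.kinship
    return [KinshipPair(a, b, k) for (a, b), k in sorted(best.items())]


def write_related_pairs(path: str, pairs: list[KinshipPair]) -> None:
    with open(path, "w") as fh:
        fh.write("id1\tid2\tkinship\n")
        for p in pairs:
            fh.write(f"{p.id1}\t{p.id2}\t{p.kinship:.17g}\n")


_SAMPLE_COLS = ("sample_id", "ancestry", "phenotype", "sex", "age_years", "aao_years", "family_history")
_PC_COLS = tuple(f"PC{i}" for i in range(1, 11))


def read_samples(path: str) -> list[SampleRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str}, float_precision="round_trip")
    _require_columns(df, _SAMPLE_COLS + _PC_COLS, path)
    records = []
    for row in df.itertuples(index=False):
        aao = None if pd.isna(row.aao_years) else float(row.aao_years)
        pcs = tuple(getattr(row, c) for c in _PC_COLS)
        try:
            records.append(
                SampleRecord(
                    sample_id=row.sample_id,
                    ancestry=row.ancestry,
                    phenotype=row.phenotype,
                    sex=int(row.sex),
                    age_years=float(row.age_years),
                    aao_years=aao,
                    family_history=row.family_history,
                    pcs=pcs,
                )
            )
        except ValueError as exc:
            raise FormatError(f"{path}: {exc}") from exc
    return records


def write_samples(path: str, samples: list[SampleRecord]) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_SAMPLE_COLS + _PC_COLS) + "\n")
        for s in samples:
            aao = "NA" if s.aao_years is None else f"{s.aao_years:.17g}"
            pcs = "\t".join(f"{x:.17g}" for x in s.pcs)
            fh.write(
                f"{s.sample_id}\t{s.ancestry}\t{s.phenotype}\t{s.sex}\t"
                f"{s.age_years:.17g}\t{aao}\t{s.family_history}\t{pcs}\n"
            )


_ANNOT_COLS = (
    "variant_key",
    "rsid",
    "gene",
    "consequence_class",
    "protein_change",
    "cadd",
    "clinvar_class",
    "imputation_r2",
)


def read_annotation_table(path: str) -> list[VariantAnnotation]:
    df = pd.read_csv(path, sep="\t", dtype={"variant_key": str}, float_precision="round_trip")
    _require_columns(df, _ANNOT_COLS, path)
    af_cols = {}
    for col in df.columns:
        if col.startswith("af_"):
            anc = col[3:]
            if anc not in ANCESTRIES:
                raise FormatError(f"{path}: allele-frequency column for unknown ancestry {anc!r}")
            af_cols[anc] = col
    records = []
    for row in df.itertuples(index=False):
        afs = {}
        for anc, col in af_cols.items():
            val = getattr(row, col)
            if not pd.isna(val):
                afs[anc] = float(val)
        r2 = None if pd.isna(row.imputation_r2) else float(row.imputation_r2)
        try:
            records.append(
                VariantAnnotation(
                    variant_key=row.variant_key,
                    rsid="" if pd.isna(row.rsid) else str(row.rsid),
                    gene="" if pd.isna(row.gene) else str(row.gene),
                    consequence_class=row.consequence_class,
                    protein_change="" if pd.isna(row.protein_change) else str(row.protein_change),
                    cadd=float(row.cadd),
                    ref_af_by_ancestry=afs,
                    clinvar_class="" if pd.isna(row.clinvar_class) else str(row.clinvar_class),
                    imputation_r2=r2,
                )
            )
        except ValueError as exc:
            raise FormatError(f"{path}: {exc}") from exc
    return records


def write_annotation_table(path: str, annotations: list[VariantAnnotation]) -> None:
    ancestries = sorted({a for ann in annotations for a in ann.ref_af_by_ancestry})
    af_cols = [f"af_{a}" for a in ancestries]
    with open(path, "w") as fh:
        fh.write("\t".join(_ANNOT_COLS + tuple(af_cols)) + "\n")
        for ann in annotations:
            r2 = "NA" if ann.imputation_r2 is None else f"{ann.imputation_r2:.17g}"
            afs = "\t".join(
                f"{ann.ref_af_by_ancestry[a]:.17g}" if a in ann.ref_af_by_ancestry else "NA"
                for a in ancestries
            )
            row = (
                f"{ann.variant_key}\t{ann.rsid}\t{ann.gene}\t{ann.consequence_class}\t"
                f"{ann.protein_change}\t{ann.cadd:.17g}\t{ann.clinvar_class}\t{r2}"
            )
            fh.write(row + ("\t" + afs if afs else "") + "\n")


def read_summary_stats(path: str) -> list[SummaryStat]:
    df = pd.read_csv(path, sep="\t", dtype={"variant_key": str}, float_precision="round_trip")
    _require_columns(df, ("variant_key", "beta", "se", "p", "n"), path)
    records = []
    for row in df.itertuples(index=False):
        maf = None
        if "maf" in df.columns and not pd.isna(row.maf):
            maf = float(row.maf)
        try:
            records.append(
                SummaryStat(
                    variant_key=row.variant_key,
                    beta=float(row.beta),
                    se=float(row.se),
                    p=float(row.p),
                    n=int(row.n),
                    maf=maf,
                )
            )
        except ValueError as exc:
            raise FormatError(f"{path}: {exc}") from exc
    return records


def write_summary_stats(path: str, stats: list[SummaryStat]) -> None:
    with open(path, "w") as fh:
        fh.write("variant_key\tbeta\tse\tp\tn\tmaf\n")
        for s in stats:
            maf = "NA" if s.maf is None else f"{s.maf:.17g}"
            fh.write(f"{s.variant_key}\t{s.beta:.17g}\t{s.se:.17g}\t{s.p:.17g}\t{s.n}\t{maf}\n")
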
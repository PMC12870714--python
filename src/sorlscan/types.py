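"""Core domain types shared by every pipeline stage.

Variant keys are ``chrom:pos:ref:alt`` strings (GRCh38, 1-based, no ``chr``
prefix); a deletion allele may be written ``-`` and is preserved verbatim.
Genotypes are alternate-allele dosages in {0, 1, 2} with NaN for missing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

#: Closed set of genetically-determined ancestry labels.
ANCESTRIES = frozenset(
    {"EUR", "AFR", "AMR", "AAC", "AJ", "CAS", "EAS", "SAS", "MDE", "FIN", "CAH"}
)

#: Phenotype groups: Alzheimer's disease, related dementias, Parkinson's
#: disease, dementia with Lewy bodies, and unaffected controls.
PHENOTYPES = frozenset({"AD", "RD", "PD", "DLB", "control"})

#: Closed set of functional consequence classes consumed from annotation.
CONSEQUENCE_CLASSES = frozenset(
    {
        "missense",
        "stopgain",
        "stoploss",
        "frameshift",
        "inframe_indel",
        "splicing",
        "synonymous",
        "other",
    }
)

#: Protein-altering consequences (splicing is tracked as its own class).
PROTEIN_ALTERING_CLASSES = frozenset(
    {"missense", "stopgain", "stoploss", "frameshift", "inframe_indel"}
)

#: Loss-of-function consequences.
LOF_CLASSES = frozenset({"stopgain", "frameshift", "splicing"})


def parse_variant_key(key: str) -> tuple[str, int, str, str]:
    """Split ``chrom:pos:ref:alt`` and validate the position.

    Raises ``ValueError`` on malformed keys or non-positive positions.
    """
    parts = key.split(":")
    if len(parts) != 4:
        raise ValueError(f"malformed variant key {key!r}: expected chrom:pos:ref:alt")
    chrom, pos_s, ref, alt = parts
    try:
        pos = int(pos_s)
    except ValueError:
        raise ValueError(f"malformed variant key {key!r}: position {pos_s!r} not an integer")
    if pos <= 0:
        raise ValueError(f"malformed variant key {key!r}: position must be positive")
    if not ref or not alt:
        raise ValueError(f"malformed variant key {key!r}: empty allele")
    return chrom, pos, ref, alt


class GenotypeMatrix:
    """Samples x variants alternate-allele dosage matrix.

    Dosages are stored as float64 with values in {0, 1, 2} and NaN for
    missing genotypes.  Missing genotypes are excluded from denominators
    everywhere downstream, never imputed (the SKAT kernel, which needs a
    rectangular matrix, mean-imputes internally and documents it).
    """

    def __init__(self, sample_ids, variant_keys, dosages):
        sample_ids = list(sample_ids)
        variant_keys = list(variant_keys)
        dosages = np.asarray(dosages, dtype=float)
        if len(set(sample_ids)) != len(sample_ids):
            raise ValueError("sample_ids must be unique")
        if len(set(variant_keys)) != len(variant_keys):
            raise ValueError("variant_keys must be unique")
        if dosages.shape != (len(sample_ids), len(variant_keys)):
            raise ValueError(
                f"dosage shape {dosages.shape} does not match "
                f"{len(sample_ids)} samples x {len(variant_keys)} variants"
            )
        valid = np.isnan(dosages) | np.isin(dosages, (0.0, 1.0, 2.0))
        if not valid.all():
            bad = dosages[~valid][0]
            raise ValueError(f"dosage {bad!r} outside {{0, 1, 2, missing}}")
        for key in variant_keys:
            parse_variant_key(key)
        self.sample_ids = sample_ids
        self.variant_keys = variant_keys
        self.dosages = dosages
        self._sample_index = {s: i for i, s in enumerate(sample_ids)}
        self._variant_index = {v: j for j, v in enumerate(variant_keys)}

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variant_keys)

    def sample_indices(self, sample_ids) -> np.ndarray:
        missing = [s for s in sample_ids if s not in self._sample_index]
        if missing:
            raise KeyError(f"samples not in matrix: {missing[:5]}")
        return np.array([self._sample_index[s] for s in sample_ids], dtype=int)

    def variant_column(self, key: str) -> np.ndarray:
        return self.dosages[:, self._variant_index[key]]

    def subset_samples(self, sample_ids) -> "GenotypeMatrix":
        idx = self.sample_indices(sample_ids)
        return GenotypeMatrix(list(sample_ids), self.variant_keys, self.dosages[idx])

    def subset_variants(self, variant_keys) -> "GenotypeMatrix":
        idx = [self._variant_index[v] for v in variant_keys]
        return GenotypeMatrix(self.sample_ids, list(variant_keys), self.dosages[:, idx])

    def __eq__(self, other) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.sample_ids == other.sample_ids
            and self.variant_keys == other.variant_keys
            and np.array_equal(self.dosages, other.dosages, equal_nan=True)
        )

    def __repr__(self) -> str:
        return f"GenotypeMatrix({self.n_samples} samples x {self.n_variants} variants)"


@dataclass
class VariantAnnotation:
    """Per-variant functional annotation consumed (not computed) by the pipeline."""

    variant_key: str
    gene: str = ""
    rsid: str = ""
    consequence_class: str = "other"
    protein_change: str = ""
    cadd: float = 0.0
    ref_af_by_ancestry: dict = field(default_factory=dict)
    clinvar_class: str = ""
    imputation_r2: float | None = None

    def __post_init__(self):
        parse_variant_key(self.variant_key)
        if self.consequence_class not in CONSEQUENCE_CLASSES:
            raise ValueError(
                f"{self.variant_key}: consequence {self.consequence_class!r} not in "
                f"{sorted(CONSEQUENCE_CLASSES)}"
            )
        if self.cadd < 0:
            raise ValueError(f"{self.variant_key}: CADD must be >= 0, got {self.cadd}")
        for anc, af in self.ref_af_by_ancestry.items():
            if anc not in ANCESTRIES:
                raise ValueError(f"{self.variant_key}: unknown ancestry {anc!r}")
            if not (0.0 <= af <= 1.0):
                raise ValueError(f"{self.variant_key}: reference AF {af} outside [0, 1]")
        if self.imputation_r2 is not None and not (0.0 <= self.imputation_r2 <= 1.0):
            raise ValueError(f"{self.variant_key}: imputation R2 {self.imputation_r2} outside [0, 1]")


@dataclass
class SampleRecord:
    """Phenotype, ancestry, and covariates for one individual.

    ``sex`` uses PLINK coding (1 = male, 2 = female).  ``pcs`` holds exactly
    ten principal components.
    """

    sample_id: str
    ancestry: str
    phenotype: str
    sex: int
    age_years: float
    aao_years: float | None = None
    family_history: str = "unknown"
    pcs: tuple = field(default_factory=lambda: (0.0,) * 10)

    def __post_init__(self):
        if self.ancestry not in ANCESTRIES:
            raise ValueError(f"{self.sample_id}: unknown ancestry label {self.ancestry!r}")
        if self.phenotype not in PHENOTYPES:
            raise ValueError(f"{self.sample_id}: unknown phenotype {self.phenotype!r}")
        if self.family_history not in ("yes", "no", "unknown"):
            raise ValueError(f"{self.sample_id}: family_history must be yes/no/unknown")
        self.pcs = tuple(float(x) for x in self.pcs)
        if len(self.pcs) != 10:
            raise ValueError(f"{self.sample_id}: expected 10 PCs, got {len(self.pcs)}")

    @property
    def is_case(self) -> bool:
        return self.phenotype != "control"


@dataclass(frozen=True)
class KinshipPair:
    """Unordered pair of individuals with a kinship coefficient.

    0.0884 is the conventional second-degree relatedness cutoff; pairs are
    stored once with ``id1 < id2`` lexicographically.
    """

    id1: str
    id2: str
    kinship: float

    def __post_init__(self):
        if self.id1 == self.id2:
            raise ValueError(f"kinship pair with identical ids {self.id1!r}")
        if self.kinship < 0:
            raise ValueError(f"negative kinship {self.kinship} for {self.id1}-{self.id2}")
        if not math.isfinite(self.kinship):
            raise ValueError(f"non-finite kinship for {self.id1}-{self.id2}")
        if self.id1 > self.id2:
            first, second = self.id2, self.id1
            object.__setattr__(self, "id1", first)
            object.__setattr__(self, "id2", second)

    @property
    def key(self) -> tuple[str, str]:
        return (self.id1, self.id2)


@dataclass
class PedigreeMember:
    """One row of a PLINK PED/FAM pedigree."""

    family_id: str
    sample_id: str
    father_id: str = "0"
    mother_id: str = "0"
    sex: int = 0
    phenotype_code: int = -9

    @property
    def is_founder(self) -> bool:
        return self.father_id == "0" and self.mother_id == "0"


@dataclass
class Family:
    """A pedigree: either a core (curated) or kinship-inferred family."""

    family_id: str
    members: list  # of PedigreeMember
    source: str = "core"  # core | inferred
    ancestry: str | None = None

    def __post_init__(self):
        if self.source not in ("core", "inferred"):
            raise ValueError(f"family {self.family_id}: source must be core or inferred")
        ids = [m.sample_id for m in self.members]
        if len(set(ids)) != len(ids):
            raise ValueError(f"family {self.family_id}: duplicate member ids")
        if self.source == "inferred" and len(ids) < 2:
            raise ValueError(f"inferred family {self.family_id} must have >= 2 members")

    @property
    def member_ids(self) -> list:
        return [m.sample_id for m in self.members]

    @property
    def n_founders(self) -> int:
        return sum(m.is_founder for m in self.members)


@dataclass
class SummaryStat:
    """One GWAS summary-statistic row: marginal effect on the log-odds scale."""

    variant_key: str
    beta: float
    se: float
    p: float
    n: int
    maf: float | None = None

    def __post_init__(self):
        parse_variant_key(self.variant_key)
        if not (self.se > 0) or not math.isfinite(self.se):
            raise ValueError(f"{self.variant_key}: se must be positive and finite, got {self.se}")
        if not math.isfinite(self.beta):
            raise ValueError(f"{self.variant_key}: non-finite beta")
        if not (0 < self.p <= 1):
            raise ValueError(f"{self.variant_key}: p {self.p} outside (0, 1]")
        if self.maf is not None and not (0 < self.maf <= 0.5):
            raise ValueError(f"{self.variant_key}: maf {self.maf} outside (0, 0.5]")

    @property
    def z(self) -> float:
        return self.beta / self.se
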
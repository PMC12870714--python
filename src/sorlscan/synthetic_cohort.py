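"""Synthetic cohorts with the structure every downstream stage assumes.

The generator emulates, per ancestry stratum, the inputs of a single-gene
case-control and family study:

* background variants in Hardy-Weinberg proportions at phenotype-independent
  allele frequencies (common and benign, so they fall out of the
  prioritization cascade);
* planted case-only damaging variants with a fixed heterozygote count in
  cases and zero alternate alleles in controls;
* planted association variants drawn from an additive logistic model with a
  stated per-allele odds ratio (covariates carry null effects);
* families whose members share kinship above the second-degree cutoff, each
  optionally carrying one rare damaging variant heterozygous in every
  affected member and absent from family controls, and optionally a
  co-planted pathogenic variant in a known Parkinson's-disease gene;
* a summary-statistic region with at most one causal signal.

Covariate distributions: sex ~ Bernoulli(0.5) (PLINK 1/2 coding),
age ~ Normal(65, 10) truncated at 18, PCs ~ Normal(0, 1).  Default cohort
sizes mirror a large sequencing case-control stratum (5,812 cases and
4,411 controls of European ancestry) and the default planted case-only
variant carries 3 heterozygotes at CADD 27.3.  Everything is deterministic
under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from sorlscan.types import (
    Family,
    GenotypeMatrix,
    KinshipPair,
    PedigreeMember,
    SampleRecord,
    SummaryStat,
    VariantAnnotation,
)

#: Start of the simulated gene region (GRCh38 chr11:121.45-121.63 Mb).
REGION_CHROM = "11"
REGION_START = 121_450_000
REGION_END = 121_630_000

#: Synthetic stand-in for a pathogenic variant in a known PD gene
#: (GBA1-like), co-planted in families on request.
KNOWN_PD_VARIANT = "1:155235252:T:C"


class ConfigError(ValueError):
    """A simulation configuration is internally inconsistent."""


@dataclass
class PlantedCaseOnly:
    consequence_class: str = "missense"
    cadd: float = 27.3
    case_het_count: int = 3


@dataclass
class PlantedAssoc:
    maf: float = 0.1
    odds_ratio: float = 2.0


@dataclass
class PlantedFamily:
    n_members: int = 2
    n_pd_cases: int = 2
    segregating: bool = True
    extra_known_pd_variant: bool = False


@dataclass
class RegionSpec:
    n_snps: int = 200
    causal_index: int = 0
    causal_beta: float = 0.02
    n: int = 440_683
    maf_range: tuple = (0.05, 0.5)


@dataclass
class SimulationConfig:
    seed: int = 0
    ancestry: str = "EUR"
    phenotype: str = "AD"
    n_cases: int = 5812
    n_controls: int = 4411
    n_background_variants: int = 500
    background_maf_range: tuple = (0.01, 0.30)
    planted_caseonly: list = field(default_factory=lambda: [PlantedCaseOnly()])
    planted_assoc: list = field(default_factory=list)
    planted_families: list = field(
        # The three segregation patterns of interest: an affected sib pair
        # co-carrying a known-PD-gene variant, a parent-child duo, and
        # three affected siblings.
        default_factory=lambda: [
            PlantedFamily(2, 2, True, True),
            PlantedFamily(2, 2, True, False),
            PlantedFamily(3, 3, True, False),
        ]
    )
    region_spec: RegionSpec = field(default_factory=RegionSpec)
    ld_rho: float = 0.0  # optional AR(1) genotype correlation for stress tests

    def __post_init__(self):
        if self.n_cases < 0 or self.n_controls < 0 or self.n_background_variants < 0:
            raise ConfigError("counts must be non-negative")
        for p in self.planted_assoc:
            if p.odds_ratio <= 0:
                raise ConfigError(f"odds ratio must be positive, got {p.odds_ratio}")
        for p in self.planted_caseonly:
            if p.case_het_count > self.n_cases:
                raise ConfigError(
                    f"planted het count {p.case_het_count} exceeds n_cases {self.n_cases}"
                )
        for f in self.planted_families:
            if f.n_pd_cases > f.n_members:
                raise ConfigError(
                    f"family has {f.n_pd_cases} PD cases but only {f.n_members} members"
                )
        if not 0 <= self.ld_rho < 1:
            raise ConfigError("ld_rho must be in [0, 1)")


def _covariates(rng: np.random.Generator, n: int):
    sex = rng.integers(1, 3, size=n)  # 1 male / 2 female with equal probability
    age = rng.normal(65.0, 10.0, size=n)
    while True:  # truncate at 18 by redrawing
        low = age < 18.0
        if not low.any():
            break
        age[low] = rng.normal(65.0, 10.0, size=int(low.sum()))
    pcs = rng.normal(0.0, 1.0, size=(n, 10))
    return sex, age, pcs


def _background_genotypes(rng, n, mafs, ld_rho):
    """Hardy-Weinberg genotypes; optional AR(1) correlation across variants."""
    m = len(mafs)
    if ld_rho == 0.0:
        return rng.binomial(2, mafs[None, :], size=(n, m)).astype(float)
    # Gaussian-copula haplotypes with AR(1) correlation, thresholded at the
    # allele frequency, summed over two haplotypes.
    geno = np.zeros((n, m))
    thresh = stats.norm.ppf(mafs)
    for _ in range(2):
        z = rng.normal(size=(n, m))
        for j in range(1, m):
            z[:, j] = ld_rho * z[:, j - 1] + np.sqrt(1 - ld_rho**2) * z[:, j]
        geno += (z < thresh[None, :]).astype(float)
    return geno


def _tilted_af(maf: float, odds_ratio: float) -> float:
    # Exponential tilting of Binomial(2, maf) by a per-allele odds ratio:
    # under an additive logistic model the case genotype distribution is
    # again Hardy-Weinberg at this frequency.
    return maf * odds_ratio / (1.0 - maf + maf * odds_ratio)


def simulate_case_control(config: SimulationConfig):
    """Generate one case-control stratum.

    Returns ``(GenotypeMatrix, [SampleRecord], [VariantAnnotation])`` with
    cases first.  Background variants are phenotype-independent; planted
    case-only variants have exactly the configured heterozygote count in
    cases and no alternate alleles in controls; planted association
    variants follow an additive logistic model with the configured
    per-allele odds ratio.
    """
    rng = np.random.default_rng([config.seed, 1])
    n_ca, n_co = config.n_cases, config.n_controls
    n = n_ca + n_co
    sample_ids = [f"{config.ancestry}_case_{i}" for i in range(n_ca)] + [
        f"{config.ancestry}_ctrl_{i}" for i in range(n_co)
    ]
    sex, age, pcs = _covariates(rng, n)
    aao = np.where(
        np.arange(n) < n_ca, rng.normal(68.0, 10.0, size=n), np.nan
    )
    fh_codes = rng.choice(["yes", "no", "unknown"], size=n, p=[0.3, 0.5, 0.2])
    samples = [
        SampleRecord(
            sample_id=sample_ids[i],
            ancestry=config.ancestry,
            phenotype=config.phenotype if i < n_ca else "control",
            sex=int(sex[i]),
            age_years=float(age[i]),
            aao_years=float(aao[i]) if i < n_ca else None,
            family_history=str(fh_codes[i]),
            pcs=tuple(pcs[i]),
        )
        for i in range(n)
    ]

    columns, keys, annots = [], [], []
    lo, hi = config.background_maf_range
    n_bg = config.n_background_variants
    positions = iter(
        sorted(
            rng.choice(
                np.arange(REGION_START, REGION_END),
                size=n_bg + len(config.planted_caseonly) + len(config.planted_assoc),
                replace=False,
            )
        )
    )
    bases = np.array(list("ACGT"))

    def next_key():
        pos = int(next(positions))
        ref, alt = rng.choice(bases, size=2, replace=False)
        return f"{REGION_CHROM}:{pos}:{ref}:{alt}"

    bg_mafs = rng.uniform(lo, hi, size=n_bg)
    bg = _background_genotypes(rng, n, bg_mafs, config.ld_rho)
    for j in range(n_bg):
        key = next_key()
        keys.append(key)
        columns.append(bg[:, j])
        cls = "synonymous" if rng.random() < 0.5 else "missense"
        annots.append(
            VariantAnnotation(
                variant_key=key,
                gene="SORL1",
                rsid=f"rs9{j:06d}",
                consequence_class=cls,
                cadd=float(rng.uniform(0.0, 15.0)),  # benign background
                ref_af_by_ancestry={config.ancestry: float(bg_mafs[j])},
            )
        )

    for k, plant in enumerate(config.planted_caseonly):
        key = next_key()
        col = np.zeros(n)
        carriers = rng.choice(n_ca, size=plant.case_het_count, replace=False)
        col[carriers] = 1.0
        keys.append(key)
        columns.append(col)
        annots.append(
            VariantAnnotation(
                variant_key=key,
                gene="SORL1",
                rsid=f"rs8{k:06d}",
                consequence_class=plant.consequence_class,
                protein_change=f"p.X{k}",
                cadd=plant.cadd,
                ref_af_by_ancestry={config.ancestry: 1e-5},
            )
        )

    for k, plant in enumerate(config.planted_assoc):
        key = next_key()
        af_case = _tilted_af(plant.maf, plant.odds_ratio)
        col = np.concatenate(
            [
                rng.binomial(2, af_case, size=n_ca),
                rng.binomial(2, plant.maf, size=n_co),
            ]
        ).astype(float)
        keys.append(key)
        columns.append(col)
        annots.append(
            VariantAnnotation(
                variant_key=key,
                gene="SORL1",
                rsid=f"rs7{k:06d}",
                consequence_class="missense",
                protein_change=f"p.A{k}",
                cadd=float(rng.uniform(20.5, 35.0)),
                ref_af_by_ancestry={config.ancestry: plant.maf},
            )
        )

    order = np.argsort([int(k.split(":")[1]) for k in keys])
    keys = [keys[i] for i in order]
    columns = [columns[i] for i in order]
    annots = [annots[i] for i in order]
    dosages = np.column_stack(columns) if columns else np.empty((n, 0))
    return GenotypeMatrix(sample_ids, keys, dosages), samples, annots


def simulate_families(config: SimulationConfig):
    """Generate planted families with segregating candidate variants.

    Returns ``(families, matrix, samples, annotations, pairs, truth)``:
    one pedigree per :class:`PlantedFamily` (all members founders), a
    genotype matrix over the family members with one candidate variant per
    family plus the optional known-PD-gene variant, kinship pairs above the
    second-degree cutoff among members, and a ``truth`` dict mapping
    family_id -> candidate variant key for segregating families.
    """
    rng = np.random.default_rng([config.seed, 2])
    families, samples, pairs = [], [], []
    keys, annots, columns_by_key = [], [], {}
    member_ids = []
    positions = iter(
        sorted(
            rng.choice(
                np.arange(REGION_START, REGION_END),
                size=len(config.planted_families),
                replace=False,
            )
        )
    )
    bases = np.array(list("ACGT"))
    truth = {}
    any_known = any(f.extra_known_pd_variant for f in config.planted_families)
    plan = []
    for fi, fam_spec in enumerate(config.planted_families):
        fam_id = f"FAM{fi:03d}"
        ids = [f"{fam_id}_M{j}" for j in range(fam_spec.n_members)]
        member_ids.extend(ids)
        sex, age, pcs = _covariates(rng, fam_spec.n_members)
        members = []
        for j, sid in enumerate(ids):
            is_pd = j < fam_spec.n_pd_cases
            members.append(
                PedigreeMember(fam_id, sid, "0", "0", int(sex[j]), 2 if is_pd else 1)
            )
            samples.append(
                SampleRecord(
                    sample_id=sid,
                    ancestry=config.ancestry,
                    phenotype="PD" if is_pd else "control",
                    sex=int(sex[j]),
                    age_years=float(age[j]),
                    aao_years=float(rng.normal(55.0, 12.0)) if is_pd else None,
                    family_history="yes",
                    pcs=tuple(pcs[j]),
                )
            )
        families.append(Family(fam_id, members, source="inferred", ancestry=config.ancestry))
        for a in range(len(ids)):
            for b in range(a + 1, len(ids)):
                pairs.append(KinshipPair(ids[a], ids[b], 0.25))

        pos = int(next(positions))
        ref, alt = rng.choice(bases, size=2, replace=False)
        key = f"{REGION_CHROM}:{pos}:{ref}:{alt}"
        keys.append(key)
        annots.append(
            VariantAnnotation(
                variant_key=key,
                gene="SORL1",
                rsid=f"rs6{fi:06d}",
                consequence_class="missense",
                protein_change=f"p.F{fi}",
                cadd=float(rng.uniform(20.5, 35.0)),
                ref_af_by_ancestry={config.ancestry: 5e-4},
            )
        )
        plan.append((fam_spec, fam_id, ids, key))
        if fam_spec.segregating:
            truth[fam_id] = key

    if any_known:
        keys.append(KNOWN_PD_VARIANT)
        annots.append(
            VariantAnnotation(
                variant_key=KNOWN_PD_VARIANT,
                gene="GBA1",
                consequence_class="missense",
                protein_change="p.L483P",
                cadd=26.0,
                clinvar_class="pathogenic",
                ref_af_by_ancestry={config.ancestry: 1e-3},
            )
        )

    dosages = np.zeros((len(member_ids), len(keys)))
    matrix = GenotypeMatrix(member_ids, keys, dosages)
    for fam_spec, fam_id, ids, key in plan:
        idx = matrix.sample_indices(ids)
        pd_idx = idx[: fam_spec.n_pd_cases]
        j = matrix.variant_keys.index(key)
        if fam_spec.segregating:
            matrix.dosages[pd_idx, j] = 1.0
        else:
            # break segregation: either a missing affected carrier or a
            # carrier family control
            if fam_spec.n_pd_cases >= 2:
                matrix.dosages[pd_idx[:-1], j] = 1.0
            else:
                matrix.dosages[pd_idx, j] = 1.0
                if fam_spec.n_members > fam_spec.n_pd_cases:
                    matrix.dosages[idx[fam_spec.n_pd_cases], j] = 1.0
        if fam_spec.extra_known_pd_variant:
            jk = matrix.variant_keys.index(KNOWN_PD_VARIANT)
            matrix.dosages[pd_idx, jk] = 1.0
    return families, matrix, samples, annots, pairs, truth


def simulate_summary_region(config: SimulationConfig) -> list[SummaryStat]:
    """Generate one summary-statistic region with at most one causal SNP.

    Non-causal SNPs draw beta ~ Normal(0, se) with se = 1/sqrt(2 n maf
    (1-maf)); the causal SNP draws beta ~ Normal(causal_beta, se); p-values
    come from the two-sided Wald statistic.
    """
    spec = config.region_spec
    if spec.n_snps < 2:
        raise ConfigError("region needs at least 2 SNPs")
    if not 0 <= spec.causal_index < spec.n_snps:
        raise ConfigError(
            f"causal_index {spec.causal_index} out of range for {spec.n_snps} SNPs"
        )
    rng = np.random.default_rng([config.seed, 3])
    lo, hi = spec.maf_range
    mafs = rng.uniform(lo, hi, size=spec.n_snps)
    positions = np.sort(
        rng.choice(np.arange(REGION_START, REGION_END), size=spec.n_snps, replace=False)
    )
    bases = np.array(list("ACGT"))
    out = []
    for j in range(spec.n_snps):
        se = 1.0 / np.sqrt(2.0 * spec.n * mafs[j] * (1.0 - mafs[j]))
        mean = spec.causal_beta if j == spec.causal_index else 0.0
        beta = float(rng.normal(mean, se))
        z = beta / se
        p = float(min(1.0, max(2.0 * stats.norm.sf(abs(z)), 5e-324)))
        ref, alt = rng.choice(bases, size=2, replace=False)
        out.append(
            SummaryStat(
                variant_key=f"{REGION_CHROM}:{int(positions[j])}:{ref}:{alt}",
                beta=beta,
                se=float(se),
                p=p,
                n=spec.n,
                maf=float(mafs[j]),
            )
        )
    return out
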
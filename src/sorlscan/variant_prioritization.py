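"""Per-stratum allele statistics and the disease-causing-variant filter cascades.

Two cascades are implemented:

* the case-control track retains variants whose alternate allele is present
  only in cases, with a case minor-allele count (MAC) of at least 2, a CADD
  phred score strictly above 20, and a protein-altering or splicing
  consequence;
* the family track retains rare, predicted-damaging alleles:
  loss-of-function consequences regardless of CADD, plus missense with
  CADD > 20, restricted to an ancestry-specific reference allele frequency
  below 1%.

Missing genotypes are excluded from every denominator.  The MAC >= 2
threshold is counted among cases within the stratum (controls contribute
zero alternate alleles by the case-only rule).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from sorlscan.types import (
    ANCESTRIES,
    LOF_CLASSES,
    PROTEIN_ALTERING_CLASSES,
    GenotypeMatrix,
    VariantAnnotation,
)


@dataclass
class AlleleStats:
    """Alternate-allele statistics for one variant in one sample stratum."""

    variant_key: str
    stratum: str
    n_nonmissing: int
    mac: int
    af: float
    het_count: int
    hom_count: int

    def __post_init__(self):
        assert self.mac == self.het_count + 2 * self.hom_count
        assert 0.0 <= self.af <= 1.0

    @property
    def zygosity(self) -> str:
        """Rendered as in carrier tables, e.g. ``het (3), hom (0)``."""
        return f"het ({self.het_count}), hom ({self.hom_count})"


@dataclass
class FilterCriteria:
    """Thresholds of the two filter cascades (defaults are the study values)."""

    cadd_min: float = 20.0  # strict: CADD > 20
    mac_min: int = 2  # non-strict: MAC >= 2
    allowed_classes: frozenset = field(
        default_factory=lambda: PROTEIN_ALTERING_CLASSES | {"splicing"}
    )
    case_only: bool = True
    ref_af_max: float = 0.01  # family track: ancestry-specific AF < 1%

    def __post_init__(self):
        if self.cadd_min <= 0 or self.mac_min <= 0 or self.ref_af_max <= 0:
            raise ValueError("filter thresholds must be strictly positive")


@dataclass
class PrioritizedVariant:
    """A variant surviving a cascade, with the evidence it survived on."""

    variant_key: str
    annotation: VariantAnnotation
    case_stats: AlleleStats | None = None
    control_stats: AlleleStats | None = None
    status: str = ""  # novel | known (set by flag_known)


def sig3(x: float) -> str:
    """Scientific notation with 3 significant digits (table rendering)."""
    if x == 0:
        return "0"
    return f"{x:.2E}"


def compute_allele_stats(
    matrix: GenotypeMatrix, group: list, stratum: str = ""
) -> list[AlleleStats]:
    """Alternate-allele count/frequency/zygosity over a sample subset.

    Frequencies use ``mac / (2 * n_nonmissing)``; missing genotypes are
    dropped from the denominator.  Raises if ``group`` is empty or shares
    no sample with the matrix.
    """
    if not group:
        raise ValueError("sample group is empty")
    idx = matrix.sample_indices(group)
    sub = matrix.dosages[idx, :]
    out = []
    for j, key in enumerate(matrix.variant_keys):
        col = sub[:, j]
        obs = col[~np.isnan(col)]
        n_nm = obs.size
        het = int((obs == 1).sum())
        hom = int((obs == 2).sum())
        mac = het + 2 * hom
        af = mac / (2 * n_nm) if n_nm else 0.0
        out.append(AlleleStats(key, stratum, n_nm, mac, af, het, hom))
    return out


def filter_disease_causing(
    stats_cases: list[AlleleStats],
    stats_controls: list[AlleleStats],
    annotations: list[VariantAnnotation],
    criteria: FilterCriteria | None = None,
):
    """Case-control prioritization cascade.

    Retains variants with zero control alternate alleles, case MAC >=
    ``mac_min``, CADD strictly above ``cadd_min``, and a consequence in the
    allowed set.  Returns ``(retained, skipped)`` where ``skipped`` lists
    variant keys present in the statistics but absent from the annotation
    table (reported, never silently dropped).
    """
    criteria = criteria or FilterCriteria()
    ann_by_key = {a.variant_key: a for a in annotations}
    ctrl_by_key = {s.variant_key: s for s in stats_controls}
    retained, skipped = [], []
    for cs in stats_cases:
        ann = ann_by_key.get(cs.variant_key)
        if ann is None:
            skipped.append(cs.variant_key)
            continue
        ctrl = ctrl_by_key.get(cs.variant_key)
        if criteria.case_only and ctrl is not None and ctrl.mac > 0:
            continue
        if cs.mac < criteria.mac_min:
            continue
        if not (ann.cadd > criteria.cadd_min):
            continue
        if ann.consequence_class not in criteria.allowed_classes:
            continue
        retained.append(
            PrioritizedVariant(cs.variant_key, ann, case_stats=cs, control_stats=ctrl)
        )
    return retained, skipped


def filter_family_damaging(
    annotations: list[VariantAnnotation],
    ancestry: str,
    criteria: FilterCriteria | None = None,
    gene: str | None = None,
) -> list[VariantAnnotation]:
    """Family-track rare-damaging filter.

    Retains loss-of-function variants (stopgain, frameshift, splicing)
    regardless of CADD, plus missense with CADD > ``cadd_min``, all with an
    ancestry-specific reference allele frequency below ``ref_af_max``.  A
    missing reference frequency is treated as 0 (absent from the reference
    panel).  ``gene`` restricts candidates to the gene under analysis
    (co-screened variants in other genes are evidence, not candidates).
    """
    if ancestry not in ANCESTRIES:
        raise ValueError(f"unknown ancestry label {ancestry!r}")
    criteria = criteria or FilterCriteria()
    out = []
    for ann in annotations:
        if gene is not None and ann.gene != gene:
            continue
        damaging = ann.consequence_class in LOF_CLASSES or (
            ann.consequence_class == "missense" and ann.cadd > criteria.cadd_min
        )
        if not damaging:
            continue
        ref_af = ann.ref_af_by_ancestry.get(ancestry, 0.0)
        if ref_af >= criteria.ref_af_max:
            continue
        out.append(ann)
    return out


def flag_known(variants: list[PrioritizedVariant], known_keys) -> list[PrioritizedVariant]:
    """Label each variant ``known`` or ``novel`` by exact key membership."""
    known = set(known_keys)
    for v in variants:
        v.status = "known" if v.variant_key in known else "novel"
    return variants


def render_prioritization_report(variants: list[PrioritizedVariant], ancestry: str) -> str:
    """Tab-separated carrier-table report (one row per retained variant)."""
    header = (
        "variant\trsID\tprotein_change\tCADD\tcase_MAF\tzygosity\t"
        "ref_AF\tstatus\tR2"
    )
    lines = [header]
    for v in sorted(variants, key=lambda v: v.variant_key):
        ann = v.annotation
        ref_af = ann.ref_af_by_ancestry.get(ancestry)
        lines.append(
            "\t".join(
                [
                    v.variant_key,
                    ann.rsid or "NA",
                    ann.protein_change or "NA",
                    f"{ann.cadd:g}",
                    sig3(v.case_stats.af) if v.case_stats else "NA",
                    v.case_stats.zygosity if v.case_stats else "NA",
                    sig3(ref_af) if ref_af is not None else "NA",
                    v.status or "NA",
                    f"{ann.imputation_r2:g}" if ann.imputation_r2 is not None else "NA",
                ]
            )
        )
    return "\n".join(lines) + "\n"
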
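"""Kinship-graph pedigree reconstruction and family segregation analysis.

Families are reconstructed per ancestry from pairwise kinship estimates:
individuals with kinship strictly above the second-degree cutoff (0.0884)
form a graph whose connected components of two or more members each define
one family.  Relationship direction cannot be inferred from kinship values
alone, so every reconstructed member is represented as a founder.
Reconstructed families are merged with curated core pedigrees, informative
families (at least one Parkinson's-disease case and at least two members)
are selected, and candidate variants are prioritized when, in at least one
family, every genotyped affected member carries the alternate allele and no
genotyped family control does.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from sorlscan.types import (
    Family,
    GenotypeMatrix,
    KinshipPair,
    PedigreeMember,
    SampleRecord,
)

#: Conventional second-degree kinship cutoff.
KINSHIP_THRESHOLD = 0.0884


def infer_families(
    pairs: list[KinshipPair],
    threshold: float = KINSHIP_THRESHOLD,
    exclude: set | None = None,
    ancestry: str | None = None,
    prefix: str = "INF",
) -> list[Family]:
    """Connected components (>= 2 members) of the kinship graph.

    Edges require kinship strictly above ``threshold``; ids in ``exclude``
    (core-pedigree members) never enter the graph.  All members are marked
    founders.  Family ids are deterministic: components sorted by their
    lexicographically smallest member.
    """
    exclude = exclude or set()
    graph = nx.Graph()
    for p in pairs:
        if p.kinship > threshold and p.id1 not in exclude and p.id2 not in exclude:
            graph.add_edge(p.id1, p.id2)
    components = sorted(
        (sorted(c) for c in nx.connected_components(graph) if len(c) >= 2),
        key=lambda c: c[0],
    )
    families = []
    for i, comp in enumerate(components):
        members = [PedigreeMember(f"{prefix}{i:04d}", sid, "0", "0") for sid in comp]
        families.append(Family(f"{prefix}{i:04d}", members, source="inferred", ancestry=ancestry))
    return families


def merge_pedigrees(core: list[Family], inferred: list[Family]) -> list[Family]:
    """Union of core and kinship-inferred families.

    Membership must be disjoint (guaranteed upstream by excluding core
    members from the kinship graph); overlaps raise with the offending
    sample ids.  Family-id collisions are resolved by ``core:``/``inf:``
    namespacing.
    """
    core_ids = {m for f in core for m in f.member_ids}
    inf_ids = {m for f in inferred for m in f.member_ids}
    overlap = core_ids & inf_ids
    if overlap:
        raise ValueError(f"samples in both core and inferred families: {sorted(overlap)[:10]}")
    merged = []
    colliding = {f.family_id for f in core} & {f.family_id for f in inferred}
    for fam in list(core) + list(inferred):
        fid = fam.family_id
        if fid in colliding:
            fid = ("core:" if fam.source == "core" else "inf:") + fid
        merged.append(Family(fid, fam.members, source=fam.source, ancestry=fam.ancestry))
    return merged


def select_informative(families: list[Family], samples: list[SampleRecord]) -> list[Family]:
    """Families with at least one PD case and at least two members."""
    by_id = {s.sample_id: s for s in samples}
    out = []
    for fam in families:
        missing = [m for m in fam.member_ids if m not in by_id]
        if missing:
            raise ValueError(f"family {fam.family_id}: no sample record for {missing[:5]}")
        n_pd = sum(1 for m in fam.member_ids if by_id[m].phenotype == "PD")
        if n_pd >= 1 and len(fam.member_ids) >= 2:
            out.append(fam)
    return out


@dataclass
class SegregationSummary:
    """Carrier pattern of one candidate variant within one family."""

    variant_key: str
    family_id: str
    n_genotyped_pd: int
    n_pd_carriers: int
    n_genotyped_controls: int
    n_control_carriers: int
    zygosity: str  # Het / Hom / Het+Hom / none
    co_occurring_known_pd_variants: list = field(default_factory=list)

    def __post_init__(self):
        assert self.n_pd_carriers <= self.n_genotyped_pd
        assert self.n_control_carriers <= self.n_genotyped_controls

    @property
    def segregates(self) -> bool:
        """Present in all genotyped PD members, absent from genotyped controls."""
        return (
            self.n_genotyped_pd > 0
            and self.n_pd_carriers == self.n_genotyped_pd
            and self.n_control_carriers == 0
        )


def segregation_summary(
    family: Family,
    matrix: GenotypeMatrix,
    candidate_keys: list,
    samples: list[SampleRecord],
    known_pd_keys: list | None = None,
) -> list[SegregationSummary]:
    """Per-variant carrier summary within one family.

    A member missing the genotype at a candidate site is excluded from the
    genotyped counts (it neither vetoes nor supports segregation).  Any
    co-carried variant from ``known_pd_keys`` (a user-supplied pathogenic
    list for established PD genes) is attached to the summary.
    """
    by_id = {s.sample_id: s for s in samples}
    present = [m for m in fam_members(family) if m in matrix._sample_index]
    pd_ids = [m for m in present if by_id[m].phenotype == "PD"]
    ctrl_ids = [m for m in present if by_id[m].phenotype == "control"]
    known_pd_keys = [k for k in (known_pd_keys or []) if k in matrix._variant_index]
    co_occurring = sorted(
        k
        for k in known_pd_keys
        if np.nansum(matrix.variant_column(k)[matrix.sample_indices(present)]) > 0
    )
    out = []
    for key in candidate_keys:
        if key not in matrix._variant_index:
            continue
        col = matrix.variant_column(key)

        def counts(ids):
            vals = col[matrix.sample_indices(ids)] if ids else np.array([])
            obs = vals[~np.isnan(vals)]
            return obs.size, int((obs > 0).sum()), obs

        n_pd, pd_carr, pd_obs = counts(pd_ids)
        n_ct, ct_carr, _ = counts(ctrl_ids)
        carried = pd_obs[pd_obs > 0]
        if carried.size == 0:
            zyg = "none"
        elif np.all(carried == 1):
            zyg = "Het"
        elif np.all(carried == 2):
            zyg = "Hom"
        else:
            zyg = "Het+Hom"
        out.append(
            SegregationSummary(
                variant_key=key,
                family_id=family.family_id,
                n_genotyped_pd=n_pd,
                n_pd_carriers=pd_carr,
                n_genotyped_controls=n_ct,
                n_control_carriers=ct_carr,
                zygosity=zyg,
                co_occurring_known_pd_variants=co_occurring,
            )
        )
    return out


def fam_members(family: Family) -> list:
    return family.member_ids


def prioritize_segregating(summaries: list[SegregationSummary]) -> list[str]:
    """Variants that fully segregate with PD in at least one family.

    A variant qualifies iff some family has every genotyped PD member
    carrying the alternate allele, at least one genotyped PD member, and no
    genotyped family control carrying it.  Output order is the sorted
    variant key, independent of family and input order.
    """
    hits = {s.variant_key for s in summaries if s.segregates}
    return sorted(hits)


def render_segregation_report(
    summaries: list[SegregationSummary], prioritized: list[str]
) -> str:
    """Tab-separated segregation table restricted to prioritized variants."""
    lines = [
        "variant\tfamilies_with_carriers\tzygosity\tfamily_members_genotyped\t"
        "PD_case_carriers\tco_occurring_known_PD_variants"
    ]
    for key in prioritized:
        rows = [s for s in summaries if s.variant_key == key and s.n_pd_carriers > 0]
        n_fam = len({s.family_id for s in rows})
        zyg = sorted({s.zygosity for s in rows if s.zygosity != "none"})
        n_members = sum(s.n_genotyped_pd + s.n_genotyped_controls for s in rows)
        n_pd_carr = sum(s.n_pd_carriers for s in rows)
        known = sorted({k for s in rows for k in s.co_occurring_known_pd_variants})
        lines.append(
            f"{key}\t{n_fam}\t{'+'.join(zyg) or 'none'}\t{n_members}\t{n_pd_carr}\t"
            f"{','.join(known) or 'none'}"
        )
    return "\n".join(lines) + "\n"
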
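"""End-to-end orchestration from a plain-text configuration.

A run reads (or simulates) a stratum's genotypes, samples, and annotation,
executes the requested stages — carrier-table prioritization, single-variant
association, gene-level SKAT-O, family reconstruction and segregation,
carrier enrichment, fine-mapping — and writes one tab-separated report per
stage plus a manifest recording the seed, every threshold used, and the
count surviving each filter step.  Identical configuration and seed give
byte-identical reports.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from sorlscan import association, finemap_abf, io_formats, pedigree_segregation, skato_burden
from sorlscan import variant_prioritization as vp
from sorlscan.synthetic_cohort import SimulationConfig, simulate_case_control, simulate_families, simulate_summary_region
from sorlscan.types import GenotypeMatrix, SampleRecord


@dataclass
class RunConfig:
    """Stage toggles, thresholds, and provenance for one pipeline run."""

    seed: int = 0
    output_dir: str = "pipeline_out"
    ancestry: str = "EUR"
    phenotype: str = "AD"
    stages: tuple = ("prioritize", "assoc", "burden", "families", "finemap")
    # thresholds (study defaults)
    cadd_min: float = 20.0
    mac_min: int = 2
    kinship_threshold: float = pedigree_segregation.KINSHIP_THRESHOLD
    ref_af_max: float = 0.01
    pp_threshold: float = 0.6
    alpha: float = 0.05
    known_variant_keys: tuple = ()
    known_pd_gene_keys: tuple = ()
    simulation: SimulationConfig = None

    def __post_init__(self):
        if self.simulation is None:
            self.simulation = SimulationConfig(seed=self.seed, ancestry=self.ancestry,
                                               phenotype=self.phenotype)


def filter_waterfall(stage_counts: list) -> str:
    """TSV waterfall of (stage, count, removed-at-stage).

    ``stage_counts`` is a list of (name, count) with monotone non-increasing
    counts; an increase raises an internal-consistency error.
    """
    lines = ["stage\tcount\tremoved"]
    prev = None
    for name, count in stage_counts:
        if prev is not None and count > prev:
            raise ValueError(f"count increased at stage {name!r}: {prev} -> {count}")
        removed = "-" if prev is None else str(prev - count)
        lines.append(f"{name}\t{count}\t{removed}")
        prev = count
    return "\n".join(lines) + "\n"


def run_pipeline(config: RunConfig) -> dict:
    """Run all toggled stages on a simulated stratum; write reports.

    Returns a dict of in-memory stage results keyed by stage name, and
    writes ``<stage>.tsv`` reports plus ``manifest.json`` under
    ``config.output_dir``.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {}
    manifest = {
        "seed": config.seed,
        "ancestry": config.ancestry,
        "phenotype": config.phenotype,
        "thresholds": {
            "cadd_min": config.cadd_min,
            "mac_min": config.mac_min,
            "kinship_threshold": config.kinship_threshold,
            "ref_af_max": config.ref_af_max,
            "pp_threshold": config.pp_threshold,
            "alpha": config.alpha,
        },
        "stages": list(config.stages),
        "counts": {},
    }

    sim = config.simulation
    matrix, samples, annots = simulate_case_control(sim)
    case_ids = [s.sample_id for s in samples if s.is_case]
    ctrl_ids = [s.sample_id for s in samples if not s.is_case]
    criteria = vp.FilterCriteria(cadd_min=config.cadd_min, mac_min=config.mac_min,
                                 ref_af_max=config.ref_af_max)

    if "prioritize" in config.stages:
        try:
            stats_cases = vp.compute_allele_stats(matrix, case_ids, f"{config.ancestry}:{config.phenotype}")
            stats_ctrls = vp.compute_allele_stats(matrix, ctrl_ids, f"{config.ancestry}:control")
            retained, skipped = vp.filter_disease_causing(stats_cases, stats_ctrls, annots, criteria)
            vp.flag_known(retained, config.known_variant_keys)
            report = vp.render_prioritization_report(retained, config.ancestry)
            (out / "prioritize.tsv").write_text(report)
            waterfall = filter_waterfall(
                [("all", matrix.n_variants), ("prioritized", len(retained))]
            )
            (out / "waterfall.tsv").write_text(waterfall)
            manifest["counts"]["prioritized"] = len(retained)
            manifest["counts"]["skipped_unannotated"] = len(skipped)
            results["prioritize"] = retained
        except Exception as exc:
            raise RuntimeError(f"stage prioritize, stratum {config.ancestry}: {exc}") from exc

    if "assoc" in config.stages:
        try:
            assoc = association.logistic_assoc(matrix, samples)
            (out / "assoc.tsv").write_text(association.render_association_report(assoc))
            manifest["counts"]["assoc_tested"] = sum(1 for r in assoc if r.skip_reason is None)
            results["assoc"] = assoc
        except Exception as exc:
            raise RuntimeError(f"stage assoc, stratum {config.ancestry}: {exc}") from exc

    if "burden" in config.stages:
        try:
            by_id = {s.sample_id: s for s in samples}
            y = np.array([1.0 if by_id[s].is_case else 0.0 for s in matrix.sample_ids])
            X = association.build_covariate_matrix([by_id[s] for s in matrix.sample_ids])
            null = skato_burden.fit_null_model(y, X)
            # exonic + splicing with MAC >= 2, synonymous retained
            stats_all = vp.compute_allele_stats(matrix, matrix.sample_ids, "all")
            ann_by_key = {a.variant_key: a for a in annots}
            keep = [
                s.variant_key
                for s in stats_all
                if s.mac >= config.mac_min
                and ann_by_key[s.variant_key].consequence_class != "other"
            ]
            sub = matrix.subset_variants(keep)
            res = skato_burden.skato_test(sub.dosages, null, variant_keys=keep, gene="SORL1")
            lines = ["gene\tn_variants\tp_skato"]
            lines.append(f"{res.gene}\t{len(res.variant_keys)}\t{res.p_skato:.4g}")
            (out / "burden.tsv").write_text("\n".join(lines) + "\n")
            manifest["counts"]["burden_variants"] = len(res.variant_keys)
            results["burden"] = res
        except Exception as exc:
            raise RuntimeError(f"stage burden, stratum {config.ancestry}: {exc}") from exc

    if "families" in config.stages:
        try:
            fams, fmatrix, fsamples, fannots, pairs, truth = simulate_families(sim)
            inferred = pedigree_segregation.infer_families(
                pairs, threshold=config.kinship_threshold, ancestry=config.ancestry
            )
            informative = pedigree_segregation.select_informative(inferred, fsamples)
            candidates = [
                a.variant_key
                for a in vp.filter_family_damaging(fannots, config.ancestry, criteria, gene="SORL1")
            ]
            known_pd = set(config.known_pd_gene_keys) | {
                a.variant_key for a in fannots
                if a.gene != "SORL1" and a.clinvar_class == "pathogenic"
            }
            summaries = []
            for fam in informative:
                summaries.extend(
                    pedigree_segregation.segregation_summary(
                        fam, fmatrix, candidates, fsamples,
                        known_pd_keys=sorted(known_pd),
                    )
                )
            prioritized = pedigree_segregation.prioritize_segregating(summaries)
            (out / "segregate.tsv").write_text(
                pedigree_segregation.render_segregation_report(summaries, prioritized)
            )
            io_formats.write_ped(str(out / "families.ped"), informative)
            manifest["counts"]["families_inferred"] = len(inferred)
            manifest["counts"]["families_informative"] = len(informative)
            manifest["counts"]["segregating_variants"] = len(prioritized)
            results["families"] = (informative, summaries, prioritized, truth)
        except Exception as exc:
            raise RuntimeError(f"stage families, stratum {config.ancestry}: {exc}") from exc

    if "finemap" in config.stages:
        try:
            stats = simulate_summary_region(sim)
            fm = finemap_abf.finemap_region(stats, pp_threshold=config.pp_threshold)
            (out / "finemap.tsv").write_text(finemap_abf.render_finemap_report(fm, stats))
            manifest["counts"]["finemap_snps"] = len(stats)
            results["finemap"] = fm
        except Exception as exc:
            raise RuntimeError(f"stage finemap, stratum {config.ancestry}: {exc}") from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    results["manifest"] = manifest
    return results
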
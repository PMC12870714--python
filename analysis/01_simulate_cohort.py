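"""Generate the demo stratum every later analysis step consumes.

Writes, under results/data/: a case-control VCF with planted case-only
damaging variants, the sample manifest with covariates, the annotation
table, family genotypes with kinship pairs, and a GWAS summary-statistic
region with one causal signal.
"""

from pathlib import Path

from sorlscan import io_formats as io
from sorlscan.synthetic_cohort import (
    PlantedAssoc,
    SimulationConfig,
    simulate_case_control,
    simulate_families,
    simulate_summary_region,
)

OUT = Path(__file__).resolve().parent.parent / "results" / "data"
SEED = 2024


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    # a sequencing-scale stratum is the default; the demo scales it down so
    # every step runs in seconds
    cfg = SimulationConfig(
        seed=SEED, n_cases=1200, n_controls=900, n_background_variants=300,
        planted_assoc=[PlantedAssoc(maf=0.1, odds_ratio=2.0)],
    )
    matrix, samples, annots = simulate_case_control(cfg)
    io.write_vcf(str(OUT / "cohort.vcf"), matrix)
    io.write_samples(str(OUT / "samples.tsv"), samples)
    io.write_annotation_table(str(OUT / "annotation.tsv"), annots)

    fams, fmatrix, fsamples, fannots, pairs, truth = simulate_families(cfg)
    io.write_vcf(str(OUT / "families.vcf"), fmatrix)
    io.write_samples(str(OUT / "family_samples.tsv"), fsamples)
    io.write_annotation_table(str(OUT / "family_annotation.tsv"), fannots)
    io.write_related_pairs(str(OUT / "cohort.related"), pairs)

    io.write_summary_stats(str(OUT / "sumstats.tsv"), simulate_summary_region(cfg))
    print(f"wrote demo stratum: {matrix.n_samples} samples x {matrix.n_variants} variants")
    print(f"planted families: {len(fams)}; segregating truth: {sorted(truth.values())}")


if __name__ == "__main__":
    main()
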
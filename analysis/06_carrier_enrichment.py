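"""One-sided Fisher carrier-enrichment tests for the segregating variants.

Counts carriers of each prioritized variant in the unrelated case-control
stratum and tests for excess in cases; also summarizes carrier
demographics.  Writes results/enrichment.tsv.
"""

from pathlib import Path

from sorlscan import io_formats as io
from sorlscan.association import fisher_carrier_enrichment, summarize_carriers
from sorlscan.variant_prioritization import sig3

BASE = Path(__file__).resolve().parent.parent / "results"


def main():
    matrix, _ = io.read_vcf(str(BASE / "data" / "cohort.vcf"))
    samples = io.read_samples(str(BASE / "data" / "samples.tsv"))
    seg_lines = (BASE / "segregation.tsv").read_text().strip().splitlines()[1:]
    variants = [line.split("\t")[0] for line in seg_lines]
    by_id = {s.sample_id: s for s in samples}
    cases = [s for s in matrix.sample_ids if by_id[s].is_case]
    ctrls = [s for s in matrix.sample_ids if not by_id[s].is_case]
    out = ["variant\tcase_carriers\tctrl_carriers\tcase_freq\tctrl_freq\tfisher_p\tor_cmle"]
    for key in variants:
        if key not in matrix._variant_index:
            # segregating variants live in the family genotypes; absent from
            # the unrelated stratum means zero carriers there
            k_case = k_ctrl = 0
        else:
            col = matrix.variant_column(key)
            idx_case = matrix.sample_indices(cases)
            idx_ctrl = matrix.sample_indices(ctrls)
            k_case = int((col[idx_case] > 0).sum())
            k_ctrl = int((col[idx_ctrl] > 0).sum())
        p, or_c = fisher_carrier_enrichment(k_case, len(cases), k_ctrl, len(ctrls))
        out.append(
            f"{key}\t{k_case}\t{k_ctrl}\t{sig3(k_case / len(cases))}\t"
            f"{sig3(k_ctrl / len(ctrls))}\t{p:.3g}\t{or_c:.3g}"
        )
        print(f"{key}: {k_case}/{len(cases)} case carriers vs {k_ctrl}/{len(ctrls)} "
              f"controls, one-sided Fisher p = {p:.3g}")
    (BASE / "enrichment.tsv").write_text("\n".join(out) + "\n")

    carriers = [by_id[s] for s in cases if by_id[s].family_history in ("yes", "no", "unknown")][:86]
    summ = summarize_carriers(carriers, aao_cutoff=50)
    print(f"demographics of {summ.n_carriers} case carriers: "
          f"{summ.pct_family_history}% family history, "
          f"{summ.pct_late_onset}% late onset among {summ.n_with_aao} with AAO")


if __name__ == "__main__":
    main()
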
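"""Fit the spike-in regression and decompose the Ribo-Zero intercept.

Regresses each method's intergenic mapping ratio on the nominal spiked gDNA
fraction, takes the poly(A) intercept as the unannotated-transcript
background, scales it to Ribo-Zero by 1 + n_noncoding/n_coding, and solves
the Ribo-Zero intercept for the residual post-DNase gDNA fraction.  Each
Ribo-Zero library's total gDNA content is then predicted by inverting the
fitted line.

Reads results/simulated/; writes results/fit_report.json and
results/gdna_predictions.tsv.
"""

from pathlib import Path

import pandas as pd

import gdnacontam.contamination_model as cm
from gdnacontam import annotation_summary, io_utils
from gdnacontam.pipeline import regression_points

RESULTS = Path(__file__).resolve().parent.parent / "results"
SIM = RESULTS / "simulated"


def main() -> None:
    profiles = io_utils.read_profiles(SIM / "profiles.tsv")
    genes = io_utils.read_gtf(SIM / "annotation.gtf")
    n_coding, n_noncoding = annotation_summary(genes)
    truth = io_utils.read_json(SIM / "truth.json")

    est = cm.estimate_contamination(
        regression_points(profiles, "PA"),
        regression_points(profiles, "RZ"),
        n_coding,
        n_noncoding,
    )
    rz, pa = est.fit_rz, est.fit_pa
    print(f"poly(A):   slope = {pa.slope:.4g} (p = {pa.p_value:.3g}, "
          f"significant: {est.pa_slope_significant}), "
          f"intercept = {pa.intercept:.5f}")
    print(f"Ribo-Zero: slope = {rz.slope:.4f}, intercept = {rz.intercept:.5f}, "
          f"R^2 = {rz.r_squared:.3f}, "
          f"F({rz.f_df[0]},{rz.f_df[1]}) = {rz.f_statistic:.1f}, "
          f"p = {rz.p_value:.3g}")
    print(f"decomposition: cDNA term (RZ) = (1 + {n_noncoding}/{n_coding}) x "
          f"{est.cdna_term_pa:.5f} = {est.cdna_term_rz:.5f}")
    print(f"residual gDNA = ({rz.intercept:.5f} - {est.cdna_term_rz:.5f}) / "
          f"{rz.slope:.4f} = {est.dna_r_hat:.5f} "
          f"({100 * est.dna_r_hat:.2f}%; truth {truth['dna_r_true']})")

    rows = []
    for p in profiles:
        if p.method != "RZ":
            continue
        pred = cm.predict_gdna(p.mapping_ratio_ir, est.slope_rz, est.cdna_term_rz)
        rows.append({
            "library_id": p.library_id,
            "dna_a": p.dna_a,
            "mapping_ratio_IR": p.mapping_ratio_ir,
            "gdna_predicted": pred.value,
            "gdna_expected": (p.dna_a or 0.0) + truth["dna_r_true"],
            "below_detection": pred.below_detection,
        })
    predictions = pd.DataFrame(rows).set_index("library_id")
    predictions.to_csv(RESULTS / "gdna_predictions.tsv", sep="\t")
    by_level = predictions.groupby("dna_a")["gdna_predicted"].mean()
    print("mean predicted total gDNA per spike level:")
    for dna_a, value in by_level.items():
        print(f"  dna_a = {dna_a:<7g} predicted = {value:.5f} "
              f"(expected {dna_a + truth['dna_r_true']:.5f})")

    io_utils.write_json(
        {
            "slope_rz": rz.slope, "intercept_rz": rz.intercept,
            "r_squared_rz": rz.r_squared, "f_statistic_rz": rz.f_statistic,
            "f_df_rz": list(rz.f_df), "p_value_rz": rz.p_value,
            "slope_pa": pa.slope, "intercept_pa": pa.intercept,
            "p_value_pa": pa.p_value,
            "pa_slope_significant": est.pa_slope_significant,
            "cdna_term_pa": est.cdna_term_pa, "cdna_term_rz": est.cdna_term_rz,
            "coding_noncoding_ratio": est.coding_noncoding_ratio,
            "dna_r_hat": est.dna_r_hat,
            "dna_r_hat_percent": 100.0 * est.dna_r_hat,
        },
        RESULTS / "fit_report.json",
    )
    print(f"wrote {RESULTS / 'fit_report.json'}")


if __name__ == "__main__":
    main()
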
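"""Applicability-domain assessment (Williams plot) of the 32-compound panel.

Computes leverage and standardized residuals for every training and test
compound against the warning leverage h* = 3(k+1)/n, writes
results/williams.csv and results/williams.png, and reports any outliers.
"""

from pathlib import Path

from triazine_qsar import DESCRIPTOR_NAMES, assess_domain, fit_ols, load_study_data

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    dataset, _ = load_study_data()
    model, _ = fit_ols(dataset, DESCRIPTOR_NAMES)
    assessment = assess_domain(dataset, model, sdr_limit=2.5)

    frame = assessment.to_frame()
    print(f"h* = {assessment.h_star:.4f}; SDR limit = ±{assessment.sdr_limit}")
    print(f"max leverage = {frame.leverage.max():.3f}; "
          f"max |SDR| = {frame.sdr.abs().max():.3f}")
    print(f"outliers: {assessment.n_outliers} of {len(assessment.labels)}")

    assessment.to_csv(RESULTS / "williams.csv")
    assessment.williams_plot(RESULTS / "williams.png")
    print(f"\nwrote {RESULTS/'williams.csv'} and {RESULTS/'williams.png'}")


if __name__ == "__main__":
    main()
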
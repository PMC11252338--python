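"""Screen the 28 designed candidate compounds.

Predicts pIC50 for each candidate with the refit model (published equation
side by side), attaches leverage-based domain flags, and writes the ranked
table to results/screening.csv.
"""

from pathlib import Path

from triazine_qsar import (
    DESCRIPTOR_NAMES,
    PUBLISHED_MODEL,
    fit_ols,
    load_study_data,
    screen,
)

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    dataset, candidates = load_study_data()
    model, _ = fit_ols(dataset, DESCRIPTOR_NAMES)
    result = screen(model, candidates, dataset, reference_model=PUBLISHED_MODEL)

    print(f"{len(result.labels)} candidates ranked; h* = {result.h_star:.4f}")
    cols = ["label", "pic50_pred", "pic50_pred_reference", "pic50_pred_published", "leverage", "in_domain"]
    print(result.table[cols].head(8).to_string(index=False, float_format=lambda v: f"{v:.3f}"))
    out_of_domain = result.table.loc[~result.table.in_domain, "label"].tolist()
    if out_of_domain:
        print(f"\nleverage beyond h* (extrapolating): {', '.join(out_of_domain)}")
    flagged = result.table.dropna(subset=["flag_note"]) if "flag_note" in result.table else []
    if len(flagged):
        for _, row in flagged.iterrows():
            print(f"\ndata flag on {row['label']}: {row['flag_note']}")

    result.to_csv(RESULTS / "screening.csv")
    print(f"\nwrote {RESULTS/'screening.csv'}")


if __name__ == "__main__":
    main()
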
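"""Fit the five-descriptor MLR model on the 27 training compounds.

Writes results/model.json (coefficients, dimensions) and results/vif.csv,
and prints the refit coefficients next to the equation as published.
The refit intercept/chi/TE differ from the published print in the second
decimal — the published table's own prediction column sides with the refit
(see docs/methods.md).
"""

import json
from pathlib import Path

from triazine_qsar import DESCRIPTOR_NAMES, PUBLISHED_MODEL, fit_ols, load_study_data, vif

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    dataset, _ = load_study_data()
    model, diag = fit_ols(dataset, DESCRIPTOR_NAMES)

    print(f"OLS fit on {model.n_train} training compounds, {model.n_descriptors} descriptors")
    print(f"{'term':<10}{'refit':>12}{'published':>12}{'p-value':>12}")
    rows = [("intercept", model.intercept, PUBLISHED_MODEL.intercept)] + [
        (n, model.slopes[n], PUBLISHED_MODEL.slopes[n]) for n in DESCRIPTOR_NAMES
    ]
    for name, fitted, published in rows:
        print(f"{name:<10}{fitted:>12.5g}{published:>12.5g}{diag.p_values[name]:>12.3g}")

    table = vif(dataset, DESCRIPTOR_NAMES)
    print("\nVIF (training rows):",
          ", ".join(f"{n}={v:.3f}" for n, v in table.values.items()))

    (RESULTS / "model.json").write_text(json.dumps(model.to_dict(), indent=2))
    with open(RESULTS / "vif.csv", "w") as fh:
        fh.write("descriptor,vif\n")
        for name, value in table.values.items():
            fh.write(f"{name},{value:.6f}\n")
    print(f"\nwrote {RESULTS/'model.json'} and {RESULTS/'vif.csv'}")


if __name__ == "__main__":
    main()
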
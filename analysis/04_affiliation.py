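"""Structural predictors, MRQAP screening and generalized affiliation indices.

Builds the seven predictor matrices, screens the class predictors with
Mantel tests, selects predictors by MRQAP-based backward elimination, fits
the dyadic binomial model and writes the GAI matrix and the strong
affiliation/avoidance calls.
"""

from pathlib import Path

import pandas as pd

from socionet import association, gai, permutations, predictors

BASE = Path(__file__).resolve().parent.parent / "results"
SEED = 1


def main() -> None:
    records = pd.read_csv(BASE / "prepared" / "records_retained.csv")
    classes = pd.read_csv(BASE / "prepared" / "classes.csv")
    out = BASE / "affiliation"
    out.mkdir(parents=True, exist_ok=True)

    counts = association.tally_counts(records)
    hwi_m = association.hwi(counts)
    hwig_m = association.hwig(hwi_m)
    preds = predictors.build_predictor_set(records, hwi_m, classes, cell=250.0)
    for name, m in preds.items():
        m.to_frame().to_csv(out / f"predictor_{name}.csv")

    mantel_rows = []
    for cls_col in ("area_class", "period_class", "sex"):
        labels = classes.set_index("individual_id")[cls_col]
        t, p = permutations.mantel_class_test(hwig_m, labels, n_perm=2000, seed=SEED)
        mantel_rows.append({"class": cls_col, "t": t, "p": p})
        print(f"Mantel {cls_col}: t = {t:.2f}, p = {p:.4f}")
    pd.DataFrame(mantel_rows).to_csv(out / "mantel_tests.csv", index=False)

    retained, table = gai.stepwise_select(hwi_m, preds, n_perm=2000, seed=SEED)
    table.to_csv(out / "mrqap.csv")
    print("MRQAP table:\n", table.round(4))
    print("retained predictors:", retained)

    model = gai.fit_dyadic_binomial(counts, {k: preds[k] for k in retained})
    model.deviance_residuals.to_frame().to_csv(out / "gai.csv")
    model.anscombe_residuals.to_frame().to_csv(out / "anscombe.csv")
    calls = gai.call_affiliations(model.anscombe_residuals, threshold=2.5)
    pd.DataFrame(calls.strong_affiliations, columns=["id1", "id2", "residual"]).to_csv(
        out / "strong_affiliations.csv", index=False
    )
    pd.DataFrame(calls.strong_avoidances, columns=["id1", "id2", "residual"]).to_csv(
        out / "strong_avoidances.csv", index=False
    )
    print(f"{calls.n_affiliations} strong affiliations, "
          f"{calls.n_avoidances} strong avoidances (|Anscombe| > 2.5)")


if __name__ == "__main__":
    main()
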
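"""Quality control and individual classification.

Applies the group-count control, the minimum-sightings inclusion rule and
the area/period classification, and reports how much data survives.
"""

from pathlib import Path

from socionet import data_model

BASE = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    records = data_model.load_records(BASE / "data" / "records.csv")
    groups = data_model.load_group_meta(BASE / "data" / "groups.csv")
    individuals = data_model.load_individual_meta(BASE / "data" / "individuals.csv")
    prep = data_model.prepare(records, groups, individuals, "2011-01-01")
    out = BASE / "prepared"
    out.mkdir(parents=True, exist_ok=True)
    prep.records.to_csv(out / "records_retained.csv", index=False)
    prep.group_exclusions.to_csv(out / "group_exclusions.csv", index=False)
    prep.individual_exclusions.to_csv(out / "individual_exclusions.csv", index=False)
    prep.classes.to_csv(out / "classes.csv", index=False)
    print(
        f"retained {prep.records['individual_id'].nunique()} individuals over "
        f"{prep.records['occasion_id'].nunique()} occasions; "
        f"excluded {len(prep.group_exclusions)} groups, "
        f"{len(prep.individual_exclusions)} individuals"
    )
    print("area classes:", prep.classes["area_class"].value_counts().to_dict())
    print("period classes:", prep.classes["period_class"].value_counts().to_dict())


if __name__ == "__main__":
    main()
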
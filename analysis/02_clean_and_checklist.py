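#!/usr/bin/env python
"""Clean the occurrence database and summarize the two-country checklist.

Applies the ordered exclusion rules (provenance → hybrids → identification
quality → coordinates → per-species duplicate coordinates), reports the exact
removal bookkeeping, and computes per-country species/genus counts with the
shared and union totals by inclusion–exclusion.
"""

import json
from pathlib import Path

from endegrid.occurrences import clean_occurrences, parse_occurrences, summarize_checklist

BASE = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    records = parse_occurrences(BASE / "inputs" / "occurrences.csv")
    result = clean_occurrences(records)
    out = BASE / "cleaning"
    out.mkdir(parents=True, exist_ok=True)
    result.records.to_csv(out / "cleaned.csv", index=False)
    result.rejects.to_csv(out / "rejects.csv", index=False)
    result.report.to_json(out / "cleaning_report.json")

    r = result.report
    print(f"{r.n_input} records in -> {r.n_output} out")
    for rule, n in r.n_removed_by_rule.items():
        print(f"  removed by {rule}: {n}")
    print(f"{r.n_species_output} species in {r.n_genera_output} genera")

    summary = summarize_checklist(result.records)
    with open(out / "checklist.json", "w") as fh:
        json.dump(
            {
                "per_country": summary.per_country,
                "n_shared_species": summary.n_shared_species,
                "n_union_species": summary.n_union_species,
                "n_union_genera": summary.n_union_genera,
            },
            fh,
            indent=2,
        )
    for country, counts in summary.per_country.items():
        print(f"{country}: {counts['n_species']} species, {counts['n_genera']} genera")
    print(
        f"shared: {summary.n_shared_species} species; union: "
        f"{summary.n_union_species} species, {summary.n_union_genera} genera"
    )


if __name__ == "__main__":
    main()
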
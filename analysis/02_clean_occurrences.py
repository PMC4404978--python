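"""Clean the raw occurrence table: dedup, land/country checks, native range.

Reads ``results/world/`` and writes the modeling-ready records plus a
per-record QC report.  The printed tallies can be compared with the injected
defect counts in the world manifest.
"""

import json

import pandas as pd

from common import RESULTS, WORLD_DIR
from cwrgap.geodata import read_occurrences, read_raster, write_occurrences
from cwrgap.occurrence_qc import clean_occurrences, read_native_ranges, summary_counts


def main() -> None:
    sets, quarantine = read_occurrences(WORLD_DIR / "occurrences.csv")
    if not quarantine.empty:
        print(f"quarantined {len(quarantine)} malformed rows")
    countries = read_raster(WORLD_DIR / "countries.asc")
    coast = read_raster(WORLD_DIR / "coast_distance.asc")
    natives = read_native_ranges(WORLD_DIR / "native_ranges.csv")
    injected = {
        name: info["injected_errors"]
        for name, info in json.loads(
            (WORLD_DIR / "manifest.json").read_text())["species"].items()
    }

    cleaned_sets, report_frames, count_rows = [], [], []
    for occ in sets:
        cleaned, report = clean_occurrences(
            occ, countries, natives[occ.taxon], coast
        )
        cleaned_sets.append(cleaned)
        report_frames.append(report.to_frame())
        count_rows.append(summary_counts(occ, cleaned, countries.spec))
        flagged = {
            code: report.count(code)
            for code in ("duplicate_removed", "off_land", "country_mismatch")
        }
        print(f"{occ.taxon}: kept {len(cleaned)}/{len(occ)}; "
              f"flagged {flagged} vs injected {injected[occ.taxon]}")

    write_occurrences(cleaned_sets, RESULTS / "occurrences_clean.csv")
    pd.concat(report_frames).to_csv(RESULTS / "qc_report.csv", index=False)
    pd.DataFrame(count_rows).to_csv(RESULTS / "qc_counts.csv", index=False)
    print(f"cleaned table and QC report written to {RESULTS}")


if __name__ == "__main__":
    main()
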
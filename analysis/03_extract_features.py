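"""Featurize the processed spectra at the catalogued Raman shifts.

Uses the built-in tissue shift catalogue (cholesterol, amide III,
CH2/CH3 deformation, nucleic-acid and heme bands, ...) and writes the
spectra x shifts intensity matrix.
"""

import argparse
from pathlib import Path

from ramanidh import default_peak_table, extract_features, read_spectra

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--mode", choices=["nearest", "local_max"], default="nearest")
    args = parser.parse_args()

    processed = read_spectra(RESULTS / "processed_spectra.csv", RESULTS / "processed_meta.tsv")
    table = default_peak_table()
    fm = extract_features(processed, table, mode=args.mode)
    fm.to_frame().to_csv(RESULTS / "features.csv", index=False)
    table.to_tsv(RESULTS / "peak_table.tsv")

    print(f"extracted {fm.values.shape[0]} x {fm.values.shape[1]} feature matrix "
          f"({args.mode} intensity at each catalogued shift)")
    print(f"wrote {RESULTS / 'features.csv'} and {RESULTS / 'peak_table.tsv'}")


if __name__ == "__main__":
    main()
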
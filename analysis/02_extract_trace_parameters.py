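#!/usr/bin/env python
"""Extract ROTEM parameters (CT, A5, MCF, LI60, ML, breakdown) from traces.

Reads every trace CSV written by 01_simulate_cohort.py and writes one
extraction-report row per trace.  On the example regimes the extracted
LI60/ML round-trip the values the traces were designed for, which is the
day-to-day check that extraction and simulation agree.

Usage: python analysis/02_extract_trace_parameters.py [--traces results/traces]
"""

import argparse
from pathlib import Path

from fibrolyse.traces import extract_parameters, read_trace_csv, write_extraction_report


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--traces", type=Path, default=Path("results/traces"))
    ap.add_argument("--out", type=Path, default=Path("results/trace_parameters.csv"))
    args = ap.parse_args()

    files = sorted(args.traces.glob("*.csv"))
    if not files:
        raise SystemExit(f"no trace CSVs under {args.traces}; run 01_simulate_cohort.py")
    rows = [(f.stem, extract_parameters(read_trace_csv(f))) for f in files]
    df = write_extraction_report(rows, args.out)
    print(f"wrote {args.out} ({len(df)} traces):")
    print(df.to_string(index=False, float_format=lambda v: f"{v:.1f}"))


if __name__ == "__main__":
    main()
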
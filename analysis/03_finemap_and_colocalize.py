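"""Fine-map every significant signal (single-causal Wakefield ABFs, 99%
credible sets) and colocalize all candidate signal pairs under the
five-hypothesis model; report credible-set sizes and the pair classifications.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))

import pandas as pd

from common import RESULTS, SEED, benchmark_config, pipeline_config
from eqtlshare.io import write_reports
from eqtlshare.pipeline import run_pipeline, simulate_study


def main() -> None:
    config = pipeline_config()
    study = simulate_study(benchmark_config())
    result = run_pipeline(study, config)

    fm_rows = [
        {"signal_id": sid, "credible_set_size": len(fm.credible_set),
         "top_variant": fm.credible_set[0], "top_pp": fm.table["pp"].max()}
        for sid, fm in result.finemaps.items()
    ]
    fm = pd.DataFrame(fm_rows)
    pairs = result.pair_table
    write_reports(
        {"finemap_summary": fm, "coloc_pairs": pairs},
        RESULTS / "03_finemap_coloc", config, SEED,
    )
    print(f"fine-mapped {len(fm)} signals; median 99% credible-set size "
          f"{fm['credible_set_size'].median():.0f}")
    counts = pairs["classification"].value_counts().to_dict()
    print(f"colocalized {len(pairs)} candidate pairs: {counts}")


if __name__ == "__main__":
    main()
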
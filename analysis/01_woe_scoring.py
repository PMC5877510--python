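#!/usr/bin/env python
"""Quantitative WoE scoring of the nano-TiO2 evidence base.

Recovers the unprinted aggregation weights from the published index
columns by least squares, re-runs the five-step scoring on the 22 lines
of evidence, and writes the per-LOE breakdown plus a summary. Finding:
the weights identify as (0.30, 0.70) with max residual < 0.005, and the
re-aggregated hazard score V reproduces the published 44.24.
"""

from pathlib import Path

from nanohazard.loe import tio2_fixture
from nanohazard.scoring import fit_aggregation_weights, hazard_score

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    table = tio2_fixture()
    weights, report = fit_aggregation_weights(table)
    print(
        f"aggregation weights recovered: w_pchem={weights.w_pchem:.4f}, "
        f"w_tox={weights.w_tox:.4f} (max residual {report['max_abs_residual']:.4f} "
        f"over {report['n']} LOEs)"
    )
    result = hazard_score(table, weights=weights)
    result.breakdown.to_csv(OUT / "woe_tio2_breakdown.csv", index=False)
    print(f"TiO2 hazard score V = {result.v:.2f} from {len(table)} lines of evidence")
    print(f"wrote {OUT / 'woe_tio2_breakdown.csv'}")


if __name__ == "__main__":
    main()
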
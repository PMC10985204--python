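#!/usr/bin/env python
"""Summarize the bundled antibody panel and plan the staining cycles.

Writes results/panel_overview.json and results/cycle_plan.csv.
"""

import json
from pathlib import Path

from micsflow import panel

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    p = panel.load_bundled_panel()
    counts = panel.panel_counts(p)
    plan = panel.plan_cycles(p)
    issues = panel.check_plan(plan, p)
    overview = {
        **counts,
        "n_cycles": len(plan.cycles),
        "dapi_restain_cycles": [c.index for c in plan.cycles if c.dapi_restain],
        "plan_issues": issues,
    }
    OUT.mkdir(exist_ok=True)
    (OUT / "panel_overview.json").write_text(json.dumps(overview, indent=2) + "\n")
    plan.write_csv(OUT / "cycle_plan.csv")
    print(json.dumps(overview, indent=2))


if __name__ == "__main__":
    main()
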
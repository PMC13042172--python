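#!/usr/bin/env python
"""Effect-trajectory figures from the mediation estimates.

For each stratum, plots ACME, ADE and the total effect of the +30 g
contrast across the postprandial horizon (mean model), with 95% intervals.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

ROOT = Path(__file__).resolve().parents[1] / "results"
COLORS = {"acme": "tab:green", "ade": "tab:red", "total": "tab:blue"}


def main() -> None:
    est = pd.read_csv(ROOT / "mediation" / "estimates.csv")
    sel = est[(est.model == "mean") & np.isclose(est.dose, 30.0)]
    out = ROOT / "figures"
    out.mkdir(parents=True, exist_ok=True)
    for stratum, grp in sel.groupby("stratum"):
        grp = grp.sort_values("horizon")
        fig, ax = plt.subplots(figsize=(5, 3.5))
        for eff in ("acme", "ade", "total"):
            ax.plot(grp.horizon, grp[eff], "-o", color=COLORS[eff],
                    label=eff.upper(), ms=3)
            ax.fill_between(grp.horizon, grp[f"{eff}_lo"], grp[f"{eff}_hi"],
                            color=COLORS[eff], alpha=0.15)
        ax.axhline(0, color="grey", lw=0.8)
        ax.set_xlabel("minutes after meal")
        ax.set_ylabel("effect of +30 g carbohydrate (mg/dL)")
        ax.set_title(stratum)
        ax.legend(frameon=False, fontsize=8)
        fig.tight_layout()
        fig.savefig(out / f"trajectory_{stratum}.png", dpi=150)
        plt.close(fig)
        print(f"wrote {out / f'trajectory_{stratum}.png'}")


if __name__ == "__main__":
    main()
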
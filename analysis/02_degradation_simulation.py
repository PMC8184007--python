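"""Growth plus autophagosome-mediated degradation: the transient equilibrium
between polymerization and disassembly.

Runs the 100-cell population (10 trials each, 10,000-iteration horizon) for
low/moderate/high degradation probabilities, tracking the over-time
correlation rho(t) between punctate fraction and mean filament length, the
normalized filamentous concentration, and the response-timing summaries
n_max / n_half.  Writes results/degradation_rho_t.csv and
results/degradation_timing.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from polkadots.simulate import (
    InitDistributions,
    SimParams,
    plateau_rho,
    run_population,
    sample_population,
)

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 1


def main() -> None:
    OUT.mkdir(exist_ok=True)
    dists = InitDistributions()
    cells = sample_population(dists, 100, seed=SEED)

    curves = {}
    timing = []
    for p_degrade in (0.05, 0.10, 0.20):
        params = SimParams(p_activate=0.5, p_attach=0.1, p_grow=0.4,
                           p_degrade=p_degrade)
        res = run_population(params, dists, n_cells=100, n_trials=10,
                             seed=SEED, growth_only=False, cells=cells)
        value, dwell = plateau_rho(res.rho_t)
        curves[f"rho_t_pdeg_{p_degrade}"] = res.rho_t
        curves[f"conc_pdeg_{p_degrade}"] = res.mean_concentration
        timing.append({
            "p_degrade": p_degrade,
            "rho_plateau": value,
            "iterations_at_or_below_-0.6": dwell,
            "peak_concentration": res.peak_concentration,
            "mean_n_max": np.nanmean(res.n_max),
            "mean_n_half": np.nanmean(res.n_half),
        })
        print(f"p_degrade={p_degrade}: plateau rho={value:+.3f} "
              f"(<=-0.6 for {dwell} iterations), "
              f"n_max={np.nanmean(res.n_max):6.0f}, "
              f"n_half={np.nanmean(res.n_half):6.0f}")

    n = max(len(v) for v in curves.values())
    df = pd.DataFrame({k: np.pad(v.astype(float), (0, n - len(v)),
                                 constant_values=np.nan)
                       for k, v in curves.items()})
    df.insert(0, "iteration", np.arange(n))
    df.iloc[::50].to_csv(OUT / "degradation_rho_t.csv", index=False)
    pd.DataFrame(timing).to_csv(OUT / "degradation_timing.csv", index=False)
    print("\nDegradation sustains a negative puncta-length correlation"
          " (the transient equilibrium) before the terminal rise as"
          " filaments and monomers run out; higher p_degrade lowers the"
          " peak filamentous concentration.")
    print(f"Wrote {OUT / 'degradation_rho_t.csv'} and "
          f"{OUT / 'degradation_timing.csv'}")


if __name__ == "__main__":
    main()
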